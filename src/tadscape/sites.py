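"""Differential DNase/ChIP signal testing, de novo site calling, and
cross-mark concordance.

Regions with replicated counts per condition are tested with a pooled
exact conditional test: given the total count n over both conditions,
the TKO total is Binomial(n, p0) under the null, with p0 determined by
the summed library size factors. Significance is declared either by
Benjamini-Hochberg FDR (DNase mode, 5%) or by raw p threshold (ChIP
window mode, 0.001). De novo sites are condition-exclusive calls that
were not "bookmarked" by active marks in the other condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import overlaps_any, validate_intervals
from .methylation import binom_two_sided

LFC_PSEUDOCOUNT = 0.5
DHS_FDR = 0.05
CHIP_P = 0.001


def size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series:
    """Per-library scaling factors: total / geometric mean of totals.

    Multiplying each library's expected rate by its factor equalizes
    null libraries of unequal depth.
    """
    if isinstance(counts, pd.DataFrame):
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(np.asarray(counts).sum(axis=0))
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"library {bad!r} has zero total count")
    log_gm = np.log(totals.astype(float)).mean()
    return totals / np.exp(log_gm)


def _cond_cols(table: pd.DataFrame, cond: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(f"{cond}_")
            and c.split("_")[-1].isdigit()]
    if not cols:
        raise ValueError(f"no replicate columns found for condition {cond!r}")
    return cols


def test_regions(table: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Pooled exact conditional test per region (vectorized).

    Adds ``lfc`` (log2 TKO/WT on size-factor-normalized pooled counts,
    pseudocount 0.5) and two-sided ``p``. Regions with zero total count
    get p = NaN.
    """
    wt_cols = _cond_cols(table, "wt")
    tko_cols = _cond_cols(table, "tko")
    counts = table[wt_cols + tko_cols]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if factors is None:
        factors = size_factors(counts)
    f_wt = float(factors[wt_cols].sum())
    f_tko = float(factors[tko_cols].sum())
    s_wt = table[wt_cols].sum(axis=1).to_numpy(dtype=float)
    s_tko = table[tko_cols].sum(axis=1).to_numpy(dtype=float)
    n = s_wt + s_tko
    p0 = f_tko / (f_wt + f_tko)
    p = np.full(len(table), np.nan)
    testable = n >= 1
    p[testable] = binom_two_sided(s_tko[testable], n[testable], p0)
    eps = LFC_PSEUDOCOUNT
    lfc = np.log2((s_tko / f_tko + eps) / (s_wt / f_wt + eps))
    out = table.copy()
    out["lfc"] = lfc
    out["p"] = p
    return out


def test_region(counts_wt, counts_tko, factors_wt=None, factors_tko=None):
    """Single-region convenience wrapper; returns (lfc, p)."""
    counts_wt = np.atleast_1d(counts_wt)
    counts_tko = np.atleast_1d(counts_tko)
    f_wt = np.sum(factors_wt) if factors_wt is not None else float(len(counts_wt))
    f_tko = np.sum(factors_tko) if factors_tko is not None else float(len(counts_tko))
    s_wt, s_tko = float(counts_wt.sum()), float(counts_tko.sum())
    n = s_wt + s_tko
    if n < 1:
        return np.nan, np.nan
    p0 = f_tko / (f_wt + f_tko)
    p = float(binom_two_sided(s_tko, n, p0))
    eps = LFC_PSEUDOCOUNT
    lfc = float(np.log2((s_tko / f_tko + eps) / (s_wt / f_wt + eps)))
    return lfc, p


def call_changes(table: pd.DataFrame, mode: str = "dhs",
                 q_threshold: float = DHS_FDR,
                 p_threshold: float = CHIP_P) -> pd.DataFrame:
    """Label regions gain/loss/none.

    ``dhs`` mode controls the FDR at ``q_threshold`` with Benjamini-
    Hochberg; ``chip`` mode thresholds the raw p at ``p_threshold``
    (mirroring sliding-window ChIP differential callers). Gains have
    positive fold change, losses negative.
    """
    if mode not in ("dhs", "chip"):
        raise ValueError(f"mode must be 'dhs' or 'chip', got {mode!r}")
    if "p" not in table.columns:
        raise ValueError("run test_regions first")
    out = table.copy()
    p = out["p"].to_numpy(dtype=float)
    q = np.full(len(out), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out["q"] = q
    sig = (q < q_threshold) if mode == "dhs" else (p < p_threshold)
    sig = sig & ok
    label = np.full(len(out), "none", dtype=object)
    label[sig & (out["lfc"].to_numpy() > 0)] = "gain"
    label[sig & (out["lfc"].to_numpy() < 0)] = "loss"
    out["label"] = label
    return out


def _normalized_wt_signal(table: pd.DataFrame) -> np.ndarray:
    """Mean size-factor-normalized WT count per region."""
    wt_cols = _cond_cols(table, "wt")
    factors = size_factors(table[wt_cols + _cond_cols(table, "tko")])
    norm = table[wt_cols].to_numpy(dtype=float) / factors[wt_cols].to_numpy()
    return norm.mean(axis=1)


def call_denovo(calls_tko: pd.DataFrame, calls_other_condition: pd.DataFrame,
                wt_signal_tables: list[pd.DataFrame],
                wt_signal_calls: list[pd.DataFrame],
                wt_signal_quantile: float = 0.25) -> pd.DataFrame:
    """Condition-exclusive calls lacking bookmark signal in the other
    condition.

    A region qualifies if it (a) is called in TKO, (b) overlaps no call
    of the same mark in WT, and (c) for every provided WT bookmark
    track, its normalized WT coverage is below the ``wt_signal_quantile``
    quantile of that track's signal over its own WT called regions.
    """
    if not wt_signal_tables:
        raise ValueError("at least one WT bookmark signal track is required")
    validate_intervals(calls_tko, "calls_tko")
    keep = ~overlaps_any(calls_tko, calls_other_condition) if len(
        calls_other_condition) else np.ones(len(calls_tko), dtype=bool)
    for sig_table, sig_calls in zip(wt_signal_tables, wt_signal_calls):
        signal = _normalized_wt_signal(sig_table)
        regions = sig_table[["chrom", "start", "end"]]
        called_mask = overlaps_any(regions, sig_calls) if len(sig_calls) else \
            np.zeros(len(regions), dtype=bool)
        if called_mask.any():
            threshold = float(np.quantile(signal[called_mask], wt_signal_quantile))
        else:
            threshold = float(np.inf)
        # signal at the candidate regions: regions above threshold are bookmarked
        hot = regions[signal >= threshold]
        keep &= ~overlaps_any(calls_tko, hot)
    return calls_tko[keep].reset_index(drop=True)


def call_denovo_dhs(dhs_tko_calls, dhs_wt_calls, k4me1_wt_table, k4me1_wt_calls,
                    k4me3_wt_table, k4me3_wt_calls,
                    wt_signal_quantile: float = 0.25) -> pd.DataFrame:
    """De novo DHSs: TKO-exclusive DHS calls with sub-threshold WT
    H3K4me1 and H3K4me3 signal (not bookmarked before H1 depletion)."""
    return call_denovo(dhs_tko_calls, dhs_wt_calls,
                       [k4me1_wt_table, k4me3_wt_table],
                       [k4me1_wt_calls, k4me3_wt_calls],
                       wt_signal_quantile)


def call_denovo_k4me1(k4me1_tko_calls, k4me1_wt_calls, k4me3_wt_table,
                      k4me3_wt_calls, dhs_wt_table, dhs_wt_calls,
                      wt_signal_quantile: float = 0.25) -> pd.DataFrame:
    """De novo H3K4me1 sites: TKO-exclusive with silent WT H3K4me3 and DHS."""
    return call_denovo(k4me1_tko_calls, k4me1_wt_calls,
                       [k4me3_wt_table, dhs_wt_table],
                       [k4me3_wt_calls, dhs_wt_calls],
                       wt_signal_quantile)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p_value: float
    fold: float


def overlap_test(a: pd.DataFrame, b: pd.DataFrame,
                 universe: pd.DataFrame) -> OverlapResult:
    """Hypergeometric test of overlap between two interval sets over a
    common universe of regions.

    Membership is >=1 bp overlap with a universe region. p is the upper
    tail P(X >= |A intersect B|) drawing |A| regions from the universe
    with |B| marked; fold is observed over expected overlap.
    """
    validate_intervals(universe, "universe")
    in_a = overlaps_any(universe, a)
    in_b = overlaps_any(universe, b)
    if len(a) and not overlaps_any(a, universe).all():
        raise ValueError("A contains intervals outside the universe")
    if len(b) and not overlaps_any(b, universe).all():
        raise ValueError("B contains intervals outside the universe")
    m = len(universe)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    k = int((in_a & in_b).sum())
    p = float(stats.hypergeom.sf(k - 1, m, n_b, n_a))
    expected = n_a * n_b / m if m else np.nan
    fold = k / expected if expected else np.nan
    return OverlapResult(n_a=n_a, n_b=n_b, n_overlap=k, universe=m,
                         p_value=p, fold=fold)


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # 2x2 gain/loss cross-table
    spearman_rho: float
    spearman_p: float
    deltas: pd.DataFrame  # paired per-region deltas


def concordance(table_x: pd.DataFrame, table_y: pd.DataFrame,
                delta_col: str = "lfc") -> ConcordanceResult | None:
    """Cross-tabulate gain/loss labels of two marks over shared regions
    and correlate their per-region changes.

    Tables must be labelled (call_changes) and indexed by the same
    region ids. Only regions significant in both marks enter; returns
    None if there are none.
    """
    merged = table_x.set_index("region_id")[["label", delta_col]].join(
        table_y.set_index("region_id")[["label", delta_col]],
        lsuffix="_x", rsuffix="_y", how="inner")
    both = merged[(merged["label_x"] != "none") & (merged["label_y"] != "none")]
    if len(both) == 0:
        return None
    cross = pd.crosstab(both["label_x"], both["label_y"]).reindex(
        index=["gain", "loss"], columns=["gain", "loss"], fill_value=0)
    dx = both[f"{delta_col}_x"]
    dy = both[f"{delta_col}_y"]
    if len(both) > 1 and dx.nunique() > 1 and dy.nunique() > 1:
        rho, p = stats.spearmanr(dx, dy)
    else:
        rho, p = np.nan, np.nan
    return ConcordanceResult(table=cross, spearman_rho=float(rho),
                             spearman_p=float(p),
                             deltas=both.rename(columns={
                                 f"{delta_col}_x": "delta_x",
                                 f"{delta_col}_y": "delta_y"}))
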