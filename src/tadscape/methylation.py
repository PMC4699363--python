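"""Differential DNA-methylation analysis of HpaII/MspI count tables.

The assay contrasts the methylation-sensitive HpaII digest with the
insensitive MspI digest at CCGG sites: relative HpaII signal reports the
unmethylated fraction. Per site we compute a 0-100 methylation score
(an arctangent of the depth-normalized HpaII:MspI ratio, monotone
decreasing in HpaII signal), an exact two-sided binomial test of the
HpaII counts between conditions, a stringent classification combining
the p-value with a score delta, a window-permutation clustering test,
and a chromatin-state composition profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import assign_points, midpoints

P_THRESHOLD = 1e-6
DELTA_THRESHOLD = 25.0


def methylation_score(hpaii, mspi, hpaii_depth: float = 1.0,
                      mspi_depth: float = 1.0):
    """Methylation score in [0, 100] from HpaII and MspI counts.

    score = 100 * (1 - (2/pi) * atan2(hpaii/hpaii_depth, mspi/mspi_depth)).
    HpaII cuts only unmethylated sites, so the score decreases with HpaII
    signal: (0, m>0) -> 100, (h>0, 0) -> 0, equal normalized counts -> 50.
    Sites with both counts zero are unassayable and return NaN.
    """
    h = np.asarray(hpaii, dtype=float) / hpaii_depth
    m = np.asarray(mspi, dtype=float) / mspi_depth
    if (h < 0).any() or (m < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(invalid="ignore"):
        score = 100.0 * (1.0 - (2.0 / np.pi) * np.arctan2(h, m))
    score = np.where((h == 0) & (m == 0), np.nan, score)
    return float(score) if score.ndim == 0 else score


def binom_two_sided(x, n, p0):
    """Vectorized two-sided exact binomial p: min(1, 2*min(lower, upper))."""
    x = np.asarray(x)
    n = np.asarray(n)
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def test_differential_methylation(table: pd.DataFrame,
                                  depth_wt: float | None = None,
                                  depth_tko: float | None = None,
                                  p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Exact binomial test of differential methylation per site.

    Conditional on the total HpaII count n = hpaii_wt + hpaii_tko, the
    TKO HpaII count is Binomial(n, p0) under no change, with p0 set by
    the HpaII library depths (raw library totals by default). Sites with
    excess TKO HpaII signal at significance are hypomethylated in TKO
    (less methylation = more HpaII cutting), deficit sites hyper.
    Zero-total sites get p = NaN and direction "none".
    """
    hw = table["hpaii_wt"].to_numpy(dtype=float)
    ht = table["hpaii_tko"].to_numpy(dtype=float)
    if depth_wt is None:
        depth_wt = float(hw.sum())
    if depth_tko is None:
        depth_tko = float(ht.sum())
    p0 = depth_tko / (depth_wt + depth_tko)
    n = hw + ht
    testable = n >= 1
    p = np.full(len(table), np.nan)
    p[testable] = binom_two_sided(ht[testable], n[testable], p0)
    direction = np.full(len(table), "none", dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        excess = ht / np.where(n > 0, n, 1) > p0
    sig = testable & (p < p_threshold)
    direction[sig & excess] = "hypo"
    direction[sig & ~excess] = "hyper"

    out = table.copy()
    mw = table["mspi_wt"].to_numpy(dtype=float)
    mt = table["mspi_tko"].to_numpy(dtype=float)
    out["score_wt"] = methylation_score(hw, mw, depth_wt, max(mw.sum(), 1.0))
    out["score_tko"] = methylation_score(ht, mt, depth_tko, max(mt.sum(), 1.0))
    out["p"] = p
    out["direction"] = direction
    return out


def classify_stringent(table: pd.DataFrame,
                       delta_threshold: float = DELTA_THRESHOLD,
                       p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Flag stringent differential sites: significant AND a methylation
    score delta of at least ``delta_threshold`` (score units of 100)."""
    if "p" not in table.columns:
        raise ValueError("run test_differential_methylation first")
    out = table.copy()
    delta = (out["score_tko"] - out["score_wt"]).abs()
    out["stringent"] = (out["p"] < p_threshold) & (delta >= delta_threshold)
    return out


@dataclass
class WindowClusterResult:
    """Permutation test of spatial clustering of differential sites in
    fixed non-overlapping genomic windows."""

    window: int
    min_sites: int
    observed: int
    null_counts: np.ndarray
    n_draws: int
    p_value: float


def _count_windows(chroms: np.ndarray, pos: np.ndarray, window: int,
                   k: int) -> int:
    """Number of windows (tiled from 0 per chromosome) with >= k sites."""
    if len(pos) == 0:
        return 0
    codes = pd.factorize(chroms)[0].astype(np.int64)
    key = codes * (1 << 40) + pos // window
    _, counts = np.unique(key, return_counts=True)
    return int((counts >= k).sum())


def window_cluster_test(dmr_sites: pd.DataFrame, assayable_sites: pd.DataFrame,
                        window: int = 20_000, min_sites: int = 5,
                        draws: int = 1000, seed: int = 0) -> WindowClusterResult:
    """Are differential sites more clustered in fixed windows than random
    draws of the same number of assayable sites?

    Windows of ``window`` bp tile each chromosome from coordinate 0 (the
    last partial window is kept). The observed statistic is the number of
    windows holding >= ``min_sites`` differential sites; each null draw
    samples ``len(dmr_sites)`` assayable sites uniformly without
    replacement and recounts. Empirical p = (1 + #{null >= obs}) / (draws + 1).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(dmr_sites) > len(assayable_sites):
        raise ValueError("more differential sites than assayable sites")
    mids_d = midpoints(dmr_sites) if len(dmr_sites) else np.array([], dtype=np.int64)
    observed = _count_windows(dmr_sites["chrom"].to_numpy(), mids_d,
                              window, min_sites)
    rng = np.random.default_rng(seed)
    all_chrom = assayable_sites["chrom"].to_numpy()
    all_mid = midpoints(assayable_sites)
    n_dmr = len(dmr_sites)
    null = np.empty(draws, dtype=np.int64)
    for i in range(draws):
        pick = rng.choice(len(assayable_sites), size=n_dmr, replace=False)
        null[i] = _count_windows(all_chrom[pick], all_mid[pick], window, min_sites)
    p = (1 + int((null >= observed).sum())) / (draws + 1)
    return WindowClusterResult(window=window, min_sites=min_sites,
                               observed=observed, null_counts=null,
                               n_draws=draws, p_value=p)


def state_composition(sites: pd.DataFrame, states: pd.DataFrame,
                      assayable_sites: pd.DataFrame | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Fraction of sites per chromatin-state label, by site midpoint.

    Sites falling outside the segmentation are counted under "other"
    (with a warning). If ``assayable_sites`` is given, a size-matched
    random draw from it is profiled alongside as the background column.
    """
    import warnings as _warnings

    if len(sites) == 0:
        raise ValueError("empty site list")

    def compose(df):
        idx = assign_points(df["chrom"].to_numpy(), midpoints(df), states)
        labels = np.where(idx >= 0,
                          states["name"].to_numpy()[np.clip(idx, 0, None)],
                          "other")
        if (idx < 0).any():
            _warnings.warn(f"{int((idx < 0).sum())} sites outside the "
                           "segmentation counted as 'other'")
        return pd.Series(labels).value_counts(normalize=True)

    result = pd.DataFrame({"sites": compose(sites)})
    if assayable_sites is not None:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(assayable_sites), size=min(len(sites), len(assayable_sites)),
                          replace=False)
        result["background"] = compose(assayable_sites.iloc[pick])
    return result.fillna(0.0)
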