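"""TAD-level enrichment statistics.

TADs are ranked by a per-TAD key (gene content, change counts, domain
score deltas, ...), binned into quintiles of equal TAD count, and any
feature's per-bin percentage and enrichment ratio relative to a
reference distribution is computed, with a chi-squared test of
non-uniformity. Sites go to the TAD containing their midpoint; genes to
the TAD containing their TSS (overlap mode available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import assign_points, midpoints, validate_intervals

N_BINS = 5


def assign_sites_to_tads(sites: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """Per-TAD site counts by midpoint assignment.

    Returns a Series indexed like ``tads`` plus an ``unassigned`` entry
    for sites in inter-TAD gaps (excluded from percentages downstream).
    """
    validate_intervals(tads, "tads")
    idx = assign_points(sites["chrom"].to_numpy(), midpoints(sites), tads)
    counts = np.zeros(len(tads), dtype=np.int64)
    inside = idx >= 0
    np.add.at(counts, idx[inside], 1)
    out = pd.Series(counts, index=tads.index, name="count")
    out.loc["unassigned"] = int((~inside).sum())
    return out


def assign_genes_to_tads(genes: pd.DataFrame, tads: pd.DataFrame,
                         by: str = "tss") -> pd.Series:
    """Per-TAD gene counts, anchored at the TSS (default) or counting any
    gene-body overlap."""
    if by == "tss":
        if "tss" not in genes.columns:
            raise ValueError("genes table has no 'tss' column")
        idx = assign_points(genes["chrom"].to_numpy(),
                            genes["tss"].to_numpy(np.int64), tads)
        counts = np.zeros(len(tads), dtype=np.int64)
        np.add.at(counts, idx[idx >= 0], 1)
        out = pd.Series(counts, index=tads.index, name="count")
        out.loc["unassigned"] = int((idx < 0).sum())
        return out
    if by == "overlap":
        from .intervals import overlaps_any
        counts = np.zeros(len(tads), dtype=np.int64)
        for i, (_, t) in enumerate(tads.iterrows()):
            one = pd.DataFrame([t[["chrom", "start", "end"]]])
            counts[i] = int(overlaps_any(genes, one).sum())
        out = pd.Series(counts, index=tads.index, name="count")
        out.loc["unassigned"] = 0
        return out
    raise ValueError(f"by must be 'tss' or 'overlap', got {by!r}")


def quintile_bins(tads: pd.DataFrame, key: pd.Series | np.ndarray) -> pd.Series:
    """Assign each TAD a quintile index 1-5 by ascending key.

    Stable sort with ties broken by genomic order (the order of the
    input table); bin 1 holds the lowest-key TADs. Bin sizes are equal
    up to a remainder distributed from the lowest bin upward.
    """
    if len(tads) < N_BINS:
        raise ValueError(f"need >= {N_BINS} TADs, got {len(tads)}")
    key = np.asarray(key, dtype=float)
    if len(key) != len(tads):
        raise ValueError("key must be defined for every TAD")
    if np.isnan(key).any():
        raise ValueError("key contains NaN")
    order = np.argsort(key, kind="stable")
    n = len(tads)
    base, rem = divmod(n, N_BINS)
    sizes = [base + 1 if i < rem else base for i in range(N_BINS)]
    bin_of_rank = np.repeat(np.arange(1, N_BINS + 1), sizes)
    bins = np.empty(n, dtype=np.int64)
    bins[order] = bin_of_rank
    return pd.Series(bins, index=tads.index, name="bin")


def bin_percentages(counts: pd.Series, bins: pd.Series,
                    tads: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percentage of a feature per quintile bin.

    ``counts`` is a per-TAD feature count (an ``unassigned`` entry, if
    present, is dropped). Emits the feature percentage and, when the TAD
    table is given, the genomic-size percentage of each bin as the
    reference baseline.
    """
    counts = counts.drop(index="unassigned", errors="ignore").astype(float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero counts")
    per_bin = counts.groupby(bins).sum().reindex(range(1, N_BINS + 1), fill_value=0.0)
    out = pd.DataFrame({"pct": 100.0 * per_bin / total})
    out["n_tads"] = bins.value_counts().reindex(range(1, N_BINS + 1), fill_value=0)
    if tads is not None:
        size = (tads["end"] - tads["start"]).astype(float)
        size_bin = size.groupby(bins).sum().reindex(range(1, N_BINS + 1), fill_value=0.0)
        out["pct_genomic_size"] = 100.0 * size_bin / size.sum()
    out.index.name = "bin"
    return out


def enrichment_ratio(pct_changed: pd.Series, pct_reference: pd.Series) -> pd.Series:
    """Per-bin ratio of the changed-feature percentage over the reference
    percentage; 1 = proportional distribution. Bins with zero reference
    are NaN-flagged."""
    ref = np.asarray(pct_reference, dtype=float)
    chg = np.asarray(pct_changed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, chg / ref, np.nan)
    return pd.Series(ratio, index=pd.RangeIndex(1, N_BINS + 1, name="bin"),
                     name="ratio")


def chisq_nonuniformity(observed: pd.Series | np.ndarray,
                        expected_pct: pd.Series | np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (4 df) of observed per-bin counts against
    expected proportions (a reference percentage vector)."""
    obs = np.asarray(observed, dtype=float)
    exp_pct = np.asarray(expected_pct, dtype=float)
    if len(obs) != N_BINS or len(exp_pct) != N_BINS:
        raise ValueError(f"need {N_BINS} bins")
    exp = exp_pct / exp_pct.sum() * obs.sum()
    if (exp <= 0).any():
        raise ValueError("expected count of zero in a bin; use an exact test")
    if obs.sum() < 25:
        raise ValueError("fewer than 25 observations; use an exact test")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(statistic, df=N_BINS - 1))
    return statistic, p


@dataclass
class TssProximalResult:
    n_genes: int
    pct_gain: float
    pct_loss: float
    window: int


def tss_proximal_changes(genes: pd.DataFrame, changed_sites: pd.DataFrame,
                         window: int = 2500) -> TssProximalResult:
    """Percentage of genes with a gained / lost site within ``window`` bp
    of the TSS (site midpoint in [TSS - window, TSS + window))."""
    if "tss" not in genes.columns:
        raise ValueError("genes table has no 'tss' column")
    n = len(genes)
    if n == 0:
        return TssProximalResult(0, np.nan, np.nan, window)
    pct = {}
    for label in ("gain", "loss"):
        sub = changed_sites[changed_sites["label"] == label] \
            if "label" in changed_sites.columns else changed_sites.iloc[0:0]
        hit = np.zeros(n, dtype=bool)
        if len(sub):
            mids = midpoints(sub)
            schrom = sub["chrom"].to_numpy()
            for chrom, grp in genes.groupby("chrom", sort=False):
                m = np.sort(mids[schrom == chrom])
                if len(m) == 0:
                    continue
                tss = grp["tss"].to_numpy(np.int64)
                lo = np.searchsorted(m, tss - window, side="left")
                hi = np.searchsorted(m, tss + window, side="left")
                hit[genes.index.get_indexer(grp.index)] = hi > lo
        pct[label] = 100.0 * hit.sum() / n
    return TssProximalResult(n_genes=n, pct_gain=pct["gain"],
                             pct_loss=pct["loss"], window=window)


def plot_quintile_bars(table: pd.DataFrame, path, title: str = "",
                       value: str = "pct") -> None:
    """Grouped bar chart of a quintile table (one bar group per bin,
    one bar per feature), written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = table["feature"].unique()
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / len(features)
    for k, feat in enumerate(features):
        sub = table[table["feature"] == feat].sort_values("bin")
        ax.bar(sub["bin"] + (k - len(features) / 2) * width + width / 2,
               sub[value], width=width, label=feat)
    ax.set_xlabel("TAD quintile (1 = lowest ranking key)")
    ax.set_ylabel("% of feature" if value == "pct" else value)
    ax.set_xticks(range(1, N_BINS + 1))
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def quintile_table(tads: pd.DataFrame, rank_key: pd.Series | np.ndarray,
                   features: dict, reference: str | None = None) -> pd.DataFrame:
    """One-call quintile analysis: bin TADs by ``rank_key``, tabulate the
    percentage of each feature (a per-TAD count Series) per bin, plus
    ratio rows against ``reference`` and a chi-squared test per feature.

    Returns a tidy frame with one row per (feature, bin).
    """
    bins = quintile_bins(tads, rank_key)
    rows = []
    ref_pct = None
    if reference is not None:
        ref_pct = bin_percentages(features[reference], bins, tads)["pct"]
    for name, counts in features.items():
        if counts.drop(index="unassigned", errors="ignore").sum() == 0:
            continue  # nothing of this feature anywhere; no percentages
        tab = bin_percentages(counts, bins, tads)
        obs = counts.drop(index="unassigned", errors="ignore").astype(float) \
            .groupby(bins).sum().reindex(range(1, N_BINS + 1), fill_value=0.0)
        chisq, p = (np.nan, np.nan)
        exp = ref_pct if ref_pct is not None else tab["pct_genomic_size"]
        try:
            chisq, p = chisq_nonuniformity(obs, exp)
        except ValueError:
            pass
        for b in range(1, N_BINS + 1):
            rows.append({
                "feature": name, "bin": b, "pct": tab.loc[b, "pct"],
                "pct_genomic_size": tab.loc[b, "pct_genomic_size"],
                "n_tads": tab.loc[b, "n_tads"],
                "ratio_vs_reference": (tab.loc[b, "pct"] / ref_pct.loc[b])
                if ref_pct is not None and ref_pct.loc[b] > 0 else np.nan,
                "chisq": chisq, "chisq_p": p,
            })
    return pd.DataFrame(rows)
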