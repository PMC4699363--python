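"""Hi-C contact-matrix topology metrics.

Per-chromosome symmetric matrices at a fixed bin size, built from
bin-pair triples or valid-pair lists, balanced by Sinkhorn-style
iterative correction. On top of them: observed/expected distance-decay
curves, A/B compartment PC1 (on the correlation of the observed/expected
matrix, sign-oriented by gene density), paired-anchor aggregate pile-ups
(PE-SCAN), and the per-TAD domain score - the sum of intra-TAD contacts
over the cis contacts crossing the TAD boundary, a measure of how
structurally insulated a TAD is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import tads as _tads

DEFAULT_BIN_SIZE = 100_000
MASK_FRACTION = 0.1  # bins with row sum < 10% of the median are masked


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    balanced: bool = False
    mask: np.ndarray = field(default=None)  # True = bin filtered out

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("matrix must be non-negative")
        self.matrix = m
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BinnedContacts:
    """bin_contacts output: cis matrices plus the cis/trans ratio."""

    matrices: dict
    n_cis: int
    n_trans: int

    @property
    def cis_fraction(self) -> float:
        total = self.n_cis + self.n_trans
        return self.n_cis / total if total else np.nan


def bin_contacts(pairs: pd.DataFrame, chrom_sizes: dict,
                 bin_size: int = DEFAULT_BIN_SIZE) -> BinnedContacts:
    """Accumulate read pairs into per-chromosome matrices.

    ``pairs`` has columns chrom1, pos1, chrom2, pos2 (bp). Each
    intra-chromosomal pair increments cells (i,j) and (j,i) once;
    inter-chromosomal pairs are only counted toward the cis/trans ratio.
    """
    for col in ("chrom1", "pos1", "chrom2", "pos2"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    mats = {c: np.zeros((size // bin_size + (1 if size % bin_size else 0),) * 2)
            for c, size in chrom_sizes.items()}
    for i, row in enumerate(pairs.itertuples(), 1):
        for c, p in ((row.chrom1, row.pos1), (row.chrom2, row.pos2)):
            if c not in chrom_sizes:
                raise ValueError(f"pair {i}: unknown chromosome {c!r}")
            if not 0 <= p < chrom_sizes[c]:
                raise ValueError(f"pair {i}: position {p} outside {c}")
    cis = pairs["chrom1"] == pairs["chrom2"]
    n_cis, n_trans = int(cis.sum()), int((~cis).sum())
    sub = pairs[cis]
    for chrom, grp in sub.groupby("chrom1", sort=False):
        b1 = grp["pos1"].to_numpy(np.int64) // bin_size
        b2 = grp["pos2"].to_numpy(np.int64) // bin_size
        m = mats[chrom]
        np.add.at(m, (b1, b2), 1.0)
        off = b1 != b2
        np.add.at(m, (b2[off], b1[off]), 1.0)
    matrices = {c: ContactMatrix(c, bin_size, m) for c, m in mats.items()}
    return BinnedContacts(matrices=matrices, n_cis=n_cis, n_trans=n_trans)


def matrix_from_coo(coo: pd.DataFrame, chrom: str, bin_size: int,
                    n_bins: int | None = None) -> ContactMatrix:
    """Dense symmetric matrix from upper-triangle COO triples."""
    sub = coo[coo["chrom"] == chrom]
    if n_bins is None:
        n_bins = int(max(sub["bin1"].max(), sub["bin2"].max())) + 1
    m = np.zeros((n_bins, n_bins))
    b1 = sub["bin1"].to_numpy(np.int64)
    b2 = sub["bin2"].to_numpy(np.int64)
    np.add.at(m, (b1, b2), sub["count"].to_numpy(float))
    off = b1 != b2
    np.add.at(m, (b2[off], b1[off]), sub["count"].to_numpy(float)[off])
    return ContactMatrix(chrom, bin_size, m)


def matrix_to_coo(cm: ContactMatrix) -> pd.DataFrame:
    iu = np.triu_indices(cm.n_bins)
    vals = cm.matrix[iu]
    keep = vals > 0
    return pd.DataFrame({"chrom": cm.chrom, "bin1": iu[0][keep],
                         "bin2": iu[1][keep], "count": vals[keep]})


def balance(cm: ContactMatrix, max_iter: int = 200,
            tol: float = 1e-5) -> ContactMatrix:
    """Sinkhorn-style iterative correction to equal row sums.

    Bins with raw row sum below 10% of the median are masked (zeroed).
    Iterates m <- m / sqrt(outer(s, s)) on unmasked bins until every
    unmasked row sum is within ``tol`` (relative) of their mean.
    """
    if cm.balanced:
        raise ValueError("matrix already balanced")
    m = cm.matrix.copy()
    row = m.sum(axis=1)
    median = np.median(row[row > 0]) if (row > 0).any() else 0.0
    mask = row < MASK_FRACTION * median
    m[mask, :] = 0.0
    m[:, mask] = 0.0
    live = ~mask
    if live.sum() == 0:
        raise ValueError("all bins masked")
    for _ in range(max_iter):
        s = m.sum(axis=1)
        mean = s[live].mean()
        resid = np.abs(s[live] / mean - 1.0).max()
        if resid <= tol:
            scaled = m / mean  # unmasked row sums ~ 1
            return ContactMatrix(cm.chrom, cm.bin_size, scaled,
                                 balanced=True, mask=mask)
        r = np.where(live, np.sqrt(s / mean), 1.0)
        m = m / np.outer(r, r)
    raise RuntimeError(f"balancing did not converge in {max_iter} iterations "
                       f"(residual {resid:.3g})")


def expected_by_distance(cm: ContactMatrix) -> pd.DataFrame:
    """Mean contact per bin distance over unmasked bin pairs."""
    n = cm.n_bins
    live = ~cm.mask
    rows = []
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = live[i] & live[j]
        vals = cm.matrix[i[ok], j[ok]]
        if len(vals):
            rows.append((d, float(vals.mean()), len(vals)))
    return pd.DataFrame(rows, columns=["distance", "expected", "n_pairs"])


def contact_fraction_curve(cm: ContactMatrix, n_bands: int = 20) -> pd.DataFrame:
    """Fraction of cis contacts per log-spaced distance band; sums to 1."""
    exp = expected_by_distance(cm)
    d = exp["distance"].to_numpy()
    total_per_d = exp["expected"].to_numpy() * exp["n_pairs"].to_numpy()
    pos = d >= 1
    d, total_per_d = d[pos], total_per_d[pos]
    edges = np.unique(np.geomspace(1, d.max() + 1, n_bands + 1).astype(int))
    idx = np.digitize(d, edges) - 1
    frac = np.zeros(len(edges) - 1)
    np.add.at(frac, np.clip(idx, 0, len(frac) - 1), total_per_d)
    frac = frac / frac.sum() if frac.sum() else frac
    return pd.DataFrame({"band_start": edges[:-1], "band_end": edges[1:],
                         "fraction": frac})


def fit_decay_exponent(cm: ContactMatrix, d_min: int = 1,
                       d_max: int | None = None) -> float:
    """Log-log regression slope of expected contact versus distance;
    returns the positive decay exponent alpha in E(d) ~ d^-alpha."""
    exp = expected_by_distance(cm)
    sub = exp[(exp["distance"] >= d_min) & (exp["expected"] > 0)]
    if d_max is not None:
        sub = sub[sub["distance"] <= d_max]
    slope = stats.linregress(np.log(sub["distance"]),
                             np.log(sub["expected"])).slope
    return -float(slope)


def observed_over_expected(cm: ContactMatrix) -> np.ndarray:
    """Divide each diagonal by its unmasked mean; masked bins left at 0."""
    exp = expected_by_distance(cm).set_index("distance")["expected"]
    n = cm.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = exp.reindex(np.arange(n)).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cm.matrix / e[d]
    oe[~np.isfinite(oe)] = 0.0
    live = ~cm.mask
    oe[~live, :] = 0.0
    oe[:, ~live] = 0.0
    return oe


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    pc1: np.ndarray          # NaN at masked bins
    labels: np.ndarray       # 'A', 'B', or '' at masked bins
    orientation: str


def compartment_pc1(cm: ContactMatrix, gene_density: np.ndarray) -> CompartmentTrack:
    """A/B compartment eigenvector.

    Pipeline: observed/expected -> Pearson correlation matrix over
    unmasked bins -> first principal component; the sign is oriented so
    PC1 correlates positively with the per-bin gene density (A =
    positive PC1, the gene-dense active compartment).
    """
    live = ~cm.mask
    if live.sum() < 20:
        raise ValueError("need >= 20 unmasked bins")
    if len(gene_density) != cm.n_bins:
        raise ValueError("gene_density length must equal bin count")
    oe = observed_over_expected(cm)[np.ix_(live, live)]
    sd = oe.std(axis=0)
    if (sd == 0).any():
        raise ValueError("degenerate correlation matrix (constant bin)")
    corr = np.corrcoef(oe)
    if not np.isfinite(corr).all():
        raise ValueError("degenerate correlation matrix")
    centered = corr - corr.mean(axis=0, keepdims=True)
    vals, vecs = np.linalg.eigh(np.cov(centered))
    pc = vecs[:, -1]
    gd = np.asarray(gene_density, dtype=float)[live]
    if np.std(gd) > 0 and np.corrcoef(pc, gd)[0, 1] < 0:
        pc = -pc
    pc1 = np.full(cm.n_bins, np.nan)
    pc1[live] = pc
    labels = np.full(cm.n_bins, "", dtype=object)
    labels[live] = np.where(pc >= 0, "A", "B")
    return CompartmentTrack(chrom=cm.chrom, bin_size=cm.bin_size, pc1=pc1,
                            labels=labels, orientation="gene-density")


@dataclass
class PeScanResult:
    aggregate: np.ndarray
    n_pairs: int
    center_enrichment: float


def pe_scan(cm: ContactMatrix, anchor_bins: np.ndarray, flank: int = 5,
            min_sep: int = 20, max_sep: int = 500) -> PeScanResult | None:
    """Aggregate observed/expected pile-up over all intra-chromosomal
    anchor pairs separated by [min_sep, max_sep] bins.

    Averages the (2*flank+1)^2 window centered on each pair; center
    enrichment is the center cell over the mean of the window border.
    Returns None when no eligible pair exists.
    """
    anchors = np.unique(np.asarray(anchor_bins, dtype=np.int64))
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchors")
    if min_sep <= 2 * flank:
        raise ValueError("min_sep must exceed 2*flank")
    oe = observed_over_expected(cm)
    w = 2 * flank + 1
    agg = np.zeros((w, w))
    n_pairs = 0
    n = cm.n_bins
    for ai in range(len(anchors)):
        for aj in range(ai + 1, len(anchors)):
            i, j = anchors[ai], anchors[aj]
            sep = j - i
            if not min_sep <= sep <= max_sep:
                continue
            if i - flank < 0 or j + flank >= n:
                continue
            agg += oe[i - flank:i + flank + 1, j - flank:j + flank + 1]
            n_pairs += 1
    if n_pairs == 0:
        return None
    agg /= n_pairs
    border = np.concatenate([agg[0, :], agg[-1, :], agg[1:-1, 0], agg[1:-1, -1]])
    center = agg[flank, flank]
    enrich = center / border.mean() if border.mean() else np.nan
    return PeScanResult(aggregate=agg, n_pairs=n_pairs,
                        center_enrichment=float(enrich))


@dataclass
class DomainScoreRecord:
    tad_id: str
    intra: float
    inter: float
    score: float
    condition: str


def domain_score(cm: ContactMatrix, tad_start: int, tad_end: int,
                 tad_id: str = "", condition: str = "",
                 pseudocount: float = 1.0) -> DomainScoreRecord | None:
    """Cross-boundary ratio of one TAD: intra-domain contacts (upper
    triangle incl. diagonal) over cis contacts with exactly one end in
    the TAD. TADs spanning < 2 bins are skipped with a warning."""
    bs = cm.bin_size
    b0 = -(-tad_start // bs)   # first bin fully inside
    b1 = tad_end // bs         # one past last bin fully inside
    if b1 - b0 < 2:
        warnings.warn(f"TAD {tad_id or '?'} spans < 2 bins; skipped")
        return None
    if b1 > cm.n_bins:
        raise ValueError(f"TAD {tad_id} extends past the matrix")
    block = cm.matrix[b0:b1, b0:b1]
    intra = float(np.triu(block).sum())
    whole = float(cm.matrix[b0:b1, :].sum())
    # rows x all = 2*intra_offdiag + intra_diag + inter
    diag = float(np.diag(block).sum())
    inter = whole - (2 * intra - diag)
    score = (intra + pseudocount) / (inter + pseudocount)
    return DomainScoreRecord(tad_id=tad_id, intra=intra, inter=inter,
                             score=score, condition=condition)


def domain_scores(matrices: dict, tads: pd.DataFrame, condition: str = "",
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Domain score for every TAD over per-chromosome matrices."""
    rows = []
    for t in tads.itertuples():
        cm = matrices.get(t.chrom)
        if cm is None:
            continue
        rec = domain_score(cm, t.start, t.end, t.tad_id, condition, pseudocount)
        if rec is not None:
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


@dataclass
class DomainScoreComparison:
    deltas: pd.DataFrame       # tad_id, score_wt, score_tko, delta
    statistic: float
    p_value: float
    fraction_decreased: float


def compare_domain_scores(records_wt: pd.DataFrame,
                          records_tko: pd.DataFrame) -> DomainScoreComparison:
    """Per-TAD domain-score delta (TKO - WT) with a two-sided Wilcoxon
    rank-sum test comparing the two score distributions."""
    set_wt = set(records_wt["tad_id"])
    set_tko = set(records_tko["tad_id"])
    if set_wt != set_tko:
        diff = sorted(set_wt ^ set_tko)
        raise ValueError(f"TAD sets differ between conditions: {diff[:10]}")
    merged = records_wt.set_index("tad_id")[["score"]].join(
        records_tko.set_index("tad_id")[["score"]], lsuffix="_wt", rsuffix="_tko")
    merged["delta"] = merged["score_tko"] - merged["score_wt"]
    res = stats.ranksums(merged["score_wt"], merged["score_tko"])
    frac = float((merged["delta"] < 0).mean())
    return DomainScoreComparison(deltas=merged.reset_index(),
                                 statistic=float(res.statistic),
                                 p_value=float(res.pvalue),
                                 fraction_decreased=frac)


def delta_score_quintiles(tads: pd.DataFrame, deltas: pd.DataFrame,
                          change_counts: dict) -> dict:
    """Quintile analysis of epigenetic changes against domain-score delta.

    Ranks TADs by delta (ascending: the leftmost bin holds the TADs with
    the strongest insulation loss when deltas are negative) and computes
    the per-bin percentage of summed changes plus each individual mark,
    with a chi-squared test against the genomic-size expectation. Also
    runs the negative-control rankings (gene count, TAD size, DE-gene
    count) when those counts are present in ``change_counts`` under the
    keys ``genes``/``de_genes``.
    """
    delta = deltas.set_index("tad_id")["delta"].reindex(tads["tad_id"]).to_numpy()
    if np.isnan(delta).any():
        raise ValueError("delta missing for some TADs")
    features = dict(change_counts)
    total = None
    control_keys = {"genes", "de_genes"}
    for name, counts in change_counts.items():
        if name in control_keys:
            continue
        c = counts.drop(index="unassigned", errors="ignore")
        total = c if total is None else total + c
    if total is not None:
        features = {"all_changes": total, **features}

    tads_idx = tads.set_index(tads.index)
    out = {}
    rankings = {"delta_score": pd.Series(delta, index=tads.index)}
    rankings["tad_size"] = (tads["end"] - tads["start"]).astype(float)
    if "genes" in change_counts:
        rankings["gene_count"] = change_counts["genes"].drop(
            index="unassigned", errors="ignore").astype(float)
    if "de_genes" in change_counts:
        rankings["de_gene_count"] = change_counts["de_genes"].drop(
            index="unassigned", errors="ignore").astype(float)
    for rank_name, key in rankings.items():
        out[rank_name] = _tads.quintile_table(
            tads_idx, key.reindex(tads.index), features)
    return out
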