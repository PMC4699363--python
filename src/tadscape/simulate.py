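"""Two-condition synthetic epigenome generator.

Emulates the signal structure of a histone-H1-depletion (TKO) versus
wild-type ES-cell study on a miniature genome: a TAD partition with a
gene-density gradient, CCGG methylation sites with planted hypo/hyper
differential sites skewed toward gene-dense TADs, DNase/ChIP signal
regions with planted gains and losses (including concordant multi-mark
gains at new open-chromatin sites), a proportionally sampled
differentially-expressed gene list, and distance-decaying, compartmented,
TAD-blocked Hi-C contact matrices in which flagged "altered" TADs lose
contact insulation in the TKO condition.

Every quantity is planted with a known truth label so downstream
estimators can be scored against ground truth. A single root seed drives
independent per-simulator streams; the same parameters always reproduce
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd

from .intervals import assign_points

HISTONE_MARKS = ["dhs", "h3k4me1", "h3k4me3", "h3k27me3", "h3k9me3"]
_ACTIVE_MARKS = ["dhs", "h3k4me1", "h3k4me3"]

# fixed sub-stream ids so adding a simulator never perturbs the others
_STREAM_GENOME = 1
_STREAM_METH = 2
_STREAM_SIGNAL = 3
_STREAM_HIC_WT = 4
_STREAM_HIC_TKO = 5
_STREAM_DE = 6


class ParameterError(ValueError):
    """Invalid simulation parameter; message names the offending field."""


@dataclass
class SimulationParams:
    """All knobs of the synthetic dataset.

    Defaults are the study conditions the generator emulates: a strong
    gene-density gradient across TADs (the gene-richest quintile carries
    over half the genes), a ~14:1 hypo:hyper asymmetry among planted
    differentially methylated sites, percent-scale gain/loss fractions
    for open-chromatin and active histone marks with near-zero change in
    repressive marks, ~30% concordance between new DHSs and H3K4me1
    gains, majority-down differential expression, and 100-kb Hi-C maps
    with power-law distance decay, alternating compartments, TAD blocks,
    and a TKO-specific insulation loss in altered (preferentially
    gene-dense) TADs.
    """

    seed: int = 0
    # genome model
    n_chroms: int = 2
    chrom_length: int = 30_000_000
    hic_bin_size: int = 100_000
    n_tads: int = 200
    gene_density_gradient: float = 12.0
    n_genes: int = 2000
    # methylation
    n_meth_sites: int = 50_000
    dmr_fraction: float = 0.015
    hypo_to_hyper_ratio: float = 14.0
    dmr_gene_density_skew: float = 4.0
    meth_depth: float = 30.0
    meth_dispersion: float = 50.0
    dmr_cluster_size: int = 5
    # signal regions
    n_signal_regions: int = 5000
    gain_fraction: float = 0.02
    loss_fraction: float = 0.02
    concordance_prob: float = 0.3
    bookmarked_gain_fraction: float = 0.3
    repressive_change_fraction: float = 0.0
    signal_background: float = 8.0
    signal_depth: float = 30.0
    signal_lfc: float = 2.0
    signal_gene_density_skew: float = 4.0
    n_reps_dhs: int = 3
    n_reps_chip: int = 2
    # differential expression
    de_fraction: float = 0.03
    down_fraction: float = 0.8
    # Hi-C
    decay_exponent: float = 1.0
    compartment_strength: float = 0.3
    compartment_block_bins: int = 20
    tad_block_strength: float = 1.0
    domain_score_shift: float = 0.6
    altered_tad_fraction: float = 0.2
    altered_gene_density_skew: float = 4.0
    altered_change_boost: float = 1.0
    reads_per_matrix: int = 1_000_000

    def __post_init__(self):
        proportions = ["dmr_fraction", "gain_fraction", "loss_fraction",
                       "concordance_prob", "bookmarked_gain_fraction",
                       "repressive_change_fraction", "de_fraction",
                       "down_fraction", "altered_tad_fraction"]
        for name in proportions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        positives = ["n_chroms", "chrom_length", "hic_bin_size", "n_genes",
                     "gene_density_gradient", "hypo_to_hyper_ratio",
                     "dmr_gene_density_skew", "meth_depth", "meth_dispersion",
                     "signal_background", "signal_depth",
                     "signal_gene_density_skew", "decay_exponent",
                     "altered_gene_density_skew", "n_signal_regions"]
        for name in positives:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ["compartment_strength", "tad_block_strength",
                     "domain_score_shift"]:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.compartment_strength >= 1:
            raise ParameterError("compartment_strength must be < 1")
        if self.n_tads < 5:
            raise ParameterError(f"n_tads must be >= 5, got {self.n_tads}")
        if self.chrom_length % self.hic_bin_size != 0:
            raise ParameterError("hic_bin_size must divide chrom_length")
        # every TAD must span at least 2 Hi-C bins for the domain score
        min_len = 2 * self.hic_bin_size * -(-self.n_tads // self.n_chroms)
        if self.chrom_length < min_len:
            raise ParameterError(
                f"chrom_length {self.chrom_length} too short for "
                f"{self.n_tads} TADs of >=2 bins ({self.hic_bin_size} bp) "
                f"on {self.n_chroms} chromosomes")
        if self.reads_per_matrix < 100_000:
            raise ParameterError("reads_per_matrix must be >= 100000")
        if self.n_meth_sites < 100:
            raise ParameterError("n_meth_sites must be >= 100")

    def rng(self, stream: int, extra: int | None = None) -> np.random.Generator:
        key = [int(self.seed), int(stream)]
        if extra is not None:
            key.append(int(extra))
        return np.random.default_rng(key)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class GenomeModel:
    """Miniature genome: chromosome sizes, TADs, genes, chromatin states.

    ``tads`` carries per-TAD annotations used by the simulators: the
    gene-density latent ``u`` in [0, 1] (rank scale; 1 = densest) and the
    planted ``altered`` flag of TADs destined to lose insulation in TKO.
    ``compartments`` holds the planted per-bin A/B labels.
    """

    chromosomes: list
    tads: pd.DataFrame
    genes: pd.DataFrame
    states: pd.DataFrame
    compartments: pd.DataFrame

    def chrom_sizes(self) -> dict:
        return dict(self.chromosomes)

    def bins_per_chrom(self, bin_size: int) -> dict:
        return {name: length // bin_size for name, length in self.chromosomes}


def make_genome(params: SimulationParams) -> GenomeModel:
    """Build the genome model: TADs tile each chromosome on Hi-C bin
    boundaries, alternating A/B compartment blocks are laid down first,
    and TAD gene rates follow the compartment structure so gene-dense
    TADs sit in A compartments (rate lambda_t = g^(1.25 u_t), which makes
    the expected top/bottom gene-content quintile ratio equal g)."""
    rng = params.rng(_STREAM_GENOME)
    bin_size = params.hic_bin_size
    chroms = [(f"chr{i + 1}", params.chrom_length) for i in range(params.n_chroms)]

    # compartment blocks: alternating A/B runs of 15-25 bins
    comp_rows = []
    for ci, (name, length) in enumerate(chroms):
        n_bins = length // bin_size
        label = "A" if rng.random() < 0.5 else "B"
        b = 0
        while b < n_bins:
            run = int(rng.integers(params.compartment_block_bins - 5,
                                   params.compartment_block_bins + 6))
            for k in range(b, min(b + run, n_bins)):
                comp_rows.append((name, k, label))
            b += run
            label = "B" if label == "A" else "A"
    compartments = pd.DataFrame(comp_rows, columns=["chrom", "bin", "label"])

    # TADs: contiguous runs of >=2 bins tiling each chromosome
    n_per = [params.n_tads // params.n_chroms] * params.n_chroms
    for i in range(params.n_tads % params.n_chroms):
        n_per[i] += 1
    tad_rows = []
    for ci, (name, length) in enumerate(chroms):
        n_bins = length // bin_size
        k = n_per[ci]
        extra = rng.multinomial(n_bins - 2 * k, np.full(k, 1.0 / k))
        sizes = 2 + extra
        edges = np.concatenate([[0], np.cumsum(sizes)]) * bin_size
        for t in range(k):
            tad_rows.append((name, int(edges[t]), int(edges[t + 1])))
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    tads["tad_id"] = [f"tad_{i:04d}" for i in range(len(tads))]

    # gene-density latent: fraction of TAD bins in A blocks plus noise,
    # converted to evenly spaced ranks in [0, 1]
    comp_by_chrom = {c: g.set_index("bin")["label"] for c, g in compartments.groupby("chrom")}
    a_frac = np.empty(len(tads))
    for i, row in enumerate(tads.itertuples()):
        b0, b1 = row.start // bin_size, row.end // bin_size
        labels = comp_by_chrom[row.chrom].loc[b0:b1 - 1]
        a_frac[i] = float((labels == "A").mean())
    score = 0.75 * a_frac + 0.25 * rng.random(len(tads))
    rank = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    u = rank / max(len(tads) - 1, 1)
    tads["u"] = u
    g = params.gene_density_gradient
    rate = np.power(g, 1.25 * u) if g != 1 else np.ones(len(tads))
    tads["gene_rate"] = rate / rate.sum()

    # altered flags: preferentially gene-dense TADs
    n_alt = int(round(params.altered_tad_fraction * len(tads)))
    w = np.power(params.altered_gene_density_skew, u)
    altered_idx = rng.choice(len(tads), size=n_alt, replace=False, p=w / w.sum())
    tads["altered"] = False
    tads.loc[tads.index[altered_idx], "altered"] = True

    # genes: multinomial over TAD rates, uniform position within the TAD
    counts = rng.multinomial(params.n_genes, tads["gene_rate"].to_numpy())
    gene_rows = []
    gid = 0
    for trow, cnt in zip(tads.itertuples(), counts):
        if cnt == 0:
            continue
        span = trow.end - trow.start
        glen = rng.integers(2_000, 20_001, size=cnt)
        gstart = trow.start + rng.integers(0, np.maximum(span - glen, 1))
        strands = rng.choice(["+", "-"], size=cnt)
        for s, L, st in zip(gstart, glen, strands):
            end = int(min(s + L, trow.end))
            tss = int(s) if st == "+" else end - 1
            gene_rows.append((trow.chrom, int(s), end, f"gene_{gid:05d}", st, tss,
                              trow.tad_id))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name",
                                             "strand", "tss", "tad_id"])

    # chromatin states: tile each chromosome; active states more likely
    # inside gene-dense TADs
    state_rows = []
    labels = np.array(["promoter", "enhancer", "transcribed",
                       "heterochromatin", "other"])
    for name, length in chroms:
        pos = 0
        chrom_tads = tads[tads["chrom"] == name]
        t_starts = chrom_tads["start"].to_numpy()
        t_u = chrom_tads["u"].to_numpy()
        while pos < length:
            seg = int(rng.integers(2_000, 50_001))
            end = min(pos + seg, length)
            mid = (pos + end) // 2
            ti = np.searchsorted(t_starts, mid, side="right") - 1
            uu = t_u[max(ti, 0)]
            wts = np.array([0.03 + 0.05 * uu, 0.07 + 0.15 * uu,
                            0.12 + 0.20 * uu, 0.40 - 0.30 * uu, 0.25])
            wts = wts / wts.sum()
            state_rows.append((name, pos, end, rng.choice(labels, p=wts)))
            pos = end
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "name"])

    return GenomeModel(chromosomes=chroms, tads=tads, genes=genes,
                       states=states, compartments=compartments)


def _change_weights(tads: pd.DataFrame, skew: float, boost: float) -> np.ndarray:
    """Per-TAD placement weight for planted epigenetic changes.

    weight = skew^(u + boost * altered): at skew=1 the placement is
    exactly uniform regardless of the altered flags; at skew>1 changes
    concentrate in gene-dense and, additionally, in altered TADs.
    """
    u = tads["u"].to_numpy()
    alt = tads["altered"].to_numpy().astype(float)
    return np.power(skew, u + boost * alt)


def _random_positions(rng, genome: GenomeModel, n: int) -> pd.DataFrame:
    lengths = np.array([L for _, L in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(lengths), size=n, p=probs)
    pos = (rng.random(n) * lengths[ci]).astype(np.int64)
    names = np.array([c for c, _ in genome.chromosomes])
    return pd.DataFrame({"chrom": names[ci], "pos": pos})


def simulate_methylation(genome: GenomeModel, params: SimulationParams) -> pd.DataFrame:
    """CCGG-site HpaII/MspI count table with planted differential sites.

    Latent methylation m per site and condition; MspI (methylation-
    insensitive reference) counts are negative binomial around the
    library depth, HpaII counts around 2*depth*(1-m) so the HpaII:MspI
    ratio spans [0, 2] across the methylation range. Planted hypo sites
    drop m from ~0.9 to ~0.07 in TKO (hyper sites the reverse); planted
    sites are placed across TADs with weight skew^(u + boost*altered).

    Returns one tidy table with per-condition counts and a ``truth``
    column in {null, hypo, hyper}.
    """
    rng = params.rng(_STREAM_METH)
    n = params.n_meth_sites
    sites = _random_positions(rng, genome, n)
    sites = sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    tad_idx = assign_points(sites["chrom"].to_numpy(), sites["pos"].to_numpy(),
                            genome.tads)

    truth = np.full(n, "null", dtype=object)
    n_dmr = int(round(params.dmr_fraction * n))
    if params.dmr_fraction > 0 and n_dmr < 1:
        warnings.warn("dmr_fraction * n_meth_sites < 1; no differential sites planted")
    if n_dmr >= 1:
        w_tad = _change_weights(genome.tads, params.dmr_gene_density_skew,
                                params.altered_change_boost)
        w = np.where(tad_idx >= 0, w_tad[np.clip(tad_idx, 0, None)], 0.0)
        k = max(int(params.dmr_cluster_size), 1)
        if k == 1:
            chosen = rng.choice(n, size=n_dmr, replace=False, p=w / w.sum())
        else:
            # differential sites clump locally: pick cluster centers with
            # the TAD weight, then take runs of k neighbouring sites
            chosen_set: list[int] = []
            taken = np.zeros(n, dtype=bool)
            chroms = sites["chrom"].to_numpy()
            while len(chosen_set) < n_dmr:
                c = int(rng.choice(n, p=w / w.sum()))
                lo = max(c - (k - 1) // 2, 0)
                run = [i for i in range(lo, min(lo + k, n))
                       if chroms[i] == chroms[c] and not taken[i]]
                need = n_dmr - len(chosen_set)
                run = run[:need]
                taken[run] = True
                chosen_set.extend(run)
            chosen = np.array(chosen_set, dtype=int)
        p_hypo = params.hypo_to_hyper_ratio / (1.0 + params.hypo_to_hyper_ratio)
        is_hypo = rng.random(n_dmr) < p_hypo
        truth[chosen[is_hypo]] = "hypo"
        truth[chosen[~is_hypo]] = "hyper"

    m_wt = rng.uniform(0.15, 0.95, size=n)
    m_tko = m_wt.copy()
    hypo = truth == "hypo"
    hyper = truth == "hyper"
    m_wt[hypo] = rng.uniform(0.90, 0.97, size=int(hypo.sum()))
    m_tko[hypo] = rng.uniform(0.03, 0.10, size=int(hypo.sum()))
    m_wt[hyper] = rng.uniform(0.03, 0.10, size=int(hyper.sum()))
    m_tko[hyper] = rng.uniform(0.90, 0.97, size=int(hyper.sum()))

    def nb(mean):
        mean = np.maximum(mean, 1e-9)
        size = params.meth_dispersion
        return rng.negative_binomial(size, size / (size + mean))

    depth = params.meth_depth
    out = pd.DataFrame({
        "site_id": [f"cpg_{i:06d}" for i in range(n)],
        "chrom": sites["chrom"],
        "start": sites["pos"],
        "end": sites["pos"] + 2,
        "hpaii_wt": nb(2 * depth * (1 - m_wt)),
        "mspi_wt": nb(np.full(n, depth)),
        "hpaii_tko": nb(2 * depth * (1 - m_tko)),
        "mspi_tko": nb(np.full(n, depth)),
        "truth": truth,
    })
    out["tad_id"] = np.where(
        tad_idx >= 0, genome.tads["tad_id"].to_numpy()[np.clip(tad_idx, 0, None)], "")
    return out


def simulate_signal_regions(genome: GenomeModel, params: SimulationParams) -> dict:
    """Replicated count tables for DHS and four histone marks.

    One shared region set; per mark a WT activity state (active regions
    at signal_depth, background at signal_background), planted gains and
    losses as 2^signal_lfc fold changes, Poisson replicate counts with
    per-library depth factors. DHS gains are planted at regions silent
    for all active marks in WT ("de novo"-eligible) except a bookmarked
    subset planted at WT H3K4me1-positive regions; with probability
    ``concordance_prob`` a de novo DHS gain also gains H3K4me1.

    Returns {mark: DataFrame} with replicate count columns wt_1..,
    tko_1.., a ``truth`` label in {gain, loss, none}, ``wt_active``, and
    ``truth_denovo`` for dhs/h3k4me1.
    """
    if params.n_reps_dhs < 2 or params.n_reps_chip < 2:
        raise ParameterError("need >=2 replicates per condition for DHS and H3K4 marks")
    rng = params.rng(_STREAM_SIGNAL)
    n = params.n_signal_regions
    # non-overlapping 600-bp regions on a 1-kb slot grid, skewed mildly
    # toward gene-dense TADs like real regulatory sites
    slot = 1000
    slot_chrom, slot_start = [], []
    for name, length in genome.chromosomes:
        starts = np.arange(0, length - 600, slot)
        slot_chrom.append(np.full(len(starts), name, dtype=object))
        slot_start.append(starts)
    slot_chrom = np.concatenate(slot_chrom)
    slot_start = np.concatenate(slot_start)
    if n > len(slot_start):
        raise ParameterError("n_signal_regions exceeds available genome slots")
    slot_tad = assign_points(slot_chrom, slot_start + 300, genome.tads)
    w_slot = np.power(3.0, genome.tads["u"].to_numpy())[np.clip(slot_tad, 0, None)]
    w_slot[slot_tad < 0] = 0.0
    pick_slots = rng.choice(len(slot_start), size=n, replace=False,
                            p=w_slot / w_slot.sum())
    regions = pd.DataFrame({"chrom": slot_chrom[pick_slots],
                            "start": slot_start[pick_slots]})
    regions["end"] = regions["start"] + 600
    regions = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    tad_idx = assign_points(regions["chrom"].to_numpy(),
                            ((regions["start"] + regions["end"]) // 2).to_numpy(),
                            genome.tads)
    regions["region_id"] = [f"reg_{i:05d}" for i in range(n)]
    regions["tad_id"] = genome.tads["tad_id"].to_numpy()[np.clip(tad_idx, 0, None)]

    p_active = {"dhs": 0.5, "h3k4me1": 0.4, "h3k4me3": 0.25,
                "h3k27me3": 0.2, "h3k9me3": 0.2}
    active = {m: rng.random(n) < p_active[m] for m in HISTONE_MARKS}
    # heterogeneous peak strength: active regions span ~0.8-3x the nominal
    # depth, as real peak sets do
    strength = {m: rng.uniform(0.8, 3.0, size=n) for m in HISTONE_MARKS}

    w_change = _change_weights(genome.tads, params.signal_gene_density_skew,
                               params.altered_change_boost)[np.clip(tad_idx, 0, None)]

    def pick(mask, size):
        idx = np.flatnonzero(mask)
        if size <= 0 or len(idx) == 0:
            return np.array([], dtype=int)
        size = min(size, len(idx))
        w = w_change[idx]
        return rng.choice(idx, size=size, replace=False, p=w / w.sum())

    labels = {m: np.full(n, "none", dtype=object) for m in HISTONE_MARKS}
    denovo = {m: np.zeros(n, dtype=bool) for m in ("dhs", "h3k4me1")}

    n_gain = int(round(params.gain_fraction * n))
    n_loss = int(round(params.loss_fraction * n))
    pure = ~(active["dhs"] | active["h3k4me1"] | active["h3k4me3"])

    # DHS gains: de novo at pure regions, a bookmarked subset at regions
    # with a clearly established WT H3K4me1 peak (strong strength draw,
    # so they sit above any reasonable "threshold level" of WT signal)
    n_book = int(round(params.bookmarked_gain_fraction * n_gain))
    dhs_denovo_idx = pick(pure, n_gain - n_book)
    dhs_book_idx = pick(~active["dhs"] & active["h3k4me1"]
                        & (strength["h3k4me1"] > 1.9), n_book)
    labels["dhs"][dhs_denovo_idx] = "gain"
    labels["dhs"][dhs_book_idx] = "gain"
    denovo["dhs"][dhs_denovo_idx] = True

    # concordant H3K4me1 gains at de novo DHSs
    coupled = dhs_denovo_idx[rng.random(len(dhs_denovo_idx)) < params.concordance_prob]
    labels["h3k4me1"][coupled] = "gain"
    denovo["h3k4me1"][coupled] = True  # WT lacks DHS/K4 signal there too
    # remaining independent K4me1 gains, de novo-eligible ones flagged
    n_extra = max(n_gain - len(coupled), 0)
    still_pure = pure.copy()
    still_pure[labels["h3k4me1"] == "gain"] = False
    still_pure[labels["dhs"] == "gain"] = False
    k4_extra = pick(still_pure & ~active["h3k4me1"], n_extra)
    labels["h3k4me1"][k4_extra] = "gain"
    denovo["h3k4me1"][k4_extra] = True

    k43_gain = pick(~active["h3k4me3"] & (labels["h3k4me3"] == "none"), n_gain)
    labels["h3k4me3"][k43_gain] = "gain"

    for m in _ACTIVE_MARKS:
        loss_idx = pick(active[m] & (labels[m] == "none"), n_loss)
        labels[m][loss_idx] = "loss"
    n_rep_change = int(round(params.repressive_change_fraction * n))
    for m in ("h3k27me3", "h3k9me3"):
        labels[m][pick(~active[m], n_rep_change)] = "gain"
        labels[m][pick(active[m] & (labels[m] == "none"), n_rep_change)] = "loss"

    fold = 2.0 ** params.signal_lfc
    tables = {}
    for m in HISTONE_MARKS:
        n_reps = params.n_reps_dhs if m == "dhs" else params.n_reps_chip
        mu_wt = np.where(active[m], params.signal_depth * strength[m],
                         params.signal_background)
        mu_tko = mu_wt.copy()
        mu_tko[labels[m] == "gain"] *= fold
        mu_tko[labels[m] == "loss"] /= fold
        df = regions.copy()
        for cond, mu in (("wt", mu_wt), ("tko", mu_tko)):
            for r in range(1, n_reps + 1):
                lib = rng.uniform(0.7, 1.4)
                df[f"{cond}_{r}"] = rng.poisson(mu * lib)
        df["truth"] = labels[m]
        df["wt_active"] = active[m]
        if m in denovo:
            df["truth_denovo"] = denovo[m]
        tables[m] = df
    return tables


def simulate_de_genes(genome: GenomeModel, params: SimulationParams) -> pd.DataFrame:
    """Differentially expressed gene list: a proportional random sample
    of all genes, majority down-regulated."""
    if len(genome.genes) == 0:
        raise ParameterError("genome has no genes")
    rng = params.rng(_STREAM_DE)
    n_de = int(round(params.de_fraction * len(genome.genes)))
    if n_de == 0:
        return genome.genes.iloc[0:0].assign(direction=pd.Series(dtype=object))
    idx = np.sort(rng.choice(len(genome.genes), size=n_de, replace=False))
    de = genome.genes.iloc[idx].copy()
    down = rng.random(n_de) < params.down_fraction
    de["direction"] = np.where(down, "down", "up")
    return de.reset_index(drop=True)


def _expected_matrix(genome: GenomeModel, params: SimulationParams,
                     chrom: str, condition: str) -> np.ndarray:
    n_bins = genome.chrom_sizes()[chrom] // params.hic_bin_size
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = np.power(np.maximum(d, 1), -params.decay_exponent).astype(float)

    comp = genome.compartments
    labels = comp.loc[comp["chrom"] == chrom].set_index("bin")["label"]
    lab = labels.reindex(np.arange(n_bins)).to_numpy()
    same = np.equal.outer(lab, lab)
    cs = params.compartment_strength
    expected *= np.where(same, 1.0 + cs, 1.0 - cs)

    tads = genome.tads[genome.tads["chrom"] == chrom]
    tad_of_bin = np.full(n_bins, -1)
    altered_of_bin = np.zeros(n_bins, dtype=bool)
    for k, row in enumerate(tads.itertuples()):
        b0, b1 = row.start // params.hic_bin_size, row.end // params.hic_bin_size
        tad_of_bin[b0:b1] = k
        altered_of_bin[b0:b1] = row.altered
    same_tad = np.equal.outer(tad_of_bin, tad_of_bin) & (tad_of_bin >= 0)[:, None]
    expected[same_tad] *= 1.0 + params.tad_block_strength

    if condition == "tko" and params.domain_score_shift > 0:
        cross = ~np.equal.outer(tad_of_bin, tad_of_bin)
        touches_alt = altered_of_bin[:, None] | altered_of_bin[None, :]
        expected[cross & touches_alt] *= 1.0 + params.domain_score_shift
    return expected


def simulate_hic(genome: GenomeModel, params: SimulationParams,
                 condition: str) -> dict:
    """Per-chromosome symmetric integer contact matrices.

    Expected contact ~ d^-decay_exponent, scaled by (1 +/- compartment
    strength) for same/cross-compartment bin pairs, (1 + TAD block
    strength) within TADs, and — in TKO only — (1 + domain_score_shift)
    for cross-TAD pairs touching an altered TAD, then Poisson-sampled to
    ``reads_per_matrix`` total reads split across chromosomes by length.
    """
    if condition not in ("wt", "tko"):
        raise ParameterError(f"condition must be 'wt' or 'tko', got {condition!r}")
    stream = _STREAM_HIC_WT if condition == "wt" else _STREAM_HIC_TKO
    total_len = sum(L for _, L in genome.chromosomes)
    out = {}
    for ci, (chrom, length) in enumerate(genome.chromosomes):
        rng = params.rng(stream, ci)
        expected = _expected_matrix(genome, params, chrom, condition)
        reads = params.reads_per_matrix * length / total_len
        iu = np.triu_indices_from(expected)
        lam = expected[iu] / expected[iu].sum() * reads
        counts = rng.poisson(lam)
        mat = np.zeros_like(expected)
        mat[iu] = counts
        mat = mat + np.triu(mat, 1).T
        out[chrom] = mat.astype(np.int64)
    return out


def simulate_anchor_matrix(seed: int, n_bins: int = 300,
                           decay_exponent: float = 1.0,
                           anchor_bins: np.ndarray | None = None,
                           n_anchors: int = 12,
                           enrichment: float = 2.0,
                           reads: int = 2_000_000):
    """Contact matrix with planted pairwise affinity between anchor bins.

    A pure power-law background whose anchor-anchor cells are multiplied
    by ``enrichment``; the pile-up validation fixture for PE-SCAN-style
    aggregation. Returns (matrix, anchor_bins).
    """
    rng = np.random.default_rng([int(seed), 97])
    if anchor_bins is None:
        anchor_bins = np.sort(rng.choice(np.arange(10, n_bins - 10),
                                         size=n_anchors, replace=False))
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = np.power(np.maximum(d, 1), -decay_exponent).astype(float)
    expected[np.ix_(anchor_bins, anchor_bins)] *= enrichment
    np.fill_diagonal(expected, np.diag(
        np.power(np.maximum(d, 1), -decay_exponent)))
    iu = np.triu_indices(n_bins)
    lam = expected[iu] / expected[iu].sum() * reads
    counts = rng.poisson(lam)
    mat = np.zeros_like(expected)
    mat[iu] = counts
    mat = mat + np.triu(mat, 1).T
    return mat.astype(np.int64), np.asarray(anchor_bins)


@dataclass
class SimulatedDataset:
    params: SimulationParams
    genome: GenomeModel
    methylation: pd.DataFrame
    signal: dict
    de_genes: pd.DataFrame
    hic: dict = field(default_factory=dict)  # condition -> {chrom: matrix}


def simulate(params: SimulationParams, with_hic: bool = True) -> SimulatedDataset:
    """Run every simulator off one root seed."""
    genome = make_genome(params)
    ds = SimulatedDataset(
        params=params,
        genome=genome,
        methylation=simulate_methylation(genome, params),
        signal=simulate_signal_regions(genome, params),
        de_genes=simulate_de_genes(genome, params),
    )
    if with_hic:
        ds.hic = {c: simulate_hic(genome, params, c) for c in ("wt", "tko")}
    return ds
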