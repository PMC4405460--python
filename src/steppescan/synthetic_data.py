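"""Synthetic inputs with recorded ground truth.

Two families of generators:

* an IBD-sharing network in which the expected per-pair sharing between two
  populations decays exponentially with geodesic distance
  (``beta_b * exp(-d / lambda)``) plus an injected directional excess
  ``delta_b`` on designated source -> recipient edges; and
* admixed diploid genotypes produced by a one-pulse admixture of two
  Balding-Nichols-diverged source populations, propagated forward ``g``
  generations through a random-mating population of ``N`` diploids with
  Poisson(1 per Morgan) recombination, with the true ancestry tracts recorded.

Every generator is a pure function of its config and seed: identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_io import GenotypeDataset, IBDSegmentTable, PopulationTable, SEGMENT_COLUMNS
from .errors import ConfigError
from .sharing_stats import LengthBin, SharingMatrix, default_bins, geodesic_matrix

logger = logging.getLogger(__name__)

_SIM_CHROM_LENGTH_CM = 150.0  # placement span for simulated IBD segments
_SIM_N_CHROMS = 22


# ---------------------------------------------------------------------------
# Single-path IBD tract lengths
# ---------------------------------------------------------------------------

def expected_single_path_length_cM(g: float) -> float:
    """Mean length of an IBD tract surviving a chain of 2g meioses: 100/(2g) cM."""
    if g < 1:
        raise ConfigError(f"generations must be >= 1, got {g}")
    return 100.0 / (2.0 * g)


def draw_ibd_segment_lengths(
    g: float, n: int, min_cM: float = 0.0, seed=None
) -> np.ndarray:
    """Draw i.i.d. single-path IBD tract lengths (cM), truncated at ``min_cM``.

    Lengths follow an exponential with mean ``100 / (2 g)`` cM conditioned on
    exceeding ``min_cM``; by memorylessness this equals ``min_cM`` plus an
    exponential of the same mean, which is drawn directly.
    """
    if g < 1:
        raise ConfigError(f"generations must be >= 1, got {g}")
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if min_cM < 0:
        raise ConfigError(f"min_cM must be >= 0, got {min_cM}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return min_cM + rng.exponential(expected_single_path_length_cM(g), size=n)


# ---------------------------------------------------------------------------
# Sharing-network simulation
# ---------------------------------------------------------------------------

@dataclass
class GeneFlowEdge:
    """Directional excess sharing from ``source`` into ``recipient``.

    ``excess_cM`` is the extra expected per-individual-pair sharing in cM,
    either a scalar applied to every bin or a per-bin mapping.
    """

    source: str
    recipient: str
    excess_cM: object = 2.0

    def excess_for(self, bin_: LengthBin) -> float:
        if isinstance(self.excess_cM, Mapping):
            return float(self.excess_cM.get(bin_, 0.0))
        return float(self.excess_cM)


@dataclass
class SharingSimConfig:
    """Study conditions for the IBD-sharing network generator."""

    populations: PopulationTable
    sample_sizes: Dict[str, int]
    baseline_rate_cM: object = 1.0  # beta_b: scalar or {LengthBin: cM per pair}
    decay_scale_km: float = 2000.0  # lambda
    gene_flow_edges: List[GeneFlowEdge] = field(default_factory=list)
    bins: List[LengthBin] = field(default_factory=default_bins)
    segment_mean_generations: float = 20.0  # parameterizes in-bin length draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_scale_km <= 0:
            raise ConfigError("decay_scale_km must be > 0")
        if self.segment_mean_generations < 1:
            raise ConfigError("segment_mean_generations must be >= 1")
        ids = set(self.populations.population_ids)
        for p in ids:
            if p not in self.sample_sizes:
                raise ConfigError(f"no sample size for population {p!r}")
        for e in self.gene_flow_edges:
            if e.source not in ids or e.recipient not in ids:
                raise ConfigError(f"gene-flow edge references unknown population: {e}")
            for b in self.bins:
                if e.excess_for(b) < 0:
                    raise ConfigError("gene-flow excess must be >= 0")

    def baseline_for(self, bin_: LengthBin) -> float:
        if isinstance(self.baseline_rate_cM, Mapping):
            return float(self.baseline_rate_cM.get(bin_, 0.0))
        return float(self.baseline_rate_cM)

    def sample_ids(self, pop: str) -> List[str]:
        return [f"{pop}_{k:03d}" for k in range(int(self.sample_sizes[pop]))]

    def sample_map(self) -> Dict[str, str]:
        return {
            s: p for p in self.populations.population_ids for s in self.sample_ids(p)
        }


def _truncated_exp_mean(mean: float, lo: float, hi: float) -> float:
    c = (hi - lo) / mean
    q = np.exp(-c)
    return lo + mean - (hi - lo) * q / (1.0 - q)


def _expected_pair_sharing(config: SharingSimConfig) -> pd.DataFrame:
    """Expected per-individual-pair sharing (cM) for every pair and bin."""
    pops = config.populations.population_ids
    dist = geodesic_matrix(config.populations)
    edges = {}
    for e in config.gene_flow_edges:
        key = tuple(sorted((e.source, e.recipient)))
        edges[key] = edges.get(key, 0.0)
    rows = []
    for i, a in enumerate(pops):
        for j in range(i, len(pops)):
            b_pop = pops[j]
            d = float(dist.loc[a, b_pop])
            key = tuple(sorted((a, b_pop)))
            flow = [e for e in config.gene_flow_edges
                    if tuple(sorted((e.source, e.recipient))) == key and a != b_pop]
            for bin_ in config.bins:
                mu = config.baseline_for(bin_) * np.exp(-d / config.decay_scale_km)
                excess = sum(e.excess_for(bin_) for e in flow)
                rows.append(
                    (a, b_pop, bin_.lower_cM, bin_.upper_cM, d,
                     mu + excess, excess > 0)
                )
    return pd.DataFrame(
        rows,
        columns=["pop_a", "pop_b", "bin_lower_cM", "bin_upper_cM",
                 "distance_km", "expected_cM_per_pair", "gene_flow"],
    )


def expected_sharing_matrix(config: SharingSimConfig) -> SharingMatrix:
    """The noiseless sharing matrix implied by the config (the generator's truth)."""
    truth = _expected_pair_sharing(config)
    pops = config.populations.population_ids
    pidx = {p: i for i, p in enumerate(pops)}
    bidx = {b: k for k, b in enumerate(config.bins)}
    values = np.zeros((len(pops), len(pops), len(config.bins)))
    for row in truth.itertuples(index=False):
        i, j = pidx[row.pop_a], pidx[row.pop_b]
        b = bidx[LengthBin(row.bin_lower_cM, row.bin_upper_cM)]
        values[i, j, b] = values[j, i, b] = row.expected_cM_per_pair
    n = np.array([config.sample_sizes[p] for p in pops])
    return SharingMatrix(pops, list(config.bins), values, n)


def simulate_sharing_network(
    config: SharingSimConfig,
) -> Tuple[IBDSegmentTable, pd.DataFrame]:
    """Realize an IBD segment table whose per-pair expected sharing follows the
    configured exponential distance decay plus injected gene-flow excess.

    For each population pair and bin, the number of segments is Poisson with
    mean ``n_pairs * mu_b / E[length | bin]`` and lengths are drawn from the
    single-path exponential (mean ``100 / (2 g_seg)`` cM) truncated to the
    bin, so the expected total sharing per individual pair equals ``mu_b``
    exactly.  Returns the segment table and the truth table of expectations.
    """
    rng = np.random.default_rng(config.seed)
    truth = _expected_pair_sharing(config)
    mean_len = expected_single_path_length_cM(config.segment_mean_generations)
    pops = config.populations.population_ids
    sizes = {p: int(config.sample_sizes[p]) for p in pops}
    ids = {p: np.asarray(config.sample_ids(p), dtype=object) for p in pops}

    out_a, out_b, out_pa, out_pb = [], [], [], []
    out_chrom, out_start, out_len = [], [], []
    for row in truth.itertuples(index=False):
        a, b_pop = row.pop_a, row.pop_b
        lo, hi = row.bin_lower_cM, row.bin_upper_cM
        na, nb = sizes[a], sizes[b_pop]
        n_pairs = na * (na - 1) // 2 if a == b_pop else na * nb
        if n_pairs == 0 or row.expected_cM_per_pair <= 0:
            continue
        e_len = _truncated_exp_mean(mean_len, lo, hi)
        count = rng.poisson(n_pairs * row.expected_cM_per_pair / e_len)
        if count == 0:
            continue
        # inverse-CDF draw from Exp(mean_len) truncated to [lo, hi)
        q = 1.0 - np.exp(-(hi - lo) / mean_len)
        lengths = lo - mean_len * np.log1p(-rng.random(count) * q)
        if a == b_pop:
            i1 = rng.integers(na, size=count)
            i2 = rng.integers(na - 1, size=count)
            i2 = i2 + (i2 >= i1)
            sa, sb = ids[a][i1], ids[a][i2]
        else:
            sa = ids[a][rng.integers(na, size=count)]
            sb = ids[b_pop][rng.integers(nb, size=count)]
        chrom = rng.integers(1, _SIM_N_CHROMS + 1, size=count)
        start = rng.random(count) * (_SIM_CHROM_LENGTH_CM - lengths)
        out_a.append(sa)
        out_b.append(sb)
        out_pa.append(np.full(count, a, dtype=object))
        out_pb.append(np.full(count, b_pop, dtype=object))
        out_chrom.append(chrom)
        out_start.append(start)
        out_len.append(lengths)

    if out_a:
        frame = pd.DataFrame(
            {
                "sample_a": np.concatenate(out_a),
                "sample_b": np.concatenate(out_b),
                "population_a": np.concatenate(out_pa),
                "population_b": np.concatenate(out_pb),
                "chromosome": np.concatenate(out_chrom).astype(str),
                "start_cM": np.concatenate(out_start),
            }
        )
        frame["end_cM"] = frame["start_cM"] + np.concatenate(out_len)
    else:
        frame = pd.DataFrame(
            columns=["sample_a", "sample_b", "population_a", "population_b",
                     "chromosome", "start_cM", "end_cM"]
        )
    segments = IBDSegmentTable.from_frame(frame)
    return segments, truth


# ---------------------------------------------------------------------------
# Admixed-haplotype simulation
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureSimConfig:
    """Study conditions for the one-pulse admixture simulator.

    ``alpha`` is the admixture proportion contributed by source 1, ``g`` the
    number of generations since the pulse, ``divergence_F`` the
    Balding-Nichols drift parameter separating the two sources, and
    ``population_size`` the number of diploids propagated each generation.
    """

    g: int
    alpha: float = 0.5
    n_haplotypes: int = 100
    chromosome_lengths_M: List[float] = field(default_factory=lambda: [3.0] * 10)
    n_snps_per_chromosome: int = 1500
    divergence_F: float = 0.2
    population_size: int = 500
    n_ref_individuals: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.g < 1:
            raise ConfigError(f"g must be >= 1, got {self.g}")
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be an even integer >= 4")
        if sum(self.chromosome_lengths_M) <= 0:
            raise ConfigError("total map length must be > 0")
        if not 0.0 < self.divergence_F < 1.0:
            raise ConfigError("divergence_F must be in (0, 1)")
        if self.population_size < self.n_haplotypes // 2:
            raise ConfigError("population_size smaller than the sample drawn from it")


@dataclass
class AncestryTractSet:
    """True ancestry tracts of sampled haplotypes.

    ``frame`` columns: ``haplotype`` (int), ``chromosome`` (str), ``start_M``,
    ``end_M``, ``ancestry`` (1 or 2).  Tracts tile each chromosome exactly and
    adjacent tracts differ in ancestry.
    """

    frame: pd.DataFrame
    chromosome_lengths_M: Dict[str, float]

    def validate(self) -> None:
        for (hap, chrom), sub in self.frame.groupby(["haplotype", "chromosome"],
                                                    sort=False):
            sub = sub.sort_values("start_M")
            starts = sub["start_M"].to_numpy(float)
            ends = sub["end_M"].to_numpy(float)
            anc = sub["ancestry"].to_numpy(int)
            L = self.chromosome_lengths_M[str(chrom)]
            if starts[0] != 0.0 or ends[-1] != L:
                raise ConfigError(f"tracts do not span chromosome {chrom}")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ConfigError(f"tract gap/overlap on chromosome {chrom}")
            if np.any(anc[1:] == anc[:-1]):
                raise ConfigError("adjacent tracts share ancestry")

    def lengths(self, ancestry: int, interior_only: bool = False) -> np.ndarray:
        """Tract lengths in Morgans for one ancestry, optionally excluding
        tracts touching a chromosome end (censored)."""
        f = self.frame[self.frame["ancestry"] == ancestry]
        if interior_only:
            L = f["chromosome"].map(self.chromosome_lengths_M).to_numpy(float)
            keep = (f["start_M"].to_numpy(float) > 0) & (
                f["end_M"].to_numpy(float) < L
            )
            f = f[keep]
        return (f["end_M"] - f["start_M"]).to_numpy(float)


def _snp_grid(config: AdmixtureSimConfig):
    """Evenly spaced marker positions; returns per-SNP chromosome labels,
    positions (Morgans) and the inter-marker switch probabilities (Haldane)."""
    chroms, pos, psw = [], [], []
    for ci, L in enumerate(config.chromosome_lengths_M):
        m = config.n_snps_per_chromosome
        p = (np.arange(m) + 0.5) * (L / m)
        chroms.append(np.full(m, str(ci + 1), dtype=object))
        pos.append(p)
        gaps = np.diff(p, prepend=np.nan)
        pr = 0.5 * (1.0 - np.exp(-2.0 * gaps))
        pr[0] = 0.5  # chromosomes assort independently
        psw.append(pr)
    return np.concatenate(chroms), np.concatenate(pos), np.concatenate(psw)


def _extract_tracts(
    ancestry: np.ndarray, chrom_labels: np.ndarray, pos: np.ndarray,
    chromosome_lengths: Dict[str, float],
) -> pd.DataFrame:
    """Tracts from per-marker ancestry; boundaries at inter-marker midpoints."""
    rows = []
    for chrom in dict.fromkeys(chrom_labels):
        sel = chrom_labels == chrom
        p = pos[sel]
        L = chromosome_lengths[chrom]
        for hap in range(ancestry.shape[0]):
            anc = ancestry[hap, sel]
            cp = np.flatnonzero(np.diff(anc))
            mids = (p[cp] + p[cp + 1]) / 2.0
            starts = np.concatenate(([0.0], mids))
            ends = np.concatenate((mids, [L]))
            labels = anc[np.concatenate(([0], cp + 1))]
            for s, e, a in zip(starts, ends, labels):
                rows.append((hap, chrom, s, e, int(a)))
    return pd.DataFrame(
        rows, columns=["haplotype", "chromosome", "start_M", "end_M", "ancestry"]
    )


def simulate_admixed_haplotypes(
    config: AdmixtureSimConfig,
) -> Tuple[GenotypeDataset, AncestryTractSet]:
    """One-pulse admixture forward simulation with known ground truth.

    Source allele frequencies are Balding-Nichols draws around a shared
    ancestral frequency ~ Uniform(0.05, 0.95).  Founder haplotypes carry
    ancestry 1 with probability ``alpha``; ``population_size`` diploids are
    then propagated ``g`` generations under random mating, recombining at the
    marker grid with the exact Haldane inter-marker switch probabilities of a
    Poisson(1 per Morgan) crossover process.  Alleles are copied from the
    local ancestry's source frequencies.  Returns diploid dosage panels for
    source 1, source 2 and the admixed sample, plus the true ancestry tracts
    of the sampled haplotypes (ancestry 1 = source 1, 2 = source 2).
    """
    rng = np.random.default_rng(config.seed)
    chrom_labels, pos, psw = _snp_grid(config)
    m = pos.size
    F = config.divergence_F
    u = rng.uniform(0.05, 0.95, size=m)
    a_par, b_par = u * (1 - F) / F, (1 - u) * (1 - F) / F
    p1 = rng.beta(a_par, b_par)
    p2 = rng.beta(a_par, b_par)

    n2 = 2 * config.population_size
    founder_anc = (rng.random(n2) < config.alpha).astype(np.uint8)
    H = np.repeat(founder_anc[:, None], m, axis=1)
    for _ in range(config.g):
        parent = rng.integers(config.population_size, size=n2)
        switches = rng.random((n2, m), dtype=np.float32) < psw.astype(np.float32)
        phase = np.bitwise_xor.accumulate(switches, axis=1)
        H = np.where(phase, H[2 * parent + 1], H[2 * parent])

    n_hap = config.n_haplotypes
    ind = rng.choice(config.population_size, size=n_hap // 2, replace=False)
    rows = np.column_stack((2 * ind, 2 * ind + 1)).ravel()
    sampled = H[rows]

    # ancestry codes: source 1 -> 1, source 2 -> 2
    chrom_lengths = {
        str(ci + 1): float(L) for ci, L in enumerate(config.chromosome_lengths_M)
    }
    tracts = AncestryTractSet(
        _extract_tracts(np.where(sampled == 1, 1, 2), chrom_labels, pos,
                        chrom_lengths),
        chrom_lengths,
    )

    freq = np.where(sampled == 1, p1[None, :], p2[None, :])
    alleles = (rng.random((n_hap, m)) < freq).astype(np.int16)
    admixed_dosage = alleles[0::2] + alleles[1::2]
    nr = config.n_ref_individuals
    src1 = rng.binomial(2, p1, size=(nr, m)).astype(np.int16)
    src2 = rng.binomial(2, p2, size=(nr, m)).astype(np.int16)

    samples = (
        [f"source1_{i:03d}" for i in range(nr)]
        + [f"source2_{i:03d}" for i in range(nr)]
        + [f"admixed_{i:03d}" for i in range(n_hap // 2)]
    )
    pops = np.asarray(
        ["source1"] * nr + ["source2"] * nr + ["admixed"] * (n_hap // 2),
        dtype=object,
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{c}_{k}" for k, c in enumerate(chrom_labels)],
            "chromosome": chrom_labels,
            "pos_bp": np.round(pos * 1e8).astype(np.int64),
            "pos_cM": pos * 100.0,
        }
    )
    dosages = np.vstack((src1, src2, admixed_dosage))
    return GenotypeDataset(samples, pops, snps, dosages), tracts


def simulate_frequency_trio(
    alpha: float,
    F: float = 0.2,
    n_snps: int = 5000,
    n_per_pop: int = 25,
    seed: int = 0,
    post_admixture_F: float = 0.0,
    target_mode: str = "admixed",
) -> GenotypeDataset:
    """Three populations for the f3 test: two Balding-Nichols sources and a
    target whose per-SNP frequency is ``alpha p1 + (1 - alpha) p2`` (plus an
    optional post-admixture drift, default none).  Genotypes are
    Binomial(2, p) per individual.

    ``target_mode="independent"`` draws the target as a third unadmixed
    Balding-Nichols population around the same ancestral frequencies — the
    null for the f3 test (``alpha`` is then ignored).
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be strictly inside (0, 1), got {alpha}")
    if target_mode not in ("admixed", "independent"):
        raise ConfigError(f"unknown target_mode {target_mode!r}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.05, 0.95, size=n_snps)
    a_par, b_par = u * (1 - F) / F, (1 - u) * (1 - F) / F
    p1 = rng.beta(a_par, b_par) if n_snps else np.empty(0)
    p2 = rng.beta(a_par, b_par) if n_snps else np.empty(0)
    if target_mode == "independent":
        p3 = rng.beta(a_par, b_par) if n_snps else np.empty(0)
    else:
        p3 = alpha * p1 + (1 - alpha) * p2
    if post_admixture_F > 0 and n_snps:
        pc = np.clip(p3, 1e-6, 1 - 1e-6)
        p3 = rng.beta(pc * (1 - post_admixture_F) / post_admixture_F,
                      (1 - pc) * (1 - post_admixture_F) / post_admixture_F)
    dosages = np.vstack(
        [rng.binomial(2, p, size=(n_per_pop, n_snps)).astype(np.int16)
         for p in (p1, p2, p3)]
    ) if n_snps else np.zeros((3 * n_per_pop, 0), np.int16)

    # spread markers over 22 chromosomes of 150 cM each
    per = max(1, int(np.ceil(n_snps / 22))) if n_snps else 1
    k = np.arange(n_snps)
    chroms = (k // per + 1).astype(str)
    pos_cm = ((k % per) + 0.5) * (150.0 / per)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in k],
            "chromosome": chroms,
            "pos_bp": np.round(pos_cm * 1e6).astype(np.int64),
            "pos_cM": pos_cm,
        }
    )
    samples = [
        f"{p}_{i:03d}"
        for p in ("source1", "source2", "target")
        for i in range(n_per_pop)
    ]
    pops = np.asarray(
        ["source1"] * n_per_pop + ["source2"] * n_per_pop + ["target"] * n_per_pop,
        dtype=object,
    )
    return GenotypeDataset(samples, pops, snps, dosages)
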