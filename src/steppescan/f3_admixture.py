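"""Three-population admixture test f3(target; source1, source2) with
weighted block-jackknife standard errors.

Per SNP with sample allele frequencies a, b (sources) and c (target), the
summand is ``(c - a)(c - b) - c(1 - c)/(n_c - 1)`` where ``n_c`` is the
observed target chromosome count; the correction removes the sampling bias of
``c``.  f3 is the SNP average; its standard error comes from a weighted
delete-one-block jackknife over contiguous cM windows (weights proportional
to SNP counts per block), and ``Z = f3 / SE``.  A significantly negative f3
indicates that the target is admixed between groups related to the two
sources; testing is one-tailed on the negative side.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeDataset
from .errors import ConfigError

DEFAULT_BLOCK_CM = 5.0


@dataclass(frozen=True)
class F3Result:
    target_id: str
    source1_id: str
    source2_id: str
    f3: float
    SE: float
    Z: float
    n_snps: int
    n_blocks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "target": self.target_id,
            "source1": self.source1_id,
            "source2": self.source2_id,
            "f3": self.f3,
            "SE": self.SE,
            "Z": self.Z,
            "n_snps": self.n_snps,
            "n_blocks": self.n_blocks,
        }])


@dataclass(frozen=True)
class SignificanceThresholds:
    alpha_nominal: float
    n_tests: int
    alpha_corrected: float
    z_critical: float


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> SignificanceThresholds:
    """Bonferroni-corrected one-tailed Z threshold: alpha / n_tests mapped
    through the standard-normal quantile function."""
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    corrected = alpha / n_tests
    return SignificanceThresholds(
        alpha_nominal=alpha,
        n_tests=n_tests,
        alpha_corrected=corrected,
        z_critical=float(stats.norm.ppf(corrected)),
    )


def enumerate_trios(pops: Sequence[str]) -> List[Tuple[str, str, str]]:
    """All (target; source1, source2) trios: ordered targets x unordered
    source pairs, all three distinct — N(N-1)(N-2)/2 trios."""
    pops = list(pops)
    if len(set(pops)) != len(pops):
        raise ConfigError("duplicate population id in list")
    if len(pops) < 3:
        raise ConfigError("need at least 3 populations")
    trios = []
    for target in pops:
        rest = [p for p in pops if p != target]
        for s1, s2 in combinations(rest, 2):
            trios.append((target, s1, s2))
    return trios


def _frequencies(geno: GenotypeDataset, pop: str) -> Tuple[np.ndarray, np.ndarray]:
    """Per-SNP sample allele frequency and observed chromosome count
    (pairwise-complete over missing genotypes)."""
    idx = geno.population_indices(pop)
    if idx.size < 2:
        raise ConfigError(f"population {pop!r} has fewer than 2 individuals")
    d = geno.dosages[idx].astype(float)
    obs = d >= 0
    counts = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, d, 0.0).sum(axis=0) / counts
    return freq, counts


def _block_ids(geno: GenotypeDataset, block_cM: float) -> np.ndarray:
    """Contiguous cM-window block labels per SNP (per chromosome)."""
    cm = geno.snps["pos_cM"].to_numpy(float)
    if not np.all(np.isfinite(cm)):
        raise ConfigError("all SNPs need cM positions for block jackknife")
    blocks = np.empty(len(cm), dtype=object)
    for chrom, sub in geno.snps.groupby("chromosome", sort=False):
        c = cm[sub.index]
        blocks[sub.index] = [f"{chrom}:{int(v)}" for v in (c - c.min()) // block_cM]
    return blocks


def weighted_block_jackknife(
    values: np.ndarray, blocks: np.ndarray
) -> Tuple[float, float, int]:
    """Mean of ``values`` with a weighted delete-one-block jackknife SE
    (block weights proportional to their element counts).

    Returns (estimate, SE, n_blocks).
    """
    n = values.size
    uniq, inv = np.unique(blocks, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ConfigError(f"only {g} jackknife block(s) with data; need >= 2")
    m = np.bincount(inv).astype(float)
    block_sums = np.bincount(inv, weights=values)
    total = values.sum()
    theta = total / n
    theta_del = (total - block_sums) / (n - m)
    h = n / m
    theta_jack = g * theta - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta - (h - 1.0) * theta_del
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    return float(theta), float(np.sqrt(var)), int(g)


def f3_statistic(
    geno: GenotypeDataset,
    target: str,
    source1: str,
    source2: str,
    block_cM: float = DEFAULT_BLOCK_CM,
) -> F3Result:
    """Compute f3(target; source1, source2) with jackknife SE and Z-score.

    SNPs monomorphic across all three populations are dropped, as are SNPs
    where any population has fewer than 2 observed chromosomes.
    """
    a, n_a = _frequencies(geno, source1)
    b, n_b = _frequencies(geno, source2)
    c, n_c = _frequencies(geno, target)
    usable = (n_a >= 2) & (n_b >= 2) & (n_c >= 2)
    mono = ((a == b) & (b == c)) & ((c == 0) | (c == 1))
    keep = usable & ~mono
    if keep.sum() == 0:
        raise ConfigError("no usable SNPs for f3")
    summand = (c - a) * (c - b) - c * (1.0 - c) / (n_c - 1.0)
    blocks = _block_ids(geno, block_cM)
    f3, se, n_blocks = weighted_block_jackknife(summand[keep], blocks[keep])
    if se > 0:
        z = f3 / se
    else:  # degenerate fixture: identical blocks
        z = float("nan") if f3 == 0 else float(np.copysign(np.inf, f3))
    return F3Result(
        target_id=target,
        source1_id=source1,
        source2_id=source2,
        f3=f3,
        SE=se,
        Z=z,
        n_snps=int(keep.sum()),
        n_blocks=n_blocks,
    )


def f3_suite(
    geno: GenotypeDataset,
    trios: Sequence[Tuple[str, str, str]] | None = None,
    block_cM: float = DEFAULT_BLOCK_CM,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """f3 over a list of trios (default: all trios of the dataset's
    populations), with nominal and Bonferroni significance columns."""
    if trios is None:
        trios = enumerate_trios(geno.populations())
    nominal = bonferroni_threshold(alpha, 1).z_critical
    corrected = bonferroni_threshold(alpha, max(len(trios), 1)).z_critical
    rows = []
    for target, s1, s2 in trios:
        res = f3_statistic(geno, target, s1, s2, block_cM)
        row = res.to_frame().iloc[0]
        row["significant_nominal"] = res.Z < nominal
        row["significant_bonferroni"] = res.Z < corrected
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)
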