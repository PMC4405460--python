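"""Pooled-neighbor permutation test for excess IBD sharing.

The observed statistic is the binned average sharing between a focal
population and a candidate source.  Under the null, the focal population is
exchangeable with its pooled geographic neighbors: each permutation draws
(without replacement) a pseudo-population of the focal's size from the pooled
neighbor individuals and recomputes the same statistic against the source.
The p-value is the fraction of permuted statistics greater than or equal to
the observed one (no +1 correction; the minimum resolvable p, 1/n_perm, is
reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_io import IBDSegmentTable, PopulationTable
from .errors import ConfigError
from .sharing_stats import LengthBin

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    focal_id: str
    source_id: str
    bin: LengthBin
    observed_cM: float
    n_perm: int
    n_geq: int
    p_value: float
    min_p: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "focal": self.focal_id,
            "source": self.source_id,
            "bin": str(self.bin),
            "observed_cM": self.observed_cM,
            "n_perm": self.n_perm,
            "n_geq": self.n_geq,
            "p_value": self.p_value,
            "min_p": self.min_p,
        }])


def _per_individual_totals(
    segments: IBDSegmentTable,
    source: str,
    bin_: LengthBin,
    individuals: Sequence[str],
) -> np.ndarray:
    """Total bin-b segment length each listed individual shares with any
    individual of the source population."""
    f = segments.frame
    lengths = f["length_cM"].to_numpy(float)
    in_bin = (lengths >= bin_.lower_cM) & (lengths < bin_.upper_cM)
    f = f[in_bin]
    totals: Dict[str, float] = {s: 0.0 for s in individuals}
    mask_a = (f["population_b"] == source).to_numpy()
    for s, ln in zip(f["sample_a"].to_numpy()[mask_a],
                     f["length_cM"].to_numpy(float)[mask_a]):
        if s in totals:
            totals[s] += ln
    mask_b = (f["population_a"] == source).to_numpy()
    for s, ln in zip(f["sample_b"].to_numpy()[mask_b],
                     f["length_cM"].to_numpy(float)[mask_b]):
        if s in totals:
            totals[s] += ln
    return np.asarray([totals[s] for s in individuals])


def _population_individuals(sample_map: Mapping[str, str], pop: str) -> List[str]:
    out = sorted(s for s, p in sample_map.items() if p == pop)
    if not out:
        raise ConfigError(f"no individuals mapped to population {pop!r}")
    return out


def _permutation_draws(
    rng: np.random.Generator, n_perm: int, pool_size: int, draw_size: int
) -> np.ndarray:
    """(n_perm, draw_size) index matrix; each row a uniform subset without
    replacement of the pool."""
    keys = rng.random((n_perm, pool_size))
    return np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]


def excess_sharing_pvalue(
    segments: IBDSegmentTable,
    focal: str,
    source: str,
    neighbor_pool: Sequence[str],
    bin_: LengthBin,
    sample_map: Mapping[str, str],
    n_perm: int = 10000,
    seed: int = 0,
    _draws: Optional[np.ndarray] = None,
) -> PermutationResult:
    """Permutation p-value for excess sharing of ``focal`` with ``source``.

    ``neighbor_pool`` lists the focal's geographic-neighbor populations whose
    individuals are pooled; it must contain neither the focal nor the source.
    """
    if focal in neighbor_pool:
        raise ConfigError("focal population must not be in the neighbor pool")
    if source in neighbor_pool:
        raise ConfigError("source population must not be in the neighbor pool")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is %.3g",
                       n_perm, 1.0 / max(n_perm, 1))
    focal_inds = _population_individuals(sample_map, focal)
    source_n = len(_population_individuals(sample_map, source))
    pool_inds = [s for p in neighbor_pool
                 for s in _population_individuals(sample_map, p)]
    if len(pool_inds) < len(focal_inds):
        raise ConfigError(
            f"pooled neighbors ({len(pool_inds)}) smaller than focal sample "
            f"({len(focal_inds)})"
        )
    n_f = len(focal_inds)
    denom = n_f * source_n
    observed = float(
        _per_individual_totals(segments, source, bin_, focal_inds).sum() / denom
    )
    pool_totals = _per_individual_totals(segments, source, bin_, pool_inds)
    rng = np.random.default_rng(seed)
    draws = _draws if _draws is not None else _permutation_draws(
        rng, n_perm, len(pool_inds), n_f
    )
    permuted = pool_totals[draws].sum(axis=1) / denom
    tol = 1e-9 * max(1.0, abs(observed))
    n_geq = int(np.sum(permuted >= observed - tol))
    return PermutationResult(
        focal_id=focal,
        source_id=source,
        bin=bin_,
        observed_cM=observed,
        n_perm=n_perm,
        n_geq=n_geq,
        p_value=n_geq / n_perm,
        min_p=1.0 / n_perm,
        seed=seed,
    )


def permtest_suite(
    segments: IBDSegmentTable,
    pops: PopulationTable,
    targets: Sequence[Tuple[str, Sequence[str], Sequence[LengthBin]]],
    sample_map: Mapping[str, str],
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.01,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Run the permutation test over ``(focal, sources, bins)`` targets.

    The pooled neighbors come from the focal's neighbor set in ``pops`` (any
    listed source is excluded from the pool).  The same permutation draws are
    reused across sources and bins within one focal so that the per-focal
    count of sources significant at ``p <= alpha`` is internally consistent.
    A failing single test is logged and skipped.
    """
    rows = []
    counts: Dict[str, int] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(targets))
    for (focal, sources, bins), ss in zip(targets, seeds):
        counts.setdefault(focal, 0)
        pool = [p for p in pops.neighbors(focal) if p not in set(sources)]
        rng = np.random.default_rng(ss)
        run_seed = int(rng.integers(2**31 - 1))
        draws = None
        sig_sources = set()
        for source in sources:
            for bin_ in bins:
                try:
                    if draws is None:
                        focal_inds = _population_individuals(sample_map, focal)
                        pool_inds = [s for p in pool
                                     for s in _population_individuals(sample_map, p)]
                        if len(pool_inds) < len(focal_inds):
                            raise ConfigError(
                                f"pool smaller than focal sample for {focal!r}"
                            )
                        draws = _permutation_draws(
                            np.random.default_rng(run_seed), n_perm,
                            len(pool_inds), len(focal_inds),
                        )
                    res = excess_sharing_pvalue(
                        segments, focal, source, pool, bin_, sample_map,
                        n_perm=n_perm, seed=run_seed, _draws=draws,
                    )
                except ConfigError as exc:
                    logger.warning("test (%s vs %s, %s) skipped: %s",
                                   focal, source, bin_, exc)
                    continue
                rows.append(res.to_frame().iloc[0])
                if res.p_value <= alpha:
                    sig_sources.add(source)
        counts[focal] = len(sig_sources)
    table = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=["focal", "source", "bin", "observed_cM", "n_perm", "n_geq",
                 "p_value", "min_p"]
    )
    summary = pd.Series(counts, name=f"n_sources_p_le_{alpha:g}")
    return table, summary
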