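"""The subtraction-accumulation scan.

For each focal population, the ordered vector of its IBD sharing with every
reference population is compared with the corresponding vector of its pooled
geographic neighbors.  Element-wise differences are summed across focal
populations; a reference that shows a *correlated* excess toward all focal
populations accumulates a large sum, flagged when it exceeds the configured
sample quantile (default 0.90).  A randomization null replaces each focal
population by one of its own neighbors and re-runs the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sharing_stats import LengthBin, SharingMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    focal_ids: List[str]
    neighbor_sets: Dict[str, List[str]]
    bin: Optional[LengthBin] = None  # default: first bin of the matrix
    reference_ids: Optional[List[str]] = None  # default: all non-focal populations
    quantile: float = 0.90
    n_null_replicates: int = 10
    seed: int = 0
    pooled: bool = True  # pooled-individual neighbor vector (False: average of rows)

    def resolved_references(self, S: SharingMatrix) -> List[str]:
        if self.reference_ids is not None:
            refs = list(self.reference_ids)
        else:
            refs = [p for p in S.pop_ids if p not in set(self.focal_ids)]
        overlap = set(refs) & set(self.focal_ids)
        if overlap:
            raise ConfigError(f"focal and reference sets overlap: {sorted(overlap)}")
        return refs

    def cleaned_neighbor_sets(self) -> Dict[str, List[str]]:
        """Neighbor sets with any focal population removed (with a warning):
        a focal inside another focal's neighbor set would subtract the very
        signal the scan accumulates."""
        focal = set(self.focal_ids)
        out = {}
        for f in self.focal_ids:
            ns = list(self.neighbor_sets.get(f, []))
            clean = [n for n in ns if n not in focal]
            if len(clean) != len(ns):
                logger.warning("removed focal population(s) from neighbor set of %s", f)
            if not clean:
                raise ConfigError(f"neighbor set of {f!r} is empty")
            out[f] = clean
        return out


@dataclass
class AccumulationResult:
    reference_ids: List[str]
    accumulated: np.ndarray  # A_ref, same order as reference_ids
    threshold: float
    flagged: List[str]
    per_focal: pd.DataFrame  # focal x reference difference vectors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference": self.reference_ids,
                "accumulated_cM": self.accumulated,
                "threshold_cM": self.threshold,
                "flagged": [r in set(self.flagged) for r in self.reference_ids],
            }
        )


def sharing_vector(
    S: SharingMatrix,
    group,
    references: Sequence[str],
    bin_: Optional[LengthBin] = None,
    pooled: bool = True,
) -> np.ndarray:
    """Ordered vector of sharing values of ``group`` with each reference.

    ``group`` is a population id or a set of ids (a pooled geographic-neighbor
    set).  For a set, the pooled statistic treats the member populations'
    individuals as one super-population: total segment length between the pool
    and the reference divided by the number of distinct cross pairs.  That
    recombination is computed exactly from the sharing matrix and the
    per-population sample sizes.  Self-comparisons (reference inside the
    group, or reference equal to a singleton group) are included.
    """
    if not references:
        raise ConfigError("empty reference list")
    b = S.bin_index(bin_) if bin_ is not None else 0
    if isinstance(group, str):
        group = [group]
    group = list(group)
    gidx = [S.index(p) for p in group]
    n = S.n.astype(float)
    n_pool = float(n[gidx].sum())
    out = np.empty(len(references))
    for k, ref in enumerate(references):
        r = S.index(ref)
        if not pooled:
            out[k] = float(np.mean(S.values[gidx, r, b]))
            continue
        inside = ref in group
        total = 0.0
        for gi in gidx:
            if gi == r:
                total += S.values[r, r, b] * n[r] * (n[r] - 1) / 2.0
            else:
                total += S.values[gi, r, b] * n[gi] * n[r]
        overlap = n[r] if inside else 0.0
        pairs = n_pool * n[r] - overlap - overlap * (overlap - 1) / 2.0
        out[k] = total / pairs
    return out


def flag_quantile(values: np.ndarray, q: float = 0.90):
    """Threshold at the linear-interpolation (type-7) sample quantile; flag
    values strictly above it (ties do not flag)."""
    values = np.asarray(values, float)
    if values.size < 5:
        raise ConfigError("need at least 5 accumulated values for a quantile")
    threshold = float(np.quantile(values, q))
    flagged = np.flatnonzero(values > threshold)
    return threshold, flagged


def subtract_accumulate(S: SharingMatrix, config: ScanConfig) -> AccumulationResult:
    """Run the subtraction-accumulation scan.

    For each focal f: ``diff_f = vector(f) - vector(neighbors(f))``;
    ``A_ref = sum_f diff_f[ref]``; references with ``A_ref`` above the
    q-quantile of all accumulated values are flagged.
    """
    refs = config.resolved_references(S)
    if len(refs) < 5:
        raise ConfigError(f"only {len(refs)} references; quantile flagging needs >= 5")
    neighbor_sets = config.cleaned_neighbor_sets()
    diffs = {}
    for f in config.focal_ids:
        vf = sharing_vector(S, f, refs, config.bin, pooled=config.pooled)
        vn = sharing_vector(S, neighbor_sets[f], refs, config.bin,
                            pooled=config.pooled)
        diffs[f] = vf - vn
    per_focal = pd.DataFrame(diffs, index=refs).T
    accumulated = per_focal.to_numpy().sum(axis=0)
    threshold, flag_idx = flag_quantile(accumulated, config.quantile)
    flagged = [refs[i] for i in flag_idx]
    return AccumulationResult(refs, accumulated, threshold, flagged, per_focal)


def null_scan_replicates(
    S: SharingMatrix, config: ScanConfig
) -> List[AccumulationResult]:
    """Randomization null: per replicate, each focal population is replaced by
    one neighbor drawn from its own set (the rest of the set becomes the
    pseudo-focal's neighbors) and the scan is re-run.  Replicate draws are
    derived deterministically from the master seed.  Focal populations whose
    neighbor set cannot be split (size 1) are skipped with a warning.
    """
    neighbor_sets = config.cleaned_neighbor_sets()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_null_replicates)
    results = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        pseudo_focal, pseudo_sets = [], {}
        for f in config.focal_ids:
            ns = neighbor_sets[f]
            if len(ns) < 2:
                logger.warning("neighbor set of %s has size 1; skipped in null", f)
                continue
            pick = ns[rng.integers(len(ns))]
            rest = [p for p in ns if p != pick]
            pseudo_focal.append(pick)
            pseudo_sets[pick] = rest
        rep_config = ScanConfig(
            focal_ids=pseudo_focal,
            neighbor_sets=pseudo_sets,
            bin=config.bin,
            reference_ids=(
                list(config.reference_ids)
                if config.reference_ids is not None
                else [p for p in S.pop_ids if p not in set(config.focal_ids)]
            ),
            quantile=config.quantile,
            pooled=config.pooled,
        )
        # the pseudo-focal populations sit inside the reference list; keep the
        # reference census identical to the focal scan so flags are comparable
        rep_config.reference_ids = [
            p for p in rep_config.reference_ids if p not in set(pseudo_focal)
        ]
        results.append(subtract_accumulate(S, rep_config))
    return results


def flag_frequency(replicates: Sequence[AccumulationResult]) -> pd.Series:
    """Fraction of replicates in which each reference was flagged."""
    counts: Dict[str, int] = {}
    seen: Dict[str, int] = {}
    for rep in replicates:
        for ref in rep.reference_ids:
            seen[ref] = seen.get(ref, 0) + 1
        for ref in rep.flagged:
            counts[ref] = counts.get(ref, 0) + 1
    return pd.Series(
        {ref: counts.get(ref, 0) / seen[ref] for ref in seen}, name="flag_frequency"
    )
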