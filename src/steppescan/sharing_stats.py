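"""Binned IBD-sharing statistics and the distance-decay correlation analysis.

The core statistic is the *IBD sharing statistic*: for a pair of populations
and a segment-length bin, the total cM of IBD segments in that bin divided by
the number of individual pairs, i.e. an average per-pair sharing in cM.  IBD
sharing between populations decays roughly exponentially with geographic
distance, so ``-ln(S)`` is approximately linear in distance; the decay
analysis correlates the two after max-standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import IBDSegmentTable, PopulationTable
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True, order=True)
class LengthBin:
    """Half-open segment-length bin ``[lower_cM, upper_cM)``."""

    lower_cM: float
    upper_cM: float

    def __post_init__(self) -> None:
        if not self.lower_cM < self.upper_cM:
            raise ConfigError(f"invalid bin [{self.lower_cM}, {self.upper_cM})")

    def __contains__(self, length_cM: float) -> bool:
        return self.lower_cM <= length_cM < self.upper_cM

    def __str__(self) -> str:
        return f"{self.lower_cM:g}-{self.upper_cM:g}"


def default_bins() -> List[LengthBin]:
    """The standard segment-length ladder: 1-2, 2-3, 3-4, 4-5, 5-6 cM."""
    return [LengthBin(float(lo), float(lo + 1)) for lo in range(1, 6)]


def _check_bins(bins: Sequence[LengthBin]) -> List[LengthBin]:
    bins = sorted(bins)
    for prev, cur in zip(bins, bins[1:]):
        if cur.lower_cM < prev.upper_cM:
            raise ConfigError(f"overlapping bins {prev} and {cur}")
    return list(bins)


def bin_segments(segments: IBDSegmentTable, bins: Sequence[LengthBin]) -> pd.DataFrame:
    """Annotate segments with their length-bin index; unbinned segments are
    dropped (count logged and stored in ``.attrs['n_unbinned']``)."""
    bins = _check_bins(bins)
    frame = segments.frame.copy()
    lengths = frame["length_cM"].to_numpy(float)
    idx = np.full(len(frame), -1)
    for b, bin_ in enumerate(bins):
        idx[(lengths >= bin_.lower_cM) & (lengths < bin_.upper_cM)] = b
    n_unbinned = int((idx < 0).sum())
    if n_unbinned:
        logger.info("dropped %d segments outside the bin ladder", n_unbinned)
    frame = frame[idx >= 0].assign(bin_index=idx[idx >= 0])
    frame = frame.reset_index(drop=True)
    frame.attrs["n_unbinned"] = n_unbinned
    return frame


@dataclass
class SharingMatrix:
    """Population-pair x length-bin average IBD sharing in cM per pair.

    ``values[i, j, b]`` is symmetric in ``(i, j)``; the diagonal uses unordered
    within-population pairs ``n_i (n_i - 1) / 2`` as denominator, off-diagonal
    entries use ``n_i n_j``.  ``n`` holds per-population sample sizes.
    """

    pop_ids: List[str]
    bins: List[LengthBin]
    values: np.ndarray  # (P, P, B)
    n: np.ndarray  # (P,) individuals per population

    def __post_init__(self) -> None:
        P, B = len(self.pop_ids), len(self.bins)
        self.values = np.asarray(self.values, float)
        self.n = np.asarray(self.n, int)
        if self.values.shape != (P, P, B):
            raise FormatError("sharing matrix shape mismatch")
        if not np.allclose(self.values, self.values.transpose(1, 0, 2)):
            raise FormatError("sharing matrix not symmetric")
        if (self.values < 0).any():
            raise FormatError("negative sharing value")

    def index(self, population_id: str) -> int:
        return self.pop_ids.index(population_id)

    def bin_index(self, bin_: LengthBin) -> int:
        return self.bins.index(bin_)

    def value(self, pop_a: str, pop_b: str, bin_: LengthBin) -> float:
        return float(
            self.values[self.index(pop_a), self.index(pop_b), self.bin_index(bin_)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (upper triangle incl. diagonal), deterministic order."""
        rows = []
        for i, a in enumerate(self.pop_ids):
            for j in range(i, len(self.pop_ids)):
                for b, bin_ in enumerate(self.bins):
                    rows.append(
                        (a, self.pop_ids[j], bin_.lower_cM, bin_.upper_cM,
                         self.values[i, j, b], self.n[i], self.n[j])
                    )
        return pd.DataFrame(
            rows,
            columns=["pop_a", "pop_b", "bin_lower_cM", "bin_upper_cM",
                     "sharing_cM", "n_a", "n_b"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SharingMatrix":
        pops = list(dict.fromkeys(frame["pop_a"]).keys())
        for p in frame["pop_b"]:
            if p not in pops:
                pops.append(p)
        bins = sorted(
            {LengthBin(lo, up)
             for lo, up in zip(frame["bin_lower_cM"], frame["bin_upper_cM"])}
        )
        P, B = len(pops), len(bins)
        values = np.zeros((P, P, B))
        n = np.zeros(P, int)
        pidx = {p: i for i, p in enumerate(pops)}
        bidx = {b: k for k, b in enumerate(bins)}
        for row in frame.itertuples(index=False):
            i, j = pidx[row.pop_a], pidx[row.pop_b]
            b = bidx[LengthBin(row.bin_lower_cM, row.bin_upper_cM)]
            values[i, j, b] = values[j, i, b] = row.sharing_cM
            n[i], n[j] = row.n_a, row.n_b
        return cls(pops, bins, values, n)


def sharing_matrix(
    segments: IBDSegmentTable,
    pops: PopulationTable,
    bins: Sequence[LengthBin] | None = None,
    sample_sizes=None,
) -> SharingMatrix:
    """Compute the binned average-sharing matrix.

    ``sample_sizes`` maps population id to its number of sampled individuals;
    it is required because individuals that share no segment still count in
    the per-pair normalization.
    """
    bins = _check_bins(bins if bins is not None else default_bins())
    if sample_sizes is None:
        raise ConfigError("sharing_matrix requires per-population sample_sizes")
    pop_ids = pops.population_ids
    pidx = {p: i for i, p in enumerate(pop_ids)}
    P, B = len(pop_ids), len(bins)
    n = np.array([int(sample_sizes[p]) for p in pop_ids])

    binned = bin_segments(segments, bins)
    unknown = set(binned["population_a"]) | set(binned["population_b"])
    unknown -= set(pop_ids)
    if unknown:
        raise FormatError(f"segment population not in table: {sorted(unknown)[0]!r}")

    totals = np.zeros((P, P, B))
    if len(binned):
        ia = binned["population_a"].map(pidx).to_numpy()
        ib = binned["population_b"].map(pidx).to_numpy()
        lo = np.minimum(ia, ib)
        hi = np.maximum(ia, ib)
        np.add.at(totals, (lo, hi, binned["bin_index"].to_numpy()),
                  binned["length_cM"].to_numpy(float))
        iu = np.triu_indices(P, 1)
        totals[iu[1], iu[0], :] = totals[iu[0], iu[1], :]

    pair_counts = np.outer(n, n).astype(float)
    diag = n * (n - 1) / 2.0
    for i in np.flatnonzero(diag == 0):
        if totals[i, i].sum() > 0:
            raise ConfigError(
                f"population {pop_ids[i]!r} has n < 2 but within-population segments"
            )
    np.fill_diagonal(pair_counts, np.where(diag > 0, diag, np.inf))
    values = totals / pair_counts[:, :, None]
    return SharingMatrix(pop_ids, bins, values, n)


# ---------------------------------------------------------------------------
# Distances and the decay correlation
# ---------------------------------------------------------------------------

def geodesic_matrix(pops: PopulationTable) -> pd.DataFrame:
    """Great-circle distance matrix in km (haversine, R = 6371.0 km)."""
    coords = np.radians(pops.coordinates())
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    ids = pops.population_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def max_standardize(dist: pd.DataFrame) -> pd.DataFrame:
    """Divide a distance matrix by its largest finite entry."""
    arr = dist.to_numpy(float)
    finite = arr[np.isfinite(arr)]
    m = np.nanmax(finite) if finite.size else np.nan
    if not np.isfinite(m) or m == 0:
        raise ConfigError("cannot max-standardize: no positive finite entries")
    return dist / m


def sharing_distance_transform(
    S: SharingMatrix,
    bin_: LengthBin | None = None,
    pooled: bool = False,
    standardize: bool = True,
) -> pd.DataFrame:
    """Convert sharing into an IBD sharing distance, ``-ln(S)``.

    With ``pooled=True`` the 1-4 cM ladder bins are summed before the
    transform; otherwise ``bin_`` selects one bin (default: first).  Pairs
    with zero sharing are masked (NaN) with a logged count rather than mapped
    to infinity.  When ``standardize`` is set, the matrix is divided by its
    own maximum finite entry.
    """
    if pooled:
        sel = [b for b, bn in enumerate(S.bins) if bn.upper_cM <= 4.0 + 1e-9]
        if not sel:
            sel = list(range(len(S.bins)))
        vals = S.values[:, :, sel].sum(axis=2)
    else:
        b = S.bin_index(bin_) if bin_ is not None else 0
        vals = S.values[:, :, b]
    if not (vals > 0).any():
        raise ConfigError("all sharing values are zero; nothing to correlate")
    n_masked = int((vals == 0).sum())
    if n_masked:
        logger.info("masked %d zero-sharing population pairs", n_masked)
    with np.errstate(divide="ignore"):
        dist = np.where(vals > 0, -np.log(np.where(vals > 0, vals, 1.0)), np.nan)
    out = pd.DataFrame(dist, index=S.pop_ids, columns=S.pop_ids)
    if standardize:
        out = max_standardize(out)
    return out


@dataclass(frozen=True)
class DecayCorrelation:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int


def decay_correlation(ibd_dist: pd.DataFrame, geo_dist: pd.DataFrame) -> DecayCorrelation:
    """Pearson correlation between two distance matrices over the off-diagonal
    upper triangle, with Fisher-z 95% CI and two-sided p-value.

    Masked (NaN) pairs are removed pairwise.  The p-value ignores the
    non-independence of matrix entries and is nominal.
    """
    if list(ibd_dist.index) != list(geo_dist.index):
        geo_dist = geo_dist.loc[ibd_dist.index, ibd_dist.columns]
    iu = np.triu_indices(len(ibd_dist), 1)
    x = ibd_dist.to_numpy(float)[iu]
    y = geo_dist.to_numpy(float)[iu]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ConfigError(f"only {x.size} unmasked pairs; need at least 3")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if abs(r) >= 1.0 or n <= 3:
        lo = hi = float(r)
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = stats.norm.ppf(0.975)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return DecayCorrelation(float(r), float(lo), float(hi), float(p), int(n))
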