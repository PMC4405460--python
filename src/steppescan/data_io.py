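"""Readers, writers and validated in-memory containers for every on-disk format
the pipeline touches.

All tabular dialects are tab-delimited UTF-8 with a header row, ``.`` as the
decimal separator and no thousands separators.  Map coordinates are in cM on a
per-chromosome scale and segment intervals are half-open ``[start_cM, end_cM)``
so that abutting segments never double-count.  The missing-dosage sentinel is
``-1`` in the matrix dialect and ``./.`` in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MISSING_DOSAGE = -1
_ALLOWED_DOSAGES = frozenset({-1, 0, 1, 2})


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------

@dataclass
class PopulationTable:
    """Population ids, coordinates, group labels and geographic-neighbor sets.

    ``frame`` holds columns ``population_id``, ``latitude``, ``longitude`` and
    ``group``; ``neighbor_sets`` maps a population id to the ids of its
    geographic neighbors (possibly empty, never containing the population
    itself).
    """

    frame: pd.DataFrame
    neighbor_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"population_id", "latitude", "longitude"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"population table missing columns: {sorted(missing)}")
        if "group" not in self.frame.columns:
            self.frame = self.frame.assign(group="reference")
        ids = self.frame["population_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate population_id: {dup.iloc[0]!r}")
        lat = self.frame["latitude"].to_numpy(float)
        lon = self.frame["longitude"].to_numpy(float)
        bad_lat = np.flatnonzero((lat < -90) | (lat > 90) | ~np.isfinite(lat))
        if bad_lat.size:
            raise FormatError(
                f"latitude out of range [-90, 90] at row {bad_lat[0] + 2}"
            )
        bad_lon = np.flatnonzero((lon < -180) | (lon > 180) | ~np.isfinite(lon))
        if bad_lon.size:
            raise FormatError(
                f"longitude out of range [-180, 180] at row {bad_lon[0] + 2}"
            )
        known = set(ids)
        for pid, neigh in self.neighbor_sets.items():
            if pid not in known:
                raise FormatError(f"neighbor_set owner {pid!r} not in table")
            for n in neigh:
                if n not in known:
                    raise FormatError(f"unknown neighbor population_id: {n!r}")
                if n == pid:
                    raise FormatError(f"population {pid!r} listed as its own neighbor")

    # -- convenience -------------------------------------------------------

    @property
    def population_ids(self) -> List[str]:
        return list(self.frame["population_id"].astype(str))

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, population_id: str) -> bool:
        return population_id in set(self.frame["population_id"].astype(str))

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (latitude, longitude) in degrees, table order."""
        return self.frame[["latitude", "longitude"]].to_numpy(float)

    def neighbors(self, population_id: str) -> List[str]:
        return list(self.neighbor_sets.get(population_id, []))

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        neighbor_sets: Mapping[str, Sequence[str]] | None = None,
    ) -> "PopulationTable":
        """Build from ``(population_id, latitude, longitude, group)`` tuples."""
        frame = pd.DataFrame(
            records, columns=["population_id", "latitude", "longitude", "group"]
        )
        ns = {k: list(v) for k, v in (neighbor_sets or {}).items()}
        return cls(frame, ns)


def read_population_table(path) -> PopulationTable:
    """Read a tab-delimited population table.

    Requires columns ``population_id``, ``latitude``, ``longitude``; optional
    ``group`` and ``neighbor_set`` (comma-separated ids, empty when absent).
    """
    df = pd.read_csv(path, sep="\t", dtype={"population_id": str})
    required = {"population_id", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    neighbor_sets: dict = {}
    if "neighbor_set" in df.columns:
        for pid, raw in zip(df["population_id"], df["neighbor_set"]):
            if pd.isna(raw) or str(raw).strip() == "":
                neighbor_sets[str(pid)] = []
            else:
                neighbor_sets[str(pid)] = [
                    s.strip() for s in str(raw).split(",") if s.strip()
                ]
        df = df.drop(columns=["neighbor_set"])
    return PopulationTable(df, neighbor_sets)


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = [
    "sample_a",
    "sample_b",
    "population_a",
    "population_b",
    "chromosome",
    "start_cM",
    "end_cM",
    "length_cM",
]


@dataclass
class IBDSegmentTable:
    """Per-pair IBD segments with cM lengths.

    Pairs are stored in canonical (lexicographic) sample order and every
    segment satisfies ``length_cM == end_cM - start_cM > 0``.
    """

    frame: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = set(SEGMENT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"segment table missing columns: {sorted(missing)}")
        f = self.frame
        if len(f):
            length = f["length_cM"].to_numpy(float)
            if not (length > 0).all():
                raise FormatError("non-positive segment length")
            resid = np.abs(
                f["end_cM"].to_numpy(float) - f["start_cM"].to_numpy(float) - length
            )
            if resid.max() > 1e-9:
                raise FormatError("length_cM inconsistent with end_cM - start_cM")
            a = f["sample_a"].astype(str).to_numpy()
            b = f["sample_b"].astype(str).to_numpy()
            if (a == b).any():
                raise FormatError("segment with sample_a == sample_b")
            if (a > b).any():
                raise FormatError("pairs not in canonical (lexicographic) order")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_dropped: int = 0) -> "IBDSegmentTable":
        """Canonicalize pair order and (re)compute ``length_cM``."""
        f = frame.copy()
        f["start_cM"] = f["start_cM"].astype(float)
        f["end_cM"] = f["end_cM"].astype(float)
        f["length_cM"] = f["end_cM"] - f["start_cM"]
        a = f["sample_a"].astype(str).to_numpy()
        b = f["sample_b"].astype(str).to_numpy()
        swap = a > b
        if swap.any():
            pa = f["population_a"].to_numpy().copy()
            pb = f["population_b"].to_numpy().copy()
            f.loc[swap, "sample_a"], f.loc[swap, "sample_b"] = b[swap], a[swap]
            f.loc[swap, "population_a"] = pb[swap]
            f.loc[swap, "population_b"] = pa[swap]
        return cls(f[SEGMENT_COLUMNS].reset_index(drop=True), n_dropped)


def read_ibd_segments(
    path,
    pop_table: PopulationTable,
    sample_map: Mapping[str, str],
) -> IBDSegmentTable:
    """Read a post-processed IBD segment table (fastIBD-style output).

    Expects columns ``sample_a``, ``sample_b``, ``chromosome``, ``start_cM``,
    ``end_cM``.  Population labels are attached from ``sample_map``; segments
    whose samples both map to populations absent from ``pop_table`` are dropped
    with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    required = {"sample_a", "sample_b", "chromosome", "start_cM", "end_cM"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = np.flatnonzero(
        df["end_cM"].to_numpy(float) <= df["start_cM"].to_numpy(float)
    )
    if bad.size:
        raise FormatError(f"{path}: end_cM <= start_cM at row {bad[0] + 2}")
    for col in ("sample_a", "sample_b"):
        unknown = set(df[col]) - set(sample_map)
        if unknown:
            raise FormatError(f"sample missing from sample map: {sorted(unknown)[0]!r}")
    df["population_a"] = df["sample_a"].map(sample_map)
    df["population_b"] = df["sample_b"].map(sample_map)
    known = set(pop_table.population_ids)
    keep = df["population_a"].isin(known) | df["population_b"].isin(known)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d segments with both samples outside the population table",
                    n_dropped)
        df = df[keep]
    return IBDSegmentTable.from_frame(df, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome monotone bp -> cM mapping, linear between anchors."""

    anchors: Mapping[str, tuple]  # chromosome -> (bp ndarray, cM ndarray)

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, float)
            cm = np.asarray(cm, float)
            order = np.argsort(bp, kind="stable")
            if np.any(np.diff(cm[order]) < 0):
                raise FormatError(f"genetic map not monotone on chromosome {chrom}")

    def interpolate(self, chromosome: str, bp) -> np.ndarray:
        """cM positions for physical positions ``bp`` on one chromosome."""
        if str(chromosome) not in self.anchors:
            raise FormatError(f"no genetic-map anchors for chromosome {chromosome}")
        abp, acm = self.anchors[str(chromosome)]
        abp = np.asarray(abp, float)
        acm = np.asarray(acm, float)
        order = np.argsort(abp, kind="stable")
        return np.interp(np.asarray(bp, float), abp[order], acm[order])

    @classmethod
    def from_plink(cls, path) -> "GeneticMap":
        """Read a PLINK-style ``.map`` file (chromosome, id, cM, bp)."""
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chromosome", "snp_id", "cM", "bp"],
            dtype={"chromosome": str},
        )
        anchors = {}
        for chrom, sub in df.groupby("chromosome", sort=False):
            anchors[str(chrom)] = (
                sub["bp"].to_numpy(float),
                sub["cM"].to_numpy(float),
            )
        return cls(anchors)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Diploid dosages with genetic-map positions and population labels.

    ``dosages`` has shape ``(n_samples, n_snps)`` with values in
    ``{0, 1, 2, -1}`` (-1 = missing).  ``snps`` holds per-SNP metadata
    (``snp_id``, ``chromosome``, ``pos_bp``, ``pos_cM``); genetic positions are
    non-decreasing within each chromosome.
    """

    samples: List[str]
    sample_populations: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_populations = np.asarray(self.sample_populations, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise FormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.dosages.size:
            vals = np.unique(self.dosages)
            bad = set(vals.tolist()) - _ALLOWED_DOSAGES
            if bad:
                r, c = np.argwhere(~np.isin(self.dosages, list(_ALLOWED_DOSAGES)))[0]
                raise FormatError(
                    f"dosage {self.dosages[r, c]} not in {{0,1,2,-1}} "
                    f"(sample {self.samples[r]!r}, snp {self.snps['snp_id'].iloc[c]!r})"
                )
        if len(self.snps) and "pos_cM" in self.snps.columns:
            for chrom, sub in self.snps.groupby("chromosome", sort=False):
                cm = sub["pos_cM"].to_numpy(float)
                cm = cm[np.isfinite(cm)]
                if cm.size and np.any(np.diff(cm) < 0):
                    raise FormatError(
                        f"pos_cM decreasing within chromosome {chrom}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.sample_populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} absent from dataset")
        return idx

    def populations(self) -> List[str]:
        seen: List[str] = []
        for p in self.sample_populations:
            if p not in seen:
                seen.append(p)
        return seen


def read_genotypes(
    path,
    format: str = "vcf",
    genetic_map: GeneticMap | None = None,
    sample_map: Mapping[str, str] | None = None,
    snp_table=None,
) -> GenotypeDataset:
    """Read genotypes from a VCF (GT field, biallelic SNPs only) or a dosage
    matrix with a sidecar SNP table.

    Multi-allelic/non-SNP VCF records are skipped with a logged count.  cM
    positions are attached from ``genetic_map`` by linear interpolation; a SNP
    on a chromosome with no map anchors is an error.
    """
    if format == "vcf":
        return _read_vcf(path, genetic_map, sample_map)
    if format == "matrix":
        if snp_table is None:
            raise FormatError("matrix format requires a sidecar snp_table path")
        return _read_matrix(path, snp_table, genetic_map, sample_map)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path, genetic_map, sample_map) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING_DOSAGE
        dosages.append(gt)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS))
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP VCF records", n_skipped)
    snps = pd.DataFrame(rows, columns=["snp_id", "chromosome", "pos_bp"])
    snps["pos_cM"] = _positions_cm(snps, genetic_map)
    dosage_matrix = (
        np.stack(dosages, axis=1) if dosages else np.zeros((len(samples), 0), np.int16)
    )
    pops = _attach_populations(samples, sample_map)
    return GenotypeDataset(samples, pops, snps, dosage_matrix)


def _read_matrix(path, snp_table, genetic_map, sample_map) -> GenotypeDataset:
    dosage_df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in dosage_df.columns:
        raise FormatError(f"{path}: first column must be named 'sample'")
    samples = list(dosage_df["sample"])
    dosages = dosage_df.drop(columns=["sample"]).to_numpy()
    bad = ~np.isin(dosages, list(_ALLOWED_DOSAGES))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: dosage {dosages[r, c]} not in {{0,1,2,-1}} at "
            f"sample {samples[r]!r}, column {dosage_df.columns[c + 1]!r}"
        )
    snps = pd.read_csv(snp_table, sep="\t", dtype={"chromosome": str, "snp_id": str})
    required = {"snp_id", "chromosome", "pos_bp"}
    missing = required - set(snps.columns)
    if missing:
        raise FormatError(f"{snp_table}: missing columns {sorted(missing)}")
    order = [c for c in dosage_df.columns if c != "sample"]
    snps = snps.set_index("snp_id").loc[order].reset_index()
    if "pos_cM" not in snps.columns:
        snps["pos_cM"] = _positions_cm(snps, genetic_map)
    pops = _attach_populations(samples, sample_map)
    return GenotypeDataset(samples, pops, snps, dosages.astype(np.int16))


def _positions_cm(snps: pd.DataFrame, genetic_map: GeneticMap | None) -> np.ndarray:
    if genetic_map is None:
        return np.full(len(snps), np.nan)
    out = np.empty(len(snps))
    for chrom, sub in snps.groupby("chromosome", sort=False):
        out[sub.index] = genetic_map.interpolate(chrom, sub["pos_bp"].to_numpy(float))
    return out


def _attach_populations(samples, sample_map) -> np.ndarray:
    if sample_map is None:
        return np.asarray([""] * len(samples), dtype=object)
    missing = [s for s in samples if s not in sample_map]
    if missing:
        raise FormatError(f"sample missing from sample map: {missing[0]!r}")
    return np.asarray([sample_map[s] for s in samples], dtype=object)


def read_sample_map(path) -> dict:
    """Read the required two-column (sample, population) mapping file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample, population)")
    cols = list(df.columns[:2])
    dup = df[cols[0]][df[cols[0]].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample in sample map: {dup.iloc[0]!r}")
    return dict(zip(df[cols[0]], df[cols[1]]))


# ---------------------------------------------------------------------------
# Generic result-table output
# ---------------------------------------------------------------------------

def write_table(records, path) -> None:
    """Write a result table as TSV with a deterministic layout.

    Accepts a DataFrame or any object exposing ``to_frame()``.  Floats are
    rendered with 10 significant digits so that read-back equals the written
    values; an empty result set produces a header-only file.
    """
    frame = records.to_frame() if hasattr(records, "to_frame") else records
    if not isinstance(frame, pd.DataFrame):
        raise FormatError(f"cannot write object of type {type(records).__name__}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
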