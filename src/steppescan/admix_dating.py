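"""Admixture-date estimation.

Three routes to the number of generations ``g`` since a one-pulse admixture:

* analytic conversions — the expected single-path IBD tract length
  ``100 / (2 g)`` cM, years <-> generations at 30 years per generation, and
  the calendar anchor ``year = 2000 - 30 g`` (negative = BCE);
* weighted-LD decay — admixture LD between loci at genetic distance ``d``
  Morgans decays as ``exp(-g d)``; the curve of SNP-pair covariances weighted
  by the reference allele-frequency contrast is fit with
  ``y(d) = A exp(-g d) + c``;
* ancestry-tract lengths — tracts of the minority-path ancestry are
  approximately exponential with mean ``1 / ((1 - alpha) g)`` Morgans, so the
  mean interior tract length inverts to ``g``.

A benchmark harness recomputes RMSE and bias of either estimator over a grid
of true ``g`` values on freshly simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .data_io import GenotypeDataset
from .errors import ConfigError, DatingError
from .synthetic_data import (
    AdmixtureSimConfig,
    AncestryTractSet,
    simulate_admixed_haplotypes,
)

logger = logging.getLogger(__name__)

GENERATION_TIME_YEARS = 30.0
PRESENT_YEAR_CE = 2000.0


# ---------------------------------------------------------------------------
# Analytic conversions
# ---------------------------------------------------------------------------

def expected_tract_length_cM(g: float) -> float:
    """Expected single-path IBD tract length after 2g meioses: 100/(2g) cM."""
    if g < 1:
        raise ConfigError(f"generations must be >= 1, got {g}")
    return 100.0 / (2.0 * g)


def years_to_generations(years: float, gen_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert years before present to generations (default 30 years each)."""
    if years < 0:
        raise ConfigError("years must be >= 0")
    if gen_time <= 0:
        raise ConfigError("gen_time must be > 0")
    return years / gen_time


def generations_to_calendar(
    g: float,
    gen_time: float = GENERATION_TIME_YEARS,
    present_year: float = PRESENT_YEAR_CE,
) -> float:
    """Calendar year CE of an event ``g`` generations ago; negative = BCE."""
    if g < 0:
        raise ConfigError("generations must be >= 0")
    return present_year - gen_time * g


# ---------------------------------------------------------------------------
# Weighted-LD dating
# ---------------------------------------------------------------------------

@dataclass
class WeightedLDCurve:
    """Binned weighted-LD decay curve.

    ``bin_mid_cM`` are midpoints of the retained distance bins (strictly
    increasing), ``value`` the average weighted covariance per bin and
    ``pair_count`` the SNP pairs per bin.  Per-chromosome accumulations are
    kept so the curve can be re-averaged leaving one chromosome out.
    """

    bin_mid_cM: np.ndarray
    value: np.ndarray
    pair_count: np.ndarray
    ref_pair: Tuple[str, str]
    per_chrom_sum: Dict[str, np.ndarray] = field(default_factory=dict)
    per_chrom_count: Dict[str, np.ndarray] = field(default_factory=dict)
    grid_mid_cM: Optional[np.ndarray] = None  # full bin grid, per-chrom layout

    def __post_init__(self) -> None:
        self.bin_mid_cM = np.asarray(self.bin_mid_cM, float)
        self.value = np.asarray(self.value, float)
        self.pair_count = np.asarray(self.pair_count)
        if np.any(np.diff(self.bin_mid_cM) <= 0):
            raise ConfigError("bin midpoints must be strictly increasing")
        if np.any(self.pair_count <= 0):
            raise ConfigError("retained bins must have pair_count > 0")

    def leave_out(self, chrom: str) -> "WeightedLDCurve":
        """The curve re-averaged with one chromosome left out."""
        if self.grid_mid_cM is None or chrom not in self.per_chrom_sum:
            raise ConfigError("no per-chromosome accumulations stored")
        sums = sum(v for c, v in self.per_chrom_sum.items() if c != chrom)
        counts = sum(v for c, v in self.per_chrom_count.items() if c != chrom)
        keep = counts > 0
        return WeightedLDCurve(
            self.grid_mid_cM[keep], sums[keep] / counts[keep], counts[keep],
            self.ref_pair,
        )


@dataclass
class DateEstimate:
    """Generations since admixture with uncertainty and calendar conversion."""

    g_hat: float
    ci_low: float
    ci_high: float
    method: str  # "weighted_ld" | "tracts"
    calendar_year: float = 0.0
    amplitude: Optional[float] = None  # A, weighted_ld only
    affine: Optional[float] = None  # c, weighted_ld only

    def __post_init__(self) -> None:
        if self.g_hat <= 0:
            raise DatingError(f"estimated g must be > 0, got {self.g_hat}")
        if not self.ci_low <= self.g_hat <= self.ci_high:
            raise DatingError("confidence interval does not bracket the estimate")
        self.calendar_year = generations_to_calendar(self.g_hat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "method": self.method,
            "g_hat": self.g_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "calendar_year": self.calendar_year,
            "amplitude": self.amplitude,
            "affine": self.affine,
        }])


def weighted_ld_curve(
    geno: GenotypeDataset,
    admixed: str,
    ref1: str,
    ref2: str,
    bin_width_cM: float = 0.25,
    d_min_cM: float = 0.5,
    d_max_cM: float = 30.0,
) -> WeightedLDCurve:
    """Weighted-LD decay curve for one reference pair.

    Per SNP ``s`` the weight is ``w_s = p_ref1,s - p_ref2,s``; for every
    within-chromosome SNP pair with genetic distance in
    ``[d_min_cM, d_max_cM]`` the admixed-sample dosage covariance
    ``D_st`` accumulates ``D_st * w_s * w_t`` into the distance bin; the curve
    reports bin averages.
    """
    if ref1 == ref2:
        raise ConfigError("ref1 and ref2 must differ")
    from .f3_admixture import _frequencies

    w1, _ = _frequencies(geno, ref1)
    w2, _ = _frequencies(geno, ref2)
    w = w1 - w2
    adm_idx = geno.population_indices(admixed)
    if adm_idx.size < 2:
        raise ConfigError("admixed population needs >= 2 individuals")
    cm = geno.snps["pos_cM"].to_numpy(float)
    if not np.all(np.isfinite(cm)):
        raise ConfigError("all SNPs need cM positions for the LD curve")

    edges = np.arange(d_min_cM, d_max_cM + bin_width_cM * (1 - 1e-9), bin_width_cM)
    n_bins = edges.size
    mids = edges + bin_width_cM / 2.0
    per_chrom_sum: Dict[str, np.ndarray] = {}
    per_chrom_count: Dict[str, np.ndarray] = {}
    X_all = geno.dosages[adm_idx].astype(float)
    X_all[X_all < 0] = np.nan
    for chrom, sub in geno.snps.groupby("chromosome", sort=False):
        cols = sub.index.to_numpy()
        if cols.size < 2:
            continue
        X = X_all[:, cols]
        D = _pairwise_complete_cov(X)
        Wmat = np.outer(w[cols], w[cols])
        d = np.abs(cm[cols][:, None] - cm[cols][None, :])
        iu = np.triu_indices(cols.size, 1)
        dv = d[iu]
        keep = (dv >= d_min_cM) & (dv <= d_max_cM) & np.isfinite(D[iu])
        if not keep.any():
            continue
        bidx = np.minimum(((dv[keep] - d_min_cM) // bin_width_cM).astype(int),
                          n_bins - 1)
        contrib = (D[iu] * Wmat[iu])[keep]
        per_chrom_sum[str(chrom)] = np.bincount(bidx, weights=contrib,
                                                minlength=n_bins)
        per_chrom_count[str(chrom)] = np.bincount(bidx, minlength=n_bins)

    if not per_chrom_sum:
        raise DatingError("no SNP pairs retained in the distance window")
    sums = sum(per_chrom_sum.values())
    counts = sum(per_chrom_count.values())
    keep = counts > 0
    return WeightedLDCurve(
        mids[keep], sums[keep] / counts[keep], counts[keep], (ref1, ref2),
        per_chrom_sum, per_chrom_count, grid_mid_cM=mids,
    )


def _pairwise_complete_cov(X: np.ndarray) -> np.ndarray:
    """Sample covariance of columns of ``X`` with NaN treated as missing
    (pairwise-complete)."""
    if not np.isnan(X).any():
        Xc = X - X.mean(axis=0)
        return Xc.T @ Xc / (X.shape[0] - 1)
    mask = np.isfinite(X)
    maskf = mask.astype(float)
    Xz = np.where(mask, X, 0.0)
    n = maskf.T @ maskf
    s1 = Xz.T @ maskf  # s1[i, j] = sum of x_i over rows where both observed
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (sxy - s1 * s1.T / n) / (n - 1)
    cov[n < 2] = np.nan
    return cov


def _exp_affine(d: np.ndarray, A: float, g: float, c: float) -> np.ndarray:
    return A * np.exp(-g * d) + c


def _fit_curve(d_M: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Constrained least-squares fit of ``y = A exp(-g d) + c`` (A, g > 0)."""
    span = y.max() - y.min()
    eps = max(span, abs(y).max(), 1e-30) * 1e-6
    ysh = y - y.min() + eps
    slope, intercept = np.polyfit(d_M, np.log(ysh), 1)
    g0 = max(-slope, 1.0)
    A0 = max(float(np.exp(intercept)), eps)
    c0 = float(y.min())
    best = None
    for scale in (1.0, 0.3, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                _exp_affine, d_M, y, p0=(A0, g0 * scale, c0),
                bounds=([1e-30, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((_exp_affine(d_M, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise DatingError("exponential-decay fit did not converge after restarts")
    A, g, c = best[0]
    # the decay term must actually vary within the fitted window, otherwise
    # the constrained amplitude is at (or degenerate with) the zero boundary
    scale = max(abs(y).max(), 1e-30)
    decay_span = A * (np.exp(-g * d_M.min()) - np.exp(-g * d_M.max()))
    if decay_span <= 1e-9 * scale:
        raise DatingError("no admixture LD detected (amplitude at zero boundary)")
    return float(A), float(g), float(c)


def fit_ld_decay(curve: WeightedLDCurve, min_bins: int = 8) -> DateEstimate:
    """Date admixture from the weighted-LD curve.

    Fits ``y(d) = A exp(-g d) + c`` with ``d`` in Morgans; the 95% CI comes
    from a delete-one-chromosome jackknife when per-chromosome accumulations
    are available.
    """
    if curve.bin_mid_cM.size < min_bins:
        raise ConfigError(
            f"only {curve.bin_mid_cM.size} bins retained; need >= {min_bins}"
        )
    d_M = curve.bin_mid_cM / 100.0
    A, g, c = _fit_curve(d_M, curve.value)
    chroms = [ch for ch in curve.per_chrom_sum]
    if len(chroms) >= 2:
        loo = []
        for ch in chroms:
            try:
                sub = curve.leave_out(ch)
                if sub.bin_mid_cM.size >= min_bins:
                    loo.append(_fit_curve(sub.bin_mid_cM / 100.0, sub.value)[1])
            except DatingError:
                continue
        if len(loo) >= 2:
            loo = np.asarray(loo)
            k = loo.size
            se = np.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2))
            lo, hi = g - 1.96 * se, g + 1.96 * se
        else:
            lo = hi = g
    else:
        lo = hi = g
    return DateEstimate(
        g_hat=g, ci_low=min(lo, g), ci_high=max(hi, g),
        method="weighted_ld", amplitude=A, affine=c,
    )


def date_admixture_ld(
    geno: GenotypeDataset,
    admixed: str,
    ref1: str,
    ref2: str,
    **curve_kwargs,
) -> DateEstimate:
    """Convenience: weighted-LD curve + exponential-decay fit in one call."""
    return fit_ld_decay(weighted_ld_curve(geno, admixed, ref1, ref2, **curve_kwargs))


# ---------------------------------------------------------------------------
# Tract-length dating
# ---------------------------------------------------------------------------

def date_from_tract_lengths(
    tracts: Union[AncestryTractSet, np.ndarray, Sequence[float]],
    ancestry: int = 1,
    alpha: Optional[float] = None,
    mode: str = "ancestry",
    n_bootstrap: int = 200,
    seed: int = 0,
    lengths_unit: str = "cM",
) -> DateEstimate:
    """Date admixture from tract lengths.

    ``mode="ancestry"``: ``g = 1 / (mean_length_M * (1 - alpha))`` using the
    mean interior (non-chromosome-end-censored) tract length of the chosen
    ancestry; requires the true admixture proportion ``alpha``.
    ``mode="ibd_single_path"``: ``g = 1 / (2 * mean_length_M)`` for a set of
    single-path IBD segment lengths (``lengths_unit`` applies to plain
    arrays; tract sets are always in Morgans).  The CI is a percentile
    bootstrap over tracts.
    """
    if mode not in ("ancestry", "ibd_single_path"):
        raise ConfigError(f"unknown mode {mode!r}")
    if isinstance(tracts, AncestryTractSet):
        lengths_M = tracts.lengths(ancestry, interior_only=True)
        if lengths_M.size == 0:
            raise DatingError("all tracts are chromosome-end censored")
    else:
        lengths = np.asarray(tracts, float)
        lengths_M = lengths / 100.0 if lengths_unit == "cM" else lengths
    if lengths_M.size < 30:
        raise ConfigError(f"need >= 30 tracts, got {lengths_M.size}")
    if mode == "ancestry":
        if alpha is None or not 0.0 < alpha < 1.0:
            raise ConfigError("ancestry mode requires alpha strictly in (0, 1)")
        to_g = lambda mean_len: 1.0 / (mean_len * (1.0 - alpha))
    else:
        to_g = lambda mean_len: 1.0 / (2.0 * mean_len)
    g_hat = to_g(lengths_M.mean())
    rng = np.random.default_rng(seed)
    boots = np.array([
        to_g(rng.choice(lengths_M, size=lengths_M.size, replace=True).mean())
        for _ in range(n_bootstrap)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DateEstimate(
        g_hat=float(g_hat),
        ci_low=float(min(lo, g_hat)),
        ci_high=float(max(hi, g_hat)),
        method="tracts",
    )


# ---------------------------------------------------------------------------
# Projection-based admixture proportion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionCoordinates:
    """Mean coordinates of the two parental populations (x1, x2) and the
    admixed population (x3) on one projection axis."""

    x1: float
    x2: float
    x3: float


def projection_admixture_proportion(coords: ProjectionCoordinates) -> float:
    """Admixture proportion of parental population 1:
    ``alpha = (x2 - x3) / (x2 - x1)``.  Values outside [0, 1] (admixed mean
    outside the parental span) are returned with a warning."""
    if coords.x1 == coords.x2:
        raise ConfigError("degenerate projection axis: x1 == x2")
    alpha = (coords.x2 - coords.x3) / (coords.x2 - coords.x1)
    if not 0.0 <= alpha <= 1.0:
        logger.warning("admixture proportion %.3f outside [0, 1]", alpha)
    return float(alpha)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

DEFAULT_SCENARIO_GRID = (5, 10, 20, 30, 40, 50, 60)

Estimator = Union[str, Callable[[GenotypeDataset, AncestryTractSet,
                                 AdmixtureSimConfig], float]]


@dataclass
class BenchmarkResult:
    """RMSE and bias of an estimator over simulated admixture scenarios.

    ``rmse = sqrt(mean((g_hat - g)^2))``; ``bias = (sum(g_hat) - sum(g)) / n``
    over the non-failed replicates.
    """

    scenarios: List[float]
    estimates: pd.DataFrame  # columns g_true, rep, g_hat (NaN = failed)
    rmse: float
    bias: float
    n_failed: int

    def __post_init__(self) -> None:
        if np.isfinite(self.rmse) and self.rmse + 1e-9 < abs(self.bias):
            raise DatingError("RMSE smaller than |bias|: inconsistent benchmark")


def _resolve_estimator(estimator: Estimator) -> Callable:
    if callable(estimator):
        return estimator
    if estimator == "tracts":
        return lambda geno, tracts, cfg: date_from_tract_lengths(
            tracts, ancestry=1, alpha=cfg.alpha, mode="ancestry",
            n_bootstrap=50, seed=cfg.seed,
        ).g_hat
    if estimator == "weighted_ld":
        return lambda geno, tracts, cfg: date_admixture_ld(
            geno, "admixed", "source1", "source2"
        ).g_hat
    raise ConfigError(f"unknown estimator {estimator!r}")


def benchmark_rmse_bias(
    scenarios: Sequence[float] = DEFAULT_SCENARIO_GRID,
    reps: int = 10,
    estimator: Estimator = "tracts",
    sim_config: Optional[AdmixtureSimConfig] = None,
    seed: int = 0,
) -> BenchmarkResult:
    """Simulate each scenario ``reps`` times, apply the estimator and compute
    RMSE and bias against the true generation counts.  A failing replicate is
    recorded as missing and excluded with a logged count."""
    if reps < 2:
        raise ConfigError("reps must be >= 2")
    fn = _resolve_estimator(estimator)
    seeds = np.random.SeedSequence(seed).spawn(len(scenarios) * reps)
    rows = []
    n_failed = 0
    k = 0
    for g_true in scenarios:
        for rep in range(reps):
            rep_seed = int(np.random.default_rng(seeds[k]).integers(2**31 - 1))
            k += 1
            base = sim_config or AdmixtureSimConfig(g=int(g_true))
            cfg = AdmixtureSimConfig(
                g=int(g_true),
                alpha=base.alpha,
                n_haplotypes=base.n_haplotypes,
                chromosome_lengths_M=list(base.chromosome_lengths_M),
                n_snps_per_chromosome=base.n_snps_per_chromosome,
                divergence_F=base.divergence_F,
                population_size=base.population_size,
                n_ref_individuals=base.n_ref_individuals,
                seed=rep_seed,
            )
            geno, tracts = simulate_admixed_haplotypes(cfg)
            try:
                g_hat = float(fn(geno, tracts, cfg))
            except (DatingError, ConfigError) as exc:
                logger.warning("estimator failed at g=%s rep=%d: %s",
                               g_true, rep, exc)
                g_hat = np.nan
                n_failed += 1
            rows.append((float(g_true), rep, g_hat))
    est = pd.DataFrame(rows, columns=["g_true", "rep", "g_hat"])
    ok = est.dropna(subset=["g_hat"])
    if len(ok):
        err = ok["g_hat"].to_numpy() - ok["g_true"].to_numpy()
        rmse = float(np.sqrt(np.mean(err**2)))
        bias = float(err.sum() / len(ok))
    else:
        rmse = bias = float("nan")
    return BenchmarkResult(
        scenarios=list(map(float, scenarios)),
        estimates=est,
        rmse=rmse,
        bias=bias,
        n_failed=n_failed,
    )
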