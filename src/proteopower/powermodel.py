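"""Abundance-dependent error model and proteome-wide power analysis.

Measurement error in label-free DIA quantification depends strongly on
signal intensity: the coefficient of variation (CV) of replicate
acquisitions falls as mean protein abundance rises.  This module

1. computes per-protein CVs over a chosen replicate set
   (:func:`protein_stats`),
2. fits a loess (locally weighted linear regression) curve of CV versus
   log2 mean abundance (:func:`fit_error_model`),
3. converts CV on the raw scale into a log2-scale SD via the log-normal
   identity (:func:`cv_to_sigma_log2`), and
4. propagates that SD into two-sample t-test power at a Bonferroni-
   corrected alpha, yielding power-vs-abundance curves per group size
   (:func:`power_surface`), required sample sizes (:func:`required_n`)
   and the percentage of the proteome reaching each power target per
   candidate group size (:func:`coverage_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleMetadata, ValidationError

LN2 = np.log(2.0)

#: Lower clamp (%) for fitted CV predictions.
CV_PREDICTION_FLOOR = 0.1


# ---------------------------------------------------------------------------
# Per-protein replicate statistics
# ---------------------------------------------------------------------------

@dataclass
class ProteinStats:
    """Per-protein mean abundance and CV across the replicate set."""

    table: pd.DataFrame  # columns: mean_abundance, mean_log2, cv_percent, n_replicates
    grouping: str = "all_samples"

    @property
    def mean_log2(self) -> np.ndarray:
        return self.table["mean_log2"].to_numpy()

    @property
    def cv_percent(self) -> np.ndarray:
        return self.table["cv_percent"].to_numpy()


def _cv_percent(values: np.ndarray) -> tuple[float, float]:
    """(mean, CV%) of one replicate vector (ddof=1)."""
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return m, 100.0 * sd / m


def protein_stats(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata | None = None,
    grouping: str = "all_samples",
) -> ProteinStats:
    """Compute per-protein mean abundance and CV on the raw scale.

    ``grouping`` selects the replicate set:

    * ``all_samples`` (default) — every acquisition is treated as a
      biological replicate; one CV per protein across all columns.
    * ``within_patient`` — CV per patient, then averaged over patients.
    * ``within_group`` — CV pooled within each IGHV group (SDs pooled,
      means per group), then averaged.
    """
    if matrix.scale != "raw":
        raise ValidationError("protein_stats expects a raw-scale matrix")
    if matrix.has_missing():
        raise ValidationError("protein_stats requires a complete matrix (impute first)")
    arr = matrix.to_numpy()
    if grouping == "all_samples":
        if arr.shape[1] < 2:
            raise ValidationError("need >= 2 replicates per CV cell")
        mean = arr.mean(axis=1)
        sd = arr.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        n_rep = arr.shape[1]
    elif grouping in ("within_patient", "within_group"):
        if metadata is None:
            raise ValidationError(f"grouping {grouping!r} requires metadata")
        key = "patient_id" if grouping == "within_patient" else "ighv_status"
        labels = metadata.aligned_to(matrix.sample_ids).table[key].to_numpy()
        cvs = []
        for lab in pd.unique(labels):
            cols = labels == lab
            if cols.sum() < 2:
                raise ValidationError(f"group {lab!r} has < 2 replicates")
            sub = arr[:, cols]
            cvs.append(100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1))
        cv = np.mean(np.column_stack(cvs), axis=1)
        mean = arr.mean(axis=1)
        n_rep = arr.shape[1]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    table = pd.DataFrame(
        {
            "mean_abundance": mean,
            "mean_log2": np.log2(mean),
            "cv_percent": cv,
            "n_replicates": n_rep,
        },
        index=matrix.protein_ids,
    )
    return ProteinStats(table=table, grouping=grouping)


# ---------------------------------------------------------------------------
# Loess error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Fitted CV-vs-log2-abundance curve with an interpolation contract.

    Predictions interpolate piecewise-linearly on the fitted grid and are
    clamped at the grid edges; fitted values never fall below
    ``CV_PREDICTION_FLOOR`` (%).
    """

    grid_log2: np.ndarray
    grid_cv: np.ndarray
    span: float = 0.75
    degree: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid_log2) > 0):
            raise ValidationError("error-model grid must be strictly increasing")
        if np.any(self.grid_cv <= 0):
            raise ValidationError("error-model predictions must be positive")

    def predict(self, mean_log2) -> np.ndarray | float:
        out = np.interp(np.asarray(mean_log2, dtype=float), self.grid_log2, self.grid_cv)
        return float(out) if np.isscalar(mean_log2) else out

    __call__ = predict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_log2": self.grid_log2, "cv_percent": self.grid_cv})


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 1,
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at ``x_eval``.

    At each evaluation point the ``ceil(span * n)`` nearest data points
    (in x) receive tricube weights ``(1 - (d/dmax)^3)^3`` and a degree-1
    or degree-2 polynomial is fitted by weighted least squares.  No
    robustness iterations are applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if degree not in (1, 2):
        raise ValidationError("loess degree must be 1 or 2")
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < degree + 1:
        raise ValidationError(
            f"span {span} covers only {k} point(s); need >= {degree + 1}"
        )
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dk = d[idx]
        dmax = dk.max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1.0 - (dk / dmax) ** 3) ** 3
        xi = xs[idx] - x0  # centre for conditioning; intercept = prediction
        cols = [np.ones_like(xi), xi]
        if degree == 2:
            cols.append(xi**2)
        X = np.column_stack(cols)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def fit_error_model(
    stats_: ProteinStats,
    span: float = 0.75,
    degree: int = 1,
    n_grid: int = 200,
) -> ErrorModel:
    """Fit the loess CV-vs-abundance curve on a regular log2 grid."""
    x = stats_.mean_log2
    y = stats_.cv_percent
    if x.size < 10:
        raise ValidationError("need >= 10 proteins to fit the error model")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = loess_fit(x, y, grid, span=span, degree=degree)
    fitted = np.maximum(fitted, CV_PREDICTION_FLOOR)
    return ErrorModel(grid_log2=grid, grid_cv=fitted, span=span, degree=degree)


# ---------------------------------------------------------------------------
# CV -> log2 sigma, and two-sample power
# ---------------------------------------------------------------------------

def cv_to_sigma_log2(cv_percent) -> np.ndarray | float:
    """Convert a raw-scale CV (%) to the SD of log2 intensity.

    Under a log-normal measurement model a raw-scale CV corresponds to a
    log2-scale standard deviation ``sqrt(ln(1 + (cv/100)^2)) / ln 2``.
    """
    cv = np.asarray(cv_percent, dtype=float)
    if np.any(cv < 0):
        raise ValidationError("cv_percent must be >= 0")
    sigma = np.sqrt(np.log1p((cv / 100.0) ** 2)) / LN2
    return float(sigma) if np.isscalar(cv_percent) else sigma


def power_two_sample(
    sigma,
    n_per_group: int,
    delta: float = 1.0,
    alpha_per_test: float = 0.05,
) -> np.ndarray | float:
    """Power of the two-sided two-sample t test for a log2 difference.

    Equal group sizes ``n`` per group, df ``2n - 2``, noncentrality
    ``delta * sqrt(n / 2) / sigma``; power is the probability that the
    noncentral |t| exceeds the central critical value.  ``sigma = 0``
    gives power 1 (the effect is seen without noise).
    """
    if n_per_group < 2:
        raise ValidationError("need n_per_group >= 2")
    if not 0.0 < alpha_per_test < 1.0:
        raise ValidationError("alpha_per_test must be in (0, 1)")
    s = np.asarray(sigma, dtype=float)
    if np.any(s < 0):
        raise ValidationError("sigma must be >= 0")
    df = 2 * n_per_group - 2
    tcrit = stats.t.ppf(1.0 - alpha_per_test / 2.0, df)
    with np.errstate(divide="ignore"):
        ncp = np.where(s > 0, delta * np.sqrt(n_per_group / 2.0) / np.where(s > 0, s, 1.0), np.inf)
    ncp_safe = np.where(np.isinf(ncp), 1.0, ncp)
    with np.errstate(invalid="ignore"):
        upper = stats.nct.sf(tcrit, df, ncp_safe)
        lower = stats.nct.cdf(-tcrit, df, ncp_safe)
    # scipy's noncentral-t returns NaN in the far tails; patch each tail
    # with the Johnson-Kotz normal approximation, which is accurate there
    scale = 1.0 - 1.0 / (4.0 * df)
    den = np.sqrt(1.0 + tcrit**2 / (2.0 * df))
    upper = np.where(
        np.isnan(upper), stats.norm.sf((tcrit * scale - ncp_safe) / den), upper
    )
    lower = np.where(
        np.isnan(lower), stats.norm.cdf((-tcrit * scale - ncp_safe) / den), lower
    )
    power = np.where(np.isinf(ncp), 1.0, upper + lower)
    power = np.clip(power, 0.0, 1.0)
    return float(power) if np.isscalar(sigma) else power


@dataclass
class PowerSpec:
    """Effect size, test family and candidate designs for power analysis.

    ``log2_fc = 1`` encodes a twofold change; the family-wise alpha
    (default 0.1) is Bonferroni-split over ``n_tests`` proteins.
    """

    log2_fc: float = 1.0
    alpha_family: float = 0.1
    n_tests: int = 5000
    n_per_group_grid: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 75, 100)
    power_targets: tuple[float, ...] = (0.95, 0.75, 0.50)

    def __post_init__(self) -> None:
        if self.log2_fc <= 0:
            raise ValidationError("log2_fc must be > 0")
        if not 0.0 < self.alpha_family < 1.0:
            raise ValidationError("alpha_family must be in (0, 1)")
        if self.n_tests < 1:
            raise ValidationError("n_tests must be >= 1")
        if any(not 0.0 < t < 1.0 for t in self.power_targets):
            raise ValidationError("power targets must be in (0, 1)")

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_family / self.n_tests


def power_surface(model: ErrorModel, spec: PowerSpec) -> pd.DataFrame:
    """Power at every (grid abundance, n-per-group) from the fitted model.

    Rows indexed by the error-model grid (log2 abundance), one column per
    candidate group size.  Each fixed-n column is non-decreasing in
    abundance wherever the fitted CV curve is non-increasing.
    """
    sigmas = cv_to_sigma_log2(model.grid_cv)
    cols = {}
    for n in spec.n_per_group_grid:
        cols[n] = power_two_sample(sigmas, n, spec.log2_fc, spec.alpha_per_test)
    out = pd.DataFrame(cols, index=pd.Index(model.grid_log2, name="mean_log2"))
    out.columns.name = "n_per_group"
    return out


def protein_sigmas(
    stats_: ProteinStats, model: ErrorModel | None = None, smoothed: bool = True
) -> np.ndarray:
    """Per-protein log2 SDs, from smoothed (default) or raw per-protein CVs."""
    if smoothed:
        if model is None:
            raise ValidationError("smoothed sigmas require a fitted error model")
        cv = model.predict(stats_.mean_log2)
    else:
        cv = stats_.cv_percent
    return np.asarray(cv_to_sigma_log2(cv))


def coverage_table(sigmas: np.ndarray, spec: PowerSpec) -> pd.DataFrame:
    """Percent of proteins reaching each power target per group size.

    Cell (n, target) = 100 * #{proteins with power(sigma_g, n) >= target}
    / #proteins.  Cells are non-decreasing in n and non-increasing in the
    target.
    """
    sig = np.asarray(sigmas, dtype=float)
    rows = {}
    for n in spec.n_per_group_grid:
        pw = power_two_sample(sig, n, spec.log2_fc, spec.alpha_per_test)
        rows[n] = {
            t: 100.0 * float(np.mean(pw >= t)) for t in spec.power_targets
        }
    out = pd.DataFrame(rows).T
    out.index.name = "n_per_group"
    out.columns = [f"power_{t:g}" for t in spec.power_targets]
    return out


NOT_REACHABLE = -1


def required_n(
    sigma: float,
    target_power: float,
    delta: float = 1.0,
    alpha_per_test: float = 0.05,
    n_max: int = 10000,
) -> int:
    """Smallest group size with power >= target (monotone search).

    Returns ``NOT_REACHABLE`` (-1) when the target is not met by
    ``n_max``.  ``sigma = 0`` gives the minimum legal design, n = 2.
    """
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must be in (0, 1)")
    if sigma == 0:
        return 2
    lo, hi = 2, 2
    if power_two_sample(sigma, lo, delta, alpha_per_test) >= target_power:
        return lo
    while power_two_sample(sigma, hi, delta, alpha_per_test) < target_power:
        hi *= 2
        if hi > n_max:
            if power_two_sample(sigma, n_max, delta, alpha_per_test) >= target_power:
                hi = n_max
                break
            return NOT_REACHABLE
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_two_sample(sigma, mid, delta, alpha_per_test) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
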