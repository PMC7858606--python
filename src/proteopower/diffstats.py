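"""Per-protein inferential statistics for the SWATH-MS study.

Implements the statistical toolkit used to separate technical from
biological variation: a joint additive fixed-effects ANOVA per protein
over the design factors (IGHV status, WBC class, gender, preparation
day, MS run), an empirical-Bayes moderated linear model for a two-group
contrast, partial correlation against the continuous %-IGHV covariate
with confounder adjustment, Benjamini-Hochberg FDR control, PCA, and
set retention/overlap metrics for before/after-correction comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .containers import (
    DifferentialResult,
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
)

#: Metadata columns treated as continuous regressors; all others are
#: categorical (including the integer-coded prep_day and ms_run).
CONTINUOUS_FACTORS = {"ighv_percent"}

DEFAULT_FACTORS = ("ighv_status", "wbc_class", "gender", "prep_day", "ms_run")


@dataclass
class DesignSpec:
    """Factors, optional two-level contrast and FDR threshold for a fit."""

    factors: tuple[str, ...] = DEFAULT_FACTORS
    contrast: tuple[str, str, str] | None = None  # (factor, high level, low level)
    fdr_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValidationError("fdr_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------

def build_design(
    metadata: SampleMetadata, factors: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Additive design matrix with intercept; treatment coding per factor.

    Returns the matrix and a map factor -> column indices of its block.
    Raises on a rank-deficient (confounded) design, naming an aliased
    factor pair.
    """
    cols: list[np.ndarray] = [np.ones(len(metadata.table))]
    blocks: dict[str, np.ndarray] = {}
    for f in factors:
        series = metadata.factor(f)
        start = len(cols)
        if f in CONTINUOUS_FACTORS:
            cols.append(series.to_numpy(dtype=float))
        else:
            levels = sorted(pd.unique(series))
            if len(levels) < 2:
                raise ValidationError(f"factor {f!r} has < 2 observed levels")
            for lev in levels[1:]:
                cols.append((series == lev).to_numpy(dtype=float))
        blocks[f] = np.arange(start, len(cols))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        pair = _find_aliased_pair(X, blocks)
        raise ValidationError(
            f"rank-deficient design: factors {pair[0]!r} and {pair[1]!r} are aliased"
        )
    return X, blocks


def _find_aliased_pair(X: np.ndarray, blocks: dict[str, np.ndarray]) -> tuple[str, str]:
    names = list(blocks)
    for a, b in itertools.combinations(names, 2):
        idx = np.concatenate(([0], blocks[a], blocks[b]))
        sub = X[:, idx]
        expected = 1 + len(blocks[a]) + len(blocks[b])
        if np.linalg.matrix_rank(sub) < expected:
            return a, b
    return names[0], names[-1] if len(names) > 1 else names[0]


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares per row of Y under OLS on X (vectorised)."""
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    return np.einsum("ij,ij->i", resid, resid)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH q-values; order-preserving, q >= p, NaNs pass through.

    ``q(i) = min over j with p(j) >= p(i) of min(1, m * p(j) / rank(j))``
    where m counts the non-NaN p-values.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    qf = np.minimum.accumulate(ranked[::-1])[::-1]
    qf = np.minimum(qf, 1.0)
    out = np.empty(m)
    out[order] = qf
    q[finite] = out
    return q


# ---------------------------------------------------------------------------
# ANOVA per protein
# ---------------------------------------------------------------------------

def anova_per_protein(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    design: DesignSpec | None = None,
) -> dict[str, DifferentialResult]:
    """Joint additive fixed-effects ANOVA per protein, one F test per factor.

    A single linear model containing all design factors is fitted to each
    protein; per-factor F statistics use Type II sums of squares (drop the
    factor from the full additive model).  BH correction is applied per
    factor across proteins.  Proteins with zero residual variance get
    ``NaN`` p-values and are excluded from the BH correction.
    """
    design = design or DesignSpec()
    if matrix.scale != "log2":
        raise ValidationError("anova expects a log2-scale matrix")
    if matrix.has_missing():
        raise ValidationError("anova requires a complete matrix (impute first)")
    meta = metadata.aligned_to(matrix.sample_ids)
    X, blocks = build_design(meta, design.factors)
    Y = matrix.to_numpy()
    n, p_full = X.shape
    df_resid = n - p_full
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom in the full model")

    rss_full = _rss(Y, X)
    denom = rss_full / df_resid
    degenerate = denom <= np.finfo(float).eps * np.maximum(1.0, np.abs(Y).max())

    results: dict[str, DifferentialResult] = {}
    for f in design.factors:
        keep = np.setdiff1d(np.arange(p_full), blocks[f])
        rss_red = _rss(Y, X[:, keep])
        df_f = len(blocks[f])
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (rss_red - rss_full) / df_f / denom
        F = np.where(degenerate, np.nan, np.maximum(F, 0.0))
        p = stats.f.sf(F, df_f, df_resid)
        p = np.where(np.isnan(F), np.nan, p)
        q = benjamini_hochberg(p)
        effect = _factor_effect(Y, meta, f)
        table = pd.DataFrame(
            {
                "statistic": F,
                "p_value": p,
                "q_value": q,
                "effect": effect,
                "significant": pd.Series(q <= design.fdr_threshold, index=matrix.protein_ids).where(~np.isnan(q), False),
            },
            index=matrix.protein_ids,
        )
        table["significant"] = table["significant"].astype(bool)
        results[f] = DifferentialResult(
            factor=f, table=table, fdr_threshold=design.fdr_threshold
        )
    return results


def _factor_effect(Y: np.ndarray, meta: SampleMetadata, factor: str) -> np.ndarray:
    """Effect column: group difference for 2-level factors, slope for
    continuous ones, NaN for factors with more than two levels."""
    series = meta.factor(factor)
    if factor in CONTINUOUS_FACTORS:
        x = series.to_numpy(dtype=float)
        xc = x - x.mean()
        return Y @ xc / np.dot(xc, xc)
    levels = sorted(pd.unique(series))
    if len(levels) != 2:
        return np.full(Y.shape[0], np.nan)
    a = (series == levels[1]).to_numpy()
    return Y[:, a].mean(axis=1) - Y[:, ~a].mean(axis=1)


# ---------------------------------------------------------------------------
# Moderated (empirical-Bayes) linear model
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-protein residual variances.

    Moment-matches the distribution of ``log s^2`` to a scaled-F model:
    with ``z = log s^2``, ``E z = log s0^2 + digamma(df/2) - log(df/2)``
    under the prior, and the excess variance of ``z`` over
    ``trigamma(df/2)`` identifies the prior df ``d0`` through
    ``trigamma(d0/2)``.  Returns ``(d0, s0^2, posterior variances)``
    where the posterior is ``(d0 s0^2 + df s^2) / (d0 + df)``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not np.any(ok):
        raise ValidationError("all residual variances are zero (degenerate input)")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if ok.sum() < 2:
        # a single observed variance carries no shrinkage information
        return 0.0, float(s2[ok][0]), s2.copy()
    if True:
        e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
        if e_var <= 0:
            d0 = np.inf
            s02 = float(np.exp(e_mean))
        else:
            d0 = 2.0 * trigamma_inverse(e_var)
            s02 = float(
                np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
            )
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return d0, s02, post


def moderated_fit(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    design: DesignSpec,
    extra_design: np.ndarray | None = None,
    d0_override: float | None = None,
) -> DifferentialResult:
    """Per-protein least squares with EB variance shrinkage and moderated t.

    The contrast factor is coded 0/1 (low/high level); its coefficient is
    the log2 group difference.  Residual variances are shrunk towards the
    cross-protein prior (``squeeze_variances``); the moderated t has
    ``df_resid + d0`` degrees of freedom.  ``extra_design`` appends
    pre-built covariate columns (used by the batch-in-model variant);
    ``d0_override`` forces the prior df (``np.inf`` = full shrinkage).
    """
    if design.contrast is None:
        raise ValidationError("moderated_fit requires a contrast")
    if matrix.has_missing():
        raise ValidationError("moderated_fit requires a complete matrix")
    meta = metadata.aligned_to(matrix.sample_ids)
    factor, hi, lo = design.contrast
    series = meta.factor(factor)
    present = set(pd.unique(series))
    if hi not in present or lo not in present:
        raise ValidationError(f"contrast levels {hi!r}/{lo!r} not present in {factor!r}")
    c = (series == hi).to_numpy(dtype=float)
    cols = [np.ones(len(c)), c]
    for f in design.factors:
        if f == factor:
            continue
        sub, blocks = build_design(meta, (f,))
        cols.extend(sub[:, i] for i in blocks[f])
    X = np.column_stack(cols)
    if extra_design is not None:
        X = np.column_stack([X, extra_design])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("contrast design is rank deficient")
    return _moderated_from_design(
        matrix, X, coef_index=1, fdr_threshold=design.fdr_threshold,
        factor_name=f"{factor}:{hi}-{lo}", d0_override=d0_override,
    )


def _moderated_from_design(
    matrix: ExpressionMatrix,
    X: np.ndarray,
    coef_index: int,
    fdr_threshold: float,
    factor_name: str,
    d0_override: float | None = None,
    Y: np.ndarray | None = None,
) -> DifferentialResult:
    Yv = matrix.to_numpy() if Y is None else Y
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValidationError("residual df must be >= 1")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Yv @ (XtX_inv @ X.T).T
    resid = Yv - beta @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / df
    effect = beta[:, coef_index]
    c2 = XtX_inv[coef_index, coef_index]

    if d0_override is not None:
        d0 = d0_override
        _, s02, post = squeeze_variances(s2, df)
        if np.isinf(d0):
            post = np.full_like(s2, s02)
        else:
            post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0, s02, post = squeeze_variances(s2, df)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(post * c2)
    df_total = df + d0
    if np.isinf(df_total):
        p_val = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_val = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_val = np.where(post <= 0, np.nan, p_val)
    q = benjamini_hochberg(p_val)
    table = pd.DataFrame(
        {
            "statistic": t,
            "p_value": p_val,
            "q_value": q,
            "effect": effect,
            "significant": np.where(np.isnan(q), False, q <= fdr_threshold),
        },
        index=matrix.protein_ids,
    )
    table["significant"] = table["significant"].astype(bool)
    return DifferentialResult(
        factor=factor_name,
        table=table,
        fdr_threshold=fdr_threshold,
        extras={"d0": d0, "s0_squared": s02, "df_resid": df},
    )


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

def partial_correlation(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    x_factor: str = "ighv_percent",
    confounders: tuple[str, ...] = ("wbc_class", "gender"),
    fdr_threshold: float = 0.10,
) -> DifferentialResult:
    """Partial Pearson correlation of each protein with a continuous covariate.

    Both the protein values and the covariate are residualised on the
    confounders (binary-coded WBC class and gender by default) by least
    squares; the Pearson correlation of the residuals is tested with
    ``t = r sqrt((n - 2 - k) / (1 - r^2))`` on ``n - 2 - k`` df.
    """
    if matrix.has_missing():
        raise ValidationError("partial_correlation requires a complete matrix")
    meta = metadata.aligned_to(matrix.sample_ids)
    x = meta.factor(x_factor).to_numpy(dtype=float)
    n = x.size
    k = 0
    cols = [np.ones(n)]
    for f in confounders:
        sub, blocks = build_design(meta, (f,))
        for i in blocks[f]:
            cols.append(sub[:, i])
            k += 1
    if n <= k + 2:
        raise ValidationError("need n > k + 2 samples for partial correlation")
    C = np.column_stack(cols)
    # rank-revealing orthonormal basis: tolerant of redundant confounders
    Q = linalg.orth(C)
    x_res = x - Q @ (Q.T @ x)
    if np.allclose(x_res, 0.0):
        raise ValidationError(f"{x_factor!r} is collinear with the confounders")
    Y = matrix.to_numpy()
    Y_res = Y - (Y @ Q) @ Q.T
    x_norm = np.linalg.norm(x_res)
    y_norm = np.linalg.norm(Y_res, axis=1)
    degenerate = y_norm <= 1e-9 * (np.linalg.norm(Y, axis=1) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y_res @ x_res) / (y_norm * x_norm)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.nan, p)
    q = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "statistic": t,
            "p_value": p,
            "q_value": q,
            "effect": r,
            "significant": np.where(np.isnan(q), False, q <= fdr_threshold),
        },
        index=matrix.protein_ids,
    )
    table["significant"] = table["significant"].astype(bool)
    return DifferentialResult(
        factor=f"partial_corr:{x_factor}", table=table, fdr_threshold=fdr_threshold
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    variance_explained: np.ndarray  # per component, sums to total variance
    fraction_explained: np.ndarray


def pca(matrix: ExpressionMatrix) -> PCAResult:
    """Protein-centred SVD of the expression matrix.

    Each protein row is centred; sample scores are the projections onto
    the principal axes.  The per-component variances sum to the total
    (protein-wise) variance.  Sign convention: the largest-magnitude
    protein loading of each component is positive.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    if matrix.has_missing():
        raise ValidationError("PCA requires a complete matrix")
    Y = matrix.to_numpy()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    # fix signs so the largest-|loading| per component is positive
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    var = s**2 / (matrix.n_samples - 1)
    total = var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame((Vt.T * s), index=matrix.sample_ids, columns=comps)
    loadings = pd.DataFrame(U, index=matrix.protein_ids, columns=comps)
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=var,
                     fraction_explained=frac)


# ---------------------------------------------------------------------------
# Retention and overlap
# ---------------------------------------------------------------------------

def retention_and_overlap(
    sig_before: set, sig_after: set, *additional: set, names: tuple[str, ...] | None = None
) -> dict:
    """Retention of a significant set after correction, plus Venn counts.

    ``retained_fraction = |before ∩ after| / |before|`` (``None`` when the
    before-set is empty).  ``venn_counts`` maps each exclusive region of
    the 2-4 sets (as a membership tuple) to its count.
    """
    sets = [set(sig_before), set(sig_after), *[set(s) for s in additional]]
    if not 2 <= len(sets) <= 4:
        raise ValidationError("retention_and_overlap supports 2-4 sets")
    if names is None:
        names = tuple(f"set{i + 1}" for i in range(len(sets)))
    before, after = sets[0], sets[1]
    retained = None if not before else len(before & after) / len(before)
    universe = set().union(*sets)
    venn: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inside = set(universe)
            for i in combo:
                inside &= sets[i]
            for i in set(range(len(sets))) - set(combo):
                inside -= sets[i]
            venn[tuple(names[i] for i in combo)] = len(inside)
    return {
        "retained_fraction": retained,
        "intersection": len(before & after),
        "venn_counts": venn,
    }
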