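"""Count-based differential expression between case and control samples.

The model is a per-feature negative-binomial GLM with log link, an offset
for the sample size factor (median-of-ratios normalization) and arbitrary
sample covariates; the status coefficient is tested with a Wald statistic
against the standard-normal reference, and p-values are adjusted with the
Benjamini-Hochberg step-up across tested features. Dispersion is a
per-feature Pearson-chi-square (method-of-moments) estimate, optionally
shrunk toward a mean-dispersion trend. This deliberately stays short of
DESeq2's Cox-Reid/MAP machinery and shrunken fold changes: fold-change
estimates are raw GLM coefficients on the log2 scale, positive when the
feature is higher in cases.

The "rlog-like" transform here is log2(normalized count + pseudocount), a
monotone variance-dampening pseudo-log used for correlations, PCA and
signature scoring downstream — not the shrinkage-based regularized log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .io import ExpressionDataset

logger = logging.getLogger("mirtarnet")

DE_COLUMNS = ["base_mean", "lfc", "se", "wald", "p_value", "fdr", "tested"]
_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def size_factors(dataset: ExpressionDataset) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For features with nonzero counts in every sample, each sample's factor
    is the median ratio of its counts to the per-feature geometric mean.
    If no feature is everywhere-nonzero, the geometric mean is taken over
    nonzero entries only (a fallback for very sparse matrices).
    """
    counts = dataset.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix has no size factors")
    everywhere = (counts > 0).all(axis=1)
    if everywhere.any():
        sub = counts[everywhere]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
    else:
        logger.warning("no feature nonzero in all samples; sparse fallback in use")
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        log_geomean = np.nanmean(logc, axis=1)
        ratios = logc - log_geomean[:, None]
    factors = np.exp(np.nanmedian(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=dataset.sample_ids, name="size_factor")


def rlog_transform(
    dataset: ExpressionDataset,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), feature x sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(dataset)
    factors = factors.loc[dataset.sample_ids]
    normalized = dataset.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    return pd.DataFrame(
        np.log2(normalized + pseudocount),
        index=dataset.feature_ids,
        columns=dataset.sample_ids,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through.

    q_i = min_{j: p_j >= p_i} m * p_j / rank_j, capped at 1, with m the
    number of non-missing p-values.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    qm = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qm, 1.0)
    q[mask] = out
    return q


# ---------------------------------------------------------------------------
# NB GLM Wald test
# ---------------------------------------------------------------------------


def _status_levels(status: pd.Series) -> tuple[str, str]:
    levels = sorted(status.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"status must have exactly 2 levels, got {levels}")
    if "control" in levels:
        ref = "control"
        case = next(l for l in levels if l != "control")
    else:
        ref, case = levels
    return ref, case


def _design_matrix(
    metadata: pd.DataFrame, covariates: list[str], test_var: str
) -> tuple[np.ndarray, list[str]]:
    """Intercept + binary status (case = 1) + covariates; dummies for factors."""
    status = metadata[test_var].astype(str)
    _, case = _status_levels(status)
    columns: dict[str, np.ndarray] = {
        "intercept": np.ones(len(metadata)),
        test_var: (status == case).to_numpy(dtype=float),
    }
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} absent from metadata")
        values = metadata[cov]
        if pd.api.types.is_numeric_dtype(values):
            centered = values.to_numpy(dtype=float)
            columns[cov] = centered - centered.mean()
        else:
            dummies = pd.get_dummies(values.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                columns[name] = dummies[name].to_numpy(dtype=float)
    X = np.column_stack(list(columns.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix (columns: {list(columns)})"
        )
    return X, list(columns)


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, dof: int) -> float:
    """Solve sum (y-mu)^2 / (mu + a*mu^2) = dof for the NB dispersion a."""

    def excess(alpha: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + alpha * mu**2)) - dof)

    if excess(_DISPERSION_FLOOR) <= 0:
        return _DISPERSION_FLOOR
    hi = 1.0
    while excess(hi) > 0 and hi < 1e4:
        hi *= 10
    if excess(hi) > 0:
        return hi
    return float(optimize.brentq(excess, _DISPERSION_FLOOR, hi, xtol=1e-10))


def _fit_feature(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[float, float, float] | None:
    """Return (log-scale coefficient, se, dispersion) for the status column.

    None signals a failed fit (all-zero feature, separation, non-convergence);
    such features are reported as untested rather than raised.
    """
    if y.sum() == 0:
        return None
    dof = max(len(y) - X.shape[1], 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
                maxiter=100
            )
            alpha = _pearson_dispersion(y, np.asarray(pois.fittedvalues), dof)
            nb = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
            # one dispersion refinement at the NB mean, then the final fit
            alpha = _pearson_dispersion(y, np.asarray(nb.fittedvalues), dof)
            nb = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
        except (np.linalg.LinAlgError, ValueError, optimize.nonlin.NoConvergence):
            return None
    coef, se = float(nb.params[1]), float(nb.bse[1])
    if not (np.isfinite(coef) and np.isfinite(se)) or se > 1e3:
        return None
    return coef, se, alpha


def nb_wald_de(
    dataset: ExpressionDataset,
    covariates: list[str] | tuple[str, ...] = ("age", "sex"),
    test_var: str = "status",
    extra_covariate_table: pd.DataFrame | None = None,
    min_base_mean_quantile: float = 0.0,
    dispersion_shrinkage: bool = False,
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of ``test_var`` adjusted for covariates.

    Parameters
    ----------
    extra_covariate_table
        Optional sample x covariate frame of continuous covariates appended
        to the design (used for cell-composition correction). Columns that
        are constant raise; collinear columns raise with their names.
    min_base_mean_quantile
        Independent-filtering rule: features whose mean normalized count
        falls below this quantile are reported untested and excluded from
        the BH denominator. Default 0 disables filtering.

    Returns a frame indexed by feature id with columns
    base_mean, lfc (log2, case vs control), se (log2), wald, p_value, fdr,
    tested.
    """
    metadata = dataset.metadata.copy()
    if extra_covariate_table is not None:
        extra = extra_covariate_table.loc[dataset.sample_ids]
        constant = [c for c in extra.columns if extra[c].nunique() <= 1]
        if constant:
            raise ValueError(f"constant covariate columns: {constant}")
        metadata = metadata.join(extra)
        covariates = list(covariates) + list(extra.columns)
    for level, group in metadata.groupby(test_var):
        if len(group) < 2:
            raise ValueError(f"fewer than 2 samples with {test_var}={level!r}")
    try:
        X, colnames = _design_matrix(metadata, list(covariates), test_var)
    except ValueError as err:
        if "rank-deficient" in str(err) and extra_covariate_table is not None:
            raise ValueError(
                "collinear covariates in design "
                f"(score columns: {list(extra_covariate_table.columns)})"
            ) from err
        raise
    factors = size_factors(dataset)
    offset = np.log(factors.to_numpy())
    counts = dataset.counts.to_numpy(dtype=float)
    base_mean = (counts / factors.to_numpy()[None, :]).mean(axis=1)
    threshold = (
        np.quantile(base_mean, min_base_mean_quantile)
        if min_base_mean_quantile > 0
        else -np.inf
    )

    n_features = dataset.n_features
    lfc = np.full(n_features, np.nan)
    se = np.full(n_features, np.nan)
    wald = np.full(n_features, np.nan)
    pval = np.full(n_features, np.nan)
    tested = np.zeros(n_features, dtype=bool)
    dispersions = np.full(n_features, np.nan)

    for i in range(n_features):
        if base_mean[i] < threshold:
            continue
        fit = _fit_feature(counts[i], X, offset)
        if fit is None:
            continue
        coef, coef_se, alpha = fit
        dispersions[i] = alpha
        lfc[i] = coef / _LN2
        se[i] = coef_se / _LN2
        wald[i] = coef / coef_se
        tested[i] = True

    if dispersion_shrinkage and tested.sum() >= 10:
        lfc, se, wald = _shrink_and_refit(
            counts, X, offset, base_mean, dispersions, tested, lfc, se, wald
        )

    pval[tested] = 2.0 * stats.norm.sf(np.abs(wald[tested]))
    fdr = bh_fdr(pval)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "lfc": lfc,
            "se": se,
            "wald": wald,
            "p_value": pval,
            "fdr": fdr,
            "tested": tested,
        },
        index=dataset.feature_ids,
    )
    logger.info(
        "nb_wald_de: %d/%d features tested, %d at FDR<0.05",
        tested.sum(), n_features, int((table["fdr"] < 0.05).sum()),
    )
    return table


def _shrink_and_refit(counts, X, offset, base_mean, dispersions, tested, lfc, se, wald):
    """Shrink per-feature dispersions toward a 1/mean trend, then refit.

    Log-dispersion is averaged (equal weight) with the trend value
    a(mu) = a0 + a1/mu fitted by least squares over tested features.
    """
    mu = base_mean[tested]
    disp = np.clip(dispersions[tested], _DISPERSION_FLOOR, None)
    A = np.column_stack([np.ones(mu.size), 1.0 / np.maximum(mu, 1e-8)])
    coef, *_ = np.linalg.lstsq(A, disp, rcond=None)
    trend = np.clip(A @ coef, _DISPERSION_FLOOR, None)
    shrunk = np.exp(0.5 * (np.log(disp) + np.log(trend)))
    idx = np.flatnonzero(tested)
    for j, alpha in zip(idx, shrunk):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                nb = sm.GLM(
                    counts[j], X,
                    family=sm.families.NegativeBinomial(alpha=float(alpha)),
                    offset=offset,
                ).fit(maxiter=100)
            except (np.linalg.LinAlgError, ValueError):
                continue
        lfc[j] = float(nb.params[1]) / _LN2
        se[j] = float(nb.bse[1]) / _LN2
        wald[j] = float(nb.params[1] / nb.bse[1])
    return lfc, se, wald


# ---------------------------------------------------------------------------
# PCA association with disease status
# ---------------------------------------------------------------------------


@dataclass
class PCAReport:
    scores: pd.DataFrame            # sample x component
    explained_variance_ratio: np.ndarray
    mwu_p: pd.Series                # per component, status comparison
    partial_p: pd.Series            # per component, status adjusted for sex/age


def pca_status_association(
    rlog_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_components: int = 2,
    covariates: tuple[str, ...] = ("sex", "age"),
    test_var: str = "status",
) -> PCAReport:
    """Top principal components of samples and their association with status.

    Components are computed on centered per-feature values (samples as
    observations). Each component score is compared across status by a
    two-sided Mann-Whitney U test, and its partial association with status
    (adjusting for the listed covariates) comes from an OLS fit of the
    score on status + covariates.
    """
    samples = list(rlog_matrix.columns)
    if len(samples) < 3:
        raise ValueError("PCA needs at least 3 samples")
    max_rank = min(len(samples) - 1, rlog_matrix.shape[0])
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank {max_rank}")
    values = rlog_matrix.to_numpy().T
    values = values - values.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    score_frame = pd.DataFrame(
        scores, index=samples, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    meta = metadata.loc[samples]
    ref, case = _status_levels(meta[test_var].astype(str))
    is_case = (meta[test_var].astype(str) == case).to_numpy()

    mwu_p, partial_p = {}, {}
    usable_covs = [c for c in covariates if c in meta.columns]
    X, colnames = _design_matrix(meta, usable_covs, test_var)
    for comp in score_frame.columns:
        a = score_frame.loc[is_case, comp]
        b = score_frame.loc[~is_case, comp]
        mwu_p[comp] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        ols = sm.OLS(score_frame[comp].to_numpy(), X).fit()
        partial_p[comp] = float(ols.pvalues[1])
    return PCAReport(
        scores=score_frame,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mwu_p=pd.Series(mwu_p),
        partial_p=pd.Series(partial_p),
    )


# ---------------------------------------------------------------------------
# Cross-table concordance
# ---------------------------------------------------------------------------


def de_concordance(
    de: pd.DataFrame,
    reference: pd.DataFrame,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Fraction of shared genes significant in both tables with matching sign.

    Both inputs carry ``lfc`` and ``fdr`` columns indexed by feature. The
    returned dict reports the shared-gene count, the concordant count and
    the percentage (whole percent).
    """
    shared = de.index.intersection(reference.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    a = de.loc[shared]
    b = reference.loc[shared]
    concordant = (
        (a["fdr"] < alpha)
        & (b["fdr"] < alpha)
        & (np.sign(a["lfc"]) == np.sign(b["lfc"]))
    )
    n = len(shared)
    k = int(concordant.sum())
    return {
        "n_shared": n,
        "n_concordant": k,
        "pct_concordant": round(100.0 * k / n) if n else 0,
    }
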