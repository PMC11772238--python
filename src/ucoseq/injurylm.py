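"""Per-timepoint association of blood expression with brain-injury severity.

Counts are first transformed to log2-CPM with per-observation precision
weights estimated from the mean-variance trend (lowess of sqrt residual
standard deviation against mean log count, span 0.5) so that ordinary
weighted least squares applies.  At each timepoint separately, every
gene's log expression is regressed on the binary injury phenotype
(severe = 1) adjusting for treatment arm, and the gene-wise residual
variances are shrunk toward an ensemble prior by empirical Bayes: the
scaled-F moment estimators give a prior df d0 and prior variance s0^2,
the posterior variance is (d0 s0^2 + d s^2) / (d0 + d), and moderated
t-statistics with d0 + d degrees of freedom yield p- and q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ucoseq.core_io import CountMatrix, SampleTable, bh_adjust
from ucoseq.normtmm import NormFactors

logger = logging.getLogger("ucoseq")

LOWESS_SPAN = 0.5
PRIOR_COUNT = 0.5


@dataclass
class WeightedExpression:
    """log2-CPM matrix (genes x samples) with congruent precision weights."""

    logcpm: np.ndarray
    weights: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    trend_x: np.ndarray  # mean log2 count knots of the fitted trend
    trend_y: np.ndarray  # sqrt residual sd at the knots

    def __post_init__(self) -> None:
        if self.logcpm.shape != self.weights.shape:
            raise ValueError("weights must be congruent with the expression matrix")
        if (self.weights <= 0).any():
            raise ValueError("precision weights must be positive")


@dataclass
class GeneFits:
    """Per-gene WLS results at one timepoint."""

    gene_ids: list[str]
    coef: np.ndarray          # injury (severe vs mild) coefficient, log2 units
    unscaled_se: np.ndarray   # sqrt of (X'WX)^-1 diagonal for the injury column
    sigma2: np.ndarray        # residual variance
    df_residual: float
    timepoint_h: float


def precision_weight_transform(
    counts: CountMatrix,
    factors: NormFactors | None,
    design: np.ndarray,
    span: float = LOWESS_SPAN,
    prior_count: float = PRIOR_COUNT,
) -> WeightedExpression:
    """Mean-variance precision weighting of log2-CPM (voom-style).

    The design is the model later fitted per gene; residual standard
    deviations from that fit drive the lowess trend.  Weights are the
    inverse squared trend evaluated at each observation's predicted log
    count.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    n = counts.n_samples
    if design.shape[0] != n:
        raise ValueError("design rows must match samples")
    if n < design.shape[1] + 1:
        raise ValueError(
            f"{n} samples cannot support a {design.shape[1]}-column design"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    libs = counts.library_sizes()
    f = factors.for_samples(counts.sample_ids) if factors is not None else np.ones(n)
    eff = libs * f
    y = np.log2((counts.values + prior_count) / eff[None, :] * 1e6)

    # gene-wise OLS on the design
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T
    fitted = beta @ design.T
    resid = y - fitted
    df = n - design.shape[1]
    sd = np.sqrt((resid**2).sum(axis=1) / df)
    sqrt_sd = np.sqrt(sd)
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)

    lo = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    knots_x, knots_y = lo[:, 0], np.maximum(lo[:, 1], 1e-6)
    # predicted log count per observation, from the gene-wise fit
    pred_logcount = fitted + (np.log2(eff)[None, :] - np.log2(1e6))
    trend = np.interp(pred_logcount, knots_x, knots_y)
    weights = 1.0 / trend**4  # trend is sqrt(sd): sd^2 = trend^4
    return WeightedExpression(
        logcpm=y,
        weights=weights,
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        trend_x=knots_x,
        trend_y=knots_y,
    )


def injury_design(samples: SampleTable) -> np.ndarray:
    """[intercept, injury(severe=1), treatment(active=1)] design rows."""
    df = samples.data
    return np.column_stack(
        [
            np.ones(len(df)),
            (df["injury_class"] == "severe").astype(float),
            (df["treatment"] == "active").astype(float),
        ]
    )


def fit_injury_model(
    wexpr: WeightedExpression,
    samples: SampleTable,
    timepoint: float | None = None,
) -> GeneFits:
    """Gene-wise weighted least squares of expression on injury + treatment.

    ``wexpr`` must already be restricted to the timepoint's samples (the
    transform is computed on the same subset the model is fitted on).
    """
    df = samples.for_samples(wexpr.sample_ids).data
    if timepoint is not None and not np.allclose(df["timepoint_h"], timepoint):
        raise ValueError("expression subset does not match the requested timepoint")
    tp = float(df["timepoint_h"].iloc[0]) if timepoint is None else float(timepoint)
    classes = set(df["injury_class"])
    if not {"mild", "severe"} <= classes:
        raise ValueError(
            f"timepoint {tp}: both injury classes required, found {sorted(classes)}"
        )
    X = injury_design(SampleTable(df))
    # drop constant non-intercept columns (e.g. single-arm subsets)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    if 1 not in keep:
        raise ValueError(f"timepoint {tp}: injury column is constant")
    X = X[:, keep]
    inj_col = keep.index(1)
    y = wexpr.logcpm
    w = wexpr.weights
    G, n = y.shape
    p = X.shape[1]
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
    XtWy = np.einsum("ni,gn,gn->gi", X, w, y)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta @ X.T
    dfres = n - p
    sigma2 = (w * (y - fitted) ** 2).sum(axis=1) / dfres
    cov_unscaled = np.linalg.inv(XtWX)
    unscaled_se = np.sqrt(cov_unscaled[:, inj_col, inj_col])
    return GeneFits(
        gene_ids=list(wexpr.gene_ids),
        coef=beta[:, inj_col],
        unscaled_se=unscaled_se,
        sigma2=sigma2,
        df_residual=float(dfres),
        timepoint_h=tp,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) of the scaled-F prior on residual variances.

    Returns d0 = inf when the log variances underdisperse the sampling
    distribution (all shrinkage: posterior = common variance).
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    if np.ptp(z) < 1e-12:  # degenerate ensemble: posterior is the common variance
        return np.inf, float(s2[ok][0])
    e = z - scipy.special.digamma(df / 2) + np.log(df / 2)
    ebar = e.mean()
    n = e.size
    evar = ((e - ebar) ** 2).sum() / (n - 1)
    target = evar * n / (n - 1) - scipy.special.polygamma(1, df / 2)
    if target <= 0:
        s0 = float(np.exp(ebar))
        return np.inf, s0
    d0 = 2 * _trigamma_inverse(target)
    s0 = float(np.exp(ebar + scipy.special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0


def moderate(fits: GeneFits, prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics for the injury coefficient.

    ``prior_df`` overrides the estimated d0 (0 = no moderation, inf =
    full pooling); by default d0 and s0^2 come from the variance ensemble.
    """
    if len(fits.gene_ids) < 10 and prior_df is None:
        raise ValueError("moderation needs >= 10 genes to estimate the prior")
    d = fits.df_residual
    if prior_df is None:
        d0, s0 = estimate_prior(fits.sigma2, d)
    else:
        d0 = float(prior_df)
        if d0 == 0:
            s0 = 0.0  # no moderation: posterior variance = gene variance
        elif np.isinf(d0):
            # full pooling: geometric-mean ensemble variance
            s0 = float(np.exp(np.mean(np.log(fits.sigma2[fits.sigma2 > 0]))))
        else:
            _, s0 = estimate_prior(fits.sigma2, d)
    if np.isinf(d0):
        post_var = np.full_like(fits.sigma2, s0)
        df_total = np.inf
    else:
        post_var = (d0 * s0 + d * fits.sigma2) / (d0 + d)
        df_total = d0 + d
    se = fits.unscaled_se * np.sqrt(post_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.coef / se
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    if np.isinf(df_total):
        p = 2 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2 * scipy.stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "coef_log2": fits.coef,
            "moderated_t": t,
            "p": p,
            "q": q,
            "timepoint_h": fits.timepoint_h,
            "prior_df": d0,
            "prior_var": s0,
        }
    )


def associated_genes(results: pd.DataFrame, fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Rows with q below the threshold, sorted by q ascending."""
    hits = results.loc[results["q"] < fdr_threshold].sort_values(["q", "gene_id"])
    hits = hits.reset_index(drop=True)
    hits.attrs["fdr_threshold"] = fdr_threshold
    return hits


def associate_at_timepoint(
    counts: CountMatrix,
    samples: SampleTable,
    factors: NormFactors | None,
    timepoint: float,
    fdr_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end association at one timepoint: transform, fit, moderate.

    Returns (full moderated table, hits below the FDR threshold).
    """
    mask = samples.data["timepoint_h"] == timepoint
    if not mask.any():
        raise ValueError(f"no samples at timepoint {timepoint}")
    sub_samples = samples.subset(mask)
    sub = counts.subset_samples(sub_samples.sample_ids)
    X = injury_design(sub_samples)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    wexpr = precision_weight_transform(sub, factors, X[:, keep])
    fits = fit_injury_model(wexpr, sub_samples, timepoint)
    table = moderate(fits)
    return table, associated_genes(table, fdr_threshold)
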