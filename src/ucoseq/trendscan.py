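"""Two-step time-series trend analysis of post-occlusion expression.

Step one screens every gene for a pre/post-occlusion expression change
with a negative-binomial log-linear model (offset = log effective library
size, phase dummy, likelihood-ratio test against the intercept-only
model), correcting across genes by Benjamini-Hochberg.  Step two fits
each screened gene a polynomial in (centred, scaled) time with backward
elimination of nonsignificant terms and computes a deviance-based
goodness of fit R^2 = 1 - D_res / D_null.  Genes with R^2 >= 0.6 and
screen FDR < 0.05 form the trend set, which is finally split by the sign
of the fitted change at the first post-occlusion timepoint (6 h) relative
to baseline.

Treatment arms only differ from 72 h onward, so — rather than adjusting
for arm — the screen and fits run on the confound-free subset: all
animals at -1/6/24 h plus vehicle-arm animals at 72 h and 7 d.

The NB-GLM IRLS solver is vectorized across genes (all genes share the
design matrix), which keeps genome-scale screens fast on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ucoseq.core_io import CountMatrix, SampleTable, bh_adjust
from ucoseq.normtmm import NormFactors

logger = logging.getLogger("ucoseq")

#: treatment infusions distinguish the arms only at timepoints >= this
TREATMENT_ONSET_H = 72.0


@dataclass
class TrendConfig:
    polynomial_degree: int = 2
    screen_alpha: float = 0.05
    r2_threshold: float = 0.6
    nb_theta: float | str = 10.0      # NB size; "estimate" for per-gene moments
    time_encoding: str = "hours"      # hours (centred/scaled) or rank
    term_alpha: float = 0.05          # backward-elimination per-term threshold

    def __post_init__(self) -> None:
        if self.polynomial_degree < 1:
            raise ValueError("polynomial_degree must be >= 1")
        if self.time_encoding not in ("hours", "rank"):
            raise ValueError("time_encoding must be 'hours' or 'rank'")


@dataclass
class TrendFit:
    gene_id: str
    screen_p: float
    screen_q: float
    coefficients: np.ndarray
    terms: tuple[int, ...]            # polynomial orders retained (0 = intercept)
    r2: float
    selected: bool = False
    direction_6h: str | None = None
    untestable: bool = False


# ---------------------------------------------------------------------------
# vectorized NB GLM


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene NB2 (or Poisson, alpha=0) deviance; y, mu are genes x n."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if alpha == 0:
        dev = term1 - (y - mu)
    else:
        r = 1.0 / alpha
        dev = term1 - (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * dev.sum(axis=1)


def nb_glm_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float = 0.1,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of a shared-design NB log-linear model for many genes at once.

    Parameters
    ----------
    y : (G, n) counts, X : (n, p) design, offset : (n,) log effective libsize,
    alpha : NB dispersion (var = mu + alpha mu^2); 0 means Poisson.

    Returns (beta (G, p), deviance (G,), cov (G, p, p)) where cov is the
    inverse weighted information, giving Wald standard errors.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    G, n = y.shape
    p = X.shape[1]
    eta = np.log(y + 0.5) - offset          # linear predictor sans offset
    beta = np.zeros((G, p))
    dev = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    cov = np.zeros((G, p, p))
    for _ in range(max_iter):
        if not active.any():
            break
        mu = np.exp(eta[active] + offset)
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + alpha * mu)
        z = eta[active] + (y[active] - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, w, z)
        # ridge whisper keeps rank-deficient corner cases solvable
        XtWX += 1e-10 * np.eye(p)
        b_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta_new = b_new @ X.T
        eta_new = np.clip(eta_new, -30, 30)
        mu_new = np.exp(eta_new + offset)
        d_new = _nb_deviance(y[active], mu_new, alpha)
        idx = np.flatnonzero(active)
        converged = np.abs(d_new - dev[idx]) < tol * (np.abs(d_new) + 0.1)
        beta[idx] = b_new
        eta[idx] = eta_new
        dev[idx] = d_new
        cov[idx] = np.linalg.inv(XtWX)
        active[idx[converged]] = False
    return beta, dev, cov


def estimate_dispersion(y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on offset-scaled counts."""
    scale = np.exp(offset - offset.mean())
    r = y / scale
    m = r.mean(axis=1)
    v = r.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    return np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, 10.0)


# ---------------------------------------------------------------------------
# subset + encodings


def vehicle_trend_subset(samples: SampleTable) -> SampleTable:
    """Confound-free trend subset: everyone early, vehicle-only late."""
    df = samples.data
    keep = (df["timepoint_h"] < TREATMENT_ONSET_H) | (df["treatment"] == "vehicle")
    return samples.subset(keep)


def encode_time(timepoints_h: np.ndarray, encoding: str = "hours") -> np.ndarray:
    """Centred/scaled time axis (hours default; rank treats points as 0..k-1)."""
    t = np.asarray(timepoints_h, dtype=float)
    if encoding == "rank":
        levels = np.unique(t)
        t = np.searchsorted(levels, t).astype(float)
    return (t - t.mean()) / t.std()


def _offsets(counts: CountMatrix, factors: NormFactors | None) -> np.ndarray:
    libs = counts.library_sizes()
    f = factors.for_samples(counts.sample_ids) if factors is not None else np.ones(len(libs))
    return np.log(libs * f)


# ---------------------------------------------------------------------------
# step 1: pre/post screen


def screen_pre_post(
    counts: CountMatrix,
    samples: SampleTable,
    factors: NormFactors | None = None,
    config: TrendConfig | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio screen of every gene for a pre/post phase effect.

    Returns a frame (gene_id, screen_p, screen_q, untestable) in the gene
    order of the input matrix; q-values are Benjamini-Hochberg over the
    testable genes.
    """
    config = config or TrendConfig()
    sub_samples = vehicle_trend_subset(samples)
    sub = counts.subset_samples(sub_samples.sample_ids)
    phases = sub_samples.data["phase"].to_numpy()
    if len(set(phases)) < 2:
        raise ValueError("both pre and post phases are required for the screen")
    offset = _offsets(sub, factors)
    alpha = _resolve_alpha(config, sub.values, offset)
    X_full = np.column_stack([np.ones(len(phases)), (phases == "post").astype(float)])
    X_null = X_full[:, :1]
    y = sub.values.astype(float)
    untestable = (y.sum(axis=1) == 0)
    _, dev_full, _ = nb_glm_fit(y, X_full, offset, alpha=alpha)
    _, dev_null, _ = nb_glm_fit(y, X_null, offset, alpha=alpha)
    lrt = np.maximum(dev_null - dev_full, 0.0)
    p = scipy.stats.chi2.sf(lrt, df=1)
    p[untestable] = 1.0
    if untestable.any():
        logger.warning("%d all-zero genes flagged untestable in screen", untestable.sum())
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "screen_p": p,
            "screen_q": q,
            "untestable": untestable,
        }
    )


def _resolve_alpha(config: TrendConfig, y: np.ndarray, offset: np.ndarray) -> float:
    if config.nb_theta == "estimate":
        per_gene = estimate_dispersion(y, offset)
        return float(np.median(per_gene))
    return 1.0 / float(config.nb_theta)


# ---------------------------------------------------------------------------
# step 2: polynomial fit


def fit_polynomial(
    counts_gene: np.ndarray,
    samples: SampleTable,
    factors: NormFactors | None = None,
    config: TrendConfig | None = None,
    counts: CountMatrix | None = None,
) -> tuple[np.ndarray, tuple[int, ...], float]:
    """Polynomial-in-time NB fit of a single gene with backward elimination.

    Terms whose Wald p >= the per-term threshold are removed highest order
    first, refitting after each removal.  Returns (coefficients, retained
    orders including the intercept 0, R^2).
    """
    config = config or TrendConfig()
    sub_samples = vehicle_trend_subset(samples)
    y = np.asarray(counts_gene, dtype=float)
    if counts is not None:
        sub = counts.subset_samples(sub_samples.sample_ids)
        offset = _offsets(sub, factors)
    else:
        if len(y) != len(sub_samples.data):
            raise ValueError("counts_gene must align with the vehicle trend subset")
        offset = np.zeros(len(y))
    t = encode_time(sub_samples.data["timepoint_h"].to_numpy(), config.time_encoding)
    degree = min(config.polynomial_degree, len(np.unique(t)) - 1)
    if len(y) < degree + 2:
        raise ValueError("too few samples for the requested polynomial degree")
    alpha = _resolve_alpha(config, y[None, :], offset)
    y2 = y[None, :]
    _, dev_null, _ = nb_glm_fit(y2, np.ones((len(y), 1)), offset, alpha=alpha)
    terms = list(range(degree + 1))  # 0 = intercept, kept always
    while True:
        X = np.column_stack([t**k for k in terms])
        beta, dev, cov = nb_glm_fit(y2, X, offset, alpha=alpha)
        se = np.sqrt(np.maximum(np.diagonal(cov[0]), 1e-300))
        wald_p = 2 * scipy.stats.norm.sf(np.abs(beta[0] / se))
        # candidate for removal: highest-order nonsignificant non-intercept term
        removable = [
            (order, i) for i, order in enumerate(terms)
            if order > 0 and wald_p[i] >= config.term_alpha
        ]
        if not removable:
            break
        worst_order = max(o for o, _ in removable)
        terms = [o for o in terms if o != worst_order]
        if terms == [0]:
            X = np.ones((len(y), 1))
            beta, dev, cov = nb_glm_fit(y2, X, offset, alpha=alpha)
            break
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - dev[0] / dev_null[0] if dev_null[0] > 0 else 0.0
    r2 = float(np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0))
    return beta[0], tuple(terms), r2


# ---------------------------------------------------------------------------
# selection + 6-h split


def scan_trends(
    counts: CountMatrix,
    samples: SampleTable,
    factors: NormFactors | None = None,
    config: TrendConfig | None = None,
) -> pd.DataFrame:
    """Full two-step scan: screen, fit screened genes, select, split at 6 h.

    Returns one row per gene with screen p/q, R^2, retained polynomial
    orders, the selected flag and the 6-h direction for selected genes,
    ordered by (q, gene_id) among selected genes first.
    """
    config = config or TrendConfig()
    screen = screen_pre_post(counts, samples, factors, config)
    sub_samples = vehicle_trend_subset(samples)
    sub = counts.subset_samples(sub_samples.sample_ids)
    t_all = sub_samples.data["timepoint_h"].to_numpy()
    tenc = encode_time(t_all, config.time_encoding)
    t_levels = np.unique(t_all)
    # encoded coordinates of baseline and first post-occlusion timepoint
    z_levels = encode_time(t_levels, config.time_encoding)
    z_pre, z_6h = z_levels[0], z_levels[1] if len(z_levels) > 1 else z_levels[-1]

    rows = []
    candidates = screen.loc[
        (screen["screen_q"] < config.screen_alpha) & ~screen["untestable"]
    ]
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    for _, srow in candidates.iterrows():
        g = srow["gene_id"]
        yi = sub.values[gene_pos[g]].astype(float)
        try:
            beta, terms, r2 = fit_polynomial(yi, samples, factors, config, counts=counts)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("gene %s excluded from trend fit: %s", g, exc)
            continue
        selected = bool(r2 >= config.r2_threshold and srow["screen_q"] < config.screen_alpha)
        direction = None
        if selected:
            def eval_poly(z):
                return sum(b * z**k for b, k in zip(beta, terms))
            diff = eval_poly(z_6h) - eval_poly(z_pre)
            if diff == 0:  # fall back to observed means
                m6 = yi[t_all == t_levels[1]].mean() if len(t_levels) > 1 else 0.0
                m0 = yi[t_all == t_levels[0]].mean()
                diff = m6 - m0
            direction = "up" if diff > 0 else "down"
        rows.append(
            {
                "gene_id": g,
                "screen_p": srow["screen_p"],
                "screen_q": srow["screen_q"],
                "r2": r2,
                "degree": max(terms) if len(terms) > 1 else 0,
                "selected": selected,
                "direction_6h": direction,
            }
        )
    fitted = pd.DataFrame(
        rows, columns=["gene_id", "screen_p", "screen_q", "r2", "degree",
                       "selected", "direction_6h"]
    )
    rest = screen.loc[~screen["gene_id"].isin(fitted["gene_id"])].copy()
    rest["r2"] = np.nan
    rest["degree"] = 0
    rest["selected"] = False
    rest["direction_6h"] = None
    out = pd.concat([fitted, rest[fitted.columns]], ignore_index=True)
    out = out.sort_values(
        ["selected", "screen_q", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out


def select_trends(fits: pd.DataFrame, config: TrendConfig | None = None) -> pd.DataFrame:
    """Rows passing both thresholds, ordered by (q, gene_id)."""
    config = config or TrendConfig()
    if fits.empty:
        return fits
    sel = fits.loc[
        (fits["screen_q"] < config.screen_alpha) & (fits["r2"] >= config.r2_threshold)
    ]
    return sel.sort_values(["screen_q", "gene_id"]).reset_index(drop=True)


def split_by_6h(selected: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Disjoint (up, down) gene lists from the 6-h direction labels."""
    up = selected.loc[selected["direction_6h"] == "up", "gene_id"].tolist()
    down = selected.loc[selected["direction_6h"] == "down", "gene_id"].tolist()
    return up, down
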