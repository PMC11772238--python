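"""Between-sample normalization: CPM scaling and trimmed mean of M-values.

TMM corrects for library composition on top of sequencing depth.  For each
sample a log2 expression ratio M and log2 mean abundance A are computed
against a reference sample over genes nonzero in both; after discarding
the most extreme 30% of M values and 5% of A values (two-sided), the scale
factor is 2 to the precision-weighted mean of the surviving M values, with
weights from the delta-method (binomial) variance of each log ratio.
Factors are re-centred so their geometric mean is one, and are applied as
effective-library multipliers — raw counts are never mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ucoseq.core_io import CountMatrix

LOGRATIO_TRIM = 0.30
SUM_TRIM = 0.05


@dataclass
class NormFactors:
    """Per-sample TMM scale factors (geometric mean 1) plus provenance."""

    sample_ids: list[str]
    factors: np.ndarray
    reference_sample: str
    logratio_trim: float = LOGRATIO_TRIM
    sum_trim: float = SUM_TRIM
    weighted: bool = True

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, self.factors))

    def for_samples(self, sample_ids) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[s] for s in sample_ids])


def cpm(
    counts: CountMatrix | np.ndarray,
    factors: NormFactors | np.ndarray | None = None,
    log: bool = False,
    prior_count: float = 0.5,
    lib_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Counts per million over TMM-effective library sizes.

    ``log=True`` returns log2((count + prior_count) / effective_lib * 1e6).
    """
    if isinstance(counts, CountMatrix):
        values = counts.values.astype(float)
        libs = counts.library_sizes()
        if isinstance(factors, NormFactors):
            f = factors.for_samples(counts.sample_ids)
        else:
            f = np.ones(values.shape[1]) if factors is None else np.asarray(factors, float)
    else:
        values = np.asarray(counts, dtype=float)
        libs = values.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
        f = np.ones(values.shape[1]) if factors is None else np.asarray(factors, float)
    eff = libs * f
    if (eff <= 0).any():
        j = int(np.flatnonzero(eff <= 0)[0])
        raise ValueError(f"zero effective library size in column {j}")
    if log:
        return np.log2((values + prior_count) / eff * 1e6)
    return values / eff * 1e6


def _choose_reference(values: np.ndarray) -> int:
    """Sample whose upper quartile of nonzero-gene CPM is nearest the mean UQ.

    Ties go to the lowest sample index.
    """
    libs = values.sum(axis=0)
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        nz = col[col > 0]
        uq[j] = np.quantile(nz / libs[j] * 1e6, 0.75) if nz.size else 0.0
    return int(np.argmin(np.abs(uq - uq.mean())))


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return np.nan
    o = obs[both] / lib_obs
    r = ref[both] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method variance of M (binomial sampling in each library)
    v = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (
        lib_ref * ref[both]
    )
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if weighted:
        return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    return float(np.mean(m[keep]))


def _rank(x: np.ndarray) -> np.ndarray:
    import scipy.stats

    return scipy.stats.rankdata(x)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = LOGRATIO_TRIM,
    sum_trim: float = SUM_TRIM,
    weighted: bool = True,
) -> NormFactors:
    """TMM normalization factors for every sample of a count matrix."""
    values = counts.values.astype(float)
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (values.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero gene")
    ref_idx = _choose_reference(values)
    libs = values.sum(axis=0)
    logf = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        if j == ref_idx:
            continue
        f = _pair_factor(
            values[:, j], values[:, ref_idx], libs[j], libs[ref_idx],
            logratio_trim, sum_trim, weighted,
        )
        if np.isnan(f):
            warnings.warn(
                f"sample {counts.sample_ids[j]!r} shares no nonzero genes with the "
                "reference; factor set to 1"
            )
            f = 0.0
        logf[j] = f
    factors = 2.0 ** (logf - logf.mean())  # geometric mean 1
    return NormFactors(
        sample_ids=list(counts.sample_ids),
        factors=factors,
        reference_sample=counts.sample_ids[ref_idx],
        logratio_trim=logratio_trim,
        sum_trim=sum_trim,
        weighted=weighted,
    )


def write_factors(factors: NormFactors, path, seed: int | None = None) -> None:
    from ucoseq.core_io import _header_comment

    with open(path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("sample_id\tfactor\treference\n")
        for s, f in zip(factors.sample_ids, factors.factors):
            flag = int(s == factors.reference_sample)
            fh.write(f"{s}\t{f:.12g}\t{flag}\n")
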