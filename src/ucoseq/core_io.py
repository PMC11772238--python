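"""Data model, validated readers/writers, and shared statistical utilities.

The pipeline's tabular currency is three objects: a gene x sample count
matrix (:class:`CountMatrix`), a per-sample design table
(:class:`SampleTable`) recording animal, timepoint, treatment arm,
pre/post-occlusion phase and injury class, and a cell-type marker table
(:class:`MarkerTable`).  All on-disk formats are plain text: TSV for counts
and samples, CSV for markers, and MatrixMarket with ``genes.txt`` /
``samples.txt`` sidecars for sparse interchange.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("ucoseq")

VALID_TREATMENTS = ("vehicle", "active")
VALID_PHASES = ("pre", "post")
VALID_INJURY_CLASSES = ("mild", "severe", "unknown")


class FormatError(ValueError):
    """Malformed input file; message carries the offending location."""


class DesignError(ValueError):
    """Counts and sample metadata are inconsistent."""


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix.

    Genes are rows, samples are columns.  Identifiers are opaque unique
    strings; no accession scheme is assumed.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("count matrix must be 2-dimensional")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != n_g:
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        _check_nonneg_int(self.values, self.gene_ids, self.sample_ids)
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.values[:, idx], list(self.gene_ids), list(sample_ids))


def _check_nonneg_int(values: np.ndarray, gene_ids, sample_ids) -> None:
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("count matrix contains non-numeric entries")
    bad = ~np.isfinite(arr.astype(float))
    bad |= arr.astype(float) < 0
    bad |= arr.astype(float) != np.floor(arr.astype(float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid count {arr[i, j]!r} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}: counts must be nonnegative integers"
        )


@dataclass
class SampleTable:
    """Per-sample design metadata.

    One row per sample: ``sample_id``, ``animal_id``, ``timepoint_h``
    (hours relative to occlusion; -1 is the pre-occlusion baseline, 7 days
    is 168), ``treatment`` (vehicle/active), ``phase`` (pre iff
    timepoint_h < 0) and ``injury_class`` (mild/severe/unknown).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "animal_id", "timepoint_h", "treatment", "phase", "injury_class")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["animal_id"] = df["animal_id"].astype(str)
        df["timepoint_h"] = df["timepoint_h"].astype(float)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        for col, valid in (("treatment", VALID_TREATMENTS), ("phase", VALID_PHASES),
                           ("injury_class", VALID_INJURY_CLASSES)):
            bad = ~df[col].isin(valid)
            if bad.any():
                raise FormatError(
                    f"invalid {col} value {df.loc[bad, col].iloc[0]!r}; legal: {valid}"
                )
        want_pre = df["timepoint_h"] < 0
        mismatch = (df["phase"] == "pre") != want_pre
        if mismatch.any():
            sid = df.loc[mismatch, "sample_id"].iloc[0]
            raise FormatError(f"sample {sid!r}: phase must be 'pre' iff timepoint_h < 0")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))

    def for_samples(self, sample_ids: Sequence[str]) -> "SampleTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(df)


@dataclass
class MarkerTable:
    """Cell-type-specific marker genes, optionally with cross-species orthologs."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        for col in ("marker_gene_id", "cell_type"):
            if col not in df.columns:
                raise FormatError(f"marker table missing column {col!r}")
        if "ortholog_id" not in df.columns:
            df["ortholog_id"] = pd.NA
        df["marker_gene_id"] = df["marker_gene_id"].astype(str)
        df["cell_type"] = df["cell_type"].astype(str)
        # cell-type-specific markers only: a gene may back exactly one type
        dup = df["marker_gene_id"].duplicated()
        if dup.any():
            raise FormatError(
                f"marker {df.loc[dup, 'marker_gene_id'].iloc[0]!r} assigned to multiple cell types"
            )
        self.data = df.reset_index(drop=True)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.data["cell_type"].unique())

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers / writers


def _header_comment(seed: int | None = None) -> str:
    from ucoseq import __version__

    tag = f"# ucoseq v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag


def write_counts(matrix: CountMatrix, path: str | Path, seed: int | None = None) -> None:
    """Write a count matrix as gene x sample TSV (``gene_id`` first column)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket (.mtx with sidecars)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene-id column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    body = df.drop(columns=[gene_col])
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric count entry ({exc})") from exc
    try:
        return CountMatrix(values, genes, list(body.columns))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts_mtx(matrix: CountMatrix, path: str | Path) -> None:
    """Write MatrixMarket triplet plus ``genes.txt``/``samples.txt`` sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
    path.parent.joinpath("genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    path.parent.joinpath("samples.txt").write_text("\n".join(matrix.sample_ids) + "\n")


def _read_counts_mtx(path: Path) -> CountMatrix:
    genes_f = path.parent / "genes.txt"
    samples_f = path.parent / "samples.txt"
    for f in (genes_f, samples_f):
        if not f.exists():
            raise FormatError(f"{path}: missing sidecar {f.name}")
    mat = scipy.io.mmread(str(path))
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = genes_f.read_text().splitlines()
    samples = samples_f.read_text().splitlines()
    try:
        return CountMatrix(values, genes, samples)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_samples(samples: SampleTable, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        samples.data.to_csv(fh, sep="\t", index=False)


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SampleTable(df)


def write_markers(markers: MarkerTable, path: str | Path) -> None:
    markers.data.to_csv(path, index=False)


def read_markers(path: str | Path) -> MarkerTable:
    return MarkerTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# shared statistics


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{k >= i} ( m * p_(k) / k ), capped at 1, returned in the
    input order.  NaNs propagate and do not count toward m.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[finite] = out
    return q


def validate_design(counts: CountMatrix, samples: SampleTable) -> tuple[CountMatrix, SampleTable]:
    """Cross-check a count matrix against its sample metadata.

    Sample sets must coincide; animals lacking a pre-occlusion baseline or
    any post sample are retained but flagged with a warning.
    """
    cs = set(counts.sample_ids)
    ms = set(samples.sample_ids)
    if not (cs & ms):
        raise DesignError("no sample ids shared between counts and metadata")
    only_counts = sorted(cs - ms)
    if only_counts:
        raise DesignError(f"samples in counts absent from metadata: {only_counts}")
    only_meta = sorted(ms - cs)
    if only_meta:
        raise DesignError(f"samples in metadata absent from counts: {only_meta}")
    df = samples.data
    for animal, grp in df.groupby("animal_id"):
        phases = set(grp["phase"])
        if "pre" not in phases:
            warnings.warn(f"animal {animal!r} has no pre-occlusion baseline sample")
            logger.warning("animal %r has no pre-occlusion baseline sample", animal)
        if "post" not in phases:
            warnings.warn(f"animal {animal!r} has no post-occlusion samples")
            logger.warning("animal %r has no post-occlusion samples", animal)
    # align metadata row order to the count matrix columns
    aligned = samples.for_samples(counts.sample_ids)
    return counts, aligned
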