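"""Core data containers and TSV input/output.

The lingua franca of the package is the :class:`OmicsMatrix`, a features-by-samples
abundance table with string identifiers on both axes.  All pipeline stages consume
and produce these matrices; :class:`MultiOmicsDataset` bundles the transcriptome
layers (mature mRNA, pre-mRNA, normalized 3'UTR length), the optional protein layer
used for training, and per-sample metadata.

On disk a matrix is a plain TSV: first column feature IDs, header row sample IDs,
``NA`` for missing cells.  Internally values are a float array with NaN for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "align_samples",
]


class MatrixError(ValueError):
    """Raised for malformed matrices or matrix files."""


class AlignmentError(ValueError):
    """Raised when datasets share no common samples."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise MatrixError(f"duplicate {what} ID {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class OmicsMatrix:
    """A features x samples abundance matrix with missing values as NaN."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_features, n_samples), float, NaN = missing

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixError("values must be 2-D")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise MatrixError(
                f"value array shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    # -- convenience -------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OmicsMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise MatrixError(f"samples not present: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return OmicsMatrix(list(self.feature_ids), list(sample_ids), self.values[:, cols])

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.feature_index()
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise MatrixError(f"features not present: {missing[:5]}")
        rows = [idx[f] for f in feature_ids]
        return OmicsMatrix(list(feature_ids), list(self.sample_ids), self.values[rows, :])


@dataclass
class MultiOmicsDataset:
    """Aligned multi-omics bundle: transcriptome layers, optional proteome, metadata.

    ``metadata`` is a per-sample DataFrame indexed by sample ID (diagnosis,
    pathology scores, cognition slope, age, sex, education, ...).
    """

    mrna: OmicsMatrix
    premrna: OmicsMatrix | None = None
    utr: OmicsMatrix | None = None
    protein: OmicsMatrix | None = None
    metadata: pd.DataFrame | None = None

    def layers(self) -> dict[str, OmicsMatrix]:
        out = {"mrna": self.mrna}
        if self.premrna is not None:
            out["premrna"] = self.premrna
        if self.utr is not None:
            out["utr"] = self.utr
        if self.protein is not None:
            out["protein"] = self.protein
        return out

    def layer(self, name: str) -> OmicsMatrix:
        got = self.layers().get(name)
        if got is None:
            raise MatrixError(f"dataset has no {name!r} layer")
        return got

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    def subset_samples(self, sample_ids: Sequence[str]) -> "MultiOmicsDataset":
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[list(sample_ids)]
        return MultiOmicsDataset(
            mrna=self.mrna.subset_samples(sample_ids),
            premrna=None if self.premrna is None else self.premrna.subset_samples(sample_ids),
            utr=None if self.utr is None else self.utr.subset_samples(sample_ids),
            protein=None if self.protein is None else self.protein.subset_samples(sample_ids),
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> OmicsMatrix:
    """Read a features x samples TSV (first column feature IDs, ``NA`` missing)."""
    header: list[str] | None = None
    feats: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise MatrixError(
                    f"{path}: row {lineno} has {len(parts) - 1} values, "
                    f"expected {len(header)}"
                )
            feats.append(parts[0])
            try:
                rows.append([np.nan if v in ("NA", "") else float(v) for v in parts[1:]])
            except ValueError as e:
                raise MatrixError(f"{path}: row {lineno}: {e}") from None
    if header is None:
        raise MatrixError(f"{path}: empty file")
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    try:
        return OmicsMatrix(feats, header, values)
    except MatrixError as e:
        raise MatrixError(f"{path}: {e}") from None


def write_matrix_tsv(matrix: OmicsMatrix, path, float_format: str = "%.12g") -> None:
    """Write a matrix as TSV; NaN is written as ``NA``.

    The default float format keeps 12 significant digits so a write/read round
    trip is lossless for practical purposes.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(["feature_id", *matrix.sample_ids]) + "\n")
        for f, row in zip(matrix.feature_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else float_format % v for v in row]
            fh.write("\t".join([f, *cells]) + "\n")


def align_samples(dataset: MultiOmicsDataset, verbose: bool = False) -> MultiOmicsDataset:
    """Restrict every layer (and metadata) to the common samples, same order.

    Order follows the mRNA layer's sample order.  Raises
    :class:`AlignmentError` if the intersection is empty.
    """
    common = set(dataset.mrna.sample_ids)
    for name, layer in dataset.layers().items():
        common &= set(layer.sample_ids)
    if dataset.metadata is not None:
        common &= set(map(str, dataset.metadata.index))
    if not common:
        raise AlignmentError("no samples shared by all dataset parts")
    ordered = [s for s in dataset.mrna.sample_ids if s in common]
    n_drop = max(len(l.sample_ids) for l in dataset.layers().values()) - len(ordered)
    if verbose and n_drop:
        print(f"align_samples: kept {len(ordered)} samples, dropped up to {n_drop}")
    return dataset.subset_samples(ordered)
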