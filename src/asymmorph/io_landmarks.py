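"""Landmark, matrix and tree I/O.

Landmark configurations travel as ``LandmarkConfiguration`` /
``LandmarkSample`` objects.  Two on-disk dialects are supported: the TPS
digitizer format (``LM=`` / ``ID=`` / ``SCALE=`` records) and a flat CSV with
one specimen per row and columns ``<label>_x, <label>_y[, <label>_z]``.
Coordinates are stored exactly as digitized — no centering or scaling happens
on read; all normalization is explicit in :mod:`asymmorph.procrustes`.

Rooted phylogenies come in as Newick via dendropy and are converted to the
lightweight :class:`~asymmorph.phylo_contrasts.Phylogeny` container.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ParseError, StructuralError

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSample",
    "SquareMatrixInput",
    "read_landmarks",
    "write_landmarks",
    "read_square_matrix",
    "write_square_matrix",
    "read_tree",
]


@dataclass
class LandmarkConfiguration:
    """k labelled points in d dimensions (d in {2, 3}).

    Coordinates are Cartesian, in whatever (uniform) length unit the
    digitizer produced.  Labels are the public identity of landmarks;
    internal indexing is 0-based.
    """

    coords: np.ndarray
    labels: list[str]
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise DimensionError(
                f"coords must be k×2 or k×3, got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinate in configuration")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.coords.shape[0]:
            raise StructuralError(
                f"{len(self.labels)} labels for {self.coords.shape[0]} landmarks"
            )
        if len(set(self.labels)) != len(self.labels):
            raise StructuralError("duplicated landmark label")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def as_vector(self) -> np.ndarray:
        """Interleaved coordinate vector (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(-1)

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, labels: Sequence[str], dim: int = 2, specimen_id: str = ""
    ) -> "LandmarkConfiguration":
        vec = np.asarray(vec, dtype=float)
        return cls(vec.reshape(-1, dim), list(labels), specimen_id)


@dataclass
class LandmarkSample:
    """An ordered sample of configurations sharing k, d, and label order."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise StructuralError("a LandmarkSample requires n >= 1 configurations")
        ref = self.configurations[0]
        for c in self.configurations[1:]:
            if c.k != ref.k or c.dim != ref.dim:
                raise StructuralError(
                    f"specimen {c.specimen_id!r}: inconsistent landmark count or dimension"
                )
            if c.labels != ref.labels:
                raise StructuralError(
                    f"specimen {c.specimen_id!r}: label order differs from first specimen"
                )

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def dim(self) -> int:
        return self.configurations[0].dim

    @property
    def labels(self) -> list[str]:
        return self.configurations[0].labels

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __len__(self) -> int:
        return self.n

    def as_matrix(self) -> np.ndarray:
        """n × (k·d) matrix of interleaved coordinate vectors."""
        return np.stack([c.as_vector() for c in self.configurations])

    @classmethod
    def from_matrix(
        cls,
        mat: np.ndarray,
        labels: Sequence[str],
        dim: int = 2,
        specimen_ids: Sequence[str] | None = None,
    ) -> "LandmarkSample":
        mat = np.asarray(mat, dtype=float)
        if specimen_ids is None:
            specimen_ids = [f"spec_{i}" for i in range(mat.shape[0])]
        return cls(
            [
                LandmarkConfiguration.from_vector(row, labels, dim, sid)
                for row, sid in zip(mat, specimen_ids)
            ]
        )


@dataclass
class SquareMatrixInput:
    """A symmetric correlation or covariance matrix with variable names."""

    values: np.ndarray
    variable_names: list[str]
    kind: Literal["correlation", "covariance"] = "covariance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise DimensionError(f"matrix must be square, got {self.values.shape}")
        if len(self.variable_names) != p:
            raise StructuralError("variable_names length must match matrix order")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise StructuralError("matrix is not symmetric to tolerance 1e-8")
        if self.kind == "correlation" and not np.allclose(
            np.diag(self.values), 1.0, atol=1e-8
        ):
            raise StructuralError("correlation matrix must have unit diagonal")

    @property
    def p(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

def _parse_tps(text: str, path: str) -> LandmarkSample:
    configs: list[LandmarkConfiguration] = []
    lines = text.splitlines()
    i = 0
    n_line = 0
    while i < len(lines):
        line = lines[i].strip()
        n_line = i + 1
        i += 1
        if not line:
            continue
        up = line.upper()
        if not up.startswith("LM"):
            raise ParseError(f"{path}:{n_line}: expected LM= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{n_line}: malformed LM= record {line!r}") from None
        coords = []
        while len(coords) < k:
            if i >= len(lines):
                raise ParseError(
                    f"{path}:{n_line}: LM={k} but file ends after {len(coords)} points"
                )
            row = lines[i].strip()
            n_row = i + 1
            i += 1
            if not row:
                continue
            parts = row.split()
            try:
                coords.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(
                    f"{path}:{n_row}: expected coordinates, got {row!r}"
                ) from None
        dims = {len(c) for c in coords}
        if len(dims) != 1 or dims.pop() not in (2, 3):
            raise ParseError(f"{path}:{n_line}: inconsistent coordinate dimension")
        arr = np.array(coords, dtype=float)
        specimen_id = ""
        scale = None
        # trailing records up to the next LM=
        while i < len(lines):
            rec = lines[i].strip()
            if rec.upper().startswith("LM"):
                break
            i += 1
            if not rec:
                continue
            key, _, val = rec.partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = val.strip()
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError:
                    raise ParseError(f"{path}:{i}: malformed SCALE= record") from None
            elif key in ("CURVES", "POINTS", "IMAGE", "COMMENT"):
                warnings.warn(
                    f"{path}:{i}: skipping unsupported TPS record {key}=", stacklevel=3
                )
            # anything else silently tolerated (digitizer comments)
        if scale is not None:
            arr = arr * scale
        labels = [f"L{j+1}" for j in range(arr.shape[0])]
        configs.append(
            LandmarkConfiguration(arr, labels, specimen_id or f"spec_{len(configs)}")
        )
    if not configs:
        raise ParseError(f"{path}: no LM= records found")
    return LandmarkSample(configs)


def _format_tps(sample: LandmarkSample) -> str:
    out = io.StringIO()
    for c in sample:
        out.write(f"LM={c.k}\n")
        for row in c.coords:
            out.write(" ".join(f"{v:.15g}" for v in row) + "\n")
        out.write(f"ID={c.specimen_id}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_AXES = ("x", "y", "z")


def _parse_csv(text: str, path: str) -> LandmarkSample:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{path}:1: empty CSV") from None
    if not header or header[0].strip() != "specimen_id":
        raise ParseError(f"{path}:1: first column must be 'specimen_id'")
    cols = [h.strip() for h in header[1:]]
    labels: list[str] = []
    dim = None
    for name in cols:
        base, _, axis = name.rpartition("_")
        if not base or axis not in _AXES:
            raise ParseError(f"{path}:1: column {name!r} is not <label>_<x|y|z>")
        if base not in labels:
            labels.append(base)
    for d_try in (2, 3):
        expected = [f"{l}_{a}" for l in labels for a in _AXES[:d_try]]
        if cols == expected:
            dim = d_try
            break
    if dim is None:
        raise ParseError(
            f"{path}:1: columns must be grouped per landmark as label_x,label_y[,label_z]"
        )
    configs = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) != len(cols) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(cols)+1} fields")
        try:
            vals = np.array([float(v) for v in row[1:]], dtype=float)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
        configs.append(
            LandmarkConfiguration(vals.reshape(-1, dim), labels, row[0].strip())
        )
    if not configs:
        raise ParseError(f"{path}: no specimen rows")
    return LandmarkSample(configs)


def _format_csv(sample: LandmarkSample) -> str:
    out = io.StringIO()
    w = csv.writer(out, lineterminator="\n")
    axes = _AXES[: sample.dim]
    w.writerow(["specimen_id"] + [f"{l}_{a}" for l in sample.labels for a in axes])
    for c in sample:
        w.writerow([c.specimen_id] + [f"{v:.15g}" for v in c.as_vector()])
    return out.getvalue()


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path, format: str | None = None) -> LandmarkSample:
    """Read a landmark sample from a TPS or CSV file.

    ``format`` defaults to the file extension (.tps / .csv).  Specimen order
    in the file is preserved; no specimen is ever silently dropped.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    text = path.read_text()
    if fmt == "tps":
        return _parse_tps(text, str(path))
    if fmt == "csv":
        return _parse_csv(text, str(path))
    raise ValueError(f"unknown landmark format {fmt!r}")


def write_landmarks(
    sample: LandmarkSample, path: str | Path, format: str | None = None
) -> None:
    """Write a sample to TPS or CSV with >= 12 significant digits.

    ``read_landmarks(write_landmarks(s))`` reproduces coordinates to 1e-12.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        path.write_text(_format_tps(sample))
    elif fmt == "csv":
        path.write_text(_format_csv(sample))
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


def read_square_matrix(path: str | Path, kind: str | None = None) -> SquareMatrixInput:
    """Read a symmetric matrix from square CSV with a header row and column.

    ``kind`` defaults to 'correlation' when the diagonal is all ones, else
    'covariance'.
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column names differ")
    values = df.to_numpy(dtype=float)
    if kind is None:
        kind = "correlation" if np.allclose(np.diag(values), 1.0, atol=1e-8) else "covariance"
    return SquareMatrixInput(values, [str(c) for c in df.columns], kind)  # type: ignore[arg-type]


def write_square_matrix(m: SquareMatrixInput, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.variable_names, columns=m.variable_names)
    df.to_csv(path, float_format="%.15g")


def read_tree(path: str | Path):
    """Read a rooted Newick tree with branch lengths on every edge.

    Returns an :class:`asymmorph.phylo_contrasts.Phylogeny`.  Missing branch
    lengths and polytomies are rejected — the contrast machinery requires a
    fully bifurcating, fully dated tree.
    """
    from .phylo_contrasts import Phylogeny

    return Phylogeny.from_newick_file(path)
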