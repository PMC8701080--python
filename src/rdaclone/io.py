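"""Reading, validating, encoding and writing binary genotype matrices.

The on-disk format is a delimited table of cells × genotype sites with
entries in {0, 1, missing}.  Missing calls are encoded by sentinel tokens
(``3`` by convention in single-cell SNV matrices; ``NA``, ``-`` and empty
fields are also accepted).  Internally missing entries are stored as ``-1``
in an int8 array and the set of observed indices Ω is the single source of
truth for observedness: an observed 0 and a missing entry are distinct even
though both enter the decomposition as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Internal representation of a missing genotype call.
MISSING: int = -1


class GenotypeFormatError(ValueError):
    """Malformed input table (ragged rows, bad shape)."""


class GenotypeValueError(ValueError):
    """A token that is neither 0, 1 nor a recognised missing sentinel."""


class DegenerateInputError(ValueError):
    """Input carries no usable information (e.g. every entry missing)."""


@dataclass(frozen=True)
class MissingDialect:
    """Tokens treated as a missing genotype call on read/write."""

    sentinel_tokens: tuple[str, ...] = ("3", "NA", "-", "")
    write_token: str = "3"

    def __post_init__(self) -> None:
        if not self.sentinel_tokens:
            raise ValueError("sentinel_tokens must be non-empty")
        if self.write_token not in self.sentinel_tokens:
            raise ValueError("write_token must be one of sentinel_tokens")


@dataclass
class ObservedGenotypeMatrix:
    """A cells × sites binary mutation matrix with missing entries.

    ``values`` holds {0, 1, MISSING} as int8; rows are cells, columns are
    genotype sites.  ``omega_mask`` (derived) is 1 where the entry was
    observed.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise GenotypeFormatError("genotype matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise GenotypeFormatError(
                f"need at least 2 cells and 1 site, got {n} x {m}"
            )
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValueError(
                f"entry at cell {i}, site {j} is {self.values[i, j]}, "
                "expected 0, 1 or missing"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i + 1:04d}" for i in range(n)]
        if not self.site_ids:
            self.site_ids = [f"site_{j + 1:04d}" for j in range(m)]
        if len(self.cell_ids) != n or len(self.site_ids) != m:
            raise GenotypeFormatError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        """Number of cells (rows)."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of genotype sites (columns)."""
        return self.values.shape[1]

    @property
    def omega_mask(self) -> np.ndarray:
        """Binary n×m mask: 1 where the entry is observed."""
        return (self.values != MISSING).astype(np.float64)

    @property
    def omega(self) -> set[tuple[int, int]]:
        """Index set Ω of observed entries, as (cell, site) pairs."""
        return {(int(i), int(j)) for i, j in np.argwhere(self.values != MISSING)}

    @property
    def missing_rate(self) -> float:
        return float((self.values == MISSING).mean())


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _is_data_token(tok: str, dialect: MissingDialect) -> bool:
    return tok in ("0", "1") or tok in dialect.sentinel_tokens


def _is_labelish(tok: str, dialect: MissingDialect) -> bool:
    # a label is something that is neither a data token nor numeric;
    # a numeric non-data token (e.g. "2") is a value error, not a label
    if _is_data_token(tok, dialect):
        return False
    try:
        float(tok)
    except ValueError:
        return True
    return False


def read_genotype_matrix(
    path: str | Path,
    dialect: MissingDialect | None = None,
    orientation: str = "cells_as_rows",
    delimiter: str | None = None,
) -> ObservedGenotypeMatrix:
    """Parse a delimited genotype table into an :class:`ObservedGenotypeMatrix`.

    A header row and/or a leading label column are detected automatically:
    any first-row/first-column token outside {0, 1, sentinels} is treated as
    a label.  ``orientation='sites_as_rows'`` transposes on read so that the
    returned matrix is always cells × sites.
    """
    if orientation not in ("cells_as_rows", "sites_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    dialect = dialect or MissingDialect()
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)

    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append([tok.strip() for tok in line.split(sep)])
    if not rows:
        raise GenotypeFormatError(f"{path}: empty file")

    has_header = any(_is_labelish(t, dialect) for t in rows[0])
    body = rows[1:] if has_header else rows
    if not body:
        raise GenotypeFormatError(f"{path}: no data rows")
    has_labels = any(_is_labelish(r[0], dialect) for r in body)

    width = len(body[0])
    for offset, r in enumerate(body):
        if len(r) != width:
            lineno = offset + 1 + (1 if has_header else 0)
            raise GenotypeFormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(r)} fields, expected {width})"
            )

    row_labels = [r[0] for r in body] if has_labels else []
    col_start = 1 if has_labels else 0
    col_labels = rows[0][col_start:] if has_header else []

    n_rows, n_cols = len(body), width - col_start
    values = np.empty((n_rows, n_cols), dtype=np.int8)
    for i, r in enumerate(body):
        for j, tok in enumerate(r[col_start:]):
            if tok in dialect.sentinel_tokens:
                values[i, j] = MISSING
            elif tok == "0":
                values[i, j] = 0
            elif tok == "1":
                values[i, j] = 1
            else:
                raise GenotypeValueError(
                    f"{path}: token {tok!r} at row {i}, col {j} is not "
                    "0, 1 or a missing sentinel"
                )

    if orientation == "sites_as_rows":
        values = values.T
        row_labels, col_labels = col_labels, row_labels

    if (values == MISSING).all():
        raise DegenerateInputError(f"{path}: every entry is missing")

    return ObservedGenotypeMatrix(
        values=values, cell_ids=list(row_labels), site_ids=list(col_labels)
    )


def write_genotype_matrix(
    g: ObservedGenotypeMatrix,
    path: str | Path,
    dialect: MissingDialect | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a genotype matrix (cells × sites) with header and row labels."""
    dialect = dialect or MissingDialect()
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w") as fh:
        fh.write("cell_id" + sep + sep.join(g.site_ids) + "\n")
        for i in range(g.n):
            toks = [
                dialect.write_token if v == MISSING else str(int(v))
                for v in g.values[i]
            ]
            fh.write(g.cell_ids[i] + sep + sep.join(toks) + "\n")


def encode_for_rda(g: ObservedGenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill missing entries and return (X, Ω-mask) for the decomposition.

    This realises the projection PΩ: X carries the observed values and 0
    elsewhere; the mask is 1 exactly on Ω.
    """
    mask = g.omega_mask
    X = np.where(g.values == MISSING, 0, g.values).astype(np.float64)
    return X, mask


def _ordered_indices(labels: np.ndarray) -> np.ndarray:
    # stable sort: cluster label first, original order within a cluster
    return np.lexsort((np.arange(len(labels)), labels))


def _write_table(path: Path, matrix: np.ndarray, row_ids, col_ids, fmt="%d"):
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, matrix):
            fh.write(rid + "\t" + "\t".join(fmt % v for v in row) + "\n")


def write_outputs(
    outdir: str | Path,
    *,
    genotype: ObservedGenotypeMatrix,
    decomposition,
    assignment,
    tree,
    metrics: dict | None = None,
    site_labels: np.ndarray | None = None,
) -> list[Path]:
    """Write the pipeline artifact set into ``outdir``.

    In ``recovered.tsv`` cells are ordered by subclone label then original
    index (heatmap-style block ordering); sites likewise when a site
    clustering is supplied, else original order.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    labels = np.asarray(assignment.labels)
    cell_order = _ordered_indices(labels)
    if site_labels is not None:
        site_order = _ordered_indices(np.asarray(site_labels))
    else:
        site_order = np.arange(genotype.m)

    written: list[Path] = []
    cid = [genotype.cell_ids[i] for i in cell_order]
    sid = [genotype.site_ids[j] for j in site_order]

    p = outdir / "recovered.tsv"
    calls = decomposition.genotype_calls[np.ix_(cell_order, site_order)]
    _write_table(p, calls, cid, sid)
    written.append(p)

    p = outdir / "sparse.tsv"
    _write_table(p, decomposition.S, genotype.cell_ids, genotype.site_ids, "%.6g")
    written.append(p)

    p = outdir / "labels.tsv"
    with open(p, "w") as fh:
        fh.write("cell_id\tsubclone_label\n")
        for i in range(genotype.n):
            fh.write(f"{genotype.cell_ids[i]}\t{labels[i]}\n")
    written.append(p)

    p = outdir / "subclone_genotypes.tsv"
    _write_table(
        p,
        tree.consensus,
        [f"subclone_{k}" for k in range(tree.consensus.shape[0])],
        genotype.site_ids,
    )
    written.append(p)

    p = outdir / "tree.nwk"
    p.write_text(tree.newick + "\n")
    written.append(p)

    p = outdir / "tree_edges.tsv"
    with open(p, "w") as fh:
        fh.write("parent\tchild\tweight\n")
        for a, b, w in tree.edges:
            fh.write(f"{a}\t{b}\t{w:.9g}\n")
    written.append(p)

    p = outdir / "convergence.tsv"
    with open(p, "w") as fh:
        fh.write("iteration\tc1\tc2\tnnz_S_observed\n")
        rows = zip(decomposition.trace, decomposition.nnz_trace)
        for it, ((c1, c2), nnz) in enumerate(rows, start=1):
            fh.write(f"{it}\t{c1:.9g}\t{c2:.9g}\t{nnz}\n")
    written.append(p)

    if metrics is not None:
        p = outdir / "metrics.json"
        with open(p, "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)

    return written
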