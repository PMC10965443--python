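"""Readers, writers and universe alignment for expression data, priors and networks.

Expression counts come in either as a 10x-style Matrix Market triplet
directory (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, gzip
tolerated) or as a dense labeled TSV with genes in rows and cells in
columns.  Priors are three-column TSV edge lists.  Finished networks are
written as dense TSV matrices (TFs in rows, genes in columns) with a JSON
metadata sidecar so that a read-back round-trips losslessly.
"""

from __future__ import annotations

import gzip
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "PriorEdgeList",
    "Network",
    "FormatError",
    "read_counts",
    "read_prior",
    "read_gmt",
    "align_universe",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Sparse nonnegative count matrix with genes in rows and cells in columns."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene labels for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell labels for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene labels")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell labels")
        data = self.values.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise FormatError("counts must be finite and nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


@dataclass
class PriorEdgeList:
    """Deduplicated (source, target, score) edges; ``kind`` marks the semantics.

    Regulatory priors are TF -> gene; cooperativity priors are TF -- TF and
    stored symmetrically (both orientations, identical score).
    """

    edges: pd.DataFrame  # columns: source, target, score
    kind: str  # "regulatory" | "cooperativity"

    def __post_init__(self) -> None:
        if self.kind not in ("regulatory", "cooperativity"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        cols = ["source", "target", "score"]
        self.edges = pd.DataFrame(self.edges, columns=cols).reset_index(drop=True)
        if len(self.edges):
            scores = self.edges["score"].to_numpy(dtype=float)
            if not np.all(np.isfinite(scores)):
                raise ValueError("prior scores must be finite")
            if self.edges.duplicated(["source", "target"]).any():
                raise ValueError("duplicate (source, target) pairs after load")

    @property
    def sources(self) -> np.ndarray:
        return self.edges["source"].unique()

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class Network:
    """A TF x gene weight matrix in z-score units, with provenance metadata."""

    weights: np.ndarray
    tf_ids: np.ndarray
    gene_ids: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tf_ids = np.asarray(self.tf_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError(
                f"weight shape {self.weights.shape} does not match "
                f"{len(self.tf_ids)} TFs x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("network weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.tf_ids, columns=self.gene_ids)


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_file(directory: Path, stems: tuple[str, ...]) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / (stem + suffix)
            if candidate.exists():
                return candidate
    return None


def _read_label_column(path: Path) -> np.ndarray:
    """First column of a (possibly gzipped) TSV: feature ids / barcodes."""
    labels = []
    with _open_maybe_gz(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line:
                labels.append(line.split("\t")[0])
    return np.asarray(labels, dtype=object)


def read_counts(path_spec: str | Path) -> ExpressionMatrix:
    """Read counts from a Matrix Market triplet directory or a dense TSV.

    A directory is expected to contain ``matrix.mtx[.gz]`` plus
    ``features.tsv[.gz]`` (or ``genes.tsv``) and ``barcodes.tsv[.gz]``;
    only the first column of the label files is used.  A file path is read
    as a dense TSV with gene row labels and cell column headers.
    """
    path = Path(path_spec)
    if path.is_dir():
        mtx = _find_triplet_file(path, ("matrix.mtx",))
        features = _find_triplet_file(path, ("features.tsv", "genes.tsv"))
        barcodes = _find_triplet_file(path, ("barcodes.tsv",))
        missing = [
            name
            for name, found in (
                ("matrix.mtx", mtx),
                ("features.tsv", features),
                ("barcodes.tsv", barcodes),
            )
            if found is None
        ]
        if missing:
            raise FormatError(f"{path}: missing triplet file(s): {', '.join(missing)}")
        try:
            if str(mtx).endswith(".gz"):
                with gzip.open(mtx, "rb") as handle:  # mmread needs binary for gz
                    matrix = scipy.io.mmread(handle)
            else:
                matrix = scipy.io.mmread(mtx)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"{mtx}: not a valid Matrix Market file: {exc}") from exc
        matrix = sp.csr_matrix(matrix)
        gene_ids = _read_label_column(features)
        cell_ids = _read_label_column(barcodes)
        if len(gene_ids) != matrix.shape[0]:
            raise FormatError(
                f"{features}: {len(gene_ids)} features but matrix declares "
                f"{matrix.shape[0]} rows"
            )
        if len(cell_ids) != matrix.shape[1]:
            raise FormatError(
                f"{barcodes}: {len(cell_ids)} barcodes but matrix declares "
                f"{matrix.shape[1]} columns"
            )
        return ExpressionMatrix(matrix, gene_ids, cell_ids)

    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in dense count TSV")
    return ExpressionMatrix(
        sp.csr_matrix(values),
        frame.index.to_numpy(dtype=object),
        frame.columns.to_numpy(dtype=object),
    )


def read_prior(path: str | Path, kind: str) -> PriorEdgeList:
    """Read a (source, target, score) TSV edge list.

    Duplicate (source, target) rows collapse to the MAXIMUM score — when a
    TF's motif matches a promoter several times, only the best match counts.
    Cooperativity priors are additionally symmetrized by the max over the
    two orientations.  A header row is tolerated (detected by a non-numeric
    third field).
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with _open_maybe_gz(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            source, target, raw_score = parts[0], parts[1], parts[2]
            try:
                score = float(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {raw_score!r}"
                ) from None
            if not np.isfinite(score):
                raise FormatError(f"{path}:{lineno}: non-finite score")
            rows.append((source, target, score))
    frame = pd.DataFrame(rows, columns=["source", "target", "score"])
    return _dedup_prior(frame, kind)


def _dedup_prior(frame: pd.DataFrame, kind: str) -> PriorEdgeList:
    if kind == "cooperativity" and len(frame):
        flipped = frame.rename(columns={"source": "target", "target": "source"})
        frame = pd.concat([frame, flipped], ignore_index=True)
    if len(frame):
        frame = (
            frame.groupby(["source", "target"], sort=True, as_index=False)["score"]
            .max()
        )
    return PriorEdgeList(frame, kind)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gz(Path(path)) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT rows need name, "
                                  "description and at least one gene")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def align_universe(
    expr: ExpressionMatrix,
    regulatory: PriorEdgeList,
    cooperativity: PriorEdgeList,
    min_cell_fraction: float = 0.05,
    keep_uncovered_genes: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Intersect the expression and prior universes.

    Genes are kept iff nonzero in at least ``min_cell_fraction`` of cells
    and (by default) covered by at least one motif edge.  The TF universe
    is every distinct source in the regulatory prior — TFs do not have to
    be expressed, which is what lets the refined network quantify the
    activity of transcription factors the assay never detected.  Missing
    prior entries are zero-filled; the cooperativity diagonal is set to the
    maximum observed PPI score (a TF maximally cooperates with itself).

    Returns the filtered expression matrix, the dense TF x gene regulatory
    prior and the dense TF x TF cooperativity prior.
    """
    if not 0 <= min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must be in [0, 1)")
    if regulatory.kind != "regulatory":
        raise ValueError("regulatory prior has wrong kind")
    if cooperativity.kind != "cooperativity":
        raise ValueError("cooperativity prior has wrong kind")
    if len(regulatory) == 0:
        raise ValueError("regulatory prior is empty: no TF universe to align")

    nnz_per_gene = np.asarray((expr.values > 0).sum(axis=1)).ravel()
    expressed = nnz_per_gene >= min_cell_fraction * expr.n_cells
    keep = expressed.copy()
    if not keep_uncovered_genes:
        covered = np.isin(expr.gene_ids, regulatory.edges["target"].unique())
        keep &= covered
    if not keep.any():
        raise ValueError(
            "no genes survive alignment: none are both expressed in "
            f">= {min_cell_fraction:.0%} of cells and covered by the "
            "regulatory prior"
        )

    genes = expr.gene_ids[keep]
    expr_out = ExpressionMatrix(expr.values[keep], genes, expr.cell_ids)

    tfs = np.asarray(sorted(regulatory.edges["source"].unique()), dtype=object)
    w0 = (
        regulatory.edges.pivot(index="source", columns="target", values="score")
        .reindex(index=tfs, columns=genes)
        .fillna(0.0)
    )
    w0.index.name = None
    w0.columns.name = None

    p0 = pd.DataFrame(0.0, index=tfs, columns=tfs)
    if len(cooperativity):
        ppi = cooperativity.edges
        mask = ppi["source"].isin(tfs) & ppi["target"].isin(tfs)
        sub = ppi[mask].pivot(index="source", columns="target", values="score")
        p0 = sub.reindex(index=tfs, columns=tfs).fillna(0.0)
        p0.index.name = None
        p0.columns.name = None
        self_score = float(ppi["score"].max())
    else:
        self_score = 1.0
    np.fill_diagonal(p0.values, self_score)
    return expr_out, w0, p0


_FLOAT_FMT = "%.17g"  # shortest round-trip repr for float64


def write_network(net: Network, path: str | Path) -> None:
    """Write a network as dense TSV plus a ``<path>.meta.json`` sidecar.

    The write is atomic (temp file + rename) so a failure leaves no
    partial file behind.
    """
    path = Path(path)
    frame = net.to_frame()
    directory = path.parent
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            frame.to_csv(handle, sep="\t", float_format=_FLOAT_FMT)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    meta_path = path.with_name(path.name + ".meta.json")
    with open(meta_path, "w") as handle:
        json.dump(net.metadata, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_network(path: str | Path) -> Network:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse network TSV: {exc}") from exc
    if frame.isna().any().any():
        raise FormatError(f"{path}: truncated or non-numeric network file")
    meta_path = path.with_name(path.name + ".meta.json")
    metadata: dict = {}
    if meta_path.exists():
        with open(meta_path) as handle:
            metadata = json.load(handle)
    return Network(
        frame.to_numpy(dtype=float),
        frame.index.to_numpy(dtype=object),
        frame.columns.to_numpy(dtype=object),
        metadata,
    )
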