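"""Readers and writers for the pipeline's on-disk formats.

Formats
-------
10x triple      matrix.mtx (MatrixMarket coordinate, genes x cells, 1-based)
                + barcodes.tsv + features.tsv (or genes.tsv)
clusters.csv    ``barcode,cluster`` (optional header, auto-detected)
markers.csv     ``cluster,rank,gene,score``
known_markers.csv  ``cluster,gene``
report          ``metric,value`` CSV or a flat JSON object

The in-memory orientation is always cells x genes; the on-disk MTX is
genes x cells, matching real 10x output.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ClusterAssignment",
    "MarkerTable",
    "KnownMarkerSet",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_norm_mtx",
    "write_norm_mtx",
    "read_clusters_csv",
    "write_clusters_csv",
    "read_known_markers",
    "write_known_markers",
    "read_marker_csv",
    "write_marker_csv",
    "write_report",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def _check_axis(names, what: str) -> list[str]:
    names = [str(x) for x in names]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate {what} identifiers")
    return names


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI count matrix, cells x genes."""

    values: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.barcodes = _check_axis(self.barcodes, "barcode")
        self.genes = _check_axis(self.genes, "gene")
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entries")
        self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterAssignment:
    """Barcode -> cluster label map with deterministic cluster order.

    Labels are opaque strings; ``cluster_order`` is first-appearance order
    and is used wherever a deterministic ordering of clusters is needed.
    """

    labels: dict[str, str]
    cluster_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        if not self.labels:
            raise ValidationError("cluster assignment is empty (zero clusters)")
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        if not self.cluster_order:
            self.cluster_order = seen
        elif set(self.cluster_order) != set(seen):
            raise ValidationError("cluster_order does not match labels")

    @property
    def barcodes(self) -> list[str]:
        return list(self.labels)

    def sizes(self) -> dict[str, int]:
        out = {c: 0 for c in self.cluster_order}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def as_codes(self, barcodes: list[str] | None = None) -> np.ndarray:
        """Integer codes following ``cluster_order``, in ``barcodes`` order."""
        idx = {c: i for i, c in enumerate(self.cluster_order)}
        bcs = barcodes if barcodes is not None else self.barcodes
        return np.array([idx[self.labels[b]] for b in bcs], dtype=np.int64)


@dataclass
class MarkerTable:
    """Per-cluster ranked marker gene lists.

    Backed by a DataFrame with columns cluster, rank, gene, score. Ranks are
    consecutive from 1 within a cluster and scores are non-increasing with
    rank (higher score = stronger marker for every method).
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = ["cluster", "rank", "gene", "score"]
        if list(self.df.columns) != required:
            self.df = self.df.loc[:, required]
        self.df = self.df.astype(
            {"cluster": str, "rank": np.int64, "gene": str, "score": float}
        ).reset_index(drop=True)
        if self.df.duplicated(subset=["cluster", "gene"]).any():
            raise ValidationError("duplicate (cluster, gene) pair in marker table")
        for cl, grp in self.df.groupby("cluster", sort=False):
            ranks = grp["rank"].to_numpy()
            if not np.array_equal(np.sort(ranks), np.arange(1, len(ranks) + 1)):
                raise ValidationError(f"ranks for cluster {cl!r} not consecutive from 1")
            scores = grp.sort_values("rank")["score"].to_numpy()
            if np.any(np.diff(scores) > 1e-9):
                raise ValidationError(f"scores for cluster {cl!r} increase with rank")

    @property
    def clusters(self) -> list[str]:
        return list(dict.fromkeys(self.df["cluster"]))

    def genes_for(self, cluster: str) -> list[str]:
        grp = self.df[self.df["cluster"] == str(cluster)]
        return list(grp.sort_values("rank")["gene"])

    def __len__(self) -> int:
        return len(self.df)


# cluster label -> set of gene symbols (sets may overlap across clusters)
KnownMarkerSet = dict


# ---------------------------------------------------------------------------
# 10x MTX triple
# ---------------------------------------------------------------------------

def _find(directory: str, names: list[str], gz_ok: bool = True) -> str:
    for name in names:
        cands = [name] + ([name + ".gz"] if gz_ok else [])
        for cand in cands:
            path = os.path.join(directory, cand)
            if os.path.exists(path):
                return path
    raise FormatError(f"missing {' or '.join(names)} in {directory}")


def _read_lines(path: str) -> list[str]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def _read_triple(directory: str):
    mtx_path = _find(directory, ["matrix.mtx"])
    bc_path = _find(directory, ["barcodes.tsv"])
    ft_path = _find(directory, ["features.tsv", "genes.tsv"])
    try:
        mat = scipy.io.mmread(mtx_path)  # genes x cells on disk
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    barcodes = _read_lines(bc_path)
    genes = [line.split("\t")[0] for line in _read_lines(ft_path)]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"matrix.mtx declares {mat.shape[0]} genes x {mat.shape[1]} cells but "
            f"features/barcodes list {len(genes)}/{len(barcodes)}"
        )
    return mat.T.tocsr(), barcodes, genes


def read_10x_mtx(directory: str) -> CountMatrix:
    """Read a 10x triple of integer counts; returns cells x genes."""
    values, barcodes, genes = _read_triple(directory)
    return CountMatrix(values=values, barcodes=barcodes, genes=genes)


def _write_triple(values_cells_x_genes, barcodes, genes, directory, field_kind):
    os.makedirs(directory, exist_ok=True)
    mat = sp.coo_matrix(values_cells_x_genes).T  # genes x cells on disk
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), mat, field=field_kind)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.writelines(b + "\n" for b in barcodes)
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        fh.writelines(g + "\n" for g in genes)


def write_10x_mtx(matrix: CountMatrix, directory: str) -> None:
    """Write the three-file 10x triple readable by :func:`read_10x_mtx`."""
    _write_triple(matrix.values, matrix.barcodes, matrix.genes, directory, "integer")


def read_norm_mtx(directory: str):
    """Read a real-valued MTX triple (normalized expression) as a NormMatrix."""
    from .prepare import NormMatrix

    mtx_path = _find(directory, ["matrix.mtx"])
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    barcodes = _read_lines(_find(directory, ["barcodes.tsv"]))
    genes = [ln.split("\t")[0] for ln in _read_lines(_find(directory, ["features.tsv", "genes.tsv"]))]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValidationError("matrix.mtx dimensions do not match barcodes/features")
    values = np.asarray(sp.coo_matrix(mat).T.todense(), dtype=float)
    return NormMatrix(values=values, barcodes=barcodes, genes=genes)


def write_norm_mtx(norm, directory: str) -> None:
    """Write a NormMatrix as a real-valued MTX triple."""
    _write_triple(sp.coo_matrix(norm.values), norm.barcodes, norm.genes, directory, "real")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _split_rows(path: str, n_fields: int, what: str):
    rows = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != n_fields:
            raise FormatError(
                f"{what} {path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
            )
        rows.append((lineno, parts))
    return rows


def _is_header(parts: list[str]) -> bool:
    return parts[1].lower() == "cluster" or parts[0].lower() == "barcode"


def read_clusters_csv(path: str) -> ClusterAssignment:
    """Read a two-column barcode,cluster CSV (header auto-detected)."""
    rows = _split_rows(path, 2, "clusters file")
    if rows and _is_header(rows[0][1]):
        rows = rows[1:]
    labels: dict[str, str] = {}
    order: list[str] = []
    for lineno, (bc, cl) in rows:
        if bc in labels:
            raise ValidationError(f"clusters file {path}: duplicate barcode {bc!r} at line {lineno}")
        labels[bc] = cl
        if cl not in order:
            order.append(cl)
    if not labels:
        raise ValidationError(f"clusters file {path} contains no assignments")
    return ClusterAssignment(labels=labels, cluster_order=order)


def write_clusters_csv(clusters: ClusterAssignment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("barcode,cluster\n")
        for bc, cl in clusters.labels.items():
            fh.write(f"{bc},{cl}\n")


def read_known_markers(path: str) -> KnownMarkerSet:
    """Read cluster,gene rows into a cluster -> gene-set mapping."""
    rows = _split_rows(path, 2, "known-markers file")
    if rows and (rows[0][1][1].lower() == "gene" or rows[0][1][0].lower() == "cluster"):
        rows = rows[1:]
    known: dict[str, set[str]] = {}
    n_dup = 0
    for _, (cl, gene) in rows:
        genes = known.setdefault(cl, set())
        if gene in genes:
            n_dup += 1
        genes.add(gene)
    if n_dup:
        logger.warning("known-markers file %s: %d duplicated (cluster,gene) rows collapsed", path, n_dup)
    return known


def write_known_markers(known: KnownMarkerSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cluster,gene\n")
        for cl in known:
            for gene in sorted(known[cl]):
                fh.write(f"{cl},{gene}\n")


def read_marker_csv(path: str) -> MarkerTable:
    """Read a cluster,rank,gene,score marker table."""
    rows = _split_rows(path, 4, "markers file")
    if rows and rows[0][1][0].lower() == "cluster" and rows[0][1][1].lower() == "rank":
        rows = rows[1:]
    recs = []
    for lineno, (cl, rank, gene, score) in rows:
        try:
            recs.append((cl, int(rank), gene, float(score)))
        except ValueError as exc:
            raise FormatError(f"markers file {path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(recs, columns=["cluster", "rank", "gene", "score"])
    return MarkerTable(df)


def write_marker_csv(table: MarkerTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cluster,rank,gene,score\n")
        for row in table.df.itertuples(index=False):
            # repr gives the shortest digits that round-trip the float exactly
            fh.write(f"{row.cluster},{row.rank},{row.gene},{row.score!r}\n")


def write_report(report: dict, path: str, format: str = "json") -> None:
    """Write a flat metric report as JSON or metric,value CSV."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w") as fh:
            fh.write("metric,value\n")
            for key, val in _flatten(report):
                fh.write(f"{key},{val}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _flatten(obj, prefix=""):
    items = []
    for key, val in obj.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            items.extend(_flatten(val, name + "."))
        else:
            items.append((name, val))
    return items
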