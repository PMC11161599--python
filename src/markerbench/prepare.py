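"""Quality filtering, normalization, scaling and highly-variable-gene reduction.

The preparation stage turns a raw UMI count matrix into the log-normalized
(and optionally per-gene standardized) expression matrix consumed by every
selection method and by the re-clustering evaluation. The normalization is
the classic library-size normalization: counts are divided by the cell total,
multiplied by a fixed scale factor (10,000 by default) and log1p-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "NormMatrix",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "hvg_dispersion",
    "scale_genes",
]


@dataclass
class QCParams:
    """Per-cell quality-control thresholds.

    ``min_genes``/``max_genes`` bound the number of detected (count > 0)
    genes per cell; ``max_mito_fraction`` bounds the fraction of counts on
    mitochondrial genes, recognized by symbol prefix.
    """

    min_genes: int = 200
    max_genes: int = 6000
    max_mito_fraction: float = 0.2
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValidationError("min_genes exceeds max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must lie in [0, 1]")


@dataclass
class NormMatrix:
    """Log-normalized expression (cells x genes), optionally with a scaled copy."""

    values: np.ndarray
    barcodes: list[str]
    genes: list[str]
    scaled: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError("normalized matrix shape does not match axes")
        if self.values.size and self.values.min() < -1e-9:
            raise ValidationError("log-normalized values must be non-negative")


def qc_filter(matrix: CountMatrix, params: QCParams = QCParams()) -> CountMatrix:
    """Retain cells passing detected-gene and mitochondrial-fraction bounds.

    A cell is kept iff min_genes <= #(genes with count > 0) <= max_genes and
    (mito counts / total counts) <= max_mito_fraction. The gene axis is
    unchanged, so the operation is idempotent.
    """
    X = matrix.values
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    is_mito = np.array(
        [any(g.startswith(p) for p in params.mito_prefixes) for g in matrix.genes]
    )
    if is_mito.any():
        mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel().astype(float)
    else:
        mito_counts = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (
        (detected >= params.min_genes)
        & (detected <= params.max_genes)
        & (mito_frac <= params.max_mito_fraction)
    )
    n_keep = int(keep.sum())
    logger.info("qc_filter: retained %d / %d cells", n_keep, matrix.n_cells)
    if n_keep == 0:
        raise ValidationError("qc_filter removed every cell")
    return CountMatrix(
        values=X[keep],
        barcodes=[b for b, k in zip(matrix.barcodes, keep) if k],
        genes=matrix.genes,
    )


def normalize_log(matrix: CountMatrix, scale_total: float = 10_000.0) -> NormMatrix:
    """Library-size normalize and log-transform counts.

    Each entry becomes ``log(1 + count / cell_total * scale_total)`` (natural
    log), which makes the result exactly invariant to scaling any cell's
    counts by a positive factor. Cells with zero total counts are dropped
    with a warning.
    """
    X = sp.csr_matrix(matrix.values, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    nonzero = totals > 0
    if not nonzero.all():
        logger.warning("normalize_log: dropping %d all-zero cells", int((~nonzero).sum()))
        X = X[nonzero]
        totals = totals[nonzero]
    barcodes = [b for b, k in zip(matrix.barcodes, nonzero) if k]
    dense = np.asarray(X.todense())
    dense = np.log1p(dense / totals[:, None] * scale_total)
    return NormMatrix(values=dense, barcodes=barcodes, genes=list(matrix.genes))


def hvg_dispersion(norm: NormMatrix, n_bins: int = 20) -> np.ndarray:
    """Bin-standardized dispersion (variance/mean) per gene.

    Dispersion is computed on the log-normalized values, then z-standardized
    within ``n_bins`` equal-frequency bins of the gene mean, so that genes are
    compared against genes of similar expression level. Constant genes get
    dispersion -inf so they can never be selected.
    """
    X = norm.values
    mean = X.mean(axis=0)
    var = X.var(axis=0)  # population variance
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    nonconst = var > 0
    out = np.full(X.shape[1], -np.inf)
    if nonconst.sum() == 0:
        return out
    means_nc = mean[nonconst]
    disp_nc = disp[nonconst]
    # keep >= ~10 genes per bin so within-bin SDs are meaningful; tiny gene
    # sets collapse to a single bin (plain dispersion ranking)
    n_bins = min(n_bins, max(1, len(means_nc) // 10), len(np.unique(means_nc)))
    bins = pd.qcut(means_nc, q=max(n_bins, 1), labels=False, duplicates="drop")
    z = np.empty_like(disp_nc)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp_nc[sel].mean(), disp_nc[sel].std()
        z[sel] = (disp_nc[sel] - mu) / sd if sd > 0 else 0.0
    out[nonconst] = z
    return out


def select_hvg(norm: NormMatrix, n_top: int) -> np.ndarray:
    """Indices of the top highly variable genes by standardized dispersion.

    Returns ``min(n_top, #non-constant genes)`` gene indices, ranked by
    descending dispersion with ties broken by gene order (stable sort), so
    the result is deterministic.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    disp = hvg_dispersion(norm)
    eligible = np.isfinite(disp)
    order = np.argsort(-disp, kind="stable")
    order = order[eligible[order]]
    return order[: min(n_top, len(order))]


def scale_genes(norm: NormMatrix, clip: float = 10.0) -> NormMatrix:
    """Attach a per-gene z-scored (population SD) copy, clipped to [-clip, clip].

    Constant genes map to all zeros.
    """
    X = norm.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scaled = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return NormMatrix(
        values=norm.values, barcodes=norm.barcodes, genes=norm.genes, scaled=scaled
    )
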