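"""V-beta gene usage profiles and PCA projection of samples.

The usage ratio of a V gene in a sample is the fraction of unique
clonotypes (not reads — expansion is deliberately excluded) carrying
that gene among clonotypes with a resolved V-gene call. Samples are
compared by centered (covariance) principal component analysis of the
samples x genes ratio matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import KeyMode, Repertoire, aggregate_clonotypes

logger = logging.getLogger(__name__)

_ALLELE_SUFFIX = re.compile(r"\*\d+$")


def normalize_gene_label(label: str) -> str:
    """Uppercase, trim, and strip an allele suffix such as ``*01``."""
    return _ALLELE_SUFFIX.sub("", label.strip().upper())


@dataclass(frozen=True)
class UsageMatrix:
    """Samples x V genes matrix of usage ratios.

    Each row sums to 1; genes absent from a sample have ratio 0; columns
    are lexicographically ordered.
    """

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.gene_ids))


@dataclass(frozen=True)
class PcaResult:
    """Scores (samples x components), loadings (genes x components) and
    per-component explained variance ratios of a centered PCA."""

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def usage_matrix(
    reps: Sequence[Repertoire],
    mode: KeyMode = "nt",
    *,
    aggregated: bool = False,
    read_weighted: bool = False,
) -> UsageMatrix:
    """Per-sample V-gene usage ratios over unique clonotypes.

    Clonotypes with an empty V-gene call are dropped (their number is
    logged). With ``read_weighted`` the ratio is weighted by template
    counts instead of counting each clonotype once.
    """
    rows: dict[str, dict[str, float]] = {}
    for rep in reps:
        agg = rep if aggregated else aggregate_clonotypes(rep, mode)
        weights: dict[str, float] = {}
        unresolved = 0
        for rec in agg.records:
            gene = normalize_gene_label(rec.v_gene)
            if not gene:
                unresolved += 1
                continue
            weights[gene] = weights.get(gene, 0.0) + (rec.count if read_weighted else 1.0)
        if unresolved:
            logger.warning("%s: dropped %d clonotypes with unresolved V gene", rep.sample_id, unresolved)
        total = sum(weights.values())
        if total == 0:
            raise ValueError(f"sample {rep.sample_id!r} has no resolved V-gene calls")
        rows[rep.sample_id] = {g: w / total for g, w in weights.items()}
    sample_ids = tuple(r.sample_id for r in reps)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids: {sample_ids}")
    gene_ids = tuple(sorted({g for row in rows.values() for g in row}))
    values = np.array([[rows[s].get(g, 0.0) for g in gene_ids] for s in sample_ids])
    return UsageMatrix(sample_ids=sample_ids, gene_ids=gene_ids, values=values)


def pca_scores(matrix: UsageMatrix, n_components: int | None = None) -> PcaResult:
    """Centered (covariance) PCA of the usage matrix via SVD.

    Columns are centered but not rescaled: ratios already share a common
    scale. Deterministic sign convention: within each component the
    loading of largest absolute value is made positive. A matrix with
    all rows identical yields all-zero scores and explained variance
    ratios reported as 0.
    """
    X = np.asarray(matrix.values, dtype=float)
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(n_samples - 1, n_genes)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}, got {n_components}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign rule: largest-|loading| entry positive per component
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    full_s = np.linalg.svd(Xc, compute_uv=False)
    denom = float((full_s**2).sum())
    evr = (s**2) / denom if denom > 0 else np.zeros_like(s)
    return PcaResult(
        sample_ids=matrix.sample_ids,
        gene_ids=matrix.gene_ids,
        scores=scores,
        loadings=Vt.T,
        explained_variance_ratio=evr,
    )
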