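"""Repertoire diversity and clonal-expansion statistics.

The diversity statistic is the normalized Shannon index (Pielou-type
evenness): the Shannon entropy H = -sum p_i ln p_i of the clonotype
frequency distribution divided by its theoretical maximum ln(k), where k
is the number of distinct clonotypes. The normalized index lies in [0, 1]
and is comparable across samples with different clonotype counts.

Clonal expansion is summarized as the fraction of sequencing reads
carried by "clonally expanding" clones, defined as clonotypes occupying
strictly more than a frequency threshold (default 0.1%) of total reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .io import EmptyRepertoireError, KeyMode, Repertoire, aggregate_clonotypes

DEFAULT_EXPANSION_THRESHOLD = 0.001


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample diversity summary.

    ``shannon`` is in nats (natural log); ``normalized_shannon`` is
    base-invariant. ``expanded_read_fraction`` is the read mass of clones
    with frequency strictly above ``threshold``.
    """

    sample_id: str
    group: str
    k: int
    shannon: float
    normalized_shannon: float
    expanded_read_fraction: float
    threshold: float


def _frequencies(rep: Repertoire) -> np.ndarray:
    if not rep.records:
        raise EmptyRepertoireError(f"sample {rep.sample_id!r} has no records")
    counts = np.asarray(rep.counts(), dtype=float)
    return counts / counts.sum()


def shannon_index(rep: Repertoire) -> float:
    """Shannon entropy of the clonotype frequency distribution, in nats.

    The repertoire must already be aggregated to the desired clonotype
    resolution. Returns 0 for a monoclonal repertoire.
    """
    return float(_scipy_entropy(_frequencies(rep)))


def normalized_shannon(rep: Repertoire) -> float:
    """H / ln(k), in [0, 1]; defined as 0 for k = 1 (monoclonal)."""
    p = _frequencies(rep)
    k = p.size
    if k == 1:
        return 0.0
    return float(_scipy_entropy(p) / np.log(k))


def expanded_read_fraction(rep: Repertoire, threshold: float = DEFAULT_EXPANSION_THRESHOLD) -> float:
    """Fraction of reads in clones with frequency strictly above ``threshold``.

    The inequality is strict: a clone at exactly the threshold frequency
    is not counted as expanding.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = _frequencies(rep)
    return float(p[p > threshold].sum())


def repertoire_diversity(
    rep: Repertoire,
    mode: KeyMode = "nt",
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
    *,
    aggregated: bool = False,
) -> DiversityResult:
    """Aggregate (unless already done) and compute all diversity statistics."""
    agg = rep if aggregated else aggregate_clonotypes(rep, mode)
    return DiversityResult(
        sample_id=rep.sample_id,
        group=rep.group,
        k=len(agg),
        shannon=shannon_index(agg),
        normalized_shannon=normalized_shannon(agg),
        expanded_read_fraction=expanded_read_fraction(agg, threshold),
        threshold=threshold,
    )
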