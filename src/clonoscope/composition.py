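"""IMGT-style CDR3 position assignment and middle-position composition.

CDR3 amino-acid strings (conserved C at IMGT position 104 through the
conserved F/W at 118, as delivered by the sequencing platform) are
numbered with the IMGT unique scheme: inner residues fill 105..117 from
both ends, the middle gapping for short loops and insertion codes
(111.1, 111.2, ... / 112.1, 112.2, ...) absorbing long loops. The
composition analysis then pools residues observed at the five middle
positions 108-112 across all CDR3 lengths jointly, over unique
clonotypes (each clonotype counted once, so clonal expansion does not
weight the composition), yielding one average frequency per amino acid
per sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil

from .io import KeyMode, Repertoire, aggregate_clonotypes

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MIDDLE_POSITIONS = (108, 109, 110, 111, 112)
HYDROPHOBIC_RESIDUES = frozenset("FLWY")


class UndefinedCompositionError(ValueError):
    """Raised when a composition with zero observations is consumed."""


@dataclass(frozen=True)
class PositionAssignment:
    """Residue-to-position labels for one CDR3.

    Labels are strings: "104".."118" for integer positions, "111.n" /
    "112.n" for insertion codes. ``assignments`` is in sequence order.
    """

    cdr3_aa: str
    assignments: tuple[tuple[str, str], ...]

    def integer_positions(self) -> dict[int, str]:
        """Map integer position -> residue (insertion codes excluded)."""
        return {int(lab): res for res, lab in self.assignments if "." not in lab}


def imgt_positions(cdr3_aa: str, *, anchors: bool = True) -> PositionAssignment:
    """Assign IMGT position labels to each residue of a CDR3.

    With ``anchors`` (the default, matching platform CDR3 strings that
    include both conserved anchor residues), the first residue is 104 and
    the last 118. The inner loop of length l splits into a left arm of
    ceil(l/2) residues labelled 105, 106, ... and a right arm of
    floor(l/2) residues labelled ..., 116, 117 from the end; left-arm
    residues beyond 111 become 111.1, 111.2, ... and right-arm residues
    beyond 112 become 112.1, 112.2, ... For anchor-free input set
    ``anchors=False`` and the whole string is treated as the inner loop.
    """
    bad = set(cdr3_aa) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"non-standard amino-acid characters {sorted(bad)!r} in {cdr3_aa!r}")
    if anchors:
        if len(cdr3_aa) < 3:
            raise ValueError(f"CDR3 {cdr3_aa!r} too short to contain anchors and a loop")
        inner = cdr3_aa[1:-1]
    else:
        if len(cdr3_aa) < 1:
            raise ValueError("empty CDR3")
        inner = cdr3_aa
    l = len(inner)
    a = ceil(l / 2)  # left arm
    b = l - a  # right arm
    labels: list[str] = []
    for i in range(a):
        pos = 105 + i
        labels.append(str(pos) if pos <= 111 else f"111.{pos - 111}")
    right: list[str] = []
    for j in range(b):  # j-th residue from the end
        pos = 117 - j
        right.append(str(pos) if pos >= 112 else f"112.{112 - pos}")
    labels.extend(reversed(right))
    pairs = list(zip(inner, labels))
    if anchors:
        pairs = [(cdr3_aa[0], "104")] + pairs + [(cdr3_aa[-1], "118")]
    return PositionAssignment(cdr3_aa=cdr3_aa, assignments=tuple(pairs))


@dataclass(frozen=True)
class PositionalComposition:
    """Per-sample amino-acid frequencies at IMGT positions 108-112.

    ``freq`` covers all 20 standard amino acids and sums to 1 when
    ``defined``; an all-short repertoire (no residue reaching positions
    108-112) yields ``defined=False`` rather than silent zeros.
    """

    sample_id: str
    freq: dict[str, float]
    n_observations: int
    n_clonotypes_used: int

    @property
    def defined(self) -> bool:
        return self.n_observations > 0


def middle_aa_frequencies(
    rep: Repertoire,
    mode: KeyMode = "nt",
    *,
    aggregated: bool = False,
    anchors: bool = True,
    per_position_average: bool = False,
) -> PositionalComposition:
    """Amino-acid composition at middle positions 108-112 of one sample.

    Each unique clonotype contributes once regardless of its template
    count. Insertion codes (111.n / 112.n) are excluded from the tally.
    By default residue counts are pooled across the five positions; with
    ``per_position_average`` the five per-position frequency vectors are
    averaged instead (the two conventions coincide when every CDR3
    reaches all five positions).
    """
    agg = rep if aggregated else aggregate_clonotypes(rep, mode)
    per_pos: dict[int, Counter] = {p: Counter() for p in MIDDLE_POSITIONS}
    n_obs = 0
    n_clono = 0
    for rec in agg.records:
        seq = rec.cdr3_aa
        if not seq or set(seq) - set(AA_ALPHABET) or len(seq) < 3:
            continue
        middle = {
            p: res
            for p, res in imgt_positions(seq, anchors=anchors).integer_positions().items()
            if p in per_pos
        }
        if middle:
            n_clono += 1
            for p, res in middle.items():
                per_pos[p][res] += 1
                n_obs += 1
    if n_obs == 0:
        return PositionalComposition(rep.sample_id, {aa: 0.0 for aa in AA_ALPHABET}, 0, 0)
    if per_position_average:
        occupied = [c for c in per_pos.values() if c.total() > 0]
        freq = {
            aa: sum(c[aa] / c.total() for c in occupied) / len(occupied) for aa in AA_ALPHABET
        }
    else:
        pooled = Counter()
        for c in per_pos.values():
            pooled.update(c)
        freq = {aa: pooled[aa] / n_obs for aa in AA_ALPHABET}
    return PositionalComposition(rep.sample_id, freq, n_obs, n_clono)


def hydrophobic_summary(
    comp: PositionalComposition, residues: frozenset[str] = HYDROPHOBIC_RESIDUES
) -> dict[str, float]:
    """Project the frequencies of selected (hydrophobic) residues.

    Pass-through of the already-computed frequencies, no renormalization.
    Default residue set F/L/W/Y (phenylalanine, leucine, tryptophan,
    tyrosine).
    """
    if not comp.defined:
        raise UndefinedCompositionError(
            f"composition for sample {comp.sample_id!r} has zero observations"
        )
    return {aa: comp.freq.get(aa, 0.0) for aa in sorted(residues)}
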