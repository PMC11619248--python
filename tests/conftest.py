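from __future__ import annotations

import numpy as np
import pytest

from clonoscope.io import ClonotypeRecord, Repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def make_record(
    cdr3_nt="TGTGCAAGCTTT",
    cdr3_aa="CASF",
    v_gene="TCRBV12-01",
    j_gene="TCRBJ02-01",
    count=1,
    productive=True,
) -> ClonotypeRecord:
    return ClonotypeRecord(cdr3_nt, cdr3_aa, v_gene, j_gene, count, productive)


def repertoire_from_counts(counts, sample_id="s", group="") -> Repertoire:
    """One distinct clonotype per count; distinct at nt, aa and aa+v level."""
    records = []
    for i, c in enumerate(counts):
        inner = "".join(AA[d % 20] for d in _digits(i, 6))
        aa = "C" + inner + "F"
        nt = "TGT" + "".join({"A": "GCT", "C": "TGC"}.get(ch, _codon(ch)) for ch in inner) + "TTT"
        records.append(make_record(cdr3_nt=nt, cdr3_aa=aa, v_gene=f"TCRBV{i % 30:02d}-01", count=int(c)))
    return Repertoire(sample_id=sample_id, records=records, group=group)


_CODONS = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _codon(aa: str) -> str:
    return _CODONS[aa]


def _digits(i: int, width: int) -> list[int]:
    out = []
    for _ in range(width):
        out.append(i % 20)
        i //= 20
    return out


def random_repertoire(rng: np.random.Generator, n=50, max_count=20, sample_id="r") -> Repertoire:
    """Random records with deliberate key collisions across modes."""
    records = []
    for _ in range(n):
        inner = "".join(rng.choice(list(AA), size=int(rng.integers(3, 8))))
        aa = "C" + inner + "F"
        nt = "TGT" + "".join(_codon(ch) for ch in inner) + "TTT"
        if rng.random() < 0.3:  # synonymous variant: same aa, different nt
            nt = "TGC" + nt[3:]
        v = f"TCRBV{int(rng.integers(1, 5)):02d}-01"
        records.append(make_record(cdr3_nt=nt, cdr3_aa=aa, v_gene=v, count=int(rng.integers(1, max_count))))
    return Repertoire(sample_id=sample_id, records=records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
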