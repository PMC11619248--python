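"""Reading, writing and aggregating clonotype tables.

Two tabular dialects are supported:

* the Adaptive immunoSEQ export dialect (one row per rearrangement, with
  CDR3 nucleotide/amino-acid columns, V/J gene calls, a template/read
  count and a frame-type column), and
* the AIRR Rearrangement TSV (community-standard field names
  ``junction``/``junction_aa``/``v_call``/``j_call``/``duplicate_count``/
  ``productive``).

Column names in real immunoSEQ exports vary by pipeline version, so the
immunoSEQ reader takes a configurable :class:`ImmunoseqDialect` mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

KeyMode = Literal["nt", "aa", "aa+v"]
KEY_MODES: tuple[KeyMode, ...] = ("nt", "aa", "aa+v")


class FormatError(ValueError):
    """A table is malformed (missing column, unparsable count, ...)."""


class EmptyRepertoireError(ValueError):
    """No usable data rows remain after filtering."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One TCR-beta rearrangement.

    ``cdr3_nt`` and ``cdr3_aa`` may be empty when the CDR3 was not
    resolved; ``count`` is the template (or read) count reported by the
    platform; ``productive`` means in-frame with no stop codon.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    productive: bool

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.productive:
            if not self.cdr3_aa:
                raise ValueError("productive record requires a CDR3 amino-acid sequence")
            if "*" in self.cdr3_aa:
                raise ValueError("productive record must not contain a stop codon '*'")
        if self.cdr3_nt and self.cdr3_aa and len(self.cdr3_aa) * 3 > len(self.cdr3_nt):
            raise ValueError(
                f"CDR3 aa length {len(self.cdr3_aa)} inconsistent with nt length {len(self.cdr3_nt)}"
            )


@dataclass
class Repertoire:
    """One sample's clonotype records plus metadata."""

    sample_id: str
    records: list[ClonotypeRecord]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> list[int]:
        return [r.count for r in self.records]


def clonotype_key(record: ClonotypeRecord, mode: KeyMode):
    """Identity of a clonotype under the chosen resolution.

    ``nt``: CDR3 nucleotide sequence (the platform's native rearrangement
    identity); ``aa``: CDR3 amino acid; ``aa+v``: CDR3 amino acid plus the
    V-gene call.
    """
    if mode == "nt":
        return record.cdr3_nt
    if mode == "aa":
        return record.cdr3_aa
    if mode == "aa+v":
        return (record.cdr3_aa, record.v_gene)
    raise ValueError(f"unknown key mode {mode!r}; expected one of {KEY_MODES}")


@dataclass(frozen=True)
class ImmunoseqDialect:
    """Column-name map for the immunoSEQ export dialect.

    ``productive_value`` is the ``frame_type`` value that marks an
    in-frame, stop-free rearrangement ("In" in Adaptive exports).
    """

    cdr3_nt: str = "nucleotide"
    cdr3_aa: str = "aminoAcid"
    v_gene: str = "vGeneName"
    j_gene: str = "jGeneName"
    count: str = "count (templates/reads)"
    frame_type: str = "frame_type"
    productive_value: str = "In"

    @property
    def columns(self) -> list[str]:
        return [self.cdr3_nt, self.cdr3_aa, self.v_gene, self.j_gene, self.count, self.frame_type]


DEFAULT_DIALECT = ImmunoseqDialect()

_AIRR_COLUMNS = ("junction", "junction_aa", "v_call", "j_call", "duplicate_count", "productive")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    return df

def _parse_count(raw: str, *, default: int | None = None) -> int | None:
    raw = raw.strip()
    if raw == "":
        if default is None:
            raise FormatError("empty count field")
        return default
    try:
        value = int(raw)
    except ValueError as exc:
        raise FormatError(f"count {raw!r} is not an integer") from exc
    if value < 0:
        raise FormatError(f"negative count {value}")
    return value


def _build(sample_id: str, rows: Iterable[ClonotypeRecord], group: str) -> Repertoire:
    records = list(rows)
    if not records:
        raise EmptyRepertoireError(f"no usable clonotype rows for sample {sample_id!r}")
    return Repertoire(sample_id=sample_id, records=records, group=group)


def read_immunoseq(
    path: str | Path,
    productive_only: bool = True,
    *,
    dialect: ImmunoseqDialect = DEFAULT_DIALECT,
    sample_id: str | None = None,
    group: str = "",
) -> Repertoire:
    """Read an immunoSEQ-dialect clonotype TSV into a :class:`Repertoire`.

    Rows whose frame type is not the dialect's productive value are
    dropped when ``productive_only``; zero-count rows are always dropped
    with a logged warning. Row order is preserved.
    """
    path = Path(path)
    df = _read_table(path, dialect.columns)
    records: list[ClonotypeRecord] = []
    dropped_zero = 0
    for vals in df.to_dict("records"):
        productive = vals[dialect.frame_type].strip() == dialect.productive_value
        if productive_only and not productive:
            continue
        count = _parse_count(vals[dialect.count])
        if count == 0:
            dropped_zero += 1
            continue
        records.append(
            ClonotypeRecord(
                cdr3_nt=vals[dialect.cdr3_nt].strip().upper(),
                cdr3_aa=vals[dialect.cdr3_aa].strip(),
                v_gene=vals[dialect.v_gene].strip(),
                j_gene=vals[dialect.j_gene].strip(),
                count=count,
                productive=productive,
            )
        )
    if dropped_zero:
        logger.warning("%s: dropped %d zero-count rows", path.name, dropped_zero)
    return _build(sample_id or path.stem, records, group)


def read_airr(
    path: str | Path,
    productive_only: bool = True,
    *,
    sample_id: str | None = None,
    group: str = "",
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    An absent or empty ``duplicate_count`` is treated as 1 (a singleton
    rearrangement).
    """
    path = Path(path)
    df = _read_table(path, [c for c in _AIRR_COLUMNS if c != "duplicate_count"])
    has_dup = "duplicate_count" in df.columns
    records: list[ClonotypeRecord] = []
    dropped_zero = 0
    for vals in df.to_dict("records"):
        productive = str(vals["productive"]).strip() in ("T", "TRUE", "true", "True", "1")
        if productive_only and not productive:
            continue
        count = _parse_count(str(vals["duplicate_count"]), default=1) if has_dup else 1
        if count == 0:
            dropped_zero += 1
            continue
        records.append(
            ClonotypeRecord(
                cdr3_nt=str(vals["junction"]).strip().upper(),
                cdr3_aa=str(vals["junction_aa"]).strip(),
                v_gene=str(vals["v_call"]).strip(),
                j_gene=str(vals["j_call"]).strip(),
                count=count,
                productive=productive,
            )
        )
    if dropped_zero:
        logger.warning("%s: dropped %d zero-count rows", path.name, dropped_zero)
    return _build(sample_id or path.stem, records, group)


def aggregate_clonotypes(rep: Repertoire, mode: KeyMode = "nt") -> Repertoire:
    """Merge records sharing a clonotype key, summing counts.

    Records whose key field is empty (e.g. unresolved CDR3 nucleotide
    under ``nt`` mode) are kept as distinct singleton clonotypes so that
    count-based statistics retain their mass. Output order is
    deterministic: descending count, then lexicographic key. Idempotent,
    and conserves ``total_count``.
    """
    if not rep.records:
        raise EmptyRepertoireError(f"sample {rep.sample_id!r} has no records")
    merged: dict = {}
    blanks: list[ClonotypeRecord] = []
    for rec in rep.records:
        key = clonotype_key(rec, mode)
        if key == "" or key == ("", ""):
            blanks.append(rec)
            continue
        if key in merged:
            prev = merged[key]
            # keep the representative fields of the largest contributor
            keep, other = (prev, rec) if prev.count >= rec.count else (rec, prev)
            merged[key] = replace(keep, count=prev.count + rec.count)
        else:
            merged[key] = rec
    records = list(merged.items()) + [(clonotype_key(r, mode), r) for r in blanks]
    records.sort(key=lambda kv: (-kv[1].count, str(kv[0])))
    out = Repertoire(sample_id=rep.sample_id, records=[r for _, r in records], group=rep.group)
    assert out.total_count == rep.total_count
    return out


def write_immunoseq(rep: Repertoire, path: str | Path, *, dialect: ImmunoseqDialect = DEFAULT_DIALECT) -> None:
    """Write a repertoire as an immunoSEQ-dialect TSV (UTF-8, no quoting).

    Refuses to write an empty repertoire. Writing then reading back
    reproduces records and counts exactly; output is byte-stable.
    """
    if not rep.records:
        raise FormatError("refusing to write an empty repertoire")
    df = pd.DataFrame(
        {
            dialect.cdr3_nt: [r.cdr3_nt for r in rep.records],
            dialect.cdr3_aa: [r.cdr3_aa for r in rep.records],
            dialect.v_gene: [r.v_gene for r in rep.records],
            dialect.j_gene: [r.j_gene for r in rep.records],
            dialect.count: [r.count for r in rep.records],
            dialect.frame_type: [dialect.productive_value if r.productive else "Out" for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_airr(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV."""
    if not rep.records:
        raise FormatError("refusing to write an empty repertoire")
    df = pd.DataFrame(
        {
            "junction": [r.cdr3_nt for r in rep.records],
            "junction_aa": [r.cdr3_aa for r in rep.records],
            "v_call": [r.v_gene for r in rep.records],
            "j_call": [r.j_gene for r in rep.records],
            "duplicate_count": [r.count for r in rep.records],
            "productive": ["T" if r.productive else "F" for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_any(path: str | Path, fmt: str, productive_only: bool = True, **kw) -> Repertoire:
    """Dispatch on ``fmt`` in {"immunoseq", "airr"}."""
    if fmt == "immunoseq":
        return read_immunoseq(path, productive_only, **kw)
    if fmt == "airr":
        return read_airr(path, productive_only, **kw)
    raise ValueError(f"unknown format {fmt!r}")
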