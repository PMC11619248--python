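"""Seeded synthetic TCR-beta repertoire generator.

Emulates per-sample clonotype tables of the kind an immunoSEQ export
contains, with controllable:

* clone-size distribution — symmetric Dirichlet (evenness dial via the
  concentration alpha) or a spike model (m expanded clones at frequency
  f_e each, the remainder uniform);
* V-gene usage profile, with optional per-group additive usage shifts;
* CDR3 amino-acid length distribution (default support 9-20 including
  both anchors, roughly bell-shaped as in beta-chain repertoires);
* amino-acid background composition, with optional additive enrichment
  of chosen residues at the middle IMGT positions 108-112.

Clone frequencies are drawn first and template counts second (one
multinomial at the requested depth), so the ground truth is well defined
independent of sequencing depth. CDR3 nucleotide sequences are
back-generated by choosing a random synonymous codon per residue.
Everything is driven by one integer seed per sample; cohorts derive
per-sample seeds from a master seed by seed-sequence spawning, so runs
are exactly reproducible. No attempt is made at biological V(D)J
recombination realism (no junctional insertion/deletion model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import AA_ALPHABET, MIDDLE_POSITIONS, imgt_positions
from .io import ClonotypeRecord, Repertoire, write_airr, write_immunoseq

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

DEFAULT_V_GENES = (
    "TCRBV01-01", "TCRBV02-01", "TCRBV03-01", "TCRBV04-01", "TCRBV05-01",
    "TCRBV12-01", "TCRBV13-01", "TCRBV13-02", "TCRBV13-03", "TCRBV15-01",
    "TCRBV16-01", "TCRBV19-01", "TCRBV20-01", "TCRBV26-01", "TCRBV29-01",
    "TCRBV31-01",
)
_J_GENES = ("TCRBJ01-01", "TCRBJ01-02", "TCRBJ02-01", "TCRBJ02-05", "TCRBJ02-07")


def _default_v_probs() -> dict[str, float]:
    # mildly skewed usage, geometric-ish decay as in real beta repertoires
    raw = [0.85**i for i in range(len(DEFAULT_V_GENES))]
    s = sum(raw)
    return {g: w / s for g, w in zip(DEFAULT_V_GENES, raw)}


def _default_length_dist() -> dict[int, float]:
    # bell-shaped over total CDR3 length 9..20 (anchors included), mode ~14
    raw = {l: exp(-((l - 14.0) ** 2) / (2 * 2.0**2)) for l in range(9, 21)}
    s = sum(raw.values())
    return {l: w / s for l, w in raw.items()}


@dataclass(frozen=True)
class DirichletModel:
    """Symmetric Dirichlet clone frequencies with concentration ``alpha``."""

    alpha: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SpikeModel:
    """``m`` expanded clones at frequency ``f_e`` each; the rest uniform."""

    m: int
    f_e: float

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if not 0 < self.f_e < 1:
            raise ValueError("f_e must be in (0, 1)")
        if self.m * self.f_e >= 1:
            raise ValueError("m * f_e must be < 1")


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one synthetic sample."""

    n_clonotypes: int = 20_000
    depth: int = 1_000_000
    clone_model: DirichletModel | SpikeModel = DirichletModel(alpha=1.0)
    v_gene_probs: Mapping[str, float] = field(default_factory=_default_v_probs)
    usage_shift: Mapping[str, float] | None = None
    length_dist: Mapping[int, float] = field(default_factory=_default_length_dist)
    aa_background: Mapping[str, float] = field(
        default_factory=lambda: {aa: 1 / 20 for aa in AA_ALPHABET}
    )
    middle_enrichment: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if isinstance(self.clone_model, SpikeModel) and self.clone_model.m > self.n_clonotypes:
            raise ValueError("spike m exceeds n_clonotypes")
        for name, vec in (
            ("v_gene_probs", self.v_gene_probs.values()),
            ("length_dist", self.length_dist.values()),
            ("aa_background", self.aa_background.values()),
        ):
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.aa_background) != set(AA_ALPHABET):
            raise ValueError("aa_background must cover the 20 standard amino acids")
        if min(self.length_dist) < 4:
            raise ValueError("CDR3 lengths below 4 are not supported")
        _shifted(self.v_gene_probs, self.usage_shift)
        _shifted(self.aa_background, self.middle_enrichment)


@dataclass(frozen=True)
class SimTruth:
    """Generator ground truth used by recovery tests."""

    clone_frequencies: np.ndarray
    expanded_mass: float
    v_gene_probs: dict[str, float]
    middle_residue_probs: dict[str, float]


def _shifted(base: Mapping[str, float], deltas: Mapping[str, float] | None) -> dict[str, float]:
    """Additive shift with exact deltas: shifted targets get base + delta,
    the remaining entries are rescaled to keep the vector normalized."""
    out = dict(base)
    if not deltas:
        return out
    unknown = set(deltas) - set(base)
    if unknown:
        raise ValueError(f"shift targets not in distribution: {sorted(unknown)}")
    target_mass = sum(out[k] + d for k, d in deltas.items())
    rest_mass = 1.0 - sum(out[k] for k in deltas)
    if not 0 < target_mass < 1:
        raise ValueError("shift drives target probabilities outside (0, 1)")
    scale = (1.0 - target_mass) / rest_mass
    for k in out:
        out[k] = out[k] + deltas[k] if k in deltas else out[k] * scale
    if any(v < 0 or v > 1 for v in out.values()):
        raise ValueError("shift produces probabilities outside [0, 1]")
    return out


def _clone_frequencies(params: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    k = params.n_clonotypes
    model = params.clone_model
    if isinstance(model, DirichletModel):
        freqs = rng.dirichlet(np.full(k, model.alpha))
        expanded = 0.0  # defined by the spike model only
    else:
        freqs = np.empty(k)
        freqs[: model.m] = model.f_e
        freqs[model.m :] = (1.0 - model.m * model.f_e) / (k - model.m) if k > model.m else 0.0
        expanded = model.m * model.f_e
    return freqs, expanded


def _sample_cdr3s(params: SimParams, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Draw (aa, nt) CDR3 pairs for every clonotype, vectorized per length.

    The conserved anchors C (104) and F (118) are fixed; inner residues
    at integer middle positions 108-112 come from the enriched
    distribution, all other inner positions from the background.
    """
    k = params.n_clonotypes
    lengths_support = sorted(params.length_dist)
    length_p = np.array([params.length_dist[l] for l in lengths_support])
    lengths = rng.choice(lengths_support, size=k, p=length_p)

    bg = np.array([params.aa_background[aa] for aa in AA_ALPHABET])
    mid = np.array([_shifted(params.aa_background, params.middle_enrichment)[aa] for aa in AA_ALPHABET])
    aa_arr = np.array(list(AA_ALPHABET))
    ncod = np.array([len(_CODONS[aa]) for aa in AA_ALPHABET])
    codon_lookup = [np.array(_CODONS[aa]) for aa in AA_ALPHABET]

    aa_out = np.empty(k, dtype=object)
    nt_out = np.empty(k, dtype=object)
    for l in lengths_support:
        idx = np.flatnonzero(lengths == l)
        if idx.size == 0:
            continue
        template = "A" * l
        labels = [lab for _, lab in imgt_positions(template).assignments]
        cols_aa: list[np.ndarray] = []
        cols_nt: list[np.ndarray] = []
        for lab in labels:
            if lab == "104":
                res_idx = np.full(idx.size, AA_ALPHABET.index("C"))
            elif lab == "118":
                res_idx = np.full(idx.size, AA_ALPHABET.index("F"))
            else:
                is_middle = "." not in lab and int(lab) in MIDDLE_POSITIONS
                res_idx = rng.choice(20, size=idx.size, p=mid if is_middle else bg)
            # synonymous codon via an inverse-CDF draw per residue
            cod_idx = np.minimum((rng.random(idx.size) * ncod[res_idx]).astype(int), ncod[res_idx] - 1)
            cols_aa.append(aa_arr[res_idx])
            cols_nt.append(np.array([codon_lookup[r][c] for r, c in zip(res_idx, cod_idx)]))
        for row, j in enumerate(idx):
            aa_out[j] = "".join(col[row] for col in cols_aa)
            nt_out[j] = "".join(col[row] for col in cols_nt)
    return list(aa_out), list(nt_out)


def simulate_repertoire(
    params: SimParams, *, sample_id: str = "sim", group: str = ""
) -> tuple[Repertoire, SimTruth]:
    """Generate one synthetic repertoire and its ground truth.

    Clonotypes receiving zero templates in the multinomial draw are
    omitted from the output table (unobserved), but remain part of the
    truth frequency vector. Deterministic under a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    freqs, expanded = _clone_frequencies(params, rng)
    counts = rng.multinomial(params.depth, freqs)
    v_probs = _shifted(params.v_gene_probs, params.usage_shift)
    v_labels = sorted(v_probs)
    v_idx = rng.choice(len(v_labels), size=params.n_clonotypes, p=np.array([v_probs[g] for g in v_labels]))
    j_idx = rng.integers(0, len(_J_GENES), size=params.n_clonotypes)
    aa_seqs, nt_seqs = _sample_cdr3s(params, rng)
    records = [
        ClonotypeRecord(
            cdr3_nt=nt_seqs[i],
            cdr3_aa=aa_seqs[i],
            v_gene=v_labels[v_idx[i]],
            j_gene=_J_GENES[j_idx[i]],
            count=int(counts[i]),
            productive=True,
        )
        for i in range(params.n_clonotypes)
        if counts[i] > 0
    ]
    truth = SimTruth(
        clone_frequencies=freqs,
        expanded_mass=expanded,
        v_gene_probs=v_probs,
        middle_residue_probs=_shifted(params.aa_background, params.middle_enrichment),
    )
    return Repertoire(sample_id=sample_id, records=records, group=group), truth


def derive_sample_seed(master_seed: int, sample_index: int) -> int:
    """Per-sample seed from (master seed, sample index); stable across runs."""
    return int(np.random.SeedSequence([master_seed, sample_index]).generate_state(1)[0] % 2**31)


def simulate_cohort(
    groups: Mapping[str, SimParams],
    n_per_group: int,
    outdir: str | Path,
    *,
    master_seed: int | None = None,
    fmt: str = "immunoseq",
) -> tuple[pd.DataFrame, dict[str, SimTruth]]:
    """Simulate and write a multi-group cohort plus a manifest.

    One table per sample (``{group}_{i}.tsv``) in the requested format
    plus ``manifest.tsv`` (sample_id, group, path, format, seed, and
    truth summary columns). Each sample's seed derives from the master
    seed (default: the group params' seed) and a running sample index.
    Returns the manifest frame and the per-sample ground truths.
    """
    if not groups:
        raise ValueError("at least one group required")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if fmt not in ("immunoseq", "airr"):
        raise ValueError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths: dict[str, SimTruth] = {}
    sample_index = 0
    for group, params in groups.items():
        for i in range(n_per_group):
            seed = derive_sample_seed(master_seed if master_seed is not None else params.seed, sample_index)
            sample_index += 1
            sp = replace(params, seed=seed)
            sample_id = f"{group}_{i + 1}"
            rep, truth = simulate_repertoire(sp, sample_id=sample_id, group=group)
            path = outdir / f"{sample_id}.tsv"
            (write_immunoseq if fmt == "immunoseq" else write_airr)(rep, path)
            truths[sample_id] = truth
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "path": str(path),
                    "format": fmt,
                    "seed": seed,
                    "n_clonotypes": sp.n_clonotypes,
                    "depth": sp.depth,
                    "expanded_mass": truth.expanded_mass,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False, lineterminator="\n")
    return manifest, truths
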