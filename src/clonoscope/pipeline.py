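"""End-to-end pipeline: manifest in, report tables out.

Runs every analysis stage (diversity/expansion, clonotype overlap,
middle-position CDR3 composition, V-gene usage + PCA) over a cohort
described by a manifest TSV (sample_id, group, path, format). All
outputs are plain TSV with a comment header recording the config hash
and the statistic conventions (log base, expansion threshold, clonotype
key mode), so a rerun with identical inputs is byte-identical.

Inferential statistics are deliberately not produced; group summaries
are descriptive (mean, sd) only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import AA_ALPHABET, middle_aa_frequencies
from .diversity import repertoire_diversity
from .io import KEY_MODES, KeyMode, Repertoire, aggregate_clonotypes, read_any
from .overlap import venn_counts
from .vusage import pca_scores, usage_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and sample."""


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    manifest: str
    outdir: str
    key_mode: KeyMode = "nt"
    productive_only: bool = True
    expansion_threshold: float = 0.001
    composition_per_position: bool = False
    pca_components: int | None = None
    overlap_sets: list[list[str]] | None = None  # lists of 2-3 sample_ids; default: all pairs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if self.key_mode not in KEY_MODES:
            raise ValueError(f"key_mode must be one of {KEY_MODES}, got {self.key_mode!r}")
        if not 0 < self.expansion_threshold < 1:
            raise ValueError(f"expansion_threshold must be in (0, 1), got {self.expansion_threshold}")
        if not Path(self.manifest).exists():
            raise FileNotFoundError(self.manifest)
        if self.overlap_sets is not None:
            for s in self.overlap_sets:
                if not 2 <= len(s) <= 3:
                    raise ValueError(f"overlap set must have 2 or 3 samples, got {s}")

    def config_hash(self) -> str:
        # identifies the analysis parameters; where the output lands is not one
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back a pipeline TSV, skipping the comment header."""
    return pd.read_csv(path, sep="\t", comment="#")


def summarize_groups(diversity_df: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and sd of each numeric statistic (descriptive only).

    A single-sample group gets sd = 0 with ``degenerate = True``.
    """
    if "group" not in diversity_df.columns:
        raise ValueError("missing 'group' column")
    stats = [c for c in diversity_df.columns if diversity_df[c].dtype.kind in "fi" and c != "threshold"]
    rows = []
    for group, sub in diversity_df.groupby("group", sort=True):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        row: dict = {"group": group, "n": len(sub), "degenerate": len(sub) < 2}
        for c in stats:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of the written tables.

    All tables are computed before anything is written, so a failing
    stage leaves no partial output behind.
    """
    config.validate()
    manifest = pd.read_csv(config.manifest, sep="\t")
    for col in ("sample_id", "group", "path", "format"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")

    reps: dict[str, Repertoire] = {}
    for row in manifest.to_dict("records"):
        sid = str(row["sample_id"])
        try:
            rep = read_any(row["path"], row["format"], config.productive_only,
                           sample_id=sid, group=str(row["group"]))
            reps[sid] = aggregate_clonotypes(rep, config.key_mode)
        except Exception as exc:
            raise PipelineError(f"stage=ingest sample={sid}: {exc}") from exc

    def _stage(name: str, sid: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage={name} sample={sid}: {exc}") from exc

    diversity_rows = [
        vars(_stage("diversity", sid, lambda r=rep: repertoire_diversity(
            r, config.key_mode, config.expansion_threshold, aggregated=True)))
        for sid, rep in reps.items()
    ]
    diversity_df = pd.DataFrame(diversity_rows).rename(columns={"shannon": "shannon_nats"})

    sets = config.overlap_sets
    if sets is None:
        sets = [list(pair) for pair in combinations(sorted(reps), 2)]
    overlap_rows = []
    for s in sets:
        missing = [sid for sid in s if sid not in reps]
        if missing:
            raise PipelineError(f"stage=overlap sample={missing[0]}: not in manifest")
        result = venn_counts([reps[sid] for sid in s], config.key_mode)
        for region, count in sorted(result.region_counts.items()):
            overlap_rows.append(
                {"set": "|".join(s), "region": "&".join(region), "n_clonotypes": count,
                 "union_size": result.union_size}
            )
    overlap_df = pd.DataFrame(overlap_rows)

    comp_rows = []
    for sid, rep in reps.items():
        comp = _stage("composition", sid, lambda r=rep: middle_aa_frequencies(
            r, config.key_mode, aggregated=True,
            per_position_average=config.composition_per_position))
        comp_rows.append(
            {"sample_id": sid, "group": rep.group, **{aa: comp.freq[aa] for aa in AA_ALPHABET},
             "n_observations": comp.n_observations, "n_clonotypes_used": comp.n_clonotypes_used}
        )
    comp_df = pd.DataFrame(comp_rows)

    usage = usage_matrix(list(reps.values()), config.key_mode, aggregated=True)
    usage_df = usage.to_frame().reset_index(names="sample_id")
    pca = pca_scores(usage, config.pca_components)
    n_comp = pca.scores.shape[1]
    pc_cols = [f"PC{i + 1}" for i in range(n_comp)]
    scores_df = pd.DataFrame(pca.scores, columns=pc_cols).assign(sample_id=list(pca.sample_ids))
    scores_df = scores_df[["sample_id", *pc_cols]]
    loadings_df = pd.DataFrame(pca.loadings, columns=pc_cols).assign(gene=list(pca.gene_ids))
    loadings_df = loadings_df[["gene", *pc_cols]]
    evr_df = pd.DataFrame({"component": pc_cols, "explained_variance_ratio": pca.explained_variance_ratio})

    summary_df = summarize_groups(diversity_df)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"clonoscope {__version__} config_hash={config.config_hash()}",
        f"key_mode={config.key_mode} productive_only={config.productive_only}",
        f"shannon log base=e (nats); expansion threshold={config.expansion_threshold} (strict >)",
    ]
    tables = {
        "diversity": diversity_df,
        "diversity_group_summary": summary_df,
        "overlap": overlap_df,
        "composition": comp_df,
        "vusage": usage_df,
        "pca_scores": scores_df,
        "pca_loadings": loadings_df,
        "pca_explained_variance": evr_df,
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        _write_table(df, path, header)
        paths[name] = path
    log_path = outdir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"clonoscope {__version__}\n")
        fh.write(f"config_hash: {config.config_hash()}\n")
        fh.write(f"config: {json.dumps(asdict(config), sort_keys=True)}\n")
        fh.write(f"samples: {len(reps)}\n")
    paths["run_log"] = log_path
    return paths
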