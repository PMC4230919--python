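"""End-to-end survey pipeline: simulate/load -> mask -> distances -> classify -> detect -> tree.

A run is fully described by a :class:`RunConfig`; identical config and seed
reproduce byte-identical artifacts.  Outputs land in the run directory under
fixed names: distances.tsv, ranges.tsv, composition.tsv, incidence.tsv,
tree.nwk, run.json, report.md (plus the synthetic-survey files when
simulating).  On a stage failure, files already written by the failed run
are removed and the error names the stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .classify import classify_alignment, composition_table, DEFAULT_THRESHOLD
from .detection import incidence_table, IncidenceTable
from .distances import ColumnMask, apply_mask, p_distance_matrix, subclade_range_table
from .io import AlignedSeqSet, read_aligned_fasta, read_manifest, write_newick
from .simulate import (
    DesignRow,
    default_divergence_matrix,
    simulate_references,
    simulate_survey,
    survey_design,
    write_survey,
)
from .tree import bootstrap_supports

__all__ = ["RunConfig", "PipelineStageError", "run_survey_pipeline", "write_report"]

log = logging.getLogger("oophila")


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str
    seed: int = 0
    # inputs: either a simulation, or file paths
    simulate: bool = False
    fasta: str | None = None
    manifest: str | None = None
    mask: str | None = None
    references: str | None = None  # FASTA of subclade references (ids = labels)
    # detection-only mode: per-host clone counts, no sequences needed
    per_host_n: dict[str, int] = field(default_factory=dict)
    # simulation parameters (used when simulate=True)
    sim_q: float = 0.0
    sim_error_rate: float = 0.002
    sim_length: int = 1000
    # stage parameters
    detection_P: float = 0.99
    classify_threshold: float = DEFAULT_THRESHOLD
    bootstrap_reps: int = 100
    tree_enabled: bool = True
    round_digits: int = 3

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_survey_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all applicable stages; returns the artifact bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    bundle: dict[str, Any] = {"config": config, "artifacts": {}}

    def track(path: Path) -> Path:
        created.append(path)
        return path

    def stage(name: str):
        log.info("stage %s", name)
        return _StageTimer(name)

    try:
        aln: AlignedSeqSet | None = None
        panel = None
        context = None
        per_host_n = dict(config.per_host_n)

        if config.simulate:
            with stage("simulate"):
                panel = simulate_references(
                    L=config.sim_length,
                    divergence_matrix=default_divergence_matrix(),
                    seed=config.seed,
                )
                survey = simulate_survey(
                    panel,
                    survey_design(q=config.sim_q),
                    error_rate=config.sim_error_rate,
                    seed=config.seed,
                )
                paths = write_survey(survey, out)
                for p in paths.values():
                    track(p)
                bundle["survey"] = survey
                aln = survey.alignment
                context = survey.truth_map()
                if not per_host_n:
                    per_host_n = survey.per_host_clone_counts()
        elif config.fasta:
            with stage("load"):
                aln = read_aligned_fasta(config.fasta)
                if config.manifest:
                    manifest = read_manifest(config.manifest)
                    bundle["manifest"] = manifest
                    if not per_host_n:
                        per_host_n = manifest.per_host_accession_counts()
                if config.references:
                    panel = _panel_from_fasta(config.references)

        if aln is not None and config.mask:
            with stage("mask"):
                aln = apply_mask(aln, ColumnMask.from_file(config.mask))

        dm = None
        if aln is not None:
            with stage("distances"):
                dm = p_distance_matrix(aln)
                dm.write_tsv(track(out / "distances.tsv"))
                bundle["distances"] = dm

        assignments = None
        if aln is not None and panel is not None:
            with stage("classify"):
                assignments = classify_alignment(
                    aln, panel, threshold=config.classify_threshold
                )
                bundle["assignments"] = assignments
                grouping = {a.clone_id: a.best_group for a in assignments}
                ranges = subclade_range_table(dm, grouping)
                ranges.write_tsv(track(out / "ranges.tsv"))
                bundle["ranges"] = ranges
                if context is None and "manifest" in bundle:
                    context = {
                        acc: (row.host, row.code)
                        for row in bundle["manifest"].rows
                        for acc in row.accessions
                    }
                if context is not None:
                    comp = composition_table(assignments, context)
                    comp.to_csv(track(out / "composition.tsv"), sep="\t", index=False)
                    bundle["composition"] = comp

        if per_host_n:
            with stage("detect"):
                table = incidence_table(per_host_n, P=config.detection_P)
                table.ndigits = config.round_digits
                table.write_tsv(track(out / "incidence.tsv"))
                bundle["incidence"] = table

        if aln is not None and config.tree_enabled:
            with stage("tree"):
                tree = bootstrap_supports(
                    aln, reps=config.bootstrap_reps, seed=config.seed
                )
                write_newick(tree, track(out / "tree.nwk"))
                bundle["tree"] = tree

        if aln is None and not per_host_n:
            raise ValueError(
                "config selects no work: provide a simulation, sequences, or per_host_n"
            )

        with stage("report"):
            run_info = {
                "oophila_version": __version__,
                "seed": config.seed,
                "config": config.to_dict(),
                "incidence": bundle["incidence"].to_dict()
                if "incidence" in bundle
                else None,
                "n_sequences": len(aln) if aln is not None else 0,
            }
            with open(track(out / "run.json"), "w", encoding="utf-8") as fh:
                json.dump(run_info, fh, indent=2, sort_keys=True)
                fh.write("\n")
            report = write_report(bundle)
            (track(out / "report.md")).write_text(report, encoding="utf-8")
        bundle["artifacts"] = {p.name: p for p in created}
        return bundle
    except PipelineStageError:
        for p in created:
            p.unlink(missing_ok=True)
        raise


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            raise PipelineStageError(self.name, exc) from exc
        log.info("stage %s done in %.2fs", self.name, dt)
        return False


def _panel_from_fasta(path: str):
    from .simulate import SubcladePanel
    import numpy as np

    aln = read_aligned_fasta(path)
    k = len(aln)
    return SubcladePanel(
        labels=tuple(aln.ids),
        references=dict(zip(aln.ids, aln.rows)),
        divergence_matrix=np.zeros((k, k)),
    )


def write_report(bundle: dict[str, Any]) -> str:
    """Human-readable run summary; every number also exists unrounded in an artifact."""
    if not bundle or "config" not in bundle:
        raise ValueError("empty or inconsistent bundle")
    config: RunConfig = bundle["config"]
    has_content = any(k in bundle for k in ("incidence", "distances", "composition"))
    if not has_content:
        raise ValueError("bundle contains no results to report")

    lines = ["# Survey run report", ""]
    lines.append(f"- seed: {config.seed}")
    lines.append(f"- detection threshold P: {config.detection_P}")
    lines.append("")

    if "incidence" in bundle:
        table: IncidenceTable = bundle["incidence"]
        lines.append("## Maximum undetected incidence")
        lines.append("")
        lines.append(table.assumption)
        lines.append("")
        df = table.to_dataframe()
        lines.append(df.to_string(index=False))
        lines.append("")

    if "composition" in bundle:
        comp = bundle["composition"]
        lines.append("## Subclade composition per host and site")
        lines.append("")
        lines.append(comp.to_string(index=False))
        lines.append("")
        lines.append(f"- total clones: {int(comp['clone_count'].sum())}")
        lines.append("")

    if "ranges" in bundle:
        lines.append("## Pairwise distance ranges between groups (percent)")
        lines.append("")
        lines.append(bundle["ranges"].to_dataframe().to_string())
        lines.append("")

    if "tree" in bundle:
        lines.append("## Tree")
        lines.append("")
        lines.append(
            "Neighbor-joining tree with column-resampling bootstrap supports "
            "written to tree.nwk."
        )
        lines.append("")
    return "\n".join(lines)
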