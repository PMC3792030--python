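"""End-to-end driver: coverage -> binning -> slopes -> DE -> selection.

The pipeline runs each growth phase independently: replicate read sets
are pooled per condition, turned into 100-bin relative coverage
profiles, differenced and regressed for the coverage-shift slope, while
the counts table feeds the NB differential-abundance stage; the dual
mean+SD rule then produces the candidate list.  Inputs come either from
files (annotation + per-sample BED reads and/or a counts table) or from
the built-in simulator.  All outputs are TSVs plus a JSON run log
recording the config hash, seed, thresholds and exclusion counts — and
nothing time-dependent, so identical configs give byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import coverage, diffexpr, select, shift
from .io import (
    CANDIDATE_COLUMNS,
    CONDITIONS,
    PHASES,
    SLOPE_COLUMNS,
    CountsTable,
    TranscriptAnnotation,
    read_annotation,
    read_counts,
    read_reads,
    write_results,
)
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable).

    Exactly one input route must be given: ``simulate`` (a
    :class:`SimulationConfig` mapping) or ``annotation`` plus per-sample
    ``reads`` paths (``sample_id -> BED path``) with sample metadata in
    ``counts``/``samples`` TSVs or derived by interval counting.
    """

    outdir: str = "results/run"
    phases: tuple[str, ...] = PHASES
    simulate: SimulationConfig | None = None
    annotation: str | None = None
    reads: dict[str, str] = field(default_factory=dict)
    counts: str | None = None
    samples: str | None = None
    stranded: bool = True
    replicate_handling: str = "pool"  # or "average"
    min_reads: int = coverage.DEFAULT_MIN_READS
    padj_threshold: float = select.DEFAULT_PADJ_THRESHOLD
    background: str = "all"  # or "significant"
    write_simulated_inputs: bool = False
    write_bedgraph: bool = False

    def __post_init__(self) -> None:
        self.phases = tuple(self.phases)  # type: ignore[assignment]
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        if self.simulate is None and self.annotation is None and self.counts is None:
            raise ValueError("config needs either a simulate: section or input paths")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases {sorted(unknown)}")
        if self.simulate is not None:
            self.phases = tuple(p for p in self.phases if p in self.simulate.phases)
            if not self.phases:
                raise ValueError("no overlap between pipeline phases and simulated phases")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def canonical_dict(self) -> dict:
        data = dataclasses.asdict(self)
        if self.simulate is not None:
            data["simulate"] = dataclasses.asdict(self.simulate)
            data["simulate"]["length_range"] = list(self.simulate.length_range)
            data["simulate"]["phases"] = list(self.simulate.phases)
        data["phases"] = list(self.phases)
        return data

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration.

        The output directory is excluded: the same analysis written to two
        locations is the same analysis (and its run logs stay identical).
        """
        payload = self.canonical_dict()
        payload.pop("outdir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class PhaseResult:
    phase: str
    slopes: pd.DataFrame
    de: pd.DataFrame
    records: pd.DataFrame  # all background transcripts with pass flags
    thresholds: select.SelectionThresholds | None
    exclusions: dict[str, dict[str, int]]


@dataclass
class PipelineResult:
    config: PipelineConfig
    phases: dict[str, PhaseResult]
    slopes: pd.DataFrame
    de: pd.DataFrame
    candidates: pd.DataFrame
    truth: pd.DataFrame | None
    log: dict
    output_paths: dict[str, Path]


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorate


@dataclass
class _Inputs:
    annotations: list[TranscriptAnnotation]
    reads: pd.DataFrame | None
    counts: CountsTable
    truth: pd.DataFrame | None


@_stage("input")
def _load_inputs(config: PipelineConfig) -> _Inputs:
    if config.simulate is not None:
        dataset: SimulatedDataset = simulate_dataset(config.simulate)
        if config.write_simulated_inputs:
            write_dataset(dataset, Path(config.outdir) / "simulated_inputs")
        return _Inputs(dataset.annotations, dataset.reads, dataset.counts, dataset.truth)
    annotations = read_annotation(config.annotation) if config.annotation else []
    reads = None
    if config.reads:
        frames = [read_reads(path, sid) for sid, path in sorted(config.reads.items())]
        reads = pd.concat(frames, ignore_index=True)
    if config.counts is not None:
        if config.samples is None:
            raise ValueError("counts TSV requires a samples metadata TSV")
        counts = read_counts(config.counts, config.samples)
    else:
        if reads is None or config.samples is None:
            raise ValueError("without a counts TSV, reads and samples metadata are required")
        samples = pd.read_csv(config.samples, sep="\t", index_col="sample_id")
        matrix = coverage.count_reads(reads, annotations, stranded=config.stranded)
        counts = CountsTable(matrix, samples)
    return _Inputs(annotations, reads, counts, None)


@_stage("profiles")
def _phase_profiles(
    config: PipelineConfig,
    inputs: _Inputs,
    phase: str,
) -> tuple[dict[str, Mapping], dict[str, dict[str, int]]]:
    """Binned profiles per condition for one phase, plus exclusion tallies."""
    samples = inputs.counts.samples
    profiles: dict[str, Mapping] = {}
    exclusions: dict[str, dict[str, int]] = {}
    for condition in CONDITIONS:
        sample_ids = list(
            samples.index[(samples["phase"] == phase) & (samples["condition"] == condition)]
        )
        binned, excluded = coverage.condition_binned_profiles(
            inputs.reads,
            inputs.annotations,
            sample_ids,
            stranded=config.stranded,
            min_reads=config.min_reads,
            replicate_handling=config.replicate_handling,
        )
        profiles[condition] = binned
        tally: dict[str, int] = {}
        for reason in excluded.values():
            tally[reason] = tally.get(reason, 0) + 1
        exclusions[condition] = tally
    return profiles, exclusions


def run_phase(config: PipelineConfig, inputs: _Inputs, phase: str) -> PhaseResult:
    has_coverage = inputs.reads is not None and bool(inputs.annotations)
    if has_coverage:
        profiles, exclusions = _phase_profiles(config, inputs, phase)
        slopes = _stage("slopes")(shift.slope_table)(
            profiles["WT"], profiles["mutant"], phase
        )
        if slopes.empty:
            logger.warning("phase %s: no transcript eligible for the slope analysis", phase)
    else:  # counts-only run: the DE stage in isolation
        slopes = pd.DataFrame(columns=SLOPE_COLUMNS)
        exclusions = {}
    de = _stage("de")(diffexpr.nb_test)(inputs.counts, phase)
    if slopes.empty:
        thresholds = None
        records = pd.DataFrame(columns=CANDIDATE_COLUMNS + ["is_candidate"])
    else:
        thresholds = _stage("thresholds")(select.compute_thresholds)(
            de, slopes, phase, config.background, config.padj_threshold
        )
        records = _stage("select")(select.select_candidates)(
            de, slopes, thresholds, phase, config.background, config.padj_threshold
        )
    return PhaseResult(phase, slopes, de, records, thresholds, exclusions)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage for every configured phase and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)

    phase_results: dict[str, PhaseResult] = {}
    for phase in config.phases:
        phase_results[phase] = run_phase(config, inputs, phase)

    slopes = pd.concat([r.slopes for r in phase_results.values()], ignore_index=True)
    de = pd.concat([r.de for r in phase_results.values()], ignore_index=True)
    candidates = pd.concat(
        [select.candidate_table(r.records) for r in phase_results.values()],
        ignore_index=True,
    )
    paths = write_results(slopes, de, candidates, outdir)

    if config.write_bedgraph and inputs.reads is not None:
        for strand in ("+", "-"):
            tag = "fwd" if strand == "+" else "rev"
            path = outdir / f"coverage_{tag}.bedgraph"
            coverage.write_bedgraph(coverage.genome_depth(inputs.reads, strand), path)
            paths[f"coverage_{tag}"] = path

    log = {
        "config_hash": config.hash(),
        "seed": config.simulate.seed if config.simulate is not None else None,
        "phases": {
            phase: {
                "thresholds": None
                if r.thresholds is None
                else {
                    "fc_mean": r.thresholds.fc_mean,
                    "fc_sd": r.thresholds.fc_sd,
                    "fc_cutoff": r.thresholds.fc_cutoff,
                    "slope_mean": r.thresholds.slope_mean,
                    "slope_sd": r.thresholds.slope_sd,
                    "slope_cutoff": r.thresholds.slope_cutoff,
                    "n_background": r.thresholds.n_background,
                },
                "exclusions": r.exclusions,
                "n_slopes": int(len(r.slopes)),
                "n_tested": int(r.de["pvalue"].notna().sum()),
                "n_significant": int((r.de["padj"] < config.padj_threshold).sum()),
                "n_candidates": int(r.records["is_candidate"].sum()),
            }
            for phase, r in phase_results.items()
        },
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_log"] = log_path

    return PipelineResult(
        config=config,
        phases=phase_results,
        slopes=slopes,
        de=de,
        candidates=candidates,
        truth=inputs.truth,
        log=log,
        output_paths=paths,
    )
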