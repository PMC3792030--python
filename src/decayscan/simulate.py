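"""Seeded simulator of a WT versus exonuclease-deletion RNA-seq experiment.

The generator emulates the design of the study this pipeline targets: two
strains (wild type carrying a 5'->3' exoribonuclease, and its deletion
mutant) sampled in two growth phases with two biological replicates each.
A configurable subset of transcripts are true decay targets: in the wild
type their read coverage is linearly depleted toward the 5' end with
strength ``decay_depth`` (relative per-base coverage proportional to
1 - d(1 - x) at normalised position x), and their abundance is shifted
up in the mutant by ``target_log2fc``.  Per-replicate transcript counts
are negative-binomial with dispersion ``nb_dispersion``
(Var = mu + alpha mu^2) around log-normally scattered transcript means.

Fragment placement models random fragmentation of surviving molecules:
every base of a molecule — including the termini — is covered by some
fragment, so sampled fragments may overhang either annotated transcript
end and are clipped to the transcript on output.  Each fragment is drawn
with probability proportional to the decay-survival law evaluated at the
(untrimmed) fragment midpoint, which makes the expected per-base
coverage exactly proportional to 1 - d(1 - x) for any read length; the
closed-form slope oracle :func:`expected_slope` is therefore exact, not
an approximation.

Randomness is organised as one independent stream per sample, derived
from the master seed by a fixed rule (see :func:`_stream`): adding
replicates or phases never perturbs the reads of existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    CONDITIONS,
    PHASES,
    CountsTable,
    TranscriptAnnotation,
    empty_reads,
    validate_reads,
    write_annotation,
    write_counts,
    write_reads,
)
from .coverage import N_BINS


def expected_slope(d: float) -> float:
    """Noiseless coverage-shift slope for decay depth ``d``.

    Under linear 5' depletion the WT relative density is
    (1 - d(1 - x))/(1 - d/2) and the mutant is uniform, so the 100-bin
    difference curve is linear in x with slope d/(100 (1 - d/2)) per unit
    of normalised position.
    """
    if not 0 <= d < 1:
        raise ValueError(f"decay depth must lie in [0, 1), got {d}")
    return d / (N_BINS * (1 - d / 2))


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    Defaults describe the standard recovery setting: 500 transcripts of
    300-2400 nt, 10% true decay targets with decay depth 0.6 and a
    two-fold-squared (log2fc = 2) abundance shift in the mutant, NB
    dispersion 0.05, two replicates per condition and an expected 2000
    fragments per transcript per replicate (so roughly 4000 pooled per
    condition).
    """

    n_transcripts: int = 500
    length_range: tuple[int, int] = (300, 2400)
    n_replicates: int = 2
    read_length: int = 36
    mean_depth: float = 2000.0
    abundance_sigma: float = 0.5
    nb_dispersion: float = 0.05
    target_fraction: float = 0.10
    decay_depth: float = 0.6
    target_log2fc: float = 2.0
    phases: tuple[str, ...] = PHASES
    chrom: str = "synthchr1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.length_range = tuple(self.length_range)  # type: ignore[assignment]
        self.phases = tuple(self.phases)  # type: ignore[assignment]
        if not 0 <= self.decay_depth < 1:
            raise ValueError(f"decay_depth must lie in [0, 1), got {self.decay_depth}")
        if not 0 < self.target_fraction < 1:
            raise ValueError(f"target_fraction must lie in (0, 1), got {self.target_fraction}")
        for name in ("n_transcripts", "n_replicates", "read_length", "mean_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.abundance_sigma < 0:
            raise ValueError("nb_dispersion and abundance_sigma must be non-negative")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["length_range"] = list(self.length_range)
        data["phases"] = list(self.phases)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SimulatedDataset:
    """Everything one simulation produces, in the containers the pipeline reads."""

    config: SimulationConfig
    annotations: list[TranscriptAnnotation]
    reads: pd.DataFrame
    counts: CountsTable
    truth: pd.DataFrame  # index transcript_id: is_target, decay_depth, true_log2fc


def sample_name(condition: str, phase: str, replicate: int) -> str:
    return f"{condition}_{phase}_{replicate}"


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (seed, key...).

    Transcript structure uses key (0,); the sample for (phase p, condition
    c, replicate r) uses key (1, p+1, c+1, r) with phases and conditions in
    their canonical order.  Streams depend only on their own key, so new
    samples never reshuffle existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _transcript_structure(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_transcripts
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = rng.choice(np.array(STRAND_CHOICES), size=n)
    base_mu = config.mean_depth * rng.lognormal(
        mean=-config.abundance_sigma**2 / 2, sigma=config.abundance_sigma, size=n
    )
    n_targets = int(round(n * config.target_fraction))
    target_idx = rng.choice(n, size=n_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    gap = max(150, config.read_length + 10)  # keeps overhanging fragments apart
    starts = np.concatenate(([0], np.cumsum(lengths + gap)[:-1])) + gap
    width = len(str(n))
    annotations = [
        TranscriptAnnotation(
            transcript_id=f"tx{i + 1:0{width}d}",
            chrom=config.chrom,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(n)
    ]
    return annotations, base_mu, is_target


STRAND_CHOICES = ("+", "-")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(r, p)


def _fragment_offsets(
    rng: np.random.Generator, k: int, length: int, read_length: int, d: float
) -> np.ndarray:
    """5'-offsets of ``k`` fragment starts for one transcript.

    Offsets range over [-(read_length - 1), length - 1] so fragments may
    overhang either end; under decay depth ``d`` each offset is weighted
    by the survival law 1 - d(1 - x) at the untrimmed fragment midpoint
    (clipped at zero for extreme d on short transcripts).
    """
    offsets = np.arange(-(read_length - 1), length)
    if d == 0:
        return rng.choice(offsets, size=k) if k else offsets[:0]
    x_mid = (offsets + (read_length - 1) / 2 + 0.5) / length
    weights = np.clip(1.0 - d * (1.0 - x_mid), 0.0, None)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    return offsets[np.searchsorted(cdf, rng.random(k), side="right")]


def _sample_reads(
    rng: np.random.Generator,
    annotations: Sequence[TranscriptAnnotation],
    counts: np.ndarray,
    read_length: int,
    decay_depths: np.ndarray,
    sample_id: str,
) -> pd.DataFrame:
    total = int(counts.sum())
    chroms = np.empty(total, dtype=object)
    starts = np.empty(total, dtype=np.int64)
    ends = np.empty(total, dtype=np.int64)
    strand_arr = np.empty(total, dtype=object)
    pos = 0
    for i, tx in enumerate(annotations):
        k = int(counts[i])
        if k == 0:
            continue
        offsets = _fragment_offsets(rng, k, tx.length, read_length, float(decay_depths[i]))
        if tx.strand == "+":
            s = tx.start + offsets
            e = s + read_length
        else:  # 5' end sits at the genomic end
            e = tx.end - offsets
            s = e - read_length
        np.clip(s, tx.start, tx.end, out=s)
        np.clip(e, tx.start, tx.end, out=e)
        sl = slice(pos, pos + k)
        chroms[sl] = tx.chrom
        starts[sl] = s
        ends[sl] = e
        strand_arr[sl] = tx.strand
        pos += k
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "strand": strand_arr,
            "sample_id": sample_id,
        }
    )
    return frame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate annotations, per-sample reads, counts and ground truth.

    Identical configs (including the seed) give bit-identical results.
    """
    structure_rng = _stream(config.seed, 0)
    annotations, base_mu, is_target = _transcript_structure(config, structure_rng)
    n = config.n_transcripts

    decay_depths = np.where(is_target, config.decay_depth, 0.0)
    truth = pd.DataFrame(
        {
            "is_target": is_target,
            "decay_depth": decay_depths,
            "true_log2fc": np.where(is_target, config.target_log2fc, 0.0),
        },
        index=pd.Index([t.transcript_id for t in annotations], name="transcript_id"),
    )

    frames: list[pd.DataFrame] = []
    count_cols: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, int]] = []
    for p, phase in enumerate(config.phases):
        for c, condition in enumerate(CONDITIONS):
            mu = base_mu.copy()
            if condition == "mutant":
                mu[is_target] *= 2.0**config.target_log2fc
            for replicate in range(1, config.n_replicates + 1):
                sid = sample_name(condition, phase, replicate)
                rng = _stream(config.seed, 1, p + 1, c + 1, replicate)
                k = _draw_counts(rng, mu, config.nb_dispersion)
                sample_decay = decay_depths if condition == "WT" else np.zeros(n)
                frames.append(
                    _sample_reads(
                        rng, annotations, k, config.read_length, sample_decay, sid
                    )
                )
                count_cols[sid] = k.astype(np.int64)
                meta_rows.append((sid, condition, phase, replicate))

    reads = pd.concat(frames, ignore_index=True) if frames else empty_reads()
    reads["sample_id"] = reads["sample_id"].astype("category")
    validate_reads(reads)

    counts = CountsTable(
        pd.DataFrame(
            count_cols, index=pd.Index([t.transcript_id for t in annotations], name="transcript_id")
        ),
        pd.DataFrame(
            meta_rows, columns=["sample_id", "condition", "phase", "replicate"]
        ).set_index("sample_id"),
    )
    return SimulatedDataset(config, annotations, reads, counts, truth)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the pipeline's input formats.

    Produces ``annotation.gff3``, one ``reads_<sample>.bed`` per sample,
    ``counts.tsv``/``samples.tsv``, ``truth.tsv`` and ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "annotation.gff3"
    write_annotation(dataset.annotations, paths["annotation"])
    for sid in dataset.counts.samples.index:
        path = outdir / f"reads_{sid}.bed"
        write_reads(dataset.reads[dataset.reads["sample_id"] == sid], path)
        paths[f"reads_{sid}"] = path
    paths["counts"] = outdir / "counts.tsv"
    paths["samples"] = outdir / "samples.tsv"
    write_counts(dataset.counts, paths["counts"], paths["samples"])
    paths["truth"] = outdir / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    paths["config"] = outdir / "config.yaml"
    dataset.config.to_yaml(paths["config"])
    return paths
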