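"""Per-base coverage profiles and 100-bin relative (metatranscript) profiles.

A transcript's positional profile is its per-base read depth ordered 5'
to 3' (index 0 = biological 5' end, so minus-strand profiles are the
reverse of genomic order).  For cross-condition comparison the profile is
normalised by its total depth and rescaled to a fixed length of 100 bins,
giving a relative coverage profile that sums to one — a probability
distribution of read mass along the transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptAnnotation, validate_reads

logger = logging.getLogger(__name__)

N_BINS = 100

#: minimum pooled read count per condition for a transcript to enter the
#: coverage-shift analysis
DEFAULT_MIN_READS = 50


class ProfileError(ValueError):
    """A transcript cannot yield a valid binned profile."""

    reason: str = "invalid"


class ZeroCoverageError(ProfileError):
    reason = "unquantifiable"


class TooShortError(ProfileError):
    reason = "too_short"


@dataclass
class PositionalProfile:
    """Per-base read depth along one transcript, 5'->3' oriented."""

    transcript_id: str
    depth: np.ndarray
    n_overlapping_reads: int


@dataclass
class BinnedProfile:
    """100-bin relative coverage profile; bins sum to 1."""

    transcript_id: str
    bins: np.ndarray


def bin_midpoints() -> np.ndarray:
    """Normalised positions of the bin centres, x_i = (i - 0.5)/100."""
    return (np.arange(N_BINS) + 0.5) / N_BINS


def compute_depth(
    reads: pd.DataFrame,
    tx: TranscriptAnnotation,
    stranded: bool = True,
) -> PositionalProfile:
    """Per-base depth of ``reads`` over ``tx``, oriented 5'->3'.

    A read contributes to every base it covers; a read counts as
    overlapping when it shares at least one base with the transcript.
    With ``stranded`` (default), only reads on the transcript's strand are
    counted.
    """
    reads = validate_reads(reads)
    mask = (
        (reads["chrom"].to_numpy() == tx.chrom)
        & (reads["start"].to_numpy() < tx.end)
        & (reads["end"].to_numpy() > tx.start)
    )
    if stranded:
        mask &= reads["strand"].to_numpy() == tx.strand
    starts = reads["start"].to_numpy()[mask]
    ends = reads["end"].to_numpy()[mask]
    return _depth_from_intervals(tx, starts, ends)


def _depth_from_intervals(
    tx: TranscriptAnnotation, starts: np.ndarray, ends: np.ndarray
) -> PositionalProfile:
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    length = tx.length
    delta = np.zeros(length + 1)
    np.add.at(delta, np.clip(starts - tx.start, 0, length), 1.0)
    np.add.at(delta, np.clip(ends - tx.start, 0, length), -1.0)
    depth = np.cumsum(delta[:-1])
    if tx.strand == "-":
        depth = depth[::-1].copy()
    return PositionalProfile(tx.transcript_id, depth, int(len(starts)))


def depth_profiles(
    reads: pd.DataFrame,
    annotations: Sequence[TranscriptAnnotation],
    stranded: bool = True,
) -> dict[str, PositionalProfile]:
    """Positional profiles for every annotation, indexed by transcript_id.

    Equivalent to calling :func:`compute_depth` per transcript but sorts
    the reads once per (chromosome, strand) group so large read sets are
    handled in near-linear time.
    """
    reads = validate_reads(reads)
    profiles: dict[str, PositionalProfile] = {}
    group_cols = ["chrom", "strand"] if stranded else ["chrom"]
    groups: dict[tuple, tuple[np.ndarray, np.ndarray, int]] = {}
    for key, grp in reads.groupby(group_cols, sort=False, observed=True):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order].astype(np.int64)
        ends = grp["end"].to_numpy()[order].astype(np.int64)
        span = int((ends - starts).max()) if len(starts) else 0
        groups[key if isinstance(key, tuple) else (key,)] = (starts, ends, span)
    for tx in annotations:
        key = (tx.chrom, tx.strand) if stranded else (tx.chrom,)
        if key not in groups:
            profiles[tx.transcript_id] = PositionalProfile(
                tx.transcript_id, np.zeros(tx.length), 0
            )
            continue
        starts, ends, span = groups[key]
        lo = np.searchsorted(starts, tx.start - span, side="left")
        hi = np.searchsorted(starts, tx.end, side="left")
        sub_start, sub_end = starts[lo:hi], ends[lo:hi]
        keep = sub_end > tx.start
        profiles[tx.transcript_id] = _depth_from_intervals(
            tx, sub_start[keep], sub_end[keep]
        )
    return profiles


def pool_profiles(profiles: Iterable[PositionalProfile]) -> PositionalProfile:
    """Sum per-base depths of replicate profiles for one transcript."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to pool")
    tid = profiles[0].transcript_id
    if any(p.transcript_id != tid for p in profiles):
        raise ValueError("pool_profiles mixes transcripts")
    depth = np.sum([p.depth for p in profiles], axis=0)
    return PositionalProfile(tid, depth, sum(p.n_overlapping_reads for p in profiles))


def bin_profile(profile: PositionalProfile) -> BinnedProfile:
    """Rescale a positional profile to 100 bins of relative coverage.

    Per-base depth is first normalised by the transcript's total depth;
    base ``p`` of a length-``L`` transcript is then assigned to bin
    ``floor(100 p / L)`` and the relative mass summed per bin, so the bins
    conserve total mass and sum to exactly 1.

    Raises
    ------
    TooShortError
        If the transcript is shorter than 100 nt (the rescaling would be
        ill-defined).
    ZeroCoverageError
        If the total depth is zero (nothing to normalise).
    """
    length = len(profile.depth)
    if length < N_BINS:
        raise TooShortError(f"{profile.transcript_id}: length {length} < {N_BINS}")
    total = profile.depth.sum()
    if total <= 0:
        raise ZeroCoverageError(f"{profile.transcript_id}: total depth is zero")
    relative = profile.depth / total
    bin_index = (N_BINS * np.arange(length, dtype=np.int64)) // length
    bins = np.bincount(bin_index, weights=relative, minlength=N_BINS)
    return BinnedProfile(profile.transcript_id, bins)


def bin_profiles(
    profiles: Mapping[str, PositionalProfile],
    min_reads: int = 0,
) -> tuple[dict[str, BinnedProfile], dict[str, str]]:
    """Bin every profile; return (binned, exclusions keyed by reason).

    Transcripts with fewer than ``min_reads`` overlapping reads are
    excluded with reason ``low_coverage``; too-short or zero-coverage
    transcripts carry the reasons raised by :func:`bin_profile`.
    """
    binned: dict[str, BinnedProfile] = {}
    excluded: dict[str, str] = {}
    for tid, profile in profiles.items():
        if profile.n_overlapping_reads < min_reads and profile.depth.sum() > 0:
            excluded[tid] = "low_coverage"
            continue
        try:
            binned[tid] = bin_profile(profile)
        except ProfileError as exc:
            excluded[tid] = exc.reason
    return binned, excluded


def condition_binned_profiles(
    reads: pd.DataFrame,
    annotations: Sequence[TranscriptAnnotation],
    sample_ids: Sequence[str],
    stranded: bool = True,
    min_reads: int = 0,
    replicate_handling: str = "pool",
) -> tuple[dict[str, BinnedProfile], dict[str, str]]:
    """Binned profiles for one condition from its replicate samples.

    ``replicate_handling='pool'`` (default) sums replicate depths before
    normalising — one profile per condition, as when replicates are merged
    prior to the coverage comparison.  ``'average'`` instead bins each
    replicate separately and averages the relative profiles (each summing
    to 1, so the average does too).
    """
    sample_ids = list(sample_ids)
    subset = reads[reads["sample_id"].isin(sample_ids)]
    if replicate_handling == "pool":
        profiles = depth_profiles(subset, annotations, stranded=stranded)
        return bin_profiles(profiles, min_reads=min_reads)
    if replicate_handling != "average":
        raise ValueError(f"replicate_handling must be 'pool' or 'average', got {replicate_handling!r}")
    per_rep = [
        depth_profiles(subset[subset["sample_id"] == sid], annotations, stranded=stranded)
        for sid in sample_ids
    ]
    binned: dict[str, BinnedProfile] = {}
    excluded: dict[str, str] = {}
    for tx in annotations:
        tid = tx.transcript_id
        pooled_reads = sum(p[tid].n_overlapping_reads for p in per_rep)
        if pooled_reads < min_reads:
            excluded[tid] = "low_coverage"
            continue
        try:
            reps = [bin_profile(p[tid]) for p in per_rep if p[tid].depth.sum() > 0]
            if not reps:
                raise ZeroCoverageError(f"{tid}: total depth is zero")
            bins = np.mean([b.bins for b in reps], axis=0)
            binned[tid] = BinnedProfile(tid, bins)
        except ProfileError as exc:
            excluded[tid] = exc.reason
    return binned, excluded


def count_reads(
    reads: pd.DataFrame,
    annotations: Sequence[TranscriptAnnotation],
    stranded: bool = True,
) -> pd.DataFrame:
    """Reads overlapping each transcript by >= 1 nt, per sample.

    Returns a transcript x sample frame of integer counts (each read
    interval counts once per transcript it overlaps).
    """
    reads = validate_reads(reads)
    sample_ids = sorted(reads["sample_id"].unique())
    counts = pd.DataFrame(
        0,
        index=pd.Index([t.transcript_id for t in annotations], name="transcript_id"),
        columns=sample_ids,
        dtype=np.int64,
    )
    for sid in sample_ids:
        profiles = depth_profiles(
            reads[reads["sample_id"] == sid], annotations, stranded=stranded
        )
        counts[sid] = [profiles[t.transcript_id].n_overlapping_reads for t in annotations]
    return counts


def genome_depth(reads: pd.DataFrame, strand: str | None = None) -> dict[str, np.ndarray]:
    """Genome-wide per-base depth per chromosome (optionally one strand)."""
    reads = validate_reads(reads)
    if strand is not None:
        reads = reads[reads["strand"] == strand]
    out: dict[str, np.ndarray] = {}
    for chrom, grp in reads.groupby("chrom", sort=True, observed=True):
        size = int(grp["end"].max())
        delta = np.zeros(size + 1)
        np.add.at(delta, grp["start"].to_numpy(), 1.0)
        np.add.at(delta, grp["end"].to_numpy(), -1.0)
        out[str(chrom)] = np.cumsum(delta[:-1])
    return out


def write_bedgraph(depth_by_chrom: Mapping[str, np.ndarray], path) -> None:
    """Write per-base depth as a bedGraph track (runs of equal depth)."""
    with open(path, "w") as fh:
        for chrom in sorted(depth_by_chrom):
            depth = np.asarray(depth_by_chrom[chrom])
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(depth)]))
            for s, e in zip(starts, ends):
                value = depth[s]
                if value != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{value:g}\n")
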