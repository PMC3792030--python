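"""Readers and writers for annotations, read intervals, counts and result tables.

All genomic intervals are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted here, at the I/O boundary, and nowhere
else.  Every downstream module consumes only the containers produced by
this module: :class:`TranscriptAnnotation`, a read-interval
:class:`pandas.DataFrame` with the fixed columns :data:`READ_COLUMNS`, and
:class:`CountsTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")
CONDITIONS = ("WT", "mutant")
PHASES = ("log", "stationary")

#: column order of a read-interval frame (one row per aligned read/fragment)
READ_COLUMNS = ["chrom", "start", "end", "strand", "sample_id"]

#: fixed output schemas
SLOPE_COLUMNS = ["transcript_id", "phase", "slope", "intercept", "r2", "n_bins"]
DE_COLUMNS = ["transcript_id", "phase", "base_mean", "log2fc", "pvalue", "padj"]
CANDIDATE_COLUMNS = [
    "transcript_id", "phase", "log2fc", "slope", "passes_fc", "passes_slope",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as its format."""


class DuplicateIdError(ParseError):
    """Raised when two annotation records share a transcript_id."""


@dataclass(frozen=True, order=True)
class TranscriptAnnotation:
    """One annotated transcript: a stranded genomic interval.

    Coordinates are 0-based, half-open.  ``strand`` fixes the biological
    orientation: on ``+`` the 5' end is ``start``, on ``-`` it is
    ``end - 1``.
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.transcript_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for tid in ids:
        if tid in seen:
            raise DuplicateIdError(f"duplicate transcript_id {tid!r}")
        seen.add(tid)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    if suffix == ".bed":
        return "bed"
    raise ValueError(f"cannot infer annotation format from {path.name!r}; pass format=")


def read_annotation(
    path: str | Path,
    format: str | None = None,
    feature_types: Sequence[str] | None = None,
) -> list[TranscriptAnnotation]:
    """Read transcript annotations from a GFF3 or BED6 file.

    GFF3 records are converted from 1-based inclusive to the internal
    0-based half-open convention; BED is adopted as-is.  ``feature_types``
    optionally restricts GFF3 parsing to the given feature types (for
    example ``("gene",)``); by default every feature is taken.

    Raises
    ------
    ParseError
        On a malformed line (the message names the line number) or a
        duplicate transcript_id.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "gff3":
        records = _read_gff3(path, feature_types)
    elif fmt == "bed":
        records = _read_bed_annotation(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    _check_unique_ids([r.transcript_id for r in records])
    return records


def _gff3_record_id(attributes: str, lineno: int, path: Path) -> str:
    for field in attributes.rstrip(";").split(";"):
        field = field.strip()
        if not field or "=" not in field:
            continue
        key, value = field.split("=", 1)
        if key.strip() in ("ID", "locus_tag", "Name"):
            return value.strip()
    raise ParseError(f"{path}:{lineno}: no ID/locus_tag/Name attribute in {attributes!r}")


def _prescan_gff3(path: Path, feature_types: Sequence[str] | None) -> list[tuple[int, str]]:
    """Validate a GFF3 file line by line; return (lineno, transcript_id) pairs."""
    out: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}")
            if feature_types is not None and fields[2] not in feature_types:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid 1-based interval [{start}, {end}]")
            if fields[6] not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {fields[6]!r}")
            out.append((lineno, _gff3_record_id(fields[8], lineno, path)))
    return out


def _read_gff3(path: Path, feature_types: Sequence[str] | None) -> list[TranscriptAnnotation]:
    import gffutils

    id_by_line = _prescan_gff3(path, feature_types)
    _check_unique_ids([tid for _, tid in id_by_line])
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True,
            merge_strategy="create_unique", from_string=False,
        )
    except Exception as exc:  # pragma: no cover - prescan catches the common cases
        raise ParseError(f"{path}: not parseable as GFF3: {exc}") from exc
    records = []
    for feature in db.all_features(order_by=None):
        if feature_types is not None and feature.featuretype not in feature_types:
            continue
        for key in ("ID", "locus_tag", "Name"):
            if key in feature.attributes:
                tid = feature.attributes[key][0]
                break
        else:  # pragma: no cover - prescan already rejects these
            raise ParseError(f"{path}: feature without ID/locus_tag/Name")
        records.append(
            TranscriptAnnotation(
                transcript_id=tid,
                chrom=feature.seqid,
                start=feature.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feature.end,
                strand=feature.strand,
            )
        )
    return sorted(records)


def _read_bed_annotation(path: Path) -> list[TranscriptAnnotation]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                records.append(
                    TranscriptAnnotation(
                        transcript_id=fields[3], chrom=fields[0],
                        start=start, end=end, strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return sorted(records)


def write_annotation(records: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    """Write annotations as GFF3 (feature type ``transcript``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(records):
            fh.write(
                f"{r.chrom}\tdecayscan\ttranscript\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={r.transcript_id}\n"
            )


# ---------------------------------------------------------------------------
# read intervals


def empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "sample_id": pd.Series(dtype=str),
        }
    )


def validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Check a read-interval frame against the ReadInterval contract."""
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read frame missing columns {missing}")
    if len(reads) and not (reads["end"].to_numpy() > reads["start"].to_numpy()).all():
        bad = int((reads["end"] <= reads["start"]).idxmax())
        raise ValueError(f"read interval with end <= start at row {bad}")
    if len(reads) and not reads["strand"].isin(STRANDS).all():
        raise ValueError("read strand must be '+' or '-'")
    return reads[READ_COLUMNS]


def read_reads(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read aligned fragments from a BED file into a read-interval frame.

    Each record becomes one unspliced interval tagged with ``sample_id``.
    Lines with ``end <= start`` raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            if fields[5] not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {fields[5]!r}")
            rows.append((fields[0], start, end, fields[5]))
    if not rows:
        return empty_reads()
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    frame["sample_id"] = sample_id
    return validate_reads(frame)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a (single-sample) read-interval frame as BED6."""
    frame = reads.copy()
    frame["name"] = "."
    frame["score"] = 0
    frame[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountsTable:
    """Gene x sample matrix of read counts plus per-sample metadata.

    ``counts`` is indexed by transcript_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns ``condition``
    (WT/mutant), ``phase`` (log/stationary) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.counts = counts.astype(np.int64)
        missing = set(counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns {sorted(missing)}")
        for column, allowed in (("condition", CONDITIONS), ("phase", PHASES)):
            if column not in self.samples.columns:
                raise ValueError(f"samples metadata needs a {column!r} column")
            bad = set(self.samples[column]) - set(allowed)
            if bad:
                raise ValueError(f"unknown {column} values {sorted(bad)}; allowed: {allowed}")

    def subset_phase(self, phase: str) -> "CountsTable":
        keep = self.samples.index[self.samples["phase"] == phase]
        return CountsTable(self.counts[list(keep)], self.samples.loc[keep])

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountsTable:
    """Read a counts TSV (transcript_id index) and a sample-metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="transcript_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return CountsTable(counts, samples)


def write_counts(table: CountsTable, counts_path: str | Path, samples_path: str | Path) -> None:
    table.counts.rename_axis("transcript_id").to_csv(counts_path, sep="\t", lineterminator="\n")
    table.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# result tables


def _write_table(frame: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    out = frame.reindex(columns=columns) if len(frame) else pd.DataFrame(columns=columns)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(
    slopes: pd.DataFrame,
    de: pd.DataFrame,
    candidates: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three result tables (TSV, fixed columns) to ``outdir``.

    ``candidates.tsv`` holds the tidy candidate list (phase column);
    ``candidates_by_phase.tsv`` repeats it split into one section per
    phase, mirroring the shape of a published per-phase candidate table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "slopes": outdir / "slopes.tsv",
        "de": outdir / "de.tsv",
        "candidates": outdir / "candidates.tsv",
        "candidates_by_phase": outdir / "candidates_by_phase.tsv",
    }
    _write_table(slopes, SLOPE_COLUMNS, paths["slopes"])
    _write_table(de, DE_COLUMNS, paths["de"])
    cand_cols = ["transcript_id", "phase", "log2fc", "slope"]
    _write_table(candidates, cand_cols, paths["candidates"])
    with open(paths["candidates_by_phase"], "w") as fh:
        phases = sorted(candidates["phase"].unique()) if len(candidates) else []
        if not phases:
            fh.write("\t".join(cand_cols) + "\n")
        for phase in phases:
            fh.write(f"# phase: {phase}\n")
            section = candidates.loc[candidates["phase"] == phase, cand_cols]
            fh.write(section.to_csv(sep="\t", index=False, lineterminator="\n"))
    return paths


def read_slopes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_de(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
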