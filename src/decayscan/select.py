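"""The dual mean+SD candidate-selection rule.

A transcript is called a 5'->3' decay target when, within one growth
phase, it is both (i) more abundant in the deletion mutant, with a log2
fold-change at least one standard deviation above the background mean,
and (ii) relatively 5'-depleted in the wild type, with a positive
coverage-shift slope at least one standard deviation above the
background slope mean.  The background is, by default, every transcript
possessing both statistics in that phase; restricting it to the
significantly differential transcripts is available as a switch.
Adjusted p-values play no role in selection — they feed only the
descriptive differential-abundance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CANDIDATE_COLUMNS

#: conventional significance threshold for the descriptive DE table and
#: for the optional significant-only selection background
DEFAULT_PADJ_THRESHOLD = 0.1


@dataclass
class SelectionThresholds:
    """Background statistics and the derived mean+SD cutoffs for one phase."""

    phase: str
    fc_mean: float
    fc_sd: float
    slope_mean: float
    slope_sd: float
    n_background: int
    background_ids: tuple[str, ...] = field(repr=False, default=())

    @property
    def fc_cutoff(self) -> float:
        return self.fc_mean + self.fc_sd

    @property
    def slope_cutoff(self) -> float:
        return self.slope_mean + self.slope_sd


def _background(
    de: pd.DataFrame,
    slopes: pd.DataFrame,
    phase: str,
    background: str = "all",
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
) -> pd.DataFrame:
    for name, frame in (("de", de), ("slopes", slopes)):
        wrong = set(frame["phase"].unique()) - {phase}
        if wrong:
            raise ValueError(f"{name} table contains phases {sorted(wrong)}, expected only {phase!r}")
    merged = de.merge(slopes, on=["transcript_id", "phase"], how="inner")
    merged = merged[np.isfinite(merged["log2fc"]) & np.isfinite(merged["slope"])]
    if background == "significant":
        merged = merged[merged["padj"] < padj_threshold]
    elif background != "all":
        raise ValueError(f"background must be 'all' or 'significant', got {background!r}")
    return merged.sort_values("transcript_id").reset_index(drop=True)


def compute_thresholds(
    de: pd.DataFrame,
    slopes: pd.DataFrame,
    phase: str,
    background: str = "all",
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
) -> SelectionThresholds:
    """Mean + 1 sample SD (n-1 denominator) of log2fc and slope.

    The background is the set of transcripts carrying both a fold-change
    and a slope in this phase; its membership is recorded on the returned
    object for reproducibility.  Fewer than two background transcripts is
    an error (the SD is undefined).
    """
    merged = _background(de, slopes, phase, background, padj_threshold)
    if len(merged) < 2:
        raise ValueError(
            f"phase {phase!r}: selection background has {len(merged)} transcript(s); need >= 2"
        )
    return SelectionThresholds(
        phase=phase,
        fc_mean=float(merged["log2fc"].mean()),
        fc_sd=float(merged["log2fc"].std(ddof=1)),
        slope_mean=float(merged["slope"].mean()),
        slope_sd=float(merged["slope"].std(ddof=1)),
        n_background=len(merged),
        background_ids=tuple(merged["transcript_id"]),
    )


def select_candidates(
    de: pd.DataFrame,
    slopes: pd.DataFrame,
    thresholds: SelectionThresholds,
    phase: str,
    background: str = "all",
    padj_threshold: float = DEFAULT_PADJ_THRESHOLD,
) -> pd.DataFrame:
    """Apply the dual rule; one record per background transcript.

    Returns a frame with the fixed candidate columns plus
    ``is_candidate``; ties at a cutoff are included (the comparisons are
    inclusive).  A candidate additionally requires a strictly positive
    slope, which matters only in the degenerate case of a cutoff <= 0.
    """
    if thresholds.phase != phase:
        raise ValueError(f"thresholds are for phase {thresholds.phase!r}, not {phase!r}")
    merged = _background(de, slopes, phase, background, padj_threshold)
    out = merged[["transcript_id", "phase", "log2fc", "slope"]].copy()
    out["passes_fc"] = out["log2fc"] >= thresholds.fc_cutoff
    out["passes_slope"] = out["slope"] >= thresholds.slope_cutoff
    out["is_candidate"] = out["passes_fc"] & out["passes_slope"] & (out["slope"] > 0)
    return out.reindex(columns=CANDIDATE_COLUMNS + ["is_candidate"])


def candidate_table(records: pd.DataFrame) -> pd.DataFrame:
    """The candidates only, in the output-table column order."""
    return (
        records.loc[records["is_candidate"], CANDIDATE_COLUMNS]
        .sort_values(["phase", "transcript_id"])
        .reset_index(drop=True)
    )


def score_against_truth(
    candidate_ids: set[str] | frozenset[str] | list[str],
    truth: pd.DataFrame,
) -> dict[str, float]:
    """Sensitivity and precision of a candidate set versus ground truth.

    ``truth`` is the simulator's table indexed by transcript_id with an
    ``is_target`` column.  Precision is defined as 1 for an empty
    candidate set.
    """
    candidates = set(candidate_ids)
    targets = set(truth.index[truth["is_target"]])
    tp = len(candidates & targets)
    sensitivity = tp / len(targets) if targets else float("nan")
    precision = tp / len(candidates) if candidates else 1.0
    return {
        "n_candidates": len(candidates),
        "n_targets": len(targets),
        "true_positives": tp,
        "sensitivity": sensitivity,
        "precision": precision,
    }
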