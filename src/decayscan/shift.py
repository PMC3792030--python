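"""The 5'->3' coverage-shift statistic.

For each transcript the mutant's 100-bin relative coverage profile is
subtracted from the wild type's, and the resulting difference curve is
summarised by the slope of an ordinary least-squares regression line
against normalised position x in (0, 1).  Because the exonuclease removes
5' read mass in the wild type, a transcript it degrades shows relatively
fewer 5' reads there, so the difference curve rises along the transcript
and the slope is positive.

Both input profiles sum to one, so the difference curve sums to zero;
regression algebra then forces intercept = -slope/2, an identity asserted
on every record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import N_BINS, BinnedProfile, bin_midpoints
from .io import SLOPE_COLUMNS


@dataclass
class DifferenceCurve:
    """Per-bin wild-type minus mutant relative coverage."""

    transcript_id: str
    values: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return bin_midpoints()


@dataclass
class SlopeRecord:
    transcript_id: str
    phase: str
    slope: float
    intercept: float
    r2: float
    n_bins: int = N_BINS


def difference_curve(wt: BinnedProfile, mut: BinnedProfile) -> DifferenceCurve:
    """Wild-type minus mutant binned profile for one transcript."""
    if wt.transcript_id != mut.transcript_id:
        raise ValueError(
            f"profile mismatch: {wt.transcript_id!r} vs {mut.transcript_id!r}"
        )
    return DifferenceCurve(wt.transcript_id, np.asarray(wt.bins) - np.asarray(mut.bins))


def ols_slope(curve: DifferenceCurve, phase: str = "log") -> SlopeRecord:
    """Ordinary least-squares line through the difference curve.

    slope = cov(x, D)/var(x) with x the bin midpoints on (0, 1); the
    reported slope is therefore per unit of normalised transcript length
    (divide by 100 for a per-bin slope).  r2 is 0 for an all-zero curve.
    """
    d = np.asarray(curve.values, dtype=float)
    if d.shape != (N_BINS,):
        raise ValueError(f"difference curve must have {N_BINS} values, got {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError(f"{curve.transcript_id}: non-finite difference curve")
    x = bin_midpoints()
    xc = x - x.mean()
    slope = float(xc @ (d - d.mean()) / (xc @ xc))
    intercept = float(d.mean() - slope * x.mean())
    fitted = intercept + slope * x
    ss_tot = float(((d - d.mean()) ** 2).sum())
    ss_res = float(((d - fitted) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SlopeRecord(curve.transcript_id, phase, slope, intercept, r2)


def slope_table(
    wt_profiles: Mapping[str, BinnedProfile],
    mut_profiles: Mapping[str, BinnedProfile],
    phase: str,
) -> pd.DataFrame:
    """Slope records for every transcript with profiles in both conditions.

    Returns a frame with the fixed slope-table columns, sorted by
    transcript_id.  Transcripts present in only one condition are simply
    absent (their exclusion reasons are tracked where the profiles were
    binned).
    """
    shared = sorted(set(wt_profiles) & set(mut_profiles))
    records = []
    for tid in shared:
        curve = difference_curve(wt_profiles[tid], mut_profiles[tid])
        rec = ols_slope(curve, phase)
        records.append(
            (rec.transcript_id, rec.phase, rec.slope, rec.intercept, rec.r2, rec.n_bins)
        )
    return pd.DataFrame(records, columns=SLOPE_COLUMNS)
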