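"""Difference-curve plots (optional; requires matplotlib)."""

from __future__ import annotations

from .shift import DifferenceCurve, SlopeRecord, ols_slope


def plot_difference_curve(curve: DifferenceCurve, record: SlopeRecord | None = None, ax=None):
    """Plot a WT-minus-mutant difference curve with its regression line.

    Mirrors the per-transcript diagnostic view: bin-wise relative
    coverage difference against normalised position, overlaid with the
    fitted line whose slope is the coverage-shift statistic.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    if record is None:
        record = ols_slope(curve)
    x = curve.x
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.plot(x, curve.values, lw=1.0, color="tab:blue", label="WT - mutant")
    ax.plot(
        x,
        record.intercept + record.slope * x,
        color="tab:red",
        lw=1.2,
        label=f"slope = {record.slope:.4f}",
    )
    ax.set_xlabel("normalised position (5' -> 3')")
    ax.set_ylabel("relative coverage difference")
    ax.set_title(curve.transcript_id)
    ax.legend(frameon=False, fontsize=8)
    return ax
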