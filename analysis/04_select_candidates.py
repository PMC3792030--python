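"""Dual mean+SD selection of 5'->3' decay targets, scored against truth.

Combines the slope tables (02) and differential-abundance tables (03):
per phase, a transcript is called a candidate when its log2 fold-change
(mutant/WT) and its coverage-shift slope each exceed the background mean
plus one standard deviation, with a strictly positive slope.  Writes
results/candidates.tsv and reports sensitivity and precision against the
simulator's ground truth.
"""

from pathlib import Path

import pandas as pd

from decayscan import compute_thresholds, score_against_truth, select_candidates
from decayscan.select import candidate_table

RESULTS = Path("results")


def main() -> None:
    truth = pd.read_csv(
        RESULTS / "simulated_inputs" / "truth.tsv", sep="\t", index_col="transcript_id"
    )
    all_candidates = []
    for phase in ("log", "stationary"):
        slopes = pd.read_csv(RESULTS / f"slopes_{phase}.tsv", sep="\t")
        de = pd.read_csv(RESULTS / f"de_{phase}.tsv", sep="\t")
        thresholds = compute_thresholds(de, slopes, phase)
        records = select_candidates(de, slopes, thresholds, phase)
        candidates = candidate_table(records)
        all_candidates.append(candidates)

        score = score_against_truth(set(candidates["transcript_id"]), truth)
        print(f"[{phase}] cutoffs: log2fc >= {thresholds.fc_cutoff:.3f}, "
              f"slope >= {thresholds.slope_cutoff:.5f} "
              f"(background n={thresholds.n_background})")
        print(f"[{phase}] {score['n_candidates']} candidates of "
              f"{score['n_targets']} true targets: "
              f"sensitivity {score['sensitivity']:.2f}, "
              f"precision {score['precision']:.2f}")

    combined = pd.concat(all_candidates, ignore_index=True)
    path = RESULTS / "candidates.tsv"
    combined.to_csv(path, sep="\t", index=False, lineterminator="\n")
    print(f"wrote {path} ({len(combined)} rows)")


if __name__ == "__main__":
    main()
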