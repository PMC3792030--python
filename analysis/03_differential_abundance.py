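"""Negative-binomial differential abundance, mutant versus wild type.

Reads the simulated counts table, estimates size factors and trend-shrunk
dispersions, and tests each transcript for an abundance difference
between the deletion mutant and the wild type, per growth phase.
Transcripts the exonuclease degrades accumulate in the mutant, so true
targets should surface with positive log2 fold-changes.  Writes
results/de_<phase>.tsv.
"""

from pathlib import Path

import pandas as pd

from decayscan import nb_test
from decayscan.io import read_counts

INDIR = Path("results/simulated_inputs")
OUTDIR = Path("results")
PADJ = 0.1


def main() -> None:
    counts = read_counts(INDIR / "counts.tsv", INDIR / "samples.tsv")
    truth = pd.read_csv(INDIR / "truth.tsv", sep="\t", index_col="transcript_id")

    for phase in ("log", "stationary"):
        result = nb_test(counts, phase)
        path = OUTDIR / f"de_{phase}.tsv"
        result.to_csv(path, sep="\t", index=False, lineterminator="\n")

        merged = result.set_index("transcript_id").join(truth)
        significant = merged["padj"] < PADJ
        n_sig = int(significant.sum())
        sig_targets = int((significant & merged["is_target"]).sum())
        mean_fc = merged.loc[merged["is_target"], "log2fc"].mean()
        print(f"[{phase}] tested {int(result['pvalue'].notna().sum())} transcripts; "
              f"{n_sig} significant at padj < {PADJ} ({sig_targets} true targets); "
              f"wrote {path}")
        print(f"[{phase}] mean log2fc of true targets: {mean_fc:.2f} (planted: 2.0)")


if __name__ == "__main__":
    main()
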