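"""Generate the standard recovery dataset.

Simulates the comparative design — wild type (exoribonuclease present)
versus deletion mutant, two growth phases, two biological replicates —
with 500 transcripts of 300-2400 nt at ~2000 fragments per transcript
per replicate.  Ten percent of transcripts are true 5'->3' decay
targets: 5'-depleted in the wild type (decay depth 0.6) and four-fold
(log2fc = 2) more abundant in the mutant.  Writes annotation (GFF3),
per-sample reads (BED), the counts table and the ground-truth table
under results/simulated_inputs/.
"""

from pathlib import Path

from decayscan import SimulationConfig, simulate_dataset, write_dataset

OUTDIR = Path("results/simulated_inputs")
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    dataset = simulate_dataset(config)
    paths = write_dataset(dataset, OUTDIR)
    n_targets = int(dataset.truth["is_target"].sum())
    print(f"simulated {config.n_transcripts} transcripts "
          f"({n_targets} true decay targets), seed {SEED}")
    print(f"samples: {', '.join(dataset.counts.samples.index)}")
    print(f"total fragments: {len(dataset.reads):,}")
    print(f"wrote {len(paths)} files to {OUTDIR}")


if __name__ == "__main__":
    main()
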