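#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes stranded 125 bp read sets over the SRL-bearing rRNA fragment (one
FASTQ per replicate: depurination planted only in the Spiroplasma + wasp
treatment) and a factorial negative-binomial count matrix with planted
Group A/B/C, male-biased, wasp-responsive and male-gonad-pattern genes.

FASTQ output goes to scratch/sim_reads/ (bulk, regenerable); the small
design/truth tables go to results/.
"""

from pathlib import Path

from ripseq import simulate as sim
from ripseq.io_formats import write_fasta, write_fastq, write_tsv

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim_reads"
RESULTS = ROOT / "results"

# Per-treatment depurination rates: the lesion signature appears only when
# both the symbiont (source of the RIP toxin) and the susceptible wasp are
# present; 0.15 is a clearly detectable sub-saturating load.
TREATMENTS = {"S+Lh": 0.15, "S-Lh": 0.0, "S+W-": 0.0, "S-W-": 0.0}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    read_cfg = sim.ReadSimConfig(seed=SEED)
    read_sets, read_truth = sim.simulate_read_treatments(
        read_cfg, TREATMENTS, replicates=4)
    write_fasta([read_cfg.reference], SCRATCH / "reference.fa")
    for rep_id, reads in read_sets.items():
        write_fastq(reads, SCRATCH / f"{rep_id}.fastq")
    write_tsv(read_truth, RESULTS / "read_sim_truth.tsv")
    print(f"wrote {len(read_sets)} read sets "
          f"({read_cfg.n_reads} reads each) to {SCRATCH}")

    count_cfg = sim.CountSimConfig(seed=SEED)
    counts, design, truth = sim.simulate_counts(count_cfg)
    counts.to_csv(SCRATCH / "counts.tsv", sep="\t", index_label="gene_id")
    write_tsv(design, RESULTS / "count_sim_design.tsv")
    write_tsv(truth, RESULTS / "count_sim_truth.tsv")
    planted = (truth["class"] != "null").sum()
    print(f"wrote {counts.shape[0]}x{counts.shape[1]} count matrix "
          f"({planted} planted genes) to {SCRATCH / 'counts.tsv'}")


if __name__ == "__main__":
    main()
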