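"""Simulate the TaDa study conditions and write the dataset to disk.

Generates the default synthetic experiment — one ~700 kb contig with ~2000
GATC fragments, 100 genes, 20% of them with a planted occupancy change at
|log2FC| = 2, and three Dam-only plus three Dam-fusion libraries of one
million reads each — and reports its basic geometry.

Outputs: scratch/sim/ (FASTA, GTF, fragment BED, count matrix, truth tables)
and results/sim_summary.tsv.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from tadascope.genome import (
    median_fragment_distance,
    write_fasta,
    write_fragments_bed,
    write_gene_models,
)
from tadascope.simulate import SimConfig, simulate_dataset, write_truth_tables

ROOT = os.path.join(os.path.dirname(__file__), "..")
OUTDIR = os.path.join(ROOT, "scratch", "sim")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    cfg = SimConfig(seed=1)
    genome, gatc, genes, truth, counts, samples = simulate_dataset(cfg)

    write_fasta(genome, f"{OUTDIR}/genome.fa")
    write_gene_models(genes, f"{OUTDIR}/genes.gtf")
    write_fragments_bed(gatc, f"{OUTDIR}/gatc_fragments.bed")
    counts.to_csv(f"{OUTDIR}/counts.tsv", sep="\t")
    samples.to_csv(f"{OUTDIR}/samples.tsv", sep="\t", index=False)
    write_truth_tables(truth, f"{OUTDIR}/truth_genes.tsv", f"{OUTDIR}/truth_fragments.tsv")

    med = median_fragment_distance(gatc)
    n_de = int((truth.gene_table["label"] != "null").sum())
    summary = pd.DataFrame(
        [
            ("contig_length_bp", cfg.contig_length),
            ("n_gatc_fragments", len(gatc.fragments)),
            ("median_gatc_distance_bp", med),
            ("n_genes", len(genes)),
            ("n_planted_de_genes", n_de),
            ("reads_per_sample", cfg.depth),
            ("replicates_per_condition", cfg.n_replicates),
            ("nb_dispersion", cfg.dispersion),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(f"{RESULTS}/sim_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nSimulated {len(gatc.fragments)} GATC fragments (median spacing {med} bp) "
        f"and {counts.shape[1]} libraries; {n_de} genes carry a planted "
        f"|log2FC| = {cfg.log2fc} occupancy change. Dataset in scratch/sim/."
    )


if __name__ == "__main__":
    main()
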