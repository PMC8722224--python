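"""Synthetic TaDa data with known truth.

Generates toy genomes with realistic GATC spacing, simple gene models, a
planted Pol-II occupancy landscape, and replicate Dam-only vs. Dam-fusion
fragment count libraries with negative-binomial noise — optionally emitted as
SAM reads whose 5' ends sit on GATC fragment boundaries, so the edge-counting
step can be tested end to end.  Every step is deterministic under the config
seed.

The generator is a stand-in for the study's NGS libraries: three biological
replicates per condition, overdispersed counts, and a minority of genes with
a planted occupancy fold change between the fusion condition and the Dam-only
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Fragment, GatcMap, Gene, GeneSet, GenomeSequences, find_gatc_sites

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults mirror the profiled experiment where the design states them:
    three biological replicates per condition, a Dam-only reference against a
    Dam-fusion treatment, and GATC spacing matching the fly-genome median of
    ~350 bp.  Noise and effect-size defaults (dispersion 0.1, 20% differential
    genes at |log2FC| = 2, one million reads per sample) are calibration
    choices documented in the methods note.
    """

    contig_length: int = 700_000
    n_genes: int = 100
    mean_gatc_spacing: int = 350
    gene_length: int = 3_000
    reference: str = "Dam"
    treatment: str = "DN"
    n_replicates: int = 3
    depth: int = 1_000_000
    dispersion: float = 0.1
    fraction_de: float = 0.2
    log2fc: float = 2.0
    background: float = 0.1
    gene_signal: float = 1.0
    read_length: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contig_length <= 0 or self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.mean_gatc_spacing <= 4:
            raise ValueError("mean GATC spacing must exceed the 4 bp motif")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.fraction_de <= 1.0:
            raise ValueError("fraction_de must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    gene_table: pd.DataFrame  # gene_id, label (up/down/null), log2fc
    fragment_table: pd.DataFrame  # fragment_id, gene_id (or ""), occ_ref, occ_treat

    def de_genes(self) -> set[str]:
        t = self.gene_table
        return set(t.loc[t["label"] != "null", "gene_id"])


_GAP_SHAPE = 4.0  # right-skewed but with median within ~10% of the mean


def simulate_genome(config: SimConfig) -> tuple[GenomeSequences, GatcMap]:
    """Random DNA with GATC motifs planted at controlled spacing.

    Inter-motif filler is random A/C/G/T with any accidental GATC occurrence
    disrupted, so motif starts are exactly where they were planted.  Gaps are
    gamma-distributed (shape 4) with mean ``mean_gatc_spacing - 4``: right-
    skewed like real motif spacing but with the empirical median close to the
    configured mean, so ``mean_gatc_spacing`` doubles as the approximate
    median fragment distance of the simulated genome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.contig_length
    mean_gap = config.mean_gatc_spacing - 4

    def draw_gap() -> int:
        return max(1, int(round(rng.gamma(_GAP_SHAPE, mean_gap / _GAP_SHAPE))))

    chunks: list[str] = []
    pos = 0
    # leading filler so the first fragment is terminal, as in a real contig
    chunks.append(_random_filler(rng, min(draw_gap(), n - pos)))
    pos += len(chunks[-1])
    while pos + 4 <= n:
        chunks.append("GATC")
        pos += 4
        gap = min(draw_gap(), n - pos)
        if gap > 0:
            chunks.append(_random_filler(rng, gap))
            pos += gap
    if pos < n:
        chunks.append(_random_filler(rng, n - pos))
    seq = "".join(chunks)
    genome = GenomeSequences([("sim1", seq)])
    return genome, find_gatc_sites(genome)


def _random_filler(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    arr = rng.choice(_BASES, size=length)
    s = arr.tobytes().decode("ascii")
    # destroy accidental motifs so planted spacing is exact
    while "GATC" in s:
        i = s.find("GATC")
        s = s[:i] + "A" + s[i + 1 :]
    return s


def simulate_genes(gatc: GatcMap, config: SimConfig) -> GeneSet:
    """Place non-overlapping gene models evenly along the contig."""
    rng = np.random.default_rng(config.seed + 1)
    contig = next(iter(gatc.contig_lengths))
    length = gatc.contig_lengths[contig]
    glen = config.gene_length
    pitch = length // config.n_genes
    if pitch <= glen:
        raise ValueError("genes do not fit: reduce n_genes or gene_length")
    genes = []
    for i in range(config.n_genes):
        slack = pitch - glen
        start = i * pitch + int(rng.integers(0, max(slack // 2, 1)))
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        mid = (start + end) // 2
        exons = [(start, mid - 100), (mid + 100, end)]
        genes.append(Gene(f"g{i:04d}", f"gene{i:04d}", contig, strand, start, end, exons))
    return GeneSet(genes)


def simulate_occupancy(genes: GeneSet, gatc: GatcMap, config: SimConfig) -> SimTruth:
    """Plant a Pol-II occupancy landscape over the fragment map.

    Baseline occupancy is a uniform background plus a gene-body signal on
    every fragment overlapping a gene span.  The treatment condition
    multiplies the whole occupancy of "up" gene fragments by 2^log2FC and of
    "down" gene fragments by 2^-log2FC; null genes are untouched, so their
    true fold change is exactly zero.
    """
    if len(genes) == 0:
        raise ValueError("no genes supplied")
    rng = np.random.default_rng(config.seed + 2)
    gene_ids = [g.id for g in genes]
    n_de = int(round(config.fraction_de * len(gene_ids)))
    de_idx = rng.choice(len(gene_ids), size=n_de, replace=False)
    labels = {gid: "null" for gid in gene_ids}
    for k, i in enumerate(sorted(de_idx)):
        labels[gene_ids[i]] = "up" if k % 2 == 0 else "down"
    planted = {
        gid: (config.log2fc if lab == "up" else -config.log2fc if lab == "down" else 0.0)
        for gid, lab in labels.items()
    }

    frag_gene = _map_fragments_to_genes(gatc, genes)
    rows = []
    for frag in gatc.fragments:
        gid = frag_gene.get(frag.id, "")
        occ = config.background + (config.gene_signal if gid else 0.0)
        mult = 2.0 ** planted[gid] if gid else 1.0
        rows.append((frag.id, gid, occ, occ * mult))
    fragment_table = pd.DataFrame(
        rows, columns=["fragment_id", "gene_id", "occ_ref", "occ_treat"]
    )
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": [labels[g] for g in gene_ids],
            "log2fc": [planted[g] for g in gene_ids],
        }
    )
    return SimTruth(gene_table=gene_table, fragment_table=fragment_table)


def _map_fragments_to_genes(gatc: GatcMap, genes: GeneSet) -> dict[str, str]:
    """Fragment -> gene id for fragments overlapping a gene span.

    Overlaps with several genes resolve to the gene covering more of the
    fragment (genes from `simulate_genes` never overlap, so ties are moot).
    """
    out: dict[str, str] = {}
    for frag in gatc.fragments:
        best, best_ov = "", 0
        for g in genes.on_contig(frag.contig):
            ov = min(frag.end, g.end) - max(frag.start, g.start)
            if ov > best_ov:
                best, best_ov = g.id, ov
        if best:
            out[frag.id] = best
    return out


def simulate_counts(
    truth: SimTruth, gatc: GatcMap, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate fragment-count libraries for both conditions.

    Per sample, fragment counts are negative binomial with mean proportional
    to the condition's normalized occupancy times the library depth and a
    single genome-wide dispersion (variance = mu + dispersion * mu^2); a
    dispersion below 1e-8 degrades to Poisson.  Returns (counts, samples):
    counts is fragments x samples, samples maps each column to its condition
    and replicate.
    """
    rng = np.random.default_rng(config.seed + 3)
    occ = truth.fragment_table
    if list(occ["fragment_id"]) != gatc.fragment_ids:
        raise ValueError("truth table does not cover the fragment map")
    cols, names, conds, reps = [], [], [], []
    for cond, occ_col in ((config.reference, "occ_ref"), (config.treatment, "occ_treat")):
        o = occ[occ_col].to_numpy(float)
        p = o / o.sum()
        mu = config.depth * p
        for r in range(1, config.n_replicates + 1):
            cols.append(_nb_draw(rng, mu, config.dispersion))
            names.append(f"{cond}_rep{r}")
            conds.append(cond)
            reps.append(r)
    counts = pd.DataFrame(
        np.column_stack(cols), index=occ["fragment_id"], columns=names
    )
    counts.index.name = "fragment_id"
    samples = pd.DataFrame({"sample": names, "condition": conds, "replicate": reps})
    return counts, samples


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def emit_sam(
    counts: pd.Series, gatc: GatcMap, path: str, read_length: int = 75, seed: int = 0
) -> None:
    """Write one sample's counts as SAM reads anchored at fragment edges.

    Each read's 5'-most aligned base sits exactly on a GATC fragment boundary:
    forward reads start at the fragment start, reverse reads end at the
    fragment end, alternating, which is how DpnI-digested DamID fragments
    present after sequencing.  Recounting this SAM with edge counting must
    reproduce ``counts`` exactly.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig, length in gatc.contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        serial = 0
        for frag in gatc.fragments:
            c = int(counts.get(frag.id, 0))
            for _ in range(c):
                rl = min(read_length, frag.length)
                forward = bool(rng.integers(0, 2))
                if forward:
                    pos, flag = frag.start, 0
                else:
                    pos, flag = frag.end - rl, 16
                fh.write(
                    f"r{serial:09d}\t{flag}\t{frag.contig}\t{pos + 1}\t60\t{rl}M\t*\t0\t0\t*\t*\n"
                )
                serial += 1


def write_truth_tables(truth: SimTruth, gene_path: str, fragment_path: str) -> None:
    truth.gene_table.to_csv(gene_path, sep="\t", index=False)
    truth.fragment_table.to_csv(fragment_path, sep="\t", index=False)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genome -> genes -> truth -> counts in one call."""
    genome, gatc = simulate_genome(config)
    genes = simulate_genes(gatc, config)
    truth = simulate_occupancy(genes, gatc, config)
    counts, samples = simulate_counts(truth, gatc, config)
    return genome, gatc, genes, truth, counts, samples
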