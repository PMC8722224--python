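"""Max-gap peak building, combined region FDR and minimum-FDR gene assignment.

Significant GATC fragments (per-site p < 1e-5 by default) are merged along
each contig into peaks whenever the gap between consecutive fragments is at
most the genome's median GATC fragment distance (350 bp for the fly genome).
Each peak gets the mean logFC of its member GATCs, a Simes-combined p-value
over member p-values, and a Benjamini-Hochberg FDR across peaks.  Every gene
is then assigned its minimum-FDR overlapping peak; genes with an assigned
peak at FDR < 0.01 are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .genome import GatcMap, GeneSet, median_fragment_distance

FDR_THRESHOLD = 0.01
MEDIAN_GATC_DISTANCE_DMEL = 350  # fly-genome median GATC spacing, default max gap


@dataclass
class Peak:
    id: str
    contig: str
    start: int
    end: int
    members: list[str]  # fragment ids, sorted by coordinate
    mean_logfc: float
    p: float = float("nan")
    q: float = float("nan")
    mixed_sign: bool = False

    @property
    def n_gatc(self) -> int:
        return len(self.members)

    @property
    def direction(self) -> int:
        return 1 if self.mean_logfc > 0 else (-1 if self.mean_logfc < 0 else 0)


def merge_gatcs(
    stats: pd.DataFrame, gatc: GatcMap, tolerance: int | None = None
) -> list[Peak]:
    """Single-linkage max-gap clustering of fragments into peaks.

    ``stats`` is the (already filtered) per-fragment table indexed by
    fragment id with at least a logFC and p column.  Consecutive fragments on
    a contig join one peak iff the gap between them (next.start - prev.end)
    is at most ``tolerance``; adjacent significant fragments have gap 0 and
    always merge.  Default tolerance is the genome's own median GATC
    fragment distance (350 bp on the fly reference).
    """
    if tolerance is None:
        tolerance = median_fragment_distance(gatc)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    frags = sorted(
        (gatc.fragment(fid) for fid in stats.index),
        key=lambda f: (f.contig, f.start),
    )
    peaks: list[Peak] = []
    cluster: list = []
    for frag in frags:
        if cluster and (
            frag.contig != cluster[-1].contig or frag.start - cluster[-1].end > tolerance
        ):
            peaks.append(_finalize(cluster, stats, len(peaks)))
            cluster = []
        cluster.append(frag)
    if cluster:
        peaks.append(_finalize(cluster, stats, len(peaks)))
    return peaks


def _finalize(cluster: list, stats: pd.DataFrame, serial: int) -> Peak:
    ids = [f.id for f in cluster]
    logfcs = stats.loc[ids, "logFC"].to_numpy(float)
    return Peak(
        id=f"peak{serial:05d}",
        contig=cluster[0].contig,
        start=cluster[0].start,
        end=cluster[-1].end,
        members=ids,
        mean_logfc=float(logfcs.mean()),
        mixed_sign=bool(logfcs.max() > 0 and logfcs.min() < 0),
    )


def simes_combine(pvalues) -> float:
    """Simes combination: min_i ( m * p_(i) / i ) over sorted p-values.

    Valid as a region-level p under positive dependence of member tests;
    equals the single p for m = 1 and collapses to the common value when all
    member p-values are equal.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    srt = np.sort(p)
    m = srt.size
    return float(min(1.0, np.min(m * srt / np.arange(1, m + 1))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_peaks(peaks: list[Peak], stats: pd.DataFrame) -> list[Peak]:
    """Attach Simes-combined p and BH q to every peak (in place)."""
    for pk in peaks:
        pk.p = simes_combine(stats.loc[pk.members, "p"].to_numpy(float))
    qs = bh_adjust([pk.p for pk in peaks]) if peaks else []
    for pk, q in zip(peaks, qs):
        pk.q = float(q)
    return peaks


def assign_genes(
    peaks: list[Peak],
    genes: GeneSet,
    fdr_threshold: float = FDR_THRESHOLD,
    upstream_margin: int = 0,
) -> pd.DataFrame:
    """Assign each gene its minimum-FDR overlapping peak.

    Overlap means a non-empty intersection of the peak interval with the gene
    span extended ``upstream_margin`` bp on the 5' side.  Ties on q break by
    larger |mean logFC|, then by leftmost peak start.  Genes without any
    overlapping peak get no assignment and are not significant.
    """
    trees: dict[str, IntervalTree] = {}
    for i, pk in enumerate(peaks):
        trees.setdefault(pk.contig, IntervalTree()).addi(pk.start, pk.end, i)
    rows = []
    for g in genes:
        lo, hi = g.start, g.end
        if upstream_margin:
            if g.strand == "+":
                lo = max(0, lo - upstream_margin)
            else:
                hi = hi + upstream_margin
        hits = trees.get(g.contig, IntervalTree()).overlap(lo, hi)
        best = None
        for iv in hits:
            pk = peaks[iv.data]
            key = (pk.q, -abs(pk.mean_logfc), pk.start)
            if best is None or key < best[0]:
                best = (key, pk)
        if best is None:
            rows.append((g.id, g.name, "", np.nan, np.nan, False))
        else:
            pk = best[1]
            rows.append(
                (g.id, g.name, pk.id, pk.mean_logfc, pk.q, bool(pk.q < fdr_threshold))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "peak_id", "logFC", "FDR", "significant"]
    ).set_index("gene_id", drop=False)


# -- genomic feature annotation ---------------------------------------------

FEATURE_PRIORITY = [
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
]


def annotate_peak_features(
    peaks: list[Peak],
    genes: GeneSet,
    promoter_bp: int = 1000,
    downstream_bp: int = 1000,
    utr_bp: int = 200,
) -> pd.DataFrame:
    """Classify each peak by the highest-priority genomic feature it touches.

    Priority: promoter (<= promoter_bp upstream of a TSS) > 5'UTR > 3'UTR >
    exon > intron > downstream (<= downstream_bp past the gene 3' end) >
    distal intergenic.  UTRs, absent explicit annotation, are approximated as
    the first/last ``utr_bp`` of the gene span.  Returns a per-peak table;
    category proportions are the pie-chart summary.
    """
    rows = []
    for pk in peaks:
        cat = _classify(pk, genes, promoter_bp, downstream_bp, utr_bp)
        rows.append((pk.id, pk.contig, pk.start, pk.end, cat))
    return pd.DataFrame(rows, columns=["peak_id", "contig", "start", "end", "feature"])


def feature_proportions(annotated: pd.DataFrame) -> pd.DataFrame:
    counts = annotated["feature"].value_counts().reindex(FEATURE_PRIORITY, fill_value=0)
    return pd.DataFrame(
        {"feature": counts.index, "count": counts.values, "proportion": counts.values / max(counts.sum(), 1)}
    )


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _classify(pk: Peak, genes: GeneSet, promoter_bp: int, downstream_bp: int, utr_bp: int) -> str:
    found = set()
    for g in genes.on_contig(pk.contig):
        if g.strand == "+":
            prom = (max(0, g.start - promoter_bp), g.start)
            down = (g.end, g.end + downstream_bp)
            utr5 = (g.start, min(g.end, g.start + utr_bp))
            utr3 = (max(g.start, g.end - utr_bp), g.end)
        else:
            prom = (g.end, g.end + promoter_bp)
            down = (max(0, g.start - downstream_bp), g.start)
            utr5 = (max(g.start, g.end - utr_bp), g.end)
            utr3 = (g.start, min(g.end, g.start + utr_bp))
        if _overlaps(pk.start, pk.end, *prom):
            found.add("promoter")
        if _overlaps(pk.start, pk.end, *utr5):
            found.add("five_prime_utr")
        if _overlaps(pk.start, pk.end, *utr3):
            found.add("three_prime_utr")
        if any(_overlaps(pk.start, pk.end, a, b) for a, b in g.exons):
            found.add("exon")
        elif _overlaps(pk.start, pk.end, g.start, g.end):
            found.add("intron")
        if _overlaps(pk.start, pk.end, *down):
            found.add("downstream")
    for cat in FEATURE_PRIORITY:
        if cat in found:
            return cat
    return "distal_intergenic"


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """BED6+-shaped table: extra columns n_gatc, mean logFC, p, q."""
    return pd.DataFrame(
        [
            (
                pk.contig,
                pk.start,
                pk.end,
                pk.id,
                0,
                ".",
                pk.n_gatc,
                pk.mean_logfc,
                pk.p,
                pk.q,
                pk.direction,
                pk.mixed_sign,
            )
            for pk in peaks
        ],
        columns=[
            "contig",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "n_gatc",
            "mean_logFC",
            "p",
            "q",
            "direction",
            "mixed_sign",
        ],
    )


def call_peaks(
    stats: pd.DataFrame,
    gatc: GatcMap,
    genes: GeneSet,
    tolerance: int | None = None,
    p_site: float = 1e-5,
    fdr_threshold: float = FDR_THRESHOLD,
    merge_all: bool = False,
) -> tuple[list[Peak], pd.DataFrame]:
    """Full peak step: filter -> merge -> Simes -> BH -> gene assignment.

    By default only fragments with per-site p < ``p_site`` enter merging; the
    ``merge_all`` mode merges every scored fragment and relies on the
    combined p and BH correction alone.
    """
    selected = stats if merge_all else stats[stats["p"] < p_site]
    peaks = merge_gatcs(selected, gatc, tolerance)
    score_peaks(peaks, stats)
    assignments = assign_genes(peaks, genes, fdr_threshold)
    return peaks, assignments
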