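"""QC and integration statistics around the core pipeline.

TSS-distance meta-profiles (do methylated GATC sites cluster near promoters?),
gene-body occupancy profiles stratified by expression quantile, Fisher exact
enrichment of labeled gene classes (e.g. transcription factors) among the
called genes, and multi-list overlap (Venn) arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import CoverageTrack
from .genome import GeneSet


# -- TSS distance profiles ---------------------------------------------------

@dataclass
class TssProfile:
    site_class: str
    bin_edges: np.ndarray  # signed bp, shared across classes
    histogram: np.ndarray  # len(bin_edges) - 1, mass == n_sites in range
    n_sites: int
    distances: np.ndarray  # signed distances, one per site


def signed_tss_distances(
    positions: list[tuple[str, int]], genes: GeneSet
) -> np.ndarray:
    """Signed distance from each position to the nearest TSS.

    Sign is relative to the strand of the gene owning the nearest TSS:
    negative = upstream of the TSS, positive = downstream (into the gene).
    """
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in {g.contig for g in genes}:
        gs = genes.on_contig(contig)
        tss = np.array([g.tss for g in gs], dtype=np.int64)
        sgn = np.array([1 if g.strand == "+" else -1 for g in gs], dtype=np.int64)
        order = np.argsort(tss)
        by_contig[contig] = (tss[order], sgn[order])
    if not by_contig:
        raise ValueError("gene set has no TSS")
    out = np.empty(len(positions), dtype=np.int64)
    pos_arr = np.array([p for _, p in positions], dtype=np.int64)
    contig_arr = np.array([c for c, _ in positions])
    for contig in np.unique(contig_arr):
        if contig not in by_contig:
            raise ValueError(f"position on contig {contig!r} with no annotated gene")
        tss, sgn = by_contig[contig]
        mask = contig_arr == contig
        pos = pos_arr[mask]
        j = np.searchsorted(tss, pos)
        left = np.clip(j - 1, 0, tss.size - 1)
        right = np.clip(j, 0, tss.size - 1)
        use_left = np.abs(pos - tss[left]) < np.abs(pos - tss[right])
        k = np.where(use_left, left, right)
        out[mask] = (pos - tss[k]) * sgn[k]
    return out


def tss_distance_profile(
    site_classes: dict[str, list[tuple[str, int]]],
    genes: GeneSet,
    bin_edges: np.ndarray | None = None,
) -> dict[str, TssProfile]:
    """Per-class histogram of signed distance-to-nearest-TSS.

    ``site_classes`` maps a class label (e.g. "methylated-GATC", "all-GATC",
    "random") to (contig, position) sites.  All classes share the bin edges;
    default is 100 bp bins over +/-5 kb.
    """
    if bin_edges is None:
        bin_edges = np.arange(-5000, 5001, 100)
    out = {}
    for label, positions in site_classes.items():
        d = signed_tss_distances(positions, genes)
        hist, _ = np.histogram(d, bins=bin_edges)
        out[label] = TssProfile(label, bin_edges, hist, len(positions), d)
    return out


def methylated_gatc_sites(
    cpm: pd.Series, gatc, quantile: float = 0.5
) -> list[tuple[str, int]]:
    """Fragments with Dam-fusion signal above a quantile of nonzero values.

    Operationalizes "methylated GATC sites": fragments whose normalized
    count exceeds the given quantile of the nonzero distribution; each
    reported as its fragment midpoint.
    """
    nonzero = cpm[cpm > 0]
    if nonzero.empty:
        return []
    thresh = float(nonzero.quantile(quantile))
    sites = []
    for fid, v in cpm.items():
        if v > thresh:
            f = gatc.fragment(fid)
            sites.append((f.contig, (f.start + f.end) // 2))
    return sites


# -- gene-body meta profile --------------------------------------------------

def gene_body_profile(
    tracks: dict[str, CoverageTrack],
    genes: GeneSet,
    expression: dict[str, float],
    n_quantiles: int = 4,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Mean track signal along scaled gene bodies, by expression quantile.

    Each gene body is rescaled to ``n_bins`` positional bins (reversed for
    minus-strand genes so bin 0 is always the 5' end); genes are grouped into
    ``n_quantiles`` expression groups (quantile 1 = lowest).  Genes without an
    expression value are excluded.  Returns a (quantile x bin) matrix as a
    tidy DataFrame.
    """
    usable = [g for g in genes if g.id in expression and g.contig in tracks]
    if not usable:
        raise ValueError("no genes with both expression and track coverage")
    expr = np.array([expression[g.id] for g in usable])
    ranks = pd.Series(expr).rank(method="first").to_numpy()
    qidx = np.ceil(ranks / len(usable) * n_quantiles).astype(int)
    profiles = np.zeros((n_quantiles, n_bins))
    counts = np.zeros(n_quantiles, dtype=int)
    for g, q in zip(usable, qidx):
        track = tracks[g.contig]
        lo = g.start // track.bin_size
        hi = max(lo + 1, -(-g.end // track.bin_size))  # ceil division
        vals = track.values[lo:hi]
        if vals.size == 0:
            continue
        scaled = np.interp(
            np.linspace(0, vals.size - 1, n_bins), np.arange(vals.size), vals
        )
        if g.strand == "-":
            scaled = scaled[::-1]
        profiles[q - 1] += scaled
        counts[q - 1] += 1
    for q in range(n_quantiles):
        if counts[q] == 0:
            raise ValueError(f"expression quantile {q + 1} is empty")
        profiles[q] /= counts[q]
    rows = []
    for q in range(n_quantiles):
        for b in range(n_bins):
            rows.append((q + 1, b, profiles[q, b]))
    return pd.DataFrame(rows, columns=["quantile", "bin", "mean_signal"])


# -- Fisher enrichment -------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    a: int  # in class, in selected set
    b: int  # in class, not selected
    c: int  # not in class, selected
    d: int  # not in class, not selected

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def fisher_enrichment(
    selected: set[str], universe: set[str], labeled_class: set[str]
) -> tuple[float, float, ContingencyTable2x2]:
    """Two-sided Fisher exact test for class enrichment among selected genes.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) at most as probable as the observed one.  The odds
    ratio is (a*d)/(b*c) with a Haldane 0.5 correction applied to every cell
    when any cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe or not labeled_class <= universe:
        raise ValueError("selected and class must be subsets of the universe")
    a = len(selected & labeled_class)
    b = len(labeled_class - selected)
    c = len(selected - labeled_class)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a, b, c, d)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), table


# -- set overlaps ------------------------------------------------------------

def normalize_gene_id(gene_id: str, strip_version: bool = True) -> str:
    if strip_version and "." in gene_id:
        head, _, tail = gene_id.rpartition(".")
        if tail.isdigit():
            return head
    return gene_id


def overlap_percent(intersection: int, size: int) -> int:
    """Integer overlap percentage: one-decimal rounding, then truncation.

    100 * 339/1094 = 30.99 reports as 31, 100 * 510/1094 = 46.62 as 46, and
    100 * 157/510 = 30.78 as 30 — percentages are resolved to one decimal
    place first and displayed as their integer part.
    """
    return int(round(100.0 * intersection / size, 1))


def set_overlap(
    lists: dict[str, list[str]], strip_version: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn-style region counts and pairwise overlap percentages.

    Returns (regions, pairwise).  ``regions`` has one row per non-empty
    membership pattern with its exclusive count; ``pairwise`` reports
    |A cap B| and round(100 * |A cap B| / |A|) for every ordered pair.
    Empty input lists are tolerated (counted as empty sets).
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    sets = {
        name: {normalize_gene_id(g, strip_version) for g in ids}
        for name, ids in lists.items()
    }
    names = list(sets)
    universe = set().union(*sets.values())
    membership: dict[tuple[str, ...], int] = {}
    for g in universe:
        key = tuple(n for n in names if g in sets[n])
        membership[key] = membership.get(key, 0) + 1
    regions = pd.DataFrame(
        [("&".join(k), v) for k, v in sorted(membership.items())],
        columns=["region", "count"],
    )
    rows = []
    for a, b in combinations(names, 2):
        for x, y in ((a, b), (b, a)):
            inter = len(sets[x] & sets[y])
            pct = overlap_percent(inter, len(sets[x])) if sets[x] else 0
            rows.append((x, y, inter, len(sets[x]), pct))
    pairwise = pd.DataFrame(
        rows, columns=["of_list", "with_list", "intersection", "list_size", "percent"]
    )
    return regions, pairwise
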