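"""Genome model: FASTA/GTF ingestion, GATC motif mapping and fragment tiling.

DamID resolution is bounded by the spacing of GATC motifs: DpnI cuts only at
methylated GATC, so the genomic interval between two consecutive motifs (a
"GATC fragment") is the smallest addressable unit of signal.  This module
locates every GATC occurrence, tiles each contig into fragments, and provides
the gene/TSS utilities the downstream statistics need.

Coordinates are 0-based, half-open everywhere internally.  BED output is
0-based half-open; GTF input/output is 1-based closed, converted at the
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

MOTIF = "GATC"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested on data that cannot define it."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequences:
    """Ordered contig sequences, uppercase A/C/G/T/N only."""

    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise FormatError("duplicate contig names in genome")
        for name, seq in self.contigs:
            if re.search(r"[^ACGTN]", seq):
                raise FormatError(f"contig {name!r} contains non-ACGTN characters")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs}

    def __getitem__(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]


@dataclass
class Fragment:
    """Half-open interval between consecutive GATC motif starts."""

    id: str
    contig: str
    start: int
    end: int
    terminal: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GatcMap:
    """Genome-wide GATC motif starts and the fragment tiling they induce.

    ``sites[contig]`` is a sorted integer array of motif start coordinates.
    ``fragments`` lists, contig by contig, the intervals between consecutive
    motif starts plus the terminal pieces before the first and after the last
    motif; together they tile each contig without gaps or overlaps.  Terminal
    pieces are flagged (they are not DpnI-digestible units) and excluded from
    spacing statistics.
    """

    sites: dict[str, np.ndarray]
    fragments: list[Fragment]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self._by_contig: dict[str, list[Fragment]] = {}
        for frag in self.fragments:
            self._by_contig.setdefault(frag.contig, []).append(frag)
        self._by_id = {f.id: f for f in self.fragments}

    def fragments_on(self, contig: str) -> list[Fragment]:
        return self._by_contig.get(contig, [])

    def fragment(self, frag_id: str) -> Fragment:
        return self._by_id[frag_id]

    @property
    def fragment_ids(self) -> list[str]:
        return [f.id for f in self.fragments]

    def validate(self) -> None:
        """Assert the tiling invariants (for tests and paranoid callers)."""
        for contig, length in self.contig_lengths.items():
            frags = self.fragments_on(contig)
            sites = self.sites.get(contig, np.empty(0, dtype=int))
            if np.any(np.diff(sites) <= 0):
                raise AssertionError(f"sites not strictly increasing on {contig}")
            if not frags:
                if length > 0:
                    raise AssertionError(f"no fragments on non-empty contig {contig}")
                continue
            if frags[0].start != 0 or frags[-1].end != length:
                raise AssertionError(f"fragments do not span {contig}")
            for prev, nxt in zip(frags, frags[1:]):
                if prev.end != nxt.start:
                    raise AssertionError(f"gap/overlap at {prev.id}->{nxt.id}")
            for f in frags:
                if f.length < 1:
                    raise AssertionError(f"empty fragment {f.id}")


def read_fasta(path: str) -> GenomeSequences:
    """Load a genome FASTA; sequences are uppercased, N is allowed."""
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors on bad syntax
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    contigs = [(rec.id, str(rec.seq).upper()) for rec in records]
    return GenomeSequences(contigs)


def write_fasta(genome: GenomeSequences, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def find_gatc_sites(genome: GenomeSequences) -> GatcMap:
    """Scan every contig for GATC occurrences and build the fragment map.

    The motif is its own reverse complement, so a single forward scan is
    strand-independent.  A contig with no motif yields a single whole-contig
    terminal fragment; zero-length terminal pieces (motif at position 0 or
    ending at the contig end) are dropped.
    """
    sites: dict[str, np.ndarray] = {}
    fragments: list[Fragment] = []
    for name, seq in genome.contigs:
        starts = _scan_motif(seq)
        sites[name] = starts
        n = len(seq)
        if starts.size == 0:
            if n > 0:
                fragments.append(Fragment(f"{name}:0-{n}", name, 0, n, terminal=True))
            continue
        bounds = [0, *starts.tolist(), n]
        # drop the leading 0 if the first motif starts at 0
        if bounds[0] == bounds[1]:
            bounds = bounds[1:]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            if b <= a:
                continue
            terminal = (a == 0 and a < starts[0]) or (a == starts[-1])
            fragments.append(Fragment(f"{name}:{a}-{b}", name, a, b, terminal=terminal))
    return GatcMap(sites=sites, fragments=fragments, contig_lengths=genome.lengths)


def _scan_motif(seq: str) -> np.ndarray:
    out = []
    pos = seq.find(MOTIF)
    while pos != -1:
        out.append(pos)
        pos = seq.find(MOTIF, pos + 1)
    return np.asarray(out, dtype=np.int64)


def median_fragment_distance(gatc: GatcMap) -> int:
    """Median distance between consecutive GATC motif start coordinates.

    Pooled over all contigs; ties resolve to the lower middle value; the
    result is floored to an integer number of base pairs.  This equals the
    median length of internal (non-terminal) fragments and is the default
    max-gap tolerance for peak merging.
    """
    spacings: list[np.ndarray] = []
    for starts in gatc.sites.values():
        if starts.size >= 2:
            spacings.append(np.diff(starts))
    if not spacings:
        raise UndefinedStatisticError(
            "median fragment distance needs >=2 GATC sites on some contig"
        )
    allsp = np.sort(np.concatenate(spacings))
    # lower median: element at index (n-1)//2 of the sorted spacings
    return int(allsp[(allsp.size - 1) // 2])


@dataclass
class Gene:
    id: str
    name: str
    contig: str
    strand: str
    start: int
    end: int  # half-open
    exons: list[tuple[int, int]] = field(default_factory=list)
    is_tf: bool = False

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: span start for +, end-1 for -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneSet:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate gene ids")
        self._by_id = {g.id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def on_contig(self, contig: str) -> list[Gene]:
        return [g for g in self.genes if g.contig == contig]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: str) -> GeneSet:
    """Read gene and exon features from a GTF (1-based closed coordinates).

    Genes missing a ``gene`` feature line are reconstructed from the union of
    their exons.  Each gene's TSS follows the strand convention (5'-most
    coordinate of the span).
    """
    spans: dict[str, Gene] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _, feature, start_s, end_s, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: missing/invalid strand")
            m = dict(_ATTR_RE.findall(attrs))
            gid = m.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            gname = m.get("gene_name", gid)
            if gid not in spans and gid not in exons:
                order.append(gid)
            if feature == "gene":
                spans[gid] = Gene(gid, gname, contig, strand, start, end)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
                if gid not in spans:
                    spans[gid] = Gene(gid, gname, contig, strand, start, end)
                else:
                    g = spans[gid]
                    g.start = min(g.start, start)
                    g.end = max(g.end, end)
    genes = []
    for gid in order:
        g = spans[gid]
        g.exons = sorted(exons.get(gid, []))
        genes.append(g)
    return GeneSet(genes)


def write_gene_models(genes: GeneSet, path: str, source: str = "tadascope") -> None:
    """Write gene + exon GTF lines (1-based closed) that round-trip."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.contig}\t{source}\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_fragments_bed(gatc: GatcMap, path: str, include_terminal: bool = True) -> None:
    """BED6 of GATC fragments: name = fragment id, score 0, strand '.'."""
    with open(path, "w") as fh:
        for f in gatc.fragments:
            if f.terminal and not include_terminal:
                continue
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.id}\t0\t.\n")


def sample_random_regions(
    genome: GenomeSequences, n: int, seed: int
) -> list[tuple[str, int]]:
    """Sample ``n`` positions uniformly over the concatenated genome.

    Used as the background class in TSS-distance meta-profiles.  Reproducible
    for a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    flat = rng.integers(0, total, size=n)
    idx = np.searchsorted(offsets, flat, side="right") - 1
    return [(names[i], int(p - offsets[i])) for i, p in zip(idx, flat)]
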