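"""Edge counting of DamID reads onto GATC fragments, CPM normalization and
browser-style log2-ratio coverage tracks.

A DamID read originates from a DpnI cut at a methylated GATC, so its 5' end
is expected to sit on (or within a few bp of) a fragment boundary.  The
counter assigns each primary mapped read to exactly one fragment via that
edge rule, with a fall-back to the fragment containing the 5' base unless
strict-edge mode discards such reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import GatcMap


@dataclass
class CountTally:
    """Bookkeeping for one counted SAM stream; conservation law:
    assigned + rejected + skipped = total records."""

    total: int = 0
    assigned: int = 0
    rejected: int = 0  # no edge match in strict mode, or unknown contig
    skipped: int = 0  # unmapped / secondary / supplementary / second mates
    unknown_contig: int = 0


def count_reads_to_fragments(
    sam_path: str,
    gatc: GatcMap,
    edge_tolerance: int = 5,
    strict_edge: bool = False,
) -> tuple[pd.Series, CountTally]:
    """Count primary mapped reads onto GATC fragments by the edge rule.

    The 5'-most aligned base (reference start for forward reads, reference
    end - 1 for reverse reads) is matched against fragment boundaries: a
    forward read whose 5' base lies within ``edge_tolerance`` of a fragment
    start is assigned to that fragment; a reverse read is matched against
    fragment ends.  Reads with no boundary within tolerance fall back to the
    fragment containing the 5' base, unless ``strict_edge`` rejects them.
    Paired-end input is counted once per template (first-in-pair only).
    """
    counts = {fid: 0 for fid in gatc.fragment_ids}
    tally = CountTally()
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    for contig in gatc.contig_lengths:
        frags = gatc.fragments_on(contig)
        starts[contig] = np.array([f.start for f in frags], dtype=np.int64)
        ends[contig] = np.array([f.end for f in frags], dtype=np.int64)
        ids[contig] = [f.id for f in frags]

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            tally.total += 1
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or (read.is_paired and read.is_read2)
            ):
                tally.skipped += 1
                continue
            contig = read.reference_name
            if contig not in starts:
                tally.rejected += 1
                tally.unknown_contig += 1
                continue
            pos5 = read.reference_start if not read.is_reverse else read.reference_end - 1
            edge = starts[contig] if not read.is_reverse else ends[contig]
            target = pos5 if not read.is_reverse else pos5 + 1
            j = int(np.searchsorted(edge, target))
            best, best_d = -1, edge_tolerance + 1
            for k in (j - 1, j):
                if 0 <= k < edge.size:
                    d = abs(int(edge[k]) - target)
                    if d < best_d:
                        best, best_d = k, d
            if best == -1:
                if strict_edge:
                    tally.rejected += 1
                    continue
                best = _containing(starts[contig], ends[contig], pos5)
                if best == -1:
                    tally.rejected += 1
                    continue
            counts[ids[contig][best]] += 1
            tally.assigned += 1
    return pd.Series(counts, name="count"), tally


def _containing(starts: np.ndarray, ends: np.ndarray, pos: int) -> int:
    j = int(np.searchsorted(starts, pos, side="right")) - 1
    if 0 <= j < starts.size and starts[j] <= pos < ends[j]:
        return j
    return -1


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to counts per million of its library size."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {', '.join(map(str, zero.index))}")
    return counts * (1e6 / libsize)


# -- coverage tracks ---------------------------------------------------------

EFFECTIVE_GENOME_SIZE_DMEL = 142_573_017  # effective fly genome, 1x scaling


@dataclass
class CoverageTrack:
    """Binned per-contig values (normalized coverage or log2 ratio)."""

    contig: str
    bin_size: int
    values: np.ndarray
    smooth_bp: int = 0


def coverage_from_sam(sam_path: str, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base read coverage per contig from primary mapped alignments."""
    cov = {c: np.zeros(n, dtype=np.float64) for c, n in contig_lengths.items()}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            c = read.reference_name
            if c in cov:
                cov[c][read.reference_start : read.reference_end] += 1.0
    return cov


def log_ratio_track(
    treatment: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
    effective_genome_size: int = EFFECTIVE_GENOME_SIZE_DMEL,
    bin_size: int = 1,
    smooth: int = 5,
    pseudocount: float = 1.0,
) -> dict[str, CoverageTrack]:
    """log2(treatment / reference) after scaling each sample to 1x coverage.

    Each sample is multiplied by effective_genome_size / total aligned bases
    (reads-per-genomic-content normalization), binned by averaging, combined
    as log2((t + pc) / (r + pc)), then smoothed with a centered running mean
    over ``smooth`` bins.  Defaults match a 1 bp bin, 5 bp smoothing window
    and the fly effective genome size.
    """
    if set(treatment) != set(reference):
        raise ValueError("treatment and reference cover different contigs")
    t_total = sum(float(v.sum()) for v in treatment.values())
    r_total = sum(float(v.sum()) for v in reference.values())
    if t_total <= 0 or r_total <= 0:
        raise ValueError("empty coverage")
    st = effective_genome_size / t_total
    sr = effective_genome_size / r_total
    out: dict[str, CoverageTrack] = {}
    for contig in treatment:
        t = _bin_mean(treatment[contig] * st, bin_size)
        r = _bin_mean(reference[contig] * sr, bin_size)
        vals = np.log2((t + pseudocount) / (r + pseudocount))
        if smooth > 1:
            vals = _running_mean(vals, smooth)
        out[contig] = CoverageTrack(contig, bin_size, vals, smooth_bp=smooth * bin_size)
    return out


def _bin_mean(values: np.ndarray, bin_size: int) -> np.ndarray:
    if bin_size <= 1:
        return values.astype(np.float64)
    n_bins = int(np.ceil(values.size / bin_size))
    padded = np.full(n_bins * bin_size, np.nan)
    padded[: values.size] = values
    with np.errstate(invalid="ignore"):
        return np.nanmean(padded.reshape(n_bins, bin_size), axis=1)


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges."""
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def write_bedgraph(tracks: dict[str, CoverageTrack], path: str) -> None:
    """4-column bedGraph (UCSC dialect), merging runs of equal value."""
    with open(path, "w") as fh:
        for contig, track in tracks.items():
            v = track.values
            bs = track.bin_size
            run_start = 0
            for i in range(1, v.size + 1):
                if i == v.size or v[i] != v[run_start]:
                    fh.write(
                        f"{contig}\t{run_start * bs}\t{i * bs}\t{v[run_start]:.6g}\n"
                    )
                    run_start = i
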