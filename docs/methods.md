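# Methods

## Coordinate and fragment conventions

All coordinates are 0-based, half-open internally; BED output is 0-based
half-open and GTF input/output 1-based closed, converted at the boundary.
A *GATC fragment* is the interval between consecutive GATC motif **start**
coordinates.  The pieces before the first and after the last motif on a
contig are retained so fragments tile the contig exactly, but are flagged
`terminal` and excluded from spacing statistics: they are not DpnI-digestible
units.  "GATC fragment distance" is the distance between consecutive motif
starts (equivalently the internal fragment length); the genome-wide median
uses the lower middle value on even counts and is floored to whole base
pairs.  Whether that distance should instead be measured between motif
midpoints or DpnI cut positions (GA^TC) is a convention choice; all
reasonable variants differ by at most 4 bp, and the start-coordinate form is
the package default with the merge tolerance overridable everywhere it is
used.  The GATC motif is its own reverse complement, so a single forward
scan is strand-independent; N never matches.

Gene TSS is the 5'-most coordinate of the gene span (span start for `+`,
span end − 1 for `−`); when a GTF carries multiple transcripts the gene span
is their union, because the pipeline operates at gene level.

## Edge counting

A DamID read begins at a DpnI cut, so its 5'-most aligned base should sit on
a fragment boundary.  The counter matches the 5' base of each primary mapped
read (reference start for forward reads; reference end − 1 for reverse
reads) against fragment starts (forward) or fragment ends (reverse) within
an `edge_tolerance` of 5 bp — the tolerance is a package choice, logged in
output metadata, since the upstream helper script it emulates does not
publish one.  Reads matching no boundary fall back to the fragment
containing the 5' base; `strict_edge` discards them instead.  Paired-end
templates are counted once (first mate).  The conservation law
assigned + rejected + skipped = total records is asserted in tests, and the
simulator's SAM emission is required to recount *exactly*.

## The moderated-t model

Statistics are computed on log2 CPM with pseudocount 1 (the expression scale
is configurable; CPM-with-pseudocount is the package default).  For fragment
*g*: pooled two-group variance *s²_g* with *d = n₁+n₂−2* df; the
scaled-F/conjugate-chi-square model

    s²_g | σ²_g ~ σ²_g χ²_d / d,    1/σ²_g ~ χ²_{d₀} / (d₀ s₀²)

gives posterior variance *s̃²_g = (d₀s₀² + d s²_g)/(d₀+d)* and a moderated t
referred to *t_{d+d₀}* (normal when *d₀ = ∞*; *d₀ = 0* recovers the
classical pooled t exactly).  Hyperparameters are fit by method of moments
on *z_g = ln s²_g*: solve trigamma(d₀/2) = var(z) − trigamma(d/2) by Newton
inversion of the trigamma function; a non-positive right-hand side means the
spread of the observed variances is explained by chi-square sampling alone
and *d₀ = ∞*.  *s₀²* comes from mean(z) with the digamma/log bias
correction.  Two degenerate cases are handled explicitly: exactly equal
variances (zero spread) return the common value as *s₀²*, and all-zero count
rows are dropped before fitting (they carry no information and would produce
degenerate variances).  An integration test verifies agreement of t and p
with an independent implementation of the same model (Bioconductor limma)
to 1e-8 on a heteroscedastic fixture.

Per-fragment significance uses the stringent gate p < 1e-5 before any
merging.  The gate is applied to the *moderated* p; the alternative reading
(gate on the ordinary t) is not exposed because the moderated statistic
dominates it in calibration at 3v3.

## Peaks, combined FDR, gene assignment

Fragments passing the gate are merged along each contig by single-linkage
max-gap clustering: consecutive fragments join one peak iff the gap
(next.start − prev.end) is at most the merge tolerance, which defaults to
the genome's own median GATC fragment distance.  A `merge_all` mode merges
every scored fragment instead and relies on the combined p and BH alone —
the default (gate first, then merge) reflects the natural reading of the
procedure this pipeline reproduces, and both modes are exposed.  Peak-level
inference: Simes combination over member p-values (valid under positive
dependence, which adjacent fragments satisfy), then Benjamini–Hochberg
step-up across peaks.  Peak direction is the sign of the mean member logFC;
mixed-sign membership is allowed but flagged.  Each gene takes the
minimum-q peak overlapping its span (upstream margin configurable, default
0 bp; synthetic-data results are insensitive to small margins), ties broken
by larger |mean logFC| then leftmost start, and is called significant at
q < 0.01.

Where a second, lower-quality fusion contrast exists (the Jeb activation
arm of the original design), it is computed identically but should be
treated as qualitative confirmation only; the pipeline makes no FDR-level
claims for it.

## Coverage tracks

Browser tracks scale each sample to 1× genome coverage (multiply per-base
coverage by effective_genome_size / total aligned bases; the fly effective
genome size 142,573,017 bp is the default), bin by averaging (default 1 bp),
form log2((t+pc)/(r+pc)) with pseudocount 1 normalized unit, and smooth with
a centered running mean over 5 bins.  Tracks are antisymmetric under
swapping treatment and reference.  Replicates may be pooled for tracks;
count matrices always keep replicates separate for the statistics.

## Synthetic data

The generator emulates the study conditions: a single contig (default
700 kb) with planted GATC motifs; 100 non-overlapping gene models; a uniform
background accessibility plus a gene-body occupancy signal; a treatment
condition multiplying the occupancy of "up"/"down" gene fragments by
2^±log2FC (default |log2FC| = 2 on 20% of genes, alternating up/down); and
per-sample fragment counts drawn negative-binomially with mean proportional
to normalized occupancy × depth (default 10⁶ reads/sample, 3 replicates per
condition) and a single genome-wide dispersion (default 0.1; below 1e-8 the
draw degrades to Poisson).  Signal-to-background (gene signal 1.0 over
background 0.1) is a calibration choice — the profiled system publishes no
quantitative ratio — picked as a realistically strong Pol-II footprint.

Motif gaps are gamma-distributed with shape 4 and mean
`mean_gatc_spacing − 4`: right-skewed like real motif spacing but with the
empirical median within ~10% of the mean, so the configured 350 bp doubles
as the approximate median fragment distance and the default config yields
~2000 fragments.  Accidental GATC occurrences in filler sequence are
disrupted so planted spacing is exact.  SAM emission places each read's 5'
end exactly on its fragment's boundary (forward reads at the start, reverse
reads ending at the end), making the edge-counting round trip exact by
construction.

What the generator does **not** model: sequencing error, PCR duplicates,
mappability/repeat structure, GC bias (a hook exists but the default is
uniform background), fragment-length distributions, or between-replicate
library composition effects beyond NB noise.  Passing recovery tests on
this generator therefore demonstrates the statistical machinery and the
interval bookkeeping, not robustness to alignment artefacts of real
libraries.

## Downstream statistics

"Methylated GATC sites" for the TSS meta-profile are fragments whose
normalized fusion-condition signal exceeds a quantile (default 0.5) of the
nonzero distribution — the threshold is configuration, not a measured
constant, and is validated only on synthetic constructions.  TSS distances
are signed relative to the strand of the gene owning the nearest TSS
(negative = upstream).  Gene bodies are rescaled to 100 positional bins
(reversed for minus-strand genes) and averaged within expression quantiles.
Fisher enrichment uses the exact two-sided point-probability rule (summing
hypergeometric probabilities ≤ the observed table's) with a Haldane 0.5
correction on the odds ratio when any cell is zero.  Overlap percentages
are resolved to one decimal and reported as their integer part (31.0 → 31,
46.6 → 46, 30.8 → 30), the convention consistent with all the worked
figures this package reproduces.

## Problem sizes and determinism

Default analysis and test sizes — ~2000 fragments for recovery, ~10⁴
fragments for null calibration, 10⁵ sites for distributional checks, ≥100
random instances per brute-force oracle — are the package's chosen balance
of statistical resolution against desk-scale runtime; the full suite runs
in seconds.  Every stochastic component takes an explicit seed, and
identical inputs produce byte-identical TSV outputs.

## Known limitations

- Single-factor, two-group design only: no covariates, batch terms or
  voom-style mean-variance weights.
- The per-peak FDR is the Simes + BH interpretation of region-combining;
  a peak-level refit is not implemented.
- Gene assignment uses the gene span with a configurable upstream margin;
  no transcript-isoform resolution.
- The real-genome median spacing (350 bp) is asserted only as the default
  merge tolerance constant, not recomputed here, since the reference genome
  is not bundled.
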