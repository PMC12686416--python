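# Methods

## Donor-anchored junction quantification

The quantification model treats the constitutive upstream exon's donor (5′
splice site) as a fixed anchor. In a STAR `SJ.out.tab` table each row is an
intron with 1-based inclusive genomic coordinates; on the plus strand the
donor side of the intron is the `intron_start` field (the first intronic
base after the donor exon), on the minus strand the `intron_end` field. All
rows on the model's chromosome whose donor boundary equals the model's donor
site are kept and classified by the opposite intron boundary, which is the
last intronic base before the acceptor exon: one category per microexon, one
for the terminal exon, and `other` for any unannotated acceptor. Rows whose
donor is any other site — including junctions leaving a microexon — are
excluded; they are downstream segments of a transcript already counted at the
anchor, and counting them would double-count isoforms.

Per sample, the category counts over the donor total give isoform
proportions. Assumptions worth stating:

* Junction reads are an unbiased multinomial sample of the isoform mix at
  the donor. This ignores mappability differences between junctions, which
  for microexon acceptors could bias against short-overhang junctions; the
  donor-anchored design at least equalizes the donor side.
* The donor exon is constitutive, so the donor total is usable as the
  gene-expression proxy.
* The denominator includes `other` acceptors, since the measure is defined
  as the share of all junctional reads leaving the donor.

### Tunable parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `min_total` | 10 donor reads | below this the proportions are reported as undefined (NaN), not 0 — avoids zero-inflation in low-coverage samples |
| `count_field` | `unique` | STAR's multi-mapper junction counts are unreliable at short overhangs; `unique+multi` available |
| detection threshold | 0.05 | an isoform is called present when its proportion is strictly above 5% |

Replicated perturbation designs are quantified per sample and aggregated as
means of per-sample proportions (not pooled counts), preserving per-replicate
error structure; pooling remains possible by summing counts upstream.

## Gene model and the synthetic RPS24 stand-in

A locus model is the donor exon, an ordered run of microexons (< 30 nt; a
longer flagged exon triggers a warning, not an error), and the terminal
exon, with 1-based inclusive coordinates (BED input is converted at load).
Enumerating inclusion/exclusion of k microexons yields 2^k combinations;
each carries the sum of included lengths (transcript length delta) and, when
the primer pair is configured, an expected amplicon size (base amplicon +
delta).

Combination labels follow the junction naming used in the field: the model's
`canonical_structures` table maps experimentally resolved exon content to
junction names (for RPS24: the 3+22 structure is `ex4:3bp`, 22-only is
`ex4:22bp`, all-skipped is `ex4:ex6` — the junction name identifies the
first included exon, not the full content). Unresolved combinations get
explicit content labels (`inc:18+22`).

The packaged `"RPS24"` model is a **synthetic stand-in**: the reference
genome is not redistributed, so coordinates are placeholders and the exon
sequences were constructed to satisfy the locus's published constraints —
microexon lengths exactly 3/18/22 nt, an in-frame stop codon inside the
22-nt exon so that the 3+22 and 22-only isoforms differ by exactly one
lysine, a Pro-Lys-Glu C-terminus for the all-skipped isoform, and the
published ex4F/ex6R primer sequences anchored in the flanking exons. Tests
that use this fixture validate the pipeline's arithmetic and translation
logic, not hg38 coordinates; users with the real annotation can supply it as
GTF/BED/YAML.

Translation starts at the configured reading-frame offset in the donor exon
and stops at the first in-frame stop; the reported C-terminal peptide is the
part of the protein encoded downstream of the donor exon, which is exactly
the region microexon choice can alter.

## Fragment-analysis twin

The electropherogram model is a sum of Gaussian peaks (per-peak width σ,
default 0.35 nt — unstated for the original instrument, chosen so that
3-nt-separated amplicons are cleanly resolved) over a calibrated size axis,
plus white baseline noise parameterized by a signal-to-noise ratio (peak
maximum / noise sd). Size calibration is assumed done upstream; a linear
ladder-based calibrator is provided.

Peak calling: detection runs on a lightly smoothed copy of the trace
(Gaussian kernel sd 0.15 nt, a matched-filter step narrow enough to keep
3-nt pairs resolved). The per-sample noise sd is estimated from the median
absolute first difference of the raw trace — robust both to the peaks
themselves and to the zero-clipping of the lower noise tail, where a plain
MAD of intensities collapses. Candidates must rise `min_snr` (default 5) ×
smoothed-noise above the baseline (trace median); each is refined by a
Gaussian fit on the raw trace (area = amplitude·σ·√2π; trapezoidal
integration over ±3σ as fallback when the fit fails), and peaks closer than
`min_separation` (default 1 nt) are merged into the taller with areas
summed.

Assignment matches each peak to expected amplicon sizes within a tolerance
(default 1 nt). When several combinations tie, junction evidence breaks the
tie: combinations containing a microexon whose own donor junction has zero
reads are removed from the candidate set. This mirrors how the junction and
fragment measurements were combined to resolve that the +25 peak is the
3+22 structure (the 18-bp junction being absent); without evidence the peak
stays `ambiguous` and is excluded (and reported) by the proportion step.
Ambiguous/unassigned peaks never enter the area denominator, so assigned
area fractions always sum to 1.

## Cohort statistics

* Contrasts: Welch's t-test (the safer default when equal variances are not
  asserted) for two groups, one-way ANOVA otherwise; two-sided throughout.
  Star notation is a pure function of p with inclusive boundaries:
  `***` p ≤ 0.0005, `**` p ≤ 0.005, `*` p ≤ 0.05.
* Correlations are Pearson, on complete pairs, with explicit excluded
  counts; constant inputs are an error rather than a NaN.
* Genome-wide ranking computes per-gene Pearson r of a (genes × samples)
  matrix against the isoform proportion, with pairwise-complete NaN
  handling; expression matrices rank descending, dependency matrices
  ascending (the expected association sign for essentiality scores is
  negative). Ties break on the gene key so ranks are deterministic. No
  multiple-testing correction by default (ranks are the object of interest);
  a Benjamini–Hochberg column is optional.
* Fold changes are ratios of arm means of per-sample proportions, with a
  Welch t-test attached when both arms have ≥ 2 replicates. The estimator is
  scale-equivariant and undefined (error) at zero control mean.
* Undefined proportions are excluded per analysis with a reported count,
  never imputed.

## Motif scan

A plain PSSM over the RNA alphabet: position frequencies (from aligned sites
or an IUPAC consensus; `Y` expands to C/U at 0.5) get a pseudocount
(`f = (f0 + pc) / (1 + 4pc)`, default pc = 0.01) and become log2-odds
against a background (uniform by default), floored at −10 per position so
zero frequencies stay finite. Every window of the scanned sequence is
scored; the z-score standardizes the raw score against the mean and
population sd of all window scores within ± half of a local background
window (default 500 nt, clipped at sequence ends). Hits pass at strict
z > 3. A homopolymer background has zero score variance; such windows get
z = NaN and never pass. The polypyrimidine-content track is a centered
sliding C/U fraction used to annotate whether hits fall in tracts
(fraction ≥ 0.7 by default).

This is deliberately simpler than database scanners built on weighted-rank
statistics and conservation filtering; the implemented decision criterion is
the local z-score threshold alone.

## Synthetic-data generator

What it emulates: multinomial junction sampling at configurable depth
(negative-binomial depth around a mean, default 5,000 donor reads,
dispersion 0.3); cohort structure as per-group Dirichlet means with
concentration 50 (moderate between-sample spread, comparable to the spread
across a cell-line panel; the default groups encode an ER+/ER− contrast of
0.40 vs 0.10 on the 3-bp-junction isoform with the 18-bp junction absent);
a continuous feature whose truth-level Pearson correlation with a chosen
isoform's proportion hits a target r exactly (the Gaussian noise is
residualized against the truth in-sample and rescaled — the realized
correlation is the configured one, not a noisy draw around it);
control/treated pairs with a planted fold change (default 2.25 on a 0.2
control proportion, 3 replicates per arm, Gaussian replicate jitter sd
0.01, treated vector renormalized so proportions stay on the simplex; folds
that push a proportion past 1 are rejected); Gaussian-peak traces; and
i.i.d. background sequences with exact planted motif substrings.

Decoy junctions (a microexon-donor junction inside the locus and a junction
on another chromosome) are generated by default so that classification
filters are always exercised. Seeding uses one master seed with per-stream
`SeedSequence` sub-keys indexed by sample, so outputs are byte-reproducible
and adding samples never changes existing ones.

What it does not emulate: read-level alignment artifacts (mappability bias
against short-overhang junctions, misalignment into microexons), library
preparation biases, instrument drift or dye artifacts in traces, and
correlated gene-gene structure in feature matrices. Passing tests therefore
demonstrate correctness of the quantification and statistics under the
stated sampling models, not robustness to alignment pathology on real data.

## Problem sizes used by the test suite

The statistical tests run at desk scale, chosen as the smallest sizes at
which the targeted properties are stable: proportion recovery uses 200
samples per depth in {100, 1k, 10k}; the oracle-equivalence check uses
1,000 random instances of ≤ 50 junction rows; junction/fragment concordance
uses 11 samples at depth 5,000 and snr 50; fold-change round trips use 100
seeds per fold at depth 10,000 with 3 + 3 replicates; calibration uses
1,000 null cohorts (type-I) and 100 powered cohorts at n = 20/20; motif
recovery uses 100 seeds of 300-nt pyrimidine-poor sequences.

## Known limitations

* The packaged RPS24 fixture is synthetic (above); coordinate-level results
  against real hg38 data require the user's own annotation and genome.
* Junction evidence in peak assignment treats "zero reads on a microexon's
  own junction" as absence of that microexon; an exon that only ever occurs
  downstream of another included microexon would evade its own junction
  category. For the modelled locus this situation is resolved by
  construction (the canonical structures encode it), but the rule is a
  heuristic on arbitrary models.
* The peak caller assumes approximately Gaussian, baseline-resolved peaks;
  heavily saturated or strongly tailed instrument peaks would need a
  different peak shape model.
* GDC dialect support covers the STAR-style 9-column layout with header
  tolerance; exotic junction formats need an explicit column mapping.
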