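# Methods

## Scope and data model

The package analyses fraction-resolved taxon tables from DNA-SIP
experiments. The unit of observation is a *fraction sample*: the relative
abundance of every taxon in one pooled gradient fraction class (heavy or
light) of one incubation (treatment × isotope × replicate, optionally ×
timepoint). Abundances are treated as given, compositional quantities — each
sample column sums to 1 and is never re-closed after filtering, so a
taxon's value is always its share of the fraction as sequenced.

## The labelling caller

A taxon's evidence is the quadruple (¹³C_H, ¹³C_L, ¹²C_H, ¹²C_L) of
replicate-averaged relative abundances. The rule is deterministic:

* floor: ¹³C_H > `floor` (default 0.001, i.e. 0.1 %) — strict;
* criterion 1: ¹³C_H > ¹²C_H — strict;
* criterion 2: ¹³C_H > k·¹³C_L (strict) **and** ¹²C_H ≤ ¹²C_L (non-strict).

Strictness follows the rule as stated; the asymmetry (non-strict on the ¹²C
side) means an exactly flat ¹²C profile does not veto a call. A consequence
worth noting: ¹³C_L = 0 with ¹³C_H > 0 passes the k test for any k — this is
intended, not special-cased. There is no multiple-testing correction because
nothing is being tested: the rule is a decision procedure, not an inference.

Replicates are averaged into one profile *before* applying the rule; taxa
absent from a replicate contribute an explicit zero. Two optional modes
deviate from the default: `floor_per_replicate=True` requires the floor in
every replicate (the default applies it to the mean, with the switch exposed
because either reading of "had to be greater than 0.1 %" is defensible), and
`vote=True` calls each replicate separately and labels by majority. Both are
off by default. Timepoints are independent analyses.

Control exclusion is a pure set operation: a taxon labelled in both the test
and the control treatment becomes `excluded_control` in the test list;
no other status is ever modified, so the final labelled set is exactly
(test labelled) \ (control labelled). The same floor and k are used for the
control calls.

## Fraction handling

Densities come from refractometer readings through an affine calibration
ρ = a·n_D + b with defaults a = 10.9276 g ml⁻¹ per RI unit, b = −13.593
g ml⁻¹ — the standard linearization of the CsCl density/refractive-index
relation at 20 °C used in SIP protocols. Heavy and light pooling windows
default to [1.725, 1.735] and [1.705, 1.720] g ml⁻¹, typical band positions
for ¹³C- and ¹²C-DNA in CsCl. Both are configuration, not constants in
logic: instruments and gradients differ, and published studies rarely print
their calibration, so every run records the values used. Window boundaries
are inclusive; anything outside both windows is discarded.

## Synthetic experiments

The generator produces the complete input of a two-treatment
(rhizosphere/unplanted), two-isotope SIP design with known truth. Its model:

* Baseline composition per treatment ~ symmetric Dirichlet(α), α =
  `base_abundance_concentration` = 1.0 by default — flat on the simplex,
  heavy-tailed enough that a realistic minority of taxa sit near or below
  the 0.1 % detection floor.
* Each taxon's DNA mass splits between the heavy and light bands with
  heavy:light odds = `background_leakage` × e, where e is its enrichment
  factor. This two-pool form conserves DNA mass, so a strongly labelled
  taxon is simultaneously enriched in the heavy band and depleted from the
  light band — the signature seen in real gradients, and the reason a
  k = 10 test is passable at all when labelled taxa dominate the heavy
  fraction. At leakage = 1 and e = 1 the two bands have identical expected
  composition (the no-signal control case).
* Enrichment factors are log-normal with log-scale median `enrichment_mean`
  (default 50) and sd `enrichment_sd` (default 0.15), redrawn per replicate
  as incubation-to-incubation jitter: labelled taxa in ¹³C rhizosphere
  incubations; cross-feeders likewise but with median
  `crossfeed_enrichment_mean` = 5 (between the k = 2 and k = 10 regimes, so
  the two k values genuinely separate them); autotrophs in the ¹³C
  incubations of *both* treatments — exactly the confounder the unplanted
  control removes.
* A high-GC subset of the unlabelled background (`n_high_gc` = 10 taxa,
  odds multiplier `gc_enrichment_mean` = 15) leaks into the heavy band of
  *both* isotopes. Without such heterogeneity the ¹²C heavy and light
  fractions would be identical in expectation and the ¹²C_H ≤ ¹²C_L clause
  would be a coin flip under sampling noise; with it, that clause does real
  work (it vetoes the high-GC taxa) while ordinary taxa sit comfortably on
  the passing side because the high-GC DNA compositionally depresses them
  in the ¹²C heavy fraction.
* Each fraction sample is a multinomial of `read_depth` (default 20 000)
  draws from the band composition, divided by the depth — amplicon-style
  count noise. All draws flow from one `numpy` generator seeded by the
  single config seed, so identical configs reproduce tables bit-for-bit.

Defaults describe a strong-signal experiment: 200 taxa, 20 labelled, 10
cross-feeders, 5 autotrophs, 3 replicates.

What the generator does *not* emulate: sequencing-read artefacts (chimeras,
clustering, taxonomy error), more than two density classes per gradient,
correlated baselines between treatments, taxon-specific read depths, or
compositional zero-inflation beyond multinomial sampling. Passing recovery
tests therefore demonstrates that the decision rule is implemented correctly
and behaves sensibly under compositional count noise — not that it is robust
to upstream bioinformatic error on real amplicon data. Recovery sensitivity
on the default design is limited mainly by genuinely rare labelled taxa
falling below the 0.1 % floor, which mirrors the rule's behaviour on real
data.

Gene-hit simulation draws Poisson counts with expectation ∝ abundance ×
gene length × library size (the length bias the per-kb normalization
removes); alignment simulation plants fully conserved columns except at
requested variable positions, each forced to ≥ 2 distinct bases.

## Primer design

Conservation is column-level: a column is conserved iff all rows carry one
identical plain base; any gap or N disqualifies the column and every window
containing it (primers cannot span indels). The scan enumerates all windows
of length 18–20 nt with at most 3 non-conserved columns — "non-conserved
base" is read as non-conserved alignment *column*, the only reading
computable from an alignment; the budget is configurable, so the alternative
reading (fully conserved window, degeneracy allowed in synthesis) is
expressible as `max_nonconserved=0`. Coordinates are 0-based, half-open.
All overlapping windows are reported; a convenience ranking sorts by
(variable columns, degeneracy, −length, start).

The consensus encodes each column as the minimal IUPAC code covering the
observed bases; degeneracy is the product of column base-set sizes. In-silico
PCR matches the forward primer on the top strand and the reverse-complement
of the reverse primer downstream of it; a degenerate code matches any base
it covers. Default mismatch allowance is 0, and in every mode the three
3′-terminal positions of each primer must match perfectly — polymerase
extension is intolerant of 3′ mismatches, so allowing them would predict
products that do not form. Product length runs from the forward 5′ end
through the reverse 5′ end inclusive.

## Gene quantification

Metagenome normalization: assembled hits are expressed per kb of the
representative reference gene; unassembled hits per kb per million reads
(hits·kb⁻¹·Mread⁻¹, the RPKM-like convention made dimensionally explicit).
Reference lengths are required inputs (nucleotide bp by convention), never
inferred. The MDH-carrying percentage of bacteria is the summed MDH-clade
abundance over the recA abundance × 100; values above 100 % are reported and
flagged rather than clipped, since multiple xoxF5 copies per genome are
common.

E-value stringency calibration takes a labelled hit list and sets the cutoff
at the e-value of the strongest wrong-clade hit; passing is strictly below
the cutoff. This makes the passing set provably sound (no wrong-clade hit
passes) and maximal (any looser threshold admits the blocking hit). If the
top hit overall is wrong-clade the calibrated cutoff passes nothing, with a
warning.

qPCR: Cq is regressed on log10(copies) by ordinary least squares over a
dilution series (≥ 3 distinct levels required); efficiency = 10^(−1/slope) −
1, reported as a percentage; a non-negative slope raises an error as an
invalid assay. Quantification inverts the curve per gene and reports copies
per reference-gene copy (16S rRNA by default) plus pairwise gene ratios.
Group-comparison statistics (ANOVA etc.) are deliberately out of scope; the
output tables are tidy so any stats package can consume them.

## Numerical and interface choices

* All tables are TSV (taxon names contain commas), UTF-8, '.' decimals.
* Blank abundance cells read as 0; a taxon absent from a fraction has
  abundance 0, never missing.
* The pipeline's summary JSON is fully deterministic (no timestamps); a
  rerun with the same config and seed is byte-identical.
* Validation errors name the offending field, sample or taxon.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 200-taxon, 3-replicate design (24 fraction samples of 20 000 reads),
100-alignment scan-oracle batches at ≤ 10 × ≤ 200, and 10⁴-profile caller
oracle batches; the complete suite executes in a few seconds on one CPU.
These sizes give stable pass/fail behaviour for every property tested while
keeping iteration fast.

## Known limitations

* The caller consumes pre-pooled heavy/light abundances; it does not model
  per-fraction density profiles (no qSIP atom-fraction-excess estimation).
* Fraction pooling windows and the RI calibration must come from the
  experimenter; defaults are typical values, not universal constants.
* The simulator's two-pool gradient is a dichotomy; partial labelling that
  shifts DNA to intermediate densities is outside its vocabulary.
* In-silico PCR scores mismatch counts only — no melting temperature,
  dimer or hairpin thermodynamics.
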