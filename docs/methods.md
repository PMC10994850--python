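# Methods

This note documents the models behind `mobactag`, the defaults that matter,
and what the synthetic-data generator does and does not emulate.

## Barcode-tag assembly model

A barcode tag is an ordered, oriented concatemer of 38-nt double-stranded
oligonucleotide units drawn from an equimolar pool of ten (labels `a`–`j`).
The simulator (`simulate_ligation`) draws, per product, a unit count *k* from
a configurable distribution, then fills each position independently with a
unit (uniform by default; per-unit weights model non-equimolar batches) and
an orientation (forward with probability 0.5 by default — blunt-end ligation
is orientation-agnostic, and the probability is configurable per unit because
real assembly batches deviate). Every array satisfies
`len(sequence) == 38·k` exactly and is reconstructable from its
`(label, orientation)` list.

**Unit-count distribution.** Size selection retains products whose fragment
length `38·k + flank_length` lies in the 200–300 bp window; with the default
100-nt flank this keeps k ∈ {3, 4, 5}. A hard retention window combined with
any monotonically decreasing pre-selection distribution would make k = 3
modal, whereas assembled tag libraries are modally four units (~150 nt). We
therefore use a peaked default, `P(k) ∝ 0.7^|k−4|` truncated to [1, 8]: the
peak absorbs both ligation kinetics and the soft transmission profile of the
size-selection instrument, which the hard window does not model. Under the
defaults the retained arrays have modal k = 4 and mean length ≈ 152 nt
(4 × 38 = 152). Mode, decay, flank and window are all config-exposed; the
flank length is a free parameter because the adapter content present during
size selection is not part of the model.

**Unit design.** Units are four "pyrosequencing-friendly" sub-barcodes of
8–10 nt (summing to 38): no homopolymer run longer than 2, no dinucleotide
tract repeated more than twice, pairwise sub-barcode edit distance ≥ 3,
non-palindromic, pairwise distinct on both strands. The generator
additionally enforces *junction safety*: every ordered, oriented pair of pool
members concatenates without creating a tract across the seam (two units may
individually end and begin with a doublet, which would otherwise stack into a
4-run after ligation). A violation crossing a junction is contained in the
last five bases of one unit plus the first five of the next, so only that
window needs checking. The shipped pool (`data/default_oligos.fasta`) is the
generator's output at a fixed seed and is regenerable bit-exactly; real oligo
sequences are not distributed.

**Scaffolds.** The array is nested inside four primer pairs, outermost to
innermost 16S → fungal ITS → plant ITS → barcode, separated by 3-nt spacers.
The 16S pair is 799F/1192R with degenerate positions resolved to single
bases; the fungal pair is ITS1F/ITS2; the plant-ITS and barcode-specific
sites are synthetic stand-ins (labelled as such in the source). Assembly
validates by in-silico PCR that each pair yields exactly one amplicon
spanning the complete array, that no site occurs twice (an array containing a
site verbatim is rejected), and that the scaffold's 16S amplicon (335 bp for
a four-unit array) is shorter than the ~393 bp endogenous V5–V7 amplicon, so
the two PCR products separate on a gel. Internal coordinates are 0-based
half-open; GenBank output converts to 1-based inclusive at the format
boundary only.

## Read assignment

Reads are classified by bounded nearest-reference edit distance (edlib,
global alignment, both strands): a read is assigned to its closest reference
if that distance ≤ `max_distance` (default 3) *and* the runner-up is worse by
at least `margin` (default 1); otherwise it is `unassigned`. Ties are never
broken arbitrarily, which makes counts invariant to read and reference order.
Distances are capped at `max_distance + margin`, beyond which the outcome
cannot change; exact matches short-circuit through a hash lookup (valid
because reference sets reject duplicate sequences on either strand). This is
a deliberately simple classifier, not a reference-based error-correction
model: paired-end merging and quality filtering are upstream concerns, and
the package consumes merged or single-end reads. With references separated by
more than `2·max_distance` edits, misassignment is impossible and the
unassigned fraction of reads with per-base error ε follows the binomial tail
`P(Bin(L, ε) > max_distance)` — a property the tests verify against the
closed form.

Near-isogenic strains (identical 16S V5–V7) must be represented by one shared
`endogenous_16S` feature; strain resolution comes only from `barcode_tag`
features. Reference sets reject identical sequences outright, naming the
offending pair.

## Normalization and correction factors

The spike design records which features are spikes and the reaction masses
(defaults 6 ng sample, 0.001 ng spike; ratio 6,000). Per sample:
`Nb = Rb / Rs_16S` per bacterial feature, `Np = Rp / Rs_pITS`, and load
`Nb/Np`, which satisfies `(Rb·Rs_pITS)/(Rp·Rs_16S)` to within 1e-12 relative
(verified at computation time). All three are invariant to scaling a sample's
counts — they measure composition against the fixed spike anchor, not depth.
A sample with zero spike reads is *flagged and excluded*, never pseudocounted:
spike failure is a library failure, not a biological zero. No pseudocounts
are used anywhere by default; an optional pseudocount exists only for the
relative-abundance view. Plant ITS copy number differs between host species;
an optional per-host scalar (default 1) is the hook for correcting it.

**Correction factors.** The tag-to-16S amplification ratio of each tag is
estimated from pure-culture calibration samples as the zero-intercept
least-squares slope of `N_tag` on `N_16S` (`Σxy/Σx²`), which down-weights
shallow samples; a per-sample ratio mean is available as an alternative
estimator. Confidence intervals are a Student-t interval on the bootstrap
standard error (1,000 seeded resamples, n/(n−1) small-sample inflation);
raw percentile intervals undercover noticeably at the typical n = 16.
With 16 Poisson-noise samples at mean 16S count 1,000 the estimator recovers
biases in the 1.4–3.5 range to well within 2% (attenuation from Poisson noise
in the regressor is of order 1/mean ≈ 0.1%). Applying a factor divides the
tag's counts (real-valued output, flagged as corrected); every tag must have
a factor or the operation fails naming the tag.

**Standard curves.** Dilution series are fitted by OLS in log10–log10 space
after normalizing the diluted (secondary) spike's counts by the primary
spike's counts to cancel depth; zero-count points are dropped with a warning
and fewer than three survivors is an error. The reported dynamic range is
`log10(max mass / min mass)` over surviving points.

## Synthetic-data generator

Counts are multinomial at fixed depth over feature propensities:
`abundance × copy_number` for 16S features (shared features accumulate),
`abundance × tag_bias` for tags, and fixed values for spike (0.05), plant ITS
(0.3) and plant-ITS spike (0.05) relative to total bacterial propensity 1 —
chosen once as realistic root-sample proportions in which spike reads are a
few percent of the library. An optional gamma-perturbation of the propensity
vector (coefficient of variation `overdispersion`, default off) models
replicate-to-replicate spread; no data constrain its value. Reads are
reference sequences with iid substitutions on a random strand (default
length 250 nt, the merged short-read regime); indels, chimeras, quality
trajectories and index hopping are *not* simulated, so passing tests bound
classifier behaviour only under substitution noise. Dilution series scale
the secondary spike's propensity proportionally to mass (reference mass
0.15 ng, the mass at which it matches the primary spike), optionally with
multiplicative lognormal jitter; series are generated at depth 10⁶ so the
lowest of the five tenfold masses still yields tens of spike reads rather
than dropping out of the fit. Everything is deterministic given the spec's
seed.

## Numerical choices and degenerate inputs

* Edit distance is Levenshtein throughout; both-strand comparisons take the
  minimum over orientation pairings.
* Enumeration of ligation products counts distinct `(label, orientation)`
  tuples as distinct even when sequences collide, with a warning on
  collision.
* Positional-frequency columns with no supporting array (e.g. p5 when no
  retained array has five units) are NaN and reported, not silently zero.
* Depleting zero features is the identity; depleting all features yields a
  valid empty table with zero depth and the original depth in provenance.
* Floats in TSV output carry 12 significant digits; tables are tab-separated
  with `#`-prefixed provenance headers.

## Known limitations

The classifier is not an error-correction model and will under-assign at
error rates or reference densities outside the regime above. The ligation
model's flank length and unit-count distribution are effective parameters
fitted to the observed post-selection outcome, not mechanistic measurements.
Default primer stand-ins make scaffold sequences suitable for pipeline
validation, not for ordering oligos. The generator's propensity model assumes
amplification bias is per-tag multiplicative and depth-independent — the same
assumption the correction-factor method itself makes.
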