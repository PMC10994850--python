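# mobactag

Strain-resolved microbiota profiling with chromosomal barcode tags: in-silico
design of ligated DNA barcode tags, assignment of amplicon reads to
barcode/marker references, and spike-normalized quantification of
near-isogenic strain abundance and microbial load.

## The problem

16S rRNA amplicon profiling cannot distinguish bacterial strains that share an
identical marker sequence — a wild type and its single-gene mutants look the
same. Chromosomally integrated barcode tags solve this: each strain carries a
unique synthetic DNA barcode flanked by binding sites for the bacterial 16S
V5–V7 (799/1192), fungal ITS, plant ITS and barcode-specific primer pairs, so
the barcode is co-amplified with whatever endogenous marker the community PCR
targets. A barcode-bearing plasmid added at known mass per reaction (6 ng
sample : 0.001 ng spike = 6,000:1 by default) serves as a spike-in that puts
read counts on an absolute scale.

This package implements the computational side of that workflow for
researchers running synthetic-community (SynCom) experiments:

* **Tag design** (`mobactag.oligo`, `mobactag.ligation`, `mobactag.scaffold`)
  — barcode tags are modelled as ordered, oriented concatemers of 38-nt
  double-stranded units assembled by random blunt-end ligation from an
  equimolar ten-unit pool, followed by 200–300 bp size selection. Retained
  arrays are modally four units long (~152 nt). Scaffolds nest the array
  inside the four primer pairs and are validated by in-silico PCR.
* **Read assignment** (`mobactag.references`, `mobactag.assign`,
  `mobactag.counts`) — bounded nearest-reference classification by edit
  distance on both strands, with an ambiguity margin (ties are never broken:
  ambiguous reads are `unassigned`), producing sample × feature count tables;
  supports in-silico depletion of focal features.
* **Quantification** (`mobactag.quantify`) — the normalization equations

  $$N_b = \frac{R_b}{R_{s,16S}}, \qquad
    N_p = \frac{R_p}{R_{s,pITS}}, \qquad
    \frac{N_b}{N_p} = \frac{R_b \cdot R_{s,pITS}}{R_p \cdot R_{s,16S}}$$

  where $R_b$, $R_p$ are reads assigned to a bacterial or plant feature and
  $R_{s,\cdot}$ the spike reads of the matching library; $N_b/N_p$ estimates
  microbial load per unit host tissue. Individual barcode tags amplify 1.4- to
  3.5-fold more efficiently than the endogenous 16S amplicon, so tag counts
  are divided by a per-tag **correction factor** — the zero-intercept
  regression slope of paired (tag, 16S) counts from pure-culture calibration
  samples. Spike standard curves over tenfold dilution series are fitted in
  log–log space.
* **Synthetic data** (`mobactag.simulate`) — a generative model (multinomial
  counts over abundance × copy-number/tag-bias propensities; reads with
  per-base substitution errors on random strands) providing ground truth for
  every step.

## Worked example

`examples/` contains one narrative script per capability. For instance,
calibrating correction factors from synthetic pure cultures
(`python examples/03_calibrate_correction_factors.py`):

```
     tag   true  estimate             95% CI   error
  tag119   3.50     3.543 [3.486, 3.599]  +1.22%
  tag120   1.90     1.896 [1.852, 1.940]  -0.21%
  tag190   1.80     1.804 [1.763, 1.845]  +0.21%
  tag104   1.60     1.604 [1.572, 1.637]  +0.27%
   tag93   1.50     1.490 [1.462, 1.518]  -0.67%
   tag94   1.40     1.406 [1.383, 1.430]  +0.45%
```

Each row is one tag's amplification bias (true generative value, point
estimate from 16 Poisson-noise calibration samples with mean 16S count 1,000,
and bootstrap CI): the estimator recovers every bias to within ~1%, which is
what makes corrected tag counts comparable to 16S counts across strains.
`examples/04_quantify_microbial_load.py` shows the compositionality trap —
a strain whose *relative* share rises while its spike-normalized abundance
falls — and fits the tenfold dilution standard curve (slope 0.987,
R² 0.9993, 4 orders of magnitude).

A thin CLI mirrors the library:
`mobactag design|simulate|assign|calibrate|quantify` (see `mobactag --help`);
every stochastic subcommand requires `--seed`, and outputs carry provenance
headers.

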