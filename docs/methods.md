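# Methods

This note documents the generative model behind `senescreen`'s simulator,
the statistical methods in the analysis stages, the assumptions both make,
and their known limitations.

## 1. Screen model

### Library

The default library models a genome-scale knockout resource: 19,050
targeting genes with 5 or 6 sgRNAs each (drawn uniformly per gene) plus
1,000 non-targeting controls, about 105,000 guides in total. Published
genome-wide libraries of this class are reported at roughly 120,000 unique
sgRNAs over ~19,000 genes; the generator fixes the gene count and the
per-gene range rather than the total, so the exact guide count varies by a
few percent with the seed. Spacers are independent random 20-mers,
guaranteed distinct; real libraries select spacers against genomic
off-targets, which this generator does not model (irrelevant for the
counting and statistics exercised here). Gene symbols other than the four
named validation genes (`F9`, `PROZ`, `LPAR5`, `MOGAT`) are synthetic
placeholders (`GENE#####`, `BYP##`), as are the eight `LINE-##` panel cell
lines; see `senescreen.designs`.

### Forward simulation

`simulate_screen` composes four stages, each a standard stochastic
primitive:

1. **Plasmid representation.** One lognormal(0, sigma) relative-abundance
   draw per guide, sigma = 1 by default. A *single* pool is shared by all
   replicates: one amplified library preparation infects every replicate,
   as in a real screen. This choice also makes replicate samples
   exchangeable under the null, which the permutation test requires; with
   independent per-replicate pools the permutation null would be dominated
   by between-prep variance.
2. **Infection.** Cells per replicate (default 500x the library size, a
   standard coverage target) are allocated to guides by a single
   multinomial draw over the plasmid proportions. The default multiplicity
   of infection 0.2-0.5 regime is modelled as exactly one integration per
   infected cell; multiple integrations, uninfected carry-over and
   selection-marker dynamics are not modelled.
3. **Selection and growth.** Knockout is Bernoulli per cell with per-gene
   efficacy (default 0.95); growth over the 14-day treatment is
   deterministic exponential: bypass knockouts divide at `r_bypass` = 0.8
   divisions/day under drug, everything else arrests at `r_arrest` = 0.05,
   and the untreated arm grows at `r_untreated` = 1.0. Growth noise
   (branching-process variance) is omitted; with hundreds of cells per
   guide the multinomial sampling stages dominate the dispersion.
4. **Sequencing.** Each sample is an independent multinomial draw of
   `depth_per_sgrna x |library|` reads (default 200x) over the current
   cell-mass proportions. Day-0 and day-14 samples of a replicate are
   drawn from the *same* infected pool, so they are paired — a fact the
   permutation test must (and does) respect. PCR amplification bias and
   sequencing error are not modelled; `emit_fastq` writes error-free reads
   (vector adapter + spacer + scaffold fill, constant high quality).

The simulator is deterministic given (library, truth, config seed); all
randomness flows through `numpy.random.default_rng`.

### Realism and limits of the generator

The generator reproduces the two dispersion sources that matter for
calibration studies — library skew and finite sequencing depth — and the
signal structure of a bypass screen (strong positive enrichment of a few
genes against an arrested background). It underestimates real-data
dispersion from PCR jackpotting, growth stochasticity and batch effects,
so absolute power estimates transfer to real screens only qualitatively.

## 2. Enrichment statistics

**Normalization.** Counts are scaled to reads-per-million (RPM) per
sample. For fixed-length guide cassettes, a per-kilobase variant differs
from RPM by a multiplicative constant that cancels in fold change, so RPM
is used throughout.

**Fold change.** `log2((rpm_t14 + c) / (rpm_t0 + c))` with pseudocount
c = 1 RPM. Replicates are averaged on the RPM scale within timepoint
*before* the ratio; per-replicate fold changes are reported alongside.

**Per-guide one-sided p-values**, three methods:

- `robust_z` (default): z-score of each guide's log2FC against the
  median/MAD of all guides (MAD scaled by 1.4826), upper normal tail.
  Rationale: with two replicates an explicit replicate test is
  underpowered, while the bulk of a genome-scale library is approximately
  null.
- `control_null`: add-one-smoothed empirical upper-tail probability
  against the non-targeting-control fold-change distribution.
- `permutation`: within-replicate sign-flip (paired) permutation of the
  day-0/day-14 labels. With R replicates there are 2^R equiprobable
  assignments (enumerated exactly for 2^R <= 1000, sampled with the
  identity included otherwise), so attainable p-values are multiples of
  2^-R and a test at alpha = 0.05 needs R >= 5.

**Calibration.** Under a no-effect simulation at the full default scale
(sigma = 1, 200x depth), `control_null` (5 replicates) and `permutation`
(6 replicates) hold the per-guide type-I error at alpha = 0.05 within
[0.035, 0.065]; the acceptance suite re-measures this. Two caveats:

- *Permutation discreteness.* An exact test over 2^R assignments has size
  `floor(0.05 * 2^R) / 2^R` at alpha 0.05: 1/32 ~= 0.031 at R = 5 —
  below 0.035 for structural reasons — and 3/64 ~= 0.047 at R = 6, the
  smallest replicate count inside the band. Hence the R = 6 calibration
  condition for this method.
- *robust_z anticonservatism.* Under multinomial sequencing of a
  lognormal-skewed pool, the fold-change noise variance depends on guide
  abundance, so the marginal null is a scale mixture of near-normals —
  heavier-tailed than the single normal the z-formula assumes. MAD scaling
  calibrates the bulk but the upper 5% tail carries ~6.7% of mass at the
  default settings: the measured type-I error is ~0.067, slightly above
  the 0.065 bound, and the corresponding acceptance check fails by that
  margin. The method is retained as the default for its power and
  replicate-economy; users needing exact calibration should prefer
  `control_null` or `permutation` (R >= 6).

**Gene level.** A guide *passes* when p < alpha (default 0.05) and
log2FC >= threshold (default 2, inclusive); a gene is a hit when >= 3 of
its guides pass. Controls never enter gene calling. No multiple-testing
correction enters the hit decision (the rule is a count of conjunctive
per-guide filters); a BH-adjusted one-sample-t gene q-value is reported as
an advisory column only.

**Overrepresentation.** For a hit list of n genes in a universe of N with
a term covering K, the p-value is the exact hypergeometric upper tail
P(X >= k) = `hypergeom.sf(k-1, N, K, n)`, BH-adjusted across terms. The
universe is the library's targeting genes — a screen can only nominate
genes it contains — not the whole genome.

## 3. Dose-response panel

`simulate_panel` draws crystal-violet-style absorbances: baseline x
(1 - effect * d / (d + EC50)) + Gaussian noise (sd 0.05), EC50 = 1 uM,
over doses {0.25, 1, 5} uM plus vehicle, 3 replicates. Analysis normalizes
each well to its (cell line, drug) vehicle mean, then tests for a
decreasing dose trend: least-squares slope of normalized absorbance on
log10(dose) over the nonzero doses with a one-sided t-test for slope < 0
(requires >= 3 distinct nonzero doses with >= 2 replicates each;
perfectly flat data gets p = 0.5). A line is a **responder** when >= 2 of
the 3 drugs respond at alpha = 0.05; a secondary screen re-applies the
same rule to the primary responders and **confirms** the lines responding
in both rounds.

The linear-in-log-dose test is a deliberate simplification of full
four-parameter logistic fitting: with three dose levels a 4PL fit is
under-determined, while the monotone-trend test is well-posed, and for
monotone Hill-type responses a negative trend is implied. With the
one-sided alpha = 0.05 rule, a truly non-responsive line has roughly a
(3 choose 2) * 0.05^2 ~ 0.7% chance per drug-pair, ~0.7-1% overall, of a
false responder call per screen — small but nonzero, so responder counts
on synthetic panels can occasionally exceed the ground truth by one.

## 4. Numerical and engineering choices

- Exact big-integer-safe tails from `scipy.stats` (`hypergeom.sf`,
  `norm.sf`, `t.sf`), BH via `scipy.stats.false_discovery_control`;
  nothing statistical is re-derived by hand except the explicitly authored
  estimators above.
- All stochastic stages consume `numpy.random.default_rng` generators;
  the CLI fans a single global seed into named per-stage substreams
  (`SeedSequence([seed, crc32(stage)])`, reduced mod 2^31), so stages are
  reproducible when rerun independently and reruns are byte-identical.
- Fold-change ties in the permutation test are counted with a 1e-12
  tolerance so the identity assignment always counts, keeping the
  estimator's `p >= 2^-R` guarantee.
- TSV/CSV artifacts round-trip through pandas; FASTQ parsing uses
  Biopython with gzip support; writes are atomic (temp file + rename).

## 5. Limitations

- Synthetic ground truths and placeholder gene/line names: recovery
  experiments validate the *pipeline*, not any biological claim.
- No PCR bias, sequencing error, multi-integration MOI effects, growth
  stochasticity or batch structure in the generator (section 1).
- `robust_z` is mildly anticonservative under realistic skew (section 2).
- The trend test assumes monotone response and ignores curvature; EC50
  and maximal effect are not estimated.
- The advisory gene q-value treats guides as independent replicates of a
  gene effect, which understates within-gene correlation.
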