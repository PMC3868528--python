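# Methods

## Data model

A tetrad is four spores genotyped at ordered markers along one chromosome.
Calls are parental-origin coded (P1/P2), with BOTH for disomic spores
(carrying both parental alleles, the genotypic signature of meiosis I
nondisjunction when seen at centromere-linked markers) and MISSING for dead
or unscorable spores. Origin coding keeps every statistic strain-agnostic;
mapping strain alleles (URA3 vs ura3, …) to origins is the I/O layer's job.
A heteroallelic pair inserted at the same centromeric locus on the two
homologs carries the same information as a single origin-coded marker, which
is how disome scoring treats it.

Classification rules:

* a marker's segregation is counted P1:P2 among viable spores; 2:2 is
  Mendelian, 3:1/1:3 flag gene conversion, 4:0/0:4 are tallied separately as
  irregular, and a BOTH or MISSING call in a viable spore is aberrant;
* an interval is PD if all four spores carry a parental two-marker
  haplotype, NPD if all four are recombinant, TT at two and two; anything
  else is UNSCORABLE. A BOTH call anywhere on the chromosome voids ditype
  classification for the whole tetrad, because the ditype algebra assumes a
  euploid tetrad.

Three filter policies control which tetrads enter interval tallies:
`paper` (the mapping convention: four viable spores and 2:2 segregation at
*every* chromosome marker — the chromosome-wide reading of the Mendelian
filter, which is the default; a per-interval reading is available as
`lenient`), and `none`. Map distances use `paper`; the conversion cross-tab
deliberately does not (below).

## Estimators

**Perkins.** cM = 100·(6·NPD + TT)/(2n). The standard error is the
multinomial delta method applied to cM = 50(6p_N + p_T):
Var = 2500[36 p_N(1−p_N) + p_T(1−p_T) − 12 p_N p_T]/n, cross-checked in the
tests against a 10,000-replicate multinomial bootstrap (agreement within 5%
relative). The estimator is exact through double crossovers; with k ≥ 3
crossovers in one interval it undercounts, so under a Poisson crossover
process its expectation is 50[5/3 + (4/3)e^(−1.5μ) − 3e^(−μ)] with
μ = d/50 — a deterministic downward bias ≈ 12.5μ³ cM that becomes visible
above ~15 cM at large n. The tests therefore check no-interference runs
against this analytic expectation (and nominal lengths only for short
intervals), and check nominal-length recovery under interference, where
multi-crossover intervals are rare. The equivalent form 100(TT/2 + 3·NPD)/n
is asserted as an identity.

**Papazian / NPD ratio.** NPD_exp(fT) = ½[(1 − fT) − (1 − 3fT/2)^(2/3)],
defined for fT ≤ 2/3; out-of-domain tetratype frequencies return NaN with a
warning rather than being clamped, since they signal data inconsistent with
the underlying model. Under a Poisson process this expression is exact:
fT = ⅔(1 − e^(−1.5μ)) makes NPD_exp = ½[(1 − fT) − e^(−μ)], the true NPD
probability — the property the no-interference calibration tests exploit.
The NPD ratio is observed/expected NPD frequency; significance is a
one-sided exact binomial test of the NPD count against NPD_exp (exact at
the small counts typical of real intervals; the test direction is toward
positive interference). No multiple-testing correction is applied across
intervals, matching per-interval reporting conventions; callers can
Bonferroni-correct externally.

**Adjacent intervals.** For a reference/test interval pair, tetrads with a
crossover in the reference (TT or NPD) form Adj^CO and those without (PD)
form Adj^PD; the statistic is cM(test | Adj^CO)/cM(test | Adj^PD), averaged
with the ratio obtained after swapping roles. Significance comes from a
label-permutation test: permuting the pairing of the two intervals' classes
across tetrads is equivalent to drawing a random 3×3 contingency table with
the observed margins, which is sampled directly via sequential multivariate
hypergeometric draws (≥10,000 permutations by default, seeded; one-sided
toward interference). A chi-square test on the collapsed 2×3 table is
reported as a cross-check. Empty subsets or a zero denominator yield an
undefined-flagged result.

**Crossover classes, assurance, purging.** Minimal crossover reconstruction
scores PD = 0, TT = 1, NPD = 2 per interval and sums; it cannot see
two-strand doubles within an interval, so it overcounts E0 slightly — a
property of the convention, quantified in the tests. The assurance test
compares the E0 count with the Poisson zero class e^(−mean), mean = total
cM/50 (each crossover involves two of four chromatids, hence 50 cM per
crossover); both one-sided exact binomial p-values are reported (excess =
assurance failure, deficit = assurance at work). `purge_nonexchange`
partitions tetrads into exchange and E0 subsets so interference statistics
can be re-run without the achiasmate subpopulation that otherwise dilutes
them — in mixtures the unpurged adjacent-interval ratio is systematically
closer to (or beyond) 1 than the purged one, because forced-E0 tetrads are
PD in both intervals and deflate cM(Adj^PD).

**Conversion cross-tab.** Conversion = any 3:1/1:3 marker. E0 status for
the cross-tab sums minimal crossover counts over the intervals that remain
scorable (`drop="interval"`), because a converted marker blinds only its two
flanking intervals and discarding the whole tetrad would exclude exactly the
events being counted; E-class distribution tallies keep the strict
drop-the-tetrad rule. Association is Fisher's exact test (small cells).
Disome fractions are reported over all input tetrads with explicit
numerator/denominator; only viable spores can be genotyped, so a
nondisjoined tetrad whose two disomic spores both died is undetectable.

**Molecular ratios.** IH fraction = r/(1+r) for IH/IS ratio r; CO/NCO
ratio = p/(1−p) for crossover fraction p (mutual inverses). The
compensation model holds event numbers fixed and predicts the mutant/wild-
type crossover level as (IHf_mut·COf_mut)/(IHf_wt·COf_wt). On a log scale
the homolog-bias defect opens a gap log(IHf_wt/IHf_mut); an observed fold
reduction smaller than that gap means compensation, and the share
attributable to crossover bias is log(COf_mut/COf_wt) divided by the
apparent compensation (gap minus log observed fold). With the hotspot
inputs shipped in the examples this share is ~33% and ~46% — the remainder
is reported as unexplained, operationalizing the inference of a second
feedback process (e.g. additional recombination initiation), which this
model deliberately excludes. Censored inputs (a ratio known only as a
bound because one species sits at the detection limit) propagate a
`censored` flag instead of pretending to be point estimates.

## Simulator

Per meiosis: crossover number and positions from either a Poisson process
(uniform per cM) or a stationary counting-model renewal process in which
crossovers are every (m+1)-th event of an underlying Poisson process —
the standard generative model for interference; m is a free knob because
no interference parameter is being estimated, only qualitative regimes
(m = 0 reduces exactly to Poisson; variance/mean of crossover numbers
decreases in m). Stationarity comes from a uniform random phase, so the
expected crossover count in any subinterval is λ·d/L regardless of m.
Obligate crossovers are implemented by rejection (zero-truncation),
preserving the count distribution above zero. With probability q a meiosis
is instead forced achiasmate (assurance failure / pairing failure) — q and
λ are independent knobs; no feedback law linking them is modelled.

Each crossover pairs one chromatid of each homolog, chosen uniformly and
independently (no chromatid interference — the assumption the Perkins and
Papazian formulas already make). Exchanges compose by strand following:
the pair refers to original chromatids, and bookkeeping tracks which output
molecule currently carries each original strand's distal segment, so that
successive exchanges give the classical single-interval class probabilities
(P(TT | k) = ⅔[1 − (−½)^k]) — a naive "swap rows i,j" implementation
silently converts some doubles into intersister no-ops and was rejected by
the calibration tests.

Gene conversions are independent per marker per meiosis (probability c),
flipping one random chromatid's allele; single-marker events only —
co-conversion tracts are a documented extension point, not implemented.
Achiasmate bivalents nondisjoin at MI with probability 1−b (b = backup
segregation efficiency): two spores become disomic (BOTH at every marker;
viable by default, since chromosome III disomy is tolerated) and two are
dead nullisomes. Exchange bivalents never nondisjoin. Finally spores die
independently at the configured rate; dead spores read MISSING.

Every stochastic decision is stored in a per-tetrad truth record;
`replay_genotypes` re-derives the emitted genotypes from truth alone and the
tests assert bit-exact agreement with the vectorized forward pass. Truth-
based oracles (`interval_recombinant_fraction`, `interval_true_cM`) bypass
genotype scoring entirely and anchor the estimator round-trip tests.
Identical config and seed give byte-identical output tables.

### Default conditions

The default map is a nine-marker, eight-interval chromosome III
configuration totalling 131.6 cM with the centromere-linked locus at
50 cM; the wild-type-like preset uses counting-model interference m = 4,
an obligate crossover, 1% per-marker conversion and 4% spore death. The
`dmc1_hed1_like` preset models the crossover-control-defective regime as a
mixture: the map scaled to 116.8 cM, weak interference (m = 1), q = 0.15
forced-achiasmate meioses with backup efficiency b = 0.9 (so ~1.5% of
tetrads contain disomes), 0.9% per-marker conversion and 29.5% spore death
(bringing overall viability to ~70%, standing in for nondisjunction of the
fifteen unmodelled chromosomes). Simulation-based tests and examples use
2,000–50,000 tetrads: 50,000 puts binomial standard errors near 0.1–0.2 cM
per interval, tight enough to detect estimator miscalibration while a full
round-trip still runs in seconds.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume — ditype
algebra, interference via a renewal process, assurance-failure mixtures,
nondisjunction genotype signatures, conversion as isolated non-2:2 markers.
It does not emulate: sequence-level mechanism (resection, heteroduplex,
joint-molecule intermediates), co-conversion tracts, crossover-associated
conversion, suppression of conversion in pairing-failed meioses (real
non-exchange tetrads show almost no conversions; simulated ones convert at
the background rate), position-dependent hotspot intensity, or
multi-chromosome karyotypes. Passing tests therefore validate the
estimators' behaviour under the stated models, not the biological fidelity
of those models.

## Numerical choices and edge cases

* Genetic coordinates are 0-based cM from the left-most marker; crossover
  placement uses half-open [left, right) intervals, so an exchange at
  position x moves markers strictly to its right.
* Internal computation keeps full precision; rounding (1 decimal for cM,
  printed precision for percentages) happens only at presentation, with raw
  values retained in TSV reports.
* Degenerate statistics are flagged, not fudged: expected NPD of zero with
  observed NPDs yields an infinite-ratio undefined result; empty
  adjacent-interval subsets or a zero denominator yield undefined; an empty
  exchange subset after purging warns.
* Permutation p-values use the add-one estimator (hits+1)/(valid+1).
* The pipeline's provenance block (input hashes or the full simulation
  config, seed, version) is sufficient to regenerate a report byte-for-byte.

## Known limitations

Perkins' multi-crossover bias (above) is inherited, not corrected — no
mapping-function or likelihood-based interference fitting is attempted.
Minimal crossover reconstruction undercounts multi-crossover intervals by
construction. The adjacent-interval permutation test conditions on the
observed class margins; with very few crossover tetrads its resolution is
limited. Fold changes are computed from the precision supplied by the
caller and are not forced to match any externally rounded value.
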