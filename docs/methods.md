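# Methods

## Per-column association model

For each alignment column the response is the natural log of adult body
mass. The allele at the column is a categorical factor with one level per
distinct unambiguous base (A/C/G/T) observed among species with
non-missing data; gaps, `N` and IUPAC ambiguity codes remove a species
from that column's model rather than forming an extra level — a gap is
absence of evidence, not an allele. Two models are fitted per column:

* **allele**: `log_mass ~ allele`, tested against the intercept-only
  model;
* **allele+habitat**: `log_mass ~ habitat + allele`, tested against
  `log_mass ~ habitat`.

The test statistic is the partial F of the allele factor,

F = [(RSS_reduced − RSS_full)/q] / [RSS_full/(n − r)],

where q is the number of estimable allele degrees of freedom and r the
rank of the full design. For a biallelic column without covariate this is
exactly one-way ANOVA (and the squared allele-coefficient t-test). Choice
of logarithm base is immaterial: rescaling the response leaves F
invariant, and the natural log is fixed only so coefficients are
reproducible.

Degenerate cases are reported explicitly rather than silently dropped:

* fewer than two allele classes → `monomorphic_skipped`, no p-value;
* allele factor collinear with habitat (zero estimable df) →
  `collinear_skipped`, no p-value;
* zero residual variance with non-zero reduced RSS (perfect fit) →
  p = 0 with `zero_residual`, not a clamped epsilon;
* allele classes of size one are tested but flagged `singleton_class`,
  since real clade-pattern sites can have minority groups of 3–5 species
  and filters must not silently discard them.

The implementation evaluates all columns simultaneously from per-class
sums computed with `bincount`; the class structure is independent of the
trait vector, so re-scanning under a permuted trait table costs a few
vectorized passes. Tests cross-check the statistics column-by-column
against statsmodels OLS `anova_lm` as an independent route.

## Permutation FDR

Mass values are permuted across species — or independently within the
aquatic and terrestrial groups when stratified — leaving habitats, clades
and the alignment untouched, so the set of tested columns is identical in
every permuted scan. For a p-value threshold t,

FDR(t) = mean permuted hit count / observed hit count,

undefined (reported as such, never 0) when there are no observed hits.
Defaults follow the two-runs-of-1,000-permutations design, with each
run's FDR reported separately as a stability check; the runs' RNG streams
are spawned deterministically from the user seed. No additional
multiple-testing correction is applied — the permutation FDR is the
correction.

The FDR estimator is calibrated *conditionally on the observed trait
vector*: under label exchangeability the permuted hit count estimates the
expected null hit count for that dataset. This matters because the
parametric F-test p-values are uniform only on average over trait draws;
for a strongly clade-structured (non-Gaussian) mass vector the parametric
tail is inflated severalfold, which is precisely the situation the
permutation scheme corrects. The test suite checks both facts: marginal
uniformity of p across independent datasets, and per-dataset agreement of
observed null hits with the permutation expectation (ratio within
[0.5, 2]).

## Low-complexity flag

Association hits inside repeat- or gap-rich alignment segments are usually
artifacts of ambiguous homology. A column is flagged when, in a ±10-column
window, the gap fraction exceeds 0.5, or the reference row's ungapped
subsequence has ≤2 distinct bases, or tandem mono-/di-nucleotide repeats
(≥3 unit copies) cover more than 80% of it. The flag is advisory
annotation only — flagged columns stay in every output — because the
boundary between artifact and signal is a judgment the analyst must be
able to revisit.

## Clade-pattern typing

A pattern is a named species bipartition (group A, conventionally the
large-bodied side; group B). A column is assigned the first pattern (in
configuration order) for which both groups are allele-uniform with
different, non-missing alleles; species outside both groups are ignored
(outgroups do not participate in the definition). Missing data inside a
pattern group yields no call plus a `missing-data` note rather than a
guess. The call depends only on the induced partition, never on which
nucleotides realize it.

## Coordinate mapping

Alignment columns are 1-based; genomic coordinates are 1-based inclusive
internally, converted to 0-based half-open only in BED output. The map is
anchored by a user-supplied reference row, anchor coordinate and
orientation (reverse orientation supports genes annotated on the minus
strand, where coordinates decrease as columns increase). Columns where the
reference row is gapped are "unmapped": a site with no reference base has
no defensible single coordinate, so such sites are skipped (with a count)
rather than attached to a neighbor.

## Windowed heterozygosity, ROH and Froh

Genotype calls are depth-filtered once, keeping sites with
mean/3 ≤ depth ≤ 2×mean (boundary-inclusive); the mean is computed on the
unfiltered track and frozen, so the filter is idempotent. Heterozygosity
is n_het/n_called in non-overlapping 1-Mb tiling windows; the final
partial window is kept and flagged, and windows without called sites
report NA rather than 0.

ROH are maximal runs of ≥25 consecutive qualifying 20-kb windows. A
window qualifies when its heterozygosity score is ≤0.025. Two score
definitions are exposed because the windowing tool this stage emulates
does not pin one down:

* `fraction` (default): n_het/n_called in the window;
* `per_kb`: heterozygous sites per kb of window span.

The distinction is consequential: with a background heterozygosity of
~1e-3 per site the `fraction` score of every ordinary window (~0.001) is
far below 0.025, so the entire genome would qualify; the `per_kb` score
(~0.9 against 0.025) separates background from true low-heterozygosity
segments. The end-to-end pipeline therefore defaults to `per_kb`, while
the library function keeps `fraction` as its documented default score
definition. Windows with no called sites do not qualify by default
(absence of calls is not evidence of homozygosity) and break runs; a
configuration flag reverses this.

F<sub>ROH</sub> is the summed length of runs ≥500 kb divided by the
assessed (callable) length; the summary also reports the ratio over all
runs regardless of length, since the appropriate denominator and minimum
length vary between studies. Run lengths are binned
(0.5–1–1.5–2–2.5–3–4–5 Mb and above by default) and the longest run is
reported with its location.

## Pseudodiploid and psmcfa export

The pseudodiploid track intersects two allele-bearing tracks on positions
called in both genomes and, at each shared site, samples one allele
uniformly from each genotype; the site is heterozygous iff the draws
differ. Coalescence between the two source populations is then readable
from the pseudodiploid's PSMC profile. The psmcfa writer emits one
FASTA-like record per scaffold, 60 characters per line, one character per
100-bp bin: `K` if the bin holds ≥1 heterozygous site, `T` if fully
homozygous, `N` if called sites fall below half the bin (the `K` state
takes precedence over `N` — an observed heterozygote is informative
regardless of callability). PSMC run settings (generation time 30.8 yr,
mutation rate 1.58e-8 /bp/generation, t = 15) are recorded in a JSON
sidecar only; PSMC itself is an external program, deliberately not
reimplemented.

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs, not
their biology:

* **Traits**: 29 species (11 aquatic, 18 terrestrial) with clade-mean log
  masses — large baleen whales (ln 50,000 kg), sperm whale (ln 40,000),
  orca (ln 4,500; the largest dolphin, comparable to a minke whale),
  smaller toothed whales (ln 300), and two terrestrial clades (ln 500,
  ln 60) — plus Gaussian noise (sd 0.6 log units). Masses therefore span
  ~50 kg to ~150,000 kg.
* **Alignment**: i.i.d. background columns with a random major allele and
  minor alleles at frequency 0.05 assigned to random species (an option
  assigns them clade-wise to create confounded nulls for probing the
  stratified permutation), gaps at rate 0.02, tandem-repeat
  low-complexity blocks with 5× elevated gap rate, and planted columns
  that realize their clade pattern exactly with no gaps. No sequence
  evolution along a tree is simulated; the scan's null is label
  exchangeability, not a substitution process, so phylogenetic
  autocorrelation of background columns is out of scope and passing tests
  say nothing about tree-aware nulls (e.g. PGLS) on real data.
* **Genotype track**: callable sites as a Bernoulli(0.9) thinning of each
  scaffold, heterozygous at 1e-3 per site (a planted segment's residual
  rate inside ROH), depth negative-binomial with mean 40× and size 3 —
  overdispersed coverage being the realistic stress for the 1/3×–2× depth
  filter. Read errors, mapping artifacts and genotype-caller biases are
  not modelled; the track is truth-level calls.

A single root seed spawns independent substreams for the three
generators, so adding planted sites never perturbs background draws and
changing permutation counts never changes the simulated data. Every
generator returns a truth table alongside its artifact.

## Problem sizes

The shipped tests and the reproduction script run the scan at up to
29 species × 20,000 columns with 2×1,000 permutations, the exhaustive
permutation check at 7 species (5,040 label permutations vs 50,000
sampled), null calibration at 5,000 columns × 200 permutations × 10
seeds, and the popgen stages on 0.8–2-Mb scaffolds — sizes chosen so the
full suite completes in about a minute of compute while every statistical
tolerance (4 binomial SEs, 3 Monte-Carlo SEs) still bites.

## Known limitations

* The scan's null is exchangeability of trait labels; it does not model
  phylogenetic signal in the alleles themselves, so clade-correlated
  background variation inflates hit counts exactly as it would in the
  emulated analysis (the stratified permutation mitigates, not removes,
  this).
* The low-complexity flag is a stated heuristic proxy for manual artifact
  curation, not a reproduction of it.
* Which anchoring (reference row, coordinate, orientation) underlies any
  particular published site table is generally unstated; the column map is
  fully user-parameterized instead of guessing.
* Froh depends on the denominator convention; both assessed-length and
  all-runs ratios are reported, but comparisons across studies still
  require matching conventions.
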