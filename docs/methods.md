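# Methods

## The enrichment screen

The screen treats repurposing as a gene-set overrepresentation problem.
Given a drug–gene interaction network (drug → set of Entrez genes
encoding its targets) and a gene–disease association network (MeSH
disease term → set of associated Entrez genes), each drug–disease pair
is reduced to a 2×2 contingency table over a background gene universe:
`a` genes both targeted and disease-associated, `b` targets only, `c`
disease genes only, `d` neither. Under the null that the two sets are
independent draws from the universe, `a` is hypergeometric with the
margins fixed, and the screen reports the one-sided upper-tail Fisher
exact P — the enrichment direction only, since the scientific hypothesis
is overrepresentation, not avoidance. A two-sided variant is exposed as
a flag for comparison but never used by default.

**Assumptions.** Gene sets are unweighted and curated edges are taken at
face value; evidence strength, direction of effect, and network topology
beyond set membership are all ignored. The hypergeometric null further
assumes exchangeability of universe genes, which real gene panels
violate (study-bias, hub genes); the synthetic generator below satisfies
it by construction, so calibration results on synthetic data bound what
the statistic itself can do, not what curation bias will do to it.

**Universe.** The background universe is the single largest analytic
choice — every P changes with it. Default: the intersection of
drug-target genes and disease-associated genes, i.e. the genes for which
both kinds of evidence exist at all; `gda_all` (every disease gene) and
`union` are available and every report records which mode was used.
With `intersection`, marginal gene sets shrink, tables get smaller and
Ps get more conservative than under `union`.

**Tested family.** Only pairs with overlap `a >= min_overlap` (default 1)
are tested, and the Benjamini–Hochberg family size `m` is exactly the
number of tested pairs. Zero-overlap pairs have P = 1 deterministically;
including them would only inflate `m` and dilute the correction without
adding information. Drugs or diseases whose in-universe gene set is
empty have no defined table and are skipped with a counted warning
rather than assigned P = 1. Significance defaults: q < 0.05 for the
screen-wide call, raw P < 0.001 for per-disease drug rankings; both are
parameters. Ties in rankings break by (P, q, drug_id) so output order is
total and reproducible.

**Numerics.** The upper tail is summed as floats: the leading
hypergeometric term is computed by correctly-rounded big-integer
division (`math.comb` products), subsequent terms by the pmf ratio
recurrence, and the sum by compensated summation (`math.fsum`). Each
term then carries only O(tail length) ulps of error, keeping the tail
accurate to ~1e-13 up to universe sizes of 10^4 (verified against exact
rational enumeration in the tests). When the observed overlap is the
smallest feasible value the tail is the whole support and P is returned
as exactly 1.0. The descriptive odds ratio is the unconditional ad/bc
(+inf when bc = 0 with ad > 0) and never drives ranking. BH is
implemented directly (vectorized step-up with a reverse running
minimum) because the family size may exceed the vector length, a case
the standard library implementations do not expose; the statsmodels
implementation serves as an independent oracle in the test suite.

## Identifier handling and deduplication

Genes are keyed by Entrez ID everywhere; symbols are annotations and
never matched on. Diseases are keyed by MeSH ID, with case-insensitive
name fallback only for rows that lack an ID. Duplicate edges — the same
(drug, gene) or (gene, disease) pair reported by multiple source
databases — are collapsed after canonicalization, with the source column
deliberately excluded from edge identity. Ingestion rejects malformed
rows with a counted warning by default (large heterogeneous exports
should load), and a strict mode turns rejections into errors. Row
accounting satisfies `kept + duplicates + rejected == raw` and is
asserted in tests. Writers sort rows by key so write→read→write is
byte-stable.

## Benchmark evaluation

Screen scores (−log10 P; untested pairs score 0, their natural floor)
are evaluated against a labelled benchmark by ROC/AUC, computed by a
threshold sweep over distinct scores with trapezoidal area — equal to
the tie-corrected Mann–Whitney probability that a random positive
outscores a random negative, with half credit for ties. Because the
screen has no trainable parameters, 5-fold cross-validation here
quantifies score stability across benchmark subsets rather than
generalization of a fitted model: folds are stratified to preserve the
class ratio, each held-out fold is scored with the same fixed screen,
and the full-set AUC is reported alongside the per-fold mean. Negative
pairs, when the benchmark supplies none, are sampled uniformly from
non-positive drug–disease pairs at a 1:1 ratio by default (a
`drug_matched` strategy that matches each positive drug's count is
available); strategy, ratio and seed are recorded in the report, since
real benchmarks rarely document their negatives and the choice moves
the AUC.

## The synthetic network generator

`generate` emulates the structure of real exports: an Entrez-like gene
pool, drugs with fixed-size target sets drawn uniformly without
replacement, diseases with fixed-size gene sets drawn the same way, and
`n_planted` drug–disease pairs whose drugs draw
`ceil(fraction * n_targets)` of their targets from their disease's gene
set. Planted pairs are therefore overlap-enriched with a controlled,
known strength, and `n_planted = 0` yields an exactly exchangeable null.
Default conditions (5,000 genes; 500 drugs × 10 targets; 50 diseases ×
100 genes; 50 planted pairs at fraction 0.8) are the package's standard
benchmark scenario; the null-calibration scenario uses the unplanted
version of the same family at 200 drugs × 20 diseases × 2,000 genes,
50 replicates, sizes chosen so a full calibration run stays in the tens
of seconds. All randomness flows through one numpy PCG64 generator
seeded from the config (the algorithm name is pinned in the config
metadata), identifiers are zero-padded (`DRUG0001`, `MESH:D0001`) so the
real-data readers parse fixtures unchanged, and emitted fixtures are
byte-identical across runs of the same seed.

What the generator does *not* emulate: real degree distributions
(hub drugs like kinase inhibitors, hub genes like TP53), correlated
gene panels across related diseases, curation and study bias, or
identifier noise. Passing calibration and recovery tests on this
generator therefore demonstrates correctness of the statistical
machinery under its own null, not robustness to the biases of curated
databases.

## Median-effect and combination-index analysis

Single-agent dose–response series (dose, fraction affected) are fitted
to the median-effect model fa/fu = (D/Dm)^m by ordinary least squares on
the log-linearization log(fa/fu) = m·log D − m·log Dm; `m` is the slope,
`Dm` (the IC50, in the dose units supplied) solves the intercept, and
`r` is the correlation of the line. fa values of exactly 0 or 1 are
log-infinite and excluded with a warning; fewer than 3 usable points
warns, fewer than 2 — or zero dose spread, or a flat response — is an
error. A viability-to-fa converter (fa = 1 − v/control, clipped with
warning) covers assays reported as viability.

Combination analysis uses the two-term, mutually exclusive form
CI = d1/Dx1(fa) + d2/Dx2(fa), the standard output for fixed-ratio
combinations; the verdict rule is the strict CI < 1 synergism / = 1
additive / > 1 antagonism, with an optional tolerance band for noisy
data (default 0). Fa–CI curves split each observed total combination
dose by the fixed ratio and evaluate CI at the observed effect level; a
zero ratio component degenerates gracefully to the single-agent CI.
CI is invariant to consistent rescaling of one drug's dose units
(its Dm and its combination dose scale together), which is tested.

Two generators support validation: `simulate_dose_response` (forward
model plus optional multiplicative Gaussian noise on fa, clipped inside
the open unit interval) and `simulate_combination`, which constructs a
fixed-ratio combination series whose true CI equals a requested potency
factor at every effect level by inverting Loewe additivity analytically
— giving exact ground truth for Fa–CI round trips. The companion
`design_doses` helper produces the serial-dilution design used in the
recovery studies: doses geometrically spaced so model effects span
fa 0.1–0.9 symmetrically around Dm. This is the standard bench design —
points on the saturation plateaus carry no information about Dm and, at
high sigmoidicity, turn small multiplicative fa noise into unbounded
logit noise.

## Determinism

Every stochastic component (generator, negative sampling, fold
assignment, noise injection) takes an explicit seed; the screen itself
is a pure function of its inputs. CLI outputs contain no timestamps,
sort all rows by key, format P/q at 6 significant digits in scientific
notation, and carry a `run.json` with tool version, resolved parameters
and their hash — so identical configuration yields byte-identical
output trees, which the test suite asserts end-to-end.

## Known limitations

- Set-overlap scoring ignores edge weights, mechanism, and network
  proximity; two drugs with identical target sets are indistinguishable.
- The universe choice is consequential and the right answer is
  data-dependent; the default is the most conservative of the three
  modes but is still a convention.
- Benchmark AUC depends strongly on how negatives are chosen; reported
  AUCs are comparable only within a fixed negative-sampling protocol.
- The median-effect fit is a 2-parameter model; multiphasic or
  incomplete-kill dose responses need a richer model (deliberately out
  of scope) and will show r well below 1.
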