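# Methods

`polyfrac` implements a comparative analysis of duplicate-gene loss
("fractionation") after an ancient whole-genome multiplication, in three
layers: reconstruction of homology sets from pairwise syntenic homology
calls, regression of Gene Ontology category representation against
fractionation score, and a two-class maximum-likelihood model of paralog
retention fitted to per-species pair/triple counts. This note records the
models, the defaults that matter, the numerical choices, and the known
limitations.

## Homology sets and fractionation score

Input is an edge list of pairwise homology calls — orthologs between
genomes, paralogs within a genome — as produced by synteny mapping (e.g.
SynMap/DAGChainer exports), plus a gene→genome table. A *homology set* is a
connected component of the undirected gene graph: the simplest reading of
"genes sharing orthologies and paralogies are grouped together". Stricter
merge rules (e.g. requiring synteny-block agreement) could be layered on
later; components are the baseline.

* Genes with no incident edge cannot be placed and are reported in a side
  listing rather than silently dropped.
* The *fractionation score* of a set is the number of genomes holding more
  than one copy (2, 3 or more all count the same); it ranges from 0 to the
  number of genomes in the group.
* Completeness labels (`full`, `missing_one`, `missing_two`, `reject`)
  partition the sets; the clade-constrained filter keeps missing-two sets
  whose two absentees fall in different named clades (the
  Panicoideae-vs-BEP design for grasses).
* Components are ordered by smallest member gene id, so runs are
  byte-reproducible.
* Tandem-array contamination is not filtered by default; a
  `max_copies_per_genome` cap is available but off, because deciding a
  principled cap requires positional data the package does not consume.

## Ontology handling

The OBO 1.2 file is parsed with `obonet`. Propagation uses `is_a` edges
only by default; `part_of` can be enabled and is then restricted to
same-namespace pairs so ancestor closure never crosses the three root
namespaces. Obsolete terms are dropped (not remapped) with a logged count.
A set's annotation is the union of its member genes' terms plus all
ancestors, presence/absence only — multiplicity within a set is
deliberately ignored, so a term hit by one gene or by five genes of the
same set counts once. "High-level terms" are the direct children of the
three namespace roots; their number is a property of the ontology release
and is never asserted.

## Trend regression

For term *t* in namespace *X* at score *s*, the normalised proportion is

    hits(t, s) / |{sets with score s hitting >= 1 term of X}|

The denominator corrects for the fact that high-score sets contain more
genes and therefore hit more terms of every kind. The per-term trend is an
ordinary least-squares regression of the binary set-level indicator of *t*
on score, over all sets hitting at least one term of *X* (the same
population as the denominator — the natural choice, though not forced by
the analysis definition). The slope's two-sided t-test at α = 0.05 yields
the call: significantly negative → fractionation-prone, significantly
positive → fractionation-resistant, else neutral. A linear probability
model is used rather than logistic regression because the trend statistic
is defined as a slope of proportions; the t-test is the standard OLS one
(`scipy.stats.linregress`, numerically identical to `statsmodels` OLS).
No multiple-testing correction is applied by default; a
Benjamini–Hochberg option exists (`fit(correction="bh")`).

Cross-group consistency compares independently fitted groups: a term is
*consistent* when significant in at least one group with all groups
agreeing on slope sign, *conflicting* when significant in opposite
directions in two groups, else *unclassified* (a term absent from any
group is unclassified). The background comparison treats each background
gene as a one-member set (annotated and closed identically) and tests each
term's namespace-normalised proportion difference with a two-proportion
z-test.

## Two-class retention model

Each of N ancestral genes is triplicated; a copy survives a shared
pre-speciation phase with probability 1−p and then phase 2 in species *i*
with probability 1−q_i. The surviving copy number in species *i* is
therefore Binomial(3, s_i) with s_i = (1−p)(1−q_i). Genes split into two
classes: a fraction θ with rates (p, q_i) and 1−θ with (αp, αq_i). The
labelling convention α ≤ 1 makes the θ class the faster, fractionation-
prone one; together with box constraints on [0, 1] this also keeps αp and
αq_i in range.

**Likelihood.** Only pairs (n2) and triples (n3) are observed per species;
single-copy and extinct families are indistinguishable in the data and are
pooled into a remainder category of size N − n2 − n3. The likelihood is
the product over species of the multinomial mass of (n3, n2, remainder)
under the mixture category probabilities (θ·P + (1−θ)·P′). Species are
multiplied as if independent even though the shared phase 1 correlates
them; the per-species marginals are unaffected, and the simulation study
below confirms the fitted parameters are insensitive to this idealisation
(the generator offers both a shared-phase and an independent-phase mode).

**Fitting.** Bounded L-BFGS-B from 32 Latin-hypercube multistarts
(seeded; `ftol` 1e-12), keeping the best converged optimum; all starts'
log-likelihoods are returned so the shape of the surface is visible.
Standard errors come from the numerically differenced observed information
and are reported as missing when the Hessian is not invertible in a
direction (common here, see below).

**Weak identification.** The category probabilities depend on the
parameters only through the per-class survival products s_i and s′_i, so
the surface carries a long, nearly flat ridge in (θ, α): very different
mixture structures reproduce the observed counts almost equally well, and
on the six-rosid counts the optimum puts one q_i on the boundary. Point
estimates of θ and α should therefore be read together with the
multistart table and the profile over N (`profile_over_n`), and simulation
replicates of the full pipeline show correspondingly wide per-replicate
spread around the truth. This is a property of the data design (two
observed categories per species), not of the optimiser.

**Score prediction.** For each class, conditioning on survival (≥ 1 copy)
in every genome of a subset — as full homology sets do — genome *i* is
multi-copy with probability (P3+P2)/(P3+P2+P1); the fractionation-score
distribution is the Poisson-binomial over those indicators, and expected
gene counts scale by N, the class share and the all-genomes survival
probability. The per-score relative weight of the two classes gives the
predicted retention-pattern curves.

## Synthetic data

The generator draws the class per ancestral gene (θ), triplicates, applies
the shared phase-1 loss once per copy and phase-2 loss per species, then
emits the gene table, the all-pairs ortholog/paralog edges within each
surviving set, a toy three-root ontology (regular tree, configurable depth
and branching, deterministic term ids), biased annotations and the
realized pair/triple counts, all keyed to a mandatory seed (same seed →
byte-identical files). Defaults used across the test suite: loss rates of
the magnitude the retention fit itself estimates (p ≈ 0.3–0.4,
q_i ≈ 0.4–0.7, θ = 0.6–0.7, α = 0.5–0.6); recovery studies use N = 20000
ancestral genes and 10 replicates, sizes at which the Monte-Carlo error of
the mean is small while a full study still runs in minutes on one CPU.

Annotation bias is drawn **once per ancestral gene** and shared by all its
descendant copies, so a term's set-level presence probability equals the
configured per-class bias exactly. Drawing per individual gene would make
presence probability grow with set size and hence with score, which would
confound planted-trend experiments with the multiplicity artifact the
normalisation exists to remove.

What the generator does not emulate: gene movement, tandem duplication,
lineage-specific family expansion, real GO topology and annotation noise
(an optional uniform false-annotation rate exists for robustness checks).
Passing tests on synthetic data therefore validate the machinery and the
statistical properties of the estimators, not biological conclusions about
any real genome group.

## Numerical conventions and degenerate inputs

* All stochastic procedures take explicit integer seeds; outputs are pure
  functions of inputs + seed (checksummed in the pipeline report).
* A constant presence indicator yields slope 0 / p-value 1 (neutral)
  rather than a 0/0 t-statistic; a single distinct score value raises a
  degenerate-design error.
* Zero normalisation denominators mark the trend point undefined rather
  than returning 0.
* The retention likelihood returns −∞ when a category with positive count
  has probability 0; the multinomial constants are included so reported
  log-likelihoods are absolute.
* `RetentionModel` requires N at least the largest per-species n2 + n3;
  score prediction raises when a genome's total survival probability is 0
  (conditioning undefined).

## Known limitations

* Homology-set construction trusts the input edges; conflicting synteny
  blocks merge components (no block-consistency check).
* The linear probability model can fit proportions outside [0, 1] at
  extreme scores; calls rest on the slope sign, not on predicted values.
* The two-class retention fit is weakly identified (see above): the
  reported θ/α point estimate is one point on a flat likelihood ridge, and
  honest uncertainty on the mixture structure is large at realistic counts.
* Evidence codes in GAF input are ignored; all annotations count equally.
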