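# Methods

This note records the models, numerical choices, and design decisions
behind `phylosignal`, and what the synthetic-data experiments do and do not
demonstrate.

## The question being modelled

Given a concatenated multi-locus alignment, monophyly constraints on a
handful of major clades, and (optionally) a discrete morphological matrix,
the package measures how much evidence the data carry about the *deep*
arrangement of those clades. The deep arrangement is isolated from
everything else by construction: all candidate topologies share one frozen
within-clade resolution and differ only in the rooted backbone joining the
clades. Every statistic downstream — likelihood ranking, AU confidence set,
gene-wise ΔGLS, parsimony tree length — compares these candidates.

## Supermatrix handling

Loci are concatenated in input order; the taxon set is the union over loci,
with taxa absent from a locus filled with `?`. Taxa are ordered
lexicographically for determinism. Occupancy of a locus is the fraction of
taxa with at least one non-missing character in it; both `-` and `?` count
as missing, IUPAC ambiguity codes count as present. Column trimming removes
a site when its missing fraction strictly exceeds the threshold (default
0.5), so a column exactly half missing survives; trimming is idempotent and
the partition scheme is remapped to the surviving columns, dropping (with a
warning) any locus that loses all of its sites. Trimming is applied to the
concatenated matrix; a per-locus flag exists but with a global
missing-fraction criterion the two modes coincide.

## Backbone enumeration and constrained candidates

Rooted binary topologies on k clade labels are generated by recursive leaf
insertion (each of the 2i−1 nodes of an i-leaf rooted tree is an insertion
point), giving (2k−3)!! shapes — 3, 15, 105, 945 for k = 3…6 — verified by
canonical-form hashing (children sorted recursively). Enumeration is over
*rooted* shapes with the outgroup attached at the root: 15 patterns for
four clades corresponds to the rooted reading.

Within each clade, a subtree is built once by neighbor joining
(scikit-bio) on Jukes–Cantor-corrected distances computed from the
supermatrix restricted to the clade; pairs with no overlapping data or
saturated divergence are capped at 5 substitutions/site so NJ stays
defined. The NJ tree is midpoint-rooted (deterministic); negative NJ branch
lengths are clamped to zero. This frozen resolution is reused across all
backbones — a deliberate desk-scale substitute for per-backbone constrained
heuristic searches. It isolates backbone signal; branch lengths are still
re-optimized per backbone, so the approximation costs little when
within-clade structure is uncontroversial, and is documented rather than
hidden when it is not.

## Likelihood model

Substitution models are JC, HKY, or GTR (default GTR), with stationary
frequencies taken as empirical counts (with a 0.5 pseudo-count) and the
generator normalized to one expected substitution per site. Rate
heterogeneity uses Yang's discrete gamma: n equal-probability categories
(default 4), category rates equal to within-bin means of Gamma(α, α), hence
mean 1. Transition probabilities come from the symmetric eigendecomposition
of diag(√π) Q diag(1/√π).

Per-site log-likelihoods use Felsenstein pruning over unique site patterns
with per-node rescaling and log accumulators; ambiguity codes and missing
cells contribute partial likelihood 1 over their compatible states. The
pruning implementation is checked against an independent oracle (exhaustive
summation over internal-state assignments, transition matrices from
scipy's `expm`) to 1e−10 relative error.

Branch lengths are optimized coordinate-wise: for each branch, upper and
lower conditional likelihoods are cached so the one-dimensional bounded
Brent search touches only a single 4×4 transition matrix per evaluation;
rounds repeat until the total log-likelihood gain falls below `tol`
(default 1e−6 for the standalone optimizer, 1e−4 inside partitioned fits)
or a round cap is reached (warning, best-so-far returned). The total
log-likelihood never decreases.

Partitioned fits use one proportional branch-length set per candidate with
per-partition rate multipliers (site-weighted mean 1 for identifiability),
rather than fully unlinked branch lengths — the smallest defensible
partitioned scheme at this scale. Model parameters (exchangeabilities,
frequencies, gamma shape, multipliers) are estimated once per partition on
the first candidate topology and then held fixed across candidates, so
site-likelihood differences between candidates are attributable to topology
alone. Parameter estimation alternates branch-length rounds with
Nelder–Mead over log-parameters. Model selection is out of scope; the
family is a configuration switch.

## Topology tests

RELL replicates resample site log-likelihoods: a replicate at scale r draws
round(r·n) sites with replacement (implemented as uniform index draws
accumulated by bincount, distributionally identical to multinomial
weights) and sums each candidate's weighted site lnL; the winner is the
argmax, with exact ties broken uniformly at random under the replicate
stream. Everything is seeded; identical seeds give identical tables.

The AU test records bootstrap proportions bp(r) at ten scales
r ∈ {0.5, …, 1.4} (CONSEL's defaults) and fits
bp(r) = Φ(−(d·√r + c/√r)). The fit is by maximum likelihood on the
binomial replicate counts (Newton/BFGS), initialized at the closed-form
weighted-least-squares estimate on the probit scale (weights from the
binomial variance via the delta method); the two estimators agree closely
in practice, and the likelihood fit is the more stable when bp sits near
0.5 at every scale. Degenerate proportions (0 or 1) receive the continuity
correction 1/(2·n_reps); scales at which every candidate is degenerate are
dropped; a candidate degenerate at all scales has its p-value clamped to 0
or 1 with a warning. p_AU = 1 − Φ(d − c). The one-sided KH p-value per
candidate comes from the same scale-1 replicates by centering the replicate
log-likelihood difference against the ML candidate (the ML candidate is
tested against the runner-up), and is cross-checked against the direct
normal approximation. The confidence set at level α contains every
candidate with p_AU ≥ α, plus the ML tree unconditionally.

### AU calibration experiment

The type-I-error simulation generates data at the *least-favourable null*:
the star tree, i.e. candidate A with its discriminating internal branch
collapsed to zero, so both NNI alternatives explain the data equally well
and a calibrated test rejects at its nominal level. The two candidates are
fixed quartet trees (pendants 0.25, internals 0.05 substitutions/site,
JC, 500 sites, 2000 replicates per scale). Moderate divergence matters:
it keeps a worthwhile fraction of sites informative, which is what the
multiscale-bootstrap asymptotics require. At much shorter branches
(pendants ~0.1) the effective number of informative sites is so small that
the AU test shows its known finite-sample over-rejection; and conversely,
when candidate branch lengths are free to collapse to zero during fitting,
the two hypothesis regions overlap at the star tree and the test becomes
strongly conservative. Neither regime says anything is wrong with the
machinery — they map the test's behavior away from its asymptotic regime.

## Gene-wise ΔGLS

Per-locus log-likelihoods are sums of site lnL over the locus's columns,
taken from a single partitioned fit so both topologies share model
parameters. ΔGLS = lnL_g(T1) − lnL_g(T2); a locus is uninformative when
|ΔGLS| < 2 (strictly — the boundary value counts as informative), favoring
T1 when ΔGLS ≥ 2 and T2 when ΔGLS ≤ −2. Σ ΔGLS equals the total
log-likelihood difference exactly (conservation), swapping the topologies
negates every record, and raising the threshold never decreases the
uninformative count. The default comparison pair in the pipeline is the ML
backbone versus the runner-up, overridable.

## Morphological parsimony

Fitch lengths treat all characters as unordered with unit cost; `?` and
`-` are fully ambiguous state sets and never force a step. The bottom-up
pass runs over all characters at once with bitmask state sets and is
verified exactly against a Sankoff dynamic program and brute-force
minimization over internal states. Multifurcating trees are rejected
rather than silently resolved. Constrained refinement starts from the
backbone-grafted tree and accepts nearest-neighbor interchanges only when
they shorten the tree and keep every clade monophyletic and the induced
backbone unchanged; move order is seeded, so results are reproducible. NNI
(not SPR/TBR) is the move set — a desk-scale choice; reported lengths are
local optima.

## Synthetic data

Trees are Yule (pure birth, unit rate) via dendropy, run past the n-th
split by the Exp(n) waiting time so tip branches are strictly positive,
relabeled in shuffled order so labeled shapes are exchangeable, and
rescaled so branch lengths read as expected substitutions per site.
Sequences evolve site-i.i.d. down the tree with category rates drawn
uniformly per site. Gene sets draw each locus's topology as Bernoulli
(prop_tree1), its length from a configured range, and impose occupancy by
masking whole taxa (mirroring how small-dataset loci are missing for whole
taxa, not random cells) until the realized fraction falls in the
configured range; masked taxa stay in the matrix as all-`?` rows so all
loci share one namespace. Mk-model morphology uses the closed-form
k-state transition probability. Everything is byte-reproducible from the
configuration seed.

Default study conditions emulate a small four-clade problem: ~14–28 taxa,
occupancy 0.25–0.96, short deep branches (`backbone_branch` 0.02
substitutions/site in the bundled fixture) against moderate within-clade
divergence. The generator does not simulate indels, alignment error, codon
structure, or among-lineage rate heterogeneity beyond what the tree's
branch lengths encode — so passing tests demonstrate correctness of the
machinery and qualitative behavior (signal recovery, calibration), not
robustness to real-data pathologies.

## Problem sizes in the test and reproduction runs

The experiments are sized for a single CPU: the AU calibration uses 300
simulations × 500 sites × 2000 replicates/scale; the ΔGLS recovery uses
200 loci × 500 sites on six taxa; the likelihood oracle uses ≤6-taxon,
≤4-category instances (exhaustive summation grows as 4^internal); the
parsimony oracle uses 200 random ≤6-taxon instances; the end-to-end
fixture uses 4 clades × 3 taxa + 2 outgroup taxa, 8 loci, JC. These sizes
give stable statistics while keeping a full run in minutes.

## Known limitations

- Within-clade NJ freezing can misresolve clades with very little data;
  the affected candidates remain comparable to each other but absolute
  likelihoods suffer.
- The proportional branch-length scheme with per-partition multipliers
  underfits strongly heterotachous data relative to unlinked lengths.
- The AU fit inherits the multiscale bootstrap's finite-sample behavior;
  with nearly information-free alignments its p-values are approximate
  (see the calibration section).
- Parsimony refinement is NNI-local; lengths can exceed the global
  constrained optimum on rugged landscapes.
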