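# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `sycodiv`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Distances and delimitation

Pairwise distances use the Kimura 2-parameter correction with **pairwise
deletion**: a column contributes to a pair only when both sequences carry an
unambiguous base (A/C/G/T). Complete deletion would discard most columns in
markers with indels (ITS2) or failed stretches (COI), so it is not offered.
Inputs are upper-cased, U is mapped to T, and any IUPAC ambiguity code other
than N is rejected — the K2P counts are defined over unambiguous bases only,
and N/gap handling is the job of pairwise deletion, not of the parser.
When the logarithm argument `(1 - 2P - Q) sqrt(1 - 2Q)` is non-positive the
pair is *saturated*: the entry is flagged undefined (NaN), excluded from
summaries with an explicit count, and never imputed.

The primary species partition is single-linkage clustering on COI at a 3%
K2P cut-off ("has at least one conspecific within 3%"), split by region —
species identity across regions is a delimitation outcome, not a name
match. Two additional criteria are reported as flags but do not override
the partition:

- the empirical-threshold rule: the 97.5th percentile of the pooled
  intraspecific distance distribution, used as an alternative conspecificity
  bound (the distribution-based reading of a "95% interval of intraspecific
  distances"); when the fixed 3% rule and this rule disagree, both flags are
  visible and the 3% rule decides;
- per-marker monophyly on neighbor-joining trees built within each genus.
  Monophyly on an unrooted tree is defined as bipartition membership (no
  outgroup exists within a genus alignment); singleton sets, their
  complements and the full tip set are trivially monophyletic.

NJ is delegated to scikit-bio; negative branch-length estimates are clamped
to zero (scikit-bio's behaviour) rather than redistributed to the sibling
branch. On additive matrices no negative estimates arise, so the
exact-recovery property is unaffected; on real data the difference only
perturbs branch lengths, never the bipartitions used for monophyly.

Marker incongruence is resolved in favour of COI: an individual whose ITS2
cluster-mates all belong to a different COI species keeps its COI
assignment and is listed as a conflict. Individuals without COI are
attached to the species their ITS2 cluster anchors to; a whole ITS2 cluster
with no COI anchor becomes a hypothesis flagged *possible extra species*,
counted separately (reported as a richness range, never silently merged).
Single-individual species are flagged low-confidence.

The MOTU sweep runs single-linkage clustering (edge iff d <= cutoff,
components via scipy's csgraph) over a default grid of 0-10% in 0.25%
steps. The barcoding gap is the longest run of consecutive cut-offs with a
constant MOTU count, excluding the terminal single-cluster plateau, ties
broken toward the lower cut-off; a profile with no such run >= 2 grid
points is a distinguished no-gap result.

## Co-divergence machinery

The simulator is a standard two-population isolation coalescent. Time is
measured in per-lineage expected substitutions per site, so a divergence of
`tau` pairwise substitutions/site is a split at depth `tau/2`; lineage pairs
within a population of parameter theta coalesce at rate `2/theta`, giving
E[pi_within] = theta and E[pi_between] = tau + theta_ancestral. Mutations
are a Poisson process on branches with Jukes-Cantor replacement on discrete
sites, so multiple hits and back-mutations occur naturally at finite length.
Jukes-Cantor (rather than HKY) is a documented simplification: observed and
simulated data pass through the identical kernel, so the ABC comparison is
internally consistent, and at the divergences of interest (< 0.35
substitutions/site) the model-choice and recovery behaviour is insensitive
to the transition/transversion ratio. The kernel is numba-compiled
(~10 us per pair simulation) and seeded per draw, so results are
independent of batch size and fully reproducible from one master seed.

Prior scenarios named "two, four, six divergences" are interpreted as the
**prior mean of Psi**, the number of distinct divergence events among the
pairs. Event assignments follow a Dirichlet-process (Chinese-restaurant)
partition; the concentration alpha is Gamma(shape 2, scale) distributed,
and the scale is solved numerically (quadrature + Brent) so that the
marginal E[Psi] equals the scenario target. A target equal to the number
of pairs is reachable only asymptotically, so it is capped at n - 0.05 —
inside the +/-0.2 Monte-Carlo band the prior tests use. Event times are
Uniform(0, tau_max) with tau_max = 0.35 (about 18 Ma at 1.9%/Myr, spanning
the plausible 4-16.5 Ma range); thetas are Uniform(~0, 0.02) per population
(three per pair: two descendants and the ancestor). Both bounds are
configurable.

Summary statistics per pair are {pi_between, pi_within per side, Watterson
theta_W per side, pi_net = pi_b - mean(pi_w)} — each testable in closed
form. Rejection uses Euclidean distance on statistics standardized by the
*simulated pool's* mean and SD (the observation is a single vector and
cannot define a scale); zero-variance statistics are dropped with a
warning. `keep_fraction` of the closest draws form the posterior.

Guild hypotheses are constraints on the event structure: SYNC(S) holds when
all pairs in S share one event index; BEFORE(S1, S2) is **strict
dominance** — every member of S1 older than every member of S2 (tau
strictly greater). The weakest reading ("mean older") cannot produce
near-zero posterior probabilities for staggered models, so strictness is
declared as this package's definition. Pollinators count among the galling
(and small-galling) species in the model sets: they gall fig flowers
exactly as the non-pollinating small gallers do, and three of the nine
models specifically separate pollinators from other guilds.

Bayes factors are posterior odds over prior odds, with the conventional
2 ln(BF) bands (2-5 positive, 5-10 strong, >10 very strong). A zero prior
probability with posterior support is reported as infinite; a zero
posterior gives BF = 0 with a -inf flag. Posterior divergence time is the
across-pair mean tau per retained draw, converted to Ma by `t = tau / rate`
— the clock is quoted as *pairwise* divergence per Myr, so there is no
division by two.

No post-rejection regression adjustment is applied, and scenarios are not
model-averaged; the printed prior probabilities of the original ABC tool
depend on its internal prior construction and only their ordering across
scenarios is expected to reproduce.

## Dating

Split time is `t = d / r` with r = 0.019 pairwise/Myr by default. The
default correction is **net-between** (mean between-group K2P minus mean
within-group K2P): raw between-group distance overestimates the split by
the ancestral polymorphism theta_anc, which for a 5 Ma split at theta =
0.005 is a ~5% upward bias. Raw mode is retained and both are reported,
since the quoted clock is a raw pairwise rate. Uncertainty is a 95%
percentile interval from resampling alignment columns with replacement
(n_boot >= 100, default 1000); saturated replicates are dropped and
counted, with a warning above 10%. The site bootstrap captures mutational
and site-sampling noise but not genealogical (coalescent) noise; at the
sample sizes used the former dominates. Percentile bootstrap intervals
stand in for Bayesian HPD intervals by design.

## Synthetic communities

The generator's default (`CommunityConfig.study_system()`) mirrors the study
system: nine genera in five guilds (pollinator Eupristina; small galler
Walkerella; small parasitoids Philotrypesis, Sycoscapter, Sycorycteridea;
large gallers Sycobia, Acophila; large parasitoids Sycophila, Ormyrus),
14 species per region with Acophila and Ormyrus only in CN and
Sycorycteridea only in AUS, one intercontinental sister pair in each of the
six shared genera, COI standardised to 394 bp, four individuals per
species, theta = 0.005, sister divergence 5.2 Ma under the 1.9%/Myr clock,
and 10% of samples missing one marker at random. ITS2 is simulated at 0.3x
the COI rate, constant 400 bp, without indels — ITS2 serves only the
congruence/monophyly criteria, so indel realism buys nothing for the
validation surface.

Within a genus the sister pair sits at the shallow end of a caterpillar
backbone; every extra (non-sister) species joins at a strictly deeper time,
staggered 3 Myr apart from a 10 Ma base. Distinct join times make
nearest-neighbour structure deterministic: each sister pair is mutually
nearest by construction, and no extra species can tie its way into a
spurious cross-continental mutual pair. Extra species are single
populations anchored to their backbone node (a stem branch joins the
species MRCA to its attachment depth).

What the generator does *not* emulate: sequencing error, alignment error,
indels, recombination, selection, rate variation among lineages, and
population structure within species. Passing recovery tests therefore
demonstrates correctness of the inference chain under its own model
assumptions, not robustness to those real-data complications.

With theta = 0.005 the intraspecific coalescent tail occasionally crosses
the 3% cut-off (a pairwise distance exceeds 3% with probability ~e^-6 per
pair), so exact-recovery properties are stated *conditionally on a >= 3x
intra/inter separation*; the recovery tests generate under theta = 0.002,
where that condition holds essentially always, and verify it explicitly
per replicate rather than assuming it.

## Problem sizes and determinism

Test and validation runs use six pairs, four sequences per side, 394 bp,
20 000 prior simulations with 1% acceptance for model choice (10 000 for
time recovery), 500-replicate bootstrap/Monte-Carlo checks, and 20 seeded
replicates for recovery rates — sizes at which the full suite completes in
a few minutes while leaving Monte-Carlo margins well clear of the asserted
thresholds. All randomness flows from explicit integer seeds: the
coalescent kernel is seeded per draw, the ABC derives per-draw streams from
one master seed, and the community generator writes byte-identical files
under a fixed seed.

## Scoring against truth

`truth_check` scores a delimitation by pair-counting: precision is the
fraction of co-clustered sample pairs that are truly conspecific, recall
the fraction of truly conspecific pairs that are co-clustered. Splitting a
true species lowers recall only; lumping lowers precision only; an empty
output has undefined precision (flagged None) and zero recall.
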