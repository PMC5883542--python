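# sycodiv

Community-level molecular ecology of fig-wasp assemblages on a shared host
fig: two-marker DNA-barcode species delimitation, hierarchical ABC testing of
simultaneous versus guild-staggered intercontinental divergence, strict-clock
split dating, and genus x region x guild community comparison.

The package is aimed at researchers comparing insect communities sampled at
the range edges of a widespread host plant (here: the chalcid wasps of
*Ficus benjamina* in Hainan, China and Queensland, Australia). It answers
three questions end to end: *how many species are in each community and are
any shared?*, *did the intercontinental splits happen together or staggered
by ecological guild?*, and *when did they happen?* A synthetic-data module
generates complete two-region communities with known truth so every stage
can be validated without any sequence download.

## Methods at a glance

**Species delimitation.** Pairwise distances use the Kimura 2-parameter
model, `d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]`, with P and Q the transition
and transversion proportions over pairwise-complete columns (gaps and N are
pairwise-deleted). Species are single-linkage clusters on COI at the
standard 3% cut-off, cross-checked per marker for monophyly on
neighbor-joining trees and against the empirical 95%-interval threshold of
pooled intraspecific distances. A MOTU sweep over a 0-10% cut-off grid
locates the barcoding gap as the longest plateau in cluster counts.
Intercontinental sister species are mutual nearest neighbours from
different regions within a genus.

**Co-divergence (hABC).** Six sister pairs share a hyperprior on the number
of divergence events Psi: pair-to-event assignments follow a
Dirichlet-process partition whose concentration alpha ~ Gamma(shape 2,
scale), with the scale calibrated so E[Psi] matches a prior scenario target
(two, four or six events). Each draw (tau per event, theta per population)
is pushed through a two-population isolation coalescent with Jukes-Cantor
mutation; rejection on standardized summary statistics (pi_b, per-side pi_w
and Watterson's theta_W, pi_net) yields the posterior. Nine guild-timing
hypotheses (SYNC / BEFORE constraints) are compared by Bayes factors,
`BF = [p/(1-p)] / [q/(1-q)]`, on the 2 ln(BF) scale (2-5 positive, >5
strong, >10 very strong evidence).

**Dating.** A strict clock of 1.9% *pairwise* divergence per Myr converts
between-species K2P to split times, `t = d / r`, with ancestral
polymorphism removed in the default net mode (`d_net = d_between -
d_within`) and a 95% site-bootstrap percentile interval.

## Worked example

Run the whole pipeline on a study-structured synthetic community (nine
genera, five guilds, 14+14 species, six sister-pair genera diverging at
5.2 Ma, 10% of samples missing one marker):

```bash
sycodiv all --outdir demo --seed 42 --n-sims 20000
```

Delimitation (`demo/delimitation_report.json`, `demo/species.tsv`) finds 14
AUS + 15 CN primary species plus 3 flagged "possible extra" species
(ITS2-only clades and singletons created by the missing-marker process —
the same ambiguity classes the two-marker criteria are designed to
surface), with a barcoding-gap plateau at 28 MOTUs spanning 4.25-8% K2P.

The guild-model comparison (`demo/guild_models.tsv`, two-event prior
scenario, 20 000 simulations) correctly favours a single community-wide
divergence:

```
model                        posterior   prior     BF
all_synchronised                 0.540   0.372   1.98
gallers_before_parasitoids       0.005   0.009   0.54
small_before_large               0.005   0.012   0.42
large_all_synchronised           0.760   0.639   1.79
...
mean divergence 5.72 +/- 1.71 Ma        (generating truth: 5.2 Ma)
```

Strict-clock dating (`demo/split_times.tsv`, net mode, 95% bootstrap CI)
brackets the generating 5.2 Ma for every pair, e.g.:

```
pair_id        t_Ma_net  ci_low  ci_high
Eupristina         4.45    2.84     6.03
Philotrypesis      5.29    3.57     7.22
Walkerella         5.40    3.92     7.08
```

and the composition comparison (`demo/composition_comparison.json`) reports
six shared genera, CN-only {Acophila, Ormyrus}, AUS-only {Sycorycteridea},
zero shared species and all five guilds present in both regions.

Each stage is also callable as a library function; see the module
docstrings under `src/sycodiv/`.

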