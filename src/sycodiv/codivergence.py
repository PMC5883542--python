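"""Hierarchical ABC test of guild-clustered vs. simultaneous co-divergence.

Six (by default) intercontinental sister-species pairs share a hyperprior on
the number of divergence events Psi: pair-to-event assignments follow a
Dirichlet-process partition whose concentration alpha is itself Gamma(shape 2)
distributed, with the Gamma scale calibrated so that E[Psi] matches a prior
scenario target (two, four or six events).  Each prior draw is pushed through
a two-population isolation coalescent simulator; rejection sampling on
standardized summary statistics (pi_between, per-side pi_within and Watterson
theta, net divergence) yields the posterior.  Guild hypotheses are expressed
as SYNC/BEFORE constraints on the event structure and compared by Bayes
factors on Raftery's 2*ln(BF) scale.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels
from .data_model import Guild
from .distances import encode_alignment

__all__ = [
    "SisterPairDataset",
    "SummaryStats",
    "PriorDraw",
    "PosteriorSample",
    "GuildModel",
    "ConstraintKind",
    "BayesFactorResult",
    "RafteryCategory",
    "simulate_pair",
    "summary_stats",
    "stats_vector",
    "sample_prior",
    "habc_reject",
    "constraint_probability",
    "bayes_factor",
    "mean_divergence_time",
    "standard_guild_models",
    "calibrate_concentration_scale",
    "expected_num_events",
]

_DECODE = np.frombuffer(b"AGCT", dtype=np.uint8)

#: Default prior upper bounds: tau in pairwise substitutions/site
#: (0.35 ~ 18 Myr at 1.9%/Myr), theta = 4N*mu per site.
DEFAULT_TAU_MAX = 0.35
DEFAULT_THETA_MAX = 0.02
_THETA_MIN = 1e-6


@dataclass
class SisterPairDataset:
    """COI sequences for one intercontinental sister-species pair.

    At least two sequences per side; both sides share alignment length L.
    """

    pair_id: str
    guild: Guild
    seqs_cn: list[str]
    seqs_aus: list[str]

    def __post_init__(self) -> None:
        self.guild = Guild(self.guild)
        if len(self.seqs_cn) < 2 or len(self.seqs_aus) < 2:
            raise ValueError(
                f"pair {self.pair_id!r}: need >=2 sequences per side "
                f"(got {len(self.seqs_cn)}/{len(self.seqs_aus)})"
            )
        lens = {len(s) for s in self.seqs_cn + self.seqs_aus}
        if len(lens) != 1:
            raise ValueError(f"pair {self.pair_id!r}: unequal sequence lengths {sorted(lens)}")

    @property
    def L(self) -> int:
        return len(self.seqs_cn[0])

    @property
    def n_cn(self) -> int:
        return len(self.seqs_cn)

    @property
    def n_aus(self) -> int:
        return len(self.seqs_aus)


@dataclass(frozen=True)
class SummaryStats:
    """Per-pair summary statistics (all proportions per site)."""

    pi_between: float
    pi_within_a: float
    pi_within_b: float
    theta_w_a: float
    theta_w_b: float
    s_a: int
    s_b: int

    @property
    def pi_within_mean(self) -> float:
        return 0.5 * (self.pi_within_a + self.pi_within_b)

    @property
    def pi_net(self) -> float:
        return self.pi_between - self.pi_within_mean

    @property
    def s_total(self) -> int:
        return self.s_a + self.s_b


def stats_vector(st: SummaryStats) -> np.ndarray:
    """Summary vector in the simulator's column order."""
    return np.array(
        [st.pi_between, st.pi_within_a, st.pi_within_b,
         st.theta_w_a, st.theta_w_b, st.pi_net]
    )


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def simulate_pair(
    theta_a: float,
    theta_b: float,
    theta_anc: float,
    tau: float,
    n_a: int,
    n_b: int,
    L: int,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Simulate one sister pair; returns (side_a, side_b) sequence lists.

    ``tau`` is in expected pairwise substitutions/site.  Deterministic under
    ``seed``.
    """
    if min(theta_a, theta_b, theta_anc) <= 0 or tau < 0:
        raise ValueError("thetas must be > 0 and tau >= 0")
    if n_a < 2 or n_b < 2 or L < 1:
        raise ValueError("need n_a, n_b >= 2 and L >= 1")
    empty = np.empty(0, dtype=np.uint8)
    codes = _kernels.seeded_pair_seqs(
        int(seed) % (2**31 - 1) + 1, float(theta_a), float(theta_b),
        float(theta_anc), float(tau), int(n_a), int(n_b), int(L), empty, 0.0
    )
    seqs = [_DECODE[row].tobytes().decode() for row in codes]
    return seqs[:n_a], seqs[n_a:]


def _side_stats(enc: np.ndarray) -> tuple[float, int]:
    """(mean pairwise diversity, segregating sites) with pairwise deletion."""
    n, L = enc.shape
    valid = enc < 4
    pis = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError("a sequence pair shares no valid sites")
            pis.append(int((enc[i][both] != enc[j][both]).sum()) / m)
    s = 0
    for col in range(L):
        bases = enc[:, col][valid[:, col]]
        if bases.size >= 2 and np.unique(bases).size > 1:
            s += 1
    return float(np.mean(pis)) if pis else 0.0, s


def summary_stats(pair: SisterPairDataset) -> SummaryStats:
    """Observed summary statistics for a sister pair (pairwise deletion)."""
    enc_a = encode_alignment(pair.seqs_cn)
    enc_b = encode_alignment(pair.seqs_aus)
    pi_wa, s_a = _side_stats(enc_a)
    pi_wb, s_b = _side_stats(enc_b)
    va, vb = enc_a < 4, enc_b < 4
    vals = []
    for i in range(pair.n_cn):
        for j in range(pair.n_aus):
            both = va[i] & vb[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError("a cross-side pair shares no valid sites")
            vals.append(int((enc_a[i][both] != enc_b[j][both]).sum()) / m)
    L = pair.L
    return SummaryStats(
        pi_between=float(np.mean(vals)),
        pi_within_a=pi_wa,
        pi_within_b=pi_wb,
        theta_w_a=s_a / (_harmonic(pair.n_cn) * L),
        theta_w_b=s_b / (_harmonic(pair.n_aus) * L),
        s_a=s_a,
        s_b=s_b,
    )


# --------------------------------------------------------------------------
# Dirichlet-process prior on the divergence-event structure

def expected_num_events(alpha: float, n_pairs: int) -> float:
    """E[Psi | alpha] under a Dirichlet-process partition of n_pairs items."""
    return sum(alpha / (alpha + i) for i in range(n_pairs))


@lru_cache(maxsize=None)
def calibrate_concentration_scale(
    target: float, n_pairs: int, shape: float = 2.0
) -> float:
    """Gamma-scale for the concentration hyperprior so that E[Psi] hits *target*.

    alpha ~ Gamma(shape, scale); the marginal E[Psi] is integrated over the
    hyperprior.  A target equal to n_pairs is only reachable asymptotically,
    so it is capped at n_pairs - 0.05 (well inside Monte-Carlo resolution).
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq
    from scipy.stats import gamma as gamma_dist

    if not 1.0 <= target <= n_pairs:
        raise ValueError(f"target E[Psi] must be in [1, {n_pairs}]")
    target = min(target, n_pairs - 0.05)

    def mean_psi(scale: float) -> float:
        dist = gamma_dist(shape, scale=scale)
        val, _ = quad(
            lambda a: expected_num_events(a, n_pairs) * dist.pdf(a),
            0.0, dist.ppf(1.0 - 1e-10), limit=200,
        )
        return val

    return float(brentq(lambda s: mean_psi(s) - target, 1e-4, 1e6, xtol=1e-6))


@dataclass
class PriorDraw:
    """One draw from the hierarchical prior.

    ``assignment[i]`` is the event index of pair i; ``event_taus[e]`` its
    divergence time (pairwise substitutions/site); ``thetas[i] = (theta_cn,
    theta_aus, theta_ancestral)`` for pair i.
    """

    assignment: tuple[int, ...]
    event_taus: tuple[float, ...]
    thetas: np.ndarray
    alpha: float

    @property
    def psi(self) -> int:
        return len(set(self.assignment))

    def tau_of_pair(self, i: int) -> float:
        return self.event_taus[self.assignment[i]]

    @property
    def mean_tau(self) -> float:
        return sum(self.tau_of_pair(i) for i in range(len(self.assignment))) / len(
            self.assignment
        )


def sample_prior(
    scenario: float,
    pairs: list[SisterPairDataset],
    n_draws: int,
    seed: int,
    tau_max: float = DEFAULT_TAU_MAX,
    theta_max: float = DEFAULT_THETA_MAX,
    concentration_shape: float = 2.0,
) -> list[PriorDraw]:
    """Draw event structures, divergence times and thetas from the prior.

    *scenario* is the prior mean number of divergence events (the two-, four-
    and six-event scenarios of the model comparison).  Event times are
    Uniform(0, tau_max); each population theta is Uniform(~0, theta_max).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not pairs:
        raise ValueError("empty pair list")
    n_pairs = len(pairs)
    scale = calibrate_concentration_scale(float(scenario), n_pairs, concentration_shape)
    rng = np.random.default_rng(seed)
    draws: list[PriorDraw] = []
    for _ in range(n_draws):
        alpha = float(rng.gamma(concentration_shape, scale))
        # Chinese-restaurant seating
        assignment = [0]
        counts = [1]
        for i in range(1, n_pairs):
            probs = np.array(counts + [alpha])
            probs /= probs.sum()
            c = int(rng.choice(len(probs), p=probs))
            if c == len(counts):
                counts.append(1)
            else:
                counts[c] += 1
            assignment.append(c)
        taus = tuple(float(x) for x in rng.uniform(0.0, tau_max, size=len(counts)))
        thetas = rng.uniform(_THETA_MIN, theta_max, size=(n_pairs, 3))
        draws.append(PriorDraw(tuple(assignment), taus, thetas, alpha))
    return draws


@dataclass
class PosteriorSample:
    """Retained ABC draws, sorted by ascending distance to the observation."""

    draws: list[PriorDraw]
    distances: np.ndarray
    tolerance: float
    n_sims: int
    keep_fraction: float
    dropped_stats: list[int] = field(default_factory=list)


def habc_reject(
    observed: list[SummaryStats],
    pairs: list[SisterPairDataset],
    scenario: float,
    n_sims: int,
    keep_fraction: float,
    seed: int,
    tau_max: float = DEFAULT_TAU_MAX,
    theta_max: float = DEFAULT_THETA_MAX,
    prior_draws: list[PriorDraw] | None = None,
) -> PosteriorSample:
    """ABC rejection: simulate the prior, keep the draws closest to the data.

    Distances are Euclidean on per-statistic vectors standardized by the
    simulated pool's mean and SD; zero-variance statistics are dropped with a
    warning.  Deterministic under ``seed`` (per-draw RNG streams are derived
    from it, so results do not depend on batching).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 sister pairs")
    if len(observed) != len(pairs):
        raise ValueError("one observed SummaryStats per pair required")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if n_sims < 1000:
        warnings.warn(f"n_sims={n_sims} is small for a meaningful posterior")
    rng = np.random.default_rng(seed)
    if prior_draws is None:
        prior_draws = sample_prior(
            scenario, pairs, n_sims, int(rng.integers(2**31 - 1)),
            tau_max=tau_max, theta_max=theta_max,
        )
    n_draws = len(prior_draws)
    n_pairs = len(pairs)
    sim = np.empty((n_draws, n_pairs * 6))
    # batch the kernel per pair (pairs may differ in L or sample sizes)
    for p, pair in enumerate(pairs):
        seeds = rng.integers(1, 2**31 - 1, size=n_draws)
        tau_u = np.array([d.tau_of_pair(p) for d in prior_draws])
        th = np.array([d.thetas[p] for d in prior_draws])
        na = np.full(n_draws, pair.n_cn, dtype=np.int64)
        nb = np.full(n_draws, pair.n_aus, dtype=np.int64)
        sim[:, p * 6 : (p + 1) * 6] = _kernels.batch_pair_stats(
            seeds, th[:, 0], th[:, 1], th[:, 2], tau_u, na, nb, pair.L
        )
    obs = np.concatenate([stats_vector(s) for s in observed])
    mean = sim.mean(axis=0)
    sd = sim.std(axis=0)
    dropped = [int(i) for i in np.flatnonzero(sd == 0.0)]
    if dropped:
        warnings.warn(f"dropping zero-variance summary statistic dims: {dropped}")
    keep_dims = sd > 0.0
    z_sim = (sim[:, keep_dims] - mean[keep_dims]) / sd[keep_dims]
    z_obs = (obs[keep_dims] - mean[keep_dims]) / sd[keep_dims]
    dist = np.sqrt(((z_sim - z_obs) ** 2).sum(axis=1))
    n_keep = max(1, math.ceil(keep_fraction * n_draws))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return PosteriorSample(
        draws=[prior_draws[i] for i in order],
        distances=dist[order],
        tolerance=float(dist[order[-1]]),
        n_sims=n_draws,
        keep_fraction=keep_fraction,
        dropped_stats=dropped,
    )


# --------------------------------------------------------------------------
# Guild models and Bayes factors

class ConstraintKind(str, enum.Enum):
    SYNC = "sync"      # all pairs in set_a share one divergence event
    BEFORE = "before"  # every pair in set_a diverged strictly earlier (older tau)


@dataclass(frozen=True)
class GuildModel:
    """A constraint on the divergence-event structure of a set of pairs."""

    name: str
    kind: ConstraintKind
    set_a: frozenset[str]
    set_b: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.set_a or (self.kind == ConstraintKind.BEFORE and not self.set_b):
            raise ValueError(f"model {self.name!r}: constraint sets must be non-empty")

    def satisfied(self, draw: PriorDraw, pair_ids: list[str]) -> bool:
        idx = {pid: i for i, pid in enumerate(pair_ids)}
        unknown = (self.set_a | self.set_b) - set(idx)
        if unknown:
            raise KeyError(f"model {self.name!r}: unknown pair ids {sorted(unknown)}")
        if self.kind == ConstraintKind.SYNC:
            events = {draw.assignment[idx[p]] for p in self.set_a}
            return len(events) == 1
        older = min(draw.tau_of_pair(idx[p]) for p in self.set_a)
        younger = max(draw.tau_of_pair(idx[p]) for p in self.set_b)
        return older > younger


_GALLING = {Guild.POLLINATOR, Guild.SMALL_GALLER, Guild.LARGE_GALLER}
_PARASITOID = {Guild.SMALL_PARASITOID, Guild.LARGE_PARASITOID}
_SMALL = {Guild.POLLINATOR, Guild.SMALL_GALLER, Guild.SMALL_PARASITOID}
_LARGE = {Guild.LARGE_GALLER, Guild.LARGE_PARASITOID}


def standard_guild_models(pairs: list[SisterPairDataset]) -> list[GuildModel]:
    """The nine guild-timing hypotheses over a set of sister pairs.

    Pollinators count among the galling (and small-galling) species: they
    gall fig flowers like the non-pollinating small gallers do.
    """
    def ids(guilds: set[Guild]) -> frozenset[str]:
        return frozenset(p.pair_id for p in pairs if p.guild in guilds)

    all_ids = frozenset(p.pair_id for p in pairs)
    S, B = ConstraintKind.SYNC, ConstraintKind.BEFORE
    return [
        GuildModel("all_synchronised", S, all_ids),
        GuildModel("gallers_before_parasitoids", B, ids(_GALLING), ids(_PARASITOID)),
        GuildModel("small_before_large", B, ids(_SMALL), ids(_LARGE)),
        GuildModel("small_all_synchronised", S, ids(_SMALL)),
        GuildModel(
            "small_gallers_before_small_parasitoids", B,
            ids({Guild.POLLINATOR, Guild.SMALL_GALLER}), ids({Guild.SMALL_PARASITOID}),
        ),
        GuildModel(
            "pollinators_and_small_parasitoids_synchronised", S,
            ids({Guild.POLLINATOR, Guild.SMALL_PARASITOID}),
        ),
        GuildModel(
            "pollinators_before_small_parasitoids", B,
            ids({Guild.POLLINATOR}), ids({Guild.SMALL_PARASITOID}),
        ),
        GuildModel("large_all_synchronised", S, ids(_LARGE)),
        GuildModel(
            "large_gallers_before_large_parasitoids", B,
            ids({Guild.LARGE_GALLER}), ids({Guild.LARGE_PARASITOID}),
        ),
    ]


def constraint_probability(
    draws: list[PriorDraw], model: GuildModel, pair_ids: list[str]
) -> float:
    """Fraction of draws whose event structure satisfies *model*."""
    if not draws:
        raise ValueError("empty draw collection")
    hits = sum(1 for d in draws if model.satisfied(d, pair_ids))
    return hits / len(draws)


class RafteryCategory(str, enum.Enum):
    NONE = "none"
    POSITIVE = "positive"        # 2 <= 2lnBF <= 5
    STRONG = "strong"            # 5 < 2lnBF <= 10
    VERY_STRONG = "very_strong"  # 2lnBF > 10
    INFINITE = "infinite"        # prior probability 0, posterior > 0


@dataclass(frozen=True)
class BayesFactorResult:
    posterior_p: float
    prior_p: float
    bf: float
    two_ln_bf: float
    category: RafteryCategory


def bayes_factor(posterior_p: float, prior_p: float) -> BayesFactorResult:
    """Bayes factor as posterior odds over prior odds, with Raftery category.

    2*ln(BF) in [2, 5] is positive evidence, (5, 10] strong, > 10 very
    strong.  A zero prior with non-zero posterior is reported as infinite
    support; a zero posterior gives BF = 0 with 2lnBF = -inf.
    """
    for name, p in (("posterior_p", posterior_p), ("prior_p", prior_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if prior_p >= 1.0:
        raise ValueError("prior_p must be < 1")
    if prior_p == 0.0:
        if posterior_p > 0.0:
            return BayesFactorResult(
                posterior_p, prior_p, math.inf, math.inf, RafteryCategory.INFINITE
            )
        return BayesFactorResult(posterior_p, prior_p, math.nan, math.nan,
                                 RafteryCategory.NONE)
    if posterior_p == 0.0:
        return BayesFactorResult(posterior_p, prior_p, 0.0, -math.inf,
                                 RafteryCategory.NONE)
    if posterior_p == 1.0:
        return BayesFactorResult(posterior_p, prior_p, math.inf, math.inf,
                                 RafteryCategory.INFINITE)
    bf = (posterior_p / (1.0 - posterior_p)) / (prior_p / (1.0 - prior_p))
    two_ln = 2.0 * math.log(bf)
    if two_ln > 10.0:
        cat = RafteryCategory.VERY_STRONG
    elif two_ln > 5.0:
        cat = RafteryCategory.STRONG
    elif two_ln >= 2.0:
        cat = RafteryCategory.POSITIVE
    else:
        cat = RafteryCategory.NONE
    return BayesFactorResult(posterior_p, prior_p, bf, two_ln, cat)


def mean_divergence_time(
    posterior: PosteriorSample, clock_rate: float
) -> tuple[float, float]:
    """Posterior mean and SD of the across-pair mean divergence time, in Ma.

    ``clock_rate`` is pairwise proportion divergence per Myr, so a pairwise
    tau converts as t = tau / rate (no further halving).
    """
    if not posterior.draws:
        raise ValueError("empty posterior")
    if clock_rate <= 0:
        raise ValueError("clock_rate must be > 0")
    taus = np.array([d.mean_tau for d in posterior.draws]) / clock_rate
    return float(taus.mean()), float(taus.std())
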