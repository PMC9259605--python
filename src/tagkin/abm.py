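"""Stochastic finite-population agent-based simulator of the lifecycle.

The simulator tracks every haploid agent (a tag in ``1..L_max`` and a
trait bit) across ``n_demes`` demes of exactly ``N`` agents.  Each
generation: every agent runs one social search in its deme (sampling
partners uniformly with replacement, excluding itself; a tag-mismatched
partner is abandoned with probability ``alpha`` at cost ``c_search``);
fecundity is ``1 + b*(help received) - c*(helped) - c_search*(abandons)``;
the next generation is drawn per deme from a post-migration gamete cloud
in which a parent's weight is its fecundity times ``1 - m`` (same deme)
or ``m/(n_demes - 1)`` (each other deme); meiosis places the trait on the
tag's gamete with probability ``1 - r``; mutation flips the trait with
probability ``mu_trait`` and moves the tag to a uniformly chosen
different tag with probability ``mu_tag``.

Used to validate the deterministic engine and to run the
tag-fixation-time (balancing-selection) experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams, ParameterError

__all__ = [
    "AgentPopulation",
    "FixationExperimentResult",
    "init_population",
    "run_generation",
    "genotype_frequencies",
    "run_trajectory",
    "fixation_experiment",
    "fixation_ratio_scan",
]


@dataclass
class AgentPopulation:
    """All agents of a finite island population.

    ``tags`` and ``traits`` have shape ``(n_demes, N)``; tags are in
    ``0..L_max-1`` and traits in ``{0, 1}`` (1 = conditional helper).
    """

    tags: np.ndarray
    traits: np.ndarray
    L_max: int

    def __post_init__(self) -> None:
        self.tags = np.asarray(self.tags, dtype=np.int64)
        self.traits = np.asarray(self.traits, dtype=np.int64)
        if self.tags.shape != self.traits.shape or self.tags.ndim != 2:
            raise ValueError("tags/traits must share a (n_demes, N) shape")
        if self.tags.min(initial=0) < 0 or self.tags.max(initial=0) >= self.L_max:
            raise ValueError("tags out of range")

    @property
    def n_demes(self) -> int:
        return self.tags.shape[0]

    @property
    def N(self) -> int:
        return self.tags.shape[1]

    @property
    def size(self) -> int:
        return self.tags.size


@dataclass(frozen=True)
class FixationExperimentResult:
    """Outcome of one tag-fixation run."""

    fixation_time: int
    censored: bool
    seed: int
    neutral: bool


def init_population(
    n_demes: int,
    N: int,
    mode: str,
    L_max: int,
    seed: int,
    helper_prop: float = 0.1,
) -> AgentPopulation:
    """Seeded initial population.

    ``uniform_tags`` samples every agent's tag uniformly (each tag at
    expected frequency ``1/L_max``); ``standard`` mirrors the engine's
    standard initial state (one tag at expected frequency 0.9, the rest
    split randomly).  Traits are Bernoulli(``helper_prop``).
    """
    if n_demes < 2 or N < 2:
        raise ParameterError("need n_demes >= 2 and N >= 2")
    rng = np.random.default_rng(seed)
    shape = (n_demes, N)
    if mode == "uniform_tags":
        tags = rng.integers(L_max, size=shape)
    elif mode == "standard":
        probs = np.empty(L_max)
        probs[0] = 0.9
        if L_max > 1:
            rest = np.maximum(rng.dirichlet(np.ones(L_max - 1)), 1e-12)
            probs[1:] = 0.1 * rest / rest.sum()
        else:
            probs[0] = 1.0
        probs /= probs.sum()
        tags = rng.choice(L_max, size=shape, p=probs)
    else:
        raise ParameterError(f"unknown init mode {mode!r}")
    traits = (rng.random(shape) < helper_prop).astype(np.int64)
    return AgentPopulation(tags=tags, traits=traits, L_max=L_max)


def _social_phase(
    tags: np.ndarray, traits: np.ndarray, alpha: float, rng: np.random.Generator
):
    """One social search per agent in every deme.

    Returns (help received, helped as actor, abandonment count), each
    shaped like ``tags``.
    """
    D, N = tags.shape
    received = np.zeros((D, N))
    gave = np.zeros((D, N), dtype=bool)
    abandons = np.zeros((D, N), dtype=np.int64)
    for d in range(D):
        t = tags[d]
        tr = traits[d]
        if alpha >= 1.0:
            # search to certainty: the ultimate partner is uniform among
            # tag-matched deme-mates; agents with no match never interact
            order = np.argsort(t, kind="stable")
            rank = np.empty(N, dtype=np.int64)
            rank[order] = np.arange(N)
            cnt = np.bincount(t, minlength=int(t.max()) + 1)
            start = np.concatenate([[0], np.cumsum(cnt)[:-1]])
            my_cnt = cnt[t]
            my_pos = rank - start[t]
            actors = np.flatnonzero((my_cnt >= 2) & (tr == 1))
            if actors.size:
                k = (rng.random(actors.size)
                     * (my_cnt[actors] - 1)).astype(np.int64)
                k += k >= my_pos[actors]
                j = order[start[t[actors]] + k]
                np.add.at(received[d], j, 1.0)
                gave[d, actors] = True
        else:
            active = np.ones(N, dtype=bool)
            while True:
                ii = np.flatnonzero(active)
                if ii.size == 0:
                    break
                jj = (ii + rng.integers(1, N, size=ii.size)) % N
                match = t[jj] == t[ii]
                mi, mj = ii[match], jj[match]
                helpers = tr[mi] == 1
                np.add.at(received[d], mj[helpers], 1.0)
                gave[d, mi[helpers]] = True
                active[mi] = False
                um = ii[~match]
                ab = rng.random(um.size) < alpha
                abandons[d, um[ab]] += 1
                active[um[~ab]] = False
    return received, gave, abandons


def run_generation(
    pop: AgentPopulation,
    params: ModelParams,
    rng: np.random.Generator,
    neutral: bool = False,
) -> AgentPopulation:
    """One full lifecycle.  ``neutral=True`` zeroes b, c and c_search
    (used for the matched neutral fixation runs) while keeping demography
    and mutation unchanged."""
    D, N = pop.n_demes, pop.N
    if N != params.N:
        raise ParameterError("population deme size disagrees with params.N")
    m, r = params.m, params.r
    b, c, cs = (0.0, 0.0, 0.0) if neutral else (params.b, params.c, params.c_search)

    if b == 0.0 and c == 0.0 and cs == 0.0:
        fec = np.ones((D, N))
    else:
        received, gave, abandons = _social_phase(pop.tags, pop.traits,
                                                 params.alpha, rng)
        fec = 1.0 + b * received - c * gave - cs * abandons
        if np.any(fec < 0):
            raise ParameterError(
                "model undefined: an agent's fecundity went negative"
            )

    tagflat = pop.tags.ravel()
    traitflat = pop.traits.ravel()
    new_tags = np.empty((D, N), dtype=np.int64)
    new_traits = np.empty((D, N), dtype=np.int64)
    deme_w = np.full(D, m / (D - 1))
    for d in range(D):
        w = deme_w.copy()
        w[d] = 1.0 - m
        weights = (fec * w[:, None]).ravel()
        cum = np.cumsum(weights)
        total = cum[-1]
        if total <= 0:
            raise ParameterError("empty gamete cloud (total weight zero)")
        draws = rng.random(2 * N) * total
        parents = np.searchsorted(cum, draws, side="right")
        g1, g2 = parents[:N], parents[N:]
        recomb = rng.random(N) < r
        new_tags[d] = tagflat[g1]
        new_traits[d] = np.where(recomb, traitflat[g2], traitflat[g1])

    # mutation
    if params.mu_trait > 0:
        flip = rng.random((D, N)) < params.mu_trait
        new_traits = np.where(flip, 1 - new_traits, new_traits)
    if params.mu_tag > 0:
        move = rng.random((D, N)) < params.mu_tag
        offset = rng.integers(1, pop.L_max, size=(D, N))
        new_tags = np.where(move, (new_tags + offset) % pop.L_max, new_tags)
    return AgentPopulation(tags=new_tags, traits=new_traits, L_max=pop.L_max)


def genotype_frequencies(pop: AgentPopulation) -> np.ndarray:
    """Population genotype-frequency matrix, shape (L_max, 2)."""
    out = np.zeros((pop.L_max, 2))
    for j in (0, 1):
        sel = pop.tags[pop.traits == j]
        out[:, j] = np.bincount(sel, minlength=pop.L_max) / pop.size
    return out


def run_trajectory(
    pop: AgentPopulation,
    params: ModelParams,
    generations: int,
    rng: np.random.Generator,
    neutral: bool = False,
) -> tuple[AgentPopulation, np.ndarray]:
    """Run ``generations`` lifecycles; returns the final population and
    the stacked per-generation genotype-frequency matrices (including the
    initial state, shape ``(generations + 1, L_max, 2)``)."""
    freqs = np.empty((generations + 1, pop.L_max, 2))
    freqs[0] = genotype_frequencies(pop)
    for g in range(generations):
        pop = run_generation(pop, params, rng, neutral=neutral)
        freqs[g + 1] = genotype_frequencies(pop)
    return pop, freqs


def fixation_experiment(
    params: ModelParams,
    n_demes: int,
    seed: int,
    neutral: bool = False,
    max_generations: int = 1_000_000,
    helper_prop: float = 0.1,
) -> FixationExperimentResult:
    """Time until tag diversity is lost, from uniform initial tags.

    Requires ``mu_tag = 0`` (tag diversity must not be replenished by
    mutation).  Runs are censored at ``max_generations``.
    """
    if params.mu_tag != 0.0:
        raise ParameterError("fixation experiments require mu_tag = 0")
    if params.L_max < 2:
        return FixationExperimentResult(0, False, seed, neutral)
    rng = np.random.default_rng(seed)
    pop = init_population(n_demes, params.N, "uniform_tags", params.L_max,
                          seed=seed, helper_prop=helper_prop)
    for gen in range(1, max_generations + 1):
        pop = run_generation(pop, params, rng, neutral=neutral)
        first = pop.tags.flat[0]
        if np.all(pop.tags == first):
            return FixationExperimentResult(gen, False, seed, neutral)
    return FixationExperimentResult(max_generations, True, seed, neutral)


def fixation_ratio_scan(
    params: ModelParams,
    population_sizes: list[int],
    alphas: list[float],
    replicates: int,
    seed: int,
    max_generations: int = 1_000_000,
    n_bootstrap: int = 200,
    helper_prop: float = 0.5,
) -> pd.DataFrame:
    """Tag-fixation ratio (selected / matched neutral) over a grid.

    ``population_sizes`` are deme counts at fixed ``params.N``.  For each
    (size, alpha) cell, ``replicates`` selected runs are paired with
    ``replicates`` neutral runs; the ratio of mean fixation times gets a
    bootstrap percentile CI.  Censored runs are excluded from means (and
    counted in ``n_censored``).
    """
    if replicates < 2:
        raise ParameterError("need replicates >= 2")
    rows = []
    rng = np.random.default_rng(seed)
    for n_demes in population_sizes:
        for alpha in alphas:
            p = ModelParams(
                demography=params.demography,
                alpha=alpha,
                c_search=params.c_search if alpha < 1 else 0.0,
                b=params.b, c=params.c,
                mu_trait=params.mu_trait, mu_tag=0.0,
                L_max=params.L_max,
            )
            sel_times, neu_times, censored = [], [], 0
            for rep in range(replicates):
                s = int(rng.integers(2**63 - 1))
                res = fixation_experiment(p, n_demes, s,
                                          max_generations=max_generations,
                                          helper_prop=helper_prop)
                if res.censored:
                    censored += 1
                else:
                    sel_times.append(res.fixation_time)
                s = int(rng.integers(2**63 - 1))
                res = fixation_experiment(p, n_demes, s, neutral=True,
                                          max_generations=max_generations,
                                          helper_prop=helper_prop)
                if res.censored:
                    censored += 1
                else:
                    neu_times.append(res.fixation_time)
            sel = np.asarray(sel_times, dtype=float)
            neu = np.asarray(neu_times, dtype=float)
            ratio = sel.mean() / neu.mean() if sel.size and neu.size else np.nan
            boots = []
            if sel.size and neu.size:
                for _ in range(n_bootstrap):
                    bs = rng.choice(sel, sel.size).mean()
                    bn = rng.choice(neu, neu.size).mean()
                    if bn > 0:
                        boots.append(bs / bn)
            lo, hi = (np.percentile(boots, [2.5, 97.5])
                      if boots else (np.nan, np.nan))
            rows.append({
                "population_size": n_demes * params.N,
                "n_demes": n_demes,
                "alpha": alpha,
                "mean_fix_time_selected": sel.mean() if sel.size else np.nan,
                "mean_fix_time_neutral": neu.mean() if neu.size else np.nan,
                "ratio": ratio,
                "ci_low": lo,
                "ci_high": hi,
                "n_replicates": replicates,
                "n_censored": censored,
            })
    return pd.DataFrame(rows)
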