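"""Neutral identity-by-descent probabilities of the island model.

Four quantities are computed for a haploid island model with deme size ``N``,
per-gamete migration ``m`` and tag-trait recombination ``r``:

``F``
    probability that genes sampled at one locus in two individuals drawn
    without replacement from one deme are identical by descent (their
    lineages coalesce in finite time, i.e. before either lineage leaves
    the deme);
``phi``
    probability that, sampling both loci in the same two individuals, the
    pair of genes at the first locus are IBD *and* the pair at the second
    locus are IBD;
``G``
    probability that genes at one locus in three individuals (the third
    drawn with replacement of the first two) are all IBD;
``gamma``
    probability that individuals 1 & 2 are IBD at one locus and
    individuals 2 & 3 are IBD at the other locus (third individual again
    drawn with replacement of the first two).

The probabilities are obtained as absorption probabilities of a
backward-in-time Markov chain over ancestral lineage configurations.  A
*lineage unit* is a haploid ancestor carrying tracked genes at one or both
loci.  Going back one generation, a unit carrying both loci places them on
the same parental gamete with probability ``1 - r`` (otherwise they split
onto the zygote's two gametes); each gamete derives from a local parent
with probability ``1 - m`` (a migrant lineage lands in a fresh deme of the
infinite island and can never again meet the others, so any pending
coalescence fails); local gametes pick parents uniformly among the ``N``
adults, and units choosing the same parent merge, coalescing any genes
they share a locus with.  The chain's state space is tiny (a handful of
configurations), so the absorption probabilities are found by a dense
linear solve.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np

from .params import DemographyParams, ParameterError

__all__ = [
    "CoalescenceProbs",
    "equilibrium_F",
    "iterate_F_recursion",
    "equilibrium_two_locus",
    "mc_coalescent_oracle",
]

# Unit bitmasks: locus A = 1, locus B = 2, both = 3.
_A, _B, _AB = 1, 2, 3


@dataclass(frozen=True)
class CoalescenceProbs:
    """The four neutral IBD probabilities of one demography."""

    F: float
    phi: float
    G: float
    gamma: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.F, self.phi, self.G, self.gamma)


def equilibrium_F(demography: DemographyParams) -> float:
    """Equilibrium single-locus IBD probability.

    Closed form ``(1-m)^2 / ((1-m)^2 + N (1 - (1-m)^2))``, the fixed point
    of :func:`iterate_F_recursion`.
    """
    a = (1.0 - demography.m) ** 2
    return a / (a + demography.N * (1.0 - a))


def iterate_F_recursion(
    demography: DemographyParams, F0: float, generations: int
) -> float:
    """Apply ``F' = (1-m)^2 (1/N + (1 - 1/N) F)`` ``generations`` times."""
    if not (0.0 <= F0 <= 1.0):
        raise ParameterError(f"F0 must be in [0, 1], got {F0}")
    if generations < 0:
        raise ParameterError("generations must be >= 0")
    a = (1.0 - demography.m) ** 2
    N = demography.N
    F = float(F0)
    for _ in range(generations):
        F = a * (1.0 / N + (1.0 - 1.0 / N) * F)
    return F


# ---------------------------------------------------------------------------
# Exact chain
# ---------------------------------------------------------------------------

def _canonical(units: tuple[int, ...]) -> tuple[int, ...]:
    """Canonical form of a configuration, applying locus completion.

    A locus carried by exactly one remaining gene has fully coalesced: the
    gene is dropped from its unit.  Units left empty disappear.  Sorting
    makes interchangeable units order-free.
    """
    units = tuple(u for u in units if u)
    for locus in (_A, _B):
        if sum(1 for u in units if u & locus) == 1:
            units = tuple(u & ~locus for u in units)
            units = tuple(u for u in units if u)
    return tuple(sorted(units))


def _set_partitions_of(items: list[int]):
    """All set partitions of ``items`` as lists of blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions_of(rest):
        for k in range(len(sub)):
            yield [[first] + sub[k] if i == k else list(b) for i, b in enumerate(sub)]
        yield [[first]] + [list(b) for b in sub]


def _transitions(state: tuple[int, ...], demography: DemographyParams):
    """One-generation transition distribution from a configuration.

    Returns (dict state -> prob, success_prob).  The residual probability
    mass is absorption into failure (a pending lineage migrated away).
    """
    N, m, r = demography.N, demography.m, demography.r
    out: dict[tuple[int, ...], float] = {}
    p_success = 0.0

    doubles = [u for u in state if u == _AB]
    singles = [u for u in state if u != _AB]
    n_ab = len(doubles)

    for k in range(n_ab + 1):  # number of double units that split at meiosis
        p_split = comb(n_ab, k) * r**k * (1.0 - r) ** (n_ab - k)
        if p_split == 0.0:
            continue
        units = list(singles) + [_AB] * (n_ab - k) + [_A, _B] * k
        U = len(units)
        p_stay = (1.0 - m) ** U  # any migration separates a pending pair
        if p_stay == 0.0:
            continue
        for blocks in _set_partitions_of(list(range(U))):
            g = len(blocks)
            # P(uniform parent choice induces this set partition) = N!/(N-g)! / N^U
            p_assign = 1.0 / N ** U
            for j in range(g):
                p_assign *= N - j
            if p_assign == 0.0:
                continue
            merged = []
            for block in blocks:
                u = 0
                for i in block:
                    u |= units[i]
                merged.append(u)
            nxt = _canonical(merged)
            p = p_split * p_stay * p_assign
            if not nxt:
                p_success += p
            else:
                out[nxt] = out.get(nxt, 0.0) + p
    return out, p_success


def _solve_chain(
    initial_states: list[tuple[int, ...]], demography: DemographyParams
) -> dict[tuple[int, ...], float]:
    """Absorption ("all required coalescences happen") probabilities.

    Explores all states reachable from ``initial_states`` and solves the
    dense linear system ``(I - T) v = s`` where ``T`` is the transient
    transition matrix and ``s`` the one-step success probabilities.
    """
    states: list[tuple[int, ...]] = []
    index: dict[tuple[int, ...], int] = {}
    queue = [_canonical(s) for s in initial_states]
    trans: dict[tuple[int, ...], tuple[dict, float]] = {}
    while queue:
        s = queue.pop()
        if s in index or not s:
            continue
        index[s] = len(states)
        states.append(s)
        t, ps = _transitions(s, demography)
        trans[s] = (t, ps)
        queue.extend(t.keys())

    n = len(states)
    if n == 0:
        return {}
    T = np.zeros((n, n))
    svec = np.zeros(n)
    for s, i in index.items():
        t, ps = trans[s]
        svec[i] = ps
        for nxt, p in t.items():
            T[i, index[nxt]] += p
    if demography.m == 0.0:
        # success is certain: (I - T) is near-singular, avoid the solve
        v = np.ones(n)
    else:
        v = np.linalg.solve(np.eye(n) - T, svec)
    return {s: float(v[i]) for s, i in index.items()}


def equilibrium_two_locus(demography: DemographyParams) -> CoalescenceProbs:
    """All four equilibrium IBD probabilities for one demography.

    ``F`` is cross-checked against the closed form; ``G`` and ``gamma``
    incorporate the with-replacement draw of the third individual (it
    coincides with individual 1 or 2 with probability ``1/N`` each).
    """
    N = demography.N
    s_pair = (_A, _A)                 # F
    s_phi = (_AB, _AB)                # phi
    s_triple = (_A, _A, _A)           # G, three distinct individuals
    s_gamma3 = (_A, _B, _AB)          # gamma, three distinct individuals
    v = _solve_chain([s_pair, s_phi, s_triple, s_gamma3], demography)

    F_chain = v.get(_canonical(s_pair), 1.0)
    F_closed = equilibrium_F(demography)
    if abs(F_chain - F_closed) > 1e-9:
        raise RuntimeError(
            f"lineage chain F={F_chain!r} disagrees with closed form {F_closed!r}"
        )
    phi = v.get(_canonical(s_phi), 1.0)
    T3 = v.get(_canonical(s_triple), 1.0)
    D3 = v.get(_canonical(s_gamma3), 1.0)

    G = 2.0 / N * F_closed + (1.0 - 2.0 / N) * T3
    gamma = phi / N + F_closed / N + (1.0 - 2.0 / N) * D3
    return CoalescenceProbs(F=F_closed, phi=phi, G=G, gamma=gamma)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def _simulate_once(units: list[int], demography: DemographyParams,
                   rng: _pyrandom.Random, max_generations: int) -> bool:
    """Mechanistic single-replicate backward simulation of the lifecycle.

    Independent of the exact chain: events (meiotic split, migration,
    parent choice) are sampled generation by generation.
    """
    N, m, r = demography.N, demography.m, demography.r
    units = [u for u in units if u]
    # apply completion rules to the initial draw
    for locus in (_A, _B):
        if sum(1 for u in units if u & locus) == 1:
            units = [u & ~locus for u in units]
            units = [u for u in units if u]
    for _ in range(max_generations):
        if not units:
            return True
        split: list[int] = []
        for u in units:
            if u == _AB and rng.random() < r:
                split.append(_A)
                split.append(_B)
            else:
                split.append(u)
        by_parent: dict[int, int] = {}
        for u in split:
            if m > 0.0 and rng.random() < m:
                return False  # a pending lineage left the deme
            parent = rng.randrange(N)
            by_parent[parent] = by_parent.get(parent, 0) | u
        units = list(by_parent.values())
        for locus in (_A, _B):
            if sum(1 for u in units if u & locus) == 1:
                units = [u & ~locus for u in units]
        units = [u for u in units if u]
    raise RuntimeError("coalescent simulation exceeded max_generations")


def mc_coalescent_oracle(
    demography: DemographyParams,
    replicates: int,
    seed: int,
    max_generations: int = 10_000_000,
) -> tuple[CoalescenceProbs, CoalescenceProbs]:
    """Monte-Carlo estimates of (F, phi, G, gamma) with standard errors.

    Per replicate and per sampling scheme, the neutral backward lifecycle
    is simulated and a coalescence-in-finite-time indicator recorded.  The
    third individual of the G and gamma schemes is drawn uniformly among
    the N adults, so it coincides with individual 1 or 2 with probability
    1/N each (with-replacement rule).

    Returns ``(estimates, standard_errors)``.  Identical seeds give
    identical output.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = _pyrandom.Random(seed)
    N = demography.N
    hits = {"F": 0, "phi": 0, "G": 0, "gamma": 0}

    for _ in range(replicates):
        if _simulate_once([_A, _A], demography, rng, max_generations):
            hits["F"] += 1
        if _simulate_once([_AB, _AB], demography, rng, max_generations):
            hits["phi"] += 1

        i3 = rng.randrange(N)  # with replacement of individuals 1 & 2
        g_units = [_A, _A] if i3 < 2 else [_A, _A, _A]
        if _simulate_once(g_units, demography, rng, max_generations):
            hits["G"] += 1

        i3 = rng.randrange(N)
        if i3 == 0:          # third individual is individual 1
            gam_units = [_AB, _AB]
        elif i3 == 1:        # third individual is individual 2: B-pair coalesced
            gam_units = [_A, _A]
        else:
            gam_units = [_A, _AB, _B]
        if _simulate_once(gam_units, demography, rng, max_generations):
            hits["gamma"] += 1

    est = {k: v / replicates for k, v in hits.items()}
    se = {
        k: sqrt(max(p * (1.0 - p), 0.0) / replicates) for k, p in est.items()
    }
    return (
        CoalescenceProbs(est["F"], est["phi"], est["G"], est["gamma"]),
        CoalescenceProbs(se["F"], se["phi"], se["G"], se["gamma"]),
    )
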