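"""Deterministic infinite-island genotype-frequency recursions.

The population state is a matrix ``x`` of genotype frequencies over
``L_max`` tags (rows) and the two trait alleles (columns: 0 = defect,
1 = help).  One generation applies, in order: selection
(``x -> x'``, via the social-interaction M-terms and the fitness table),
recombination (``x' -> x''``) and mutation (``x'' -> x'''``).

All expectations entering fitness ("M-terms") are per-generation
quantities conditioned on a focal genotype, expressed through the neutral
IBD probabilities ``F, phi, G, gamma`` of the demography (weak selection:
the IBD probabilities do not depend on ``b``, ``c`` or ``c_search``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coalescence import CoalescenceProbs, equilibrium_two_locus
from .params import ModelParams, ParameterError

__all__ = [
    "PopulationState",
    "MTerms",
    "FitnessTable",
    "SummaryStats",
    "ConvergenceConfig",
    "m_interact",
    "m_helped",
    "m_abandon",
    "compute_mterms",
    "fitness",
    "selection_step",
    "recombination_step",
    "mutation_step",
    "generation_step",
    "standard_initial_state",
    "summary_stats",
    "state_stats",
    "iterate_to_equilibrium",
]

_SUM_TOL = 1e-9


@dataclass
class PopulationState:
    """Genotype frequency table over tags x trait alleles.

    ``x[i, 0]`` is the frequency of defectors with tag ``i`` and
    ``x[i, 1]`` the frequency of conditional helpers with tag ``i``.
    """

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] != 2:
            raise ValueError(f"state must have shape (L_max, 2), got {self.x.shape}")
        if np.any(self.x < -1e-15):
            raise ValueError("genotype frequencies must be non-negative")
        if abs(self.x.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {self.x.sum()!r}, not 1")

    @property
    def L_max(self) -> int:
        return self.x.shape[0]

    @property
    def tag_freq(self) -> np.ndarray:
        """x_i = x_i0 + x_i1."""
        return self.x.sum(axis=1)

    @property
    def helper_prop(self) -> np.ndarray:
        """p_i = x_i1 / x_i, defined as 0 for absent tags."""
        xi = self.tag_freq
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(xi > 0, self.x[:, 1] / np.where(xi > 0, xi, 1.0), 0.0)
        return p

    @property
    def p_bar(self) -> float:
        """Population frequency of the helping allele."""
        return float(self.x[:, 1].sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.x.copy())


@dataclass(frozen=True)
class MTerms:
    """Per-tag expected interaction / help-received / abandonment counts."""

    interact: np.ndarray          # M_interact_i
    ind_helped_1: np.ndarray      # M_ind_helped_i1 (focal is a helper)
    ind_helped_0: np.ndarray      # M_ind_helped_i0 (focal is a defector)
    deme_helped_1: np.ndarray
    deme_helped_0: np.ndarray
    ind_abandon: np.ndarray
    deme_abandon: np.ndarray
    pop_helped: float
    pop_abandon: float
    unbounded_abandon: bool = False  # alpha = 1 sentinel; requires c_search = 0


@dataclass(frozen=True)
class FitnessTable:
    """Absolute fitness w_ij (expected surviving offspring; mean is 1)."""

    w: np.ndarray  # shape (L_max, 2), columns as in PopulationState


def m_interact(x_i, F: float, alpha: float):
    """Per-generation probability of obtaining a tag-matched ultimate partner.

    ``(F + (1-F) x_i) / (1 - alpha (1-x_i)(1-F))``.  The singular point
    ``alpha = 1, x_i = 0, F = 0`` is defined as 0: a match can never be
    found.
    """
    x_i = np.asarray(x_i, dtype=float)
    num = F + (1.0 - F) * x_i
    den = 1.0 - alpha * (1.0 - x_i) * (1.0 - F)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def m_helped(state: PopulationState, probs: CoalescenceProbs, params: ModelParams):
    """Expected help-received counts (focal, local competitor, population).

    Returns ``(ind_helped_1, ind_helped_0, deme_helped_1, deme_helped_0,
    pop_helped)``.  The helper-conditioned components are hypothetical
    expectations for the genotype whether or not it segregates; they enter
    the recursion weighted by genotype frequency.
    """
    F, phi, gamma = probs.F, probs.phi, probs.gamma
    alpha, N = params.alpha, params.N
    x_i = state.tag_freq
    p_i = state.helper_prop

    den = 1.0 - alpha * (1.0 - x_i) * (1.0 - F)
    safe_den = np.where(den > 0, den, 1.0)
    ind1 = np.where(
        den > 0,
        (phi + (F - phi) * p_i + (F - phi) * x_i + (1 - 2 * F + phi) * p_i * x_i)
        / safe_den,
        0.0,
    )
    ind0 = np.where(
        den > 0,
        ((F - phi) * p_i + (1 - 2 * F + phi) * p_i * x_i) / safe_den,
        0.0,
    )

    mint = m_interact(x_i, F, alpha)
    helper_freq = float(np.sum(x_i * p_i))  # p_bar
    reach = x_i + (1.0 - x_i) * alpha * mint  # chance tag l is the actor's match
    if helper_freq > 0:
        w_reach = float(np.sum(x_i * p_i * reach)) / helper_freq
    else:
        w_reach = 0.0  # no helpers anywhere: trait-IBD actor class is empty
    uw_reach = float(np.sum(p_i * x_i * reach))

    frac = (N - 2) / N
    deme1 = (
        mint / N
        + ind1 / N
        + frac
        * (gamma + (F - gamma) * helper_freq + (F - gamma) * w_reach
           + (1 - 2 * F + gamma) * uw_reach)
    )
    deme0 = ind0 / N + frac * ((F - gamma) * helper_freq
                               + (1 - 2 * F + gamma) * uw_reach)
    pop_helped = float(np.sum(p_i * x_i * mint))
    return ind1, ind0, deme1, deme0, pop_helped


def m_abandon(state: PopulationState, probs: CoalescenceProbs, params: ModelParams):
    """Expected abandonment counts (focal, local competitor, population).

    Returns ``(ind_abandon, deme_abandon, pop_abandon, unbounded)``.  At
    ``alpha = 1`` the geometric series for a rare tag diverges; affected
    entries are ``inf`` and ``unbounded`` is flagged — valid only under
    ``c_search = 0`` (enforced by :class:`~tagkin.params.ModelParams`).
    """
    F, G = probs.F, probs.G
    alpha, N = params.alpha, params.N
    if alpha == 1.0 and params.c_search > 0:
        raise ParameterError("alpha = 1 with c_search > 0 is not a valid model")
    x_i = state.tag_freq

    q = alpha * (1.0 - F) * (1.0 - x_i)  # per-encounter abandonment probability
    with np.errstate(divide="ignore", invalid="ignore"):
        ind = np.where(q < 1.0, q / np.where(q < 1.0, 1.0 - q, 1.0), np.inf)
    unbounded = bool(np.any(~np.isfinite(ind)))

    # sum_{l != i} x_l * M_ind_abandon_l, per focal tag i
    total = float(np.sum(x_i * ind)) if not unbounded else np.inf
    excl = total - x_i * ind

    deme = (
        ind / N
        + (1.0 / N) * (1.0 - F) * alpha * ((1.0 - x_i) + excl)
        + ((N - 2) / N)
        * (
            (F - G) * (1.0 - x_i) * alpha * (1.0 + ind)
            + (F - G) * alpha * ((1.0 - x_i) + excl)
            + (1 - 3 * F + 2 * G)
            * float(np.sum(x_i * (1.0 - x_i) * alpha * (1.0 + ind)))
        )
    )
    pop = total
    return ind, deme, pop, unbounded


def compute_mterms(
    state: PopulationState, probs: CoalescenceProbs, params: ModelParams
) -> MTerms:
    """All M-terms for one state under one parameter set."""
    ind1, ind0, deme1, deme0, pop_helped = m_helped(state, probs, params)
    ind_ab, deme_ab, pop_ab, unbounded = m_abandon(state, probs, params)
    return MTerms(
        interact=m_interact(state.tag_freq, probs.F, params.alpha),
        ind_helped_1=ind1,
        ind_helped_0=ind0,
        deme_helped_1=deme1,
        deme_helped_0=deme0,
        ind_abandon=ind_ab,
        deme_abandon=deme_ab,
        pop_helped=pop_helped,
        pop_abandon=pop_ab,
        unbounded_abandon=unbounded,
    )


def fitness(
    state: PopulationState, mterms: MTerms, params: ModelParams
) -> FitnessTable:
    """Absolute fitness of every genotype.

    Helpers pay ``c`` per interaction and both morphs receive ``b`` per
    help received; helping elsewhere displaces offspring through local
    (weight ``1-m``) and global (weight ``m``) competition; searching
    costs ``c_search`` per abandonment, rebated through the competitive
    relief of everyone else's abandonments.
    """
    b, c, m, cs = params.b, params.c, params.m, params.c_search
    comp = (1.0 - m)
    w1 = (
        1.0
        - c * mterms.interact
        + b * mterms.ind_helped_1
        - (b - c) * (comp * mterms.deme_helped_1 + m * mterms.pop_helped)
    )
    w0 = (
        1.0
        + b * mterms.ind_helped_0
        - (b - c) * (comp * mterms.deme_helped_0 + m * mterms.pop_helped)
    )
    if cs > 0.0:
        if mterms.unbounded_abandon:
            raise ParameterError("unbounded abandonment with c_search > 0")
        search = cs * (
            mterms.ind_abandon - comp * mterms.deme_abandon - m * mterms.pop_abandon
        )
        w1 = w1 - search
        w0 = w0 - search
    w = np.column_stack([w0, w1])
    if np.any(w < 0):
        raise ParameterError(
            "model undefined: negative fitness (negative offspring) encountered"
        )
    return FitnessTable(w=w)


def selection_step(state: PopulationState, fit: FitnessTable) -> PopulationState:
    """``x'_ij = x_ij w_ij`` (mean fitness is 1, so the sum is conserved)."""
    x = state.x * fit.w
    total = x.sum()
    if abs(total - 1.0) > _SUM_TOL:
        warnings.warn(
            f"selection step drifted total frequency to {total!r}; renormalising",
            RuntimeWarning,
            stacklevel=2,
        )
    return PopulationState(x / total)


def recombination_step(
    state: PopulationState, probs: CoalescenceProbs, params: ModelParams
) -> PopulationState:
    """Recombination in randomly fused zygotes.

    A fraction ``(2F - phi)(1-m)^2`` of zygotes unite gametes that are IBD
    at one or both loci and pass through unchanged; among the rest,
    recombination (probability ``r``) exchanges tag-trait combinations.
    Marginal tag frequencies and the trait-allele frequency are invariant.
    """
    F, phi = probs.F, probs.phi
    m, r = params.m, params.r
    A = (2.0 * F - phi) * (1.0 - m) ** 2
    xd = state.x[:, 0]
    xh = state.x[:, 1]
    Sd, Sh = float(xd.sum()), float(xh.sum())
    od, oh = Sd - xd, Sh - xh  # other-tag column totals
    new_h = A * xh + (1.0 - A) * (
        xh * (xh + xd + (1.0 - r) * od + oh) + r * xd * oh
    )
    new_d = A * xd + (1.0 - A) * (
        xd * (xd + xh + (1.0 - r) * oh + od) + r * xh * od
    )
    return PopulationState(np.column_stack([new_d, new_h]))


def mutation_step(state: PopulationState, params: ModelParams) -> PopulationState:
    """Symmetric trait mutation and uniform tag mutation."""
    mu_t, mu_g = params.mu_trait, params.mu_tag
    if mu_g > 0 and params.L_max == 1:
        raise ParameterError("tag mutation undefined for L_max = 1")
    x = state.x
    out = x * (1.0 - mu_t - mu_g) + x[:, ::-1] * mu_t
    if mu_g > 0:
        out = out + (x.sum(axis=0, keepdims=True) - x) * mu_g / (params.L_max - 1)
    return PopulationState(out)


def generation_step(
    state: PopulationState, params: ModelParams, probs: CoalescenceProbs
) -> PopulationState:
    """One full generation: selection, then recombination, then mutation."""
    fit = fitness(state, compute_mterms(state, probs, params), params)
    out = selection_step(state, fit)
    out = recombination_step(out, probs, params)
    return mutation_step(out, params)


def standard_initial_state(L_max: int, seed: int) -> PopulationState:
    """One tag at frequency 0.9, the remaining 0.1 split randomly (flat
    Dirichlet, all strictly positive) among the other tags; helper
    proportion 0.1 on every tag."""
    if L_max < 1:
        raise ParameterError("L_max must be >= 1")
    rng = np.random.default_rng(seed)
    tags = np.empty(L_max)
    tags[0] = 0.9
    if L_max > 1:
        rest = rng.dirichlet(np.ones(L_max - 1))
        # flat Dirichlet gives positive mass a.s.; clip pathological draws
        rest = np.maximum(rest, 1e-12)
        tags[1:] = 0.1 * rest / rest.sum()
    else:
        tags[0] = 1.0
    x = np.column_stack([0.9 * tags, 0.1 * tags])
    return PopulationState(x / x.sum())


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    """Windowed summary statistics of a trajectory."""

    L_eff: float                  # effective segregating tag number
    coop: float                   # helping-allele frequency
    tag_diversity: float          # fraction of available diversity
    D: float                      # tag-frequency/helping linkage disequilibrium
    pedigree_deviation: float     # mean |R_tag - R_tag at p_i = p_bar|
    excess_helping: np.ndarray    # x_i (p_i - p_bar), per tag
    window: tuple[int, int]       # (T_end, T_interval)


def state_stats(
    state: PopulationState, probs: CoalescenceProbs | None = None
) -> dict:
    """Point-in-time statistics of one state.

    ``pedigree_deviation`` needs the IBD probabilities; it is ``nan`` when
    ``probs`` is omitted.
    """
    x_i = state.tag_freq
    p_i = state.helper_prop
    p_bar = state.p_bar
    sumsq = float(np.sum(x_i**2))
    L_eff = 1.0 / sumsq if sumsq > 0 else float("nan")
    L_max = state.L_max
    diversity = (L_eff - 1.0) / (L_max - 1.0) if L_max > 1 else 0.0
    D = float(np.sum(x_i * (x_i - sumsq) * (p_i - p_bar)))
    excess = x_i * (p_i - p_bar)
    ped = float("nan")
    if probs is not None:
        from .inclusive_fitness import r_tag  # local import: avoids a cycle

        seg = x_i > 0
        if p_bar < 1.0:
            dev = np.zeros(L_max)
            for i in np.nonzero(seg)[0]:
                full = r_tag(float(x_i[i]), float(p_i[i]), p_bar, probs)
                no_ld = r_tag(float(x_i[i]), p_bar, p_bar, probs)
                dev[i] = abs(no_ld - full)
            ped = float(np.sum(x_i * dev))
    return {
        "L_eff": L_eff,
        "coop": p_bar,
        "tag_diversity": diversity,
        "D": D,
        "pedigree_deviation": ped,
        "excess_helping": excess,
        "sumsq": sumsq,
    }


def summary_stats(
    trajectory: Sequence[PopulationState] | Sequence[np.ndarray],
    T_end: int,
    T_interval: int,
    probs: CoalescenceProbs | None = None,
) -> SummaryStats:
    """Window-averaged summary statistics of a recorded trajectory.

    The window runs from generation ``T_end - T_interval`` to ``T_end``
    inclusive (generation 0 is the initial state).  ``L_eff`` is the
    inverse of the frequency-weighted mean tag frequency averaged over the
    window; ``coop`` the window-mean helping-allele frequency.  The
    remaining statistics are evaluated at generation ``T_end``.
    """
    if T_interval < 0 or T_end < 1:
        raise ParameterError("need T_interval >= 0 and T_end >= 1")
    if T_end >= len(trajectory) or T_end - T_interval < 0:
        raise ParameterError(
            f"window [{T_end - T_interval}, {T_end}] outside trajectory of "
            f"length {len(trajectory)}"
        )

    def as_state(s):
        return s if isinstance(s, PopulationState) else PopulationState(s)

    sumsq_acc = 0.0
    coop_acc = 0.0
    for t in range(T_end - T_interval, T_end + 1):
        s = as_state(trajectory[t])
        xf = s.tag_freq
        sumsq_acc += float(np.sum(xf**2))
        coop_acc += s.p_bar
    n = T_interval + 1
    final = as_state(trajectory[T_end])
    pt = state_stats(final, probs)
    L_max = final.L_max
    L_eff = n / sumsq_acc
    return SummaryStats(
        L_eff=L_eff,
        coop=coop_acc / n,
        tag_diversity=(L_eff - 1.0) / (L_max - 1.0) if L_max > 1 else 0.0,
        D=pt["D"],
        pedigree_deviation=pt["pedigree_deviation"],
        excess_helping=pt["excess_helping"],
        window=(T_end, T_interval),
    )


# ---------------------------------------------------------------------------
# Iteration to equilibrium
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceConfig:
    """Equilibrium detection settings.

    Equilibrium is declared when the windowed summary statistics
    ``(L_eff, coop)`` change by less than ``tol`` between consecutive
    windows of ``window`` generations.
    """

    tol: float = 1e-9
    window: int = 1000
    max_generations: int = 2_000_000
    record_every: int = 0  # 0: do not record per-generation statistics


@dataclass
class EquilibriumResult:
    state: PopulationState
    stats: SummaryStats
    converged: bool
    generations: int
    trajectory: "pd.DataFrame | None" = None  # noqa: F821 (optional pandas)


def iterate_to_equilibrium(
    initial: PopulationState,
    params: ModelParams,
    convergence: ConvergenceConfig | None = None,
    probs: CoalescenceProbs | None = None,
) -> EquilibriumResult:
    """Iterate the recursion until the windowed summaries stop changing.

    Returns the final state, the last window's summary statistics, a
    convergence flag (``False`` if the generation cap was reached first)
    and, when ``record_every > 0``, a tidy per-generation trajectory.
    """
    conv = convergence or ConvergenceConfig()
    if probs is None:
        probs = equilibrium_two_locus(params.demography)
    try:
        from ._kernels import run_generations_fast as _fast
    except Exception:  # pragma: no cover - numba missing
        _fast = None

    state = initial.copy()
    if state.L_max != params.L_max:
        raise ParameterError("state and params disagree on L_max")

    records: list[dict] = []
    gen = 0

    def record(s: PopulationState) -> None:
        if conv.record_every and gen % conv.record_every == 0:
            st = state_stats(s, probs)
            row = {
                "generation": gen,
                "L_eff": st["L_eff"],
                "coop": st["coop"],
                "tag_diversity": st["tag_diversity"],
                "D": st["D"],
                "pedigree_deviation": st["pedigree_deviation"],
            }
            xf = s.tag_freq
            pp = s.helper_prop
            for i in range(s.L_max):
                row[f"x_{i + 1}"] = xf[i]
                row[f"p_{i + 1}"] = pp[i]
            records.append(row)

    record(state)
    prev_summary: tuple[float, float] | None = None
    converged = False
    last_window = (0.0, 0.0)

    while gen < conv.max_generations:
        sumsq_acc = 0.0
        coop_acc = 0.0
        steps = min(conv.window, conv.max_generations - gen)
        if _fast is not None and not conv.record_every:
            x, sumsq_acc, coop_acc = _fast(
                state.x, steps, probs.F, probs.phi, probs.gamma, probs.G,
                params.alpha, params.c_search, params.b, params.c,
                params.mu_trait, params.mu_tag, params.N, params.m, params.r,
            )
            if np.any(x < 0) or not np.isfinite(x).all():
                raise ParameterError("model undefined: negative fitness")
            state = PopulationState(x)
            gen += steps
        else:
            for _ in range(steps):
                state = generation_step(state, params, probs)
                gen += 1
                xf = state.tag_freq
                sumsq_acc += float(np.sum(xf**2))
                coop_acc += state.p_bar
                record(state)
        window_summary = (steps / sumsq_acc, coop_acc / steps)
        last_window = window_summary
        if prev_summary is not None:
            delta = max(
                abs(window_summary[0] - prev_summary[0]),
                abs(window_summary[1] - prev_summary[1]),
            )
            if delta < conv.tol:
                converged = True
                break
        prev_summary = window_summary

    pt = state_stats(state, probs)
    stats = SummaryStats(
        L_eff=last_window[0],
        coop=last_window[1],
        tag_diversity=(last_window[0] - 1.0) / (params.L_max - 1.0)
        if params.L_max > 1
        else 0.0,
        D=pt["D"],
        pedigree_deviation=pt["pedigree_deviation"],
        excess_helping=pt["excess_helping"],
        window=(gen, conv.window - 1),
    )
    traj = None
    if records:
        import pandas as pd

        traj = pd.DataFrame.from_records(records)
    return EquilibriumResult(
        state=state, stats=stats, converged=converged, generations=gen,
        trajectory=traj,
    )
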