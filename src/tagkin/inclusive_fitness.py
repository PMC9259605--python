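"""Relatedness coefficients and Hamilton's-rule analytics.

Relatedness is a regression coefficient through the population mean
helping-allele frequency: ``R = (lambda - p_bar) / (1 - p_bar)`` where
``lambda`` is the probability that the affected individual carries the
helping allele.  Two coefficients matter for the conditional-helping
trait: ``R_tag`` (actor to its tag-matched recipient) and
``R_competitor`` (actor to the individuals displaced by the competition
its help induces).  Kin discrimination is favoured when

    R_tag * b - c - (b - c) * R_competitor > 0,

with both coefficients evaluated at equalised tag frequencies
(``x_i = 1/L_max``) and no tag-trait association (``p_i = p_bar``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .coalescence import CoalescenceProbs
from .engine import m_interact
from .params import ModelParams, ParameterError

__all__ = [
    "InclusiveFitnessPayoffs",
    "relatedness_from_lambda",
    "r_tag",
    "r_tag_no_ld",
    "r_tag_equalised",
    "r_competitor",
    "r_competitor_local",
    "r_competitor_no_ld",
    "hamilton_condition",
    "if_payoffs",
]


@dataclass(frozen=True)
class InclusiveFitnessPayoffs:
    """Per-interaction inclusive-fitness payoffs of the three strategies."""

    IF_conditional: float
    IF_indiscriminate: float
    IF_defection: float = 0.0  # non-social baseline, zero by definition
    hamilton_satisfied: bool = False


def relatedness_from_lambda(lam: float, p_bar: float) -> float:
    """``(lambda - p_bar) / (1 - p_bar)``; the actor itself has lambda = 1."""
    if not (0.0 <= lam <= 1.0):
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    if not (0.0 <= p_bar < 1.0):
        raise ParameterError(
            f"p_bar must be in [0, 1); relatedness is undefined at fixation "
            f"(got {p_bar})"
        )
    return (lam - p_bar) / (1.0 - p_bar)


def r_tag(x_i: float, p_i: float, p_bar: float, probs: CoalescenceProbs) -> float:
    """Relatedness of an actor (tag ``i``) to its tag-matched recipient.

    Full tag-trait-association form; reduces to :func:`r_tag_no_ld` when
    ``p_i = p_bar``.
    """
    if x_i <= 0.0:
        raise ParameterError("r_tag undefined for an absent tag (x_i = 0)")
    if not (0.0 <= p_bar < 1.0):
        raise ParameterError("r_tag undefined at helping-allele fixation")
    F, phi = probs.F, probs.phi
    num = (
        x_i * (-2.0 * F * p_i + F + (p_i - 1.0) * phi + p_i)
        + F * p_i
        - p_i * phi
        + phi
    )
    den = x_i * (1.0 - F) + F
    lam = num / den
    return (lam - p_bar) / (1.0 - p_bar)


def r_tag_no_ld(x_i: float, probs: CoalescenceProbs) -> float:
    """``(phi + (F - phi) x_i) / (F + (1 - F) x_i)``: the no-association
    (pedigree) relatedness between tag-matched social partners."""
    F, phi = probs.F, probs.phi
    den = F + (1.0 - F) * x_i
    if den == 0.0:
        raise ParameterError("r_tag_no_ld undefined at F = 0, x_i = 0")
    return (phi + (F - phi) * x_i) / den


def r_tag_equalised(L_max: int, probs: CoalescenceProbs) -> float:
    """No-association relatedness with all tags at frequency 1/L_max:
    ``(F + phi (L_max - 1)) / (1 + F (L_max - 1))``."""
    F, phi = probs.F, probs.phi
    return (F + phi * (L_max - 1)) / (1.0 + F * (L_max - 1))


def _lambda_competitor(
    x_i: float, p_bar: float, probs: CoalescenceProbs, alpha: float
) -> float:
    """Helping-allele probability of a non-self, non-recipient deme-mate.

    Mixture over the four IBD classes of (actor, competitor, actor's
    ultimate partner), each divided by the interaction probability because
    relatedness is counted per realised social interaction.
    """
    F, gamma = probs.F, probs.gamma
    M = m_interact(x_i, F, alpha)
    if M <= 0.0:
        raise ParameterError("competitor relatedness undefined when the "
                             "interaction probability is zero")
    S = x_i + (1.0 - x_i) * alpha * M
    return (
        gamma / M
        + (F - gamma) * p_bar / M
        + (F - gamma) * (S / M)
        + (1.0 - 2.0 * F + gamma) * (S / M) * p_bar
    )


def r_competitor_local(
    x_i: float,
    p_i: float,
    p_bar: float,
    probs: CoalescenceProbs,
    params: ModelParams,
) -> float:
    """Expected relatedness of an actor to a displaced *local* competitor.

    Mixture over: the competitor being the actor itself (1/N), the
    recipient (1/N), or another deme-mate.  At ``x_i = 1`` this is
    ``1/N + (N - 1) F / N``.
    """
    if x_i <= 0.0:
        raise ParameterError("competitor relatedness undefined for an absent tag")
    N = params.N
    rt = r_tag(x_i, p_i, p_bar, probs)
    lam = _lambda_competitor(x_i, p_bar, probs, params.alpha)
    other = (lam - p_bar) / (1.0 - p_bar)
    return 1.0 / N + rt / N + (1.0 - 2.0 / N) * other


def r_competitor(
    x_i: float,
    p_i: float,
    p_bar: float,
    probs: CoalescenceProbs,
    params: ModelParams,
) -> float:
    """Expected relatedness of an actor to a displaced competitor.

    With probability ``m`` the competitor is from another deme
    (relatedness 0), else it is a local competitor, hence the ``1 - m``
    prefactor on :func:`r_competitor_local`.
    """
    return (1.0 - params.m) * r_competitor_local(x_i, p_i, p_bar, probs, params)


def r_competitor_no_ld(
    x_i: float, probs: CoalescenceProbs, params: ModelParams
) -> float:
    """Closed no-association form of :func:`r_competitor`.

    ``(1-m) (1/N + R_tag_no_ld/N + (1 - 2/N)
    (gamma + x (F - gamma) - alpha (1-x)(gamma - F^2)) / (F + (1-F) x))``.
    """
    F, gamma = probs.F, probs.gamma
    N, m, alpha = params.N, params.m, params.alpha
    den = F + (1.0 - F) * x_i
    if den == 0.0:
        raise ParameterError("undefined at F = 0, x_i = 0")
    other = (gamma + x_i * (F - gamma)
             - alpha * (1.0 - x_i) * (gamma - F * F)) / den
    return (1.0 - m) * (
        1.0 / N + r_tag_no_ld(x_i, probs) / N + (1.0 - 2.0 / N) * other
    )


def hamilton_condition(params: ModelParams, probs: CoalescenceProbs) -> bool:
    """Is kin discrimination favoured over defection?

    Evaluates ``R_tag b - c - (b - c) R_competitor > 0`` with both
    coefficients at equalised tags (``x_i = 1/L_max``) and no tag-trait
    association (``p_i = p_bar``).  Boundary points (equality) classify as
    not favoured.
    """
    return if_payoffs(params, probs).hamilton_satisfied


def if_payoffs(params: ModelParams, probs: CoalescenceProbs) -> InclusiveFitnessPayoffs:
    """Inclusive-fitness payoffs of conditional and indiscriminate helping.

    ``IF_conditional`` uses the equalised-tag relatedness coefficients;
    ``IF_indiscriminate`` is the closed form obtained at tag fixation,
    which is negative whenever ``m > 0`` and ``c > 0``.
    """
    b, c, N, m = params.b, params.c, params.N, params.m
    x_eq = 1.0 / params.L_max
    rt = r_tag_equalised(params.L_max, probs)
    rc = r_competitor_no_ld(x_eq, probs, params)
    if_cond = rt * b - (b - c) * rc - c
    if_ind = -(
        m * ((b - c) * (1.0 - m) + c * N * (2.0 - m))
        / (m * (2.0 - m) * (N - 1) + 1.0)
    )
    return InclusiveFitnessPayoffs(
        IF_conditional=if_cond,
        IF_indiscriminate=if_ind,
        hamilton_satisfied=if_cond > 0.0,
    )
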