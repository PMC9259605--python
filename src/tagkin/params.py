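"""Parameter containers and validity checks for the island-model lifecycle."""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass(frozen=True)
class DemographyParams:
    """Demographic parameters of the island model.

    Attributes
    ----------
    N : int
        Number of haploid adults per deme (>= 2).
    m : float
        Per-gamete migration probability, in [0, 1].
    r : float
        Recombination probability between the tag and trait loci, in [0, 0.5].
    """

    N: int
    m: float
    r: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int,)) and self.N >= 2):
            raise ParameterError(f"deme size N must be an integer >= 2, got {self.N!r}")
        if not (0.0 <= self.m <= 1.0):
            raise ParameterError(f"migration m must be in [0, 1], got {self.m}")
        if not (0.0 <= self.r <= 0.5):
            raise ParameterError(f"recombination r must be in [0, 0.5], got {self.r}")


@dataclass(frozen=True)
class ModelParams:
    """All parameters of one model instance.

    The validity constraint ``1 - alpha/(1-alpha) * c_search - c > 0`` (for
    ``alpha < 1``) guarantees that no individual can have negative fitness: the
    worst-case total search cost is ``alpha * c_search / (1 - alpha)``.  At
    ``alpha = 1`` the expected abandonment count is unbounded for a rare tag,
    so ``c_search`` must be exactly 0 there.
    """

    demography: DemographyParams
    alpha: float = 1.0
    c_search: float = 0.0
    b: float = 0.3
    c: float = 0.1
    mu_trait: float = 0.001
    mu_tag: float = 0.0
    L_max: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.c_search < 0:
            raise ParameterError(f"c_search must be >= 0, got {self.c_search}")
        neutral = self.b == 0.0 and self.c == 0.0
        if not neutral and not (self.b > self.c >= 0):
            raise ParameterError(
                f"need net benefit b > c >= 0 (or b = c = 0 for a neutral "
                f"model), got b={self.b}, c={self.c}"
            )
        if not (0.0 <= self.mu_trait <= 1.0):
            raise ParameterError(f"mu_trait must be in [0, 1], got {self.mu_trait}")
        if not (0.0 <= self.mu_tag <= 1.0):
            raise ParameterError(f"mu_tag must be in [0, 1], got {self.mu_tag}")
        if not (isinstance(self.L_max, int) and self.L_max >= 1):
            raise ParameterError(f"L_max must be an integer >= 1, got {self.L_max!r}")
        if self.L_max == 1 and self.mu_tag > 0:
            raise ParameterError("tag mutation requires L_max > 1")
        if self.alpha == 1.0:
            if self.c_search != 0.0:
                raise ParameterError(
                    "alpha = 1 requires c_search = 0 (unbounded abandonment count)"
                )
        else:
            worst = 1.0 - self.alpha / (1.0 - self.alpha) * self.c_search - self.c
            if worst <= 0.0:
                raise ParameterError(
                    "invalid parameters: 1 - alpha/(1-alpha)*c_search - c = "
                    f"{worst:.6g} <= 0 (fitness could go negative)"
                )

    @property
    def N(self) -> int:
        return self.demography.N

    @property
    def m(self) -> float:
        return self.demography.m

    @property
    def r(self) -> float:
        return self.demography.r

    @property
    def max_search_cost(self) -> float:
        """Worst-case per-generation total search cost, alpha*c_search/(1-alpha)."""
        if self.alpha == 1.0:
            return 0.0 if self.c_search == 0.0 else float("inf")
        return self.alpha * self.c_search / (1.0 - self.alpha)
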