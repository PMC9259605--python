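"""Parameter-space scans and stability classification.

A scan iterates the deterministic recursion to equilibrium on a grid of
(m, r) points, classifies each point as showing stable kin recognition
(more than ``min_tags`` effective tags maintained and helping frequency
above ``min_coop``) and compares the classification with the
Hamilton's-rule prediction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coalescence import equilibrium_two_locus
from .engine import ConvergenceConfig, iterate_to_equilibrium, m_interact, \
    standard_initial_state
from .inclusive_fitness import hamilton_condition
from .params import DemographyParams, ModelParams, ParameterError

__all__ = [
    "ScanConfig",
    "StabilityMap",
    "run_scan",
    "area_fraction",
    "interaction_probability_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Grid definition and classification thresholds for one scan."""

    m_values: np.ndarray
    r_values: np.ndarray
    N: int = 30
    alpha: float = 1.0
    c_search: float = 0.0
    b: float = 0.3
    c: float = 0.1
    mu_trait: float = 0.001
    mu_tag: float = 0.0
    L_max: int = 100
    min_tags: float = 10.0
    min_coop: float = 0.4
    seed: int = 0
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)

    def __post_init__(self) -> None:
        self.m_values = np.atleast_1d(np.asarray(self.m_values, dtype=float))
        self.r_values = np.atleast_1d(np.asarray(self.r_values, dtype=float))
        if self.m_values.size == 0 or self.r_values.size == 0:
            raise ParameterError("scan grids must be non-empty")

    @classmethod
    def default_grid(cls, **kwargs) -> "ScanConfig":
        """Coarse 8x8 default grid over m in [0.02, 0.9], r in [0, 0.5]."""
        return cls(
            m_values=np.linspace(0.02, 0.9, 8),
            r_values=np.linspace(0.0, 0.5, 8),
            **kwargs,
        )


@dataclass
class StabilityMap:
    """Per-grid-point equilibrium summaries and classifications."""

    table: pd.DataFrame
    config: ScanConfig

    @property
    def n_stable(self) -> int:
        return int(self.table["stable"].sum())


def run_scan(config: ScanConfig) -> StabilityMap:
    """Run the full grid scan.

    Invalid grid points (violating the fitness-positivity constraint) are
    recorded with ``valid = False`` rather than skipped.
    """
    rows = []
    for m in config.m_values:
        for r in config.r_values:
            t0 = time.perf_counter()
            row = {
                "m": float(m), "r": float(r), "alpha": config.alpha,
                "c_search": config.c_search, "L_star": np.nan,
                "coop_star": np.nan, "stable": False,
                "hamilton_favoured": False, "converged": False,
                "valid": True, "generations_used": 0,
            }
            try:
                demo = DemographyParams(N=config.N, m=float(m), r=float(r))
                params = ModelParams(
                    demography=demo, alpha=config.alpha,
                    c_search=config.c_search, b=config.b, c=config.c,
                    mu_trait=config.mu_trait, mu_tag=config.mu_tag,
                    L_max=config.L_max,
                )
            except ParameterError as exc:
                row["valid"] = False
                logger.info("scan point m=%.3g r=%.3g invalid: %s", m, r, exc)
                rows.append(row)
                continue
            probs = equilibrium_two_locus(demo)
            row["hamilton_favoured"] = hamilton_condition(params, probs)
            init = standard_initial_state(config.L_max, config.seed)
            res = iterate_to_equilibrium(init, params, config.convergence,
                                         probs=probs)
            row["L_star"] = res.stats.L_eff
            row["coop_star"] = res.stats.coop
            row["converged"] = res.converged
            row["generations_used"] = res.generations
            row["stable"] = bool(
                res.converged
                and res.stats.L_eff > config.min_tags
                and res.stats.coop > config.min_coop
            )
            logger.info(
                "scan point m=%.3g r=%.3g: L*=%.2f coop*=%.3f stable=%s "
                "hamilton=%s (%.2fs, %d gens)",
                m, r, row["L_star"], row["coop_star"], row["stable"],
                row["hamilton_favoured"], time.perf_counter() - t0,
                row["generations_used"],
            )
            rows.append(row)
    return StabilityMap(table=pd.DataFrame(rows), config=config)


def area_fraction(map_a: StabilityMap, map_b: StabilityMap) -> float:
    """Fraction of grid cells stable in ``map_a`` relative to ``map_b``.

    Both maps must share a grid.  Returns ``nan`` (with a log warning)
    when ``map_b`` has no stable cells.
    """
    for col in ("m", "r"):
        if not np.array_equal(map_a.table[col].values, map_b.table[col].values):
            raise ParameterError("area_fraction requires identical grids")
    denom = map_b.n_stable
    if denom == 0:
        logger.warning("area_fraction undefined: reference map has no "
                       "stable cells")
        return float("nan")
    return map_a.n_stable / denom


def interaction_probability_curve(
    alpha_values, tag_frequencies, probs
) -> pd.DataFrame:
    """Tabulate the interaction probability over (alpha, tag frequency)."""
    rows = []
    for x in np.atleast_1d(tag_frequencies):
        for a in np.atleast_1d(alpha_values):
            rows.append({
                "alpha": float(a),
                "tag_frequency": float(x),
                "p_interact": float(m_interact(float(x), probs.F, float(a))),
            })
    return pd.DataFrame(rows)
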