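"""Shared numerical configuration.

All modules report a quantity as "zero" iff its magnitude is at most
``zero_tol``; the same threshold is used for blocked reactions and for
lethality of forced balancing, and the LP solver is run with a feasibility
tolerance one order of magnitude tighter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Config:
    """Numerical and screening parameters used across the package.

    Parameters
    ----------
    zero_tol:
        Threshold below which an LP optimum (an activity, a flux) counts
        as zero. Units: flux (mmol gDW^-1 h^-1).
    lethal_tol:
        Optimal biomass flux below which forced balancing counts as lethal
        (strict ``<`` comparison).
    healthy_fraction:
        Minimum fraction of the healthy model's optimal growth a candidate
        complex must retain under forced balancing.
    x_min:
        Smallest balancing potential included in distribution fits.
    bound_cap:
        Finite bound substituted for infinite flux bounds before any LP.
    solver:
        LP backend name; only "highs" (scipy's HiGHS interface) is shipped.
    """

    zero_tol: float = 1e-9
    lethal_tol: float = 1e-9
    healthy_fraction: float = 0.9
    x_min: int = 1
    bound_cap: float = 1000.0
    solver: str = "highs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zero_tol <= 0 or self.lethal_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must lie in [0, 1]")

    @property
    def feasibility_tol(self) -> float:
        return self.zero_tol / 10.0

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = Config()
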