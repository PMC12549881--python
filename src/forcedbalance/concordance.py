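"""Concordance modules of non-balanced complexes.

Two complexes are *concordant* when their activities are proportional with
a nonzero ratio across the whole steady-state flux space: there is a
gamma != 0 with ``A^{i:} v = gamma A^{j:} v`` for every ``v`` in ``S``.
Concordance is an equivalence relation on the non-balanced complexes and
partitions them into *concordance modules*.

The test uses a witness flux ``w`` with nonzero activity of ``i`` (cached
from balanced-complex detection): if coupling holds, the ratio is uniquely
``gamma = (A^{j:} w) / (A^{i:} w)``, so two verification LPs — minimum and
maximum of ``(A^{j:} - gamma A^{i:}) v`` over ``S`` — certify or refute it.
A candidate gamma of magnitude <= zero_tol refutes immediately (coupling
requires a nonzero ratio). Normalization tricks such as fixing
``A^{i:} v = 1`` are unsound here because ``S`` contains ``v = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balancing import BalanceStatus, find_balanced
from .config import Config, DEFAULT_CONFIG
from .decomposition import ComplexDecomposition
from .lp import optimize_row
from .model import InfeasibleModelError, MetabolicNetwork

__all__ = ["ConcordancePartition", "are_concordant", "build_partition"]


@dataclass(frozen=True)
class ConcordancePartition:
    """Modules (lists of complex indices) with coupling coefficients.

    ``gamma[j]`` satisfies ``A^{j:} v = gamma[j] * A^{r:} v`` on S, where
    ``r`` is the module representative (the lowest index in the module);
    gamma of a representative is 1.
    """

    modules: tuple[tuple[int, ...], ...]
    gamma: dict[int, float] = field(default_factory=dict)

    @property
    def representatives(self) -> tuple[int, ...]:
        return tuple(min(m) for m in self.modules)

    @property
    def module_of(self) -> dict[int, int]:
        return {j: k for k, m in enumerate(self.modules) for j in m}

    def module_members(self, i: int) -> tuple[int, ...]:
        return self.modules[self.module_of[i]]


def are_concordant(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    i: int,
    j: int,
    witness_i: np.ndarray,
    config: Config = DEFAULT_CONFIG,
) -> tuple[bool, float | None]:
    """Test coupling of the activities of complexes i and j.

    ``witness_i`` must have nonzero activity of ``i``. Returns (True,
    gamma) with ``A^{j:} v = gamma A^{i:} v`` on S, or (False, None).
    """
    row_i = dec.activity_row(i)
    act_i = float(row_i @ witness_i)
    if abs(act_i) <= config.zero_tol:
        raise ValueError("witness flux has zero activity for complex i")
    if i == j:
        return True, 1.0
    row_j = dec.activity_row(j)
    gamma = float(row_j @ witness_i) / act_i
    if abs(gamma) <= config.zero_tol:
        return False, None
    diff = row_j - gamma * row_i
    lo = optimize_row(net, diff, "min", config=config)
    hi = optimize_row(net, diff, "max", config=config)
    if lo.status != "optimal" or hi.status != "optimal":
        raise InfeasibleModelError("flux space empty while testing concordance")
    if abs(float(lo.objective_value)) <= config.zero_tol and abs(
        float(hi.objective_value)
    ) <= config.zero_tol:
        return True, gamma
    return False, None


def build_partition(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    statuses: list[BalanceStatus] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> ConcordancePartition:
    """Partition the non-balanced complexes into concordance modules.

    Each non-balanced complex (in index order, for determinism) is tested
    against the representative of every existing module only — transitivity
    makes that sufficient — and opens a new module when no test succeeds.
    """
    if statuses is None:
        statuses = find_balanced(net, dec, config=config)
    witnesses = {s.index: s.witness for s in statuses if not s.balanced}
    modules: list[list[int]] = []
    reps: list[int] = []
    gamma: dict[int, float] = {}
    for j in sorted(witnesses):
        placed = False
        for k, r in enumerate(reps):
            ok, g = are_concordant(net, dec, r, j, witnesses[r], config=config)
            if ok:
                modules[k].append(j)
                gamma[j] = g
                placed = True
                break
        if not placed:
            modules.append([j])
            reps.append(j)
            gamma[j] = 1.0
    return ConcordancePartition(
        modules=tuple(tuple(m) for m in modules), gamma=gamma
    )
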