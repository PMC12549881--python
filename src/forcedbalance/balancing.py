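"""Balanced complexes, forced balancing and balancing potentials.

A complex ``C_i`` is *balanced* when its activity ``A^{i:} v`` is zero for
every steady-state flux distribution in ``S``; this is certified by two
LPs (the minimum and maximum of the activity over ``S`` both vanish). A
balanced complex is *trivially* balanced when it contains a species that
occurs in no other complex — species balancing then forces the activity to
zero regardless of the rest of the network.

*Forced balancing* of a non-balanced complex ``C_i`` intersects ``S`` with
the hyperplane ``A^{i:} v = 0`` and asks which other non-balanced complexes
become balanced; that set is ``Q_i`` and its size is the *balancing
potential* of ``C_i``. Members of ``Q_i`` split into:

- trivially forcedly balanced: concordant with ``C_i`` (same module);
- non-trivially forcedly balanced, type I: every reaction around the
  member is blocked under the constraint;
- non-trivially forcedly balanced, type II: some incoming and some
  outgoing reactions around the member still carry flux.

All complexes in a concordance module share one balancing potential, so
potentials are computed once per module via a representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .decomposition import ComplexDecomposition, sinks_and_sources
from .lp import optimize_row
from .model import InfeasibleModelError, MetabolicNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .concordance import ConcordancePartition

__all__ = [
    "BalanceStatus",
    "ForcedBalancingResult",
    "find_trivially_balanced",
    "find_balanced",
    "force_balance",
    "balancing_potential_all",
    "classify_forced_summary",
    "TRIVIAL",
    "TYPE_I",
    "TYPE_II",
]

TRIVIAL = "trivial"
TYPE_I = "nontrivial_type_I"
TYPE_II = "nontrivial_type_II"


@dataclass(frozen=True)
class BalanceStatus:
    index: int
    balanced: bool
    trivially_balanced: bool
    witness: np.ndarray | None = None  # flux with nonzero activity, if non-balanced


@dataclass(frozen=True)
class ForcedBalancingResult:
    source: int
    Q: frozenset[int]
    classification: dict[int, str] = field(default_factory=dict)

    @property
    def potential(self) -> int:
        return len(self.Q)


def find_trivially_balanced(dec: ComplexDecomposition) -> set[int]:
    """Complexes containing a species that appears in no other complex."""
    count: dict[str, int] = {}
    for c in dec.complexes:
        for s in c.species_ids:
            count[s] = count.get(s, 0) + 1
    return {
        c.id
        for c in dec.complexes
        if any(count[s] == 1 for s in c.species_ids)
    }


def find_balanced(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    extra_equalities=(),
    config: Config = DEFAULT_CONFIG,
) -> list[BalanceStatus]:
    """Decide balancedness of every complex by LP min/max of its activity.

    For sinks (activity pointwise <= 0 under non-negative fluxes) and
    sources (>= 0) one LP suffices in a blocked-free network, and it doubles
    as the non-balancedness witness reused by concordance.
    """
    sinks, sources = sinks_and_sources(dec)
    trivial = find_trivially_balanced(dec)
    statuses: list[BalanceStatus] = []
    for c in dec.complexes:
        i = c.id
        row = dec.activity_row(i)
        if i in sinks or i in sources:
            sense = "max" if i in sinks else "min"
            res = optimize_row(net, row, sense, extra_equalities, config)
            if res.status != "optimal":
                raise InfeasibleModelError("flux space empty while testing balance")
            extreme = float(res.objective_value)
            balanced = abs(extreme) <= config.zero_tol
            witness = None if balanced else res.solution
            statuses.append(BalanceStatus(i, balanced, False, witness))
            continue
        lo_res = optimize_row(net, row, "min", extra_equalities, config)
        hi_res = optimize_row(net, row, "max", extra_equalities, config)
        if lo_res.status != "optimal" or hi_res.status != "optimal":
            raise InfeasibleModelError("flux space empty while testing balance")
        lo, hi = float(lo_res.objective_value), float(hi_res.objective_value)
        balanced = abs(lo) <= config.zero_tol and abs(hi) <= config.zero_tol
        witness = None
        if not balanced:
            witness = hi_res.solution if abs(hi) >= abs(lo) else lo_res.solution
        statuses.append(BalanceStatus(i, balanced, balanced and i in trivial, witness))
    return statuses


def _balanced_under(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    j: int,
    extra_equalities,
    config: Config,
) -> bool:
    row = dec.activity_row(j)
    lo = optimize_row(net, row, "min", extra_equalities, config)
    hi = optimize_row(net, row, "max", extra_equalities, config)
    if lo.status != "optimal" or hi.status != "optimal":
        raise InfeasibleModelError("constrained flux space empty")
    return (
        abs(float(lo.objective_value)) <= config.zero_tol
        and abs(float(hi.objective_value)) <= config.zero_tol
    )


def force_balance(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    i: int,
    partition: "ConcordancePartition | None" = None,
    statuses: list[BalanceStatus] | None = None,
    classify: bool = True,
    config: Config = DEFAULT_CONFIG,
) -> ForcedBalancingResult:
    """Impose A^{i:} v = 0 and collect the induced balanced set Q_i.

    ``Q_i`` contains the non-balanced complexes (excluding ``i`` itself)
    whose activity vanishes everywhere on the constrained space. When
    ``classify`` is true each member is labelled trivial (concordant with
    ``i``; requires ``partition``), type I (all incident reactions blocked
    under the constraint) or type II. Forcing an already-balanced complex
    yields an empty ``Q`` — the constraint is implied by ``S``.
    """
    if statuses is None:
        statuses = find_balanced(net, dec, config=config)
    nonbalanced = [s.index for s in statuses if not s.balanced]
    if i not in nonbalanced:
        return ForcedBalancingResult(source=i, Q=frozenset())
    constraint = ((dec.activity_row(i), 0.0),)
    members: list[int] = []
    for j in nonbalanced:
        if j == i:
            continue
        if _balanced_under(net, dec, j, constraint, config):
            members.append(j)
    classification: dict[int, str] = {}
    if classify:
        module_of = partition.module_of if partition is not None else {}
        for j in members:
            if partition is not None and module_of.get(j) == module_of.get(i):
                classification[j] = TRIVIAL
                continue
            classification[j] = _type_of(net, dec, j, constraint, config)
    return ForcedBalancingResult(source=i, Q=frozenset(members),
                                 classification=classification)


def _type_of(net, dec, j, constraint, config: Config) -> str:
    """Type I iff every reaction around j is blocked under the constraint."""
    from .lp import fva

    incident = dec.incident_reactions(j)
    ranges = fva(net, incident, constraint, config=config)
    all_blocked = all(
        abs(lo) <= config.zero_tol and abs(hi) <= config.zero_tol
        for lo, hi in ranges
    )
    return TYPE_I if all_blocked else TYPE_II


def balancing_potential_all(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    partition: "ConcordancePartition",
    statuses: list[BalanceStatus] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> dict[int, int]:
    """Balancing potential for every complex.

    Concordant complexes share one potential, so each module is forced once
    through its representative and the value copied to the members.
    Balanced complexes map to zero.
    """
    if statuses is None:
        statuses = find_balanced(net, dec, config=config)
    potentials = {s.index: 0 for s in statuses}
    for module in partition.modules:
        rep = min(module)
        res = force_balance(
            net, dec, rep, partition=partition, statuses=statuses,
            classify=False, config=config,
        )
        for j in module:
            potentials[j] = res.potential
    return potentials


def classify_forced_summary(
    results: list[ForcedBalancingResult],
    partition: "ConcordancePartition",
) -> dict[str, float | None]:
    """Per-network fractions over non-balanced complexes.

    Reports which fraction of the forced complexes (the sources in
    ``results``, expected to be all non-balanced complexes) have nonzero
    potential, balance at least one complex outside their own concordance
    module, and induce at least one type-II member. ``None`` when there are
    no non-balanced complexes.
    """
    n = len(results)
    if n == 0:
        return {"nonzero_potential": None, "balances_outside_module": None,
                "induces_type_II": None}
    module_of = partition.module_of
    nonzero = sum(1 for r in results if r.potential > 0)
    outside = sum(
        1
        for r in results
        if any(module_of.get(j) != module_of.get(r.source) for j in r.Q)
    )
    type2 = sum(
        1 for r in results if any(c == TYPE_II for c in r.classification.values())
    )
    return {
        "nonzero_potential": nonzero / n,
        "balances_outside_module": outside / n,
        "induces_type_II": type2 / n,
    }
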