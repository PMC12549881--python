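"""FBA-based lethality of forced balancing and differential screening.

Given a model with a biomass reaction, the screen computes the optimal
growth ``z`` and, for every non-balanced complex ``C_i``, the optimum
``z_i*`` under the forced-balancing constraint ``A^{i:} v = 0``. Forcing is
*lethal* when ``z_i* < lethal_tol`` (strict). Across a paired
disease/healthy model, *candidate complexes* are the complexes present in
both models (matched by canonical label) whose forcing is lethal in the
disease model yet leaves at least ``healthy_fraction`` of the healthy
model's optimum.

Reaction essentiality (single knockout abolishes growth) and a Fisher
exact enrichment of essential reactions among the reactions incident on a
concordance module connect the screen back to classical essentiality
analysis. The Fisher test is computed directly from the hypergeometric
distribution (two-sided by summing tables no more probable than the
observed one), so its values do not depend on the LP backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .balancing import BalanceStatus, find_balanced
from .concordance import ConcordancePartition
from .config import Config, DEFAULT_CONFIG
from .decomposition import ComplexDecomposition, build_decomposition
from .lp import optimize_row
from .model import MetabolicNetwork, Reaction

__all__ = [
    "GrowthResult",
    "ScreenResult",
    "fba",
    "lethality_screen",
    "candidate_complexes",
    "essential_reactions",
    "module_enrichment",
    "fisher_exact_p",
    "exchange_balancing",
]


@dataclass(frozen=True)
class GrowthResult:
    model_id: str
    biomass_id: str
    z: float
    z_star: dict[int, float]  # complex index -> optimum under forcing
    lethal: dict[int, bool]
    labels: dict[int, str]  # complex index -> canonical label


@dataclass(frozen=True)
class ScreenResult:
    shared_complexes: tuple[str, ...]
    candidates: tuple[str, ...]
    detail: dict[str, dict] = field(default_factory=dict)


def fba(
    net: MetabolicNetwork,
    biomass_id: str,
    extra_equalities=(),
    config: Config = DEFAULT_CONFIG,
) -> float:
    """Maximum biomass flux over S (plus optional equalities).

    An infeasible constrained space is reported as zero growth — the
    biological reading of "no steady state supports growth".
    """
    j = net.reaction_index(biomass_id)
    obj = np.zeros(len(net.reactions))
    obj[j] = 1.0
    res = optimize_row(net, obj, "max", extra_equalities, config)
    if res.status != "optimal":
        return 0.0
    z = float(res.objective_value)
    return 0.0 if abs(z) <= config.zero_tol else z


def lethality_screen(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    biomass_id: str,
    statuses: list[BalanceStatus] | None = None,
    model_id: str = "model",
    config: Config = DEFAULT_CONFIG,
) -> GrowthResult:
    """z_i* for every non-balanced complex; lethal iff z_i* < lethal_tol.

    z_i* is computed per complex, not per concordance module: the optimal
    objective value is not proven constant within a module, only the
    balanced/non-balanced status is. Balanced complexes are skipped (their
    constraint is implied, so z_i* = z).
    """
    if statuses is None:
        statuses = find_balanced(net, dec, config=config)
    z = fba(net, biomass_id, config=config)
    z_star: dict[int, float] = {}
    lethal: dict[int, bool] = {}
    for s in statuses:
        if s.balanced:
            z_star[s.index] = z
            lethal[s.index] = z < config.lethal_tol
            continue
        zi = fba(net, biomass_id,
                 extra_equalities=((dec.activity_row(s.index), 0.0),),
                 config=config)
        z_star[s.index] = zi
        lethal[s.index] = zi < config.lethal_tol
    return GrowthResult(
        model_id=model_id,
        biomass_id=biomass_id,
        z=z,
        z_star=z_star,
        lethal=lethal,
        labels={c.id: c.label for c in dec.complexes},
    )


def candidate_complexes(
    disease: GrowthResult,
    healthy: GrowthResult,
    healthy_fraction: float | None = None,
    config: Config = DEFAULT_CONFIG,
) -> ScreenResult:
    """Shared complexes lethal in disease but tolerated by the healthy model.

    Complexes are matched across the pair by canonical label (identical
    composition in a shared species namespace). A candidate must be lethal
    in the disease model and retain at least ``healthy_fraction`` of the
    healthy model's own optimal growth.
    """
    if healthy_fraction is None:
        healthy_fraction = config.healthy_fraction
    d_by_label = {disease.labels[i]: i for i in disease.labels}
    h_by_label = {healthy.labels[i]: i for i in healthy.labels}
    shared = sorted(set(d_by_label) & set(h_by_label))
    candidates = []
    detail: dict[str, dict] = {}
    for lab in shared:
        di, hi = d_by_label[lab], h_by_label[lab]
        ok = disease.lethal[di] and (
            healthy.z_star[hi] >= healthy_fraction * healthy.z
        )
        detail[lab] = {
            "z_disease": disease.z,
            "z_star_disease": disease.z_star[di],
            "z_healthy": healthy.z,
            "z_star_healthy": healthy.z_star[hi],
            "candidate": ok,
        }
        if ok:
            candidates.append(lab)
    return ScreenResult(
        shared_complexes=tuple(shared),
        candidates=tuple(candidates),
        detail=detail,
    )


def essential_reactions(
    net: MetabolicNetwork,
    biomass_id: str,
    split_pairs: dict[str, tuple[str, str]] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> set[str]:
    """Reactions whose single knockout abolishes growth (z < lethal_tol).

    A split reversible reaction is knocked out as a forward/backward pair
    and reported once under its original id.
    """
    split_pairs = split_pairs or {}
    in_pair = {m for pair in split_pairs.values() for m in pair}
    n = len(net.reactions)
    groups: dict[str, list[int]] = {}
    for orig, (fwd, bwd) in split_pairs.items():
        groups[orig] = [net.reaction_index(fwd), net.reaction_index(bwd)]
    for j, r in enumerate(net.reactions):
        if r.id not in in_pair:
            groups[r.id] = [j]
    essential = set()
    for name, idx in groups.items():
        eqs = []
        for j in idx:
            e = np.zeros(n)
            e[j] = 1.0
            eqs.append((e, 0.0))
        if fba(net, biomass_id, extra_equalities=tuple(eqs), config=config) < config.lethal_tol:
            essential.add(name)
    return essential


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (with the observed
    margins) whose probability does not exceed the observed table's, with
    the customary (1 + 1e-7) slack on the comparison. A zero margin gives
    p = 1 (only one table is possible).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def module_enrichment(
    candidates: tuple[str, ...],
    partition: ConcordancePartition,
    dec: ComplexDecomposition,
    essential: set[str],
    config: Config = DEFAULT_CONFIG,
) -> dict[int, float | None]:
    """Fisher enrichment of essential reactions per candidate module.

    For every concordance module containing a candidate complex, the 2x2
    table counts reactions incident on the module's complexes versus the
    rest of the network, crossed with essential versus non-essential.
    Returns p-values keyed by module id; None for an empty module.
    """
    module_of = partition.module_of
    label_to_idx = {c.label: c.id for c in dec.complexes}
    cand_modules = sorted(
        {
            module_of[label_to_idx[lab]]
            for lab in candidates
            if label_to_idx.get(lab) in module_of
        }
    )
    all_rids = [r.id for r in dec.network.reactions]
    out: dict[int, float | None] = {}
    for k in cand_modules:
        incident: set[str] = set()
        for i in partition.modules[k]:
            incident.update(all_rids[j] for j in dec.incident_reactions(i))
        if not incident:
            out[k] = None
            continue
        a = len(incident & essential)
        b = len(incident) - a
        c = len(essential - incident)
        d = len(set(all_rids) - incident - essential)
        out[k] = fisher_exact_p(a, b, c, d)
    return out


def exchange_balancing(
    net: MetabolicNetwork,
    dec: ComplexDecomposition,
    species_id: str,
    target_complex: int,
    config: Config = DEFAULT_CONFIG,
) -> tuple[MetabolicNetwork, bool]:
    """Add an exchange for an internal species; recompute a target's balance.

    Emulates transporter engineering: a reversible exchange reaction for
    ``species_id`` is added as an already-split import/export pair, and the
    balanced status of the target complex (matched by label in the modified
    network) is recomputed. For sink or source complexes the outcome can
    differ from direct ``A^{i:} v = 0`` forcing, since the added exchange
    does not block the reactions around them.
    """
    if not net.is_internal(species_id):
        raise ValueError(f"species {species_id!r} already has an exchange reaction")
    if species_id not in {s.id for s in net.species}:
        raise KeyError(species_id)
    ub = max((r.upper_bound for r in net.reactions), default=config.bound_cap)
    label = dec.complexes[target_complex].label
    new = MetabolicNetwork(
        net.species,
        list(net.reactions)
        + [
            Reaction(f"EX_{species_id}__in", {}, {species_id: 1}, 0.0, ub),
            Reaction(f"EX_{species_id}__out", {species_id: 1}, {}, 0.0, ub),
        ],
    )
    new_dec = build_decomposition(new)
    statuses = find_balanced(new, new_dec, config=config)
    i = new_dec.by_label(label)
    return new, statuses[i].balanced
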