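"""Deterministic network generators.

Three generators back the test suite and the examples:

- :func:`toy_network` — an 18-reaction, 11-species TCA/glyoxylate-cycle toy
  network with 14 complexes whose balancing structure (balanced set,
  concordance modules, forced-balancing classification) is known in full
  and serves as the package's worked example;
- :func:`random_network` — small random mass-consistent irreversible
  networks for property tests;
- :func:`planted_pair` — paired "disease"/"healthy" models in which forced
  balancing of one planted complex severs the only biomass route of the
  disease model while the healthy model carries a bypass, emulating the
  tissue-pair screening setting. Invariants are verified by LP before the
  pair is returned.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .model import MetabolicNetwork, Reaction, Species

__all__ = ["toy_network", "random_network", "planted_pair", "PlantedPairSpec",
           "GenerationError"]


class GenerationError(RuntimeError):
    """A generator could not satisfy its invariants."""


# ---------------------------------------------------------------------------
# toy network
# ---------------------------------------------------------------------------

_TOY_SPECIES = (
    "AcCoa", "Cit", "Fum", "Gly", "Isocit", "Mal", "Oaa", "OG", "Pep",
    "Pyr", "Succ",
)

# (id, substrates, products); bounds (0, 1000) throughout. The reversible
# steps of the cycle (aconitase, SDH, fumarase, MDH) appear as explicit
# forward/backward pairs, for 18 irreversible reactions in total.
_TOY_REACTIONS = (
    ("r1", {"AcCoa": 1, "Oaa": 1}, {"Cit": 1}),
    ("r2", {"Cit": 1}, {"Isocit": 1}),
    ("r3", {"Isocit": 1}, {"Cit": 1}),
    ("r4", {"Isocit": 1}, {"OG": 1}),
    ("r5", {"OG": 1}, {"Succ": 1}),
    ("r6", {"Succ": 1}, {"Fum": 1}),
    ("r7", {"Fum": 1}, {"Succ": 1}),
    ("r8", {"Fum": 1}, {"Mal": 1}),
    ("r9", {"Mal": 1}, {"Fum": 1}),
    ("r10", {"Mal": 1}, {"Oaa": 1}),
    ("r11", {"Oaa": 1}, {"Mal": 1}),
    ("r12", {"Isocit": 1}, {"Succ": 1, "Gly": 1}),
    ("r13", {"AcCoa": 1, "Gly": 1}, {"Mal": 1}),
    ("r14", {"Pep": 1}, {"Oaa": 1}),
    ("r15", {"Pep": 1}, {"Pyr": 1}),
    ("r16", {"Pyr": 1}, {"AcCoa": 1}),
    ("r17", {}, {"Pep": 1}),
    ("r18", {"Oaa": 1}, {}),
)


def toy_network() -> MetabolicNetwork:
    """The 18-reaction, 11-species toy network (14 complexes).

    A TCA cycle with glyoxylate shunt, phosphoenolpyruvate entry point and
    two exchange reactions (Pep uptake, Oaa export). Every reaction is
    irreversible with bounds (0, 1000); the network contains no blocked
    reactions.
    """
    return MetabolicNetwork(
        [Species(s) for s in _TOY_SPECIES],
        [Reaction(rid, subs, prods, 0.0, 1000.0)
         for rid, subs, prods in _TOY_REACTIONS],
    )


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------


def random_network(
    n_species: int,
    n_reactions: int,
    seed: int = 0,
    exchange_fraction: float = 0.3,
) -> MetabolicNetwork:
    """Random connected irreversible network with unit bounds (0, 1000).

    A backbone chain through all species guarantees connectivity; the
    remaining reactions pick random small substrate/product sides, and a
    fraction of species get exchange reactions so the steady-state flux
    space has nonzero volume. Deterministic per seed.
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("n_species and n_reactions must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"S{k}" for k in range(n_species)]
    reactions: list[Reaction] = []
    rid = 0

    def add(subs: dict, prods: dict) -> None:
        nonlocal rid
        reactions.append(Reaction(f"R{rid}", subs, prods, 0.0, 1000.0))
        rid += 1

    # uptake, backbone chain, export: keeps the network connected and unblocked
    add({}, {species[0]: 1})
    for k in range(min(n_species - 1, n_reactions - 2)):
        add({species[k]: 1}, {species[k + 1]: 1})
    add({species[min(n_species - 1, max(0, n_reactions - 2))]: 1}, {})
    while rid < n_reactions:
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        subs = {s: 1 for s in rng.choice(species, size=min(n_sub, n_species),
                                         replace=False)}
        prods = {s: 1 for s in rng.choice(species, size=min(n_prod, n_species),
                                          replace=False)}
        if set(subs) == set(prods):
            continue
        add(subs, prods)
    n_exchange = int(round(exchange_fraction * n_species))
    for s in rng.choice(species, size=n_exchange, replace=False):
        if rid >= n_reactions + n_exchange:
            break
        if rng.random() < 0.5:
            add({}, {s: 1})
        else:
            add({s: 1}, {})
    return MetabolicNetwork([Species(s) for s in species], reactions[:max(n_reactions, rid)])


# ---------------------------------------------------------------------------
# planted disease/healthy pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPairSpec:
    """Recipe for a paired disease/healthy model with one planted candidate.

    The shared core is a linear biomass route that produces a by-product
    species ``E`` as part of a two-species complex; ``E`` drains through
    the single-species complex ``1*E`` in both models. Forcing
    ``A^{1*E:} v = 0`` therefore stops the drain and, by mass balance, all
    growth — unless an alternative drain *not* incident on ``1*E`` exists.
    The healthy model carries such a bypass (a two-substrate drain through
    the complex ``E + X``); the disease model does not. ``n_decoys`` extra
    species/reaction pairs are appended to vary network size.
    """

    seed: int = 0
    n_decoys: int = 3
    shared_bypass: bool = False  # give the disease model the bypass too
    # (makes the pair effectively identical; the lethality invariant is then
    # unmeetable and the generator refuses)


def _planted_networks(spec: PlantedPairSpec) -> tuple[MetabolicNetwork, MetabolicNetwork]:
    rng = np.random.default_rng(spec.seed)
    species = ["S", "B", "E", "X", "W", "M1", "M2", "K"]
    # The M1+M2->K merge consumes two imports per export; it gives the zero
    # complex slack so that forcing the zero complex is not lethal in either
    # model and the planted complex remains the unique candidate.
    core = [
        ("up_S", {}, {"S": 1}),
        ("conv", {"S": 1}, {"B": 1, "E": 1}),
        ("drain_E", {"E": 1}, {}),
        ("biomass", {"B": 1}, {}),
        ("up_M1", {}, {"M1": 1}),
        ("up_M2", {}, {"M2": 1}),
        ("merge", {"M1": 1, "M2": 1}, {"K": 1}),
        ("ex_K", {"K": 1}, {}),
    ]
    bypass = [
        ("up_X", {}, {"X": 1}),
        ("alt_drain", {"E": 1, "X": 1}, {"W": 1}),
        ("ex_W", {"W": 1}, {}),
    ]
    decoys = []
    for k in range(spec.n_decoys):
        d = f"D{k}"
        species.append(d)
        decoys.append((f"up_{d}", {}, {d: 1}))
        decoys.append((f"ex_{d}", {d: 1}, {}))
    ub = 1000.0
    uptake_scale = float(rng.uniform(0.5, 1.0))  # paired models may differ in uptake

    def build(extra) -> MetabolicNetwork:
        rs = []
        for rid, subs, prods in core + extra + decoys:
            bound = ub * uptake_scale if rid == "up_S" else ub
            rs.append(Reaction(rid, subs, prods, 0.0, bound))
        return MetabolicNetwork([Species(s) for s in species], rs)

    return build(bypass if spec.shared_bypass else []), build(bypass)


def planted_pair(
    spec: PlantedPairSpec = PlantedPairSpec(),
    config: Config = DEFAULT_CONFIG,
) -> tuple[MetabolicNetwork, MetabolicNetwork, str]:
    """Return (disease, healthy, planted complex label), LP-verified.

    Raises :class:`GenerationError` if the constructed pair violates its
    invariants (planted complex non-balanced in both models; forced
    balancing lethal in the disease model; healthy model retains at least
    ``config.healthy_fraction`` of its optimum under the constraint).
    """
    from .balancing import find_balanced
    from .decomposition import build_decomposition
    from .screen import fba

    disease, healthy = _planted_networks(spec)
    label = "1*E"
    for name, net, must_survive in (("disease", disease, False),
                                    ("healthy", healthy, True)):
        dec = build_decomposition(net)
        i = dec.by_label(label)
        statuses = find_balanced(net, dec, config=config)
        if statuses[i].balanced:
            raise GenerationError(f"planted complex balanced in {name} model")
        z = fba(net, "biomass", config=config)
        zi = fba(net, "biomass", extra_equalities=((dec.activity_row(i), 0.0),),
                 config=config)
        if must_survive:
            if z <= 0 or zi < config.healthy_fraction * z:
                raise GenerationError("healthy model does not tolerate forcing")
        else:
            if not (zi < config.lethal_tol):
                raise GenerationError("forcing is not lethal in the disease model")
    return disease, healthy, label
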