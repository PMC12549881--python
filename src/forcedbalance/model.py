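"""Metabolic network container and model I/O.

A :class:`MetabolicNetwork` holds species, reactions with stoichiometry and
flux bounds, and exposes the stoichiometric matrix ``N`` whose null space
(intersected with the box of flux bounds) is the steady-state flux space

    S = { v | N v = 0, v_min <= v <= v_max }.

``S`` is the single source of truth for every linear program downstream.

Three dialects are supported: SBML (read-only, via cobrapy), a simple JSON
dialect (one document with species and reactions; human-auditable) and a
simple TSV dialect (one stoichiometry row per reaction/species pair).

Preprocessing follows the standard constraint-based recipe: blocked
reactions (|flux| below a threshold in every steady state, detected by flux
variability analysis) are removed first, on the original reversible model;
then every reversible reaction is split into a forward and a sign-flipped
backward irreversible copy, all lower bounds are set to zero and all upper
bounds are standardized to the maximum upper bound of the original model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .config import Config, DEFAULT_CONFIG

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "PreprocessingReport",
    "ModelFormatError",
    "ModelValidationError",
    "InfeasibleModelError",
    "read_model",
    "write_model",
    "remove_blocked",
    "split_reversible",
    "preprocess",
]


class ModelFormatError(ValueError):
    """The file does not parse under the named dialect."""


class ModelValidationError(ValueError):
    """The parsed model violates an internal consistency rule."""


class InfeasibleModelError(RuntimeError):
    """The steady-state flux space is empty."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str | None = None
    compartment: str | None = None


@dataclass(frozen=True)
class Reaction:
    """An irreversible or reversible reaction.

    ``substrates`` and ``products`` map species ids to strictly positive
    stoichiometric coefficients; a species occurring on both sides is
    net-cancelled at construction time so the two maps are disjoint. A
    reaction with one empty side is an exchange reaction (the empty side
    becomes the zero complex downstream).
    """

    id: str
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def __post_init__(self) -> None:
        subs, prods = _cancel_shared(self.substrates, self.products)
        object.__setattr__(self, "substrates", subs)
        object.__setattr__(self, "products", prods)
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.substrates and not self.products:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return not self.substrates or not self.products

    def stoichiometry(self) -> dict[str, float]:
        """Signed products-minus-substrates coefficients."""
        out = {s: -c for s, c in self.substrates.items()}
        for s, c in self.products.items():
            out[s] = out.get(s, 0.0) + c
        return out


def _cancel_shared(
    substrates: Mapping[str, float], products: Mapping[str, float]
) -> tuple[dict[str, float], dict[str, float]]:
    subs = {s: float(c) for s, c in substrates.items() if c}
    prods = {s: float(c) for s, c in products.items() if c}
    for s, c in subs.items():
        if c <= 0:
            raise ModelValidationError(f"non-positive substrate coefficient for {s!r}")
    for s, c in prods.items():
        if c <= 0:
            raise ModelValidationError(f"non-positive product coefficient for {s!r}")
    for s in sorted(set(subs) & set(prods)):
        m = min(subs[s], prods[s])
        subs[s] -= m
        prods[s] -= m
        if subs[s] == 0:
            del subs[s]
        if prods[s] == 0:
            del prods[s]
    return subs, prods


@dataclass(frozen=True)
class PreprocessingReport:
    removed_blocked_reactions: tuple[str, ...] = ()
    split_pairs: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    bound_cap: float | None = None

    def to_rows(self) -> list[tuple[str, str, str]]:
        rows = [(r, "removed_blocked", "") for r in self.removed_blocked_reactions]
        for orig, (fwd, bwd) in self.split_pairs.items():
            rows.append((orig, "split", f"{fwd},{bwd}"))
        return rows


class MetabolicNetwork:
    """Species, reactions and the stoichiometric matrix N."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        self._sidx = {s.id: k for k, s in enumerate(self.species)}
        for r in self.reactions:
            for s in list(r.substrates) + list(r.products):
                if s not in self._sidx:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared species {s!r}"
                    )

    # -- matrix views ------------------------------------------------------

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """N: species x reactions, products minus substrates."""
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for s, c in r.stoichiometry().items():
                N[self._sidx[s], j] = c
        return N

    @property
    def flux_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- lookups -----------------------------------------------------------

    def species_index(self, species_id: str) -> int:
        return self._sidx[species_id]

    def reaction_index(self, reaction_id: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.id == reaction_id:
                return j
        raise KeyError(reaction_id)

    def is_internal(self, species_id: str) -> bool:
        """True iff no exchange reaction touches the species."""
        for r in self.reactions:
            if r.is_exchange and (
                species_id in r.substrates or species_id in r.products
            ):
                return False
        return True

    @property
    def is_irreversible(self) -> bool:
        return all(not r.reversible for r in self.reactions)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetabolicNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions)"
        )


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

_DIALECTS = ("sbml", "simple-json", "simple-tsv")


def _gcd_normalize(net: MetabolicNetwork) -> MetabolicNetwork:
    """Divide integer-coefficient reactions by their gcd.

    Complexes are sensitive to stoichiometric scaling, so the simple
    dialects are normalized to smallest-integer coefficients on read.
    """
    new = []
    for r in net.reactions:
        coefs = list(r.substrates.values()) + list(r.products.values())
        if all(float(c).is_integer() for c in coefs):
            g = math.gcd(*(int(c) for c in coefs)) if coefs else 1
            if g > 1:
                new.append(
                    replace(
                        r,
                        substrates={s: c / g for s, c in r.substrates.items()},
                        products={s: c / g for s, c in r.products.items()},
                    )
                )
                continue
        new.append(r)
    return MetabolicNetwork(net.species, new)


def read_model(
    path: str | Path,
    dialect: str = "simple-json",
    gcd_normalize: bool | None = None,
) -> MetabolicNetwork:
    """Read a metabolic model.

    ``gcd_normalize`` defaults to True for the simple dialects (integer
    stoichiometries by convention) and False for SBML (float coefficients).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if gcd_normalize is None:
        gcd_normalize = dialect != "sbml"
    if dialect == "sbml":
        net = _read_sbml(path)
    elif dialect == "simple-json":
        net = _read_simple_json(path)
    else:
        net = _read_simple_tsv(path)
    if gcd_normalize:
        net = _gcd_normalize(net)
    return net


def write_model(net: MetabolicNetwork, path: str | Path, dialect: str = "simple-json") -> None:
    path = Path(path)
    if dialect == "simple-json":
        _write_simple_json(net, path)
    elif dialect == "simple-tsv":
        _write_simple_tsv(net, path)
    else:
        raise ValueError(f"write supports simple-json and simple-tsv, not {dialect!r}")


def _read_sbml(path: Path) -> MetabolicNetwork:
    try:
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover
        raise ModelFormatError("SBML support requires cobrapy") from exc
    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc
    species = [
        Species(m.id, name=m.name or None, compartment=m.compartment or None)
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        subs = {m.id: -c for m, c in r.metabolites.items() if c < 0}
        prods = {m.id: c for m, c in r.metabolites.items() if c > 0}
        reactions.append(
            Reaction(r.id, subs, prods, float(r.lower_bound), float(r.upper_bound))
        )
    return MetabolicNetwork(species, reactions)


def _read_simple_json(path: Path) -> MetabolicNetwork:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if not isinstance(doc, dict) or "reactions" not in doc:
        raise ModelFormatError(f"{path}: expected object with 'species' and 'reactions'")
    species = [
        Species(s["id"], s.get("name"), s.get("compartment"))
        if isinstance(s, dict)
        else Species(s)
        for s in doc.get("species", [])
    ]
    reactions = [
        Reaction(
            r["id"],
            r.get("substrates", {}),
            r.get("products", {}),
            float(r.get("lb", 0.0)),
            float(r.get("ub", 1000.0)),
        )
        for r in doc["reactions"]
    ]
    return MetabolicNetwork(species, reactions)


def _write_simple_json(net: MetabolicNetwork, path: Path) -> None:
    doc = {
        "species": [
            {
                "id": s.id,
                **({"name": s.name} if s.name else {}),
                **({"compartment": s.compartment} if s.compartment else {}),
            }
            for s in net.species
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": dict(r.substrates),
                "products": dict(r.products),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
            }
            for r in net.reactions
        ],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


_TSV_HEADER = "reaction_id\tspecies_id\tcoefficient\tlower_bound\tupper_bound"


def _read_simple_tsv(path: Path) -> MetabolicNetwork:
    lines = path.read_text().splitlines()
    if not lines or lines[0].rstrip() != _TSV_HEADER:
        raise ModelFormatError(f"{path}: line 1: expected header {_TSV_HEADER!r}")
    order: list[str] = []
    rows: dict[str, dict] = {}
    species_seen: list[str] = []
    for k, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ModelFormatError(f"{path}: line {k}: expected 5 tab-separated fields")
        rid, sid, coef, lb, ub = parts
        try:
            coef, lb, ub = float(coef), float(lb), float(ub)
        except ValueError as exc:
            raise ModelFormatError(f"{path}: line {k}: non-numeric field") from exc
        if rid not in rows:
            order.append(rid)
            rows[rid] = {"subs": {}, "prods": {}, "lb": lb, "ub": ub}
        if sid:
            if sid not in species_seen:
                species_seen.append(sid)
            side = rows[rid]["prods"] if coef > 0 else rows[rid]["subs"]
            side[sid] = side.get(sid, 0.0) + abs(coef)
    reactions = [
        Reaction(rid, d["subs"], d["prods"], d["lb"], d["ub"])
        for rid, d in ((r, rows[r]) for r in order)
    ]
    return MetabolicNetwork([Species(s) for s in species_seen], reactions)


def _write_simple_tsv(net: MetabolicNetwork, path: Path) -> None:
    out = [_TSV_HEADER]
    for r in net.reactions:
        sto = r.stoichiometry()
        if not sto:  # pragma: no cover - reactions are non-empty by invariant
            continue
        for s in sorted(sto):
            out.append(f"{r.id}\t{s}\t{sto[s]:g}\t{r.lower_bound:g}\t{r.upper_bound:g}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _cap_bounds(net: MetabolicNetwork, cap: float) -> MetabolicNetwork:
    new = []
    for r in net.reactions:
        lb = max(r.lower_bound, -cap) if np.isfinite(r.lower_bound) else -cap
        if r.lower_bound >= 0:
            lb = min(r.lower_bound, cap)
        ub = min(r.upper_bound, cap) if np.isfinite(r.upper_bound) else cap
        new.append(replace(r, lower_bound=lb, upper_bound=ub))
    return MetabolicNetwork(net.species, new)


def remove_blocked(
    net: MetabolicNetwork,
    epsilon: float | None = None,
    config: Config = DEFAULT_CONFIG,
) -> tuple[MetabolicNetwork, PreprocessingReport]:
    """Remove reactions blocked in every steady state.

    Flux variability analysis is run on the model with its original bounds
    (infinite bounds capped at ``config.bound_cap``); a reaction is blocked
    when both its minimum and maximum flux have magnitude below ``epsilon``
    (default ``config.zero_tol``).
    """
    from .lp import fva  # local import to avoid a cycle

    if epsilon is None:
        epsilon = config.zero_tol
    capped = _cap_bounds(net, config.bound_cap)
    if epsilon <= 0:
        return net, PreprocessingReport(bound_cap=config.bound_cap)
    ranges = fva(capped, config=config)
    removed = [
        r.id
        for r, (lo, hi) in zip(net.reactions, ranges)
        if abs(lo) < epsilon and abs(hi) < epsilon
    ]
    keep = [r for r in net.reactions if r.id not in set(removed)]
    return (
        MetabolicNetwork(net.species, keep),
        PreprocessingReport(
            removed_blocked_reactions=tuple(removed), bound_cap=config.bound_cap
        ),
    )


def split_reversible(
    net: MetabolicNetwork, config: Config = DEFAULT_CONFIG
) -> tuple[MetabolicNetwork, PreprocessingReport]:
    """Split reversible reactions and standardize bounds.

    Every reversible reaction becomes a forward and a sign-flipped backward
    irreversible copy; all lower bounds become zero; every upper bound is
    set to the maximum (finite) upper bound of the original model, or to
    ``config.bound_cap`` when the model has no finite upper bound.
    """
    finite_ubs = [r.upper_bound for r in net.reactions if np.isfinite(r.upper_bound)]
    ub = max(finite_ubs, default=config.bound_cap)
    if ub <= 0:
        ub = config.bound_cap
    new: list[Reaction] = []
    split: dict[str, tuple[str, str]] = {}
    for r in net.reactions:
        if r.reversible:
            fwd, bwd = f"{r.id}__fwd", f"{r.id}__bwd"
            split[r.id] = (fwd, bwd)
            new.append(Reaction(fwd, r.substrates, r.products, 0.0, ub))
            new.append(Reaction(bwd, r.products, r.substrates, 0.0, ub))
        else:
            new.append(replace(r, lower_bound=0.0, upper_bound=ub))
    return (
        MetabolicNetwork(net.species, new),
        PreprocessingReport(split_pairs=split, bound_cap=ub),
    )


def preprocess(
    net: MetabolicNetwork,
    epsilon: float | None = None,
    config: Config = DEFAULT_CONFIG,
) -> tuple[MetabolicNetwork, PreprocessingReport]:
    """Blocked-reaction removal followed by reversible splitting."""
    net1, rep1 = remove_blocked(net, epsilon=epsilon, config=config)
    net2, rep2 = split_reversible(net1, config=config)
    return net2, PreprocessingReport(
        removed_blocked_reactions=rep1.removed_blocked_reactions,
        split_pairs=rep2.split_pairs,
        bound_cap=rep2.bound_cap,
    )
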