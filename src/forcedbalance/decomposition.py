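"""Complex decomposition of a stoichiometric model.

Each reaction side (the multiset of species it jointly consumes or
produces, with stoichiometric coefficients) is a *complex*; an exchange
reaction contributes the empty *zero complex* that models the environment.
The network is then a directed graph on complexes whose edges are the
reactions, encoded by the incidence matrix ``A`` (one -1 for the substrate
complex and one +1 for the product complex per column) and the non-negative
composition matrix ``Y`` (species x complexes), with the factorization

    N = Y A.

The row ``A^{i:}`` selects the reactions around complex ``C_i``; the
*activity* of ``C_i`` under a flux distribution ``v`` is ``A^{i:} v``
(incoming minus outgoing flux).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model import MetabolicNetwork

__all__ = ["Complex", "ComplexDecomposition", "build_decomposition",
           "complex_activity", "sinks_and_sources"]

_FLOAT_TOL = 1e-9  # complex-identity tolerance for float coefficients


@dataclass(frozen=True)
class Complex:
    """One side of a reaction: species-id -> positive coefficient.

    The empty composition is the zero complex, labelled "0". Labels are
    canonical ("1*AcCoa + 1*Oaa": coefficients sorted by species id) so
    complexes can be matched across models and runs.
    """

    id: int
    composition: tuple[tuple[str, float], ...]  # sorted by species id

    @property
    def is_zero(self) -> bool:
        return not self.composition

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.composition)

    @property
    def label(self) -> str:
        if not self.composition:
            return "0"
        return " + ".join(f"{c:g}*{s}" for s, c in self.composition)


def _canonical_key(side: dict[str, float]) -> tuple[tuple[str, float], ...]:
    # round to kill float jitter below the identity tolerance
    return tuple(
        (s, round(side[s] / _FLOAT_TOL) * _FLOAT_TOL if not float(side[s]).is_integer() else float(side[s]))
        for s in sorted(side)
    )


class ComplexDecomposition:
    """Complexes plus the Y/A factorization of N."""

    def __init__(
        self,
        net: MetabolicNetwork,
        complexes: list[Complex],
        substrate_of: list[int],
        product_of: list[int],
    ):
        self.network = net
        self.complexes = complexes
        self.substrate_of = substrate_of  # reaction j -> substrate complex index
        self.product_of = product_of
        self._label_index = {c.label: c.id for c in complexes}

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def Y(self) -> np.ndarray:
        Y = np.zeros((len(self.network.species), self.n_complexes))
        for c in self.complexes:
            for s, coef in c.composition:
                Y[self.network.species_index(s), c.id] = coef
        return Y

    @property
    def A(self) -> np.ndarray:
        A = np.zeros((self.n_complexes, len(self.network.reactions)))
        for j, (sub, prod) in enumerate(zip(self.substrate_of, self.product_of)):
            A[sub, j] -= 1.0
            A[prod, j] += 1.0
        return A

    def activity_row(self, i: int) -> np.ndarray:
        """A^{i:}: +1 for incoming reactions, -1 for outgoing."""
        row = np.zeros(len(self.network.reactions))
        for j, (sub, prod) in enumerate(zip(self.substrate_of, self.product_of)):
            if sub == i:
                row[j] -= 1.0
            if prod == i:
                row[j] += 1.0
        return row

    def incident_reactions(self, i: int) -> list[int]:
        return [
            j
            for j, (sub, prod) in enumerate(zip(self.substrate_of, self.product_of))
            if sub == i or prod == i
        ]

    def by_label(self, label: str) -> int:
        """Complex index for a canonical label."""
        return self._label_index[label]

    def labels(self) -> list[str]:
        return [c.label for c in self.complexes]

    def edge_list(self) -> list[tuple[str, str, str]]:
        """(reaction_id, substrate_complex_label, product_complex_label)."""
        return [
            (r.id, self.complexes[self.substrate_of[j]].label,
             self.complexes[self.product_of[j]].label)
            for j, r in enumerate(self.network.reactions)
        ]


def build_decomposition(net: MetabolicNetwork) -> ComplexDecomposition:
    """Build complexes and the Y/A factorization.

    The network must be irreversible (preprocessed). Two reaction sides are
    the same complex iff their coefficient maps are equal (float
    coefficients compared with a 1e-9 tolerance); all empty sides map to a
    single global zero complex regardless of compartment.
    """
    if not net.is_irreversible:
        raise ValueError("decomposition requires an irreversible (preprocessed) network")
    keys: dict[tuple, int] = {}
    complexes: list[Complex] = []

    def intern(side: dict[str, float]) -> int:
        key = _canonical_key(side)
        if key not in keys:
            keys[key] = len(complexes)
            complexes.append(Complex(len(complexes), key))
        return keys[key]

    substrate_of, product_of = [], []
    for r in net.reactions:
        substrate_of.append(intern(dict(r.substrates)))
        product_of.append(intern(dict(r.products)))
    return ComplexDecomposition(net, complexes, substrate_of, product_of)


def complex_activity(dec: ComplexDecomposition, i: int, v: Iterable[float]) -> float:
    """Activity A^{i:} v of complex i under flux distribution v."""
    v = np.asarray(list(v), dtype=float)
    if v.shape[0] != len(dec.network.reactions):
        raise ValueError(
            f"flux vector has {v.shape[0]} entries, expected "
            f"{len(dec.network.reactions)}"
        )
    return float(dec.activity_row(i) @ v)


def sinks_and_sources(dec: ComplexDecomposition) -> tuple[set[int], set[int]]:
    """Complexes with only incoming (sinks) or only outgoing (sources) reactions.

    In a network without blocked reactions these cannot be balanced.
    """
    has_in = set(dec.product_of)
    has_out = set(dec.substrate_of)
    sinks = has_in - has_out
    sources = has_out - has_in
    return sinks, sources
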