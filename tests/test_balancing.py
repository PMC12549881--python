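import numpy as np
import pytest

import forcedbalance as fb
from forcedbalance.balancing import (
    TRIVIAL,
    TYPE_I,
    TYPE_II,
    balancing_potential_all,
    classify_forced_summary,
    find_balanced,
    find_trivially_balanced,
    force_balance,
)
from forcedbalance.concordance import build_partition
from forcedbalance.decomposition import build_decomposition

from conftest import Q_OAA, TOY_BALANCED, TOY_NONBALANCED, labels_of


def test_toy_trivially_balanced_set(toy_dec):
    triv = labels_of(toy_dec, find_trivially_balanced(toy_dec))
    assert triv == TOY_BALANCED  # all seven single-species complexes


def test_unique_species_makes_complex_trivially_balanced():
    net = fb.MetabolicNetwork(
        [fb.Species(s) for s in "ABC"],
        [fb.Reaction("r1", {"A": 1, "B": 1}, {"C": 1}, 0, 10),
         fb.Reaction("r2", {"C": 1}, {"B": 1}, 0, 10)],
    )
    dec = build_decomposition(net)
    triv = labels_of(dec, find_trivially_balanced(dec))
    assert "1*A + 1*B" in triv  # A appears in no other complex


def test_zero_complex_never_trivially_balanced(toy_dec):
    assert toy_dec.by_label("0") not in find_trivially_balanced(toy_dec)


def test_toy_balanced_exactly_the_trivial_seven(toy_dec, toy_statuses):
    balanced = labels_of(toy_dec, (s.index for s in toy_statuses if s.balanced))
    assert balanced == TOY_BALANCED
    nonbal = labels_of(toy_dec, (s.index for s in toy_statuses if not s.balanced))
    assert nonbal == TOY_NONBALANCED
    for s in toy_statuses:
        if not s.balanced:
            assert s.witness is not None
            act = toy_dec.activity_row(s.index) @ s.witness
            assert abs(act) > 1e-9
        if s.trivially_balanced:
            assert s.balanced


def test_only_zero_steady_state_means_all_balanced():
    net = fb.MetabolicNetwork(
        [fb.Species("A"), fb.Species("B")],
        [fb.Reaction("r", {"A": 1}, {"B": 1}, 0, 10)],
    )
    dec = build_decomposition(net)
    assert all(s.balanced for s in find_balanced(net, dec))


def test_forcing_oaa_balances_succ(toy_net, toy_dec):
    row = toy_dec.activity_row(toy_dec.by_label("1*Oaa"))
    statuses = find_balanced(toy_net, toy_dec, extra_equalities=((row, 0.0),))
    succ = toy_dec.by_label("1*Succ")
    assert statuses[succ].balanced


def test_force_balance_oaa(toy_net, toy_dec, toy_statuses, toy_partition):
    i = toy_dec.by_label("1*Oaa")
    res = force_balance(toy_net, toy_dec, i, partition=toy_partition,
                        statuses=toy_statuses)
    assert res.potential == 6
    assert labels_of(toy_dec, res.Q) == Q_OAA
    by_class = {}
    for j, c in res.classification.items():
        by_class.setdefault(c, set()).add(toy_dec.complexes[j].label)
    assert by_class[TRIVIAL] == {"1*AcCoa + 1*Oaa", "0"}
    assert by_class[TYPE_I] == {"1*AcCoa", "1*AcCoa + 1*Gly", "1*Gly + 1*Succ"}
    assert by_class[TYPE_II] == {"1*Succ"}


def test_force_balance_of_balanced_complex_is_empty(toy_net, toy_dec,
                                                    toy_statuses, toy_partition):
    i = toy_dec.by_label("1*Mal")
    res = force_balance(toy_net, toy_dec, i, partition=toy_partition,
                        statuses=toy_statuses)
    assert res.potential == 0 and res.Q == frozenset()


def test_concordant_sources_induce_same_balanced_set(toy_net, toy_dec,
                                                     toy_statuses, toy_partition):
    """Q_i + {i} is an invariant of the concordance module of i."""
    module = toy_partition.modules[0]  # {1*Oaa, 1*AcCoa+1*Oaa, 0}
    closures = []
    for i in module:
        res = force_balance(toy_net, toy_dec, i, partition=toy_partition,
                            statuses=toy_statuses, classify=False)
        closures.append(set(res.Q) | {i})
    assert all(c == closures[0] for c in closures)


def test_toy_potentials(toy_net, toy_dec, toy_statuses, toy_partition):
    pots = balancing_potential_all(toy_net, toy_dec, toy_partition, toy_statuses)
    by_label = {toy_dec.complexes[i].label: p for i, p in pots.items()}
    for lab in TOY_BALANCED:
        assert by_label[lab] == 0
    assert by_label["1*Oaa"] == 6
    for module in toy_partition.modules:
        vals = {pots[i] for i in module}
        assert len(vals) == 1
        assert vals.pop() >= len(module) - 1


@pytest.mark.parametrize("seed", [1, 4, 9])
def test_representative_potentials_match_exhaustive(seed):
    """Module-representative computation equals forcing every complex."""
    net = fb.random_network(5, 9, seed=seed)
    dec = build_decomposition(net)
    statuses = find_balanced(net, dec)
    part = build_partition(net, dec, statuses)
    fast = balancing_potential_all(net, dec, part, statuses)
    for s in statuses:
        res = force_balance(net, dec, s.index, partition=part,
                            statuses=statuses, classify=False)
        assert fast[s.index] == res.potential


@pytest.mark.parametrize("seed", range(8))
def test_forced_balanced_set_is_superset_of_balanced(seed):
    """Adding A^{i:}v = 0 can only enlarge the balanced set."""
    net = fb.random_network(6, 10, seed=seed)
    dec = build_decomposition(net)
    statuses = find_balanced(net, dec)
    balanced0 = {s.index for s in statuses if s.balanced}
    triv = find_trivially_balanced(dec)
    assert all(statuses[i].balanced for i in triv)
    nonbal = [s.index for s in statuses if not s.balanced]
    if not nonbal:
        return
    row = dec.activity_row(nonbal[0])
    constrained = find_balanced(net, dec, extra_equalities=((row, 0.0),))
    balanced1 = {s.index for s in constrained if s.balanced}
    assert balanced0 <= balanced1


def test_classify_summary_on_toy(toy_net, toy_dec, toy_statuses, toy_partition):
    results = [
        force_balance(toy_net, toy_dec, s.index, partition=toy_partition,
                      statuses=toy_statuses)
        for s in toy_statuses if not s.balanced
    ]
    summary = classify_forced_summary(results, toy_partition)
    assert summary["nonzero_potential"] == 1.0
    assert summary["balances_outside_module"] > 0
    assert 0 < summary["induces_type_II"] <= 1


def test_classify_summary_empty():
    part = fb.ConcordancePartition(modules=())
    summary = classify_forced_summary([], part)
    assert all(v is None for v in summary.values())


def test_disjoint_motifs_balance_only_within_module():
    """Two species-disjoint motifs: forcing a complex of one copy never
    balances complexes of the other."""
    rs = []
    species = []
    for k in (1, 2):
        species += [f"S{k}", f"B{k}", f"E{k}"]
        rs += [
            fb.Reaction(f"up{k}", {}, {f"S{k}": 1}, 0, 1000),
            fb.Reaction(f"conv{k}", {f"S{k}": 1}, {f"B{k}": 1, f"E{k}": 1}, 0, 1000),
            fb.Reaction(f"drain{k}", {f"E{k}": 1}, {}, 0, 1000),
            fb.Reaction(f"bio{k}", {f"B{k}": 1}, {}, 0, 1000),
        ]
    # merge gadget gives the zero complex slack (see generate.planted_pair)
    species += ["M1", "M2", "K"]
    rs += [
        fb.Reaction("upM1", {}, {"M1": 1}, 0, 1000),
        fb.Reaction("upM2", {}, {"M2": 1}, 0, 1000),
        fb.Reaction("merge", {"M1": 1, "M2": 1}, {"K": 1}, 0, 1000),
        fb.Reaction("exK", {"K": 1}, {}, 0, 1000),
    ]
    net = fb.MetabolicNetwork([fb.Species(s) for s in species], rs)
    dec = build_decomposition(net)
    statuses = find_balanced(net, dec)
    part = build_partition(net, dec, statuses)
    copy1 = {i for i in range(dec.n_complexes)
             if any(s.endswith("1") and s[0] in "SBE"
                    for s in dec.complexes[i].species_ids)}
    i = dec.by_label("1*E1")
    res = force_balance(net, dec, i, partition=part, statuses=statuses)
    assert res.potential > 0
    assert all(j in copy1 for j in res.Q)
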