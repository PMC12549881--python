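import pytest

import forcedbalance as fb

# canonical labels of the toy network's structure, used across test modules
TOY_BALANCED = {"1*Cit", "1*Fum", "1*Isocit", "1*Mal", "1*OG", "1*Pep", "1*Pyr"}
TOY_NONBALANCED = {
    "1*Oaa", "1*AcCoa + 1*Oaa", "0", "1*Succ", "1*Gly + 1*Succ",
    "1*AcCoa + 1*Gly", "1*AcCoa",
}
TOY_MODULES = [
    {"1*Oaa", "1*AcCoa + 1*Oaa", "0"},
    {"1*Succ", "1*Gly + 1*Succ", "1*AcCoa + 1*Gly"},
    {"1*AcCoa"},
]
Q_OAA = {
    "1*AcCoa", "1*AcCoa + 1*Oaa", "1*Succ", "1*AcCoa + 1*Gly",
    "1*Gly + 1*Succ", "0",
}


@pytest.fixture(scope="session")
def toy_net():
    return fb.toy_network()


@pytest.fixture(scope="session")
def toy_dec(toy_net):
    return fb.build_decomposition(toy_net)


@pytest.fixture(scope="session")
def toy_statuses(toy_net, toy_dec):
    return fb.find_balanced(toy_net, toy_dec)


@pytest.fixture(scope="session")
def toy_partition(toy_net, toy_dec, toy_statuses):
    return fb.build_partition(toy_net, toy_dec, toy_statuses)


def labels_of(dec, indices):
    return {dec.complexes[i].label for i in indices}
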