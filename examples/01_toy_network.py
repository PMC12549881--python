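"""Worked example: balanced complexes and forced balancing on the toy network.

The bundled 18-reaction TCA/glyoxylate toy network decomposes into 14
complexes. Seven single-species complexes are balanced (all trivially: each
contains a species occurring in no other complex); the seven non-balanced
complexes fall into three concordance modules. Forcing the activity of
1*Oaa to zero balances six further complexes — its balancing potential —
split into trivially forced (its module co-members), type I (all incident
reactions blocked) and type II (flux still flows through them).
"""

from collections import defaultdict

import forcedbalance as fb

net = fb.toy_network()
dec = fb.build_decomposition(net)
print(f"{len(net.species)} species, {len(net.reactions)} reactions, "
      f"{dec.n_complexes} complexes")

statuses = fb.find_balanced(net, dec)
balanced = sorted(dec.complexes[s.index].label for s in statuses if s.balanced)
print("balanced complexes:", ", ".join(balanced))

part = fb.build_partition(net, dec, statuses)
for k, module in enumerate(part.modules):
    print(f"concordance module {k}:",
          ", ".join(dec.complexes[i].label for i in module))

i = dec.by_label("1*Oaa")
res = fb.force_balance(net, dec, i, partition=part, statuses=statuses)
print(f"balancing potential of 1*Oaa: {res.potential}")
by_class = defaultdict(list)
for j, cls in res.classification.items():
    by_class[cls].append(dec.complexes[j].label)
for cls in ("trivial", "nontrivial_type_I", "nontrivial_type_II"):
    print(f"  {cls}: {', '.join(sorted(by_class[cls]))}")
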