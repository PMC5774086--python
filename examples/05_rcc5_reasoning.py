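"""RCC-5 reasoning: composition, path consistency and the model oracle.

Path consistency refines edge sets using the composition table; the
exhaustive oracle decides satisfiability over a 4-element universe.
"""

from taxograph.rcc5 import (ConstraintNetwork, compose, model_check_oracle,
                            path_consistency)
from taxograph.vocabulary import RCC5

print("compose(PP, PP) =", sorted(r.name for r in compose(RCC5.PP, RCC5.PP)))
print("compose(PP, DR) =", sorted(r.name for r in compose(RCC5.PP, RCC5.DR)))

# A proper-part chain forces the third edge.
net = ConstraintNetwork()
net.set("A", "B", frozenset({RCC5.PP}))
net.set("B", "C", frozenset({RCC5.PP}))
result = path_consistency(net)
print("A-C refined to:", sorted(r.name for r in result.network.get("A", "C")))

# A contradiction: A inside B but disjoint from something containing B.
bad = ConstraintNetwork()
bad.restrict("A", "B", frozenset({RCC5.PP}))
bad.restrict("B", "C", frozenset({RCC5.PP}))
bad.restrict("A", "C", frozenset({RCC5.DR}))
print("contradictory network:", path_consistency(bad).verdict)
print("oracle agrees (unsatisfiable):", not model_check_oracle(bad))

# Path consistency is sound: it never rejects a satisfiable network.
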