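"""Enumerating all equally parsimonious indel histories.

Two cherries carry conflicting gap patterns (101 vs 110), so the root
pattern is ambiguous: either choice explains the data at the same cost.
Enumeration with no-good cuts recovers both optimal histories.
"""

import indelopt as idl

records = [("A", "M-K"), ("B", "M-K"), ("C", "MK-"), ("D", "MK-")]
tree = idl.parse_newick("((A,B),(C,D));")

result = idl.infer_indel_history(
    records, tree, idl.SolveConfig(max_alternatives=10), enumerate_ties=True
)

print(f"{len(result.solutions)} optimal histories at objective "
      f"{result.solution.objective_value}")
for sol in result.solutions:
    pats = sol.pattern_strings(tree)
    print(f"  solution {sol.solution_rank}: root={pats['N1']} "
          f"N2={pats['N2']} N3={pats['N3']}")

# Both histories place one indel event on a branch out of the root; the
# data cannot say whether the root carried the 101 or the 110
# arrangement, and the enumeration reports exactly these two optima.
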