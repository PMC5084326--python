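"""Majority-rule consensus of a tree collection.

Generates 15 eight-leaf trees of which 60% share one topology, and
builds the strict majority-rule consensus.  Internal-node labels are
bipartition support percentages: splits present in more than half of the
trees survive; conflicting minority splits collapse.
"""

from molevo import majority_rule_consensus, make_random_trees

trees = make_random_trees(k=8, n=15, seed=42, agreement=0.6)
consensus = majority_rule_consensus(trees)
print(consensus.as_string(schema="newick", suppress_rooting=True).strip())
print(
    "\nEach internal label is the percentage of input trees containing "
    "that bipartition (all > 50 by construction of the majority rule)."
)
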