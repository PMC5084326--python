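# molevo

A molecular-evolution toolkit for Python, for researchers who assemble
phylogenetic workflows from public sequence databases: partitioning
annotated sequence collections into per-gene sets, detecting annotation
errors statistically, transferring reference annotation onto bare
sequences, decomposing datasets for divide-and-conquer tree building,
tracking data provenance, building consensus trees, and driving external
alignment/inference tools through one keyword-configured interface.

## The core method: annotation-driven gene partitioning

Public databases impose no standardization on feature qualifiers, so one
gene accumulates several nomenclatures ("ATP6", "atpase 6", "ATP synthase
F0 subunit 6", ...). The classical approach — grouping by the `gene` *or*
`product` qualifier alone — fragments genes across these vocabularies.
`molevo` instead uses **all** qualifier evidence jointly:

- every normalized qualifier value of every (filtered) feature instance
  becomes a node of a *term graph*, with `n_t` the number of records
  containing term *t*;
- values co-occurring within a single feature instance are joined by an
  edge whose *support* is the set of record ids exhibiting the link;
- connected components of the graph define gene identity, and each
  feature instance carrying any component term contributes one extracted
  fragment (0-based half-open loci, reverse-complemented on the minus
  strand) to that component's set.

An edge (a, b) is flagged **uncertain** iff

```
|support(a, b)| < max(f, ⌈p · min(n_a, n_b)⌉)        (defaults p = 0.05, f = 2)
```

— a link observed in almost no records, although both of its terms are
deeply sampled, is an annotation error (a record carrying another gene's
product), not a rare nomenclature. Flagged pairs are logged with their
supporting accessions; the user decides whether to drop the edges or the
records. Records with no usable annotation are handled by
reference-guided liftover: a global Needleman–Wunsch alignment to an
annotated reference, deletion of the columns that would gap the
reference, `N`-padding of query deletions, and verbatim projection of
the reference loci.

The toolkit also provides: naïve row/column splitting; centroid-edge
decomposition of a guide phylogeny into bounded-size overlapping leaf
sets; the `(2k−5)!!` unrooted-topology count; majority-rule consensus
(native bipartition counting); provenance-ledgered collections with
`.rep` report files, version-based update diffs and batch sizing; and
profile-driven dispatch of Mafft/Clustal Omega/MUSCLE/FastTree/RAxML or
any user-registered tool, with automatic format conversion.

## Worked example

```python
from molevo import PanelSpec, make_hmtdna_panel, partition_genes

records, truth = make_hmtdna_panel(
    PanelSpec(n_records=50, seed=7, nomenclature_profile="split_atp")
)
result = partition_genes(records, {"CDS"}, qualifier_mode="all")
print(len(result))                     # 15
print(sorted(result.sets)[:4])
# ['CDS_atp synthase f0 subunit 6', 'CDS_atp synthase f0 subunit 8',
#  'CDS_atpase 6', 'CDS_atpase 8']
```

The synthetic panel mimics a human-mtDNA collection (13 CDS + 2 rRNA +
22 tRNA genes per record) in which half the records use one ATP6/ATP8
vocabulary and half another, with no bridging record. The method finds
15 CDS sets instead of 13: each ATP gene honestly splits into its two
nomenclatures — exactly the behaviour seen on small real samples, and the
reason the per-set fragment counts above read 25 (half the panel) for
the four ATP sets and 50 for the other nine. On a clean panel the same
call returns 13 CDS, 2 rRNA and 22 tRNA sets, and
`examples/error_detection_demo.py` shows a single corrupted record in a
1000-record panel being pinpointed by its uncertain pair:

```
CDS:nadh dehydrogenase subunit 4    CDS:nd5    1
    SYN00944.1
```

Each `examples/*.py` script is a self-contained narrative of one
capability (partitioning, error detection, liftover, consensus,
decomposition, provenance, external tools) and prints what the numbers
mean.

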