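"""Annotate information-less sequences from a reference.

A fraction of the panel's records carry no features (and small indels on
top of the usual substitutions).  Supplying the panel's reference record
lets the partitioner align each bare sequence to the reference, drop the
columns that would gap the reference, pad deletions with N, and project
the reference loci — after which every record contributes a fragment to
every gene set.
"""

from molevo import PanelSpec, make_hmtdna_panel, make_hmtdna_refseq, partition_genes

records, truth = make_hmtdna_panel(
    PanelSpec(n_records=10, seed=3, unannotated_fraction=0.3)
)
refseq = make_hmtdna_refseq(3)
print(f"unannotated records: {', '.join(truth.unannotated_ids)}")

without = partition_genes(records, {"CDS"})
print(f"without a reference: {len(without)} sets, "
      f"unassignable: {without.unassignable}")

with_ref = partition_genes(records, {"CDS"}, refseq=refseq)
set_name, fragments = sorted(with_ref.sets.items())[0]
print(f"with the reference:  {len(with_ref)} sets, unassignable: none")
print(f"  e.g. {set_name}: {len(fragments)} fragments "
      f"(one per record, lifted-over records included)")
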