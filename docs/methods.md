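# Methods

## The gene-partition model

The partitioner treats gene identity as a purely set-algebraic question
over annotation evidence. For a record collection *R*, a feature filter
*F* (e.g. {CDS}) and a qualifier mode (gene / product / all), each
feature instance passing the filter contributes the normal forms of its
selected qualifier values as terms. Normalization is deliberately
minimal — case folding, whitespace collapse, quote stripping — because
anything stronger (dictionaries, edit-distance merging) would inject
curation the method is designed to avoid; two spellings merge only when
some record links them.

`gene`-kind features contribute their values to a filtered feature only
when their locus intervals are identical. This is the conservative
reading of co-location: overlapping-but-nested intervals are common
(genes containing other genes, nested ORFs), and linking on overlap
would merge distinct genes through containment alone.

Multiple loci annotated under one name (the mitochondrial Leu/Ser tRNA
twins) land in one set by construction, as separate fragments per
record — the set count drops from 22 to 20 on such panels, which is the
honest answer given the annotation; the generator can also emit
per-locus-distinguished names, restoring 22.

### The uncertainty rule

The flagging rule — edge (a, b) is uncertain iff
`|support| < max(f, ⌈p·min(n_a, n_b)⌉)` with defaults `p = 0.05`,
`f = 2` — is this package's concrete choice of "anomalously low sampling
representation". The `min` makes the threshold scale with the rarer
endpoint, so a legitimate minority nomenclature (hundreds of records on
both endpoints, hundreds of supporting links) is not flagged, while a
single record bridging two deeply sampled terms always is. The floor
`f = 2` flags any singleton link once a second record exists, yet a
two-record panel whose only two records agree is not flagged
(`2 ≮ max(2, ⌈0.1⌉)`). Both parameters are exposed; the defaults are not
tuned to any dataset. Flagging is log-only by default — `drop_uncertain`
removes edges, never records, since record removal is the user's
decision.

Set identifiers are `kind_term` with the component's most frequent term,
frequency ties broken lexicographically: deterministic and
human-readable, nothing more.

## Annotation liftover

Global alignment uses match +1, mismatch −1, linear gap −2 — no scheme
is canonical for this task, so the simplest exposed one is used. The DP
is row-vectorized in numpy (the in-row linear-gap dependency is a prefix
maximum with decay), keeping ~6 kb × 6 kb genome pairs around a second;
the full int32 score matrix is kept for traceback, ~150 MB at that size.
Traceback ties are broken diagonal → gap-in-reference → gap-in-query, so
outputs are reproducible across platforms.

The transfer rule makes reference coordinates apply verbatim: columns
gapping the reference are deleted from the query (the query insertion is
information the reference annotation cannot address), and query
deletions are padded with `N` (the minimal representation that preserves
locus arithmetic; downstream fragments show `N` at the missing sites).
Consequently the edited query always has the reference's exact length
and the operation is idempotent.

## Decomposition

`prd_decompose` fixes one concrete contract for phylogeny-guided
overlapping decomposition: a worklist of (leaf set, induced subtree)
pairs; any set within `max_size` is emitted; otherwise the induced tree
is cut at the centroid edge (minimizing the larger side, ties by the
smallest label on the smaller side) and each side is padded with the
`overlap` topologically nearest leaves (edge-count distance to the cut,
ties by label) of the other side. Padding is trimmed to at most
`k − |side| − 1` leaves so each queued subproblem is strictly smaller
than its parent — without this guard a near-pendant cut plus padding
could re-enqueue a set of unchanged size and loop. Polytomies are
resolved with zero-length edges before the centroid search. There is no
randomness anywhere; identical inputs give identical decompositions
regardless of evaluation order.

`naive_rows` uses contiguous input-order blocks (first `n mod k` blocks
one larger); `naive_cols` derives the range width `⌈L/k⌉` from the
longest sequence and clips per record, so short records contribute empty
fragments rather than shifting ranges.

## Consensus

Bipartitions are canonicalized as the side excluding the globally
smallest leaf label. For thresholds in [0.5, 1) the selected sides are
pairwise nested-or-disjoint, hence a laminar family, and the tree is
assembled by size-descending insertion. Support labels are percentages
with one decimal place. The strict rule (> threshold) is the default;
the extended variant adds minority bipartitions in descending frequency
(ties by sorted label tuple) when compatible. Thresholds below 0.5 are
rejected rather than silently producing incompatible selections. Input
trees are treated as unrooted; rooted inputs contribute the bipartitions
of their unrooted form.

## Tool dispatch

Profiles (executable, supported formats, input flag, score regex,
keyword→argument map with a mandatory `default`) are JSON data, editable
without touching code, because external tools change their flag
inventories faster than wrappers are updated. Inference keywords follow
the `[model]+[method]` scheme (`gtr+cat`, `gtr+gamma`). Input files are
converted (via Biopython) only when the tool does not read the given
format, inside a temporary directory that is removed on any outcome, so
failures leave no partial files. The score is the last regex match in
the combined stdout+stderr — tools print intermediate likelihoods, and
the final one is the fit of the returned tree. Unregistered executables
run through the same path when the caller supplies a format list and
input flag.

## Provenance

The report file syntax (`count:` header, `source:`/`override:`
tab-separated lines) is this package's own; only its content — counts,
per-source timestamp/origin, and the collision ledger — is contractually
meaningful. Collisions are recorded by identifier, not version, so
re-supplying an identical item still leaves a trace; this is what makes
the ledger a usable audit trail. Batch sizing uses an explicit byte
budget (default 16 MiB, cap 500) in place of a measured
bandwidth × download-time product, which is not observable offline; the
formula `min(cap, max(1, ⌊budget/avg⌋))` preserves the intent. All
remote interaction is injected: `apply_remote_update` takes an
id→version index and a fetch callable, and the package contains no
network code.

## Synthetic panels: what they emulate, and what they do not

`make_hmtdna_panel` reproduces the *annotation structure* of a human
mitochondrial DNA collection: 37 features per record (13 CDS, 2 rRNA,
22 tRNA) in organelle gene order with realistic strand assignments and
the Leu/Ser two-locus tRNAs; divergent nomenclatures (consistent,
split-ATP with provably unbridged vocabularies, per-record mixed
spellings); seeded cross-gene product swaps; and records stripped of all
annotation (given short indels so liftover has gaps to resolve). Gene
regions are scaled down (tRNAs ~70 nt, rRNA/CDS a few hundred nt,
genome ~6.5 kb) from the ~1–2 kb originals so panels of 1000 records
build in under a second; loci are fixed synthetic coordinates, not any
published reference's, and residues are seeded random mutations of a
per-seed base genome. Corruption counts are exact — `round(rate·n)`
records, drawn without replacement, unannotated before mislabelled — so
a 1000-record panel at rate 0.001 contains exactly one corrupted record.

Because residues are random, passing tests demonstrate correctness of
the annotation algebra, the liftover procedure and the contracts — not
performance on real sequence biology (no codon structure, no haplogroup
signal, no real nomenclature tables). The partitioner never reads
residues except to extract fragments, so this is the appropriate level
of realism for what is being tested.

## Problem sizes used in the checks

The self-checks run at desk scale by design: gene-recovery counts on
50-record panels (error detection at 1000 records); alignment-oracle
equivalence exhaustively over all 2-letter pairs up to length 4 plus a
seeded sample of 150 pairs up to length 8 (plain enumeration of every
alignment path is the oracle); consensus against a newick-level
bipartition counter on 200 random tree sets with up to 10 leaves;
decomposition contracts on 500 random trees with up to 64 leaves;
topology counts against exhaustive enumeration for k = 3..6.

## Known limitations

- GenBank coverage is the common subset (LOCUS/FEATURES/ORIGIN, joins,
  complements, partial markers); CONTIG, remote joins and protein
  records are out of scope, as are formats beyond GenBank/FASTA/newick.
- Mixed-strand compound loci are extracted under the first interval's
  strand; such features do not occur in the supported organelle-style
  annotations.
- Liftover assumes query and reference are globally colinear
  (no rearrangements), which is the regime the method is meant for.
- Consensus requires identical leaf sets; supertree assembly over
  partial overlaps is not implemented.
- Tool profiles ship with sensible flag sets for current tool versions
  but make no compatibility guarantee; they are data precisely so users
  can repair drift.
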