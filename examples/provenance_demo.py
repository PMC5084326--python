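"""Track data provenance with report files.

Merges two sources into one collection — the second source re-supplies
one identifier at a newer version, which is recorded as an override —
then writes the GenBank data file with its .rep sidecar.  The report
alone documents counts, sources, access times and every collision, so it
can stand in for a large data file when sharing an analysis.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

from molevo import (
    DataCollection,
    PanelSpec,
    compute_batch_size,
    make_hmtdna_panel,
    merge_source,
    save_collection,
    update_diff,
)

first, _ = make_hmtdna_panel(PanelSpec(n_records=5, seed=1))
second, _ = make_hmtdna_panel(PanelSpec(n_records=8, seed=1))
second = [replace(r, version=2) for r in second[3:]]  # ids 3,4 collide, newer

coll = merge_source(DataCollection(), first, "/data/batch1.gb", "2016-07-07T09:00:00")
coll = merge_source(coll, second, "nucleotide: atp6 OR atp8", "2016-07-07T10:30:00")

with tempfile.TemporaryDirectory() as tmp:
    rep = save_collection(coll, str(Path(tmp) / "panel.gb"))
    print(Path(rep).read_text())

fetch, delete, keep = update_diff(
    {r.id: r.version for r in first},
    {r.id: 2 for r in second} | {first[0].id: 1},
)
print(f"incremental update plan -> fetch {sorted(fetch)}, delete {sorted(delete)}")
print(f"batch size for 64 KiB records under a 16 MiB budget: "
      f"{compute_batch_size(64 * 1024)}")
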