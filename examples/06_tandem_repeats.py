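"""Exact 8-10-bp tandem-repeat catalogs and accession-vs-reference bands.

Repeats are maximal runs of >= 2 exact unit copies reported under their
minimal period; comparison projects accession coordinates through known
deletions and classifies loci as gained (accession only) or lost
(reference only) — the red/green bands of a TR track.
"""

import numpy as np

import sd1hap as s
from sd1hap.trs import render_track

rng = np.random.default_rng(7)
reference = "".join(rng.choice(list("ACGT"), size=2000))
unit = "ACGTTGCA"
reference = reference[:500] + unit * 3 + reference[524:]       # plant one TR

ref_loci = s.scan_trs(reference)
print(f"reference TR loci: {[(int(l.start), l.unit, float(l.copies)) for l in ref_loci]}")

# accession: deletes the reference TR, duplicates an 8-mer elsewhere
accession = reference[:495] + reference[535:]
accession = accession[:1000] + accession[1000:1008] + accession[1000:]
acc_loci = s.scan_trs(accession)

comp = s.compare_trs(acc_loci, ref_loci, deletions=[(496, 535)])
print(f"gained: {[(int(l.start), l.unit) for l in comp.gained]}")
print(f"lost:   {[(int(l.start), l.unit) for l in comp.lost]} "
      f"(inside deletion: {len(comp.lost_in_deletion)})")
print(f"shared: {comp.shared_count}")
print("band view (+ gained, - lost, = shared):")
print(render_track(comp, length=len(reference)))
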