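"""Detect the 383-bp DGWG deletion from paired-end insert sizes.

Properly oriented pairs spanning deleted reference material realign with a
template length inflated by the deletion length; clustering those
discordant pairs localises the deletion, and exact flank matching refines
the breakpoints when the accession sequence is available.
"""

import numpy as np

import sd1hap as s
from sd1hap.simulate import Deletion

config = s.SimConfig(seed=7)  # 30x, insert 400 +/- 30, 100-bp reads
reference, model = s.make_reference(config)
defs = s.load_definitions().shifted(-s.CHR1_OFFSET)

seq, edits = s.apply_haplotype(reference, model, defs[7])  # DGWG accession
deletions = tuple(e for e in edits if isinstance(e, Deletion))
pairs = s.simulate_read_pairs(seq, config, np.random.default_rng(1), deletions=deletions)

insert_model = s.fit_insert_model(pairs)
print(f"fitted insert model: mean {insert_model.mean:.0f} bp, sd {insert_model.sd:.1f} bp "
      f"({insert_model.n_observations} pairs)")

(call,) = s.detect_deletions(pairs, insert_model)
truth = deletions[0]
print(f"call: {call.start}-{call.end}  support={call.support} pairs  "
      f"size estimate {call.size_estimate:.0f} bp  coverage drop: {call.coverage_drop}")
print(f"truth: {truth.start}-{truth.end} ({truth.length} bp) — "
      f"contained in call: {call.start <= truth.start and call.end >= truth.end}")

refined = s.refine_breakpoints(reference, reference[: truth.start - 1] + reference[truth.end :])
print(f"flank-refined breakpoints: {refined} (exact to the base)")
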