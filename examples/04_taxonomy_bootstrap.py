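"""Train the word-model classifier and read its bootstrap confidences.

A synthetic reference set doubles as training data. A clean sequence
classifies to its genus with full confidence; a heavily mutated copy
keeps confident calls only at shallow ranks — exactly the behaviour the
per-rank confidence threshold is for. The N spacer inside stitched
representatives contributes no words at all.
"""

import numpy as np

import hybridotu as h

cfg = h.SimConfig(n_species=12, seed=5)
refs, lineages = h.generate_reference_set(cfg)
model = h.train(refs, lineages)

rid, seq = refs[0]
call = h.classify(seq, model, seed=1, seq_id=rid)
print(f"{rid} self-classification: {call.lineage_string()}")
print("  confidences:", {r: round(c, 2) for r, c in call.confidence.items()})

rng = np.random.default_rng(3)
mutated = list(seq)
for p in rng.choice(len(seq), 180, replace=False):  # ~26% divergence
    mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
call = h.classify("".join(mutated), model, seed=1, seq_id="mutant")
print(f"mutant assigned down to rank: {call.assigned_rank}")
print("  confidences:", {r: round(c, 2) for r, c in call.confidence.items()})

stitched = seq[:250] + "N" * 8 + "N" * 200
a = h.classify(seq[:250], model, seed=1, seq_id="x")
b = h.classify(stitched, model, seed=1, seq_id="x")
print(f"all-N reverse segment changes the call: {a.confidence != b.confidence}")
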