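"""Simulate the Glires-like preset and recover every planted lesion.

The preset plants a stop gain at motif codon 53 on the stem of a seven-leaf
clade, frameshift deletions of 16 and 19 nt on its subclades, a Cys->Lys
motif substitution plus a 20-nt deletion on a cottontail-like sub-branch, and
a heterozygous pika-like leaf.  Scanning the emitted alignment against the
emitted truth measures event-level precision/recall and verdict agreement.
"""

from genedecay import build_coordinate_map, scan_alignment, summarize_species
from genedecay.synthetic_data import (
    GLIRES_MOTIF,
    glires_preset,
    recover_events,
    score_recovery,
    simulate,
)

for scale, label in [(0.0, "noise-free (branch lengths scaled to 0)"),
                     (1.0, "realistic noise (JC69, paths <= 0.3 subs/site)")]:
    config = glires_preset(seed=7)
    config.branch_scale = scale
    aln, truth = simulate(config, seed=7)
    score = score_recovery(truth, recover_events(aln, motif=GLIRES_MOTIF))
    print(f"{label}:")
    print(f"  planted events recovered: precision {score.precision:.3f}, "
          f"recall {score.recall:.3f} "
          f"(tp={score.true_positives}, fp={score.false_positives}, "
          f"fn={score.false_negatives})")

config = glires_preset(seed=7)
aln, truth = simulate(config, seed=7)
cmap = build_coordinate_map(aln, mode="ungapped_reference")
statuses = scan_alignment(aln, cmap, motif=GLIRES_MOTIF)
agree = sum(s.verdict == truth.expected_verdict[s.seq_id] for s in statuses)
print(f"\nverdict agreement with truth: {agree}/{len(statuses)} alleles")
print("\nper-species verdicts under realistic noise:")
print(summarize_species(statuses).to_string(index=False))
print("\nExtra premature stops on pseudogenized branches are real "
      "(post-loss drift), which is why precision drops under noise while "
      "recall of planted lesions stays at 1.")
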