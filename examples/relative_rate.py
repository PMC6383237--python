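"""Tajima's relative-rate test: published counts and a simulated batch.

First reproduces the test from the six published unique-difference count
pairs (degu as taxon A, human outgroup): chi^2 = (nA - nB)^2 / (nA + nB) with
one degree of freedom.  Then runs the full pipeline on a simulated Glires-like
alignment, where pseudogenized leaves evolve at twice the base rate and should
reject the equal-rates null more often than intact leaves.
"""

from genedecay import batch_rrt, rrt_table, tajima_rrt
from genedecay.synthetic_data import glires_preset, simulate

ROWS = [("guinea pig", 11, 69), ("kangaroo rat", 17, 68),
        ("European rabbit", 16, 72), ("chinchilla", 18, 10),
        ("jerboa", 26, 37), ("ground squirrel", 19, 27)]

print("relative-rate test from published unique-difference counts:")
print(f"  {'taxon B':18s} {'nA':>3s} {'nB':>3s} {'chi2':>6s} {'p':>7s}")
for name, na, nb in ROWS:
    res = tajima_rrt(na, nb)
    print(f"  {name:18s} {na:3d} {nb:3d} {res.chi_square:6.2f} "
          f"{res.p_value:7.4f}")
print("  (p < 0.05 rejects equal rates: the three pseudogene rows reject)")

print("\nsame test on a simulated alignment (intact pika-like taxon A, "
      "outgroup as outgroup):")
aln, truth = simulate(glires_preset(seed=11), seed=11)
taxon_b = [r.id for r in aln.records
           if r.id not in ("ancestor", "pika_a", "outgroup")]
results = batch_rrt(aln, "pika_a", taxon_b, "outgroup")
table = rrt_table(results)
table["truth"] = [truth.expected_verdict[b] for b in table["taxon_b"]]
print(table.to_string(index=False))
print("\nPseudogenized leaves carry systematically more unique differences "
      "(nB > nA) because post-loss branches evolve at twice the base rate.")
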