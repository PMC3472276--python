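"""Model-corrected pairwise distances and the saturation diagnostic.

Simulates a sequence pair under GTR+G at a known divergence, shows how
the corrected distance undoes the multiple-hit compression of the raw
p-distance, and runs the per-codon-position saturation profile on an
alignment whose third positions evolve 10x faster.
"""

import postphylo as pp
from postphylo.distances import (AlignedSequences, SubstModel, ml_distance,
                                 p_distance, saturation_profile)

model = SubstModel.gtr((1, 2, 1, 1, 4, 1), (0.3, 0.2, 0.2, 0.3), alpha=0.5)
aln = pp.simulate_sequences(0.3, model, 50_000, seed=41)
a, b = aln.seqs["a"], aln.seqs["b"]
print(f"true divergence 0.3 subst/site: p-distance = {p_distance(a, b):.4f}, "
      f"corrected = {ml_distance(a, b, model):.4f}")

# third positions 10x faster: the p/d ratio drops in class 3
jc = SubstModel.jc69()
slow = pp.simulate_sequences(0.12, jc, 3000, seed=42)
fast = pp.simulate_sequences(1.2, jc, 3000, seed=43)
seq_a = "".join(slow.seqs["a"][i] if i % 3 != 2 else fast.seqs["a"][i]
                for i in range(3000))
seq_b = "".join(slow.seqs["b"][i] if i % 3 != 2 else fast.seqs["b"][i]
                for i in range(3000))
codon = [1 + i % 3 for i in range(3000)]
profile = saturation_profile(
    AlignedSequences({"x": seq_a, "y": seq_b}, codon_positions=codon), jc)
for cls, row in profile.items():
    print(f"codon position {cls}: mean p = {row['mean_p']:.3f}, "
          f"mean d = {row['mean_d']:.3f}, ratio = {row['ratio']:.2f}"
          f"{'  ** saturated' if row['saturated'] else ''}")
print("a ratio near 1 means little multiple-hit loss; a low ratio at "
      "position 3 is the classic saturation signature.")
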