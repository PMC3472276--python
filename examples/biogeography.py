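"""Ancestral geographic ranges: DEC likelihood and DIVA parsimony.

Ranges over three areas (WA = western Atlantic, EP = eastern Pacific,
IP = Indo-Pacific) are simulated under dispersal-extinction-
cladogenesis, the rates are re-estimated by maximum likelihood, and
ancestral ranges are reconstructed with both DEC (marginal
probabilities) and DIVA (minimum event cost), then summarised over an
emulated posterior sample of trees.
"""

import postphylo as pp

areas = pp.AreaSet(("WA", "EP", "IP"))
tree = pp.simulate_yule(20, 1.0, seed=31)
true = pp.DECParams(d=0.2, e=0.05)
ranges = pp.simulate_dec_ranges(tree, true, areas, root_range={"EP"}, seed=32)
print("tip ranges:", {k: "+".join(sorted(v)) for k, v in sorted(ranges.items())})

fitted, ll = pp.fit_dec(tree, ranges, areas)
print(f"DEC ML fit: d = {fitted.d:.3f} (true 0.2), e = {fitted.e:.3f} "
      f"(true 0.05), lnL = {ll:.3f}")

marg = pp.dec_ancestral_ranges(tree, ranges, fitted, areas)
root_dist = sorted(marg[tree.root.index].items(), key=lambda kv: -kv[1])[:3]
print("root range marginals:",
      ", ".join(f"{'+'.join(sorted(r))}: {p:.3f}" for r, p in root_dist))

cost, optimal = pp.diva_parsimony(tree, ranges, areas=areas)
roots = {"+".join(sorted(r)) for r in optimal[tree.root.index]}
print(f"DIVA: minimum cost {cost} events; optimal root range(s): {roots}")

# summarise DIVA reconstructions over a posterior sample, the tabular
# analogue of per-node pie charts
sample = pp.emulate_posterior(tree, 50, 0.1, topology_swap_rate=0.5, seed=33)
summary = pp.posterior_range_summary(sample, ranges, "DIVA", n_trees=50,
                                     seed=34, areas=areas)
root_clade = max(summary, key=len)
dist = summary[root_clade]["ranges"]
print("root clade range frequencies over 50 trees:",
      ", ".join(f"{'+'.join(sorted(r))}: {f:.2f}"
                for r, f in sorted(dist.items(), key=lambda kv: -kv[1])))
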