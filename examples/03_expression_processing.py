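"""Process transcript counts: detection filter, cpm, TMM, DEG calling.

Differential expression between genotypes uses a negative-binomial
likelihood-ratio test with a common dispersion estimated from the
replicated parental checks; the cpm filter threshold is chosen to maximize
the number of significant DEG.
"""

import rilgp
from rilgp import expression as xpr

sim = rilgp.simulate_study(rilgp.SimConfig(
    n_variants=400, n_transcripts=1000, pop_sizes=(30, 30, 30),
    array_size=100, seed=3,
))

total = xpr.detection_filter(sim.expression)  # >= 2% of samples nonzero
print(f"detected transcripts: {total.counts.shape[0]} of "
      f"{sim.expression.counts.shape[0]}")

factors = xpr.tmm_factors(total)
print(f"TMM factors: range [{factors.min():.3f}, {factors.max():.3f}], "
      f"geometric mean 1 (between-sample composition correction)")

disp = xpr.estimate_dispersion(total)
print(f"common NB dispersion from parental replicates: {disp.iloc[0]:.4f}")

deg = xpr.deg_lrt(total)
print(f"DEG at FDR < 0.05: {deg.n_significant} "
      f"(genotype-dependent expression)")

scan = xpr.cpm_threshold_scan(total, n_candidates=20)
print(f"cpm threshold maximizing DEG count: {scan.threshold:.3f} "
      f"-> {scan.counts[scan.threshold]} DEG "
      f"(vs {scan.counts[0.0]} with no cpm filter)")
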