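"""Generate a synthetic three-population RIL study and inspect its pieces.

Three homozygous parents are crossed pairwise and selfed to F7; each RIL
gets RNA-seq-like transcript counts, noisy expression-coupled variant
calls, and multi-environment phenotypes with calibrated heritability.
"""

import rilgp

cfg = rilgp.SimConfig(
    n_variants=1000,
    n_transcripts=400,
    pop_sizes=(30, 30, 30),
    traits=(("plant_height", 5, 0.76), ("grain_area", 4, 0.89)),
    array_size=150,
    seed=1,
)
sim = rilgp.simulate_study(cfg)

rils = sim.popmap.ril_lines
print(f"RIL lines: {len(rils)} in populations "
      f"{ {p: len(sim.popmap.lines_of(p)) for p in sim.popmap.populations} }")
print(f"true genotypes: {sim.genotypes.data.shape} (lines x variants)")
het = float((sim.genotypes.data.loc[rils] == 1).mean().mean())
print(f"residual heterozygosity: {het:.4f} (expected ~(1/2)^6 = 0.0156)")
print(f"expression counts: {sim.expression.counts.shape} "
      f"(transcripts x samples, parents replicated per block)")
print(f"observed variant calls: {sim.observed.shape}, "
      f"{100 * sim.observed.isna().mean().mean():.1f}% missing")
print(f"phenotype records: {len(sim.phenotypes)} "
      f"(single-replicate RILs + replicated parental checks)")
# The observed-call matrix carries realistic DP/QUAL/NS/MAF metadata that
# the quality-filtering stages operate on:
print(sim.variants[["DP", "QUAL", "NS", "MAF"]].describe().loc[["mean", "50%"]])
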