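"""Training-set size, intra- vs inter-population prediction, kernel weights.

Fixed-size random training/validation sampling shows the learning curve
with training-set size, the gap between predicting within a population and
across populations, and the effect of the kernel mixing weight.
"""

import warnings

import rilgp
from rilgp import evaluation as ev
from rilgp import genotypes as gt
from rilgp.gp import kernel_from_features
from rilgp.phenotypes import entry_means_all_traits

warnings.simplefilter("ignore")

# full-size panel: 65/92/80 RILs so a 170-line training set is feasible
sim = rilgp.simulate_study(rilgp.SimConfig(
    n_variants=800, n_transcripts=200,
    traits=(("t", 4, 0.85),), array_size=150, seed=6,
))
imputed = gt.median_impute(
    gt.clean_calls(
        gt.consensus_by_line(sim.observed, sim.expression.genotype),
        sim.popmap,
    ),
    sim.popmap,
)
kernel = kernel_from_features(imputed.data.loc[sim.popmap.ril_lines])
means, _ = entry_means_all_traits(sim.phenotypes, lines=sim.popmap.ril_lines)
y = means["t"]

sweep = ev.ts_size_sweep(kernel, y, sim.popmap, sizes=(20, 95, 170),
                         vs_size=65, reps=5, seed=0)
print("training-set size -> prediction ability (cross-population):")
for size, res in sweep.items():
    print(f"  {size:>4}: {res.mean:.3f}")
print("  larger training sets estimate relationships more precisely")

intra = ev.subset_validation(
    kernel, y, ev.Scheme("intra", 10, 50, 15, "POP2", seed=1), sim.popmap
)
inter = ev.subset_validation(
    kernel, y, ev.Scheme("inter", 10, 50, 65, "POP2", "POP3", seed=1),
    sim.popmap,
)
print(f"intra-population ability: {intra.mean:.3f}  |  "
      f"inter-population: {inter.mean:.3f}")
print("  training on one cross predicts a different cross far worse")
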