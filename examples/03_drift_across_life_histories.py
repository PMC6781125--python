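"""Heterozygosity loss under drift for fast vs slow life histories.

Runs the stochastic Leslie-matrix simulator for the three headline
populations at two displacements of the reproductive schedule — 20 years
earlier ("fast", generation time around 9) and 20 years later ("slow",
around 47) — and compares the heterozygosity retained after 300 years
across 200 replicates of a 1000-individual population.

Expected picture: with Type-I survival, fast life histories lose
heterozygosity much faster than slow ones (the interquartile boxes
separate); with Type-II survival, generation time barely matters.

Takes about half a minute on one CPU.

Run:  python examples/03_drift_across_life_histories.py
"""

import agedrift as ad

cfg = ad.ExperimentConfig(
    shifts=(-20.0, 20.0),
    selection=(0.0,),
    simulation=ad.SimulationConfig(
        N_total=1000, years=300, replicates=200, seed=12345
    ),
)
results, table = ad.run_drift_experiment(ad.default_populations(), cfg)

cols = ["run", "T", "mean", "median", "notch", "retention", "implied_Ne"]
print(table[cols].round(4).to_string(index=False))

print()
for name in ("type1_modern", "type1_preindustrial", "type2"):
    fast = results[(name, -20.0, 0.0)].final_summary()
    slow = results[(name, 20.0, 0.0)].final_summary()
    separated = abs(fast["median"] - slow["median"]) > fast["notch"] + slow["notch"]
    print(f"{name:22s} median het fast {fast['median']:.3f} vs slow "
          f"{slow['median']:.3f} -> {'separated' if separated else 'overlapping'}")
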