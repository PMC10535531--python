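"""Train a pigment retrieval and attribute importance to channels.

Generates a small water-leaving dataset, trains the phycocyanin retrieval
on the 100-channel configuration, reports held-out metrics, and computes
the permutation attribution profile whose peaks drive band selection.
Takes a couple of minutes on one CPU.
"""

import dataclasses

import cyanospec as cs

grid = cs.default_grid()
gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
dataset = cs.generate_dataset(2000, seed=42, config=gen, grid=grid)

full = cs.decimate(cs.srf_matrix(cs.cyanosat_centers(), 12.0, grid,
                                 name="Full"), 3)
res = cs.evaluate(dataset, "pc", full, cs.TrainConfig(), seed=0, run_cv=False)
rep = res.report
print(f"PC retrieval (held-out n={rep.n_test}): R2={rep.r2:.3f} "
      f"MAPE={rep.mape_percent:.0f}% RMSELE={rep.rmsele:.3f}")

profile = cs.permutation_importance(res.model, res.X_test, res.y_test,
                                    full.centers, n_repeats=5, seed=1,
                                    product="pc", data_type="RRS")
print("top 5 channels by permutation importance (1-R2 increase):")
for center, fi in profile.sorted_view()[:5]:
    print(f"  {center:6.1f} nm  FI={fi:.3f}")
print("the 620 nm region ranks high: that is where phycocyanin absorbs.")
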