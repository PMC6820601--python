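"""Joint analysis of four trials with grouped spatial hyperparameters.

Synthetic multi-trial data in the style of a two-year, two-irrigation wheat
experiment: the same lines in all four trials, spatial fields independent
per trial but sharing hyperparameters within year groups.  Compares
single-trial fits against the joint fit with trial-specific intercepts.
"""

from fieldspatial import MultiTrialConfig, run_multitrial

config = MultiTrialConfig(n_lines=50, n_rows=10, n_cols=10, n_markers=200)
res = run_multitrial(config, seed=5)

print("trials:", ", ".join(config.trial_ids))
print(f"joint model spatial hyperparameter sets: {res.n_spatial_hyper_sets} "
      "(2011 trials share one, 2012 trials the other)")
print(f"marker matrix compressed to p* = {res.manifest['p_star']} components\n")

print("posterior genetic variance (iid line effect), estimate +- sd:")
for _, row in res.genetic_sd.iterrows():
    print(f"  {row['fit']:>15s}: {row['estimate']:.3f} +- {row['sd']:.3f}")

sd = res.genetic_sd
joint = float(sd.loc[sd["fit"] == "W1M", "sd"].iloc[0])
single_mean = float(sd.loc[sd["fit"] != "W1M", "sd"].astype(float).mean())
print(
    f"\njoint-fit sd {joint:.3f} vs single-trial mean {single_mean:.3f}: "
    "pooling four trials sharpens the genetic variance estimate"
)

print("\ngrouped spatial hyperparameters (joint fit):")
hs = res.joint_fit.hyper_summary
print(hs[hs["kind"] == "derived"].to_string(index=False))
# group g0 (2011) was simulated with range 8 and variance 0.6, group g1
# (2012) with range 4 and variance 0.3; at this reduced size the variance
# contrast is recovered clearly, the range contrast only weakly (it
# sharpens at the full 20x10-per-trial configuration)
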