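"""Bias-adjusted areas with 90% CIs from a stratified accuracy sample.

A stratified random sample of reference-labelled points (rows = map
class, columns = reference class) turns mapped pixel counts into
bias-adjusted class areas with standard errors, then into a net change
and a yearly rate.
"""

import pandas as pd

import marshchange as mc

sample = mc.ConfusionSample(
    classes=["stable", "loss", "gain"],
    mapped_counts=[940_000, 40_000, 20_000],   # mapped pixels per stratum
    matrix=[[285, 10, 5],                       # reference labels of sampled points
            [12, 135, 3],
            [8, 4, 138]],
)
est = mc.stratified_area(sample, total_area_km2=900.0)
print(est[["mapped_km2", "adjusted_km2", "se_km2", "ci90_low", "ci90_high"]]
      .round(2))
print(f"overall accuracy: {est.attrs['overall_accuracy']:.3f}")

summary = mc.aggregate_changes(pd.DataFrame([{
    "region": "demo",
    "loss_km2": est.loc["loss", "adjusted_km2"],
    "gain_km2": est.loc["gain", "adjusted_km2"],
    "loss_se_km2": est.loc["loss", "se_km2"],
    "gain_se_km2": est.loc["gain", "se_km2"],
}]))
net = summary.loc[0, "net_km2"]
rate = mc.change_rate(net, base_extent_km2=900.0, years=20)
print(f"net change {net:.2f} +- {summary.loc[0, 'net_se_km2']:.2f} km2 "
      f"-> {rate:.3f} % per yr over 20 yr")
# Adjusted areas correct the map's omission/commission bias; the net rate
# is net loss relative to the baseline extent.
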