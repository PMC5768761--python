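"""Run the rank-sum + k-means discrimination protocol on the default
simulated 15-day culture.

Days 1-5 hold a pure progenitor population; from day 6 a neuron +
astrocyte mixture appears, with the evanescent channel (TIRM) sampling the
adherent astrocyte layer and the phase channel (QPC) the taller neurons.
The protocol should divide the time course at day 6 and split the
post-division day-medians into an astrocyte-like and a neuron-like cluster
by modality.
"""

from qpcdiff import RunConfig, simulate_and_discriminate

report = simulate_and_discriminate(RunConfig(master_seed=7))

print("per-day two-sided rank-sum p-values (QPC vs TIRM):")
for day in sorted(set(report.ranksum["day"])):
    sub = report.ranksum[report.ranksum["day"] == day]
    p_area = float(sub[sub["metric"] == "area"]["p_two_sided"].iloc[0])
    p_ar = float(sub[sub["metric"] == "aspect_ratio"]["p_two_sided"].iloc[0])
    print(f"  day {day:2d}: area p={p_area:8.5f}  aspect ratio p={p_ar:8.5f}")

print(f"\ndivision day (progenitor phase ends before): {report.division_day}")
print("\npost-division day-medians and cluster assignment:")
for (_, row), lab in zip(report.cluster.points.iterrows(),
                         report.cluster.labels):
    print(f"  day {int(row['day']):2d} {row['modality']:4s} "
          f"median area {row['median_area']:7.1f} px^2, "
          f"median AR {row['median_aspect_ratio']:4.2f} -> "
          f"{report.phenotype_labels[int(lab)]}")
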