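"""Cross-validated comparison of Models 1, 2A and 2B.

Generates rearing data with real slow/fast structure (20/20/60), splits each
population 70/30 at the individual level, fits all thermal responses and the
strategy composition on the calibration side, simulates each model along
every temperature's series, and scores every (temperature, stage) cell:
Dhat1 overlap for the probabilistic models (1 = the predicted emergence-day
distribution matches the observed one), RMSE in days for Model 1.
"""

from tpphen import cross_validated_comparison, default_truth, generate_rearing_dataset

truth = default_truth(n_per_temp=60, composition=(0.2, 0.2), seed=5)
dataset = generate_rearing_dataset(truth)

report = cross_validated_comparison(dataset, n_repeats=2, seed=3, n_individuals=80)
print(f"cells: {len(report.best_overlap)}  "
      f"M2B wins {report.wins['M2B']:.0%} of decided cells, "
      f"M2A wins {report.wins['M2A']:.0%}")
print(f"mean Dhat1 overlap: M2A={report.mean_overlap['M2A']:.2f}  "
      f"M2B={report.mean_overlap['M2B']:.2f}")
print(f"Model 1 RMSE: median={report.rmse_table['rmse'].median():.1f} d, "
      f"max={report.rmse_table['rmse'].max():.1f} d")
print("Accounting for persistent slow/fast strategies (M2B) predicts the "
      "observed phenology distributions better than population variability "
      "alone (M2A); the mean-curve model (M1) can miss by weeks.")
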