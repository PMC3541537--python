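"""False-positive control under bivariate-outlier contamination.

At rho = 0 with 10% of points drawn from a cloud centered at [6, 6],
Pearson's test rejects independence almost always while the skipped
Pearson test stays near the 5% nominal level.  Desk-scale run: 500
replicates on three sample sizes (the validation study uses 10,000).
"""

from robustcorr import PopulationSpec, run_fpr_power

spec = PopulationSpec(rho=0.0, contamination="bivariate")
res = run_fpr_power(spec, methods=("pearson", "skipped-pearson"),
                    n_grid=(20, 60, 100), n_reps=500, seed=42)
print(res.table[["n", "method", "mean_r", "rejection_rate"]]
      .to_string(index=False))
print("\nmean_r shows why: the contaminated mixture has population "
      "correlation ~0.76, which Pearson dutifully estimates; the skipped "
      "estimator removes the [6, 6] cloud and reports ~0, rejecting at "
      "roughly the nominal 5% rate.")
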