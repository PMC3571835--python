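"""The full comparison: 4 feature combinations x 2 classifiers.

Runs the end-to-end experiment on the default synthetic dataset
(20 samples per variety, 64x64 ROIs, 128 bands) and prints the
calibration/prediction accuracy table. Expect the spectra-only modes (PC,
KPC) to stumble over the twin varieties II and V while the +GLCM modes
recover them, and LS-SVM to outperform the BPNN.
"""

from hyperseed.pipeline import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=42))

print(result.summary.to_string())
print()
print("selected bands (nm):", result.band_set.wavelengths.round(1).tolist())
for mode, grid in result.grid_results.items():
    print(
        f"{mode:9s} best gamma = {grid.best_gamma:7.1f}   "
        f"best sigma^2 = {grid.best_sigma2:7.1f}   "
        f"RMSECV = {grid.cv_surface.rmsecv.min():.4f}"
    )
rep = result.reports[("PC", "lssvm", "prediction")]
print("\nPC-only LS-SVM prediction confusion (rows = truth, I..VI):")
print(rep.confusion)
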