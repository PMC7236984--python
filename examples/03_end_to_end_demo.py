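"""Run the whole pipeline end to end on synthetic data.

Generates references, builds both layouts, simulates a ten-rater panel,
extracts the 36 NSS features of all 470 images, runs the 100-iteration
80/20 epsilon-SVR protocol (C=512, g=0.25), and scores the held-back
evaluation layout. Takes about a minute at the 256-pixel scale used
here.
"""

from woodiqa import demo_end_to_end

summary = demo_end_to_end(seed=1, size=256, n_iter=100, rater_sd=0.5)

print(f"training images: {summary.train_size}, evaluation images: {summary.eval_size}")
print(f"median held-out PLCC over 100 iterations: {summary.median_plcc:.3f}")
print(f"median held-out RMSE: {summary.median_rmse:.3f}")
print(f"Spearman(mean prediction, noise level): {summary.spearman_gwn:.3f}")
print(f"Spearman(mean prediction, blur level):  {summary.spearman_mb:.3f}")
print()
print(summary.report.to_string(index=False))
print()
print("PLCC near 1 in the gwn/mb strata shows the metric tracks the panel's")
print("opinion on the distortions it was trained on; the negative Spearman")
print("values confirm predicted quality falls monotonically with severity.")
print("The mixed stratum is harder: the model never saw combined noise+blur")
print("during training, so its correlation there is much weaker.")
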