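"""Build the two dataset layouts used to train and evaluate the metric.

Ten references are each distorted by Gaussian white noise
(sigma 10..50) and motion blur (severity 2..10): the training layout has
110 images (references + single distortions) and the evaluation layout
360 (adding every noise x blur combination, blur applied after noise).
"""

from woodiqa import build_eval_set, build_training_set
from woodiqa.synthetic import make_reference_set

references = make_reference_set(seed=1, n=10, size=128)

train = build_training_set(references, seed=2)
evalset = build_eval_set(references, seed=3)

print(f"training layout: {len(train)} images, by kind {train.counts_by_kind()}")
print(f"evaluation layout: {len(evalset)} images, by kind {evalset.counts_by_kind()}")
print()
print(train.frame.head(8).to_string(index=False))
print()
print("Each row records the reference, distortion kind and severities;")
print("pass out_dir= to also write the images as 8-bit PNGs.")
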