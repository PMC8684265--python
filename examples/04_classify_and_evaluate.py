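"""The full loop: synthesize, split 80/20, learn references, train the
encoder, encode test images into binary semantic codes, classify by
self-matching, and print the evaluation report.

Each test image becomes a bit string (1 = "this patch looks benign");
l is the fraction of benign bits and the image is called benign when
l > 0.5.  Benign is the positive class in all metrics.
"""

import json

from lrscnet import PipelineConfig, SynthSpec, generate_images, run_on_images
from lrscnet.synth import stratified_split

spec = SynthSpec(image_side=96, n_per_class=15, seed=42)
images = generate_images(spec)
tags = stratified_split([im.label for im in images], 0.8, seed=42)
train = [im for im, t in zip(images, tags) if t == "train"]
test = [im for im, t in zip(images, tags) if t == "test"]

config = PipelineConfig()
config.references.k = config.references.r = 5
config.encoder.epochs = 10
config.encoder.pairs_per_epoch = 1024

result = run_on_images(config, train, test)
for row in result["per_image"][:4]:
    print(f"{row['image_id']}: l={row['l']:.2f} score={row['score']:.2f} "
          f"-> {row['predicted']} (truth {row['truth']})  bits={row['bits'][:24]}...")
print(json.dumps(result["report"], indent=2, sort_keys=True))
# accuracy/sensitivity/specificity/ppv/npv are computed with benign as
# the positive class; auc uses the mean pre-threshold benign similarity.
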