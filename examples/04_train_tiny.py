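"""Two-step training of the tiny profile on eight phantom radiographs.

Step 1 fine-tunes the dense backbone on lesion-biased 75x75 crops under the
focal segmentation loss; step 2 trains the attention stages and both heads
end-to-end with the backbone frozen, LesionMix-balanced minibatches and
online augmentation.  Prints the loss trajectory and the final train
accuracy.  (A short run for illustration; the test suite runs the full
overfitting check.)
"""

import warnings

import numpy as np

from jawnet.config import tiny_config
from jawnet.phantom import generate_dataset, tiny_spec
from jawnet.training import finetune_backbone, train_end_to_end

warnings.filterwarnings("ignore")

cfg = tiny_config(seed=0)
dataset = generate_dataset(tiny_spec(seed=0))
print("training on:", [s.label for s in dataset])

backbone, h1 = finetune_backbone(dataset, cfg, epochs=20)
print(f"step 1 (backbone, focal loss): {h1['loss'][0]:.4f} -> "
      f"{h1['loss'][-1]:.4f} over {len(h1['loss'])} epochs")

model, h2 = train_end_to_end(dataset, backbone, cfg, epochs=25)
print(f"step 2 (end-to-end): loss {h2['loss'][0]:.3f} -> {h2['loss'][-1]:.3f}")
print(f"train accuracy trajectory (every 5th epoch): "
      f"{h2['train_acc'][::5]}")
# The loss components (classification cross-entropy, heatmap MSE, focal
# segmentation) all decrease.  Run deterministically (use_online_aug=False,
# use_lesionmix=False) the model memorises the eight phantoms — accuracy
# 1.0 within ~20 epochs — while the backbone stays bitwise frozen; with the
# stochastic augmentation on, memorisation is (by design) much slower.

before = backbone.state_dict()
after = model.backbone.state_dict()
drift = max(float(np.abs(before[k] - after[k]).max()) for k in before)
print("max backbone weight drift during step 2:", drift)   # exactly 0.0
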