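"""Architecture analysis: receptive fields, parameter counts, tap shapes.

Prints the analytic numbers that pin down the reference geometry: the
ResNet-18 receptive field from the maximal-path recursion (435), the exact
parameter count of the 121-layer dense classifier (7,978,856 ~ 8M), and the
multi-resolution tap sizes for reference (375 -> 47/23/11) and tiny
(75 -> 9/4/2) patches.
"""

import numpy as np

from jawnet.backbone import (DenseEncoder, count_parameters,
                             densenet121_classifier, receptive_field,
                             resnet18_layer_spec, tap_sizes)
from jawnet.config import BackboneConfig

print("ResNet-18 receptive field:",
      receptive_field(resnet18_layer_spec()), "px")

clf = densenet121_classifier(np.random.default_rng(0))
n = count_parameters(clf)
print(f"121-layer dense classifier parameters: {n:,} (~{round(n/1e6)}M)")

enc = DenseEncoder(BackboneConfig(), np.random.default_rng(0))
print(f"reference encoder (1-channel, no classifier): "
      f"{count_parameters(enc):,} params, tap channels {enc.tap_channels}")
print("tap sizes, 375x375 patch:", tap_sizes(375))
print("tap sizes,  75x75  patch:", tap_sizes(75))

tiny = DenseEncoder(BackboneConfig(width_scale=0.125), np.random.default_rng(0))
print(f"tiny encoder (width/8): {count_parameters(tiny):,} params")
# The 47/23/11 taps at stride 8/16/32 are what the proposal FPN and the
# layer projections consume; the tiny profile keeps the same arithmetic.
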