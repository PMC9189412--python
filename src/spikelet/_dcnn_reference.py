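"""Reference training configuration of the detector stage (not executed).

The counting system's detector is a Faster RCNN with Inception-V2 features,
pre-trained on COCO and fine-tuned on the watershed-labeled datasets.
Training is out of scope for this package (it needs GPU-scale compute and
the trained weights were never deposited); the constants are recorded here
so a user wiring a real detector behind
:class:`~spikelet.detectors.DetectorInterface` can reproduce the setup.

Nothing in the package imports this module at run time.
"""

# Anchor geometry
ANCHOR_SCALES = (0.25, 0.5, 1.0, 2.0)
ANCHOR_RATIOS = (0.5, 1.0, 2.0)
ANCHOR_POSITIVE_IOU = 0.6

# Proposal pruning
NMS_IOU_THRESHOLD = 0.6

# First training round (initial watershed labels)
ROUND1_BATCH_SIZE = 1
ROUND1_MOMENTUM = 1.0
ROUND1_LEARNING_RATE_SCHEDULE = {0: 0.0005, 4000: 0.0003, 8000: 0.0001}

# Second training round (optimized, manually corrected labels)
ROUND2_BATCH_SIZE = 2
ROUND2_MOMENTUM = 0.8
ROUND2_LEARNING_RATE_SCHEDULE = {0: 0.0005, 6000: 0.0001, 10000: 0.00001}

# Inference
DETECTION_CONFIDENCE_THRESHOLD = 0.75
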