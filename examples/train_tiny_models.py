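"""Train miniature segmentation and talus-landmark models on phantoms.

A quick, scaled-down version of the learning pipeline (few phantoms, few
epochs, coarse internal resolution) that finishes in about a minute on a
laptop CPU.  Prints the held-out mask overlap (IoU, 1.0 = perfect) per
bone and the mean talus landmark error in pixels at the 256x256 crop.
"""

from limbalign.evaluate import (TinyPipeline, heldout_landmark_error,
                                heldout_segmentation_iou)
from limbalign.landmarks import train_landmark_model
from limbalign.models import LandmarkTrainConfig, SegTrainConfig
from limbalign.segmentation import train_segmenter
from limbalign.training import phantom_crop_dataset, phantom_seg_dataset

images, masks, _ = phantom_seg_dataset(10, seed=0)
segmenter = train_segmenter(images, masks, SegTrainConfig(epochs=8, seed=0))
print(f"segmenter final loss: {segmenter.history['loss_per_epoch'][-1]:.4f}")

crops, landmark_sets = phantom_crop_dataset("talus", 15, seed=1)
talus_model = train_landmark_model(
    "talus", crops, landmark_sets,
    LandmarkTrainConfig(epochs=10, seed=0, internal_size=64, hidden=8))
print(f"talus model final loss: {talus_model.history['loss_per_epoch'][-1]:.4f}")

pipeline = TinyPipeline(segmenter=segmenter,
                        landmark_models={"talus": talus_model})
for label, score in heldout_segmentation_iou(pipeline, n=5, seed=99).items():
    print(f"held-out IoU {label}: mean {score['mean']:.3f}")
err = heldout_landmark_error(pipeline, "talus", n=5, seed=99)
print(f"held-out talus landmark error: {err['mean_error_px']:.2f} px")
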