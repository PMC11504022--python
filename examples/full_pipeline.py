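"""Detect -> crop -> prompt -> classify -> report on one phantom patient.

Uses a quickly-trained tiny detector and classifier; prints the per-patient
evaluation report (sensitivity, false positives per patient, and the two
patient-level accuracy rules) plus the closed-form timing bookkeeping.
"""

import numpy as np

from cmbscreen.classifier import CFConfig, train_classifier
from cmbscreen.detector import DetectorConfig, build_detector, train_detector
from cmbscreen.experiments import _tiny_cf, build_candidate_set, slice_dataset
from cmbscreen.phantom import PhantomSpec, generate_patient
from cmbscreen.pipeline import TimingModel, estimate_infertime, run_patient

spec = PhantomSpec(slices_per_patient=6, image_side=96, cmb_diameter=(4, 12))

det_cfg = DetectorConfig(scale="N", input_size=96, channels=(8, 16, 32, 64), depth=1,
                         score_threshold=0.5, seed=0)
detector = build_detector(det_cfg)
detector, _ = train_detector(detector, slice_dataset(spec, range(20)), epochs=5, seed=1)

clf_cfg = CFConfig(variant="S", crop_mode="fixed32", with_text=True)
crops = build_candidate_set(spec, range(100, 160), clf_cfg)
classifier = _tiny_cf(0, with_text=True)
classifier, _ = train_classifier(classifier, crops, epochs=10, seed=2)

rec = generate_patient(spec, 999, force_positive=True)
detections, results, report = run_patient(rec, detector, classifier, det_cfg)

n_gt = sum(len(b) for b in rec.gt_boxes)
print(f"patient {rec.patient_id} ({rec.meta.gender}, {rec.meta.age} y): "
      f"{n_gt} true CMB boxes")
print(f"stage 1 proposed {len(detections)} candidates; "
      f"stage 2 accepted {sum(r.label for r in results)}")
for k, v in report.to_dict().items():
    if k != "counts":
        print(f"  {k}: {v}")

tm = TimingModel(num_image=130, d_image_ms=14.6, c_image_ms=26.12, candidates=100)
print(f"closed-form inference time at full scale: {estimate_infertime(tm)} s/patient")
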