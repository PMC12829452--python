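"""Clean one synthetic recording and inspect the audit log.

The pipeline order is fixed: notch + band-pass FIR filter, crop, ICA
removal of EOG-correlated components, common-average reference,
segmentation into overlapping 4-s epochs, peak-to-peak rejection.
"""

import eegdx
from eegdx.preprocess import PreprocConfig, preprocess_subject

cfg = eegdx.SimConfig.test_scale(1, seed=3, noise_burst_prob=0.2)
recs, _ = eegdx.generate_cohort(cfg)
pcfg = PreprocConfig(crop_seconds=60.0, n_ica_components=6, eog_match_threshold=2.0)

epochs, audit = preprocess_subject(recs[0], pcfg)

print(f"subject {epochs.subject_id}: {epochs.n_epochs} clean epochs of "
      f"{epochs.epochs.shape[2]} samples "
      f"({epochs.kept_mask.size - epochs.n_epochs} rejected at "
      f"{pcfg.reject_p2p_uv:.0f} µV peak-to-peak)")
print("\naudit trail:")
for step in audit["steps"]:
    print(" ", step)
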