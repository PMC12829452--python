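"""Generate a synthetic resting-EEG cohort and inspect its structure.

Builds a desk-scale two-group cohort (8 EEG + 2 EOG channels, 256 Hz,
60 s per subject) carrying the band-power-neutral spectro-temporal group
effect, prints the per-band group power ratios (matched to within 2% by
construction) and the covariate table head.
"""

import numpy as np

import eegdx
from eegdx.simulate import CANONICAL_BANDS, burst_chirp_statistic
from scipy import signal


def band_power(x, sr, lo, hi):
    f, p = signal.welch(x, fs=sr, nperseg=int(2 * sr), axis=-1)
    return p[..., (f >= lo) & (f < hi)].mean()


# artifacts off: band-power matching concerns the stationary signal;
# blink/burst injections are group-balanced but Poisson-noisy at small n
cfg = eegdx.SimConfig.test_scale(
    5, seed=7, effect_kind="spectrotemporal", blink_rate=0.0, noise_burst_prob=0.0
)
recs, covariates = eegdx.generate_cohort(cfg)

print(f"{len(recs)} recordings, {recs[0].eeg.shape[0]} EEG channels, "
      f"{recs[0].duration:.0f} s at {recs[0].sample_rate:.0f} Hz")

print("\nper-band case/control mean power ratio (1.0 = matched):")
for name, (lo, hi) in CANONICAL_BANDS.items():
    p0 = np.mean([band_power(r.eeg, r.sample_rate, lo, hi) for r in recs if r.group == 0])
    p1 = np.mean([band_power(r.eeg, r.sample_rate, lo, hi) for r in recs if r.group == 1])
    print(f"  {name:6s} {p1 / p0:.3f}")

print("\nchirp-direction statistic (s): upper-band minus lower-band"
      "\narrival lag — the group difference lives in time-frequency"
      "\norientation, not power:")
for g in (0, 1):
    stat = np.mean([burst_chirp_statistic(r) for r in recs if r.group == g])
    print(f"  group {g}: {stat:+.3f}")

print("\ncovariates:")
print(covariates.head(4).to_string(index=False))
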