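"""Decompose a PPG slice by EMD and inspect the 4-channel model input.

Shows that the channel stack is a lossless re-arrangement of the slice
(channels sum back to the input exactly) and how the leading IMFs isolate
the fast oscillatory content.
"""

import numpy as np

from ppgvitals.emd import assemble_channels, emd_decompose
from ppgvitals.synth import GroundTruthMap, SyntheticPatientSpec, generate_record

spec = SyntheticPatientSpec(patient_id="demo", heart_rate_bpm=75.0, noise_sd=0.02)
rec = generate_record(spec, 20.0, 125.0, seed=1, gt_map=GroundTruthMap.noiseless())
ppg = rec.channel("PLETH")

imfs = emd_decompose(ppg)
channels = assemble_channels(ppg, imfs, n_channels=4)

print(f"extracted IMFs: {len(imfs.imfs)}; channel matrix shape: {channels.shape}")
recon_err = np.max(np.abs(channels.sum(axis=0) - ppg))
print(f"max |sum(channels) - ppg| = {recon_err:.2e}  (lossless by construction)")
for i, row in enumerate(channels, start=1):
    print(f"channel {i}: variance {np.var(row):.4f}")
print("channel 1 carries the fastest mode; channel 4 is the remainder, so")
print("the encoder always sees the complete slice.")
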