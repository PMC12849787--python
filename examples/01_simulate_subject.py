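"""Generate one synthetic EEG subject and export it to EDF + NPZ.

The generator mimics a single-subject recording: 16 bipolar channels at
256 Hz with correlated background activity, interrupted by seizures that are
louder (amplitude gain), rhythmic (3-5 Hz spike-wave surrogate) and more
strongly coupled across channels than the background.
"""

from pathlib import Path

import seizformer as sz

cfg = sz.SimConfig(duration_s=600.0, seizure_rate=6, seizure_len_s=(20, 60),
                   seed=42)
rec = sz.make_subject(cfg)

out = Path("scratch_example")
out.mkdir(exist_ok=True)
sz.write_edf(rec, out / "subject.edf")      # + subject.csv annotation sidecar
sz.write_npz(rec, out / "subject.npz")

print(f"subject: {rec.n_channels} channels x {rec.duration_s:.0f} s "
      f"at {rec.fs:.0f} Hz")
print(f"seizures ({len(rec.seizure_intervals)}):")
for a, b in rec.seizure_intervals:
    print(f"  [{a:7.1f} s, {b:7.1f} s)  duration {b - a:5.1f} s")
burden = sum(b - a for a, b in rec.seizure_intervals)
print(f"total ictal time: {burden:.0f} s "
      f"({100 * burden / rec.duration_s:.0f}% of the record)")
# Each interval is annotated ground truth: downstream windows whose majority
# lies inside one of these spans are labeled seizure (1), the rest 0.
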