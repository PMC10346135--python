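"""Generate one synthetic paired session and export the two CSV streams.

The session emulates a biofeedback-guided hip-flexion bout recorded
simultaneously by a thigh-worn IMU (30 Hz quaternions + raw inertial
channels, clock delayed by 0.5 s) and an optoelectronic reference (100 Hz
angle trace with a 2-degree constant offset). Every corruption is known, so
the printed ground truth is what downstream stages should recover.
"""

from pathlib import Path

from kinagree import SimConfig, generate_session, make_template
from kinagree.io import write_angle_csv, write_imu_csv

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)

cfg = SimConfig(
    template=make_template("hip_flexion"),
    lag=0.5,
    inter_system_offset=2.0,
    rng_seed=7,
)
session = generate_session(cfg)

write_imu_csv(session.imu_stream, out / "hip_flexion_imu.csv")
write_angle_csv(session.mocap_trace, out / "hip_flexion_mocap.csv")

t = session.truth
print(f"IMU stream: {len(session.imu_stream)} samples at {session.imu_stream.rate:.0f} Hz")
print(f"MoCap trace: {len(session.mocap_trace)} samples at {session.mocap_trace.rate:.0f} Hz")
print(f"ground truth: lag {t.lag_seconds} s ({t.lag_samples} samples at 30 Hz), "
      f"offset {t.offset} deg, per-repetition ROM {t.rom_per_rep_mocap[0]:.2f} deg x "
      f"{len(t.rom_per_rep_mocap)} repetitions")
print(f"exports written to {out}/")
# The two files are what the device cloud and the motion-capture software
# would hand you; the rest of the toolkit works from exactly these.
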