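"""Effect of medial/lateral sensor misplacement on the measured ROM.

Displacing the thigh-worn sensor by 10 % of the thigh diameter around the
circumference rotates its frame ~11.5 deg about the segment's longitudinal
axis. The same session is processed three times (correct, medial, lateral
mounting); under the pure axial-rotation model both displaced arms
attenuate the in-plane ROM by ~cos(theta), symmetrically.
"""

import numpy as np

from kinagree import SimConfig, make_template
from kinagree.sensitivity import misplacement_comparison, rom_vs_misplacement_sweep
from kinagree.synth import DEFAULT_MISPLACEMENT_DEG

cfg = SimConfig(template=make_template("hip_flexion"), rng_seed=9)
comp = misplacement_comparison(cfg)

theta = DEFAULT_MISPLACEMENT_DEG
print(f"axial misplacement theta = {theta:.1f} deg")
print(f"correct : ROM {comp.rom_correct.mean_rom:.2f} ({comp.rom_correct.sd_rom:.2f}) deg")
print(f"medial  : ROM {comp.rom_medial.mean_rom:.2f} deg   "
      f"RMSE {comp.rmse_medial:.2f}  delta {comp.delta_medial:+.2f} deg")
print(f"lateral : ROM {comp.rom_lateral.mean_rom:.2f} deg   "
      f"RMSE {comp.rmse_lateral:.2f}  delta {comp.delta_lateral:+.2f} deg")

thetas = np.arange(0.0, 61.0, 10.0)
sweep = rom_vs_misplacement_sweep(30.0, thetas)
print("\ntheta sweep on a 30-deg excursion (extracted in-plane ROM):")
for th, rom in zip(thetas, sweep):
    print(f"  theta {th:4.0f} deg -> {rom:5.2f} deg  (cos model: {30*np.cos(np.radians(th)):5.2f})")
# The attenuation grows monotonically with |theta|; at the protocol's
# ~11.5 deg it costs only ~0.6 deg of a 30-deg excursion, i.e. the device
# is fairly tolerant of realistic placement error.
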