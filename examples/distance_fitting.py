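"""Internuclear distances from dipolar dephasing curves.

Simulates a noisy PITHIRDs-CT 13C-13C dephasing curve for a known
interstrand distance, then recovers the distance by matching against the
simulated 4-8 A curve family, and shows a REDOR 13C-31P build-up for a
peptide-lipid contact.
"""

import numpy as np

import memfibril as mf
from memfibril.synthetic import gen_dephasing

# a residue in a parallel-in-register beta sheet: ~5 A interstrand distance
observed = gen_dephasing(5.0, experiment="PITHIRDS_CT", noise_sd=0.05, seed=7)
est = mf.estimate_distance(observed)
print(
    f"PITHIRDs: true r = 5.0 A, best fit r = {est.r_best:.1f} A "
    f"({est.contact_class} contact)"
)
print("  (strong <= 5.5 A indicates parallel-in-register stacking)")

# dipolar couplings behind the curves: the r^-3 law
for r in (4.0, 5.0, 6.0, 8.0):
    print(f"  d(13C-13C, {r:.0f} A) = {mf.dipolar_coupling(r):6.1f} Hz")

# REDOR build-up for a 13C-31P peptide-phosphate contact at 8 kHz MAS
curve = mf.simulate_redor_buildup(5.0, np.arange(0, 200, 16), rotor_period=1 / 8000)
print("\nREDOR dS/S0 build-up at r = 5.0 A (8 kHz MAS):")
for t, s in zip(curve.times[::3], curve.signal[::3]):
    print(f"  {t*1e3:5.1f} ms  dS/S0 = {s:.3f}")
print("  (a plateau well below 1 indicates a large non-contacting population)")
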