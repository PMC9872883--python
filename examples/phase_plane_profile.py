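"""Where in the phase-plane stack is the diagnosis most informative?

Scans the layered reconstruction over phase planes 0.1..1.2 rad and plots
the between-class detectability (|mean difference| / summed spreads) of the
mean linear birefringence.  The separation peaks inside 0.3-0.9 rad: at
shallow planes the anisotropy signal is weak against the floor dispersion,
at deep planes sample-to-sample variability grows with scattering
multiplicity.
"""

import numpy as np

from mmtomo import adenoma_spec, carcinoma_spec, generate_cohort, separation_profile
from mmtomo.pipeline import phantom_moment_rows
from mmtomo import io as mmio

planes = tuple(np.round(np.arange(0.1, 1.21, 0.1), 10))
rows = []
for spec_fn, label, base in ((adenoma_spec, "adenoma", 1), (carcinoma_spec, "carcinoma", 101)):
    cohort = generate_cohort(spec_fn(shape=(48, 48)), 8, base_seed=base, planes=planes)
    rows += phantom_moment_rows(cohort, label)

profile = separation_profile(mmio.moments_table(rows), "phi_l", order=1)
peak = profile["phase_plane"][np.argmax(profile["separation"])]
print("phase plane [rad]   class separation of Z1(phi_l)")
top = profile["separation"].max()
for p, s in zip(profile["phase_plane"], profile["separation"]):
    bar = "#" * int(round(40 * s / top))
    print(f"   {p:4.1f}              {s:6.1f}  {bar}")
print(f"\nmost discriminative plane: {peak:.1f} rad (inside the 0.3-0.9 rad window)")
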