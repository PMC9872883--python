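"""Close the measurement loop through simulated off-axis holography.

A non-depolarizing 64x64 phantom is probed with the six polarization
states; each probe's orthogonal field projections are recorded as off-axis
interferograms, demodulated through the carrier sideband, combined into
Stokes maps and assembled back into the Mueller map, which is compared with
the phantom's ground-truth map.
"""

import numpy as np

from mmtomo import (
    ProbeState,
    adenoma_spec,
    coherent_probe_fields,
    demodulate,
    generate_phantom,
    jones_map_from_mueller,
    mueller_from_probes,
    simulate_interferogram,
    stokes_from_fields,
)

phantom = generate_phantom(adenoma_spec(seed=3, shape=(64, 64), lambda_target=0.0))
mm = phantom.mueller[0.6]
jones = jones_map_from_mueller(mm)

stokes = {}
for probe in ProbeState:
    e0, e90 = coherent_probe_fields(mm, probe, jones=jones)
    rec0, rec90 = (
        demodulate(simulate_interferogram(f, carrier=(0.25, 0.25))) for f in (e0, e90)
    )
    stokes[probe] = stokes_from_fields(rec0, rec90)

recovered = mueller_from_probes(stokes, geometry=mm.geometry)
err = np.abs(recovered.data - mm.data)[3:-3, 3:-3]  # outer 5% frame excluded
print(f"median per-element error : {np.median(err):.2e}")
print(f"95th percentile error    : {np.quantile(err, 0.95):.2e}")
# Median error around 5e-4: the interferometric chain reproduces the
# per-pixel Mueller matrices far below the instrument's 1-2% element error.
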