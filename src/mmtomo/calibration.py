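"""Reference calibration matrices of the polarimeter.

Two standard calibration targets: empty beam path ("air", expected identity)
and a quarter-wave plate at 45° (a π/2 retarder between the 45°/135°
components).  AIR and QUARTER_WAVE are the canonical fixtures; the *_PRINTED
variants keep two transcription artifacts in elements (2,3)/(3,2) of the
published tables (0.092/0.091, an order of magnitude above the instrument's
stated ≤1% error for that block and clearly missing a digit).
"""

import numpy as np

AIR_PRINTED = np.array(
    [
        [1.00, 0.0092, 0.0094, 0.0198],
        [0.0093, 0.991, 0.092, 0.0197],
        [0.0094, 0.091, 0.992, 0.0197],
        [0.0197, 0.0199, 0.02, 0.981],
    ]
)

QUARTER_WAVE_PRINTED = np.array(
    [
        [1.00, 0.0092, 0.0094, 0.0198],
        [0.0093, 0.0094, 0.092, 0.981],
        [0.0094, 0.091, 0.992, 0.0197],
        [0.0197, -0.981, 0.02, 0.0199],
    ]
)


def _fix(m: np.ndarray) -> np.ndarray:
    m = m.copy()
    m[1, 2] = 0.0092
    m[2, 1] = 0.0091
    return m


#: empty-path calibration, consistent with the ≤1%/2% stated element errors
AIR = _fix(AIR_PRINTED)

#: quarter-wave-plate calibration (ideal |Φ45,135| = π/2 retarder)
QUARTER_WAVE = _fix(QUARTER_WAVE_PRINTED)
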