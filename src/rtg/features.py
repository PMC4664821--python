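"""Per-trial kinematic measures within the movement window.

Five measures: total movement time (TMT), peak transport velocity and its time
(percent of TMT), peak aperture and its time (percent of TMT).  Coordination
fields (r_max, Fisher-z, lag) are filled by the coordination module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .events import MovementWindow
from .signal import TrialSignals


@dataclass
class TrialFeatures:
    tmt: float            # s
    v_max: float          # m/s
    t_v_max: float        # % of TMT
    a_max: float          # m
    t_a_max: float        # % of TMT
    r_max: float | None = None
    z_r_max: float | None = None
    lag_ms: float | None = None
    degenerate: bool = False


def extract_features(signals: TrialSignals, window: MovementWindow) -> TrialFeatures:
    """Maxima and their %-of-TMT times over the inclusive movement window.

    Ties between equal maxima resolve to the earliest sample; peaks are taken
    at sample resolution (no sub-sample interpolation).
    """
    n = signals.transport_velocity.shape[0]
    if window.end_index > n - 1:
        raise ParameterError(
            f"window end {window.end_index} exceeds signal length {n}"
        )
    s, e = window.start_index, window.end_index
    span = e - s
    v = signals.transport_velocity[s : e + 1]
    a = signals.aperture[s : e + 1]
    iv = int(np.argmax(v))
    ia = int(np.argmax(a))
    degenerate = bool(np.ptp(v) == 0.0 or np.ptp(a) == 0.0)
    return TrialFeatures(
        tmt=span / signals.fs,
        v_max=float(v[iv]),
        t_v_max=100.0 * iv / span,
        a_max=float(a[ia]),
        t_a_max=100.0 * ia / span,
        degenerate=degenerate,
    )
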