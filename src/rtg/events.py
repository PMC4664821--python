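"""Movement initiation / termination detection and the analysis window.

Initiation: the first bin of a continuous rise of at least 3 data points in
transport velocity, i.e. the sample at which a run of (by default) three
consecutive strict increments begins — the local minimum preceding the rise.
The scan is anchored at the LED-onset sample when available, so pre-cue drift
cannot trigger initiation.  Termination: the sample nearest the object-lift
switch timestamp, ties resolved toward the later sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InitiationNotDetectedError, ParameterError
from .synth import TrialRecording


@dataclass
class MovementWindow:
    start_index: int
    end_index: int
    tmt: float  # s

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ParameterError(
                f"window indices must satisfy 0 <= start < end, "
                f"got ({self.start_index}, {self.end_index})"
            )
        if self.tmt <= 0:
            raise ParameterError(f"tmt must be strictly positive, got {self.tmt}")


def detect_initiation(
    transport_velocity: np.ndarray,
    start_index: int = 0,
    n_rises: int = 3,
    strict: bool = True,
) -> int:
    """Index of the first bin of a run of ``n_rises`` consecutive velocity rises."""
    v = np.asarray(transport_velocity, dtype=float)
    if v.ndim != 1 or v.shape[0] < n_rises + 1:
        raise ParameterError(f"need at least {n_rises + 1} samples, got {v.shape}")
    d = np.diff(v)
    rising = d > 0 if strict else d >= 0
    runs = sliding_window_view(rising, n_rises).all(axis=1)
    start = max(0, int(start_index))
    if start >= runs.shape[0] or not runs[start:].any():
        raise InitiationNotDetectedError(
            f"no run of {n_rises} consecutive velocity rises at or after sample {start}"
        )
    return start + int(np.argmax(runs[start:]))


def detect_termination(recording: TrialRecording) -> int:
    """Index of the sample nearest the object-lift timestamp (ties -> later)."""
    t = recording.timestamps
    if recording.object_lift is None:
        raise ParameterError("object_lift timestamp missing")
    if not t[0] - 1e-9 <= recording.object_lift <= t[-1] + 1e-9:
        raise ParameterError(
            f"object_lift {recording.object_lift} outside recording span [{t[0]}, {t[-1]}]"
        )
    pos = (recording.object_lift - t[0]) * recording.fs
    idx = int(np.floor(pos + 0.5))  # round half up = ties toward the later sample
    return min(idx, t.shape[0] - 1)


def robust_initiation(
    transport_velocity: np.ndarray,
    start_index: int = 0,
    end_index: int | None = None,
    floor_fraction: float = 0.2,
    rise_tol_fraction: float = 1e-4,
) -> int:
    """Noise-robust onset: first bin of the continuous rise that carries the
    velocity past ``floor_fraction`` of its peak.

    The threshold-free rise rule fires on arbitrarily small fluctuations — the
    acausal precursor of zero-phase filtering, or pre-movement sensor noise —
    so the pipeline anchors on the first crossing of ``floor_fraction * vmax``
    at or after the cue and walks backward through the rise, treating
    increments below ``rise_tol_fraction * vmax`` as flat.  The returned bin
    is the start of that (tolerance-strict) continuous rise.
    """
    v = np.asarray(transport_velocity, dtype=float)
    start = max(0, int(start_index))
    stop = v.shape[0] if end_index is None else int(end_index) + 1
    vmax = float(v[start:stop].max())
    if vmax <= 0.0:
        raise InitiationNotDetectedError("velocity never rises above zero after the cue")
    floor = floor_fraction * vmax
    above = np.nonzero(v[start:stop] >= floor)[0]
    if above.size == 0:
        raise InitiationNotDetectedError(
            f"velocity never reaches {floor_fraction:.0%} of its peak after the cue"
        )
    j = start + int(above[0])
    tol = rise_tol_fraction * vmax
    while j - 1 >= start and v[j] - v[j - 1] > tol:
        j -= 1
    return j


def movement_window(
    recording: TrialRecording,
    transport_velocity: np.ndarray,
    floor_fraction: float = 0.2,
    rise_tol_fraction: float = 1e-4,
) -> MovementWindow:
    """Detect the analysis window [initiation, object lift] for one trial."""
    led_index = int(np.ceil((recording.led_onset - recording.timestamps[0]) * recording.fs - 1e-9))
    end = detect_termination(recording)
    start = robust_initiation(
        transport_velocity,
        start_index=max(0, led_index),
        end_index=end,
        floor_fraction=floor_fraction,
        rise_tol_fraction=rise_tol_fraction,
    )
    if end <= start:
        raise InitiationNotDetectedError(
            f"initiation (sample {start}) not before termination (sample {end})"
        )
    return MovementWindow(start_index=start, end_index=end, tmt=(end - start) / recording.fs)
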