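"""MEP peak-to-peak amplitudes and the corticomotor-excitability comparison.

A motor evoked potential (MEP) is the EMG deflection a single TMS pulse evokes
in the target muscle; its peak-to-peak amplitude indexes corticomotor
excitability.  Amplitude is measured inside a fixed post-stimulus window
(default 10-60 ms, excluding the stimulus artifact), and the 10 sweeps of a
session are averaged into one value per subject and session.

The packaged participant table (9 chronic-stroke subjects: demographics,
Fugl-Meyer scores and pre/post-rTMS MEP session means in microvolts) ships as
a CSV fixture; ``table1_analysis`` reruns the paired pre/post comparison on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError
from .synth import MEPSweepRecord


@dataclass
class MEPResult:
    amplitude_uv: float
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ParameterError("peak-to-peak amplitude cannot be negative")


def peak_to_peak(sweep: MEPSweepRecord, window_ms: tuple[float, float] = (10.0, 60.0)) -> MEPResult:
    """max - min of the EMG inside the post-stimulus window (DC-offset invariant)."""
    lo, hi = window_ms
    if not 0.0 <= lo < hi:
        raise ParameterError(f"window must satisfy 0 <= start < end, got {window_ms}")
    t0 = sweep.stimulus_time + lo / 1000.0
    t1 = sweep.stimulus_time + hi / 1000.0
    t = sweep.timestamps
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ParameterError(
            f"window [{t0:.4f}, {t1:.4f}] s falls outside the sweep span [{t[0]}, {t[-1]}] s"
        )
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    segment = sweep.emg_uv[mask]
    return MEPResult(amplitude_uv=float(segment.max() - segment.min()), window_ms=window_ms)


def session_mean(amplitudes_uv) -> float:
    """Arithmetic mean MEP amplitude of one session's sweeps."""
    amplitudes_uv = np.asarray(amplitudes_uv, dtype=float)
    if amplitudes_uv.size == 0:
        raise ParameterError("session mean of an empty amplitude list is undefined")
    return float(amplitudes_uv.mean())


def load_table1() -> pd.DataFrame:
    """The packaged 9-subject participant table (printed values, verbatim)."""
    with resources.files("rtg.data").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh)


def table1_analysis() -> dict:
    """Group summaries and the paired pre/post MEP comparison on the fixture."""
    from .stats import paired_t  # local import to avoid a cycle

    df = load_table1()
    report = paired_t(df["mep_pre_uv"].to_numpy(), df["mep_post_uv"].to_numpy())
    summary = {
        "n": int(len(df)),
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)),
        "fugl_meyer_mean": float(df["fugl_meyer"].mean()),
        "fugl_meyer_sd": float(df["fugl_meyer"].std(ddof=1)),
        "years_since_stroke_mean": float(df["years_since_stroke"].mean()),
        "years_since_stroke_sd": float(df["years_since_stroke"].std(ddof=1)),
        "mep_pre_mean_uv": float(df["mep_pre_uv"].mean()),
        "mep_pre_sd_uv": float(df["mep_pre_uv"].std(ddof=1)),
        "mep_post_mean_uv": float(df["mep_post_uv"].mean()),
        "mep_post_sd_uv": float(df["mep_post_uv"].std(ddof=1)),
    }
    return {"summary": summary, "paired_t": report}
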