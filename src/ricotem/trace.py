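"""ROTEM clot-amplitude traces and standard viscoelastic parameters.

A rotational-thromboelastometry channel records clot firmness (mm) against
time from assay start (the two-sided TEMogram is folded, so amplitudes are
unsigned). From one trace the conventional parameters are extracted:

* CT  (clotting time)        -- first time the amplitude reaches a small
                                threshold, conventionally 2 mm;
* CFT (clot formation time)  -- time for the amplitude to climb from the CT
                                threshold to 20 mm;
* MCF (maximum clot firmness)-- maximum amplitude over the record;
* AUC30                      -- area under the first-derivative (velocity)
                                curve of the amplitude, ending 30 min after
                                test start, times a device scale factor.

For a trace starting at 0 mm the AUC30 equals scale x amplitude(30 min)
by the fundamental theorem of calculus; the implementation preserves this
identity exactly (to float rounding) because it integrates the same
piecewise-constant velocity curve that :func:`velocity_curve` reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import InsufficientSpanError, InvalidParameterError, InvalidTraceError

__all__ = [
    "RotemTrace",
    "ClotParameters",
    "extract_ct",
    "extract_cft",
    "extract_mcf",
    "velocity_curve",
    "auc30",
    "extract_all",
    "DEFAULT_CT_THRESHOLD_MM",
    "DEFAULT_CFT_LOW_MM",
    "DEFAULT_CFT_HIGH_MM",
    "DEFAULT_AUC_SCALE",
]

#: Universal ROTEM conventions; the assay itself does not redefine them.
DEFAULT_CT_THRESHOLD_MM = 2.0
DEFAULT_CFT_LOW_MM = 2.0
DEFAULT_CFT_HIGH_MM = 20.0
#: Device AUC normalization. Only ratios of AUCs are used downstream, so the
#: scale cancels in every Ricotem statistic; it exists to reproduce the
#: magnitudes a ROTEM delta prints.
DEFAULT_AUC_SCALE = 100.0


@dataclass(frozen=True)
class RotemTrace:
    """A sampled clot-amplitude time series for one assay channel.

    Parameters
    ----------
    channel_label:
        Assay condition, e.g. ``"extem"``, ``"rico"``, ``"rico_haemate"``,
        ``"fibtem"`` or ``"intem"``.
    times_s:
        Sample times in seconds from test start; strictly increasing.
        Irregular sampling is allowed.
    amplitudes_mm:
        Clot firmness in mm, same length as ``times_s``, non-negative.
    """

    channel_label: str
    times_s: np.ndarray
    amplitudes_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.amplitudes_mm, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or t.size != a.size:
            raise InvalidTraceError("times and amplitudes must be 1-D and equal length")
        if t.size < 2:
            raise InvalidTraceError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise InvalidTraceError("trace contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise InvalidTraceError("times must be strictly increasing (deduplicate first)")
        if np.any(a < 0):
            raise InvalidTraceError("amplitudes must be non-negative (folded TEMogram)")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "amplitudes_mm", a)

    @classmethod
    def from_samples(
        cls,
        channel_label: str,
        times_s: Sequence[float],
        amplitudes_mm: Sequence[float],
    ) -> "RotemTrace":
        """Build a trace, dropping exact duplicate (time, amplitude) samples.

        Duplicate timestamps with *different* amplitudes are contradictory and
        rejected.
        """
        t = np.asarray(times_s, dtype=float)
        a = np.asarray(amplitudes_mm, dtype=float)
        if t.size != a.size:
            raise InvalidTraceError("times and amplitudes must be equal length")
        order = np.argsort(t, kind="stable")
        t, a = t[order], a[order]
        keep = np.ones(t.size, dtype=bool)
        dup = np.flatnonzero(np.diff(t) == 0)
        for i in dup:
            if a[i] != a[i + 1]:
                raise InvalidTraceError(
                    f"duplicate timestamp t={t[i]} s with conflicting amplitudes"
                )
            keep[i + 1] = False
        return cls(channel_label, t[keep], a[keep])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def amplitude_at(self, t_s: float) -> float:
        """Linearly interpolated amplitude at ``t_s`` (no extrapolation)."""
        if t_s < self.times_s[0] or t_s > self.times_s[-1]:
            raise InsufficientSpanError(
                f"t={t_s} s outside sampled span "
                f"[{self.times_s[0]}, {self.times_s[-1]}] s"
            )
        return float(np.interp(t_s, self.times_s, self.amplitudes_mm))


@dataclass(frozen=True)
class ClotParameters:
    """CT, CFT, MCF and AUC30 extracted from one trace.

    ``ct_s``/``cft_s`` are ``None`` when the respective threshold is never
    reached — routine for weak post-ristocetin clots that stay below 20 mm.
    """

    ct_s: Optional[float]
    cft_s: Optional[float]
    mcf_mm: float
    auc30: float
    channel_label: str = field(default="")


def _first_crossing(trace: RotemTrace, threshold_mm: float) -> Optional[float]:
    """First time the amplitude reaches ``threshold_mm``, linearly interpolated."""
    t, a = trace.times_s, trace.amplitudes_mm
    idx = np.flatnonzero(a >= threshold_mm)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    # linear interpolation on the bracketing segment; a[i-1] < threshold <= a[i]
    frac = (threshold_mm - a[i - 1]) / (a[i] - a[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract_ct(trace: RotemTrace, threshold_mm: float = DEFAULT_CT_THRESHOLD_MM) -> Optional[float]:
    """Clotting time: first time the clot firmness reaches ``threshold_mm``.

    Returns ``None`` if the threshold is never reached.
    """
    if threshold_mm <= 0:
        raise InvalidParameterError("CT threshold must be positive")
    return _first_crossing(trace, threshold_mm)


def extract_cft(
    trace: RotemTrace,
    low_mm: float = DEFAULT_CFT_LOW_MM,
    high_mm: float = DEFAULT_CFT_HIGH_MM,
) -> Optional[float]:
    """Clot formation time: elapsed time between the ``low_mm`` and ``high_mm``
    amplitude crossings; ``None`` if ``high_mm`` is never reached."""
    if low_mm >= high_mm:
        raise InvalidParameterError(f"CFT band requires low < high, got {low_mm} >= {high_mm}")
    t_high = _first_crossing(trace, high_mm)
    if t_high is None:
        return None
    t_low = _first_crossing(trace, low_mm)
    assert t_low is not None  # amplitude is continuous piecewise-linear from >= 0
    return t_high - t_low


def extract_mcf(trace: RotemTrace) -> float:
    """Maximum clot firmness: the maximum amplitude over the record."""
    return float(np.max(trace.amplitudes_mm))


def velocity_curve(trace: RotemTrace) -> Tuple[np.ndarray, np.ndarray]:
    """First-difference clot-formation velocity in mm/min.

    Returns ``(mid_times_s, velocity_mm_per_min)`` with one value per sample
    interval, timestamped at the interval midpoint. No smoothing is applied.
    """
    t, a = trace.times_s, trace.amplitudes_mm
    dt = np.diff(t)
    vel = np.diff(a) / dt * 60.0
    mid = t[:-1] + dt / 2.0
    return mid, vel


def auc30(
    trace: RotemTrace,
    scale: float = DEFAULT_AUC_SCALE,
    end_min: float = 30.0,
) -> float:
    """Area under the velocity curve from test start to ``end_min`` minutes.

    The per-interval first-difference velocities are integrated exactly over
    their intervals (the final interval clipped at ``end_min``), then
    multiplied by the device ``scale`` factor. For a trace starting at 0 mm
    this equals ``scale * amplitude(end_min)``.

    Raises :class:`InsufficientSpanError` if the trace ends before
    ``end_min`` — the value is never extrapolated.
    """
    if scale <= 0:
        raise InvalidParameterError("AUC scale factor must be positive")
    end_s = end_min * 60.0
    t, a = trace.times_s, trace.amplitudes_mm
    if t[-1] < end_s:
        raise InsufficientSpanError(
            f"trace ends at {t[-1]:.0f} s; AUC{end_min:.0f} needs {end_s:.0f} s"
        )
    vel_per_s = np.diff(a) / np.diff(t)  # mm/s, constant on each interval
    width = np.clip(np.minimum(t[1:], end_s) - np.minimum(t[:-1], end_s), 0.0, None)
    return float(scale * np.sum(vel_per_s * width))


def extract_all(
    trace: RotemTrace,
    ct_threshold_mm: float = DEFAULT_CT_THRESHOLD_MM,
    cft_low_mm: float = DEFAULT_CFT_LOW_MM,
    cft_high_mm: float = DEFAULT_CFT_HIGH_MM,
    scale: float = DEFAULT_AUC_SCALE,
) -> ClotParameters:
    """Extract CT, CFT, MCF and AUC30 from one trace in a single call."""
    return ClotParameters(
        ct_s=extract_ct(trace, ct_threshold_mm),
        cft_s=extract_cft(trace, cft_low_mm, cft_high_mm),
        mcf_mm=extract_mcf(trace),
        auc30=auc30(trace, scale),
        channel_label=trace.channel_label,
    )
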