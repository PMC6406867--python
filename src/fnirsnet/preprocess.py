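"""Band-pass filtering and motion-artifact channel rejection.

Hemodynamic signals of interest live roughly between slow drifts (< 0.01 Hz)
and respiratory/cardiac oscillations (> 0.3 Hz), so each channel is band-pass
filtered to 0.010-0.33 Hz with a zero-phase (forward-backward) Butterworth
filter.  Motion artifacts appear as abrupt baseline steps; a channel whose
raw oxy-Hb trace jumps by more than 0.1 mM.mm between consecutive samples is
excluded from analysis.  Screening runs on the *unfiltered* data — filtering
smears a step across many samples — and channels are masked, never deleted,
so the 116-slot indexing stays aligned with the region lookup.

The artifact rule is evaluated on the oxy trace only; the deoxy trace of a
flagged channel inherits the flag.  The "change per unit time" is read as
the per-sample first difference at the native sampling rate; both the
threshold and the time base are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import HbTimeSeries

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "detect_motion_channels",
    "apply_channel_mask",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and artifact-screening parameters.

    Attributes
    ----------
    passband_low, passband_high
        Band edges in Hz (defaults 0.010 and 0.33).
    artifact_step_threshold
        Maximum tolerated single-sample step in the raw oxy trace, mM.mm
        (default 0.1).
    filter_order
        Butterworth design order per band edge (default 4; the effective
        attenuation is doubled by the forward-backward pass).
    """

    passband_low: float = 0.010
    passband_high: float = 0.33
    artifact_step_threshold: float = 0.1
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.passband_low < self.passband_high:
            raise ValueError(
                f"need 0 < passband_low < passband_high, got "
                f"({self.passband_low}, {self.passband_high})"
            )
        if self.artifact_step_threshold <= 0:
            raise ValueError("artifact_step_threshold must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be at least 1")

    def validate_for_rate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if self.passband_high >= nyquist:
            raise ValueError(
                f"passband_high {self.passband_high} Hz is not below the "
                f"Nyquist frequency {nyquist} Hz"
            )


def _design_sos(config: PreprocessConfig, sampling_rate: float) -> np.ndarray:
    config.validate_for_rate(sampling_rate)
    return signal.butter(
        config.filter_order,
        [config.passband_low, config.passband_high],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_array(
    data: np.ndarray, sampling_rate: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase band-pass of a (channels x samples) array."""
    config = config or PreprocessConfig()
    sos = _design_sos(config, sampling_rate)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def bandpass(series: HbTimeSeries, config: PreprocessConfig | None = None) -> HbTimeSeries:
    """Band-pass filter oxy and deoxy traces channel-wise; annotations kept."""
    config = config or PreprocessConfig()
    return series.with_data(
        bandpass_array(series.oxy, series.sampling_rate, config),
        bandpass_array(series.deoxy, series.sampling_rate, config),
    )


def max_abs_step(data: np.ndarray) -> np.ndarray:
    """Largest absolute single-sample first difference per channel."""
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < 2:
        return np.zeros(data.shape[0])
    return np.max(np.abs(np.diff(data, axis=-1)), axis=-1)


def detect_motion_channels(
    series: HbTimeSeries, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Per-channel validity mask from the step-artifact rule.

    A channel is invalid (``False``) iff any absolute single-sample first
    difference of its raw oxy trace exceeds the threshold.  Run this on
    unfiltered data.
    """
    config = config or PreprocessConfig()
    return max_abs_step(series.oxy) <= config.artifact_step_threshold


def apply_channel_mask(series: HbTimeSeries, mask: np.ndarray) -> HbTimeSeries:
    """Conjoin ``mask`` into the series' ``valid_channels``; data retained."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (series.n_channels,):
        raise ValueError(
            f"mask length {mask.shape} does not match channel count {series.n_channels}"
        )
    return series.with_valid_channels(series.valid_channels & mask)


def preprocess(series: HbTimeSeries, config: PreprocessConfig | None = None) -> HbTimeSeries:
    """Screen artifacts on the raw data, then band-pass filter.

    Returns a new series with filtered signals and the motion mask folded
    into ``valid_channels``.
    """
    config = config or PreprocessConfig()
    mask = detect_motion_channels(series, config)
    return apply_channel_mask(bandpass(series, config), mask)
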