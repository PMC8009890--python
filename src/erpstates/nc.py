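"""Classic Nc component features: mean amplitude, peak latency, difference scores.

The Nc ("negative central") is an infant ERP negativity over frontal
channels roughly 300-800 ms after stimulus onset, indexing attention
engagement. Features are computed on region-averaged waveforms inside an
inclusive time window; the window is clipped to the recorded epoch if it
extends past the last sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .erp import FRONTAL_REGIONS, ErpWaveform, Montage, average_reference, region_mean

logger = logging.getLogger(__name__)

DEFAULT_NC_WINDOW = (300.0, 800.0)

_clip_warned: set[tuple[float, float]] = set()


@dataclass
class NcFeatures:
    """Nc mean amplitude (µV) and peak latency (ms) per region x condition."""

    mean_amplitude: dict[tuple[str, str], float]
    peak_latency: dict[tuple[str, str], float]
    window: tuple[float, float] = DEFAULT_NC_WINDOW


def _window_samples(
    wave: np.ndarray, fs: float, t0_offset: float, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    wave = np.asarray(wave, dtype=float).ravel()
    dt = 1000.0 / fs
    times = t0_offset + np.arange(wave.size) * dt
    lo, hi = window
    epoch_end = times[-1]
    if hi > epoch_end + 1e-9:
        key = (hi, epoch_end)
        if key not in _clip_warned:
            _clip_warned.add(key)
            logger.warning(
                "Nc window end %.0f ms exceeds epoch end %.0f ms; clipping", hi, epoch_end
            )
        hi = epoch_end
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("window contains no samples after discretization")
    return wave[mask], times[mask]


def nc_mean_amplitude(
    wave: np.ndarray, fs: float, t0_offset: float,
    window: tuple[float, float] = DEFAULT_NC_WINDOW,
) -> float:
    """Mean amplitude (µV) over all samples with time inside the window.

    Both window bounds are inclusive; values outside the window never enter.
    """
    w, _ = _window_samples(wave, fs, t0_offset, window)
    return float(w.mean())


def nc_peak_latency(
    wave: np.ndarray, fs: float, t0_offset: float,
    window: tuple[float, float] = DEFAULT_NC_WINDOW,
) -> float:
    """Latency (ms) of the most negative in-window sample; ties -> earliest."""
    w, t = _window_samples(wave, fs, t0_offset, window)
    return float(t[int(np.argmin(w))])  # argmin returns the first minimum


def difference_score(feat_a: float, feat_b: float) -> float:
    """Condition difference, e.g. FD minus Noise."""
    return feat_a - feat_b


def extract_nc_features(
    erps: dict[str, ErpWaveform],
    montage: Montage,
    window: tuple[float, float] = DEFAULT_NC_WINDOW,
    regions: tuple[str, ...] = FRONTAL_REGIONS,
) -> NcFeatures:
    """Nc features for one subject across conditions and frontal regions.

    ``erps`` maps condition label to that condition's averaged ERP. Region
    averaging is done on average-referenced data for consistency with the
    topographic analyses.
    """
    amp: dict[tuple[str, str], float] = {}
    lat: dict[tuple[str, str], float] = {}
    for cond, erp in erps.items():
        ref = average_reference(erp)
        for region in regions:
            w = region_mean(ref, montage, region)
            amp[(region, cond)] = nc_mean_amplitude(w, erp.fs, erp.t0_offset, window)
            lat[(region, cond)] = nc_peak_latency(w, erp.fs, erp.t0_offset, window)
    return NcFeatures(mean_amplitude=amp, peak_latency=lat, window=window)


def nc_feature_frame(
    subject_erps: dict[str, dict[str, ErpWaveform]],
    montage: Montage,
    window: tuple[float, float] = DEFAULT_NC_WINDOW,
) -> pd.DataFrame:
    """Tidy table of Nc features: one row per subject x region x condition."""
    rows = []
    for sid, erps in subject_erps.items():
        feats = extract_nc_features(erps, montage, window)
        for (region, cond), a in feats.mean_amplitude.items():
            rows.append(
                {
                    "subject_id": sid,
                    "region": region,
                    "condition": cond,
                    "mean_amplitude_uv": a,
                    "peak_latency_ms": feats.peak_latency[(region, cond)],
                }
            )
    return pd.DataFrame(rows)
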