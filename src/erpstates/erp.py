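"""Containers and basic operations for averaged ERP waveforms.

An :class:`ErpWaveform` holds one subject's trial-averaged ERP for one
stimulus condition as a channel x sample matrix in microvolts, together
with the sampling metadata needed to convert between sample indices and
time relative to stimulus onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

CONDITIONS = ("FD", "FA", "Noise")


@dataclass
class ErpWaveform:
    """One subject x condition averaged ERP.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Averaged potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    t0_offset : float
        Time of the first sample in ms relative to stimulus onset
        (negative for a pre-stimulus baseline).
    channel_ids : tuple of str
        Ordered channel labels.
    condition : str
        Stimulus condition label (typically FD, FA or Noise).
    subject_id : str
    reference : str
        ``"average"`` once re-referenced, otherwise the recording reference.
    """

    data: np.ndarray
    fs: float
    t0_offset: float
    channel_ids: tuple[str, ...] = ()
    condition: str = ""
    subject_id: str = ""
    reference: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ERP data must be a 2-D channel x sample matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ERP data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_ids:
            self.channel_ids = tuple(f"ch{i + 1:02d}" for i in range(self.n_channels))
        if len(self.channel_ids) != self.n_channels:
            raise ValueError("channel_ids length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        """Sample period in ms."""
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_offset + np.arange(self.n_samples) * self.dt

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of samples with time in ``[window[0], window[1]]`` (inclusive)."""
        t = self.times
        idx = np.nonzero((t >= window[0] - 1e-9) & (t <= window[1] + 1e-9))[0]
        return idx


@dataclass
class Montage:
    """Mapping from channel id to scalp-region label.

    Regions of interest must be non-empty and disjoint; channels outside
    any region of interest map to ``"other"``.
    """

    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ch, region in self.regions.items():
            if ch in seen:
                raise ValueError(f"channel {ch} mapped twice")
            seen[ch] = region

    def channels_in(self, region: str) -> list[str]:
        chans = [ch for ch, r in self.regions.items() if r == region]
        return chans

    @property
    def region_labels(self) -> list[str]:
        return sorted({r for r in self.regions.values() if r != "other"})


FRONTAL_REGIONS = ("frontal-left", "frontal-central", "frontal-right")


def default_montage(n_channels: int, channels_per_region: int = 4) -> Montage:
    """Default frontal montage for a generic ``n_channels`` layout.

    The first three blocks of ``channels_per_region`` channels are assigned
    to the left, central and right frontal regions; the rest map to
    ``"other"``. Real layouts should override this via a montage file:
    region membership is configuration, not code.
    """
    if n_channels < 3 * channels_per_region:
        raise ValueError("too few channels for three frontal regions")
    mapping: dict[str, str] = {}
    for i in range(n_channels):
        ch = f"ch{i + 1:02d}"
        block = i // channels_per_region
        mapping[ch] = FRONTAL_REGIONS[block] if block < 3 else "other"
    return Montage(mapping)


def average_reference(erp: ErpWaveform) -> ErpWaveform:
    """Re-reference to the common average: subtract the channel mean per sample.

    Idempotent; rejects single-channel input (an average-referenced single
    channel is identically zero and carries no topographic information).
    """
    if erp.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = erp.data - erp.data.mean(axis=0, keepdims=True)
    return replace(erp, data=data, reference="average")


def region_mean(erp: ErpWaveform, montage: Montage, region: str) -> np.ndarray:
    """Unweighted mean waveform (1-D, microvolts) over a montage region."""
    chans = montage.channels_in(region)
    if not chans:
        raise KeyError(f"region {region!r} not present in montage")
    idx = [i for i, ch in enumerate(erp.channel_ids) if ch in set(chans)]
    if not idx:
        raise ValueError(f"region {region!r} has no channels in this recording")
    return erp.data[idx].mean(axis=0)


def grand_average(erps: list[ErpWaveform]) -> ErpWaveform:
    """Unweighted mean over subjects; all ERPs must share shape and timing."""
    if not erps:
        raise ValueError("no ERPs to average")
    first = erps[0]
    for e in erps[1:]:
        if e.data.shape != first.data.shape or e.fs != first.fs or e.t0_offset != first.t0_offset:
            raise ValueError("ERPs are not aligned (shape, fs or t0 differ)")
    data = np.mean([e.data for e in erps], axis=0)
    return replace(first, data=data, subject_id="grand-average")
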