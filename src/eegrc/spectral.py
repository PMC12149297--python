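"""Relative band power in the five canonical EEG bands.

Power spectra are Welch averages of 2 s Hamming-windowed segments with 50%
overlap (0.5 Hz native resolution, re-gridded to 1 Hz steps for reporting).
Band power is integrated with half-open band edges — delta [1,4), theta
[4,8), alpha [8,13), beta [13,30), gamma [30,45] — so the five bands tile
the 1-45 Hz broadband range exactly and the five relative powers sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import Epoch


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not self.low_hz < self.high_hz:
            raise ValueError("empty band")


#: Canonical bands; edges half-open except gamma, closed at 45 Hz.
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)
BAND_NAMES = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class BandPowerTable:
    """Per-channel relative band power plus broadband absolute power.

    ``table`` has one row per channel, columns ``delta..gamma`` (unitless
    ratios summing to 1 per row) and ``broadband_abs`` (uV^2 over 1-45 Hz).
    """

    subject_id: str
    table: pd.DataFrame

    def regional_input(self, band: str) -> dict[str, float]:
        return self.table[band].to_dict()


def _welch(epoch: Epoch, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(window_s * epoch.fs))
    if nperseg > epoch.n_samples:
        raise ValueError(
            f"window ({window_s:g} s) exceeds epoch duration "
            f"({epoch.duration_s:g} s)"
        )
    return sps.welch(epoch.data, fs=epoch.fs, window="hamming",
                     nperseg=nperseg, noverlap=nperseg // 2, axis=1)


def power_spectrum(epoch: Epoch, window_s: float = 2.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel power on a 1 Hz grid from 1 to 45 Hz.

    Returns ``(freqs, power)`` where ``power[c, i]`` is the integrated
    Welch power (uV^2) of the native 0.5 Hz bins nearest each integer
    frequency; summing across the grid recovers the 1-45 Hz signal
    variance to within window loss.
    """
    f, psd = _welch(epoch, window_s)
    df = f[1] - f[0]
    freqs = np.arange(1.0, 46.0)
    grid = np.round(f).astype(int)
    power = np.zeros((epoch.data.shape[0], freqs.size))
    for i, fc in enumerate(freqs):
        power[:, i] = psd[:, grid == int(fc)].sum(axis=1) * df
    return freqs, power


def relative_band_power(epoch: Epoch, bands=CANONICAL_BANDS,
                        window_s: float = 2.0) -> BandPowerTable:
    """Relative power per channel: band power / broadband (1-45 Hz) power.

    Normalisation is by the union of the five bands, so the relative
    powers tile to exactly 1 per channel and are invariant to channel
    scaling.
    """
    if not bands:
        raise ValueError("no bands given")
    f, psd = _welch(epoch, window_s)
    df = f[1] - f[0]
    band_abs = np.empty((epoch.data.shape[0], len(bands)))
    hi_edge = max(b.high_hz for b in bands)
    for j, b in enumerate(bands):
        closed_hi = b.high_hz == hi_edge  # outermost band closes the range
        sel = (f >= b.low_hz) & ((f <= b.high_hz) if closed_hi
                                 else (f < b.high_hz))
        if not sel.any():
            raise ValueError(f"band {b.name} contains no spectral bins")
        band_abs[:, j] = psd[:, sel].sum(axis=1) * df
    total = band_abs.sum(axis=1)
    if np.any(total <= 0):
        rel = np.full_like(band_abs, np.nan)
        ok = total > 0
        rel[ok] = band_abs[ok] / total[ok, None]
    else:
        rel = band_abs / total[:, None]
    table = pd.DataFrame(rel, index=list(epoch.channels),
                         columns=[b.name for b in bands])
    table["broadband_abs"] = total
    return BandPowerTable(subject_id=epoch.subject_id, table=table)
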