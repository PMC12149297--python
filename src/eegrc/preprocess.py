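"""Filtering, re-referencing, epoching and amplitude envelopes.

Recordings arrive already artifact-cleaned; this module applies the
analysis-side conditioning: a zero-phase 1-45 Hz broadband band-pass,
common-average re-referencing, selection of a 15 s artifact-free epoch,
and (for the long-range temporal correlation branch) a zero-phase FIR
narrowband filter plus Hilbert amplitude envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording


class EpochSelectionError(RuntimeError):
    """No artifact-free window of the requested duration exists."""

    def __init__(self, needed_s: float, max_clean_s: float):
        self.needed_s = needed_s
        self.max_clean_s = max_clean_s
        super().__init__(
            f"no clean window of {needed_s:g} s; longest clean stretch is "
            f"{max_clean_s:g} s"
        )


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification.

    ``broadband`` uses a 4th-order Butterworth applied forward-backward;
    ``narrowband`` uses a window-method FIR (2 Hz transition width), also
    zero-phase.  Both therefore preserve waveform shape, which matters for
    the fractal estimators downstream.
    """

    low_hz: float
    high_hz: float
    kind: str = "broadband"

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.kind not in ("broadband", "narrowband"):
            raise ValueError("kind must be 'broadband' or 'narrowband'")

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )


BROADBAND = FilterSpec(1.0, 45.0, "broadband")
ALPHA_NARROWBAND = FilterSpec(8.0, 13.0, "narrowband")


@dataclass
class Epoch:
    """A fixed-duration artifact-free segment of a recording."""

    data: np.ndarray
    fs: float
    channels: list[str]
    source_offset_s: float = 0.0
    subject_id: str = ""
    group: str = "unknown"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _fir_taps(spec: FilterSpec, fs: float, transition_hz: float = 2.0) -> np.ndarray:
    # Hamming-window FIR: ~53 dB stopband; numtaps from the standard
    # 3.3/normalized-transition-width rule, forced odd (type I).
    numtaps = int(np.ceil(3.3 * fs / transition_hz)) | 1
    return sps.firwin(numtaps, [spec.low_hz, spec.high_hz], pass_zero=False, fs=fs)


def bandpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase band-pass filter every channel.

    Broadband uses an order-4 Butterworth via ``sosfiltfilt``; narrowband an
    FIR via ``filtfilt``.  Forward-backward application squares the
    magnitude response, so one-octave-out attenuation exceeds 40 dB.
    """
    spec.validate_for(rec.fs)
    if spec.kind == "broadband":
        sos = sps.butter(4, [spec.low_hz, spec.high_hz], btype="bandpass",
                         output="sos", fs=rec.fs)
        out = sps.sosfiltfilt(sos, rec.data, axis=1)
    else:
        taps = _fir_taps(spec, rec.fs)
        if rec.data.shape[1] <= 3 * len(taps):
            raise ValueError(
                f"recording too short ({rec.data.shape[1]} samples) for the "
                f"{len(taps)}-tap narrowband filter"
            )
        out = sps.filtfilt(taps, 1.0, rec.data, axis=1)
    return rec.copy_with(data=out)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.data.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def select_epoch(rec: Recording, duration_s: float = 15.0,
                 amp_limit_uv: float = 100.0) -> Epoch:
    """Earliest contiguous window with no sample beyond ``amp_limit_uv``.

    Raises :class:`EpochSelectionError` (reporting the longest clean
    stretch found) when no qualifying window exists.
    """
    win = int(round(duration_s * rec.fs))
    if win > rec.n_samples:
        raise ValueError(
            f"recording ({rec.duration_s:g} s) shorter than epoch "
            f"({duration_s:g} s)"
        )
    bad = (np.abs(rec.data) > amp_limit_uv).any(axis=0)
    csum = np.concatenate([[0], np.cumsum(bad)])
    n_bad_in_win = csum[win:] - csum[:-win]
    clean_starts = np.flatnonzero(n_bad_in_win == 0)
    if clean_starts.size == 0:
        # longest run of clean samples, for the error message
        good = ~bad
        if not good.any():
            max_clean = 0.0
        else:
            edges = np.flatnonzero(np.diff(np.concatenate([[0], good, [0]])))
            max_clean = (edges[1::2] - edges[::2]).max() / rec.fs
        raise EpochSelectionError(duration_s, max_clean)
    start = int(clean_starts[0])
    return Epoch(
        data=rec.data[:, start:start + win].copy(), fs=rec.fs,
        channels=list(rec.channels), source_offset_s=start / rec.fs,
        subject_id=rec.subject_id, group=rec.group,
    )


def hilbert_envelope(rec: Recording, trim_s: float = 1.0) -> Recording:
    """Magnitude of the analytic signal, trimmed at both ends.

    The input must already be narrowband filtered.  ``trim_s`` seconds are
    removed from each end to suppress Hilbert/filter edge transients; the
    default 1 s exceeds the narrowband FIR group delay at 500 Hz.
    """
    n = rec.n_samples
    trim = int(round(trim_s * rec.fs))
    if 2 * trim >= n:
        raise ValueError("trim_s removes the whole recording")
    from scipy.fft import next_fast_len

    env = np.abs(sps.hilbert(rec.data, N=next_fast_len(n), axis=1))[:, :n]
    sl = slice(trim, n - trim) if trim else slice(None)
    return rec.copy_with(data=env[:, sl])
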