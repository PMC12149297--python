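"""Detrended fluctuation analysis of alpha-band amplitude envelopes.

DFA quantifies long-range temporal correlations (LRTCs): the envelope is
mean-centred and cumulatively summed into a profile, the profile is cut
into windows of size n (50% overlap by default), each window is linearly
detrended and the root-mean-square residual averaged into the fluctuation
function F(n).  The scaling exponent alpha is the log-log slope of F(n)
over the fit interval: alpha ~ 0.5 for an uncorrelated (white-noise-like)
envelope, alpha -> 1 for strongly persistent (pink-noise-like) dynamics.
For a fractional Gaussian noise envelope with Hurst exponent H, alpha = H.

Defaults follow the pipeline convention: 10 log-spaced window sizes
spanning a calculation interval of 0.8-30 s, 50% overlap, fit restricted
to 2-25 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import Recording
from .preprocess import ALPHA_NARROWBAND, bandpass, hilbert_envelope

#: NBT-style defaults: calculation interval, fit interval (s), overlap, sizes.
CALC_INTERVAL_S = (0.8, 30.0)
FIT_INTERVAL_S = (2.0, 25.0)
OVERLAP = 0.5
N_WINDOW_SIZES = 10


def default_window_sizes(calc_interval_s=CALC_INTERVAL_S,
                         n_sizes: int = N_WINDOW_SIZES) -> np.ndarray:
    """Log-spaced (base 10) window sizes spanning the calculation interval."""
    lo, hi = calc_interval_s
    return np.logspace(np.log10(lo), np.log10(hi), n_sizes)


@dataclass
class DfaResult:
    """Per-channel DFA exponents with the underlying fluctuation functions."""

    channels: list[str]
    exponents: np.ndarray            # one alpha per channel
    window_sizes_s: np.ndarray
    fluctuations: np.ndarray         # (n_channels, n_sizes), uV
    fit_interval_s: tuple
    calc_interval_s: tuple
    overlap: float
    residuals: np.ndarray            # log-log fit RMS residual per channel
    subject_id: str = ""
    group: str = "unknown"

    def exponent(self, channel: str) -> float:
        return float(self.exponents[self.channels.index(channel)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channels, map(float, self.exponents)))


def dfa_fluctuation(envelope: np.ndarray, fs: float,
                    window_sizes_s=None, overlap: float = OVERLAP
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fluctuation function F(n) of a single-channel envelope.

    Returns the retained window sizes (s) and F(n).  Window sizes shorter
    than 4 samples or longer than the record are skipped with a warning.
    """
    envelope = np.asarray(envelope, dtype=float).ravel()
    if window_sizes_s is None:
        window_sizes_s = default_window_sizes()
    if not 0 <= overlap <= 0.9:
        raise ValueError("overlap must be in [0, 0.9]")
    profile = np.cumsum(envelope - envelope.mean())
    n_total = profile.size
    kept_s, fvals = [], []
    for size_s in np.asarray(window_sizes_s, dtype=float):
        n = int(round(size_s * fs))
        if n < 4 or n > n_total:
            warnings.warn(f"skipping DFA window of {size_s:g} s "
                          f"({n} samples)", stacklevel=2)
            continue
        step = max(1, int(round(n * (1.0 - overlap))))
        segs = sliding_window_view(profile, n)[::step]
        t = np.arange(n, dtype=float)
        t -= t.mean()
        # least-squares line removal: slope via centred time axis
        seg_mean = segs.mean(axis=1, keepdims=True)
        slope = (segs @ t) / (t @ t)
        resid = segs - seg_mean - slope[:, None] * t
        rms = np.sqrt((resid ** 2).mean(axis=1))
        kept_s.append(size_s)
        fvals.append(rms.mean())
    if not kept_s:
        raise ValueError("no usable DFA window sizes")
    return np.asarray(kept_s), np.asarray(fvals)


def dfa_exponent(window_sizes_s: np.ndarray, fluctuations: np.ndarray,
                 fit_interval_s=FIT_INTERVAL_S) -> tuple[float, float]:
    """Log-log slope of F(n) restricted to the fit interval.

    Returns ``(alpha, residual)`` where residual is the RMS deviation of
    log10 F from the fitted line (a goodness-of-fit diagnostic; large
    values flag non-power-law fluctuation functions).
    """
    sizes = np.asarray(window_sizes_s, dtype=float)
    f = np.asarray(fluctuations, dtype=float)
    lo, hi = fit_interval_s
    sel = (sizes >= lo) & (sizes <= hi) & (f > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 window sizes inside the fit interval {fit_interval_s}"
        )
    lx, ly = np.log10(sizes[sel]), np.log10(f[sel])
    coeffs = np.polyfit(lx, ly, 1)
    resid = float(np.sqrt(np.mean((ly - np.polyval(coeffs, lx)) ** 2)))
    return float(coeffs[0]), resid


def dfa_channel(envelope: np.ndarray, fs: float, window_sizes_s=None,
                overlap: float = OVERLAP,
                fit_interval_s=FIT_INTERVAL_S) -> tuple[float, float]:
    """Convenience: fluctuation function plus exponent for one channel."""
    sizes, f = dfa_fluctuation(envelope, fs, window_sizes_s, overlap)
    return dfa_exponent(sizes, f, fit_interval_s)


def alpha_lrtc_pipeline(rec: Recording, duration_s: float = 300.0,
                        calc_interval_s=CALC_INTERVAL_S,
                        fit_interval_s=FIT_INTERVAL_S,
                        overlap: float = OVERLAP,
                        n_sizes: int = N_WINDOW_SIZES,
                        envelope_trim_s: float = 1.0) -> DfaResult:
    """Alpha-band LRTC exponents for every channel of a recording.

    Takes the first ``duration_s`` seconds, applies the 8-13 Hz zero-phase
    FIR filter and Hilbert envelope, then DFA with ``n_sizes`` log-spaced
    window sizes over the calculation interval at the given overlap, fitted
    over the fit interval.
    """
    if rec.duration_s < duration_s:
        raise ValueError(
            f"recording ({rec.duration_s:g} s) shorter than the DFA "
            f"duration ({duration_s:g} s)"
        )
    n = int(round(duration_s * rec.fs))
    segment = rec.copy_with(data=rec.data[:, :n].copy())
    narrow = bandpass(segment, ALPHA_NARROWBAND)
    env = hilbert_envelope(narrow, trim_s=envelope_trim_s)
    sizes_req = default_window_sizes(calc_interval_s, n_sizes)
    exps, resids, fmat, kept = [], [], [], None
    for ci in range(env.data.shape[0]):
        sizes, f = dfa_fluctuation(env.data[ci], env.fs, sizes_req, overlap)
        a, r = dfa_exponent(sizes, f, fit_interval_s)
        exps.append(a)
        resids.append(r)
        fmat.append(f)
        kept = sizes
    return DfaResult(
        channels=list(rec.channels), exponents=np.asarray(exps),
        window_sizes_s=kept, fluctuations=np.asarray(fmat),
        fit_interval_s=tuple(fit_interval_s),
        calc_interval_s=tuple(calc_interval_s), overlap=overlap,
        residuals=np.asarray(resids), subject_id=rec.subject_id,
        group=rec.group,
    )
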