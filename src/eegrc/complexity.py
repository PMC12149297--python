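"""Fractal-dimension estimators for EEG time series.

Two estimators of the graph dimension of a single-channel signal, both
bounded in [1, 2] (1 = smooth curve, 2 = plane-filling, e.g. white noise;
for fractional Brownian motion with Hurst exponent H the dimension is
2 - H):

* box-counting: the signal is normalised to the unit square and the number
  of grid boxes N(eps) intersected by its linear interpolant is counted
  over a dyadic ladder of box sizes; the dimension is the slope of
  log N(eps) versus log(1/eps).
* Higuchi: mean curve lengths L(k) at step sizes k = 1..kmax with the
  standard (N-1)/(n_mk * k^2) normalisation; the dimension is the slope of
  log L(k) versus log(1/k).

Higuchi values over an epoch are averaged across non-overlapping 1 s
windows; box-counting uses the whole epoch.  ``kmax_scan`` reproduces the
cohort-level kmax selection curve (group mean +/- SEM of the 19-channel
average versus kmax) and picks the tested kmax whose across-subject mean
is closest to the median of that curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import Epoch

#: kmax defaults matching the two sampling rates handled by the pipeline.
DEFAULT_KMAX = {500: 126, 128: 32}


@dataclass
class ComplexityTable:
    """Per-channel fractal-dimension values for one recording."""

    subject_id: str
    method: str  # 'box_counting' | 'higuchi'
    values: pd.Series  # index = channel labels
    params: dict = field(default_factory=dict)
    degenerate: list = field(default_factory=list)  # channels flagged constant


@dataclass
class KmaxScan:
    """Cohort Higuchi-dimension curves across tested kmax values."""

    kmax_values: list
    subject_means: pd.DataFrame      # index kmax, one column per subject
    group_means: pd.DataFrame        # index kmax, one column per group
    group_sems: pd.DataFrame
    selected_kmax: int
    selection_rule: str = (
        "tested kmax whose across-subject mean HFD is closest to the "
        "median of the across-subject mean HFD curve"
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.group_means.columns:
            for k in self.kmax_values:
                rows.append({"kmax": k, "group": g,
                             "mean": self.group_means.loc[k, g],
                             "sem": self.group_sems.loc[k, g]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# box counting

def box_counting_fd(x: np.ndarray, return_counts: bool = False):
    """Box-counting dimension of a single-channel signal graph.

    The curve is normalised to the unit square (time to [0, 1], amplitude
    min-max to [0, 1]); box sizes are eps = 2^-j, j = 1..floor(log2 N) - 4;
    boxes crossed by the linear interpolant are counted per size and the
    log-log slope is clamped to [1, 2].  The ladder stops four octaves
    above the sample spacing: below that the interpolant is resolution
    limited (locally straight), which drags the slope toward 1.  A constant
    signal returns exactly 1.0 (degenerate input).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 256:
        raise ValueError("box counting needs >= 256 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return (1.0, None) if return_counts else 1.0
    y = (x - lo) / (hi - lo)
    t = np.linspace(0.0, 1.0, n)
    j_max = int(np.floor(np.log2(n))) - 4
    ladder = np.arange(1, j_max + 1)
    counts = np.empty(ladder.size)
    for idx, j in enumerate(ladder):
        nb = 2 ** j
        eps = 1.0 / nb
        col = np.minimum((t * nb).astype(int), nb - 1)
        first = np.searchsorted(col, np.arange(nb), side="left")
        mx = np.maximum.reduceat(y, first)
        mn = np.minimum.reduceat(y, first)
        if nb > 1:  # interpolant values at the column boundaries
            vb = np.interp(np.arange(1, nb) * eps, t, y)
            mx[:-1] = np.maximum(mx[:-1], vb)
            mx[1:] = np.maximum(mx[1:], vb)
            mn[:-1] = np.minimum(mn[:-1], vb)
            mn[1:] = np.minimum(mn[1:], vb)
        top = np.floor(np.clip(mx, 0.0, 1.0 - 1e-12) / eps)
        bot = np.floor(np.clip(mn, 0.0, 1.0 - 1e-12) / eps)
        counts[idx] = (top - bot + 1.0).sum()
    # slope of log N(eps) vs log(1/eps); 1/eps = 2^j
    slope = np.polyfit(ladder * np.log(2.0), np.log(counts), 1)[0]
    fd = float(np.clip(slope, 1.0, 2.0))
    if return_counts:
        return fd, (2.0 ** -ladder, counts)
    return fd


def box_counting_table(epoch: Epoch) -> ComplexityTable:
    """Box-counting dimension per channel over the whole epoch."""
    vals, degen = {}, []
    for i, ch in enumerate(epoch.channels):
        sig = epoch.data[i]
        if np.ptp(sig) == 0:
            degen.append(ch)
        vals[ch] = box_counting_fd(sig)
    return ComplexityTable(
        subject_id=epoch.subject_id, method="box_counting",
        values=pd.Series(vals, name="fd"),
        params={"ladder": "2^-j, j=1..floor(log2 N)-4"},
        degenerate=degen,
    )


# ---------------------------------------------------------------------------
# Higuchi

def higuchi_k_grid(kmax: int) -> np.ndarray:
    """Step sizes: all integers up to 64, log-spaced augmentation above."""
    if kmax <= 64:
        return np.arange(1, kmax + 1)
    dense = np.arange(1, 17)
    sparse = np.unique(np.round(np.logspace(
        np.log10(17), np.log10(kmax), 25)).astype(int))
    return np.unique(np.concatenate([dense, sparse]))


def _curve_lengths(x: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Higuchi mean curve length L(k) for each step size in ``ks``."""
    n = x.size
    out = np.empty(ks.size)
    for j, k in enumerate(ks):
        d = np.abs(x[k:] - x[:-k])
        sums = np.bincount(np.arange(d.size) % k, weights=d, minlength=k)
        n_mk = (n - np.arange(1, k + 1)) // k
        valid = n_mk > 0
        lm = sums[valid] * (n - 1) / (n_mk[valid] * k * k)
        out[j] = lm.mean()
    return out


def higuchi_fd(x: np.ndarray, kmax: int, ks: np.ndarray | None = None) -> float:
    """Higuchi fractal dimension with maximum step size ``kmax``.

    Requires kmax >= 2 and kmax <= len(x) // 2 so every offset contributes
    at least one curve increment.
    """
    x = np.asarray(x, dtype=float).ravel()
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax > x.size // 2:
        raise ValueError(
            f"kmax={kmax} too large for signal of length {x.size} "
            f"(max {x.size // 2})"
        )
    if ks is None:
        ks = higuchi_k_grid(kmax)
    lengths = _curve_lengths(x, ks)
    if np.any(lengths <= 0):  # constant signal: zero curve length
        return 1.0
    # log L(k) vs log(1/k): slope is the dimension
    return float(np.polyfit(-np.log(ks), np.log(lengths), 1)[0])


def windowed_hfd(epoch: Epoch, kmax: int | None = None,
                 window_s: float = 1.0) -> ComplexityTable:
    """Mean Higuchi dimension over non-overlapping windows, per channel.

    The trailing partial window is dropped.  ``kmax`` defaults to 126 at
    500 Hz and 32 at 128 Hz.
    """
    if kmax is None:
        kmax = DEFAULT_KMAX.get(int(round(epoch.fs)), 126)
    wlen = int(round(window_s * epoch.fs))
    if wlen < 2 * kmax:
        raise ValueError(
            f"window of {wlen} samples too short for kmax={kmax} "
            f"(needs >= {2 * kmax})"
        )
    n_win = epoch.n_samples // wlen
    if n_win == 0:
        raise ValueError("epoch shorter than one window")
    ks = higuchi_k_grid(kmax)
    vals, degen = {}, []
    for i, ch in enumerate(epoch.channels):
        fds = [higuchi_fd(epoch.data[i, w * wlen:(w + 1) * wlen], kmax, ks)
               for w in range(n_win)]
        vals[ch] = float(np.mean(fds))
        if np.ptp(epoch.data[i]) == 0:
            degen.append(ch)
    return ComplexityTable(
        subject_id=epoch.subject_id, method="higuchi",
        values=pd.Series(vals, name="fd"),
        params={"kmax": kmax, "window_s": window_s, "n_windows": n_win},
        degenerate=degen,
    )


def kmax_scan(epochs: Sequence[Epoch], kmax_values: Sequence[int],
              window_s: float = 1.0) -> KmaxScan:
    """19-channel-average Higuchi dimension per subject across kmax values.

    Curve lengths are computed once per window on the union step-size grid
    of the largest kmax; each tested kmax is then fitted on the sub-grid of
    steps <= kmax.  Returns group mean +/- SEM curves and the selected
    kmax (closest-to-median-of-curve rule; ties break to the smaller kmax).
    """
    kmax_values = sorted(int(k) for k in kmax_values)
    if not kmax_values:
        raise ValueError("empty kmax list")
    if len(epochs) < 2:
        raise ValueError("kmax scan needs >= 2 subjects")
    if any(k < 2 for k in kmax_values):
        raise ValueError("kmax values must be >= 2")
    ks_all = higuchi_k_grid(max(kmax_values))
    # least-squares slope of log L vs -log k as a linear map of log L,
    # one weight row per tested kmax (restricted to steps <= kmax)
    weights = np.zeros((len(kmax_values), ks_all.size))
    for j, kmax in enumerate(kmax_values):
        sel = ks_all <= kmax
        design = np.column_stack([-np.log(ks_all[sel]),
                                  np.ones(int(sel.sum()))])
        weights[j, sel] = np.linalg.pinv(design)[0]
    per_subject: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for ep in epochs:
        wlen = int(round(window_s * ep.fs))
        if wlen < 2 * max(kmax_values):
            raise ValueError("window too short for the largest kmax")
        n_win = ep.n_samples // wlen
        fd_per_kmax = np.zeros(len(kmax_values))
        cnt = 0
        for ci in range(ep.data.shape[0]):
            for w in range(n_win):
                seg = ep.data[ci, w * wlen:(w + 1) * wlen]
                lengths = _curve_lengths(seg, ks_all)
                fd_per_kmax += weights @ np.log(lengths)
                cnt += 1
        fd_per_kmax /= cnt
        sid = ep.subject_id or f"subject{len(per_subject)}"
        per_subject[sid] = fd_per_kmax
        groups[sid] = ep.group
    subj_df = pd.DataFrame(per_subject, index=kmax_values)
    glabels = pd.Series(groups)
    gmeans = subj_df.T.groupby(glabels).mean().T
    gsems = subj_df.T.groupby(glabels).sem().T
    curve = subj_df.mean(axis=1)  # across-subject mean per kmax
    med = np.median(curve.to_numpy())
    selected = int(curve.index[np.argmin(np.abs(curve.to_numpy() - med))])
    return KmaxScan(kmax_values=kmax_values, subject_means=subj_df,
                    group_means=gmeans, group_sems=gsems,
                    selected_kmax=selected)
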