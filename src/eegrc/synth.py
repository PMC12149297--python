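"""Seeded synthetic EEG signals and diagnostic-group cohorts.

Single-channel generators cover the calibration primitives the estimators
are validated against: Gaussian white noise, power-law (1/f^beta) noise by
spectral synthesis, fractional Gaussian noise / Brownian motion by exact
circulant embedding (Davies-Harte), pure tones, and amplitude-modulated
alpha carriers whose envelope carries a prescribed Hurst exponent.

``gen_cohort`` builds 19-channel recordings for three diagnostic groups
(control, AD-like, FTD-like).  Each channel is a mixture of

* band-limited noise per canonical band, scaled to the group's band
  amplitude profile (patient-like groups: delta/theta up, alpha down);
* a broadband 1/f^beta "complexity backbone" whose spectral slope beta is
  shifted along the rostrocaudal axis with a group-dependent sign (smoother
  signal = lower fractal dimension; AD-like caudal smoothing produces
  rostral FD dominance, FTD-like the opposite);
* an alpha carrier amplitude-modulated by fractional Gaussian noise with a
  region- and group-dependent Hurst exponent (patient-like groups: weaker
  long-range temporal correlations, more so caudally);
* a small white sensor-noise floor.

Subject-level jitter uses per-subject seed streams spawned from the master
seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ALL19, CAUDAL, ROSTRAL, Recording

BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
              "beta": (13.0, 30.0), "gamma": (30.0, 45.0)}


@dataclass(frozen=True)
class SignalSpec:
    """Specification of one synthetic single-channel signal."""

    kind: str                  # white | pink | power_law | fgn | fbm | tone
    fs: float = 500.0
    duration_s: float = 15.0
    seed: int = 0
    hurst: float = 0.5         # fgn / fbm
    beta: float = 1.0          # power_law (pink = 1)
    freq_hz: float = 10.0      # tone
    amplitude: float = 1.0     # tone

    def __post_init__(self):
        if self.kind not in ("white", "pink", "power_law", "fgn", "fbm",
                             "tone", "mixture"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.kind in ("fgn", "fbm") and not 0 < self.hurst < 1:
            raise ValueError("Hurst exponent must lie in (0, 1)")
        if self.kind == "power_law" and self.beta < 0:
            raise ValueError("spectral exponent beta must be >= 0")
        if self.kind == "tone" and self.freq_hz >= self.fs / 2:
            raise ValueError("tone frequency at or above Nyquist")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via Davies-Harte circulant embedding."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    c = np.concatenate([gamma, gamma[-2:0:-1]])     # length 2n
    lam = np.fft.fft(c).real
    if lam.min() < -1e-6 * lam.max():
        raise ValueError(f"circulant embedding not nonnegative for H={hurst}")
    lam = np.clip(lam, 0.0, None)
    m = c.size
    half = m // 2
    v = np.empty(m, dtype=complex)
    v[0] = np.sqrt(lam[0]) * rng.standard_normal()
    v[half] = np.sqrt(lam[half]) * rng.standard_normal()
    re = rng.standard_normal(half - 1)
    im = rng.standard_normal(half - 1)
    v[1:half] = np.sqrt(lam[1:half] / 2) * (re + 1j * im)
    v[half + 1:] = np.conj(v[1:half][::-1])
    x = np.fft.fft(v) / np.sqrt(m)
    return x.real[:n]


def _power_law(n: int, beta: float, fs: float, rng: np.random.Generator,
               notch_hz: tuple | None = None,
               band_hz: tuple | None = None) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^-beta.

    ``band_hz`` confines the spectrum to an interval and ``notch_hz``
    zeroes one inside it.  The cohort generator uses both for its
    arrhythmic backbone: limiting it to the 1-45 Hz analysis band makes
    the unit-RMS normalisation independent of record duration (otherwise a
    steep slope puts nearly all variance below the high-pass edge), and
    the alpha-band notch keeps it out of the planted envelope dynamics.
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros(f.size)
    amp[1:] = f[1:] ** (-beta / 2.0)
    if band_hz is not None:
        amp[(f < band_hz[0]) | (f > band_hz[1])] = 0.0
    if notch_hz is not None:
        amp[(f >= notch_hz[0]) & (f <= notch_hz[1])] = 0.0
    coef = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    coef *= amp / np.sqrt(2.0)
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real * np.sqrt(2.0)
    x = np.fft.irfft(coef, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise spectrally confined to [lo, hi] Hz."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    coef = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    coef[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(coef, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_signal(spec: SignalSpec) -> np.ndarray:
    """Generate the signal described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if spec.kind == "white":
        return rng.standard_normal(n)
    if spec.kind == "pink":
        return _power_law(n, 1.0, spec.fs, rng)
    if spec.kind == "power_law":
        return _power_law(n, spec.beta, spec.fs, rng)
    if spec.kind == "fgn":
        return _fgn(n, spec.hurst, rng)
    if spec.kind == "fbm":
        return np.cumsum(_fgn(n, spec.hurst, rng))
    if spec.kind == "tone":
        t = np.arange(n) / spec.fs
        return spec.amplitude * np.sin(2 * np.pi * spec.freq_hz * t)
    raise ValueError(f"cannot generate kind {spec.kind!r}")


def lrtc_envelope(n: int, hurst: float, rng: np.random.Generator,
                  depth: float = 0.4) -> np.ndarray:
    """Strictly positive modulator whose DFA exponent approximates ``hurst``.

    A standardised fGn is shifted to mean 1 and clipped well away from
    zero; for moderate depth the clipping is rare enough to leave the
    scaling exponent essentially unchanged.
    """
    z = _fgn(n, hurst, rng)
    z /= z.std()
    return np.clip(1.0 + depth * z, 0.05, None)


def gen_alpha_lrtc_channel(hurst: float, fs: float = 500.0,
                           duration_s: float = 300.0, seed: int = 0,
                           carrier_hz: float = 10.0,
                           depth: float = 0.4) -> np.ndarray:
    """Alpha carrier amplitude-modulated so its envelope has DFA alpha ~ H."""
    if not 0 < hurst < 1:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    env = lrtc_envelope(n, hurst, rng, depth)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    return env * np.sin(2 * np.pi * carrier_hz * t + phase)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one diagnostic group.

    ``band_amp_uv``: RMS amplitude (uV) of each band-limited component.
    ``backbone_beta``: spectral slope of the broadband 1/f^beta backbone
    (higher = smoother signal = lower fractal dimension).
    ``rc_beta_gradient``: slope increment added along the rostrocaudal axis
    (axis = -1 rostral, 0 midline, +1 caudal); positive values smooth the
    caudal channels, producing rostral FD dominance.
    ``rc_amp_gradient``: relative change of the backbone amplitude along the
    same axis (the regional complexity loss is carried jointly by a smoother
    and a stronger arrhythmic component, which is what moves the fractal
    estimators decisively).
    ``env_hurst_rostral`` / ``env_hurst_caudal``: Hurst exponent of the
    alpha-envelope modulator per region (midline uses their mean).
    """

    band_amp_uv: dict
    backbone_beta: float
    rc_beta_gradient: float
    rc_amp_gradient: float
    env_hurst_rostral: float
    env_hurst_caudal: float
    backbone_amp_uv: float = 4.8
    sensor_noise_uv: float = 0.3


#: Default group profiles.  Directions mirror the dementia-EEG pattern the
#: pipeline is designed to detect: patient-like groups raise delta/theta and
#: suppress alpha, smooth the broadband signal (lower FD), and weaken
#: alpha-envelope LRTCs more caudally than rostrally; the AD-like and
#: FTD-like rostrocaudal complexity gradients have opposite sign.
#: Magnitudes are set so patient-vs-control contrasts land near Cohen's
#: d ~ 1 at n = 20 per group.
DEFAULT_PROFILES = {
    "control": GroupProfile(
        band_amp_uv={"delta": 2.4, "theta": 2.1, "alpha": 4.8,
                     "beta": 1.5, "gamma": 0.75},
        backbone_beta=0.9, rc_beta_gradient=0.0, rc_amp_gradient=0.0,
        env_hurst_rostral=0.78, env_hurst_caudal=0.78,
    ),
    "AD": GroupProfile(
        band_amp_uv={"delta": 3.1, "theta": 2.8, "alpha": 3.3,
                     "beta": 1.5, "gamma": 0.75},
        backbone_beta=1.3, rc_beta_gradient=0.4, rc_amp_gradient=0.2,
        env_hurst_rostral=0.71, env_hurst_caudal=0.66,
    ),
    "FTD": GroupProfile(
        band_amp_uv={"delta": 3.3, "theta": 2.65, "alpha": 3.5,
                     "beta": 1.5, "gamma": 0.75},
        backbone_beta=1.25, rc_beta_gradient=-0.4, rc_amp_gradient=-0.2,
        env_hurst_rostral=0.71, env_hurst_caudal=0.66,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic multi-subject cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "control": 20, "AD": 20, "FTD": 20})
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    fs: float = 500.0
    duration_s: float = 300.0
    master_seed: int = 0
    amp_jitter: float = 0.30       # lognormal sigma on component amplitudes
    beta_jitter: float = 0.10      # normal sd on backbone beta
    hurst_jitter: float = 0.06     # normal sd on envelope Hurst

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} needs n >= 1 (got {n})")
            if g not in self.profiles:
                raise ValueError(f"no profile for group {g!r}")
        for g, p in self.profiles.items():
            for h in (p.env_hurst_rostral, p.env_hurst_caudal):
                if not 0 < h < 1:
                    raise ValueError("Hurst exponents must lie in (0, 1)")
            if any(a < 0 for a in p.band_amp_uv.values()):
                raise ValueError("band amplitudes must be >= 0")


def _channel_axis(channel: str) -> float:
    if channel in ROSTRAL:
        return -1.0
    if channel in CAUDAL:
        return 1.0
    return 0.0


def _clip_hurst(h: float) -> float:
    return float(np.clip(h, 0.05, 0.95))


def gen_subject(spec: CohortSpec, group: str, subject_id: str,
                seed_seq: np.random.SeedSequence) -> Recording:
    """Generate one 19-channel recording from a group profile."""
    prof = spec.profiles[group]
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng(seed_seq)
    # subject-level jitter, shared across channels
    amp_fac = {b: np.exp(rng.normal(0.0, spec.amp_jitter))
               for b in prof.band_amp_uv}
    backbone_fac = np.exp(rng.normal(0.0, spec.amp_jitter))
    beta_subj = prof.backbone_beta + rng.normal(0.0, spec.beta_jitter)
    h_r = _clip_hurst(prof.env_hurst_rostral
                      + rng.normal(0.0, spec.hurst_jitter))
    h_c = _clip_hurst(prof.env_hurst_caudal
                      + rng.normal(0.0, spec.hurst_jitter))
    alpha_hz = rng.uniform(9.0, 11.0)
    t = np.arange(n) / spec.fs
    data = np.empty((len(ALL19), n))
    for ci, ch in enumerate(ALL19):
        axis = _channel_axis(ch)
        x = np.zeros(n)
        for band, (lo, hi) in BAND_EDGES.items():
            amp = prof.band_amp_uv.get(band, 0.0) * amp_fac[band]
            if amp == 0:
                continue
            if band == "alpha":
                h = {-1.0: h_r, 1.0: h_c}.get(axis, 0.5 * (h_r + h_c))
                env = lrtc_envelope(n, h, rng)
                carrier = np.sin(2 * np.pi * alpha_hz * t
                                 + rng.uniform(0, 2 * np.pi))
                comp = env * carrier
                comp /= comp.std()
            else:
                comp = _band_noise(n, spec.fs, lo, hi, rng)
            x += amp * comp
        beta_ch = max(0.0, beta_subj + prof.rc_beta_gradient * axis)
        amp_ch = max(0.0, 1.0 + prof.rc_amp_gradient * axis)
        x += (prof.backbone_amp_uv * backbone_fac * amp_ch
              * _power_law(n, beta_ch, spec.fs, rng,
                           notch_hz=BAND_EDGES["alpha"],
                           band_hz=(1.0, 45.0)))
        x += prof.sensor_noise_uv * rng.standard_normal(n)
        data[ci] = x
    return Recording(data=data, fs=spec.fs, channels=list(ALL19),
                     subject_id=subject_id, group=group)


def gen_cohort(spec: CohortSpec | None = None) -> list[Recording]:
    """Generate the full cohort (bit-reproducible from the master seed)."""
    spec = spec or CohortSpec()
    total = sum(spec.group_sizes.values())
    children = np.random.SeedSequence(spec.master_seed).spawn(total)
    recs = []
    idx = 0
    for group in spec.group_sizes:  # insertion order: deterministic
        for j in range(spec.group_sizes[group]):
            sid = f"sub-{group.lower()}{j + 1:03d}"
            recs.append(gen_subject(spec, group, sid, children[idx]))
            idx += 1
    return recs
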