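"""Reading and writing multichannel EEG and the 19-channel 10-20 montage.

The canonical on-disk fixture format is ``matrix_tsv``: a tab-separated
matrix with one column per channel (header row = channel labels, values in
microvolts) plus a JSON sidecar (same stem, ``.json``) carrying the sampling
rate, subject id and diagnostic group.  EDF (16-bit) and EEGLAB ``.set``
files are supported for interoperability with clinical tooling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

GROUPS = ("control", "AD", "FTD", "unknown")

#: The 19 scalp electrodes of the international 10-20 system, front to back.
ALL19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

ROSTRAL = frozenset({"Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"})
CAUDAL = frozenset({"T5", "P3", "Pz", "P4", "T6", "O1", "O2"})

# Modern (10-10) names for the temporal chain, unified to the classic labels.
_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}
# Reference / auxiliary channels silently dropped when present.
_IGNORABLE = {"a1", "a2", "m1", "m2", "ecg", "ekg", "eog", "status"}

_CANONICAL = {c.lower(): c for c in ALL19}
_CANONICAL.update(_ALIASES)


class FormatError(ValueError):
    """File could not be parsed under the requested format."""


class MontageError(ValueError):
    """Required 10-20 channels are absent."""


@dataclass(frozen=True)
class Montage:
    """The fixed 19-channel montage with rostral/caudal channel groups."""

    all19: tuple[str, ...] = ALL19
    rostral: frozenset[str] = ROSTRAL
    caudal: frozenset[str] = CAUDAL

    @property
    def midline(self) -> frozenset[str]:
        """Channels in neither region (central/temporal chain)."""
        return frozenset(self.all19) - self.rostral - self.caudal


def standard_montage() -> Montage:
    """Return the standard 19-channel 10-20 montage.

    Rostral = 7 frontal channels, caudal = 7 posterior channels; the five
    central/temporal channels (T3, C3, Cz, C4, T4) belong to neither group.
    """
    return Montage()


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Channel labels, one per row of ``data``.
    subject_id
        Identifier used in output tables.
    group
        Diagnostic group: one of ``control``, ``AD``, ``FTD``, ``unknown``.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


def _canonicalize(
    labels: Sequence[str], data: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Map labels to canonical 10-20 names, dropping non-montage channels."""
    keep_idx: list[int] = []
    keep_lab: list[str] = []
    dropped: list[str] = []
    for i, lab in enumerate(labels):
        key = lab.strip().lower()
        canon = _CANONICAL.get(key)
        if canon is not None and canon not in keep_lab:
            keep_idx.append(i)
            keep_lab.append(canon)
        else:
            dropped.append(lab)
    if dropped:
        logger.warning("dropping non-montage channels: %s", ", ".join(dropped))
    missing = [c for c in ALL19 if c not in keep_lab]
    if missing:
        raise MontageError(f"missing 10-20 channels: {', '.join(missing)}")
    # reorder to the canonical front-to-back order
    order = [keep_lab.index(c) for c in ALL19]
    return list(ALL19), data[[keep_idx[j] for j in order]]


# ---------------------------------------------------------------------------
# matrix_tsv

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_matrix_tsv(path: Path) -> Recording:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path} as matrix_tsv: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = float(meta.get("fs", 500.0))
    labels, data = _canonicalize(list(df.columns), df.to_numpy(dtype=float).T)
    return Recording(
        data=data, fs=fs, channels=labels,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "unknown")),
    )


def _write_matrix_tsv(rec: Recording, path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    _sidecar_path(path).write_text(json.dumps(
        {"fs": rec.fs, "subject_id": rec.subject_id, "group": rec.group},
        indent=1,
    ))


# ---------------------------------------------------------------------------
# EDF (16-bit).  Reading goes through MNE; the writer below emits a minimal
# single-record-per-second EDF with a fixed physical range.

EDF_PHYS_RANGE_UV = 1000.0  # +/- physical range; typical scalp-EEG headroom


def _write_edf(rec: Recording, path: Path, phys_range: float = EDF_PHYS_RANGE_UV) -> None:
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch = len(rec.channels)
    spr = fs  # samples per 1-s data record
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        logger.warning("EDF writer truncating %d trailing samples",
                       rec.n_samples - n_rec * spr)
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (2 * phys_range)
    dig = np.clip(np.round((rec.data[:, : n_rec * spr] + phys_range) * scale)
                  + dig_min, dig_min, dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id or 'X'}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(c, 16) for c in rec.channels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{-phys_range:g}", 8) for _ in range(n_ch)),
        b"".join(pad(f"{phys_range:g}", 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    labels, data = _canonicalize(raw.ch_names, data_uv)
    return Recording(data=data, fs=float(raw.info["sfreq"]), channels=labels,
                     subject_id=path.stem)


def _read_eeglab_set(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_eeglab(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EEGLAB .set: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    labels, data = _canonicalize(raw.ch_names, data_uv)
    return Recording(data=data, fs=float(raw.info["sfreq"]), channels=labels,
                     subject_id=path.stem)


# ---------------------------------------------------------------------------

_READERS = {
    "matrix_tsv": _read_matrix_tsv,
    "edf": _read_edf,
    "eeglab_set": _read_eeglab_set,
}
_EXT_TO_FORMAT = {".tsv": "matrix_tsv", ".edf": "edf", ".set": "eeglab_set"}


def read_recording(path, format: str = "auto") -> Recording:
    """Read one EEG recording.

    Channel labels are mapped to canonical 10-20 names (case-insensitive;
    P7/P8 and T7/T8 unified to T5/T6/T3/T4); reference and other
    non-montage channels are dropped with a warning.

    Raises
    ------
    FormatError
        If the file cannot be parsed under the requested format.
    MontageError
        If any of the 19 montage channels is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _EXT_TO_FORMAT.get(path.suffix.lower(), "matrix_tsv")
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}")
    return _READERS[format](path)


def write_recording(rec: Recording, path, format: str = "auto") -> None:
    """Write a recording as ``matrix_tsv`` (+ JSON sidecar) or EDF.

    The full 19-channel montage is required; matrix_tsv round-trips are
    exact to the printed precision, EDF round-trips are exact to the 16-bit
    quantization step of the +/-1000 microvolt physical range.
    """
    path = Path(path)
    if list(rec.channels) != list(ALL19):
        raise ValueError("write_recording requires the full 19-channel montage")
    if format == "auto":
        format = _EXT_TO_FORMAT.get(path.suffix.lower(), "matrix_tsv")
    if format == "matrix_tsv":
        _write_matrix_tsv(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported write format {format!r}")


def read_cohort(root, format: str = "auto") -> list[Recording]:
    """Read every recording under ``root``.

    Accepts a flat directory of recordings or a BIDS-style layout
    (``sub-XXX/eeg/*``).  Group labels come from the matrix_tsv sidecars
    where present.
    """
    root = Path(root)
    paths: list[Path] = []
    for pattern in ("*.tsv", "*.edf", "*.set", "sub-*/eeg/*"):
        paths.extend(p for p in sorted(root.glob(pattern))
                     if p.suffix.lower() in _EXT_TO_FORMAT)
    recs = [read_recording(p, format) for p in dict.fromkeys(paths)]
    if not recs:
        raise FileNotFoundError(f"no recordings found under {root}")
    return recs
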