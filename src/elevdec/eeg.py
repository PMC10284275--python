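"""EEG band-power feature extraction.

Raw multichannel EEG (32 channels, 250 Hz in the reference setup) is
preprocessed (50-Hz notch, 0.05-47 Hz band limitation, all zero-phase),
decomposed into the canonical theta (4-7 Hz), alpha (8-13 Hz), beta
(14-29 Hz) and gamma (30-47 Hz) bands, and reduced to one feature row per
second: the sum of squared band-filtered samples over each non-overlapping
1-s window, per channel and band.  With the default montage this yields
32 x 4 = 128 feature dimensions per second.  Per-participant matrices can
be averaged element-wise into group-level features.

The 0.05-47 Hz band limitation is implemented as a cascade (notch, then a
4th-order Butterworth high-pass run with Gustafsson's forward-backward
method, then a 4th-order Butterworth low-pass): a single band-pass with a
0.05 Hz edge is dominated by start-up transients at any practical padding
length, while the cascade attenuates a pure 50-Hz line by >25 dB in RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "FeatureMatrix",
    "DEFAULT_BANDS",
    "DEFAULT_MONTAGE",
    "preprocess",
    "band_decompose",
    "segment_power",
    "extract_features",
    "group_average",
    "read_matrix",
    "write_matrix",
    "read_edf",
]


class EEGError(ValueError):
    """Invalid recording, band definition or feature matrix."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise EEGError(
                f"band {self.name!r}: low edge {self.low_hz} must be below "
                f"high edge {self.high_hz}"
            )


#: Canonical bands: theta 4-7, alpha 8-13, beta 14-29, gamma 30-47 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 29.0),
    BandDefinition("gamma", 30.0, 47.0),
)

#: 32-channel 10-20 montage of the reference recording system
#: (modern temporo-parietal names T7/T8/P7/P8; A1/A2 are the mastoids).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6",
    "Cz", "C3", "C4",
    "CP1", "CP2", "CP5", "CP6",
    "T7", "T8", "P7", "P8",
    "Pz", "P3", "P4", "PO3", "PO4",
    "Oz", "O1", "O2", "A1", "A2",
)


@dataclass(frozen=True)
class EEGRecording:
    """One participant's recording for one video: channels x samples."""

    participant_id: str
    video_id: str
    data: np.ndarray
    channel_names: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise EEGError(f"data must be 2-D channels x samples, got {data.shape}")
        if len(self.channel_names) != data.shape[0]:
            raise EEGError(
                f"{len(self.channel_names)} channel names for {data.shape[0]} rows"
            )
        if not self.fs / 2 > 47.0:
            raise EEGError(f"fs={self.fs} too low: Nyquist must exceed 47 Hz")
        if data.shape[1] < self.fs:
            raise EEGError("recording shorter than one second")
        if not np.isfinite(data).all():
            raise EEGError("non-finite samples in recording")

    @property
    def n_seconds(self) -> int:
        return int(self.data.shape[1] // self.fs)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-second band-power features: seconds x (channel, band) columns.

    Columns are ordered channel-major: all bands of channel 1, then all
    bands of channel 2, and so on, bands in the order given at extraction.
    """

    values: np.ndarray
    feature_labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_labels", tuple(
            (str(c), str(b)) for c, b in self.feature_labels
        ))
        if values.ndim != 2:
            raise EEGError(f"values must be 2-D, got shape {values.shape}")
        if values.shape[1] != len(self.feature_labels):
            raise EEGError(
                f"{len(self.feature_labels)} labels for {values.shape[1]} columns"
            )

    @property
    def n_seconds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, channel: str, band: str) -> np.ndarray:
        try:
            idx = self.feature_labels.index((channel, band))
        except ValueError:
            raise KeyError((channel, band)) from None
        return self.values[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{c}_{b}" for c, b in self.feature_labels]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "second", np.arange(self.n_seconds))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "second":
            raise EEGError(f"{path}: first column must be 'second'")
        labels = []
        for col in df.columns[1:]:
            channel, _, band = col.rpartition("_")
            if not channel:
                raise EEGError(f"{path}: column {col!r} is not '<channel>_<band>'")
            labels.append((channel, band))
        return cls(df.iloc[:, 1:].to_numpy(dtype=float), tuple(labels))


# --- filtering ---------------------------------------------------------------

def _pad(n_samples: int, fs: float, seconds: float = 3.0) -> int:
    return int(min(n_samples - 1, seconds * fs))


def preprocess(
    rec: EEGRecording,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    band: tuple[float, float] = (0.05, 47.0),
    artifact_hook: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> EEGRecording:
    """Notch powerline noise and band-limit the recording, zero-phase.

    ``artifact_hook(data, fs) -> data`` is an optional pluggable stage (for
    ICA-style ocular-artifact removal) applied after filtering; it must
    preserve the array shape.  Disabled by default.
    """
    x = rec.data
    pl = _pad(x.shape[1], rec.fs)
    b_notch, a_notch = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
    y = signal.filtfilt(b_notch, a_notch, x, axis=1, padlen=pl)
    b_hp, a_hp = signal.butter(4, band[0], btype="high", fs=rec.fs)
    y = signal.filtfilt(b_hp, a_hp, y, method="gust", axis=1)
    sos_lp = signal.butter(4, band[1], btype="low", fs=rec.fs, output="sos")
    y = signal.sosfiltfilt(sos_lp, y, axis=1, padlen=pl)
    if artifact_hook is not None:
        y = artifact_hook(y, rec.fs)
        if y.shape != x.shape:
            raise EEGError("artifact_hook changed the data shape")
    return replace(rec, data=y)


def band_decompose(
    rec: EEGRecording, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> dict[str, np.ndarray]:
    """Zero-phase 4th-order Butterworth band-pass copy per frequency band."""
    if len({b.name for b in bands}) != len(bands):
        raise EEGError("duplicate band names")
    for b in bands:
        if b.high_hz >= rec.fs / 2:
            raise EEGError(f"band {b.name!r} upper edge {b.high_hz} >= Nyquist")
    out: dict[str, np.ndarray] = {}
    pl = _pad(rec.data.shape[1], rec.fs)
    for b in bands:
        sos = signal.butter(4, (b.low_hz, b.high_hz), btype="band",
                            fs=rec.fs, output="sos")
        out[b.name] = signal.sosfiltfilt(sos, rec.data, axis=1, padlen=pl)
    return out


def segment_power(
    banded: Mapping[str, np.ndarray],
    fs: float,
    channel_names: Sequence[str],
    band_order: Sequence[str] | None = None,
    log10: bool = False,
) -> FeatureMatrix:
    """Per-second band power: sum of squared samples in each 1-s window.

    Rows are seconds (a trailing partial second is dropped); columns are
    channel-major (channel, band) pairs.  ``log10=True`` returns log10 of
    the power instead of raw power.
    """
    if band_order is None:
        band_order = list(banded)
    shapes = {banded[b].shape for b in band_order}
    if len(shapes) != 1:
        raise EEGError("band arrays differ in shape")
    (n_ch, n_samp), = shapes
    if n_ch != len(channel_names):
        raise EEGError(f"{len(channel_names)} channel names for {n_ch} rows")
    fs_int = int(round(fs))
    n_sec = n_samp // fs_int
    if n_sec < 1:
        raise EEGError("fewer samples than one second")
    # powers[band] : (n_sec, n_ch)
    powers = {
        b: (banded[b][:, : n_sec * fs_int]
            .reshape(n_ch, n_sec, fs_int) ** 2).sum(axis=2).T
        for b in band_order
    }
    values = np.empty((n_sec, n_ch * len(band_order)))
    labels: list[tuple[str, str]] = []
    for ci, ch in enumerate(channel_names):
        for bi, b in enumerate(band_order):
            values[:, ci * len(band_order) + bi] = powers[b][:, ci]
            labels.append((ch, b))
    if log10:
        values = np.log10(values)
    return FeatureMatrix(values, tuple(labels))


def extract_features(
    rec: EEGRecording,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    do_preprocess: bool = True,
    log10: bool = False,
    artifact_hook: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> FeatureMatrix:
    """Full per-participant path: preprocess, band-decompose, segment power."""
    if do_preprocess:
        rec = preprocess(rec, artifact_hook=artifact_hook)
    banded = band_decompose(rec, bands)
    return segment_power(banded, rec.fs, rec.channel_names,
                         [b.name for b in bands], log10=log10)


def group_average(per_participant: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Element-wise mean of identically shaped per-participant matrices."""
    if not per_participant:
        raise EEGError("need at least one participant")
    first = per_participant[0]
    for fm in per_participant[1:]:
        if fm.values.shape != first.values.shape:
            raise EEGError("participant feature matrices differ in shape")
        if fm.feature_labels != first.feature_labels:
            raise EEGError("participant feature labels differ")
    mean = np.mean([fm.values for fm in per_participant], axis=0)
    return FeatureMatrix(mean, first.feature_labels)


# --- I/O ---------------------------------------------------------------------

def write_matrix(rec: EEGRecording, data_path: str | Path,
                 meta_path: str | Path) -> None:
    """Write a recording as a delimited (or .npy) matrix plus channel metadata.

    ``data_path`` ending in ``.npy`` selects the binary numpy format
    (faster for large simulated sets); anything else writes CSV with one
    row per channel.  The metadata CSV holds channel names, fs and ids.
    """
    data_path = Path(data_path)
    if data_path.suffix == ".npy":
        np.save(data_path, rec.data)
    else:
        np.savetxt(data_path, rec.data, delimiter=",")
    meta = pd.DataFrame({"channel": rec.channel_names})
    meta["fs"] = rec.fs
    meta["participant_id"] = rec.participant_id
    meta["video_id"] = rec.video_id
    meta.to_csv(meta_path, index=False)


def read_matrix(data_path: str | Path, meta_path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_matrix`."""
    data_path = Path(data_path)
    if data_path.suffix == ".npy":
        data = np.load(data_path)
    else:
        data = np.loadtxt(data_path, delimiter=",", ndmin=2)
    meta = pd.read_csv(meta_path)
    return EEGRecording(
        participant_id=str(meta["participant_id"].iloc[0]),
        video_id=str(meta["video_id"].iloc[0]),
        data=data,
        channel_names=tuple(meta["channel"].astype(str)),
        fs=float(meta["fs"].iloc[0]),
    )


def read_edf(path: str | Path, participant_id: str, video_id: str) -> EEGRecording:
    """Read an EDF recording via :mod:`mne` (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        participant_id=participant_id,
        video_id=video_id,
        data=raw.get_data(),
        channel_names=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
    )
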