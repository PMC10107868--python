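"""Calling-song analysis: echeme segmentation, dominant frequency and
species-level trait tables.

A cicada calling song is a train of echemes (tone bursts) separated by
silences.  Segmentation thresholds a smoothed absolute-amplitude
envelope; per-echeme dominant frequency is read off short-time FFT
frames (Hanning window, FFT size 512) as a 12-point series; the song
summarises to six variables — call duration CD (s), number of echemes
NE, echeme rate ER (= NE/CD, echemes/s), mean echeme duration ED (s),
mean inter-echeme interval ID (s) and dominant frequency DF (Hz).
Species values are means of individual means (two-level averaging),
never pooled song means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Waveform", "EchemeSegmentation", "SongVariables",
    "read_wav", "detect_echemes", "dominant_frequency_series",
    "compute_song_variables", "aggregate_species",
]

SONG_VARS = ("CD", "NE", "ER", "ED", "ID", "DF")


@dataclass
class Waveform:
    rate: int
    samples: np.ndarray
    individual: str = ""
    site: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono")
        if self.samples.size == 0 or not np.all(np.isfinite(self.samples)):
            raise ValueError("empty or non-finite signal")


@dataclass
class EchemeSegmentation:
    """Echeme intervals (s) with per-echeme 12-point dominant-frequency
    series; echemes too short for 12 analysis frames carry None and an
    exclusion flag."""

    intervals: list[tuple[float, float]]
    freq_series: list[np.ndarray | None]
    excluded: list[bool]
    params: dict = field(default_factory=dict)


@dataclass
class SongVariables:
    CD: float
    NE: int
    ER: float
    ED: float
    ID: float | None  # None (undefined) when NE == 1
    DF: float | None


def read_wav(path, species: str = "", individual: str = "", site: str = "") -> Waveform:
    """Read a PCM mono WAV file, scaling integer formats to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("stereo input is out of scope; supply mono WAV")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return Waveform(rate=rate, samples=np.asarray(data, dtype=float),
                    species=species, individual=individual, site=site)


def _envelope(x: np.ndarray, rate: int, rms_window: float) -> np.ndarray:
    """Absolute-amplitude envelope: moving RMS of the rectified signal."""
    win = max(1, int(round(rms_window * rate)))
    return np.sqrt(np.clip(uniform_filter1d(x**2, size=win, mode="nearest"),
                           0.0, None))


def detect_echemes(w: Waveform, threshold: float = 0.1, min_dur: float = 0.005,
                   min_gap: float = 0.003, fft_size: int = 512,
                   rms_window: float = 0.002, n_points: int = 12
                   ) -> EchemeSegmentation:
    """Segment echemes by thresholding the amplitude envelope.

    Intervals are maximal runs where the envelope is at least
    ``threshold`` times its peak, merged across gaps shorter than
    ``min_gap`` and discarded when shorter than ``min_dur``.  Dominant-
    frequency series are attached per retained echeme.
    """
    if len(w.samples) <= fft_size:
        raise ValueError("waveform shorter than one analysis frame")
    env = _envelope(w.samples, w.rate, rms_window)
    peak = env.max()
    if peak == 0:
        return EchemeSegmentation(intervals=[], freq_series=[], excluded=[],
                                  params=_params(threshold, min_dur, min_gap,
                                                 fft_size, rms_window))
    mask = env >= threshold * peak
    runs = _runs(mask)
    # merge runs separated by short gaps
    merged: list[list[int]] = []
    gap_n = int(round(min_gap * w.rate))
    for a, b in runs:
        if merged and a - merged[-1][1] < gap_n:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_n = int(round(min_dur * w.rate))
    kept = [(a, b) for a, b in merged if b - a >= min_n]

    intervals = [(a / w.rate, b / w.rate) for a, b in kept]
    series: list[np.ndarray | None] = []
    excluded: list[bool] = []
    for a, b in kept:
        try:
            f = dominant_frequency_series(w, (a / w.rate, b / w.rate),
                                          n_points=n_points, fft_size=fft_size)
            series.append(f)
            excluded.append(False)
        except ValueError:
            series.append(None)
            excluded.append(True)
    return EchemeSegmentation(intervals=intervals, freq_series=series,
                              excluded=excluded,
                              params=_params(threshold, min_dur, min_gap,
                                             fft_size, rms_window))


def _params(threshold, min_dur, min_gap, fft_size, rms_window):
    return {"threshold": threshold, "min_dur": min_dur, "min_gap": min_gap,
            "fft_size": fft_size, "window": "hann", "rms_window": rms_window}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def dominant_frequency_series(w: Waveform, interval: tuple[float, float],
                              n_points: int = 12, fft_size: int = 512
                              ) -> np.ndarray:
    """Dominant frequency in ``n_points`` evenly spaced Hanning-windowed
    FFT frames across an echeme.

    Raises ValueError when the interval cannot hold ``n_points``
    distinct frames of ``fft_size`` samples (such echemes are excluded
    from analysis).
    """
    a = int(round(interval[0] * w.rate))
    b = int(round(interval[1] * w.rate))
    length = b - a
    if length < fft_size + n_points - 1:
        raise ValueError(
            f"interval of {length} samples too short for {n_points} frames "
            f"of {fft_size}")
    starts = np.round(np.linspace(a, b - fft_size, n_points)).astype(int)
    win = np.hanning(fft_size)
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / w.rate)
    out = np.empty(n_points)
    for i, s in enumerate(starts):
        spec = np.abs(np.fft.rfft(w.samples[s:s + fft_size] * win))
        out[i] = freqs[int(np.argmax(spec))]
    return out


def compute_song_variables(seg: EchemeSegmentation) -> SongVariables:
    """Reduce a segmentation to the six song variables.

    DF: each retained echeme contributes the median of its 12-point
    series (robust to octave-jump outliers); the song DF is the mean of
    the per-echeme values.  ID is undefined (None) for single-echeme
    songs.
    """
    iv = seg.intervals
    if not iv:
        raise ValueError("zero echemes: no song variables defined")
    ne = len(iv)
    cd = iv[-1][1] - iv[0][0]
    ed = float(np.mean([b - a for a, b in iv]))
    gaps = [iv[i + 1][0] - iv[i][1] for i in range(ne - 1)]
    id_ = float(np.mean(gaps)) if gaps else None
    dfs = [float(np.median(f)) for f in seg.freq_series if f is not None]
    df = float(np.mean(dfs)) if dfs else None
    return SongVariables(CD=float(cd), NE=ne, ER=ne / cd, ED=ed, ID=id_, DF=df)


def aggregate_species(per_song: pd.DataFrame) -> pd.DataFrame:
    """Two-level averaging of song variables to a species trait table.

    ``per_song`` needs columns ``species``, ``individual`` and any of
    CD, NE, ER, ED, ID, DF.  Each individual's value is the mean over
    its songs; the species mean and standard error (sd/sqrt(n), 0 when
    n = 1) are taken over individual values.  Missing values (e.g. ID
    of single-echeme songs) are excluded, not zero-filled.
    """
    required = {"species", "individual"}
    if not required <= set(per_song.columns):
        raise ValueError(f"per-song table needs columns {sorted(required)}")
    value_cols = [c for c in SONG_VARS if c in per_song.columns]
    empty = per_song.groupby("species")["individual"].nunique() == 0
    if empty.any():  # pragma: no cover - groupby drops empty groups
        warnings.warn(f"species without individuals dropped: "
                      f"{list(empty[empty].index)}")
    ind = per_song.groupby(["species", "individual"])[value_cols].mean()
    rows = []
    for sp, sub in ind.groupby(level="species"):
        row: dict = {"species": sp, "n_individuals": len(sub),
                     "n_songs": int((per_song["species"] == sp).sum())}
        for c in value_cols:
            vals = sub[c].dropna().to_numpy()
            if len(vals) == 0:
                row[f"{c}_mean"], row[f"{c}_se"] = np.nan, np.nan
            else:
                row[f"{c}_mean"] = float(np.mean(vals))
                row[f"{c}_se"] = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                                  if len(vals) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
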