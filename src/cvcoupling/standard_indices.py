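"""Standard time- and frequency-domain HRV/BPV indices.

Time-domain indices operate on the filtered beat series (NN values):
meanNN, sdNN (sample convention, N-1), rmssd, and pNN50 -- the fraction of
successive differences exceeding 50 units of the channel (ms for BBI; the
same 50-unit rule is applied in mmHg for the pressure series, configurable).

Frequency-domain indices operate on the 2 Hz resampled series.  The power
spectral density is estimated by averaged modified periodograms (Welch,
256-sample segments, 50% overlap, per-segment mean detrending) and
integrated over the conventional bands: VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.4 Hz, plus LF/HF and the normalized powers LFn = LF/(LF+HF),
HFn = HF/(LF+HF).

Seven core indices per channel (meanNN, sdNN, rmssd, pNN50, LF, HF, LF/HF)
make up the 21 standard features; VLF, LFn and HFn are supplementary.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .exceptions import InsufficientDataError
from .io_preprocess import BeatSeries, UniformSeries, resample_2hz

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: channel prefixes used in the feature table
PREFIX = {"BBI": "BBI", "SBP": "SYS", "DBP": "DIA"}

CORE_INDEX_SUFFIXES = ("meanNN", "sdNN", "rmssd", "pNN50", "LF", "HF", "LF/HF")
SUPPLEMENTARY_SUFFIXES = ("VLF", "LFn", "HFn")


def time_domain_indices(values, nn50_threshold: float = 50.0) -> dict[str, float]:
    """meanNN, sdNN, rmssd, pNN50 of one beat-value series."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("time-domain indices require at least 2 beats")
    d = np.diff(x)
    return {
        "meanNN": float(np.mean(x)),
        "sdNN": float(np.std(x, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "pNN50": float(np.mean(np.abs(d) > nn50_threshold)),
    }


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Integrate a PSD over a frequency band (trapezoid on the grid)."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def frequency_domain_indices(series: UniformSeries, nperseg: int = 256) -> dict[str, float]:
    """Band powers and ratios of a uniformly resampled channel.

    Requires at least five minutes of samples so the LF band is resolved.
    """
    x = series.values
    fs = series.sample_rate
    if len(x) < 5 * 60 * fs:
        raise InsufficientDataError("frequency-domain indices require >= 5 min of samples")
    nperseg = min(nperseg, len(x))
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                              detrend="constant", window="hann")
    vlf = band_power(freqs, psd, VLF_BAND)
    lf = band_power(freqs, psd, LF_BAND)
    hf = band_power(freqs, psd, HF_BAND)
    total = lf + hf
    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "LF/HF": lf / hf if hf > 0 else float("inf"),
        "LFn": lf / total if total > 0 else float("nan"),
        "HFn": hf / total if total > 0 else float("nan"),
    }


def standard_indices(series: BeatSeries, include_supplementary: bool = True) -> dict[str, float]:
    """All standard HRV/BPV indices of one recording, named per channel.

    The 21 core indices carry the channel prefixes BBI/SYS/DIA; VLF, LFn and
    HFn are appended when ``include_supplementary`` is set.
    """
    out: dict[str, float] = {}
    for channel, prefix in PREFIX.items():
        td = time_domain_indices(series.channel(channel))
        fd = frequency_domain_indices(resample_2hz(series, channel))
        for suffix in CORE_INDEX_SUFFIXES:
            src = td if suffix in td else fd
            out[f"{prefix}_{suffix}"] = src[suffix]
        if include_supplementary:
            for suffix in SUPPLEMENTARY_SUFFIXES:
                out[f"{prefix}_{suffix}"] = fd[suffix]
    return out
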