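"""Normalized short-time partial directed coherence (NSTPDC).

A multichannel autoregressive (MAR) model of order p is fitted to the
z-normalized, uniformly resampled channels (stepwise least squares with
Schwarz's Bayesian criterion for order selection).  Partial directed
coherence in the column-normalized form of Baccala & Sameshima is

    pi_{i<-j}(f) = |A_ij(f)| / sqrt( sum_k |A_kj(f)|^2 ),
    A(f) = I - sum_r A_r exp(-i 2 pi f r / fs),

so for every source j and frequency the squared outflows sum to one.  The
short-time variant fits the MAR model in sliding windows, giving a field
pi(f, n) over frequency and window index.

Direction and strength are summarised per channel pair by the coupling
factor CF = a / b with a the window-and-frequency mean of the forward PDC
and b the backward mean, quantized to the normalized factor
NF in {-2, -1, 0, 1, 2}:

    |NF| = 2  strong unidirectional coupling (dominant/weaker ratio > 5)
    |NF| = 1  bidirectional coupling        (ratio in (2, 5])
     NF = 0  equal influence, or no coupling when both means vanish

with NF > 0 when the first-listed channel drives and NF < 0 when the
second does.  The area coupling strengths are the per-window frequency
means of each direction averaged across windows, bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.tsa.api import VAR

from .exceptions import InsufficientDataError, ParameterError
from .io_preprocess import UniformSeries


@dataclass
class MarModel:
    """Fitted multichannel AR model."""

    dim: int
    order: int
    coeffs: np.ndarray        # (order, dim, dim); coeffs[r, i, j]: var j lag r+1 -> eq i
    noise_cov: np.ndarray     # (dim, dim)
    sbc: float
    coef_se: np.ndarray       # same shape as coeffs
    stable: bool


@dataclass
class TvPdcField:
    """Windowed PDC field pi[window, frequency, target, source]."""

    pdc: np.ndarray
    freqs: np.ndarray
    window_len: int
    window_shift: int
    channels: tuple[str, ...]
    skipped_windows: list[int]

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise ParameterError(f"channel {channel!r} not in field") from None


@dataclass
class CouplingSummary:
    pair: tuple[str, str]
    cf: float
    a_bar: float
    b_bar: float
    nf: int
    area_xy: float
    area_yx: float
    flag: str = ""


def _as_matrix(series: Sequence[UniformSeries] | np.ndarray) -> tuple[np.ndarray, tuple[str, ...], float]:
    if isinstance(series, np.ndarray):
        return np.asarray(series, dtype=float), tuple(f"ch{i}" for i in range(series.shape[1])), 2.0
    arrs = [s.values for s in series]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ParameterError("all channels must have equal length")
    fs = series[0].sample_rate
    names = tuple(s.channel for s in series)
    return np.column_stack(arrs), names, fs


def fit_mar(series: Sequence[UniformSeries] | np.ndarray, p_max: int = 20) -> MarModel:
    """Least-squares MAR fit with SBC (BIC) order selection over 1..p_max.

    An unstable selected model is returned with ``stable=False`` and a
    warning; rank-deficient regressors raise a numerical error upstream.
    """
    data, _, _ = _as_matrix(series)
    n, m = data.shape
    if n < 10 * max(p_max, 1):
        # keep enough observations per parameter; shrink the order cap
        p_max = max(1, n // 10)
    model = VAR(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxlags=p_max, ic='bic', trend='c')
        if res.k_ar == 0:
            res = model.fit(1, trend='c')
    p = res.k_ar
    stderr = np.asarray(res.stderr)
    coef_se = np.empty((p, m, m))
    for r in range(p):
        for j in range(m):
            coef_se[r, :, j] = stderr[1 + r * m + j, :]
    stable = bool(res.is_stable())
    if not stable:
        warnings.warn("selected MAR model is unstable (companion spectral radius >= 1)", stacklevel=2)
    return MarModel(
        dim=m, order=p, coeffs=np.asarray(res.coefs),
        noise_cov=np.asarray(res.sigma_u), sbc=float(res.bic),
        coef_se=coef_se, stable=stable,
    )


def pdc_from_mar(model: MarModel, freqs: np.ndarray, fs: float = 2.0) -> np.ndarray:
    """Column-normalized PDC pi[frequency, target, source] of a fitted MAR model."""
    freqs = np.asarray(freqs, dtype=float)
    m, p = model.dim, model.order
    lags = np.arange(1, p + 1)
    # phase[f, r] = exp(-i 2 pi f r / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)
    a_f = np.eye(m)[None, :, :] - np.einsum("fr,rij->fij", phase, model.coeffs)
    mag = np.abs(a_f)
    denom = np.sqrt((mag**2).sum(axis=1, keepdims=True))
    return mag / denom


def tvpdc(
    series: Sequence[UniformSeries] | np.ndarray,
    window_len: int = 600,
    window_shift: int = 300,
    p_max: int = 20,
    n_freq: int = 64,
) -> TvPdcField:
    """Sliding-window PDC field over [0, fs/2].

    Defaults: 5-minute windows at 2 Hz with 50% overlap.  Windows whose MAR
    fit fails are skipped and recorded in ``skipped_windows``.
    """
    data, names, fs = _as_matrix(series)
    n = data.shape[0]
    if window_shift < 1:
        raise ParameterError("window_shift must be >= 1")
    if n < window_len:
        raise InsufficientDataError(f"series of {n} samples shorter than window {window_len}")
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    starts = list(range(0, n - window_len + 1, window_shift))
    fields, skipped = [], []
    for w, s0 in enumerate(starts):
        seg = data[s0:s0 + window_len]
        try:
            mdl = fit_mar(seg, p_max=p_max)
            fields.append(pdc_from_mar(mdl, freqs, fs))
        except Exception:  # noqa: BLE001 - per-window failure is recorded, not fatal
            skipped.append(w)
    if not fields:
        raise InsufficientDataError("every window failed to fit")
    return TvPdcField(
        pdc=np.stack(fields), freqs=freqs,
        window_len=window_len, window_shift=window_shift,
        channels=names, skipped_windows=skipped,
    )


def quantize_nf(a_bar: float, b_bar: float) -> tuple[int, str]:
    """Quantize mean forward/backward PDC into the normalized factor.

    Returns ``(nf, flag)`` with flag ``'no coupling'`` when both means are
    zero and ``'equal influence'`` when they are equal and positive.
    """
    if a_bar == 0.0 and b_bar == 0.0:
        return 0, "no coupling"
    if a_bar == b_bar:
        return 0, "equal influence"
    if a_bar > b_bar:
        ratio = np.inf if b_bar == 0 else a_bar / b_bar
        sign = 1
    else:
        ratio = np.inf if a_bar == 0 else b_bar / a_bar
        sign = -1
    if ratio > 5:
        return 2 * sign, ""
    if ratio > 2:
        return 1 * sign, ""
    return 0, ""


DEFAULT_BAND = (0.0, 0.4)


def coupling_summary(field: TvPdcField, x: str | int, y: str | int,
                     band: tuple[float, float] | None = DEFAULT_BAND) -> CouplingSummary:
    """Coupling factor, NF and area strengths for the ordered pair (x, y).

    Positive NF means x drives y; the area strengths are window-averaged
    frequency means of the directed PDC, in [0, 1].

    ``band`` restricts the frequency averaging; the default 0-0.4 Hz covers
    the VLF+LF+HF range where cardiovascular regulation operates.  On
    beat series interpolated onto a 2 Hz grid the band above ~0.4 Hz is
    dominated by interpolation artifacts of the ~1 Hz beat process (which
    systematically blur and can even invert the apparent direction), so the
    full-Nyquist average (``band=None``) is offered but not the default.
    """
    ix = field.index(x) if isinstance(x, str) else x
    iy = field.index(y) if isinstance(y, str) else y
    if band is None:
        fmask = np.ones(len(field.freqs), dtype=bool)
    else:
        fmask = (field.freqs >= band[0]) & (field.freqs <= band[1])
        if not fmask.any():
            raise ParameterError("frequency band contains no grid points")
    forward = field.pdc[:, fmask, iy, ix]   # x -> y
    backward = field.pdc[:, fmask, ix, iy]  # y -> x
    area_xy = float(forward.mean(axis=1).mean())
    area_yx = float(backward.mean(axis=1).mean())
    a_bar, b_bar = area_xy, area_yx
    nf, flag = quantize_nf(a_bar, b_bar)
    cf = float(np.inf) if b_bar == 0 else a_bar / b_bar
    name = lambda c: c if isinstance(c, str) else field.channels[c]
    return CouplingSummary(pair=(name(x), name(y)), cf=cf, a_bar=a_bar, b_bar=b_bar,
                           nf=nf, area_xy=area_xy, area_yx=area_yx, flag=flag)


_PAIRS = {"cs": ("BBI", "SBP"), "cd": ("BBI", "DBP"), "ds": ("DBP", "SBP")}


def nstpdc_indices(field: TvPdcField,
                   band: tuple[float, float] | None = DEFAULT_BAND) -> dict[str, float]:
    """The nine named NSTPDC indices (NF and both areas per coupling)."""
    letter = {"BBI": "c", "SBP": "s", "DBP": "d"}
    out: dict[str, float] = {}
    for tag, (x, y) in _PAIRS.items():
        s = coupling_summary(field, x, y, band=band)
        out[f"NSTPDC{tag}_NF"] = float(s.nf)
        out[f"NSTPDC{tag}_Area_{letter[x]}-{letter[y]}"] = s.area_xy
        out[f"NSTPDC{tag}_Area_{letter[y]}-{letter[x]}"] = s.area_yx
    return out
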