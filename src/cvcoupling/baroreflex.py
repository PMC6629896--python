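"""Spontaneous baroreflex sensitivity by the dual sequence method (DSM).

The sequence method scans the systogram for runs of three or more beats in
which SBP progressively rises (or falls) with every step exceeding 1 mmHg,
and pairs each run with the tachogram segment one beat later whose steps all
exceed 5 ms in the same direction.  The least-squares slope of BBI on SBP
over such a paired run is a local baroreflex gain in ms/mmHg.

The dual variant keeps the two response types separate: *bradycardic*
sequences (SBP up, BBI up -- the classical spontaneous baroreflex) yield
``bslope``, *tachycardic* sequences (SBP down, BBI down) yield ``tslope``.
Per-recording indices aggregate the per-sequence slopes (mean by default;
``slope_agg='max'`` keeps the steepest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .io_preprocess import BeatSeries

SBP_STEP = 1.0   # mmHg, minimum per-step SBP change
BBI_STEP = 5.0   # ms,  minimum per-step BBI change
MIN_LEN = 3      # beats


@dataclass
class BrsSequences:
    bradycardic: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    tachycardic: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    delay: int = 1
    min_len: int = MIN_LEN


@dataclass
class BrsResult:
    bslope: float  # ms/mmHg, NaN when no bradycardic sequence found
    tslope: float
    n_brady: int
    n_tachy: int


def _slope(sbp: np.ndarray, bbi: np.ndarray) -> float:
    return float(np.polyfit(sbp, bbi, 1)[0])


def detect_sequences(series: BeatSeries, delay: int = 1,
                     sbp_step: float = SBP_STEP, bbi_step: float = BBI_STEP,
                     min_len: int = MIN_LEN) -> BrsSequences:
    """Find maximal baroreflex sequences and their regression slopes.

    A maximal run of ``>= min_len`` beats with every SBP step ``> sbp_step``
    (same sign throughout) qualifies when the BBI segment ``delay`` beats
    later moves in the same direction with every step ``> bbi_step``.
    An empty result is valid output, not an error.
    """
    if delay < 0:
        raise ParameterError("delay must be non-negative")
    sbp, bbi = series.sbp, series.bbi
    n = len(series)
    out = BrsSequences(delay=delay, min_len=min_len)
    if n < min_len + delay:
        return out

    d_sbp = np.diff(sbp)
    direction = np.where(d_sbp > sbp_step, 1, np.where(d_sbp < -sbp_step, -1, 0))

    i = 0
    while i < n - 1:
        sgn = direction[i]
        if sgn == 0:
            i += 1
            continue
        j = i
        while j < n - 1 and direction[j] == sgn:
            j += 1
        # run of beats i .. j (j - i steps)
        run_len = j - i + 1
        if run_len >= min_len and j + delay < n:
            sbp_run = sbp[i:j + 1]
            bbi_run = bbi[i + delay:j + 1 + delay]
            d_bbi = np.diff(bbi_run)
            ok = np.all(d_bbi > bbi_step) if sgn == 1 else np.all(d_bbi < -bbi_step)
            if ok:
                seq = (sbp_run, bbi_run, _slope(sbp_run, bbi_run))
                (out.bradycardic if sgn == 1 else out.tachycardic).append(seq)
        i = j
    return out


def brs_indices(seqs: BrsSequences, slope_agg: str = "mean") -> BrsResult:
    """Aggregate per-sequence slopes into bslope/tslope (NaN when absent)."""
    if slope_agg not in ("mean", "max"):
        raise ParameterError("slope_agg must be 'mean' or 'max'")
    agg = np.mean if slope_agg == "mean" else np.max

    def summarize(seqlist) -> float:
        if not seqlist:
            return float("nan")
        return float(agg([s[2] for s in seqlist]))

    return BrsResult(
        bslope=summarize(seqs.bradycardic),
        tslope=summarize(seqs.tachycardic),
        n_brady=len(seqs.bradycardic),
        n_tachy=len(seqs.tachycardic),
    )


def dsm_indices(series: BeatSeries, delay: int = 1, slope_agg: str = "mean") -> dict[str, float]:
    """The two DSM feature-table indices for one recording."""
    res = brs_indices(detect_sequences(series, delay=delay), slope_agg=slope_agg)
    return {"bslope": res.bslope, "tslope": res.tslope}
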