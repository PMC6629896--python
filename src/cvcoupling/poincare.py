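"""Poincare plot indices and segmented Poincare plot analysis (SPPA).

A Poincare plot is the lag plot x(n) vs. x(n+1); its cloud hugs the
identity line, and the sample standard deviations along the minor and major
axes (SD1, SD2) quantify short- and long-term variability:

    SD1 = sd((y - x) / sqrt 2),   SD2 = sd((y + x) / sqrt 2).

SPPA rotates the cloud 45 degrees about its centroid so the major axis is
horizontal, then draws an adaptive 12 x 12 grid centred on the centroid with
row height SD1/2 and column width SD2/2 (the grid spans +-3 SD on each
axis).  Cell occupancy probabilities (in percent), and their row and column
sums, are the SPPA indices; mass outside the grid is reported separately.

For cross-signal couplings the plot pairs channel one at beat n with channel
two at beat n+1, mirroring the univariate lag-1 construction and the
orientation of the coupling (lag 0 available via ``lag=0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError, PairingError


@dataclass
class PoincareSummary:
    sd1: float
    sd2: float

    @property
    def ratio(self) -> float:
        if self.sd2 == 0:
            raise DegenerateInputError("SD1/SD2 undefined for SD2 = 0")
        return self.sd1 / self.sd2


@dataclass
class SPPAResult:
    cell_probs: np.ndarray      # 12 x 12, percent; [0][0] = bottom-left
    row_probs: np.ndarray       # 12, percent (sums over columns)
    col_probs: np.ndarray       # 12, percent (sums over rows)
    out_of_grid: float          # percent
    summary: PoincareSummary
    rotation_deg: float = 45.0


def _paired(x, y, lag: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise PairingError("channels must have equal length")
    if lag:
        x, y = x[:-lag], y[lag:]
    return x, y


def ppa_summary(x, y=None, lag: int = 1) -> PoincareSummary:
    """SD1/SD2 of a Poincare cloud.

    With ``y=None`` the univariate lag plot of ``x`` is used; otherwise the
    cross plot of ``x`` at beat n vs. ``y`` at beat n+lag.
    """
    if y is None:
        y = x
    x, y = _paired(x, y, lag)
    if len(x) < 3:
        raise InsufficientDataError("Poincare summary requires at least 3 paired points")
    sd1 = float(np.std((y - x) / np.sqrt(2), ddof=1))
    sd2 = float(np.std((y + x) / np.sqrt(2), ddof=1))
    if sd2 == 0:
        raise DegenerateInputError("degenerate Poincare geometry (SD2 = 0)")
    return PoincareSummary(sd1=sd1, sd2=sd2)


def sppa_analyze(x, y=None, lag: int = 1, n_cells: int = 12,
                 cell_sd_fraction: float = 0.5) -> SPPAResult:
    """Segmented Poincare plot analysis of one series or a channel pair.

    The cloud is rotated -45 degrees about its centroid (major axis to the
    horizontal), and an ``n_cells x n_cells`` grid with rows of height
    ``cell_sd_fraction * SD1`` and columns of width ``cell_sd_fraction *
    SD2`` is centred on the rotated centroid.  Cells are half-open
    [low, high): a point exactly on an edge belongs to the higher-index
    cell.  Row 1 is the bottom row, column 1 the leftmost column.
    """
    if y is None:
        y = x
    x, y = _paired(x, y, lag)
    if len(x) < n_cells:
        raise InsufficientDataError(f"SPPA requires at least {n_cells} paired points")
    summary = ppa_summary(x, y, lag=0)
    sd1, sd2 = summary.sd1, summary.sd2
    if sd1 == 0 or sd2 == 0:
        raise DegenerateInputError("degenerate Poincare geometry (zero SD)")

    dx = x - x.mean()
    dy = y - y.mean()
    # rotate -45 deg: major (identity-line) axis -> horizontal u, minor -> vertical v
    u = (dx + dy) / np.sqrt(2)
    v = (dy - dx) / np.sqrt(2)

    half = n_cells / 2.0
    col = np.floor(u / (cell_sd_fraction * sd2) + half)
    row = np.floor(v / (cell_sd_fraction * sd1) + half)
    inside = (col >= 0) & (col < n_cells) & (row >= 0) & (row < n_cells)
    counts = np.zeros((n_cells, n_cells))
    np.add.at(counts, (row[inside].astype(int), col[inside].astype(int)), 1.0)
    cell = counts / len(x) * 100.0
    return SPPAResult(
        cell_probs=cell,
        row_probs=cell.sum(axis=1),
        col_probs=cell.sum(axis=0),
        out_of_grid=float(100.0 - cell.sum()),
        summary=summary,
    )


def ppa_indices(x, y=None, tag: str = "") -> dict[str, float]:
    """Named PPA indices (SD1, SD2, SD1/SD2) for the feature table."""
    s = ppa_summary(x, y)
    return {f"PPA{tag}_SD1": s.sd1, f"PPA{tag}_SD2": s.sd2, f"PPA{tag}_SD1/SD2": s.ratio}


def sppa_indices(x, y=None, tag: str = "", include_cells: bool = False) -> dict[str, float]:
    """Named SPPA row/column (and optionally cell) probabilities in percent."""
    r = sppa_analyze(x, y)
    out: dict[str, float] = {}
    for i in range(12):
        out[f"SPPA{tag}_Row_{i + 1}"] = r.row_probs[i]
        out[f"SPPA{tag}_Column_{i + 1}"] = r.col_probs[i]
    if include_cells:
        for i in range(12):
            for j in range(12):
                out[f"SPPA{tag}_Cell_{i + 1}_{j + 1}"] = r.cell_probs[i, j]
    return out
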