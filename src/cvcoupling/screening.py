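"""Feature table assembly, Mann-Whitney screening and correlation pruning.

Screening compares two groups index by index with the two-sided
Mann-Whitney U test (exact enumeration when both groups have at most eight
subjects and no ties; normal approximation with tie correction otherwise)
and assigns significance tiers at alpha, alpha/10 and the Bonferroni cut
alpha/m with m the number of indices tested.

Pruning then removes redundancy among the significant indices: for every
pair with absolute Spearman correlation at or above ``rho_max`` the index
with the larger p-value is dropped (greedy, strongest correlations first,
ties broken by column name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

TIERS = ("n.s.", "*", "**", "***")


@dataclass
class FeatureTable:
    """Subjects x named-indices matrix with group labels.

    ``provenance`` tags each column with the method that produced it
    (``hrjsd``, ``sppa``, ``nstpdc``, ``standard``, ``dsm`` ...).
    """

    values: pd.DataFrame
    labels: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated feature columns: {dupes}")
        self.labels = pd.Series(self.labels, index=self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def group(self, label: str) -> pd.DataFrame:
        return self.values.loc[self.labels == label]

    def subset(self, labels: list[str]) -> "FeatureTable":
        mask = self.labels.isin(labels)
        return FeatureTable(self.values.loc[mask], self.labels.loc[mask], self.provenance)


@dataclass
class ScreenResult:
    table: pd.DataFrame          # index: feature name; columns: U, p, tier
    alpha: float
    n_tests: int

    @property
    def kept(self) -> list[str]:
        return self.table.index[self.table["kept"]].tolist()

    def significant(self) -> list[str]:
        return self.table.index[self.table["tier"] != "n.s."].tolist()


def mwu_screen(table: FeatureTable, group_a: str, group_b: str,
               alpha: float = 0.01) -> ScreenResult:
    """Two-sided Mann-Whitney screen of every index between two groups."""
    a = table.group(group_a)
    b = table.group(group_b)
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    m = len(table.columns)
    bonferroni = alpha / m
    rows = []
    for col in table.columns:
        xa = a[col].dropna().to_numpy()
        xb = b[col].dropna().to_numpy()
        if len(xa) < 3 or len(xb) < 3:
            raise ValueError(f"index {col!r} has fewer than 3 values in a group")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            exact = (len(xa) <= 8 and len(xb) <= 8
                     and len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb))
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="exact" if exact else "asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        if p <= bonferroni:
            tier = "***"
        elif p <= alpha / 10:
            tier = "**"
        elif p <= alpha:
            tier = "*"
        else:
            tier = "n.s."
        rows.append((col, u, p, tier))
    df = pd.DataFrame(rows, columns=["index", "U", "p", "tier"]).set_index("index")
    df["kept"] = df["tier"] != "n.s."
    return ScreenResult(table=df, alpha=alpha, n_tests=m)


def correlation_prune(table: FeatureTable, screen: ScreenResult,
                      rho_max: float = 0.7) -> ScreenResult:
    """Drop the lower-significance member of every highly correlated pair.

    Operates on the currently kept (significant) indices; pairs with
    |Spearman rho| >= ``rho_max`` are processed in descending |rho| (name
    order on ties) and the larger-p index of each still-kept pair is
    dropped.  The surviving set contains no pair at or above the threshold.
    """
    kept = set(screen.kept)
    cols = sorted(kept)
    if len(cols) < 2:
        return screen
    sub = table.values[cols]
    rho = sub.corr(method="spearman").abs()
    pvals = screen.table["p"]
    pairs = []
    for c1, c2 in combinations(cols, 2):
        r = rho.loc[c1, c2]
        if np.isfinite(r) and r >= rho_max:
            pairs.append((r, c1, c2))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, c1, c2 in pairs:
        if c1 in kept and c2 in kept:
            if pvals[c1] < pvals[c2]:
                drop = c2
            elif pvals[c2] < pvals[c1]:
                drop = c1
            else:
                drop = max(c1, c2)  # deterministic name tie-break
            kept.discard(drop)
    out = screen.table.copy()
    out["kept"] = [c in kept for c in out.index]
    return ScreenResult(table=out, alpha=screen.alpha, n_tests=screen.n_tests)
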