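"""Joint symbolic dynamics of cardiovascular series, binary and ternary.

Two parallel beat series (e.g. tachogram and systogram) are coded
increment-wise into symbols, overlapping length-3 words are formed in each
series, and the joint distribution of word pairs quantifies the coupling.

Binary coding (classic JSD): 1 for an increment, 0 otherwise, giving an
8 x 8 joint word matrix.  Ternary coding (high-resolution JSD) uses a
threshold ``l`` in the channel's units::

    0  if x[n+1] - x[n] < -l      (decrement beyond the threshold)
    1  if |x[n+1] - x[n]| <= l    (equilibrium)
    2  if x[n+1] - x[n] > +l      (increment beyond the threshold)

which yields 27 word types per series and a 27 x 27 (729-cell) joint
matrix.  The 27 ternary words are grouped into eight pattern families that
summarise the qualitative 3-beat behaviour; the joint family matrix is
8 x 8 and its Shannon entropy measures coupling complexity.

Note on symbol semantics: the ternary map above assigns 0 to decrements and
1 to equilibrium.  Descriptions that swap those two codes circulate in the
literature; here the threshold-rule form is authoritative, and the family
E0 = "000" therefore denotes three successive *decrements*.

Default thresholds: 5 ms for BBI, 1 mmHg for pressure series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .exceptions import InsufficientDataError, PairingError, ParameterError

FAMILIES = ("E0", "E1", "E2", "LU1", "LD1", "LA1", "P", "V")

#: verbatim family membership of the 27 ternary words
_FAMILY_WORDS: dict[str, tuple[str, ...]] = {
    "E0": ("000",),
    "E1": ("111",),
    "E2": ("222",),
    "LU1": ("122", "022", "112", "221", "220", "211", "121", "212"),
    "LD1": ("011", "001", "002", "110", "100", "200", "010", "101"),
    "LA1": ("020", "202"),
    "P": ("120", "201", "210"),
    "V": ("021", "102", "012"),
}

DEFAULT_THRESHOLDS = {"BBI": 5.0, "SBP": 1.0, "DBP": 1.0}


@dataclass
class SymbolSeq:
    """Symbol sequence over {0,1} (binary) or {0,1,2} (ternary)."""

    symbols: np.ndarray
    alphabet_size: int
    source_channel: str = ""
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and self.symbols.max() >= self.alphabet_size:
            raise ParameterError("symbol out of alphabet")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class JointWordMatrix:
    """Joint distribution of overlapping length-k word pairs."""

    counts: np.ndarray
    probs: np.ndarray
    word_length: int
    alphabet_size: int


@dataclass
class FamilyMatrix:
    """8 x 8 joint pattern-family distribution with marginals and entropy."""

    probs: np.ndarray
    marginals_ch1: np.ndarray
    marginals_ch2: np.ndarray
    entropy: float


def symbolize(values, mode: str = "ternary", threshold: float | None = None,
              channel: str = "") -> SymbolSeq:
    """Code successive increments of a beat series into symbols.

    ``mode='binary'``: 1 iff increment > 0, else 0 (threshold ignored).
    ``mode='ternary'``: threshold rule above; ``threshold`` defaults to the
    channel's conventional value (5 ms BBI, 1 mmHg pressures) or 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("symbolization requires at least 2 values")
    d = np.diff(x)
    if mode == "binary":
        return SymbolSeq((d > 0).astype(np.int64), 2, channel, 0.0)
    if mode != "ternary":
        raise ParameterError(f"unknown mode {mode!r}")
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(channel, 0.0)
    if threshold < 0:
        raise ParameterError("threshold must be non-negative")
    sym = np.ones(d.shape, dtype=np.int64)
    sym[d < -threshold] = 0
    sym[d > threshold] = 2
    return SymbolSeq(sym, 3, channel, float(threshold))


def _word_indices(symbols: np.ndarray, k: int, base: int) -> np.ndarray:
    """Integer index of each overlapping length-k word (most significant first)."""
    n = len(symbols) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * base + symbols[j:j + n]
    return idx


def joint_word_distribution(s1: SymbolSeq, s2: SymbolSeq, k: int = 3) -> JointWordMatrix:
    """Joint counts/probabilities of simultaneous length-k words (stride 1)."""
    if len(s1) != len(s2):
        raise PairingError("symbol sequences must have equal length")
    if s1.alphabet_size != s2.alphabet_size:
        raise PairingError("symbol sequences must share an alphabet")
    if len(s1) < k:
        raise InsufficientDataError(f"need at least {k} symbols")
    base = s1.alphabet_size
    dim = base**k
    w1 = _word_indices(s1.symbols, k, base)
    w2 = _word_indices(s2.symbols, k, base)
    counts = np.zeros((dim, dim), dtype=np.int64)
    np.add.at(counts, (w1, w2), 1)
    probs = counts / counts.sum()
    return JointWordMatrix(counts=counts, probs=probs, word_length=k, alphabet_size=base)


def family_of(word: str) -> str:
    """Pattern family of a length-3 ternary word (e.g. '202' -> 'LA1')."""
    try:
        return _WORD_TO_FAMILY[word]
    except KeyError:
        raise ParameterError(f"{word!r} is not a length-3 ternary word") from None


_WORD_TO_FAMILY: dict[str, str] = {w: f for f, ws in _FAMILY_WORDS.items() for w in ws}
assert len(_WORD_TO_FAMILY) == 27

#: family index of ternary word index 0..26 (word index base-3, MSB first)
_FAMILY_INDEX = np.array([
    FAMILIES.index(_WORD_TO_FAMILY["".join(map(str, w))])
    for w in product(range(3), repeat=3)
])


def shannon_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 log 0 := 0."""
    p = np.asarray(probs, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def family_distribution(m: JointWordMatrix) -> FamilyMatrix:
    """Regroup a 27 x 27 joint word matrix into the 8 x 8 family matrix."""
    if m.alphabet_size != 3 or m.probs.shape != (27, 27):
        raise ParameterError("family grouping requires a ternary 27 x 27 matrix")
    probs = np.zeros((8, 8))
    np.add.at(probs, (_FAMILY_INDEX[:, None], _FAMILY_INDEX[None, :]), m.probs)
    return FamilyMatrix(
        probs=probs,
        marginals_ch1=probs.sum(axis=1),
        marginals_ch2=probs.sum(axis=0),
        entropy=shannon_entropy(probs),
    )


def hrjsd_indices(x, y, pair: str, ch1: str, ch2: str,
                  threshold1: float | None = None, threshold2: float | None = None) -> dict[str, float]:
    """Named HRJSD indices for one coupling (64 cells + 16 marginals + entropy).

    ``pair`` is the coupling tag (``cs``/``cd``/``ds``); ``ch1``/``ch2`` the
    channel names used for threshold defaults and marginal suffixes.
    """
    s1 = symbolize(x, "ternary", threshold1, ch1)
    s2 = symbolize(y, "ternary", threshold2, ch2)
    fam = family_distribution(joint_word_distribution(s1, s2))
    suffix = {"BBI": "c", "SBP": "s", "DBP": "d"}
    out: dict[str, float] = {}
    for i, f1 in enumerate(FAMILIES):
        for j, f2 in enumerate(FAMILIES):
            out[f"HRJSD{pair}_{f1}-{f2}"] = fam.probs[i, j]
    for i, f in enumerate(FAMILIES):
        out[f"HRJSD{pair}-{f}{suffix.get(ch1, '1')}"] = fam.marginals_ch1[i]
        out[f"HRJSD{pair}-{f}{suffix.get(ch2, '2')}"] = fam.marginals_ch2[i]
    out[f"HRJSDSh{pair}"] = fam.entropy
    return out


def jsd_indices(x, y, pair: str) -> dict[str, float]:
    """Binary-JSD word-pair probabilities (8 x 8 = 64 cells) plus entropy."""
    s1 = symbolize(x, "binary")
    s2 = symbolize(y, "binary")
    m = joint_word_distribution(s1, s2)
    out = {}
    for i in range(8):
        for j in range(8):
            out[f"JSD{pair}-{i}_{j}"] = m.probs[i, j]
    out[f"JSDSh{pair}"] = shannon_entropy(m.probs)
    return out
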