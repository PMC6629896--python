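"""Per-subject feature extraction and cohort-level table assembly.

One recording yields named indices from up to six method groups:

    standard  time- and frequency-domain HRV/BPV indices (21 core + extras)
    dsm       dual-sequence baroreflex slopes (bslope, tslope)
    ppa       Poincare SD1/SD2/ratio per channel and channel pair
    sppa      segmented Poincare row/column probabilities per coupling
    hrjsd     ternary joint-symbolic family matrix indices per coupling
    jsd       binary joint-symbolic word probabilities per coupling
    nstpdc    directed-coupling NF and area strengths (9 indices)

Couplings are tagged cs (cardiac-systolic: BBI-SBP), cd (cardiac-diastolic:
BBI-DBP) and ds (diastolic-systolic: DBP-SBP); univariate tags are c, s, d.
Artifact filtering runs before extraction; the NSTPDC group resamples the
filtered channels to 2 Hz and z-normalizes them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .baroreflex import dsm_indices
from .io_preprocess import BeatSeries, filter_artifacts, resample_2hz, znormalize
from .nstpdc import nstpdc_indices, tvpdc
from .poincare import ppa_indices, sppa_indices
from .screening import FeatureTable
from .standard_indices import standard_indices
from .symbolic import hrjsd_indices, jsd_indices

ALL_METHODS = ("standard", "dsm", "ppa", "sppa", "hrjsd", "jsd", "nstpdc")

_COUPLINGS = {"cs": ("BBI", "SBP"), "cd": ("BBI", "DBP"), "ds": ("DBP", "SBP")}
_UNIVARIATE = {"c": "BBI", "s": "SBP", "d": "DBP"}


def extract_features(
    series: BeatSeries,
    methods: Sequence[str] = ALL_METHODS,
    prefiltered: bool = False,
    lambda_sd: float = 3.0,
    sppa_cells: bool = False,
    tvpdc_kwargs: dict | None = None,
) -> dict[str, float]:
    """All named indices of one recording as a flat mapping."""
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method groups: {sorted(unknown)}")
    s = series if prefiltered else filter_artifacts(series, lambda_sd=lambda_sd)[0]
    out: dict[str, float] = {}
    if "standard" in methods:
        out.update(standard_indices(s))
    if "dsm" in methods:
        out.update(dsm_indices(s))
    if "ppa" in methods:
        for tag, ch in _UNIVARIATE.items():
            out.update(ppa_indices(s.channel(ch), tag=tag))
        for tag, (c1, c2) in _COUPLINGS.items():
            out.update(ppa_indices(s.channel(c1), s.channel(c2), tag=tag))
    if "sppa" in methods:
        for tag, (c1, c2) in _COUPLINGS.items():
            out.update(sppa_indices(s.channel(c1), s.channel(c2), tag=tag,
                                    include_cells=sppa_cells))
    if "hrjsd" in methods:
        for tag, (c1, c2) in _COUPLINGS.items():
            out.update(hrjsd_indices(s.channel(c1), s.channel(c2), tag, c1, c2))
    if "jsd" in methods:
        for tag, (c1, c2) in _COUPLINGS.items():
            out.update(jsd_indices(s.channel(c1), s.channel(c2), tag))
    if "nstpdc" in methods:
        uniform = [znormalize(resample_2hz(s, ch)) for ch in ("BBI", "SBP", "DBP")]
        field = tvpdc(uniform, **(tvpdc_kwargs or {}))
        out.update(nstpdc_indices(field))
    return out


def _provenance(name: str) -> str:
    for tag in ("HRJSDSh", "HRJSD", "SPPA", "JSDSh", "JSD", "PPA", "NSTPDC"):
        if name.startswith(tag):
            return {"HRJSDSh": "hrjsd", "JSDSh": "jsd"}.get(tag, tag.lower())
    if name in ("bslope", "tslope"):
        return "dsm"
    return "standard"


def extract_feature_table(
    subjects: Iterable[BeatSeries],
    methods: Sequence[str] = ALL_METHODS,
    **kwargs,
) -> FeatureTable:
    """Feature table (subjects x indices) for a cohort, labels from groups."""
    rows, labels, ids = [], [], []
    for s in subjects:
        rows.append(extract_features(s, methods=methods, **kwargs))
        labels.append(s.group)
        ids.append(s.subject_id)
    values = pd.DataFrame(rows, index=ids)
    table = FeatureTable(values=values, labels=pd.Series(labels, index=ids))
    table.provenance = {c: _provenance(c) for c in values.columns}
    return table


def write_feature_csv(table: FeatureTable, path) -> None:
    """Long-format feature CSV: subject_id, group, index_name, value."""
    long = table.values.stack().rename("value").reset_index()
    long.columns = ["subject_id", "index_name", "value"]
    long.insert(1, "group", long["subject_id"].map(table.labels))
    long.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureTable:
    """Read a long-format feature CSV back into a FeatureTable."""
    long = pd.read_csv(path)
    values = long.pivot(index="subject_id", columns="index_name", values="value")
    labels = long.drop_duplicates("subject_id").set_index("subject_id")["group"]
    table = FeatureTable(values=values, labels=labels.reindex(values.index))
    table.provenance = {c: _provenance(c) for c in values.columns}
    return table
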