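"""SVM risk-stratification: custom kernels, LOOCV grid search, cascade.

Index pairs surviving the screening feed soft-margin support vector
machines with one of four kernels (sigma > 0, integer d >= 1):

    gaussian         K(x,y) = exp(-||x-y||^2 / (2 sigma^2))
    laplace          K(x,y) = exp(-||x-y|| / sigma)
    laplace_printed  K(x,y) = exp(-||x-y||^2 / (2 sigma))
    anova            K(x,y) = sum_k exp(-sigma (x_k-y_k)^2)^d

(`laplace_printed` is a Gaussian-shaped variant that appears in parts of
the literature under the Laplace name; the standard Laplacian kernel is the
default.)  Features are standardized to zero mean and unit variance using
training-set statistics only; under leave-one-out cross-validation the
scaler is refit on every training fold, so no information from the held-out
subject leaks into the model.

Model selection iterates C and the kernel parameters over grids, scoring
each configuration by LOOCV accuracy (ties: higher AUC, then configuration
order).  Reports carry accuracy, sensitivity and specificity in percent
(positive class = the patient / higher-risk group) and the AUC computed as
a rank statistic on the pooled held-out decision values.

The cascade classifier stratifies an unlabelled subject in two stages:
a CON-vs-IDC model first, and an LR-vs-HR model for those called IDC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .exceptions import ParameterError
from .screening import FeatureTable

KERNEL_KINDS = ("gaussian", "laplace", "laplace_printed", "anova")

#: default search grids; they bracket the values typically selected on
#: cardiovascular index pairs (C around 0.3-7, sigma around 0.3-1.5)
DEFAULT_C_GRID = (0.1, 0.3, 1.0, 3.0, 5.5, 7.0, 10.0)
DEFAULT_SIGMA_GRID = (0.1, 0.3, 1.0, 1.5, 3.0)
DEFAULT_D_GRID = (1, 2, 3)


@dataclass(frozen=True)
class KernelSpec:
    kind: str
    sigma: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ParameterError(f"unknown kernel {self.kind!r}")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.kind == "anova" and self.d < 1:
            raise ParameterError("anova degree d must be >= 1")


def kernel_matrix(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(x_i, y_j)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ParameterError("dimension mismatch between feature vectors")
    diff = x[:, None, :] - y[None, :, :]
    sq = (diff**2).sum(axis=2)
    if spec.kind == "gaussian":
        return np.exp(-sq / (2.0 * spec.sigma**2))
    if spec.kind == "laplace":
        return np.exp(-np.sqrt(sq) / spec.sigma)
    if spec.kind == "laplace_printed":
        return np.exp(-sq / (2.0 * spec.sigma))
    # anova
    return (np.exp(-spec.sigma * diff**2) ** spec.d).sum(axis=2)


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Kernel value for a single pair of feature vectors."""
    return float(kernel_matrix(spec, np.atleast_2d(x), np.atleast_2d(y))[0, 0])


@dataclass
class SvmModel:
    """Trained soft-margin SVM with a precomputed custom kernel.

    Decision function f(x) = sum_i alpha_i y_i K(x_i, x) + b on features
    standardized by the stored training-set mean/sd.  ``positive_label``
    maps f(x) > 0.
    """

    kernel: KernelSpec
    C: float
    feature_names: list[str]
    support_vectors: np.ndarray   # scaled space
    dual_coef: np.ndarray         # alpha_i * y_i
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    positive_label: str
    negative_label: str

    @property
    def alpha(self) -> np.ndarray:
        return np.abs(self.dual_coef)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.scale_mean) / self.scale_sd

    def decision_function(self, x) -> np.ndarray:
        k = kernel_matrix(self.kernel, self._scale(x), self.support_vectors)
        return k @ self.dual_coef + self.intercept

    def predict(self, x) -> np.ndarray:
        f = self.decision_function(x)
        return np.where(f > 0, self.positive_label, self.negative_label)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma, "d": self.kernel.d},
            "C": self.C,
            "feature_names": self.feature_names,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        p = json.loads(Path(path).read_text())
        return cls(
            kernel=KernelSpec(**p["kernel"]), C=p["C"], feature_names=p["feature_names"],
            support_vectors=np.asarray(p["support_vectors"]),
            dual_coef=np.asarray(p["dual_coef"]), intercept=p["intercept"],
            scale_mean=np.asarray(p["scale_mean"]), scale_sd=np.asarray(p["scale_sd"]),
            positive_label=p["positive_label"], negative_label=p["negative_label"],
        )


@dataclass
class ClassificationReport:
    acc: float       # percent
    sn: float        # percent
    sp: float        # percent
    auc: float
    confusion: dict[str, int] = field(default_factory=dict)
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def train_svm(x, y, C: float, kernel: KernelSpec,
              positive_label: str, feature_names: Sequence[str] | None = None) -> SvmModel:
    """Fit a soft-margin SVM on standardized features (deterministic).

    ``x`` is (n_subjects, n_features); ``y`` holds exactly two label values,
    with ``positive_label`` the patient / higher-risk class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    labels = set(np.unique(y))
    if len(labels) != 2:
        raise ParameterError(f"training requires exactly 2 classes, got {sorted(map(str, labels))}")
    if positive_label not in labels:
        raise ParameterError(f"positive label {positive_label!r} not present")
    if np.isnan(x).any():
        raise ParameterError("missing values in training features")
    negative_label = (labels - {positive_label}).pop()
    ybin = np.where(y == positive_label, 1, -1)
    if min((ybin == 1).sum(), (ybin == -1).sum()) < 2:
        raise ParameterError("need at least 2 subjects per class")

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd

    gram = kernel_matrix(kernel, xs, xs)
    clf = SVC(kernel="precomputed", C=C, tol=1e-6)
    clf.fit(gram, ybin)
    sv_idx = clf.support_
    # sklearn orders dual_coef_ by class; map back to alpha_i * y_i per SV
    dual = clf.dual_coef_[0]
    return SvmModel(
        kernel=kernel, C=C,
        feature_names=list(feature_names) if feature_names is not None else [f"f{i}" for i in range(x.shape[1])],
        support_vectors=xs[sv_idx], dual_coef=dual, intercept=float(clf.intercept_[0]),
        scale_mean=mean, scale_sd=sd,
        positive_label=str(positive_label), negative_label=str(negative_label),
    )


def _report(y_true, y_pred, decisions, positive_label) -> ClassificationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_label
    tp = int(np.sum(pos & (y_pred == positive_label)))
    fn = int(np.sum(pos & (y_pred != positive_label)))
    tn = int(np.sum(~pos & (y_pred != positive_label)))
    fp = int(np.sum(~pos & (y_pred == positive_label)))
    acc = 100.0 * (tp + tn) / len(y_true)
    sn = 100.0 * tp / max(tp + fn, 1)
    sp = 100.0 * tn / max(tn + fp, 1)
    if len(np.unique(pos)) == 2 and decisions is not None:
        auc = float(roc_auc_score(pos.astype(int), decisions))
    else:
        auc = float("nan")
    return ClassificationReport(acc=acc, sn=sn, sp=sp, auc=auc,
                                confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn})


def loocv_report(x, y, C: float, kernel: KernelSpec, positive_label: str) -> ClassificationReport:
    """Leave-one-out evaluation of one configuration (fold-wise rescaling)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(y)
    decisions = np.empty(n)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_svm(x[mask], y[mask], C=C, kernel=kernel, positive_label=positive_label)
        decisions[i] = model.decision_function(x[i])[0]
        preds[i] = model.positive_label if decisions[i] > 0 else model.negative_label
    return _report(y, preds, decisions, positive_label)


@dataclass
class GridSearchResult:
    features: tuple[str, str]
    kernel: KernelSpec
    C: float
    report: ClassificationReport
    model: SvmModel


def kernel_grid(kinds: Iterable[str] = ("gaussian", "laplace"),
                sigmas: Sequence[float] = DEFAULT_SIGMA_GRID,
                ds: Sequence[int] = DEFAULT_D_GRID) -> list[KernelSpec]:
    """Expand kernel kinds x parameter grids into a list of specs."""
    specs = []
    for kind in kinds:
        for sigma in sigmas:
            if kind == "anova":
                specs.extend(KernelSpec(kind, sigma, d) for d in ds)
            else:
                specs.append(KernelSpec(kind, sigma))
    return specs


def loocv_grid_search(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    positive_label: str,
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
    kernels: Sequence[KernelSpec] | None = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
) -> GridSearchResult:
    """Exhaustive LOOCV search over (index pair, kernel, C).

    ``candidate_pairs`` defaults to all pairs of the table's columns.  The
    winning configuration maximises LOOCV accuracy (ties: higher AUC, then
    enumeration order); its final model is refit on all subjects.
    """
    sub = table.subset([group_a, group_b])
    y = sub.labels.to_numpy()
    if min((y == group_a).sum(), (y == group_b).sum()) < 3:
        raise ParameterError("need at least 3 subjects per class for LOOCV")
    if candidate_pairs is None:
        candidate_pairs = list(combinations(sub.columns, 2))
    if kernels is None:
        kernels = kernel_grid()
    if not candidate_pairs or not kernels or not len(C_grid):
        raise ParameterError("empty search grid")

    best: GridSearchResult | None = None
    best_key: tuple = ()
    for k, pair in enumerate(candidate_pairs):
        x = sub.values[list(pair)].to_numpy()
        for kk, kern in enumerate(kernels):
            for kc, C in enumerate(C_grid):
                rep = loocv_report(x, y, C=C, kernel=kern, positive_label=positive_label)
                key = (rep.acc, rep.auc, -k, -kk, -kc)
                if best is None or key > best_key:
                    model = train_svm(x, y, C=C, kernel=kern, positive_label=positive_label,
                                      feature_names=list(pair))
                    best = GridSearchResult(features=tuple(pair), kernel=kern, C=C,
                                            report=rep, model=model)
                    best_key = key
    assert best is not None
    return best


@dataclass
class CascadeModel:
    """Two-stage risk stratification: CON vs IDC, then LR vs HR."""

    stage1: SvmModel  # positive = IDC (patient)
    stage2: SvmModel  # positive = IDC_HR

    def predict_one(self, features: dict[str, float] | pd.Series) -> str:
        def pick(model: SvmModel) -> np.ndarray:
            try:
                return np.array([[float(features[name]) for name in model.feature_names]])
            except KeyError as exc:
                raise ParameterError(f"missing feature {exc.args[0]!r} for cascade scoring") from None
        if self.stage1.predict(pick(self.stage1))[0] == self.stage1.negative_label:
            return self.stage1.negative_label   # CON verdict is terminal
        return str(self.stage2.predict(pick(self.stage2))[0])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_one(row) for _, row in table.iterrows()])


def cascade_loocv(
    table: FeatureTable,
    stage1_features: tuple[str, str],
    stage2_features: tuple[str, str],
    stage1_kernel: KernelSpec,
    stage2_kernel: KernelSpec,
    stage1_C: float = 1.0,
    stage2_C: float = 1.0,
    con_label: str = "CON",
    lr_label: str = "IDC_LR",
    hr_label: str = "IDC_HR",
) -> tuple[float, dict[str, dict[str, float]]]:
    """Leave-one-out evaluation of the cascade on a three-group table.

    For every held-out subject both stages are retrained on the remaining
    subjects (stage 1 on CON vs pooled IDC, stage 2 on LR vs HR) and the
    cascade label is compared with the truth.  Returns overall accuracy in
    percent and one-vs-all sensitivity/specificity per class.
    """
    y = table.labels.to_numpy()
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        vals = table.values.iloc[mask]
        labs = y[mask]
        y1 = np.where(labs == con_label, con_label, "IDC")
        m1 = train_svm(vals[list(stage1_features)].to_numpy(), y1, C=stage1_C,
                       kernel=stage1_kernel, positive_label="IDC",
                       feature_names=stage1_features)
        sel2 = labs != con_label
        m2 = train_svm(vals.loc[sel2, list(stage2_features)].to_numpy(), labs[sel2],
                       C=stage2_C, kernel=stage2_kernel, positive_label=hr_label,
                       feature_names=stage2_features)
        preds[i] = CascadeModel(stage1=m1, stage2=m2).predict_one(table.values.iloc[i])
    acc = 100.0 * float(np.mean(preds == y))
    per_class = {}
    for label in (con_label, lr_label, hr_label):
        pos = y == label
        ppos = preds == label
        tp = np.sum(pos & ppos)
        fn = np.sum(pos & ~ppos)
        tn = np.sum(~pos & ~ppos)
        fp = np.sum(~pos & ppos)
        per_class[label] = {
            "sn": 100.0 * tp / max(tp + fn, 1),
            "sp": 100.0 * tn / max(tn + fp, 1),
        }
    return acc, per_class
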