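"""Filter-bank common spatial patterns with RBF-SVM classification.

The classical-BCI stage: each 1 s window is band-passed into nine
contiguous 4 Hz bands spanning 4-40 Hz; within each band, CSP spatial
filters are fitted per condition pair (the generalized eigenvectors of the
two class covariance matrices), windows are projected and summarized as
normalized log-variance features; the concatenated 9 x 2m feature vector
feeds a binary RBF support-vector machine (gamma = 1/360, C = 1.6).
Four pairs are evaluated: guided vs stressor, baseline vs stressor,
unguided vs guided, and unguided vs stressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from sklearn.svm import SVC

from .preprocess import LABEL_TO_ID, SplitSpec, WindowSet, split_train_test

#: The four condition pairs reported for the binary SVM stage.
CONDITION_PAIRS = (
    ("guided", "stressor"),
    ("baseline", "stressor"),
    ("unguided", "guided"),
    ("unguided", "stressor"),
)


def _default_bands() -> tuple[tuple[float, float], ...]:
    return tuple((4.0 + 4.0 * i, 8.0 + 4.0 * i) for i in range(9))


@dataclass(frozen=True)
class FilterBankSpec:
    """Nine contiguous 4 Hz band-pass filters from 4 to 40 Hz."""

    bands: tuple[tuple[float, float], ...] = field(default_factory=_default_bands)
    order: int = 4  # Butterworth order per band, applied forward-backward

    def __post_init__(self):
        for (lo, hi) in self.bands:
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(self.bands, self.bands[1:]):
            if abs(hi - lo2) > 1e-9:
                raise ValueError("bands must be contiguous")


def design_filter_bank(
    ws: WindowSet, spec: FilterBankSpec | None = None
) -> np.ndarray:
    """Band-pass every window once per band.

    Returns an array of shape (n_bands, n, channels, samples): zero-phase
    order-``spec.order`` Butterworth per band.
    """
    spec = spec or FilterBankSpec()
    nyq = ws.rate / 2.0
    for (lo, hi) in spec.bands:
        if hi >= nyq:
            raise ValueError(f"band ({lo}, {hi}) reaches Nyquist ({nyq})")
    n, c, m = ws.windows.shape
    out = np.empty((len(spec.bands), n, c, m))
    flat = ws.windows.reshape(n * c, m)
    for bi, (lo, hi) in enumerate(spec.bands):
        sos = signal.butter(spec.order, [lo, hi], btype="bandpass",
                            fs=ws.rate, output="sos")
        out[bi] = signal.sosfiltfilt(sos, flat, axis=1).reshape(n, c, m)
    return out


def _class_covariance(windows: np.ndarray, shrinkage: float) -> np.ndarray:
    """Average of trace-normalized per-window covariances, plus eps*I."""
    n, c, _ = windows.shape
    cov = np.zeros((c, c))
    for w in windows:
        s = w @ w.T
        tr = np.trace(s)
        if tr > 0:
            cov += s / tr
    cov /= n
    return cov + shrinkage * np.eye(c)


@dataclass
class CSPModel:
    """CSP filters for one band and one class pair.

    ``filters`` has shape (channels, 2m): the m most class-a-dominant and m
    most class-b-dominant generalized eigenvectors of (C_a, C_a + C_b),
    ordered by descending class-a variance ratio. The whitening invariant
    W^T (C_a + C_b) W = I holds by construction.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray  # class-a variance ratios of the kept filters
    classes: tuple[str, str]


def fit_csp(
    class_a: np.ndarray,
    class_b: np.ndarray,
    m: int = 2,
    shrinkage: float = 1e-6,
    classes: tuple[str, str] = ("a", "b"),
) -> CSPModel:
    """Fit 2m CSP filters from two stacks of (n, channels, samples) windows."""
    if len(class_a) < 2 or len(class_b) < 2:
        raise ValueError("need >= 2 windows per class")
    ca = _class_covariance(class_a, shrinkage)
    cb = _class_covariance(class_b, shrinkage)
    comp = ca + cb
    try:
        evals, evecs = linalg.eigh(ca, comp)
    except linalg.LinAlgError as e:  # pragma: no cover - shrinkage prevents this
        raise np.linalg.LinAlgError(
            f"rank-deficient composite covariance; increase shrinkage ({e})"
        )
    order = np.argsort(evals)[::-1]  # descending class-a variance ratio
    evals, evecs = evals[order], evecs[:, order]
    n_ch = ca.shape[0]
    if 2 * m > n_ch:
        raise ValueError(f"2m = {2 * m} exceeds channel count {n_ch}")
    keep = list(range(m)) + list(range(n_ch - m, n_ch))
    return CSPModel(filters=evecs[:, keep], eigenvalues=evals[keep], classes=classes)


@dataclass
class CSPBankModel:
    """Per-band CSP models plus the band layout they were fitted on."""

    bands: tuple[tuple[float, float], ...]
    models: list[CSPModel]
    m: int
    classes: tuple[str, str]


def fit_csp_bank(
    banded: np.ndarray,
    labels: np.ndarray,
    class_pair: tuple[int, int],
    bands: tuple[tuple[float, float], ...],
    m: int = 2,
    shrinkage: float = 1e-6,
    class_names: tuple[str, str] = ("a", "b"),
) -> CSPBankModel:
    """Fit one CSP model per filter-bank band for a binary class pair."""
    a_idx = np.flatnonzero(labels == class_pair[0])
    b_idx = np.flatnonzero(labels == class_pair[1])
    models = [
        fit_csp(banded[bi][a_idx], banded[bi][b_idx], m=m,
                shrinkage=shrinkage, classes=class_names)
        for bi in range(banded.shape[0])
    ]
    return CSPBankModel(bands=tuple(bands), models=models, m=m, classes=class_names)


def extract_features(model: CSPBankModel, banded: np.ndarray) -> np.ndarray:
    """Normalized log-variance features, (n, n_bands * 2m).

    Per band: project each window through the 2m filters, take the variance
    of each projected trace, normalize by the sum over the 2m filters, and
    log. Scale-invariant: scaling a window leaves its feature row unchanged.
    """
    n = banded.shape[1]
    feats = []
    for bi, csp in enumerate(model.models):
        proj = np.einsum("cf,ncs->nfs", csp.filters, banded[bi])
        var = proj.var(axis=2)
        denom = var.sum(axis=1, keepdims=True)
        denom = np.where(denom < 1e-300, 1.0, denom)
        ratio = np.clip(var / denom, 1e-12, None)
        feats.append(np.log(ratio))
    out = np.concatenate(feats, axis=1)
    if out.shape != (n, len(model.models) * 2 * model.m):
        raise AssertionError("feature layout mismatch")
    return out


@dataclass(frozen=True)
class SVMSpec:
    """RBF-SVM hyperparameters used for every condition pair."""

    gamma: float = 1.0 / 360.0
    C: float = 1.6
    kernel: str = "rbf"

    def __post_init__(self):
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be > 0")


def train_eval_binary(
    feat_train: np.ndarray,
    y_train: np.ndarray,
    feat_test: np.ndarray,
    y_test: np.ndarray,
    spec: SVMSpec | None = None,
) -> tuple[float, np.ndarray]:
    """Fit the binary RBF-SVM and report holdout accuracy and predictions."""
    spec = spec or SVMSpec()
    if len(np.unique(y_train)) != 2:
        raise ValueError("exactly two classes required in the training labels")
    clf = SVC(kernel=spec.kernel, gamma=spec.gamma, C=spec.C)
    clf.fit(feat_train, y_train)
    pred = clf.predict(feat_test)
    return float(np.mean(pred == y_test)), pred


def train_eval_multiclass(
    feat_train: np.ndarray,
    y_train: np.ndarray,
    feat_test: np.ndarray,
    y_test: np.ndarray,
    spec: SVMSpec | None = None,
) -> tuple[float, np.ndarray]:
    """The discarded variant: one multiclass SVM over all four conditions.

    Kept behind this explicit entry point (polynomial/sigmoid kernels via
    ``SVMSpec.kernel``) but excluded from default reports — the binary
    pairwise classifiers are the reported configuration.
    """
    spec = spec or SVMSpec()
    if len(np.unique(y_train)) < 3:
        raise ValueError("use train_eval_binary for two-class problems")
    clf = SVC(kernel=spec.kernel, gamma=spec.gamma, C=spec.C)
    clf.fit(feat_train, y_train)
    pred = clf.predict(feat_test)
    return float(np.mean(pred == y_test)), pred


def classify_pair(
    ws: WindowSet,
    pair: tuple[str, str],
    split: SplitSpec | None = None,
    bank: FilterBankSpec | None = None,
    m: int = 2,
    svm: SVMSpec | None = None,
) -> float:
    """Full FBCSP-SVM run for one condition pair on one participant.

    80:20 stratified split, filter bank and CSP fitted on the training
    windows only; returns holdout accuracy.
    """
    split = split or SplitSpec(train_fraction=0.8)
    bank = bank or FilterBankSpec()
    sub = ws.restrict_classes(pair)
    train, test = split_train_test(sub, split)
    banded_train = design_filter_bank(train, bank)
    banded_test = design_filter_bank(test, bank)
    ids = (LABEL_TO_ID[pair[0]], LABEL_TO_ID[pair[1]])
    model = fit_csp_bank(banded_train, train.labels, ids, bank.bands, m=m,
                         class_names=pair)
    ft_train = extract_features(model, banded_train)
    ft_test = extract_features(model, banded_test)
    acc, _ = train_eval_binary(ft_train, train.labels, ft_test, test.labels, svm)
    return acc


def run_all_pairs(
    ws: WindowSet,
    split: SplitSpec | None = None,
    bank: FilterBankSpec | None = None,
    m: int = 2,
    svm: SVMSpec | None = None,
) -> dict[str, float | None]:
    """Accuracies for the four reported condition pairs of one participant.

    A pair whose conditions are absent from the window set is reported as
    ``None`` rather than raising.
    """
    present = set(np.unique(ws.labels))
    out: dict[str, float | None] = {}
    for pair in CONDITION_PAIRS:
        key = f"{pair[0]}_vs_{pair[1]}"
        ids = {LABEL_TO_ID[pair[0]], LABEL_TO_ID[pair[1]]}
        if not ids <= present:
            out[key] = None
            continue
        out[key] = classify_pair(ws, pair, split=split, bank=bank, m=m, svm=svm)
    return out
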