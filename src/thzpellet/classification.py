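"""PCA + linear-SVM separability of amplitude-ratio spectra.

Rows of the feature matrix are spectra — the amplitude ratio A_sam/A_ref at
each frequency in the configured band — one row per measurement, labelled by
class.  PCA (mean-centered, no per-column scaling: the columns share units)
reduces the band to a few scores; a linear-kernel SVM at penalty C = 1.0 then
reports whether a maximum-margin hyperplane separates the two classes on the
first two component scores.  Separability is reported on training data (an
illustration of class structure, not a validated predictive model); a
label-permutation control distinguishes real structure from overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .errors import DomainError
from .extraction import Spectrum

_VALID_BAND = (0.2, 1.4)  # THz


@dataclass
class FeatureMatrix:
    """Amplitude-ratio spectra: one row per measurement, one column per frequency."""

    X: np.ndarray  # (n_rows, n_freqs)
    frequencies: np.ndarray  # THz, ascending
    labels: np.ndarray  # class per row


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_rows, k)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, in [0, 1]
    loadings: np.ndarray  # (k, n_freqs)
    frequencies: np.ndarray
    labels: np.ndarray


@dataclass
class SeparabilityReport:
    training_accuracy: float
    margin: float  # full margin width, 2/||w||
    n_support_vectors: int
    hyperplane_normal: np.ndarray
    intercept: float


@dataclass
class ClassificationReport:
    pca: PCAResult
    svm: SeparabilityReport
    informative_frequencies: list[float]  # THz, per component
    permutation_p: float | None = None
    permutation_accuracies: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def separable(self) -> bool:
        return self.svm.training_accuracy == 1.0


def build_feature_matrix(
    spectra: list[tuple[Spectrum, Spectrum]],
    labels: list[str] | np.ndarray,
    band: tuple[float, float] = _VALID_BAND,
    valid_band: tuple[float, float] = _VALID_BAND,
) -> FeatureMatrix:
    """Stack A_sam/A_ref rows restricted to ``band``.

    All (reference, sample) spectrum pairs must share one frequency grid;
    the band must lie inside the instrument's valid range.
    """
    if len(spectra) != len(labels):
        raise DomainError("one label per spectrum pair required")
    if not spectra:
        raise DomainError("no spectra given")
    if band[0] < valid_band[0] or band[1] > valid_band[1] or band[0] >= band[1]:
        raise DomainError(
            f"band {band} THz outside the valid range {valid_band} THz"
        )
    f0 = spectra[0][0].frequencies
    mask = (f0 >= band[0]) & (f0 <= band[1])
    if not mask.any():
        raise DomainError("no grid points inside the requested band")
    rows = []
    for ref, sam in spectra:
        for s in (ref, sam):
            if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0):
                raise DomainError("all spectra must share one frequency grid")
        if np.any(ref.amplitude[mask] <= 0):
            raise DomainError("reference amplitude must be positive inside the band")
        rows.append(sam.amplitude[mask] / ref.amplitude[mask])
    X = np.vstack(rows)
    if not np.all(np.isfinite(X)):
        raise DomainError("feature matrix contains non-finite values")
    return FeatureMatrix(X=X, frequencies=f0[mask].copy(), labels=np.asarray(labels))


def pca_decompose(fm: FeatureMatrix, k: int) -> PCAResult:
    """Mean-centered PCA with a deterministic sign convention.

    Each loading vector is flipped, if needed, so its largest-magnitude entry
    is positive; scores follow.  k must satisfy k <= min(rows - 1, columns).
    """
    n_rows, n_cols = fm.X.shape
    if n_rows < 2:
        raise DomainError("PCA needs at least 2 rows")
    if not (1 <= k <= min(n_rows - 1, n_cols)):
        raise DomainError(
            f"k={k} out of range (max {min(n_rows - 1, n_cols)} for this matrix)"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(fm.X)
    loadings = pca.components_.copy()
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        frequencies=fm.frequencies.copy(),
        labels=np.asarray(fm.labels).copy(),
    )


def informative_frequency(r: PCAResult, component: int) -> float:
    """Frequency (THz) of the maximum |loading| of one component.

    Ties break toward the lower frequency (argmax returns the first hit on
    an ascending grid).
    """
    if not (0 <= component < r.loadings.shape[0]):
        raise DomainError(f"component {component} out of range")
    return float(r.frequencies[int(np.argmax(np.abs(r.loadings[component])))])


def svm_separability(
    scores: np.ndarray,
    labels: np.ndarray | list[str],
    c_penalty: float = 1.0,
) -> SeparabilityReport:
    """Linear-kernel maximum-margin fit on the first two component scores.

    With two classes the one-versus-rest decision function reduces to a
    single binary hyperplane, which is what is fit here.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise DomainError(f"exactly 2 classes required, got {classes.size}")
    if np.any(counts < 2):
        raise DomainError("each class needs at least 2 rows")
    x = np.asarray(scores, dtype=float)[:, :2]
    svc = SVC(kernel="linear", C=c_penalty)
    svc.fit(x, labels)
    w = svc.coef_[0]
    return SeparabilityReport(
        training_accuracy=float(svc.score(x, labels)),
        margin=float(2.0 / np.linalg.norm(w)),
        n_support_vectors=int(svc.n_support_.sum()),
        hyperplane_normal=w.copy(),
        intercept=float(svc.intercept_[0]),
    )


def classify_pipeline(
    spectra: list[tuple[Spectrum, Spectrum]],
    labels: list[str] | np.ndarray,
    band: tuple[float, float] = _VALID_BAND,
    k: int = 2,
    c_penalty: float = 1.0,
    n_permutations: int = 199,
    seed: int = 0,
) -> ClassificationReport:
    """Feature matrix -> PCA -> SVM separability, with a permutation control.

    The permutation p-value is the fraction of label shuffles whose training
    accuracy reaches the observed one (add-one smoothed); a cohort with no
    class structure yields p well above 0.05 even when the SVM overfits.
    """
    if len(spectra) < 4:
        raise DomainError("at least 4 spectra required")
    fm = build_feature_matrix(spectra, labels, band)
    pca = pca_decompose(fm, k)
    svm = svm_separability(pca.scores, pca.labels, c_penalty)
    freqs = [informative_frequency(pca, i) for i in range(k)]

    perm_p = None
    perm_acc = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        accs = np.empty(n_permutations)
        for i in range(n_permutations):
            shuffled = rng.permutation(pca.labels)
            accs[i] = svm_separability(pca.scores, shuffled, c_penalty).training_accuracy
        perm_acc = accs
        perm_p = float((1 + np.sum(accs >= svm.training_accuracy)) / (n_permutations + 1))
    return ClassificationReport(
        pca=pca,
        svm=svm,
        informative_frequencies=freqs,
        permutation_p=perm_p,
        permutation_accuracies=perm_acc,
        meta={"band": band, "k": k, "C": c_penalty, "n_rows": fm.X.shape[0]},
    )
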