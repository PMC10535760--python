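"""PCA-based quality control: Hotelling T² and Q-residual outlier tests.

PCA is fitted by SVD of the mean-centered matrix.  Outlier thresholds
come in two flavours:

* ``mode="training"`` (default): the samples being tested are the ones
  the model was fitted on.  T² of a training sample follows the scaled
  beta law T² ~ (n−1)²/n · Beta(A/2, (n−A−1)/2) exactly under
  normality, so the beta quantile is used; the Q threshold applies the
  same beta tail shape at Box's moment-matched effective degrees of
  freedom h = θ1²/θ2, scale g = θ2/θ1.
* ``mode="new"``: thresholds for observations not in the training set —
  the classical F form T²_lim = A(n−1)/(n−A)·F_{1−α}(A, n−A) and Box's
  weighted chi-square g·χ²_{1−α}(h) for Q.

At moderate n the two agree closely; the training-mode thresholds keep
the nominal false-flag rate α when screening the fitted cohort itself,
which is how the tests are used here (per-group outlier screening).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PCAModel", "OutlierReport", "fit_pca", "outlier_tests"]


@dataclass
class PCAModel:
    loadings: np.ndarray          # p x A, orthonormal columns
    scores: np.ndarray            # n x A
    eigenvalues: np.ndarray       # all min(n-1, p) eigenvalues of the covariance
    mean: np.ndarray              # column means (p,)
    A: int
    variance_fractions: np.ndarray  # per retained component
    training_q: np.ndarray | None = None  # squared residual of each training sample

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


@dataclass
class OutlierReport:
    t2: np.ndarray
    q: np.ndarray | None
    t2_limit: float
    q_limit: float | None
    t2_flags: np.ndarray
    q_flags: np.ndarray | None
    alpha: float


def default_n_components(eigenvalues: np.ndarray) -> int:
    """Components with eigenvalue above the mean eigenvalue (at least 1)."""
    return max(int((eigenvalues > eigenvalues.mean()).sum()), 1)


def fit_pca(X: np.ndarray, A: int | None = None) -> PCAModel:
    """Mean-centered SVD PCA; components ordered by decreasing eigenvalue;
    sign convention: the largest-magnitude loading of each component is
    positive."""
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    if A is None:
        A = default_n_components(eig)
    if A < 1:
        raise ValueError("A must be at least 1")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    loadings = Vt[:A].T
    # sign convention
    for a in range(A):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
    scores = Xc @ loadings
    total = eig.sum()
    training_q = (Xc**2).sum(axis=1) - (scores**2).sum(axis=1)
    training_q = np.maximum(training_q, 0.0)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        eigenvalues=eig,
        mean=mean,
        A=A,
        variance_fractions=eig[:A] / total,
        training_q=training_q,
    )


def _t2_limit(n: int, A: int, alpha: float, mode: str) -> float:
    if mode == "training":
        return (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, A / 2.0, (n - A - 1) / 2.0)
    return A * (n - 1) / (n - A) * stats.f.ppf(1 - alpha, A, n - A)


def _q_limit(n: int, g: float, h: float, alpha: float, mode: str) -> float:
    if mode == "training":
        return g * (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, h / 2.0, (n - h - 1) / 2.0)
    return g * stats.chi2.ppf(1 - alpha, h)


def outlier_tests(model: PCAModel, alpha: float = 0.05, X: np.ndarray | None = None,
                  mode: str = "training") -> OutlierReport:
    """Hotelling T² and Q-residual outlier tests at significance ``alpha``.

    With ``X`` given, the statistics are computed for those samples
    (``mode="new"`` is then appropriate); otherwise the training scores
    are screened.
    """
    if mode not in ("training", "new"):
        raise ValueError("mode must be 'training' or 'new'")
    n, A = model.n_samples, model.A
    if n <= A + 1:
        raise ValueError("need n > A + 1 for the outlier thresholds")
    if X is None:
        T = model.scores
        q = model.training_q
    else:
        Xc = np.atleast_2d(np.asarray(X, float)) - model.mean
        T = Xc @ model.loadings
        recon = T @ model.loadings.T
        q = ((Xc - recon) ** 2).sum(axis=1)
    lam = model.eigenvalues[:A]
    t2 = (T**2 / lam).sum(axis=1)
    t2_limit = _t2_limit(n, A, alpha, mode)

    resid_eig = model.eigenvalues[A:]
    theta1 = resid_eig.sum()
    theta2 = (resid_eig**2).sum()
    if theta1 <= 0 or theta2 <= 0:
        warnings.warn(
            "residual eigenvalue spectrum is degenerate; Q test skipped",
            RuntimeWarning,
        )
        q = q_limit = q_flags = None
    else:
        g = theta2 / theta1
        h = theta1**2 / theta2
        q_limit = _q_limit(n, g, h, alpha, mode)
        q_flags = q > q_limit
    t2_flags = t2 > t2_limit
    return OutlierReport(
        t2=t2,
        q=q,
        t2_limit=t2_limit,
        q_limit=q_limit,
        t2_flags=t2_flags,
        q_flags=q_flags,
        alpha=alpha,
    )
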