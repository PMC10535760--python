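"""Two-block joint/unique variance decomposition.

``fit_opls_w2a`` extracts *parallel* components shared by two centered
blocks via Wold's Mode A inter-block iteration (alternating projections
u → w1 → t1 → w2 → t2 until convergence, maximizing inter-block score
covariance, deflating both blocks after each component), then per-block
*orthogonal* components: dominant principal directions of the deflated
block whose scores are orthogonalized against all parallel scores.

``fit_ocpca`` performs orthogonally constrained PCA: the block is
projected onto the orthocomplement of given constraint scores (e.g. the
parallel scores), and PCA of the remainder exposes the block's *unique*
variation; variance fractions are reported against the total variance
of the original block.

``joint_unique_summary`` assembles the percent-variance bookkeeping and
the correlation between the parallel score(s) and an external reference
component (e.g. the predictive score of another block's classifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoBlockModel",
    "OCPCAResult",
    "JointUniqueSummary",
    "fit_opls_w2a",
    "fit_ocpca",
    "joint_unique_summary",
]


@dataclass
class TwoBlockModel:
    T1: np.ndarray; W1: np.ndarray; P1: np.ndarray   # block-1 parallel
    T2: np.ndarray; W2: np.ndarray; P2: np.ndarray   # block-2 parallel
    To1: np.ndarray; Po1: np.ndarray                 # block-1 orthogonal
    To2: np.ndarray; Po2: np.ndarray                 # block-2 orthogonal
    variance_fractions: list[dict]                   # per block: parallel/orthogonal/residual
    n_iterations: list[int]

    @property
    def k_par(self) -> int:
        return self.T1.shape[1]


@dataclass
class OCPCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray   # per component, of the original block total
    n_retained: int                  # eigenvalue > mean rule (overridable upstream)


@dataclass
class JointUniqueSummary:
    n_parallel: int
    n_orthogonal: int
    n_unique: int
    pct_parallel: float
    pct_orthogonal: float
    pct_unique: float
    pct_residual: float
    reference_correlations: list[float]


def _check_centered(X: np.ndarray, name: str, tol: float = 1e-6) -> None:
    scale = np.abs(X).max() or 1.0
    if np.abs(X.mean(axis=0)).max() > tol * scale:
        raise ValueError(f"{name} must be column mean-centered")


def fit_opls_w2a(
    X1: np.ndarray,
    X2: np.ndarray,
    k_par: int,
    k_orth: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> TwoBlockModel:
    """Wold Mode A two-block PLS with post-hoc orthogonal components."""
    X1 = np.atleast_2d(np.asarray(X1, float)).copy()
    X2 = np.atleast_2d(np.asarray(X2, float)).copy()
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    _check_centered(X1, "X1")
    _check_centered(X2, "X2")
    n = X1.shape[0]
    r1 = np.linalg.matrix_rank(X1)
    r2 = np.linalg.matrix_rank(X2)
    if k_par > min(r1, r2):
        raise ValueError(f"k_par={k_par} exceeds the rank of a block ({min(r1, r2)})")
    tot1 = (X1**2).sum()
    tot2 = (X2**2).sum()
    T1 = np.empty((n, k_par)); T2 = np.empty((n, k_par))
    W1 = np.empty((X1.shape[1], k_par)); W2 = np.empty((X2.shape[1], k_par))
    P1 = np.empty_like(W1); P2 = np.empty_like(W2)
    iters = []
    R1, R2 = X1.copy(), X2.copy()
    for a in range(k_par):
        # the alternating Mode A update is power iteration on R1'R2, so
        # start at its leading singular pair; the loop then polishes the
        # fixed point and provides convergence diagnostics
        _, _, Vt0 = np.linalg.svd(R1.T @ R2, full_matrices=False)
        u = R2 @ Vt0[0]
        t1 = np.zeros(n)
        for it in range(max_iter):
            w1 = R1.T @ u
            w1 /= np.linalg.norm(w1)
            t1_new = R1 @ w1
            w2 = R2.T @ t1_new
            w2 /= np.linalg.norm(w2)
            u = R2 @ w2
            delta = np.linalg.norm(t1_new - t1) / max(np.linalg.norm(t1_new), 1e-300)
            t1 = t1_new
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"Mode A iteration for component {a + 1} did not converge in "
                f"{max_iter} iterations (last relative change {delta:.2e})"
            )
        iters.append(it + 1)
        t2 = u
        p1 = R1.T @ t1 / (t1 @ t1)
        p2 = R2.T @ t2 / (t2 @ t2)
        R1 -= np.outer(t1, p1)
        R2 -= np.outer(t2, p2)
        T1[:, a], W1[:, a], P1[:, a] = t1, w1, p1
        T2[:, a], W2[:, a], P2[:, a] = t2, w2, p2

    fractions = []
    orth = []
    for (X, R, T, tot) in ((X1, R1, T1, tot1), (X2, R2, T2, tot2)):
        # project the deflated block onto the orthocomplement of the
        # parallel score space: orthogonal scores must not correlate with
        # the parallel ones
        Qt, _ = np.linalg.qr(T)
        Rp = R - Qt @ (Qt.T @ R)
        U, s, Vt = np.linalg.svd(Rp, full_matrices=False)
        k = min(k_orth, (s > 1e-12 * s.max()).sum() if s.size else 0)
        To = U[:, :k] * s[:k]
        Po = Vt[:k].T
        par_ss = tot - (Rp**2).sum()
        orth_ss = (s[:k] ** 2).sum()
        fractions.append(
            {
                "parallel": par_ss / tot,
                "orthogonal": orth_ss / tot,
                "residual": 1.0 - (par_ss + orth_ss) / tot,
            }
        )
        orth.append((To, Po))
    return TwoBlockModel(
        T1=T1, W1=W1, P1=P1, T2=T2, W2=W2, P2=P2,
        To1=orth[0][0], Po1=orth[0][1], To2=orth[1][0], Po2=orth[1][1],
        variance_fractions=fractions, n_iterations=iters,
    )


def fit_ocpca(X: np.ndarray, constraint_scores: np.ndarray | None) -> OCPCAResult:
    """PCA of a block constrained orthogonal to given scores.

    With an empty constraint set this is plain (uncentered) PCA of the
    block, which is assumed centered.  Variance fractions are relative to
    the total variance of the original block.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    tot = (X**2).sum()
    if constraint_scores is None or (
        hasattr(constraint_scores, "size") and constraint_scores.size == 0
    ):
        Xp = X
    else:
        C = np.atleast_2d(np.asarray(constraint_scores, float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("constraint scores must have one row per sample")
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("constraint scores must be linearly independent")
        if C.shape[1] >= n:
            raise ValueError("constraints span the full sample space")
        Q, _ = np.linalg.qr(C)
        Xp = X - Q @ (Q.T @ X)
    U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
    keep = s > 1e-12 * (s.max() if s.size else 1.0)
    s = s[keep]
    scores = U[:, keep] * s
    loadings = Vt[keep].T
    eig = s**2 / max(n - 1, 1)
    fractions = s**2 / tot
    n_retained = max(int((eig > eig.mean()).sum()), 1) if eig.size else 0
    return OCPCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        variance_fractions=fractions,
        n_retained=n_retained,
    )


def joint_unique_summary(
    model: TwoBlockModel,
    ocpca: OCPCAResult,
    reference_component: np.ndarray,
    block: int = 1,
    n_unique: int | None = None,
) -> JointUniqueSummary:
    """Percent-variance bookkeeping for one block plus the correlation of
    each parallel score with a reference component."""
    T = model.T1 if block == 1 else model.T2
    frac = model.variance_fractions[block - 1]
    ref = np.asarray(reference_component, float).ravel()
    if ref.size != T.shape[0]:
        raise ValueError("reference component length mismatch")
    corrs = [float(np.corrcoef(T[:, a], ref)[0, 1]) for a in range(T.shape[1])]
    k_unique = ocpca.n_retained if n_unique is None else n_unique
    pct_unique = float(ocpca.variance_fractions[:k_unique].sum()) * 100.0
    return JointUniqueSummary(
        n_parallel=T.shape[1],
        n_orthogonal=(model.To1 if block == 1 else model.To2).shape[1],
        n_unique=k_unique,
        pct_parallel=frac["parallel"] * 100.0,
        pct_orthogonal=frac["orthogonal"] * 100.0,
        pct_unique=pct_unique,
        pct_residual=frac["residual"] * 100.0,
        reference_correlations=corrs,
    )
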