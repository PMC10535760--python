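"""PLS2C: partial least squares for two-class classification.

The classifier regresses a ±1-coded class response on the feature matrix
by NIPALS with deflation of X only, exactly the construction whose score
space is later rotated ("post-transformed") into one predictive
component t_p — the direction carrying all of the fitted response — and
A−1 response-orthogonal components.  Model quality is summarised by the
Matthews correlation coefficient (MCC) and the area under the ROC curve
(AUC), in fitting and under repeated stratified cross-validation, with
significance assessed by permutation of the class response.  Variable
relevance is measured by Variable Influence on Projection (VIP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLS2CModel",
    "PTModel",
    "CVReport",
    "fit_pls2c",
    "classify",
    "decision_scores",
    "compute_mcc",
    "compute_auc",
    "repeated_cv",
    "select_ncomp",
    "permutation_test",
    "post_transform",
    "predictive_block",
    "compute_vip",
]


@dataclass
class PLS2CModel:
    """Fitted PLS2C classifier.

    The class response is coded +1 for the positive class (sepsis) and −1
    for the negative class, then centered; the decision threshold on the
    fitted response is 0, with ties assigned to the positive class.
    """

    A: int
    W: np.ndarray            # p x A X-weights, unit-norm columns
    P: np.ndarray            # p x A X-loadings
    T: np.ndarray            # n x A X-scores, mutually orthogonal columns
    q: np.ndarray            # A   y-loadings
    b: np.ndarray            # p   regression vector
    x_mean: np.ndarray
    y_mean: float
    classes: tuple           # (positive, negative)

    def coded_y(self, labels) -> np.ndarray:
        pos, neg = self.classes
        labels = np.asarray(labels)
        y = np.where(labels == pos, 1.0, -1.0)
        unknown = ~np.isin(labels, [pos, neg])
        if unknown.any():
            raise ValueError(f"unknown class label(s): {set(labels[unknown])}")
        return y


def _code_labels(y, positive=None) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = list(dict.fromkeys(y.tolist()))  # order of appearance
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive is None:
        if "sepsis" in classes:
            positive = "sepsis"
        elif set(classes) in ({1.0, -1.0}, {1, -1}):
            positive = [c for c in classes if c > 0][0]
        else:
            positive = classes[0]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not present")
    negative = classes[0] if classes[1] == positive else classes[1]
    coded = np.where(y == positive, 1.0, -1.0)
    return coded, (positive, negative)


def fit_pls2c(X: np.ndarray, y, A: int, positive=None) -> PLS2CModel:
    """NIPALS PLS with a univariate ±1-coded response; X deflated, y not.

    ``y`` may be ±1 floats or a two-level label vector; ``positive`` names
    the class coded +1 (default: "sepsis" when present, else the first
    label encountered).
    """
    X = np.atleast_2d(np.asarray(X, float))
    coded, classes = _code_labels(y, positive)
    n, p = X.shape
    if coded.size != n:
        raise ValueError("X and y length mismatch")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    y_mean = coded.mean()
    yc = coded - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if A < 1:
        raise ValueError("A must be at least 1")
    if A > rank:
        raise ValueError(f"A={A} exceeds rank(X)={rank}")
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    Xa = Xc.copy()
    for a in range(A):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"component {a + 1}: X carries no covariance with y")
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt == 0:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        pvec = Xa.T @ t / tt
        q[a] = yc @ t / tt
        Xa -= np.outer(t, pvec)
        W[:, a], P[:, a], T[:, a] = w, pvec, t
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLS2CModel(
        A=A, W=W, P=P, T=T, q=q, b=b, x_mean=x_mean, y_mean=y_mean, classes=classes
    )


def decision_scores(model: PLS2CModel, X: np.ndarray) -> np.ndarray:
    """Continuous fitted response ŷ = (X − x̄)·b + ȳ."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.b.size:
        raise ValueError(
            f"X has {X.shape[1]} columns; model expects {model.b.size}"
        )
    return (X - model.x_mean) @ model.b + model.y_mean


def classify(model: PLS2CModel, X: np.ndarray):
    """Labels and continuous scores; ŷ ≥ 0 → positive class (ties assigned
    to the positive class)."""
    scores = decision_scores(model, X)
    pos, neg = model.classes
    labels = np.where(scores >= 0, pos, neg)
    return labels, scores


def compute_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def mcc_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC of ±1-coded truth vs ±1-coded (or thresholded) predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true > 0) & (y_pred > 0)).sum())
    tn = int(((y_true < 0) & (y_pred < 0)).sum())
    fp = int(((y_true < 0) & (y_pred > 0)).sum())
    fn = int(((y_true > 0) & (y_pred < 0)).sum())
    return compute_mcc(tp, fp, tn, fn)


def compute_auc(scores: np.ndarray, labels) -> float:
    """AUC via the Mann–Whitney U statistic; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if labels.dtype.kind not in "fiub":
        raise ValueError("labels must be ±1 (or boolean) coded for compute_auc")
    posmask = labels > 0
    neg = scores[~posmask]
    pos = scores[posmask]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[posmask].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..folds-1) balanced within each class."""
    assign = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < folds:
            raise ValueError(
                f"class {cls} has {idx.size} samples, fewer than {folds} folds"
            )
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _fit_path_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, A_max: int
) -> np.ndarray:
    """Out-of-fold continuous predictions for every component count 1..A_max.

    One NIPALS pass; returns an (n_te, A_max) matrix of ŷ.  Centering is
    re-estimated on the training rows.
    """
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    Xa = Xtr - x_mean
    yc = ytr - y_mean
    Xt = Xte - x_mean
    n_te = Xte.shape[0]
    out = np.empty((n_te, A_max))
    p = Xtr.shape[1]
    W = np.empty((p, A_max))
    P = np.empty((p, A_max))
    q = np.empty(A_max)
    for a in range(A_max):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            # no covariance left: predictions stop improving; repeat previous
            out[:, a:] = (out[:, a - 1 : a] if a else y_mean)
            return out
        w /= nw
        t = Xa @ w
        tt = t @ t
        pvec = Xa.T @ t / tt
        q[a] = yc @ t / tt
        Xa = Xa - np.outer(t, pvec)
        W[:, a], P[:, a] = w, pvec
        b = W[:, : a + 1] @ np.linalg.solve(P[:, : a + 1].T @ W[:, : a + 1], q[: a + 1])
        out[:, a] = Xt @ b + y_mean
    return out


@dataclass
class CVReport:
    """Repeated stratified cross-validation summary.

    ``mcc_cv``/``auc_cv`` are (repeats x A_max): per repeat, out-of-fold
    predictions are pooled into one confusion matrix / one score set.
    """

    mcc_cv: np.ndarray
    auc_cv: np.ndarray
    repeats: int
    folds: int
    seed: int
    summary: str = "mean"
    chosen_A: int | None = None
    p_values: dict = field(default_factory=dict)

    def summarize(self, which: str = "mcc", how: str | None = None) -> np.ndarray:
        arr = self.mcc_cv if which == "mcc" else self.auc_cv
        how = how or self.summary
        return arr.mean(axis=0) if how == "mean" else np.median(arr, axis=0)


def repeated_cv(
    X: np.ndarray,
    y,
    A_max: int,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    positive=None,
) -> CVReport:
    """20-repeated 5-fold stratified CV by default; per repeat the
    out-of-fold predictions are pooled into one MCCcv and one AUCcv."""
    X = np.atleast_2d(np.asarray(X, float))
    coded, _classes = _code_labels(y, positive)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mcc = np.empty((repeats, A_max))
    auc = np.empty((repeats, A_max))
    for r in range(repeats):
        assign = _stratified_folds(coded, folds, rng)
        pred = np.empty((coded.size, A_max))
        for k in range(folds):
            te = assign == k
            pred[te] = _fit_path_predict(X[~te], coded[~te], X[te], A_max)
        for a in range(A_max):
            mcc[r, a] = mcc_from_predictions(coded, np.where(pred[:, a] >= 0, 1, -1))
            auc[r, a] = compute_auc(pred[:, a], coded)
    return CVReport(mcc_cv=mcc, auc_cv=auc, repeats=repeats, folds=folds, seed=seed)


def select_ncomp(report: CVReport, which: str = "mcc") -> int:
    """First local maximum of the summarized CV curve; plateaus resolve to
    the smaller A; a curve still rising at A_max selects A_max."""
    if report.mcc_cv.size == 0:
        raise ValueError("empty CV report")
    curve = report.summarize(which)
    for a in range(curve.size):
        rising = a == 0 or curve[a] > curve[a - 1]
        # >= on the right resolves plateaus to the smaller A; the last
        # point of a still-rising curve counts as a maximum
        peak = a == curve.size - 1 or curve[a] >= curve[a + 1]
        if rising and peak:
            return a + 1
    return int(curve.size)


def _observed_statistic(
    X: np.ndarray,
    coded: np.ndarray,
    statistic: str,
    A: int,
    repeats: int,
    folds: int,
    seed: int,
) -> float:
    if statistic in ("mcc", "auc"):
        model = fit_pls2c(X, coded, A, positive=1.0)
        yhat = decision_scores(model, X)
        if statistic == "mcc":
            return mcc_from_predictions(coded, np.where(yhat >= 0, 1, -1))
        return compute_auc(yhat, coded)
    if statistic in ("mcc_cv", "auc_cv"):
        rep = repeated_cv(X, coded, A, repeats=repeats, folds=folds, seed=seed, positive=1.0)
        return float(rep.summarize("mcc" if statistic == "mcc_cv" else "auc")[A - 1])
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    X: np.ndarray,
    y,
    statistic: str,
    A: int,
    n_perm: int = 1000,
    seed: int = 0,
    repeats: int = 20,
    folds: int = 5,
    positive=None,
) -> float:
    """Permutation test on the class response.

    ``statistic`` is one of "mcc", "auc" (in fitting) or "mcc_cv",
    "auc_cv" (cross-validated; the permuted analyses reuse the same fold
    seed as the observed one so the null matches the design).
    p = (1 + #{perm ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    X = np.atleast_2d(np.asarray(X, float))
    coded, _cls = _code_labels(y, positive)
    obs = _observed_statistic(X, coded, statistic, A, repeats, folds, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(coded)
        val = _observed_statistic(X, perm, statistic, A, repeats, folds, seed)
        if val >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class PTModel:
    """Post-transformed PLS2C model: one predictive score t_p carrying all
    of the fitted response, plus A−1 response-orthogonal scores."""

    t_p: np.ndarray          # n, unit norm
    p_p: np.ndarray          # p, predictive loading
    w_p: np.ndarray          # p, predictive weight direction
    T_o: np.ndarray          # n x (A-1), orthonormal, orthogonal to ŷ
    model: PLS2CModel
    yhat: np.ndarray         # fitted values (unchanged by the rotation)


def post_transform(model: PLS2CModel) -> PTModel:
    """Rotate the score space so the fitted response lives on a single
    predictive component; the remaining A−1 components are orthogonal to
    the fitted response.  Fitted values are unchanged."""
    if model.A < 1:
        raise ValueError("model must have at least one component")
    T, q = model.T, model.q
    yhat_c = T @ q
    norm = np.linalg.norm(yhat_c)
    if norm == 0:
        raise ValueError("fitted response is identically zero; nothing predictive")
    t_p = yhat_c / norm
    # orthonormal completion of span(T) orthogonal to t_p
    if model.A > 1:
        proj = T - np.outer(t_p, t_p @ T)
        Qm, R = np.linalg.qr(proj)
        keep = np.abs(np.diag(R)) > 1e-12 * max(1.0, np.abs(np.diag(R)).max())
        T_o = Qm[:, keep][:, : model.A - 1]
    else:
        T_o = np.empty((T.shape[0], 0))
    # Xc in the score space: loadings of t_p by regression of Xc on t_p;
    # Xc itself equals T P' + residual, and t_p lies in span(T)
    # p_p = (T P')' t_p  since residual is orthogonal to span(T)
    p_p = model.P @ (T.T @ t_p)
    # t_p' t_p = 1, so regression coefficient is just the projection above
    w_p = model.W @ q
    nw = np.linalg.norm(w_p)
    if nw > 0:
        w_p = w_p / nw
    yhat = yhat_c + model.y_mean
    return PTModel(t_p=t_p, p_p=p_p, w_p=w_p, T_o=T_o, model=model, yhat=yhat)


def predictive_block(pt: PTModel) -> np.ndarray:
    """Rank-1 predictive reconstruction t_p p_p' on the centered scale —
    the part of X that carries the between-group separation, usable as the
    second block of a two-block decomposition."""
    return np.outer(pt.t_p, pt.p_p)


def compute_vip(model: PLS2CModel) -> np.ndarray:
    """Variable Influence on Projection.

    VIP_j = sqrt( p * Σ_a q_a² t_a't_a (w_ja/||w_a||)² / Σ_a q_a² t_a't_a );
    mean square over variables is 1 by construction.
    """
    p = model.W.shape[0]
    tt = (model.T**2).sum(axis=0)
    ssy = model.q**2 * tt
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wnorm2 = (model.W**2).sum(axis=0)
    contrib = (model.W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / total)
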