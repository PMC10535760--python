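"""VIP-based stability selection over PLS2C sub-models.

Binary matrix sampling draws Bernoulli inclusion masks over both the
observations (probability 0.7) and the predictors (probability 0.5); 500
sub-training sets are extracted and a PLS2C sub-model fitted on each.  A
sampled predictor counts as *selected* in a sub-model when its VIP
exceeds 1 (the conventional relevance cut).  Each predictor's selection
frequency is compared against an empirical null obtained by rerunning
the whole procedure with a permuted class response on the same masks;
predictors whose frequency exceeds the (1−α) quantile of the null
frequencies form the relevant set.  Samples left out of a sub-model
receive an out-of-bag prediction, aggregated per sample by the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pls

__all__ = [
    "StabilityConfig",
    "StabilityReport",
    "binary_matrix_sampling",
    "stability_select",
    "oob_mcc",
]


@dataclass
class StabilityConfig:
    p_obs: float = 0.7
    p_var: float = 0.5
    n_sub: int = 500
    vip_threshold: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.p_obs < 1 and 0 < self.p_var <= 1):
            raise ValueError("inclusion probabilities must lie in (0, 1]")
        if self.n_sub < 1:
            raise ValueError("n_sub must be at least 1")


@dataclass
class StabilityReport:
    sampled: np.ndarray            # per variable: times included in a mask
    selected: np.ndarray           # per variable: times VIP > threshold
    frequency: np.ndarray          # selected / sampled
    null_frequency: np.ndarray     # frequencies from the permuted-y rerun
    null_threshold: float          # (1 - alpha) quantile of null frequencies
    relevant: np.ndarray           # indices of relevant variables
    oob_score: np.ndarray          # per-sample median out-of-bag ŷ
    oob_counts: np.ndarray         # per-sample number of OOB predictions
    oob_mcc: float
    config: StabilityConfig
    classes: tuple


def binary_matrix_sampling(
    labels, p: int, config: StabilityConfig, rng: np.random.Generator | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent Bernoulli masks over observations and variables.

    A draw is rejected and redrawn when either class retains fewer than 2
    observations or fewer than 2 variables are included.
    """
    coded, _cls = pls._code_labels(labels)
    n = coded.size
    if n < 2 or p < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    for cls in (1.0, -1.0):
        if (coded == cls).sum() < 2:
            raise ValueError(
                "each class needs at least 2 members for binary matrix sampling"
            )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    masks = []
    for _ in range(config.n_sub):
        for _try in range(config.max_redraws):
            obs = rng.random(n) < config.p_obs
            var = rng.random(p) < config.p_var
            ok = (
                var.sum() >= 2
                and (obs & (coded > 0)).sum() >= 2
                and (obs & (coded < 0)).sum() >= 2
            )
            if ok:
                masks.append((obs, var))
                break
        else:
            raise RuntimeError("could not draw an admissible mask")
    return masks


def stability_select(
    X: np.ndarray, y, A: int, config: StabilityConfig | None = None, positive=None
) -> StabilityReport:
    """Run the full stability-selection procedure; see the module docstring."""
    config = config or StabilityConfig()
    X = np.atleast_2d(np.asarray(X, float))
    coded, classes = pls._code_labels(y, positive)
    n, p = X.shape
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    masks = binary_matrix_sampling(coded, p, config, rng)
    y_perm = rng.permutation(coded)

    def _run(y_used: np.ndarray, collect_oob: bool):
        sampled = np.zeros(p, dtype=int)
        selected = np.zeros(p, dtype=int)
        oob_lists: list[list[float]] = [[] for _ in range(n)] if collect_oob else []
        failures = 0
        for obs, var in masks:
            Xs = X[np.ix_(obs, var)]
            ys = y_used[obs]
            a_cap = min(A, min(obs.sum() - 1, var.sum()))
            if a_cap < A:
                failures += 1
            try:
                model = pls.fit_pls2c(Xs, ys, a_cap, positive=1.0)
            except ValueError:
                failures += 1
                continue
            vip = pls.compute_vip(model)
            sampled[var] += 1
            selected[np.nonzero(var)[0][vip > config.vip_threshold]] += 1
            if collect_oob:
                out = ~obs
                if out.any():
                    scores = pls.decision_scores(model, X[np.ix_(out, var)])
                    for i, s in zip(np.nonzero(out)[0], scores):
                        oob_lists[i].append(float(s))
        if failures > 0.1 * len(masks):
            raise ValueError(
                f"requested A={A} unachievable in {failures}/{len(masks)} sub-models; "
                "use a smaller A"
            )
        with np.errstate(invalid="ignore"):
            freq = np.where(sampled > 0, selected / np.maximum(sampled, 1), 0.0)
        return freq, sampled, selected, oob_lists

    freq, sampled, selected, oob_lists = _run(coded, collect_oob=True)
    null_freq, _, _, _ = _run(y_perm, collect_oob=False)
    threshold = float(np.quantile(null_freq, 1.0 - config.alpha))
    relevant = np.nonzero(freq > threshold)[0]

    oob_counts = np.array([len(v) for v in oob_lists])
    if (oob_counts == 0).any():
        missing = int(np.nonzero(oob_counts == 0)[0][0])
        raise RuntimeError(
            f"sample {missing} was never out-of-bag; increase n_sub"
        )
    oob_score = np.array([np.median(v) for v in oob_lists])
    mcc = pls.mcc_from_predictions(coded, np.where(oob_score >= 0, 1, -1))
    return StabilityReport(
        sampled=sampled,
        selected=selected,
        frequency=freq,
        null_frequency=null_freq,
        null_threshold=threshold,
        relevant=relevant,
        oob_score=oob_score,
        oob_counts=oob_counts,
        oob_mcc=mcc,
        config=config,
        classes=classes,
    )


def oob_mcc(report: StabilityReport, y) -> float:
    """MCC of the thresholded per-sample median out-of-bag predictions."""
    coded, _cls = pls._code_labels(y)
    if (report.oob_counts == 0).any():
        raise ValueError("a sample has no out-of-bag prediction")
    return pls.mcc_from_predictions(coded, np.where(report.oob_score >= 0, 1, -1))
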