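"""Synthetic urinary NMR spectra and MS-like feature tables.

The generator emulates the statistical structure a low-field (~80 MHz)
urinary fingerprinting study presents to the downstream analysis:

* two small groups (sepsis n=8, control n=10 by default);
* a shared ppm axis from 0.05 to 9.00 ppm on a ~0.001 ppm grid;
* Lorentzian (absorption-mode) metabolite signals with log-normal
  between-subject concentration variation;
* a multiplicative per-sample dilution factor (the structure PQN removes);
* per-signal chemical-shift jitter (the structure peak alignment removes);
* a subset of signals whose concentration differs between groups by a
  multiplicative fold change (≈0.8–1.5, typical of urinary cohorts);
* MS-like feature matrices that share a latent group factor with the
  spectra, so joint/unique two-block decompositions can be validated
  against a known construction.

Every draw is reproducible from a single seed: the seed is expanded into
independent substreams (dilution, concentration, jitter, noise, baseline)
so regenerating one ingredient does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io import SpectraCollection

__all__ = [
    "SignalSpec",
    "SimConfig",
    "GroundTruth",
    "lorentzian",
    "lorentzian_area",
    "default_signals",
    "generate_spectra",
    "generate_feature_table",
    "generate_shared_blocks",
]

SEPSIS = "sepsis"
CONTROL = "control"


@dataclass(frozen=True)
class SignalSpec:
    """One metabolite signal: a (possibly multiplet) Lorentzian resonance.

    ``group_fold_change`` is the multiplicative factor applied to the
    sepsis-group mean concentration, i.e. the expected FC[sepsis/control]
    of the signal's integral after dilution correction.
    """

    center_ppm: float
    line_width: float = 0.010  # Lorentzian half width at half maximum, ppm
    multiplet_offsets: tuple[float, ...] = (0.0,)
    base_concentration: float = 1.0
    cv: float = 0.25  # between-subject coefficient of variation
    group_fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.line_width <= 0:
            raise ValueError("line_width must be positive")
        if self.group_fold_change <= 0:
            raise ValueError("group_fold_change must be positive")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")

    @property
    def informative(self) -> bool:
        return self.group_fold_change != 1.0


def default_signals() -> list[SignalSpec]:
    """A urine-like signal panel.

    Positions loosely follow common urinary metabolites (lactate/alanine
    doublets in the aliphatic region, citrate AB pattern, creatinine
    singlets, carbohydrate envelope, urea, hippurate aromatics, formate).
    At 80 MHz a 7 Hz scalar coupling spans 0.0875 ppm, so doublet line
    offsets are ±0.0437 ppm.  Fold changes of the informative signals sit
    in the 0.8–1.5 range typical of the urinary sepsis signature.
    """
    j2 = 7.0 / 80.112 / 2.0  # half of a 7 Hz doublet splitting, in ppm
    return [
        SignalSpec(1.33, 0.010, (-j2, +j2), 1.00, 0.25, 1.45),   # lactate CH3
        SignalSpec(1.48, 0.010, (-j2, +j2), 0.60, 0.25, 1.49),   # alanine CH3
        SignalSpec(1.92, 0.010, (0.0,), 0.50, 0.30, 1.00),       # acetate
        SignalSpec(2.61, 0.012, (-0.06, +0.06), 0.80, 0.30, 1.00),  # citrate
        SignalSpec(3.05, 0.010, (0.0,), 1.50, 0.20, 0.88),       # creatinine CH3
        SignalSpec(3.42, 0.014, (0.0,), 0.90, 0.25, 0.88),       # sugars
        SignalSpec(3.70, 0.014, (0.0,), 0.80, 0.25, 0.97),       # sugars
        SignalSpec(4.06, 0.010, (0.0,), 1.20, 0.20, 1.11),       # creatinine CH2
        SignalSpec(5.60, 0.025, (0.0,), 1.60, 0.30, 1.46),       # urea (broad)
        SignalSpec(7.56, 0.012, (-j2, +j2), 0.50, 0.30, 1.36),   # hippurate m
        SignalSpec(7.83, 0.012, (-j2, +j2), 0.45, 0.30, 1.52),   # hippurate d
        SignalSpec(8.46, 0.010, (0.0,), 0.25, 0.30, 1.00),       # formate
    ]


@dataclass
class SimConfig:
    """Configuration of the spectral simulator. Defaults mirror the study
    conditions: 8 sepsis vs 10 control samples, axis 0.05–9.00 ppm at a
    ~0.001 ppm grid."""

    n_group1: int = 8   # sepsis
    n_group2: int = 10  # controls
    ppm_min: float = 0.05
    ppm_max: float = 9.00
    n_points: int = 8951
    signals: list[SignalSpec] = field(default_factory=default_signals)
    dilution_range: tuple[float, float] = (0.5, 2.0)
    jitter_sd: float = 0.003  # ppm, per signal per sample
    noise_sd: float = 0.004
    baseline_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be smaller than ppm_max")
        lo, hi = self.dilution_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("dilution_range bounds must be positive with lo <= hi")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not self.signals:
            raise ValueError("signal list must not be empty")
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("group sizes must be positive")


@dataclass
class GroundTruth:
    """Record of every latent quantity used to build a synthetic dataset."""

    dilution: np.ndarray            # (n,)
    concentrations: np.ndarray      # (n, n_signals) realized, incl. fold change
    shifts: np.ndarray              # (n, n_signals) realized jitter, ppm
    informative: np.ndarray         # indices of informative signals
    group_labels: list[str]
    latent: np.ndarray | None = None  # shared group factor of feature tables

    def to_json(self, path) -> None:
        payload = {
            "dilution": self.dilution.tolist(),
            "concentrations": self.concentrations.tolist(),
            "shifts": self.shifts.tolist(),
            "informative": np.asarray(self.informative).tolist(),
            "group_labels": list(self.group_labels),
            "latent": None if self.latent is None else self.latent.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            dilution=np.asarray(d["dilution"], float),
            concentrations=np.asarray(d["concentrations"], float),
            shifts=np.asarray(d["shifts"], float),
            informative=np.asarray(d["informative"], int),
            group_labels=list(d["group_labels"]),
            latent=None if d["latent"] is None else np.asarray(d["latent"], float),
        )


def lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Height-normalised Lorentzian: value 1 at ``center``, HWHM ``hwhm``."""
    return hwhm**2 / ((x - center) ** 2 + hwhm**2)


def lorentzian_area(hwhm: float, lo: float = -np.inf, hi: float = np.inf,
                    center: float = 0.0) -> float:
    """Analytic integral of the height-normalised Lorentzian over [lo, hi].

    The full-line area is pi * hwhm.
    """
    return hwhm * (np.arctan2(hi - center, hwhm) - np.arctan2(lo - center, hwhm))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_spectra(config: SimConfig) -> tuple[SpectraCollection, GroundTruth]:
    """Simulate a two-group collection of 1D spectra.

    intensity_i(x) = dilution_i * sum_s conc_is * L_s(x; jittered centers)
                     + baseline_i(x) + noise,

    where L_s spreads the signal's unit height over its multiplet lines and
    conc_is is log-normal with mean ``base_concentration`` (times the fold
    change for sepsis samples of informative signals).
    """
    cfg = config
    n = cfg.n_group1 + cfg.n_group2
    n_sig = len(cfg.signals)
    ppm = np.linspace(cfg.ppm_min, cfg.ppm_max, cfg.n_points)
    labels = [SEPSIS] * cfg.n_group1 + [CONTROL] * cfg.n_group2
    sample_ids = [f"SEP{i+1:02d}" for i in range(cfg.n_group1)] + [
        f"CTR{i+1:02d}" for i in range(cfg.n_group2)
    ]

    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_dil = np.random.default_rng(streams[0])
    rng_conc = np.random.default_rng(streams[1])
    rng_jit = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    rng_base = np.random.default_rng(streams[4])

    lo, hi = cfg.dilution_range
    # log-uniform: symmetric on the multiplicative scale, as urine dilution is
    dilution = np.exp(rng_dil.uniform(np.log(lo), np.log(hi), size=n))

    conc = np.empty((n, n_sig))
    for s, sig in enumerate(cfg.signals):
        mu, sigma = _lognormal_params(sig.base_concentration, sig.cv)
        draw = rng_conc.lognormal(mu, sigma, size=n)
        if sig.informative:
            draw[: cfg.n_group1] *= sig.group_fold_change
        conc[:, s] = draw

    shifts = rng_jit.normal(0.0, cfg.jitter_sd, size=(n, n_sig)) \
        if cfg.jitter_sd > 0 else np.zeros((n, n_sig))

    intensities = np.zeros((n, cfg.n_points))
    for i in range(n):
        y = np.zeros(cfg.n_points)
        for s, sig in enumerate(cfg.signals):
            weight = 1.0 / len(sig.multiplet_offsets)
            for off in sig.multiplet_offsets:
                y += conc[i, s] * weight * lorentzian(
                    ppm, sig.center_ppm + off + shifts[i, s], sig.line_width
                )
        y *= dilution[i]
        if cfg.baseline_amplitude > 0:
            phase = rng_base.uniform(0, 2 * np.pi, size=2)
            u = (ppm - cfg.ppm_min) / (cfg.ppm_max - cfg.ppm_min)
            y += cfg.baseline_amplitude * (
                np.sin(2 * np.pi * u + phase[0]) + 0.5 * np.sin(4 * np.pi * u + phase[1])
            )
        if cfg.noise_sd > 0:
            y += rng_noise.normal(0.0, cfg.noise_sd, size=cfg.n_points)
        intensities[i] = y

    collection = SpectraCollection(
        ppm=ppm, intensities=intensities, sample_ids=sample_ids, group_labels=labels
    )
    informative = np.array(
        [s for s, sig in enumerate(cfg.signals) if sig.informative], dtype=int
    )
    truth = GroundTruth(
        dilution=dilution,
        concentrations=conc,
        shifts=shifts,
        informative=informative,
        group_labels=labels,
    )
    return collection, truth


def generate_feature_table(
    n1: int,
    n2: int,
    p: int,
    n_informative: int,
    effect_size: float,
    latent_share: float = 0.5,
    seed: int = 0,
    latent: np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """MS-like feature matrix: ``n_informative`` columns separate the groups
    by ``effect_size`` within-group standard deviations, and ``latent_share``
    of each informative column's variance is carried by one shared latent
    factor (the same factor can be passed to a second block for two-block
    recovery experiments)."""
    if p < 1:
        raise ValueError("p must be at least 1")
    if n_informative > p:
        raise ValueError("n_informative cannot exceed p")
    if not 0.0 <= latent_share <= 1.0:
        raise ValueError("latent_share must be in [0, 1]")
    n = n1 + n2
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = np.concatenate([np.ones(n1), -np.ones(n2)])  # +1 = sepsis
    if latent is None:
        if latent_share > 0:
            delta = effect_size / (2.0 * np.sqrt(latent_share))
        else:
            delta = 0.0
        latent = delta * g + rng.standard_normal(n)

    X = rng.standard_normal((n, p))
    idx = np.arange(n_informative)
    if latent_share > 0:
        X[:, idx] = (
            np.sqrt(latent_share) * latent[:, None]
            + np.sqrt(1.0 - latent_share) * X[:, idx]
        )
    else:
        X[:, idx] += (effect_size / 2.0) * g[:, None]
    labels = [SEPSIS] * n1 + [CONTROL] * n2
    truth = GroundTruth(
        dilution=np.ones(n),
        concentrations=np.empty((n, 0)),
        shifts=np.empty((n, 0)),
        informative=idx,
        group_labels=labels,
        latent=np.asarray(latent, float),
    )
    return X, truth


def generate_shared_blocks(
    n1: int,
    n2: int,
    p1: int,
    p2: int,
    shared_share: float = 0.35,
    unique_share: float = 0.35,
    group_sep: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two centered blocks sharing one latent factor.

    X_k = sqrt(shared) z a_k' + sqrt(unique) f_k b_k' + sqrt(noise) E_k,
    each term scaled to unit expected Frobenius norm, so the nominal
    variance shares are (shared_share, unique_share, 1-both).  The returned
    dict carries the latent factor and the *realized* per-block variance
    fractions of each term, for recovery tests.
    """
    if shared_share < 0 or unique_share < 0 or shared_share + unique_share > 1:
        raise ValueError("variance shares must be non-negative and sum to <= 1")
    n = n1 + n2
    noise_share = 1.0 - shared_share - unique_share
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = np.concatenate([np.ones(n1), -np.ones(n2)])
    z = group_sep / 2.0 * g + rng.standard_normal(n)
    z = (z - z.mean()) / z.std()

    out = {"latent": z, "fractions": []}
    blocks = []
    for p in (p1, p2):
        a = rng.standard_normal(p)
        a /= np.linalg.norm(a)
        b = rng.standard_normal(p)
        b /= np.linalg.norm(b)
        f = rng.standard_normal(n)
        f -= f @ z / (z @ z) * z  # unique factor orthogonal to the shared one
        f = (f - f.mean()) / f.std()
        E = rng.standard_normal((n, p)) / np.sqrt(p)
        shared = np.sqrt(shared_share) * np.outer(z, a)
        unique = np.sqrt(unique_share) * np.outer(f, b)
        noise = np.sqrt(noise_share) * E
        X = shared + unique + noise
        X = X - X.mean(axis=0)
        tot = (X**2).sum()
        out["fractions"].append(
            {
                "shared": (shared**2).sum() / tot,
                "unique": (unique**2).sum() / tot,
                "noise": (noise**2).sum() / tot,
            }
        )
        blocks.append(X)
    out["group_labels"] = [SEPSIS] * n1 + [CONTROL] * n2
    return blocks[0], blocks[1], out
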