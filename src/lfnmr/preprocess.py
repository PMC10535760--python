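"""Spectral preprocessing: CWT peak picking, CluPA-style segment-wise
alignment, region exclusion, intelligent bucketing and probabilistic
quotient normalization (PQN); plus the generic feature-table path
(log-transform / mean-centering) used for MS-like matrices.

The alignment follows the cluster-based peak alignment (CluPA) idea:
spectra are aligned to a reference spectrum by shifting whole segments,
where segments are found by hierarchically splitting the pooled
reference+target peak list at its largest gaps; each segment's shift is
the lag maximizing the FFT cross-correlation with the reference, and the
procedure recurses into the sub-segments.  Points vacated at segment
edges are filled by repeating the boundary value, which avoids creating
artificial minima at segment joins.

Intelligent bucketing places bucket boundaries at local minima of the
average spectrum by recursively splitting each interval at its deepest
interior minimum, subject to a minimum bucket width (default 0.04 ppm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .io import BucketTable, SpectraCollection

__all__ = [
    "PeakList",
    "AlignmentResult",
    "NormalizationRecord",
    "detect_peaks",
    "select_reference",
    "align_clupa",
    "align_spectra",
    "exclude_regions",
    "intelligent_bucket",
    "pqn_normalize",
    "prep_feature_table",
    "DEFAULT_CWT_SCALES",
    "WATER_REGION",
]

#: CWT scales (ppm) used for ridge-based peak picking.
DEFAULT_CWT_SCALES: tuple[float, ...] = tuple(np.geomspace(0.002, 0.05, 8))

#: Residual water resonance region excluded from urinary spectra (ppm).
WATER_REGION: tuple[float, float] = (4.50, 5.25)


@dataclass
class PeakList:
    """Peaks of one spectrum: positions (ppm), heights, half-width scales
    (ppm) and signal-to-noise ratios, sorted by position."""

    positions: np.ndarray
    heights: np.ndarray
    scales: np.ndarray
    snr: np.ndarray

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class AlignmentResult:
    collection: SpectraCollection
    #: per sample: list of (lo_ppm, hi_ppm, shift_ppm) applied segment shifts
    shifts: list[list[tuple[float, float, float]]]
    reference: int


@dataclass
class NormalizationRecord:
    """Per-sample normalization factors estimated by PQN.

    ``dilution_factor = total_factor * quotient`` is the overall estimated
    multiplicative dilution of each sample relative to the cohort.
    """

    quotient: np.ndarray       # median-quotient factor f_i
    total_factor: np.ndarray   # integral-normalization factor t_i / mean(t)
    reference: np.ndarray      # reference spectrum/profile used

    @property
    def dilution_factor(self) -> np.ndarray:
        return self.quotient * self.total_factor


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based)."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _half_width(y: np.ndarray, idx: int, step: float) -> float:
    """Empirical half width at half maximum around a peak apex, in ppm."""
    h = y[idx] / 2.0
    left = idx
    while left > 0 and y[left] > h:
        left -= 1
    right = idx
    while right < y.size - 1 and y[right] > h:
        right += 1
    return max((right - left) / 2.0 * step, step)


def detect_peaks(
    collection: SpectraCollection,
    scales: tuple[float, ...] = DEFAULT_CWT_SCALES,
    snr_min: float = 3.0,
) -> list[PeakList]:
    """Mexican-hat CWT ridge peak detection, one PeakList per spectrum."""
    if len(scales) == 0:
        raise ValueError("scale list must not be empty")
    if collection.n_points < 32:
        raise ValueError("need at least 32 points per spectrum for CWT detection")
    step = collection.step
    widths = np.unique(np.clip(np.round(np.asarray(scales) / step), 1, None)).astype(int)
    out: list[PeakList] = []
    w_ref = max(2, int(widths.min()))
    for i in range(collection.n_samples):
        y = collection.intensities[i]
        idx = _signal.find_peaks_cwt(y, widths, min_snr=snr_min)
        idx = np.asarray(idx, dtype=int)
        if idx.size:
            # snap each ridge position to the local apex and drop ridge
            # artifacts that sit on a monotone slope (common at broad
            # scales near line tails and spectrum edges)
            refined = []
            for j in idx:
                lo = max(j - w_ref, 0)
                hi = min(j + w_ref + 1, y.size)
                k = lo + int(np.argmax(y[lo:hi]))
                if k in (lo, hi - 1):
                    continue  # apex at window edge: monotone slope, not a peak
                if y[k] < y[k - 1] or y[k] < y[k + 1]:
                    continue
                refined.append(k)
            idx = np.unique(refined).astype(int)
        if idx.size:
            sigma = _noise_sigma(y)
            heights = y[idx]
            snr = heights / sigma if sigma > 0 else np.full(idx.size, np.inf)
            keep = snr >= snr_min
            idx, heights, snr = idx[keep], heights[keep], snr[keep]
        if idx.size == 0:
            out.append(
                PeakList(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
            )
            continue
        order = np.argsort(idx)
        idx, heights, snr = idx[order], heights[order], snr[order]
        hw = np.array([_half_width(y, j, step) for j in idx])
        out.append(PeakList(collection.ppm[idx], heights, hw, snr))
    return out


def _asym_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean distance from each peak of ``a`` to its nearest peak of ``b``."""
    j = np.searchsorted(b, a)
    j0 = np.clip(j - 1, 0, b.size - 1)
    j1 = np.clip(j, 0, b.size - 1)
    return float(np.minimum(np.abs(a - b[j0]), np.abs(a - b[j1])).mean())


def select_reference(peaklists: list[PeakList]) -> int:
    """Index of the spectrum minimizing the summed symmetric nearest-peak
    distance to all others; ties break to the lowest index."""
    m = len(peaklists)
    if m < 2:
        raise ValueError("need at least 2 spectra to select a reference")
    for i, pl in enumerate(peaklists):
        if len(pl) == 0:
            raise ValueError(f"spectrum {i} has an empty peak list")
    pos = [np.sort(pl.positions) for pl in peaklists]
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = _asym_distance(pos[i], pos[j]) + _asym_distance(pos[j], pos[i])
    return int(np.argmin(d.sum(axis=1)))


def _best_lag(ref: np.ndarray, tgt: np.ndarray, max_lag: int) -> int:
    """Lag maximizing cross-correlation; shifting ``tgt`` right by the
    returned lag best matches ``ref``."""
    n = ref.size
    max_lag = min(max_lag, n - 1)
    c = _signal.correlate(ref, tgt, mode="full", method="fft")
    lags = np.arange(-(n - 1), n)
    sel = np.abs(lags) <= max_lag
    return int(lags[sel][np.argmax(c[sel])])


def _shift_segment(seg: np.ndarray, lag: int) -> np.ndarray:
    """Shift right by ``lag`` points (left if negative); vacated points are
    filled by repeating the boundary value."""
    if lag == 0:
        return seg
    out = np.empty_like(seg)
    if lag > 0:
        out[lag:] = seg[:-lag]
        out[:lag] = seg[0]
    else:
        out[:lag] = seg[-lag:]
        out[lag:] = seg[-1]
    return out


def _align_recursive(
    ref_y: np.ndarray,
    tgt_y: np.ndarray,
    lo: int,
    hi: int,
    ref_pk: np.ndarray,
    tgt_pk: np.ndarray,
    max_lag: int,
    ppm: np.ndarray,
    records: list,
    min_seg: int,
) -> np.ndarray:
    """Align tgt_y[lo:hi] to ref_y[lo:hi] in place (returns updated target
    peak indices)."""
    if hi - lo < min_seg:
        return tgt_pk
    in_ref = ref_pk[(ref_pk >= lo) & (ref_pk < hi)]
    in_tgt_mask = (tgt_pk >= lo) & (tgt_pk < hi)
    if in_ref.size == 0 or not in_tgt_mask.any():
        return tgt_pk
    lag = _best_lag(ref_y[lo:hi], tgt_y[lo:hi], max_lag)
    if lag != 0:
        tgt_y[lo:hi] = _shift_segment(tgt_y[lo:hi], lag)
        tgt_pk = tgt_pk.copy()
        tgt_pk[in_tgt_mask] = np.clip(tgt_pk[in_tgt_mask] + lag, lo, hi - 1)
        records.append((float(ppm[lo]), float(ppm[hi - 1]), lag))
    pooled = np.sort(np.concatenate([in_ref, tgt_pk[(tgt_pk >= lo) & (tgt_pk < hi)]]))
    if pooled.size < 2:
        return tgt_pk
    gaps = np.diff(pooled)
    k = int(np.argmax(gaps))
    # splitting inside a dense cluster would cut through a peak; require a
    # gap at least as wide as the minimum segment
    if gaps[k] < min_seg:
        return tgt_pk
    mid = int((pooled[k] + pooled[k + 1]) // 2)
    if mid - lo >= min_seg and hi - mid >= min_seg:
        tgt_pk = _align_recursive(
            ref_y, tgt_y, lo, mid, ref_pk, tgt_pk, max_lag, ppm, records, min_seg
        )
        tgt_pk = _align_recursive(
            ref_y, tgt_y, mid, hi, ref_pk, tgt_pk, max_lag, ppm, records, min_seg
        )
    return tgt_pk


def _align_to_profile(
    collection: SpectraCollection,
    peaklists: list[PeakList],
    ref_y: np.ndarray,
    ref_positions: np.ndarray,
    max_lag: int,
    min_segment_points: int,
    skip: int | None = None,
) -> tuple[SpectraCollection, list[list[tuple[float, float, float]]]]:
    aligned = collection.copy()
    step = collection.step
    ref_pk = np.searchsorted(collection.ppm, ref_positions)
    all_shifts: list[list[tuple[float, float, float]]] = []
    for i in range(collection.n_samples):
        records: list[tuple[float, float, int]] = []
        if i != skip:
            tgt_pk = np.searchsorted(collection.ppm, peaklists[i].positions)
            _align_recursive(
                ref_y,
                aligned.intensities[i],
                0,
                collection.n_points,
                ref_pk,
                tgt_pk,
                max_lag,
                collection.ppm,
                records,
                min_segment_points,
            )
        all_shifts.append([(lo, hi, lag * step) for lo, hi, lag in records])
    return aligned, all_shifts


def align_clupa(
    collection: SpectraCollection,
    peaklists: list[PeakList],
    reference: int,
    max_shift: float = 0.05,
    min_segment_points: int = 32,
    refine: bool = False,
    scales: tuple[float, ...] = DEFAULT_CWT_SCALES,
    snr_min: float = 3.0,
) -> AlignmentResult:
    """Segment-wise alignment of every spectrum to the reference spectrum.

    ``max_shift`` (ppm) bounds every applied segment shift; it must be at
    least one grid step.  With ``refine=True`` a second pass aligns every
    spectrum (including the reference) against the average profile of the
    *input* spectra: aligning to one real spectrum stamps that spectrum's
    own shift errors onto the whole cohort, while the cohort-average
    profile has its peaks near the consensus positions, so the refinement
    removes the reference's residual shifts.
    """
    step = collection.step
    max_lag = int(np.floor(max_shift / step))
    if max_lag < 1:
        raise ValueError(
            f"max_shift {max_shift} ppm is below one grid step ({step:.6f} ppm)"
        )
    if not 0 <= reference < collection.n_samples:
        raise ValueError(f"reference index {reference} out of range")
    aligned, all_shifts = _align_to_profile(
        collection,
        peaklists,
        collection.intensities[reference],
        peaklists[reference].positions,
        max_lag,
        min_segment_points,
        skip=reference,
    )
    if refine:
        mean_y = collection.intensities.mean(axis=0)
        mean_coll = SpectraCollection(
            ppm=collection.ppm, intensities=mean_y[None, :], sample_ids=["_mean"]
        )
        mean_peaks = detect_peaks(mean_coll, scales=scales, snr_min=snr_min)[0]
        pass1_peaks = detect_peaks(aligned, scales=scales, snr_min=snr_min)
        aligned, shifts2 = _align_to_profile(
            aligned,
            pass1_peaks,
            mean_y,
            mean_peaks.positions,
            max_lag,
            min_segment_points,
        )
        all_shifts = [a + b for a, b in zip(all_shifts, shifts2)]
    return AlignmentResult(collection=aligned, shifts=all_shifts, reference=reference)


def align_spectra(
    collection: SpectraCollection,
    scales: tuple[float, ...] = DEFAULT_CWT_SCALES,
    snr_min: float = 3.0,
    max_shift: float = 0.05,
    refine: bool = True,
) -> AlignmentResult:
    """Convenience pipeline: detect peaks, select the reference spectrum
    and run the segment-wise alignment (with the mean-profile refinement
    pass by default)."""
    peaklists = detect_peaks(collection, scales=scales, snr_min=snr_min)
    reference = select_reference(peaklists)
    return align_clupa(
        collection,
        peaklists,
        reference,
        max_shift=max_shift,
        refine=refine,
        scales=scales,
        snr_min=snr_min,
    )


def exclude_regions(obj, regions=(WATER_REGION,)):
    """Remove grid points (SpectraCollection) or ROIs (BucketTable) that
    intersect any of the given ppm intervals.  Default: the residual water
    region 4.50–5.25 ppm."""
    for lo, hi in regions:
        if not lo < hi:
            raise ValueError(f"inverted region ({lo}, {hi})")
    if isinstance(obj, SpectraCollection):
        keep = np.ones(obj.n_points, dtype=bool)
        for lo, hi in regions:
            keep &= ~((obj.ppm >= lo) & (obj.ppm <= hi))
        if keep.sum() < 2:
            raise ValueError("exclusion regions cover the whole axis; nothing left")
        return SpectraCollection(
            ppm=obj.ppm[keep],
            intensities=obj.intensities[:, keep],
            sample_ids=list(obj.sample_ids),
            group_labels=None if obj.group_labels is None else list(obj.group_labels),
        )
    if isinstance(obj, BucketTable):
        keep = []
        for j, v in enumerate(obj.variables):
            if isinstance(v, tuple):
                vlo, vhi = v
                hit = any(vlo < hi and lo < vhi for lo, hi in regions)
            else:
                hit = False
            if not hit:
                keep.append(j)
        if not keep:
            raise ValueError("exclusion regions cover every ROI; nothing left")
        return obj.copy(
            values=obj.values[:, keep],
            variables=[obj.variables[j] for j in keep],
        )
    raise TypeError(f"cannot exclude regions from {type(obj).__name__}")


def _contiguous_regions(ppm: np.ndarray) -> list[tuple[int, int]]:
    """Split an axis with gaps (e.g. after water exclusion) into contiguous
    index ranges [i0, i1] (inclusive)."""
    d = np.diff(ppm)
    step = np.median(d)
    breaks = np.nonzero(d > 1.5 * step)[0]
    bounds = [0, *(b + 1 for b in breaks), ppm.size]
    return [(bounds[k], bounds[k + 1] - 1) for k in range(len(bounds) - 1)]


def _split_bucket(avg: np.ndarray, ppm: np.ndarray, i0: int, i1: int, min_width: float) -> list[tuple[int, int]]:
    """Recursively split [i0, i1] at the deepest admissible interior local
    minimum of the average spectrum."""
    interior = np.arange(i0 + 1, i1)
    if interior.size == 0:
        return [(i0, i1)]
    # a local minimum must be no higher than both neighbours and strictly
    # lower than at least one (a constant stretch contains no minima)
    is_min = (
        (avg[interior] <= avg[interior - 1])
        & (avg[interior] <= avg[interior + 1])
        & ((avg[interior] < avg[interior - 1]) | (avg[interior] < avg[interior + 1]))
    )
    admissible = (
        is_min
        & (ppm[interior] - ppm[i0] >= min_width)
        & (ppm[i1] - ppm[interior] >= min_width)
    )
    cand = interior[admissible]
    if cand.size == 0:
        return [(i0, i1)]
    j = int(cand[np.argmin(avg[cand])])
    return _split_bucket(avg, ppm, i0, j, min_width) + _split_bucket(avg, ppm, j, i1, min_width)


def intelligent_bucket(collection: SpectraCollection, min_width: float = 0.04) -> BucketTable:
    """Bucket spectra with boundaries at local minima of the average
    spectrum; every bucket is at least ``min_width`` ppm wide; bucket
    values are per-sample trapezoidal integrals.  Adjacent buckets share
    their boundary grid point so the bucket integrals tile the retained
    axis exactly."""
    if min_width <= 0:
        raise ValueError("min_width must be positive")
    step = collection.step
    if min_width <= step:
        raise ValueError(
            f"min_width {min_width} ppm must exceed the grid step ({step:.6f} ppm)"
        )
    avg = collection.intensities.mean(axis=0)
    buckets: list[tuple[int, int]] = []
    for i0, i1 in _contiguous_regions(collection.ppm):
        if i1 > i0:
            buckets.extend(_split_bucket(avg, collection.ppm, i0, i1, min_width))
    if not buckets:
        raise ValueError("no buckets could be formed")
    values = np.empty((collection.n_samples, len(buckets)))
    variables = []
    for k, (i0, i1) in enumerate(buckets):
        seg = slice(i0, i1 + 1)
        values[:, k] = np.trapezoid(collection.intensities[:, seg], collection.ppm[seg], axis=1)
        variables.append((float(collection.ppm[i0]), float(collection.ppm[i1])))
    return BucketTable(
        values=values,
        variables=variables,
        sample_ids=list(collection.sample_ids),
        group_labels=None if collection.group_labels is None else list(collection.group_labels),
        aligned=True,
    )


def pqn_normalize(table, reference: np.ndarray | None = None, eps_fraction: float = 1e-9):
    """Probabilistic quotient normalization.

    Rows are first integral-normalized to the cohort-mean total; the
    reference is the element-wise median profile across rows (or a
    supplied vector); each row is divided by the median of its quotients
    against the reference.  Returns ``(normalized, NormalizationRecord)``.
    Accepts a BucketTable or a plain matrix.
    """
    is_table = isinstance(table, BucketTable)
    X = (table.values if is_table else np.atleast_2d(np.asarray(table, float))).copy()
    ids = table.sample_ids if is_table else [str(i) for i in range(X.shape[0])]
    totals = X.sum(axis=1)
    bad = np.nonzero(totals <= 0)[0]
    if bad.size:
        raise ValueError(f"sample {ids[bad[0]]} has a non-positive total intensity")
    total_factor = totals / totals.mean()
    X /= total_factor[:, None]
    ref = np.median(X, axis=0) if reference is None else np.asarray(reference, float)
    eps = eps_fraction * np.max(np.abs(ref)) if np.max(np.abs(ref)) > 0 else 0.0
    valid = ref > eps
    if valid.sum() < 0.5 * ref.size:
        raise ValueError(
            "reference profile must be positive on at least 50% of variables"
        )
    quotient = np.median(X[:, valid] / ref[valid], axis=1)
    if np.any(quotient <= 0):
        i = int(np.nonzero(quotient <= 0)[0][0])
        raise ValueError(f"sample {ids[i]} has a non-positive quotient median")
    X /= quotient[:, None]
    record = NormalizationRecord(
        quotient=quotient, total_factor=total_factor, reference=ref
    )
    if is_table:
        return table.copy(values=X, normalized=True), record
    return X, record


def prep_feature_table(
    matrix,
    log_transform: bool = False,
    center: bool = True,
    sample_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
    variables: list | None = None,
) -> BucketTable:
    """Generic feature-table preparation: optional log10 (zeros replaced by
    half the smallest positive value of the column) and mean-centering."""
    if isinstance(matrix, BucketTable):
        X = matrix.values.copy()
        sample_ids = sample_ids or list(matrix.sample_ids)
        group_labels = group_labels or matrix.group_labels
        variables = variables or list(matrix.variables)
    else:
        X = np.atleast_2d(np.asarray(matrix, float)).copy()
    n, p = X.shape
    sample_ids = sample_ids or [f"S{i+1:03d}" for i in range(n)]
    variables = variables or [f"V{j+1}" for j in range(p)]
    if log_transform:
        for j in range(p):
            col = X[:, j]
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError(f"column {variables[j]} is all-zero; cannot log-transform")
            if (col < 0).any():
                raise ValueError(f"column {variables[j]} has negative entries; cannot log-transform")
            col[col == 0] = pos.min() / 2.0
            X[:, j] = np.log10(col)
    if center:
        X -= X.mean(axis=0)
    return BucketTable(
        values=X,
        variables=variables,
        sample_ids=sample_ids,
        group_labels=group_labels,
        centered=center,
        log_transformed=log_transform,
    )
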