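"""Spectral preprocessing: raw profiles -> aligned samples x peak-areas matrix.

The workflow mirrors the standard low-mass profiling chain: trim to the
analyzed 800-10,000 Da window, normalize each spectrum to its total ion
current, recalibrate the m/z axes on prominent peaks common to the cohort,
smooth (Savitzky-Golay), subtract the baseline by a morphological top-hat
(signal minus its grey opening with a flat structuring element spanning 10%
of the mass range), detect peaks on the cohort average spectrum at a
signal-to-noise threshold of 5, and integrate each sample's area within the
consensus peak bounds down to the zero level.

All intervals are closed on the left and open on the right, in Da. The chain
is deterministic: no step draws random numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sp_signal

from serumpep.spectrum import RawSpectrum

QC_OK = "ok"
QC_INVALID = "invalid"


class DegenerateSpectrumError(ValueError):
    """A spectrum without usable signal where signal is required."""


class RecalibrationError(ValueError):
    """Too few common prominent peaks to fit an affine recalibration."""


@dataclass
class PeakDefinition:
    """A consensus peak: centroid with integration bounds, all in Da."""

    centroid: float
    left_bound: float
    right_bound: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.left_bound < self.centroid < self.right_bound:
            raise ValueError(
                f"peak {self.index}: bounds must bracket the centroid "
                f"({self.left_bound}, {self.centroid}, {self.right_bound})")


@dataclass
class FeatureMatrix:
    """Samples x peak-areas table consumed by all statistics and classifiers."""

    sample_ids: list
    peak_definitions: list
    areas: np.ndarray  # shape (n_samples, n_peaks); NaN rows for invalid samples
    qc_flags: list

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.peak_definitions)):
            raise ValueError("areas shape does not match sample/peak lists")
        finite = self.areas[np.isfinite(self.areas)]
        if np.any(finite < 0):
            raise ValueError("areas must be nonnegative")

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.peak_definitions])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, columns=[f"{c:.2f}" for c in self.centroids])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "qc_flag", self.qc_flags)
        return df

    def valid_mask(self) -> np.ndarray:
        return np.array([f == QC_OK for f in self.qc_flags])


# ---------------------------------------------------------------------------
# elementary steps

def normalize_tic(spectrum: RawSpectrum, target_tic: float = 1.0) -> RawSpectrum:
    """Scale intensities so the trapezoidal integral equals ``target_tic``."""
    tic = spectrum.tic()
    if tic <= 0:
        raise DegenerateSpectrumError(f"{spectrum.sample_id}: nonpositive TIC")
    return spectrum.copy_with(intensity=spectrum.intensity * (target_tic / tic))


def smooth(spectrum: RawSpectrum, window: float = 2.0, order: int = 3) -> RawSpectrum:
    """Savitzky-Golay smoothing with a window expressed in Da.

    Constant signals are fixed points; peaks much wider than the window keep
    their area. ``order=0`` degenerates to a moving average.
    """
    step = float(np.median(np.diff(spectrum.mz)))
    npts = max(3, int(round(window / step)) | 1)  # odd, >= 3
    if npts > len(spectrum):
        raise ValueError("smoothing window wider than the spectrum")
    if order >= npts:
        order = npts - 1
    out = sp_signal.savgol_filter(spectrum.intensity, npts, order, mode="interp")
    return spectrum.copy_with(intensity=out)


def opening(intensity: np.ndarray, size: int) -> np.ndarray:
    """Grey opening (erosion then dilation) with a flat element of ``size`` points."""
    return ndimage.grey_opening(intensity, size=size, mode="nearest")


def subtract_baseline_tophat(spectrum: RawSpectrum,
                             min_width_frac: float = 0.10,
                             despike_window: float = 2.0) -> RawSpectrum:
    """Top-hat baseline subtraction.

    The baseline is the grey opening of the intensity with a flat structuring
    element spanning ``min_width_frac`` of the analyzed mass range; features
    narrower than the element pass through, broad trends are removed.

    The opening's erosion takes a strict minimum over a wide window, so it
    latches onto any artificial dip — in particular the negative sidelobes a
    polynomial smoother leaves next to peaks much narrower than its window —
    and then underestimates the baseline across the whole neighborhood. The
    baseline is therefore estimated on a median-despiked copy of the signal
    (window ``despike_window`` Da, wide enough to erase few-point sidelobes,
    far narrower than the structuring element) while the subtraction itself
    uses the original intensity. Output is clipped at zero.
    """
    if not 0.0 < min_width_frac <= 1.0:
        raise ValueError("min_width_frac must lie in (0, 1]")
    step = float(np.median(np.diff(spectrum.mz)))
    span = spectrum.mz[-1] - spectrum.mz[0]
    size = max(3, int(round(min_width_frac * span / step)))
    med = max(3, int(round(despike_window / step)) | 1)
    despiked = ndimage.median_filter(spectrum.intensity, size=med, mode="nearest")
    base = opening(despiked, size)
    return spectrum.copy_with(intensity=np.maximum(spectrum.intensity - base, 0.0))


def estimate_noise(spectrum: RawSpectrum, window: float = 250.0) -> np.ndarray:
    """Robust local noise level per grid point.

    The intensity is detrended by a running median (which tracks baseline
    residue and the bodies of broad peaks but not point-to-point noise, even
    when smoothing has correlated it over a few samples); the spectrum is
    then cut into windows of ``window`` Da and within each the noise is the
    median absolute deviation of the detrended residual scaled to a Gaussian
    sigma (x 1.4826), insensitive to sparse tall peaks. Block estimates are
    linearly interpolated back onto the grid.
    """
    mz, y = spectrum.mz, spectrum.intensity
    step = float(np.median(np.diff(mz)))
    block = max(8, int(round(window / step)))
    trend_size = min(max(25, block // 16) | 1, len(y))
    resid = y - ndimage.median_filter(y, size=trend_size, mode="nearest")
    centers, levels = [], []
    for start in range(0, len(y), block):
        seg = resid[start:start + block]
        if len(seg) < 4:
            continue
        mad = np.median(np.abs(seg - np.median(seg)))
        centers.append(mz[start + len(seg) // 2])
        levels.append(1.4826 * mad)
    if not centers:
        return np.zeros_like(y)
    return np.interp(mz, centers, levels)


def recalibrate(spectra: list[RawSpectrum], min_presence: float = 0.8,
                match_tol: float | None = None,
                reference_grid: np.ndarray | None = None,
                ) -> tuple[list[RawSpectrum], list[tuple[float, float]]]:
    """Affine recalibration of each spectrum onto cohort-consensus peak positions.

    Prominent peaks (apex SNR >= 5 against a robust noise floor) are picked per
    spectrum, clustered across spectra, and clusters present in at least
    ``min_presence`` of spectra become landmarks; each spectrum's m/z axis is
    warped by the least-squares affine map of its matched landmark positions
    onto the consensus (median) positions, then resampled onto a common grid.

    Returns the warped spectra and the fitted ``(scale, offset)`` per spectrum.
    Raises :class:`RecalibrationError` when fewer than two landmark clusters
    exist; callers may catch it and pass spectra through unwarped.
    """
    if len(spectra) < 2:
        raise RecalibrationError("need at least 2 spectra to recalibrate")
    per_spec_peaks = []
    for spec in spectra:
        noise = estimate_noise(spec)
        floor = np.maximum(noise, 1e-12)
        base = opening(spec.intensity,
                       max(3, int(0.10 * len(spec))))
        net = spec.intensity - base
        idx, _ = sp_signal.find_peaks(net, height=5.0 * floor,
                                      prominence=5.0 * float(np.median(floor)))
        per_spec_peaks.append(spec.mz[idx])

    if match_tol is None:
        match_tol_fn = lambda m: max(0.003 * m, 2.0 * float(np.median(np.diff(spectra[0].mz))))
    else:
        match_tol_fn = lambda m: match_tol

    def nearest(sorted_arr: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Value in ``sorted_arr`` nearest to each target (vectorized)."""
        pos = np.clip(np.searchsorted(sorted_arr, targets), 1, len(sorted_arr) - 1)
        lo, hi = sorted_arr[pos - 1], sorted_arr[pos]
        return np.where(np.abs(targets - lo) <= np.abs(hi - targets), lo, hi)

    # cluster peak positions across spectra by single-pass gap splitting
    nonempty = [p for p in per_spec_peaks if len(p)]
    if not nonempty:
        raise RecalibrationError("no prominent peaks found")
    allpos = np.sort(np.concatenate(nonempty))
    gaps = np.diff(allpos)
    tol = np.array([match_tol_fn(m) for m in allpos[:-1]])
    cluster_ids = np.concatenate([[0], np.cumsum(gaps > tol)])
    consensus = np.array([float(np.median(allpos[cluster_ids == cid]))
                          for cid in np.unique(cluster_ids)])
    cons_tol = np.array([match_tol_fn(c) for c in consensus])
    presence = np.zeros(len(consensus), dtype=int)
    for p in per_spec_peaks:
        if len(p) < 1:
            continue
        if len(p) == 1:
            hit = np.abs(consensus - p[0]) <= cons_tol
        else:
            hit = np.abs(nearest(p, consensus) - consensus) <= cons_tol
        presence += hit.astype(int)
    landmarks = consensus[presence >= min_presence * len(spectra)]
    if len(landmarks) < 2:
        raise RecalibrationError(
            f"only {len(landmarks)} common prominent peak(s); need >= 2")
    lm_tol = np.array([match_tol_fn(lm) for lm in landmarks])

    grid = reference_grid if reference_grid is not None else spectra[0].mz
    warped, warps = [], []
    for spec, peaks in zip(spectra, per_spec_peaks):
        if len(peaks) >= 2:
            obs_all = nearest(peaks, landmarks)
            matched = np.abs(obs_all - landmarks) <= lm_tol
            obs, ref = obs_all[matched], landmarks[matched]
        else:
            obs, ref = np.array([]), np.array([])
        if len(obs) >= 2:
            a, b = np.polyfit(obs, ref, 1)
        else:
            a, b = 1.0, 0.0
        mz_corr = a * spec.mz + b
        intensity = np.interp(grid, mz_corr, spec.intensity)
        out = RawSpectrum(spec.sample_id, grid.copy(), np.maximum(intensity, 0.0),
                          dict(spec.metadata))
        out.metadata["recal_scale"] = float(a)
        out.metadata["recal_offset"] = float(b)
        warped.append(out)
        warps.append((float(a), float(b)))
    return warped, warps


def detect_peaks(mean_spectrum: RawSpectrum, noise: np.ndarray,
                 snr_threshold: float = 5.0) -> list[PeakDefinition]:
    """Detect peaks on the cohort average spectrum.

    Local maxima whose apex intensity *and* topographic prominence are at
    least ``snr_threshold`` times the local noise become peaks; the dual
    requirement keeps slow baseline residue from spawning spurious
    definitions. Integration bounds extend to the flanking local minima (or
    zero crossings), truncated so that adjacent definitions do not overlap.
    Centroids are intensity-weighted means over the upper part of the peak
    (>= 25% of apex), which is insensitive to asymmetric shoulders.
    """
    y = mean_spectrum.intensity
    mz = mean_spectrum.mz
    floor = np.maximum(np.asarray(noise, dtype=float), 1e-300)
    apex_idx, _ = sp_signal.find_peaks(y, height=snr_threshold * floor,
                                       prominence=snr_threshold * floor)
    if len(apex_idx) == 0:
        return []

    minima_idx, _ = sp_signal.find_peaks(-y)
    defs: list[PeakDefinition] = []
    prev_right = 0
    for apex in apex_idx:
        pos = np.searchsorted(minima_idx, apex)
        left = int(minima_idx[pos - 1]) if pos > 0 else 0
        right = int(minima_idx[pos]) if pos < len(minima_idx) else len(y) - 1
        # tighten to zero crossings inside the minima window
        zero_left = np.nonzero(y[left:apex] <= 0)[0]
        if len(zero_left):
            left = left + int(zero_left[-1])
        zero_right = np.nonzero(y[apex:right + 1] <= 0)[0]
        if len(zero_right):
            right = apex + int(zero_right[0])
        left = max(left, prev_right)
        if right <= left:
            continue
        seg = slice(left, right + 1)
        w = np.maximum(y[seg], 0.0)
        w = np.where(w >= 0.25 * y[apex], w, 0.0)
        centroid = float(np.sum(mz[seg] * w) / np.sum(w)) if np.sum(w) > 0 \
            else float(mz[apex])
        if not mz[left] < centroid < mz[right]:
            centroid = float(mz[apex])
        defs.append(PeakDefinition(centroid=centroid, left_bound=float(mz[left]),
                                   right_bound=float(mz[right]), index=len(defs)))
        prev_right = right
    return defs


def integrate_areas(spectrum: RawSpectrum, peak_definitions: list[PeakDefinition],
                    recenter_tol_frac: float = 0.003) -> np.ndarray:
    """Zero-level trapezoidal peak areas at the consensus bounds.

    Before integrating, each window is re-centered on the sample's own local
    apex within ±``recenter_tol_frac`` of the centroid m/z, absorbing
    residual calibration error. The apex search never leaves the peak's own
    consensus bounds: a definition next to a much larger neighbor must not
    latch onto that neighbor's flank, which would integrate a different
    feature than the one the definition names. Areas are clipped below at
    zero.
    """
    mz, y = spectrum.mz, spectrum.intensity
    out = np.empty(len(peak_definitions))
    for i, p in enumerate(peak_definitions):
        if p.left_bound < mz[0] - 1e-9 or p.right_bound > mz[-1] + 1e-9:
            raise ValueError(f"peak {i} at {p.centroid:.2f} Da outside spectrum range")
        shift = 0.0
        if recenter_tol_frac > 0:
            tol = min(recenter_tol_frac * p.centroid, 2.0)
            lo = np.searchsorted(mz, max(p.centroid - tol, p.left_bound))
            hi = np.searchsorted(mz, min(p.centroid + tol, p.right_bound))
            if hi - lo >= 3:
                local_apex = float(mz[lo + int(np.argmax(y[lo:hi]))])
                shift = local_apex - p.centroid
        lo = np.searchsorted(mz, p.left_bound + shift)
        hi = np.searchsorted(mz, p.right_bound + shift)
        if hi - lo < 2:
            out[i] = 0.0
            continue
        out[i] = max(float(np.trapezoid(y[lo:hi], mz[lo:hi])), 0.0)
    return out


# ---------------------------------------------------------------------------
# full chain

def build_feature_matrix(spectra: list[RawSpectrum],
                         mz_min: float = 800.0, mz_max: float = 10_000.0,
                         target_tic: float = 1.0,
                         smooth_window: float = 2.0, smooth_order: int = 3,
                         baseline_width_frac: float = 0.10,
                         snr_threshold: float = 5.0,
                         peak_definitions: list[PeakDefinition] | None = None,
                         qc_min_snr: float = 5.0, qc_min_frac: float = 0.8,
                         ) -> FeatureMatrix:
    """Run the full preprocessing chain over a cohort.

    Steps: trim -> TIC normalization -> recalibration -> smoothing -> top-hat
    baseline -> peak detection on the cohort mean spectrum (unless
    ``peak_definitions`` pins an existing consensus, as in blinded
    classification of a new cohort) -> per-sample integration.

    Quality control: consensus detection happens on the cohort mean spectrum,
    whose noise floor is far below a single acquisition's, so some consensus
    peaks are never individually detectable; judging a spectrum on those
    would penalize everyone. QC therefore scores each sample only on the
    *major* peaks — those whose cohort-median intensity reaches
    ``qc_min_snr`` times the cohort-median noise, i.e. peaks a typical valid
    spectrum does show. A sample is flagged invalid when fewer than
    ``qc_min_frac`` of the major peaks reach a local SNR of ``qc_min_snr``
    in it; its areas are reported missing (NaN).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    processed = []
    for spec in spectra:
        s = spec.trimmed(mz_min, mz_max)
        s = normalize_tic(s, target_tic=target_tic)
        processed.append(s)

    grid = processed[0].mz
    try:
        processed, _ = recalibrate(processed, reference_grid=grid)
    except RecalibrationError as exc:
        warnings.warn(f"recalibration skipped: {exc}", stacklevel=2)
        processed = [
            s.copy_with(intensity=np.maximum(np.interp(grid, s.mz, s.intensity), 0.0),
                        mz=grid)
            for s in processed]

    cleaned = []
    for s in processed:
        s = smooth(s, window=smooth_window, order=smooth_order)
        s = subtract_baseline_tophat(s, min_width_frac=baseline_width_frac)
        cleaned.append(s)

    if peak_definitions is None:
        mean_int = np.mean([s.intensity for s in cleaned], axis=0)
        mean_spec = RawSpectrum("cohort_mean", grid, np.maximum(mean_int, 0.0))
        noise = estimate_noise(mean_spec)
        peak_definitions = detect_peaks(mean_spec, noise, snr_threshold=snr_threshold)
        if not peak_definitions:
            raise ValueError("no peaks detected on the cohort mean spectrum")

    n, p = len(cleaned), len(peak_definitions)
    areas = np.full((n, p), np.nan)
    centroid_idx = np.searchsorted(grid, [pd_.centroid for pd_ in peak_definitions])
    centroid_idx = np.clip(centroid_idx, 0, len(grid) - 1)
    heights = np.array([s.intensity[centroid_idx] for s in cleaned])
    noises = np.array([estimate_noise(s)[centroid_idx] for s in cleaned])
    typical_noise = np.maximum(np.median(noises, axis=0), 1e-300)
    major = np.median(heights, axis=0) >= qc_min_snr * typical_noise
    if not major.any():
        raise ValueError("no consensus peak is detectable in a typical spectrum")
    qc_flags = []
    for i, s in enumerate(cleaned):
        local_snr = heights[i, major] / np.maximum(noises[i, major], 1e-300)
        ok = np.mean(local_snr >= qc_min_snr) >= qc_min_frac
        qc_flags.append(QC_OK if ok else QC_INVALID)
        if ok:
            areas[i] = integrate_areas(s, peak_definitions)
    if all(f == QC_INVALID for f in qc_flags):
        raise ValueError("every spectrum in the cohort failed the quality check")
    return FeatureMatrix(sample_ids=[s.sample_id for s in cleaned],
                         peak_definitions=list(peak_definitions),
                         areas=areas, qc_flags=qc_flags)
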