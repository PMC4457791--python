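"""Synthetic serum-peptidome cohorts with linked clinical outcomes.

The generator emulates linear-mode MALDI-TOF serum profiles over 800-10,000 Da:
a decaying-exponential chemical baseline, ~120 non-discriminating background
peptide peaks, ten class-informative peaks whose areas are drawn from
class-conditional normal distributions truncated at zero, heteroscedasticity
through multiplicative total-ion-current variation, additive Gaussian detector
noise, and a small affine miscalibration of the m/z axis per spectrum. A
configurable fraction of spectra is rendered low-quality (peak amplitudes
collapsed below the detection limit) to exercise the unclassifiable path.

Clinical outcomes (RECIST response category, progression-free and overall
survival with right-censoring) are drawn per patient conditionally on the true
mutation class, with exponential event times parameterized by their medians.

Everything is a pure function of (config, seed): the config seed spawns one
substream per patient, so cohorts are reproducible patient by patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from serumpep.spectrum import RawSpectrum

MUTANT = "mutant"
WILD = "wild"

#: Class-informative peaks: (centroid m/z, wild mean, wild SD, mutant mean,
#: mutant SD) of the zero-truncated normal peak-area distributions. The first
#: nine carry the reference training-cohort effect sizes; m/z 4438.43 entered
#: the reference classifier without a reported effect size and is simulated as
#: weakly informative (class means 0.5 pooled SD apart).
DISCRIMINATING_PEAKS: tuple[tuple[float, float, float, float, float], ...] = (
    (1365.10, 15.96, 5.37, 9.10, 4.01),
    (1866.47, 638.60, 548.70, 170.42, 124.03),
    (3315.75, 40.92, 26.80, 77.98, 59.56),
    (3883.79, 7.13, 2.97, 12.26, 5.33),
    (3956.66, 32.42, 31.73, 56.98, 35.78),
    (4092.40, 4.57, 1.63, 10.00, 4.29),
    (4585.05, 4.04, 1.67, 8.15, 3.30),
    (4643.49, 30.23, 14.08, 48.54, 23.42),
    (5866.96, 1.80, 0.97, 3.96, 3.18),
    (4438.43, 4.00, 1.50, 4.75, 1.50),
)

#: The five peaks composing the reference classifier.
CLASSIFIER_PEAKS: tuple[float, ...] = (4092.40, 4585.05, 1365.10, 4643.49, 4438.43)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the spectral cohort generator.

    Defaults reproduce the study conditions: a 50/50 training cohort or a
    52/71 validation cohort over 800-10,000 Da, ten informative peaks with the
    reference class-conditional area statistics, 120 background peaks, and
    mild per-spectrum miscalibration.
    """

    n_mutant: int = 50
    n_wild: int = 50
    mz_min: float = 800.0
    mz_max: float = 10_000.0
    grid_step: float = 0.25
    discriminating_peaks: tuple = DISCRIMINATING_PEAKS
    n_background_peaks: int = 120
    background_area_mean: float = 25.0
    background_area_sd: float = 12.0
    resolution: float = 1.0 / 3000.0  # sigma = centroid * resolution (Da)
    baseline_amplitude: float = 2.0
    baseline_decay: float = 2000.0  # Da
    baseline_offset: float = 0.2
    noise_sigma: float = 0.05
    tic_variation: float = 0.10  # lognormal sigma of the multiplicative TIC factor
    calibration_scale_max: float = 2e-4  # |a - 1| bound of the affine distortion
    calibration_offset_max: float = 0.3  # |b| bound in Da
    invalid_rate: float = 0.0
    invalid_attenuation: float = 0.02
    seed: int = 0
    #: seed of the background-peptide catalog; defaults to ``seed``. Cohorts
    #: of one study (training and blinded validation) must share it: they
    #: assay the same serum matrix, so the non-discriminating peptide
    #: population is common even though every patient draw is fresh.
    catalog_seed: int = None  # type: ignore[assignment]
    background_peaks: tuple = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_mutant < 0 or self.n_wild < 0 or self.n_mutant + self.n_wild == 0:
            raise ConfigurationError("cohort sizes must be nonnegative and total > 0")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be > 0")
        if self.mz_max <= self.mz_min:
            raise ConfigurationError("mz_max must exceed mz_min")
        if not self.discriminating_peaks and not self.n_background_peaks:
            raise ConfigurationError("peak catalog is empty")
        for row in self.discriminating_peaks:
            if row[2] <= 0 or row[4] <= 0:
                raise ConfigurationError(f"peak {row[0]}: SDs must be > 0")
        if not 0.0 <= self.invalid_rate <= 1.0:
            raise ConfigurationError("invalid_rate must lie in [0, 1]")
        if self.catalog_seed is None:
            self.catalog_seed = self.seed
        if self.background_peaks is None:
            self.background_peaks = self._draw_background_catalog()

    def _draw_background_catalog(self) -> tuple:
        """Background (non-discriminating) peak catalog, fixed by the config seed.

        Centroids are uniform over the interior of the mass window, kept >= 10 Da
        away from any informative centroid; shared (class-independent) mean areas
        are normal around ``background_area_mean``, floored at 1.
        """
        rng = np.random.default_rng([self.catalog_seed, 0xBACC])
        lo, hi = self.mz_min + 50.0, self.mz_max - 50.0
        informative = np.array([row[0] for row in self.discriminating_peaks])
        centroids: list[float] = []
        while len(centroids) < self.n_background_peaks:
            c = float(rng.uniform(lo, hi))
            if informative.size and np.min(np.abs(informative - c)) < 10.0:
                continue
            if centroids and np.min(np.abs(np.array(centroids) - c)) < 6.0:
                continue
            centroids.append(c)
        means = np.maximum(
            rng.normal(self.background_area_mean, self.background_area_sd,
                       size=self.n_background_peaks), 1.0)
        sds = 0.25 * means
        return tuple((c, m, s) for c, m, s in zip(sorted(centroids), means, sds))

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.grid_step)) + 1
        return self.mz_min + self.grid_step * np.arange(n)

    def sigma_at(self, mz: float) -> float:
        return mz * self.resolution

    def nominal_tic(self) -> float:
        """Expected raw TIC of a valid spectrum (baseline + mean peak areas),
        used as the normalization target so that recovered peak areas stay on
        the generator's area scale."""
        span = self.mz_max - self.mz_min
        base = (self.baseline_amplitude * self.baseline_decay
                * (1.0 - math.exp(-span / self.baseline_decay))
                + self.baseline_offset * span)
        disc = sum(0.5 * (row[1] + row[3]) for row in self.discriminating_peaks)
        bg = sum(row[1] for row in self.background_peaks)
        return base + disc + bg


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) conditioned on being >= 0, by rejection."""
    while True:
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)


def _add_gaussian_peak(grid: np.ndarray, intensity: np.ndarray, centroid: float,
                       area: float, sigma: float) -> None:
    """Add a Gaussian of the given integrated area in place (5-sigma support)."""
    step = grid[1] - grid[0]
    lo = np.searchsorted(grid, centroid - 5.0 * sigma)
    hi = np.searchsorted(grid, centroid + 5.0 * sigma)
    if hi <= lo:
        return
    window = grid[lo:hi]
    amp = area / (sigma * math.sqrt(2.0 * math.pi))
    intensity[lo:hi] += amp * np.exp(-0.5 * ((window - centroid) / sigma) ** 2)


def draw_peak_areas(patient_class: str, config: SimulationConfig,
                    rng: np.random.Generator) -> dict[float, float]:
    """Draw one patient's true peak areas (zero-truncated normals).

    Informative peaks use the class-conditional parameters; background peaks
    are class-independent.
    """
    if patient_class not in (MUTANT, WILD):
        raise ConfigurationError(f"unknown class {patient_class!r}")
    areas: dict[float, float] = {}
    for centroid, w_mean, w_sd, m_mean, m_sd in config.discriminating_peaks:
        mean, sd = (m_mean, m_sd) if patient_class == MUTANT else (w_mean, w_sd)
        areas[centroid] = _truncated_normal(rng, mean, sd)
    for centroid, mean, sd in config.background_peaks:
        areas[centroid] = _truncated_normal(rng, mean, sd)
    return areas


def simulate_spectrum(patient_class: str, config: SimulationConfig,
                      rng: np.random.Generator, sample_id: str = "S0",
                      invalid: bool = False) -> RawSpectrum:
    """Render one raw spectrum for a patient of the given true class.

    The reported m/z axis is distorted by an affine map ``mz_obs = a*mz + b``
    (true parameters recorded in the metadata); intensities are
    baseline + peaks + iid Gaussian noise, scaled by a lognormal TIC factor,
    floored at zero. ``invalid`` collapses all peak amplitudes below the
    detection limit, emulating an unusable acquisition.
    """
    grid = config.grid
    areas = draw_peak_areas(patient_class, config, rng)

    signal = np.zeros_like(grid)
    for centroid, area in areas.items():
        _add_gaussian_peak(grid, signal, centroid, area, config.sigma_at(centroid))
    if invalid:
        signal *= config.invalid_attenuation

    baseline = (config.baseline_amplitude
                * np.exp(-(grid - config.mz_min) / config.baseline_decay)
                + config.baseline_offset)

    tic_factor = float(np.exp(rng.normal(0.0, config.tic_variation))) \
        if config.tic_variation > 0 else 1.0
    intensity = tic_factor * (signal + baseline)
    if config.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sigma, size=len(grid))
    intensity = np.maximum(intensity, 0.0)

    cal_a = 1.0 + float(rng.uniform(-config.calibration_scale_max,
                                    config.calibration_scale_max))
    cal_b = float(rng.uniform(-config.calibration_offset_max,
                              config.calibration_offset_max))
    mz_obs = cal_a * grid + cal_b

    return RawSpectrum(
        sample_id=sample_id, mz=mz_obs, intensity=intensity,
        metadata={
            "true_class": patient_class, "invalid": bool(invalid),
            "cal_scale": cal_a, "cal_offset": cal_b, "tic_factor": tic_factor,
        },
    )


def simulate_cohort(config: SimulationConfig) -> tuple[list[RawSpectrum], pd.DataFrame]:
    """Simulate a full cohort: ``n_mutant + n_wild`` spectra plus metadata.

    Patients are laid out mutants first, then wild-type; each draws from its
    own child RNG stream so per-patient reproducibility survives reordering.
    Low-quality spectra occur independently with probability ``invalid_rate``.
    """
    labels = [MUTANT] * config.n_mutant + [WILD] * config.n_wild
    spectra: list[RawSpectrum] = []
    rows = []
    for i, cls in enumerate(labels):
        rng = np.random.default_rng([config.seed, 1, i])
        invalid = bool(rng.random() < config.invalid_rate)
        sid = f"P{i:04d}"
        spectra.append(simulate_spectrum(cls, config, rng, sample_id=sid,
                                         invalid=invalid))
        rows.append({"sample_id": sid, "true_class": cls, "invalid_flag": invalid})
    return spectra, pd.DataFrame(rows)


@dataclass
class OutcomeParams:
    """Clinical-outcome model conditional on the true mutation class.

    Response probabilities follow RECIST (objective response = CR+PR; disease
    control adds SD); complete responses are generated with probability zero,
    matching their observed absence. Event times are exponential with the
    stated medians (months); follow-up is administratively censored at
    ``censor_horizon``.
    """

    p_objective_response: dict = field(
        default_factory=lambda: {MUTANT: 0.596, WILD: 0.088})
    p_disease_control: dict = field(
        default_factory=lambda: {MUTANT: 0.872, WILD: 0.353})
    pfs_median: dict = field(default_factory=lambda: {MUTANT: 10.0, WILD: 2.3})
    os_median: dict = field(default_factory=lambda: {MUTANT: 29.0, WILD: 28.0})
    p_tki_treated: dict = field(default_factory=lambda: {MUTANT: 0.90, WILD: 0.50})
    censor_horizon: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in (MUTANT, WILD):
            p_or = self.p_objective_response[cls]
            p_dc = self.p_disease_control[cls]
            if not (0.0 <= p_or <= 1.0 and 0.0 <= p_dc <= 1.0):
                raise ConfigurationError("response probabilities must lie in [0, 1]")
            if p_dc < p_or:
                raise ConfigurationError(
                    f"{cls}: disease-control probability < objective-response probability")
            if self.pfs_median[cls] <= 0 or self.os_median[cls] <= 0:
                raise ConfigurationError("survival medians must be > 0")


def _exponential_time(rng: np.random.Generator, median: float) -> float:
    return float(rng.exponential(median / math.log(2.0)))


def simulate_outcomes(metadata: pd.DataFrame, params: OutcomeParams) -> pd.DataFrame:
    """Attach response, PFS and OS columns to a cohort metadata table.

    Each patient's outcome depends only on ``true_class``. Times exceeding the
    censoring horizon are truncated there with event flag 0.
    """
    if "true_class" not in metadata.columns:
        raise ConfigurationError("metadata lacks a true_class column")
    out = metadata.copy()
    responses, tki, pfs_t, pfs_e, os_t, os_e = [], [], [], [], [], []
    for i, row in enumerate(out.itertuples(index=False)):
        cls = row.true_class
        rng = np.random.default_rng([params.seed, 2, i])
        treated = bool(rng.random() < params.p_tki_treated[cls])
        u = rng.random()
        if u < params.p_objective_response[cls]:
            resp = "PR"
        elif u < params.p_disease_control[cls]:
            resp = "SD"
        else:
            resp = "PD"
        t_pfs = _exponential_time(rng, params.pfs_median[cls])
        t_os = _exponential_time(rng, params.os_median[cls])
        t_os = max(t_os, t_pfs)  # death cannot precede progression-free interval
        h = params.censor_horizon
        responses.append(resp if treated else "missing")
        tki.append(treated)
        pfs_t.append(min(t_pfs, h))
        pfs_e.append(int(t_pfs <= h))
        os_t.append(min(t_os, h))
        os_e.append(int(t_os <= h))
    out["tki_treated"] = tki
    out["response"] = responses
    out["pfs_months"] = pfs_t
    out["pfs_event"] = pfs_e
    out["os_months"] = os_t
    out["os_event"] = os_e
    return out
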