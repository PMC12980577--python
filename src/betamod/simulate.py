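"""Synthetic EEG sessions, EMG traces, and multimodal cohort feature tables.

The generator emulates a cued-pinch motor-task study in relapsing-remitting
MS: three groups (fatigued MS-F, non-fatigued MS-NF, healthy controls HC),
300 cue-locked 2 s EEG epochs per subject at 256 Hz over 61 scalp channels,
one EMG trace per trial, and a per-subject feature table (clinical scales,
TMS indices, MRI volumetry, tract FA) with configurable group means and
rank-correlation structure.

EEG model per trial: spatially correlated 1/f background noise plus a
narrowband beta carrier (random frequency across 13.5-25 Hz, random phase)
whose squared amplitude envelope q(t) is 1 at baseline, dips during movement
(ERD) and rebounds after it (ERS), spatially weighted by a smooth Gaussian
topography centred on one electrode per candidate region.

Because the downstream statistic is defined *through* the analysis pipeline
(CSD -> Morlet band power -> whole-trial subtract-and-divide normalization ->
personalized-ROI peaks), the generator calibrates the envelope levels by
running that very pipeline on deterministic noise-free probe trials plus a
background power estimate, solving for the envelope dip/bump coefficients
that realize each subject's target peak ERD and ERS. The calibration is
seeded and bit-reproducible.

Feature tables use a one-factor Gaussian copula anchored on the subject's
frontal modulation depth: the latent loading of each correlated column is
found by a seeded Monte-Carlo bisection so that the *pooled* Spearman
correlation (across the configured groups) matches its configured target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .beta_metrics import ERD_WINDOW, ERS_WINDOW, select_roi
from .containers import EMGTraces, EpochedEEG
from .montage import CANDIDATE_REGIONS, Montage, standard_61_montage
from .spectral import NormalizedBeta, baseline_normalize, beta_band_power, csd_transform

__all__ = [
    "SimScenario",
    "SubjectRecord",
    "GroupBetaParams",
    "generate_session",
    "generate_cohort",
    "cohort_frame",
    "GROUPS",
    "FATIGUE_PREDICTORS",
    "ParameterError",
]

GROUPS = ("MS-F", "MS-NF", "HC")


class ParameterError(ValueError):
    """Invalid or infeasible generator parameters."""


# ---------------------------------------------------------------------------
# Default generator parameters (the stated world)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupBetaParams:
    """Per-group, per-region targets for the pipeline-recovered quantities."""

    erd_mean: float
    erd_sd: float
    ers_mean: float
    ers_sd: float

    @property
    def depth_mean(self) -> float:
        return self.ers_mean - self.erd_mean

    @property
    def depth_sd(self) -> float:
        # ERD and ERS share one latent severity factor per subject
        return self.ers_sd + self.erd_sd


# Group means (SD) of peak ERD / peak ERS on the normalized beta time course.
DEFAULT_BETA_PARAMS: dict[str, dict[str, GroupBetaParams]] = {
    "frontal": {
        "MS-F": GroupBetaParams(-0.85, 0.02, 2.68, 0.24),
        "MS-NF": GroupBetaParams(-0.89, 0.03, 3.31, 0.59),
        "HC": GroupBetaParams(-0.88, 0.02, 3.20, 0.42),
    },
    "left_sensorimotor": {
        "MS-F": GroupBetaParams(-0.83, 0.032, 2.38, 0.31),
        "MS-NF": GroupBetaParams(-0.83, 0.032, 2.83, 0.49),
        "HC": GroupBetaParams(-0.85, 0.03, 2.79, 0.72),
    },
    "right_sensorimotor": {
        "MS-F": GroupBetaParams(-0.83, 0.03, 2.62, 0.47),
        "MS-NF": GroupBetaParams(-0.86, 0.04, 3.07, 0.65),
        "HC": GroupBetaParams(-0.86, 0.03, 2.82, 0.45),
    },
}

# Centre electrodes of the injected topographies. Fz (not FCz) for the
# frontal region keeps the frontal blob's CSD footprint off the vertex, where
# it would otherwise contaminate the midline members of both sensorimotor
# candidate lists and couple the three regions' calibrations.
DEFAULT_CENTRES = {
    "frontal": "Fz",
    "left_sensorimotor": "C4",
    "right_sensorimotor": "C3",
}

# EMG burst onset (reaction time, s): HC fastest, MS-F slowest
DEFAULT_RT = {"MS-F": 0.34, "MS-NF": 0.31, "HC": 0.28}

# Pooled Spearman targets against frontal modulation depth. FSS is pooled over
# the two patient groups (the fatigue analyses are patient-only); ICF and
# caudate volume over all three groups.
DEFAULT_RHO_TARGETS = {
    "FSS": (-0.54, ("MS-F", "MS-NF")),
    "ICF": (0.49, GROUPS),
    "caudate_volume": (0.35, GROUPS),
}

_MISSING = (None, None)

# col -> {group: (mean, sd)}; None means structurally missing (HC on
# patient-only scales). Clip bounds applied afterwards where physical.
DEFAULT_MARGINALS: dict[str, dict] = {
    "age": {"MS-F": (41.84, 10.56), "MS-NF": (42.41, 9.62), "HC": (41.61, 11.07)},
    "education": {"MS-F": (13.26, 3.53), "MS-NF": (14.14, 3.06), "HC": (16.39, 3.01)},
    "disease_duration": {"MS-F": (107.69, 90.71), "MS-NF": (107.53, 90.94), "HC": _MISSING},
    "FSS": {"MS-F": (5.24, 0.82), "MS-NF": (2.40, 0.86), "HC": (1.80, 0.60)},
    "MADRS": {"MS-F": (8.56, 4.26), "MS-NF": (4.68, 5.38), "HC": (2.67, 2.35)},
    "mFIS_total": {"MS-F": (42.74, 11.43), "MS-NF": (22.05, 14.41), "HC": _MISSING},
    "mFIS_cog": {"MS-F": (18.05, 6.20), "MS-NF": (9.96, 7.54), "HC": _MISSING},
    "mFIS_ph": {"MS-F": (20.84, 5.53), "MS-NF": (10.77, 7.10), "HC": _MISSING},
    "mFIS_psy": {"MS-F": (3.63, 2.06), "MS-NF": (1.32, 1.29), "HC": _MISSING},
    "EDSS": {"MS-F": (1.76, 0.61), "MS-NF": (1.48, 0.47), "HC": _MISSING},
    "MSQOL54_ph": {"MS-F": (4.68, 1.60), "MS-NF": (5.74, 2.04), "HC": _MISSING},
    "MSQOL54_mh": {"MS-F": (4.22, 1.50), "MS-NF": (5.62, 1.91), "HC": _MISSING},
    "HPT9_right": {"MS-F": (20.66, 3.01), "MS-NF": (23.94, 3.58), "HC": (21.66, 3.57)},
    "HPT9_left": {"MS-F": (22.12, 4.85), "MS-NF": (24.06, 2.22), "HC": (24.20, 7.50)},
    "RMT": {g: (45.0, 8.0) for g in GROUPS},
    "MEP_latency": {g: (22.0, 1.5) for g in GROUPS},
    "SICI": {g: (0.5, 0.2) for g in GROUPS},
    "ICF": {"MS-F": (100.0, 55.0), "MS-NF": (226.0, 70.0), "HC": (167.0, 60.0)},
    "CSP": {g: (120.0, 30.0) for g in GROUPS},
    "WM_volume": {"MS-F": (477.7, 25.0), "MS-NF": (492.2, 25.0), "HC": (500.0, 25.0)},
    "GM_volume": {g: (600.0, 40.0) for g in GROUPS},
    "total_volume": {"MS-F": (1100.0, 60.0), "MS-NF": (1130.0, 60.0), "HC": (1150.0, 60.0)},
    "thalamus_volume": {"MS-F": (14.5, 1.6), "MS-NF": (14.9, 1.5), "HC": (16.5, 1.6)},
    "caudate_volume": {"MS-F": (6.47, 0.90), "MS-NF": (7.00, 0.90), "HC": (7.30, 0.90)},
    "lesion_count": {"MS-F": (25.0, 15.0), "MS-NF": (25.0, 15.0), "HC": (1.0, 1.5)},
    "lesion_volume": {"MS-F": (6.0, 5.0), "MS-NF": (6.0, 5.0), "HC": (0.2, 0.4)},
    "FA_CST_right": {"MS-F": (0.565, 0.020), "MS-NF": (0.575, 0.020), "HC": (0.580, 0.020)},
    "FA_CST_left": {"MS-F": (0.565, 0.020), "MS-NF": (0.585, 0.020), "HC": (0.570, 0.020)},
    "FA_SLF_right": {"MS-F": (0.475, 0.020), "MS-NF": (0.495, 0.020), "HC": (0.480, 0.020)},
    "FA_SLF_left": {"MS-F": (0.478, 0.020), "MS-NF": (0.493, 0.020), "HC": (0.480, 0.020)},
    "FA_thal_rad_right": {"MS-F": (0.515, 0.020), "MS-NF": (0.530, 0.020), "HC": (0.520, 0.020)},
    "FA_thal_rad_left": {g: (0.520, 0.020) for g in GROUPS},
    "FA_cingulum_right": {g: (0.520, 0.020) for g in GROUPS},
    "FA_cingulum_left": {g: (0.520, 0.020) for g in GROUPS},
}

_CLIP = {
    "FSS": (1.0, 7.0), "MADRS": (0.0, 60.0), "EDSS": (0.0, 10.0),
    "mFIS_total": (0.0, 84.0), "mFIS_cog": (0.0, 40.0), "mFIS_ph": (0.0, 36.0),
    "mFIS_psy": (0.0, 8.0), "MSQOL54_ph": (0.0, 10.0), "MSQOL54_mh": (0.0, 10.0),
    "lesion_count": (0.0, None), "lesion_volume": (0.0, None),
    "SICI": (0.05, None), "ICF": (10.0, None),
    "disease_duration": (1.0, None), "education": (5.0, None),
}

_FEMALE_P = {"MS-F": 0.68, "MS-NF": 0.50, "HC": 0.61}

# Pre-specified predictor set for the fatigue classifier (MS patients only).
FATIGUE_PREDICTORS = [
    "age", "sex", "disease_duration", "education", "MADRS",
    "MSQOL54_ph", "MSQOL54_mh", "HPT9_right",
    "WM_volume", "caudate_volume", "thalamus_volume", "lesion_count", "lesion_volume",
    "CSP", "SICI", "ICF", "RMT", "MEP_latency",
    "beta_depth_left", "beta_depth_right", "beta_depth_frontal",
    "FA_CST_left", "FA_CST_right", "FA_SLF_left", "FA_SLF_right",
]

# columns eligible for random missingness in patients (drives the
# complete-case count of the classifier)
_MISSABLE = ["CSP", "SICI", "ICF", "RMT", "MEP_latency",
             "FA_CST_left", "FA_CST_right", "FA_SLF_left", "FA_SLF_right"]


# ---------------------------------------------------------------------------
# Scenario and subject records
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Stated world of the simulation; defaults mirror the study design."""

    n_per_group: tuple[int, int, int] = (19, 22, 18)  # MS-F, MS-NF, HC
    n_trials: int = 300
    fs: float = 256.0
    fs_emg: float = 1024.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    beta_params: dict = field(default_factory=lambda: DEFAULT_BETA_PARAMS)
    centres: dict = field(default_factory=lambda: DEFAULT_CENTRES)
    snr: float = 30.0               # baseline beta power / background band power (at centre, post-CSD)
    sigma_topo: float = 0.9         # Gaussian topography width (chord length)
    bg_scale: float = 10.0          # background RMS, uV
    bg_slope: float = 1.0           # 1/f^slope background power
    spatial_scale: float = 0.8      # e-folding distance of background channel correlation
    carrier_band: tuple[float, float] = (13.5, 25.0)
    erd_latency: float = 0.30       # s, between-subject SD below
    ers_latency: float = 0.85
    latency_sd: float = 0.03
    erd_sigma: float = 0.12         # envelope dip width, s
    ers_sigma: float = 0.08         # envelope bump width, s
    rt_by_group: dict = field(default_factory=lambda: dict(DEFAULT_RT))
    rt_subject_sd: float = 0.03
    rt_trial_sd: float = 0.04
    emg_fail_p: float = 0.0462      # trials with no clear EMG burst (~286/300 kept)
    rho_targets: dict = field(default_factory=lambda: dict(DEFAULT_RHO_TARGETS))
    region_coupling: float = 0.8    # latent correlation of regional severity factors
    p_missing: float = 0.32         # patients with >=1 missing classifier predictor
    frac_no_dynamics: float = 0.0   # subjects with flat beta envelopes
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.epoch_window) != (-0.5, 1.5):
            raise ParameterError("epoch window must be [-0.5, 1.5] s")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if any(n < 0 for n in self.n_per_group):
            raise ParameterError("group sizes must be non-negative")

    # -- derived geometry/time axes (cached, deterministic) -----------------

    @property
    def montage(self) -> Montage:
        if "montage" not in self._cache:
            self._cache["montage"] = standard_61_montage()
            for lab in self.centres.values():
                self._cache["montage"].index(lab)
        return self._cache["montage"]

    @property
    def times(self) -> np.ndarray:
        if "times" not in self._cache:
            n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs))
            self._cache["times"] = self.epoch_window[0] + np.arange(n) / self.fs
        return self._cache["times"]

    @property
    def times_emg(self) -> np.ndarray:
        if "times_emg" not in self._cache:
            n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs_emg))
            self._cache["times_emg"] = self.epoch_window[0] + np.arange(n) / self.fs_emg
        return self._cache["times_emg"]

    def gains(self, region: str) -> np.ndarray:
        """Topography amplitude gain per channel for a region's centre."""
        key = ("gains", region)
        if key not in self._cache:
            d = self.montage.distances_from(self.centres[region])
            self._cache[key] = np.exp(-(d ** 2) / (2 * self.sigma_topo ** 2))
        return self._cache[key]



@dataclass
class SubjectRecord:
    """One simulated participant: identity, features, and ground truth."""

    id: str
    index: int
    group: str
    features: dict          # clinical/TMS/MRI columns; None = missing
    true_beta: dict         # region -> dict(erd, ers, depth, erd_latency, ers_latency)
    rt_mean: float
    no_dynamics: bool = False

    @property
    def fatigued(self) -> bool:
        return self.group == "MS-F"


# ---------------------------------------------------------------------------
# Background EEG and carrier synthesis
# ---------------------------------------------------------------------------

def _spatial_mixer(scenario: SimScenario) -> np.ndarray:
    key = "mixer"
    if key not in scenario._cache:
        pos = scenario.montage.positions
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        cov = np.exp(-d / scenario.spatial_scale)
        # Cholesky with a tiny jitter for numerical safety
        scenario._cache[key] = np.linalg.cholesky(cov + 1e-10 * np.eye(len(pos)))
    return scenario._cache[key]


def _background(scenario: SimScenario, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated 1/f^slope noise, (n_trials, n_ch, n_samp), RMS=bg_scale."""
    n_samp = len(scenario.times)
    n_ch = len(scenario.montage)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / scenario.fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = np.maximum(freqs[nz], 1.0) ** (-scenario.bg_slope / 2.0)
    spec = (rng.standard_normal((n_trials, n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_trials, n_ch, len(freqs)))) * amp
    x = np.fft.irfft(spec, n_samp, axis=-1)
    # normalize expected RMS analytically: var = 2*sum(amp^2)/n^2 per sample
    expected_rms = math.sqrt(2.0 * float(np.sum(amp ** 2))) / n_samp
    x *= scenario.bg_scale / expected_rms
    mixer = _spatial_mixer(scenario)
    # unit-diagonal covariance: rows of cholesky have unit norm by construction
    return np.einsum("ij,tjs->tis", mixer, x)


def _envelope(times: np.ndarray, c_d: float, c_s: float, t_d: float, t_s: float,
              sig_d: float, sig_s: float, floor: float = 0.02) -> np.ndarray:
    """Squared-amplitude envelope q(t): baseline 1, ERD dip, ERS rebound."""
    q = (1.0
         - c_d * np.exp(-((times - t_d) ** 2) / (2 * sig_d ** 2))
         + c_s * np.exp(-((times - t_s) ** 2) / (2 * sig_s ** 2)))
    return np.clip(q, floor, None)


def _region_envelopes(scenario: SimScenario, record: SubjectRecord,
                      coeffs: dict) -> dict:
    """Squared-amplitude envelope per region at the subject's latencies."""
    out = {}
    for region, (c_d, c_s) in coeffs.items():
        t = record.true_beta[region]
        out[region] = _envelope(scenario.times, c_d, c_s,
                                t["erd_latency"], t["ers_latency"],
                                scenario.erd_sigma, scenario.ers_sigma)
    return out


def _carrier(times: np.ndarray, freqs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """(n_trials, n_samp) cosine carriers."""
    return np.cos(2 * np.pi * freqs[:, None] * times[None, :] + phases[:, None])


# ---------------------------------------------------------------------------
# Pipeline-based calibration
# ---------------------------------------------------------------------------

def _band_power_of(scenario: SimScenario, data: np.ndarray) -> np.ndarray:
    """CSD + Morlet beta-band power of raw epochs; (trials, ch, grid_times)."""
    eeg = EpochedEEG(data, scenario.fs, scenario.times, scenario.montage)
    tfr = beta_band_power(csd_transform(eeg), band=scenario.carrier_band)
    return tfr.power.mean(axis=2, dtype=np.float64), tfr.times


def _probe_carriers(scenario: SimScenario) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = scenario.carrier_band
    k = np.arange(6)
    freqs = lo + (hi - lo) * (k + 0.5) / 6.0
    phases = k * (2 * np.pi / 6.0)
    return freqs, phases


def _scenario_calibration(scenario: SimScenario) -> dict:
    """Scenario-level calibration: background band power and source amplitudes.

    ``b_ch`` is the post-CSD Morlet band power of the background alone, per
    channel; ``amps[region]`` the carrier amplitude that realizes the
    configured snr (baseline beta power / background band power) at the
    region's centre electrode, both measured through the actual pipeline.
    Deterministic (internal sub-seed); cached on the scenario.
    """
    if "cal" in scenario._cache:
        return scenario._cache["cal"]
    rng = np.random.default_rng([scenario.seed % (2 ** 31), 7919])
    bg = _background(scenario, 8, rng)
    p_bg, _ = _band_power_of(scenario, bg)
    b_ch = p_bg.mean(axis=(0, 2))  # stationary: average over trials and time
    freqs, phases = _probe_carriers(scenario)
    car = _carrier(scenario.times, freqs, phases)
    amps = {}
    for region in scenario.centres:
        g = scenario.gains(region)
        data = car[:, None, :] * g[None, :, None]
        p_sig, _ = _band_power_of(scenario, data)
        centre = scenario.montage.index(scenario.centres[region])
        s1 = float(p_sig[:, centre, :].mean())
        amps[region] = math.sqrt(scenario.snr * b_ch[centre] / s1)
    cal = {"b_ch": b_ch, "amps": amps}
    scenario._cache["cal"] = cal
    return cal


def _probe_beta(scenario: SimScenario, record: SubjectRecord, coeffs: dict,
                cal: dict) -> NormalizedBeta:
    """Expected pipeline output: noise-free probe trials + background power.

    Six deterministic probe carriers span the band. In real sessions the
    regional sources carry independent phases, so regional powers add
    incoherently on average; the probes reproduce that exactly by rotating the
    relative phase between any two regions uniformly around the circle across
    the probe trials (cross terms cancel in the probe average). Background
    enters as its stationary band power, added per channel before the
    per-trial subtract-and-divide normalization.
    """
    freqs, phases = _probe_carriers(scenario)
    n_probe = len(freqs)
    envs = _region_envelopes(scenario, record, coeffs)
    data = np.zeros((n_probe, len(scenario.montage), len(scenario.times)))
    for k, region in enumerate(scenario.centres):
        ph = phases + 2 * np.pi * np.arange(n_probe) * k / n_probe
        car = _carrier(scenario.times, freqs, ph)
        sig = cal["amps"][region] * car * np.sqrt(envs[region])[None, :]
        data += sig[:, None, :] * scenario.gains(region)[None, :, None]
    p_sig, grid = _band_power_of(scenario, data)
    p_tot = p_sig + cal["b_ch"][None, :, None]
    mu = p_tot.mean(axis=-1, keepdims=True)
    value = (p_tot - mu) / mu
    return NormalizedBeta(value=value, times=grid, band=scenario.carrier_band,
                          band_power_mean=mu[..., 0],
                          flagged=np.zeros(n_probe, bool))


def _window_extrema(beta: NormalizedBeta, member_idx) -> tuple[float, float]:
    tc = beta.value[:, member_idx, :].mean(axis=(0, 1))
    erd_m = (beta.times >= ERD_WINDOW[0]) & (beta.times < ERD_WINDOW[1])
    ers_m = (beta.times >= ERS_WINDOW[0]) & (beta.times <= ERS_WINDOW[1])
    return float(tc[erd_m].min()), float(tc[ers_m].max())


def _mini_session_extraction(scenario: SimScenario, record: SubjectRecord,
                             coeffs: dict, cal: dict, n_trials: int = 96) -> np.ndarray:
    """Mean per-trial peak ERD/ERS of a small noisy session (fixed sub-seed).

    The pipeline's subject-level statistic averages *per-trial* extrema, which
    are inflated by trial noise relative to the extrema of the noise-free
    expected time course. This measures that inflated statistic directly,
    with common random numbers so repeated calls are smooth in ``coeffs``.
    Returns array (n_regions, 2) of (peak ERD, peak ERS).
    """
    from .beta_metrics import extract_metrics

    rng = np.random.default_rng([scenario.seed % (2 ** 31), 4242, record.index])
    data = _background(scenario, n_trials, rng)
    envs = _region_envelopes(scenario, record, coeffs)
    lo, hi = scenario.carrier_band
    f = rng.uniform(lo, hi, size=n_trials)  # shared across regions, as in sessions
    for region in scenario.centres:
        ph = rng.uniform(0, 2 * np.pi, size=n_trials)
        sig = cal["amps"][region] * _carrier(scenario.times, f, ph) * np.sqrt(envs[region])[None, :]
        data += sig[:, None, :] * scenario.gains(region)[None, :, None]
    p, grid = _band_power_of(scenario, data)
    mu = p.mean(axis=-1, keepdims=True)
    beta = NormalizedBeta(value=(p - mu) / mu, times=grid,
                          band=scenario.carrier_band, band_power_mean=mu[..., 0],
                          flagged=np.zeros(n_trials, bool))
    out = np.empty((len(scenario.centres), 2))
    for i, region in enumerate(scenario.centres):
        roi = select_roi(beta, region, scenario.montage)
        m = extract_metrics(beta, roi, scenario.montage)
        out[i] = (m.subject["peak_erd"], m.subject["peak_ers"])
    return out


def _calibrate_subject(scenario: SimScenario, record: SubjectRecord,
                       tol: float = 0.02, loose_tol: float = 0.06) -> dict:
    """Solve the six envelope coefficients (c_d, c_s per region) jointly.

    Two nested levels. Inner: the realized ROI peak ERD/ERS of the noise-free
    expected time course respond to *all* regional coefficients
    (volume-conduction-like spatial leakage couples them), so they are solved
    as a joint bounded least-squares problem, with the data-driven ROI
    memberships frozen during each solve and refreshed between rounds.
    Outer: the pipeline's subject-level statistic is the mean of *per-trial*
    extrema, which trial noise inflates relative to the noise-free extrema; a
    fixed-seed mini-session measures the inflation and the noise-free targets
    are shifted to compensate (one correction round). Raises ParameterError
    when the targets are infeasible at the configured snr.
    """
    from scipy.optimize import least_squares

    cal = _scenario_calibration(scenario)
    regions = list(scenario.centres)
    mont = scenario.montage
    targets = np.array([[record.true_beta[r]["erd"], record.true_beta[r]["ers"]]
                        for r in regions])
    ers_scale = np.maximum(1.0, np.abs(targets[:, 1]))

    def coeffs_of(x):
        return {r: (x[2 * i], x[2 * i + 1]) for i, r in enumerate(regions)}

    lo = np.zeros(2 * len(regions))
    hi = np.empty_like(lo)
    hi[0::2] = 0.98
    hi[1::2] = 30.0

    def select_members(beta):
        out = {}
        for r in regions:
            roi = select_roi(beta, r, mont)
            out[r] = [mont.index(lab) for lab in roi.members]
        return out

    def solve(adj: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, float]:
        """Noise-free solve toward the (possibly shifted) targets ``adj``."""
        def residuals_with(rois):
            def f(xv):
                beta = _probe_beta(scenario, record, coeffs_of(xv), cal)
                res = np.empty(2 * len(regions))
                for i, r in enumerate(regions):
                    erd_m, ers_m = _window_extrema(beta, rois[r])
                    res[2 * i] = erd_m - adj[i, 0]
                    res[2 * i + 1] = (ers_m - adj[i, 1]) / ers_scale[i]
                return res
            return f

        x = x0.copy()
        err = np.inf
        for _ in range(3):
            beta = _probe_beta(scenario, record, coeffs_of(x), cal)
            fun = residuals_with(select_members(beta))
            if (err := np.max(np.abs(fun(x)))) < tol:
                return x, err
            sol = least_squares(fun, x, bounds=(lo, hi), diff_step=0.08,
                                xtol=1e-3, ftol=1e-4, max_nfev=60)
            x = sol.x
            beta = _probe_beta(scenario, record, coeffs_of(x), cal)
            err = np.max(np.abs(residuals_with(select_members(beta))(x)))
            if err < tol:
                return x, err
        return x, err

    x0 = np.empty(2 * len(regions))
    for i in range(len(regions)):
        x0[2 * i] = min(0.95, -targets[i, 0])
        x0[2 * i + 1] = max(targets[i, 1], 0.1)

    adj = targets.copy()
    x, err = solve(adj, x0)
    feasibility_err = err
    bias_norm = 0.0
    for _ in range(2):
        measured = _mini_session_extraction(scenario, record, coeffs_of(x), cal)
        bias = measured - targets
        bias_norm = float(np.max(np.abs(bias)
                                 / np.column_stack([np.ones(len(regions)), ers_scale])))
        if bias_norm < 1.5 * tol:
            break
        adj = adj - bias
        adj[:, 0] = np.clip(adj[:, 0], -0.95, -0.01)
        adj[:, 1] = np.clip(adj[:, 1], 0.05, 12.0)
        x, err = solve(adj, x)
    # The residual bias estimate carries the mini-session's Monte-Carlo noise,
    # so it is not held to the solver tolerance; only a large noise-free
    # residual together with a large measured bias marks true infeasibility.
    if feasibility_err > loose_tol and bias_norm > 2 * loose_tol:
        raise ParameterError(
            f"envelope calibration did not converge (noise-free residual "
            f"{feasibility_err:.3f}, measured bias {bias_norm:.3f}); ERD/ERS "
            f"targets are infeasible at snr={scenario.snr:.1f}"
        )
    return coeffs_of(x)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def generate_session(scenario: SimScenario, record: SubjectRecord) -> tuple[EpochedEEG, EMGTraces]:
    """Simulate one subject's full motor-task session (EEG epochs + EMG).

    Identical (scenario.seed, record.index) yield bit-identical arrays.
    """
    rng = np.random.default_rng([scenario.seed % (2 ** 31), 1000, record.index])
    n_tr = scenario.n_trials
    times = scenario.times
    data = _background(scenario, n_tr, rng)

    cal = _scenario_calibration(scenario)
    if record.no_dynamics:
        # flat envelopes: baseline beta present, no movement-locked dynamics
        coeffs = {r: (0.0, 0.0) for r in scenario.centres}
    else:
        coeffs = _calibrate_subject(scenario, record)
    envs = _region_envelopes(scenario, record, coeffs)
    lo, hi = scenario.carrier_band
    # one carrier frequency per trial, shared by the three regional sources
    # (independent phases): regional powers add incoherently across trials
    # without producing within-trial beat oscillations, which would otherwise
    # inflate the per-trial peak extraction
    f = rng.uniform(lo, hi, size=n_tr)
    for region in scenario.centres:
        ph = rng.uniform(0, 2 * np.pi, size=n_tr)
        sig = cal["amps"][region] * _carrier(times, f, ph) * np.sqrt(envs[region])[None, :]
        data += sig[:, None, :] * scenario.gains(region)[None, :, None]

    eeg = EpochedEEG(data, scenario.fs, times, scenario.montage)
    emg = _generate_emg(scenario, record, rng)
    return eeg, emg


def _generate_emg(scenario: SimScenario, record: SubjectRecord,
                  rng: np.random.Generator) -> EMGTraces:
    """Baseline noise plus a burst of high-frequency activity at the RT."""
    t = scenario.times_emg
    n_tr = scenario.n_trials
    noise_sd = 1.0
    data = rng.standard_normal((n_tr, len(t))) * noise_sd + 2.0  # DC offset, removed by rectification
    onset = record.rt_mean + rng.normal(0.0, scenario.rt_trial_sd, size=n_tr)
    onset = np.clip(onset, 0.05, 0.8)
    dur = np.clip(rng.normal(0.45, 0.08, size=n_tr), 0.15, 1.0)
    failed = rng.random(n_tr) < scenario.emg_fail_p
    ramp = 0.01  # burst rise/fall time, s
    for i in range(n_tr):
        if failed[i]:
            continue
        rise = 0.5 * (1 + np.tanh((t - onset[i]) / ramp))
        fall = 0.5 * (1 + np.tanh((onset[i] + dur[i] - t) / ramp))
        burst_env = rise * fall
        data[i] += 12.0 * noise_sd * burst_env * rng.standard_normal(len(t))
    return EMGTraces(data, scenario.fs_emg, t)


# ---------------------------------------------------------------------------
# Cohort generation (feature table + ground-truth beta targets)
# ---------------------------------------------------------------------------

def _pooled_spearman(loading: float, col: str, groups: tuple, scenario: SimScenario,
                     rng: np.random.Generator, n_mc: int = 4000) -> float:
    """MC estimate of the pooled Spearman between *col* and frontal depth."""
    xs, ys = [], []
    params = scenario.beta_params["frontal"]
    for g in groups:
        mu, sd = DEFAULT_MARGINALS[col][g]
        z = rng.standard_normal(n_mc)
        eps = rng.standard_normal(n_mc)
        val = mu + sd * (loading * z + math.sqrt(max(0.0, 1 - loading ** 2)) * eps)
        depth = params[g].depth_mean + params[g].depth_sd * z
        xs.append(val)
        ys.append(depth)
    rho = spearmanr(np.concatenate(xs), np.concatenate(ys)).statistic
    return float(rho)


def _solve_loading(col: str, target: float, groups: tuple,
                   scenario: SimScenario) -> float:
    """Bisection on the latent loading to hit the pooled Spearman target."""
    col_key = sum(ord(c) for c in col) % 1000  # stable across processes
    rng = np.random.default_rng([scenario.seed % (2 ** 31), 555, col_key])
    state = rng.bit_generator.state

    def rho_at(r: float) -> float:
        rng.bit_generator.state = state  # common random numbers
        return _pooled_spearman(r, col, groups, scenario, rng)

    lo, hi = -0.999, 0.999
    r_lo, r_hi = rho_at(lo), rho_at(hi)
    if not (min(r_lo, r_hi) - 0.02 <= target <= max(r_lo, r_hi) + 0.02):
        nearest = r_lo if abs(r_lo - target) < abs(r_hi - target) else r_hi
        raise ParameterError(
            f"pooled Spearman target {target:+.2f} for {col!r} infeasible; "
            f"achievable range [{min(r_lo, r_hi):+.2f}, {max(r_lo, r_hi):+.2f}] "
            f"(nearest achievable {nearest:+.2f})"
        )
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if (rho_at(mid) - target) * (r_lo - target) <= 0:
            hi = mid
        else:
            lo, r_lo = mid, rho_at(mid)
    return 0.5 * (lo + hi)


def _feature_loadings(scenario: SimScenario) -> dict:
    if "loadings" not in scenario._cache:
        scenario._cache["loadings"] = {
            col: (_solve_loading(col, target, groups, scenario), groups)
            for col, (target, groups) in scenario.rho_targets.items()
        }
    return scenario._cache["loadings"]


def _clip(col: str, v: float) -> float:
    lo, hi = _CLIP.get(col, (None, None))
    if lo is not None:
        v = max(lo, v)
    if hi is not None:
        v = min(hi, v)
    return v


def _draw_subject(scenario: SimScenario, group: str, index: int,
                  rng: np.random.Generator, loadings: dict) -> SubjectRecord:
    # latent severity factors: frontal anchor, coupled regional factors
    z_f = rng.standard_normal()
    rho_r = scenario.region_coupling
    z_reg = {"frontal": z_f}
    for region in ("left_sensorimotor", "right_sensorimotor"):
        z_reg[region] = rho_r * z_f + math.sqrt(1 - rho_r ** 2) * rng.standard_normal()

    true_beta = {}
    for region, by_group in scenario.beta_params.items():
        p = by_group[group]
        z = z_reg[region]
        true_beta[region] = {
            "erd": p.erd_mean - p.erd_sd * z,     # deeper dip with higher severity factor
            "ers": p.ers_mean + p.ers_sd * z,
            "depth": p.depth_mean + p.depth_sd * z,
            "erd_latency": float(np.clip(scenario.erd_latency + rng.normal(0, scenario.latency_sd), 0.1, 0.45)),
            "ers_latency": float(np.clip(scenario.ers_latency + rng.normal(0, scenario.latency_sd), 0.75, 0.95)),
        }

    feats: dict = {}
    feats["sex"] = "F" if rng.random() < _FEMALE_P[group] else "M"
    for col, by_group in DEFAULT_MARGINALS.items():
        mu, sd = by_group[group]
        if mu is None:
            feats[col] = None
            continue
        if col in loadings:
            r, groups = loadings[col]
            if group in groups:
                z_col = r * z_f + math.sqrt(1 - r ** 2) * rng.standard_normal()
            else:
                z_col = rng.standard_normal()
        else:
            z_col = rng.standard_normal()
        v = mu + sd * z_col
        # FSS must respect the group cut-off (label derives from FSS)
        if col == "FSS":
            for _ in range(200):
                ok = (v >= 4.0) if group == "MS-F" else (v < 4.0) if group == "MS-NF" else True
                if ok:
                    break
                z_col = (r * z_f + math.sqrt(1 - r ** 2) * rng.standard_normal()
                         if col in loadings and group in loadings[col][1]
                         else rng.standard_normal())
                v = mu + sd * z_col
            else:
                v = 4.01 if group == "MS-F" else 3.99
        feats[col] = _clip(col, v)
    feats["lesion_count"] = float(round(feats["lesion_count"]))

    for region, short in [("left_sensorimotor", "left"), ("right_sensorimotor", "right"),
                          ("frontal", "frontal")]:
        feats[f"beta_depth_{short}"] = true_beta[region]["depth"]

    # random predictor missingness (patients only), driving complete-case count
    if group != "HC" and rng.random() < scenario.p_missing:
        col = _MISSABLE[rng.integers(len(_MISSABLE))]
        feats[col] = None

    rt = scenario.rt_by_group[group] + rng.normal(0, scenario.rt_subject_sd)
    no_dyn = rng.random() < scenario.frac_no_dynamics
    return SubjectRecord(
        id=f"{group.replace('-', '')}{index:03d}", index=index, group=group,
        features=feats, true_beta=true_beta, rt_mean=float(np.clip(rt, 0.1, 0.7)),
        no_dynamics=no_dyn,
    )


def mean_subject(scenario: SimScenario, group: str, index: int = 0) -> SubjectRecord:
    """A subject whose targets are exactly the group means (no between-subject
    variation): the canonical ground truth for parameter-recovery checks."""
    true_beta = {}
    for region, by_group in scenario.beta_params.items():
        p = by_group[group]
        true_beta[region] = {
            "erd": p.erd_mean, "ers": p.ers_mean, "depth": p.depth_mean,
            "erd_latency": scenario.erd_latency, "ers_latency": scenario.ers_latency,
        }
    return SubjectRecord(
        id=f"{group.replace('-', '')}mean{index:03d}", index=index, group=group,
        features={}, true_beta=true_beta, rt_mean=scenario.rt_by_group[group],
    )


def generate_cohort(scenario: SimScenario) -> tuple[list[SubjectRecord], Callable]:
    """Draw the full cohort; returns (records, session_factory).

    ``session_factory(record)`` lazily simulates that subject's EEG + EMG via
    :func:`generate_session` (sessions are large; generate on demand).
    """
    loadings = _feature_loadings(scenario)
    records: list[SubjectRecord] = []
    idx = 0
    for group, n in zip(GROUPS, scenario.n_per_group):
        rng = np.random.default_rng([scenario.seed % (2 ** 31), 2000, GROUPS.index(group)])
        for _ in range(n):
            records.append(_draw_subject(scenario, group, idx, rng, loadings))
            idx += 1
    return records, lambda rec: generate_session(scenario, rec)


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Feature table as a DataFrame (one row per subject; NaN = missing)."""
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group, "fatigued": int(r.fatigued)}
        row.update({k: (np.nan if v is None else v) for k, v in r.features.items()})
        rows.append(row)
    return pd.DataFrame(rows)
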