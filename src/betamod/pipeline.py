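"""End-to-end per-subject analysis: epochs -> CSD -> beta power -> ROI metrics.

Glue for the common case: take one subject's cue-locked EEG epochs (and
optionally the EMG-based trial exclusion), run the current source density
transform, Morlet beta-band power on the 10 ms grid, whole-trial
subtract-and-divide normalization, personalized-ROI selection, and per-trial
metric extraction for the three candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beta_metrics import BetaMetrics, exclude_no_modulation, subject_metrics
from .containers import EMGTraces, EpochedEEG
from .preprocess import EMGTrialMetrics, process_emg
from .spectral import BETA_BAND, baseline_normalize, beta_band_power, csd_transform

__all__ = ["SubjectResult", "analyze_session"]


@dataclass
class SubjectResult:
    """Per-region metrics plus bookkeeping for one analyzed session."""

    metrics: dict[str, BetaMetrics]       # region -> BetaMetrics
    kept: bool                            # False = no discernible beta dynamics
    kept_trial_ids: np.ndarray
    emg_metrics: list[EMGTrialMetrics] | None = None

    def depth(self, region: str) -> float:
        return self.metrics[region].subject["modulation_depth"]


def analyze_session(
    eeg: EpochedEEG,
    emg: EMGTraces | None = None,
    band: tuple[float, float] = BETA_BAND,
) -> SubjectResult:
    """Run the full beta ERD/ERS pipeline on one subject's session.

    When EMG is given, trials without a clear EMG burst are excluded jointly
    from the EEG metrics (same trial ids on both sides).
    """
    emg_metrics = None
    kept_ids = eeg.trial_ids
    if emg is not None:
        emg_metrics = process_emg(emg)
        kept_ids = np.array([m.trial_id for m in emg_metrics if m.kept])
        eeg = eeg.select_trials(kept_ids)
    if eeg.n_trials == 0:
        raise ValueError("no kept trials after EMG exclusion")
    csd = csd_transform(eeg)
    tfr = beta_band_power(csd, band=band)
    beta = baseline_normalize(tfr, band=band, trial_ids=eeg.trial_ids)
    metrics = subject_metrics(beta, eeg.montage)
    return SubjectResult(
        metrics=metrics,
        kept=exclude_no_modulation(metrics),
        kept_trial_ids=kept_ids,
        emg_metrics=emg_metrics,
    )
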