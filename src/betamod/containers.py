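"""In-memory containers shared across the pipeline, with plain-text/NPZ I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import Montage

__all__ = ["EpochedEEG", "EMGTraces"]


@dataclass
class EpochedEEG:
    """Cue-locked EEG epochs: ``data`` is (n_trials, n_channels, n_samples).

    ``times`` are seconds relative to the cue and span [-0.5, 1.5) at the
    recording rate. ``trial_ids`` tracks provenance through trial exclusion so
    EEG/EMG bookkeeping stays joint. ``units`` flips from "uV" to "uV/r^2"
    after the current-source-density transform (unit head radius).
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    montage: Montage
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[1]} channels but montage has {len(self.montage)}"
            )
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match sample axis")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in epoched data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, ids) -> "EpochedEEG":
        mask = np.isin(self.trial_ids, np.asarray(ids))
        return EpochedEEG(
            self.data[mask], self.fs, self.times, self.montage,
            trial_ids=self.trial_ids[mask], units=self.units,
        )

    def save(self, path) -> None:
        path = Path(path)
        np.savez(
            path,
            data=self.data, fs=self.fs, times=self.times,
            trial_ids=self.trial_ids, units=np.str_(self.units),
            labels=np.array(self.montage.labels),
            positions=self.montage.positions,
        )

    @classmethod
    def load(cls, path) -> "EpochedEEG":
        with np.load(path, allow_pickle=False) as z:
            mont = Montage(tuple(str(s) for s in z["labels"]), z["positions"])
            return cls(
                z["data"], float(z["fs"]), z["times"], mont,
                trial_ids=z["trial_ids"], units=str(z["units"]),
            )


@dataclass
class EMGTraces:
    """Single-channel EMG per trial: ``data`` is (n_trials, n_samples).

    Sampled at ``fs`` (EMG rate, independent of the EEG rate) on the same
    cue-relative window as the EEG epochs.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (trials, samples)")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.data.shape[1],):
            raise ValueError("times length must match sample axis")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]
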