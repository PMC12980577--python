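"""Personalized-ROI beta ERD/ERS metrics.

The core statistic: on the whole-trial-normalized beta (13.5-25 Hz) power
time course, peak ERD is the minimum in the movement window [0, 0.7) s after
the cue, peak ERS the maximum in the rebound window [0.7, 1.0] s, and the
modulation depth their difference (ERS - ERD). ROIs are personalized in two
passes: within each of three printed candidate regions, the electrode with the
largest trial-averaged modulation depth is found, the ROI is that electrode
plus its six nearest montage neighbours, and the per-trial metrics are then
re-computed on the ROI-mean time course.

Window conventions: the ERD window is half-open [0, 0.7) and the ERS window
closed [0.7, 1.0], so the 0.7 s grid sample belongs to the ERS window only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import CANDIDATE_REGIONS, Montage, MontageError
from .spectral import NormalizedBeta

__all__ = [
    "PersonalizedROI",
    "BetaMetrics",
    "select_roi",
    "extract_metrics",
    "exclude_no_modulation",
    "subject_metrics",
    "metrics_frame",
    "ERD_WINDOW",
    "ERS_WINDOW",
]

ERD_WINDOW = (0.0, 0.7)   # [0, 0.7)
ERS_WINDOW = (0.7, 1.0)   # [0.7, 1.0]


@dataclass(frozen=True)
class PersonalizedROI:
    region: str
    peak_electrode: str
    members: tuple[str, ...]  # peak + 6 nearest neighbours

    def __post_init__(self) -> None:
        if len(self.members) != 7:
            raise ValueError("personalized ROI must have exactly 7 members")
        if self.peak_electrode not in self.members:
            raise ValueError("peak electrode must be an ROI member")


@dataclass
class BetaMetrics:
    """Per-trial and trial-averaged ROI metrics for one subject and region."""

    roi: PersonalizedROI
    # per-trial arrays
    peak_erd: np.ndarray
    erd_latency: np.ndarray
    peak_ers: np.ndarray
    ers_latency: np.ndarray
    modulation_depth: np.ndarray
    mean_beta: np.ndarray          # epoch-mean of normalized ROI time course (~0)
    band_power: np.ndarray         # pre-normalization ROI band power, per trial
    trial_ids: np.ndarray
    # extrema of the trial-averaged ROI time course (noise averages out here,
    # unlike in the mean of per-trial extrema) — used by the exclusion rule
    avg_peak_erd: float = 0.0
    avg_peak_ers: float = 0.0
    # subject-level (mean over kept trials)
    subject: dict[str, float] | None = None

    def summarize(self) -> dict[str, float]:
        self.subject = {
            "peak_erd": float(self.peak_erd.mean()),
            "erd_latency": float(self.erd_latency.mean()),
            "peak_ers": float(self.peak_ers.mean()),
            "ers_latency": float(self.ers_latency.mean()),
            "modulation_depth": float(self.modulation_depth.mean()),
            "mean_beta": float(self.mean_beta.mean()),
            "band_power": float(self.band_power.mean()),
        }
        return self.subject


def _window_masks(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    erd = (times >= ERD_WINDOW[0]) & (times < ERD_WINDOW[1])
    ers = (times >= ERS_WINDOW[0]) & (times <= ERS_WINDOW[1])
    return erd, ers


def _depth_of(tc: np.ndarray, times: np.ndarray) -> float:
    """Modulation depth (max in ERS window - min in ERD window) of one course."""
    erd, ers = _window_masks(times)
    return float(tc[ers].max() - tc[erd].min())


def select_roi(
    beta: NormalizedBeta,
    region: str,
    montage: Montage,
    restrict_neighbours: bool = False,
) -> PersonalizedROI:
    """Find the subject's peak-modulation electrode and its 6 nearest neighbours.

    Works on the trial-averaged time course. Depth ties are broken by distance
    to the region centroid, then lexicographically. Neighbour search ranges
    over the whole montage unless ``restrict_neighbours``.
    """
    try:
        members = CANDIDATE_REGIONS[region]
    except KeyError:
        raise MontageError(f"unknown candidate region {region!r}") from None
    avg = beta.value.mean(axis=0)  # (channels, times)
    idx = [montage.index(lab) for lab in members]
    depths = np.array([_depth_of(avg[i], beta.times) for i in idx])
    centroid = montage.positions[idx].mean(axis=0)
    centroid /= np.linalg.norm(centroid)
    dist_c = np.linalg.norm(montage.positions[idx] - centroid, axis=1)
    order = sorted(
        range(len(members)),
        key=lambda k: (-depths[k], dist_c[k], members[k]),
    )
    peak = members[order[0]]
    if restrict_neighbours:
        d = montage.distances_from(peak)
        pool = sorted(
            (lab for lab in members if lab != peak),
            key=lambda lab: (d[montage.index(lab)], lab),
        )
        neigh = pool[:6]
    else:
        neigh = montage.nearest_neighbours(peak, 6)
    return PersonalizedROI(region=region, peak_electrode=peak,
                           members=(peak, *neigh))


def extract_metrics(beta: NormalizedBeta, roi: PersonalizedROI,
                    montage: Montage) -> BetaMetrics:
    """Per-trial peaks/latencies/depth on the ROI-mean time course.

    The ROI time course is the mean of the 7 member channels of the
    *normalized* per-trial power; peaks are then read off that single course
    (no per-electrode peak-picking at this stage).
    """
    idx = [montage.index(lab) for lab in roi.members]
    tc = beta.value[:, idx, :].mean(axis=1)         # (trials, times)
    bp = beta.band_power_mean[:, idx].mean(axis=1)  # (trials,)
    erd_m, ers_m = _window_masks(beta.times)
    t_erd, t_ers = beta.times[erd_m], beta.times[ers_m]
    erd_seg, ers_seg = tc[:, erd_m], tc[:, ers_m]
    i_min = erd_seg.argmin(axis=1)
    i_max = ers_seg.argmax(axis=1)
    rows = np.arange(tc.shape[0])
    peak_erd = erd_seg[rows, i_min]
    peak_ers = ers_seg[rows, i_max]
    avg = tc.mean(axis=0)
    ids = beta.trial_ids if beta.trial_ids is not None else np.arange(tc.shape[0])
    m = BetaMetrics(
        roi=roi,
        peak_erd=peak_erd,
        erd_latency=t_erd[i_min],
        peak_ers=peak_ers,
        ers_latency=t_ers[i_max],
        modulation_depth=peak_ers - peak_erd,
        mean_beta=tc.mean(axis=1),
        band_power=bp,
        trial_ids=np.asarray(ids),
        avg_peak_erd=float(avg[erd_m].min()),
        avg_peak_ers=float(avg[ers_m].max()),
    )
    m.summarize()
    return m


def exclude_no_modulation(
    metrics: dict[str, BetaMetrics],
    erd_threshold: float = -0.2,
    ers_threshold: float = 0.2,
) -> bool:
    """True = keep the subject; False = no discernible beta dynamics anywhere.

    A subject is excluded when in *every* ROI the trial-averaged time course
    fails to dip below ``erd_threshold`` or to rebound above
    ``ers_threshold`` — i.e. no region shows a clear dip-plus-rebound. The
    rule reads the extrema of the *averaged* course, not the average of
    per-trial extrema: the latter are inflated by trial noise even for a flat
    envelope, which would defeat the rule's purpose.
    """
    for m in metrics.values():
        if m.avg_peak_erd <= erd_threshold and m.avg_peak_ers >= ers_threshold:
            return True
    return False


def subject_metrics(beta: NormalizedBeta, montage: Montage,
                    regions=tuple(CANDIDATE_REGIONS)) -> dict[str, BetaMetrics]:
    """ROI selection + per-trial extraction for every candidate region."""
    out: dict[str, BetaMetrics] = {}
    for region in regions:
        roi = select_roi(beta, region, montage)
        out[region] = extract_metrics(beta, roi, montage)
    return out


def metrics_frame(per_subject: dict[str, dict[str, BetaMetrics]]) -> pd.DataFrame:
    """Tidy frame: one row per (subject, region, trial, metric)."""
    rows = []
    for sid, by_region in per_subject.items():
        for region, m in by_region.items():
            for k, tid in enumerate(m.trial_ids):
                for name, arr in [
                    ("peak_erd", m.peak_erd), ("erd_latency", m.erd_latency),
                    ("peak_ers", m.peak_ers), ("ers_latency", m.ers_latency),
                    ("modulation_depth", m.modulation_depth),
                    ("mean_beta", m.mean_beta),
                ]:
                    rows.append((sid, region, int(tid), name, float(arr[k])))
    return pd.DataFrame(rows, columns=["subject", "region", "trial", "metric", "value"])
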