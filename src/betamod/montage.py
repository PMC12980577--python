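"""Idealized 61-channel 10-10 scalp montage on the unit sphere.

The montage provides the geometry the rest of the pipeline needs: unit-sphere
electrode positions for the spherical-spline current source density transform,
for nearest-neighbour ROI construction, and for the spatially correlated
synthetic background EEG. Positions are an idealized spherical layout built
from the standard 10-10 construction (midline electrodes at 10% steps along
the nasion-inion arc, rim electrodes at 18 degree azimuth steps on the head
circumference, interior electrodes equally spaced along the arc joining the
midline electrode of their row to the rim electrode of their row). Real caps
deviate slightly from this ideal; for synthetic work only the topology and
smooth distances matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_61_montage", "CANDIDATE_REGIONS", "MontageError"]


class MontageError(ValueError):
    """Raised for unknown labels or degenerate electrode geometry."""


# Candidate-region electrode lists used to seed the personalized-ROI search.
# The region names follow the naming used in the motor-task literature for a
# right-hand pinch task; note the "left_sensorimotor" list intentionally
# contains even-numbered (right-hemisphere) labels and vice versa — the lists
# index the hemisphere *contralateral to the responding effector's cortex*
# naming convention of the source protocol and are used verbatim.
CANDIDATE_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "AFz", "AF3", "AF4", "Fz", "F1", "F2", "F3", "F4", "F5", "F6",
        "FCz", "FC1", "FC2", "FC3", "FC4",
    ),
    "left_sensorimotor": (
        "Cz", "C2", "C4", "C6", "CP6", "CP4", "CP2", "CPz", "P6", "P4", "P2", "Pz",
    ),
    "right_sensorimotor": (
        "Cz", "C1", "C3", "C5", "CPz", "CP1", "CP3", "CP5", "Pz", "P1", "P3", "P5",
    ),
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels with 3-D unit-sphere positions (head-centred).

    Axes: +x right ear, +y nasion, +z vertex. Positions are dimensionless
    (unit head radius).
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise MontageError("duplicate electrode labels")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise MontageError(f"positions shape {pos.shape} != ({len(self.labels)}, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MontageError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"unknown electrode label {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def distances_from(self, label: str) -> np.ndarray:
        """Euclidean distances from *label* to every electrode (chord length)."""
        return np.linalg.norm(self.positions - self.position(label), axis=1)

    def nearest_neighbours(self, label: str, k: int) -> list[str]:
        """The *k* nearest electrodes to *label*, excluding itself.

        Ties broken lexicographically for determinism.
        """
        d = self.distances_from(label)
        order = sorted(
            (i for i in range(len(self)) if self.labels[i] != label),
            key=lambda i: (d[i], self.labels[i]),
        )
        return [self.labels[i] for i in order[:k]]

    def save(self, path) -> None:
        """Write a whitespace-delimited ``label x y z`` electrode file."""
        with open(path, "w") as fh:
            for lab, p in zip(self.labels, self.positions):
                fh.write(f"{lab} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")

    @classmethod
    def load(cls, path) -> "Montage":
        labels, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:4]])
        return cls(tuple(labels), np.asarray(rows))


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Point at *frac* of the great-circle arc from a to b (unit vectors)."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def _equator_point(azimuth_deg: float) -> np.ndarray:
    """Rim point; azimuth measured from nasion (+y), positive toward left (-x)."""
    a = np.deg2rad(azimuth_deg)
    return np.array([-np.sin(a), np.cos(a), 0.0])


def _midline_point(polar_deg: float) -> np.ndarray:
    """Midline point at *polar_deg* from vertex; positive toward nasion."""
    t = np.deg2rad(polar_deg)
    return np.array([0.0, np.sin(t), np.cos(t)])


# (row prefix, midline polar angle from vertex [deg, + front], rim azimuth of
#  the row's outermost electrode [deg from nasion], interior electrode numbers)
_ROWS = [
    ("Fp", 72.0, 18.0, []),          # Fp1/Fp2 sit on the rim themselves
    ("AF", 54.0, 36.0, [3]),
    ("F", 36.0, 54.0, [1, 3, 5]),
    ("FC", 18.0, 72.0, [1, 3, 5]),
    ("C", 0.0, 90.0, [1, 3, 5]),
    ("CP", -18.0, 108.0, [1, 3, 5]),
    ("P", -36.0, 126.0, [1, 3, 5]),
    ("PO", -54.0, 144.0, [3]),
    ("O", -72.0, 162.0, []),
]

# rim label per row & hemisphere: odd = left, even = right
_RIM = {
    "Fp": ("Fp1", "Fp2"), "AF": ("AF7", "AF8"), "F": ("F7", "F8"),
    "FC": ("FT7", "FT8"), "C": ("T7", "T8"), "CP": ("TP7", "TP8"),
    "P": ("P7", "P8"), "PO": ("PO7", "PO8"), "O": ("O1", "O2"),
}

_MIDLINE = {
    "Fp": "Fpz", "AF": "AFz", "F": "Fz", "FC": "FCz", "C": "Cz",
    "CP": "CPz", "P": "Pz", "PO": "POz", "O": "Oz",
}


def standard_61_montage() -> Montage:
    """The 61-channel average-referenced scalp set used throughout.

    9 sagittal rows (Fp..O) with a midline electrode, rim electrodes on the
    head circumference, and interior electrodes interpolated along each row
    arc — 61 labels total, covering every member of the three candidate
    regions.
    """
    labels: list[str] = []
    positions: list[np.ndarray] = []

    for prefix, polar, rim_az, interior in _ROWS:
        mid = _midline_point(polar)
        labels.append(_MIDLINE[prefix])
        positions.append(mid)
        rim_l = _equator_point(rim_az)
        rim_r = _equator_point(-rim_az)
        lab_l, lab_r = _RIM[prefix]
        # interior electrodes: equal arc fractions between midline and rim
        n_seg = len(interior) + 1
        for k, num in enumerate(interior, start=1):
            frac = k / n_seg
            labels.append(f"{prefix}{num}")
            positions.append(_slerp(mid, rim_l, frac))
            labels.append(f"{prefix}{num + 1}")
            positions.append(_slerp(mid, rim_r, frac))
        labels.append(lab_l)
        positions.append(rim_l)
        labels.append(lab_r)
        positions.append(rim_r)

    pos = np.array(positions)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    mont = Montage(tuple(labels), pos)
    assert len(mont) == 61
    for region in CANDIDATE_REGIONS.values():
        for lab in region:
            mont.index(lab)  # raises MontageError if missing
    return mont
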