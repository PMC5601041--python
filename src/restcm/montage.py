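"""Electrode montages on the unit sphere.

Coordinate convention (normalized head units): the sphere center is the
origin, x points to the right ear, y to the nasion, z to the vertex.  All
electrode positions are unit vectors (the scalp has radius 1.0 in the
normalized three-shell head model).

The packaged 63-channel cap is built analytically from the proportional-arc
construction of the extended 10/20 (10/10) system: the outer 10% ring sits at
polar angle 72 deg from the vertex, midline electrodes step by 18 deg along the
nasion-inion arc, and interior electrodes are placed by great-circle
interpolation between the midline electrode and the ring electrode of the same
coronal row.  TP9/TP10 sit on the equator below TP7/TP8.  VEOG/HEOG carry
nominal periocular positions and are flagged non-scalp.  This is an idealized
fixture, not digitized ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "standard_cap63",
    "cm_montage",
    "read_sfp",
    "write_sfp",
    "ideal_position",
]

#: labels excluded from CM analysis on top of the non-scalp channels
MASTOIDS = ("TP9", "TP10")
EOG_LABELS = ("VEOG", "HEOG")


@dataclass(frozen=True)
class ElectrodeMontage:
    """A named set of electrode positions on the unit sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit vectors
    non_scalp: frozenset[str] = field(default_factory=frozenset)
    name: str = "montage"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, 1.0, atol=1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage {self.name!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    @property
    def scalp_mask(self) -> np.ndarray:
        return np.array([l not in self.non_scalp for l in self.labels])

    def subset(self, labels) -> "ElectrodeMontage":
        idx = [self.index(l) for l in labels]
        return ElectrodeMontage(
            labels=tuple(labels),
            positions=self.positions[idx],
            non_scalp=self.non_scalp & set(labels),
            name=self.name + ":subset",
        )

    def drop(self, labels) -> "ElectrodeMontage":
        drop = set(labels)
        keep = [l for l in self.labels if l not in drop]
        return self.subset(keep)


# ---------------------------------------------------------------------------
# ideal extended 10/20 construction


def _sph(polar_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector at polar angle from vertex, azimuth from nasion (+ = right)."""
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])

def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    w = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if w < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * w) * a + np.sin(t * w) * b) / np.sin(w)


def _ideal_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # midline, 18 deg (10%) steps along the nasion-inion arc
    midline = {
        "Fpz": -72, "AFz": -54, "Fz": -36, "FCz": -18, "Cz": 0,
        "CPz": 18, "Pz": 36, "POz": 54, "Oz": 72,
    }
    for lab, ang in midline.items():
        pos[lab] = _sph(abs(ang), 0.0 if ang <= 0 else 180.0)
    # outer 10% ring at polar 72 deg; azimuth steps of 18 deg (5% of circumference)
    ring = ["Fp", "AF", "F", "FT", "T", "TP", "P", "PO", "O"]
    ring_num = {"Fp": ("1", "2"), "AF": ("7", "8"), "F": ("7", "8"), "FT": ("7", "8"),
                "T": ("7", "8"), "TP": ("7", "8"), "P": ("7", "8"), "PO": ("7", "8"),
                "O": ("1", "2")}
    for i, row in enumerate(ring):
        az = 18.0 * (i + 1)
        left, right = ring_num[row]
        pos[row + left] = _sph(72.0, -az)
        pos[row + right] = _sph(72.0, az)
    # interior rows: great-circle interpolation midline -> ring electrode
    interior = {
        "AF": ("3", "4"),
        "F": ("1", "2", "3", "4", "5", "6"),
        "FC": ("1", "2", "3", "4", "5", "6"),
        "C": ("1", "2", "3", "4", "5", "6"),
        "CP": ("1", "2", "3", "4", "5", "6"),
        "P": ("1", "2", "3", "4", "5", "6"),
        "PO": ("3", "4"),
    }
    ring_of = {"FC": "FT", "C": "T", "CP": "TP"}  # rows whose ring anchor is named differently
    for row, nums in interior.items():
        mid = pos[row + "z"]
        anchor = ring_of.get(row, row)
        for num in nums:
            n = int(num)
            side = "7" if n % 2 == 1 else "8"
            edge = pos[anchor + side]
            if row in ("AF", "PO"):
                t = 0.5
            else:
                t = (n + 1) // 2 / 4.0  # 1,2 -> 0.25; 3,4 -> 0.5; 5,6 -> 0.75
            pos[row + num] = _slerp(mid, edge, t)
    # inferior row: equator, 10% below the FT/TP/PO ring electrodes
    pos["FT9"] = _sph(90.0, -72.0)
    pos["FT10"] = _sph(90.0, 72.0)
    pos["TP9"] = _sph(90.0, -108.0)
    pos["TP10"] = _sph(90.0, 108.0)
    pos["PO9"] = _sph(90.0, -144.0)
    pos["PO10"] = _sph(90.0, 144.0)
    # nominal periocular positions (non-scalp placeholders)
    pos["VEOG"] = _sph(100.0, -18.0)
    pos["HEOG"] = _sph(95.0, -54.0)
    return pos


_IDEAL = _ideal_positions()


def ideal_position(label: str) -> np.ndarray:
    """Unit-sphere position of an extended 10/20 label (e.g. a virtual FCz)."""
    try:
        return _IDEAL[label].copy()
    except KeyError:
        raise KeyError(f"no ideal position for label {label!r}") from None


#: the 61 scalp channels of the packaged cap (reference FCz and ground AFz excluded)
CAP61_LABELS = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F3", "F1", "Fz", "F2", "F4", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C3", "C1", "Cz", "C2", "C4", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
)


def standard_cap63() -> ElectrodeMontage:
    """The packaged 63-channel montage: 61 scalp electrodes + VEOG/HEOG."""
    labels = CAP61_LABELS + EOG_LABELS
    positions = np.array([_IDEAL[l] for l in labels])
    return ElectrodeMontage(
        labels=labels,
        positions=positions,
        non_scalp=frozenset(EOG_LABELS),
        name="cap63",
    )


def cm_montage(montage: ElectrodeMontage | None = None) -> ElectrodeMontage:
    """CM analysis montage: EOG and mastoid electrodes removed (59 channels
    for the packaged cap)."""
    if montage is None:
        montage = standard_cap63()
    drop = set(montage.non_scalp) | set(MASTOIDS)
    out = montage.drop([l for l in montage.labels if l in drop])
    return ElectrodeMontage(out.labels, out.positions, frozenset(), name="cm59")


# ---------------------------------------------------------------------------
# .sfp I/O (label x y z per line)


def read_sfp(path, non_scalp=EOG_LABELS) -> ElectrodeMontage:
    """Read a .sfp montage and normalize positions to the unit sphere."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed .sfp line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    pos = np.asarray(rows, dtype=float)
    radii = np.linalg.norm(pos, axis=1)
    if np.any(radii <= 0):
        raise ValueError("electrode at the origin cannot be normalized")
    pos = pos / radii[:, None]
    return ElectrodeMontage(
        labels=tuple(labels),
        positions=pos,
        non_scalp=frozenset(l for l in labels if l in set(non_scalp)),
        name=str(path),
    )


def write_sfp(montage: ElectrodeMontage, path) -> None:
    with open(path, "w") as fh:
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{p[0]:.8f}\t{p[1]:.8f}\t{p[2]:.8f}\n")
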