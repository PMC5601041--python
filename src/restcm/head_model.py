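"""Three-concentric-sphere volume conductor and lead fields.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) with normalized radii (0.87, 0.92, 1.0) and conductivity ratios
(1.0, 0.0125, 1.0).  The potential of a current dipole inside the brain
compartment is the classic Legendre / associated-Legendre series: for each
spherical-harmonic degree n the primary (infinite-medium) coefficient is
scaled by a shell-transfer factor f_n obtained from the boundary conditions
(potential and radial current continuity at the two interfaces, zero radial
current at the scalp surface).  For equal conductivities f_n reduces to the
bounded homogeneous-sphere factor (2n+1)/n.

The scalp potential of a dipole with moment m at position r0 (|r0| = b < r_brain),
observed at a scalp electrode r_e (|r_e| = 1) is

    V = 1/(4 pi sigma_brain) * sum_n  b^(n-1) f_n
        [ n m_r P_n(cos g) + m_t P_n^1(cos g) cos phi ]

with g the angle between r_e and the dipole axis, m_r / m_t the radial /
tangential moment components, and phi the electrode azimuth about the dipole
axis measured from the tangential moment direction.  Associated Legendre
functions are used without the Condon-Shortley phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .montage import ElectrodeMontage, ideal_position

__all__ = [
    "HeadModel",
    "DipoleGrid",
    "LeadField",
    "dipole_potential",
    "build_dipole_grid",
    "leadfield_infinity",
    "leadfield_for_reference",
]

#: default series truncation degree; the tail beyond degree 160 is below
#: 1e-9 relative at the grid's maximum source eccentricity (0.86)
DEFAULT_MAX_DEGREE = 160


@dataclass(frozen=True)
class HeadModel:
    """Three-shell spherical head model (normalized units)."""

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0)

    def __post_init__(self) -> None:
        r = self.radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("radii must be strictly increasing and positive")
        if abs(r[2] - 1.0) > 1e-12:
            raise ValueError("outermost (scalp) radius must be 1.0")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]


@lru_cache(maxsize=32)
def _shell_factors(radii: tuple, conductivities: tuple, n_max: int) -> np.ndarray:
    """Per-degree surface transfer factors f_n, n = 0..n_max (f_0 unused).

    Solves, for each degree, the 5x5 linear system in the shell expansion
    coefficients (A1; A2, B2; A3, B3) with the primary coefficient normalized
    to 1; f_n is the scalp-surface potential coefficient A3 + B3.
    """
    r1, r2, _ = radii
    s1, s2, s3 = conductivities
    f = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        A = np.array([
            [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0],
            [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
             s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0],
            [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))],
            [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
             -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)],
            [0.0, 0.0, 0.0, float(n), -(float(n) + 1)],
        ])
        b = np.array([-(r1 ** -(n + 1)), s1 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0, 0.0])
        sol = np.linalg.solve(A, b)
        f[n] = sol[3] + sol[4]
    return f


def shell_transfer_factors(model: HeadModel, n_max: int = DEFAULT_MAX_DEGREE) -> np.ndarray:
    return _shell_factors(tuple(model.radii), tuple(model.conductivities), int(n_max))


class ConvergenceError(RuntimeError):
    pass


def _axis_geometry(dip_pos: np.ndarray, elec_dirs: np.ndarray):
    """cos(gamma), P-azimuth unit vectors and dipole axis for one dipole.

    elec_dirs: (E, 3) unit vectors.  Returns (zhat, cosg (E,), ehat (E, 3))
    where ehat is the tangential direction of each electrode about the dipole
    axis (zero vector where electrode and axis are collinear).
    """
    b = np.linalg.norm(dip_pos)
    zhat = dip_pos / b if b > 1e-14 else np.array([0.0, 0.0, 1.0])
    cosg = np.clip(elec_dirs @ zhat, -1.0, 1.0)
    perp = elec_dirs - cosg[:, None] * zhat
    sing = np.linalg.norm(perp, axis=1)
    ehat = np.zeros_like(perp)
    ok = sing > 1e-12
    ehat[ok] = perp[ok] / sing[ok, None]
    return b, zhat, cosg, ehat


def dipole_potential(
    model: HeadModel,
    dipole_position,
    dipole_moment,
    electrode_position,
    max_degree: int = DEFAULT_MAX_DEGREE,
    tol: float = 1e-10,
) -> float:
    """Infinity-referenced scalp potential of a single dipole (series solution).

    Parameters are in normalized head units; the result is linear in the
    dipole moment.  Raises on sources at or outside the inner-skull radius and
    when the series has not converged to `tol` (relative) at `max_degree`.
    """
    r0 = np.asarray(dipole_position, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    re = np.asarray(electrode_position, dtype=float)
    b = np.linalg.norm(r0)
    if b >= model.brain_radius:
        raise ValueError(
            f"dipole eccentricity {b:.4f} is not inside the brain compartment "
            f"(radius {model.brain_radius})"
        )
    if abs(np.linalg.norm(re) - 1.0) > 1e-6:
        raise ValueError("electrode must lie on the scalp surface (radius 1.0)")
    if not np.any(m):
        return 0.0

    f = shell_transfer_factors(model, max_degree)
    b_, zhat, cosg, ehat = _axis_geometry(r0, re[None, :] / np.linalg.norm(re))
    cosg = float(cosg[0])
    sing = float(np.sqrt(max(0.0, 1.0 - cosg * cosg)))
    m_r = float(m @ zhat)
    m_perp = m - m_r * zhat
    mt_cosphi = float(m_perp @ ehat[0])

    total = 0.0
    p_nm1, p_n = 1.0, cosg                # P_0, P_1
    q_nm1, q_n = 0.0, sing                # P_0^1, P_1^1 (no Condon-Shortley phase)
    last_rel = np.inf
    for n in range(1, max_degree + 1):
        if n > 1:
            p_nm1, p_n = p_n, ((2 * n - 1) * cosg * p_n - (n - 1) * p_nm1) / n
            q_nm1, q_n = q_n, ((2 * n - 1) * cosg * q_n - n * q_nm1) / (n - 1)
        term = b ** (n - 1) * f[n] * (n * m_r * p_n + mt_cosphi * q_n)
        total += term
        scale = max(abs(total), 1e-300)
        last_rel = abs(term) / scale
        # envelope bound on the remaining tail (|P_n| <= 1, |P_n^1| <= n)
        bound = b**n * abs(f[min(n, max_degree)]) * n * (abs(m_r) + abs(mt_cosphi))
        if last_rel < tol and bound / scale < tol * 10:
            break
    else:
        if last_rel > 1e-6 and b > 0:
            raise ConvergenceError(
                f"series not converged at degree {max_degree} (last term rel {last_rel:.2e})"
            )
    return total / (4.0 * np.pi * model.conductivities[0])


# ---------------------------------------------------------------------------
# dipole grid


@dataclass(frozen=True)
class DipoleGrid:
    """Origin-anchored cubic lattice of dipole locations inside the brain."""

    positions: np.ndarray  # (n, 3)
    spacing: float
    radius_limit: float
    hemisphere_only: bool = True

    def __len__(self) -> int:
        return len(self.positions)


def build_dipole_grid(
    spacing: float = 0.0905,
    radius_limit: float = 0.86,
    hemisphere_only: bool = True,
) -> DipoleGrid:
    """All lattice points (i d, j d, k d) with x^2+y^2+z^2 <= radius_limit^2
    (and z >= 0 when hemisphere_only), ordered lexicographically in (k, i, j).

    The defaults reproduce the 1994-point upper-hemisphere source grid.
    """
    if spacing <= 0 or radius_limit <= 0:
        raise ValueError("spacing and radius_limit must be positive")
    nmax = int(np.floor(radius_limit / spacing))
    idx = np.arange(-nmax, nmax + 1)
    pts = []
    kk = idx[idx >= 0] if hemisphere_only else idx
    for k in kk:
        for i in idx:
            for j in idx:
                if (i * i + j * j + k * k) * spacing**2 <= radius_limit**2:
                    pts.append((i * spacing, j * spacing, k * spacing))
    return DipoleGrid(
        positions=np.array(pts, dtype=float),
        spacing=float(spacing),
        radius_limit=float(radius_limit),
        hemisphere_only=bool(hemisphere_only),
    )


# ---------------------------------------------------------------------------
# lead fields


@dataclass(frozen=True)
class LeadField:
    """Gain matrix: electrodes x (3 * dipoles), orientation order x, y, z."""

    gain: np.ndarray
    montage: ElectrodeMontage
    grid: DipoleGrid
    model: HeadModel
    reference_tag: str = "infinity"

    def __post_init__(self) -> None:
        if self.gain.shape != (len(self.montage), 3 * len(self.grid)):
            raise ValueError("gain shape inconsistent with montage/grid")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    def column(self, dipole: int, orientation: int | str) -> np.ndarray:
        o = "xyz".index(orientation) if isinstance(orientation, str) else int(orientation)
        return self.gain[:, 3 * dipole + o]


def _gain_matrix(
    model: HeadModel,
    elec_pos: np.ndarray,
    dip_pos: np.ndarray,
    max_degree: int = DEFAULT_MAX_DEGREE,
) -> np.ndarray:
    """Vectorized series evaluation: (E, 3*D) gain, infinity reference."""
    E = len(elec_pos)
    D = len(dip_pos)
    f = shell_transfer_factors(model, max_degree)
    elec_dirs = elec_pos / np.linalg.norm(elec_pos, axis=1, keepdims=True)

    b = np.linalg.norm(dip_pos, axis=1)  # (D,)
    if np.any(b >= model.brain_radius):
        bad = int(np.argmax(b >= model.brain_radius))
        raise ValueError(f"dipole {bad} at eccentricity {b[bad]:.4f} outside brain")
    zhat = np.where(b[:, None] > 1e-14, dip_pos / np.maximum(b, 1e-300)[:, None],
                    np.array([0.0, 0.0, 1.0]))
    cosg = np.clip(zhat @ elec_dirs.T, -1.0, 1.0)            # (D, E)
    perp = elec_dirs[None, :, :] - cosg[:, :, None] * zhat[:, None, :]  # (D, E, 3)
    sing = np.linalg.norm(perp, axis=2)
    ehat = perp / np.maximum(sing, 1e-300)[:, :, None]
    ehat[sing <= 1e-12] = 0.0

    # accumulate S1 = sum n f_n b^(n-1) P_n, S2 = sum f_n b^(n-1) P_n^1
    S1 = np.zeros((D, E))
    S2 = np.zeros((D, E))
    p_nm1 = np.ones_like(cosg)
    p_n = cosg.copy()
    q_nm1 = np.zeros_like(cosg)
    q_n = np.sqrt(np.maximum(0.0, 1.0 - cosg**2))
    bpow = np.ones(D)  # b^(n-1)
    for n in range(1, max_degree + 1):
        if n > 1:
            p_nm1, p_n = p_n, ((2 * n - 1) * cosg * p_n - (n - 1) * p_nm1) / n
            q_nm1, q_n = q_n, ((2 * n - 1) * cosg * q_n - n * q_nm1) / (n - 1)
            bpow = bpow * b
        S1 += (f[n] * n) * bpow[:, None] * p_n
        S2 += f[n] * bpow[:, None] * q_n

    gain = np.empty((E, 3 * D))
    eye = np.eye(3)
    for o in range(3):
        m = eye[o]
        m_r = zhat @ m                                        # (D,)
        m_perp = m[None, :] - m_r[:, None] * zhat             # (D, 3)
        mt_cosphi = np.einsum("dc,dec->de", m_perp, ehat)     # (D, E)
        V = m_r[:, None] * S1 + mt_cosphi * S2                # (D, E)
        gain[:, o::3] = V.T
    return gain / (4.0 * np.pi * model.conductivities[0])


def leadfield_infinity(
    model: HeadModel,
    montage: ElectrodeMontage,
    grid: DipoleGrid,
    max_degree: int = DEFAULT_MAX_DEGREE,
) -> LeadField:
    """Infinity-referenced lead field for every grid dipole (unit moments
    along x, y, z)."""
    gain = _gain_matrix(model, montage.positions, grid.positions, max_degree)
    return LeadField(gain=gain, montage=montage, grid=grid, model=model,
                     reference_tag="infinity")


def _reference_row(lf: LeadField, reference: str) -> np.ndarray:
    """The potential row to subtract for a named reference scheme."""
    m = lf.montage
    if reference == "AR":
        scalp = m.scalp_mask
        return lf.gain[scalp].mean(axis=0)
    if reference == "LM":
        for lab in ("TP9", "TP10"):
            if lab not in m:
                raise KeyError(f"LM reference requires electrode {lab!r}")
        return 0.5 * (lf.gain[m.index("TP9")] + lf.gain[m.index("TP10")])
    label = "Cz" if reference == "CZ" else reference
    if label in m:
        return lf.gain[m.index(label)]
    # virtual reference electrode (e.g. a recorded FCz not kept as a channel)
    pos = ideal_position(label)[None, :]
    return _gain_matrix(lf.model, pos, lf.grid.positions)[0]


def leadfield_for_reference(lf: LeadField, reference: str) -> LeadField:
    """Re-reference an infinity lead field to AR, LM, CZ or a named electrode."""
    if lf.reference_tag != "infinity":
        raise ValueError("input lead field must be infinity-referenced")
    row = _reference_row(lf, reference)
    return LeadField(
        gain=lf.gain - row[None, :],
        montage=lf.montage,
        grid=lf.grid,
        model=lf.model,
        reference_tag=reference,
    )
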