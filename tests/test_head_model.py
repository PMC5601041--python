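import numpy as np
import pytest

import restcm as rc
from restcm.head_model import (ConvergenceError, _gain_matrix,
                               leadfield_for_reference)


def homogeneous_sphere_potential(r0, m, re, sigma=1.0):
    """Closed-form dipole potential in a bounded homogeneous unit sphere.

    Independent oracle (classic image-free closed form): the infinite-medium
    dipole term plus the boundary correction enforcing zero radial current.
    """
    r0 = np.asarray(r0, float)
    m = np.asarray(m, float)
    re = np.asarray(re, float)
    R = np.linalg.norm(re)
    d = re - r0
    D = np.linalg.norm(d)
    t1 = 2.0 * (d @ m) / D**3
    t2 = ((d / D + re / R) @ m) / (R**2 * (D + R - (r0 @ re) / R))
    return (t1 + t2) / (4.0 * np.pi * sigma)


def random_pair(rng, ecc_max=0.86):
    r0 = rng.normal(size=3)
    r0 = r0 / np.linalg.norm(r0) * rng.uniform(0.0, ecc_max)
    m = rng.normal(size=3)
    re = rng.normal(size=3)
    re /= np.linalg.norm(re)
    return r0, m, re


class TestDipolePotential:
    def test_zero_moment(self, model):
        assert rc.dipole_potential(model, [0.1, 0.2, 0.3], [0, 0, 0],
                                   [0, 0, 1.0]) == 0.0

    def test_homogeneous_oracle(self):
        """Equal conductivities reduce the three-shell series to the
        homogeneous-sphere closed form (100 random dipole/electrode pairs)."""
        hom = rc.HeadModel(conductivities=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(7)
        for _ in range(100):
            r0, m, re = random_pair(rng)
            v = rc.dipole_potential(hom, r0, m, re)
            ref = homogeneous_sphere_potential(r0, m, re)
            assert v == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_rotation_invariance(self, model, rng):
        from scipy.spatial.transform import Rotation
        r0, m, re = random_pair(rng, ecc_max=0.7)
        v0 = rc.dipole_potential(model, r0, m, re)
        for _ in range(5):
            R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            v = rc.dipole_potential(model, R @ r0, R @ m, R @ re)
            assert v == pytest.approx(v0, abs=1e-10 + 1e-10 * abs(v0))

    def test_superposition(self, model, rng):
        r0, _, re = random_pair(rng, ecc_max=0.6)
        m1, m2 = rng.normal(size=3), rng.normal(size=3)
        v = rc.dipole_potential(model, r0, m1 + 2.5 * m2, re)
        v12 = (rc.dipole_potential(model, r0, m1, re)
               + 2.5 * rc.dipole_potential(model, r0, m2, re))
        assert v == pytest.approx(v12, abs=1e-12 + 1e-12 * abs(v))

    def test_dipole_outside_brain_rejected(self, model):
        with pytest.raises(ValueError, match="brain"):
            rc.dipole_potential(model, [0, 0, 0.9], [0, 0, 1], [0, 0, 1.0])

    def test_electrode_off_scalp_rejected(self, model):
        with pytest.raises(ValueError, match="scalp"):
            rc.dipole_potential(model, [0, 0, 0.3], [0, 0, 1], [0, 0, 0.5])


class TestHeadModel:
    def test_defaults(self, model):
        assert model.radii == (0.87, 0.92, 1.0)
        assert model.conductivities == (1.0, 0.0125, 1.0)

    @pytest.mark.parametrize("radii,cond", [
        ((0.92, 0.87, 1.0), (1, 1, 1)),      # not increasing
        ((0.87, 0.92, 1.1), (1, 1, 1)),      # scalp != 1
        ((0.87, 0.92, 1.0), (1, -1, 1)),     # negative conductivity
    ])
    def test_invalid(self, radii, cond):
        with pytest.raises(ValueError):
            rc.HeadModel(radii=radii, conductivities=cond)


class TestDipoleGrid:
    def test_default_count(self, grid1994):
        assert len(grid1994) == 1994

    def test_full_sphere_count(self):
        """Hemisphere + mirrored hemisphere - z=0 plane: 2*1994 - 293."""
        full = rc.build_dipole_grid(hemisphere_only=False)
        assert len(full) == 3695
        nz0 = int(np.sum(np.abs(full.positions[:, 2]) < 1e-12))
        assert nz0 == 293
        assert 2 * 1994 - nz0 == 3695

    def test_coarse_grid_is_origin_only(self):
        g = rc.build_dipole_grid(spacing=2.0, radius_limit=0.86)
        assert len(g) == 1
        assert np.allclose(g.positions[0], 0.0)

    def test_lattice_and_ball_membership(self, grid1994):
        p = grid1994.positions
        assert np.all(np.einsum("ij,ij->i", p, p) <= 0.86**2 + 1e-12)
        assert np.all(p[:, 2] >= 0)
        ijk = p / grid1994.spacing
        assert np.allclose(ijk, np.round(ijk), atol=1e-9)

    def test_deterministic_order(self):
        a = rc.build_dipole_grid().positions
        b = rc.build_dipole_grid().positions
        assert np.array_equal(a, b)
        # lexicographic in (k, i, j): z-index is the slowest key
        kz = np.round(a[:, 2] / 0.0905).astype(int)
        assert np.all(np.diff(kz) >= 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            rc.build_dipole_grid(spacing=-1.0)


class TestLeadField:
    def test_shape_and_column_consistency(self, model, scalp61, lf61, grid1994):
        assert lf61.gain.shape == (61, 3 * 1994)
        j, o, e = 700, 2, 5
        v = rc.dipole_potential(model, grid1994.positions[j], np.eye(3)[o],
                                scalp61.positions[e])
        assert lf61.column(j, o)[e] == pytest.approx(v, rel=1e-8)
        assert np.array_equal(lf61.column(j, "z"), lf61.column(j, 2))

    def test_axial_symmetry(self, model, grid1994):
        """Electrodes at equal colatitude see equal potentials from a
        z-directed dipole on the z-axis."""
        th = np.deg2rad(50.0)
        az = np.deg2rad([0, 45, 111, 222, 303])
        pos = np.c_[np.sin(th) * np.cos(az), np.sin(th) * np.sin(az),
                    np.full(len(az), np.cos(th))]
        ring = rc.ElectrodeMontage(tuple(f"e{i}" for i in range(len(az))), pos)
        lf = rc.leadfield_infinity(model, ring, rc.build_dipole_grid(2.0, 0.86))
        on_axis = rc.dipole_potential(model, [0, 0, 0], [0, 0, 1], pos[0])
        col = lf.column(0, "z")
        assert np.allclose(col, on_axis, atol=1e-9 * max(1.0, abs(on_axis)))
        assert np.ptp(col) < 1e-9 * abs(on_axis)

    def test_truncation_convergence(self, model, scalp61, grid1994):
        """Doubling the series degree barely changes the most eccentric
        dipole's gain (relative to the map peak)."""
        ecc = np.linalg.norm(grid1994.positions, axis=1)
        jm = int(np.argmax(ecc))
        g1 = _gain_matrix(model, scalp61.positions, grid1994.positions[[jm]], 160)
        g2 = _gain_matrix(model, scalp61.positions, grid1994.positions[[jm]], 320)
        assert np.abs(g1 - g2).max() / np.abs(g2).max() < 1e-8

    def test_reference_leadfields(self, lf61, scalp61):
        ar = leadfield_for_reference(lf61, "AR")
        assert ar.reference_tag == "AR"
        assert np.abs(ar.gain.sum(axis=0)).max() < 1e-10 * np.abs(ar.gain).max()
        cz = leadfield_for_reference(lf61, "CZ")
        assert np.abs(cz.gain[scalp61.index("Cz")]).max() == 0.0
        lm = leadfield_for_reference(lf61, "LM")
        mast = 0.5 * (lm.gain[scalp61.index("TP9")]
                      + lm.gain[scalp61.index("TP10")])
        assert np.abs(mast).max() < 1e-10 * np.abs(lm.gain).max()

    def test_virtual_reference_row(self, model, grid1994, scalp61, lf61):
        """An FCz reference works even though FCz is not a data channel."""
        fcz = leadfield_for_reference(lf61, "FCz")
        assert fcz.reference_tag == "FCz"
        # subtracting the explicit FCz electrode row gives the same matrix
        from restcm.montage import ideal_position
        aug = rc.ElectrodeMontage(scalp61.labels + ("FCz",),
                                  np.vstack([scalp61.positions,
                                             ideal_position("FCz")]))
        lf_aug = rc.leadfield_infinity(model, aug, rc.build_dipole_grid(0.4, 0.8))
        fcz_small = leadfield_for_reference(
            rc.leadfield_infinity(model, scalp61, rc.build_dipole_grid(0.4, 0.8)),
            "FCz")
        expect = lf_aug.gain[:-1] - lf_aug.gain[-1][None, :]
        assert np.allclose(fcz_small.gain, expect, atol=1e-12)

    def test_rereference_requires_infinity(self, lf61):
        ar = leadfield_for_reference(lf61, "AR")
        with pytest.raises(ValueError, match="infinity"):
            leadfield_for_reference(ar, "CZ")
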