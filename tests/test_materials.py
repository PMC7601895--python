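"""Hamaker physics, PMF interpolation and material data handling.

The closed-form potentials are checked against independent numerical
volume integrals of the underlying r^-6 London kernel, evaluated in a
different coordinate parametrisation from the implementation.
"""

import numpy as np
import pytest
from scipy import integrate

from npadsorb import (
    HamakerTable,
    MaterialOptics,
    PMFTable,
    WATER_OPTICS,
    average_hamaker,
    core_potential_far,
    core_potential_near,
    hamaker_constant_from_optics,
    lens_correction,
    load_material,
    save_material,
)
from npadsorb.constants import CANONICAL_AA3
from npadsorb.materials import get_core_table, load_aa_optics
from npadsorb.fixtures import gold_like_spec, make_material, titania_like_spec


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def sphere_point_integral(a: float, r: float) -> float:
    """Closed London integral of a sphere of radius a against a point at r."""
    return (4.0 * np.pi * a**3 / 3.0) / (r * r - a * a) ** 3


def numeric_two_sphere(A: float, R1: float, R2: float, D: float) -> float:
    """-(A/pi^2) double volume integral of r^-6, reduced over sphere 1."""
    def f(mu, s):
        r2 = s * s + D * D - 2.0 * s * D * mu
        return 2.0 * np.pi * s * s * sphere_point_integral(R2, np.sqrt(r2))

    val, _ = integrate.dblquad(f, 0, R1, -1, 1, epsrel=1e-9)
    return -(A / np.pi**2) * val


def numeric_lens(A: float, R: float, Raa: float, D: float, rc: float) -> float:
    """Bead-lens energy integrated in NP-centred spherical coordinates.

    The lens is the part of the NP sphere within rc of the bead centre;
    points are parametrised by distance s from the NP centre and the cosine
    of the polar angle towards the bead, an independent route from the
    bead-centred reduction used in the implementation.
    """
    def f(mu, s):
        r2 = s * s + D * D - 2.0 * s * D * mu
        return 2.0 * np.pi * s * s * sphere_point_integral(Raa, r2**0.5)

    def mu_lo(s):  # within-rc-of-bead condition as an angular bound
        return np.clip((s * s + D * D - rc * rc) / (2.0 * s * D), -1.0, 1.0)

    s_min = max(D - rc, 0.0)
    val, _ = integrate.dblquad(f, s_min, R, mu_lo, 1.0, epsrel=1e-9)
    return -(A / np.pi**2) * val


# ---------------------------------------------------------------------------
# Hamaker constants from optics
# ---------------------------------------------------------------------------

class TestHamakerFromOptics:
    def test_index_matched_media_give_zero(self):
        assert hamaker_constant_from_optics(WATER_OPTICS, WATER_OPTICS) == pytest.approx(0.0, abs=1e-12)

    def test_metal_exceeds_oxide_against_same_residue(self):
        gold = gold_like_spec().optics
        anatase = titania_like_spec().optics
        aa = load_aa_optics()["ALA"]
        a_gold = hamaker_constant_from_optics(gold, aa)
        a_anatase = hamaker_constant_from_optics(anatase, aa)
        assert abs(a_gold) > abs(a_anatase)
        assert a_gold > 0 and a_anatase > 0

    def test_symmetric_in_outer_media(self):
        gold = gold_like_spec().optics
        aa = load_aa_optics()["TRP"]
        assert hamaker_constant_from_optics(gold, aa) == pytest.approx(
            hamaker_constant_from_optics(aa, gold)
        )

    def test_all_residues_covered(self):
        optics = load_aa_optics()
        assert sorted(optics) == CANONICAL_AA3


# ---------------------------------------------------------------------------
# core potential, far branch
# ---------------------------------------------------------------------------

class TestCoreFar:
    def test_zero_hamaker_gives_zero(self):
        assert core_potential_far(5.0, 0.3, 7.0, 0.0) == 0.0

    def test_matches_volume_integral(self, rng):
        for _ in range(8):
            R = rng.uniform(1.0, 20.0)
            Raa = rng.uniform(0.2, 0.4)
            D = R + Raa + rng.uniform(0.05, 3.0)
            closed = core_potential_far(R, Raa, D, 70.0)
            numeric = numeric_two_sphere(70.0, R, Raa, D)
            assert closed == pytest.approx(numeric, rel=5e-3)

    def test_far_field_asymptote(self):
        R, Raa, A = 5.0, 0.3, 70.0
        D = 100.0 * (R + Raa)
        asym = -(16.0 / 9.0) * A * R**3 * Raa**3 / D**6
        assert core_potential_far(R, Raa, D, A) / asym == pytest.approx(1.0, abs=0.01)

    def test_attractive_and_monotone_toward_zero(self):
        D = np.linspace(5.5, 30.0, 200)
        u = core_potential_far(5.0, 0.3, D, 70.0)
        assert np.all(u < 0)
        assert np.all(np.diff(u) > 0)  # increases toward zero with distance

    def test_linear_in_hamaker_constant(self):
        u1 = core_potential_far(5.0, 0.3, 6.0, 1.0)
        u7 = core_potential_far(5.0, 0.3, 6.0, 7.0)
        assert u7 == pytest.approx(7.0 * u1)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            core_potential_far(5.0, 0.3, 5.2, 70.0)


class TestCoreNear:
    def test_vanishing_cutoff_reduces_to_far(self):
        far = core_potential_far(5.0, 0.3, 5.5, 70.0)
        assert core_potential_near(5.0, 0.3, 5.5, 70.0, rc=0.4) == pytest.approx(far)

    def test_zero_hamaker_gives_zero(self):
        assert core_potential_near(5.0, 0.3, 5.5, 0.0, rc=1.0) == 0.0

    def test_lens_matches_direct_volume_integration(self):
        R, Raa, rc, A = 5.0, 0.3, 1.0, 70.0
        D = R + 0.5
        assert lens_correction(R, Raa, D, A, rc) == pytest.approx(
            numeric_lens(A, R, Raa, D, rc), rel=1e-2
        )

    def test_continuous_at_cutoff_boundary(self):
        R, Raa, rc, A = 5.0, 0.3, 1.0, 70.0
        just_in = core_potential_near(R, Raa, R + rc * (1 - 1e-6), A, rc)
        just_out = core_potential_far(R, Raa, R + rc * (1 + 1e-6), A)
        assert just_in == pytest.approx(just_out, abs=1e-3)

    def test_inside_np_rejected(self):
        with pytest.raises(ValueError):
            lens_correction(5.0, 0.3, 4.0, 70.0, 1.0)

    def test_table_matches_scalar_evaluation(self):
        table = get_core_table(5.0, 0.3, 1.0)
        seps = np.array([0.35, 0.5, 0.8, 0.99, 1.5, 3.0])
        expected = np.array(
            [core_potential_near(5.0, 0.3, 5.0 + s, 70.0, 1.0) for s in seps]
        )
        got = table(seps, 70.0)
        np.testing.assert_allclose(got, expected, rtol=3e-3, atol=1e-3)


# ---------------------------------------------------------------------------
# PMF tables
# ---------------------------------------------------------------------------

def single_well_table(depth=-5.0, d0=0.4, width=0.08, rc=1.0):
    grid = np.arange(0.1, rc + 1e-9, 0.02)
    energy = depth * np.exp(-((grid - d0) ** 2) / (2 * width**2))
    energy -= energy[-1]
    curves = {aa: (grid, energy) for aa in CANONICAL_AA3}
    return PMFTable(curves, rc=rc)


class TestPMF:
    def test_zero_beyond_cutoff(self):
        t = single_well_table()
        assert t.energy("ALA", 1.5) == 0.0

    def test_exact_at_grid_nodes(self):
        t = single_well_table()
        grid, en = t.curves["GLY"]
        np.testing.assert_allclose(t.energy("GLY", grid), en, atol=1e-12)

    def test_interpolated_minimum_location_and_depth(self):
        t = single_well_table(depth=-5.0, d0=0.4)
        fine = np.linspace(0.1, 1.0, 2000)
        u = t.energy("TRP", fine)
        i = np.argmin(u)
        assert u[i] == pytest.approx(-5.0, abs=0.05)
        assert abs(fine[i] - 0.4) <= 0.02  # within one grid spacing

    def test_below_grid_clamps_with_warning(self):
        t = single_well_table()
        grid, en = t.curves["ALA"]
        with pytest.warns(UserWarning, match="clamping"):
            assert t.energy("ALA", 0.01) == pytest.approx(en[0])

    def test_unknown_residue_rejected(self):
        t = single_well_table()
        with pytest.raises(ValueError):
            t.energy("XYZ", 0.5)

    def test_nonvanishing_tail_rejected(self):
        grid = np.arange(0.1, 1.0 + 1e-9, 0.1)
        with pytest.raises(ValueError, match="vanish"):
            PMFTable({"ALA": (grid, np.full_like(grid, -2.0))}, rc=1.0)

    def test_nonmonotone_grid_rejected(self):
        grid = np.array([0.1, 0.3, 0.2, 1.0])
        with pytest.raises(ValueError, match="increasing"):
            PMFTable({"ALA": (grid, np.zeros(4))}, rc=1.0)


class TestAverageHamaker:
    def _table(self, value):
        return HamakerTable("m", {aa: value for aa in CANONICAL_AA3})

    def test_uniform_constants_recovered(self):
        assert average_hamaker(self._table(42.0), {"A": 0.3, "W": 0.7}) == pytest.approx(42.0)

    def test_two_residue_weighted_mean(self):
        t = HamakerTable("m", {aa: 0.0 for aa in CANONICAL_AA3} | {"ALA": 10.0, "GLY": 20.0})
        assert average_hamaker(t, {"A": 1.0, "G": 3.0}) == pytest.approx(17.5)

    def test_bounded_by_extremes(self, gold_material):
        from npadsorb.constants import DAYHOFF_FREQUENCIES

        avg = average_hamaker(gold_material.hamaker, DAYHOFF_FREQUENCIES)
        vals = list(gold_material.hamaker.constants.values())
        assert min(vals) <= avg <= max(vals)

    def test_zero_weights_rejected(self, gold_material):
        with pytest.raises(ValueError):
            average_hamaker(gold_material.hamaker, {"A": 0.0})

    def test_negative_weight_rejected(self, gold_material):
        with pytest.raises(ValueError):
            average_hamaker(gold_material.hamaker, {"A": -1.0, "G": 2.0})


class TestManifestIO:
    def test_round_trip(self, gold_material, tmp_path):
        path = save_material(gold_material, tmp_path / "mat")
        back = load_material(path)
        assert back.name == gold_material.name
        assert back.rc == gold_material.rc
        for aa in CANONICAL_AA3:
            assert back.hamaker[aa] == pytest.approx(gold_material.hamaker[aa])
            g0, e0 = gold_material.pmfs.curves[aa]
            g1, e1 = back.pmfs.curves[aa]
            np.testing.assert_allclose(g1, g0, atol=1e-9)
            np.testing.assert_allclose(e1, e0, atol=1e-7)
        assert back.average_hamaker == pytest.approx(gold_material.average_hamaker, rel=1e-6)

    def test_missing_manifest_reported(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_material(tmp_path / "nope" / "manifest.yaml")

    def test_same_seed_byte_identical_manifest(self, tmp_path):
        for sub in ("a", "b"):
            save_material(make_material(gold_like_spec(), seed=5), tmp_path / sub)
        blobs = [
            (tmp_path / sub / "manifest.yaml").read_bytes() for sub in ("a", "b")
        ]
        assert blobs[0] == blobs[1]
        pmf_a = (tmp_path / "a" / "pmf" / "ALA.tsv").read_bytes()
        pmf_b = (tmp_path / "b" / "pmf" / "ALA.tsv").read_bytes()
        assert pmf_a == pmf_b
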