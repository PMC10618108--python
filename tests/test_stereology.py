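"""Point counting, Cavalieri, overprojection, appearance counting, star volume."""

import numpy as np
import pytest

from mitostereo.geometry import BodyShape, Slab, volume
from mitostereo.microtome import cut_serial, cut_tomographic
from mitostereo.population import CohortConfig, generate_cohort
from mitostereo.stereology import (
    PointGrid,
    cavalieri_volume,
    coefficient_of_error,
    ce_gundersen,
    constriction_density,
    count_by_appearance,
    derive_correction_factor,
    estimate_area,
    estimate_total_number,
    fractionator_number_estimate,
    link_profiles,
    model_based_factor,
    number_density,
    overprojection_factor,
    point_count,
    random_grid,
    sample_star_chords,
    stack_cavalieri,
    star_volume,
    volume_fraction,
)

SPHERE25 = BodyShape("sphere", [0, 0, 0], 25)
CAPSULE = BodyShape("spherocylinder", [0, 0, 0], 25, axis=[1, 0, 0], length=150)


def circle_membership(pts):
    return np.einsum("ij,ij->i", pts, pts) <= 625.0


class TestPointCounting:
    def test_unbiased_over_random_offsets(self, rng):
        window = ((-40.0, -40.0), (40.0, 40.0))
        areas = np.array([
            estimate_area(circle_membership, random_grid(window, 5.0, rng))
            for _ in range(1000)
        ])
        sem = areas.std(ddof=1) / np.sqrt(len(areas))
        assert abs(areas.mean() - np.pi * 625) < 3 * sem

    def test_empty_profile_zero(self, rng):
        grid = random_grid(((-10.0, -10.0), (10.0, 10.0)), 2.0, rng)
        assert point_count(lambda p: np.zeros(len(p), dtype=bool), grid) == 0

    def test_exact_when_spacing_divides_window(self):
        # full 20x20 window, spacing 2: always exactly 100 corners inside
        grid = PointGrid(2.0, (0.7, 1.3), ((0.0, 0.0), (20.0, 20.0)))
        full = lambda p: np.ones(len(p), dtype=bool)
        assert estimate_area(full, grid) == pytest.approx(400.0)

    def test_window_must_cover_profile(self, rng):
        grid = random_grid(((0.0, 0.0), (10.0, 10.0)), 2.0, rng)
        with pytest.raises(ValueError, match="does not cover"):
            point_count(circle_membership, grid, profile_bbox=((-25, -25), (25, 25)))


class TestCavalieri:
    def test_zero_areas_zero_volume(self):
        assert cavalieri_volume([0, 0, 0], 43.0).value == 0.0

    def test_simple_arithmetic(self):
        assert cavalieri_volume([100.0, 100.0], 43.0).value == pytest.approx(8600.0)

    def test_thin_slice_recovers_sphere(self, rng):
        stack = cut_tomographic({"s": SPHERE25}, dz=1.0, rng=rng)
        assert stack_cavalieri(stack).value == pytest.approx(volume(SPHERE25), rel=0.01)

    def test_mismatched_point_counts_rejected(self):
        with pytest.raises(ValueError):
            cavalieri_volume([100.0], 43.0, point_counts=[3], grid_spacing_nm=5.0)

    def test_correction_divides(self):
        rec = cavalieri_volume([100.0, 100.0], 43.0, correction_factor=1.61)
        assert rec.value == pytest.approx(8600.0 / 1.61)
        assert rec.correction_applied == 1.61


class TestOverprojection:
    def test_factor_arithmetic(self):
        assert overprojection_factor(100.0, 161.0) == pytest.approx(1.61)
        assert overprojection_factor(100.0, 100.0) == 1.0
        with pytest.raises(ValueError):
            overprojection_factor(0.0, 100.0)

    @pytest.mark.parametrize(
        "body, t, expected",
        [
            (SPHERE25, 0.0, 1.0),
            (SPHERE25, 43.0, 2.290),
            (CAPSULE, 43.0, 1.967),
        ],
    )
    def test_model_based_factor(self, body, t, expected):
        assert model_based_factor(t, body) == pytest.approx(expected, abs=5e-4)

    def test_phase_averaged_shadow_factor_matches_analytic(self, rng):
        # full-shadow Holmes factor of a sphere: 1 + 3 t / (4 r)
        vals = [
            stack_cavalieri(cut_serial({"s": SPHERE25}, 43.0, rng=rng)).value
            for _ in range(800)
        ]
        f = np.mean(vals) / volume(SPHERE25)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals)) / volume(SPHERE25)
        assert abs(f - 2.29) < max(3 * sem, 0.01 * 2.29)

    def test_factor_monotone_in_thickness(self, rng):
        factors = []
        for t in (5.0, 20.0, 43.0, 80.0):
            vals = [
                stack_cavalieri(cut_serial({"s": SPHERE25}, t, rng=rng)).value
                for _ in range(200)
            ]
            factors.append(np.mean(vals) / volume(SPHERE25))
        assert all(f > 1.0 for f in factors)
        assert all(b > a for a, b in zip(factors, factors[1:]))
        assert factors[0] == pytest.approx(1 + 3 * 5 / 100, rel=0.02)

    def test_cohort_derived_factor_recovers_truth(self, rng):
        cells = generate_cohort(CohortConfig(n_cells=12, seed=31))
        bodies = [c.mitosome_bodies() for c in cells]
        factor = derive_correction_factor(bodies[:4], t=43.0, dz=1.0, rng=rng)
        thick_total = sum(
            stack_cavalieri(cut_serial(b, 43.0, rng=rng)).value for b in bodies
        )
        true_total = sum(c.v_true for c in cells)
        assert thick_total / factor == pytest.approx(true_total, rel=0.05)


class TestAppearanceCounting:
    def test_three_separated_bodies(self, rng):
        bodies = {
            "a": BodyShape("sphere", [0, 0, -200], 30),
            "b": BodyShape("sphere", [50, 0, 0], 25),
            "c": BodyShape("spherocylinder", [0, 40, 210], 20, axis=[0, 0, 1], length=90),
        }
        stack = cut_serial(bodies, 43.0, rng=rng, compute_areas=False)
        assert count_by_appearance(stack, final_section_closes=True).n == 3

    def test_single_slab_body_counts_once(self):
        small = {"s": BodyShape("sphere", [0, 0, 0], 10)}
        stack = cut_serial(small, 500.0, rng=0, compute_areas=False)
        assert count_by_appearance(stack, final_section_closes=True).n == 1

    def test_truncated_run_flagged_not_counted(self, rng):
        stack = cut_serial({"s": SPHERE25}, 43.0, rng=rng, compute_areas=False)
        with pytest.warns(UserWarning, match="truncated"):
            res = count_by_appearance(stack, final_section_closes=False)
        # the run reaching the last section is excluded and reported
        assert res.n + len(res.truncated) == 1

    def test_exact_on_cohort(self, small_cohort, rng):
        for cell in small_cohort:
            stack = cut_serial(cell.mitosome_bodies(), 43.0, rng=rng, compute_areas=False)
            assert count_by_appearance(stack, final_section_closes=True).n == cell.n_true

    def test_link_profiles_by_overlap(self):
        a = np.zeros((4, 4), bool); a[1:3, 1:3] = True
        b = np.zeros((4, 4), bool); b[2:4, 2:4] = True
        c = np.zeros((4, 4), bool); c[0, 0] = True
        groups = link_profiles([{"p1": a}, {"p2": b, "p3": c}])
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 2]  # p1-p2 linked, p3 separate


class TestDensities:
    def test_number_density_arithmetic(self):
        nv = number_density(10, 2e9)  # 10 counts in 2 um^3
        assert nv * 1e9 == pytest.approx(5.0)
        assert estimate_total_number(nv, 2e9) == pytest.approx(10.0)

    def test_zero_count_warns(self):
        with pytest.warns(UserWarning, match="small sample"):
            assert number_density(0, 1e9) == 0.0

    def test_volume_fraction(self):
        assert volume_fraction(47, 10_000) == pytest.approx(0.0047)
        assert volume_fraction(0, 10) == 0.0
        with pytest.raises(ValueError):
            volume_fraction(1, 0)

    def test_vv_recovers_truth_on_cohort(self, rng):
        # thin planes across the whole cell, exact areas: the pooled
        # area ratio estimates the cohort volume fraction without bias
        from mitostereo.geometry import profile_areas
        from mitostereo.stereology import cytoplasm_slab_volume

        cells = generate_cohort(CohortConfig(n_cells=25, seed=41))
        dz = 20.0
        a_struct = 0.0
        a_ref = 0.0
        v_true = 0.0
        v_cyto = 0.0
        for c in cells:
            r_cell = c.cytoplasm_radius
            phase = rng.uniform(0, dz)
            z = np.arange(-r_cell + phase, r_cell, dz)
            for body in c.mitosomes:
                a_struct += float(profile_areas(body, z, z).sum())
            for zi in z:
                a_ref += cytoplasm_slab_volume(c, zi - 1e-9, zi + 1e-9) / 2e-9
            v_true += c.v_true
            v_cyto += c.v_cytoplasm
        assert a_struct / a_ref == pytest.approx(v_true / v_cyto, rel=0.10)

    def test_fractionator_number_recovery(self):
        from mitostereo.population import thominis_config

        cells = generate_cohort(thominis_config(seed=11, n_cells=100))
        rng = np.random.default_rng(2)
        n_hat = [
            fractionator_number_estimate(c, t=40.0, n_sections_per_stack=8,
                                         n_stacks=60, rng=rng)
            for c in cells
        ]
        assert np.mean(n_hat) == pytest.approx(16.0, rel=0.05)

    def test_constriction_density(self):
        assert constriction_density(4, 8e9) * 1e9 == pytest.approx(0.5)
        assert constriction_density(8, 8e9) == pytest.approx(2 * constriction_density(4, 8e9))


class TestStarVolume:
    def test_single_chord_definition(self):
        assert star_volume([1.0]) == pytest.approx(np.pi / 3)
        assert star_volume([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            star_volume([])

    def test_sphere_identity(self, rng):
        chords = sample_star_chords(SPHERE25, 100_000, rng)
        assert star_volume(chords) == pytest.approx(volume(SPHERE25), rel=0.02)

    def test_cube_scaling_law(self, rng):
        # doubling every length scales v* by 8
        small = BodyShape("spherocylinder", [0, 0, 0], 20, axis=[0, 0, 1], length=100)
        big = BodyShape("spherocylinder", [0, 0, 0], 40, axis=[0, 0, 1], length=200)
        vs = star_volume(sample_star_chords(small, 20_000, np.random.default_rng(5)))
        vb = star_volume(sample_star_chords(big, 20_000, np.random.default_rng(5)))
        assert vb / vs == pytest.approx(8.0, rel=0.05)


class TestCoefficientOfError:
    def test_hand_computed_example(self):
        assert coefficient_of_error([1, 2, 3]) == pytest.approx(0.28868, abs=1e-4)

    def test_constant_list_zero(self):
        assert coefficient_of_error([4.2, 4.2, 4.2]) == 0.0

    def test_scale_invariance(self):
        vals = [3.0, 5.0, 9.0, 4.0]
        assert coefficient_of_error(vals) == pytest.approx(
            coefficient_of_error([10 * v for v in vals]))

    def test_gundersen_ce_positive_for_varying_series(self):
        assert ce_gundersen([5, 9, 14, 12, 7, 3]) > 0.0
        with pytest.raises(ValueError):
            ce_gundersen([1, 2])
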