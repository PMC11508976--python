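"""Frequency matrices, kernel density profiles, and 3D heat-map painting."""

import numpy as np
import pytest

from ribmap import (
    SimulationParams,
    all_density_profiles,
    build_default_template,
    density_profile,
    frequency_matrix,
    generate_cohort,
    paint_heatmap,
)
from ribmap.heatmap import FrequencyMatrix

from conftest import make_cohort


class TestFrequencyMatrix:
    def test_counts_and_conservation_on_small_cohort(self):
        cohort = make_cohort([
            ("A", 5, "left", 25.0), ("A", 5, "right", 25.0), ("B", 5, "left", 65.0),
        ])
        m = frequency_matrix(cohort)
        assert m.counts[4, 2] == 2
        assert m.counts[4, 6] == 1
        assert m.total == 3

    def test_empty_cohort_gives_zero_matrix(self):
        m = frequency_matrix(make_cohort([], flags={"A": {}}))
        assert m.total == 0
        assert m.counts.shape == (12, 10)

    def test_pooled_equals_left_plus_right(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=50, seed=3))
        left = frequency_matrix(cohort, side_scope="left")
        right = frequency_matrix(cohort, side_scope="right")
        pooled = frequency_matrix(cohort, side_scope="pooled")
        np.testing.assert_array_equal(pooled.counts, left.counts + right.counts)

    def test_mirrored_counts_match_pooled(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=50, seed=4))
        np.testing.assert_array_equal(
            frequency_matrix(cohort, side_scope="mirrored").counts,
            frequency_matrix(cohort, side_scope="pooled").counts,
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grand_total_equals_record_count(self, seed):
        cohort, _ = generate_cohort(SimulationParams(n_patients=40, seed=seed))
        assert frequency_matrix(cohort).total == cohort.n_fractures

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix(make_cohort([("A", 1, "left", 5.0)]), bin_width=30)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FrequencyMatrix(-np.ones((12, 10), dtype=int), "pooled", 10)


class TestDensityProfile:
    def test_single_record_peaks_at_its_position(self):
        cohort = make_cohort([("A", 5, "left", 50.0)])
        prof = density_profile(cohort, 5, bandwidth=5.0)
        argmax = prof.sample_positions[np.argmax(prof.density)]
        assert abs(argmax - 50.0) <= 0.5

    def test_integral_equals_record_count(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=30, seed=7))
        for rib in (1, 5, 9):
            n_rib = sum(1 for r in cohort.fracture_records() if r.rib_index == rib)
            prof = density_profile(cohort, rib)
            assert prof.integral == pytest.approx(n_rib, rel=0.01, abs=0.01)

    def test_two_separated_records_give_two_maxima(self):
        cohort = make_cohort([("A", 5, "left", 20.0), ("A", 5, "left", 80.0)])
        prof = density_profile(cohort, 5, bandwidth=3.0)
        d = prof.density
        interior_max = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
        assert interior_max.sum() == 2

    def test_matches_brute_force_kernel_sum(self):
        # independent oracle: direct double loop over records and reflections
        rng = np.random.default_rng(11)
        positions = rng.uniform(0, 100, 37)
        cohort = make_cohort([("A", 4, "left", float(p)) for p in positions])
        bw = 5.0
        prof = density_profile(cohort, 4, bandwidth=bw)
        norm = 1.0 / (bw * np.sqrt(2 * np.pi))
        for x, d in zip(prof.sample_positions[::20], prof.density[::20]):
            expected = sum(
                norm * (
                    np.exp(-0.5 * ((x - p) / bw) ** 2)
                    + np.exp(-0.5 * ((x + p) / bw) ** 2)
                    + np.exp(-0.5 * ((x - (200 - p)) / bw) ** 2)
                )
                for p in positions
            )
            assert d == pytest.approx(expected, abs=1e-9)

    def test_rib_without_records_yields_zero_profile(self):
        cohort = make_cohort([("A", 5, "left", 50.0)])
        prof = density_profile(cohort, 12)
        assert np.all(prof.density == 0.0)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            density_profile(make_cohort([("A", 5, "left", 50.0)]), 5, bandwidth=0.0)


@pytest.fixture(scope="module")
def template():
    from ribmap import TemplateConfig
    return build_default_template(TemplateConfig(n_vertices=50))


class TestPaintHeatmap:
    def test_all_zero_matrix_paints_uniform_minimum(self, template):
        m = FrequencyMatrix(np.zeros((12, 10), dtype=int), "pooled", 10)
        mesh = paint_heatmap(template, m)
        colors = np.asarray(mesh.visual.vertex_colors)
        assert (colors == colors[0]).all()

    def test_color_order_follows_density_order(self, template):
        cohort = make_cohort(
            [("A", 5, "left", 25.0)] * 5 + [("A", 5, "left", 75.0)]
        )
        profiles = all_density_profiles(cohort)
        mesh = paint_heatmap(template, profiles)
        # with the jet map, higher density -> larger red-minus-blue score
        colors = np.asarray(mesh.visual.vertex_colors, dtype=float)
        score = colors[:, 0] - colors[:, 2]
        verts = np.asarray(mesh.vertices)
        curve = template.get(5, "left")
        near_peak = np.linalg.norm(
            verts - np.asarray(curve.vertices[len(curve.vertices) // 4]), axis=1
        ).argmin()
        far_field = np.linalg.norm(verts - np.asarray(curve.vertices[-1]), axis=1).argmin()
        assert score[near_peak] > score[far_field]

    def test_painting_is_deterministic(self, template):
        cohort = make_cohort([("A", 3, "right", 40.0), ("A", 7, "left", 60.0)])
        profiles = all_density_profiles(cohort)
        m1 = paint_heatmap(template, profiles)
        m2 = paint_heatmap(template, profiles)
        np.testing.assert_array_equal(
            np.asarray(m1.visual.vertex_colors), np.asarray(m2.visual.vertex_colors)
        )
        np.testing.assert_array_equal(np.asarray(m1.vertices), np.asarray(m2.vertices))

    def test_mirrored_scope_paints_one_hemithorax(self, template):
        cohort = make_cohort([("A", 5, "left", 50.0)])
        profiles = all_density_profiles(cohort, side_scope="mirrored")
        mesh = paint_heatmap(template, profiles)
        pooled = paint_heatmap(template, all_density_profiles(cohort))
        assert len(mesh.vertices) == len(pooled.vertices) // 2

    def test_ply_export_round_trips_geometry(self, template, tmp_path):
        import trimesh
        cohort = make_cohort([("A", 5, "left", 50.0)])
        mesh = paint_heatmap(template, all_density_profiles(cohort))
        path = tmp_path / "heat.ply"
        mesh.export(str(path))
        back = trimesh.load(str(path))
        assert len(back.vertices) == len(mesh.vertices)
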