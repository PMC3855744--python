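"""Tests for fragmentation, aggregate and depolarization scoring."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import fisher_exact

from mitodyn.morphology import (Aggregate, MorphologyReport, analyze_series,
                                cohort_fraction, depolarization_score,
                                detect_aggregates, fragmentation_index,
                                segment_network)
from mitodyn.netsim import (DEFAULT_GEOMETRY, build_lattice, evolve,
                            get_preset, render)

PX = 0.5  # um per pixel for synthetic images


def rect_image(rects, shape=(100, 200), value=1.0):
    img = np.zeros(shape)
    for (r0, c0, r1, c1) in rects:
        img[r0:r1, c0:c1] = value
    return img


class TestSegmentNetwork:
    def test_single_rectangle_is_one_component(self):
        labels = segment_network(rect_image([(10, 10, 30, 80)]), pixel_size=PX)
        assert labels.max() == 1

    def test_two_separated_rectangles(self):
        labels = segment_network(
            rect_image([(10, 10, 30, 80), (40, 10, 60, 80)]), pixel_size=PX)
        assert labels.max() == 2

    def test_empty_foreground_reports_zero(self):
        labels = segment_network(np.zeros((50, 50)), pixel_size=PX)
        assert labels.max() == 0

    def test_min_area_filter_removes_specks(self):
        img = rect_image([(10, 10, 30, 80)])
        img[45, 45] = 1.0  # one-pixel speck, 0.25 um^2
        labels = segment_network(img, pixel_size=PX, min_area_um2=1.0)
        assert labels.max() == 1

    def test_nonfinite_rejected(self):
        img = np.zeros((20, 20))
        img[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            segment_network(img, pixel_size=PX)

    def test_mad_method_for_sparse_foreground(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.0, 0.01, (100, 200))
        img[10:20, 10:40] += 1.0
        labels = segment_network(img, pixel_size=PX, threshold_method="mad")
        assert labels.max() == 1

    def test_more_components_when_fragmented(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        base = get_preset("control").params
        full = build_lattice(g, replace(base, p_frag0=0.0, seed=11))
        frag = build_lattice(g, replace(base, p_frag0=0.6, seed=11))
        n = {}
        for name, state in (("full", full), ("frag", frag)):
            _, tmre = render(state, g, noise_free_optics)
            n[name] = segment_network(tmre, pixel_size=g.pixel_size).max()
        assert n["frag"] > n["full"]


class TestFragmentationIndex:
    def test_single_long_component_not_fragmented(self):
        # one component spanning 20 sarcomeres: 44 um at 0.5 um/px = 88 px
        labels = (rect_image([(10, 10, 20, 98)]) > 0).astype(int)
        n, med, frag = fragmentation_index(labels, PX)
        assert n == 1
        assert med == pytest.approx(44.0)
        assert frag is False

    def test_all_single_sarcomere_components_fragmented(self):
        rects = [(10, 10 + 9 * k, 14, 10 + 9 * k + 4) for k in range(8)]
        labels_img = rect_image(rects)
        from skimage.measure import label
        labels = label(labels_img > 0)
        n, med, frag = fragmentation_index(labels, 0.55)
        assert n == 8
        assert med == pytest.approx(2.2)
        assert frag is True

    def test_no_components_flagged_undefined(self):
        n, med, frag = fragmentation_index(np.zeros((10, 10), int), PX)
        assert n == 0
        assert np.isnan(med)
        assert frag is None

    def test_area_weighted_median_follows_dominant_structure(self):
        # one big component and two specks: the call follows the big one
        labels_img = rect_image([(10, 10, 40, 190)])
        labels_img[60, 10] = labels_img[60, 50] = 1.0
        from skimage.measure import label
        n, med, frag = fragmentation_index(label(labels_img > 0), PX)
        assert n == 3
        assert med == pytest.approx(90.0)
        assert frag is False


class TestDetectAggregates:
    def test_uniform_image_has_no_aggregates(self):
        assert detect_aggregates(np.full((50, 50), 2.0), PX) == []

    def test_single_punctum_found_at_centroid(self):
        yy, xx = np.mgrid[:200, :200]
        img = 1.0 + 0.2 * np.sin(xx / 9.0) * np.cos(yy / 7.0)
        sd = img.std()
        disk = (yy - 60) ** 2 + (xx - 110) ** 2 <= 3 ** 2
        img[disk] = img.mean() + 6 * sd
        found = detect_aggregates(img, PX, k_sd=4.0)
        assert len(found) == 1
        cy, cx = found[0].centroid_px
        assert abs(cy - 60) <= 1 and abs(cx - 110) <= 1
        assert found[0].peak_intensity >= img.mean() + 4 * sd

    def test_area_bounds_exclude_large_blobs(self):
        img = np.zeros((100, 200))
        img[20:80, 20:180] = 10.0  # huge blob, way over max area
        assert detect_aggregates(img, PX, max_area_um2=12.0) == []

    def test_zero_false_positives_on_clean_renders(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        state = build_lattice(g, get_preset("control").params)
        tracer, _ = render(state, g, noise_free_optics)
        assert detect_aggregates(tracer, g.pixel_size) == []

    def test_count_recovery_on_mutant_renders(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        detected = truth = 0
        for seed in range(20):
            p = replace(get_preset("mtSOD1G93A").params, seed=seed)
            state = build_lattice(g, p)
            tracer, _ = render(state, g, noise_free_optics)
            detected += len(detect_aggregates(tracer, g.pixel_size))
            truth += state.aggregate_nodes.size
        assert truth > 0
        assert detected == pytest.approx(truth, rel=0.20)


class TestDepolarizationScore:
    def _agg(self, cy, cx):
        return Aggregate(centroid_px=(cy, cx), area_um2=1.0, peak_intensity=5.0)

    def test_uniform_tmre_scores_zero(self):
        img = np.full((100, 100), 0.8)
        [score] = depolarization_score([self._agg(50, 50)], img, PX)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_dark_footprint_scores_one(self):
        img = np.full((100, 100), 1.0)
        yy, xx = np.mgrid[:100, :100]
        img[(yy - 50) ** 2 + (xx - 50) ** 2 <= (0.9 / PX) ** 2] = 0.0
        [score] = depolarization_score([self._agg(50, 50)], img, PX)
        assert score == pytest.approx(1.0, abs=0.05)

    def test_border_aggregate_flagged_nan(self):
        img = np.ones((100, 100))
        [score] = depolarization_score([self._agg(1, 1)], img, PX)
        assert np.isnan(score)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.5, 1.0, (100, 100))
        aggs = [self._agg(50, 50), self._agg(30, 70)]
        s1 = depolarization_score(aggs, img, PX)
        s2 = depolarization_score(aggs, img * 7.3, PX)
        assert np.allclose(s1, s2)

    def test_configured_dip_recovered_on_renders(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        scores = []
        for seed in range(10):
            p = replace(get_preset("mtSOD1G93A").params, seed=seed)
            assert p.depol_at_aggregate == 0.5
            state = build_lattice(g, p)
            tracer, tmre = render(state, g, noise_free_optics)
            aggs = detect_aggregates(tracer, g.pixel_size)
            scores += [s for s in depolarization_score(aggs, tmre, g.pixel_size)
                       if np.isfinite(s)]
        scores = np.asarray(scores)
        assert scores.size >= 10
        assert scores.mean() == pytest.approx(0.5, abs=0.10)
        assert np.all(np.abs(scores - 0.5) < 0.15)


class TestCohortFraction:
    def _report(self, fragmented=False, n_agg=0):
        return MorphologyReport(
            fiber_id="f", n_components=1, median_component_length_um=10.0,
            fragmented=fragmented,
            aggregates=[Aggregate((0, 0), 1.0, 5.0)] * n_agg)

    def test_zero_of_36(self):
        reports = [self._report(n_agg=0) for _ in range(36)]
        assert cohort_fraction(reports, lambda r: r.has_aggregates) == (0, 36)

    def test_all_satisfy(self):
        reports = [self._report(fragmented=True) for _ in range(7)]
        assert cohort_fraction(reports, lambda r: r.fragmented) == (100, 7)

    def test_rounding_half_up(self):
        reports = [self._report(fragmented=i < 9) for i in range(40)]
        assert cohort_fraction(reports, lambda r: r.fragmented) == (23, 40)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_fraction([], lambda r: True)


class TestCohortContrasts:
    def test_fragmented_fraction_higher_under_g93a(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        counts = {}
        for name in ("control", "g93a"):
            frag = 0
            for seed in range(20):
                p = replace(get_preset(name).params, seed=seed)
                state = build_lattice(g, p)
                state = evolve(state, p, 10.0, np.random.default_rng(seed))
                _, tmre = render(state, g, noise_free_optics)
                labels = segment_network(tmre, pixel_size=g.pixel_size)
                _, _, fragged = fragmentation_index(labels, g.pixel_size)
                frag += bool(fragged)
            counts[name] = frag
        table = [[counts["g93a"], 20 - counts["g93a"]],
                 [counts["control"], 20 - counts["control"]]]
        assert counts["g93a"] > counts["control"]
        assert fisher_exact(table, alternative="greater").pvalue < 0.05

    def test_component_count_monotone_in_p_frag0(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        base = get_preset("control").params
        means = []
        for p0 in (0.0, 0.3, 0.6):
            n = []
            for seed in range(20):
                state = build_lattice(g, replace(base, p_frag0=p0, seed=seed))
                _, tmre = render(state, g, noise_free_optics)
                n.append(segment_network(tmre, pixel_size=g.pixel_size).max())
            means.append(np.mean(n))
        assert means[0] <= means[1] <= means[2]

    def test_component_count_monotone_in_k_fis(self, noise_free_optics):
        g = DEFAULT_GEOMETRY
        base = get_preset("control").params
        means = []
        for k_fis in (0.05, 0.35):
            n = []
            for seed in range(20):
                p = replace(base, k_fis=k_fis, seed=seed)
                state = build_lattice(g, p)
                state = evolve(state, p, 8.0, np.random.default_rng(seed))
                _, tmre = render(state, g, noise_free_optics)
                n.append(segment_network(tmre, pixel_size=g.pixel_size).max())
            means.append(np.mean(n))
        assert means[0] < means[1]


class TestProfilePlot:
    def test_writes_png(self, tmp_path):
        pytest.importorskip("matplotlib")
        from mitodyn.morphology import profile_plot
        tracer = np.random.default_rng(0).uniform(0, 1, (20, 50))
        fig = profile_plot(tracer, tracer * 0.5, row=10, pixel_size=0.25,
                           out_path=tmp_path / "profile.png")
        assert (tmp_path / "profile.png").exists()
        import matplotlib.pyplot as plt
        plt.close(fig)


class TestAnalyzeSeries:
    def test_report_fields(self, control_series):
        rep = analyze_series(control_series, fiber_id="fiber-1")
        assert rep.fiber_id == "fiber-1"
        assert rep.n_components > 0
        assert rep.fragmented is not None
        assert len(rep.depol_scores) == len(rep.aggregates)
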