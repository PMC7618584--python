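"""Synthetic templates, degradations, rendering and paired simulation."""

import numpy as np
import pytest

from kneealign.agreement import icc_agreement, mad
from kneealign.landmarks import SchemaId, validate
from kneealign.measurement import (
    builtin_definitions,
    compute_aFTA,
    definitions_for_schema,
    measure_set,
)
from kneealign.synthetic import (
    PairedSimConfig,
    SimulationConfig,
    degrade,
    inject_alignment,
    make_template,
    render,
    simulate_dataset,
    simulate_paired,
    template_layout,
)

SHAFT_ONLY = ["Pre-fem-tib-shafts", "PreX-fem-tib-shafts",
              "Post-fem-tib-shafts", "PostX-fem-tib-shafts"]


class TestTemplate:
    @pytest.mark.parametrize("sid, n", [
        (SchemaId.PRE_ORIGINAL, 110), (SchemaId.PRE_EXTENDED, 134),
        (SchemaId.POST_ORIGINAL, 157), (SchemaId.POST_EXTENDED, 181),
    ])
    def test_point_counts(self, sid, n):
        assert make_template(sid).base.n_points == n

    def test_zero_afta_and_valid(self, templates):
        for tpl in templates.values():
            validate(tpl.base)
            for r in measure_set(tpl.base):
                assert abs(r.aFTA_deg) < 1e-9

    def test_deterministic(self):
        a = make_template(SchemaId.PRE_EXTENDED).base.points
        b = make_template(SchemaId.PRE_EXTENDED).base.points
        np.testing.assert_array_equal(a, b)

    def test_unknown_schema_raises(self):
        with pytest.raises(ValueError):
            make_template("long_leg")

    def test_fibula_lateral_of_tibia(self, templates):
        for tpl in templates.values():
            fib = tpl.base.schema.role("fibula_indices")
            tib = tpl.base.schema.role("tibial_shaft_proximal_pair")
            assert (tpl.base.points[list(fib), 0].mean()
                    > tpl.base.points[list(tib), 0].mean())


class TestInjection:
    def test_zero_is_identity(self, templates):
        for tpl in templates.values():
            np.testing.assert_array_equal(inject_alignment(tpl, 0.0).points,
                                          tpl.base.points)

    @pytest.mark.parametrize("angle", [6.0, -10.0])
    def test_recovery(self, templates, angle):
        for tpl in templates.values():
            ls = inject_alignment(tpl, angle)
            for r in measure_set(ls):
                assert r.aFTA_deg == pytest.approx(angle, abs=1e-6)

    def test_round_trip_grid_shaft_only(self, templates):
        defs = builtin_definitions()
        for t in range(-15, 16, 5):
            for tpl in templates.values():
                ls = inject_alignment(tpl, float(t))
                for name in SHAFT_ONLY:
                    d = defs[name]
                    if d.schema_id != tpl.schema_id:
                        continue
                    assert compute_aFTA(ls, d).aFTA_deg == pytest.approx(
                        t, abs=1e-6)

    def test_out_of_range_rejected(self, pre_original_template):
        with pytest.raises(ValueError):
            inject_alignment(pre_original_template, 45.0)


class TestDegrade:
    def test_identity_config(self, templates):
        for tpl in templates.values():
            cfg = SimulationConfig(point_noise_sd_px=0.0)
            np.testing.assert_allclose(degrade(tpl.base, cfg).points,
                                       tpl.base.points, atol=1e-12)

    def test_global_rotation_preserves_afta(self, templates):
        for tpl in templates.values():
            ls = inject_alignment(tpl, 4.0)
            cfg = SimulationConfig(point_noise_sd_px=0.0,
                                   global_rotation_deg=3.0)
            for r in measure_set(degrade(ls, cfg)):
                assert r.aFTA_deg == pytest.approx(4.0, abs=1e-6)

    def test_truncation_shrinks_visible_shaft(self, templates):
        tpl = templates[SchemaId.PRE_EXTENDED]
        cfg = SimulationConfig(point_noise_sd_px=0.0,
                               femoral_shaft_fraction=0.5,
                               tibial_shaft_fraction=0.5)
        out = degrade(tpl.base, cfg)
        schema = tpl.base.schema
        for prox, dist in (("femoral_shaft_proximal_pair",
                            "femoral_shaft_distal_pair"),
                           ("tibial_shaft_distal_pair",
                            "tibial_shaft_proximal_pair")):
            def span(pts):
                a = pts[list(schema.role(prox))].mean(axis=0)
                b = pts[list(schema.role(dist))].mean(axis=0)
                return np.linalg.norm(a - b)
            assert span(out.points) == pytest.approx(
                0.5 * span(tpl.base.points), rel=1e-9)

    def test_truncation_keeps_afta_noiseless(self, templates):
        for tpl in templates.values():
            ls = inject_alignment(tpl, -7.0)
            cfg = SimulationConfig(point_noise_sd_px=0.0,
                                   femoral_shaft_fraction=0.4,
                                   tibial_shaft_fraction=0.6)
            for r in measure_set(degrade(ls, cfg)):
                assert r.aFTA_deg == pytest.approx(-7.0, abs=1e-6)

    def test_short_shaft_amplifies_noise_error(self, templates):
        # annotation noise hurts more when the visible shaft is short
        tpl = templates[SchemaId.PRE_EXTENDED]
        d = builtin_definitions()["PreX-fem-tib-shafts"]
        errs = {}
        for frac in (1.0, 0.2):
            e = []
            for seed in range(500):
                cfg = SimulationConfig(point_noise_sd_px=1.0,
                                       femoral_shaft_fraction=frac, seed=seed)
                e.append(compute_aFTA(degrade(tpl.base, cfg), d).aFTA_deg)
            errs[frac] = np.var(e)
        assert errs[0.2] > errs[1.0]

    def test_noise_error_scales_linearly(self, templates):
        # SD of (measured - true) should grow ~ proportionally with sigma
        tpl = templates[SchemaId.PRE_EXTENDED]
        d = builtin_definitions()["PreX-fem-tib-shafts"]
        sds = {}
        for sigma in (0.5, 1.0, 2.0):
            vals = [compute_aFTA(degrade(
                tpl.base, SimulationConfig(point_noise_sd_px=sigma,
                                           seed=1000 + s)), d).aFTA_deg
                for s in range(1000)]
            sds[sigma] = np.std(vals)
        assert sds[1.0] / sds[0.5] == pytest.approx(2.0, rel=0.25)
        assert sds[2.0] / sds[1.0] == pytest.approx(2.0, rel=0.25)

    def test_deterministic_per_seed(self, pre_original_template):
        cfg = SimulationConfig(point_noise_sd_px=1.5, seed=99)
        a = degrade(pre_original_template.base, cfg).points
        b = degrade(pre_original_template.base, cfg).points
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(femoral_shaft_fraction=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(point_noise_sd_px=-1.0)


class TestRender:
    def test_polygon_brighter_than_background(self, templates):
        for sid in (SchemaId.PRE_ORIGINAL, SchemaId.POST_ORIGINAL):
            tpl = make_template(sid, size=256)
            img = render(tpl.base, 256, blur_sd=0.0, noise_sd=0.0)
            femur_idx, _ = template_layout(sid).polygons[0]
            from skimage.draw import polygon as draw_polygon
            poly = tpl.base.points[list(femur_idx)]
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
            inside = np.zeros_like(img, dtype=bool)
            inside[rr, cc] = True
            assert img[inside].mean() > img[~inside].mean() + 50.0

    def test_deterministic_per_seed(self):
        tpl = make_template(SchemaId.PRE_ORIGINAL, size=128)
        a = render(tpl.base, 128, seed=5)
        b = render(tpl.base, 128, seed=5)
        np.testing.assert_array_equal(a, b)
        c = render(tpl.base, 128, seed=6)
        assert not np.array_equal(a, c)

    def test_out_of_frame_rejected(self):
        tpl = make_template(SchemaId.PRE_ORIGINAL, size=256)
        with pytest.raises(ValueError, match="out of frame"):
            render(tpl.base, 128)


class TestSimulatePaired:
    def test_noise_free_is_perfect_agreement(self):
        cfg = PairedSimConfig(n=20, err_sd_a_deg=0.0, err_sd_b_deg=0.0,
                              bias_deg=0.0, seed=1)
        p = simulate_paired(cfg)
        assert icc_agreement(p)[0] == pytest.approx(1.0)
        assert mad(p)[0] == pytest.approx(0.0)

    def test_deterministic(self):
        cfg = PairedSimConfig(n=10, seed=44)
        p1, p2 = simulate_paired(cfg), simulate_paired(cfg)
        np.testing.assert_array_equal(p1.a_deg, p2.a_deg)
        np.testing.assert_array_equal(p1.b_deg, p2.b_deg)

    def test_icc_decreases_with_method_error(self):
        # averaged over 20 seeds, more method-A noise means lower ICC
        mean_icc = {}
        for sd_a in (0.5, 2.0):
            vals = []
            for seed in range(20):
                cfg = PairedSimConfig(n=100, true_sd_deg=4.0,
                                      err_sd_a_deg=sd_a, err_sd_b_deg=1.0,
                                      seed=seed)
                vals.append(icc_agreement(simulate_paired(cfg))[0])
            mean_icc[sd_a] = np.mean(vals)
        assert mean_icc[2.0] < mean_icc[0.5]


class TestSimulateDataset:
    def test_emits_manifest_truth_and_pts(self, tmp_path):
        truth = simulate_dataset(tmp_path / "ds", SchemaId.PRE_ORIGINAL, 5,
                                 seed=7)
        assert len(truth) == 5
        assert (tmp_path / "ds" / "manifest.csv").exists()
        assert (tmp_path / "ds" / "truth.csv").exists()
        assert sorted(p.name for p in (tmp_path / "ds").glob("*.pts")) == [
            f"synth_{i:04d}.pts" for i in range(5)]

    def test_reproducible_per_seed(self, tmp_path):
        t1 = simulate_dataset(tmp_path / "a", SchemaId.POST_ORIGINAL, 4, seed=3)
        t2 = simulate_dataset(tmp_path / "b", SchemaId.POST_ORIGINAL, 4, seed=3)
        np.testing.assert_array_equal(t1["true_aFTA_deg"], t2["true_aFTA_deg"])
        assert ((tmp_path / "a" / "synth_0000.pts").read_text()
                == (tmp_path / "b" / "synth_0000.pts").read_text())
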