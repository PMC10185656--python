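"""Morphometry: soma delimitation, AIS detection, GAP geometry, densities."""

import math

import numpy as np
import pytest

from aisquant import aismorph as am
from aisquant import imgcore as ic
from aisquant import synthgen as sg


def _mip(stack, ch):
    return ic.max_intensity_projection(stack, ch)


@pytest.fixture(scope="module")
def one_cell(render_cfg):
    gt = sg.generate_neuron(
        sg.NeuronParams(gap_length=(5.0, 5.0), p_accumulation=0.0),
        1, field_um=render_cfg.field_um,
    )
    stack, masks = sg.render_stack(gt, render_cfg)
    return gt, stack, masks, sg.annotation_for(gt, render_cfg)


class TestDelimitSoma:
    def test_jaccard_against_ground_truth(self, one_cell, render_cfg):
        gt, stack, masks, ann = one_cell
        soma = am.delimit_soma(
            _mip(stack, "map2"), _mip(stack, "tuj1"), ann,
            render_cfg.pixel_size,
        )
        inter = (soma.mask & masks["soma"]).sum()
        union = (soma.mask | masks["soma"]).sum()
        assert inter / union >= 0.9

    def test_polygon_pass_through_area(self, one_cell, render_cfg):
        gt, stack, _, ann = one_cell
        import dataclasses

        ann2 = dataclasses.replace(ann, soma_polygon_um=gt.soma_polygon)
        soma = am.delimit_soma(
            _mip(stack, "map2"), _mip(stack, "tuj1"), ann2,
            render_cfg.pixel_size,
        )
        # rasterised area within a one-pixel boundary ring of polygon area
        perimeter = 2 * np.pi * np.sqrt(gt.soma_area / np.pi)
        assert abs(soma.area(render_cfg.pixel_size) - gt.soma_area) <= (
            perimeter * render_cfg.pixel_size + 1.0
        )

    def test_seed_on_background_raises(self, one_cell, render_cfg):
        gt, stack, _, ann = one_cell
        import dataclasses

        bad = dataclasses.replace(ann, soma_seed=(2, 2))
        with pytest.raises(am.SegmentationError, match="seed"):
            am.delimit_soma(
                _mip(stack, "map2"), _mip(stack, "tuj1"), bad,
                render_cfg.pixel_size,
            )


class TestDetectAis:
    def test_single_ais_jaccard(self, one_cell, render_cfg, thresholds):
        gt, stack, masks, ann = one_cell
        soma = am.delimit_soma(
            _mip(stack, "map2"), _mip(stack, "tuj1"), ann,
            render_cfg.pixel_size,
        )
        rois, n = am.detect_ais(
            _mip(stack, "ankg"), thresholds["ankg"], soma,
            render_cfg.pixel_size,
        )
        assert n == 1
        inter = (rois[0].mask & masks["ais"]).sum()
        union = (rois[0].mask | masks["ais"]).sum()
        assert inter / union >= 0.8

    @pytest.mark.parametrize("p_zero,p_double,expected", [
        (1.0, 0.0, 0), (0.0, 0.0, 1), (0.0, 1.0, 2),
    ])
    def test_multiplicity(self, render_cfg, thresholds, p_zero, p_double,
                          expected):
        params = sg.NeuronParams(p_zero_ais=p_zero, p_double_ais=p_double)
        gt = sg.generate_neuron(params, 40, field_um=render_cfg.field_um)
        stack, _ = sg.render_stack(gt, render_cfg)
        ann = sg.annotation_for(gt, render_cfg)
        soma = am.delimit_soma(
            _mip(stack, "map2"), _mip(stack, "tuj1"), ann,
            render_cfg.pixel_size,
        )
        _, n = am.detect_ais(
            _mip(stack, "ankg"), thresholds["ankg"], soma,
            render_cfg.pixel_size,
        )
        assert n == expected

    def test_background_only_channel_gives_zero(self, thresholds):
        img = np.full((60, 60), 0.03)
        soma = ic.Roi("soma", np.zeros((60, 60), bool))
        _, n = am.detect_ais(img, thresholds["ankg"], soma, 0.2)
        assert n == 0


class TestInclusionFilter:
    def test_single_ais_rule(self):
        ms = [
            am.ProximalAxonMeasurement("a", n_ais=0, ais_connected=False),
            am.ProximalAxonMeasurement("b", n_ais=1, ais_connected=True),
            am.ProximalAxonMeasurement("c", n_ais=2, ais_connected=True),
        ]
        out = am.apply_inclusion_filter(ms)
        assert [m.included for m in out] == [False, True, False]

    def test_disconnected_ais_excluded(self):
        m = am.ProximalAxonMeasurement("a", n_ais=1, ais_connected=False)
        assert not am.apply_inclusion_filter([m])[0].included

    def test_empty_list(self):
        assert am.apply_inclusion_filter([]) == []


class TestDelineateGap:
    def test_gap_length_recovery(self, one_cell, render_cfg, thresholds):
        gt, stack, masks, ann = one_cell
        m = am.measure_cell(stack, ann, thresholds)
        assert m.gap_length == pytest.approx(5.0, abs=0.5)

    def test_ais_abutting_soma_gives_zero_gap(self, render_cfg, thresholds):
        params = sg.NeuronParams(gap_length=(0.0, 0.0))
        gt = sg.generate_neuron(params, 3, field_um=render_cfg.field_um)
        stack, _ = sg.render_stack(gt, render_cfg)
        m = am.measure_cell(stack, sg.annotation_for(gt, render_cfg),
                            thresholds)
        assert m.gap_length == 0.0
        assert not m.has_gap
        assert math.isnan(m.nav_ais_to_gap_ratio)
        assert m.nav_ratio_reason == "no_gap"

    def test_disconnected_ais_raises(self):
        # soma and AIS in separate corners with no axon between them
        shape = (40, 40)
        soma = np.zeros(shape, bool)
        soma[2:8, 2:8] = True
        ais = np.zeros(shape, bool)
        ais[30:36, 30:36] = True
        axon = soma.copy()  # no path to the AIS
        with pytest.raises(am.DelineationError):
            am.delineate_gap(
                ic.Roi("soma", soma), ic.Roi("ais", ais), axon, 0.2
            )

    def test_straight_tube_medial_length_matches_euclidean(self):
        """Pixelated straight corridor: smoothed geodesic ≈ anchor distance."""
        shape = (60, 220)
        soma = np.zeros(shape, bool)
        soma[20:40, 0:20] = True
        ais = np.zeros(shape, bool)
        ais[27:33, 170:210] = True
        axon = np.zeros(shape, bool)
        axon[27:33, 10:210] = True
        _, length = am.delineate_gap(
            ic.Roi("soma", soma), ic.Roi("ais", ais), axon, pixel_size=1.0
        )
        assert length == pytest.approx(150.0, abs=1.5)


class TestMeasureGeometry:
    def test_caliber_is_area_over_length(self):
        gap = ic.Roi("gap", np.ones((2, 6), bool))  # 12 px = 12 µm² at ps 1
        ais = ic.Roi("ais", np.ones((2, 10), bool))
        out = am.measure_geometry(gap, ais, 6.0, 10.0, pixel_size=1.0)
        assert out["gap_caliber"] == pytest.approx(2.0)
        assert out["ais_caliber"] == pytest.approx(2.0)

    def test_zero_length_caliber_undefined_with_reason(self):
        gap = ic.Roi("gap", np.zeros((2, 2), bool))
        ais = ic.Roi("ais", np.ones((2, 2), bool))
        out = am.measure_geometry(gap, ais, 0.0, 2.0, 1.0)
        assert math.isnan(out["gap_caliber"])
        assert out["gap_caliber_reason"] == "zero_length"


class TestChannelDistributions:
    def test_totals_are_exact_sums(self, rng):
        pnf = rng.uniform(size=(30, 30))
        nav = rng.uniform(size=(30, 30))
        gap = ic.Roi("gap", rng.uniform(size=(30, 30)) < 0.2)
        ais = ic.Roi("ais", (rng.uniform(size=(30, 30)) < 0.2) & ~gap.mask)
        out = am.channel_distributions(pnf, nav, gap, ais, 0.2)
        assert out["id_pnf_total"] == out["id_pnf_gap"] + out["id_pnf_ais"]
        assert out["id_nav_total"] == out["id_nav_gap"] + out["id_nav_ais"]

    def test_ratio_worked_example(self):
        img = np.zeros((4, 8))
        img[:, :4] = 100.0 / 16  # gap integrated density 100 at ps 1...
        gap = ic.Roi("gap", np.zeros((4, 8), bool))
        gap.mask[:, :4] = True
        ais = ic.Roi("ais", ~gap.mask)
        nav = np.zeros((4, 8))
        nav[gap.mask] = 100.0 / 16
        nav[ais.mask] = 300.0 / 16
        out = am.channel_distributions(np.ones((4, 8)), nav, gap, ais, 1.0)
        assert out["nav_ais_to_gap_ratio"] == pytest.approx(3.0)

    def test_empty_ais_raises(self):
        gap = ic.Roi("gap", np.ones((2, 2), bool))
        ais = ic.Roi("ais", np.zeros((2, 2), bool))
        with pytest.raises(ic.MeasurementError):
            am.channel_distributions(
                np.ones((2, 2)), np.ones((2, 2)), gap, ais, 1.0
            )

    def test_noiseless_conservation(self, noiseless_cfg):
        """Integrated densities equal amplitude × pixel count × pixel_size²
        on a PSF-free render."""
        params = sg.NeuronParams(p_accumulation=0.0, amp_jitter=0.0)
        gt = sg.generate_neuron(params, 17, field_um=noiseless_cfg.field_um)
        stack, masks = sg.render_stack(gt, noiseless_cfg)
        ps = noiseless_cfg.pixel_size
        gap = ic.Roi("gap", masks["gap"])
        ais = ic.Roi("ais", masks["ais"])
        pnf = stack.channel("pnf").max(axis=0)
        nav = stack.channel("pannav").max(axis=0)
        out = am.channel_distributions(pnf, nav, gap, ais, ps)
        amps = gt.channel_amplitudes
        assert out["id_nav_ais"] == pytest.approx(
            amps["pannav"]["ais"] * masks["ais"].sum() * ps**2, rel=1e-9
        )
        assert out["id_pnf_gap"] == pytest.approx(
            amps["pnf"]["gap"] * masks["gap"].sum() * ps**2, rel=1e-9
        )


class TestDetectAccumulation:
    @pytest.mark.parametrize("extent", ["gap_only", "gap_and_ais"])
    def test_true_accumulations_found_with_extent(
        self, render_cfg, thresholds, extent
    ):
        params = sg.mutant_params()
        params.p_accumulation = 1.0
        params.p_acc_gap_and_ais = 1.0 if extent == "gap_and_ais" else 0.0
        gt = sg.generate_neuron(params, 23, field_um=render_cfg.field_um)
        stack, _ = sg.render_stack(gt, render_cfg)
        m = am.measure_cell(stack, sg.annotation_for(gt, render_cfg),
                            thresholds)
        assert m.has_accumulation
        assert m.accumulation_extent == extent

    def test_control_like_cell_negative(self, one_cell, thresholds):
        gt, stack, _, ann = one_cell
        m = am.measure_cell(stack, ann, thresholds)
        assert not m.has_accumulation
        assert m.accumulation_extent == "none"


class TestParameterRecovery:
    def test_length_regression_and_calibers(self, recovery_cohort):
        """Measured vs true geometry over 100 cells at default noise."""
        inc = [(g, m) for g, m in recovery_cohort if m.included]
        assert len(inc) >= 90
        for attr in ("gap_length", "ais_length"):
            pairs = [
                (getattr(g, attr), getattr(m, attr))
                for g, m in inc
                if not (attr == "gap_length" and not m.has_gap)
            ]
            t = np.array([p[0] for p in pairs])
            v = np.array([p[1] for p in pairs])
            slope = np.polyfit(t, v, 1)[0]
            rmse = float(np.sqrt(np.mean((v - t) ** 2)))
            assert abs(slope - 1.0) <= 0.05, attr
            assert rmse <= 1.0, attr
        for attr in ("gap_caliber", "ais_caliber"):
            errs = [
                abs(getattr(m, attr) - getattr(g, attr))
                for g, m in inc
                if not math.isnan(getattr(m, attr))
            ]
            assert np.mean(errs) <= 0.2, attr

    def test_additivity_holds_for_every_cell(self, recovery_cohort):
        for _, m in recovery_cohort:
            if not m.included:
                continue
            assert m.id_pnf_total == m.id_pnf_gap + m.id_pnf_ais
            assert m.id_nav_total == m.id_nav_gap + m.id_nav_ais


def test_nav_ratio_monotone_in_gap_leak(render_cfg, thresholds):
    """More Nav leakage into the GAP ⇒ lower measured AIS/GAP ratio."""
    ratios = []
    for leak in (0.05, 0.2, 0.45):
        params = sg.NeuronParams(
            gap_length=(8.0, 8.0), nav_gap_amplitude=(leak, leak),
            p_accumulation=0.0,
        )
        vals = []
        for seed in (60, 61, 62):
            gt = sg.generate_neuron(params, seed,
                                    field_um=render_cfg.field_um)
            stack, _ = sg.render_stack(gt, render_cfg)
            m = am.measure_cell(
                stack, sg.annotation_for(gt, render_cfg), thresholds
            )
            if not math.isnan(m.nav_ais_to_gap_ratio):
                vals.append(m.nav_ais_to_gap_ratio)
        ratios.append(np.median(vals))
    assert ratios[0] > ratios[1] > ratios[2]
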