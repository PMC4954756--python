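import numpy as np
import pytest

import hcsquant as hq
from hcsquant.eres import (
    ERESObject,
    aggregate_correlations,
    assign_to_cells,
    correlate_within_eres,
    count_eres_per_cell,
    detect_eres,
    measure_eres,
    product_image,
    treatment_correlation_table,
)
from hcsquant.segmentation import LabelMap

from conftest import channel_image


def disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def disk_image(diameters_um, px=0.11, value=100.0, shape=None):
    """Flat disks of known equivalent diameter on a zero background."""
    radii = [d / 2 / px for d in diameters_um]
    if shape is None:
        side = int(4 * max(radii) + 20)
        shape = (side, side * len(radii))
    img = np.zeros(shape)
    centers = []
    for i, r in enumerate(radii):
        c = (shape[0] // 2, int((i + 0.5) * shape[1] / len(radii)))
        img[disk(shape, c, r)] = value
        centers.append(c)
    return channel_image(img, pixel_size_um=px, channel="product"), centers


class TestProductImage:
    def test_zero_channel_zeroes_product(self):
        a = channel_image(np.random.default_rng(0).uniform(0, 10, (16, 16)), channel="sec31a")
        b = channel_image(np.zeros((16, 16)), channel="sec16")
        assert product_image(a, b).pixels.max() == 0.0

    def test_forced_arithmetic_with_zero_background(self):
        pa = np.zeros((9, 9))
        pb = np.zeros((9, 9))
        pa[4, 4] = 3.0
        pb[4, 4] = 4.0
        prod = product_image(
            channel_image(pa, channel="sec31a"), channel_image(pb, channel="sec16")
        )
        assert prod.pixels[4, 4] == 12.0

    def test_background_is_removed_before_multiplying(self):
        # constant positive backgrounds multiply to zero after median subtraction
        pa = np.full((32, 32), 7.0)
        pb = np.full((32, 32), 5.0)
        pa[10, 10] += 50.0
        pb[20, 20] += 50.0
        prod = product_image(
            channel_image(pa, channel="sec31a"), channel_image(pb, channel="sec16")
        )
        assert prod.pixels.max() == 0.0  # disjoint puncta -> empty product

    def test_dimension_mismatch_rejected(self):
        a = channel_image(np.zeros((8, 8)), channel="sec31a")
        b = channel_image(np.zeros((8, 4)), channel="sec16")
        with pytest.raises(ValueError):
            product_image(a, b)


class TestDetectEres:
    def test_blank_product_gives_no_objects(self):
        prod = channel_image(np.zeros((64, 64)), pixel_size_um=0.11, channel="product")
        assert detect_eres(prod) == []

    def test_in_range_punctum_retained(self):
        prod, _ = disk_image([1.0])
        objs = detect_eres(prod)
        assert len(objs) == 1
        assert objs[0].equivalent_diameter_um == pytest.approx(1.0, rel=0.1)

    def test_oversize_punctum_gated_out(self):
        prod, _ = disk_image([2.5])
        assert detect_eres(prod) == []

    def test_size_gate_soundness_across_sweep(self):
        diameters = [0.08, 0.3, 0.5, 1.0, 1.5, 2.0, 2.6]
        prod, _ = disk_image(diameters)
        objs = detect_eres(prod)
        for o in objs:
            assert 0.167 <= o.equivalent_diameter_um <= 1.67
        # the clearly-in-range disks are all present
        assert len(objs) == 4  # 0.3, 0.5, 1.0, 1.5

    def test_declumping_separates_overlapping_peaks(self):
        shape = (64, 64)
        img = np.zeros(shape)
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        sigma = 3.0
        for c in ((32, 26), (32, 44)):  # 18 px apart, tails overlap
            img += 100.0 * np.exp(
                -((rr - c[0]) ** 2 + (cc - c[1]) ** 2) / (2 * sigma**2)
            )
        prod = channel_image(img, pixel_size_um=0.11, channel="product")
        objs = detect_eres(prod, declump_min_distance_px=5)
        assert len(objs) == 2


class TestAssignMeasure:
    def test_centroid_assignment(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[4:16, 4:16] = 3
        lm = LabelMap(labels, 0.11)
        inside = ERESObject(1, 0, pixel_idx=np.array([10 * 32 + 10]), shape=(32, 32),
                            centroid_rc=(10.0, 10.0))
        outside = ERESObject(2, 0, pixel_idx=np.array([30 * 32 + 30]), shape=(32, 32),
                             centroid_rc=(30.0, 30.0))
        assign_to_cells([inside, outside], lm)
        assert inside.cell_id == 3
        assert outside.cell_id == 0

    def test_uniform_channel_measures_its_value(self):
        obj = ERESObject(1, 0, pixel_idx=np.arange(4), shape=(8, 8))
        ch = {"sec31a": channel_image(np.full((8, 8), 7.0), channel="sec31a")}
        measure_eres([obj], ch)
        assert obj.mean_intensity["sec31a"] == 7.0

    def test_forced_mean(self):
        img = np.zeros((8, 8))
        img.ravel()[:4] = [1.0, 2.0, 3.0, 6.0]
        obj = ERESObject(1, 0, pixel_idx=np.arange(4), shape=(8, 8))
        measure_eres([obj], {"atf6": channel_image(img, channel="atf6")})
        assert obj.mean_intensity["atf6"] == 3.0

    def test_no_channels_is_configuration_error(self):
        from hcsquant.io import ConfigurationError

        obj = ERESObject(1, 0, pixel_idx=np.arange(4), shape=(8, 8))
        with pytest.raises(ConfigurationError):
            measure_eres([obj], {})

    def test_detected_vs_true_mask_means_agree(self, eres_field_clean):
        spec, ch, truth = eres_field_clean
        objs = detect_eres(product_image(ch["sec31a"], ch["sec16"]))
        measure_eres(objs, {"sec31a": ch["sec31a"]})
        det = np.mean([o.mean_intensity["sec31a"] for o in objs])
        flat = ch["sec31a"].pixels.ravel()
        tru = np.mean(
            [flat[p.pixel_idx].mean() for p in truth.puncta if p.in_both_channels]
        )
        assert det == pytest.approx(tru, rel=0.25)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 10, (16, 16))
        a = channel_image(img, channel="atf6")
        b = channel_image(img.copy(), channel="sec31a")
        obj = ERESObject(1, 0, pixel_idx=np.arange(50), shape=(16, 16))
        assert correlate_within_eres([obj], a, b) == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(1, 10, (16, 16))
        a = channel_image(img, channel="atf6")
        b = channel_image(20.0 - img, channel="sec31a")
        obj = ERESObject(1, 0, pixel_idx=np.arange(50), shape=(16, 16))
        assert correlate_within_eres([obj], a, b) == pytest.approx(-1.0)

    def test_undefined_cases_return_none(self):
        a = channel_image(np.ones((8, 8)), channel="atf6")
        b = channel_image(np.ones((8, 8)), channel="sec31a")
        short = ERESObject(1, 0, pixel_idx=np.arange(2), shape=(8, 8))
        assert correlate_within_eres([short], a, b) is None  # < 3 pixels
        const = ERESObject(1, 0, pixel_idx=np.arange(8), shape=(8, 8))
        assert correlate_within_eres([const], a, b) is None  # constant channel
        assert correlate_within_eres([], a, b) is None

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(3)
        pa = rng.uniform(0, 100, (32, 32))
        pb = 0.6 * pa + rng.uniform(0, 40, (32, 32))
        idx = rng.choice(1024, size=200, replace=False)
        obj = ERESObject(1, 0, pixel_idx=idx, shape=(32, 32))
        r = correlate_within_eres(
            [obj],
            channel_image(pa, channel="atf6"),
            channel_image(pb, channel="sec31a"),
        )
        x, y = pa.ravel()[idx], pb.ravel()[idx]
        n = len(x)
        brute = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert r == pytest.approx(brute, rel=1e-12)

    def test_rho_recovery_is_monotone_in_target(self):
        means = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            spec = hq.eres_scene(
                n_cells=1, seed=41, field_shape_px=(400, 400),
                cell_diameter_um=30, nucleus_diameter_um=8,
                eres=hq.EresParams(
                    n_puncta_per_cell=30, target_rho=rho, coloc_fraction=1.0,
                    diameter_range_um=(0.3, 0.8), min_separation_um=1.0,
                ),
                noise=hq.NoiseParams(photon_scale=4.0, read_sd=1.0),
            )
            images, truth = hq.generate_eres_field(spec)
            ch = {im.channel: im for im in images}
            objs = detect_eres(product_image(ch["sec31a"], ch["sec16"]))
            assign_to_cells(objs, LabelMap(truth.cell_labels, spec.pixel_size_um))
            r = correlate_within_eres(
                [o for o in objs if o.cell_id == 1], ch["atf6"], ch["sec31a"]
            )
            means.append(r)
        assert means == sorted(means)


class TestAggregation:
    def test_constant_slices(self):
        (cc,) = aggregate_correlations({7: [0.5] * 6})
        assert cc.mean_r == 0.5 and cc.sd_r == 0.0

    def test_two_slice_mean(self):
        (cc,) = aggregate_correlations({1: [0.2, 0.4]})
        assert cc.mean_r == pytest.approx(0.3)

    def test_invalid_slices_skipped_and_empty_cells_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            out = aggregate_correlations({1: [0.2, None, 0.4], 2: [None, None]})
        assert len(out) == 1 and out[0].cell_id == 1

    def test_experiment_mean_equals_mean_of_cell_means(self):
        cells = aggregate_correlations({1: [0.2, 0.4], 2: [0.6, 0.8]})
        table = treatment_correlation_table({"Tg": cells})
        expected = np.mean([c.mean_r for c in cells])
        assert table.mean_r.iloc[0] == expected


class TestCounts:
    def test_no_objects_gives_empty_table(self):
        assert len(count_eres_per_cell([])) == 0

    def test_planted_count_recovered_noise_free(self, eres_field_clean):
        spec, ch, truth = eres_field_clean
        objs = detect_eres(product_image(ch["sec31a"], ch["sec16"]))
        assign_to_cells(objs, LabelMap(truth.cell_labels, spec.pixel_size_um))
        counts = count_eres_per_cell(objs)
        planted = {cid: sum(1 for p in truth.puncta if p.cell_id == cid)
                   for cid in (1, 2)}
        for _, row in counts.iterrows():
            assert row.n_eres == planted[row.cell_id]

    def test_counts_invariant_to_intensity_rescaling(self, eres_field_clean):
        spec, ch, truth = eres_field_clean
        objs = detect_eres(product_image(ch["sec31a"], ch["sec16"]))
        scaled = {
            name: channel_image(
                im.pixels * 3.0, pixel_size_um=im.pixel_size_um, channel=name
            )
            for name, im in ch.items() if name in ("sec31a", "sec16")
        }
        objs2 = detect_eres(product_image(scaled["sec31a"], scaled["sec16"]))
        assert len(objs) == len(objs2)
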