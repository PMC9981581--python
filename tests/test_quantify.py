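"""Segmentation, morphometry, classification and compartment statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dffoct.dyncontrast import DEFAULT_BANDS, AcquisitionParams, DynamicImage, compute_dffoct, compute_static
from dffoct.phantom import PhantomSpec, build_scene, simulate_timestack
from dffoct.quantify import (
    ClassifierParams,
    NucleusRecord,
    classify_by_area,
    compartment_summary,
    detection_report,
    match_to_ground_truth,
    measure_regions,
    records_frame,
    segment_ganglia,
    segment_nuclei,
    size_histogram,
)


def make_dynamic(channels, pixel_size=1.0):
    return DynamicImage(np.asarray(channels, dtype=float), DEFAULT_BANDS,
                        pixel_size)


def record(id=1, area=50.0, cy=0.0, cx=0.0, low=1.0, med=1.0, high=1.0):
    return NucleusRecord(id, (cy, cx), area, low, med, high)


class TestSegmentGanglia:
    def test_phantom_ganglia_recovered_with_good_overlap(
        self, default_scene, default_ganglia
    ):
        """Every ground-truth ganglion overlaps one detection at IoU >= 0.5."""
        assert default_ganglia.max() >= 1
        for gt_mask in default_scene.ganglion_masks:
            ious = [
                (gt_mask & (default_ganglia == lab)).sum()
                / (gt_mask | (default_ganglia == lab)).sum()
                for lab in range(1, default_ganglia.max() + 1)
            ]
            assert max(ious) >= 0.5

    def test_uniform_images_give_empty_mask_set(self, caplog):
        dyn = make_dynamic(np.ones((3, 40, 40)))
        with caplog.at_level("WARNING"):
            labels = segment_ganglia(np.ones((40, 40)), dyn)
        assert labels.max() == 0

    def test_manual_mask_passthrough(self):
        dyn = make_dynamic(np.zeros((3, 20, 20)))
        manual = np.zeros((20, 20), dtype=bool)
        manual[5:10, 5:10] = True
        labels = segment_ganglia(np.zeros((20, 20)), dyn, manual_mask=manual)
        assert (labels[manual] == 1).all()
        assert labels.max() == 1


class TestSegmentNuclei:
    def test_phantom_nuclei_found_near_ground_truth_centroids(
        self, default_scene, default_records
    ):
        """Well-separated visible nuclei are each matched within 3 µm."""
        visible = [n for n in default_scene.nuclei if not n.dropout]
        cents = np.array([r.centroid_um for r in default_records])
        n_hit = 0
        for nuc in visible:
            d = np.linalg.norm(cents - np.array(nuc.centroid_um), axis=1)
            if d.min() < 3.0:
                n_hit += 1
        assert n_hit >= 0.9 * len(visible)

    def test_dropout_nuclei_absent_from_labels(self, default_scene,
                                               default_records):
        dropped = [n for n in default_scene.nuclei if n.dropout]
        cents = np.array([r.centroid_um for r in default_records])
        for nuc in dropped:
            d = np.linalg.norm(cents - np.array(nuc.centroid_um), axis=1)
            assert d.min() > 2.0

    def test_all_zero_dynamic_image_gives_no_labels(self):
        dyn = make_dynamic(np.zeros((3, 30, 30)))
        labels = segment_nuclei(dyn, np.ones((30, 30), dtype=np.int32))
        assert labels.max() == 0

    def test_nuclei_outside_ganglion_mask_suppressed(self):
        chans = np.full((3, 40, 40), 0.1)
        chans[1:, 10:16, 10:16] = 5.0  # blob inside the mask
        chans[1:, 30:36, 30:36] = 5.0  # blob outside
        gang = np.zeros((40, 40), dtype=np.int32)
        gang[:20, :20] = 1
        labels = segment_nuclei(make_dynamic(chans), gang)
        assert labels[12, 12] > 0
        assert (labels[25:, 25:] == 0).all()


class TestMeasureRegions:
    def test_square_region_area_and_mean(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:14, 6:16] = 1  # 10 x 10 px at 1 µm/px
        chans = np.stack([np.full((20, 20), c) for c in (0.5, 1.5, 2.5)])
        recs = measure_regions(labels, make_dynamic(chans))
        assert len(recs) == 1
        assert recs[0].area_um2 == pytest.approx(100.0)
        assert (recs[0].mean_low, recs[0].mean_medium, recs[0].mean_high) == (
            0.5, 1.5, 2.5,
        )

    def test_pixel_size_scales_area_quadratically(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:5, :5] = 1
        recs = measure_regions(
            labels, make_dynamic(np.ones((3, 10, 10)), pixel_size=0.5)
        )
        assert recs[0].area_um2 == pytest.approx(25 * 0.25)

    def test_neuron_regions_brighter_than_glia_in_all_bands(
        self, default_scene, default_records
    ):
        """Neuronal nuclei carry more power in every band than glial ones."""
        table = records_frame(default_records)
        det = match_to_ground_truth(default_records, default_scene)
        gt_cls = {n.id: n.cls for n in default_scene.nuclei}
        table = records_frame(default_records)  # refresh matched ids
        cls = table["matched_gt_id"].map(gt_cls)
        for band in ("mean_low", "mean_medium", "mean_high"):
            assert (
                table.loc[cls == "neuron", band].mean()
                > table.loc[cls == "glia", band].mean()
            )

    def test_rasterised_ellipse_areas_match_analytic(self, default_scene):
        """Rasterisation at 1 µm/px is within 10% of πab for areas >=30 µm²."""
        for nuc in default_scene.nuclei:
            if nuc.analytic_area_um2 >= 30.0:
                assert nuc.raster_area_um2 == pytest.approx(
                    nuc.analytic_area_um2, rel=0.10
                )


class TestClassifyByArea:
    @pytest.mark.parametrize(
        "area,expected",
        [(49.9, "glia"), (89.9, "neuron"), (65.0, "neuron"), (64.99, "glia")],
    )
    def test_printed_class_means_and_boundary(self, area, expected):
        recs = classify_by_area([record(area=area)])
        assert recs[0].predicted_class == expected

    def test_boundary_rule_configurable(self):
        recs = classify_by_area(
            [record(area=65.0)], ClassifierParams(boundary_class="glia")
        )
        assert recs[0].predicted_class == "glia"

    def test_determinism(self):
        recs = [record(id=i, area=a) for i, a in enumerate([30, 65, 90], 1)]
        first = [r.predicted_class for r in classify_by_area(recs)]
        second = [r.predicted_class for r in classify_by_area(recs)]
        assert first == second == ["glia", "neuron", "neuron"]

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ClassifierParams(area_cutoff_um2=0.0)


class TestDetectionReporting:
    def test_printed_counts_reproduce_percentages(self):
        """163/170 -> 95.9% (96% rounded); 71/91 -> 78.0%."""
        table = detection_report(
            {"neuron": 163, "glia": 71}, {"neuron": 170, "glia": 91}
        )
        neuron = table[table["class"] == "neuron"].iloc[0]
        glia = table[table["class"] == "glia"].iloc[0]
        assert neuron["percent"] == pytest.approx(95.88, abs=0.01)
        assert neuron["percent_rounded"] == 96
        assert glia["percent"] == pytest.approx(78.02, abs=0.01)
        assert glia["percent_rounded"] == 78

    def test_empty_records_give_zero_percent(self, default_scene):
        table = match_to_ground_truth([], default_scene)
        assert (table["percent"] == 0.0).all()

    def test_matching_is_one_to_one_within_radius(self, default_scene,
                                                  default_records):
        recs = [dataclasses.replace(r, matched_gt_id=None)
                for r in default_records]
        match_to_ground_truth(recs, default_scene, max_dist_um=5.0)
        matched = [r.matched_gt_id for r in recs if r.matched_gt_id]
        assert len(matched) == len(set(matched))
        gt = {n.id: n for n in default_scene.nuclei}
        for r in recs:
            if r.matched_gt_id:
                d = np.linalg.norm(
                    np.array(r.centroid_um)
                    - np.array(gt[r.matched_gt_id].centroid_um)
                )
                assert d <= 5.0


class TestSizeHistogram:
    def test_empty_input_gives_empty_histogram(self):
        hist = size_histogram([])
        assert hist.empty

    def test_counts_sum_to_record_count(self, default_records):
        hist = size_histogram(default_records)
        assert hist["count"].sum() == len(default_records)
        assert (hist["bin_left"] % 10 == 0).all()

    def test_glial_mode_left_of_neuronal_mode(self, default_records):
        hist = size_histogram(default_records)
        modes = {}
        for cls in ("glia", "neuron"):
            sub = hist[hist["class"] == cls]
            modes[cls] = sub.loc[sub["count"].idxmax(), "bin_left"]
        assert modes["glia"] < modes["neuron"]


class TestDetectionRateRecovery:
    def test_dropout_rates_reproduce_study_detection_percentages(self):
        """With 4%/22% dropout at the study's counted populations (170
        neurons, 91 glia), measured detection percentages fall within 3
        binomial SE of 96% and 78%."""
        from dffoct.experiments import run_area_recovery

        res = run_area_recovery(n_neuron=170, n_glia=91, seed=5,
                                n_phantoms=6)
        s = res["summary"]
        pct_n = 100.0 * s["neuron"]["detected"] / s["neuron"]["total"]
        pct_g = 100.0 * s["glia"]["detected"] / s["glia"]["total"]
        se_n = 100 * np.sqrt(0.96 * 0.04 / 170)
        se_g = 100 * np.sqrt(0.78 * 0.22 / 91)
        assert abs(pct_n - 96.0) < 3 * se_n
        assert abs(pct_g - 78.0) < 3 * se_g

    def test_neuron_fraction_above_cutoff_matches_binomial_expectation(self):
        """Fraction of ground-truth neurons measured >= 65 µm² within 3 SE
        of the Gaussian-model binomial expectation at n = 219."""
        from scipy.stats import norm

        from dffoct.experiments import run_area_recovery

        res = run_area_recovery(seed=2, dropout={"neuron": 0.0, "glia": 0.0})
        frac = res["summary"]["neuron"]["frac_ge_65"]
        n = res["summary"]["neuron"]["n"]
        p = norm.cdf((89.9 - 65.0) / 17.9)  # P(area >= 65) under the model
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestCompartmentSummary:
    def test_intra_exceeds_extra_with_significance(
        self, default_dynamic, default_ganglia, rng
    ):
        summary = compartment_summary(
            default_dynamic, default_ganglia, n_regions=5, rng=rng
        )
        t = summary.table.set_index(["compartment", "band"])["mean"]
        for band in ("low", "medium", "high"):
            assert t["intra", band] > t["extra", band]
            assert summary.p_values[band] < 0.05

    def test_single_region_reports_missing_sem(
        self, default_dynamic, default_ganglia, rng
    ):
        summary = compartment_summary(
            default_dynamic, default_ganglia, n_regions=1, rng=rng
        )
        assert summary.table["sem"].isna().all()
        assert all(np.isnan(p) for p in summary.p_values.values())

    def test_insufficient_area_raises_with_sizes(self, rng):
        dyn = make_dynamic(np.ones((3, 30, 30)))
        gang = np.ones((30, 30), dtype=np.int32)  # no extra-ganglionic room
        with pytest.raises(ValueError, match="px"):
            compartment_summary(dyn, gang, n_regions=3, rng=rng)

    def test_type_i_error_control_under_null(self):
        """Identical fluctuation statistics inside and outside: the per-band
        Mann-Whitney comparison rejects at ~alpha (discrete exact test, 8
        regions per side, 200 simulations)."""
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            chans = rng.standard_normal((3, 64, 64)) ** 2
            dyn = make_dynamic(chans)
            gang = np.zeros((64, 64), dtype=np.int32)
            gang[:, :28] = 1
            summary = compartment_summary(
                dyn, gang, n_regions=8, box_um=5.0, border_um=2.0, rng=rng
            )
            rejections += sum(
                1 for p in summary.p_values.values() if p < 0.05
            )
        rate = rejections / (3 * n_sims)
        assert 0.005 <= rate <= 0.09
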