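"""Synthetic whole-mount generator: geometry, spectra, treatments, confocal."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from dffoct.dyncontrast import (
    DEFAULT_BANDS,
    AcquisitionParams,
    band_power_map,
    compute_dffoct,
)
from dffoct.phantom import (
    FluctuationModel,
    PhantomSpec,
    apply_treatment,
    build_scene,
    mannitol,
    render_confocal,
    rescue_dropouts,
    simulate_timestack,
    ttx,
    vehicle,
    veratridine,
    washout,
    TreatmentCondition,
)
from dffoct.registration import RigidTransform


def tiny_spec(**kwargs) -> PhantomSpec:
    from dffoct.phantom import GanglionGeometry

    defaults = dict(
        field_of_view=(128.0, 128.0),
        n_ganglia=2,
        ganglion_geometry=GanglionGeometry(
            semi_major_range=(20.0, 25.0), axis_ratio_range=(1.1, 1.4),
            margin=6.0,
        ),
        class_counts={"neuron": 5, "glia": 3},
        seed=3,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestSpecValidation:
    def test_dropout_probability_bounds(self):
        with pytest.raises(ValueError):
            PhantomSpec(detection_dropout={"neuron": 1.2, "glia": 0.0})

    def test_area_sd_must_be_below_mean(self):
        with pytest.raises(ValueError):
            PhantomSpec(class_area_dists={"neuron": (50.0, 60.0),
                                          "glia": (49.9, 15.8)})

    def test_band_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FluctuationModel(1.0, (0.5, 0.2, 0.2))

    def test_acquisition_band_nyquist_invariant(self):
        acq = AcquisitionParams()  # 300 Hz / 4 -> Nyquist 37.5 Hz
        acq.validate_bands(DEFAULT_BANDS)  # 25 < 37.5: fine
        with pytest.raises(ValueError):
            AcquisitionParams(1000, 300.0, 8).validate_bands(DEFAULT_BANDS)

    def test_frames_divisible_by_averaging_factor(self):
        with pytest.raises(ValueError):
            AcquisitionParams(n_frames=1001, block_average=4)


class TestBuildScene:
    def test_empty_class_counts_give_nucleus_free_scene(self):
        scene = build_scene(tiny_spec(class_counts={"neuron": 0, "glia": 0}))
        assert scene.nuclei == []
        assert scene.nucleus_labels.max() == 0
        assert (scene.compartment_labels > 0).all()

    def test_neuron_area_sampling_recovers_printed_mean(self):
        """219 sampled neuronal areas average within 3 SE of 89.9 µm²."""
        from dffoct.phantom import GanglionGeometry

        spec = PhantomSpec(
            field_of_view=(288.0, 288.0),
            n_ganglia=4,
            ganglion_geometry=GanglionGeometry(semi_major_range=(32.0, 44.0)),
            class_counts={"neuron": 28, "glia": 0},
            seed=11,
        )
        areas = []
        for k in range(8):
            n_here = 28 if k < 3 else 27
            scene = build_scene(
                dataclasses.replace(
                    spec, seed=11 + k,
                    class_counts={"neuron": n_here, "glia": 0},
                )
            )
            areas += [n.analytic_area_um2 for n in scene.nuclei]
        assert len(areas) == 219
        se = 17.9 / np.sqrt(219)
        assert abs(np.mean(areas) - 89.9) < 3 * se

    def test_deterministic_under_seed(self):
        a = build_scene(tiny_spec())
        b = build_scene(tiny_spec())
        np.testing.assert_array_equal(a.nucleus_labels, b.nucleus_labels)
        np.testing.assert_array_equal(a.static_template, b.static_template)
        assert [n.centroid_um for n in a.nuclei] == [
            n.centroid_um for n in b.nuclei
        ]

    def test_nuclei_disjoint_and_inside_ganglia(self, default_scene):
        labels = default_scene.nucleus_labels
        in_ganglia = default_scene.ganglion_labels > 0
        assert (labels[~in_ganglia] == 0).all()
        # labels are disjoint by construction of a single label image; check
        # each nucleus covers the pixels its record claims
        for nuc in default_scene.nuclei:
            count = (labels == nuc.id).sum()
            assert count * default_scene.pixel_size**2 == nuc.raster_area_um2

    def test_raster_area_close_to_analytic_ellipse(self, default_scene):
        for nuc in default_scene.nuclei:
            assert nuc.raster_area_um2 == pytest.approx(
                nuc.analytic_area_um2, rel=0.10
            )

    def test_muscle_layers_have_orthogonal_fiber_orientations(
        self, default_scene
    ):
        """Dominant gradient direction differs by ~90° between the layers."""
        tex = default_scene.static_template.astype(float)

        def dominant_angle(mask):
            gy, gx = np.gradient(tex)
            # structure-tensor orientation over the masked region
            jxx = (gx * gx)[mask].mean()
            jyy = (gy * gy)[mask].mean()
            jxy = (gx * gy)[mask].mean()
            return 0.5 * np.arctan2(2 * jxy, jxx - jyy)

        m_long = ndi.binary_erosion(
            default_scene.compartment_labels == 1, iterations=3
        )
        m_circ = ndi.binary_erosion(
            default_scene.compartment_labels == 2, iterations=3
        )
        diff = abs(dominant_angle(m_long) - dominant_angle(m_circ))
        diff = min(diff, np.pi - diff)
        assert diff > np.pi / 3  # within 30° of orthogonal

    def test_impossible_packing_raises_naming_ganglion(self):
        spec = tiny_spec(class_counts={"neuron": 200, "glia": 0})
        with pytest.raises(RuntimeError, match="ganglion"):
            build_scene(spec)


class TestSimulateTimestack:
    def test_seeded_determinism_bit_identical(self):
        spec = tiny_spec()
        scene = build_scene(spec)
        a = simulate_timestack(scene, spec)
        b = simulate_timestack(scene, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_variance_compartment_is_static_plus_noise(self):
        spec = tiny_spec(
            compartment_psd={
                "nucleus_neuron": FluctuationModel(0.0, (0, 0, 1)),
                "nucleus_glia": FluctuationModel(0.0, (0, 0, 1)),
                "ganglion_cytoplasm": FluctuationModel(0.0, (0, 0, 1)),
                "extra_ganglionic": FluctuationModel(0.0, (0, 0, 1)),
                "muscle": FluctuationModel(0.0, (0, 0, 1)),
            },
            detector_noise_sd=0.05,
        )
        scene = build_scene(spec)
        stack = simulate_timestack(scene, spec)
        resid = stack.data - scene.static_template[None]
        assert abs(resid.mean()) < 1e-3
        assert resid.std() == pytest.approx(0.05, rel=0.05)

    def test_pure_high_band_compartment_concentrates_power(self):
        """Weights (0,0,1): >=80% of estimated AC power in 5.4-25 Hz."""
        spec = tiny_spec(
            compartment_psd={
                "nucleus_neuron": FluctuationModel(4.0, (0.0, 0.0, 1.0)),
                "nucleus_glia": FluctuationModel(4.0, (0.0, 0.0, 1.0)),
                "ganglion_cytoplasm": FluctuationModel(4.0, (0.0, 0.0, 1.0)),
                "extra_ganglionic": FluctuationModel(4.0, (0.0, 0.0, 1.0)),
                "muscle": FluctuationModel(4.0, (0.0, 0.0, 1.0)),
            },
            detector_noise_sd=0.0,
        )
        scene = build_scene(spec)
        acq = AcquisitionParams()
        dyn = compute_dffoct(simulate_timestack(scene, spec, acq), acq)
        frac = dyn.high / np.maximum(dyn.total, 1e-30)
        assert frac.size >= 100
        assert frac.mean() >= 0.80

    def test_white_noise_band_powers_proportional_to_bandwidth(self):
        """Detector-noise-only phantom analysed without averaging."""
        spec = tiny_spec(
            compartment_psd={
                k: FluctuationModel(0.0, (0, 0, 1))
                for k in ("nucleus_neuron", "nucleus_glia",
                          "ganglion_cytoplasm", "extra_ganglionic", "muscle")
            },
            detector_noise_sd=1.0,
        )
        scene = build_scene(spec)
        acq = AcquisitionParams(n_frames=250, sampling_rate=75.0,
                                block_average=1)
        stack = simulate_timestack(scene, spec, acq)
        bp = band_power_map(
            np.asarray(stack.data, dtype=np.float64), 75.0
        ).reshape(3, -1).mean(axis=1)
        widths = np.array([0.6, 4.8, 19.6])
        np.testing.assert_allclose(bp / widths / (bp[2] / 19.6), 1.0, rtol=0.10)

    def test_ganglionic_variance_exceeds_extra_ganglionic(
        self, default_scene, default_dynamic
    ):
        intra = default_dynamic.total[default_scene.ganglion_labels > 0]
        extra = default_dynamic.total[default_scene.ganglion_labels == 0]
        assert intra.mean() > extra.mean()

    def test_no_power_above_generation_nyquist(self):
        spec = tiny_spec(detector_noise_sd=0.0)
        scene = build_scene(spec)
        acq = AcquisitionParams()
        stack = simulate_timestack(scene, spec, acq)
        freqs = np.fft.rfftfreq(stack.n_frames, 1 / 300.0)
        spectrum = np.abs(
            np.fft.rfft(
                stack.data[:, ::16, ::16]
                - stack.data[:, ::16, ::16].mean(axis=0),
                axis=0,
            )
        ).mean(axis=(1, 2))
        in_band = spectrum[(freqs > 0) & (freqs <= 25.0)].mean()
        above = spectrum[freqs > 25.5].mean()
        assert above < 1e-3 * in_band

    def test_dropout_nucleus_fluctuates_like_cytoplasm(self, default_spec):
        spec = dataclasses.replace(
            default_spec, detection_dropout={"neuron": 1.0, "glia": 1.0}
        )
        scene = build_scene(spec)
        acq = AcquisitionParams()
        dyn = compute_dffoct(simulate_timestack(scene, spec, acq), acq)
        nuc_mask = scene.nucleus_labels > 0
        cyto_mask = (scene.ganglion_labels > 0) & ~nuc_mask
        assert dyn.total[nuc_mask].mean() == pytest.approx(
            dyn.total[cyto_mask].mean(), rel=0.10
        )


class TestTreatments:
    def test_vehicle_is_identity(self):
        spec = tiny_spec()
        out = apply_treatment(spec, vehicle())
        for key, model in spec.compartment_psd.items():
            assert out.compartment_psd[key].total_variance == pytest.approx(
                model.total_variance
            )

    def test_mannitol_dose_zero_is_identity(self):
        cond = mannitol(0.0)
        assert cond.band_gains == (1.0, 1.0, 1.0)

    def test_mannitol_gains_strictly_decrease_with_dose(self):
        gains = [mannitol(d).band_gains for d in (100.0, 200.0, 300.0)]
        for b in range(3):
            seq = [g[b] for g in gains]
            assert seq[0] > seq[1] > seq[2]
            assert all(g < 1 for g in seq)

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            TreatmentCondition("bad", (-0.1, 1.0, 1.0))

    def test_veratridine_scales_ganglionic_band_variances_by_gain_squared(self):
        spec = tiny_spec()
        cond = veratridine(gain_lf=0.8, gain_mf=1.5, gain_hf=1.5)
        out = apply_treatment(spec, cond)
        for key in ("nucleus_neuron", "nucleus_glia", "ganglion_cytoplasm"):
            before = spec.compartment_psd[key].band_variances
            after = out.compartment_psd[key].band_variances
            np.testing.assert_allclose(
                after, before * np.array([0.64, 2.25, 2.25]), rtol=1e-9
            )
        for key in ("extra_ganglionic", "muscle"):
            np.testing.assert_allclose(
                out.compartment_psd[key].band_variances,
                spec.compartment_psd[key].band_variances,
            )

    def test_ttx_touches_only_low_band(self):
        spec = tiny_spec()
        out = apply_treatment(spec, ttx(gain_lf=0.85))
        before = spec.compartment_psd["nucleus_neuron"].band_variances
        after = out.compartment_psd["nucleus_neuron"].band_variances
        assert after[0] == pytest.approx(before[0] * 0.85**2)
        assert after[1:] == pytest.approx(before[1:])

    def test_washout_restores_baseline(self):
        spec = tiny_spec()
        out = apply_treatment(spec, washout())
        assert out.compartment_psd == spec.compartment_psd

    def test_dropout_rescue_clears_flags(self, rng):
        spec = tiny_spec(detection_dropout={"neuron": 1.0, "glia": 1.0})
        scene = build_scene(spec)
        assert all(n.dropout for n in scene.nuclei)
        rescued = rescue_dropouts(scene, 1.0, rng)
        assert not any(n.dropout for n in rescued.nuclei)
        untouched = rescue_dropouts(scene, 0.0, rng)
        assert all(n.dropout for n in untouched.nuclei)


class TestRenderConfocal:
    def test_identity_transform_zero_jitter_landmarks_match(self):
        scene = build_scene(tiny_spec())
        bundle = render_confocal(scene, RigidTransform.identity(2))
        np.testing.assert_allclose(
            bundle.landmarks[["x_a", "y_a"]].to_numpy(),
            bundle.landmarks[["x_b", "y_b"]].to_numpy(),
        )

    def test_dropout_nucleus_present_in_dapi_but_dynamically_silent(self):
        spec = tiny_spec(detection_dropout={"neuron": 0.0, "glia": 1.0})
        scene = build_scene(spec)
        bundle = render_confocal(scene, RigidTransform.identity(2))
        glia = [n for n in scene.nuclei if n.cls == "glia"]
        assert glia and all(n.dropout for n in glia)
        acq = AcquisitionParams()
        dyn = compute_dffoct(simulate_timestack(scene, spec, acq), acq)
        cyto = (scene.ganglion_labels > 0) & (scene.nucleus_labels == 0)
        for nuc in glia:
            mask = scene.nucleus_labels == nuc.id
            assert bundle.channels[0][mask].mean() > 0.3  # DAPI-positive
            assert dyn.total[mask].mean() < 2 * dyn.total[cyto].mean()

    def test_rotation_moves_dapi_centroids_with_transform(self):
        scene = build_scene(tiny_spec())
        ny = scene.nucleus_labels.shape[0] * scene.pixel_size
        transform = RigidTransform.from_angle(np.pi / 2, (ny, 0.0))
        bundle = render_confocal(scene, transform)
        from skimage.measure import regionprops

        lab, _ = ndi.label(bundle.channels[0] > 0.5)
        got = np.array([p.centroid for p in regionprops(lab)])
        expected = transform.apply(
            np.array([n.centroid_um for n in scene.nuclei])
        )
        for e in expected:
            assert np.linalg.norm(got - e, axis=1).min() < 1.0  # within 1 px

    def test_transform_ejecting_all_nuclei_rejected(self):
        scene = build_scene(tiny_spec())
        bad = RigidTransform.identity(2)
        bad = RigidTransform(bad.rotation, np.array([1e5, 1e5]))
        with pytest.raises(ValueError, match="outside"):
            render_confocal(scene, bad)

    def test_jitter_perturbs_only_confocal_frame(self, rng):
        scene = build_scene(tiny_spec())
        bundle = render_confocal(
            scene, RigidTransform.identity(2), jitter_um=1.0, rng=rng
        )
        d = np.hypot(
            bundle.landmarks.x_a - bundle.landmarks.x_b,
            bundle.landmarks.y_a - bundle.landmarks.y_b,
        )
        assert d.max() > 0
        assert d.max() < 6.0  # a few sigma
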