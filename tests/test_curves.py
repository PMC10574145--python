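"""Curve ingestion, segmentation, normalization and overlay tests."""

import numpy as np
import pytest

from chitinmech import (
    CurveFormatError,
    ForceExtensionCurve,
    NormalizedCurve,
    SyntheticCurveSpec,
    extension_at_force,
    fjc_extension,
    generate_fec,
    load_curves,
    normalize_curve,
    overlay_dispersion,
    segment_curve,
    tsqm_fjc_extension,
    write_curves,
)


def make_curve(extension, force, **kw):
    return ForceExtensionCurve(np.asarray(extension, float), np.asarray(force, float), **kw)


class TestTsvDialect:
    def test_write_read_round_trip(self, base_params, tmp_path):
        spec = SyntheticCurveSpec(params=base_params, n_curves=3, force_noise=5.0, seed=11)
        curves = generate_fec(spec)
        path = tmp_path / "curves.tsv"
        write_curves(curves, path)
        loaded = load_curves(path)
        assert [c.curve_id for c in loaded] == [c.curve_id for c in curves]
        assert len({c.curve_id for c in loaded}) == 3
        for a, b in zip(curves, loaded):
            np.testing.assert_array_equal(a.extension, b.extension)
            np.testing.assert_array_equal(a.force, b.force)
            assert b.environment == a.environment
            assert b.metadata == a.metadata

    def test_environment_metadata_parsed(self, tmp_path):
        rows = "\n".join(f"{x}\t{x * 10.0}" for x in range(1, 13))
        (tmp_path / "c.tsv").write_text(
            f"#id: c1\n#environment: pH3\nextension_nm\tforce_pN\n{rows}\n"
        )
        (curve,) = load_curves(tmp_path / "c.tsv")
        assert curve.environment == "pH3"

    def test_malformed_row_names_line(self, tmp_path):
        (tmp_path / "bad.tsv").write_text(
            "extension_nm\tforce_pN\n1.0\t2.0\noops\t??\n"
        )
        with pytest.raises(CurveFormatError, match="line 3"):
            load_curves(tmp_path / "bad.tsv")

    def test_missing_header_is_format_error(self, tmp_path):
        (tmp_path / "nohdr.tsv").write_text("1.0\t2.0\n" * 12)
        with pytest.raises(CurveFormatError):
            load_curves(tmp_path / "nohdr.tsv")


class TestSegmentation:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_generator_ground_truth(self, base_params, seed):
        spec = SyntheticCurveSpec(params=base_params, n_curves=3, force_noise=0.0, seed=seed)
        for curve in generate_fec(spec):
            seg = segment_curve(curve)
            truth_adh = int(curve.metadata["truth_adhesion_end_index"])
            truth_det = int(curve.metadata["truth_detachment_index"])
            assert abs(seg.adhesion_end_index - truth_adh) <= 2
            assert seg.detachment_index is not None
            assert abs(seg.detachment_index - truth_det) <= 2

    def test_detachment_at_appended_drop(self, base_params):
        ext = np.linspace(0.0, 25.0, 100)
        force = 1800.0 * (ext / 25.0) ** 3  # smooth monotone rise
        ext = np.append(ext, 25.3)
        force = np.append(force, 0.0)
        seg = segment_curve(make_curve(ext, force))
        assert seg.detachment_index == 100
        assert seg.adhesion_end_index == 0

    def test_flat_zero_trace_is_unruptured(self):
        seg = segment_curve(make_curve(np.linspace(0, 10, 50), np.zeros(50)))
        assert not seg.ruptured

    def test_global_maximum_never_in_adhesion_region(self, base_params):
        spec = SyntheticCurveSpec(params=base_params, n_curves=5, force_noise=10.0, seed=21)
        for curve in generate_fec(spec):
            seg = segment_curve(curve)
            assert int(np.argmax(curve.force)) >= seg.stretch_start_index


class TestExtensionAtForce:
    def test_exact_sample_and_midpoint(self):
        ext = np.array([90.0, 92, 94, 96, 98, 100, 102, 104, 106, 108, 110])
        force = np.array([1000.0, 1100, 1200, 1300, 1350, 1400, 1600, 1700, 1800, 1900, 2000])
        curve = make_curve(ext, force)
        seg = segment_curve(curve, min_peak_force=1e9)  # treat as unruptured stretch
        assert extension_at_force(curve, seg, 1400.0) == pytest.approx(100.0)
        assert extension_at_force(curve, seg, 1500.0) == pytest.approx(101.0)

    def test_noiseless_curve_matches_forward_model(self, base_params):
        spec = SyntheticCurveSpec(
            params=base_params, n_curves=1, force_noise=0.0, n_units_jitter=0.0, seed=3
        )
        (curve,) = generate_fec(spec)
        seg = segment_curve(curve)
        expected = 50 * base_params.unit_length_free * tsqm_fjc_extension(1500.0, base_params)
        assert extension_at_force(curve, seg, 1500.0) == pytest.approx(expected, rel=1e-3)

    def test_target_above_range_raises(self):
        curve = make_curve(np.linspace(1, 10, 10), np.linspace(100, 900, 10))
        seg = segment_curve(curve, min_peak_force=1e9)
        with pytest.raises(ValueError, match="outside"):
            extension_at_force(curve, seg, 1500.0)


class TestNormalization:
    def test_unity_at_reference_force(self, noiseless_norms):
        for norm in noiseless_norms(1.5, 1):
            assert norm.extension_at(1500.0) == pytest.approx(1.0, abs=1e-6)

    def test_contour_length_invariance(self, noiseless_norms):
        short = noiseless_norms(5.53, 4, n_curves=1, n_units=50)[0]
        long_ = noiseless_norms(5.53, 4, n_curves=1, n_units=200)[0]
        grid = np.linspace(50.0, 1500.0, 200)
        np.testing.assert_allclose(
            short.extension_at(grid), long_.extension_at(grid), atol=1e-3
        )

    def test_scale_invariance_of_raw_extension(self, base_params):
        spec = SyntheticCurveSpec(params=base_params, n_curves=1, force_noise=0.0, seed=5)
        (curve,) = generate_fec(spec)
        seg = segment_curve(curve)
        doubled = make_curve(curve.extension * 2.0, curve.force, metadata=dict(curve.metadata))
        norm_a = normalize_curve(curve, seg)
        norm_b = normalize_curve(doubled, segment_curve(doubled, adhesion_window=16.0))
        grid = np.linspace(50.0, 1500.0, 100)
        np.testing.assert_allclose(norm_a.extension_at(grid), norm_b.extension_at(grid), atol=1e-9)

    def test_idempotence(self, noiseless_norms):
        norm = noiseless_norms(1.5, 1)[0]
        as_curve = ForceExtensionCurve(norm.extension, norm.force, curve_id="renorm")
        seg = segment_curve(as_curve, min_peak_force=1e9, spike_min_force=1e9)
        again = normalize_curve(as_curve, seg)
        grid = np.linspace(50.0, 1500.0, 100)
        np.testing.assert_allclose(again.extension_at(grid), norm.extension_at(grid), atol=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="reference force"):
            NormalizedCurve(np.linspace(0.1, 0.9, 10), np.linspace(10, 1500, 10))


class TestOverlayDispersion:
    GRID = np.linspace(50.0, 500.0, 60)
    REPLICATE_BOUND = 0.05  # frozen regression bound: σ=10 pN, 20 curves

    def test_identical_curves_give_zero(self, noiseless_norms):
        norm = noiseless_norms(1.5, 1)[0]
        assert overlay_dispersion([norm, norm, norm], self.GRID) < 1e-12

    def test_noisy_replicates_overlap_neatly(self, noisy_norms):
        assert overlay_dispersion(noisy_norms, self.GRID) < self.REPLICATE_BOUND

    def test_different_hydration_energies_separate(self, noiseless_norms):
        weak = noiseless_norms(1.5, 9, n_curves=1)
        strong = noiseless_norms(5.53, 9, n_curves=1)
        replicates = noiseless_norms(5.53, 10, n_curves=5)
        d_diff = overlay_dispersion(weak + strong, self.GRID)
        d_same = overlay_dispersion(replicates, self.GRID)
        assert d_diff > 5 * d_same

    def test_grid_outside_range_names_curve(self, noiseless_norms):
        norms = noiseless_norms(1.5, 1)
        with pytest.raises(ValueError, match=norms[0].curve_id):
            norms[0].extension_at(np.array([1.0]))
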