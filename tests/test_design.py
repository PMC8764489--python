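"""Design construction: HRF kernels, signal/drift regressors, orthogonalization."""

import numpy as np
import pandas as pd
import pytest

import fmriverse as fv
from fmriverse.design import DesignError, DriftProjection


class TestHrfKernel:
    def test_spm_style_peaks_near_five_seconds(self):
        spec = fv.HrfSpec.preset("S")
        k = fv.hrf_kernel(spec, dt=0.01, length=32.0)
        t_peak = np.argmax(k) * 0.01
        assert 4.0 <= t_peak <= 6.0

    @pytest.mark.parametrize("style", ["A", "F", "S"])
    def test_zero_at_origin_single_peak_then_undershoot(self, style):
        k = fv.hrf_kernel(fv.HrfSpec.preset(style), dt=0.05, length=32.0)
        assert k[0] == 0.0
        assert k.max() == pytest.approx(1.0)  # unit peak normalization
        peak = int(np.argmax(k))
        # rises to a single positive maximum ...
        assert np.all(np.diff(k[: peak + 1]) >= -1e-12)
        # ... followed by a negative undershoot
        assert k.min() < 0

    def test_style_only_selects_defaults(self):
        a = fv.HrfSpec(style="A", peak_delay=6, undershoot_delay=16)
        s = fv.HrfSpec(style="S", peak_delay=6, undershoot_delay=16)
        np.testing.assert_array_equal(
            fv.hrf_kernel(a, 0.1, 32), fv.hrf_kernel(s, 0.1, 32)
        )

    def test_length_too_short_for_peak_errors(self):
        with pytest.raises(DesignError, match="too short"):
            fv.hrf_kernel(fv.HrfSpec.preset("S"), dt=0.1, length=3.0)


class TestSignalRegressors:
    def test_identity_kernel_gives_shifted_impulse(self, frame_times):
        events = fv.EventTable(
            pd.DataFrame({"onset": [20.0], "duration": [0.0], "condition": ["a"]})
        )
        col = fv.build_signal_regressors(
            events, fv.HrfSpec.preset("S"), frame_times, kernel=np.array([1.0])
        )["a"].to_numpy()
        assert col[10] == pytest.approx(1.0)  # onset 20 s at TR 2 -> frame 10
        assert np.sum(np.abs(col) > 1e-9) == 1

    def test_modulation_is_mean_centered(self, frame_times):
        events = fv.EventTable(
            pd.DataFrame(
                {
                    "onset": [10.0, 60.0, 110.0],
                    "duration": [0.0] * 3,
                    "condition": ["m"] * 3,
                    "modulation": [2.0, 4.0, 6.0],
                }
            )
        )
        col = fv.build_signal_regressors(
            events, fv.HrfSpec.preset("S"), frame_times, kernel=np.array([1.0])
        )["m"].to_numpy()
        heights = col[[5, 30, 55]]
        np.testing.assert_allclose(heights, [-2.0, 0.0, 2.0], atol=1e-9)

    def test_doubling_modulation_doubles_column(self, frame_times):
        def build(scale):
            events = fv.EventTable(
                pd.DataFrame(
                    {
                        "onset": [10.0, 60.0, 110.0],
                        "duration": [1.0] * 3,
                        "condition": ["m"] * 3,
                        "modulation": np.array([1.0, 2.5, 4.0]) * scale,
                    }
                )
            )
            return fv.build_signal_regressors(
                events, fv.HrfSpec.preset("S"), frame_times
            )["m"].to_numpy()

        np.testing.assert_allclose(build(2.0), 2.0 * build(1.0), atol=1e-10)

    def test_constant_modulation_raises_naming_condition(self, frame_times):
        events = fv.EventTable(
            pd.DataFrame(
                {
                    "onset": [10.0, 50.0],
                    "duration": [1.0, 1.0],
                    "condition": ["flat", "flat"],
                    "modulation": [3.0, 3.0],
                }
            )
        )
        with pytest.raises(DesignError, match="flat"):
            fv.build_signal_regressors(events, fv.HrfSpec.preset("S"), frame_times)

    def test_events_beyond_scan_rejected(self):
        events = fv.EventTable(
            pd.DataFrame({"onset": [500.0], "duration": [1.0], "condition": ["a"]})
        )
        with pytest.raises(DesignError, match="beyond the scan"):
            fv.build_signal_regressors(
                events, fv.HrfSpec.preset("S"), np.arange(100) * 2.0
            )

    def test_temporal_derivative_appended(self, frame_times, event_table):
        spec = fv.HrfSpec.preset("S", include_temporal_derivative=True)
        cols = fv.build_signal_regressors(event_table, spec, frame_times)
        assert "task_average_derivative" in cols.columns


class TestOrthogonalization:
    def test_projection_onto_constant_matches_hand_least_squares(self, frame_times):
        n = len(frame_times)
        data = pd.DataFrame(
            {
                "ref": np.ones(n),
                "tgt": np.array([1.0, 2.0, 3.0, 4.0] * (n // 4)),
            }
        )
        prov = {"ref": ("signal", "S"), "tgt": ("signal", "S")}
        dm = fv.DesignMatrix(frame_times, data, prov)
        scheme = fv.OrthoScheme(style="pairwise_explicit", pairs=(("tgt", "ref"),))
        out = fv.apply_orthogonalization(dm, scheme)
        np.testing.assert_allclose(
            out.data["tgt"].to_numpy()[:4], [-1.5, -0.5, 0.5, 1.5], atol=1e-12
        )

    def test_already_orthogonal_pair_unchanged(self, frame_times):
        n = len(frame_times)
        t = np.arange(n)
        data = pd.DataFrame({"a": np.cos(2 * np.pi * t / 8), "b": np.sin(2 * np.pi * t / 8)})
        prov = {"a": ("signal", "S"), "b": ("signal", "S")}
        dm = fv.DesignMatrix(frame_times, data, prov)
        out = fv.apply_orthogonalization(
            dm, fv.OrthoScheme(style="pairwise_explicit", pairs=(("b", "a"),))
        )
        np.testing.assert_allclose(out.data["b"], data["b"], atol=1e-10)

    def test_serial_orthogonalization_preserves_design_span(self, simple_design):
        """The hat matrix — hence any GLM fit — is invariant to the scheme."""
        before = simple_design.hat_matrix()
        out = fv.apply_orthogonalization(
            simple_design, fv.OrthoScheme(style="serial_preceding")
        )
        after = out.hat_matrix()
        assert np.abs(before - after).max() < 1e-8

    def test_zero_reference_column_guard(self, frame_times):
        n = len(frame_times)
        data = pd.DataFrame({"a": np.full(n, 1e-15), "b": np.arange(n, dtype=float) + 1})
        prov = {"a": ("signal", "S"), "b": ("signal", "S")}
        dm = fv.DesignMatrix(frame_times, data, prov)
        with pytest.raises(DesignError, match="zero"):
            fv.apply_orthogonalization(
                dm, fv.OrthoScheme(style="pairwise_explicit", pairs=(("b", "a"),))
            )


class TestDriftRegressors:
    def test_dct_column_count_floor_rule(self):
        # 160 frames at TR 2 -> T = 320 s; floor(2*320/128) = 5 columns
        ft = np.arange(160) * 2.0
        cols = fv.drift_regressors(fv.DriftSpec("dct_basis", cutoff=128.0), ft, 2.0)
        assert cols.shape[1] == 5

    def test_polynomial_degree_zero_is_constant_direction(self, frame_times):
        cols = fv.drift_regressors(
            fv.DriftSpec("polynomial_basis", max_degree=0), frame_times, 2.0
        )
        assert cols.shape[1] == 1
        assert np.ptp(cols.iloc[:, 0]) < 1e-12

    @pytest.mark.parametrize("style", ["dct_basis", "polynomial_basis"])
    def test_basis_columns_mutually_orthogonal(self, frame_times, style):
        spec = (
            fv.DriftSpec(style, cutoff=100.0)
            if style == "dct_basis"
            else fv.DriftSpec(style, max_degree=4)
        )
        cols = fv.drift_regressors(spec, frame_times, 2.0).to_numpy()
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_highpass_returns_projection_recipe(self, frame_times):
        out = fv.drift_regressors(
            fv.DriftSpec("highpass_residualization", cutoff=128.0), frame_times, 2.0
        )
        assert isinstance(out, DriftProjection)
        # projecting the basis itself must annihilate it
        assert np.abs(out.apply(out.basis)).max() < 1e-10

    def test_cutoff_below_nyquist_period_rejected(self, frame_times):
        with pytest.raises(DesignError, match="twice the TR"):
            fv.drift_regressors(fv.DriftSpec("dct_basis", cutoff=3.0), frame_times, 2.0)


class TestAssembleDesign:
    def _blocks(self, frame_times, event_table, signal_style="S"):
        rng = np.random.default_rng(2)
        sig = fv.build_signal_regressors(
            event_table, fv.HrfSpec.preset(signal_style), frame_times
        )
        drift = fv.drift_regressors(fv.DriftSpec("dct_basis", cutoff=128.0), frame_times, 2.0)
        motion = fv.RegressorBlock(
            pd.DataFrame(rng.standard_normal((len(frame_times), 6)) * 0.02), "fmriprep"
        )
        return fv.RegressorBlock(sig, signal_style), fv.RegressorBlock(drift, "S"), motion

    def test_hybrid_override_carries_source_style(self, frame_times, event_table):
        sig_s, drift_s, motion = self._blocks(frame_times, event_table, "S")
        sig_f, _, _ = self._blocks(frame_times, event_table, "F")
        dm = fv.assemble_design(
            sig_s, drift_s, motion, frame_times, hybrid_overrides={"signal": sig_f}
        )
        styles = dm.block_styles()
        assert styles == {"signal": "F", "drift": "S", "motion": "fmriprep"}

    def test_no_override_keeps_styles(self, frame_times, event_table):
        sig, drift, motion = self._blocks(frame_times, event_table)
        dm = fv.assemble_design(sig, drift, motion, frame_times)
        assert dm.block_styles() == {"signal": "S", "drift": "S", "motion": "fmriprep"}

    def test_interchange_symmetry(self, frame_times, event_table):
        """Building style S with an F signal override equals building style F
        with an S drift override, up to column order."""
        sig_s, drift_s, motion = self._blocks(frame_times, event_table, "S")
        sig_f, _, _ = self._blocks(frame_times, event_table, "F")
        a = fv.assemble_design(
            sig_s, drift_s, motion, frame_times, hybrid_overrides={"signal": sig_f}
        )
        b = fv.assemble_design(
            sig_f, drift_s, motion, frame_times, hybrid_overrides={"drift": drift_s}
        )
        for col in a.data.columns:
            np.testing.assert_allclose(a.data[col], b.data[col], atol=1e-12)
            assert a.provenance[col] == b.provenance[col]

    def test_motion_block_required_with_six_columns(self, frame_times, event_table):
        sig, drift, _ = self._blocks(frame_times, event_table)
        bad = fv.RegressorBlock(pd.DataFrame(np.ones((len(frame_times), 4))), "fmriprep")
        with pytest.raises(DesignError, match="6 columns"):
            fv.assemble_design(sig, drift, bad, frame_times)
        with pytest.raises(DesignError, match="motion"):
            fv.assemble_design(sig, drift, None, frame_times)

    def test_rank_deficiency_reports_collinear_columns(self, frame_times, event_table):
        sig, drift, motion = self._blocks(frame_times, event_table)
        dup = sig.columns.copy()
        dup["task_average_copy"] = dup["task_average"]
        with pytest.raises(DesignError, match="rank deficient"):
            fv.assemble_design(
                fv.RegressorBlock(dup, "S"), drift, motion, frame_times
            )

    def test_design_tsv_roundtrip(self, tmp_path, simple_design):
        path = tmp_path / "design.tsv"
        simple_design.to_tsv(path)
        back = fv.DesignMatrix.from_tsv(path)
        np.testing.assert_allclose(back.matrix, simple_design.matrix, atol=1e-9)
        assert back.provenance == simple_design.provenance
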