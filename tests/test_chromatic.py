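"""%FCR computation, plate aggregation, standardization and normalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reactomics as rx

from conftest import make_plate


class TestComputeFcr:
    def test_zero_and_full_response(self):
        assert rx.compute_fcr(10.0, 10.0, 110.0) == 0.0
        assert rx.compute_fcr(110.0, 10.0, 110.0) == 100.0

    def test_linear_interpolation(self):
        assert rx.compute_fcr(35.0, 10.0, 110.0) == pytest.approx(25.0)

    def test_not_clipped(self):
        assert rx.compute_fcr(130.0, 10.0, 110.0) == pytest.approx(120.0)
        assert rx.compute_fcr(0.0, 10.0, 110.0) == pytest.approx(-10.0)

    def test_degenerate_span_rejected(self):
        with pytest.raises(rx.DegeneratePlateError):
            rx.compute_fcr(50.0, 110.0, 110.0)


class TestAggregatePlate:
    def test_triplicate_mean(self):
        # wells at Em_c, Em_r and the midpoint -> %FCR mean of (0, 100, 50)
        plate = make_plate(samples={"s1": ("control", (10.0, 110.0, 60.0))})
        table = rx.aggregate_plate(plate)
        assert table.em_c == 10.0 and table.em_r == 110.0
        assert table.data.loc[0, "fcr"] == pytest.approx(50.0)

    def test_noise_free_cohort_recovers_latents_exactly(self, tiny_cfg):
        cfg = dataclasses.replace(
            tiny_cfg, em_c_sd=0.0, em_r_sd=0.0, serum_sd=0.0, replicate_sd=0.0,
            plate_gain_sd=0.0, plate_offset_sd=0.0,
        )
        for plate in rx.generate_cohort(cfg):
            table = rx.aggregate_plate(plate)
            sub = table.data[table.data["role"] == "sample"]
            for g, f in zip(sub["group"], sub["fcr"]):
                expected = cfg.group_effect.loc[g, plate.vesicle_id]
                assert f == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        gain=st.floats(min_value=0.1, max_value=10.0),
        offset=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, gain, offset):
        """%FCR is an exact invariant of any common affine map applied to
        every well of the plate, controls included."""
        plate = make_plate(samples={"s1": ("control", (25.0, 47.0, 80.0))})
        distorted_wells = [
            dataclasses.replace(w, emission=gain * w.emission + offset)
            for w in plate.wells
        ]
        distorted = rx.Plate("p1", "v1", distorted_wells, 3)
        a = rx.aggregate_plate(plate).data["fcr"].to_numpy()
        b = rx.aggregate_plate(distorted).data["fcr"].to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_degenerate_plate_propagates(self):
        plate = make_plate(neg=(110.0,) * 3, pos=(10.0,) * 3,
                           samples={"s1": ("control", (50.0, 50.0, 50.0))})
        with pytest.raises(rx.DegeneratePlateError):
            rx.aggregate_plate(plate)


def _table(plate_id, fcrs, std_fcrs, vesicle_id="v1"):
    data = pd.DataFrame(
        {
            "sample_id": [f"std-{i+1}" for i in range(len(std_fcrs))]
            + [f"s{i+1}" for i in range(len(fcrs))],
            "role": ["standard"] * len(std_fcrs) + ["sample"] * len(fcrs),
            "group": ["none"] * len(std_fcrs) + ["control"] * len(fcrs),
            "fcr": list(std_fcrs) + list(fcrs),
        }
    )
    return rx.FcrTable(plate_id, vesicle_id, 10.0, 110.0, data)


class TestStandardize:
    def test_identical_plates_identity(self):
        t1 = _table("p1", [45.0, 55.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        t2 = _table("p2", [45.0, 55.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        out = rx.standardize_across_plates([t1, t2])
        for t in out:
            assert np.allclose(t.data["fcr"], t1.data["fcr"], atol=1e-9)

    def test_affine_distortion_recovered(self):
        """Plate 2 equals plate 1 with x -> 2x + 5 everywhere; after
        standardization both plates report identical sample %FCRs."""
        stds = [30.0, 40.0, 50.0, 60.0, 70.0]
        t1 = _table("p1", [45.0, 55.0], stds)
        t2 = _table("p2", [2 * f + 5 for f in (45.0, 55.0)], [2 * f + 5 for f in stds])
        out = rx.standardize_across_plates([t1, t2])
        s1 = out[0].data.loc[out[0].data["role"] == "sample", "fcr"].to_numpy()
        s2 = out[1].data.loc[out[1].data["role"] == "sample", "fcr"].to_numpy()
        assert np.allclose(s1, s2, atol=1e-9)

    def test_single_plate_passthrough(self):
        t1 = _table("p1", [45.0, 55.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        (out,) = rx.standardize_across_plates([t1])
        assert np.allclose(out.data["fcr"], t1.data["fcr"])
        assert out.data is not t1.data  # input not aliased

    def test_zero_variance_standards_offset_only(self, caplog):
        t1 = _table("p1", [45.0], [50.0] * 5)
        t2 = _table("p2", [47.0], [60.0] * 5)
        with caplog.at_level("WARNING", logger="reactomics"):
            out = rx.standardize_across_plates([t1, t2])
        assert "offset-only" in caplog.text
        # references are all 55; each plate shifted by +/-5, scale untouched
        assert np.allclose(out[0].data["fcr"], [55.0] * 5 + [50.0])
        assert np.allclose(out[1].data["fcr"], [55.0] * 5 + [42.0])

    def test_idempotent_on_affine_distorted_cohort(self, default_cfg):
        """Applying standardization twice equals once, exactly, when plates
        are pure affine distortions of shared latent responses."""
        cfg = dataclasses.replace(default_cfg, em_c_sd=0.0, em_r_sd=0.0,
                                  replicate_sd=0.0)
        tables = [rx.aggregate_plate(p) for p in rx.generate_cohort(cfg)]
        once = rx.standardize_across_plates(tables)
        twice = rx.standardize_across_plates(once)
        for a, b in zip(once, twice):
            assert np.allclose(a.data["fcr"], b.data["fcr"], atol=1e-9)


class TestNormalize:
    def test_control_z_scores(self):
        t = _table("p1", [10.0, 20.0, 30.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        matrix = rx.normalize_to_controls([t])
        assert np.allclose(
            matrix.values["v1"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_per_plate_control_moments(self, cohort):
        """After normalization every plate's control samples have mean 0 and
        sample SD 1 exactly (by construction)."""
        tables = rx.standardize_across_plates(
            [rx.aggregate_plate(p) for p in cohort]
        )
        matrix = rx.normalize_to_controls(tables)
        for t in tables:
            sub = t.data[(t.data["role"] == "sample") & (t.data["group"] == "control")]
            z = matrix.values.loc[sub["sample_id"], t.vesicle_id]
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_end_to_end_affine_invariance(self, default_cfg):
        """The full %FCR -> standardize -> normalize chain yields identical
        features whether or not per-plate gain/offset distortions were
        applied to the raw emissions."""
        clean_cfg = dataclasses.replace(
            default_cfg, plate_gain_sd=0.0, plate_offset_sd=0.0
        )
        distorted = rx.build_features(rx.generate_cohort(default_cfg))
        clean = rx.build_features(rx.generate_cohort(clean_cfg))
        assert distorted.values.index.equals(clean.values.index)
        assert np.abs(
            distorted.values.to_numpy() - clean.values.to_numpy()
        ).max() < 1e-9

    def test_too_few_controls_rejected(self):
        t = _table("p1", [10.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        with pytest.raises(rx.NormalizationError, match=">=2"):
            rx.normalize_to_controls([t])

    def test_zero_control_sd_rejected(self):
        t = _table("p1", [10.0, 10.0, 10.0], [30.0, 40.0, 50.0, 60.0, 70.0])
        with pytest.raises(rx.NormalizationError, match="p1"):
            rx.normalize_to_controls([t])

    def test_incomplete_samples_dropped_with_warning(self, caplog):
        t1 = _table("p1", [10.0, 20.0, 30.0], [30.0, 40.0, 50.0, 60.0, 70.0], "v1")
        t2 = _table("p2", [10.0, 20.0], [30.0, 40.0, 50.0, 60.0, 70.0], "v2")
        with caplog.at_level("WARNING", logger="reactomics"):
            matrix = rx.normalize_to_controls([t1, t2])
        assert "s3" in caplog.text
        assert list(matrix.values.index) == ["s1", "s2"]
        assert matrix.feature_names == ["v1", "v2"]


class TestRsd:
    def test_constant_repeats_zero(self):
        frame = pd.DataFrame({"sample_id": ["a"] * 3, "fcr": [50.0, 50.0, 50.0]})
        per, avg = rx.compute_rsd(frame)
        assert per["a"] == pytest.approx(0.0)
        assert avg == pytest.approx(0.0)

    def test_known_spread(self):
        frame = pd.DataFrame({"sample_id": ["a"] * 3, "fcr": [40.0, 50.0, 60.0]})
        per, avg = rx.compute_rsd(frame)
        assert per["a"] == pytest.approx(20.0)  # SD 10, mean 50

    def test_zero_mean_undefined(self):
        frame = pd.DataFrame({"sample_id": ["a"] * 2, "fcr": [-5.0, 5.0]})
        with pytest.raises(rx.ReactomicsError, match="zero mean"):
            rx.compute_rsd(frame)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_repeat_assay_band(self, seed):
        """A 10-repeat assay of five control sera with 4%-of-scale replicate
        noise lands in the 2-8% average-RSD band."""
        cfg = rx.default_study_config(seed=seed)
        tables = [rx.aggregate_plate(p) for p in rx.generate_repeat_assay(cfg)]
        _, avg = rx.compute_rsd(tables)
        assert 2.0 <= avg <= 8.0
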