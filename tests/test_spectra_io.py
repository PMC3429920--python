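"""Spectra container, unit transforms, replicate averaging, CSV round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirfly.errors import SpectraFormatError, ValidationError
from nirfly.spectra_io import (SpectrumSet, absorbance_to_reflectance,
                               attach_metadata, average_replicates,
                               read_metadata, read_spectra,
                               reflectance_to_absorbance, write_metadata,
                               write_spectra)

from conftest import make_set


class TestSpectrumSetValidation:
    def test_accepts_uniform_grid_and_reports_spacing(self):
        s = make_set(np.ones((3, 5)), wavelengths=[350, 352, 354, 356, 358])
        assert s.spacing == 2.0
        assert s.n_samples == 3 and s.n_wavelengths == 5

    @pytest.mark.parametrize("wl", [[3, 2, 1], [1, 1, 2], [1, 2, 4]])
    def test_rejects_bad_grids(self, wl):
        with pytest.raises(ValidationError):
            make_set(np.ones((1, 3)), wavelengths=wl)

    def test_rejects_duplicate_sample_ids(self):
        meta = pd.DataFrame({"sample_id": ["a", "a"]})
        with pytest.raises(ValidationError, match="duplicated"):
            SpectrumSet([1.0, 2.0], np.ones((2, 2)), meta)

    def test_rejects_shape_mismatch_and_nonfinite(self):
        with pytest.raises(ValidationError):
            make_set(np.ones((2, 4)), wavelengths=[1, 2, 3])
        with pytest.raises(ValidationError):
            make_set([[1.0, np.nan]])

    def test_reflectance_range_enforced(self):
        with pytest.raises(ValidationError):
            make_set([[0.5, 1.2]], units="reflectance")

    def test_where_filters_by_metadata(self):
        s = make_set(np.arange(8).reshape(4, 2), sex=list("mmff"))
        assert s.where(sex="f").n_samples == 2
        assert s.where(sex=["m", "f"]).n_samples == 4


class TestUnitTransforms:
    @pytest.mark.parametrize("r, expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log_one_over_r(self, r, expected):
        s = make_set([[r]], units="reflectance")
        out = reflectance_to_absorbance(s)
        assert out.units == "absorbance"
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=8))
    def test_round_trip_restores_reflectance(self, reflectances):
        s = make_set([reflectances], units="reflectance")
        back = absorbance_to_reflectance(reflectance_to_absorbance(s))
        np.testing.assert_allclose(back.values, s.values, atol=1e-12, rtol=0)

    def test_nonpositive_reflectance_names_offender(self):
        s = make_set([[0.5, 0.5]], units="reflectance")
        s.values[0, 1] = -0.2  # corrupt after construction
        with pytest.raises(ValidationError, match="s0"):
            reflectance_to_absorbance(s)

    def test_wrong_unit_flag_rejected(self):
        with pytest.raises(ValidationError):
            reflectance_to_absorbance(make_set([[1.0]], units="absorbance"))


class TestAverageReplicates:
    def test_mean_of_equal_replicates_is_identity(self):
        s = make_set([[1.0, 2.0], [1.0, 2.0]])
        out = average_replicates(s, {"s0": "fly", "s1": "fly"})
        assert out.n_samples == 1
        np.testing.assert_allclose(out.values, [[1.0, 2.0]])

    def test_arithmetic_mean(self):
        s = make_set([[0.0, 2.0], [2.0, 0.0]])
        out = average_replicates(s, {"s0": "g", "s1": "g"})
        np.testing.assert_allclose(out.values, [[1.0, 1.0]])

    def test_singleton_groups_idempotent(self):
        s = make_set(np.arange(6).reshape(3, 2))
        out = average_replicates(s, {sid: sid for sid in s.sample_ids})
        np.testing.assert_allclose(out.values, s.values)

    def test_fifty_scan_average_near_truth(self, rng):
        # 50 noisy scans of one fly: mean within 4*sigma/sqrt(50) everywhere
        truth = rng.uniform(0.2, 0.8, size=20)
        sigma = 0.05
        scans = truth + rng.normal(0, sigma, size=(50, 20))
        s = make_set(scans)
        out = average_replicates(s, {sid: "fly" for sid in s.sample_ids})
        assert np.all(np.abs(out.values[0] - truth) < 4 * sigma / np.sqrt(50))

    def test_conflicting_group_metadata_rejected(self):
        s = make_set(np.ones((2, 2)), sex=["male", "female"])
        with pytest.raises(ValidationError, match="conflicting"):
            average_replicates(s, {"s0": "g", "s1": "g"})


class TestCsvRoundTrips:
    @pytest.mark.parametrize("fmt", ["wide", "long"])
    def test_write_read_round_trip(self, tmp_path, fmt, rng):
        s = make_set(rng.uniform(0.1, 0.9, (3, 6)),
                     wavelengths=350.0 + np.arange(6))
        path = tmp_path / "spec.csv"
        write_spectra(s, path, format=fmt)
        back = read_spectra(path, format=fmt)
        np.testing.assert_allclose(back.values, s.values, atol=1e-12)
        np.testing.assert_allclose(back.wavelengths, s.wavelengths)
        assert back.sample_ids == s.sample_ids
        assert back.units == s.units

    def test_wide_and_long_agree(self, tmp_path, rng):
        s = make_set(rng.uniform(size=(2, 4)))
        write_spectra(s, tmp_path / "w.csv", format="wide")
        write_spectra(s, tmp_path / "l.csv", format="long")
        a = read_spectra(tmp_path / "w.csv", format="wide")
        b = read_spectra(tmp_path / "l.csv", format="long")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_units_override_beats_header(self, tmp_path):
        s = make_set([[0.5, 0.5]], units="reflectance")
        path = tmp_path / "s.csv"
        write_spectra(s, path)
        assert read_spectra(path).units == "reflectance"
        assert read_spectra(path, units="absorbance").units == "absorbance"

    def test_missing_units_header_rejected(self, tmp_path):
        path = tmp_path / "bare.csv"
        path.write_text("sample_id,350,351\na,0.1,0.2\n")
        with pytest.raises(SpectraFormatError, match="units"):
            read_spectra(path)
        assert read_spectra(path, units="absorbance").n_samples == 1

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("# units: absorbance\nsample_id,350,351\na,0.1\n")
        with pytest.raises(SpectraFormatError):
            read_spectra(path)

    def test_metadata_round_trip_and_validation(self, tmp_path):
        meta = pd.DataFrame({
            "sample_id": ["s0", "s1"], "line": ["Alst", "Hw"],
            "species": ["melanogaster", "simulans"],
            "sex": ["male", "female"], "age_days": [5, 13],
            "infection": ["unknown", "unknown"],
            "split": ["calibration", "independent"],
        })
        path = tmp_path / "meta.csv"
        write_metadata(meta, path)
        back = read_metadata(path)
        pd.testing.assert_frame_equal(back, meta)
        s = make_set(np.ones((2, 3)))
        joined = attach_metadata(s, back)
        assert list(joined.meta["species"]) == ["melanogaster", "simulans"]

    def test_bad_split_value_rejected(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,line,species,sex,age_days,infection,split\n"
                        "a,Alst,melanogaster,male,5,unknown,test\n")
        with pytest.raises(ValidationError, match="split"):
            read_metadata(path)
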