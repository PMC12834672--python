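"""Dataset readers, validation rules and report round-tripping."""

import numpy as np
import pandas as pd
import pytest

from locscale.data import (
    SCHEMA_PRESETS,
    SchemaError,
    ValidationError,
    read_effect_sizes,
    read_fragments,
    read_report,
    write_report,
)


def _write(tmp_path, name, frame):
    path = tmp_path / name
    frame.to_csv(path, index=False)
    return path


class TestReadEffectSizes:
    def test_z_and_variance_computed_from_r_n(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "study_id": ["a", "a", "b"], "case_id": ["1", "2", "1"],
            "r": [0.0, 0.5, -0.5], "n": [103, 103, 103],
            "log_grain": [0.0, 1.0, 2.0],
        }))
        ds = read_effect_sizes(path)
        assert ds.n_obs == 3 and ds.n_studies == 2
        assert np.allclose(ds.table["z"], [0.0, 0.5493061443340549, -0.5493061443340549],
                           atol=1e-4)
        assert np.allclose(ds.table["var_z"], 0.01)
        # exact identity in floats
        assert np.allclose(ds.table["var_z"] * (ds.table["n"] - 3), 1.0, atol=1e-12)

    def test_small_n_rejected(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "study_id": ["a"], "case_id": ["1"], "r": [0.2], "n": [3],
            "log_grain": [0.0],
        }))
        with pytest.raises(ValidationError, match="n <= 3"):
            read_effect_sizes(path)

    def test_perfect_correlation_rejected_not_clamped(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "study_id": ["a"], "case_id": ["1"], "r": [1.0], "n": [30],
            "log_grain": [0.0],
        }))
        with pytest.raises(ValidationError, match="refusing to clamp"):
            read_effect_sizes(path)

    def test_empty_file_gives_empty_dataset(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame(
            columns=["study_id", "case_id", "r", "n", "log_grain"]))
        ds = read_effect_sizes(path)
        assert ds.n_obs == 0 and ds.n_studies == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "study_id": ["a"], "case_id": ["1"], "r": [0.1], "n": [30],
        }))
        with pytest.raises(SchemaError, match="log_grain"):
            read_effect_sizes(path)

    def test_schema_map_resolves_foreign_names(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "Study": ["a"], "Case": ["1"], "cor": [0.3], "N": [53],
            "grain": [1.5],
        }))
        ds = read_effect_sizes(path, {"study_id": "Study", "case_id": "Case",
                                      "r": "cor", "n": "N", "log_grain": "grain"})
        assert ds.table["var_z"].iloc[0] == pytest.approx(0.02)

    def test_rereading_is_bytewise_stable(self, tmp_path):
        frame = pd.DataFrame({
            "study_id": ["a", "b"], "case_id": ["1", "1"],
            "r": [0.1, 0.7], "n": [40, 60], "log_grain": [0.3, -0.2],
        })
        path = _write(tmp_path, "m.csv", frame)
        d1, d2 = read_effect_sizes(path), read_effect_sizes(path)
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_unknown_extent_label_rejected(self, tmp_path):
        path = _write(tmp_path, "m.csv", pd.DataFrame({
            "study_id": ["a"], "case_id": ["1"], "r": [0.1], "n": [30],
            "log_grain": [0.0], "extent_bin": ["huge"],
        }))
        with pytest.raises(ValidationError, match="fixed label set"):
            read_effect_sizes(path)


class TestReadFragments:
    def test_centering_is_symmetric(self, tmp_path):
        path = _write(tmp_path, "f.csv", pd.DataFrame({
            "study_id": ["a", "a"], "fragment_id": ["1", "2"],
            "richness": [5.0, 7.0], "frag_size": [np.e, np.e ** 3],
        }))
        ds = read_fragments(path)
        assert np.allclose(ds.table["log_frag_size"], [-1.0, 1.0], atol=1e-12)
        assert ds.center_log_size == pytest.approx(2.0)

    def test_constant_sizes_center_to_zero(self, tmp_path):
        path = _write(tmp_path, "f.csv", pd.DataFrame({
            "study_id": ["a"] * 4, "fragment_id": list("1234"),
            "richness": [2.0, 3.0, 4.0, 5.0], "frag_size": [1.0] * 4,
        }))
        ds = read_fragments(path)
        assert np.allclose(ds.table["log_frag_size"], 0.0)
        assert abs(ds.table["log_frag_size"].mean()) < 1e-9

    @pytest.mark.parametrize("col, bad", [("richness", 0.0), ("frag_size", -2.0)])
    def test_nonpositive_values_rejected(self, tmp_path, col, bad):
        frame = pd.DataFrame({
            "study_id": ["a"], "fragment_id": ["1"],
            "richness": [4.0], "frag_size": [10.0],
        })
        frame.loc[0, col] = bad
        path = _write(tmp_path, "f.csv", frame)
        with pytest.raises(ValidationError):
            read_fragments(path)


class TestReports:
    def test_round_trip_preserves_floats(self, tmp_path):
        frame = pd.DataFrame({"model": ["m1_1", "m1_2"],
                              "elpd": [-12.345678901234567, 3.14159e-8]})
        path = tmp_path / "report.csv"
        write_report(frame, path)
        back = read_report(path)
        assert np.allclose(back["elpd"], frame["elpd"], rtol=0, atol=1e-12)

    def test_empty_report_is_valid(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_report(pd.DataFrame(), path)
        assert read_report(path).empty

    def test_perturbation_detected_by_checksum(self, tmp_path):
        frame = pd.DataFrame({"x": [1.0, 2.0]})
        path = tmp_path / "r.csv"
        write_report(frame, path)
        text = path.read_text().replace("2", "3")
        path.write_text(text)
        with pytest.raises(ValidationError, match="checksum"):
            read_report(path)


def test_schema_presets_cover_required_fields():
    assert {"study_id", "r", "n", "log_grain"} <= set(SCHEMA_PRESETS["native-exotic-meta"])
    assert {"study_id", "richness", "frag_size"} <= set(SCHEMA_PRESETS["fragmentation-richness"])
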