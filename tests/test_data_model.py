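"""Registry, long-table parsing, section averaging, normalization."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from iegnet import (
    ExpressionTable,
    SectionMeasurement,
    average_sections,
    default_registry,
    generate,
    load_study,
    make_study_template,
    normalize_by_reference,
    read_long_table,
    write_long_table,
)
from iegnet.registry import ROIRegistry


class TestRegistry:
    def test_default_has_33_analysis_rois_with_gcc_reference(self, registry):
        assert registry.n_rois == 33
        assert registry.abbreviations[0] == "LSV"
        assert registry.abbreviations[-1] == "S1jO"
        assert registry.reference_roi == "gcc"
        assert "gcc" not in registry

    def test_duplicate_abbreviations_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ROIRegistry(entries=(("A", "a"), ("A", "b")))

    def test_reference_must_not_be_analysis_roi(self):
        with pytest.raises(ValueError, match="reference"):
            ROIRegistry(entries=(("gcc", "genu"),), reference_roi="gcc")

    def test_subset_preserves_order(self, registry):
        sub = registry.subset(["CPDM", "LSV", "MS"])
        assert sub.abbreviations == ("LSV", "MS", "CPDM")


class TestLongTable:
    def _write(self, tmp_path, text, name="t.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_row_count_preserved(self, tmp_path, small_registry):
        path = self._write(
            tmp_path,
            "animal_id,group,roi,section,value\n"
            "a1,G,LSV,1,0.5\na1,G,LSV,2,0.6\na1,G,MS,1,0.4\na1,G,MS,2,0.3\n",
        )
        ms = read_long_table(path, small_registry)
        assert len(ms) == 4
        assert {m.roi for m in ms} == {"LSV", "MS"}

    def test_unknown_roi_rejected(self, tmp_path, small_registry):
        path = self._write(
            tmp_path, "animal_id,group,roi,section,value\na1,G,XYZ,1,0.5\n"
        )
        with pytest.raises(ValueError, match="XYZ"):
            read_long_table(path, small_registry)

    def test_missing_column_rejected(self, tmp_path, small_registry):
        path = self._write(tmp_path, "animal_id,group,roi,value\na1,G,LSV,0.5\n")
        with pytest.raises(ValueError, match="section"):
            read_long_table(path, small_registry)

    def test_unknown_group_rejected_when_declared(self, tmp_path, small_registry):
        path = self._write(
            tmp_path, "animal_id,group,roi,section,value\na1,BAD,LSV,1,0.5\n"
        )
        with pytest.raises(ValueError, match="BAD"):
            read_long_table(path, small_registry, groups=["G"])

    def test_negative_value_rejected(self, tmp_path, small_registry):
        path = self._write(
            tmp_path, "animal_id,group,roi,section,value\na1,G,LSV,1,-0.5\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_long_table(path, small_registry)

    def test_synthetic_round_trip(self, tmp_path, small_registry):
        config = make_study_template("null", registry=small_registry, seed=11)
        measurements, _ = generate(config)
        path = write_long_table(measurements, tmp_path / "study.tsv")
        back = read_long_table(path, small_registry)
        assert len(back) == len(measurements)
        for got, want in zip(back, measurements):
            assert (got.animal_id, got.group, got.roi, got.section) == (
                want.animal_id, want.group, want.roi, want.section,
            )
            assert got.value == pytest.approx(want.value, rel=1e-12, abs=1e-15)


class TestAveraging:
    def _ms(self, roi, values, animal="a1"):
        return [
            SectionMeasurement(animal, "G", roi, s + 1, v)
            for s, v in enumerate(values)
        ]

    def test_arithmetic_mean(self):
        out = average_sections(self._ms("LSV", [1, 2, 3]))
        assert out.loc[0, "mean"] == pytest.approx(2.0)

    def test_single_replicate_sd_zero(self):
        out = average_sections(self._ms("LSV", [5]))
        assert out.loc[0, "mean"] == 5.0
        assert out.loc[0, "sd"] == 0.0

    def test_sample_sd_formula(self):
        out = average_sections(self._ms("LSV", [2, 4, 9]))
        assert out.loc[0, "mean"] == pytest.approx(5.0)
        assert out.loc[0, "sd"] == pytest.approx(math.sqrt(13.0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_sections([])

    def test_nonstandard_replicate_count_logged(self, caplog):
        with caplog.at_level(logging.WARNING, logger="iegnet.data"):
            average_sections(self._ms("LSV", [1, 2]))
        assert any("replicate count" in r.message for r in caplog.records)

    def test_negative_measurement_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            SectionMeasurement("a1", "G", "LSV", 1, -0.1)


def _averaged(rows):
    """rows: (animal, roi, mean) -> frame shaped like average_sections output."""
    return pd.DataFrame(
        [(a, "G", r, v, 0.0, 3) for a, r, v in rows],
        columns=["animal_id", "group", "roi", "mean", "sd", "n_sections"],
    )


class TestNormalization:
    @pytest.fixture
    def two_roi_registry(self):
        return ROIRegistry(entries=(("LSV", "x"), ("MS", "y")))

    def _frame(self, ref_value=100.0, lsv=150.0, ms=100.0, n_animals=3):
        rows = []
        for i in range(n_animals):
            a = f"a{i}"
            rows += [(a, "LSV", lsv), (a, "MS", ms), (a, "gcc", ref_value)]
        return _averaged(rows)

    def test_ratio_self_normalization_is_one(self, two_roi_registry):
        ds = normalize_by_reference(self._frame(100, 100, 100), two_roi_registry)
        assert np.allclose(ds.table("G").values, 1.0)

    def test_ratio_arithmetic(self, two_roi_registry):
        ds = normalize_by_reference(self._frame(100, 150, 80), two_roi_registry)
        table = ds.table("G").to_frame()
        assert table["LSV"].iloc[0] == pytest.approx(1.5)
        assert table["MS"].iloc[0] == pytest.approx(0.8)

    def test_subtract_mode(self, two_roi_registry):
        ds = normalize_by_reference(
            self._frame(100, 150, 80), two_roi_registry, mode="subtract"
        )
        table = ds.table("G").to_frame()
        assert table["LSV"].iloc[0] == pytest.approx(50.0)
        assert table["MS"].iloc[0] == pytest.approx(-20.0)

    def test_zero_reference_rejected_naming_animal(self, two_roi_registry):
        with pytest.raises(ValueError, match="a0"):
            normalize_by_reference(self._frame(ref_value=0.0), two_roi_registry)

    def test_missing_reference_rejected(self, two_roi_registry):
        frame = self._frame()
        frame = frame.loc[~((frame.animal_id == "a1") & (frame.roi == "gcc"))]
        with pytest.raises(ValueError, match="a1"):
            normalize_by_reference(frame.reset_index(drop=True), two_roi_registry)

    def test_missing_cell_is_hard_error(self, two_roi_registry):
        frame = self._frame()
        frame = frame.loc[~((frame.animal_id == "a1") & (frame.roi == "MS"))]
        with pytest.raises(ValueError):
            normalize_by_reference(frame.reset_index(drop=True), two_roi_registry)

    def test_reference_channel_removed_and_order_matches_registry(
        self, two_roi_registry
    ):
        ds = normalize_by_reference(self._frame(), two_roi_registry)
        table = ds.table("G")
        assert table.rois == ["LSV", "MS"]
        assert table.values.shape == (3, 2)

    def test_denormalization_recovers_input(self, small_registry):
        config = make_study_template("null", registry=small_registry, seed=3)
        for g in config.groups:  # keep draws far from the non-negativity clamp
            g.roi_means = g.roi_means + 2.0
        measurements, _ = generate(config)
        averaged = average_sections(measurements)
        ds = normalize_by_reference(averaged, small_registry, mode="ratio")
        ref = averaged.loc[averaged.roi == "gcc"].set_index("animal_id")["mean"]
        for label, table in ds.tables.items():
            wide = averaged.loc[
                (averaged.group == label) & (averaged.roi != "gcc")
            ].pivot(index="animal_id", columns="roi", values="mean")
            wide = wide.reindex(index=table.animals, columns=table.rois)
            recovered = table.values * ref.loc[table.animals].to_numpy()[:, None]
            np.testing.assert_allclose(recovered, wide.to_numpy(), rtol=1e-12)


class TestExpressionTable:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionTable("G", ["a", "b", "c"], ["R1"], np.ones((3, 2)))

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError, match="n=2"):
            ExpressionTable("G", ["a", "b"], ["R1"], np.ones((2, 1)))

    def test_missing_cells_rejected(self):
        values = np.ones((3, 2))
        values[1, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ExpressionTable("G", ["a", "b", "c"], ["R1", "R2"], values)

    def test_load_study_orders_rois_by_registry(self, tmp_path):
        registry = default_registry()
        config = make_study_template("null", seed=2)
        for g in config.groups:  # keep draws far from the non-negativity clamp
            g.roi_means = g.roi_means + 2.0
        measurements, truth = generate(config)
        path = write_long_table(measurements, tmp_path / "long.csv")
        ds = load_study(path)
        for label in ds.groups:
            assert ds.table(label).rois == list(registry.abbreviations)
            np.testing.assert_allclose(
                ds.table(label).values, truth.table(label).values, atol=1e-10
            )
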