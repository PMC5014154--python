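import numpy as np
import pandas as pd
import pytest

from rubiscotemp import compendium, datasets, synthetic
from rubiscotemp.compendium import (
    classify,
    dedupe_species,
    fit_records,
    read_records_csv,
    run_pipeline,
    summarize_group,
    summarize_groups,
)


class TestClassify:
    def test_c4_pathway_wins(self):
        assert classify("C4", 10.0) == "C4"

    def test_c3_split_at_25(self):
        assert classify("C3", 24.9) == "C3-cool"
        assert classify("C3", 25.0) == "C3-warm"  # boundary is warm
        assert classify("C3", 30.0) == "C3-warm"

    def test_intermediates_are_warm(self):
        assert classify("C3-C4", 10.0) == "C3-warm"

    def test_non_seed_plants_keep_phylogenetic_group(self):
        assert classify("", None, "Cyanobacteria") == "Cyanobacteria"
        assert classify("C3", None, "Bacillariophyta") == "Bacillariophyta"

    def test_c3_without_growth_temperature_fails(self):
        with pytest.raises(ValueError):
            classify("C3", None)

    def test_unknown_pathway_fails(self):
        with pytest.raises(ValueError):
            classify("CAM", 25.0)


class TestDedupe:
    def test_multi_source_species_average(self):
        t2 = datasets.source_fits()
        sp = dedupe_species(t2)
        row = sp[(sp.species == "Spinacia oleracea") & (sp.trait == "Sc/o")]
        assert len(row) == 1
        # four sources, one flagged unreliable and excluded -> mean of 3
        assert row.iloc[0]["n_sources"] == 3
        assert row.iloc[0]["dha_kj"] == pytest.approx(
            np.mean([-19.8, -17.6, -20.5]), abs=1e-9)

    def test_single_source_species_unchanged(self):
        t2 = datasets.source_fits()
        sp = dedupe_species(t2)
        row = sp[(sp.species == "Zea mays") & (sp.trait == "Sc/o")].iloc[0]
        assert row["n_sources"] == 1
        assert row["dha_kj"] == pytest.approx(-20.1)

    def test_empty_frame_passthrough(self):
        assert dedupe_species(pd.DataFrame()).empty


@pytest.fixture(scope="module")
def species_fits():
    return dedupe_species(datasets.source_fits())


class TestGroupSummary:

    def test_group_size_counts_excluded_members(self, species_fits):
        gk = summarize_group(species_fits, "C3-cool")
        # the high-altitude outlier is excluded from the Kc parameter means
        # but still counts toward group size
        assert gk.stats["Kc"]["n"] == 6
        assert gk.stats["Kc"]["dha_kj"] == pytest.approx(40.5, abs=0.06)

    def test_exclusion_flag_respected_in_means(self, species_fits):
        gk = summarize_group(species_fits, "C3-cool")
        included = [32.4, 44.2, 34.6, 50.2, 41.3]  # without the flagged 23.7
        assert gk.stats["Kc"]["dha_kj"] == pytest.approx(np.mean(included), abs=1e-9)

    def test_upper_q10_exclusion(self, species_fits):
        # one member's upper two Q10 values are unreliable and must not enter
        # the 25-35 / 35-45 group means while the lower intervals keep it
        gk = summarize_group(species_fits, "C3-cool")
        sub = species_fits[(species_fits.group == "C3-cool")
                           & (species_fits.trait == "Sc/o")]
        assert gk.stats["Sc/o"]["q10"][0] == pytest.approx(
            sub["q10_5_15"].mean(), abs=1e-9)
        kept = sub[~sub["q10_upper_unreliable"]]
        assert gk.stats["Sc/o"]["q10"][3] == pytest.approx(
            kept["q10_35_45"].mean(), abs=1e-9)

    def test_se_none_for_single_member(self, species_fits):
        gk = summarize_group(species_fits, "C4")
        assert gk.stats["Ko"]["n"] == 1
        assert gk.stats["Ko"]["dha_se"] is None

    def test_missing_group_fails(self, species_fits):
        with pytest.raises(ValueError):
            summarize_group(species_fits, "CAM")

    def test_tidy_summary_contains_all_groups(self, species_fits):
        g = summarize_groups(species_fits)
        assert {"C3-cool", "C3-warm", "C4"} <= set(g["group"])
        assert {"trait", "n", "c", "dha_kj"} <= set(g.columns)


class TestCSVAndPipeline:
    @pytest.fixture()
    def records_csv(self, tmp_path):
        cfg = synthetic.GeneratorConfig(
            seed=11, noise_cv=0.0,
            species_per_group={"C3-cool": 2, "C3-warm": 2, "C4": 1})
        records, _ = synthetic.gen_records(synthetic.gen_truth(cfg), cfg)
        path = tmp_path / "records.csv"
        records.to_csv(path, index=False)
        return path, cfg

    def test_read_missing_column_fails(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"species": ["x"], "trait": ["Kc"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="required columns"):
            read_records_csv(path)

    def test_read_bad_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({
            "species": ["x", "y"], "trait": ["Kc", "Km"],
            "t_meas_c": [25.0, 25.0], "value": [41.0, 41.0],
        }).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 2"):
            read_records_csv(path)

    def test_pipeline_from_csv_end_to_end(self, records_csv):
        path, cfg = records_csv
        result = run_pipeline(str(path))
        assert set(result) == {"standardized", "fits", "species_fits",
                               "groups", "log"}
        assert result["standardized"]["standardized"].all()
        assert not result["groups"].empty

    def test_pipeline_recovers_noiseless_truth(self, records_csv):
        path, cfg = records_csv
        truth = synthetic.gen_truth(cfg)
        result = run_pipeline(str(path))
        merged = result["species_fits"].merge(
            truth, on=["species", "trait"], suffixes=("", "_t"))
        assert len(merged) == len(truth)
        np.testing.assert_allclose(
            merged["dha_kj"] * 1000.0, merged["dha_true"], rtol=1e-6)
        np.testing.assert_allclose(merged["c"], merged["c_true"], rtol=1e-5,
                                   atol=1e-5)

    def test_short_series_skipped_with_log(self):
        std = pd.DataFrame({
            "species": ["a", "b", "b"], "trait": ["Kc"] * 3,
            "source": ["s"] * 3, "phylo_group": ["Spermatophyta"] * 3,
            "pathway": ["C3"] * 3, "tgrowth_c": [20.0] * 3,
            "t_meas_k": [298.15, 288.15, 298.15],
            "value_corrected": [40.0, 25.0, 40.0],
        })
        log = []
        fits = fit_records(std, log)
        assert list(fits["species"]) == ["b"]
        assert any("skipped a/Kc" in line for line in log)

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            run_pipeline([])
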