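"""Pipeline orchestration: naming, combinatorics, outputs, relevance,
distances, project files and the sklearn estimator surface."""

import numpy as np
import pandas as pd
import pytest

from protdescal.engine import (
    DescriptorCalculator,
    DescriptorTable,
    ProjectConfig,
    ShannonRelevanceFilter,
    distance_matrix,
    generate_descriptors,
    read_descriptor_table,
    run_multi,
    run_project,
    shannon_relevance,
    write_outputs,
)
from protdescal.fixtures import FixtureSpec, synthetic_structure
from protdescal.scales import get_scale

from conftest import make_model


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "in.fasta"
    path.write_text(">p1\nHGGGWGQP\n>p2\nACDEFGHIKLMNPQRSTVWY\n>p3\nKKKDDDGGG\n")
    return path


class TestDescriptorCalculator:
    def test_single_combination_shape(self):
        models = [make_model(s) for s in ("AAA", "GGG", "WWW")]
        calc = DescriptorCalculator().fit()
        out = calc.transform(models)
        assert out.shape == (3, 1)

    def test_hp_prt_q2_is_the_median_hydrophobicity(self):
        model = make_model("HGGGWGQP")
        hp = get_scale("HP")
        expected = float(np.median([hp[c] for c in "HGGGWGQP"]))
        calc = DescriptorCalculator(indices=["HP"], groups=["PRT"],
                                    aggregators=["Q2"]).fit()
        assert calc.transform([model])[0, 0] == pytest.approx(expected)
        assert list(calc.get_feature_names_out()) == ["HP_PRT_Q2"]

    def test_column_count_law(self):
        calc = DescriptorCalculator(
            indices=["HP", "z1"],
            weightings=["none", "AC2", "ES"],
            groups=["PRT", "GLY", "BSC", "ARM"],
            aggregators=["Q2", "AM", "N1", "MX", "SIC"],
        ).fit()
        names = calc.get_feature_names_out()
        assert len(names) == 2 * 3 * 4 * 5
        assert len(set(names)) == len(names)

    def test_name_grammar_embeds_weighting_tag(self):
        calc = DescriptorCalculator(indices=["HP"], weightings=["AC3"],
                                    groups=["PRT"], aggregators=["AM"]).fit()
        assert list(calc.get_feature_names_out()) == ["HP_AC3_PRT_AM"]

    def test_group_family_shortcuts_expand(self):
        calc = DescriptorCalculator(groups=["type"]).fit()
        assert len(calc.group_names_) == 20

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError, match="no input"):
            DescriptorCalculator().fit().compute([])

    def test_structure_selection_on_fasta_gives_sentinel(self):
        calc = DescriptorCalculator(indices=["HP", "wNc"], groups=["PRT"],
                                    aggregators=["AM"]).fit()
        out = calc.transform([make_model("AAAA")])
        assert np.isfinite(out[0, 0])
        assert np.isnan(out[0, 1])

    def test_strict_mode_raises_instead(self):
        calc = DescriptorCalculator(indices=["wNc"], strict=True).fit()
        with pytest.raises(ValueError, match="sequence-only"):
            calc.transform([make_model("AAAA")])

    def test_empty_group_yields_sentinel_but_column_remains(self):
        calc = DescriptorCalculator(indices=["HP"], groups=["TRP"],
                                    aggregators=["AM"]).fit()
        out = calc.transform([make_model("AAAA")])
        assert out.shape == (1, 1) and np.isnan(out[0, 0])

    def test_residue_table_labels_and_weighted_columns(self):
        models = [make_model("HGGGWGQP", model_id="1OEH")]
        calc = DescriptorCalculator(indices=["HP"], weightings=["none", "AC2"]).fit()
        residue_table, _ = calc.compute(models)
        assert residue_table.index[0] == "1OEH_aa1_HIS"
        assert list(residue_table.columns) == ["HP", "HP_AC2"]

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        calc = DescriptorCalculator(indices=["z1"], d_cut=7.5)
        cloned = clone(calc)
        assert cloned.get_params()["d_cut"] == 7.5
        assert cloned.get_params()["indices"] == ["z1"]

    def test_structure_pipeline_with_all_families(self, cluster40):
        calc = DescriptorCalculator(
            indices=["HP", "wCO", "Ghp"],
            weightings=["none", "ES"],
            groups=["PRT", "INT", "SUP"],
            aggregators=["AM", "Q2"],
            zero_on_degenerate=True,
        ).fit()
        out = calc.transform([cluster40])
        assert out.shape == (1, 3 * 2 * 3 * 2)
        assert np.isfinite(out).all()

    def test_throughput_at_desk_scale(self):
        # a 500-residue protein against a >1000-descriptor configuration
        # must complete in well under a minute
        import time

        model = synthetic_structure(FixtureSpec("synthetic_helix", 500, seed=0))
        calc = DescriptorCalculator(
            indices=["HP", "z1", "wNc"],
            weightings=["none", "AC2", "ES"],
            groups=["type", "PRT"],
            aggregators=["AM", "Q2", "N1", "SD", "MIC", "MX"],
        ).fit()
        start = time.perf_counter()
        out = calc.transform([model])
        elapsed = time.perf_counter() - start
        assert out.shape[1] == 3 * 3 * 21 * 6 == 1134
        assert elapsed < 60


class TestOutputs:
    def test_written_files_and_roundtrip(self, tmp_path):
        models = [make_model("HGGGWGQP", model_id="1OEH"), make_model("AAAA")]
        calc = DescriptorCalculator(indices=["HP"], groups=["PRT", "GLY"],
                                    aggregators=["Q2", "AM"]).fit()
        residue_table, table = calc.compute(models)
        aa_path, prot_path = write_outputs(residue_table, table, tmp_path / "out")
        assert aa_path.name == "out_AA.txt" and prot_path.name == "out_Prot.txt"
        first_row = aa_path.read_text().splitlines()[1]
        assert first_row.startswith("1OEH_aa1_HIS\t")
        back = read_descriptor_table(prot_path)
        assert back.protein_ids == table.protein_ids
        assert back.descriptor_names == table.descriptor_names
        np.testing.assert_allclose(back.values, table.values, rtol=1e-5)

    def test_sentinel_column_written_with_header(self, tmp_path):
        models = [make_model("AAAA")]
        calc = DescriptorCalculator(indices=["HP"], groups=["TRP"],
                                    aggregators=["AM"]).fit()
        residue_table, table = calc.compute(models)
        _, prot_path = write_outputs(residue_table, table, tmp_path / "s")
        lines = prot_path.read_text().splitlines()
        assert lines[0] == "Protein\tHP_TRP_AM"
        assert lines[1] == "test\tNA"


class TestShannonRelevance:
    def test_constant_column_has_zero_entropy(self):
        table = DescriptorTable(["a", "b", "c"], ["const", "varied"],
                                np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]]))
        ranking = dict(shannon_relevance(table, n_bins=4))
        assert ranking["const"] == 0.0
        assert ranking["varied"] > 0.0

    def test_uniform_eight_bins_give_three_bits(self):
        values = (np.arange(8) + 0.5).reshape(-1, 1)
        table = DescriptorTable([f"p{i}" for i in range(8)], ["u"], values)
        (name, h), = shannon_relevance(table, n_bins=8)
        assert h == pytest.approx(3.0)

    def test_ranking_matches_histogram_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(50, 6))
        names = [f"d{i}" for i in range(6)]
        table = DescriptorTable([f"p{i}" for i in range(50)], names, values)
        n_bins = 10
        expected = {}
        for j, name in enumerate(names):
            counts, _ = np.histogram(values[:, j], bins=n_bins)
            p = counts[counts > 0] / counts.sum()
            expected[name] = float(-(p * np.log2(p)).sum())
        ranking = shannon_relevance(table, n_bins=n_bins)
        for name, h in ranking:
            assert h == pytest.approx(expected[name], rel=1e-12)
        assert [r[0] for r in ranking] == sorted(
            names, key=lambda n: (-expected[n], n)
        )

    def test_all_missing_column_excluded(self):
        table = DescriptorTable(["a", "b"], ["dead", "live"],
                                np.array([[np.nan, 1.0], [np.nan, 2.0]]))
        ranking = shannon_relevance(table, n_bins=4)
        assert [r[0] for r in ranking] == ["live"]

    def test_selector_filters_constant_columns(self):
        frame = pd.DataFrame({"const": [1.0, 1.0, 1.0], "varied": [1.0, 2.0, 3.0]})
        selector = ShannonRelevanceFilter(n_bins=4).fit(frame)
        kept = selector.transform(frame)
        assert kept.shape == (3, 1)
        assert list(selector.get_feature_names_out()) == ["varied"]

    def test_requires_two_proteins_and_two_bins(self):
        table = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError, match="two proteins"):
            ShannonRelevanceFilter().fit(table)
        with pytest.raises(ValueError, match="n_bins"):
            ShannonRelevanceFilter(n_bins=1).fit(pd.DataFrame({"x": [1.0, 2.0]}))


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        table = DescriptorTable(["a", "b"], ["d1", "d2"],
                                np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(distance_matrix(table).to_numpy(), 0.0)

    def test_single_descriptor_euclidean(self):
        table = DescriptorTable(["a", "b"], ["d"], np.array([[1.0], [4.0]]))
        assert distance_matrix(table).loc["a", "b"] == pytest.approx(3.0)

    def test_matches_brute_force_metrics(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(5, 20))
        table = DescriptorTable([f"p{i}" for i in range(5)],
                                [f"d{i}" for i in range(20)], values)
        for metric, func in [
            ("euclidean", lambda a, b: np.sqrt(((a - b) ** 2).sum())),
            ("manhattan", lambda a, b: np.abs(a - b).sum()),
        ]:
            matrix = distance_matrix(table, metric).to_numpy()
            for i in range(5):
                for j in range(5):
                    assert matrix[i, j] == pytest.approx(
                        func(values[i], values[j]), abs=1e-12
                    )
            # metric axioms on the computed matrix
            np.testing.assert_allclose(matrix, matrix.T)
            assert np.allclose(np.diag(matrix), 0.0)
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert matrix[i, j] <= matrix[i, k] + matrix[k, j] + 1e-9

    def test_sentinel_columns_excluded(self):
        values = np.array([[1.0, np.nan], [4.0, 2.0]])
        table = DescriptorTable(["a", "b"], ["ok", "holed"], values)
        assert distance_matrix(table).loc["a", "b"] == pytest.approx(3.0)

    def test_errors(self):
        single = DescriptorTable(["a"], ["d"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="two proteins"):
            distance_matrix(single)
        holed = DescriptorTable(["a", "b"], ["d"], np.array([[np.nan], [1.0]]))
        with pytest.raises(ValueError, match="sentinel-free"):
            distance_matrix(holed)
        ok = DescriptorTable(["a", "b"], ["d"], np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError, match="metric"):
            distance_matrix(ok, metric="chebyshev")


class TestProjects:
    def make_config(self, fasta_file, tmp_path, **overrides):
        cfg = ProjectConfig(
            inputs=[str(fasta_file)],
            indices=["HP", "Ghp(U)"],
            weightings=["none", "AC2"],
            groups=["PRT", "GLY"],
            aggregators=["Q2", "AM", "SD"],
            output_prefix=str(tmp_path / "proj"),
            **overrides,
        )
        return cfg

    def test_saved_config_roundtrips_losslessly(self, fasta_file, tmp_path):
        cfg = self.make_config(fasta_file, tmp_path)
        path = cfg.save(tmp_path / "p.yaml")
        assert ProjectConfig.load(path) == cfg

    def test_rerun_is_byte_identical(self, fasta_file, tmp_path):
        cfg = self.make_config(fasta_file, tmp_path)
        path = cfg.save(tmp_path / "p.yaml")
        aa1, prot1 = run_project(path)
        first = (aa1.read_bytes(), prot1.read_bytes())
        aa2, prot2 = run_project(path)
        assert (aa2.read_bytes(), prot2.read_bytes()) == first

    def test_output_column_count_follows_law(self, fasta_file, tmp_path):
        cfg = self.make_config(fasta_file, tmp_path)
        _, prot = run_project(cfg.save(tmp_path / "p.yaml"))
        header = prot.read_text().splitlines()[0].split("\t")
        assert len(header) - 1 == 2 * 2 * 2 * 3

    def test_malformed_config_names_field(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("inputs: []\nwibble: 3\n")
        with pytest.raises(ValueError, match="wibble"):
            ProjectConfig.load(bad)

    def test_multi_isolates_failures(self, fasta_file, tmp_path):
        good = self.make_config(fasta_file, tmp_path).save(tmp_path / "good.yaml")
        bad = tmp_path / "bad.yaml"
        bad.write_text("nonsense_field: 1\n")
        summaries = run_multi([good, bad])
        assert [s["status"] for s in summaries] == ["ok", "error"]

    def test_generate_descriptors_wrapper(self, fasta_file, tmp_path):
        from protdescal.protein_io import read_fasta

        cfg = self.make_config(fasta_file, tmp_path)
        models = read_fasta(fasta_file)
        residue_table, table = generate_descriptors(models, cfg)
        assert table.protein_ids == ["p1", "p2", "p3"]
        assert len(residue_table) == sum(len(m) for m in models)
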