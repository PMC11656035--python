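"""Replicate orchestration, locus runs, plot-data export and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from susiekit import (
    LocusConfig,
    ScenarioConfig,
    aggregate_replicates,
    choose_causal_variants,
    export_locus_plot,
    generate_haplotype_panel,
    run_locus,
    run_replicates,
)
from susiekit import io as skio
from susiekit.benchmark import read_locus_plot
from susiekit.cli import main as cli_main


def write_toy_locus(tmp_path, z=(6.0, 0.0, 0.0), p=None):
    p = len(z) if p is None else p
    ss = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(1, len(z) + 1)],
            "CHR": "1",
            "BP": np.arange(100, 100 + len(z)),
            "A1": "A",
            "A2": "G",
            "BETA": np.asarray(z) * 0.1,
            "SE": 0.1,
            "P": 0.5,
            "MAF": 0.3,
        }
    )
    ss_path = tmp_path / "ss.tsv"
    ld_path = tmp_path / "ld.txt"
    skio.write_sumstats(ss, ss_path)
    skio.write_ld(np.eye(p), ld_path)
    return ss_path, ld_path


class TestAggregation:
    def test_hand_computed_bookkeeping(self):
        # replicates with set counts (1, 0, 2) and sizes ((3), (), (2, 4))
        detected = np.array([[True], [False], [True]])
        out = aggregate_replicates(detected, [[3], [], [2, 4]])
        assert out.n_cs_mean == pytest.approx(1.0)
        assert out.cs_size_mean == pytest.approx(3.0)  # over the 2 contributing reps
        assert out.power_per_causal[0] == pytest.approx(2 / 3)

    def test_degenerate_all_singletons(self):
        detected = np.ones((5, 1), dtype=bool)
        out = aggregate_replicates(detected, [[1]] * 5)
        assert out.power_per_causal[0] == 1.0
        assert out.power_all == 1.0
        assert out.n_cs_mean == 1.0 and out.n_cs_sd == 0.0
        assert out.cs_size_mean == 1.0 and out.cs_size_sd == 0.0

    def test_no_sets_anywhere(self):
        out = aggregate_replicates(np.zeros((3, 2), dtype=bool), [[], [], []])
        assert out.n_cs_mean == 0.0
        assert np.isnan(out.cs_size_mean)


class TestRunReplicates:
    def test_null_scenario_power_is_nominal(self, small_panel):
        sc = ScenarioConfig(
            causal_indices=[10],
            grr_het=1.0,
            grr_hom=1.0,
            n_cases=200,
            n_controls=200,
            n_replicates=40,
            seed=3,
        )
        out = run_replicates(sc, small_panel)
        assert out.power_per_causal[0] <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40)
        assert out.n_failures == 0

    def test_single_causal_scenario_detects_signal(self, small_panel):
        sc = ScenarioConfig(
            causal_indices=choose_causal_variants(small_panel, 1),
            n_cases=300,
            n_controls=300,
            n_replicates=10,
            seed=5,
        )
        out = run_replicates(sc, small_panel)
        assert out.power_per_causal[0] >= 0.7
        assert out.n_cs_mean >= 0.7

    def test_deterministic_given_seed(self, small_panel):
        sc = ScenarioConfig(
            causal_indices=[10], n_cases=150, n_controls=150, n_replicates=3, seed=8
        )
        a = run_replicates(sc, small_panel)
        b = run_replicates(sc, small_panel)
        assert a.to_row() == b.to_row()

    def test_prs_mechanism_end_to_end(self, small_panel):
        sc = ScenarioConfig(
            causal_indices=choose_causal_variants(small_panel, 1),
            effect_model="logor",
            log_ors=[0.8],
            n_cases=300,
            n_controls=300,
            n_replicates=5,
            seed=9,
        )
        out = run_replicates(sc, small_panel)
        assert out.n_failures == 0
        assert out.power_per_causal[0] >= 0.6


class TestHighLdMerging:
    def test_two_causals_in_near_perfect_ld_yield_one_set(self):
        """Two causal variants with |r| > 0.9 are reported as a single
        credible set: the signals are statistically indistinguishable, so
        the model should merge them rather than split."""
        pan = generate_haplotype_panel(
            n_haplotypes=2000,
            n_blocks=3,
            block_size=30,
            within_block_corr=0.999,
            maf_low=0.35,
            maf_high=0.5,
            seed=2,
        )
        c2 = choose_causal_variants(pan, 2)
        assert abs(pan.haplotype_corr()[c2[0], c2[1]]) > 0.9
        sc = ScenarioConfig(
            causal_indices=c2, n_cases=500, n_controls=500, n_replicates=20, seed=77
        )
        out = run_replicates(sc, pan)
        counts = np.bincount(out.n_cs_counts)
        assert int(np.argmax(counts)) == 1
        assert abs(out.n_cs_mean - 1.0) <= 0.2


class TestChooseCausalVariants:
    def test_scenario_geometries(self, panel):
        c1 = choose_causal_variants(panel, 1)
        assert len(c1) == 1 and panel.maf[c1[0]] >= 0.2
        c2 = choose_causal_variants(panel, 2)
        assert len(c2) == 2
        assert panel.block_id[c2[0]] == panel.block_id[c2[1]]
        assert c2[1] - c2[0] == 3
        c3 = choose_causal_variants(panel, 3)
        assert panel.block_id[c3[0]] != panel.block_id[c3[1]]

    def test_scenario_two_picks_most_correlated_pair(self, panel):
        c2 = choose_causal_variants(panel, 2)
        r = np.abs(panel.haplotype_corr())
        chosen = r[c2[0], c2[1]]
        maf = panel.maf
        for b in np.unique(panel.block_id):
            idx = np.flatnonzero(panel.block_id == b)
            for j in idx[:-3]:
                if maf[j] >= 0.2 and maf[j + 3] >= 0.2:
                    assert r[j, j + 3] <= chosen + 1e-12


class TestRunLocus:
    def test_toy_locus_single_set(self, tmp_path):
        ss_path, ld_path = write_toy_locus(tmp_path)
        fit, sets, plot = run_locus(ss_path, ld_path)
        assert len(sets) == 1
        assert sets[0].members == [0]
        assert plot["cs_label"].tolist() == [1, 0, 0]

    def test_truncated_ld_raises_mismatch(self, tmp_path):
        ss_path, _ = write_toy_locus(tmp_path)
        ld_path = tmp_path / "short.txt"
        skio.write_ld(np.eye(2), ld_path)
        with pytest.raises(ValueError, match="3 summary-statistic rows vs 2"):
            run_locus(ss_path, ld_path)

    def test_coverage_override_plumbs_through(self, tmp_path):
        ss_path, ld_path = write_toy_locus(tmp_path, z=(3.0, 2.8, 0.0))
        cfg = LocusConfig(coverage=0.6)
        _, sets, _ = run_locus(ss_path, ld_path, cfg)
        for cs in sets:
            assert cs.achieved_coverage >= 0.6

    def test_nonfinite_z_lists_offenders(self, tmp_path):
        ss_path, ld_path = write_toy_locus(tmp_path)
        ss = skio.read_sumstats(ss_path)
        ss.loc[1, ["BETA", "SE"]] = [0.2, 0.0]  # Z becomes inf
        ss["Z"] = ss["BETA"] / ss["SE"]
        skio.write_sumstats(ss, ss_path)
        with pytest.raises(ValueError, match="rs2"):
            run_locus(ss_path, ld_path)


class TestPlotExport:
    def test_round_trip_and_label_consistency(self, tmp_path):
        ss_path, ld_path = write_toy_locus(tmp_path, z=(8.0, 7.5, 0.0))
        fit, sets, plot = run_locus(ss_path, ld_path)
        out = tmp_path / "plot.tsv"
        export_locus_plot(plot, out, figure_path=tmp_path / "plot.png")
        back = read_locus_plot(out)
        pd.testing.assert_frame_equal(back, plot)
        labels = set(back["cs_label"]) - {0}
        assert labels == set(range(1, len(sets) + 1))
        for k, cs in enumerate(sets, start=1):
            members = back.index[back["cs_label"] == k].tolist()
            assert members == cs.members
        assert (tmp_path / "plot.png").exists()

    def test_no_sets_all_grey(self, tmp_path):
        ss_path, ld_path = write_toy_locus(tmp_path, z=(0.5, 0.2, 0.1))
        _, sets, plot = run_locus(ss_path, ld_path)
        assert sets == []
        assert (plot["cs_label"] == 0).all()


class TestCli:
    def test_simulate_assoc_finemap_round_trip(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "panel:\n"
            "  n_haplotypes: 400\n  n_blocks: 2\n  block_size: 15\n"
            "scenario:\n"
            "  scenario_kind: 1\n  n_cases: 200\n  n_controls: 200\n  seed: 4\n"
        )
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg), "--out-prefix", str(tmp_path / "sim")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            [
                "assoc",
                "--dosages", str(tmp_path / "sim.dosages.tsv"),
                "--pheno", str(tmp_path / "sim.pheno.tsv"),
                "--sumstats-out", str(tmp_path / "ss.tsv"),
                "--ld-out", str(tmp_path / "ld.txt"),
            ],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            [
                "finemap",
                "--sumstats", str(tmp_path / "ss.tsv"),
                "--ld", str(tmp_path / "ld.txt"),
                "--out-prefix", str(tmp_path / "fm"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "fm.cs.tsv").exists()
        assert (tmp_path / "fm.fit.json").exists()
        plot = read_locus_plot(tmp_path / "fm.plot.tsv")
        assert set(plot.columns) == {"variant_id", "pos", "neg_log10_p", "cs_label"}

    def test_benchmark_command(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "panel:\n"
            "  n_haplotypes: 400\n  n_blocks: 2\n  block_size: 10\n"
            "scenario:\n"
            "  scenario_kind: 1\n  n_cases: 150\n  n_controls: 150\n"
            "  n_replicates: 2\n  seed: 4\n"
        )
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["benchmark", "--config", str(cfg), "--out", str(tmp_path / "bm.json")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "bm.json").exists()


class TestIORoundTrips:
    def test_sumstats_z_round_trip(self, tmp_path, rng):
        ss = pd.DataFrame(
            {
                "SNP": ["a", "b"],
                "CHR": "2",
                "BP": [10, 20],
                "A1": "A",
                "A2": "G",
                "BETA": rng.normal(size=2),
                "SE": rng.uniform(0.05, 0.2, size=2),
                "P": [0.1, 0.2],
                "MAF": [0.1, 0.3],
            }
        )
        ss["Z"] = ss["BETA"] / ss["SE"]
        path = tmp_path / "ss.tsv"
        skio.write_sumstats(ss, path)
        back = skio.read_sumstats(path)
        assert np.allclose(back["Z"], ss["Z"], atol=1e-10)

    def test_sumstats_reader_recomputes_z_and_ignores_extras(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\tMAF\tINFO\n"
            "a\t1\t5\tA\tG\t0.2\t0.1\t0.04\t0.2\t0.99\n"
        )
        back = skio.read_sumstats(path)
        assert back["Z"].iloc[0] == pytest.approx(2.0)

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = ScenarioConfig(
            causal_indices=[3, 7], effect_model="logor", log_ors=[0.3, -0.2], seed=12
        )
        path = tmp_path / "sc.yaml"
        skio.scenario_to_yaml(sc, path)
        back = skio.scenario_from_yaml(path)
        assert back == sc

    def test_dosage_and_phenotype_round_trip(self, small_panel, tmp_path):
        from susiekit import PhenotypeVector, simulate_genotypes

        g = simulate_genotypes(small_panel, 30, seed=2)
        skio.write_dosages(g, tmp_path / "d.tsv")
        back = skio.read_dosages(tmp_path / "d.tsv")
        assert np.array_equal(back.dosages, g.dosages)
        assert list(back.variant_ids) == list(g.variant_ids)
        ph = PhenotypeVector(y=np.array([0, 1, 1], dtype=np.int8))
        skio.write_phenotype(ph, tmp_path / "p.tsv")
        assert np.array_equal(skio.read_phenotype(tmp_path / "p.tsv").y, ph.y)

    def test_external_credible_set_import(self, tmp_path):
        path = tmp_path / "cs.tsv"
        path.write_text(
            "locus\tcs_index\tvariant_id\tpos\talpha\tpip\tachieved_coverage\tpurity\n"
            "12p13.31\t1\trs1800693\t100\t0.99\t0.99\t0.99\t1.0\n"
        )
        df = skio.read_credible_sets(path)
        assert df["variant_id"].iloc[0] == "rs1800693"
        with pytest.raises(ValueError, match="lacks columns"):
            bad = tmp_path / "bad.tsv"
            bad.write_text("foo\tbar\n1\t2\n")
            skio.read_credible_sets(bad)
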