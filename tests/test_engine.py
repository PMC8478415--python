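"""End-to-end pipeline: run_model, presets, serialization, CLI, plotting."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from panelped import (
    CancerHistory, ModelOptions, build_model_database, enumerate_genotypes,
    future_risk, make_toy_database, parse_output, peel, plot_risk, preset_model,
    run_model, save_database, serialize_output, simulate_family, write_pedigree,
)
from panelped.cli import main as cli_main
from conftest import nuclear_family


@pytest.fixture(scope="module")
def db7():
    """Seven genes: includes the full BRCAPRO6 panel."""
    return make_toy_database(K=7, R=2, seed=1)


class TestRunModel:
    def test_four_gene_pared_model_has_eleven_genotypes(self, toy_db4):
        ped = nuclear_family()
        ped[1].cancers["BC"] = CancerHistory(affected=1, diagnosis_age=55)
        res = run_model(ped, toy_db4, cancers=["Breast", "Ovarian"],
                        genes=["BRCA1", "BRCA2", "ATM", "MSH2"],
                        options=ModelOptions(max_mut=2, iterations=1))
        post = res["posterior"]
        assert len(post.labels) == 11
        assert post.labels[0] == "noncarrier"
        assert "BRCA1_hetero_anyPV.BRCA2_hetero_anyPV" in post.labels
        assert post.probands[3]["estimate"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_max_mut_one_gives_five_labels(self, toy_db4):
        res = run_model(nuclear_family(), toy_db4,
                        genes=["BRCA1", "BRCA2", "ATM", "MSH2"],
                        options=ModelOptions(max_mut=1, iterations=1))
        assert len(res["posterior"].labels) == 5

    def test_preset_equals_explicit_call_bit_for_bit(self, db7):
        ped = nuclear_family()
        ped[1].cancers["BC"] = CancerHistory(affected=1, diagnosis_age=48)
        opts = ModelOptions(iterations=1, seed=0)
        via_preset = run_model(ped, db7, preset="BRCAPRO6", options=opts)
        cancers, genes = preset_model("BRCAPRO6")
        explicit = run_model(ped, db7, cancers=cancers, genes=genes, options=opts)
        assert via_preset["posterior"].labels == explicit["posterior"].labels
        for pid in via_preset["posterior"].probands:
            for key in ("estimate", "lower", "upper"):
                np.testing.assert_array_equal(
                    via_preset["posterior"].probands[pid][key],
                    explicit["posterior"].probands[pid][key])
        assert serialize_output(via_preset) == serialize_output(explicit)

    @pytest.mark.parametrize("name,n_cancers,n_genes", [
        ("BRCAPRO", 2, 2), ("BRCAPRO5", 2, 5), ("BRCAPRO6", 2, 6),
        ("MMRPRO", 2, 3)])
    def test_preset_contents(self, name, n_cancers, n_genes):
        cancers, genes = preset_model(name)
        assert len(cancers) == n_cancers and len(genes) == n_genes

    def test_unknown_preset_lists_supported_names(self):
        from panelped import ResolutionError
        with pytest.raises(ResolutionError, match="BRCAPRO6"):
            preset_model("BOADICEA")

    def test_deterministic_under_seed_with_missing_data(self, toy_db):
        sim = simulate_family([2, 2], toy_db, seed=3)
        from panelped import mask_ages
        ped = mask_ages(sim.pedigree, 0.4, seed=5)
        opts = ModelOptions(iterations=4, seed=99)
        a = run_model(ped, toy_db, options=opts)
        b = run_model(ped, toy_db, options=opts)
        assert serialize_output(a) == serialize_output(b)

    def test_parallel_flag_does_not_change_results(self, toy_db):
        sim = simulate_family([2, 2], toy_db, seed=3)
        from panelped import mask_ages
        ped = mask_ages(sim.pedigree, 0.4, seed=5)
        seq = run_model(ped, toy_db, options=ModelOptions(iterations=3, seed=7,
                                                          parallel=False))
        par = run_model(ped, toy_db, options=ModelOptions(iterations=3, seed=7,
                                                          parallel=True))
        assert serialize_output(seq) == serialize_output(par)

    def test_no_missing_data_equals_direct_peel_and_risk(self, toy_db):
        ped = nuclear_family()
        ped[1].cancers["OC"] = CancerHistory(affected=1, diagnosis_age=60)
        res = run_model(ped, toy_db, options=ModelOptions(iterations=1))
        from panelped import check_pedigree
        checked, _ = check_pedigree(ped, toy_db)
        mdb = build_model_database(toy_db, ped=checked)
        space = enumerate_genotypes(mdb.gene_variants, 2)
        direct_post = peel(checked, mdb, space)
        direct_risk = future_risk(direct_post, checked, mdb, space)
        np.testing.assert_array_equal(res["posterior"].probands[3]["estimate"],
                                      direct_post.probands[3]["estimate"])
        for cancer, d in res["future_risk"].probands[3].items():
            np.testing.assert_array_equal(
                d["estimate"], direct_risk.probands[3][cancer]["estimate"])

    def test_brute_engine_agrees_with_peel(self, toy_db):
        ped = nuclear_family()
        ped[1].cancers["BC"] = CancerHistory(affected=1, diagnosis_age=50)
        opts = ModelOptions(iterations=1)
        a = run_model(ped, toy_db, options=opts, engine="peel")
        b = run_model(ped, toy_db, options=opts, engine="brute")
        np.testing.assert_allclose(a["posterior"].probands[3]["estimate"],
                                   b["posterior"].probands[3]["estimate"],
                                   atol=1e-10)


class TestSerialization:
    def test_round_trip(self, toy_db):
        ped = nuclear_family()
        ped[4].cur_age = None
        res = run_model(ped, toy_db, options=ModelOptions(iterations=3, seed=1))
        doc = serialize_output(res)
        assert set(doc) == {"posterior.prob", "future.risk"}
        assert "3" in doc["posterior.prob"]
        row = doc["posterior.prob"]["3"][0]
        assert set(row) == {"genes", "estimate", "lower", "upper"}
        assert row["genes"] == "noncarrier"
        risk_rows = doc["future.risk"]["3"]["Breast"]
        assert set(risk_rows[0]) == {"ByAge", "estimate", "lower", "upper"}
        back = parse_output(json.loads(json.dumps(doc)))
        np.testing.assert_allclose(back["posterior"].probands[3]["estimate"],
                                   res["posterior"].probands[3]["estimate"])
        np.testing.assert_allclose(
            back["future_risk"].probands[3]["Breast"]["estimate"],
            res["future_risk"].probands[3]["Breast"]["estimate"])

    def test_proband_with_all_cancers_serializes_empty_risk(self, toy_db):
        ped = nuclear_family()
        ped[3].cancers["BC"] = CancerHistory(affected=1, diagnosis_age=39)
        ped[3].cancers["OC"] = CancerHistory(affected=1, diagnosis_age=40)
        res = run_model(ped, toy_db, options=ModelOptions(iterations=1))
        doc = serialize_output(res)
        assert doc["future.risk"]["3"] == {}


class TestPlot:
    def test_plot_file_created(self, toy_db, tmp_path):
        ped = nuclear_family()
        res = run_model(ped, toy_db, options=ModelOptions(iterations=1))
        out = tmp_path / "risk.png"
        plot_risk(res, out)
        assert out.exists() and out.stat().st_size > 0

    def test_multi_proband_plot(self, toy_db, tmp_path):
        ped = nuclear_family()
        ped[4].is_proband = 1
        res = run_model(ped, toy_db, options=ModelOptions(iterations=1))
        out = tmp_path / "risk2.png"
        plot_risk(res, out)
        assert out.exists() and out.stat().st_size > 0


class TestCli:
    def test_run_subcommand(self, toy_db, tmp_path):
        ped_path = tmp_path / "fam.csv"
        db_path = tmp_path / "db.json"
        write_pedigree(nuclear_family(), ped_path)
        save_database(toy_db, db_path)
        out_path = tmp_path / "out.json"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "run", str(ped_path), str(db_path), "--iterations", "1",
            "--max-mut", "1", "--out", str(out_path)])
        assert result.exit_code == 0, result.output
        doc = json.loads(out_path.read_text())
        assert "posterior.prob" in doc and "3" in doc["posterior.prob"]
        assert len(doc["posterior.prob"]["3"]) == 4  # 1 + 3 genes at paring 1

    def test_check_subcommand_reports_loop_with_nonzero_exit(self, toy_db, tmp_path):
        from test_check import _ped
        from panelped import Individual
        members = [
            Individual(id=1, sex=0, cur_age=90), Individual(id=2, sex=1, cur_age=90),
            Individual(id=3, sex=0, cur_age=88), Individual(id=4, sex=1, cur_age=88),
            Individual(id=5, sex=1, mother_id=1, father_id=2, cur_age=59),
            Individual(id=6, sex=0, mother_id=1, father_id=2, cur_age=55),
            Individual(id=7, sex=0, mother_id=3, father_id=4, cur_age=60),
            Individual(id=8, sex=1, mother_id=3, father_id=4, cur_age=62),
            Individual(id=9, sex=0, mother_id=7, father_id=5, cur_age=30, is_proband=1),
            Individual(id=10, sex=1, mother_id=6, father_id=8, cur_age=28),
        ]
        ped_path = tmp_path / "loop.csv"
        db_path = tmp_path / "db.json"
        write_pedigree(_ped(members), ped_path)
        save_database(toy_db, db_path)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["check", str(ped_path), str(db_path)])
        assert result.exit_code == 1
        assert "LoopError" in result.output

    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "simulate", "--families", "2", "--seed", "4",
            "--out-dir", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sim_fam_1.csv").exists()
        assert (tmp_path / "sim_fam_2.truth.json").exists()
        assert (tmp_path / "toy_database.json").exists()
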