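"""Shared I/O round-trips and the command-line interface."""

import numpy as np
import pytest
from click.testing import CliRunner

from splicescreen import io as sio
from splicescreen.cli import main
from splicescreen.motifs import HexamerSet, Pwm


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nACGT\n")
        assert sio.read_fasta(p) == [("x", "ACGT")]

    def test_lowercase_wraps_and_u_normalised(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nacgu\nACGU\n")
        assert sio.read_fasta(p) == [("x", "ACGTACGT")]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nAC\n>x\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            sio.read_fasta(p)

    def test_gaps_preserved_and_round_trip(self, tmp_path):
        records = [("a", "AC-GT"), ("b", "ACGGT")]
        p = tmp_path / "aln.fasta"
        sio.write_fasta(p, records)
        assert sio.read_fasta(p) == records


class TestNewick:
    def test_two_leaves_with_root_label(self):
        tree = sio.read_newick("(A:1,B:2)R;")
        labels = sio.node_labels(tree)
        assert set(labels) == {"A", "B", "R"}

    def test_round_trip_identical(self, tmp_path):
        newick = "((A:1,B:2)X:0.5,(C:1,(D:1,E:1)Y:2)Z:0.5)R;"
        tree = sio.read_newick(newick)
        p = tmp_path / "t.nwk"
        sio.write_newick(p, tree)
        again = sio.read_newick(p)
        assert sio.node_labels(again) == sio.node_labels(tree)

    def test_unlabelled_internals_get_deterministic_preorder_names(self):
        tree = sio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labels = sio.node_labels(tree)
        assert [l for l in labels if l.startswith("N")] == ["N1", "N2", "N3"]

    def test_malformed_tree_raises(self):
        with pytest.raises(Exception):
            sio.read_newick("((A:1,B:1;")


class TestMotifFiles:
    def test_pwm_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        pwm = Pwm("m1", rng.normal(size=(5, 4)), threshold_frac=0.9)
        p = tmp_path / "m.tsv"
        sio.write_pwm(p, pwm)
        again = sio.read_pwm(p)
        assert again.name == "m1"
        assert np.array_equal(again.matrix, pwm.matrix)

    def test_hexamer_round_trip_with_scores(self, tmp_path):
        hs = HexamerSet("ess", {"AAATTT", "GGGCCC"},
                        scores={"AAATTT": -1.25}, silencer=True)
        p = tmp_path / "h.tsv"
        sio.write_hexamers(p, hs)
        again = sio.read_hexamers(p, silencer=True)
        assert again.members == hs.members
        assert again.scores == {"AAATTT": -1.25}

    def test_comma_decimal_scores_accepted(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("AAATTT\t0,75\n")
        assert sio.read_hexamers(p).scores == {"AAATTT": 0.75}

    def test_packaged_fixture_shapes(self):
        pwms = sio.load_packaged_pwms()
        assert len(pwms) == 4
        assert sorted(p.width for p in pwms) == [6, 7, 7, 8]
        ess = sio.load_packaged_hexamers("ess")
        assert ess.silencer and ess.scores


class TestVelocityTable:
    def test_comma_and_dot_decimals(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("enzyme\tS_mM\tv_uM_per_s\treplicate\n"
                     "e1\t0,5\t0.3\t0\n"
                     "e1\t1.0\t0,45\t0\n"
                     "e1\t2.0\t0.5\t1\n")
        (ds,) = sio.read_velocity_tsv(p)
        assert ds.points == [(0.5, 0.3, 0), (1.0, 0.45, 0), (2.0, 0.5, 1)]


class TestCli:
    def test_help_exits_zero(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        assert "scan" in result.output

    def test_scan_counts_match_hand_enumeration(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">s1\nAAATTTGGG\n>s2\nAAATTTAAATTT\n")
        hexfile = tmp_path / "h.tsv"
        hexfile.write_text("AAATTT\n")
        out = tmp_path / "hits.bed"
        result = CliRunner().invoke(main, [
            "scan", "--seq", str(fasta), "--hex", str(hexfile),
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        rows = [l for l in out.read_text().splitlines()
                if l and not l.startswith("#")]
        # s1 has one occurrence; s2 has two
        assert len(rows) == 3
        assert rows[0].split("\t")[:3] == ["s1", "0", "6"]

    def test_identical_inputs_give_byte_identical_output(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">s1\nAAATTTGGGAAATTT\n")
        hexfile = tmp_path / "h.tsv"
        hexfile.write_text("AAATTT\n")
        outs = []
        for name in ("a.bed", "b.bed"):
            out = tmp_path / name
            result = CliRunner().invoke(main, [
                "scan", "--seq", str(fasta), "--hex", str(hexfile),
                "--out", str(out)])
            assert result.exit_code == 0
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_missing_input_path_exits_two(self, tmp_path):
        result = CliRunner().invoke(main, [
            "scan", "--seq", str(tmp_path / "nope.fasta"),
            "--out", str(tmp_path / "o.bed")])
        assert result.exit_code == 2

    def test_train_and_score_round_trip(self, tmp_path):
        from splicescreen import simulate as sim
        windows = sim.gen_splice_training(sim.donor_params("strong"), 300, 4)
        wfasta = tmp_path / "w.fasta"
        sio.write_fasta(wfasta, [(f"w{i}", w) for i, w in enumerate(windows)])
        model_path = tmp_path / "donor.model"
        r1 = CliRunner().invoke(main, [
            "splice-train", "--windows", str(wfasta), "--site-type", "donor",
            "--out", str(model_path)])
        assert r1.exit_code == 0, r1.output
        out = tmp_path / "scores.tsv"
        r2 = CliRunner().invoke(main, [
            "splice-score", "--model", str(model_path), "--seq", str(wfasta),
            "--cutoff-weak", "3", "--cutoff-strong", "6", "--out", str(out)])
        assert r2.exit_code == 0, r2.output
        df = sio.read_tsv(out)
        assert len(df) == 300
        assert set(df.label) <= {"weak", "strong", "intermediate"}

    def test_simulate_family_then_screen(self, tmp_path):
        from splicescreen import simulate as sim
        out_dir = tmp_path / "fam"
        r1 = CliRunner().invoke(main, [
            "simulate", "family", "--seed", "42", "--out", str(out_dir),
            "--n-members", "3"])
        assert r1.exit_code == 0, r1.output
        assert (out_dir / "family.fasta").exists()
        assert (out_dir / "truth.json").exists()
        # train models and run the screen CLI over the simulated family
        models = sim.train_reference_models(seed=7)
        amodel = tmp_path / "acceptor.model"
        dmodel = tmp_path / "donor.model"
        models["acceptor"].save(amodel)
        models["donor"].save(dmodel)
        hexfile = tmp_path / "h.tsv"
        hexfile.write_text("GAAGAA\n")
        report = tmp_path / "report.tsv"
        r2 = CliRunner().invoke(main, [
            "screen", "--family", str(out_dir / "family.tsv"),
            "--fasta", str(out_dir / "family.fasta"),
            "--acceptor-model", str(amodel), "--donor-model", str(dmodel),
            "--hex", str(hexfile), "--cutoff-weak", "3", "--cutoff-strong", "6",
            "--min-delta", "2", "--out", str(report)])
        assert r2.exit_code == 0, r2.output
        df = sio.read_tsv(report)
        import json
        truth = json.loads((out_dir / "truth.json").read_text())
        got = sorted(map(tuple, zip(df.weak_member, df.strong_member)))
        assert got == sorted(map(tuple, truth["expected_candidates"]))

    def test_kinetics_cli_reproduces_parameters(self, tmp_path):
        out_dir = tmp_path / "kin"
        r1 = CliRunner().invoke(main, [
            "simulate", "kinetics", "--seed", "1", "--out", str(out_dir),
            "--noise-cv", "0"])
        assert r1.exit_code == 0, r1.output
        out = tmp_path / "fits.tsv"
        r2 = CliRunner().invoke(main, [
            "kinetics-fit", "--data", str(out_dir / "velocities.tsv"),
            "--out", str(out)])
        assert r2.exit_code == 0, r2.output
        df = sio.read_tsv(out)
        assert df.Km_mM.iloc[0] == pytest.approx(0.2239, abs=1e-4)
        assert df.Vmax_uM_s.iloc[0] == pytest.approx(0.0751, abs=1e-4)
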