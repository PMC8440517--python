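import gzip

import numpy as np
import pandas as pd
import pytest

from famcond import sumstats_io as sio

from conftest import make_table

HEADER = "variant_id chrom pos effect_allele other_allele eaf beta se n"


def _write(tmp_path, lines, name="sumstats.txt"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER] + lines) + "\n")
    return path


class TestRead:
    def test_well_formed_rows_parse(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "rs1 1 1000 A G 0.3 0.10 0.02 5000",
                "rs2 1 2000 C T 0.5 -0.05 0.03 5000",
                "rs3 2 3000 G A 0.1 0.00 0.04 4000",
            ],
        )
        table = sio.read_sumstats(path, trait_label="bw")
        assert len(table) == 3
        assert table.records["pos"].tolist() == [1000, 2000, 3000]
        assert table.records["beta"].tolist() == [0.10, -0.05, 0.00]

    def test_invalid_rows_dropped_with_reason(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "rs1 1 1000 A G 0.3 0.10 0.02 5000",
                "rs2 1 2000 C T 0.5 -0.05 0.00 5000",  # se = 0
                "rs3 2 3000 G G 0.1 0.00 0.04 4000",  # identical alleles
                "rs4 2 4000 G A 1.2 0.00 0.04 4000",  # eaf out of range
            ],
        )
        table = sio.read_sumstats(path)
        assert len(table) == 1
        reasons = dict(zip(table.dropped_log["variant_id"], table.dropped_log["reason"]))
        assert reasons["rs2"] == "nonpositive se"
        assert reasons["rs3"] == "identical alleles"
        assert reasons["rs4"] == "eaf outside (0,1)"

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("variant_id chrom pos\nrs1 1 1000\n")
        with pytest.raises(sio.ConfigurationError):
            sio.read_sumstats(path)

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        path = _write(tmp_path, ["rs1 1 1000 A G 0.3 0.10 0.00 5000"])
        with pytest.raises(sio.InputError):
            sio.read_sumstats(path)

    def test_column_map_and_gzip(self, tmp_path):
        content = "SNP CHR BP A1 A2 FRQ BETA SE N\nrs1 1 1000 A G 0.3 0.1 0.02 5000\n"
        path = tmp_path / "mapped.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        table = sio.read_sumstats(
            path,
            column_map={
                "variant_id": "SNP",
                "chrom": "CHR",
                "pos": "BP",
                "effect_allele": "A1",
                "other_allele": "A2",
                "eaf": "FRQ",
                "beta": "BETA",
                "se": "SE",
                "n": "N",
            },
        )
        assert len(table) == 1
        assert table.records.at[0, "eaf"] == 0.3

    def test_write_read_round_trip(self, tmp_path):
        table = make_table("bw", beta=[0.1, -0.2, 0.0], se=[0.01, 0.02, 0.03])
        out = tmp_path / "out.txt"
        sio.write_sumstats(table, out)
        back = sio.read_sumstats(
            out,
            column_map={"beta": "beta_bw", "se": "se_bw"},
            trait_label="bw",
        )
        for col in ("variant_id", "chrom", "effect_allele", "other_allele"):
            assert back.records[col].tolist() == table.records[col].tolist()
        np.testing.assert_allclose(back.records["beta"], table.records["beta"])
        np.testing.assert_allclose(back.records["se"], table.records["se"])
        np.testing.assert_array_equal(back.records["pos"], table.records["pos"])


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        t1 = make_table("a", ["rs1"], ea="A", oa="G", beta=0.1, eaf=0.3)
        t2 = make_table("b", ["rs1"], ea="G", oa="A", beta=-0.1, eaf=0.7)
        hset = sio.harmonize([t1, t2])
        b1 = hset.tables[0].records.at[0, "beta"]
        b2 = hset.tables[1].records.at[0, "beta"]
        assert b1 == b2 == pytest.approx(0.1)
        assert hset.tables[1].records.at[0, "eaf"] == pytest.approx(0.3)

    def test_maf_filter_drops_rare_variant(self):
        t1 = make_table("a", ["rs1", "rs2"], eaf=[0.003, 0.3])
        t2 = make_table("b", ["rs1", "rs2"], eaf=[0.003, 0.3])
        hset = sio.harmonize([t1, t2], maf_min=0.005)
        assert hset.variant_ids.tolist() == ["rs2"]
        log = dict(zip(hset.dropped_log["variant_id"], hset.dropped_log["reason"]))
        assert log["rs1"] == "maf"

    def test_strand_ambiguous_dropped_when_requested(self):
        t1 = make_table("a", ["rs1", "rs2"], ea=["A", "A"], oa=["T", "G"])
        t2 = make_table("b", ["rs1", "rs2"], ea=["A", "A"], oa=["T", "G"])
        hset = sio.harmonize([t1, t2], drop_strand_ambiguous=True)
        assert hset.variant_ids.tolist() == ["rs2"]
        log = dict(zip(hset.dropped_log["variant_id"], hset.dropped_log["reason"]))
        assert log["rs1"] == "strand_ambiguous"
        # kept by default
        assert sio.harmonize([t1, t2]).variant_ids.tolist() == ["rs1", "rs2"]

    def test_irreconcilable_alleles_dropped(self):
        t1 = make_table("a", ["rs1", "rs2"], ea=["A", "A"], oa=["G", "G"])
        t2 = make_table("b", ["rs1", "rs2"], ea=["A", "A"], oa=["C", "G"])
        hset = sio.harmonize([t1, t2])
        assert hset.variant_ids.tolist() == ["rs2"]
        log = dict(zip(hset.dropped_log["variant_id"], hset.dropped_log["reason"]))
        assert log["rs1"] == "allele_mismatch"

    def test_strand_complement_reconciled(self):
        # T/C on the other strand is A/G; effect allele T corresponds to A
        t1 = make_table("a", ["rs1", "rs2"], ea="A", oa="G", beta=0.1, eaf=0.3)
        t2 = make_table("b", ["rs1", "rs2"], ea="T", oa="C", beta=0.1, eaf=0.3)
        hset = sio.harmonize([t1, t2])
        np.testing.assert_allclose(hset.tables[1].records["beta"], 0.1)

    def test_eaf_mismatch_dropped(self):
        t1 = make_table("a", ["rs1", "rs2"], eaf=[0.1, 0.3])
        t2 = make_table("b", ["rs1", "rs2"], eaf=[0.5, 0.3])
        hset = sio.harmonize([t1, t2])
        assert hset.variant_ids.tolist() == ["rs2"]
        log = dict(zip(hset.dropped_log["variant_id"], hset.dropped_log["reason"]))
        assert log["rs1"] == "eaf_mismatch"

    def test_orientation_invariance(self):
        rng = np.random.default_rng(4)
        ids = [f"rs{i}" for i in range(20)]
        eaf = rng.uniform(0.05, 0.95, 20)
        beta = rng.normal(0, 0.05, 20)
        t1 = make_table("a", ids, eaf=eaf, beta=beta)
        t2 = make_table("b", ids, eaf=eaf + rng.normal(0, 0.01, 20), beta=beta)
        base = sio.harmonize([t1, t2])
        # flip every allele/beta/eaf of the second input
        flipped = t2.records.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        alt = sio.harmonize([t1, sio.SumstatsTable("b", flipped)])
        for tb, ta in zip(base.tables, alt.tables):
            pd.testing.assert_frame_equal(tb.records, ta.records)
        pd.testing.assert_frame_equal(base.dropped_log, alt.dropped_log)

    def test_output_and_dropped_log_disjoint(self):
        t1 = make_table("a", ["rs1", "rs2", "rs3"], eaf=[0.003, 0.3, 0.4])
        t2 = make_table("b", ["rs2", "rs3", "rs4"], eaf=[0.3, 0.4, 0.5])
        hset = sio.harmonize([t1, t2], maf_min=0.005)
        kept = set(hset.variant_ids)
        dropped = set(hset.dropped_log["variant_id"])
        assert kept.isdisjoint(dropped)
        assert dropped == {"rs1", "rs4"}

    def test_empty_intersection_is_input_error(self):
        t1 = make_table("a", ["rs1"])
        t2 = make_table("b", ["rs2"])
        with pytest.raises(sio.InputError):
            sio.harmonize([t1, t2])


class TestLDScores:
    def test_read_and_floor(self, tmp_path):
        path = tmp_path / "ld.txt"
        path.write_text("variant_id ld_score\nrs1 5.0\nrs2 0.2\n")
        panel = sio.read_ldscores(path, m=1000)
        assert panel.m == 1000
        assert panel.records["ld_score"].tolist() == [5.0, 1.0]

    def test_default_m_is_panel_size(self, tmp_path):
        path = tmp_path / "ld.txt"
        path.write_text("variant_id ld_score\nrs1 5.0\nrs2 2.0\n")
        assert sio.read_ldscores(path).m == 2
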