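"""Summary-statistics parsing, round-tripping and harmonization rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tsmr import (
    SummaryStatRecord,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)
from tsmr.gwas_io import ConfigError, EmptyInputError, EmptyOverlapError

from conftest import make_record


def _write(tmp_path, text, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "snp\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"


class TestRead:
    def test_well_formed_rows_parse_cleanly(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "rs1\t1\t100\ta\tg\t0.3\t0.1\t0.01\t1e-8\t10000\n"
            + "rs2\t2\t200\tC\tT\tNA\t-0.2\t0.02\t1e-6\tNA\n"
            + "rs3\t3\t300\tG\tA\t0.5\t0.05\t0.01\t0.5\t10000\n",
        )
        records, log = read_summary_stats(path)
        assert len(records) == 3 and log.n_dropped == 0
        assert records[0].effect_allele == "A"  # upper-cased
        assert records[1].eaf is None and records[1].n is None
        assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]

    def test_unparseable_se_row_dropped_with_reason(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.3\t0.1\tNA\t1e-8\t10000\n"
            + "rs2\t1\t200\tA\tG\t0.3\t0.1\t0.01\t1e-8\t10000\n",
        )
        records, log = read_summary_stats(path)
        assert [r.snp_id for r in records] == ["rs2"]
        assert log.n_dropped == 1 and "beta/se/pval" in log.drops[0][1]

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write(tmp_path, "snp\teffect_allele\tother_allele\tse\tpval\nrs1\tA\tG\t0.1\t0.5\n")
        with pytest.raises(ConfigError, match="beta"):
            read_summary_stats(path)

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(EmptyInputError):
            read_summary_stats(_write(tmp_path, HEADER))

    def test_column_map_resolves_nonstandard_headers(self, tmp_path):
        path = _write(
            tmp_path,
            "MarkerName\tA1\tA2\tEffect\tStdErr\tP\nrs1\tA\tG\t0.1\t0.01\t1e-8\n",
        )
        records, _ = read_summary_stats(
            path,
            column_map={
                "snp": "MarkerName",
                "effect_allele": "A1",
                "other_allele": "A2",
                "beta": "Effect",
                "se": "StdErr",
                "pval": "P",
            },
        )
        assert records[0].snp_id == "rs1" and records[0].beta == 0.1


class TestRoundTrip:
    def test_two_records_round_trip_exactly(self, tmp_path):
        records = [
            make_record("rs1", beta=0.123456789, se=0.01, pval=1e-8, chrom="1", pos=100,
                        eaf=0.3, n=50_000),
            make_record("rs2", "T", "C", beta=-0.2, se=0.5, pval=0.99),
        ]
        path = tmp_path / "out.tsv"
        write_summary_stats(records, path)
        back, log = read_summary_stats(path)
        assert back == records and log.n_dropped == 0

    def test_empty_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_summary_stats([], path)
        assert path.read_text().strip() == "\t".join(
            ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta",
             "se", "pval", "n"]
        )

    def test_missing_eaf_serialized_as_na(self, tmp_path):
        path = tmp_path / "na.tsv"
        write_summary_stats([make_record(eaf=None)], path)
        assert "\tNA\t" in path.read_text().splitlines()[1]
        back, _ = read_summary_stats(path)
        assert back[0].eaf is None


class TestHarmonize:
    def test_identical_alleles_kept_unchanged(self):
        h = harmonize([make_record(beta=0.1)], [make_record(beta=0.3, se=0.02)])
        assert h.beta_outcome[0] == 0.3
        assert h.provenance == [("rs1", "kept", "identical-alleles")]

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = make_record(effect_allele="A", other_allele="G")
        out = make_record(effect_allele="G", other_allele="A", beta=0.3, eaf=0.2)
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == pytest.approx(-0.3)
        assert h.provenance[0][1] == "sign-flipped"

    def test_strand_complement_resolved(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="T", other_allele="C", beta=0.3)
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == 0.3
        assert h.provenance[0][1] == "strand-flipped"

    @pytest.mark.parametrize(
        "eaf_exp,eaf_out,expected_reason",
        [
            (0.50, 0.30, "palindromic-ambiguous"),
            (0.30, 0.45, "palindromic-ambiguous"),
            (None, 0.30, "palindromic-missing-eaf"),
            (0.30, 0.70, "palindromic-strand-inconsistent"),
        ],
    )
    def test_palindromic_drop_rules(self, eaf_exp, eaf_out, expected_reason):
        exp = make_record(effect_allele="A", other_allele="T", eaf=eaf_exp)
        out = make_record(effect_allele="A", other_allele="T", beta=0.3, eaf=eaf_out)
        with pytest.raises(EmptyOverlapError):
            harmonize([exp], [out])
        # Reason is visible when another SNP keeps the set nonempty.
        keeper_exp = make_record("rs9")
        keeper_out = make_record("rs9", beta=0.1)
        h = harmonize([exp, keeper_exp], [out, keeper_out])
        assert (exp.snp_id, "dropped", expected_reason) in h.provenance

    def test_palindromic_unambiguous_kept(self):
        exp = make_record(effect_allele="A", other_allele="T", eaf=0.2)
        out = make_record(effect_allele="A", other_allele="T", beta=0.3, eaf=0.25)
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == 0.3

    def test_incompatible_alleles_dropped(self):
        exp = make_record(effect_allele="A", other_allele="G")
        out = make_record(effect_allele="A", other_allele="C", beta=0.3)
        keeper = make_record("rs9")
        h = harmonize([exp, keeper], [out, make_record("rs9", beta=0.1)])
        assert ("rs1", "dropped", "incompatible-alleles") in h.provenance

    def test_zero_overlap_raises(self):
        with pytest.raises(EmptyOverlapError):
            harmonize([make_record("rs1")], [make_record("rs2")])

    def test_conservation_every_overlap_snp_accounted(self):
        rng = np.random.default_rng(11)
        alleles = [("A", "G"), ("T", "C"), ("A", "T"), ("C", "G"), ("G", "A")]
        exp, out = [], []
        for i in range(20):
            ea, oa = alleles[i % len(alleles)]
            exp.append(make_record(f"rs{i}", ea, oa, eaf=float(rng.uniform(0.05, 0.95))))
            ea2, oa2 = alleles[rng.integers(len(alleles))]
            out.append(
                make_record(f"rs{i}", ea2, oa2, beta=0.2, eaf=float(rng.uniform(0.05, 0.95)))
            )
        h = harmonize(exp, out)
        kept = sum(1 for _, action, _ in h.provenance if action != "dropped")
        dropped = sum(1 for _, action, _ in h.provenance if action == "dropped")
        assert kept + dropped == 20
        assert kept == h.n_snp
        assert all(reason for _, action, reason in h.provenance if action == "dropped")

    def test_idempotent_on_already_harmonized_records(self):
        exp = [
            make_record("rs1", "A", "G", beta=0.1, eaf=0.3),
            make_record("rs2", "T", "C", beta=-0.2, eaf=0.6),
        ]
        out = [
            make_record("rs1", "G", "A", beta=0.3, eaf=0.7),
            make_record("rs2", "T", "C", beta=0.4, eaf=0.6),
        ]
        h1 = harmonize(exp, out)
        # Rebuild outcome records in the harmonized convention and re-run.
        out2 = [
            SummaryStatRecord(
                snp_id=s,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta=float(b),
                se=float(se),
                pval=0.5,
                eaf=None if np.isnan(f) else float(f),
            )
            for s, e, b, se, f in zip(
                h1.snp_ids, exp, h1.beta_outcome, h1.se_outcome, h1.eaf
            )
        ]
        h2 = harmonize(exp, out2)
        np.testing.assert_array_equal(h1.beta_outcome, h2.beta_outcome)
        np.testing.assert_array_equal(h1.beta_exposure, h2.beta_exposure)

    @given(st.integers(0, 2**31 - 1))
    def test_joint_allele_and_sign_flip_of_outcome_is_invariant(self, seed):
        rng = np.random.default_rng(seed)
        exp = [
            make_record(f"rs{i}", "A", "G", beta=float(rng.normal()), eaf=0.3)
            for i in range(5)
        ]
        out = [
            make_record(f"rs{i}", "A", "G", beta=float(rng.normal()), eaf=0.3)
            for i in range(5)
        ]
        flipped = [
            SummaryStatRecord(
                snp_id=r.snp_id,
                effect_allele=r.other_allele,
                other_allele=r.effect_allele,
                beta=-r.beta,
                se=r.se,
                pval=r.pval,
                eaf=None if r.eaf is None else 1 - r.eaf,
            )
            for r in out
        ]
        h1, h2 = harmonize(exp, out), harmonize(exp, flipped)
        np.testing.assert_allclose(h1.beta_outcome, h2.beta_outcome)
        np.testing.assert_allclose(h1.beta_exposure, h2.beta_exposure)
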