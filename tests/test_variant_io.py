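"""Parsing the four-column annotated variant table."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpriority import (
    ConfigurationError,
    ParseError,
    UnsupportedResidue,
    extract_depth,
    generate_fixture,
    parse_effect,
    parse_position,
    parse_variant_table,
)

HEADER = "Gene\tAmino_Acid_Position\tEffect\tEvidence\n"


def table_of(*rows):
    return io.StringIO(HEADER + "".join(f"{r}\n" for r in rows))


class TestParseEffect:
    @pytest.mark.parametrize(
        "effect, expected",
        [
            ("Val170Leu", ("V", 170, "L")),
            ("Ala5Ala", ("A", 5, "A")),  # synonymous
            ("p.Val170Leu", ("V", 170, "L")),
            ("missense_variant c.508G>C p.Val170Leu", ("V", 170, "L")),
            ("trp12gly", ("W", 12, "G")),  # case-insensitive codes
        ],
    )
    def test_extracts_last_substitution_token(self, effect, expected):
        assert parse_effect(effect) == expected

    def test_stop_codon_is_unsupported_not_a_parse_failure(self):
        with pytest.raises(UnsupportedResidue):
            parse_effect("p.Trp12Ter")

    @pytest.mark.parametrize("bad", ["", "frameshift", "170", "Val/Leu"])
    def test_no_substitution_token_raises(self, bad):
        with pytest.raises(ParseError):
            parse_effect(bad)


class TestParsePosition:
    @pytest.mark.parametrize(
        "text, expected", [("170/875", (170, 875)), ("1/1", (1, 1)), (" 3 / 10 ", (3, 10))]
    )
    def test_valid_positions(self, text, expected):
        assert parse_position(text) == expected

    @pytest.mark.parametrize("bad", ["900/875", "0/10", "abc", "5", "5/", "/10", "-1/10"])
    def test_invalid_positions_raise(self, bad):
        with pytest.raises(ParseError):
            parse_position(bad)


class TestExtractDepth:
    @pytest.mark.parametrize(
        "evidence, expected",
        [("45", 45.0), (" 12.5 ", 12.5), ("T:21 C:0", 21.0), ("A:300 G:12 T:1", 300.0)],
    )
    def test_bare_and_snippy_forms(self, evidence, expected):
        assert extract_depth(evidence) == expected

    def test_forced_snippy_format_rejects_bare_number(self):
        with pytest.raises(ParseError):
            extract_depth("45", evidence_format="snippy")

    def test_forced_bare_format_rejects_allele_tokens(self):
        with pytest.raises(ParseError):
            extract_depth("T:21 C:0", evidence_format="bare")

    @pytest.mark.parametrize("bad", ["n/a", "", "depth"])
    def test_non_numeric_evidence_raises(self, bad):
        with pytest.raises(ParseError):
            extract_depth(bad)


class TestParseVariantTable:
    def test_documented_example_row(self):
        table = parse_variant_table(table_of("gyrA\t170/875\tVal170Leu\t45"))
        (record,) = table.records
        assert record.gene == "gyrA"
        assert record.site == 170
        assert record.protein_length == 875
        assert (record.ref_residue, record.alt_residue) == ("V", "L")
        assert record.depth == 45.0

    def test_missing_required_column_is_fatal_and_named(self):
        stream = io.StringIO("Gene\tAmino_Acid_Position\tEffect\n" "gyrA\t1/2\tVal1Leu\n")
        with pytest.raises(ConfigurationError, match="Evidence"):
            parse_variant_table(stream)

    def test_header_only_file_is_fatal(self):
        with pytest.raises(ConfigurationError, match="no variants"):
            parse_variant_table(io.StringIO(HEADER))

    def test_unscoreable_rows_are_skipped_with_reasons_not_fatal(self):
        table = parse_variant_table(
            table_of(
                "gyrA\t170/875\tVal170Leu\t45",
                "rpoB\t12/300\tTrp12Ter\t20",       # stop gain
                "recA\t10/300\tVal11Leu\t20",       # effect/position disagree
                "dnaA\t5/300\tfs\t20",              # unparseable effect
            )
        )
        assert table.rows_read == 4
        assert table.rows_kept == 1
        assert table.rows_skipped == 3
        reasons = [s.reason for s in table.skipped]
        assert any("unsupported residue" in r for r in reasons)
        assert "position mismatch" in reasons

    def test_synonymous_rows_kept_by_default_skippable_on_request(self):
        rows = [
            f"geneA\t{i}/100\tVal{i}Leu\t{10 + i}" for i in range(1, 9)
        ] + ["geneB\t9/100\tAla9Ala\t5", "geneB\t10/100\tGly10Gly\t5"]
        kept_all = parse_variant_table(table_of(*rows))
        assert kept_all.rows_kept == 10 and kept_all.rows_skipped == 0

        skipped = parse_variant_table(table_of(*rows), skip_synonymous=True)
        assert skipped.rows_kept == 8
        assert [s.reason for s in skipped.skipped] == ["synonymous", "synonymous"]

    def test_extra_columns_are_preserved(self):
        stream = io.StringIO(
            "Gene\tAmino_Acid_Position\tEffect\tEvidence\tContig\n"
            "gyrA\t170/875\tVal170Leu\t45\tctg_1\n"
        )
        table = parse_variant_table(stream)
        assert table.extra_columns == ("Contig",)
        assert table.records[0].extras["Contig"] == "ctg_1"

    def test_column_map_remaps_nonstandard_headers(self):
        stream = io.StringIO("gene\tpos\tEffect\tEvidence\ngyrA\t170/875\tVal170Leu\t45\n")
        table = parse_variant_table(
            stream, column_map={"gene": "Gene", "pos": "Amino_Acid_Position"}
        )
        assert table.rows_kept == 1

    def test_csv_dialect_detected_from_extension(self, tmp_path):
        path = tmp_path / "variants.csv"
        path.write_text(generate_fixture(5, seed=3, dialect="csv"), encoding="utf-8")
        table = parse_variant_table(path)
        assert table.dialect == "csv"
        assert table.rows_kept == 5


class TestGenerateFixture:
    def test_round_trips_without_skips(self, make_table):
        table = parse_variant_table(make_table(n=25, seed=7))
        assert table.rows_read == table.rows_kept == 25
        assert table.rows_skipped == 0

    def test_determinism_under_fixed_seed(self):
        assert generate_fixture(50, seed=11) == generate_fixture(50, seed=11)
        assert generate_fixture(50, seed=11) != generate_fixture(50, seed=12)

    def test_degenerate_depth_range(self):
        table = parse_variant_table(io.StringIO(generate_fixture(20, (30, 30), seed=1)))
        assert {r.depth for r in table.records} == {30.0}

    def test_snippy_evidence_variant_parses_identically(self):
        bare = parse_variant_table(io.StringIO(generate_fixture(10, seed=5)))
        snippy = parse_variant_table(
            io.StringIO(generate_fixture(10, seed=5, snippy_evidence=True))
        )
        assert [r.depth for r in bare.records] == [r.depth for r in snippy.records]

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture(0)
        with pytest.raises(ValueError):
            generate_fixture(5, depth_range=(100, 10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(1, 60), seed=st.integers(0, 2**20))
    def test_counts_conserved_and_order_preserved(self, n, seed):
        table = parse_variant_table(
            io.StringIO(generate_fixture(n, seed=seed, synonymous_fraction=0.3))
        )
        assert table.rows_read == table.rows_kept + table.rows_skipped
        indices = [r.row_index for r in table.records]
        assert indices == sorted(indices)
        for record in table.records:
            # effect string and position column agree on the site
            assert parse_effect(record.raw_effect)[1] == record.site
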