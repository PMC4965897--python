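"""Flat-file parsing, annotation profiles, and the cached KEGG fetcher."""

import io
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reverse_ecology.errors import (
    ConnectivityError,
    FormatError,
    LookupError_,
    ParseError,
)
from reverse_ecology.kegg_io import (
    AnnotationProfile,
    ReactionRecord,
    fetch_org_metabolic_data,
    load_ko_reaction_map,
    parse_annotation_profile,
    parse_reaction_flatfile,
    reactions_for_profile,
    write_reaction_flatfile,
)

TEN_ENTRY_FIXTURE = """\
ENTRY       R00001
EQUATION    C00031 => C00022
///
ENTRY       R00002
EQUATION    C00022 + C00003 <=> C00024 + C00004
///
ENTRY       R00003
EQUATION    2 C00002 -> C00008 + C00020
///
ENTRY       R00004
EQUATION    C00009 + C00031 <=> C00103
///
ENTRY       R00005
EQUATION    c00041 => c00133
///
ENTRY       R00006
EQUATION    (n+1) C00404 + C00001 <=> n C02174
///
ENTRY       R00007
EQUATION    C00019 + C00082 => C00021 +
            C91000
///
ENTRY       R00008
EQUATION    C00036 -> C00011 + C00074
///
ENTRY       R00009
EQUATION    C00117 <=> C00119
///
ENTRY       R00010
EQUATION    C00668 + C00002 => C00085 + C00008
///
"""

# hand enumeration of the fixture above (before implementation)
TEN_ENTRY_EXPECTED = {
    "R00001": ({"C00031"}, {"C00022"}, False),
    "R00002": ({"C00022", "C00003"}, {"C00024", "C00004"}, True),
    "R00003": ({"C00002"}, {"C00008", "C00020"}, False),
    "R00004": ({"C00009", "C00031"}, {"C00103"}, True),
    "R00005": ({"C00041"}, {"C00133"}, False),
    "R00006": ({"C00404", "C00001"}, {"C02174"}, True),
    "R00007": ({"C00019", "C00082"}, {"C00021", "C91000"}, False),
    "R00008": ({"C00036"}, {"C00011", "C00074"}, False),
    "R00009": ({"C00117"}, {"C00119"}, True),
    "R00010": ({"C00668", "C00002"}, {"C00085", "C00008"}, False),
}


class TestReactionFlatfile:
    def test_single_irreversible_entry(self):
        recs = parse_reaction_flatfile(
            io.StringIO("ENTRY       R1\nEQUATION    C00031 => C00022\n///\n")
        )
        assert recs == [
            ReactionRecord("R1", frozenset({"C00031"}), frozenset({"C00022"}), False)
        ]

    def test_reversible_arrow_maps_to_two_by_two_record(self):
        recs = parse_reaction_flatfile(
            io.StringIO(
                "ENTRY       R1\nEQUATION    C00022 + C00003 <=> C00024 + C00004\n///\n"
            )
        )
        (rec,) = recs
        assert len(rec.substrates) == 2 and len(rec.products) == 2
        assert rec.reversible

    def test_ten_entry_fixture_matches_hand_enumeration(self):
        recs = parse_reaction_flatfile(io.StringIO(TEN_ENTRY_FIXTURE))
        assert len(recs) == 10
        got = {r.reaction_id: (set(r.substrates), set(r.products), r.reversible)
               for r in recs}
        assert got == TEN_ENTRY_EXPECTED

    @pytest.mark.parametrize("default,expected", [(True, True), (False, False)])
    def test_directionless_equation_uses_configured_default(self, default, expected):
        recs = parse_reaction_flatfile(
            io.StringIO("ENTRY       R1\nEQUATION    C00001 = C00002\n///\n"),
            default_reversible=default,
        )
        assert recs[0].reversible is expected

    def test_empty_stream_gives_empty_list(self):
        assert parse_reaction_flatfile(io.StringIO("")) == []

    def test_missing_equation_is_a_parse_error_naming_the_entry(self):
        with pytest.raises(ParseError, match="R0077"):
            parse_reaction_flatfile(io.StringIO("ENTRY       R0077\n///\n"))

    def test_missing_arrow_is_a_parse_error_with_line(self):
        with pytest.raises(ParseError, match=r"entry R1, line \d"):
            parse_reaction_flatfile(
                io.StringIO("ENTRY       R1\nEQUATION    C00001 C00002\n///\n")
            )

    def test_compound_on_both_sides_is_flagged_not_dropped(self):
        text = "ENTRY       R1\nEQUATION    C00001 + C00002 => C00001\n///\n"
        with pytest.warns(UserWarning, match="R1"):
            recs = parse_reaction_flatfile(io.StringIO(text))
        assert recs[0].shared_compounds == {"C00001"}

    def test_no_record_has_empty_sides(self):
        for rec in parse_reaction_flatfile(io.StringIO(TEN_ENTRY_FIXTURE)):
            assert rec.substrates and rec.products

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.builds(
                ReactionRecord,
                reaction_id=st.from_regex(r"R[0-9]{5}", fullmatch=True),
                substrates=st.frozensets(
                    st.from_regex(r"C[0-9]{5}", fullmatch=True), min_size=1, max_size=3
                ),
                products=st.frozensets(
                    st.from_regex(r"D[0-9]{5}", fullmatch=True), min_size=1, max_size=3
                ),
                reversible=st.booleans(),
            ),
            max_size=8,
        )
    )
    def test_flatfile_round_trip(self, records):
        buf = io.StringIO()
        write_reaction_flatfile(records, buf)
        buf.seek(0)
        reparsed = parse_reaction_flatfile(buf)
        assert sorted(reparsed, key=lambda r: r.reaction_id) == sorted(
            records, key=lambda r: r.reaction_id
        )


ANNOTATION_20_ROWS = "gene_id\tko_id\n" + "".join(
    f"g{i:03d}\tK{ko:05d}\n"
    for i, ko in enumerate(
        # 20 rows, 12 distinct KO terms (hand-written manifest)
        [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6, 1, 2]
    )
)


class TestAnnotationProfile:
    def test_duplicate_ko_rows_collapse(self):
        prof = parse_annotation_profile(
            io.StringIO("gene_id\tko_id\ng1\tK00001\ng2\tK00001\n"), "org"
        )
        assert prof.ko_terms == {"K00001"}
        assert prof.gene_count == 2

    def test_twenty_row_fixture_has_twelve_distinct_terms(self):
        prof = parse_annotation_profile(io.StringIO(ANNOTATION_20_ROWS), "org")
        assert len(prof.ko_terms) == 12
        assert prof.gene_count == 20

    def test_empty_table_refused_downstream(self):
        prof = parse_annotation_profile(io.StringIO("gene_id\tko_id\n"), "org")
        assert prof.ko_terms == frozenset()
        with pytest.raises(FormatError, match="no KO terms"):
            reactions_for_profile(prof, {}, {})

    def test_missing_ko_column_is_a_format_error(self):
        with pytest.raises(FormatError, match="KO column"):
            parse_annotation_profile(io.StringIO("gene_id\tname\ng1\tfoo\n"))

    def test_profile_maps_to_reactions_through_ko_map(self):
        prof = AnnotationProfile("org", frozenset({"K00001", "K00002"}), 2)
        ko_map = load_ko_reaction_map(
            io.StringIO("ko_id\treaction_id\nK00001\tR1\nK00002\tR2\nK00002\tR3\n")
        )
        db = {
            rid: ReactionRecord(rid, frozenset({"A"}), frozenset({"B"}), False)
            for rid in ("R1", "R2", "R3", "R4")
        }
        recs = reactions_for_profile(prof, ko_map, db)
        assert [r.reaction_id for r in recs] == ["R1", "R2", "R3"]


UNREACHABLE = "http://127.0.0.1:1"


class TestFetchWithCache:
    def _seed_cache(self, cache_dir: Path, org: str) -> None:
        d = cache_dir / org
        d.mkdir(parents=True)
        (d / "reactions.txt").write_text(TEN_ENTRY_FIXTURE)

    def test_seeded_cache_equals_direct_parse_without_network(self, tmp_path):
        self._seed_cache(tmp_path, "eco")
        recs = fetch_org_metabolic_data("eco", tmp_path, base_url=UNREACHABLE)
        assert recs == parse_reaction_flatfile(io.StringIO(TEN_ENTRY_FIXTURE))

    def test_warm_cache_is_idempotent(self, tmp_path):
        self._seed_cache(tmp_path, "eco")
        first = fetch_org_metabolic_data("eco", tmp_path, base_url=UNREACHABLE)
        second = fetch_org_metabolic_data("eco", tmp_path, base_url=UNREACHABLE)
        assert first == second

    def test_empty_org_code_is_a_lookup_error(self, tmp_path):
        with pytest.raises(LookupError_):
            fetch_org_metabolic_data("", tmp_path, base_url=UNREACHABLE)

    def test_no_cache_and_no_network_is_a_connectivity_error(self, tmp_path):
        with pytest.raises(ConnectivityError):
            fetch_org_metabolic_data(
                "eco", tmp_path, base_url=UNREACHABLE, timeout=0.5
            )
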