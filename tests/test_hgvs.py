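import pytest

from tprtchar.hgvs import (
    apply_c_description,
    classify_frame,
    name_insertion,
    name_transcript_effect,
    render_summary,
)


def test_name_insertion_dup_dialect(paper, fixture_set):
    rec = paper.per_case["UAB-R340101"]
    c = fixture_set.case("UAB-R340101")
    desc = name_insertion(rec["call"], rec["classification"], c.map)
    assert desc == "c.4319_4320insAluYb8, 4305_4319dupAAAAGAAGAACATAT"


def test_name_insertion_delins(paper, fixture_set):
    rec = paper.per_case["UAB-R119201"]
    c = fixture_set.case("UAB-R119201")
    desc = name_insertion(rec["call"], rec["classification"], c.map)
    assert desc == "c.1186-86_1186-16delinsAluY"


def test_name_insertion_nontemplated_segment(paper, fixture_set):
    rec = paper.per_case["UAB-R316001"]
    c = fixture_set.case("UAB-R316001")
    desc = name_insertion(rec["call"], rec["classification"], c.map)
    assert "insTGTGAATT" in desc
    assert desc.startswith("c.3048_3049")


def test_strict_mode_spells_full_insert(paper, fixture_set):
    rec = paper.per_case["UAB-R340101"]
    c = fixture_set.case("UAB-R340101")
    desc = name_insertion(rec["call"], rec["classification"], c.map, strict=True)
    assert rec["call"].inserted_seq in desc


def test_name_apply_roundtrip_all_tsd_fixtures(paper, fixture_set):
    for c in fixture_set:
        rec = paper.per_case[c.case_id]
        call = rec["call"]
        if call.tsd_length == 0 and call.target_deletion_length == 0:
            continue
        desc = name_insertion(call, rec["classification"], c.map)
        rebuilt = apply_c_description(desc, c.reference_allele, c.map, call.inserted_seq)
        assert rebuilt == c.mutant_allele


def test_transcript_effect_strings():
    assert name_transcript_effect([{"lost": (2851, 2990), "gained": []}]) == "r.2851_2990del"
    assert (
        name_transcript_effect(
            [{"lost": (6859, 6999), "gained": []}, {"lost": (6938, 6999), "gained": []}]
        )
        == "r.[6859_6999del;6938_6999del]"
    )
    assert (
        name_transcript_effect([{"lost": (1355, 1392), "gained": [("element", 61)]}])
        == "r.1355_1392delins61"
    )
    with pytest.raises(ValueError):
        name_transcript_effect([])


@pytest.mark.parametrize(
    "lost,gained,expected",
    [
        ((2851, 2990), [], ("OOF", -140)),
        ((1186, 1260), [], ("IF", -75)),
        ((889, 1062), [("element", 130)], ("OOF", -44)),
    ],
)
def test_classify_frame(lost, gained, expected):
    assert classify_frame([{"lost": lost, "gained": gained}]) == expected


def test_render_summary_shapes(paper):
    assert len(paper.summary) == 18
    empty = render_summary([])
    assert len(empty) == 0 and "case_id" in empty.columns


def test_summary_tallies_self_consistent(paper):
    fam = paper.summary["family"].value_counts().to_dict()
    assert fam == paper.family_tallies
    alu = paper.summary[paper.summary["family"].str.startswith("Alu")]
    assert alu["orientation"].value_counts().to_dict() == paper.orientation_tallies
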