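import numpy as np
import pytest

from tprtchar.classifier import (
    classify,
    classify_family,
    detect_inversion,
    l1_subset,
    measure_truncation,
)
from tprtchar.fastaio import revcomp


def test_exact_consensus_zero_distance(library):
    cls = classify_family(library["AluYa5"].sequence, library)
    assert cls.family == "AluYa5"
    assert cls.per_family_distance["AluYa5"] == 0


def test_polyT_body_is_polyN(library):
    assert classify_family("T" * 120, library).family == "polyN"


def test_empty_library_rejected():
    from tprtchar.elements import ElementLibrary

    with pytest.raises(ValueError):
        classify_family("ACGT" * 20, ElementLibrary())


def test_strand_symmetry(library):
    rng = np.random.default_rng(2)
    for name in ("AluY", "AluYa5", "AluYb8"):
        body = library[name].sequence
        fwd = classify_family(body, library)
        rev = classify_family(revcomp(body), library)
        assert fwd.family == rev.family == name
        assert fwd.strand != rev.strand


def test_substitutions_bounded_distance(library):
    rng = np.random.default_rng(3)
    tpl = library["AluYb8"].sequence
    for k in (1, 4, 9):
        body = list(tpl)
        sites = rng.choice(len(body), size=k, replace=False)
        for s in sites:
            body[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[body[s]]
        cls = classify_family("".join(body), library)
        assert cls.per_family_distance["AluYb8"] <= k


def test_truncation_full_length_zero(library):
    assert measure_truncation(library["AluY"].sequence + "A" * 60, library["AluY"], "+") == 0


def test_truncation_fixture_39(fixture_set, paper):
    rec = paper.per_case["UAB-R869001"]
    assert rec["classification"].truncation_offset == 39
    assert rec["classification"].family == "AluYb8"


def test_simulated_truncation_recovery(sim_recovery):
    checked = 0
    for _, _, truth, call, cls in sim_recovery:
        if truth.inversion:
            continue
        assert cls.truncation_offset == truth.truncation_offset
        checked += 1
    assert checked > 100


def test_detect_inversion_negative(library):
    flag, junction, micro = detect_inversion(
        library["L1"].sequence[200:2000] + "A" * 80, library["L1"]
    )
    assert flag is False and junction is None and micro == 0


def test_detect_inversion_forced_two(library):
    from tprtchar.simulator import simulate_inverted_l1

    body, info = simulate_inverted_l1(library["L1"], np.random.default_rng(4), microhomology=2)
    flag, junction, micro = detect_inversion(body + "A" * 100, library["L1"])
    assert flag is True
    assert micro == 2
    assert junction == info["junction"]


def test_detect_inversion_batch_junction_recovery(library):
    from tprtchar.simulator import simulate_inverted_l1

    rng = np.random.default_rng(8)
    for _ in range(15):
        body, info = simulate_inverted_l1(library["L1"], rng)
        flag, junction, micro = detect_inversion(body, library["L1"])
        assert flag
        assert junction == info["junction"]
        assert micro == info["micro"]


def test_l1_subset_preTa_fixture(paper):
    assert paper.per_case["UAB-R316001"]["classification"].l1_subset == "preTa"


def test_l1_subset_truncated_Ta(library):
    tpl = library["L1"]
    body = tpl.sequence[5000:]  # truncated upstream of the site, still covering it
    assert l1_subset(body, tpl) == "Ta"


def test_l1_subset_site_not_covered(library):
    tpl = library["L1"]
    assert l1_subset(tpl.sequence[:4000], tpl) == "n/a"


def test_family_tie_reported_unknown(library):
    # a chimera equally distant from two subfamilies must not pick a side
    from tprtchar.elements import ElementLibrary, ElementTemplate

    lib = ElementLibrary()
    lib.templates["A1"] = ElementTemplate("A1", "A1", "ACGT" * 30)
    lib.templates["A2"] = ElementTemplate("A2", "A2", "ACGT" * 30)
    cls = classify_family("ACGT" * 30, lib)
    assert cls.family == "unknown"
    assert cls.per_family_distance["A1"] == cls.per_family_distance["A2"]


def test_nontemplated_extraction(paper):
    assert paper.per_case["UAB-R316001"]["call"].nontemplated_5prime == "TGTGAATT"
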