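import pytest
from hypothesis import given
from hypothesis import strategies as st

from tprtchar.characterizer import (
    NoVariantError,
    find_variant_interval,
    infer_orientation,
    measure_poly_tail,
    resolve_tsd,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


def test_interval_simple_insertion():
    assert find_variant_interval("AAATTTCCC", "AAAGGTTTCCC") == (3, 3, 3, 5)


def test_interval_identical_raises():
    with pytest.raises(NoVariantError):
        find_variant_interval("ACGT", "ACGT")


@given(dna, dna, st.data())
def test_interval_prefix_suffix_property(ref, ins, data):
    p = data.draw(st.integers(min_value=0, max_value=len(ref)))
    mut = ref[:p] + ins + ref[p:]
    if mut == ref:
        return
    a, r_right, m_left, m_right = find_variant_interval(ref, mut)
    assert ref[:a] == mut[:a]
    assert ref[r_right:] == mut[m_right:]
    # minimal replacement: applying it reproduces the mutant
    assert ref[:a] + mut[m_left:m_right] + ref[r_right:] == mut


def test_resolve_tsd_fixture_r340101(fixture_set):
    c = fixture_set.case("UAB-R340101")
    call = resolve_tsd(c.reference_allele, c.mutant_allele, library=fixture_set.library)
    assert call.tsd_seq == "AAAAGAAGAACATAT"
    assert call.tsd_length == 15


def test_resolve_tsd_fixture_r119201_deletion(fixture_set):
    c = fixture_set.case("UAB-R119201")
    call = resolve_tsd(c.reference_allele, c.mutant_allele, library=fixture_set.library)
    assert call.tsd_length == 0
    assert call.target_deletion_length == 71


def test_resolve_no_repeated_flank():
    ref = "ACGTACGTGGGG" + "CCCCTTTTACGT"
    mut = ref[:12] + "GAGAGAGAGA" + ref[12:]
    call = resolve_tsd(ref, mut)
    assert call.tsd_length == 0
    assert call.inserted_seq == "GAGAGAGAGA"


def test_resolve_maximality_without_library():
    """Without an element library the longest textual duplication wins, and
    extending it by one base breaks the duplication property (brute-force
    check over all equivalent placements)."""
    import numpy as np

    rng = np.random.default_rng(9)
    for _ in range(20):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        p = int(rng.integers(50, 250))
        L = int(rng.integers(5, 15))
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        mut = ref[:p] + body + ref[p - L : p] + ref[p:]
        call = resolve_tsd(ref, mut)
        assert call.apply(ref) == mut
        # brute-force maximal dup over every valid decomposition
        best = 0
        a, r_right, m_left, m_right = find_variant_interval(ref, mut)
        ins, q = mut[m_left:m_right], a
        while True:
            k = 0
            while k < min(q, len(ins)) and ref[q - 1 - k] == ins[len(ins) - 1 - k]:
                k += 1
            best = max(best, k)
            if q == 0 or not ins or ref[q - 1] != ins[-1]:
                break
            ins = ref[q - 1] + ins[:-1]
            q -= 1
        assert call.tsd_length == best


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("G" * 30 + "A" * 120, ("A-at-3'", 120)),
        ("ACGT", ("none", 0)),
        ("T" * 80 + "G" * 30, ("T-at-5'", 80)),
        ("T" * 15 + "G" * 30 + "A" * 40, ("T-at-5'", 15)),  # 5' poly(T) dominates
    ],
)
def test_measure_poly_tail(seq, expected):
    assert measure_poly_tail(seq) == expected


def test_measure_poly_tail_impurity():
    seq = "G" * 30 + "A" * 50 + "G" + "A" * 50
    kind, length = measure_poly_tail(seq, impurity=0.02)
    assert kind == "A-at-3'" and length == 101
    assert measure_poly_tail(seq, impurity=0.0) == ("A-at-3'", 50)


def test_orientation_pure_polyT_antisense(fixture_set):
    from tprtchar.characterizer import characterize

    c = fixture_set.case("UAB-R75103")
    call, cls = characterize(c.reference_allele, c.mutant_allele, fixture_set.library)
    assert call.orientation == "antisense"
    assert cls.family == "polyN"


def test_orientation_tailless_unmatched_undetermined(library):
    call_or = infer_orientation("GACGATCGAT" * 4, ("none", 0), None)
    assert call_or == "undetermined"


def test_fixture_reconstruction_bit_exact(paper):
    recon = paper.assertions.query("check == 'reconstruction'")
    assert len(recon) == 18
    assert recon["pass"].all()
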