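import numpy as np
import pytest

from tprtchar.fastaio import revcomp
from tprtchar.simulator import (
    NoSiteError,
    SimulationConfig,
    draw_l1_category,
    emit_dataset,
    pick_insertion_site,
    simulate_insertion,
    simulate_inverted_l1,
)
from tprtchar.sites import scan_en_sites, score_en_site


def test_pick_perfect_site_only():
    # top-strand TTAAAA = perfect consensus for a bottom-strand nick
    ref = "G" * 40 + "TTAAAA" + "G" * 40
    rng = np.random.default_rng(0)
    b, strand = pick_insertion_site(ref, rng, min_en_score=6)
    assert (b, strand) == (42, "bottom")


def test_pick_no_site():
    with pytest.raises(NoSiteError):
        pick_insertion_site("G" * 100, np.random.default_rng(0), min_en_score=4)


def test_pick_sites_pass_rescan_oracle():
    rng = np.random.default_rng(1)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10000))
    for _ in range(25):
        b, strand = pick_insertion_site(ref, rng, min_en_score=5)
        assert score_en_site(ref, b, strand).matches >= 5


def test_forced_full_length_sense_arithmetic(library):
    config = SimulationConfig(
        tsd_length_range=(12, 12),
        polyA_length_range=(100, 100),
        l1_category_probs=(1.0, 0.0, 0.0),
        alu_truncation_prob=0.0,
        target_deletion_prob=0.0,
        nontemplated_addition_prob=0.0,
        seed=3,
    )
    rng = np.random.default_rng(3)
    template = library["AluYa5"]
    for _ in range(10):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        try:
            mutant, truth = simulate_insertion(ref, template, config, rng)
        except (NoSiteError, RuntimeError):
            continue
        if truth.orientation != "sense":
            continue
        assert len(mutant) == len(ref) + 12 + len(template.sequence) + 100
        p = truth.insertion_point
        # the 12 nt preceding the element equal the 12 nt that follow the tail
        ins_len = truth.inserted_length
        assert mutant[p - 12 : p] == mutant[p + ins_len : p + ins_len + 12] == truth.tsd_seq
        return
    pytest.skip("no sense event drawn in 10 attempts")


def test_antisense_leading_polyT(library):
    config = SimulationConfig(target_deletion_prob=0.0, nontemplated_addition_prob=0.0, seed=11)
    rng = np.random.default_rng(11)
    template = library["AluY"]
    seen = False
    for _ in range(20):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        try:
            mutant, truth = simulate_insertion(ref, template, config, rng)
        except (NoSiteError, RuntimeError):
            continue
        if truth.orientation != "antisense":
            continue
        p = truth.insertion_point
        insert = mutant[p : p + truth.inserted_length]
        assert insert.startswith("T" * truth.polyA_length)
        assert revcomp(template.sequence) in insert
        seen = True
        break
    assert seen


def test_inverted_l1_forced_microhomology(library):
    template = library["L1"]
    rng = np.random.default_rng(5)
    body, info = simulate_inverted_l1(template, rng, microhomology=2)
    assert info["micro"] == 2
    j, f = info["junction"]
    assert j - f == 2
    # junction flanks share exactly the 2-nt overlap with the template
    tpl = template.sequence
    assert tpl[f : j] == tpl[f : f + 2]


def test_inverted_l1_zero_microhomology_partitions(library):
    template = library["L1"]
    rng = np.random.default_rng(6)
    body, info = simulate_inverted_l1(template, rng, microhomology=0)
    j, f = info["junction"]
    assert j == f
    a = info["rc_start"]
    rc_len = j - a
    assert body == revcomp(template.sequence[a:j]) + template.sequence[f:]
    assert len(body) == rc_len + (len(template.sequence) - f)


def test_inversion_undo_oracle(library):
    # reconstructing the template segments from the recorded geometry
    template = library["L1"]
    rng = np.random.default_rng(7)
    tpl = template.sequence
    for _ in range(10):
        body, info = simulate_inverted_l1(template, rng)
        j, f = info["junction"]
        a = info["rc_start"]
        # the inverted segment covers template [a, j), the forward segment
        # [f, end); on the body they abut, overlapping by micro on the template
        assert revcomp(body[: j - a]) == tpl[a:j]
        assert body[len(body) - (len(tpl) - f) :] == tpl[f:]
        assert info["micro"] == max(0, j - f)


def test_emit_dataset_deterministic(tmp_path, library):
    config = SimulationConfig(seed=42, reference_length=1500)
    p1 = emit_dataset(5, config, tmp_path / "a", library=library)
    p2 = emit_dataset(5, config, tmp_path / "b", library=library)
    for a, b in zip(p1, p2):
        assert a.read_bytes() == b.read_bytes()


def test_emit_dataset_single_record(tmp_path, library):
    from tprtchar.fastaio import read_fasta

    _, muts, _ = emit_dataset(1, SimulationConfig(seed=1, reference_length=1500),
                              tmp_path / "one", library=library)
    assert len(read_fasta(muts)) == 1
    with pytest.raises(ValueError):
        emit_dataset(0, SimulationConfig(seed=1), tmp_path / "zero", library=library)


def test_conservation_and_ranges(sim_events):
    """Replay oracle: every truth row reproduces its mutant, and all drawn
    lengths respect the configured ranges."""
    config = SimulationConfig()
    for reference, mutant, t in sim_events:
        if t.target_deletion_length:
            rebuilt = (
                reference[: t.site_offset]
                + mutant[t.site_offset : t.site_offset + t.inserted_length]
                + reference[t.site_offset + t.target_deletion_length :]
            )
            assert t.tsd_length == 0
        else:
            p = t.insertion_point
            insert = mutant[p : p + t.inserted_length]
            rebuilt = reference[:p] + insert + t.tsd_seq + reference[p:]
            lo, hi = config.tsd_length_range
            assert lo <= t.tsd_length <= hi
        assert rebuilt == mutant
        lo, hi = config.polyA_length_range
        assert lo <= t.polyA_length <= hi


def test_category_probs_validate():
    with pytest.raises(ValueError):
        SimulationConfig(l1_category_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(tsd_length_range=(9, 3))


def test_l1_category_sampling_unbiased():
    config = SimulationConfig()
    rng = np.random.default_rng(123)
    n = 10000
    draws = [draw_l1_category(rng, config) for _ in range(n)]
    p = config.l1_category_probs[0]
    se = (p * (1 - p) / n) ** 0.5
    frac = draws.count("full_length") / n
    assert abs(frac - p) <= 3 * se
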