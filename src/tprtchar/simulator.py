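"""Synthetic TPRT (target-primed reverse transcription) products.

Generates mutant/reference allele pairs with exact ground truth: an
element copy with a poly(A) (sense) or leading poly(T) (antisense)
tail, flanked by a target-site duplication drawn from the configured
range, optionally 5'-truncated or 5'-inverted (twin priming), with
optional non-templated 5' additions and deletion-associated insertions
that lack a TSD.

Every event is constructed so that its TruthRecord is the *canonical*
description of the edit: sites or draws that would make the textual
decomposition ambiguous (e.g. an A immediately 5' of a sense-strand
TSD, which would let the duplication absorb a tail base) are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .elements import ElementLibrary, ElementTemplate, default_library
from .classifier import _inversion_info
from .fastaio import revcomp, write_fasta
from .sites import scan_en_sites

L1_CATEGORIES = ("full_length", "truncated", "inverted")


class NoSiteError(RuntimeError):
    """No qualifying EN site in the reference."""


@dataclass
class SimulationConfig:
    tsd_length_range: Tuple[int, int] = (7, 20)
    polyA_length_range: Tuple[int, int] = (60, 178)
    l1_category_probs: Tuple[float, float, float] = (0.255, 0.438, 0.307)
    alu_truncation_prob: float = 0.08
    target_deletion_prob: float = 0.05
    target_deletion_range: Tuple[int, int] = (10, 100)
    nontemplated_addition_prob: float = 0.05
    nontemplated_length_range: Tuple[int, int] = (1, 10)
    polyA_impurity: float = 0.0
    min_en_score: int = 4
    element_probs: Dict[str, float] = field(
        default_factory=lambda: {"AluY": 0.2, "AluYa5": 0.4, "AluYb8": 0.2, "L1": 0.2}
    )
    reference_length: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.l1_category_probs) - 1.0) > 1e-9:
            raise ValueError("l1_category_probs must sum to 1")
        for lo, hi in (self.tsd_length_range, self.polyA_length_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        for p in (
            self.alu_truncation_prob,
            self.target_deletion_prob,
            self.nontemplated_addition_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("tsd_length_range", "polyA_length_range", "target_deletion_range",
                    "nontemplated_length_range", "l1_category_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthRecord:
    case_id: str
    site_offset: int  # first-nick boundary, reference coordinates
    strand: str  # top | bottom (nicked strand)
    orientation: str  # sense | antisense
    element: str
    tsd_length: int
    tsd_seq: str
    target_deletion_length: int
    truncation_offset: int
    inversion: bool
    inversion_junction: Optional[Tuple[int, int]]
    microhomology_length: int
    polyA_length: int
    nontemplated_5prime: str
    insertion_point: int  # canonical point after the first duplicated copy
    inserted_length: int


def draw_l1_category(rng: np.random.Generator, config: SimulationConfig) -> str:
    return L1_CATEGORIES[rng.choice(3, p=list(config.l1_category_probs))]


def pick_insertion_site(
    reference: str, rng: np.random.Generator, min_en_score: int
) -> Tuple[int, str]:
    """Uniformly choose a nick boundary whose EN score passes the floor."""
    sites = scan_en_sites(reference, min_score=min_en_score)
    # keep clear of the ends so flanks always exist for TSD/deletion draws
    sites = [s for s in sites if 20 <= s.nick_position <= len(reference) - 20]
    if not sites:
        raise NoSiteError(f"no EN site scoring >= {min_en_score}")
    s = sites[rng.integers(len(sites))]
    return s.nick_position, s.strand


def simulate_inverted_l1(
    template: ElementTemplate,
    rng: np.random.Generator,
    microhomology: Optional[int] = None,
) -> Tuple[str, dict]:
    """Twin-priming product: rc of an internal 5' segment + forward 3' segment.

    The recorded junction and microhomology follow the maximal-overlap
    convention (the identical junction overlap assignable to either
    segment), so detection on the constructed body recovers them
    exactly.  A requested microhomology is honored by rejection.
    """
    n = len(template.sequence)
    if n < 200:
        raise ValueError("template too short for twin priming")
    for _ in range(200):
        mh = int(microhomology) if microhomology is not None else int(rng.integers(0, 5))
        j = int(rng.integers(max(mh + 100, n // 3), n - 150))
        rc_len = int(rng.integers(100, min(j, 2500)))
        a = j - rc_len
        f = j - mh
        body = revcomp(template.sequence[a:j]) + template.sequence[f:]
        info = _inversion_info(body, template)
        if info is None:
            continue
        realized = info["micro"]
        if microhomology is not None and realized != mh:
            continue
        info["rc_start"] = min(info["rc_start"], a)
        return body, info
    raise RuntimeError("could not realize the requested inversion geometry")


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _draw_body(
    template: ElementTemplate, config: SimulationConfig, rng: np.random.Generator
) -> Tuple[str, int, bool, Optional[Tuple[int, int]], int]:
    """Element body (element orientation, no tail) plus truth fields."""
    seq = template.sequence
    if template.family == "L1":
        category = draw_l1_category(rng, config)
        if category == "inverted":
            body, info = simulate_inverted_l1(template, rng)
            trunc = min(info["rc_start"], info["fwd_start"])
            return body, trunc, True, info["junction"], info["micro"]
        if category == "truncated":
            trunc = int(rng.integers(1, len(seq) - 200))
            return seq[trunc:], trunc, False, None, 0
        return seq, 0, False, None, 0
    if rng.random() < config.alu_truncation_prob:
        trunc = int(rng.integers(1, max(2, len(seq) - 100)))
        return seq[trunc:], trunc, False, None, 0
    return seq, 0, False, None, 0


def _tail(config: SimulationConfig, rng: np.random.Generator) -> str:
    lo, hi = config.polyA_length_range
    length = int(rng.integers(lo, hi + 1))
    tail = ["A"] * length
    if config.polyA_impurity > 0:
        for i in range(length):
            if rng.random() < config.polyA_impurity:
                tail[i] = "CGT"[rng.integers(3)]
    return "".join(tail)


def simulate_insertion(
    reference: str,
    template: ElementTemplate,
    config: SimulationConfig,
    rng: np.random.Generator,
    case_id: str = "sim",
) -> Tuple[str, TruthRecord]:
    """One TPRT event on ``reference``; returns (mutant, truth)."""
    for _ in range(200):
        b, strand = pick_insertion_site(reference, rng, config.min_en_score)
        orientation = "sense" if strand == "bottom" else "antisense"
        body, trunc, inv, junction, micro = _draw_body(template, config, rng)
        tail = _tail(config, rng)

        # template base that would extend the body's 5' end by one: a TSD
        # terminus equal to it makes the drawn decomposition non-canonical
        # (the element would parse as one base less truncated)
        seq = template.sequence
        if inv and junction is not None and junction[0] < len(seq):
            ext5 = revcomp(seq[junction[0]])
        elif not inv and trunc > 0:
            ext5 = seq[trunc - 1]
        else:
            ext5 = None

        nt = ""
        if rng.random() < config.nontemplated_addition_prob:
            lo, hi = config.nontemplated_length_range
            nt = _rand_bases(rng, int(rng.integers(lo, hi + 1)))

        if rng.random() < config.target_deletion_prob:
            lo, hi = config.target_deletion_range
            d = int(rng.integers(lo, hi + 1))
            if b + d + 20 > len(reference):
                continue
            if orientation == "sense":
                insert = nt + body + tail
            else:
                insert = revcomp(nt + body + tail)
            if reference[b] == insert[0] or reference[b + d - 1] == insert[-1]:
                continue
            mutant = reference[:b] + insert + reference[b + d :]
            truth = TruthRecord(
                case_id=case_id, site_offset=b, strand=strand,
                orientation=orientation, element=template.name,
                tsd_length=0, tsd_seq="", target_deletion_length=d,
                truncation_offset=trunc, inversion=inv,
                inversion_junction=junction, microhomology_length=micro,
                polyA_length=len(tail), nontemplated_5prime=nt,
                insertion_point=b, inserted_length=len(insert),
            )
            return mutant, truth

        lo, hi = config.tsd_length_range
        L = int(rng.integers(lo, hi + 1))
        if orientation == "sense":
            # first nick (bottom strand) at b; TSD is reference[b : b+L]
            p = b + L
            insert = nt + body + tail
            if b + L + 20 > len(reference):
                continue
            if reference[b - 1] == insert[-1]:
                continue  # duplication would absorb the tail terminus
            if reference[p] == insert[0]:
                continue  # canonical point would shift right
            tsd = reference[b:p]
            if ext5 is not None and tsd[-1] == ext5:
                continue  # element would parse as less truncated
        else:
            # first nick (top strand) at b; TSD is reference[b-L : b]
            p = b
            insert = revcomp(nt + body + tail)
            if b - L < 20:
                continue
            if reference[b] == insert[0]:
                continue  # canonical point would shift right
            if reference[b - L - 1] == insert[-1]:
                continue  # duplication would absorb the element/NT terminus
            tsd = reference[b - L : b]
            if ext5 is not None and tsd[0] == revcomp(ext5):
                continue  # element would parse as less truncated
        mutant = reference[:p] + insert + tsd + reference[p:]
        truth = TruthRecord(
            case_id=case_id, site_offset=b, strand=strand,
            orientation=orientation, element=template.name,
            tsd_length=L, tsd_seq=tsd, target_deletion_length=0,
            truncation_offset=trunc, inversion=inv,
            inversion_junction=junction, microhomology_length=micro,
            polyA_length=len(tail), nontemplated_5prime=nt,
            insertion_point=p, inserted_length=len(insert),
        )
        return mutant, truth
    raise RuntimeError("could not place an unambiguous event (200 attempts)")


def simulate_dataset(
    n: int,
    config: SimulationConfig,
    library: Optional[ElementLibrary] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[str, str, TruthRecord]]:
    """n independent events, each on its own random reference."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if library is None:
        library = default_library()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(config.element_probs)
    probs = np.array([config.element_probs[k] for k in names], dtype=float)
    probs /= probs.sum()
    out = []
    for i in range(n):
        template = library[names[rng.choice(len(names), p=probs)]]
        for _ in range(50):
            reference = _rand_bases(rng, config.reference_length)
            try:
                mutant, truth = simulate_insertion(
                    reference, template, config, rng, case_id=f"sim{i:05d}"
                )
                break
            except (NoSiteError, RuntimeError):
                continue
        else:
            raise RuntimeError("reference redraw limit reached")
        out.append((reference, mutant, truth))
    return out


def emit_dataset(
    n: int,
    config: SimulationConfig,
    out_prefix: str,
    library: Optional[ElementLibrary] = None,
) -> Tuple[Path, Path, Path]:
    """Write references/mutants FASTA plus a truth TSV; deterministic per seed."""
    events = simulate_dataset(n, config, library=library)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ref_path = prefix.with_suffix(".refs.fa")
    mut_path = prefix.with_suffix(".muts.fa")
    truth_path = prefix.with_suffix(".truth.tsv")
    write_fasta([(t.case_id, r) for r, _, t in events], ref_path)
    write_fasta([(t.case_id, m) for _, m, t in events], mut_path)
    rows = []
    for _, _, t in events:
        row = asdict(t)
        row["inversion_junction"] = (
            "" if t.inversion_junction is None
            else f"{t.inversion_junction[0]}:{t.inversion_junction[1]}"
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return ref_path, mut_path, truth_path
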