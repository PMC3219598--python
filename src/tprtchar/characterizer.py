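"""Compare a mutant allele against its reference allele.

Locates the minimal variant interval, resolves the target-site
duplication (TSD) or target-site deletion, measures the poly(A)/poly(T)
tail and infers the insert orientation.

Breakpoint placement for a TPRT insertion is textually ambiguous
whenever the insert shares sequence with its flanks (poly(A) tails next
to A-rich duplications, element termini equal to flank bases).  The
canonical call is *element-anchored*: among all equivalent
decompositions ``reference[:q] + body + dup + reference[q:]`` the one is
chosen whose body best matches an element template (smallest edit
distance, then least truncation plus non-templated junk, then the
longest duplication).  The insertion point is then reported after the
first duplicated copy, and HGVS-style 3'-shifting is never applied to
the element body.  Without a template library the longest duplication
wins outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .classifier import (
    ElementClassification,
    classify,
    classify_family,
    locate_body,
    trim_tails,
)
from .elements import ElementLibrary
from .fastaio import revcomp

MIN_TAIL_RUN = 10
_MAX_SHIFT = 400
_K_WINDOW = 6


class NoVariantError(ValueError):
    """Reference and mutant alleles are identical."""


@dataclass
class InsertionCall:
    """A resolved insertion (or deletion-associated insertion) event.

    ``left_break``/``right_break`` delimit the replaced reference
    interval (0-based half-open; empty for a pure insertion).  The
    mutant allele is reconstructed as
    ``reference[:left_break] + inserted_seq + tsd_seq + reference[right_break:]``.
    """

    left_break: int
    right_break: int
    inserted_seq: str
    tsd_seq: str = ""
    target_deletion_length: int = 0
    poly_tail_kind: str = "none"  # A-at-3' | T-at-5' | none
    poly_tail_length: int = 0
    orientation: str = "undetermined"  # sense | antisense | undetermined
    nontemplated_5prime: str = ""
    tentative: bool = False
    warnings: List[str] = field(default_factory=list)

    @property
    def tsd_length(self) -> int:
        return len(self.tsd_seq)

    def apply(self, reference: str) -> str:
        return (
            reference[: self.left_break]
            + self.inserted_seq
            + self.tsd_seq
            + reference[self.right_break :]
        )


def find_variant_interval(reference: str, mutant: str) -> Tuple[int, int, int, int]:
    """Minimal replacement interval between two alleles.

    Returns ``(ref_left, ref_right, mut_left, mut_right)`` where the
    maximal common prefix ends at ``ref_left == mut_left`` and the
    maximal common suffix (clamped to not overlap the prefix) starts at
    ``ref_right``/``mut_right``.
    """
    if reference == mutant:
        raise NoVariantError("alleles are identical")
    n, m = len(reference), len(mutant)
    a = 0
    limit = min(n, m)
    while a < limit and reference[a] == mutant[a]:
        a += 1
    b = 0
    while b < limit - a and reference[n - 1 - b] == mutant[m - 1 - b]:
        b += 1
    return a, n - b, a, m - b


def _dup_len(reference: str, q: int, insert: str) -> int:
    """Longest reference suffix ending at q that also ends the insert."""
    k = 0
    limit = min(q, len(insert))
    while k < limit and reference[q - 1 - k] == insert[len(insert) - 1 - k]:
        k += 1
    return k


def _candidate_placements(reference: str, q0: int, insert0: str):
    """Yield (q, insert) decompositions, shifting left from the maximal-
    prefix placement while the flank permits."""
    q, ins = q0, insert0
    for _ in range(_MAX_SHIFT):
        yield q, ins
        if q == 0 or not ins or reference[q - 1] != ins[-1]:
            break
        ins = reference[q - 1] + ins[:-1]
        q -= 1


def resolve_tsd(
    reference: str,
    mutant: str,
    interval: Optional[Tuple[int, int, int, int]] = None,
    library: Optional[ElementLibrary] = None,
) -> InsertionCall:
    """Resolve TSD and canonical breakpoints for one allele pair."""
    if interval is None:
        interval = find_variant_interval(reference, mutant)
    ref_left, ref_right, mut_left, mut_right = interval
    inserted = mutant[mut_left:mut_right]

    if ref_right > ref_left:  # replacement: target deletion, no TSD
        return InsertionCall(
            left_break=ref_left,
            right_break=ref_right,
            inserted_seq=inserted,
            tsd_seq="",
            target_deletion_length=ref_right - ref_left,
            tentative=True,
        )

    q0 = ref_left
    template = strand = None
    inverted_probe = False
    if library is not None:
        k0 = _dup_len(reference, q0, inserted)
        probe = classify_family(inserted[: len(inserted) - k0] or inserted, library)
        if probe.family not in ("polyN", "unknown"):
            template = library[probe.family]
            core, lead_t, trail_a = trim_tails(inserted)
            if lead_t and not trail_a:
                strand = "-"
            elif trail_a and not lead_t:
                strand = "+"
            else:
                strand = probe.strand
            if template.family == "L1":
                from .classifier import _inversion_info

                oriented0 = revcomp(core) if strand == "-" else core
                inverted_probe = _inversion_info(trim_tails(oriented0)[0], template) is not None

    best = None
    seen = set()
    aln_memo = {}
    for q, ins in _candidate_placements(reference, q0, inserted):
        k_max = _dup_len(reference, q, ins)
        k_lo = 0 if template is not None else k_max
        for k in range(k_max, k_lo - 1, -1):
            body = ins[: len(ins) - k] if k else ins
            key = (body, k)
            if key in seen:
                continue
            seen.add(key)
            if template is not None:
                core, _, _ = trim_tails(body)
                oriented = revcomp(core) if strand == "-" else core
                if oriented in aln_memo:
                    dist, junk, start = aln_memo[oriented]
                else:
                    dist, junk, start, _ = locate_body(oriented, template.sequence)
                    aln_memo[oriented] = (dist, junk, start)
                # for twin-priming bodies the inverted 5' part leaves no
                # exact anchor: the located start is alignment noise, so
                # only the distance (then the dup length) discriminates
                fit = 0 if inverted_probe else junk + start
                score = (dist, fit, -k, -q)
            else:
                score = (0, 0, -k, -q)
            if best is None or score < best[0]:
                best = (score, q, k, body)

    _, q, k, body = best
    return InsertionCall(
        left_break=q,
        right_break=q,
        inserted_seq=body,
        tsd_seq=reference[q - k : q] if k else "",
    )


def measure_poly_tail(
    inserted_seq: str, min_run: int = MIN_TAIL_RUN, impurity: float = 0.0
) -> Tuple[str, int]:
    """Longest 3' poly(A) or 5' poly(T) run of the inserted sequence.

    With a nonzero impurity fraction, the run may contain up to that
    fraction of other bases but must terminate on the run base.  A
    5' poly(T) (antisense tail) dominates when both are present.
    """
    if not inserted_seq:
        return "none", 0

    def longest_run(seq: str, base: str) -> int:
        best = mism = 0
        for i, ch in enumerate(seq, start=1):
            if ch != base:
                mism += 1
            if ch == base and mism <= impurity * i:
                best = i
        return best

    t5 = longest_run(inserted_seq, "T")
    a3 = longest_run(inserted_seq[::-1], "A")
    if t5 >= min_run:
        return "T-at-5'", t5
    if a3 >= min_run:
        return "A-at-3'", a3
    return "none", 0


def infer_orientation(
    inserted_seq: str,
    tail: Tuple[str, int],
    classification: Optional[ElementClassification] = None,
) -> str:
    """Orientation from the tail, confirmed (or supplied) by alignment."""
    kind, _ = tail
    by_tail = {"T-at-5'": "antisense", "A-at-3'": "sense"}.get(kind)
    by_aln = None
    if classification is not None and classification.family not in ("polyN", "unknown"):
        by_aln = "sense" if classification.strand == "+" else "antisense"
    if by_tail and by_aln and by_tail != by_aln and not (
        classification is not None and classification.inversion
    ):
        return "undetermined"
    return by_tail or by_aln or "undetermined"


def characterize(
    reference: str,
    mutant: str,
    library: Optional[ElementLibrary] = None,
    tail_impurity: float = 0.0,
) -> Tuple[InsertionCall, Optional[ElementClassification]]:
    """Full characterization of one reference/mutant allele pair."""
    interval = find_variant_interval(reference, mutant)
    call = resolve_tsd(reference, mutant, interval, library)
    tail = measure_poly_tail(call.inserted_seq, impurity=tail_impurity)
    call.poly_tail_kind, call.poly_tail_length = tail
    cls = classify(call.inserted_seq, library) if library is not None else None
    call.orientation = infer_orientation(call.inserted_seq, tail, cls)
    if cls is not None:
        call.nontemplated_5prime = cls.nontemplated_5prime
    if call.orientation == "undetermined" and (cls is None or cls.family == "unknown"):
        call.warnings.append("orientation undetermined")
    return call, cls
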