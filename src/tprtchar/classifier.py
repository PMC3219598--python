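"""Classify inserted element bodies against the template library.

The body handed in is the inserted sequence in top-strand orientation,
free of target-site duplication copies (see ``characterizer``).  Family
assignment is by global-style alignment (edlib, infix mode so that 5'
truncation is not penalized) against each template on both strands;
truncation, non-templated 5' additions, twin-priming inversions and the
L1 Ta/pre-Ta subset are read off the located alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import edlib

from .elements import ElementLibrary, ElementTemplate, L1_SUBSET_CODES
from .fastaio import revcomp

POLYN_FRACTION = 0.9
MIN_BODY_LEN = 20
MIN_TAIL_RUN = 10

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ElementClassification:
    family: str
    strand: str = "+"
    per_family_distance: Dict[str, int] = field(default_factory=dict)
    truncation_offset: int = 0
    inversion: bool = False
    inversion_junction: Optional[Tuple[int, int]] = None
    microhomology_length: int = 0
    l1_subset: str = "n/a"
    nontemplated_5prime: str = ""
    diagnostic_votes: Dict[str, int] = field(default_factory=dict)


def trim_tails(body: str, min_run: int = MIN_TAIL_RUN) -> Tuple[str, int, int]:
    """Strip a leading poly(T) and/or trailing poly(A) run of >= min_run.

    Returns (core, leading_t, trailing_a).
    """
    lead = len(body) - len(body.lstrip("T"))
    if lead < min_run:
        lead = 0
    trail = len(body) - len(body.rstrip("A"))
    if trail < min_run or lead + trail >= len(body):
        trail = 0
    return body[lead : len(body) - trail if trail else len(body)], lead, trail


def _is_polyn(seq: str) -> bool:
    if not seq:
        return True
    top = max(seq.count(b) for b in "ACGT")
    return top / len(seq) >= POLYN_FRACTION


def locate_body(
    core: str, template: str, probe_len: int = 20, max_scan: int = 64
) -> Tuple[int, int, int, int]:
    """Align core within template (infix mode, truncations free).

    Returns ``(distance, junk, trunc, end)``: edit distance, length of
    the unaligned (non-templated) query prefix, first and one-past-last
    template positions covered.  The non-templated prefix is anchored by
    the first exact ``probe_len``-mer shared with the template (the
    alignment alone cannot distinguish a short random 5' addition from a
    run of mismatches); a prefix that matches its implied template
    context after all is treated as aligned, not non-templated.
    """
    res = edlib.align(core, template, mode="HW", task="path")
    dist = res["editDistance"]
    start, end = res["locations"][0]
    junk = 0
    m = _CIGAR_RE.match(res["cigar"] or "")
    if m and m.group(2) == "I":
        junk = int(m.group(1))
    if len(core) >= probe_len:
        for i in range(0, min(max_scan, len(core) - probe_len) + 1):
            pos = template.find(core[i : i + probe_len])
            if pos < 0:
                continue
            junk, start = i, pos
            if 0 < i <= pos:
                context = template[pos - i : pos]
                matched = sum(a == b for a, b in zip(core[:i], context))
                if matched >= 0.7 * i:
                    junk, start = 0, pos - i
            break
    return dist, junk, start, end + 1


def classify_family(
    body: str, library: ElementLibrary, min_body_len: int = MIN_BODY_LEN
) -> ElementClassification:
    """Assign a family by alignment distance over both strands.

    Homopolymer-dominated bodies are ``polyN``; distance ties between
    families give ``unknown`` (both distances stay reported).
    """
    if len(library) == 0:
        raise ValueError("empty element library")
    core, lead_t, trail_a = trim_tails(body)
    if len(core) < min_body_len:
        fam = "polyN" if _is_polyn(body) else "unknown"
        strand = "-" if lead_t else "+"
        return ElementClassification(family=fam, strand=strand)
    if _is_polyn(core):
        return ElementClassification(family="polyN", strand="-" if lead_t else "+")

    distances: Dict[str, int] = {}
    strands: Dict[str, str] = {}
    for tpl in library:
        d_f = edlib.align(core, tpl.sequence, mode="HW")["editDistance"]
        d_r = edlib.align(revcomp(core), tpl.sequence, mode="HW")["editDistance"]
        if d_f <= d_r:
            distances[tpl.family], strands[tpl.family] = d_f, "+"
        else:
            distances[tpl.family], strands[tpl.family] = d_r, "-"
    best = min(distances.values())
    winners = [f for f, d in distances.items() if d == best]
    if len(winners) > 1:
        return ElementClassification(family="unknown", per_family_distance=distances)
    fam = winners[0]
    return ElementClassification(
        family=fam, strand=strands[fam], per_family_distance=distances
    )


def measure_truncation(body: str, template: ElementTemplate, strand: str) -> int:
    """Missing 5' bases of the element relative to its template."""
    core, _, _ = trim_tails(body)
    if strand == "-":
        core = revcomp(core)
    _, _, start, _ = locate_body(core, template.sequence)
    return start


def extract_nontemplated(body: str, template: ElementTemplate, strand: str) -> str:
    """Non-templated 5' addition: unaligned element-orientation prefix."""
    core, _, _ = trim_tails(body)
    if strand == "-":
        core = revcomp(core)
    _, junk, _, _ = locate_body(core, template.sequence)
    return core[:junk]


def _kmer_index(template: str, k: int) -> Dict[str, list]:
    index: Dict[str, list] = {}
    for i in range(len(template) - k + 1):
        index.setdefault(template[i : i + k], []).append(i)
    return index


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _inversion_info(core: str, template: ElementTemplate, k: int = 21, stride: int = 7):
    """Anchor-based twin-priming geometry for an element-orientation body.

    A twin-priming body is ``rc(tpl[a:j]) + tpl[f:b]``: a reverse-
    complemented internal segment followed by a forward segment running
    to the template 3' end, overlapping on the template by the junction
    microhomology ``j - f`` when positive.  Body position ``i`` inside
    the inverted part maps to template position ``j - 1 - i``, so any
    reverse-orientation k-mer anchor at (body ``i``, template ``x``)
    fixes ``j = x + i + k``.
    """
    tpl = template.sequence
    if len(core) < 2 * k:
        return None
    index = _kmer_index(tpl, k)
    anchors = []  # (body_pos, 'F'/'R', template_pos)
    for i in range(0, len(core) - k + 1, stride):
        kmer = core[i : i + k]
        if kmer in index:
            anchors.append((i, "F", index[kmer][0]))
        else:
            hits = index.get(revcomp(kmer))
            if hits:
                anchors.append((i, "R", hits[0]))
    kinds = {kind for _, kind, _ in anchors}
    if kinds != {"F", "R"}:
        return None
    last_r = max(a for a in anchors if a[1] == "R")
    first_f = min(a for a in anchors if a[1] == "F")
    if last_r[0] > first_f[0]:
        return None
    j = last_r[2] + last_r[0] + k  # template end (exclusive) of the rc segment

    # forward segment: extend its first anchor leftwards (maximal overlap)
    bi, f = first_f[0], first_f[2]
    while bi > 0 and f > 0 and core[bi - 1] == tpl[f - 1]:
        bi -= 1
        f -= 1
    # rc segment: extend rightwards in the body (downwards in the template)
    i = last_r[0] + k
    while i < len(core) and j - 1 - i >= 0 and core[i] == _COMP[tpl[j - 1 - i]]:
        i += 1
    a = j - i  # deepest template position reached by the inverted part
    micro = max(0, j - f)
    return {"junction": (j, f), "micro": micro, "rc_start": a, "fwd_start": f}


def detect_inversion(
    body: str, template: ElementTemplate, k: int = 21, stride: int = 7
) -> Tuple[bool, Optional[Tuple[int, int]], int]:
    """Detect a twin-priming 5' inversion.

    Returns ``(flag, (rc_segment_end, forward_segment_start),
    microhomology_length)`` in template coordinates.  The microhomology
    is the maximal identical junction overlap assignable to either
    segment.
    """
    core, _, _ = trim_tails(body)
    info = _inversion_info(core, template, k=k, stride=stride)
    if info is None:
        return False, None, 0
    return True, info["junction"], info["micro"]


def l1_subset(body: str, template: ElementTemplate, strand: str = "+") -> str:
    """Type the L1 Ta/pre-Ta subset from the diagnostic trinucleotide."""
    if template.l1_subset_site is None:
        return "n/a"
    core, _, _ = trim_tails(body)
    if strand == "-":
        core = revcomp(core)
    site = template.l1_subset_site
    probe = template.sequence[site - 20 : site]
    idx = core.find(probe)
    if idx < 0:
        return "n/a"
    triple = core[idx + 20 : idx + 23]
    return L1_SUBSET_CODES.get(triple, "n/a")


def diagnostic_votes(core: str, library: ElementLibrary, trunc: int, junk: int) -> Dict[str, int]:
    """Count matches at each family's diagnostic sites, assuming the
    co-linear placement implied by (truncation, non-templated prefix)."""
    votes: Dict[str, int] = {}
    for tpl in library:
        if not tpl.diagnostic_sites:
            continue
        n = 0
        for pos, base in tpl.diagnostic_sites:
            bi = junk + (pos - trunc)
            if 0 <= bi < len(core) and core[bi] == base:
                n += 1
        votes[tpl.family] = n
    return votes


def classify(body: str, library: ElementLibrary) -> ElementClassification:
    """Full classification driver for one body."""
    cls = classify_family(body, library)
    if cls.family in ("polyN", "unknown"):
        return cls
    tpl = library[cls.family]
    core, lead_t, trail_a = trim_tails(body)
    # A tail pins the strand: a leading poly(T) is a reverse-complemented
    # poly(A).  For 5'-inverted bodies the alignment alone is ambiguous
    # (both orientations are part-forward, part-reverse).
    if lead_t and not trail_a:
        cls.strand = "-"
    elif trail_a and not lead_t:
        cls.strand = "+"
    oriented = revcomp(core) if cls.strand == "-" else core
    dist, junk, start, end = locate_body(oriented, tpl.sequence)
    cls.nontemplated_5prime = oriented[:junk]
    cls.truncation_offset = start
    cls.diagnostic_votes = diagnostic_votes(oriented, library, start, junk)
    if cls.family == "L1":
        info = _inversion_info(trim_tails(oriented)[0], tpl)
        if info is not None:
            cls.inversion = True
            cls.inversion_junction = info["junction"]
            cls.microhomology_length = info["micro"]
            cls.truncation_offset = min(info["rc_start"], info["fwd_start"])
        cls.l1_subset = l1_subset(oriented, tpl, "+")
    return cls
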