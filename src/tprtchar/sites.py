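"""Integration-site analysis against the L1 endonuclease consensus.

The L1 EN consensus cleavage site is 3'-AA/TTTT-5' on the nicked
strand.  On a top-strand sequence with a nick at boundary ``b``
(between ``seq[b-1]`` and ``seq[b]``):

* bottom-strand nick: the consensus asks for TT immediately left of the
  boundary and AAAA immediately right (top-strand reading);
* top-strand nick: AA immediately right and TTTT immediately left.

Scores are strict 0-6 match counts; the paper applies no numeric
cutoff, so none is hard-coded here — callers may flag sites >= a
reporting threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .characterizer import InsertionCall
from .fastaio import revcomp
from .genemodel import CoordinateError, GeneLayout

EN_CONSENSUS = "AATTTT"  # 3'->5' on the nicked strand: AA / TTTT


@dataclass(frozen=True)
class ENSiteScore:
    nick_position: int
    strand: str  # top | bottom
    matches: int
    motif_window: str  # the six scored nt, 3'->5' on the nicked strand


@dataclass
class SiteAnnotation:
    region: str  # exonic | intronic
    feature_kind: str  # exon | intron
    feature_index: int
    feature_label: str
    distance_to_acceptor: Optional[int]
    distance_to_donor: Optional[int]
    splice_region_class: str  # canonical-AG | polypyrimidine-tract | none


@dataclass
class RecurrenceReport:
    groups: List[dict]
    n_distinct_sites: int
    n_multiply_used: int
    grouping_window: int


@dataclass
class ClusterReport:
    windows: List[dict]
    window_bp: int
    min_count: int


def _matches(observed: str, expected: str) -> int:
    return sum(1 for o, e in zip(observed, expected) if o == e)


def score_en_site(sequence: str, nick_position: int, strand: str) -> ENSiteScore:
    """Score one putative nick against the EN cleavage consensus."""
    b = nick_position
    if strand == "bottom":
        if b - 2 < 0 or b + 4 > len(sequence):
            raise CoordinateError(f"EN window around {b} out of range")
        n = _matches(sequence[b - 2 : b], "TT") + _matches(sequence[b : b + 4], "AAAA")
        window = complement(sequence[b - 2 : b + 4])
    elif strand == "top":
        if b - 4 < 0 or b + 2 > len(sequence):
            raise CoordinateError(f"EN window around {b} out of range")
        n = _matches(sequence[b : b + 2], "AA") + _matches(sequence[b - 4 : b], "TTTT")
        window = sequence[b - 4 : b + 2][::-1]
    else:
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")
    return ENSiteScore(nick_position=b, strand=strand, matches=n, motif_window=window)


def complement(seq: str) -> str:
    return revcomp(seq)[::-1]


def scan_en_sites(sequence: str, min_score: int = 0) -> List[ENSiteScore]:
    """Score every boundary on both strands; keep scores >= min_score."""
    out: List[ENSiteScore] = []
    for b in range(4, len(sequence) - 3):
        for strand in ("bottom", "top"):
            try:
                s = score_en_site(sequence, b, strand)
            except CoordinateError:
                continue
            if s.matches >= min_score:
                out.append(s)
    return out


def infer_nick(call: InsertionCall) -> Tuple[int, str, bool]:
    """Nick position and nicked strand for a resolved call.

    Sense-oriented inserts arise from a bottom-strand first nick at the
    left TSD boundary; antisense inserts from a top-strand nick at the
    right TSD boundary (the reported insertion point).  Deletion-
    associated calls get a tentative assignment at the deletion start.
    Returns ``(nick_position, strand, tentative)`` in call coordinates.
    """
    if call.target_deletion_length > 0:
        strand = "top" if call.orientation == "antisense" else "bottom"
        return call.left_break, strand, True
    if call.orientation == "sense":
        return call.left_break - call.tsd_length, "bottom", False
    if call.orientation == "antisense":
        return call.left_break, "top", False
    return call.left_break, "bottom", True


def annotate_site(
    layout: GeneLayout,
    position: int,
    end: Optional[int] = None,
    acceptor_window: Tuple[int, int] = (3, 20),
) -> SiteAnnotation:
    """Annotate an insertion point (boundary) or replaced interval.

    ``position`` is a genomic boundary for pure insertions; for
    deletion-associated events pass the replaced interval as
    ``[position, end)``.  The 3'-splice-region call is canonical-AG when
    the event interrupts the intron-terminal AG, polypyrimidine-tract
    when any affected intronic base lies within ``acceptor_window``
    (intron positions -3..-20 by default) of an acceptor.
    """
    if end is None:
        affected = [position - 1, position]  # the two bases flanking the boundary
        boundary = True
    else:
        affected = list(range(position, end))
        boundary = False
    pos_c = [layout.c(g) for g in affected]

    exonic = [p for p in pos_c if p.intron_offset == 0]
    if boundary and len(exonic) == 2:
        exon = layout.model.exon_of(pos_c[1].base)
        return SiteAnnotation(
            region="exonic",
            feature_kind="exon",
            feature_index=exon.index,
            feature_label=exon.label,
            distance_to_acceptor=pos_c[1].base - exon.c_start,
            distance_to_donor=exon.c_end - pos_c[0].base,
            splice_region_class="none",
        )
    if not boundary and all(p.intron_offset == 0 for p in pos_c):
        exon = layout.model.exon_of(pos_c[0].base)
        return SiteAnnotation(
            region="exonic",
            feature_kind="exon",
            feature_index=exon.index,
            feature_label=exon.label,
            distance_to_acceptor=pos_c[0].base - exon.c_start,
            distance_to_donor=exon.c_end - pos_c[-1].base,
            splice_region_class="none",
        )

    # intronic (possibly boundary-spanning) event
    intronic = [p for p in pos_c if p.intron_offset != 0]
    anchor = intronic[0] if intronic else pos_c[0]
    exon = layout.model.exon_of(anchor.base)
    if anchor.intron_offset > 0:
        intron_index = exon.index
    else:
        intron_index = exon.index - 1
    lo, hi = acceptor_window
    offsets = [p.intron_offset for p in intronic if p.intron_offset < 0]
    splice_class = "none"
    if boundary:
        # insertion between -1 and the exon, or inside the terminal AG
        if any(p.intron_offset == 0 for p in pos_c) and offsets and max(offsets) == -1:
            splice_class = "canonical-AG"
        elif offsets and any(o in (-1, -2) for o in offsets) and (
            -1 in offsets and -2 in offsets
        ):
            splice_class = "canonical-AG"
        elif offsets and any(-hi <= o <= -lo for o in offsets):
            splice_class = "polypyrimidine-tract"
    else:
        if any(o in (-1, -2) for o in offsets):
            splice_class = "canonical-AG"
        elif any(-hi <= o <= -lo for o in offsets):
            splice_class = "polypyrimidine-tract"

    donor_exon_end = layout.model.exon(intron_index).c_end
    acceptor_exon_start = layout.model.exon(intron_index + 1).c_start
    g_donor = layout.g(type(anchor)(donor_exon_end))
    g_acceptor = layout.g(type(anchor)(acceptor_exon_start))
    intron = layout.model.exon(intron_index)
    return SiteAnnotation(
        region="intronic",
        feature_kind="intron",
        feature_index=intron_index,
        feature_label=f"{intron_index} ({intron.legacy_label})",
        distance_to_acceptor=g_acceptor - affected[-1],
        distance_to_donor=affected[0] - g_donor,
        splice_region_class=splice_class,
    )


def find_recurrent_sites(
    calls: Sequence[Tuple[str, int]], grouping_window: int = 12
) -> RecurrenceReport:
    """Group nick positions within one EN motif locus (strand-agnostic).

    ``calls`` are ``(case_id, nick_position)`` in a shared coordinate
    frame; positions chained within ``grouping_window`` bp form one
    group.
    """
    if not calls:
        raise ValueError("no calls to group")
    ordered = sorted(calls, key=lambda c: (c[1], c[0]))
    groups: List[dict] = []
    current = [ordered[0]]
    for item in ordered[1:]:
        if item[1] - current[-1][1] <= grouping_window:
            current.append(item)
        else:
            groups.append(current)
            current = [item]
    groups.append(current)
    out = [
        {
            "case_ids": [c[0] for c in g],
            "representative": g[0][1],
            "span": g[-1][1] - g[0][1],
            "size": len(g),
        }
        for g in groups
    ]
    return RecurrenceReport(
        groups=out,
        n_distinct_sites=len(out),
        n_multiply_used=sum(1 for g in out if g["size"] > 1),
        grouping_window=grouping_window,
    )


def find_clusters(
    calls: Sequence[Tuple[str, int]],
    window_bp: int = 1500,
    min_count: int = 3,
) -> ClusterReport:
    """Greedy left-to-right maximal windows holding >= min_count calls."""
    ordered = sorted(calls, key=lambda c: (c[1], c[0]))
    positions = [c[1] for c in ordered]
    windows: List[dict] = []
    i, n = 0, len(ordered)
    while i < n:
        j = i
        while j + 1 < n and positions[j + 1] - positions[i] <= window_bp:
            j += 1
        if j - i + 1 >= min_count:
            windows.append(
                {
                    "start": positions[i],
                    "end": positions[j],
                    "case_ids": [c[0] for c in ordered[i : j + 1]],
                    "size": j - i + 1,
                }
            )
            i = j + 1
        else:
            i += 1
    return ClusterReport(windows=windows, window_bp=window_bp, min_count=min_count)
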