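"""Reconstruction of the 18 published insertion cases as fixtures.

Each case is rebuilt from the machine-readable transcription of the
published per-case truth (integration-site flanking windows, TSD/dup
strings, element families, orientations, truncations, transcript
effects).  A synthetic mini-gene genome carries the published local
sequences: the 12+24-nt integration-site windows are embedded at their
mapped positions on a seeded random background, exon boundaries come
from the published r.-level intervals, and each case's reference allele
is a ~2.4-kb slice around its integration site.  The mutant allele is
the reference with the full TPRT product applied: TSD copy, optional
non-templated 5' addition, the (possibly truncated or 5'-inverted,
reverse-complemented when antisense) element body, and the tail.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .elements import ElementLibrary, default_library
from .fastaio import revcomp
from .genemodel import CoordinateMap, CPosition, GeneLayout, GeneModel, parse_c_interval

_COMPLEMENT_ONLY = str.maketrans("ACGTN", "TGCAN")

DEFAULT_TAIL = 100  # nt, for tails printed without an exact estimate
SLICE_FLANK = 1200


class FixtureBuildError(RuntimeError):
    pass


@dataclass
class FixtureCase:
    case_id: str
    row: int
    location: str
    reference_allele: str
    mutant_allele: str
    map: CoordinateMap
    truth: Dict

    def __repr__(self) -> str:  # keep test output readable
        return f"FixtureCase({self.case_id}, row {self.row})"


@dataclass
class FixtureSet:
    cases: List[FixtureCase]
    layout: GeneLayout
    genome: str
    library: ElementLibrary

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> FixtureCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


def _data_path(name: str) -> str:
    return str(importlib.resources.files("tprtchar") / "data" / name)


def load_table_spec(path: Optional[str] = None) -> dict:
    with open(path or _data_path("table_cases.yaml")) as handle:
        return yaml.safe_load(handle)


def default_gene_model() -> GeneModel:
    return GeneModel.from_tsv(_data_path("gene_model.tsv"), transcript_id="synthetic-NF1")


def build_layout(spec: dict, model: GeneModel) -> GeneLayout:
    lay = spec["layout"]
    default = int(lay["default_intron_length"])
    lengths = [default] * (len(model.exons) - 1)
    for idx, val in (lay.get("intron_lengths") or {}).items():
        lengths[int(idx) - 1] = int(val)
    return GeneLayout(
        model,
        lengths,
        upstream_flank=int(lay.get("upstream_flank", 2000)),
        downstream_flank=int(lay.get("downstream_flank", 2000)),
    )


def _window_top(case: dict) -> Tuple[str, str]:
    """Top-strand 5'->3' window and its anchoring rule."""
    w = case["window"]
    printed = w["left"] + w["right"]
    conv = w["conversion"]
    if conv == "complement":
        return printed.translate(_COMPLEMENT_ONLY), conv
    if conv == "reverse":
        return printed[::-1], conv
    if conv == "identity":
        return printed, conv
    raise FixtureBuildError(f"unknown window conversion {conv!r}")


def _window_start(case: dict, layout: GeneLayout) -> int:
    w = case["window"]
    if "anchor" in w:
        return layout.g(CPosition.parse(w["anchor"]))
    if "dup" in case:
        start_c, end_c = CPosition.parse(case["dup"]["start"]), CPosition.parse(case["dup"]["end"])
        if w["conversion"] == "reverse":
            return layout.g(end_c) - 23
        return layout.g(start_c) - 12
    raise FixtureBuildError(f"{case['case_id']}: window not anchorable")


def _build_genome(spec: dict, layout: GeneLayout, seed: int) -> str:
    rng = np.random.default_rng(seed)
    genome = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=layout.genome_length)))

    # splice-site dinucleotides on the filler (windows may overwrite)
    model = layout.model
    for i, exon in enumerate(model.exons[:-1]):
        donor = layout.g(CPosition(exon.c_end)) + 1
        genome[donor : donor + 2] = list("GT")
        acceptor = layout.g(CPosition(model.exons[i + 1].c_start))
        genome[acceptor - 2 : acceptor] = list("AG")

    written: Dict[int, Tuple[str, str]] = {}
    for case in spec["cases"]:
        top, _ = _window_top(case)
        start = _window_start(case, layout)
        for i, base in enumerate(top):
            g = start + i
            if g in written and written[g][0] != base:
                raise FixtureBuildError(
                    f"window conflict at genomic {g}: {written[g]} vs "
                    f"({base}, {case['case_id']})"
                )
            written[g] = (base, case["case_id"])
            genome[g] = base

    # the unprinted deleted bases of the intron 10 (8) case must not extend
    # the minimal replacement interval of its poly(T)-leading delins
    for case in spec["cases"]:
        if "deletion" in case:
            d_end = layout.g(CPosition.parse(case["deletion"]["end"]))
            if genome[d_end] == "C":
                genome[d_end] = "A"
    return "".join(genome)


def _element_body(case: dict, library: ElementLibrary, genome: str, layout: GeneLayout) -> Tuple[str, Dict]:
    """Element-orientation body plus classification-truth fields."""
    name = case["element"]
    meta: Dict = {
        "element": name,
        "truncation": 0,
        "inversion": False,
        "microhomology": 0,
        "l1_subset": "n/a",
    }
    if name == "polyT":
        meta["family"] = "polyN"
        return "", meta
    template = library[name]
    meta["family"] = template.family
    seq = template.sequence

    if "inversion" in case:
        inv = case["inversion"]
        j, mh = int(inv["junction"]), int(inv["microhomology"])
        a0 = int(inv["rc_start"])
        dup_start = CPosition.parse(case["dup"]["start"])
        before_dup = genome[layout.g(dup_start) - 1]
        body = None
        for dj in range(0, 40):
            for jj in (j - dj, j + dj):
                if not (a0 + 100 < jj - mh and jj < len(seq) - 100):
                    continue
                if seq[jj - 1] == before_dup:  # would extend the duplication
                    continue
                cand = revcomp(seq[a0 : jj]) + seq[jj - mh :]
                from .classifier import _inversion_info  # local to avoid cycle

                info = _inversion_info(cand, template)
                if info is not None and info["micro"] == mh:
                    body = cand
                    meta.update(
                        inversion=True,
                        microhomology=mh,
                        inversion_junction=info["junction"],
                        truncation=min(a0, info["fwd_start"]),
                    )
                    break
            if body is not None:
                break
        if body is None:
            raise FixtureBuildError(f"{case['case_id']}: no inversion geometry found")
        meta["l1_subset"] = "Ta"  # synthetic template carries the Ta consensus
        return body, meta

    trunc = int(case.get("truncation", 0))
    if "keep_3prime" in case:
        trunc = len(seq) - int(case["keep_3prime"])
    body = seq[trunc:]
    meta["truncation"] = trunc

    subset = case.get("l1_subset")
    if template.l1_subset_site is not None:
        site = template.l1_subset_site - trunc
        if subset == "preTa":
            body = body[:site] + "ACG" + body[site + 3 :]
            meta["l1_subset"] = "preTa"
        elif 0 <= site <= len(body) - 3:
            meta["l1_subset"] = "Ta"
    return body, meta


def build_fixture_set(
    table_spec: Optional[dict] = None,
    library: Optional[ElementLibrary] = None,
    model: Optional[GeneModel] = None,
    seed: int = 2011,
    slice_flank: int = SLICE_FLANK,
) -> FixtureSet:
    """Build the 18 in-table cases on a fresh synthetic genome."""
    spec = table_spec or load_table_spec()
    library = library or default_library()
    model = model or default_gene_model()
    layout = build_layout(spec, model)
    genome = _build_genome(spec, layout, seed)

    cases: List[FixtureCase] = []
    for case in spec["cases"]:
        body, meta = _element_body(case, library, genome, layout)
        tail_len = case.get("poly_tail")
        tail_asserted = tail_len is not None
        tail = "A" * int(tail_len if tail_len is not None else DEFAULT_TAIL)
        nt = case.get("nontemplated", "")
        orientation = "sense" if case["orientation"] == "S" else "antisense"

        if case["element"] == "polyT":
            insert = "T" * int(case["polyT_length"])
            tail_asserted = False
        elif orientation == "sense":
            insert = nt + body + tail
        else:
            insert = revcomp(nt + body + tail)

        if "deletion" in case:
            ds = layout.g(CPosition.parse(case["deletion"]["start"]))
            de = layout.g(CPosition.parse(case["deletion"]["end"])) + 1
            anchor = ds
            if genome[ds] == insert[0] or genome[de - 1] == insert[-1]:
                raise FixtureBuildError(f"{case['case_id']}: deletion bounds ambiguous")
            dup_seq = ""
            tsd_len = 0
            deletion_len = de - ds
        else:
            dup = case["dup"]
            p = layout.g(CPosition.parse(case["insertion_after"])) + 1
            dup_seq = dup["seq"].upper()
            tsd_len = len(dup_seq)
            observed = genome[p - tsd_len : p]
            if observed != dup_seq:
                raise FixtureBuildError(
                    f"{case['case_id']}: genome flank {observed} != dup {dup_seq}"
                )
            anchor = p
            deletion_len = 0

        slice_start = anchor - slice_flank
        slice_end = anchor + slice_flank
        reference = genome[slice_start:slice_end]
        p_s = anchor - slice_start
        if deletion_len:
            mutant = reference[:p_s] + insert + reference[p_s + deletion_len :]
            left_break, right_break = p_s, p_s + deletion_len
        else:
            mutant = reference[:p_s] + insert + dup_seq + reference[p_s:]
            left_break = right_break = p_s

        products = []
        for prod in case["effect"]["products"]:
            lo, hi = parse_c_interval(prod["lost"])
            gained = [(src, int(ln)) for src, ln in prod.get("gained", [])]
            products.append({"lost": (lo.base, hi.base), "gained": gained})
        splice_types = {int(t) for t in case["effect"]["splice_type"].split("&")}

        if orientation == "sense":
            nick_s = left_break - tsd_len
            nick_strand = "bottom"
        else:
            nick_s = left_break
            nick_strand = "top"

        resolved = case.get("resolved", {})
        shift = int(resolved.get("shift", 0))
        tail_truth = len(tail) if case["element"] != "polyT" else len(insert)
        truth = {
            "resolved_tsd_length": int(resolved.get("tsd_length", tsd_len)),
            "resolved_left_break": left_break + shift,
            "resolved_poly_tail_length": tail_truth - shift,
            "breakpoint_ambiguous": bool(resolved),
            "left_break": left_break,
            "right_break": right_break,
            "inserted_seq": insert,
            "tsd_seq": dup_seq,
            "tsd_length": tsd_len,
            "target_deletion_length": deletion_len,
            "orientation": orientation,
            "poly_tail_length": len(tail) if case["element"] != "polyT" else len(insert),
            "tail_asserted": tail_asserted,
            "nontemplated_5prime": nt,
            "nick_offset": nick_s,
            "nick_strand": nick_strand,
            "nick_genomic": slice_start + nick_s,
            "insertion_c": case.get("insertion_after"),
            "dup_c": (case["dup"]["start"], case["dup"]["end"]) if "dup" in case else None,
            "deletion_c": (
                (case["deletion"]["start"], case["deletion"]["end"])
                if "deletion" in case
                else None
            ),
            "effect_products": products,
            "frame_printed": case["effect"]["frame_printed"],
            "splice_types": splice_types,
            **meta,
        }

        fixture = FixtureCase(
            case_id=case["case_id"],
            row=int(case["row"]),
            location=case["location"],
            reference_allele=reference,
            mutant_allele=mutant,
            map=CoordinateMap(layout, slice_start),
            truth=truth,
        )
        # replay check: the recorded edit must reproduce the mutant
        rebuilt = (
            reference[:left_break] + insert + dup_seq + reference[right_break:]
        )
        if rebuilt != mutant:
            raise FixtureBuildError(f"{case['case_id']}: replay mismatch")
        cases.append(fixture)

    return FixtureSet(cases=cases, layout=layout, genome=genome, library=library)
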