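"""Mutation naming in the published HGVS dialect.

Insertions are reported after the first duplicated copy with a
comma-separated dup segment (``c.4319_4320insAluYb8,
4305_4319dupAAAAGAAGAACATAT``); deletion-associated insertions as a
delins (``c.1186-86_1186-16delinsAluY``); non-templated 5' additions as
an extra literal ins segment.  A strict mode spells the complete
inserted sequence as a single ins/delins instead of the element token.
Transcript-level effects are rendered as ``r.`` descriptions, with the
bracketed multi-product form for dual effects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .characterizer import InsertionCall
from .classifier import ElementClassification
from .genemodel import CoordinateMap, CPosition


@dataclass
class MutationName:
    c_description: str
    r_description: str
    frame_status: str  # IF | OOF | n/a
    net_exonic_change: int


def element_token(classification: Optional[ElementClassification]) -> str:
    if classification is None:
        return "INS"
    fam = classification.family
    if fam == "polyN":
        return "polyN"
    if fam == "L1":
        if classification.l1_subset != "n/a" and classification.truncation_offset > 0:
            return f"L1({classification.l1_subset})"
        return "L1"
    return fam


def name_insertion(
    call: InsertionCall,
    classification: Optional[ElementClassification],
    cmap: CoordinateMap,
    strict: bool = False,
) -> str:
    """c.-level description of a resolved call in fixture coordinates."""
    token = call.inserted_seq if strict else element_token(classification)
    if call.target_deletion_length > 0:
        a = cmap.offset_to_c(call.left_break)
        b = cmap.offset_to_c(call.right_break - 1)
        return f"c.{a}_{b}delins{token}"
    x = cmap.offset_to_c(call.left_break - 1)
    y = cmap.offset_to_c(call.left_break)
    ins = f"ins{token}"
    if call.nontemplated_5prime and not strict:
        if call.orientation == "antisense":
            ins = f"ins{token}ins{call.nontemplated_5prime}"
        else:
            ins = f"ins{call.nontemplated_5prime}ins{token}"
    desc = f"c.{x}_{y}{ins}"
    if call.tsd_length > 0 and not strict:
        a = cmap.offset_to_c(call.left_break - call.tsd_length)
        desc += f", {a}_{x}dup{call.tsd_seq}"
    return desc


_C_DESC_RE = re.compile(
    r"c\.(?P<x>[0-9+-]+)_(?P<y>[0-9+-]+)"
    r"(?:(?P<delins>delins)|(?P<ins>(?:ins[A-Za-z0-9()~]+)+))"
    r"(?:,\s*(?P<da>[0-9+-]+)_(?P<db>[0-9+-]+)dup(?P<dupseq>[ACGTN]+))?"
)


def parse_c_description(desc: str) -> Dict:
    """Parse the dialect back into its structural parts."""
    m = _C_DESC_RE.match(desc.strip())
    if not m:
        raise ValueError(f"unparsable description {desc!r}")
    out: Dict = {
        "left": CPosition.parse(m.group("x")),
        "right": CPosition.parse(m.group("y")),
        "kind": "delins" if (m.group("delins") or desc.count("delins")) else "ins",
    }
    if m.group("dupseq"):
        out["dup"] = (
            CPosition.parse(m.group("da")),
            CPosition.parse(m.group("db")),
            m.group("dupseq"),
        )
    return out


def apply_c_description(
    desc: str, reference: str, cmap: CoordinateMap, inserted_seq: str
) -> str:
    """Re-apply a parsed description (with the called insert) to the reference."""
    parts = parse_c_description(desc)
    if parts["kind"] == "delins":
        lo = cmap.c_to_offset(parts["left"])
        hi = cmap.c_to_offset(parts["right"]) + 1
        return reference[:lo] + inserted_seq + reference[hi:]
    p = cmap.c_to_offset(parts["right"])
    dup = ""
    if "dup" in parts:
        a, b, seq = parts["dup"]
        lo, hi = cmap.c_to_offset(a), cmap.c_to_offset(b) + 1
        if reference[lo:hi] != seq:
            raise ValueError("dup segment does not match the reference")
        dup = seq
    return reference[:p] + inserted_seq + dup + reference[p:]


def name_transcript_effect(products: Sequence[Dict], model=None) -> str:
    """r.-level description: ``r.A_Bdel``, ``r.A_BdelinsN`` or ``r.[x;y]``."""
    if not products:
        raise ValueError("empty transcript observation")
    parts = []
    for prod in products:
        lo, hi = prod["lost"]
        s = f"{lo}_{hi}del"
        gained = sum(n for _, n in prod.get("gained", []))
        if gained:
            s += f"ins{gained}"
        parts.append(s)
    if len(parts) == 1:
        return "r." + parts[0]
    return "r.[" + ";".join(parts) + "]"


def classify_frame(products: Sequence[Dict]) -> Tuple[str, int]:
    """Frame status from the net exonic change of the primary product."""
    if not products:
        raise ValueError("empty transcript observation")
    prod = products[0]
    lo, hi = prod["lost"]
    lost = hi - lo + 1
    gained = sum(n for _, n in prod.get("gained", []))
    net = gained - lost
    return ("IF" if net % 3 == 0 else "OOF"), net


def render_summary(rows: Sequence[Dict]) -> pd.DataFrame:
    """One row per case, Table-1-style plus EN score and recurrence group."""
    columns = [
        "case_id", "location", "family", "element_size", "truncated",
        "orientation", "poly_tail", "tsd_length", "target_deletion",
        "c_description", "r_description", "frame", "splice_types",
        "en_score", "recurrence_group",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(list(rows))
    for col in columns:
        if col not in df.columns:
            df[col] = None
    return df[columns].sort_values("case_id", kind="stable").reset_index(drop=True)
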