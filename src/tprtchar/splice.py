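"""Splicing-effect typing of characterized insertions.

Classifies each observed transcript product into the six effect types:

1. intronic 3'-splice-region insertion with complete skipping of the
   downstream exon;
2. exonic insertion with complete skipping of the affected exon;
3. exonic insertion with loss of the exon's 3' portion (cryptic 5'
   splice site upstream of the integration site);
4. exonic insertion with loss of the exon's 5' portion (cryptic 3'
   splice site downstream);
5. exonic insertion with loss of the exon's 3' portion plus inclusion
   of a 5' fragment of the element (cryptic 5' site inside the element);
6. intronic insertion with skipping of an adjacent natural exon plus
   inclusion of an element-derived cryptic exon.

Classification is a pure function of the site annotation, the observed
transcript products and the gene model; it never predicts splice
outcomes from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .genemodel import CoordinateError, GeneModel
from .sites import SiteAnnotation


@dataclass
class TranscriptObservation:
    """Observed products: lost r. intervals plus gained segments."""

    products: List[Dict]  # {"lost": (lo, hi), "gained": [(source, length), ...]}

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("at least one product is required")


@dataclass
class SpliceEffectCall:
    types: Set[int]
    per_product: List[Optional[int]]
    rationale: List[str] = field(default_factory=list)
    donor_side_extension: bool = False


def _classify_product(
    annotation: SiteAnnotation, product: Dict, model: GeneModel
) -> Tuple[Optional[int], str]:
    lo, hi = product["lost"]
    if not (1 <= lo <= hi <= model.c_end):
        raise CoordinateError(f"lost interval r.{lo}_{hi} outside the transcript")
    element_gain = any(src == "element" for src, _ in product.get("gained", []))

    if annotation.region == "exonic":
        exon = model.exon(annotation.feature_index)
        s, e = exon.c_start, exon.c_end
        if (lo, hi) == (s, e) and not element_gain:
            return 2, f"complete skip of exon {exon.label}"
        if hi == e and lo > s and not element_gain:
            return 3, f"loss of the 3' portion of exon {exon.label} (cryptic 5' site upstream)"
        if lo == s and hi < e and not element_gain:
            return 4, f"loss of the 5' portion of exon {exon.label} (cryptic 3' site downstream)"
        if hi == e and lo > s and element_gain:
            return 5, f"3' loss of exon {exon.label} with inclusion of a 5' element fragment"
        return None, f"unmatched exonic pattern r.{lo}_{hi}"

    intron = annotation.feature_index
    for adj in (intron, intron + 1):
        exon = model.exon(adj)
        if (lo, hi) == (exon.c_start, exon.c_end):
            if element_gain:
                return 6, f"skip of adjacent exon {exon.label} with an element-derived cryptic exon"
            return 1, f"skip of exon {exon.label} downstream of a splice-region insertion"
    return None, f"unmatched intronic pattern r.{lo}_{hi}"


def classify_effect(
    annotation: SiteAnnotation,
    observation: TranscriptObservation,
    model: GeneModel,
) -> SpliceEffectCall:
    """Assign splice-effect types to every product of one case."""
    labels: List[Optional[int]] = []
    rationale: List[str] = []
    donor_side = False
    for product in observation.products:
        label, why = _classify_product(annotation, product, model)
        if label == 1 and annotation.splice_region_class == "none":
            # donor-side or deep-intronic skip: accepted symmetrically
            donor_side = True
        labels.append(label)
        rationale.append(why)
    types = {t for t in labels if t is not None}
    if not types:
        types = set()
        rationale.append("unclassified")
    return SpliceEffectCall(
        types=types, per_product=labels, rationale=rationale,
        donor_side_extension=donor_side,
    )


def tally_effects(
    calls: Dict[str, SpliceEffectCall],
    annotations: Dict[str, SiteAnnotation],
) -> Dict:
    """Summary counts by type and by site class."""
    if not calls:
        raise ValueError("no splice-effect calls to tally")
    by_type: Dict[int, int] = {}
    for call in calls.values():
        for t in call.types:
            by_type[t] = by_type.get(t, 0) + 1
    exonic = [cid for cid, a in annotations.items() if a.region == "exonic"]
    intronic_acceptor = [
        cid
        for cid, a in annotations.items()
        if a.region == "intronic"
        and a.splice_region_class in ("canonical-AG", "polypyrimidine-tract")
    ]
    exonic_pure_skip = [cid for cid in exonic if calls[cid].types == {2}]
    exonic_cryptic5 = [cid for cid in exonic if calls[cid].types == {3}]
    exonic_cryptic3 = [cid for cid in exonic if calls[cid].types == {4}]
    return {
        "n_cases": len(calls),
        "by_type": dict(sorted(by_type.items())),
        "n_exonic": len(exonic),
        "n_intronic_acceptor_region": len(intronic_acceptor),
        "exonic_pure_skip": sorted(exonic_pure_skip),
        "n_exonic_pure_skip": len(exonic_pure_skip),
        "n_exonic_cryptic5_only": len(exonic_cryptic5),
        "n_exonic_cryptic3_only": len(exonic_cryptic3),
    }
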