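"""End-to-end orchestration: reproduction of the published per-case
summaries from the reconstructed fixtures, and simulator benchmarks."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .characterizer import characterize
from .fastaio import write_tsv
from .fixtures import FixtureSet, build_fixture_set
from .hgvs import classify_frame, name_insertion, name_transcript_effect, render_summary
from .simulator import SimulationConfig, simulate_dataset
from .sites import (
    annotate_site,
    find_clusters,
    find_recurrent_sites,
    infer_nick,
    score_en_site,
)
from .splice import TranscriptObservation, classify_effect, tally_effects

log = logging.getLogger("tprtchar")


@dataclass
class PaperReproduction:
    summary: pd.DataFrame
    recurrence: object
    clusters: object
    effect_tallies: Dict
    family_tallies: Dict[str, int]
    orientation_tallies: Dict[str, int]
    assertions: pd.DataFrame
    all_pass: bool
    per_case: Dict[str, Dict] = field(default_factory=dict)
    fixtures: Optional[FixtureSet] = None


def _config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _headers(seed: int, extra: str = "") -> List[str]:
    return [f"tprtchar {__version__}", f"seed={seed}", f"config={extra}"]


def run_paper_reproduction(
    seed: int = 2011,
    recurrence_window: int = 12,
    cluster_window: int = 1500,
    cluster_min_count: int = 3,
    outdir: Optional[str] = None,
    fixtures: Optional[FixtureSet] = None,
) -> PaperReproduction:
    """Rebuild the 18 fixtures, characterize them blind, and check every
    recovered quantity against the transcribed per-case truth."""
    fs = fixtures or build_fixture_set(seed=seed)
    per_case: Dict[str, Dict] = {}
    nicks = []
    annotations = {}
    effect_calls = {}
    checks: List[Dict] = []

    def check(case_id, name, expected, observed):
        checks.append(
            {
                "case_id": case_id,
                "check": name,
                "expected": expected,
                "observed": observed,
                "pass": expected == observed,
            }
        )

    for c in fs:
        t = c.truth
        call, cls = characterize(c.reference_allele, c.mutant_allele, fs.library)
        nick, strand, tentative = infer_nick(call)
        g_nick = c.map.to_genomic(nick)
        nicks.append((c.case_id, g_nick))
        if call.target_deletion_length:
            anno = annotate_site(
                fs.layout,
                c.map.to_genomic(call.left_break),
                c.map.to_genomic(call.right_break),
            )
        else:
            anno = annotate_site(fs.layout, c.map.to_genomic(call.left_break))
        annotations[c.case_id] = anno
        obs = TranscriptObservation(products=t["effect_products"])
        eff = classify_effect(anno, obs, fs.layout.model)
        effect_calls[c.case_id] = eff
        frame, net = classify_frame(t["effect_products"])
        try:
            en = score_en_site(c.reference_allele, nick, strand).matches
        except Exception:
            en = None

        check(c.case_id, "tsd_length", t["resolved_tsd_length"], call.tsd_length)
        check(c.case_id, "target_deletion", t["target_deletion_length"], call.target_deletion_length)
        check(c.case_id, "orientation", t["orientation"], call.orientation)
        check(c.case_id, "family", t["family"], cls.family)
        if t["family"] not in ("polyN", "unknown"):
            check(c.case_id, "truncation", t["truncation"], cls.truncation_offset)
        if t["tail_asserted"]:
            check(c.case_id, "poly_tail", t["resolved_poly_tail_length"], call.poly_tail_length)
        check(c.case_id, "nontemplated", t["nontemplated_5prime"], call.nontemplated_5prime)
        check(c.case_id, "splice_types", t["splice_types"], eff.types)
        check(c.case_id, "reconstruction", True, call.apply(c.reference_allele) == c.mutant_allele)
        if t["family"] == "L1":
            check(c.case_id, "inversion", t["inversion"], cls.inversion)
            if t["inversion"]:
                check(c.case_id, "microhomology", t["microhomology"], cls.microhomology_length)
            if t["l1_subset"] != "n/a":
                check(c.case_id, "l1_subset", t["l1_subset"], cls.l1_subset)

        per_case[c.case_id] = {
            "case_id": c.case_id,
            "row": c.row,
            "location": c.location,
            "call": call,
            "classification": cls,
            "annotation": anno,
            "effect": eff,
            "nick_genomic": g_nick,
            "nick_strand": strand,
            "nick_tentative": tentative,
            "summary_row": {
                "case_id": c.case_id,
                "location": c.location,
                "family": cls.family,
                "element_size": len(call.inserted_seq),
                "truncated": "Y" if cls.truncation_offset else "N",
                "orientation": call.orientation,
                "poly_tail": call.poly_tail_length,
                "tsd_length": call.tsd_length,
                "target_deletion": call.target_deletion_length,
                "c_description": name_insertion(call, cls, c.map),
                "r_description": name_transcript_effect(t["effect_products"]),
                "frame": frame,
                "splice_types": "&".join(str(x) for x in sorted(eff.types)),
                "en_score": en,
            },
        }

    recurrence = find_recurrent_sites(nicks, grouping_window=recurrence_window)
    clusters = find_clusters(nicks, window_bp=cluster_window, min_count=cluster_min_count)
    group_of = {}
    for gi, grp in enumerate(recurrence.groups):
        for cid in grp["case_ids"]:
            group_of[cid] = gi
    rows = []
    for cid, rec in per_case.items():
        row = rec["summary_row"]
        row["recurrence_group"] = group_of.get(cid)
        rows.append(row)
    summary = render_summary(rows)

    family_tallies: Dict[str, int] = {}
    orient_tallies = {"sense": 0, "antisense": 0}
    for rec in per_case.values():
        fam = rec["classification"].family
        family_tallies[fam] = family_tallies.get(fam, 0) + 1
        if fam.startswith("Alu"):
            orient_tallies[rec["call"].orientation] += 1
    tallies = tally_effects(effect_calls, annotations)

    check("-", "n_distinct_sites", 15, recurrence.n_distinct_sites)
    check("-", "n_multiply_used", 3, recurrence.n_multiply_used)

    assertions = pd.DataFrame(checks)
    all_pass = bool(assertions["pass"].all())

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        headers = _headers(seed, _config_hash((recurrence_window, cluster_window, cluster_min_count)))
        write_tsv(summary, out / "summary.tsv", headers)
        write_tsv(assertions, out / "assertions.tsv", headers)
        with open(out / "site_reports.json", "w") as handle:
            json.dump(
                {
                    "recurrence": {
                        "n_distinct_sites": recurrence.n_distinct_sites,
                        "n_multiply_used": recurrence.n_multiply_used,
                        "groups": recurrence.groups,
                    },
                    "clusters": clusters.windows,
                    "effect_tallies": tallies,
                    "family_tallies": family_tallies,
                    "orientation_tallies": orient_tallies,
                    "header": headers,
                },
                handle,
                indent=2,
            )
        _write_bed(out / "nicks.bed", per_case, clusters)

    return PaperReproduction(
        summary=summary,
        recurrence=recurrence,
        clusters=clusters,
        effect_tallies=tallies,
        family_tallies=family_tallies,
        orientation_tallies=orient_tallies,
        assertions=assertions,
        all_pass=all_pass,
        per_case=per_case,
        fixtures=fs,
    )


def _write_bed(path, per_case: Dict[str, Dict], clusters) -> None:
    with open(path, "w") as handle:
        for cid, rec in sorted(per_case.items()):
            g = rec["nick_genomic"]
            strand = "+" if rec["nick_strand"] == "top" else "-"
            handle.write(f"minigene\t{g}\t{g + 1}\tnick:{cid}\t0\t{strand}\n")
        for i, w in enumerate(clusters.windows):
            handle.write(f"minigene\t{w['start']}\t{w['end'] + 1}\tcluster{i}\t{w['size']}\t.\n")


def run_simulation_benchmark(
    n: int,
    config: Optional[SimulationConfig] = None,
    outdir: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate n events, characterize them blind, report exact-recovery rates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SimulationConfig()
    events = simulate_dataset(n, config)
    from .elements import default_library

    library = default_library()
    fields = [
        "tsd_length", "target_deletion_length", "orientation", "family",
        "truncation", "poly_tail", "nontemplated", "nick", "reconstruction",
    ]
    hits = {f: 0 for f in fields}
    totals = {f: 0 for f in fields}
    for reference, mutant, truth in events:
        call, cls = characterize(reference, mutant, library)
        nick, strand, tentative = infer_nick(call)

        def score(fname, expected, observed):
            totals[fname] += 1
            hits[fname] += int(expected == observed)

        score("tsd_length", truth.tsd_length, call.tsd_length)
        score("target_deletion_length", truth.target_deletion_length, call.target_deletion_length)
        score("orientation", truth.orientation, call.orientation)
        score("family", library[truth.element].family, cls.family)
        score("truncation", truth.truncation_offset, cls.truncation_offset)
        score("poly_tail", truth.polyA_length, call.poly_tail_length)
        score("nontemplated", truth.nontemplated_5prime, call.nontemplated_5prime)
        if truth.tsd_length > 0:
            score("nick", (truth.site_offset, truth.strand), (nick, strand))
        score("reconstruction", mutant, call.apply(reference))
    df = pd.DataFrame(
        {
            "field": fields,
            "n": [totals[f] for f in fields],
            "exact_recovery": [
                hits[f] / totals[f] if totals[f] else float("nan") for f in fields
            ],
        }
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(df, out / "benchmark.tsv", _headers(config.seed, _config_hash(config)))
    return df
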