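"""Element template library: Alu subfamilies and L1.

The bundled library holds one consensus-style template per family
(AluY, AluYa5, AluYb8, L1) plus sidecar metadata: subfamily-diagnostic
positions and, for L1, the trinucleotide site that separates the young
Ta subset (ACA) from the older pre-Ta subset (ACG).

The bundled sequences are *synthetic* stand-ins generated with a fixed
seed (see :func:`build_synthetic_library`): they reproduce the relevant
structure of the real consensus sequences — lengths, a shared backbone
with family-diagnostic substitutions, an A-rich linker, a non-A 3'
terminus — without being the deposited consensus sequences themselves.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .fastaio import read_fasta, revcomp, write_fasta

ALU_FAMILIES = ("AluY", "AluYa5", "AluYb8")
L1_SUBSET_CODES = {"ACA": "Ta", "ACG": "preTa"}


@dataclass(frozen=True)
class ElementTemplate:
    name: str
    family: str
    sequence: str
    diagnostic_sites: Tuple[Tuple[int, str], ...] = ()
    l1_subset_site: Optional[int] = None

    def __post_init__(self) -> None:
        for pos, base in self.diagnostic_sites:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"{self.name}: diagnostic site {pos} out of range")
        if self.l1_subset_site is not None and not (
            0 <= self.l1_subset_site + 3 <= len(self.sequence)
        ):
            raise ValueError(f"{self.name}: subset site out of range")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ElementLibrary:
    templates: Dict[str, ElementTemplate] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ElementTemplate:
        try:
            return self.templates[name]
        except KeyError:
            raise KeyError(f"element family {name!r} not in library") from None

    def __contains__(self, name: str) -> bool:
        return name in self.templates

    def __iter__(self):
        return iter(self.templates.values())

    def __len__(self) -> int:
        return len(self.templates)


def _rand_seq(rng: np.random.Generator, n: int, p=(0.2, 0.3, 0.3, 0.2)) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))


def build_synthetic_library(seed: int = 20111117) -> ElementLibrary:
    """Deterministically generate the synthetic template library.

    AluY/AluYa5/AluYb8 share a 281-bp GC-rich backbone; Ya5 carries five
    and Yb8 eight diagnostic substitutions plus a 7-bp insertion
    (length 288).  L1 is 6000 bp with the Ta/pre-Ta trinucleotide site
    near the 3' end.  All templates start with G and end with C so that
    poly(A)/poly(T) tail boundaries stay unambiguous.
    """
    rng = np.random.default_rng(seed)

    alu_len = 281
    core = list(_rand_seq(rng, alu_len, p=(0.18, 0.32, 0.32, 0.18)))
    core[0:7] = list("GGCCGGG")
    core[130:142] = list("AAAAATACAAAA")  # A-rich inter-monomer linker
    core[-1] = "C"
    alu_y = "".join(core)

    ya5_sites = [(57, "T"), (101, "A"), (150, "G"), (211, "C"), (251, "T")]
    ya5 = list(alu_y)
    for pos, base in ya5_sites:
        if ya5[pos] == base:  # force a real substitution
            base = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
            ya5_sites[ya5_sites.index((pos, ya5[pos]))] = (pos, base)
        ya5[pos] = base
    ya5_sites = [(pos, ya5[pos]) for pos, _ in ya5_sites]
    alu_ya5 = "".join(ya5)

    yb8 = list(alu_y)
    yb8_sub_positions = [30, 66, 95, 123, 170, 205, 240, 266]
    for pos in yb8_sub_positions:
        yb8[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[yb8[pos]]
    insert_at = 246
    yb8 = yb8[:insert_at] + list("GAGGCGG") + yb8[insert_at:]
    yb8_sites = [
        (p if p < insert_at else p + 7, yb8[p if p < insert_at else p + 7])
        for p in yb8_sub_positions
    ]
    alu_yb8 = "".join(yb8)
    assert len(alu_yb8) == 288 and alu_yb8[-1] == "C"

    l1_len = 6000
    l1 = list(_rand_seq(rng, l1_len, p=(0.3, 0.2, 0.2, 0.3)))
    l1[0] = "G"
    l1[-1] = "C"
    subset_site = 5910
    l1[subset_site : subset_site + 3] = list("ACA")  # Ta consensus
    # the base preceding the 1753-bp 3' segment (the bundled 5'-truncated
    # pre-Ta case) must differ from the terminus of that case's printed
    # non-templated addition (...T), or the addition would be templated
    l1[l1_len - 1753 - 1] = "G"
    l1_seq = "".join(l1)

    lib = ElementLibrary()
    lib.templates["AluY"] = ElementTemplate("AluY", "AluY", alu_y)
    lib.templates["AluYa5"] = ElementTemplate(
        "AluYa5", "AluYa5", alu_ya5, tuple(ya5_sites)
    )
    lib.templates["AluYb8"] = ElementTemplate(
        "AluYb8", "AluYb8", alu_yb8, tuple(yb8_sites)
    )
    lib.templates["L1"] = ElementTemplate(
        "L1", "L1", l1_seq, l1_subset_site=subset_site
    )
    return lib


def write_library(lib: ElementLibrary, fasta_path, yaml_path) -> None:
    write_fasta([(t.name, t.sequence) for t in lib], fasta_path)
    meta = {
        t.name: {
            "family": t.family,
            "diagnostic_sites": [[int(p), b] for p, b in t.diagnostic_sites],
            **({"l1_subset_site": int(t.l1_subset_site)} if t.l1_subset_site is not None else {}),
        }
        for t in lib
    }
    with open(yaml_path, "w") as handle:
        yaml.safe_dump(meta, handle, sort_keys=True)


def load_library(fasta_path, yaml_path=None) -> ElementLibrary:
    """Load a template FASTA plus optional sidecar metadata YAML."""
    meta: Dict[str, dict] = {}
    if yaml_path is not None:
        with open(yaml_path) as handle:
            meta = yaml.safe_load(handle) or {}
    lib = ElementLibrary()
    for name, seq in read_fasta(fasta_path):
        m = meta.get(name, {})
        lib.templates[name] = ElementTemplate(
            name=name,
            family=m.get("family", name),
            sequence=seq,
            diagnostic_sites=tuple((int(p), b) for p, b in m.get("diagnostic_sites", [])),
            l1_subset_site=m.get("l1_subset_site"),
        )
    if not lib.templates:
        raise ValueError(f"{fasta_path}: empty element library")
    return lib


def default_library() -> ElementLibrary:
    """The library bundled with the package."""
    data = importlib.resources.files("tprtchar") / "data"
    return load_library(
        str(data / "elements_synthetic.fa"), str(data / "elements_synthetic.yaml")
    )
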