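"""Gene model and coordinate systems.

Transcript (c.) coordinates are 1-based and partition ``1..c_end`` into
ordered exons; intronic positions are written relative to the nearest
exon boundary (``c.1062+195``, ``c.1642-12``), mirroring HGVS usage.
Internally everything is mapped onto a 0-based half-open genomic frame:
a synthetic gene layout assigns each intron a length and places the
transcript in a padded genomic sequence.  All HGVS-facing output is
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .fastaio import read_gene_model_tsv


class CoordinateError(ValueError):
    """A c. position cannot be resolved against the gene model."""


@dataclass(frozen=True)
class Exon:
    index: int
    legacy_label: str
    c_start: int
    c_end: int

    def __post_init__(self) -> None:
        if self.index < 1 or self.c_start > self.c_end:
            raise ValueError(f"bad exon {self.index}: c.{self.c_start}_{self.c_end}")

    @property
    def label(self) -> str:
        return f"{self.index} ({self.legacy_label})"


@dataclass(frozen=True)
class CPosition:
    """A c. coordinate: base plus an intronic offset (0 when exonic)."""

    base: int
    intron_offset: int = 0

    def __str__(self) -> str:
        if self.intron_offset > 0:
            return f"{self.base}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{self.base}{self.intron_offset}"
        return str(self.base)

    @classmethod
    def parse(cls, text: str) -> "CPosition":
        m = re.fullmatch(r"(-?\d+)(?:([+-])(\d+))?", text.strip())
        if not m:
            raise CoordinateError(f"unparsable c. position {text!r}")
        base = int(m.group(1))
        off = int(m.group(3)) if m.group(3) else 0
        if m.group(2) == "-":
            off = -off
        return cls(base, off)


class GeneModel:
    """Ordered exons of one transcript in c. coordinates."""

    def __init__(self, transcript_id: str, exons: Sequence[Exon]):
        self.transcript_id = transcript_id
        self.exons = sorted(exons, key=lambda e: e.c_start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.c_start != a.c_end + 1:
                raise ValueError(
                    f"exons {a.index} and {b.index} do not tile the transcript"
                )
            if b.index != a.index + 1:
                raise ValueError("exon indices must be consecutive")
        self._by_index = {e.index: e for e in self.exons}

    @classmethod
    def from_tsv(cls, path, transcript_id: str = "synthetic") -> "GeneModel":
        df = read_gene_model_tsv(path)
        exons = [
            Exon(int(r["index"]), str(r["legacy_label"]), int(r["c_start"]), int(r["c_end"]))
            for _, r in df.iterrows()
        ]
        return cls(transcript_id, exons)

    @property
    def c_end(self) -> int:
        return self.exons[-1].c_end

    def exon(self, index: int) -> Exon:
        return self._by_index[index]

    def exon_of(self, base: int) -> Exon:
        for e in self.exons:
            if e.c_start <= base <= e.c_end:
                return e
        raise CoordinateError(f"c.{base} outside transcript 1..{self.c_end}")

    def validate(self, pos: CPosition) -> Exon:
        """Check a position resolves; return the anchoring exon."""
        exon = self.exon_of(pos.base)
        if pos.intron_offset > 0 and pos.base != exon.c_end:
            raise CoordinateError(f"c.{pos}: +offset not at an exon 3' boundary")
        if pos.intron_offset < 0 and pos.base != exon.c_start:
            raise CoordinateError(f"c.{pos}: -offset not at an exon 5' boundary")
        if pos.intron_offset < 0 and exon.index == 1:
            raise CoordinateError(f"c.{pos}: no intron upstream of exon 1")
        return exon


@dataclass
class GeneLayout:
    """Genomic placement of a gene model: intron lengths plus flanks.

    ``intron_lengths[i]`` is the length of the intron following exon
    ``i+1`` (0-based list over the ``n_exons - 1`` introns).
    """

    model: GeneModel
    intron_lengths: List[int]
    upstream_flank: int = 2000
    downstream_flank: int = 2000
    _exon_g_start: Dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.model.exons) - 1:
            raise ValueError("need one intron length per internal junction")
        g = self.upstream_flank
        for i, exon in enumerate(self.model.exons):
            self._exon_g_start[exon.index] = g
            g += exon.c_end - exon.c_start + 1
            if i < len(self.intron_lengths):
                g += self.intron_lengths[i]
        self.genome_length = g + self.downstream_flank

    def intron_length(self, intron_index: int) -> int:
        return self.intron_lengths[intron_index - 1]

    def g(self, pos: CPosition) -> int:
        """0-based genomic offset of a c. position."""
        exon = self.model.validate(pos)
        base_g = self._exon_g_start[exon.index] + (pos.base - exon.c_start)
        g = base_g + pos.intron_offset
        if not 0 <= g < self.genome_length:
            raise CoordinateError(f"c.{pos} maps outside the genomic frame")
        return g

    def c(self, offset: int) -> CPosition:
        """Inverse of :meth:`g` for any offset within the gene span."""
        exons = self.model.exons
        first_g = self._exon_g_start[exons[0].index]
        last = exons[-1]
        last_g_end = self._exon_g_start[last.index] + (last.c_end - last.c_start)
        if offset < first_g:
            return CPosition(exons[0].c_start, offset - first_g)
        if offset > last_g_end:
            return CPosition(last.c_end, offset - last_g_end)
        for i, exon in enumerate(exons):
            start = self._exon_g_start[exon.index]
            end = start + (exon.c_end - exon.c_start)
            if start <= offset <= end:
                return CPosition(exon.c_start + (offset - start))
            if i < len(exons) - 1:
                nxt = exons[i + 1]
                nxt_start = self._exon_g_start[nxt.index]
                if offset < nxt_start:
                    d_donor = offset - end
                    d_acceptor = offset - nxt_start  # negative
                    if d_donor <= -d_acceptor:
                        return CPosition(exon.c_end, d_donor)
                    return CPosition(nxt.c_start, d_acceptor)
        raise CoordinateError(f"offset {offset} not within the gene span")

    def intron_of(self, offset: int) -> Optional[int]:
        """Intron index (1-based, after that exon) containing ``offset``; None if exonic."""
        pos = self.c(offset)
        if pos.intron_offset == 0:
            return None
        exon = self.model.exon_of(pos.base)
        return exon.index if pos.intron_offset > 0 else exon.index - 1


@dataclass(frozen=True)
class CoordinateMap:
    """Affine map between a genomic layout and a fixture sub-sequence."""

    layout: GeneLayout
    slice_start: int = 0

    def c_to_offset(self, pos: CPosition) -> int:
        off = self.layout.g(pos) - self.slice_start
        if off < 0:
            raise CoordinateError(f"c.{pos} upstream of the fixture slice")
        return off

    def offset_to_c(self, offset: int) -> CPosition:
        return self.layout.c(offset + self.slice_start)

    def to_genomic(self, offset: int) -> int:
        return offset + self.slice_start


def c_to_offset(model_map: CoordinateMap, pos: CPosition) -> int:
    """Module-level convenience wrapper."""
    return model_map.c_to_offset(pos)


def offset_to_c(model_map: CoordinateMap, offset: int) -> CPosition:
    return model_map.offset_to_c(offset)


def parse_c_interval(text: str) -> Tuple[CPosition, CPosition]:
    """Parse ``"4305_4319"`` or ``"1642-11_1642-1"`` into two positions."""
    left, _, right = text.partition("_")
    if not right:
        p = CPosition.parse(left)
        return p, p
    return CPosition.parse(left), CPosition.parse(right)
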