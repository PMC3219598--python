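"""FASTA and tabular I/O helpers.

Sequences are handled as plain uppercase strings over the DNA alphabet
ACGTN.  Reading normalizes case; anything outside the alphabet is a
format error that names the offending line, which is why reading is done
with a thin line-tracking scanner rather than a generic parser.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaFormatError(ValueError):
    """Malformed FASTA input; message names the line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> List[Tuple[str, str]]:
    """Read a FASTA file into a list of ``(id, sequence)`` tuples.

    Sequences are uppercased and restricted to ACGTN.  The record id is
    the first whitespace-delimited token of the header.
    """
    records: List[Tuple[str, str]] = []
    name = None
    chunks: List[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}: empty header at line {lineno}")
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                seq = line.upper()
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise FastaFormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    """Write ``(id, sequence)`` records as wrapped FASTA."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_gene_model_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an exon table (columns: index, legacy_label, c_start, c_end)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"legacy_label": str})
    required = {"index", "legacy_label", "c_start", "c_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV with optional ``#`` header comment lines."""
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        df.to_csv(handle, sep="\t", index=False)
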