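"""Candidate tRF construction from tRNA sequences.

tRFs (tRNA-derived fragments) are short RNAs cleaved from mature tRNAs.
This module builds the terminal fragment classes — 5' tRFs (from the tRNA 5'
end) and 3' tRFs (ending at the tRNA 3' end) — at configurable lengths, with
a deterministic id scheme ``{parent}_{5p|3p}_{length}`` so fragment
provenance is recoverable from the id alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FIVE_PRIME",
    "THREE_PRIME",
    "SeqRecordLike",
    "TRFRecord",
    "FastaFormatError",
    "read_fasta",
    "make_fragments",
    "write_fragments_fasta",
    "parse_fragment_id",
    "DEFAULT_LENGTHS",
    "HEADLINE_LENGTH",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

#: default fragment length set when the caller gives none; 22 nt is the
#: headline length for 5' tRFs acting as siRNA-like silencers.
DEFAULT_LENGTHS = tuple(range(18, 35))
HEADLINE_LENGTH = 22

_RNA_ALPHABET = set("ACGU")


class FastaFormatError(ValueError):
    """Raised for empty files, empty records or non-nucleotide characters."""


@dataclass(frozen=True)
class SeqRecordLike:
    """Minimal RNA sequence record (id + sequence over {A,C,G,U})."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TRFRecord:
    """A candidate tRNA-derived fragment.

    Invariants: ``sequence`` equals the parent slice ``[offset, offset+length)``;
    5' fragments start at offset 0; 3' fragments end at the parent's 3' end.
    """

    id: str
    parent_id: str
    end: str  # FIVE_PRIME or THREE_PRIME
    offset: int  # 0-based start in parent
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown fragment end {self.end!r}")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with declared length")


def read_fasta(path: str | Path) -> list[SeqRecordLike]:
    """Read a nucleotide FASTA, normalizing T to U.

    Record order is preserved.  Duplicate ids are disambiguated with a
    ``.2``, ``.3``, ... suffix and a warning.  Empty files, empty sequences
    and non-IUPAC-nucleotide characters raise :class:`FastaFormatError`
    naming the offending record.
    """
    path = Path(path)
    records: list[SeqRecordLike] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has an empty sequence")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {rec.id!r} in {path} contains non-nucleotide characters {sorted(bad)}"
            )
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid = new_id
        else:
            seen[rid] = 1
        records.append(SeqRecordLike(id=rid, sequence=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecordLike], path: str | Path) -> None:
    """Write records as FASTA (U preserved; no line wrapping surprises)."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def make_fragments(
    trnas: Sequence[SeqRecordLike],
    lengths: Sequence[int] = (HEADLINE_LENGTH,),
    ends: Iterable[str] = (FIVE_PRIME,),
) -> list[TRFRecord]:
    """Slice terminal fragments from every eligible tRNA.

    One :class:`TRFRecord` per (tRNA x length x end).  Parents shorter than a
    requested length are skipped for that length with a logged warning.
    """
    if not lengths:
        raise ValueError("make_fragments requires at least one fragment length")
    ends = sorted(set(ends))
    for e in ends:
        if e not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown fragment end {e!r}")
    frags: list[TRFRecord] = []
    for trna in trnas:
        for length in lengths:
            if length < 1:
                raise ValueError(f"fragment length must be positive, got {length}")
            if length > len(trna):
                logger.warning(
                    "tRNA %s (%d nt) shorter than requested fragment length %d; skipped",
                    trna.id,
                    len(trna),
                    length,
                )
                continue
            for end in ends:
                if end == FIVE_PRIME:
                    offset = 0
                    tag = "5p"
                else:
                    offset = len(trna) - length
                    tag = "3p"
                frags.append(
                    TRFRecord(
                        id=f"{trna.id}_{tag}_{length}",
                        parent_id=trna.id,
                        end=end,
                        offset=offset,
                        length=length,
                        sequence=trna.sequence[offset : offset + length],
                    )
                )
    return frags


def write_fragments_fasta(frags: Sequence[TRFRecord], path: str | Path) -> None:
    """Write fragments as FASTA; round-trips through :func:`read_fasta`."""
    write_fasta([SeqRecordLike(id=f.id, sequence=f.sequence) for f in frags], path)


def parse_fragment_id(frag_id: str) -> tuple[str, str, int]:
    """Recover (parent_id, end, length) from the deterministic id scheme."""
    parent, tag, length = frag_id.rsplit("_", 2)
    end = {"5p": FIVE_PRIME, "3p": THREE_PRIME}.get(tag)
    if end is None:
        raise ValueError(f"not a fragment id: {frag_id!r}")
    return parent, end, int(length)
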