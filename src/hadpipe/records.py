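"""Sequence records and FASTA / table I/O.

Transcripts are plain DNA records (A/C/G/T/N) carrying the host-strain and
sex labels of the library they were assembled from; protein references are
amino-acid records used for CDS annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")

_ID_RE = re.compile(r"^(?P<gene>[^_\s]+)_(?P<strain>[^_\s]+)$")


@dataclass
class Transcript:
    """A single assembled transcript with its library labels."""

    id: str
    seq: str
    strain: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRef:
    """A reference protein used to anchor CDS boundaries."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrthologPair:
    """A reciprocal-best-match pair that survived the double filter."""

    id_a: str
    id_b: str
    ref_id: str | None = None
    prot_id: str | None = None


def read_transcripts(path: str | Path, strain: str = "", sex: str = "") -> list[Transcript]:
    """Read a transcript FASTA.

    If ``strain`` is empty, ids of the form ``g{N}_{strain}`` have their
    strain parsed from the id suffix.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        st = strain
        if not st:
            m = _ID_RE.match(rec.id)
            if m:
                st = m.group("strain")
        out.append(Transcript(id=rec.id, seq=str(rec.seq), strain=st, sex=sex))
    return out


def read_proteins(path: str | Path) -> list[ProteinRef]:
    return [ProteinRef(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[Transcript | ProteinRef], path: str | Path, width: int = 80) -> Path:
    """Write records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
    return path


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
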