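"""CDS / 5'UTR / 3'UTR partitioning of transcripts from protein hits.

The protein hit pins the reading frame; the CDS is grown outward from the
hit region — upstream to the nearest in-frame ATG (never across a stop) and
downstream to the first in-frame stop codon. Transcripts with an in-frame
stop strictly inside the hit region, or whose CDS ends up shorter than
150 bp, are removed, matching the filtering the divergence analysis
assumes. The stop codon itself belongs to neither the CDS nor the 3'UTR: it
is held out as a 3-base buffer so that per-region substitution counts never
mix regions under different selective pressure.

All coordinates are 0-based half-open on the coding strand; minus-strand
hits are annotated on the reverse complement and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetics import STOP_CODONS
from .orthology import ProteinHit
from .records import Transcript, revcomp

MIN_CDS_LEN = 150  # bp; CDS shorter than this is removed
MIN_REGION_LEN = 10  # bp; shorter UTRs are not used for divergence


@dataclass
class RegionAnnotation:
    transcript_id: str
    strand: str
    frame: int
    utr5: tuple[int, int]
    cds: tuple[int, int]  # ATG-initiated; stop codon excluded
    utr3: tuple[int, int]
    stop: tuple[int, int] | None  # the held-out stop-codon buffer
    partial_start: bool = False
    partial_stop: bool = False

    def __post_init__(self) -> None:
        if (self.cds[1] - self.cds[0]) % 3:
            raise ValueError("CDS length must be divisible by 3")
        if not (self.utr5[1] == self.cds[0] and self.utr5[0] <= self.utr5[1]):
            raise ValueError("5'UTR must directly precede the CDS")


@dataclass
class Rejection:
    transcript_id: str
    reason: str  # 'internal_stop' or 'too_short'


def _coding_seq(transcript: Transcript, strand: str) -> str:
    return transcript.seq if strand == "+" else revcomp(transcript.seq)


def locate_cds(
    transcript: Transcript, protein_hit: ProteinHit, min_cds_len: int = MIN_CDS_LEN
) -> RegionAnnotation | Rejection:
    """Derive region boundaries from a protein hit, or reject the transcript.

    Rejection reasons: ``internal_stop`` (an in-frame stop codon strictly
    inside the hit region) and ``too_short`` (CDS < ``min_cds_len``).
    """
    seq = _coding_seq(transcript, protein_hit.strand)
    hit_start, hit_end = protein_hit.nt_span()

    # any whole in-frame stop codon inside the hit region disqualifies
    for c in range(hit_start, hit_end - 2, 3):
        if seq[c : c + 3] in STOP_CODONS:
            return Rejection(transcript.id, "internal_stop")

    cds_start, partial_start = hit_start, True
    c = hit_start
    while c >= 0:
        codon = seq[c : c + 3]
        if codon in STOP_CODONS and c < hit_start:
            break
        if codon == "ATG":
            cds_start, partial_start = c, False
            break
        c -= 3

    cds_end, partial_stop = None, False
    c = hit_end
    while c + 3 <= len(seq):
        if seq[c : c + 3] in STOP_CODONS:
            cds_end = c
            break
        c += 3
    if cds_end is None:
        # no downstream stop: CDS runs to the last whole in-frame codon
        cds_end = cds_start + ((len(seq) - cds_start) // 3) * 3
        partial_stop = True

    if cds_end - cds_start < min_cds_len:
        return Rejection(transcript.id, "too_short")

    stop = None if partial_stop else (cds_end, cds_end + 3)
    utr3_start = cds_end if partial_stop else cds_end + 3
    return RegionAnnotation(
        transcript_id=transcript.id,
        strand=protein_hit.strand,
        frame=cds_start % 3,
        utr5=(0, cds_start),
        cds=(cds_start, cds_end),
        utr3=(utr3_start, len(seq)),
        stop=stop,
        partial_start=partial_start,
        partial_stop=partial_stop,
    )


def partition_regions(
    transcript: Transcript, annotation: RegionAnnotation
) -> tuple[str, str, str]:
    """(utr5, cds, utr3) sequences in coding orientation.

    ``utr5 + cds + stop + utr3`` reconstructs the coding-strand sequence.
    """
    seq = _coding_seq(transcript, annotation.strand)
    return (
        seq[annotation.utr5[0] : annotation.utr5[1]],
        seq[annotation.cds[0] : annotation.cds[1]],
        seq[annotation.utr3[0] : annotation.utr3[1]],
    )


def pair_regions(
    transcript_a: Transcript,
    annotation_a: RegionAnnotation,
    transcript_b: Transcript,
    annotation_b: RegionAnnotation,
    min_region_len: int = MIN_REGION_LEN,
) -> list[tuple[str, str, str]]:
    """Region-matched sequence pairs (region, seq_a, seq_b).

    A region pair is emitted only when both members have at least
    ``min_region_len`` bases of it — which is why UTR pair counts fall below
    the ortholog count in real data.
    """
    regions_a = partition_regions(transcript_a, annotation_a)
    regions_b = partition_regions(transcript_b, annotation_b)
    out = []
    for name, sa, sb in zip(("utr5", "cds", "utr3"), regions_a, regions_b):
        if len(sa) >= min_region_len and len(sb) >= min_region_len:
            out.append((name, sa, sb))
    return out


_GFF_FEATURE = {"utr5": "five_prime_UTR", "cds": "CDS", "utr3": "three_prime_UTR"}


def to_gff_lines(annotation: RegionAnnotation, source: str = "hadpipe") -> list[str]:
    """GFF3-style lines (1-based inclusive coordinates) for one annotation."""
    lines = []
    for region in ("utr5", "cds", "utr3"):
        start, end = getattr(annotation, region)
        if end <= start:
            continue
        frame = str(annotation.frame) if region == "cds" else "."
        lines.append(
            "\t".join(
                [
                    annotation.transcript_id,
                    source,
                    _GFF_FEATURE[region],
                    str(start + 1),
                    str(end),
                    ".",
                    annotation.strand,
                    frame,
                    f"ID={annotation.transcript_id}.{region}",
                ]
            )
        )
    return lines
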