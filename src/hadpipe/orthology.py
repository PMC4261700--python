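"""Similarity search and reciprocal-best-match ortholog pairing.

The search is an exact-k-mer-seeded local aligner: subjects sharing at
least ``min_seed_hits`` words with the query (either strand) are candidate
hits and are scored by affine-gap local alignment; everything else is never
aligned. A Karlin-Altschul-style length-normalized quantity is attached to
each hit as an expected-chance-hit surrogate, but filtering is by raw score
against a threshold calibrated once on a shuffled-sequence null (see the
methods note), because the database here is tiny compared to a public one.

Ambiguity always resolves to "no call": tied top scores yield no best hit,
mirroring the requirement that paired sequences correspond *unambiguously*.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import translate_codon
from .records import OrthologPair, ProteinRef, Transcript, revcomp


@dataclass
class SearchParams:
    """Nucleotide search parameters (defaults follow megablast-style scoring)."""

    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # a gap of length L costs gap_open + gap_extend * L
    gap_extend: int = 2
    min_score: float = 40.0  # 99.9th percentile of the shuffled-sequence null
    min_seed_hits: int = 5  # shared words required before a pair is aligned
    karlin_lambda: float = 0.62
    karlin_k: float = 0.41
    max_n_fraction: float = 0.5


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    evalue_surrogate: float
    q_span: tuple[int, int]  # 0-based half-open, query-forward coordinates
    s_span: tuple[int, int]
    strand: str  # '+' or '-'


def _dna_matrix(match: int, mismatch: int):
    """ACGTN scoring; N scores as a mismatch against everything, itself included."""
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _dna_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _dna_matrix(params.match, params.mismatch)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            yield w


def _kmer_index(subjects: list[Transcript], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for j, sub in enumerate(subjects):
        for w in _kmers(sub.seq, k):
            index[w].add(j)
    return index


def similarity_search(
    queries: list[Transcript],
    subjects: list[Transcript],
    params: SearchParams | None = None,
) -> list[SimilarityHit]:
    """All significant local hits of each query against the subject set.

    Both strands of the query are searched; minus-strand hits are reported
    in query-forward coordinates with ``strand='-'``. Hits are ordered per
    query by descending score.
    """
    if not queries or not subjects:
        raise ValueError("query and subject sets must both be nonempty")
    params = params or SearchParams()
    index = _kmer_index(subjects, params.word_size)
    aligner = _dna_aligner(params, "local")
    db_len = sum(len(s) for s in subjects)

    hits: list[SimilarityHit] = []
    for q in queries:
        if q.seq.count("N") > params.max_n_fraction * len(q.seq):
            warnings.warn(f"skipping query {q.id!r}: more than 50% N", stacklevel=2)
            continue
        q_hits: dict[tuple[str, str], SimilarityHit] = {}
        for strand, qseq in (("+", q.seq), ("-", revcomp(q.seq))):
            seed_counts: dict[int, int] = defaultdict(int)
            n_words = 0
            for w in _kmers(qseq, params.word_size):
                n_words += 1
                for j in index.get(w, ()):
                    seed_counts[j] += 1
            # short queries cannot carry many words; scale the seed gate down
            eff_min = max(1, min(params.min_seed_hits, n_words // 2))
            for j, n_seeds in seed_counts.items():
                if n_seeds < eff_min:
                    continue
                sub = subjects[j]
                if qseq == sub.seq:  # exact duplicate: alignment is trivial
                    score = float(params.match * len(qseq))
                    qs, qe, ss, se = 0, len(qseq), 0, len(qseq)
                else:
                    aln = aligner.align(qseq, sub.seq)
                    score = float(aln.score)
                    if score < params.min_score:
                        continue
                    best = aln[0]
                    qs, qe = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
                    ss, se = int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])
                if score < params.min_score:
                    continue
                if strand == "-":
                    qs, qe = len(q.seq) - qe, len(q.seq) - qs
                ev = params.karlin_k * len(q.seq) * db_len * math.exp(-params.karlin_lambda * score)
                hit = SimilarityHit(q.id, sub.id, score, ev, (qs, qe), (ss, se), strand)
                key = (q.id, sub.id)
                if key not in q_hits or score > q_hits[key].score:
                    q_hits[key] = hit
        hits.extend(sorted(q_hits.values(), key=lambda h: (-h.score, h.subject_id)))
    return hits


def transpose_hits(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Swap query and subject roles of every hit.

    Local alignment scores are symmetric in the two sequences, so the
    transpose of an A-vs-B search is a valid B-vs-A search; the pipeline
    uses this to avoid aligning every pair twice.
    """
    return [
        SimilarityHit(
            query_id=h.subject_id,
            subject_id=h.query_id,
            score=h.score,
            evalue_surrogate=h.evalue_surrogate,
            q_span=h.s_span,
            s_span=h.q_span,
            strand=h.strand,
        )
        for h in hits
    ]


def _unique_best(hits: list[SimilarityHit]) -> dict[str, str]:
    """query -> subject of the unique top-scoring hit; tied tops give no entry."""
    by_query: dict[str, list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    best = {}
    for qid, hs in by_query.items():
        top = max(h.score for h in hs)
        winners = {h.subject_id for h in hs if h.score == top}
        if len(winners) == 1:
            best[qid] = next(iter(winners))
    return best


def reciprocal_best_matches(
    hits_ab: list[SimilarityHit], hits_ba: list[SimilarityHit]
) -> list[tuple[str, str]]:
    """Pairs (a, b) where each is the other's unique top hit.

    Output is a one-to-one partial matching; any tie for a top score removes
    that query from consideration.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


def map_to_reference(
    transcripts: list[Transcript],
    pooled_reference: list[Transcript],
    params: SearchParams | None = None,
) -> dict[str, str]:
    """Best-scoring pooled-reference sequence per transcript.

    Transcripts whose best mapping is tied are left out (flagged unmapped).
    """
    if not pooled_reference:
        raise ValueError("pooled reference must be nonempty")
    hits = similarity_search(transcripts, pooled_reference, params)
    return _unique_best(hits)


# ---------------------------------------------------------------- hit I/O


def write_hits_tsv(hits: list[SimilarityHit], path) -> None:
    """Hits as TSV: query, subject, score, evalue_surrogate, q_start, q_end,
    s_start, s_end, strand (0-based half-open spans)."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tevalue_surrogate\tq_start\tq_end\ts_start\ts_end\tstrand\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.score:g}\t{h.evalue_surrogate:.3g}\t"
                f"{h.q_span[0]}\t{h.q_span[1]}\t{h.s_span[0]}\t{h.s_span[1]}\t{h.strand}\n"
            )


def read_hits_tsv(path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                SimilarityHit(
                    f[0], f[1], float(f[2]), float(f[3]),
                    (int(f[4]), int(f[5])), (int(f[6]), int(f[7])), f[8],
                )
            )
    return hits


def read_blast_tabular(path) -> list[SimilarityHit]:
    """Read externally produced hits in the standard 12-column blast-tabular
    dialect (qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore; 1-based inclusive coordinates).

    The bit score is used as the hit score and the reported E-value as the
    chance-hit surrogate; minus-strand hits are recognized by a descending
    subject span and re-expressed in this module's forward/half-open
    convention.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if se >= ss else "-"
            if strand == "-":
                ss, se = se, ss
            hits.append(
                SimilarityHit(
                    query_id=f[0],
                    subject_id=f[1],
                    score=float(f[11]),
                    evalue_surrogate=float(f[10]),
                    q_span=(qs - 1, qe),
                    s_span=(ss - 1, se),
                    strand=strand,
                )
            )
    return hits


# ------------------------------------------------------------- protein side


@dataclass
class ProteinHit:
    """Best local amino-acid alignment of one reading frame to a protein."""

    prot_id: str
    frame: int  # 0/1/2 offset on the coding strand
    strand: str  # '+': transcript as given; '-': reverse complement
    score: float
    q_aa_span: tuple[int, int]  # coordinates in the frame's translation
    s_aa_span: tuple[int, int]  # coordinates in the protein

    def nt_span(self) -> tuple[int, int]:
        """Hit interval in nucleotides on the coding-strand-oriented sequence."""
        return (self.frame + 3 * self.q_aa_span[0], self.frame + 3 * self.q_aa_span[1])


class ProteinIndex:
    """Amino-acid k-mer prefilter over a protein set (built once, reused).

    A protein is a candidate for a translated frame when they share at
    least ``min_hits`` words of length ``k`` — chance 5-mer matches are rare
    enough that unrelated frames are almost never aligned.
    """

    def __init__(self, proteins: list[ProteinRef], k: int = 5, min_hits: int = 2):
        self.proteins = proteins
        self.k = k
        self.min_hits = min_hits
        self.index: dict[str, set[int]] = defaultdict(set)
        for j, p in enumerate(proteins):
            for i in range(len(p.seq) - k + 1):
                w = p.seq[i : i + k]
                if "X" not in w and "*" not in w:
                    self.index[w].add(j)

    def candidates(self, aa_seq: str) -> set[int]:
        counts: dict[int, int] = defaultdict(int)
        for i in range(len(aa_seq) - self.k + 1):
            w = aa_seq[i : i + self.k]
            if "X" not in w and "*" not in w:
                for j in self.index.get(w, ()):
                    counts[j] += 1
        min_hits = min(self.min_hits, max(1, len(aa_seq) - self.k + 1))
        return {j for j, c in counts.items() if c >= min_hits}


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def six_frame_translations(seq: str) -> list[tuple[str, int, str]]:
    """(strand, frame, translation) for all six reading frames."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            n = (len(s) - f) // 3
            aa = "".join(translate_codon(s[f + 3 * i : f + 3 * i + 3]) for i in range(n))
            out.append((strand, f, aa))
    return out


def best_protein_match(
    transcript: Transcript,
    proteins: list[ProteinRef] | ProteinIndex,
    cutoff: float = 50.0,
) -> ProteinHit | None:
    """Translate all six frames and return the best local protein hit.

    Returns None when no alignment reaches ``cutoff`` or when two different
    proteins tie at the top score (ambiguous annotation).
    """
    if isinstance(proteins, ProteinIndex):
        pindex = proteins
    else:
        if not proteins:
            raise ValueError("protein set must be nonempty")
        pindex = ProteinIndex(proteins)
    aligner = _protein_aligner()

    best: ProteinHit | None = None
    tied_other_protein = False
    for strand, frame, aa in six_frame_translations(transcript.seq):
        if len(aa) < pindex.k:
            continue
        for j in sorted(pindex.candidates(aa)):
            prot = pindex.proteins[j]
            aln = aligner.align(aa, prot.seq)
            score = float(aln.score)
            if score < cutoff:
                continue
            a0 = aln[0]
            hit = ProteinHit(
                prot_id=prot.id,
                frame=frame,
                strand=strand,
                score=score,
                q_aa_span=(int(a0.aligned[0][0][0]), int(a0.aligned[0][-1][1])),
                s_aa_span=(int(a0.aligned[1][0][0]), int(a0.aligned[1][-1][1])),
            )
            if best is None or score > best.score:
                best, tied_other_protein = hit, False
            elif score == best.score and hit.prot_id != best.prot_id:
                tied_other_protein = True
    if best is None or tied_other_protein:
        return None
    return best


def best_protein_matches(
    transcripts: list[Transcript], proteins: list[ProteinRef], cutoff: float = 50.0
) -> dict[str, ProteinHit]:
    """Batch form of :func:`best_protein_match` sharing one prefilter index."""
    pindex = ProteinIndex(proteins)
    out = {}
    for t in transcripts:
        hit = best_protein_match(t, pindex, cutoff)
        if hit is not None:
            out[t.id] = hit
    return out


# ------------------------------------------------------------- double filter

FILTER_REASONS = ("kept", "ref_unmapped", "ref_mismatch", "prot_missing", "prot_mismatch")


def filter_orthologs(
    rbm_pairs: list[tuple[str, str]],
    ref_map_a: dict[str, str],
    ref_map_b: dict[str, str],
    prot_a: dict[str, ProteinHit | str],
    prot_b: dict[str, ProteinHit | str],
) -> tuple[list[OrthologPair], dict[tuple[str, str], str]]:
    """Keep RBM pairs that agree on the pooled-reference sequence AND on the
    annotated protein; everything else is dropped with a reason code."""

    def _pid(v) -> str:
        return v.prot_id if isinstance(v, ProteinHit) else v

    kept: list[OrthologPair] = []
    reasons: dict[tuple[str, str], str] = {}
    for a, b in rbm_pairs:
        if a not in ref_map_a or b not in ref_map_b:
            reasons[(a, b)] = "ref_unmapped"
        elif ref_map_a[a] != ref_map_b[b]:
            reasons[(a, b)] = "ref_mismatch"
        elif a not in prot_a or b not in prot_b:
            reasons[(a, b)] = "prot_missing"
        elif _pid(prot_a[a]) != _pid(prot_b[b]):
            reasons[(a, b)] = "prot_mismatch"
        else:
            reasons[(a, b)] = "kept"
            kept.append(
                OrthologPair(id_a=a, id_b=b, ref_id=ref_map_a[a], prot_id=_pid(prot_a[a]))
            )
    return kept, reasons
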