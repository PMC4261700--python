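"""Per-region sequence divergence and Ka/Ks estimation.

Divergence is the number of substitutions divided by the number of base
pairs compared; alignment columns containing a gap or an N on either side
are excluded from the denominator.

Two Ka/Ks estimators are provided side by side:

* NG86 — equal-weight counting of synonymous/nonsynonymous sites and
  pathway-averaged substitution counts, Jukes-Cantor corrected. Transparent
  and exactly checkable by enumeration; used as the oracle.
* YN00-style — the headline approximate method: the transition/transversion
  ratio kappa is estimated from fourfold-degenerate and nondegenerate site
  comparisons, sites are weighted by kappa and position-specific codon
  frequencies (F3x4), mutational pathways are weighted by their rates
  (kappa and the current omega), and pS/pN are corrected with the
  transition/transversion-aware K80 distance; omega is iterated to
  convergence.

Stop-codon conventions (implementations differ, so they are pinned here):
single-base mutants that create a stop are excluded from a position's
site-count denominator and the position's one site is rescaled over the
remaining mutants, so every codon still contributes exactly 3 sites;
mutational pathways passing through a stop codon are dropped before
averaging (all-blocked pairs fall back to unrestricted averaging).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio import Align

from .genetics import (
    BASES,
    CODON_MUTANTS,
    SENSE_CODONS,
    STOP_CODONS,
    codon_degeneracy,
    is_transition,
    translate_codon,
)

# --------------------------------------------------------------- alignment


@dataclass
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # a gap of length L costs gap_open + gap_extend * L
    gap_extend: int = 2


@dataclass
class PairwiseAlignment:
    a: str  # gapped sequence A
    b: str  # gapped sequence B
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped rows must have equal length")


def align_global(seq_a: str, seq_b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    The aligner's first-reported optimum is taken, which is deterministic
    for fixed input.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    from Bio.Align import substitution_matrices

    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            m[x, y] = params.match if (x == y and x != "N") else params.mismatch
    aligner.substitution_matrix = m
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(seq_a, seq_b)
    best = aln[0]
    return PairwiseAlignment(a=str(best[0]), b=str(best[1]), score=float(aln.score))


def count_substitutions(alignment: PairwiseAlignment) -> tuple[int, int]:
    """(substitutions, bases_compared); gap or N columns are excluded."""
    subs = compared = 0
    for x, y in zip(alignment.a, alignment.b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            subs += 1
    return subs, compared


@dataclass
class DivergenceResult:
    pair_id: str
    region: str  # 'utr5' | 'cds' | 'utr3'
    substitutions: int
    bases_compared: int

    @property
    def divergence(self) -> float:
        return self.substitutions / self.bases_compared if self.bases_compared else float("nan")


def region_divergence(
    pair_id: str, region: str, seq_a: str, seq_b: str, params: AlignParams | None = None
) -> DivergenceResult:
    subs, compared = count_substitutions(align_global(seq_a, seq_b, params))
    return DivergenceResult(pair_id, region, subs, compared)


def region_divergence_summary(results: list[DivergenceResult]) -> pd.DataFrame:
    """Per-region pair counts and unweighted mean divergence (fraction and %)."""
    if not results:
        raise ValueError("no divergence results to summarize")
    df = pd.DataFrame(
        {
            "region": [r.region for r in results],
            "divergence": [r.divergence for r in results],
        }
    )
    out = (
        df.groupby("region", sort=False)
        .agg(n_pairs=("divergence", "size"), mean_divergence=("divergence", "mean"))
        .reindex([r for r in ("utr5", "cds", "utr3") if r in set(df["region"])])
    )
    out["mean_divergence_pct"] = 100.0 * out["mean_divergence"]
    return out


# ------------------------------------------------------------ NG86 counting


@lru_cache(maxsize=None)
def ng86_site_count(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    Per position the single site is split by the synonymous fraction among
    the non-stop single-base mutants, so s + n = 3 exactly.
    """
    if codon in STOP_CODONS or codon not in CODON_MUTANTS:
        raise ValueError(f"need an unambiguous sense codon, got {codon!r}")
    s = 0.0
    for pos in range(3):
        muts = [m for m in CODON_MUTANTS[codon] if m[0] == pos and not m[5]]
        if muts:
            s += sum(1 for m in muts if m[4]) / len(muts)
    return s, 3.0 - s


def _step_class(c1: str, c2: str) -> tuple[bool, bool]:
    """(is_synonymous, is_transition) for two codons differing at one site."""
    pos = next(i for i in range(3) if c1[i] != c2[i])
    return translate_codon(c1) == translate_codon(c2), is_transition(c1[pos], c2[pos])


@lru_cache(maxsize=None)
def codon_paths(c1: str, c2: str) -> tuple[tuple[tuple[bool, bool], ...], ...]:
    """All stop-free minimal mutational pathways between two sense codons.

    Each path is a tuple of per-step (is_synonymous, is_transition) labels.
    Falls back to all pathways when every one passes through a stop.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid, blocked = [], []
    for order in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append(_step_class(cur, nxt))
            cur = nxt
        (blocked if through_stop else valid).append(tuple(steps))
    return tuple(valid) if valid else tuple(blocked)


def _pair_differences(
    c1: str, c2: str, kappa: float = 1.0, omega: float = 1.0
) -> tuple[float, float, float, float]:
    """(Sd, Nd, Sd_transitions, Nd_transitions) for one codon pair, averaged
    over minimal pathways weighted by their substitution rates.

    With kappa = omega = 1 the weights are uniform (the NG86 convention).
    """
    if c1 == c2:
        return 0.0, 0.0, 0.0, 0.0
    paths = codon_paths(c1, c2)
    weights = []
    for steps in paths:
        w = 1.0
        for syn, ts in steps:
            w *= (kappa if ts else 1.0) * (1.0 if syn else omega)
        weights.append(w)
    total = sum(weights)
    if total == 0.0:  # omega == 0 with only nonsynonymous paths
        weights = [1.0] * len(paths)
        total = float(len(paths))
    sd = nd = sd_ts = nd_ts = 0.0
    for w, steps in zip(weights, paths):
        f = w / total
        for syn, ts in steps:
            if syn:
                sd += f
                sd_ts += f * ts
            else:
                nd += f
                nd_ts += f * ts
    return sd, nd, sd_ts, nd_ts


@dataclass
class KaKsResult:
    pair_id: str
    method: str  # 'NG86' | 'YN00'
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    kappa: float | None
    Ka: float
    Ks: float
    ratio: float  # nan when undefined (Ks == 0)
    classification: str  # 'positive' | 'purifying' | 'neutral' | 'undefined'
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)


def _classify(ka: float, ks: float) -> tuple[float, str]:
    if ks == 0.0:
        return float("nan"), "undefined"
    r = ka / ks
    if r > 1.0:
        return r, "positive"
    if r < 1.0:
        return r, "purifying"
    return r, "neutral"


def _jc_correct(p: float) -> float | None:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _k80_correct(p_ts: float, q_tv: float) -> float | None:
    a1 = 1.0 - 2.0 * p_ts - q_tv
    a2 = 1.0 - 2.0 * q_tv
    if a1 <= 0.0 or a2 <= 0.0:
        return None
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _usable_codon_pairs(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS pair must be codon-aligned to equal length")
    if len(cds_a) % 3:
        raise ValueError("CDS length must be divisible by 3")
    pairs = []
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in c1 or "N" in c2 or c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        pairs.append((c1, c2))
    return pairs


def codon_align(cds_a: str, cds_b: str, params: AlignParams | None = None) -> tuple[str, str]:
    """Codon-granular alignment of two CDS: equal-length pairs pass through;
    otherwise gap columns of a global alignment are dropped and the tail
    truncated to whole codons (substitution-only data never needs this)."""
    if len(cds_a) == len(cds_b):
        return cds_a, cds_b
    aln = align_global(cds_a, cds_b, params)
    a = "".join(x for x, y in zip(aln.a, aln.b) if x != "-" and y != "-")
    b = "".join(y for x, y in zip(aln.a, aln.b) if x != "-" and y != "-")
    n = (len(a) // 3) * 3
    return a[:n], b[:n]


def ng86_kaks(cds_a: str, cds_b: str, pair_id: str = "") -> KaKsResult:
    """Nei-Gojobori style Ka/Ks with Jukes-Cantor correction."""
    pairs = _usable_codon_pairs(cds_a, cds_b)
    if not pairs:
        raise ValueError("no usable codon pairs")
    s_a = sum(ng86_site_count(c1)[0] for c1, _ in pairs)
    s_b = sum(ng86_site_count(c2)[0] for _, c2 in pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for c1, c2 in pairs:
        sd, nd, _, _ = _pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    flags = []
    ks = _jc_correct(Sd / S) if S > 0 else 0.0
    ka = _jc_correct(Nd / N) if N > 0 else 0.0
    if ks is None or ka is None:
        flags.append("correction_undefined")
        ks = Sd / S if ks is None else ks
        ka = Nd / N if ka is None else ka
    ratio, classification = _classify(ka, ks)
    return KaKsResult(
        pair_id, "NG86", S, N, Sd, Nd, None, ka, ks, ratio, classification,
        n_codons=len(pairs), flags=flags,
    )


# ------------------------------------------------------------- YN00 style


def _f3x4(pairs: list[tuple[str, str]]) -> list[dict[str, float]]:
    """Position-specific nucleotide frequencies pooled over both sequences."""
    counts = [Counter() for _ in range(3)]
    for c1, c2 in pairs:
        for pos in range(3):
            counts[pos][c1[pos]] += 1
            counts[pos][c2[pos]] += 1
    freqs = []
    for pos in range(3):
        total = sum(counts[pos][b] for b in BASES)
        freqs.append({b: (counts[pos][b] / total if total else 0.25) for b in BASES})
    return freqs


def _kappa_from_degenerate_sites(pairs: list[tuple[str, str]]) -> float | None:
    """K80 kappa estimate pooled over fourfold-degenerate and nondegenerate
    sites (positions whose degeneracy class agrees between the two codons),
    weighted by site counts."""
    stats = {0: [0, 0, 0], 3: [0, 0, 0]}  # class -> [sites, ts, tv]
    for c1, c2 in pairs:
        for pos in range(3):
            d1, d2 = codon_degeneracy(c1, pos), codon_degeneracy(c2, pos)
            if d1 != d2 or d1 not in stats:
                continue
            stats[d1][0] += 1
            if c1[pos] != c2[pos]:
                stats[d1][1 if is_transition(c1[pos], c2[pos]) else 2] += 1
    estimates, weights = [], []
    for cls, (n, ts, tv) in stats.items():
        if n == 0:
            continue
        P, Q = ts / n, tv / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0.0 or a2 <= 0.0:
            continue
        l1, l2 = -math.log(a1), -math.log(a2)
        if l2 <= 0.0:
            continue  # no transversions observed in this class
        estimates.append((2.0 * l1 - l2) / l2)
        weights.append(n)
    if not estimates:
        return None
    k = float(np.average(estimates, weights=weights))
    return min(max(k, 0.01), 100.0)


def _weighted_site_count(
    codon: str, kappa: float, freqs: list[dict[str, float]] | None
) -> float:
    """Synonymous site count of one codon with mutation rates weighted by
    kappa and (optionally) F3x4 target-base frequencies."""
    s = 0.0
    for pos in range(3):
        muts = [m for m in CODON_MUTANTS[codon] if m[0] == pos and not m[5]]
        if not muts:
            continue
        weights = []
        for _pos, b, _m, ts, _syn, _stop in muts:
            w = kappa if ts else 1.0
            if freqs is not None:
                w *= freqs[pos][b]
            weights.append(w)
        total = sum(weights)
        if total == 0.0:
            continue
        s += sum(w for w, m in zip(weights, muts) if m[4]) / total
    return s


def yn00_kaks(
    cds_a: str,
    cds_b: str,
    pair_id: str = "",
    kappa: float | None = None,
    codon_freqs: str = "f3x4",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> KaKsResult:
    """Approximate Ka/Ks accounting for transition bias and codon usage.

    ``kappa=None`` estimates kappa from degenerate-site comparisons;
    ``codon_freqs`` is ``'f3x4'`` or ``'uniform'``. Non-convergence of the
    omega iteration is flagged and the last iterate returned.
    """
    pairs = _usable_codon_pairs(cds_a, cds_b)
    if not pairs:
        raise ValueError("no usable codon pairs")
    flags: list[str] = []
    if kappa is None:
        kappa = _kappa_from_degenerate_sites(pairs)
        if kappa is None:
            kappa = 1.0
            flags.append("kappa_fallback")
    freqs = _f3x4(pairs) if codon_freqs == "f3x4" else None

    s_a = sum(_weighted_site_count(c1, kappa, freqs) for c1, _ in pairs)
    s_b = sum(_weighted_site_count(c2, kappa, freqs) for _, c2 in pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(pairs) - S

    omega = 1.0
    converged = False
    Sd = Nd = sd_ts = nd_ts = 0.0
    ka = ks = 0.0
    for _ in range(max_iter):
        Sd = Nd = sd_ts = nd_ts = 0.0
        for c1, c2 in pairs:
            sd, nd, sts, nts = _pair_differences(c1, c2, kappa=kappa, omega=omega)
            Sd += sd
            Nd += nd
            sd_ts += sts
            nd_ts += nts
        ks = _correct_class(Sd, sd_ts, S, flags, "ks")
        ka = _correct_class(Nd, nd_ts, N, flags, "ka")
        if ks == 0.0:
            break
        omega_new = ka / ks
        if abs(omega_new - omega) < tol:
            omega = omega_new
            converged = True
            break
        omega = omega_new
    if not converged and ks > 0.0:
        flags.append("not_converged")
        flags.append("ng86_fallback_available")
    ratio, classification = _classify(ka, ks)
    return KaKsResult(
        pair_id, "YN00", S, N, Sd, Nd, kappa, ka, ks, ratio, classification,
        n_codons=len(pairs), flags=sorted(set(flags)),
    )


def _correct_class(d: float, d_ts: float, sites: float, flags: list[str], tag: str) -> float:
    if sites <= 0.0 or d == 0.0:
        return 0.0
    p_ts, q_tv = d_ts / sites, (d - d_ts) / sites
    corrected = _k80_correct(p_ts, q_tv)
    if corrected is None:
        corrected = _jc_correct(d / sites)
        if corrected is None:
            flags.append(f"{tag}_correction_undefined")
            corrected = d / sites
    return corrected


# ------------------------------------------------------------ classification


@dataclass
class SelectionSummary:
    classes: dict[str, str]
    tallies: dict[str, int]
    bands: dict[str, int]  # '>1', '0.5-1', '<0.5', 'undefined'
    n_positive: int


def classify_selection(results: list[KaKsResult], threshold: float = 1.0) -> SelectionSummary:
    """Per-pair selection classes plus the summary banding.

    Ka/Ks above the threshold is positive selection, below is purifying;
    Ks = 0 pairs are tallied separately as undefined rather than inflating
    the positive count.
    """
    if not results:
        raise ValueError("no Ka/Ks results to classify")
    classes: dict[str, str] = {}
    bands = {">1": 0, "0.5-1": 0, "<0.5": 0, "undefined": 0}
    for r in results:
        classes[r.pair_id] = r.classification
        if math.isnan(r.ratio):
            bands["undefined"] += 1
        elif r.ratio > threshold:
            bands[">1"] += 1
        elif r.ratio >= 0.5:
            bands["0.5-1"] += 1
        else:
            bands["<0.5"] += 1
    tallies = dict(Counter(classes.values()))
    return SelectionSummary(
        classes=classes,
        tallies=tallies,
        bands=bands,
        n_positive=sum(1 for c in classes.values() if c == "positive"),
    )


def kaks_table(results: list[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": r.pair_id,
                "method": r.method,
                "S": r.S_sites,
                "N": r.N_sites,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "kappa": r.kappa,
                "Ka": r.Ka,
                "Ks": r.Ks,
                "ratio": r.ratio,
                "class": r.classification,
            }
            for r in results
        ]
    )
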