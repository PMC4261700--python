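"""Standard genetic code tables and codon mutation bookkeeping.

Everything downstream (the codon-evolution simulator and the Ka/Ks
estimators) shares these tables so that "synonymous" and "transition" mean
exactly the same thing on both sides.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(b1: str, b2: str) -> bool:
    """True for A<->G and C<->T substitutions."""
    return (b1 in _PURINES and b2 in _PURINES) or (b1 in _PYRIMIDINES and b2 in _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stops, 'X' if ambiguous."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon, "X")


# For every sense codon: the 9 single-base mutants as
# (position, new_base, mutant_codon, is_transition, is_synonymous, is_stop).
CODON_MUTANTS: dict[str, list[tuple[int, str, str, bool, bool, bool]]] = {}
for _codon in SENSE_CODONS:
    _muts = []
    for _pos in range(3):
        for _b in BASES:
            if _b == _codon[_pos]:
                continue
            _m = _codon[:_pos] + _b + _codon[_pos + 1 :]
            _stop = _m in STOP_CODONS
            _syn = (not _stop) and CODON_TO_AA[_m] == CODON_TO_AA[_codon]
            _muts.append((_pos, _b, _m, is_transition(_codon[_pos], _b), _syn, _stop))
    CODON_MUTANTS[_codon] = _muts


def codon_degeneracy(codon: str, pos: int) -> int:
    """Number of synonymous single-base alternatives at ``pos`` (0, 1, 2 or 3).

    3 marks a fourfold-degenerate site, 0 a nondegenerate one.
    """
    return sum(1 for p, _b, _m, _ts, syn, _st in CODON_MUTANTS[codon] if p == pos and syn)
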