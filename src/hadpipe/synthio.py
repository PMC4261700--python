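"""Synthetic ortholog pairs and count matrices with known ground truth.

The generator emulates the setting the analysis assumes: a single ancestral
transcript pool whose copies diverge on two host plants. Each gene is an
ancestral transcript (5'UTR + ATG-initiated, stop-terminated CDS + 3'UTR);
the "derived" copy carries substitutions placed independently per region —
UTRs at a flat per-site rate, the CDS codon-by-codon under a kappa/omega
weighted scheme whose expected nonsynonymous/synonymous rate ratio equals
the gene's omega. Count matrices are drawn multinomially from a shared
abundance vector with planted fold-changes.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; identical configs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetics import BASES, SENSE_CODONS, STOP_CODONS, is_transition, translate_codon
from .records import ProteinRef, Transcript, write_fasta

_START = "ATG"
_STOPS = tuple(sorted(STOP_CODONS))
_NONSTART_SENSE = tuple(c for c in SENSE_CODONS if c != _START)


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Region lengths are (mean, min) pairs in base pairs; realized CDS lengths
    are rounded to whole codons. Divergence targets ``d_*`` are expected
    per-site substitution fractions. ``omega`` fixes a single dN/dS for every
    gene; when None, genes draw from a two-component mixture
    (``fraction_positive`` of genes at ``omega_positive`` > 1, the rest at
    ``omega_purifying`` < 1).
    """

    n_genes: int = 200
    utr5_len: tuple[int, int] = (150, 30)
    cds_len: tuple[int, int] = (900, 300)
    utr3_len: tuple[int, int] = (250, 30)
    d_utr5: float = 0.0023
    d_cds_target: float = 0.0013
    d_utr3: float = 0.0019
    omega: float | None = None
    fraction_positive: float = 0.05
    omega_positive: float = 2.0
    omega_purifying: float = 0.2
    kappa: float = 2.0
    n_samples: int = 2
    lib_size: int = 1_000_000
    frac_de: float = 0.05
    fold_change: float = 4.0
    frac_decoy: float = 0.10
    strain_original: str = "Ca"
    strain_derived: str = "Co"
    sex: str = "f"
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("d_utr5", "d_cds_target", "d_utr3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2], got {v}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must lie in [0, 1]")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be nonnegative")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            mean, lo = getattr(self, name)
            if lo < 0 or mean < lo:
                raise ValueError(f"{name}: need 0 <= min <= mean, got {(mean, lo)}")
        if self.cds_len[1] % 3:
            raise ValueError("cds_len minimum must be divisible by 3")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass
class SimTruth:
    """Ground truth for recovery tests: who pairs with whom, where the
    regions are, how many substitutions of each kind were placed, and which
    genes carry planted expression changes."""

    ortholog_map: dict[str, str] = field(default_factory=dict)
    region_coords: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    sub_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)
    de_up: dict[str, set[str]] = field(default_factory=dict)
    de_down: dict[str, set[str]] = field(default_factory=dict)
    decoy_ids: set[str] = field(default_factory=set)


@dataclass
class CountMatrix:
    """Gene x sample counts with library sizes and (strain, sex) labels."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index = sample ids; columns: strain, sex
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample labels do not match count columns")
        colsum = self.counts.sum(axis=0)
        if self.lib_sizes is None:
            self.lib_sizes = colsum.astype(float)
        else:
            self.lib_sizes = self.lib_sizes.astype(float)
            if (self.lib_sizes < colsum - 1e-9).any():
                raise ValueError("supplied library sizes are below column sums")


def _draw_len(rng: np.random.Generator, dist: tuple[int, int]) -> int:
    mean, lo = dist
    return lo + int(rng.poisson(max(mean - lo, 0)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTART_SENSE, size=max(n_codons - 1, 0))
    return _START + "".join(body)


def _mutate_utr(rng: np.random.Generator, seq: str, rate: float, replace: bool) -> tuple[str, int]:
    if not seq or rate == 0:
        return seq, 0
    n_sub = int(rng.binomial(len(seq), rate))
    n_sub = min(n_sub, len(seq)) if not replace else n_sub
    if n_sub == 0:
        return seq, 0
    sites = rng.choice(len(seq), size=n_sub, replace=replace)
    chars = list(seq)
    for s in sites:
        alternatives = [b for b in BASES if b != chars[s]]
        chars[s] = alternatives[int(rng.integers(3))]
    # with replacement a site can revert; realized count is still the number
    # of placement events, which is what the truth table records
    return "".join(chars), n_sub


def _mutate_cds(
    rng: np.random.Generator,
    cds: str,
    rate: float,
    kappa: float,
    omega: float,
    replace: bool,
) -> tuple[str, int, int]:
    """Place substitutions codon-by-codon.

    Candidate draws: site uniform, target base with transition weight kappa,
    nonsynonymous changes accepted with probability proportional to omega,
    stop-creating changes always rejected and resampled. Returns the mutated
    CDS and the realized (synonymous, nonsynonymous) counts.
    """
    n = len(cds)
    if n == 0 or rate == 0:
        return cds, 0, 0
    n_sub = int(rng.binomial(n, rate))
    if not replace:
        n_sub = min(n_sub, n)
    if n_sub == 0:
        return cds, 0, 0
    chars = list(cds)
    available = list(range(n))
    w_max = max(1.0, omega)
    syn_count = nonsyn_count = 0
    # transition target gets weight kappa, each transversion target weight 1
    for _ in range(n_sub):
        for attempt in range(1000):
            idx = int(rng.integers(len(available)))
            site = available[idx]
            cstart = site - site % 3
            codon = "".join(chars[cstart : cstart + 3])
            pos = site - cstart
            cur = chars[site]
            targets = [b for b in BASES if b != cur]
            weights = np.array([kappa if is_transition(cur, b) else 1.0 for b in targets])
            b = targets[int(rng.choice(3, p=weights / weights.sum()))]
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            syn = translate_codon(mutant) == translate_codon(codon)
            w = 1.0 if syn else omega
            if rng.random() < w / w_max:
                chars[site] = b
                if syn:
                    syn_count += 1
                else:
                    nonsyn_count += 1
                if not replace:
                    available.pop(idx)
                break
        else:
            raise RuntimeError(
                "codon mutation resampling failed 1000 times; "
                "config is incompatible with the stop-avoidance rule"
            )
    return "".join(chars), syn_count, nonsyn_count


def simulate_transcript_pairs(
    config: SimConfig,
) -> tuple[list[Transcript], list[Transcript], list[ProteinRef], SimTruth]:
    """Generate matched original/derived transcript sets with ground truth.

    Each gene contributes one transcript per strain plus one reference
    protein (the ancestral CDS translation). ``frac_decoy`` of extra random
    transcripts are planted in each set to exercise the ortholog filters.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    original: list[Transcript] = []
    derived: list[Transcript] = []
    proteins: list[ProteinRef] = []

    if config.omega is not None:
        omegas = np.full(config.n_genes, float(config.omega))
    else:
        pos = rng.random(config.n_genes) < config.fraction_positive
        omegas = np.where(pos, config.omega_positive, config.omega_purifying)

    for i in range(config.n_genes):
        gene = f"g{i + 1}"
        u5 = _random_seq(rng, _draw_len(rng, config.utr5_len))
        n_codons = max(config.cds_len[1] // 3, _draw_len(rng, config.cds_len) // 3)
        cds = _random_cds(rng, n_codons)
        stop = _STOPS[int(rng.integers(len(_STOPS)))]
        u3 = _random_seq(rng, _draw_len(rng, config.utr3_len))

        omega = float(omegas[i])
        du5, n_u5 = _mutate_utr(rng, u5, config.d_utr5, config.with_replacement)
        dcds, n_syn, n_nonsyn = _mutate_cds(
            rng, cds, config.d_cds_target, config.kappa, omega, config.with_replacement
        )
        du3, n_u3 = _mutate_utr(rng, u3, config.d_utr3, config.with_replacement)

        id_a = f"{gene}_{config.strain_original}"
        id_b = f"{gene}_{config.strain_derived}"
        seq_a = u5 + cds + stop + u3
        seq_b = du5 + dcds + stop + du3
        original.append(Transcript(id_a, seq_a, config.strain_original, config.sex))
        derived.append(Transcript(id_b, seq_b, config.strain_derived, config.sex))
        prot = "".join(translate_codon(cds[j : j + 3]) for j in range(0, len(cds), 3))
        proteins.append(ProteinRef(id=f"p{i + 1}", seq=prot))

        coords = {
            "utr5": (0, len(u5)),
            "cds": (len(u5), len(u5) + len(cds)),
            "stop": (len(u5) + len(cds), len(u5) + len(cds) + 3),
            "utr3": (len(u5) + len(cds) + 3, len(seq_a)),
        }
        truth.ortholog_map[id_a] = id_b
        truth.region_coords[id_a] = coords
        truth.region_coords[id_b] = dict(coords)
        truth.sub_counts[gene] = {
            "utr5": n_u5,
            "cds": n_syn + n_nonsyn,
            "utr3": n_u3,
            "syn": n_syn,
            "nonsyn": n_nonsyn,
        }
        truth.omega[gene] = omega

    n_decoy = int(round(config.frac_decoy * config.n_genes))
    mean_len = config.utr5_len[0] + config.cds_len[0] + config.utr3_len[0]
    for k in range(n_decoy):
        for strain, bucket in ((config.strain_original, original), (config.strain_derived, derived)):
            did = f"d{k + 1}_{strain}"
            bucket.append(
                Transcript(did, _random_seq(rng, max(60, int(rng.poisson(mean_len)))), strain, config.sex)
            )
            truth.decoy_ids.add(did)
    return original, derived, proteins, truth


def simulate_count_matrix(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a gene x sample count matrix from a shared abundance vector.

    Sample 1 is the original-host library; the rest are derived-host
    libraries. Null genes share one abundance across samples. Planted "up"
    genes (higher in the original host) have their abundance multiplied by
    ``fold_change`` in the original library; "down" genes are multiplied by
    it in the derived libraries. Counts are multinomial draws to
    ``lib_size`` per library.
    """
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if config.lib_size < config.n_genes:
        raise ValueError(
            f"lib_size {config.lib_size} too small to represent {config.n_genes} genes"
        )
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"g{i + 1}" for i in range(config.n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    up_idx = de_idx[: n_de // 2 + n_de % 2]
    down_idx = de_idx[n_de // 2 + n_de % 2 :]

    abund = np.tile(base[:, None], (1, config.n_samples))
    abund[up_idx, 0] *= config.fold_change
    abund[down_idx, 1:] *= config.fold_change

    mat = np.empty((config.n_genes, config.n_samples), dtype=np.int64)
    for j in range(config.n_samples):
        p = abund[:, j] / abund[:, j].sum()
        mat[:, j] = rng.multinomial(config.lib_size, p)

    sample_ids = [f"{config.strain_original}{config.sex}"] + [
        f"{config.strain_derived}{config.sex}" if config.n_samples == 2 else f"S{j + 1}"
        for j in range(1, config.n_samples)
    ]
    samples = pd.DataFrame(
        {
            "strain": [config.strain_original] + [config.strain_derived] * (config.n_samples - 1),
            "sex": [config.sex] * config.n_samples,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples.index)
    cm = CountMatrix(counts=counts, samples=samples)

    truth = SimTruth()
    up = {genes[i] for i in up_idx}
    down = {genes[i] for i in down_idx}
    for j in range(1, config.n_samples):
        contrast = f"{sample_ids[0]}/{sample_ids[j]}"
        truth.de_up[contrast] = set(up)
        truth.de_down[contrast] = set(down)
    return cm, truth


# ---------------------------------------------------------------- fixtures


def write_fixtures(
    directory: str | Path,
    *,
    original: list[Transcript] | None = None,
    derived: list[Transcript] | None = None,
    proteins: list[ProteinRef] | None = None,
    truth: SimTruth | None = None,
    counts: CountMatrix | None = None,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write a self-contained fixture directory (FASTA + TSV + YAML).

    Everything round-trips losslessly through this module's readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if original is not None:
        paths["original"] = write_fasta(original, directory / "original.fasta")
    if derived is not None:
        paths["derived"] = write_fasta(derived, directory / "derived.fasta")
    if proteins is not None:
        paths["proteins"] = write_fasta(proteins, directory / "proteins.fasta")
    if counts is not None:
        p = directory / "counts.tsv"
        counts.counts.to_csv(p, sep="\t")
        counts.samples.to_csv(directory / "samples.tsv", sep="\t")
        paths["counts"] = p
        paths["samples"] = directory / "samples.tsv"
    if truth is not None:
        paths.update(_write_truth(truth, directory))
    if config is not None:
        p = directory / "config.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
        paths["config"] = p
    return paths


def _write_truth(truth: SimTruth, directory: Path) -> dict[str, Path]:
    paths = {}
    p = directory / "truth_orthologs.tsv"
    pd.DataFrame(
        sorted(truth.ortholog_map.items()), columns=["original_id", "derived_id"]
    ).to_csv(p, sep="\t", index=False)
    paths["truth_orthologs"] = p

    rows = [
        {"transcript_id": tid, "region": region, "start": s, "end": e}
        for tid, regions in sorted(truth.region_coords.items())
        for region, (s, e) in regions.items()
    ]
    p = directory / "truth_regions.tsv"
    pd.DataFrame(rows, columns=["transcript_id", "region", "start", "end"]).to_csv(
        p, sep="\t", index=False
    )
    paths["truth_regions"] = p

    rows = [
        {"gene": g, **counts, "omega": truth.omega.get(g, float("nan"))}
        for g, counts in sorted(truth.sub_counts.items())
    ]
    p = directory / "truth_substitutions.tsv"
    pd.DataFrame(
        rows, columns=["gene", "utr5", "cds", "utr3", "syn", "nonsyn", "omega"]
    ).to_csv(p, sep="\t", index=False)
    paths["truth_substitutions"] = p

    p = directory / "truth_de.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "de_up": {k: sorted(v) for k, v in truth.de_up.items()},
                "de_down": {k: sorted(v) for k, v in truth.de_down.items()},
                "decoy_ids": sorted(truth.decoy_ids),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["truth_de"] = p
    return paths


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples = samples.astype({"strain": str, "sex": str})
    return CountMatrix(counts=counts, samples=samples)


def read_truth(directory: str | Path) -> SimTruth:
    directory = Path(directory)
    truth = SimTruth()
    p = directory / "truth_orthologs.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        truth.ortholog_map = dict(zip(df["original_id"], df["derived_id"]))
    p = directory / "truth_regions.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for tid, grp in df.groupby("transcript_id"):
            truth.region_coords[tid] = {
                r["region"]: (int(r["start"]), int(r["end"])) for _, r in grp.iterrows()
            }
    p = directory / "truth_substitutions.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for _, r in df.iterrows():
            truth.sub_counts[r["gene"]] = {
                k: int(r[k]) for k in ("utr5", "cds", "utr3", "syn", "nonsyn")
            }
            truth.omega[r["gene"]] = float(r["omega"])
    p = directory / "truth_de.json"
    if p.exists():
        with open(p) as fh:
            d = json.load(fh)
        truth.de_up = {k: set(v) for k, v in d["de_up"].items()}
        truth.de_down = {k: set(v) for k, v in d["de_down"].items()}
        truth.decoy_ids = set(d["decoy_ids"])
    return truth
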