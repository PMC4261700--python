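"""End-to-end orchestration: ortholog pairing -> annotation -> divergence /
Ka/Ks reports, and count-matrix -> DE reports with intersections.

Every run can be written to a directory as TSV/JSON together with a
provenance file (config + seed + package version) sufficient to reproduce
the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import RegionAnnotation, Rejection, locate_cds, pair_regions, to_gff_lines
from .diffexpr import (
    call_dets,
    det_tallies,
    intersect_up_sets,
    mars_table,
    qvalues,
    sample_correlations,
    tmm_normalization,
)
from .divergence import (
    DivergenceResult,
    KaKsResult,
    classify_selection,
    codon_align,
    kaks_table,
    ng86_kaks,
    region_divergence,
    region_divergence_summary,
    yn00_kaks,
)
from .orthology import (
    SearchParams,
    best_protein_matches,
    filter_orthologs,
    map_to_reference,
    reciprocal_best_matches,
    similarity_search,
    transpose_hits,
)
from .records import ProteinRef, Transcript
from .synthio import CountMatrix

log = logging.getLogger("hadpipe")


@dataclass
class DivergenceRun:
    """Everything one Table-1-style contrast produces."""

    contrast: str
    n_matched: int
    n_orthologs: int
    summary: pd.DataFrame
    divergences: list[DivergenceResult]
    kaks_ng86: list[KaKsResult]
    kaks_yn00: list[KaKsResult]
    n_positive: int
    filter_reasons: dict[tuple[str, str], str]
    annotations: dict[str, RegionAnnotation]
    rejections: list[Rejection]
    attrition: list[str] = field(default_factory=list)

    def report_row(self) -> dict:
        """One row mirroring the divergence summary table: matched count,
        ortholog count, per-region pair counts with mean % divergence, and
        the number of pairs under positive selection."""
        row: dict = {
            "contrast": self.contrast,
            "matched_sequences": self.n_matched,
            "orthologs": self.n_orthologs,
        }
        for region in ("utr5", "cds", "utr3"):
            if region in self.summary.index:
                row[f"{region}_pairs"] = int(self.summary.loc[region, "n_pairs"])
                row[f"{region}_divergence_pct"] = round(
                    float(self.summary.loc[region, "mean_divergence_pct"]), 2
                )
            else:
                row[f"{region}_pairs"] = 0
                row[f"{region}_divergence_pct"] = float("nan")
        row["kaks_gt1"] = self.n_positive
        return row


def run_divergence(
    original: list[Transcript],
    derived: list[Transcript],
    proteins: list[ProteinRef],
    reference: list[Transcript] | None = None,
    contrast: str = "original/derived",
    search_params: SearchParams | None = None,
    protein_cutoff: float = 50.0,
    min_cds_len: int = 150,
    min_region_len: int = 10,
) -> DivergenceRun:
    """Full divergence contrast between two transcript sets.

    ``reference`` is the pooled reference transcriptome; when omitted the
    original set doubles as the pool (appropriate for synthetic runs where
    the originals are the ancestral sequences).
    """
    attrition = []
    reference = reference if reference is not None else original

    hits_ab = similarity_search(original, derived, search_params)
    hits_ba = transpose_hits(hits_ab)  # local scores are symmetric
    rbm = reciprocal_best_matches(hits_ab, hits_ba)
    attrition.append(f"reciprocal best matches: {len(rbm)}")
    log.info("reciprocal best matches: %d", len(rbm))

    in_pairs_a = {a for a, _ in rbm}
    in_pairs_b = {b for _, b in rbm}
    sub_a = [t for t in original if t.id in in_pairs_a]
    sub_b = [t for t in derived if t.id in in_pairs_b]
    ref_map_a = map_to_reference(sub_a, reference, search_params) if rbm else {}
    ref_map_b = map_to_reference(sub_b, reference, search_params) if rbm else {}
    prot_a = best_protein_matches(sub_a, proteins, protein_cutoff) if rbm else {}
    prot_b = best_protein_matches(sub_b, proteins, protein_cutoff) if rbm else {}
    pairs, reasons = filter_orthologs(rbm, ref_map_a, ref_map_b, prot_a, prot_b)
    attrition.append(f"orthologs after double filter: {len(pairs)}")
    log.info("orthologs after double filter: %d", len(pairs))

    by_id_a = {t.id: t for t in original}
    by_id_b = {t.id: t for t in derived}
    annotations: dict[str, RegionAnnotation] = {}
    rejections: list[Rejection] = []
    divergences: list[DivergenceResult] = []
    ng86_results: list[KaKsResult] = []
    yn00_results: list[KaKsResult] = []
    n_annotated_pairs = 0
    for pair in pairs:
        ta, tb = by_id_a[pair.id_a], by_id_b[pair.id_b]
        ann_a = locate_cds(ta, prot_a[pair.id_a], min_cds_len)
        ann_b = locate_cds(tb, prot_b[pair.id_b], min_cds_len)
        bad = [r for r in (ann_a, ann_b) if isinstance(r, Rejection)]
        if bad:
            rejections.extend(bad)
            continue
        annotations[pair.id_a] = ann_a
        annotations[pair.id_b] = ann_b
        n_annotated_pairs += 1
        pair_id = f"{pair.id_a}|{pair.id_b}"
        regions = pair_regions(ta, ann_a, tb, ann_b, min_region_len)
        cds_pair = None
        for region, sa, sb in regions:
            divergences.append(region_divergence(pair_id, region, sa, sb))
            if region == "cds":
                cds_pair = (sa, sb)
        if cds_pair is not None:
            ca, cb = codon_align(*cds_pair)
            if ca:
                ng86_results.append(ng86_kaks(ca, cb, pair_id))
                yn00_results.append(yn00_kaks(ca, cb, pair_id))
    attrition.append(f"annotated ortholog pairs: {n_annotated_pairs} (rejected: {len(rejections)})")
    log.info("annotated ortholog pairs: %d (rejected %d)", n_annotated_pairs, len(rejections))

    summary = (
        region_divergence_summary(divergences)
        if divergences
        else pd.DataFrame(columns=["n_pairs", "mean_divergence", "mean_divergence_pct"])
    )
    n_positive = classify_selection(yn00_results).n_positive if yn00_results else 0
    return DivergenceRun(
        contrast=contrast,
        n_matched=len(rbm),
        n_orthologs=len(pairs),
        summary=summary,
        divergences=divergences,
        kaks_ng86=ng86_results,
        kaks_yn00=yn00_results,
        n_positive=n_positive,
        filter_reasons=reasons,
        annotations=annotations,
        rejections=rejections,
        attrition=attrition,
    )


def write_divergence_run(run: DivergenceRun, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "divergence_report.tsv"
    pd.DataFrame([run.report_row()]).to_csv(p, sep="\t", index=False)
    paths["report"] = p

    p = outdir / "region_divergence.tsv"
    pd.DataFrame(
        [
            {
                "pair": d.pair_id,
                "region": d.region,
                "subs": d.substitutions,
                "bases": d.bases_compared,
                "divergence": d.divergence,
            }
            for d in run.divergences
        ],
        columns=["pair", "region", "subs", "bases", "divergence"],
    ).to_csv(p, sep="\t", index=False)
    paths["region_divergence"] = p

    for name, results in (("ng86", run.kaks_ng86), ("yn00", run.kaks_yn00)):
        p = outdir / f"kaks_{name}.tsv"
        kaks_table(results).to_csv(p, sep="\t", index=False)
        paths[f"kaks_{name}"] = p

    p = outdir / "annotations.gff"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in sorted(run.annotations):
            for line in to_gff_lines(run.annotations[tid]):
                fh.write(line + "\n")
    paths["annotations"] = p

    p = outdir / "summary.json"
    bands = classify_selection(run.kaks_yn00).bands if run.kaks_yn00 else {}
    with open(p, "w") as fh:
        json.dump(
            {
                "report": run.report_row(),
                "selection_bands": bands,
                "attrition": run.attrition,
                "filter_reasons": {
                    f"{a}|{b}": r for (a, b), r in sorted(run.filter_reasons.items())
                },
            },
            fh,
            indent=1,
            sort_keys=True,
            allow_nan=True,
        )
    paths["summary"] = p
    return paths


# ------------------------------------------------------------------- DE


@dataclass
class DERun:
    tallies: dict[str, dict[str, int]]  # contrast -> {up, down, total_de}
    results: dict[str, pd.DataFrame]  # contrast -> per-gene table with calls
    up_sets: dict[str, set[str]]
    intersections: dict[str, set[str]]
    factors: pd.Series
    correlations: pd.DataFrame


def run_de(
    cm: CountMatrix,
    contrasts: list[tuple[str, str]] | None = None,
    original_strain: str | None = None,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    stat_col: str = "q",
    qvalue_method: str = "storey",
) -> DERun:
    """Two-library DE over every (original, derived) contrast.

    Contrasts default to the original-strain library vs every derived-host
    library of the same sex; ``original_strain`` defaults to the strain of
    the first sample column.
    """
    samples = cm.samples
    if contrasts is None:
        if original_strain is None:
            original_strain = str(samples["strain"].iloc[0])
        contrasts = []
        for sex in samples["sex"].unique():
            sex_samples = samples[samples["sex"] == sex]
            orig = sex_samples[sex_samples["strain"] == original_strain]
            rest = sex_samples[sex_samples["strain"] != original_strain]
            for o in orig.index:
                contrasts.extend((o, d) for d in rest.index)
    if not contrasts:
        raise ValueError("no contrasts to test")

    factors = tmm_normalization(cm.counts, cm.lib_sizes)
    correlations = sample_correlations(cm.counts, cm.lib_sizes, factors)

    tallies, results, up_sets, sex_of = {}, {}, {}, {}
    for o, d in contrasts:
        name = f"{o}/{d}"
        tab = mars_table(cm.counts, o, d, cm.lib_sizes, factors)
        tab["q"] = qvalues(tab["p"].to_numpy(), method=qvalue_method)
        called = call_dets(tab, q_max, min_abs_log2fc, stat_col=stat_col)
        results[name] = called
        tallies[name] = det_tallies(called)
        up_sets[name] = set(called.index[called["call"] == "up"])
        sex_of[name] = str(samples.loc[o, "sex"])
        log.info("%s: %s", name, tallies[name])

    intersections = intersect_up_sets(up_sets, sex_of)
    return DERun(
        tallies=tallies,
        results=results,
        up_sets=up_sets,
        intersections=intersections,
        factors=factors,
        correlations=correlations,
    )


def write_de_run(run: DERun, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "de_report.tsv"
    pd.DataFrame(
        [{"contrast": c, **t} for c, t in sorted(run.tallies.items())]
    ).to_csv(p, sep="\t", index=False)
    paths["report"] = p
    for contrast, tab in run.results.items():
        safe = contrast.replace("/", "_vs_")
        q = outdir / f"de_{safe}.tsv"
        tab.to_csv(q, sep="\t")
        paths[f"de_{safe}"] = q
    p = outdir / "intersections.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "up_sets": {k: sorted(v) for k, v in run.up_sets.items()},
                "intersections": {k: sorted(v) for k, v in run.intersections.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["intersections"] = p
    p = outdir / "normalization_factors.tsv"
    run.factors.rename("factor").to_csv(p, sep="\t")
    paths["factors"] = p
    p = outdir / "sample_correlations.tsv"
    run.correlations.to_csv(p, sep="\t")
    paths["correlations"] = p
    return paths


def write_provenance(outdir: str | Path, config: object, seed: int | None) -> Path:
    """Machine-readable record (config + seed + version) that reproduces a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    p = outdir / "provenance.json"
    with open(p, "w") as fh:
        json.dump(
            {"config": config, "seed": seed, "version": __version__},
            fh,
            indent=1,
            sort_keys=True,
            default=str,
        )
    return p
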