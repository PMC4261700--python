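"""The generator's output must carry exactly the structure its truth tables claim."""

import numpy as np
import pytest

from hadpipe.genetics import STOP_CODONS, translate_codon
from hadpipe.records import read_transcripts
from hadpipe.synthio import (
    SimConfig,
    read_counts,
    read_truth,
    simulate_count_matrix,
    simulate_transcript_pairs,
    write_fixtures,
)


def _translate(seq):
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3))


def _regions(truth, tid, seq):
    c = truth.region_coords[tid]
    return {r: seq[s:e] for r, (s, e) in c.items()}


def test_zero_rates_give_identical_pairs(zero_rate_study):
    _, original, derived, _, truth = zero_rate_study
    by_id = {t.id: t for t in derived}
    for a in original:
        if a.id in truth.decoy_ids:
            continue
        assert by_id[truth.ortholog_map[a.id]].seq == a.seq
    assert all(
        all(v == 0 for v in counts.values()) for counts in truth.sub_counts.values()
    )


def test_omega_zero_forbids_amino_acid_change():
    cfg = SimConfig(n_genes=30, omega=0.0, d_cds_target=0.05, seed=5, frac_decoy=0.0)
    original, derived, _, truth = simulate_transcript_pairs(cfg)
    by_id = {t.id: t for t in derived}
    for a in original:
        b = by_id[truth.ortholog_map[a.id]]
        ra, rb = _regions(truth, a.id, a.seq), _regions(truth, b.id, b.seq)
        assert _translate(ra["cds"]) == _translate(rb["cds"])
    assert all(c["nonsyn"] == 0 for c in truth.sub_counts.values())


def test_cds_structure_and_protein_consistency(small_study):
    cfg, original, _, proteins, truth = small_study
    prot = {p.id: p.seq for p in proteins}
    for i, a in enumerate(t for t in original if t.id not in truth.decoy_ids):
        r = _regions(truth, a.id, a.seq)
        assert r["cds"].startswith("ATG")
        assert len(r["cds"]) % 3 == 0
        assert a.seq[truth.region_coords[a.id]["stop"][0] :][:3] in STOP_CODONS
        assert "*" not in _translate(r["cds"])
        assert prot[f"p{i + 1}"] == _translate(r["cds"])


def test_truth_substitution_counts_are_recountable(small_study):
    """Without repeat hits, truth counts equal observable per-region differences."""
    _, original, derived, _, truth = small_study
    by_id = {t.id: t for t in derived}
    for a in original:
        if a.id in truth.decoy_ids:
            continue
        b = by_id[truth.ortholog_map[a.id]]
        gene = a.id.split("_")[0]
        ra, rb = _regions(truth, a.id, a.seq), _regions(truth, b.id, b.seq)
        for region in ("utr5", "cds", "utr3"):
            observed = sum(x != y for x, y in zip(ra[region], rb[region]))
            assert observed == truth.sub_counts[gene][region]


def test_determinism_same_seed_same_fasta(tmp_path):
    cfg = SimConfig(n_genes=10, seed=7)
    for d in ("one", "two"):
        out = simulate_transcript_pairs(cfg)
        write_fixtures(tmp_path / d, original=out[0], derived=out[1], proteins=out[2])
    for name in ("original.fasta", "derived.fasta", "proteins.fasta"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_ortholog_map_is_bijection(small_study):
    _, original, derived, _, truth = small_study
    assert len(set(truth.ortholog_map.values())) == len(truth.ortholog_map)
    originals = {t.id for t in original} - truth.decoy_ids
    deriveds = {t.id for t in derived} - truth.decoy_ids
    assert set(truth.ortholog_map) == originals
    assert set(truth.ortholog_map.values()) == deriveds


def test_utr_divergence_recovers_configured_rate():
    """Mean realized UTR divergence over 200 genes within 3 binomial SE."""
    cfg = SimConfig(n_genes=200, d_utr5=0.004, d_utr3=0.004, d_cds_target=0.002, seed=13)
    original, _, _, truth = simulate_transcript_pairs(cfg)
    for region, rate in (("utr5", 0.004), ("utr3", 0.004), ("cds", 0.002)):
        subs = total = 0
        for a in original:
            if a.id in truth.decoy_ids:
                continue
            gene = a.id.split("_")[0]
            s, e = truth.region_coords[a.id][region]
            subs += truth.sub_counts[gene][region]
            total += e - s
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(subs / total - rate) < 3 * se, region


def test_realized_kaks_converges_to_omega():
    """Truth-labelled substitution ratio approaches the configured omega for
    long CDS (kappa-weighted site normalization)."""
    from hadpipe.divergence import _weighted_site_count

    cfg = SimConfig(
        n_genes=10,
        cds_len=(9000, 9000),
        utr5_len=(30, 30),
        utr3_len=(30, 30),
        omega=0.5,
        kappa=2.0,
        d_cds_target=0.05,
        seed=17,
        frac_decoy=0.0,
    )
    original, _, _, truth = simulate_transcript_pairs(cfg)
    syn = sum(c["syn"] for c in truth.sub_counts.values())
    nonsyn = sum(c["nonsyn"] for c in truth.sub_counts.values())
    S = N = 0.0
    for a in original:
        s, e = truth.region_coords[a.id]["cds"]
        cds = a.seq[s:e]
        for i in range(0, len(cds), 3):
            sc = _weighted_site_count(cds[i : i + 3], kappa=2.0, freqs=None)
            S += sc
            N += 3.0 - sc
    realized = (nonsyn / N) / (syn / S)
    assert realized == pytest.approx(0.5, rel=0.15)


def test_count_matrix_null_and_determinism():
    cfg = SimConfig(n_genes=500, frac_de=0.0, lib_size=10**6, seed=23)
    cm1, truth = simulate_count_matrix(cfg)
    cm2, _ = simulate_count_matrix(cfg)
    assert (cm1.counts.values == cm2.counts.values).all()
    assert not truth.de_up["Caf/Cof"] and not truth.de_down["Caf/Cof"]
    assert cm1.counts.sum(axis=0).eq(10**6).all()


def test_planted_fold_change_recovered_across_seeds():
    """Monte-Carlo mean count ratio of a planted 4-fold gene within 3 SE of
    the abundance-model expectation."""
    n_seeds = 100
    ratios, expected = [], []
    for seed in range(n_seeds):
        cfg = SimConfig(
            n_genes=1000, frac_de=0.001, fold_change=4.0, lib_size=10**6, seed=seed
        )
        cm, truth = simulate_count_matrix(cfg)
        (gene,) = truth.de_up["Caf/Cof"]
        k = cm.counts.loc[gene]
        ratios.append(k.iloc[0] / k.iloc[1])
        # expectation from the sampling model: fold change times the ratio of
        # the two libraries' abundance normalizers, estimated from null genes
        null = cm.counts.drop(index=gene)
        expected.append(4.0 * null.iloc[:, 0].sum() / null.iloc[:, 1].sum())
    ratios, expected = np.array(ratios), np.array(expected)
    se = (ratios - expected).std(ddof=1) / np.sqrt(n_seeds)
    assert abs((ratios - expected).mean()) < 3 * se


def test_fixture_round_trip(tmp_path):
    for n in (1, 100):
        cfg = SimConfig(n_genes=n, seed=n)
        original, derived, proteins, truth = simulate_transcript_pairs(cfg)
        cm, de_truth = simulate_count_matrix(cfg)
        truth.de_up, truth.de_down = de_truth.de_up, de_truth.de_down
        d = tmp_path / f"n{n}"
        write_fixtures(
            d, original=original, derived=derived, proteins=proteins, truth=truth,
            counts=cm, config=cfg,
        )
        back = read_transcripts(d / "original.fasta")
        assert [(t.id, t.seq, t.strain) for t in back] == [
            (t.id, t.seq, t.strain) for t in original
        ]
        cm_back = read_counts(d / "counts.tsv", d / "samples.tsv")
        assert (cm_back.counts.values == cm.counts.values).all()
        truth_back = read_truth(d)
        assert truth_back.ortholog_map == truth.ortholog_map
        assert truth_back.sub_counts == truth.sub_counts
        assert truth_back.de_up == truth.de_up
    # empty set round-trips too
    from hadpipe.records import write_fasta

    write_fasta([], tmp_path / "empty.fasta")
    assert read_transcripts(tmp_path / "empty.fasta") == []


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_genes": 0},
        {"d_cds_target": 0.5},
        {"kappa": 0.0},
        {"fraction_positive": 1.5},
        {"cds_len": (900, 301)},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_lib_size_too_small_errors():
    with pytest.raises(ValueError, match="too small"):
        simulate_count_matrix(SimConfig(n_genes=100, lib_size=50))
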