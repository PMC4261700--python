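import pytest

from hadpipe.synthio import SimConfig, simulate_transcript_pairs


@pytest.fixture(scope="session")
def small_study():
    """100 synthetic ortholog pairs at ~1% divergence with decoys."""
    cfg = SimConfig(
        n_genes=100,
        d_utr5=0.01,
        d_cds_target=0.01,
        d_utr3=0.01,
        seed=11,
    )
    original, derived, proteins, truth = simulate_transcript_pairs(cfg)
    return cfg, original, derived, proteins, truth


@pytest.fixture(scope="session")
def small_orthology(small_study):
    """Orthology stage (hits, RBM, reference maps, protein hits) run once."""
    from hadpipe.orthology import (
        best_protein_matches,
        map_to_reference,
        reciprocal_best_matches,
        similarity_search,
        transpose_hits,
    )

    _, original, derived, proteins, _ = small_study
    hits = similarity_search(original, derived)
    rbm = reciprocal_best_matches(hits, transpose_hits(hits))
    return {
        "hits": hits,
        "rbm": rbm,
        "ref_map_a": map_to_reference(original, original),
        "ref_map_b": map_to_reference(derived, original),
        "prot_a": best_protein_matches(original, proteins),
        "prot_b": best_protein_matches(derived, proteins),
    }


@pytest.fixture(scope="session")
def zero_rate_study():
    cfg = SimConfig(n_genes=20, d_utr5=0.0, d_cds_target=0.0, d_utr3=0.0, seed=3)
    return cfg, *simulate_transcript_pairs(cfg)
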