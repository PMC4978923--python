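"""Global alignment, homology-acceptance gate, and variant mapping."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

from pinmap.regions import Region, classify_regions
from pinmap.seqmap import (
    AlignmentMap,
    ChainRegions,
    DomainInterval,
    HomologMatch,
    MapStatus,
    VariantRecord,
    accept_homolog,
    align_pair,
    map_variants,
    rank_matches,
)
from pinmap.structure_model import chain_sequence

from _oracles import gotoh_score

_B62 = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def test_identity_alignment():
    aln = align_pair("ACDEFG", "ACDEFG")
    assert aln.identity == 100.0
    assert aln.coverage == 100.0
    assert aln.pairs == [(i, i) for i in range(1, 7)]


def test_single_deletion_alignment():
    aln = align_pair("ACDEFG", "ACEFG")
    assert aln.pairs == [(1, 1), (2, 2), (4, 3), (5, 4), (6, 5)]
    assert aln.identity == 100.0  # 5 identical pairs of 5 aligned pairs
    assert aln.score == pytest.approx(gotoh_score("ACDEFG", "ACEFG", _score))


def test_dissimilar_sequences_zero_identity():
    aln = align_pair("AAAA", "WWWW")
    assert aln.identity == 0.0


def test_x_never_counts_identical():
    aln = align_pair("AXA", "AXA")
    assert aln.identity == pytest.approx(100.0 * 2 / 3)


@pytest.mark.parametrize("seed", range(6))
def test_score_matches_brute_force_dp(seed):
    """Optimal score equals an independent Gotoh DP on random pairs (len <= 30)."""
    rng = np.random.default_rng(seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(8):
        q = "".join(rng.choice(letters, size=rng.integers(1, 31)))
        t = "".join(rng.choice(letters, size=rng.integers(1, 31)))
        aln = align_pair(q, t)
        assert aln.score == pytest.approx(gotoh_score(q, t, _score)), (q, t)


@given(
    q=st.text(alphabet="ACDEG", min_size=1, max_size=15),
    t=st.text(alphabet="ACDEG", min_size=1, max_size=15),
)
def test_pairs_strictly_monotone(q, t):
    aln = align_pair(q, t)
    for (q1, t1), (q2, t2) in zip(aln.pairs, aln.pairs[1:]):
        assert q2 > q1 and t2 > t1
    assert 0.0 <= aln.identity <= 100.0
    assert 0.0 <= aln.coverage <= 100.0


def test_alignment_input_validation():
    with pytest.raises(ValueError, match="non-empty"):
        align_pair("", "ACD")
    with pytest.raises(ValueError, match="invalid residues"):
        align_pair("ACB1", "ACD")
    with pytest.raises(ValueError, match="cell cap"):
        align_pair("A" * 100, "A" * 100, cell_cap=100)


def test_domain_coverage_denominator():
    # pairs restricted to the domain interval over the interval length
    aln = align_pair("ACDEFG", "ACEFG", domain=DomainInterval("P", 3, 6))
    covered = sum(1 for q, _ in aln.pairs if 3 <= q <= 6)
    assert aln.coverage == pytest.approx(100.0 * covered / 4)


def _aln(identity, coverage):
    return AlignmentMap(pairs=[(1, 1)], identity=identity, coverage=coverage, score=0.0)


@pytest.mark.parametrize(
    "identity,coverage,expected",
    [
        (30.0, 95.0, False),  # "more than 30%" is strict
        (45.0, 80.0, False),  # "more than 80%" is strict
        (45.0, 85.0, True),
        (30.0001, 80.0001, True),
        (100.0, 100.0, True),
    ],
)
def test_homolog_acceptance_gate(identity, coverage, expected):
    assert accept_homolog(_aln(identity, coverage), cognate=False) is expected


def test_cognate_always_accepted():
    assert accept_homolog(_aln(5.0, 10.0), cognate=True)


def test_ranking_cognate_first_then_identity():
    low_cognate = HomologMatch(_aln(20.0, 50.0), "2zzz", "A", cognate=True)
    good_homolog = HomologMatch(_aln(90.0, 95.0), "1aaa", "A", cognate=False)
    other_homolog = HomologMatch(_aln(90.0, 90.0), "1aaa", "B", cognate=False)
    ranked = rank_matches([other_homolog, good_homolog, low_cognate])
    assert ranked[0] is low_cognate
    assert ranked[1] is good_homolog


@pytest.fixture()
def slab_mapping_setup(slab, slab_labels):
    model, truth = slab
    seq, index_map = chain_sequence(model, "A")
    aln = align_pair(seq, seq)
    match = HomologMatch(aln, "slab", "A", cognate=True)
    chain_regions = {
        ("slab", "A"): ChainRegions("slab", "A", seq, index_map, slab_labels)
    }
    return model, truth, seq, match, chain_regions


def test_variant_maps_to_interface_residue(slab_mapping_setup):
    model, truth, seq, match, chain_regions = slab_mapping_setup
    iface_num = next(
        k[1] for k, t in truth.items() if k[0] == "A" and t is Region.INTERFACE
    )
    alt = "A" if seq[iface_num - 1] != "A" else "G"
    v = VariantRecord("P", iface_num, seq[iface_num - 1], alt, id="v1")
    (mv,) = map_variants([v], seq, [match], chain_regions)
    assert mv.status is MapStatus.MAPPED
    assert mv.residue == ("A", iface_num, "")
    assert mv.region.region is Region.INTERFACE


def test_mapping_statuses_are_total(slab_mapping_setup):
    model, truth, seq, match, chain_regions = slab_mapping_setup
    ok = VariantRecord("P", 1, seq[0], "A" if seq[0] != "A" else "G", id="ok")
    mismatch_alt = "A" if seq[1] != "A" else "G"
    mismatch_ref = next(a for a in "ACDEG" if a not in (seq[1], mismatch_alt))
    mismatch = VariantRecord("P", 2, mismatch_ref, mismatch_alt, id="bad_ref")
    mapped = map_variants([ok, mismatch], seq, [match], chain_regions)
    assert [m.status for m in mapped] == [MapStatus.MAPPED, MapStatus.REF_MISMATCH]
    assert len(mapped) == 2

    no_struct = map_variants([ok], seq, [], chain_regions)
    assert no_struct[0].status is MapStatus.NO_ACCEPTED_STRUCTURE

    with pytest.raises(ValueError, match="beyond"):
        map_variants(
            [VariantRecord("P", len(seq) + 5, "A", "G", id="oob")],
            seq, [match], chain_regions,
        )


def test_gap_position_is_unaligned():
    aln = align_pair("ACDEFG", "ACEFG")  # query position 3 deleted
    target_labels = {}
    cr = ChainRegions("s", "A", "ACEFG", [(i, i, "") for i in range(1, 6)], target_labels)
    match = HomologMatch(aln, "s", "A", cognate=True)
    v = VariantRecord("P", 3, "D", "N", id="gap")
    (mv,) = map_variants([v], "ACDEFG", [match], {("s", "A"): cr})
    assert mv.status is MapStatus.UNALIGNED_POSITION


def test_cognate_outranks_homolog_in_mapping(slab_mapping_setup, slab_labels):
    model, truth, seq, cognate_match, chain_regions = slab_mapping_setup
    # a homolog match pointing at chain B of the same complex
    seq_b, index_map_b = chain_sequence(model, "B")
    aln_b = align_pair(seq, seq_b)
    homolog = HomologMatch(aln_b, "slab", "B", cognate=False)
    chain_regions[("slab", "B")] = ChainRegions("slab", "B", seq_b, index_map_b, slab_labels)
    v = VariantRecord("P", 1, seq[0], "A" if seq[0] != "A" else "G", id="v")
    matches = [homolog, cognate_match]
    (mv,) = map_variants([v], seq, matches, chain_regions)
    if homolog.accepted:
        assert mv.match is cognate_match


def test_variant_record_validation():
    with pytest.raises(ValueError):
        VariantRecord("P", 0, "A", "G")
    with pytest.raises(ValueError):
        VariantRecord("P", 1, "A", "A")
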