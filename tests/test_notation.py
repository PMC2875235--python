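"""Parsing, rendering, and pairwise-difference counting of variant strings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthaplopop.notation import (
    CODING,
    HVRI,
    HVRII,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    DistancePolicy,
    VariantParseError,
    distance_matrix,
    haplotype_distance,
    parse_haplotype_row,
    parse_region_string,
    parse_variant_token,
    render_region_string,
    render_variant,
)


@pytest.mark.parametrize(
    "token,region,position,kind,derived,idx",
    [
        ("129", HVRI, 16129, SUBSTITUTION, (), 0),
        ("309.2", HVRII, 309, INSERTION, ("C",), 2),
        ("318A/C", HVRI, 16318, SUBSTITUTION, ("A", "C"), 0),
        ("193del", HVRI, 16193, DELETION, (), 0),
        ("193d", HVRI, 16193, DELETION, (), 0),
        ("196insT", HVRII, 196, INSERTION, ("T",), 1),
        ("315.1", HVRII, 315, INSERTION, ("C",), 1),
        ("315.3", HVRII, 315, INSERTION, ("C",), 3),
        ("184C", HVRI, 16184, SUBSTITUTION, ("C",), 0),
        ("3010", CODING, 3010, SUBSTITUTION, (), 0),
        ("16129", HVRI, 16129, SUBSTITUTION, (), 0),  # already offset-free
    ],
)
def test_parse_variant_token(token, region, position, kind, derived, idx):
    v = parse_variant_token(token, region)
    assert (v.position, v.kind, v.derived, v.insert_index) == (position, kind, derived, idx)


@pytest.mark.parametrize(
    "token,region",
    [
        ("16570", HVRII),  # beyond the rCRS
        ("0X", HVRI),
        ("abc", HVRI),
        ("129A/A", HVRI),  # degenerate ambiguity
        ("", HVRII),
    ],
)
def test_parse_errors(token, region):
    with pytest.raises(VariantParseError):
        parse_variant_token(token, region)


def test_parse_haplotype_row_examples():
    h = parse_haplotype_row("J1", "0", "263 309.1 315.1", "")
    assert h.variants(HVRI) == frozenset()
    assert len(h.variants(HVRII)) == 3
    assert not h.is_typed(CODING)

    h4 = parse_haplotype_row("J4", "0", "263 315.1", "3010")
    assert h4.is_typed(CODING)
    assert {v.position for v in h4.variants(CODING)} == {3010}

    with pytest.raises(VariantParseError):
        parse_haplotype_row("X", "129 129", "", "")


def test_duplicate_insertion_indices_are_distinct_keys():
    h = parse_haplotype_row("J55", "0", "263 309.1 309.2 315.1", "")
    assert len(h.variants(HVRII)) == 4


def test_fixture_loads_81_labelled_haplotypes(eljadida):
    assert len(eljadida) == 81
    assert eljadida[0].sample_id == "J1"
    assert all(h.haplogroup_label for h in eljadida)
    assert all(h.population == "El Jadida" for h in eljadida)


def test_fixture_tokens_round_trip(eljadida):
    """render(parse(token)) is idempotent over every fixture region string."""
    for h in eljadida:
        for region in (HVRI, HVRII, CODING):
            if not h.is_typed(region):
                continue
            canon = render_region_string(h.variants(region), region)
            reparsed = parse_region_string(canon, region)
            assert reparsed == h.variants(region)
            assert render_region_string(reparsed, region) == canon


@given(pos=st.integers(min_value=24, max_value=569))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_hvri_offset_restoration_is_involutive(pos):
    v = parse_variant_token(str(pos), HVRI)
    assert v.position == pos + 16000
    assert render_variant(v, HVRI) == str(pos)
    assert parse_variant_token(render_variant(v, HVRI), HVRI) == v


def test_distance_examples(eljadida):
    by_id = {h.sample_id: h for h in eljadida}
    subs_only = DistancePolicy()
    assert haplotype_distance(by_id["J5"], by_id["J9"], subs_only, HVRI) == 1
    assert haplotype_distance(by_id["J2"], by_id["J3"], subs_only, HVRI) == 3
    for h in eljadida[:10]:
        assert haplotype_distance(h, h, subs_only, HVRI) == 0


def test_distance_is_pseudometric_on_fixture(eljadida, policy):
    d = distance_matrix(eljadida, policy.for_dataset(eljadida, HVRI), HVRI).astype(float)
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)
    # triangle inequality over all 81^3 triples
    assert np.all(d[:, None, :] + d[None, :, :] >= d[:, :, None] - 1e-12)


def test_indel_and_window_policy_toggles(eljadida):
    by_id = {h.sample_id: h for h in eljadida}
    j42, j17 = by_id["J42"], by_id["J17"]  # J42 carries 193del; J17 carries 193
    base = DistancePolicy()
    with_indels = DistancePolicy(count_indels=True)
    assert haplotype_distance(j42, j17, with_indels, HVRI) == haplotype_distance(j42, j17, base, HVRI) + 1
    wide = DistancePolicy(range_start=16024, range_end=16400)
    j44, j1 = by_id["J44"], by_id["J1"]  # J44 carries 390, outside the default window
    assert haplotype_distance(j44, j1, wide, HVRI) == haplotype_distance(j44, j1, base, HVRI) + 1


def test_ambiguity_modes(eljadida):
    by_id = {h.sample_id: h for h in eljadida}
    j33, j34 = by_id["J33"], by_id["J34"]  # 280G/C vs 280C/G: same base set
    for mode in ("state", "overlap", "missing"):
        pol = DistancePolicy(ambiguous=mode)
        assert haplotype_distance(j33, j34, pol, HVRII) == 0
    j38, j53 = by_id["J38"], by_id["J53"]  # 265A/T vs 265A/C: overlapping sets
    d_state = haplotype_distance(j38, j53, DistancePolicy(ambiguous="state"), HVRI)
    d_overlap = haplotype_distance(j38, j53, DistancePolicy(ambiguous="overlap"), HVRI)
    assert d_state == d_overlap + 1


def test_excluded_positions_removed_before_counting(eljadida):
    by_id = {h.sample_id: h for h in eljadida}
    j2, j1 = by_id["J2"], by_id["J1"]
    pol = DistancePolicy()
    excl = pol.with_excluded([16129])
    assert haplotype_distance(j2, j1, excl, HVRI) == haplotype_distance(j2, j1, pol, HVRI) - 1


def test_dataset_ambiguous_site_filter(eljadida, policy):
    filtered = policy.for_dataset(eljadida, HVRI)
    # 16183 carries ambiguous calls in 6/81 samples (> 5%): excluded
    assert 16183 in filtered.excluded_positions
    # 16318 is ambiguous in only one sample: retained
    assert 16318 not in filtered.excluded_positions
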