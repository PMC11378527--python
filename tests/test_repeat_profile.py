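"""Unit tests for repeat profiles and the NG86-style selection screen.

The codon-pair oracles are frozen hand counts over mutational pathways
(Nei & Gojobori 1986 counting, stop-codon pathways excluded).
"""

import math

import numpy as np
import pytest

from lrrshuffle import (build_family, pair_dn_ds_counts, position_profile,
                        site_selection_screen)
from lrrshuffle.repeat_profile import SENSE_CODONS, EmptyFamilyError
from lrrshuffle.synthetic_data import SimConfig, generate_repeat_family

# ---------------------------------------------------------------------------
# family assembly
# ---------------------------------------------------------------------------

def test_build_family_rejects_wrong_length():
    fam = build_family(["L" * 23, "L" * 22, "A" * 23])
    assert fam.n_units == 2 and fam.n_rejected == 1


def test_build_family_codon_translation_checked():
    pep = "M" + "L" * 22
    codons = [["ATG"] + ["CTG"] * 22]
    fam = build_family([pep], codons=codons)
    assert fam.codon_units == codons
    with pytest.raises(ValueError):
        build_family(["A" * 23], codons=codons)


def test_build_family_empty_raises():
    with pytest.raises(EmptyFamilyError):
        build_family(["L" * 5])


def test_build_family_keeps_duplicates():
    fam = build_family(["L" * 23] * 4)
    assert fam.n_units == 4


# ---------------------------------------------------------------------------
# position profiles
# ---------------------------------------------------------------------------

def test_information_content_extremes():
    # one invariant column -> log2(20) bits; 20-way uniform column -> 0 bits
    fam = build_family(["A" + "ACDEFGHIKLMNPQRSTVWY"[i] + "L" * 21
                        for i in range(20)])
    prof = position_profile(fam)
    assert prof.information[0] == pytest.approx(math.log2(20))
    assert prof.information[1] == pytest.approx(0.0, abs=1e-12)
    assert prof.consensus[0] == "A"


def test_information_content_partial():
    # 3:1 split -> log2(20) - H(0.75, 0.25) = 3.5106 bits
    fam = build_family(["A" * 23, "A" * 23, "A" * 23, "C" + "A" * 22])
    prof = position_profile(fam)
    expected = math.log2(20) + 0.75 * math.log2(0.75) + 0.25 * math.log2(0.25)
    assert prof.information[0] == pytest.approx(expected, abs=1e-9)
    assert prof.information[1] == pytest.approx(math.log2(20))


def test_consensus_tie_recorded():
    fam = build_family(["A" + "L" * 22, "C" + "L" * 22])
    prof = position_profile(fam)
    assert prof.consensus[0] == "A"      # alphabetical tie-break
    assert 0 in prof.ties


def test_counts_sum_to_n_units():
    fam = build_family(["ALX" + "G" * 20, "CLL" + "G" * 20])
    prof = position_profile(fam)
    assert np.allclose(prof.counts.sum(axis=1), fam.n_units)
    # X lands in the extra column, not in canonical frequencies
    assert prof.counts[2, 20] == 1


# ---------------------------------------------------------------------------
# NG86-style codon-pair counting (frozen hand counts)
# ---------------------------------------------------------------------------

def test_pair_counts_identical_codons():
    s, n, ss, ns = pair_dn_ds_counts("ATG", "ATG")
    assert (s, n) == (0.0, 0.0)
    # ATG (Met): every single-base change is nonsynonymous; pos3 G->A
    # gives ATA (Ile), nonsyn; no stops reachable -> 0 syn sites
    assert ss == pytest.approx(0.0)
    assert ns == pytest.approx(3.0)


def test_pair_counts_synonymous_leucine():
    s, n, ss, ns = pair_dn_ds_counts("CTT", "CTG")
    assert (s, n) == (1.0, 0.0)
    # CTT: syn sites 1 (third position); CTG: 4/3 (third + TTG at pos 1)
    assert ss == pytest.approx((1.0 + 4.0 / 3.0) / 2)
    assert ns == pytest.approx((2.0 + 5.0 / 3.0) / 2)


def test_pair_counts_two_pathways_averaged():
    # TTT -> GTA: pathway via GTT gives (1 syn, 1 nonsyn), via TTA gives
    # (0 syn, 2 nonsyn); equal-weight average = (0.5, 1.5)
    s, n, _, _ = pair_dn_ds_counts("TTT", "GTA")
    assert s == pytest.approx(0.5)
    assert n == pytest.approx(1.5)


def test_pair_counts_stop_pathway_excluded():
    # TTA -> TGG: the pathway through TGA (stop) is discarded, leaving
    # TTA -> TTG (syn) -> TGG (nonsyn)
    s, n, _, _ = pair_dn_ds_counts("TTA", "TGG")
    assert (s, n) == (1.0, 1.0)


def test_pair_counts_symmetric():
    for c1, c2 in [("TTT", "GTA"), ("CTT", "CTG"), ("ATG", "TGG")]:
        assert pair_dn_ds_counts(c1, c2) == pytest.approx(
            pair_dn_ds_counts(c2, c1))


def test_sense_codon_table():
    assert len(SENSE_CODONS) == 61
    assert "TAA" not in SENSE_CODONS
    assert SENSE_CODONS == tuple(sorted(SENSE_CODONS))


# ---------------------------------------------------------------------------
# selection screen
# ---------------------------------------------------------------------------

def test_screen_identical_units_flags_nothing():
    rows = [["CTG"] * 23] * 6
    fam = build_family(["L" * 23] * 6, codons=rows)
    screen = site_selection_screen(fam, n_perm=199, seed=0)
    assert screen.flagged_sites == ()
    assert screen.note is not None
    assert all(r.p_perm == 1.0 for r in screen.results)


def test_screen_requires_codons_and_enough_units():
    fam = build_family(["L" * 23] * 6)
    with pytest.raises(ValueError):
        site_selection_screen(fam)
    small = build_family(["L" * 23] * 3, codons=[["CTG"] * 23] * 3)
    with pytest.raises(ValueError):
        site_selection_screen(small)
    with pytest.raises(ValueError):
        site_selection_screen(
            build_family(["L" * 23] * 6, codons=[["CTG"] * 23] * 6),
            n_perm=10)


def test_screen_deterministic():
    fam = generate_repeat_family(12, seed=3)
    a = site_selection_screen(fam, n_perm=199, seed=7)
    b = site_selection_screen(fam, n_perm=199, seed=7)
    assert [r.p_perm for r in a.results] == [r.p_perm for r in b.results]
    assert a.flagged_sites == b.flagged_sites


def test_screen_row_order_invariant():
    fam = generate_repeat_family(12, seed=3)
    rev = build_family(fam.units[::-1], codons=fam.codon_units[::-1])
    a = site_selection_screen(fam, n_perm=199, seed=7)
    b = site_selection_screen(rev, n_perm=199, seed=7)
    assert [r.p_perm for r in a.results] == [r.p_perm for r in b.results]


def test_screen_recovers_planted_sites_single_seed():
    fam = generate_repeat_family(30, seed=0)
    screen = site_selection_screen(fam, n_perm=999, seed=100)
    assert screen.flagged_sites == SimConfig().selected_sites
    for r in screen.results:
        if r.flagged:
            assert r.omega_hat > 1.0 and r.p_adjusted <= screen.alpha


def test_screen_pvalues_valid():
    fam = generate_repeat_family(10, seed=1)
    screen = site_selection_screen(fam, n_perm=199, seed=0)
    for r in screen.results:
        assert 1.0 / 200.0 <= r.p_perm <= 1.0
        assert r.p_adjusted >= r.p_perm - 1e-12
        assert r.dn >= 0.0
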