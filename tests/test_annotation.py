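import math

import numpy as np
import pytest

from conftest import GLUTAMATE_MASS, GLUTAMATE_RT
from isocred.annotation import (
    TIER_FORMULA,
    TIER_MS2,
    TIER_NONE,
    TIER_STANDARD,
    match_library,
    ms2_cosine,
)
from isocred.formula import decompose
from isocred.matching import match_quartets, neutral_mass
from isocred.peaks_io import ReferenceEntry


SPEC_A = [(85.03, 100.0), (101.02, 50.0)]
SPEC_B = [(85.03, 50.0), (101.02, 100.0)]


class TestCosine:
    def test_self_similarity(self):
        assert ms2_cosine(SPEC_A, SPEC_A) == pytest.approx(1.0)

    def test_orthogonal_spectra(self):
        assert ms2_cosine([(85.03, 100.0)], [(212.9, 100.0)]) == 0.0

    def test_swapped_intensities_hand_computed(self):
        # sqrt scaling: vectors (10, sqrt(50)) and (sqrt(50), 10);
        # cosine = 2*10*sqrt(50) / 150 = 2*sqrt(2)/3
        expected = 2 * math.sqrt(2) / 3
        assert ms2_cosine(SPEC_A, SPEC_B) == pytest.approx(expected, abs=1e-12)
        # sanity: without sqrt scaling the same spectra give 0.8
        raw = (100 * 50 + 50 * 100) / (100**2 + 50**2)
        assert raw == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [(float(m), float(i)) for m, i in
                 zip(rng.uniform(50, 500, 6), rng.uniform(1, 100, 6))]
            b = [(float(m), float(i)) for m, i in
                 zip(rng.uniform(50, 500, 6), rng.uniform(1, 100, 6))]
            assert ms2_cosine(a, b) == pytest.approx(ms2_cosine(b, a), abs=1e-12)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = [(float(m), float(i)) for m, i in
                 zip(rng.uniform(50, 200, 5), rng.uniform(1, 100, 5))]
            b = [(m + float(rng.normal(0, 0.005)), i * 2) for m, i in a]
            s = ms2_cosine(a, b)
            assert 0.0 <= s <= 1.0 + 1e-12

    def test_global_scaling_invariance(self):
        scaled = [(m, i * 7.3) for m, i in SPEC_A]
        assert ms2_cosine(SPEC_A, scaled) == pytest.approx(1.0)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            ms2_cosine([], SPEC_A)


def _glutamate_quartet(glutamate_quartet_sets):
    quartets = match_quartets(*glutamate_quartet_sets)
    assert len(quartets) == 1
    return quartets[0]


def _candidates(q):
    return decompose(neutral_mass(q.u), q.c, q.n, 5.0)


class TestMatchLibrary:
    def test_rt_match_gives_standard_confirmed(self, glutamate_quartet_sets, tiny_library):
        q = _glutamate_quartet(glutamate_quartet_sets)
        ann = match_library(q, _candidates(q), tiny_library)
        assert ann.tier == TIER_STANDARD
        assert ann.best_name == "Glutamate"

    def test_ms2_match_without_rt(self, glutamate_quartet_sets, tiny_library):
        q = _glutamate_quartet(glutamate_quartet_sets)
        lib = [ReferenceEntry("Glutamate", tiny_library[0].formula,
                              tiny_library[0].neutral_mass, rt=None,
                              ms2=tiny_library[0].ms2)]
        query = [(85.031, 90.0), (101.021, 55.0), (128.031, 28.0)]
        ann = match_library(q, _candidates(q), lib, query_ms2=query)
        assert ann.tier == TIER_MS2
        assert ann.score >= 0.7

    def test_formula_only_when_no_library_evidence(self, glutamate_quartet_sets):
        q = _glutamate_quartet(glutamate_quartet_sets)
        ann = match_library(q, _candidates(q), [])
        assert ann.tier == TIER_FORMULA
        assert ann.best_formula == "C5H9NO4"
        assert ann.best_name is None

    def test_unannotated_without_candidates(self, glutamate_quartet_sets):
        q = _glutamate_quartet(glutamate_quartet_sets)
        ann = match_library(q, [], [])
        assert ann.tier == TIER_NONE
        assert ann.identity is None

    def test_cn_mismatch_excludes_entry(self, glutamate_quartet_sets):
        """A C6 sugar can never match a (c=5, n=1) quartet, whatever its
        mass."""
        q = _glutamate_quartet(glutamate_quartet_sets)
        decoy = ReferenceEntry("FakeGlucose", {"C": 6, "H": 12, "O": 6},
                               neutral_mass=neutral_mass(q.u), rt=q.u.rt)
        ann = match_library(q, _candidates(q), [decoy])
        assert ann.matches == []
        assert ann.tier == TIER_FORMULA

    def test_all_matches_respect_cn(self, glutamate_quartet_sets, tiny_library):
        q = _glutamate_quartet(glutamate_quartet_sets)
        ann = match_library(q, _candidates(q), tiny_library)
        for entry, _, _ in ann.matches:
            assert entry.formula.get("C", 0) == q.c
            assert entry.formula.get("N", 0) == q.n

    def test_tier_monotone_under_added_evidence(self, glutamate_quartet_sets):
        """Randomized: enriching the same library entry with RT and/or MS2
        never lowers the annotation tier."""
        rank = {TIER_STANDARD: 0, TIER_MS2: 1, TIER_FORMULA: 2, TIER_NONE: 3}
        q = _glutamate_quartet(glutamate_quartet_sets)
        cands = _candidates(q)
        ms2 = ((85.03, 100.0), (101.02, 50.0))
        rng = np.random.default_rng(8)
        for _ in range(25):
            has_rt = bool(rng.integers(0, 2))
            has_ms2 = bool(rng.integers(0, 2))
            base = ReferenceEntry("Glutamate", {"C": 5, "H": 9, "N": 1, "O": 4},
                                  GLUTAMATE_MASS,
                                  rt=GLUTAMATE_RT if has_rt else None,
                                  ms2=ms2 if has_ms2 else None)
            ann = match_library(q, cands, [base], query_ms2=list(ms2))
            richer = ReferenceEntry("Glutamate", base.formula, base.neutral_mass,
                                    rt=GLUTAMATE_RT, ms2=ms2)
            ann2 = match_library(q, cands, [richer], query_ms2=list(ms2))
            assert rank[ann2.tier] <= rank[ann.tier]
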