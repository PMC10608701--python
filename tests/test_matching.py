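import numpy as np
import pytest

from conftest import make_peakset
from helpers import IUPAC, brute_match, quartets_as_tuples, random_instance
from isocred.constants import DELTAS, PROTON
from isocred.matching import (
    MatchConfig,
    credential,
    expected_shift,
    match_quartets,
    neutral_mass,
    quartets_to_frame,
)
from isocred.peaks_io import Peak


class TestExpectedShift:
    def test_identity(self):
        assert expected_shift(0, 0) == 0.0

    def test_derived_values(self):
        assert expected_shift(5, 0) == pytest.approx(5.0167742, abs=1e-6)
        assert expected_shift(5, 1) == pytest.approx(6.0138091, abs=1e-6)

    def test_matches_iupac_isotope_table(self):
        """Independent check against CIAAW isotope masses for the full
        (c <= 40, n <= 10) search box."""
        d13 = IUPAC["13C"] - IUPAC["12C"]
        d15 = IUPAC["15N"] - IUPAC["14N"]
        for c in range(41):
            for n in range(11):
                assert expected_shift(c, n) == pytest.approx(c * d13 + n * d15, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            expected_shift(-1, 0)


class TestNeutralMass:
    def test_glutamate_deprotonated(self):
        p = Peak(146.04588, 7.9, 1e6, 50.0, "negative", "ESI")
        assert neutral_mass(p) == pytest.approx(147.05316, abs=1e-5)

    def test_urea_protonated(self):
        # [M+H]+ of urea: 60.032363 + 1.007276
        p = Peak(61.039639, 2.0, 1e6, 50.0, "positive", "ESI")
        assert neutral_mass(p) == pytest.approx(60.032363, abs=1e-5)

    def test_polarity_symmetry(self):
        m = 147.05316
        neg = Peak(m - PROTON, 5.0, 1e6, 50.0, "negative", "ESI")
        pos = Peak(m + PROTON, 5.0, 1e6, 50.0, "positive", "ESI")
        assert neutral_mass(neg) == pytest.approx(neutral_mass(pos), abs=1e-9)


class TestMatchQuartets:
    def test_planted_glutamate_quartet(self, glutamate_quartet_sets):
        u, c13, n15, dual = glutamate_quartet_sets
        quartets = match_quartets(u, c13, n15, dual)
        assert len(quartets) == 1
        q = quartets[0]
        assert (q.c, q.n) == (5, 1)
        assert q.support == "full"
        assert q.ppm_residual == pytest.approx(0.0, abs=1e-6)
        assert q.credentialed

    def test_empty_labeled_sets_yield_nothing(self, glutamate_quartet_sets):
        u, *_ = glutamate_quartet_sets
        empty = lambda cond: make_peakset(cond, [])
        assert match_quartets(u, empty("C13"), empty("N15"), empty("C13N15")) == []

    def test_mixed_polarity_rejected(self, glutamate_quartet_sets):
        u, c13, n15, dual = glutamate_quartet_sets
        pos = make_peakset("C13N15", [(500.0, 5.0, 1e6)], polarity="positive")
        with pytest.raises(ValueError):
            match_quartets(u, c13, n15, pos)

    def test_background_only_peak_never_credentialed(self, glutamate_quartet_sets):
        """A peak present only in the unlabeled condition (media
        contaminant) has no partners and is never credentialed."""
        u, c13, n15, dual = glutamate_quartet_sets
        u2 = make_peakset("U", [(u.mz[0], u.rt[0], u.intensity[0]),
                                (350.123, 9.0, 5e6)])
        quartets = match_quartets(u2, c13, n15, dual)
        cred = credential(quartets)
        assert len(cred) == 1
        assert cred[0].u.mz == pytest.approx(u.mz[0])

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            u, c13, n15, dual = random_instance(rng)
            got = match_quartets(u, c13, n15, dual)
            want = brute_match(u, c13, n15, dual)
            assert quartets_as_tuples(u, c13, n15, dual, got) == want

    def test_tolerance_monotonicity(self):
        """Shrinking the m/z or RT windows never grows the credentialed set."""
        rng = np.random.default_rng(77)
        u, c13, n15, dual = random_instance(rng, max_per_set=8)

        def cred_keys(mz_tol, rt_tol):
            cfg = MatchConfig(mz_tol_ppm=mz_tol, rt_tol=rt_tol)
            return {(q.u.id, q.c, q.n) for q in credential(match_quartets(u, c13, n15, dual, cfg))}

        for big, small in [((10, 0.5), (5, 0.5)), ((5, 0.5), (5, 0.2)), ((10, 1.0), (2, 0.1))]:
            assert cred_keys(*small) <= cred_keys(*big)

    def test_shared_partner_demotes_lower_intensity_quartet(self):
        """Two unlabeled peaks wanting the same 13C partner: the stronger
        one claims it, the weaker one is emitted but not credentialed."""
        d = DELTAS
        mz, rt = 300.0, 5.0
        u = make_peakset("U", [(mz, rt, 2e6), (mz * (1 + 3e-6), rt, 1e6)])
        c13 = make_peakset("C13", [(mz + 4 * d.d13c, rt, 2e6)])
        n15 = make_peakset("N15", [(mz + d.d15n, rt, 2e6),
                                   (mz * (1 + 3e-6) + d.d15n, rt, 1e6)])
        dual = make_peakset("C13N15", [(mz + 4 * d.d13c + d.d15n, rt, 2e6),
                                       (mz * (1 + 3e-6) + 4 * d.d13c + d.d15n, rt, 1e6)])
        quartets = match_quartets(u, c13, n15, dual)
        assert len(quartets) == 2
        by_intensity = sorted(quartets, key=lambda q: -q.u.intensity)
        assert by_intensity[0].credentialed
        assert by_intensity[1].conflict and not by_intensity[1].credentialed
        assert len(credential(quartets)) == 1

    def test_determinism_byte_identical(self):
        rng = np.random.default_rng(123)
        u, c13, n15, dual = random_instance(rng, max_per_set=10)
        a = quartets_to_frame(match_quartets(u, c13, n15, dual)).to_csv(index=False)
        b = quartets_to_frame(match_quartets(u, c13, n15, dual)).to_csv(index=False)
        assert a == b

    def test_conservation_of_partner_ppm(self):
        """Every credentialed quartet's partners sit within the ppm window
        of their predicted m/z."""
        rng = np.random.default_rng(99)
        cfg = MatchConfig()
        d = DELTAS
        for _ in range(10):
            u, c13, n15, dual = random_instance(rng, max_per_set=8)
            for q in credential(match_quartets(u, c13, n15, dual, cfg)):
                preds = [
                    (q.p13c.mz, q.u.mz + q.c * d.d13c),
                    (q.p15n.mz, q.u.mz + q.n * d.d15n),
                    (q.pdual.mz, q.u.mz + q.c * d.d13c + q.n * d.d15n),
                ]
                for obs, pred in preds:
                    assert abs(obs - pred) / pred * 1e6 <= cfg.mz_tol_ppm + 1e-9


class TestCredential:
    def test_missing_dual_partner_removed(self, glutamate_quartet_sets):
        u, c13, n15, _ = glutamate_quartet_sets
        quartets = match_quartets(u, c13, n15, make_peakset("C13N15", []))
        assert len(quartets) == 1 and quartets[0].support == "triad"
        assert credential(quartets) == []

    def test_full_unique_input_is_identity(self, glutamate_quartet_sets):
        quartets = match_quartets(*glutamate_quartet_sets)
        assert credential(quartets) == quartets
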