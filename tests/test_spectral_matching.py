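"""Cosine scoring, greedy peak pairing vs optimal assignment, search thresholds."""

import numpy as np
import pytest

from neometab.io_model import MatchThresholds
from neometab import spectral_matching as sm
from conftest import make_spectrum


def random_spectrum(rng, n_peaks, sid="s", precursor=100.0):
    mz = np.sort(rng.uniform(50, 500, n_peaks))
    intensity = rng.uniform(0.05, 1.0, n_peaks)
    return make_spectrum(mz, intensity, precursor, sid)


class TestMatchPeaks:
    def test_identical_spectra_full_pairing(self, rng):
        s = random_spectrum(rng, 4)
        assert len(sm.match_peaks(s, s, 0.05)) == 4

    def test_single_candidate_pair(self):
        a = make_spectrum([100.00, 150.00], [1.0, 1.0])
        b = make_spectrum([100.03, 200.00], [1.0, 1.0])
        assert sm.match_peaks(a, b, 0.05) == [(0, 0)]

    def test_each_peak_used_once(self):
        a = make_spectrum([100.00, 100.02], [1.0, 0.5])
        b = make_spectrum([100.01], [1.0])
        pairs = sm.match_peaks(a, b, 0.05)
        assert len(pairs) == 1
        assert pairs[0] == (0, 0)  # highest intensity product wins


class TestCosineScore:
    def test_identical_spectra_exactly_one(self, rng):
        s = random_spectrum(rng, 6)
        cos, n = sm.cosine_score(s, s, 0.05)
        assert cos == 1.0
        assert n == 6

    def test_half_overlap_hand_value(self):
        a = make_spectrum([100.0, 150.0], [1.0, 1.0])
        b = make_spectrum([100.0, 200.0], [1.0, 1.0])
        cos, n = sm.cosine_score(a, b, 0.05)
        assert cos == pytest.approx(0.5)
        assert n == 1

    def test_disjoint_spectra_zero(self):
        a = make_spectrum([100.0, 150.0], [1.0, 1.0])
        b = make_spectrum([300.0, 400.0], [1.0, 1.0])
        cos, n = sm.cosine_score(a, b, 0.05)
        assert cos == 0.0 and n == 0

    def test_symmetric_and_scale_invariant(self, rng):
        for _ in range(20):
            a = random_spectrum(rng, int(rng.integers(2, 7)))
            b = random_spectrum(rng, int(rng.integers(2, 7)))
            c_ab, n_ab = sm.cosine_score(a, b, 0.05)
            c_ba, n_ba = sm.cosine_score(b, a, 0.05)
            assert c_ab == pytest.approx(c_ba, abs=1e-12)
            assert n_ab == n_ba
            scaled = make_spectrum(a.mz, a.intensity * 37.0)
            c_scaled, _ = sm.cosine_score(scaled, b, 0.05)
            assert c_scaled == pytest.approx(c_ab, abs=1e-12)
            assert 0.0 <= c_ab <= 1.0

    def test_greedy_equals_optimal_assignment(self, rng):
        """Greedy pairing reaches the exhaustive max-weight assignment cosine
        on random small spectra (200 pairs, <= 6 peaks)."""
        worst = 0.0
        for _ in range(200):
            a = random_spectrum(rng, int(rng.integers(2, 7)))
            b = random_spectrum(rng, int(rng.integers(2, 7)))
            if rng.random() < 0.5:  # force overlaps
                k = min(len(a.peaks), len(b.peaks))
                mzb = b.mz.copy()
                mzb[:k] = a.mz[:k] + rng.normal(0, 0.02, k)
                b = make_spectrum(np.sort(mzb), b.intensity)
            c_greedy, _ = sm.cosine_score(a, b, 0.05)
            c_opt, _ = sm.cosine_score_optimal(a, b, 0.05)
            assert c_greedy <= c_opt + 1e-12
            worst = max(worst, c_opt - c_greedy)
        assert worst < 1e-9

    def test_agrees_with_matchms(self, rng):
        """Independent cross-check against the community implementation."""
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        scorer = CosineGreedy(tolerance=0.05)
        for _ in range(30):
            a = random_spectrum(rng, int(rng.integers(3, 7)))
            b = random_spectrum(rng, int(rng.integers(3, 7)))
            k = min(len(a.peaks), len(b.peaks))
            mzb = b.mz.copy()
            mzb[:k] = a.mz[:k] + rng.normal(0, 0.02, k)
            b = make_spectrum(np.sort(mzb), b.intensity)
            ours, n_ours = sm.cosine_score(a, b, 0.05)
            ref = scorer.pair(
                Spectrum(mz=a.mz, intensities=a.intensity, metadata={"precursor_mz": 100.0}),
                Spectrum(mz=b.mz, intensities=b.intensity, metadata={"precursor_mz": 100.0}),
            )
            assert ours == pytest.approx(float(ref["score"]), abs=1e-9)
            assert n_ours == int(ref["matches"])

    def test_jittered_spectrum_still_matches_parent(self, rng):
        for _ in range(20):
            parent = random_spectrum(rng, 8)
            jitter = rng.uniform(-0.02, 0.02, 8)  # < tol/2
            noisy = make_spectrum(
                np.sort(parent.mz + jitter),
                parent.intensity * (1 + rng.normal(0, 0.05, 8)).clip(0.01),
            )
            cos, _ = sm.cosine_score(parent, noisy, 0.05)
            assert cos > 0.95


class TestLibrarySearch:
    def _library_entry(self, rng, query, cosine_target, n_shared):
        """Construct an entry sharing n_shared peaks with controlled extras."""
        keep = query.peaks[:n_shared].copy()
        extras = np.column_stack([
            np.sort(rng.uniform(600, 900, 3)), rng.uniform(0.1, 1.0, 3)
        ])
        return make_spectrum(
            np.concatenate([keep[:, 0], extras[:, 0]]),
            np.concatenate([keep[:, 1], extras[:, 1]]),
            precursor=query.precursor_mz + 0.005,
            sid="lib",
        )

    def test_accepts_hit_meeting_all_criteria(self, rng):
        # mirror of the reported match profile: cosine ~0.8, 4 shared peaks,
        # parent mass difference < 0.01
        query = make_spectrum(
            [58.065, 59.073, 101.107, 142.123, 160.133],
            [100.0, 30.0, 55.0, 20.0, 10.0],
            precursor=160.1332, sid="q",
        )
        lib = make_spectrum(
            [58.065, 59.073, 101.107, 142.123, 700.0],
            [95.0, 35.0, 50.0, 22.0, 60.0],
            precursor=160.1340, sid="lib",
        )
        hits = sm.library_search(query, [lib], MatchThresholds())
        assert len(hits) == 1
        assert hits[0].cosine > 0.7
        assert hits[0].n_matched_peaks >= 4
        assert hits[0].parent_mass_diff < 0.01

    def test_rejects_high_cosine_with_too_few_peaks(self):
        query = make_spectrum([100.0, 200.0, 300.0], [50.0, 30.0, 5.0], precursor=150.0)
        lib = make_spectrum([100.0, 200.0, 300.0], [50.0, 30.0, 5.0], precursor=150.0)
        cos, n = sm.cosine_score(query, lib, 0.05)
        assert cos > 0.9 and n == 3
        assert sm.library_search(query, [lib], MatchThresholds()) == []

    def test_rejects_parent_mass_outside_tolerance(self, rng):
        query = random_spectrum(rng, 5, precursor=200.0)
        lib = make_spectrum(query.mz, query.intensity, precursor=200.2)
        assert sm.library_search(query, [lib], MatchThresholds()) == []

    def test_identity_is_top_hit(self, rng):
        query = random_spectrum(rng, 6, sid="q", precursor=300.0)
        decoy = random_spectrum(rng, 6, sid="d", precursor=300.01)
        identical = make_spectrum(query.mz, query.intensity, precursor=300.0, sid="same")
        hits = sm.library_search(query, [decoy, identical], MatchThresholds())
        assert hits and hits[0].library_id == "same"
        assert hits[0].cosine == pytest.approx(1.0)

    def test_empty_library_error(self, rng):
        with pytest.raises(ValueError):
            sm.library_search(random_spectrum(rng, 3), [])
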