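"""MS/MS cosine similarity and MASST-style library search.

The score is the plain spectral cosine: tolerance-matched fragment peaks are
paired one-to-one, and the sum of intensity products over matched pairs is
divided by the product of the full-spectrum L2 norms (raw intensities, no
square-root transform; a toggle is provided since deployments differ).
Peak pairing is greedy by descending intensity product with ties broken by
smallest m/z difference — deterministic, and on small spectra it agrees with
the exhaustive optimal assignment (used as a test oracle).

A library hit must pass all of: parent mass difference below tolerance,
cosine above the minimum, and at least the minimum number of matched peaks.
No precursor-shifted ("modified") cosine is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import MatchThresholds, SpectrumMS2

__all__ = [
    "SpectralMatch",
    "match_peaks",
    "cosine_score",
    "library_search",
]


@dataclass
class SpectralMatch:
    query_id: str
    library_id: str
    cosine: float
    n_matched_peaks: int
    parent_mass_diff: float


def match_peaks(
    a: SpectrumMS2, b: SpectrumMS2, fragment_tol: float = 0.05, sqrt_intensity: bool = False
) -> list[tuple[int, int]]:
    """One-to-one pairing of peaks within the fragment m/z tolerance.

    Candidate pairs (|mz_a - mz_b| <= tol) are taken greedily by descending
    intensity product, ties broken by smaller m/z difference then by index;
    each peak is used at most once.
    """
    ia = np.sqrt(a.intensity) if sqrt_intensity else a.intensity
    ib = np.sqrt(b.intensity) if sqrt_intensity else b.intensity
    cand = []
    for i in range(len(a.peaks)):
        dm = np.abs(b.mz - a.mz[i])
        for j in np.nonzero(dm <= fragment_tol)[0]:
            cand.append((ia[i] * ib[j], -abs(a.mz[i] - b.mz[j]), -i, -int(j), i, int(j)))
    cand.sort(reverse=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def cosine_score(
    a: SpectrumMS2, b: SpectrumMS2, fragment_tol: float = 0.05, sqrt_intensity: bool = False
) -> tuple[float, int]:
    """Spectral cosine over tolerance-matched peaks, plus the match count.

    Normalization uses all peaks of each spectrum, so unmatched peaks
    penalize the score; identical spectra give exactly 1.0 and disjoint m/z
    sets give 0.0.
    """
    ia = np.sqrt(a.intensity) if sqrt_intensity else a.intensity
    ib = np.sqrt(b.intensity) if sqrt_intensity else b.intensity
    sa, sb = float(ia @ ia), float(ib @ ib)
    if sa == 0 or sb == 0:
        raise ValueError("spectrum has zero total intensity")
    pairs = match_peaks(a, b, fragment_tol, sqrt_intensity=sqrt_intensity)
    if not pairs:
        return 0.0, 0
    # dot product in index order so a self-match reproduces sa bit-for-bit
    # and the self-cosine is exactly 1.0
    order = sorted(pairs)
    dot = float(np.dot(ia[[i for i, _ in order]], ib[[j for _, j in order]]))
    return min(dot / math.sqrt(sa * sb), 1.0), len(pairs)


def cosine_score_optimal(
    a: SpectrumMS2, b: SpectrumMS2, fragment_tol: float = 0.05, sqrt_intensity: bool = False
) -> tuple[float, int]:
    """Exhaustive maximum-weight assignment cosine (small spectra only).

    Intended as the reference the greedy pairing is checked against.
    """
    from scipy.optimize import linear_sum_assignment

    ia = np.sqrt(a.intensity) if sqrt_intensity else a.intensity
    ib = np.sqrt(b.intensity) if sqrt_intensity else b.intensity
    na, nb = float(np.linalg.norm(ia)), float(np.linalg.norm(ib))
    W = np.zeros((len(a.peaks), len(b.peaks)))
    feasible = np.abs(a.mz[:, None] - b.mz[None, :]) <= fragment_tol
    W[feasible] = (ia[:, None] * ib[None, :])[feasible]
    ri, cj = linear_sum_assignment(-W)
    used = W[ri, cj] > 0
    return float(W[ri, cj].sum() / (na * nb)), int(used.sum())


def library_search(
    query: SpectrumMS2,
    library: Sequence[SpectrumMS2],
    thresholds: MatchThresholds = MatchThresholds(),
    sqrt_intensity: bool = False,
) -> list[SpectralMatch]:
    """Screen a query spectrum against a library with MASST-style criteria.

    A candidate is accepted when its parent mass difference is strictly
    below the parent tolerance, its cosine strictly exceeds the minimum, and
    it shares at least the minimum number of matched peaks.  Hits are sorted
    by descending cosine.
    """
    if not library:
        raise ValueError("empty spectral library")
    hits = []
    for entry in library:
        dm = abs(query.precursor_mz - entry.precursor_mz)
        if dm >= thresholds.parent_mass_tol:
            continue
        cos, n_matched = cosine_score(query, entry, thresholds.fragment_tol, sqrt_intensity)
        if cos > thresholds.min_cosine and n_matched >= thresholds.min_matched_peaks:
            hits.append(SpectralMatch(query.spectrum_id, entry.spectrum_id, cos, n_matched, dm))
    hits.sort(key=lambda h: -h.cosine)
    return hits
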