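"""Mean matching of hit/miss target-onset distributions.

Targets appear at an exponentially distributed time after stimulus onset,
and early targets (< 750 ms) are missed more often.  Because the analysis
window is the 500 ms before the target, early-target trials overlap the
stimulus-onset transient, so an unmatched hit-vs-miss comparison conflates
behavioral outcome with onset time — inflating apparent low-frequency
effects.  Matching subsamples hit and miss trials within 250 ms onset bins
so both groups share the same onset histogram, and the whole analysis is
repeated over many random matchings and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ONSET_MIN_MS = 500.0
ONSET_MAX_MS = 5500.0
MATCH_BIN_MS = 250.0
N_BOOTSTRAP_DEFAULT = 50


@dataclass
class MatchResult:
    """Retained hit/miss trial indices after one onset-matching draw."""

    hit_indices: np.ndarray
    miss_indices: np.ndarray
    per_bin_hit: list
    per_bin_miss: list


def _bin_index(onsets: np.ndarray) -> np.ndarray:
    """250 ms bin of each onset; edges 500:250:5500, last bin right-closed."""
    edges = np.arange(ONSET_MIN_MS, ONSET_MAX_MS + MATCH_BIN_MS / 2, MATCH_BIN_MS)
    idx = np.digitize(onsets, edges) - 1
    n_bins = len(edges) - 1
    idx[onsets == ONSET_MAX_MS] = n_bins - 1
    if np.any((idx < 0) | (idx >= n_bins)):
        raise ValueError("target onsets outside [500, 5500] ms cannot be matched")
    return idx


def match_onset_distributions(
    hit_onsets_ms: np.ndarray,
    miss_onsets_ms: np.ndarray,
    rng: np.random.Generator,
    hit_indices: np.ndarray = None,
    miss_indices: np.ndarray = None,
) -> MatchResult:
    """One random matching of hit and miss onset-time distributions.

    Within each of the twenty 250 ms bins, the larger group is randomly
    subsampled (without replacement) to the size of the smaller; bins that
    are empty in either group contribute nothing.  ``hit_indices`` /
    ``miss_indices`` optionally carry original trial indices through; by
    default positions within each input array are returned.
    """
    hit_onsets = np.asarray(hit_onsets_ms, dtype=np.float64)
    miss_onsets = np.asarray(miss_onsets_ms, dtype=np.float64)
    hit_ids = (np.arange(len(hit_onsets)) if hit_indices is None
               else np.asarray(hit_indices))
    miss_ids = (np.arange(len(miss_onsets)) if miss_indices is None
                else np.asarray(miss_indices))
    hit_bins = _bin_index(hit_onsets)
    miss_bins = _bin_index(miss_onsets)
    n_bins = int(round((ONSET_MAX_MS - ONSET_MIN_MS) / MATCH_BIN_MS))

    kept_hits, kept_misses, per_bin_hit, per_bin_miss = [], [], [], []
    for b in range(n_bins):
        h = hit_ids[hit_bins == b]
        m = miss_ids[miss_bins == b]
        k = min(len(h), len(m))
        if k == 0:
            per_bin_hit.append(np.empty(0, dtype=hit_ids.dtype))
            per_bin_miss.append(np.empty(0, dtype=miss_ids.dtype))
            continue
        h_kept = np.sort(rng.choice(h, size=k, replace=False))
        m_kept = np.sort(rng.choice(m, size=k, replace=False))
        per_bin_hit.append(h_kept)
        per_bin_miss.append(m_kept)
        kept_hits.append(h_kept)
        kept_misses.append(m_kept)
    hit_out = (np.concatenate(kept_hits) if kept_hits
               else np.empty(0, dtype=hit_ids.dtype))
    miss_out = (np.concatenate(kept_misses) if kept_misses
                else np.empty(0, dtype=miss_ids.dtype))
    return MatchResult(hit_indices=hit_out, miss_indices=miss_out,
                       per_bin_hit=per_bin_hit, per_bin_miss=per_bin_miss)


def bootstrap_average(
    measure_fn,
    hit_onsets_ms: np.ndarray,
    miss_onsets_ms: np.ndarray,
    n_iter: int = N_BOOTSTRAP_DEFAULT,
    seed=0,
    hit_indices: np.ndarray = None,
    miss_indices: np.ndarray = None,
):
    """Average a measure over ``n_iter`` independent onset matchings.

    ``measure_fn(match: MatchResult) -> ndarray`` must return a fixed-shape
    numeric structure (e.g. per-electrode or per-pair values); the mean over
    iterations is returned, so per-unit values are averaged across
    iterations *before* any population summary across units.  One master
    seed spawns independent per-iteration generators.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    total = None
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        match = match_onset_distributions(
            hit_onsets_ms, miss_onsets_ms, rng,
            hit_indices=hit_indices, miss_indices=miss_indices,
        )
        try:
            value = np.asarray(measure_fn(match), dtype=np.float64)
        except Exception as exc:
            raise RuntimeError(f"measure_fn failed on iteration {i}") from exc
        total = value if total is None else total + value
    return total / n_iter
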