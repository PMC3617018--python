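"""Calling structurally divergent regions with a moderated permutation test.

For every orthologous region the two species' normalised structure values
are compared with a moderated two-class unpaired statistic

    d = (mean_A - mean_B) / (s + s0)

where ``s`` is the pooled standard error of the mean difference and ``s0``
an exchangeability constant that damps the influence of regions with tiny
sample variance.  Significance comes from permuting species labels over
dataset columns — the same relabelling applied to all regions, preserving
inter-region correlation — and the false discovery rate is the median, over
permutations, of the number of permuted scores beyond the call cut-offs,
divided by the number of observed calls.  Cut-offs are found by the
delta-search on the observed-versus-expected order statistics, taking the
loosest cuts whose estimated FDR stays at or below the target.  Calls are
necessarily bipolar: polarity +1 means open in species A / closed in B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .binning import StructureMatrix
from .layout import InvalidParameterError


class DegenerateInputError(ValueError):
    """A class has too few observations for the statistic."""


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------


def _sam_d(arr: np.ndarray, idx_A: np.ndarray, idx_B: np.ndarray, s0: float):
    """Moderated d and pooled SE for every row of a regions x columns array."""
    a = arr[:, idx_A]
    b = arr[:, idx_B]
    na, nb = a.shape[1], b.shape[1]
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return (ma - mb) / (s + s0), s


def region_statistic(values_A, values_B, s0: float) -> float:
    """Moderated difference statistic for one region.

    Antisymmetric under class swap; with zero within-class variance the
    statistic is regularised by ``s0`` alone.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each class needs at least 2 values")
    if s0 < 0:
        raise InvalidParameterError("s0 must be >= 0")
    arr = np.concatenate([a, b])[None, :]
    d, _ = _sam_d(arr, np.arange(a.size), np.arange(a.size, a.size + b.size), s0)
    return float(d[0])


def estimate_s0(s_values, method: str = "median") -> float:
    """Exchangeability constant from the per-region pooled SEs.

    ``median`` (default) returns the median of s.  ``percentile_grid``
    scans s-percentiles and returns the one minimising the coefficient of
    variation of the median absolute d-scale (1 / (s + s0)) across
    s-quantile bands — a flat dispersion of |d| in s is the SAM rationale.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise InvalidParameterError("empty s vector")
    if (s < 0).any():
        raise InvalidParameterError("s values must be non-negative")
    if method == "median":
        return float(np.median(s))
    if method == "percentile_grid":
        qs = np.percentile(s, np.arange(0, 101, 5))
        edges = np.percentile(s, np.linspace(0, 100, 11))
        band = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
        best, best_cv = float(np.median(s)), np.inf
        for s0 in qs:
            scale = 1.0 / (s + s0) if s0 > 0 or (s > 0).all() else None
            if scale is None:
                continue
            meds = [np.median(scale[band == b]) for b in range(10) if (band == b).any()]
            m = np.mean(meds)
            cv = np.std(meds) / m if m > 0 else np.inf
            if cv < best_cv:
                best, best_cv = float(s0), cv
        return best
    raise InvalidParameterError(f"unknown s0 method {method!r}")


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _label_assignments(n_cols: int, n_A: int, n_perm: int, seed: int, exhaustive_limit: int):
    """Index sets of columns assigned to species A, one per permutation.

    Enumerates all C(n_cols, n_A) assignments when that count is within
    ``exhaustive_limit``; otherwise draws ``n_perm`` uniform assignments.
    Returns (list of index arrays, exhaustive flag).
    """
    total = math.comb(n_cols, n_A)
    if total <= exhaustive_limit:
        return [np.array(c) for c in combinations(range(n_cols), n_A)], True
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(n_cols)
        out.append(np.sort(perm[:n_A]))
    return out, False


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class DivergenceResult:
    """Per-region divergence calls plus the global FDR bookkeeping."""

    table: pd.DataFrame  # region_id, d, polarity, mean_A, mean_B
    s0: float
    cut_up: float
    cut_low: float
    n_perm: int
    fdr_target: float
    fdr_achieved: float
    seed: int
    expected_scores: np.ndarray = field(repr=False)
    exhaustive: bool = False
    no_calls: bool = False
    species_A: str = "A"
    species_B: str = "B"

    @property
    def n_calls(self) -> int:
        return int((self.table["polarity"] != 0).sum())

    def calls(self) -> pd.DataFrame:
        return self.table[self.table["polarity"] != 0].reset_index(drop=True)


def divergent_fraction(n_called: int, n_total: int) -> float:
    """Percentage of orthologous regions called divergent."""
    if n_total <= 0:
        raise InvalidParameterError("n_total must be positive")
    return 100.0 * n_called / n_total


def expected_false_positives(fdr: float, n_calls: int) -> float:
    """Expected number of false positives among the calls at a given FDR."""
    return fdr * n_calls


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def call_divergence(
    matrix: StructureMatrix,
    fdr_target: float = 2e-4,
    n_perm: int = 100_000,
    seed: int = 0,
    *,
    s0_method: str = "median",
    exhaustive_limit: int = 10_000,
    max_cut_candidates: int = 1024,
    simple_symmetric: bool = False,
) -> DivergenceResult:
    """Call divergent regions at a target median-false-positive FDR.

    Each permutation reassigns species labels to dataset columns (the same
    reassignment for every region).  For candidate cut pairs on the observed
    d order statistics, the estimated FDR is the median permuted exceedance
    count divided by the observed call count; the loosest cuts meeting
    ``fdr_target`` are chosen.  If no cut qualifies, zero calls are returned
    with ``no_calls`` set (not an error).

    ``simple_symmetric`` replaces the delta search with a plain symmetric
    |d| threshold scanned over the observed |d| values.
    """
    if not (0 < fdr_target < 1):
        raise InvalidParameterError("fdr_target must be in (0, 1)")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    species = matrix.species_labels
    if len(species) != 2:
        raise InvalidParameterError(f"need exactly 2 species, got {species}")
    sp_A, sp_B = species
    cols_A = matrix.species_columns(sp_A)
    cols_B = matrix.species_columns(sp_B)
    if len(cols_A) < 2 or len(cols_B) < 2:
        raise DegenerateInputError("each species needs at least 2 datasets")

    cols = cols_A + cols_B
    arr = matrix.values[cols].to_numpy(dtype=float)
    n_regions = arr.shape[0]
    obs_idx_A = np.arange(len(cols_A))
    obs_idx_B = np.arange(len(cols_A), len(cols))

    _, s_obs = _sam_d(arr, obs_idx_A, obs_idx_B, 0.0)
    s0 = estimate_s0(s_obs, method=s0_method)
    d_obs, _ = _sam_d(arr, obs_idx_A, obs_idx_B, s0)

    assignments, exhaustive = _label_assignments(
        len(cols), len(cols_A), n_perm, seed, exhaustive_limit
    )
    n_used = len(assignments)
    perm_sorted = np.empty((n_used, n_regions), dtype=np.float64)
    na, nb = len(cols_A), len(cols_B)
    arr_sq = arr**2
    tot_sum = arr.sum(axis=1, keepdims=True)
    tot_sq = arr_sq.sum(axis=1, keepdims=True)
    se_factor = (1.0 / na + 1.0 / nb) / (na + nb - 2)
    chunk = max(1, int(2e7) // max(n_regions, 1))
    for c0 in range(0, n_used, chunk):
        block = assignments[c0 : c0 + chunk]
        masks = np.zeros((len(cols), len(block)))
        for p, idx_A in enumerate(block):
            masks[idx_A, p] = 1.0
        sa = arr @ masks
        qa = arr_sq @ masks
        sb = tot_sum - sa
        qb = tot_sq - qa
        ssa = qa - sa**2 / na
        ssb = qb - sb**2 / nb
        s = np.sqrt(np.maximum(se_factor * (ssa + ssb), 0.0))
        d_block = (sa / na - sb / nb) / (s + s0)
        perm_sorted[c0 : c0 + len(block)] = np.sort(d_block.T, axis=1)
    expected_scores = perm_sorted.mean(axis=0)

    order = np.argsort(d_obs, kind="mergesort")
    d_sorted = d_obs[order]
    diff = d_sorted - expected_scores
    mid = int(np.searchsorted(expected_scores, 0.0))
    mid = min(max(mid, 1), n_regions - 1)

    # candidate cut pairs, loosest first
    if simple_symmetric:
        mags = np.unique(np.abs(d_obs))[::-1]
        if len(mags) > max_cut_candidates:
            mags = mags[np.linspace(0, len(mags) - 1, max_cut_candidates).astype(int)]
        deltas = np.sort(mags)
        cut_ups = deltas.copy()
        cut_lows = -deltas.copy()
    else:
        up_diffs = diff[mid:]
        low_diffs = -diff[:mid]
        deltas = np.unique(
            np.concatenate([up_diffs[up_diffs > 0], low_diffs[low_diffs > 0]])
        )
        if deltas.size == 0:
            deltas = np.array([np.inf])
        if len(deltas) > max_cut_candidates:
            deltas = deltas[np.linspace(0, len(deltas) - 1, max_cut_candidates).astype(int)]
        cut_ups = np.empty(len(deltas))
        cut_lows = np.empty(len(deltas))
        for k, delta in enumerate(deltas):
            iu = np.flatnonzero(diff[mid:] >= delta)
            cut_ups[k] = d_sorted[mid + iu[0]] if iu.size else np.inf
            il = np.flatnonzero(diff[:mid] <= -delta)
            cut_lows[k] = d_sorted[il[-1]] if il.size else -np.inf

    n_up = n_regions - np.searchsorted(d_sorted, cut_ups, side="left")
    n_low = np.searchsorted(d_sorted, cut_lows, side="right")
    n_calls_cand = n_up + n_low

    counts = np.empty((n_used, len(deltas)), dtype=np.int64)
    for p in range(n_used):
        row = perm_sorted[p]
        counts[p] = (
            n_regions
            - np.searchsorted(row, cut_ups, side="left")
            + np.searchsorted(row, cut_lows, side="right")
        )
    med_false = np.median(counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_cand = np.where(n_calls_cand > 0, med_false / np.maximum(n_calls_cand, 1), 0.0)
    fdr_cand = np.minimum(fdr_cand, 1.0)

    ok = np.flatnonzero((fdr_cand <= fdr_target) & (n_calls_cand > 0))
    if ok.size:
        k = int(ok[0])  # loosest qualifying cuts
        cut_up, cut_low = float(cut_ups[k]), float(cut_lows[k])
        fdr_achieved = float(fdr_cand[k])
        no_calls = False
    else:
        cut_up, cut_low = np.inf, -np.inf
        fdr_achieved = 0.0
        no_calls = True

    polarity = np.zeros(n_regions, dtype=np.int8)
    polarity[d_obs >= cut_up] = 1
    polarity[d_obs <= cut_low] = -1

    mean_A = arr[:, obs_idx_A].mean(axis=1)
    mean_B = arr[:, obs_idx_B].mean(axis=1)
    table = pd.DataFrame(
        {
            "region_id": matrix.values.index,
            "d": d_obs,
            "polarity": polarity,
            "mean_A": mean_A,
            "mean_B": mean_B,
        }
    ).reset_index(drop=True)
    return DivergenceResult(
        table=table,
        s0=s0,
        cut_up=cut_up,
        cut_low=cut_low,
        n_perm=n_used,
        fdr_target=fdr_target,
        fdr_achieved=fdr_achieved,
        seed=seed,
        expected_scores=expected_scores,
        exhaustive=exhaustive,
        no_calls=no_calls,
        species_A=sp_A,
        species_B=sp_B,
    )
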