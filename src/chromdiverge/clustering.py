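"""Divergence clusters: maximal same-polarity runs of adjacent divergent bins.

Runs require exact coordinate adjacency (orthology coverage gaps break
runs, no gap tolerance) and constant polarity.  Their lengths are assessed
against a null in which the per-bin call labels are shuffled uniformly among
each chromosome's orthologous bins — coordinates fixed, polarity labels
travelling with the bins — so the null preserves each chromosome's label
multiset.  A run length never reached in the permuted genomes is reported
as p < 1/n_perm and such runs form the significant divergence clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import StructureMatrix
from .divergence import DivergenceResult
from .layout import InvalidParameterError


def calls_frame(
    result: DivergenceResult, matrix: StructureMatrix, frame: str = "A"
) -> pd.DataFrame:
    """Per-region calls in one species' coordinate frame, sorted."""
    if frame not in ("A", "B"):
        raise InvalidParameterError("frame must be 'A' or 'B'")
    coords = matrix.regions[
        ["region_id", f"chrom_{frame}", f"start_{frame}", f"end_{frame}"]
    ].rename(
        columns={f"chrom_{frame}": "chrom", f"start_{frame}": "start", f"end_{frame}": "end"}
    )
    out = coords.merge(result.table[["region_id", "polarity"]], on="region_id")
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _adjacency(calls: pd.DataFrame) -> np.ndarray:
    """adj[i] is True when bin i starts exactly where bin i-1 ends (same chrom)."""
    adj = np.zeros(len(calls), dtype=bool)
    if len(calls) > 1:
        same_chrom = calls["chrom"].to_numpy()[1:] == calls["chrom"].to_numpy()[:-1]
        contiguous = calls["start"].to_numpy()[1:] == calls["end"].to_numpy()[:-1]
        adj[1:] = same_chrom & contiguous
    return adj


def _run_segments(labels: np.ndarray, adj: np.ndarray):
    """(start_index, length) of maximal nonzero same-label adjacent runs."""
    nz = labels != 0
    cont = np.zeros(len(labels), dtype=bool)
    if len(labels) > 1:
        cont[1:] = nz[1:] & nz[:-1] & (labels[1:] == labels[:-1]) & adj[1:]
    starts = np.flatnonzero(nz & ~cont)
    if starts.size == 0:
        return starts, np.array([], dtype=int)
    lengths = np.empty(len(starts), dtype=int)
    for k, s in enumerate(starts):
        e = s + 1
        while e < len(labels) and cont[e]:
            e += 1
        lengths[k] = e - s
    return starts, lengths


def find_runs(calls: pd.DataFrame) -> pd.DataFrame:
    """Maximal same-polarity runs of exactly adjacent divergent bins.

    ``calls`` must be a sorted per-bin frame (chrom, start, end, polarity)
    as produced by :func:`calls_frame`; region ids are carried along when
    present.
    """
    calls = calls.sort_values(["chrom", "start"]).reset_index(drop=True)
    labels = calls["polarity"].to_numpy()
    adj = _adjacency(calls)
    starts, lengths = _run_segments(labels, adj)
    rows = []
    has_ids = "region_id" in calls.columns
    for s, ln in zip(starts, lengths):
        rows.append(
            {
                "chrom": calls["chrom"].iloc[s],
                "start": int(calls["start"].iloc[s]),
                "end": int(calls["end"].iloc[s + ln - 1]),
                "length_bins": int(ln),
                "polarity": int(labels[s]),
                "region_ids": (
                    tuple(calls["region_id"].iloc[s : s + ln]) if has_ids else ()
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length_bins", "polarity", "region_ids"]
    )


@dataclass
class RunLengthNull:
    """Null distribution of the longest run under within-chromosome shuffles."""

    n_perm: int
    max_run_per_perm: np.ndarray
    seed: int

    def exceedance_count(self, n: int) -> int:
        return int((self.max_run_per_perm >= n).sum())

    def p_ge(self, n: int) -> float:
        """Fraction of permuted genomes containing a run of length >= n."""
        if n <= 0:
            return 1.0
        return self.exceedance_count(n) / self.n_perm

    def table(self, max_n: int) -> pd.DataFrame:
        ns = np.arange(1, max_n + 1)
        return pd.DataFrame(
            {"run_length": ns, "p_ge": [self.p_ge(int(n)) for n in ns]}
        )


def run_length_null(calls: pd.DataFrame, n_perm: int = 10_000, seed: int = 0) -> RunLengthNull:
    """Permute call labels among each chromosome's bins, 'n_perm' times.

    Bin coordinates stay fixed (coverage gaps keep breaking runs); the
    polarity-bearing labels are shuffled uniformly within each chromosome.
    The longest run in each permuted genome is recorded; p(n) is then the
    fraction of permuted genomes with any run of length >= n, monotone
    non-increasing in n.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    calls = calls.sort_values(["chrom", "start"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    per_chrom = []
    for _, sub in calls.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        per_chrom.append((sub["polarity"].to_numpy().copy(), _adjacency(sub)))
    max_run = np.zeros(n_perm, dtype=int)
    for p in range(n_perm):
        best = 0
        for labels, adj in per_chrom:
            shuffled = rng.permutation(labels)
            _, lengths = _run_segments(shuffled, adj)
            if lengths.size:
                best = max(best, int(lengths.max()))
        max_run[p] = best
    return RunLengthNull(n_perm=n_perm, max_run_per_perm=max_run, seed=seed)


def call_clusters(
    runs: pd.DataFrame, null: RunLengthNull, alpha: float = 1e-4
) -> pd.DataFrame:
    """Runs whose length is improbable under the permutation null.

    The p-value of a run of length n is the fraction of permuted genomes
    containing any run at least that long; lengths never seen in the null
    are reported as bounded above by 1/n_perm (``p_is_upper_bound``), and
    significance compares the raw exceedance fraction against ``alpha``.
    """
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    out = runs.copy()
    counts = np.array([null.exceedance_count(int(n)) for n in out["length_bins"]])
    out["p_value"] = np.maximum(counts, 1) / null.n_perm
    out["p_is_upper_bound"] = counts == 0
    out["significant"] = (counts / null.n_perm) < alpha
    return out


def reconcile_clusters(clusters_A: pd.DataFrame, clusters_B: pd.DataFrame) -> pd.DataFrame:
    """Clusters detected in both species frames, matched by shared regions."""
    sig_A = clusters_A[clusters_A["significant"]].reset_index(drop=True)
    sig_B = clusters_B[clusters_B["significant"]].reset_index(drop=True)
    rows = []
    sets_B = [set(r) for r in sig_B["region_ids"]]
    for i, row in sig_A.iterrows():
        ids = set(row["region_ids"])
        for j, ids_B in enumerate(sets_B):
            shared = ids & ids_B
            if shared:
                rows.append(
                    {
                        "chrom_A": row["chrom"],
                        "start_A": row["start"],
                        "end_A": row["end"],
                        "chrom_B": sig_B["chrom"].iloc[j],
                        "start_B": sig_B["start"].iloc[j],
                        "end_B": sig_B["end"].iloc[j],
                        "polarity": row["polarity"],
                        "n_shared_regions": len(shared),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom_A",
            "start_A",
            "end_A",
            "chrom_B",
            "start_B",
            "end_B",
            "polarity",
            "n_shared_regions",
        ],
    )
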