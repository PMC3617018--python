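"""Probe binning, within-species collation and cross-species orthology.

Probe-level tracks are averaged into fixed-width (default 100 kb) bins,
bins are collated across a species' datasets by coordinate overlap, and the
two species' collated tables are paired through a reciprocal-best-overlap
orthology map into a complete-case region x dataset structure matrix.
Regions without a reciprocal orthologous partner are reported as putatively
lineage specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import CoordinateError, DEFAULT_BIN_SIZE, GenomeLayout, InvalidParameterError


@dataclass
class BinTrack:
    """Binned values of one dataset: (chrom, start, end, value, probe_count)."""

    species: str
    dataset: str
    bin_size: int
    data: pd.DataFrame
    assay: str = "generic"
    cell_type: str = "generic"


@dataclass
class OrthologyMap:
    """Raw candidate interval pairs with reciprocal overlap fractions."""

    pairs: pd.DataFrame  # chrom_A/start_A/end_A, chrom_B/..., overlap_A, overlap_B
    threshold: float = 0.5


@dataclass
class StructureMatrix:
    """Orthologous region pairs x datasets matrix of structure values."""

    regions: pd.DataFrame  # region_id + coords in both species frames
    values: pd.DataFrame  # index region_id, one column per dataset
    datasets: pd.DataFrame  # dataset, species, assay, cell_type
    stage: str = "raw"
    reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise InvalidParameterError("duplicate dataset column labels")

    def species_columns(self, species: str) -> list[str]:
        cols = self.datasets.loc[self.datasets["species"] == species, "dataset"].tolist()
        if not cols:
            raise InvalidParameterError(f"no datasets for species {species!r}")
        return cols

    @property
    def species_labels(self) -> list[str]:
        return list(dict.fromkeys(self.datasets["species"]))

    def n_regions(self) -> int:
        return len(self.values)


def bin_probes(
    probes: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_probes: int = 10,
    *,
    species: str = "A",
    dataset: str | None = None,
    assay: str = "generic",
    cell_type: str = "generic",
) -> BinTrack:
    """Average probe values into consecutive non-overlapping bins.

    A probe is assigned to the bin containing its midpoint (0-based
    half-open); bins represented by fewer than ``min_probes`` probes are
    discarded as unreliable.
    """
    if min_probes < 1:
        raise InvalidParameterError(f"min_probes must be >= 1, got {min_probes}")
    if dataset is None:
        if "dataset" in probes.columns:
            uniq = probes["dataset"].unique()
            if len(uniq) != 1:
                raise InvalidParameterError(
                    "bin_probes expects a single dataset; got " + ", ".join(map(str, uniq))
                )
            dataset = str(uniq[0])
        else:
            dataset = "dataset"
    lengths = layout.lengths
    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()
    for chrom, pos in zip(chrom_arr, pos_arr):
        if chrom not in lengths:
            raise CoordinateError(f"probe on unknown chromosome: {chrom}:{pos}")
    out_of_bounds = np.array(
        [not (0 <= p < lengths[c]) for c, p in zip(chrom_arr, pos_arr)]
    )
    if out_of_bounds.any():
        i = int(np.flatnonzero(out_of_bounds)[0])
        raise CoordinateError(
            f"probe outside chromosome bounds: {chrom_arr[i]}:{pos_arr[i]}"
        )

    df = probes.assign(start=(probes["pos"] // bin_size) * bin_size)
    grouped = df.groupby(["chrom", "start"], sort=True)["value"].agg(["mean", "count"])
    grouped = grouped.reset_index().rename(columns={"mean": "value", "count": "probe_count"})
    grouped = grouped[grouped["probe_count"] >= min_probes].reset_index(drop=True)
    # drop terminal remnants shorter than a whole bin
    grouped = grouped[
        grouped.apply(lambda r: r["start"] + bin_size <= lengths[r["chrom"]], axis=1)
    ].reset_index(drop=True)
    grouped["end"] = grouped["start"] + bin_size
    data = grouped[["chrom", "start", "end", "value", "probe_count"]]
    return BinTrack(
        species=species,
        dataset=dataset,
        bin_size=bin_size,
        data=data,
        assay=assay,
        cell_type=cell_type,
    )


def _pair_to_reference(
    ref: pd.DataFrame, other: pd.DataFrame, bin_size: int, min_frac: float
) -> pd.Series:
    """For each reference bin, the other track's best-overlap value.

    Bins are equal width, so the overlap fraction between bins starting at
    s_ref and s_other (same chromosome) is ``max(0, bin - |s_ref - s_other|)
    / bin``; with identical grids this reduces to exact coordinate match.
    Returns a Series of values aligned to ``ref``'s rows (NaN = unpaired).
    """
    out = np.full(len(ref), np.nan)
    for chrom, ref_idx in ref.groupby("chrom").groups.items():
        sub = other[other["chrom"] == chrom]
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        order = np.argsort(starts)
        starts = starts[order]
        vals = sub["value"].to_numpy()[order]
        ref_starts = ref.loc[ref_idx, "start"].to_numpy()
        pos = np.searchsorted(starts, ref_starts)
        for k, (i, rs) in enumerate(zip(ref_idx, ref_starts)):
            best_ov, best_val = -1, np.nan
            for j in (pos[k] - 1, pos[k]):
                if 0 <= j < len(starts):
                    ov = bin_size - abs(int(rs) - int(starts[j]))
                    if ov > best_ov:
                        best_ov, best_val = ov, vals[j]
            if best_ov >= min_frac * bin_size:
                out[i] = best_val
    return pd.Series(out, index=ref.index)


def collate_species(
    tracks: list[BinTrack], min_collate_overlap: float = 0.5
) -> pd.DataFrame:
    """Collate one species' bin tracks into a complete-case region table.

    The first track's bins define the reference grid; every other dataset
    must supply a bin overlapping each reference bin by at least
    ``min_collate_overlap`` (inclusive) or the region is dropped.

    Returns a frame (chrom, start, end, one value column per dataset).
    """
    if not tracks:
        raise InvalidParameterError("no tracks to collate")
    if not (0 < min_collate_overlap <= 1):
        raise InvalidParameterError("min_collate_overlap must be in (0, 1]")
    species = {t.species for t in tracks}
    if len(species) != 1:
        raise InvalidParameterError(f"mixed species labels in collation: {sorted(species)}")
    bin_size = tracks[0].bin_size
    ref = tracks[0].data[["chrom", "start", "end"]].reset_index(drop=True)
    table = ref.copy()
    table[tracks[0].dataset] = tracks[0].data["value"].to_numpy()
    for t in tracks[1:]:
        table[t.dataset] = _pair_to_reference(ref, t.data, bin_size, min_collate_overlap)
    table = table.dropna().reset_index(drop=True)
    return table


def _reciprocal_best(pairs: pd.DataFrame) -> pd.DataFrame:
    """Retain pairs that are each side's best-overlap partner.

    Preference is by larger overlap (bp equivalent: the side's own overlap
    fraction, bins being fixed width), ties broken by lexicographic partner
    chromosome then lower partner start — deterministic.
    """
    if pairs.empty:
        return pairs.reset_index(drop=True)
    df = pairs.copy()
    df["_ia"] = df["chrom_A"].astype(str) + ":" + df["start_A"].astype(str)
    df["_ib"] = df["chrom_B"].astype(str) + ":" + df["start_B"].astype(str)
    best_a = (
        df.sort_values(
            ["_ia", "overlap_A", "chrom_B", "start_B"],
            ascending=[True, False, True, True],
        )
        .groupby("_ia", sort=False)
        .head(1)[["_ia", "_ib"]]
    )
    best_b = (
        df.sort_values(
            ["_ib", "overlap_B", "chrom_A", "start_A"],
            ascending=[True, False, True, True],
        )
        .groupby("_ib", sort=False)
        .head(1)[["_ia", "_ib"]]
    )
    keys_a = set(map(tuple, best_a.to_numpy()))
    keys_b = set(map(tuple, best_b.to_numpy()))
    keep = [tuple(k) in keys_a and tuple(k) in keys_b for k in df[["_ia", "_ib"]].to_numpy()]
    return df[keep].drop(columns=["_ia", "_ib"]).reset_index(drop=True)


def map_orthologs(
    table_A: pd.DataFrame,
    table_B: pd.DataFrame,
    ortho_map: OrthologyMap | pd.DataFrame,
    threshold: float = 0.5,
    *,
    datasets_A: pd.DataFrame | None = None,
    datasets_B: pd.DataFrame | None = None,
    species_A: str = "A",
    species_B: str = "B",
) -> tuple[StructureMatrix, pd.DataFrame, pd.DataFrame]:
    """Pair the two species' collated tables by reciprocal-best overlap.

    A candidate pair is retained when both overlap fractions are >= the
    threshold (inclusive) and each interval's best-overlap partner is the
    other.  All regions left unpaired are returned as putatively lineage
    specific, so every input region is accounted for.
    """
    if not (0 < threshold <= 1):
        raise InvalidParameterError("threshold must be in (0, 1]")
    pairs = ortho_map.pairs if isinstance(ortho_map, OrthologyMap) else ortho_map
    key_cols = ["chrom_A", "start_A", "end_A", "chrom_B", "start_B", "end_B"]
    if pairs.duplicated(subset=key_cols).any():
        raise InvalidParameterError("duplicate interval pairs in orthology map")

    candidates = pairs[
        (pairs["overlap_A"] >= threshold) & (pairs["overlap_B"] >= threshold)
    ].reset_index(drop=True)
    retained = _reciprocal_best(candidates)

    a_key = table_A["chrom"].astype(str) + ":" + table_A["start"].astype(str)
    b_key = table_B["chrom"].astype(str) + ":" + table_B["start"].astype(str)
    ra_key = retained["chrom_A"].astype(str) + ":" + retained["start_A"].astype(str)
    rb_key = retained["chrom_B"].astype(str) + ":" + retained["start_B"].astype(str)

    ds_cols_A = [c for c in table_A.columns if c not in ("chrom", "start", "end")]
    ds_cols_B = [c for c in table_B.columns if c not in ("chrom", "start", "end")]
    ta = table_A.set_index(a_key)
    tb = table_B.set_index(b_key)
    present = ra_key.isin(ta.index).to_numpy() & rb_key.isin(tb.index).to_numpy()
    retained = retained[present].reset_index(drop=True)
    ra_key, rb_key = ra_key[present].reset_index(drop=True), rb_key[present].reset_index(drop=True)

    region_ids = [f"R{i:06d}" for i in range(len(retained))]
    regions = retained[key_cols + ["overlap_A", "overlap_B"]].copy()
    regions.insert(0, "region_id", region_ids)
    vals_A = ta.loc[ra_key, ds_cols_A].reset_index(drop=True)
    vals_B = tb.loc[rb_key, ds_cols_B].reset_index(drop=True)
    values = pd.concat([vals_A, vals_B], axis=1)
    values.index = pd.Index(region_ids, name="region_id")

    if datasets_A is None:
        datasets_A = pd.DataFrame(
            {"dataset": ds_cols_A, "assay": "generic", "cell_type": "generic"}
        )
    if datasets_B is None:
        datasets_B = pd.DataFrame(
            {"dataset": ds_cols_B, "assay": "generic", "cell_type": "generic"}
        )
    datasets = pd.concat(
        [datasets_A.assign(species=species_A), datasets_B.assign(species=species_B)],
        ignore_index=True,
    )[["dataset", "species", "assay", "cell_type"]]

    ls_A = table_A[~a_key.isin(set(ra_key))][["chrom", "start", "end"]].reset_index(drop=True)
    ls_B = table_B[~b_key.isin(set(rb_key))][["chrom", "start", "end"]].reset_index(drop=True)
    matrix = StructureMatrix(regions=regions, values=values, datasets=datasets, stage="raw")
    return matrix, ls_A, ls_B
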