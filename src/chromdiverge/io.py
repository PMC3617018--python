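"""Readers and writers for the pipeline's standard text formats.

All genomic coordinates are 0-based half-open.  BED/bedGraph files are
plain TSV without headers; tables carry explicit header lines; the
structure matrix embeds its dataset metadata in ``#dataset`` comment lines
so that one file round-trips the whole object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinTrack, StructureMatrix
from .divergence import DivergenceResult
from .layout import GenomeLayout


# --- simple tracks ---------------------------------------------------------


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_bed(df: pd.DataFrame, path, name_col: str | None = None, score_col: str | None = None) -> None:
    out = df[["chrom", "start", "end"]].copy()
    if name_col is not None:
        out["name"] = df[name_col]
        if score_col is not None:
            out["score"] = df[score_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_probes(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "dataset", "value"]].to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- layout / orthology / expression ---------------------------------------


def write_layout(layout: GenomeLayout, path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def read_layout(path, species_tag: str) -> GenomeLayout:
    return GenomeLayout.from_frame(pd.read_csv(path, sep="\t"), species_tag)


def write_orthology(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_orthology(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- structure matrix -------------------------------------------------------


def write_matrix(matrix: StructureMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#stage\t{matrix.stage}\n")
        for r in matrix.datasets.itertuples():
            fh.write(f"#dataset\t{r.dataset}\t{r.species}\t{r.assay}\t{r.cell_type}\n")
        body = matrix.regions.merge(
            matrix.values.reset_index(), on="region_id", how="left"
        )
        body.to_csv(fh, sep="\t", index=False)


def read_matrix(path) -> StructureMatrix:
    stage = "raw"
    ds_rows = []
    with open(path) as fh:
        offset = 0
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#stage":
                stage = parts[1]
            elif parts[0] == "#dataset":
                ds_rows.append(
                    {
                        "dataset": parts[1],
                        "species": parts[2],
                        "assay": parts[3],
                        "cell_type": parts[4],
                    }
                )
            offset += 1
    body = pd.read_csv(path, sep="\t", skiprows=offset)
    datasets = pd.DataFrame(ds_rows)
    region_cols = [c for c in body.columns if c not in set(datasets["dataset"])]
    regions = body[region_cols]
    values = body.set_index("region_id")[list(datasets["dataset"])]
    return StructureMatrix(regions=regions, values=values, datasets=datasets, stage=stage)


# --- divergence result ------------------------------------------------------


def write_divergence(result: DivergenceResult, matrix: StructureMatrix, outdir) -> None:
    """TSV of per-region results, BED of calls, JSON of global fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = matrix.regions.merge(result.table, on="region_id")
    table.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    calls = table[table["polarity"] != 0]
    bed = calls[["chrom_A", "start_A", "end_A", "polarity"]].rename(
        columns={"chrom_A": "chrom", "start_A": "start", "end_A": "end"}
    )
    write_bed(bed, outdir / "divergent_calls_A.bed", name_col="polarity")
    sidecar = {
        "s0": result.s0,
        "cut_up": None if np.isinf(result.cut_up) else result.cut_up,
        "cut_low": None if np.isinf(result.cut_low) else result.cut_low,
        "fdr_target": result.fdr_target,
        "fdr_achieved": result.fdr_achieved,
        "n_perm": result.n_perm,
        "exhaustive": result.exhaustive,
        "no_calls": result.no_calls,
        "seed": result.seed,
        "n_calls": result.n_calls,
    }
    (outdir / "divergence.json").write_text(json.dumps(sidecar, indent=2) + "\n")


# --- manifests --------------------------------------------------------------


def read_manifest(path) -> list[dict]:
    """Dataset manifest YAML: list of {id, species, assay, cell_type, path,
    sign_flip, probe_based}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    out = []
    for e in entries:
        out.append(
            {
                "id": e["id"],
                "species": e["species"],
                "assay": e.get("assay", "generic"),
                "cell_type": e.get("cell_type", "generic"),
                "path": e["path"],
                "sign_flip": bool(e.get("sign_flip", False)),
                "probe_based": bool(e.get("probe_based", True)),
            }
        )
    return out


def load_track(entry: dict, layout: GenomeLayout, bin_size: int, min_probes: int) -> BinTrack:
    """Load one manifest entry into a BinTrack, applying the sign convention.

    Lamina-association tracks are stored with larger = more lamina-associated
    (= more closed); their manifest entries set ``sign_flip`` so that after
    loading, larger always means more open.
    """
    from .binning import bin_probes

    if entry["probe_based"]:
        probes = read_probes(entry["path"])
        if entry["sign_flip"]:
            probes = probes.assign(value=-probes["value"])
        track = bin_probes(
            probes,
            layout,
            bin_size=bin_size,
            min_probes=min_probes,
            species=entry["species"],
            dataset=entry["id"],
            assay=entry["assay"],
            cell_type=entry["cell_type"],
        )
    else:
        data = read_bedgraph(entry["path"])
        if entry["sign_flip"]:
            data = data.assign(value=-data["value"])
        data["probe_count"] = np.nan
        track = BinTrack(
            species=entry["species"],
            dataset=entry["id"],
            bin_size=bin_size,
            data=data,
            assay=entry["assay"],
            cell_type=entry["cell_type"],
        )
    return track
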