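"""End-to-end orchestration: simulate -> bin -> normalise -> call -> cluster
-> enrich -> associate, with deterministic per-stage seeding.

The default :class:`StudyConfig` is the package's reference study: 5,000
100-kb bins over 8 chromosomes, six datasets per species with a 2-unit
open/closed separation against 0.5-unit per-bin noise (a 4-sigma implant
effect), 10% of bins divergent in 4-8 bin tracts, half of the tracts placed
inside 5-Mb subtelomeric windows.  Problem sizes and permutation counts are
chosen so a full run completes in well under a minute on one CPU while the
permutation machinery still operates far from its small-sample edge cases.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clustering, enrichment, io
from .binning import BinTrack, StructureMatrix, bin_probes, collate_species, map_orthologs
from .divergence import DivergenceResult, call_divergence, divergent_fraction
from .layout import GenomeLayout, InvalidParameterError
from .normalise import quantile_normalise
from . import simulate as sim


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent, reproducible RNG seed per pipeline stage (< 2^31)."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class StudyConfig:
    """Simulation + analysis parameters for one synthetic study."""

    # genome
    n_chrom: int = 8
    chrom_len: int = 62_500_000
    bin_size: int = 100_000
    # compartments
    mean_domain_bins: float = 8.0
    p_open: float = 0.5
    # divergence implants: ~10% of bins in 4-8 bin tracts
    n_tracts: int = 83
    tract_len_bins: tuple[int, int] = (4, 8)
    end_bias: float = 0.5
    end_window_bins: int = 50  # 5 Mb
    # structure signal
    n_datasets_per_species: int = 6
    mu_open: float = 1.0
    mu_closed: float = -1.0
    sigma_dataset: float = 0.2
    sigma_noise: float = 0.5
    # probe level
    probe_level: bool = True
    probes_per_bin: float = 30.0
    probe_sigma: float = 0.3
    min_probes: int = 10
    # orthology (reference study keeps full coverage so implanted tracts stay
    # contiguous in the orthologous frame; dropout is exercised separately)
    n_rearrangements: int = 3
    min_overlap: float = 0.5
    frac_unmappable: float = 0.0
    decoy_frac: float = 0.0
    nonreciprocal_frac: float = 0.0
    # annotations
    gc_rho_target: float = 0.6
    gene_density_open: float = 3.0
    gene_density_closed: float = 1.5
    lincrna_density: float = 0.05
    lincrna_tract_factor: float = 4.0
    # expression
    effect_log2: float = 1.0
    sd_log2: float = 1.5
    baseline_shift: float = 0.0
    # analysis
    fdr_target: float = 2e-4
    n_perm_divergence: int = 10_000
    n_perm_cluster: int = 2_000
    n_perm_enrich: int = 2_000
    alpha_cluster: float = 1e-4
    subtelomere_windows: tuple[int, ...] = (1_000_000, 5_000_000, 10_000_000)
    collate_overlap: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tract_len_bins", "subtelomere_windows"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["tract_len_bins"] = list(self.tract_len_bins)
        data["subtelomere_windows"] = list(self.subtelomere_windows)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class StudyBundle:
    """Everything the generator emits for one seeded study."""

    config: StudyConfig
    layout_A: GenomeLayout
    layout_B: GenomeLayout
    track_A: sim.CompartmentTrack
    track_B: sim.CompartmentTrack
    truth: sim.TruthTable
    binned_A: pd.DataFrame
    binned_B: pd.DataFrame
    datasets_A: pd.DataFrame
    datasets_B: pd.DataFrame
    orthology: pd.DataFrame
    gc: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame


def simulate_study(config: StudyConfig, seed: int) -> StudyBundle:
    """Generate the full two-species study for one master seed."""
    c = config
    layout_A = sim.gen_layout(
        c.n_chrom, c.chrom_len, stage_seed(seed, "layout_A"),
        bin_size=c.bin_size, species_tag="A",
    )
    layout_B = sim.gen_layout(
        c.n_chrom, c.chrom_len, stage_seed(seed, "layout_B"),
        bin_size=c.bin_size, species_tag="B",
    )
    track_A = sim.gen_compartments(
        layout_A, c.mean_domain_bins, c.p_open, stage_seed(seed, "compartments"),
        bin_size=c.bin_size,
    )
    # species B starts structurally conserved (index-aligned with A);
    # divergence is then implanted on the aligned track
    track_B_cons = sim.CompartmentTrack(
        layout=layout_B, bin_size=c.bin_size,
        states={k: v.copy() for k, v in track_A.states.items()},
    )
    track_B_aligned, truth = sim.implant_divergence(
        track_A, track_B_cons, c.n_tracts, c.tract_len_bins,
        stage_seed(seed, "implant"),
        end_bias=c.end_bias, end_window_bins=c.end_window_bins,
    )
    # the B genome is a block-rearranged relabelling of the aligned bins;
    # the orthology map below uses the same rearrangement
    order = sim.rearrangement_order(
        track_A.n_bins(), c.n_rearrangements, stage_seed(seed, "rearrange")
    )
    aligned = track_B_aligned.concat()
    scattered = np.empty_like(aligned)
    scattered[order] = aligned
    track_B = sim.CompartmentTrack(layout=layout_B, bin_size=c.bin_size, states={})
    pos = 0
    for chrom in layout_B:
        nb = chrom.length_bp // c.bin_size
        track_B.states[chrom.name] = scattered[pos : pos + nb]
        pos += nb
    ds_A = [(f"A_ds{i}", "RT" if i < c.n_datasets_per_species - 1 else "HiC", f"cellA{i}")
            for i in range(c.n_datasets_per_species)]
    ds_B = [(f"B_ds{i}", "RT" if i < c.n_datasets_per_species - 1 else "HiC", f"cellB{i}")
            for i in range(c.n_datasets_per_species)]
    binned_A, meta_A = sim.gen_structure(
        track_A, ds_A, c.mu_open, c.mu_closed, c.sigma_dataset, c.sigma_noise,
        stage_seed(seed, "structure_A"),
    )
    binned_B, meta_B = sim.gen_structure(
        track_B, ds_B, c.mu_open, c.mu_closed, c.sigma_dataset, c.sigma_noise,
        stage_seed(seed, "structure_B"),
    )
    orthology = sim.gen_orthology(
        layout_A, layout_B, c.n_rearrangements, c.min_overlap, c.frac_unmappable,
        stage_seed(seed, "orthology"), bin_size=c.bin_size,
        decoy_frac=c.decoy_frac, nonreciprocal_frac=c.nonreciprocal_frac,
        order=order,
    )
    gc, genes = sim.gen_gc_and_genes(
        track_A, c.gc_rho_target, c.gene_density_open, c.gene_density_closed,
        stage_seed(seed, "gc_genes"),
        gene_classes={
            "protein_coding": (c.gene_density_open, c.gene_density_closed, 1.0),
            "lincRNA": (c.lincrna_density, c.lincrna_density, c.lincrna_tract_factor),
        },
        truth=truth,
    )
    expression = sim.gen_expression(
        truth, genes[genes["gene_class"] == "protein_coding"].reset_index(drop=True),
        c.effect_log2, c.sd_log2, c.baseline_shift, stage_seed(seed, "expression"),
    )
    return StudyBundle(
        config=c, layout_A=layout_A, layout_B=layout_B,
        track_A=track_A, track_B=track_B, truth=truth,
        binned_A=binned_A, binned_B=binned_B,
        datasets_A=meta_A, datasets_B=meta_B,
        orthology=orthology, gc=gc, genes=genes, expression=expression,
    )


def _tracks_from_binned(
    bundle: StudyBundle, species: str, seed: int
) -> list[BinTrack]:
    """Bin tracks for one species, via probe sampling when configured."""
    c = bundle.config
    binned = bundle.binned_A if species == "A" else bundle.binned_B
    layout = bundle.layout_A if species == "A" else bundle.layout_B
    meta = bundle.datasets_A if species == "A" else bundle.datasets_B
    tracks = []
    for r in meta.itertuples():
        one = binned[["chrom", "start", "end", r.dataset]]
        if c.probe_level:
            probes = sim.gen_probes(
                one, c.probes_per_bin, c.probe_sigma,
                stage_seed(seed, f"probes_{r.dataset}"), bin_size=c.bin_size,
            )
            tracks.append(
                bin_probes(
                    probes, layout, bin_size=c.bin_size, min_probes=c.min_probes,
                    species=species, dataset=r.dataset,
                    assay=r.assay, cell_type=r.cell_type,
                )
            )
        else:
            data = one.rename(columns={r.dataset: "value"}).assign(probe_count=np.nan)
            tracks.append(
                BinTrack(
                    species=species, dataset=r.dataset, bin_size=c.bin_size,
                    data=data, assay=r.assay, cell_type=r.cell_type,
                )
            )
    return tracks


@dataclass
class StudyResult:
    """Outputs of a full pipeline run plus ground-truth recovery metrics."""

    bundle: StudyBundle
    matrix_raw: StructureMatrix
    matrix: StructureMatrix
    lineage_specific_A: pd.DataFrame
    lineage_specific_B: pd.DataFrame
    divergence: DivergenceResult
    labels: association.ClassLabel
    truth_labels: np.ndarray
    clusters_A: pd.DataFrame
    clusters_B: pd.DataFrame
    reconciled: pd.DataFrame
    null_A: clustering.RunLengthNull
    subtelomere: dict[int, enrichment.EnrichmentResult]
    recovery: dict = field(default_factory=dict)


def run_study(config: StudyConfig, seed: int) -> StudyResult:
    """Simulate one study and run the whole analysis on it."""
    bundle = simulate_study(config, seed)
    c = config

    tracks_A = _tracks_from_binned(bundle, "A", seed)
    tracks_B = _tracks_from_binned(bundle, "B", seed)
    table_A = collate_species(tracks_A, c.collate_overlap)
    table_B = collate_species(tracks_B, c.collate_overlap)
    matrix_raw, ls_A, ls_B = map_orthologs(
        table_A, table_B, bundle.orthology, c.min_overlap,
        datasets_A=bundle.datasets_A, datasets_B=bundle.datasets_B,
    )
    matrix = quantile_normalise(matrix_raw)
    result = call_divergence(
        matrix, fdr_target=c.fdr_target, n_perm=c.n_perm_divergence,
        seed=stage_seed(seed, "divergence"),
    )
    labels = association.ClassLabel.from_result(result)
    bins_A = matrix.regions[["chrom_A", "start_A", "end_A"]].rename(
        columns={"chrom_A": "chrom", "start_A": "start", "end_A": "end"}
    )
    truth_labels = bundle.truth.label_for_bins(bins_A)

    clusters = {}
    nulls = {}
    for frame in ("A", "B"):
        calls = clustering.calls_frame(result, matrix, frame)
        runs = clustering.find_runs(calls)
        null = clustering.run_length_null(
            calls, n_perm=c.n_perm_cluster, seed=stage_seed(seed, f"cluster_{frame}")
        )
        clusters[frame] = clustering.call_clusters(runs, null, c.alpha_cluster)
        nulls[frame] = null
    reconciled = clustering.reconcile_clusters(clusters["A"], clusters["B"])

    called = matrix.regions.merge(result.table, on="region_id")
    called = called[called["polarity"] != 0]
    div_bed = called[["chrom_A", "start_A", "end_A"]].rename(
        columns={"chrom_A": "chrom", "start_A": "start", "end_A": "end"}
    )
    subtel = {}
    for w in c.subtelomere_windows:
        features = enrichment.subtelomere_intervals(bundle.layout_A, w)
        subtel[w] = enrichment.permutation_test(
            div_bed, features, bundle.layout_A,
            statistic="overlap_count", n_perm=c.n_perm_enrich,
            seed=stage_seed(seed, f"subtel_{w}"),
        )

    res = StudyResult(
        bundle=bundle, matrix_raw=matrix_raw, matrix=matrix,
        lineage_specific_A=ls_A, lineage_specific_B=ls_B,
        divergence=result, labels=labels, truth_labels=truth_labels,
        clusters_A=clusters["A"], clusters_B=clusters["B"],
        reconciled=reconciled, null_A=nulls["A"], subtelomere=subtel,
    )
    res.recovery = recovery_report(res)
    return res


def recovery_report(res: StudyResult) -> dict:
    """Ground-truth confusion metrics for a synthetic study run."""
    c = res.bundle.config
    pol = res.divergence.table["polarity"].to_numpy()
    truth = res.truth_labels
    n_true = int((truth != 0).sum())
    n_calls = int((pol != 0).sum())
    tp = int(((truth != 0) & (pol == truth)).sum())
    fp = int(((pol != 0) & (pol != truth)).sum())
    sensitivity = tp / n_true if n_true else float("nan")
    fdp = fp / n_calls if n_calls else 0.0

    # tracts long enough that their run length is significant under the null
    null = res.null_A
    min_len = None
    for n in range(1, 64):
        if null.exceedance_count(n) / null.n_perm < c.alpha_cluster:
            min_len = n
            break
    tracts = res.bundle.truth.tracts
    tracts = tracts.assign(length_bins=(tracts["end"] - tracts["start"]) // c.bin_size)
    detectable = tracts[tracts["length_bins"] >= (min_len or np.inf)]
    sig = res.clusters_A[res.clusters_A["significant"]]
    recovered = 0
    for t in detectable.itertuples():
        hit = sig[
            (sig["chrom"] == t.chrom)
            & (sig["polarity"] == t.polarity)
            & (np.abs(sig["start"] - t.start) <= c.bin_size)
            & (np.abs(sig["end"] - t.end) <= c.bin_size)
        ]
        if len(hit):
            recovered += 1
    cluster_recovery = recovered / len(detectable) if len(detectable) else float("nan")

    subtel_5mb = res.subtelomere.get(5_000_000)
    return {
        "n_regions": res.matrix.n_regions(),
        "n_truth_divergent": n_true,
        "n_calls": n_calls,
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": sensitivity,
        "fdp": fdp,
        "divergent_fraction_pct": divergent_fraction(n_calls, res.matrix.n_regions()),
        "min_significant_run_bins": min_len,
        "n_detectable_tracts": int(len(detectable)),
        "n_recovered_clusters": recovered,
        "cluster_recovery": cluster_recovery,
        "n_significant_clusters_A": int(res.clusters_A["significant"].sum()),
        "subtelomere_p_enrich_5mb": subtel_5mb.p_enrich if subtel_5mb else None,
    }


def run_pipeline(config: StudyConfig, seed: int, outdir) -> StudyResult:
    """Run the full study and write every stage's outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = run_study(config, seed)
    b = res.bundle

    io.write_layout(b.layout_A, outdir / "layout_A.tsv")
    io.write_layout(b.layout_B, outdir / "layout_B.tsv")
    io.write_orthology(b.orthology, outdir / "orthology.tsv")
    io.write_bed(b.truth.tracts, outdir / "truth_tracts.bed", name_col="polarity")
    io.write_bedgraph(b.gc, outdir / "gc.bedgraph", value_col="gc")
    io.write_bed(b.genes, outdir / "genes.bed", name_col="gene_class")
    io.write_expression(b.expression, outdir / "expression.tsv")
    io.write_matrix(res.matrix_raw, outdir / "matrix_raw.tsv")
    io.write_matrix(res.matrix, outdir / "matrix_normalised.tsv")
    io.write_divergence(res.divergence, res.matrix, outdir)
    for frame, cl in (("A", res.clusters_A), ("B", res.clusters_B)):
        out = cl.copy()
        out["score"] = (-np.log10(out["p_value"])).round(3)
        io.write_bed(out, outdir / f"clusters_{frame}.bed", name_col="polarity",
                     score_col="score")
    res.reconciled.to_csv(outdir / "clusters_reconciled.tsv", sep="\t", index=False)
    subtel = {
        str(w): {
            "observed": r.observed, "null_mean": r.null_mean,
            "p_enrich": r.p_enrich, "p_deplete": r.p_deplete,
        }
        for w, r in res.subtelomere.items()
    }
    (outdir / "enrichment.json").write_text(json.dumps(subtel, indent=2) + "\n")
    (outdir / "recovery.json").write_text(json.dumps(res.recovery, indent=2) + "\n")

    manifest = {
        "seed": seed,
        "stage_seeds": {
            s: stage_seed(seed, s)
            for s in ("layout_A", "layout_B", "compartments", "implant", "structure_A",
                      "structure_B", "orthology", "gc_genes", "expression",
                      "divergence", "cluster_A", "cluster_B")
        },
        "config": {**asdict(config),
                   "tract_len_bins": list(config.tract_len_bins),
                   "subtelomere_windows": list(config.subtelomere_windows)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return res
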