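"""Synthetic two-species chromatin landscapes with known ground truth.

The generator emulates the statistical structure that the divergence analysis
assumes of real replication-timing / lamina-association / Hi-C-eigenvalue
tracks:

* contiguous open/closed compartment domains along each chromosome,
  produced by a renewal two-state chain (geometric run lengths);
* bimodal per-dataset marginals: each dataset reports the latent state mean
  plus a dataset-level offset and per-bin noise, so inter-dataset rank
  correlations are strong and positive;
* implanted bipolar divergent tracts — contiguous runs of bins whose latent
  state is flipped in species B only — recorded in a :class:`TruthTable`;
* probe-level sampling whose per-bin mean recovers the bin value;
* an orthology interval map with controlled reciprocal overlap fractions,
  sub-threshold decoys and unmappable (lineage-specific) bins;
* GC content correlated with structure, gene annotations with
  state-dependent density, and orthologous expression whose log2 fold change
  is shifted inside implanted tracts.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import (
    DEFAULT_BIN_SIZE,
    Chromosome,
    GenomeLayout,
    InvalidParameterError,
)


class InfeasibleImplantError(ValueError):
    """Requested divergent tracts do not fit without overlap."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompartmentTrack:
    """Per-bin latent open(1)/closed(0) states tiling each chromosome."""

    layout: GenomeLayout
    bin_size: int
    states: dict[str, np.ndarray]

    def n_bins(self) -> int:
        return int(sum(len(s) for s in self.states.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.states[c.name] for c in self.layout])

    def copy(self) -> "CompartmentTrack":
        return CompartmentTrack(
            layout=self.layout,
            bin_size=self.bin_size,
            states={k: v.copy() for k, v in self.states.items()},
        )

    def run_lengths(self) -> np.ndarray:
        """Lengths of maximal same-state runs, over all chromosomes."""
        out = []
        for s in self.states.values():
            if len(s) == 0:
                continue
            breaks = np.flatnonzero(np.diff(s) != 0)
            edges = np.concatenate(([-1], breaks, [len(s) - 1]))
            out.append(np.diff(edges))
        return np.concatenate(out) if out else np.array([], dtype=int)


@dataclass
class TruthTable:
    """Implanted divergent tracts and the per-bin ground-truth polarity.

    Polarity is +1 where species A is open and B closed, -1 for the reverse,
    0 where structure is conserved.
    """

    bin_size: int
    tracts: pd.DataFrame  # chrom, start, end, polarity (species-A frame)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def n_divergent_bins(self) -> int:
        return int(sum((v != 0).sum() for v in self.labels.values()))

    def label_for_bins(self, bins: pd.DataFrame) -> np.ndarray:
        """Ground-truth polarity for each row of a (chrom, start, end) table."""
        out = np.zeros(len(bins), dtype=np.int8)
        for i, (chrom, start) in enumerate(zip(bins["chrom"], bins["start"])):
            lab = self.labels.get(chrom)
            if lab is None:
                continue
            j = int(start) // self.bin_size
            if 0 <= j < len(lab):
                out[i] = lab[j]
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_layout(
    n_chrom: int,
    mean_len: int,
    seed: int,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    species_tag: str = "A",
    length_cv: float = 0.0,
    centromere_frac: float | None = 0.4,
    acrocentric: bool = False,
) -> GenomeLayout:
    """Generate a genome layout with lengths rounded to whole bins.

    With the default ``length_cv=0`` every chromosome has exactly
    ``mean_len`` (rounded down to whole bins); a positive coefficient of
    variation draws log-normal lengths around the mean.
    """
    if n_chrom < 1:
        raise InvalidParameterError(f"n_chrom must be >= 1, got {n_chrom}")
    if mean_len < 10 * bin_size:
        raise InvalidParameterError(
            f"mean_len must be at least 10 bins ({10 * bin_size} bp), got {mean_len}"
        )
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chrom):
        if length_cv > 0:
            length = int(mean_len * np.exp(rng.normal(0.0, length_cv)))
        else:
            length = int(mean_len)
        n_bins = max(10, length // bin_size)
        length = n_bins * bin_size
        cen = None
        if centromere_frac is not None and not acrocentric:
            cen = int(round(centromere_frac * n_bins)) * bin_size
            cen = min(max(cen, bin_size), length - bin_size)
        chroms.append(
            Chromosome(
                name=f"chr{i + 1}",
                length_bp=length,
                centromere_bp=cen,
                acrocentric=acrocentric,
            )
        )
    return GenomeLayout(species_tag=species_tag, chromosomes=chroms)


def gen_compartments(
    layout: GenomeLayout,
    mean_domain_bins: float,
    p_open: float,
    seed: int,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> CompartmentTrack:
    """Two-state renewal chain along each chromosome.

    Each bin resamples its state i.i.d. Bernoulli(``p_open``) with
    probability ``r = min(1, 2 / mean_domain_bins)`` and otherwise copies the
    previous bin.  Run lengths are geometric; at ``p_open = 0.5`` the mean
    same-state run length equals ``mean_domain_bins`` (for
    ``mean_domain_bins >= 2``), and ``mean_domain_bins = 1`` degenerates to
    i.i.d. states.
    """
    if mean_domain_bins < 1:
        raise InvalidParameterError(f"mean_domain_bins must be >= 1, got {mean_domain_bins}")
    if not (0 < p_open <= 1):
        raise InvalidParameterError(f"p_open must be in (0, 1], got {p_open}")
    r = min(1.0, 2.0 / mean_domain_bins)
    rng = np.random.default_rng(seed)
    states: dict[str, np.ndarray] = {}
    for c in layout:
        n = c.length_bp // bin_size
        draws = (rng.random(n) < p_open).astype(np.int8)
        resample = rng.random(n) < r
        resample[0] = True
        # index of the most recent resampled bin
        idx = np.where(resample, np.arange(n), 0)
        idx = np.maximum.accumulate(idx)
        states[c.name] = draws[idx]
    return CompartmentTrack(layout=layout, bin_size=bin_size, states=states)


def implant_divergence(
    track_A: CompartmentTrack,
    track_B: CompartmentTrack,
    n_tracts: int,
    tract_len_bins: int | tuple[int, int],
    seed: int,
    *,
    require_uniform: bool = True,
    end_bias: float = 0.0,
    end_window_bins: int = 0,
    max_tries: int = 20_000,
) -> tuple[CompartmentTrack, TruthTable]:
    """Flip species-B latent states over non-overlapping tracts.

    Species A is the reference: its track is never modified, and tract
    polarity is +1 where A is open (B flipped to closed) and -1 where A is
    closed.  With ``require_uniform`` (default) tracts are only placed where
    A's state is constant, so every tract has a single well-defined polarity.

    ``end_bias`` is the probability that a tract is placed within
    ``end_window_bins`` of a chromosome end, used to emulate subtelomeric
    enrichment of divergence.
    """
    if n_tracts < 0:
        raise InvalidParameterError(f"n_tracts must be >= 0, got {n_tracts}")
    rng = np.random.default_rng(seed)
    new_B = track_B.copy()
    bin_size = track_A.bin_size
    occupied = {name: np.zeros(len(s), dtype=bool) for name, s in track_A.states.items()}
    chrom_names = [c.name for c in track_A.layout]
    chrom_nbins = np.array([len(track_A.states[n]) for n in chrom_names])
    chrom_p = chrom_nbins / chrom_nbins.sum()

    if isinstance(tract_len_bins, (tuple, list)):
        lo, hi = int(tract_len_bins[0]), int(tract_len_bins[1])
    else:
        lo = hi = int(tract_len_bins)
    if lo < 1:
        raise InvalidParameterError("tract lengths must be >= 1 bin")

    tract_rows = []
    for _ in range(n_tracts):
        length = int(rng.integers(lo, hi + 1))
        placed = False
        for _try in range(max_tries):
            ci = rng.choice(len(chrom_names), p=chrom_p)
            name = chrom_names[ci]
            n = int(chrom_nbins[ci])
            if n < length:
                continue
            if end_bias > 0 and end_window_bins > 0 and rng.random() < end_bias:
                w = min(end_window_bins, n)
                if rng.random() < 0.5:
                    start = int(rng.integers(0, max(1, w - length + 1)))
                else:
                    start = int(rng.integers(max(0, n - w), n - length + 1))
            else:
                start = int(rng.integers(0, n - length + 1))
            stop = start + length
            if occupied[name][start:stop].any():
                continue
            seg_A = track_A.states[name][start:stop]
            if require_uniform and not (seg_A == seg_A[0]).all():
                continue
            occupied[name][start:stop] = True
            new_B.states[name][start:stop] = 1 - new_B.states[name][start:stop]
            placed = True
            tract_rows.append((name, start, stop))
            break
        if not placed:
            raise InfeasibleImplantError(
                f"could not place {n_tracts} non-overlapping tracts of {lo}-{hi} bins"
            )

    labels = {
        name: (track_A.states[name].astype(np.int8) - new_B.states[name].astype(np.int8))
        for name in chrom_names
    }
    rows = []
    for name, start, stop in tract_rows:
        seg = labels[name][start:stop]
        pol = int(np.sign(seg.sum())) or int(seg[0])
        rows.append(
            {
                "chrom": name,
                "start": start * bin_size,
                "end": stop * bin_size,
                "polarity": pol,
            }
        )
    tracts = pd.DataFrame(rows, columns=["chrom", "start", "end", "polarity"])
    if len(tracts):
        tracts = tracts.sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = TruthTable(bin_size=bin_size, tracts=tracts, labels=labels)
    return new_B, truth


def gen_structure(
    track: CompartmentTrack,
    datasets: list[tuple[str, str, str]],
    mu_open: float = 1.0,
    mu_closed: float = -1.0,
    sigma_dataset: float = 0.2,
    sigma_noise: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dataset binned structure values over a compartment track.

    value = state mean + dataset offset (Normal, sd ``sigma_dataset``)
    + per-bin noise (Normal, sd ``sigma_noise``).  Larger values mean more
    open chromatin.

    Returns ``(values, meta)``: a (chrom, start, end, one column per dataset)
    frame and a dataset metadata frame (id, assay, cell_type).
    """
    if not datasets:
        raise InvalidParameterError("dataset list must not be empty")
    if mu_open <= mu_closed:
        raise InvalidParameterError("mu_open must exceed mu_closed (larger = more open)")
    if sigma_dataset < 0 or sigma_noise < 0:
        raise InvalidParameterError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    bins = track.layout.bin_table(track.bin_size)
    state = track.concat()
    mu = np.where(state == 1, mu_open, mu_closed)
    values = bins.copy()
    meta_rows = []
    for ds in datasets:
        if isinstance(ds, str):
            ds_id, assay, cell = ds, "generic", "generic"
        else:
            ds_id, assay, cell = ds
        offset = rng.normal(0.0, sigma_dataset) if sigma_dataset > 0 else 0.0
        noise = rng.normal(0.0, sigma_noise, size=len(mu)) if sigma_noise > 0 else 0.0
        values[ds_id] = mu + offset + noise
        meta_rows.append({"dataset": ds_id, "assay": assay, "cell_type": cell})
    meta = pd.DataFrame(meta_rows)
    return values, meta


def gen_probes(
    binned: pd.DataFrame,
    probes_per_bin: float,
    probe_sigma: float,
    seed: int,
    *,
    constant: bool = False,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Scatter probe records whose per-bin mean recovers the bin value.

    Probe counts per (bin, dataset) are Poisson with mean ``probes_per_bin``
    unless ``constant`` is set; probe midpoints are uniform within the bin
    and probe values are Normal(bin value, ``probe_sigma``).

    Returns a long frame (chrom, pos, dataset, value).
    """
    rng = np.random.default_rng(seed)
    ds_cols = [c for c in binned.columns if c not in ("chrom", "start", "end")]
    rows = []
    for ds in ds_cols:
        vals = binned[ds].to_numpy()
        if constant:
            counts = np.full(len(vals), int(probes_per_bin))
        else:
            counts = rng.poisson(probes_per_bin, size=len(vals))
        total = int(counts.sum())
        bin_idx = np.repeat(np.arange(len(vals)), counts)
        pos = binned["start"].to_numpy()[bin_idx] + rng.integers(0, bin_size, size=total)
        pvals = vals[bin_idx]
        if probe_sigma > 0:
            pvals = pvals + rng.normal(0.0, probe_sigma, size=total)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": binned["chrom"].to_numpy()[bin_idx],
                    "pos": pos,
                    "dataset": ds,
                    "value": pvals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def rearrangement_order(n_bins: int, n_rearrangements: int, seed: int) -> np.ndarray:
    """Bin permutation produced by random block reversals.

    ``order[i]`` is the B-genome bin slot carrying the material orthologous
    to A bin ``i``; reversals preserve adjacency within blocks, as real
    genome rearrangements preserve local synteny.
    """
    rng = np.random.default_rng(seed)
    order = np.arange(n_bins)
    for _ in range(n_rearrangements):
        i, j = sorted(rng.integers(0, n_bins, size=2))
        order[i:j] = order[i:j][::-1]
    return order


def gen_orthology(
    layout_A: GenomeLayout,
    layout_B: GenomeLayout,
    n_rearrangements: int,
    min_overlap: float,
    frac_unmappable: float,
    seed: int,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    decoy_frac: float = 0.05,
    nonreciprocal_frac: float = 0.02,
    order: np.ndarray | None = None,
) -> pd.DataFrame:
    """Emit an orthology interval map pairing A bins with (rearranged) B bins.

    Both layouts must contain the same number of whole bins; ``n_rearrangements``
    random block reversals scramble the B-side order to emulate genome
    rearrangements.  A fraction ``frac_unmappable`` of bins is left unpaired
    (lineage specific); ``decoy_frac`` of pairs receive a sub-threshold
    overlap fraction on one side; ``nonreciprocal_frac`` adds duplicate
    candidate pairs that a reciprocal-best filter must discard.

    Columns: chrom_A, start_A, end_A, chrom_B, start_B, end_B, overlap_A,
    overlap_B, keep_truth.
    """
    if not (0 <= frac_unmappable < 1):
        raise InvalidParameterError("frac_unmappable must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bins_A = layout_A.bin_table(bin_size)
    bins_B = layout_B.bin_table(bin_size)
    if len(bins_A) != len(bins_B):
        raise InvalidParameterError(
            "layouts must tile to the same number of bins for the synthetic map"
        )
    n = len(bins_A)
    if order is None:
        order = rearrangement_order(n, n_rearrangements, seed)
    elif len(order) != n:
        raise InvalidParameterError("rearrangement order length != number of bins")
    paired = rng.random(n) >= frac_unmappable
    idx_A = np.flatnonzero(paired)
    idx_B = order[idx_A]

    m = len(idx_A)
    ov_A = rng.uniform(min_overlap, 1.0, size=m)
    ov_B = rng.uniform(min_overlap, 1.0, size=m)
    decoy = rng.random(m) < decoy_frac
    which = rng.random(m) < 0.5
    low = rng.uniform(0.05, max(min_overlap - 1e-6, 0.06), size=m)
    ov_A = np.where(decoy & which, low, ov_A)
    ov_B = np.where(decoy & ~which, low, ov_B)

    pairs = pd.DataFrame(
        {
            "chrom_A": bins_A["chrom"].to_numpy()[idx_A],
            "start_A": bins_A["start"].to_numpy()[idx_A],
            "end_A": bins_A["end"].to_numpy()[idx_A],
            "chrom_B": bins_B["chrom"].to_numpy()[idx_B],
            "start_B": bins_B["start"].to_numpy()[idx_B],
            "end_B": bins_B["end"].to_numpy()[idx_B],
            "overlap_A": ov_A,
            "overlap_B": ov_B,
            "keep_truth": (ov_A >= min_overlap) & (ov_B >= min_overlap),
        }
    )

    # non-reciprocal decoys: an A interval also matched (more weakly) to the
    # B partner of another pair; a reciprocal-best filter must drop these.
    n_extra = int(round(nonreciprocal_frac * m))
    if n_extra > 0 and m > 1:
        src = rng.choice(m, size=n_extra, replace=False)
        other = (src + 1 + rng.integers(0, m - 1, size=n_extra)) % m
        extra = pairs.iloc[src][["chrom_A", "start_A", "end_A"]].reset_index(drop=True)
        extra[["chrom_B", "start_B", "end_B"]] = (
            pairs.iloc[other][["chrom_B", "start_B", "end_B"]].reset_index(drop=True)
        )
        # strictly weaker than the primary overlap on the A side
        extra["overlap_A"] = np.minimum(
            pairs["overlap_A"].to_numpy()[src] * rng.uniform(0.6, 0.95, size=n_extra),
            pairs["overlap_A"].to_numpy()[src] - 1e-3,
        )
        extra["overlap_B"] = np.minimum(
            pairs["overlap_B"].to_numpy()[other] * rng.uniform(0.6, 0.95, size=n_extra),
            pairs["overlap_B"].to_numpy()[other] - 1e-3,
        )
        extra["keep_truth"] = False
        pairs = pd.concat([pairs, extra], ignore_index=True)

    return pairs.sort_values(["chrom_A", "start_A", "chrom_B", "start_B"]).reset_index(
        drop=True
    )


def gen_gc_and_genes(
    track: CompartmentTrack,
    rho_target: float,
    gene_density_open: float,
    gene_density_closed: float,
    seed: int,
    *,
    gc_open: float = 0.41,
    gc_closed: float = 0.35,
    gene_classes: dict[str, tuple[float, float, float]] | None = None,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin GC fractions correlated with structure, plus gene intervals.

    GC is drawn as ``gc_closed + amp * state + Normal(0, sigma)`` with sigma
    calibrated so that the rank correlation between GC and the latent state
    approaches ``rho_target``.  Gene counts per bin are Poisson with a
    state-dependent rate.

    ``gene_classes`` maps class name -> (rate_open, rate_closed,
    tract_rate_factor); the tract factor multiplies the rate inside implanted
    divergent tracts (requires ``truth``), emulating e.g. elevated lincRNA
    density in divergent regions.  The default is a single
    ``protein_coding`` class using the two density arguments.
    """
    if not (0 < rho_target < 1):
        raise InvalidParameterError("rho_target must be in (0, 1)")
    if gene_density_open < 0 or gene_density_closed < 0:
        raise InvalidParameterError("gene densities must be >= 0")
    rng = np.random.default_rng(seed)
    bins = track.layout.bin_table(track.bin_size)
    state = track.concat().astype(float)
    p = state.mean() if 0 < state.mean() < 1 else 0.5
    amp = gc_open - gc_closed
    sigma = amp * np.sqrt(p * (1 - p)) * np.sqrt(1.0 / rho_target**2 - 1.0)
    gc = gc_closed + amp * state + rng.normal(0.0, sigma, size=len(state))
    gc_frame = bins.copy()
    gc_frame["gc"] = np.clip(gc, 0.0, 1.0)

    if gene_classes is None:
        gene_classes = {"protein_coding": (gene_density_open, gene_density_closed, 1.0)}
    tract_label = (
        truth.label_for_bins(bins) if truth is not None else np.zeros(len(bins), dtype=np.int8)
    )
    gene_rows = []
    counter = 0
    for cls, (rate_open, rate_closed, tract_factor) in gene_classes.items():
        rate = np.where(state == 1, rate_open, rate_closed).astype(float)
        rate = np.where(tract_label != 0, rate * tract_factor, rate)
        counts = rng.poisson(rate)
        bin_idx = np.repeat(np.arange(len(bins)), counts)
        total = len(bin_idx)
        starts = bins["start"].to_numpy()[bin_idx] + rng.integers(
            0, track.bin_size, size=total
        )
        lengths = rng.integers(1_000, 20_000, size=total)
        gene_rows.append(
            pd.DataFrame(
                {
                    "chrom": bins["chrom"].to_numpy()[bin_idx],
                    "start": starts,
                    "end": starts + lengths,
                    "gene_id": [f"{cls}_{counter + i}" for i in range(total)],
                    "gene_class": cls,
                }
            )
        )
        counter += total
    genes = (
        pd.concat(gene_rows, ignore_index=True)
        if gene_rows
        else pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "gene_class"])
    )
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    return gc_frame, genes


def gen_expression(
    truth: TruthTable,
    genes: pd.DataFrame,
    effect_log2: float = 1.0,
    sd_log2: float = 1.5,
    baseline_shift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Orthologous expression pairs whose log2 fold change tracks polarity.

    Genes inside +1 tracts (open in species A) have mean log2(A/B) of
    ``baseline_shift + effect_log2``; -1 tracts the mirror image; all other
    genes ``baseline_shift``.  RPKM values are strictly positive.
    """
    if sd_log2 < 0:
        raise InvalidParameterError("sd_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    pol = truth.label_for_bins(genes[["chrom", "start"]].assign(end=genes["start"] + 1))
    mean = baseline_shift + pol.astype(float) * effect_log2
    log2fc = mean + (rng.normal(0.0, sd_log2, size=len(genes)) if sd_log2 > 0 else 0.0)
    rpkm_B = rng.lognormal(1.0, 0.8, size=len(genes))
    rpkm_A = rpkm_B * np.power(2.0, log2fc)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["start"].to_numpy(),
            "end": genes["end"].to_numpy(),
            "rpkm_A": rpkm_A,
            "rpkm_B": rpkm_B,
        }
    )


def gen_regulatory_flags(
    in_divergent: np.ndarray,
    odds_ratio: float,
    p_background: float,
    seed: int = 0,
) -> np.ndarray:
    """Binary 'divergently regulated' gene flags with a chosen odds ratio.

    Genes resident in divergent regions are flagged with the probability
    implied by ``odds_ratio`` against the background rate, so the expected
    2x2 cross-product ratio equals ``odds_ratio``.
    """
    if odds_ratio <= 0 or not (0 < p_background < 1):
        raise InvalidParameterError("odds_ratio > 0 and p_background in (0,1) required")
    rng = np.random.default_rng(seed)
    odds_in = odds_ratio * p_background / (1 - p_background)
    p_in = odds_in / (1 + odds_in)
    p = np.where(np.asarray(in_divergent, dtype=bool), p_in, p_background)
    return rng.random(len(p)) < p
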