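"""Downstream statistics relating divergence calls to genome features.

Covers the inter-dataset correlation structure, the chromosome-level
distribution of calls, GC-content contrasts by divergence class,
gene-density comparisons, expression-divergence contrasts (relative and
absolute-value-restricted classes), a generic two-class Fisher enrichment,
and the alignment-overlap control showing that divergence calls are not an
artefact of poor cross-species alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .binning import StructureMatrix
from .divergence import DivergenceResult
from .layout import InvalidParameterError

NONDIVERGENT = "nondivergent"
OPEN_A = "divergent_open_A"
CLOSED_A = "divergent_closed_A"

_CLASS_BY_POLARITY = {0: NONDIVERGENT, 1: OPEN_A, -1: CLOSED_A}


@dataclass
class ClassLabel:
    """Region id -> divergence class, with absolute-value-restricted flags.

    The relative classes partition all regions by call polarity.  The
    absolute subclasses additionally require the normalised species means to
    straddle zero (open side positive, closed side negative), restricting
    each relative class to regions whose absolute conformations differ.
    """

    table: pd.DataFrame  # region_id, cls, absolute_flag

    @classmethod
    def from_result(cls, result: DivergenceResult) -> "ClassLabel":
        t = result.table
        labels = t["polarity"].map(_CLASS_BY_POLARITY)
        absolute = np.where(
            (t["polarity"] == 1) & (t["mean_A"] > 0) & (t["mean_B"] < 0),
            True,
            np.where(
                (t["polarity"] == -1) & (t["mean_A"] < 0) & (t["mean_B"] > 0), True, False
            ),
        )
        return cls(
            table=pd.DataFrame(
                {"region_id": t["region_id"], "cls": labels, "absolute_flag": absolute}
            )
        )

    def of(self, name: str) -> pd.Index:
        return pd.Index(self.table.loc[self.table["cls"] == name, "region_id"])


def correlation_matrix(matrix: StructureMatrix, method: str = "spearman"):
    """Pairwise rank correlations between datasets plus a heatmap ordering.

    Returns (rho frame, leaf order) where the order comes from
    average-linkage hierarchical clustering on (1 - rho) distances.
    Constant columns yield undefined correlations and are flagged.
    """
    if matrix.n_regions() < 3:
        raise InvalidParameterError("need at least 3 regions for correlations")
    vals = matrix.values
    constant = [c for c in vals.columns if vals[c].nunique() == 1]
    if constant:
        raise InvalidParameterError(f"constant columns, correlation undefined: {constant}")
    if method != "spearman":
        raise InvalidParameterError("only rank (spearman) correlation is supported")
    rho, _ = stats.spearmanr(vals.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    frame = pd.DataFrame(rho, index=vals.columns, columns=vals.columns)
    if len(vals.columns) > 2:
        dist = squareform(np.clip(1.0 - rho, 0.0, None), checks=False)
        order = leaves_list(average(dist))
    else:
        order = np.arange(len(vals.columns))
    return frame, [vals.columns[i] for i in order]


def chrom_distribution_test(
    calls_per_chrom: pd.Series, bins_per_chrom: pd.Series
) -> pd.DataFrame:
    """Chi-squared test of call counts against per-chromosome bin proportions.

    Expected counts are total calls apportioned by each chromosome's share
    of orthologous bins; chromosomes with |standardized residual| > 1.96 are
    flagged as of interest.  Returns the per-chromosome table with the
    global statistic attached as attrs (statistic, df, p_value).
    """
    bins_per_chrom = bins_per_chrom[bins_per_chrom > 0]
    if len(bins_per_chrom) < 2:
        raise InvalidParameterError("need >= 2 chromosomes with orthologous bins")
    obs = calls_per_chrom.reindex(bins_per_chrom.index).fillna(0).astype(float)
    total = obs.sum()
    expected = total * bins_per_chrom / bins_per_chrom.sum()
    resid = (obs - expected) / np.sqrt(expected)
    statistic = float((resid**2).sum())
    df = len(bins_per_chrom) - 1
    p = float(stats.chi2.sf(statistic, df))
    out = pd.DataFrame(
        {
            "chrom": bins_per_chrom.index,
            "observed": obs.to_numpy(),
            "expected": expected.to_numpy(),
            "residual": resid.to_numpy(),
            "flagged": np.abs(resid.to_numpy()) > 1.96,
        }
    )
    out.attrs.update({"statistic": statistic, "df": df, "p_value": p})
    return out


def gc_by_class(
    gc: pd.Series,
    labels: ClassLabel,
    structure: pd.Series,
    n_bins_for_categories: int = 10,
) -> dict:
    """GC contrasts between divergence classes across the structure spectrum.

    Returns per-class means, two-sided rank-sum p-values of each divergent
    class against the nondivergent background, per-class least-squares
    regression lines of GC on mean structure, and the per-category GC
    difference table over equal-width structure bins.
    """
    lab = labels.table.set_index("region_id")["cls"].reindex(gc.index)
    out: dict = {"class_mean_gc": {}, "mw_p": {}, "regression": {}, "categories": None}
    nd = gc[lab == NONDIVERGENT]
    for cls in (NONDIVERGENT, OPEN_A, CLOSED_A):
        sel = gc[lab == cls]
        if sel.empty:
            continue
        out["class_mean_gc"][cls] = float(sel.mean())
        if cls != NONDIVERGENT and len(nd) and len(sel):
            out["mw_p"][cls] = float(
                stats.mannwhitneyu(sel, nd, alternative="two-sided").pvalue
            )
        sub_x = structure[lab == cls]
        if len(sel) >= 2 and sub_x.nunique() > 1:
            res = stats.linregress(sub_x.to_numpy(), sel.to_numpy())
            out["regression"][cls] = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
            }
        else:
            out["regression"][cls] = None

    edges = np.linspace(structure.min(), structure.max(), n_bins_for_categories + 1)
    cat = np.clip(np.searchsorted(edges, structure, side="right") - 1, 0, n_bins_for_categories - 1)
    cat = pd.Series(cat, index=structure.index)
    rows = []
    for b in range(n_bins_for_categories):
        in_cat = cat == b
        div = gc[in_cat & (lab != NONDIVERGENT)]
        nod = gc[in_cat & (lab == NONDIVERGENT)]
        if len(div) == 0 or len(nod) == 0:
            continue
        p = (
            float(stats.mannwhitneyu(div, nod, alternative="two-sided").pvalue)
            if len(div) > 0 and len(nod) > 0
            else np.nan
        )
        rows.append(
            {
                "category": b,
                "structure_low": edges[b],
                "structure_high": edges[b + 1],
                "gc_divergent": float(div.mean()),
                "gc_nondivergent": float(nod.mean()),
                "gc_difference": float(div.mean() - nod.mean()),
                "mw_p": p,
            }
        )
    out["categories"] = pd.DataFrame(rows)
    return out


def density_compare(
    annotations: pd.DataFrame,
    labels: ClassLabel,
    regions: pd.DataFrame,
    frame: str = "A",
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Annotation density (per 100 kb and per Mb) by divergence class.

    Genes are assigned to regions by start coordinate; densities are
    compared between each divergent class and the nondivergent background
    with two-sided Mann-Whitney tests, separately per annotation class.
    """
    coords = regions[["region_id", f"chrom_{frame}", f"start_{frame}", f"end_{frame}"]]
    coords = coords.rename(
        columns={f"chrom_{frame}": "chrom", f"start_{frame}": "start", f"end_{frame}": "end"}
    )
    lab = labels.table.set_index("region_id")["cls"]
    rows = []
    if "gene_class" in annotations.columns and len(annotations):
        classes = annotations["gene_class"].unique()
    else:
        classes = ["all"]
    for gcls in classes:
        ann = (
            annotations[annotations["gene_class"] == gcls]
            if ("gene_class" in annotations.columns and gcls != "all")
            else annotations
        )
        counts = _count_starts_per_region(ann, coords)
        per_bin = pd.Series(counts, index=coords["region_id"])
        groups = {
            name: per_bin[lab.reindex(per_bin.index) == name]
            for name in (NONDIVERGENT, OPEN_A, CLOSED_A)
        }
        for name, vals in groups.items():
            if vals.empty:
                continue
            if name == NONDIVERGENT or groups[NONDIVERGENT].empty:
                p = np.nan
            elif vals.nunique() == 1 and groups[NONDIVERGENT].nunique() == 1 and vals.iloc[0] == groups[NONDIVERGENT].iloc[0]:
                p = np.nan  # degenerate: identical constant densities
            else:
                p = float(
                    stats.mannwhitneyu(
                        vals, groups[NONDIVERGENT], alternative="two-sided"
                    ).pvalue
                )
            rows.append(
                {
                    "gene_class": gcls,
                    "region_class": name,
                    "n_regions": int(len(vals)),
                    "density_per_100kb": float(vals.mean() * (100_000 / bin_size)),
                    "density_per_mb": float(vals.mean() * (1_000_000 / bin_size)),
                    "mw_p_vs_nondivergent": p,
                }
            )
    return pd.DataFrame(rows)


def _count_starts_per_region(ann: pd.DataFrame, coords: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(coords), dtype=int)
    for chrom, sub in coords.groupby("chrom"):
        g = ann[ann["chrom"] == chrom]
        if g.empty:
            continue
        starts = np.sort(g["start"].to_numpy())
        lo = np.searchsorted(starts, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(starts, sub["end"].to_numpy(), side="left")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


def assign_genes_to_regions(
    genes: pd.DataFrame, regions: pd.DataFrame, frame: str = "A"
) -> pd.Series:
    """Region id for each gene by start coordinate (NaN when unassigned)."""
    coords = regions[["region_id", f"chrom_{frame}", f"start_{frame}", f"end_{frame}"]]
    coords = coords.rename(
        columns={f"chrom_{frame}": "chrom", f"start_{frame}": "start", f"end_{frame}": "end"}
    )
    out = pd.Series(pd.NA, index=genes.index, dtype="object")
    for chrom, sub in coords.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["region_id"].to_numpy()
        j = np.searchsorted(starts, g["start"].to_numpy(), side="right") - 1
        ok = (j >= 0) & (g["start"].to_numpy() < ends[np.maximum(j, 0)])
        out.loc[g.index[ok]] = ids[j[ok]]
    return out


def expression_divergence(
    expr: pd.DataFrame,
    labels: ClassLabel,
    mode: str = "relative",
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-class log2 fold-change medians with rank-sum tests vs background.

    ``expr`` needs columns (gene_id, region_id, rpkm_A, rpkm_B); log2FC is
    log2((rpkm_A + c) / (rpkm_B + c)) with the pseudocount recorded in the
    output attrs.  ``absolute`` mode restricts the divergent classes to the
    absolute-value subclass flags; an emptied subclass is reported as not
    testable rather than dropped silently.
    """
    if mode not in ("relative", "absolute"):
        raise InvalidParameterError(f"mode must be relative or absolute, got {mode!r}")
    df = expr.copy()
    df["log2fc"] = np.log2((df["rpkm_A"] + pseudocount) / (df["rpkm_B"] + pseudocount))
    lab = labels.table.set_index("region_id")
    df = df[df["region_id"].notna()]
    df["cls"] = lab["cls"].reindex(df["region_id"]).to_numpy()
    df["absolute_flag"] = lab["absolute_flag"].reindex(df["region_id"]).to_numpy()
    background = df.loc[df["cls"] == NONDIVERGENT, "log2fc"]
    rows = []
    for cls in (NONDIVERGENT, OPEN_A, CLOSED_A):
        sel = df[df["cls"] == cls]
        if cls != NONDIVERGENT and mode == "absolute":
            sel = sel[sel["absolute_flag"].astype(bool)]
        testable = len(sel) > 0
        if cls == NONDIVERGENT or not testable or background.empty:
            p = np.nan
        else:
            p = float(
                stats.mannwhitneyu(
                    sel["log2fc"], background, alternative="two-sided"
                ).pvalue
            )
        rows.append(
            {
                "region_class": cls,
                "mode": mode,
                "n_genes": int(len(sel)),
                "median_log2fc": float(sel["log2fc"].median()) if testable else np.nan,
                "p_vs_nondivergent": p,
                "testable": testable,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["pseudocount"] = pseudocount
    return out


def class_enrichment_fisher(
    gene_flags: pd.Series, in_divergent: pd.Series
) -> dict:
    """Fisher's exact test of a binary gene property against divergent residence.

    ``gene_flags`` marks e.g. divergently regulated genes; ``in_divergent``
    marks residence in a divergent region.  Returns the 2x2 table, the
    cross-product odds ratio (with a Haldane-corrected companion when a
    margin is zero) and the two-sided exact p.
    """
    f = gene_flags.astype(bool).to_numpy()
    d = in_divergent.astype(bool).to_numpy()
    a = int((f & d).sum())
    b = int((f & ~d).sum())
    c = int((~f & d).sum())
    dd = int((~f & ~d).sum())
    table = np.array([[a, b], [c, dd]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * dd > 0 else np.nan
    else:
        odds = (a * dd) / (b * c)
    haldane = ((a + 0.5) * (dd + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else odds,
        "odds_ratio_haldane": float(haldane),
        "p_value": float(p),
    }


def overlap_qc(regions: pd.DataFrame, labels: ClassLabel) -> pd.DataFrame:
    """Alignment-overlap summaries by divergence class.

    Compares the orthology overlap fractions of divergent and nondivergent
    regions (rank-sum test per side) — the control that structural
    divergence does not merely track poor cross-species alignment.
    """
    lab = labels.table.set_index("region_id")["cls"]
    df = regions.set_index("region_id")
    df = df.assign(cls=lab.reindex(df.index))
    rows = []
    for side in ("overlap_A", "overlap_B"):
        nd = df.loc[df["cls"] == NONDIVERGENT, side]
        dv = df.loc[df["cls"] != NONDIVERGENT, side]
        p = (
            float(stats.mannwhitneyu(dv, nd, alternative="two-sided").pvalue)
            if len(nd) and len(dv)
            else np.nan
        )
        for name, vals in (("divergent", dv), ("nondivergent", nd)):
            rows.append(
                {
                    "side": side,
                    "region_class": name,
                    "n": int(len(vals)),
                    "mean_overlap": float(vals.mean()) if len(vals) else np.nan,
                    "median_overlap": float(vals.median()) if len(vals) else np.nan,
                    "mw_p": p,
                }
            )
    return pd.DataFrame(rows)
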