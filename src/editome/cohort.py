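"""Cohort-level editome analytics.

Editing level (edited bases per million uniquely mapped bases), the
cell x site frequency matrix with its 0 / -1 coverage coding,
hierarchical clustering of cells, correlation with expression, per-stage
summaries with rank-sum comparisons, and the miRNA-target
stage-specificity Fisher tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from .detect import bh_adjust
from .filters import fisher_exact_2x2
from .ingest import STAGES

MISSING = -1.0  # matrix code for depth < 4
DEFAULT_MIN_STAGE_CELLS = 4


@dataclasses.dataclass(frozen=True)
class StageSummary:
    stage: str
    n_cells: int
    mean_sites: float
    sd_sites: float
    mean_level: float
    sd_level: float
    single_cell: bool = False  # sd reported as 0 from one observation


def editing_level(edited_base_count: int, uniquely_mapped_bases: int) -> float:
    """Edited bases per million uniquely mapped bases in one cell."""
    if uniquely_mapped_bases <= 0:
        raise ValueError("uniquely_mapped_bases must be positive")
    return 1e6 * edited_base_count / uniquely_mapped_bases


def cell_editing_levels(annotated: pd.DataFrame, meta: pd.DataFrame,
                        per_site: bool = False) -> pd.DataFrame:
    """Per-cell editing level over retained sites.

    Edited bases = sum of variant-supporting read bases (k) over retained
    sites; with ``per_site`` the count of retained sites is used instead.
    Cells with no retained site get level 0.
    """
    retained = annotated.loc[annotated["retained"]]
    agg = retained.groupby("cell_id").agg(
        edited_bases=("k", "sum"), n_sites=("k", "size"))
    out = meta.set_index("cell_id").join(agg).fillna(
        {"edited_bases": 0, "n_sites": 0})
    numer = out["n_sites"] if per_site else out["edited_bases"]
    out["editing_level"] = 1e6 * numer / out["uniquely_mapped_bases"]
    return out.reset_index()


def build_editing_matrix(annotated: pd.DataFrame,
                         depths: pd.DataFrame,
                         min_depth: int = 4) -> pd.DataFrame:
    """Cell x site editing-frequency matrix.

    Entry = frequency where the site is a retained detection in that
    cell; 0 where covered (depth >= min_depth) but unedited; -1 where
    depth < min_depth. ``depths`` holds cell_id, chrom, pos, depth for
    the union of retained sites. Columns ordered by (chrom, pos).
    """
    retained = annotated.loc[annotated["retained"]]
    sites = (retained[["chrom", "pos"]].drop_duplicates()
             .sort_values(["chrom", "pos"]))
    if len(sites) == 0:
        raise ValueError("no retained sites; empty editing matrix")
    site_index = [f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])]
    cells = sorted(depths["cell_id"].unique())
    mat = pd.DataFrame(MISSING, index=cells, columns=site_index, dtype=float)
    dkey = depths.assign(site=[f"{c}:{p}" for c, p in
                               zip(depths["chrom"], depths["pos"])])
    covered = dkey.loc[dkey["depth"] >= min_depth]
    for cell, grp in covered.groupby("cell_id"):
        cols = [s for s in grp["site"] if s in mat.columns]
        mat.loc[cell, cols] = 0.0
    rkey = retained.assign(site=[f"{c}:{p}" for c, p in
                                 zip(retained["chrom"], retained["pos"])])
    for row in rkey.itertuples(index=False):
        if row.cell_id in mat.index and row.site in mat.columns:
            mat.loc[row.cell_id, row.site] = row.freq
    return mat


def cluster_cells(matrix: pd.DataFrame, linkage_method: str = "complete"
                  ) -> tuple[np.ndarray, "TreeNode"]:
    """Hierarchical clustering of cells on Euclidean row distances.

    Returns (scipy linkage matrix, newick-exportable tree). Complete
    linkage mirrors R hclust's default.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two cells")
    dist = pdist(matrix.to_numpy(), metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage_method)
    tree = TreeNode.from_linkage_matrix(Z, list(matrix.index))
    return Z, tree


def cut_clusters(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided P between two per-cell vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def rpkm(count: float, gene_length_bases: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bases <= 0 or total_mapped_reads <= 0:
        raise ValueError("gene length and total mapped reads must be positive")
    return 1e9 * count / (gene_length_bases * total_mapped_reads)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum P; exact for small samples without
    ties, normal approximation with continuity correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    exact = (min(a.size, b.size) <= 10
             and np.unique(np.concatenate([a, b])).size == a.size + b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def stage_summaries(levels: pd.DataFrame) -> tuple[list[StageSummary], pd.DataFrame]:
    """Per-stage mean +/- sample sd of retained-site counts and editing
    levels, plus rank-sum P-values between consecutive stages."""
    summaries = []
    present = [s for s in STAGES if (levels["stage"] == s).any()]
    for stage in present:
        grp = levels.loc[levels["stage"] == stage]
        single = len(grp) == 1
        summaries.append(StageSummary(
            stage=stage, n_cells=len(grp),
            mean_sites=float(grp["n_sites"].mean()),
            sd_sites=0.0 if single else float(grp["n_sites"].std(ddof=1)),
            mean_level=float(grp["editing_level"].mean()),
            sd_level=0.0 if single else float(grp["editing_level"].std(ddof=1)),
            single_cell=single))
    rows = []
    for s1, s2 in zip(present, present[1:]):
        a = levels.loc[levels["stage"] == s1, "editing_level"]
        b = levels.loc[levels["stage"] == s2, "editing_level"]
        if len(a) and len(b):
            rows.append({"stage_a": s1, "stage_b": s2,
                         "rank_sum_p": rank_sum_test(a, b)})
    return summaries, pd.DataFrame(rows)


def expression_vs_frequency(annotated: pd.DataFrame, matrix: pd.DataFrame,
                            expression: pd.DataFrame,
                            bh_alpha: float = 0.1,
                            min_cells: int = 3) -> pd.DataFrame:
    """Spearman association between gene expression and editing frequency
    for exonic-edited genes.

    ``expression`` is a gene x cell RPKM table. For each exonic retained
    site (feature CDS/5UTR/3UTR/ncRNA), frequencies (matrix entries >= 0)
    are correlated with the gene's RPKM across cells; BH over all tested
    sites; ``flagged`` marks adjusted P < bh_alpha.
    """
    exonic = annotated.loc[annotated["retained"] &
                           annotated["feature"].isin(["CDS", "5UTR", "3UTR",
                                                      "ncRNA"])]
    pairs = (exonic[["chrom", "pos", "gene_id"]].dropna()
             .drop_duplicates())
    rows = []
    for row in pairs.itertuples(index=False):
        site = f"{row.chrom}:{row.pos}"
        if site not in matrix.columns or row.gene_id not in expression.index:
            continue
        freqs = matrix[site]
        expr = expression.loc[row.gene_id, matrix.index]
        ok = (freqs >= 0) & expr.notna()
        if ok.sum() < min_cells:
            continue
        f = freqs[ok].to_numpy()
        e = expr[ok].to_numpy(dtype=float)
        if np.ptp(f) == 0 or np.ptp(e) == 0:
            continue
        r, p = stats.spearmanr(f, e)
        rows.append({"gene_id": row.gene_id, "site": site,
                     "spearman_r": float(r), "p": float(p),
                     "n_cells": int(ok.sum())})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["flagged"] = out["p_adj"] < bh_alpha
    return out


def _stage_windows(stages: list[str], mode: str) -> list[tuple[str, ...]]:
    if mode == "single_stage":
        return [(s,) for s in stages]
    if mode == "two_sequential":
        return [tuple(p) for p in zip(stages, stages[1:])]
    raise ValueError(f"unknown mode {mode!r}")


def stage_specific_editing(edited_cells: pd.DataFrame, meta: pd.DataFrame,
                           mode: str = "single_stage",
                           fet_alpha: float = 0.05,
                           min_stage_cells: int = DEFAULT_MIN_STAGE_CELLS
                           ) -> pd.DataFrame:
    """Fisher tests for stage-preferential editing of miRNA-target regions.

    ``edited_cells`` has columns gene_id, cell_id marking cells with at
    least one retained edit in the gene's miRNA-target region. For each
    gene and stage window the 2x2 table [[edited_in, unedited_in],
    [edited_out, unedited_out]] is tested (two-tailed); a window is
    flagged when P < fet_alpha and the in-window edited fraction exceeds
    the out-window fraction. Stages with fewer than ``min_stage_cells``
    cells are excluded (the pronucleus-style exclusion).
    """
    counts = meta.groupby("stage")["cell_id"].nunique()
    stages = [s for s in STAGES
              if counts.get(s, 0) >= min_stage_cells]
    cells_by_stage = {s: set(meta.loc[meta["stage"] == s, "cell_id"])
                      for s in stages}
    usable = set().union(*cells_by_stage.values()) if stages else set()
    rows = []
    for gene, grp in edited_cells.groupby("gene_id"):
        edited = set(grp["cell_id"]) & usable
        for window in _stage_windows(stages, mode):
            in_cells = set().union(*(cells_by_stage[s] for s in window))
            out_cells = usable - in_cells
            if not in_cells or not out_cells:
                continue
            ein = len(edited & in_cells)
            eout = len(edited & out_cells)
            table = [[ein, len(in_cells) - ein],
                     [eout, len(out_cells) - eout]]
            p = fisher_exact_2x2(table)
            frac_in = ein / len(in_cells)
            frac_out = eout / len(out_cells)
            rows.append({"gene_id": gene, "window": "+".join(window),
                         "p": p, "edited_frac_in": frac_in,
                         "edited_frac_out": frac_out,
                         "flagged": p < fet_alpha and frac_in > frac_out})
    return pd.DataFrame(rows)


def to_newick(tree: "TreeNode") -> str:
    return str(tree).strip()
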