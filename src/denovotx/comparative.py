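"""Cross-species comparison of tissue expression profiles.

Per-gene Spearman correlations between matched tissue-proportion
vectors, an ortholog-shuffle Monte-Carlo null for the count of
correlated genes, complete-linkage clustering of tissue columns, the
all-pairs tissue correlation matrix, and the ORF-expansion counter-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "NullResult",
    "ClusterResult",
    "spearman",
    "profile_correlations",
    "ortholog_shuffle_null",
    "cluster_tissues",
    "tissue_pair_matrix",
    "orf_expansion_test",
]


@dataclass(frozen=True)
class NullResult:
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_sim: int
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed_count,
            "p_value": self.p_value,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_counts)),
        }


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    labels: Tuple[str, ...]
    newick: str


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation with average ranks for ties; NaN for a constant
    vector (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _matched_proportions(
    focal: pd.DataFrame,
    outgroup: pd.DataFrame,
    ortholog_map: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Row-align the two matrices via the ortholog map, matching tissues."""
    tissues = [t for t in focal.columns if t in set(outgroup.columns)]
    if len(tissues) < 3:
        raise ValueError("need >= 3 shared tissues")
    if ortholog_map is None:
        ortholog_map = {g: g for g in focal.index}
    pairs = [
        (g, ortholog_map[g])
        for g in focal.index
        if g in ortholog_map and ortholog_map[g] in outgroup.index
    ]
    skipped = set(focal.index) - {g for g, _ in pairs}
    if skipped:
        logger.info("genes without out-group ortholog skipped: %s", sorted(skipped))
    f = focal.loc[[g for g, _ in pairs], tissues]
    o = outgroup.loc[[g2 for _, g2 in pairs], tissues]
    o.index = f.index
    return f, o


def profile_correlations(
    focal: pd.DataFrame,
    outgroup: pd.DataFrame,
    ortholog_map: Optional[Mapping[str, str]] = None,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Spearman r between matched tissue vectors.

    Rows of the inputs are genes (restricted by the caller to genes
    transcribed in both species), columns tissues; values are tissue
    proportions.  The ``correlated`` flag is strict (``r > cutoff``).
    """
    f, o = _matched_proportions(focal, outgroup, ortholog_map)
    rows = []
    for gene in f.index:
        r = spearman(f.loc[gene].values, o.loc[gene].values)
        rows.append(
            {"gene": gene, "r": r, "correlated": bool(r > cutoff)}
        )
    return pd.DataFrame(rows).set_index("gene")


def _normalized_rank_rows(mat: np.ndarray) -> np.ndarray:
    """Center-and-normalize average ranks per row, so that the dot
    product of two rows is their Spearman correlation.  Constant rows
    (undefined correlation) become NaN rows."""
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / norms[:, None]
    z[norms == 0] = np.nan
    return z


def ortholog_shuffle_null(
    focal: pd.DataFrame,
    outgroup: pd.DataFrame,
    ortholog_map: Optional[Mapping[str, str]] = None,
    cutoff: float = 0.5,
    n_sim: int = 10_000,
    seed: Optional[int] = None,
) -> NullResult:
    """Monte-Carlo null neglecting ortholog relationships.

    Each simulation pairs every focal gene with a uniformly permuted
    out-group gene (fixed points allowed) and recounts genes with
    ``r > cutoff``; the p-value is (1 + #{null >= observed}) / (1 + n).
    """
    if len(focal.index) < 2:
        raise ValueError("need >= 2 genes")
    if n_sim < 100:
        logger.warning("n_sim=%d is small; null will be coarse", n_sim)
    f, o = _matched_proportions(focal, outgroup, ortholog_map)
    fz = _normalized_rank_rows(f.values.astype(float))
    oz = _normalized_rank_rows(o.values.astype(float))
    # r for every (focal gene, out-group gene) pairing in one product;
    # NaN rows (constant vectors) never exceed the cutoff
    pairwise_r = fz @ oz.T
    n = fz.shape[0]
    idx = np.arange(n)
    with np.errstate(invalid="ignore"):
        observed = int(np.sum(pairwise_r[idx, idx] > cutoff))
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        perm = rng.permutation(n)
        with np.errstate(invalid="ignore"):
            null_counts[s] = int(np.sum(pairwise_r[idx, perm] > cutoff))
    p = (1 + int(np.sum(null_counts >= observed))) / (1 + n_sim)
    return NullResult(
        observed_count=observed,
        null_counts=null_counts,
        p_value=float(p),
        n_sim=n_sim,
        seed=seed,
    )


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def cluster_tissues(
    proportion_matrices: Mapping[str, pd.DataFrame],
    distance: str = "euclidean",
    linkage_method: str = "complete",
) -> ClusterResult:
    """Complete-linkage clustering of tissue-species columns.

    Columns are labeled ``tissue@species``; genes with missing values in
    any column are dropped (complete-case) with a log note.  Distance is
    Euclidean on proportion columns by default, ``1 - Pearson`` via
    ``distance="correlation"``.
    """
    frames = []
    for species, mat in proportion_matrices.items():
        renamed = mat.copy()
        renamed.columns = [f"{t}@{species}" for t in mat.columns]
        frames.append(renamed)
    combined = pd.concat(frames, axis=1, join="inner")
    if combined.shape[1] < 4 and len(proportion_matrices) > 1:
        raise ValueError("need >= 4 tissue-species columns")
    before = combined.shape[0]
    combined = combined.dropna(axis=0)
    if combined.shape[0] < before:
        logger.info(
            "dropped %d genes with missing values", before - combined.shape[0]
        )
    data = combined.values.T  # columns become observations
    dists = pdist(data, metric=distance)
    link = hierarchy.linkage(dists, method=linkage_method)
    labels = tuple(combined.columns)
    return ClusterResult(
        linkage=link, labels=labels, newick=_linkage_to_newick(link, labels)
    )


def tissue_pair_matrix(
    focal: pd.DataFrame,
    outgroup: pd.DataFrame,
    focal_species: str = "focal",
    outgroup_species: str = "outgroup",
    min_genes: int = 5,
) -> pd.DataFrame:
    """Spearman r across the gene set for every tissue pair.

    Rows/columns span both species' tissues; entries where either tissue
    vector is constant (e.g. all-low expression) are NaN.
    """
    shared = [g for g in focal.index if g in set(outgroup.index)]
    if len(shared) < min_genes:
        raise ValueError(f"need >= {min_genes} shared genes")
    cols: Dict[str, np.ndarray] = {}
    for t in focal.columns:
        cols[f"{t}@{focal_species}"] = focal.loc[shared, t].values.astype(float)
    for t in outgroup.columns:
        cols[f"{t}@{outgroup_species}"] = outgroup.loc[shared, t].values.astype(float)
    names = list(cols)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                r = 1.0
            else:
                va, vb = cols[a], cols[b]
                if np.all(va == va[0]) or np.all(vb == vb[0]):
                    r = float("nan")
                else:
                    r = float(stats.spearmanr(va, vb).statistic)
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat


def orf_expansion_test(
    orf_length_ratio: Sequence[float],
    relative_expression: Sequence[float],
    profile_r: Sequence[float],
    exon_counts: Sequence[int],
    transcribed_flags: Sequence[bool],
) -> dict:
    """Counter-test of the ORF-expansion model.

    Returns Spearman correlations of out-group/focal ORF length ratio
    against relative expression and against profile correlation, plus a
    one-sided Fisher exact p for (multi-exon vs single-exon) x
    (out-group transcribed vs not), alternative: multi-exon genes more
    often transcribed.
    """
    ratio = np.asarray(orf_length_ratio, dtype=float)
    if ratio.size < 5:
        raise ValueError("need >= 5 genes")
    rho_expr = spearman(ratio, np.asarray(relative_expression, dtype=float))
    rho_prof = spearman(ratio, np.asarray(profile_r, dtype=float))
    multi = np.asarray(exon_counts) > 1
    transcribed = np.asarray(transcribed_flags, dtype=bool)
    table = np.array(
        [
            [int(np.sum(multi & transcribed)), int(np.sum(multi & ~transcribed))],
            [int(np.sum(~multi & transcribed)), int(np.sum(~multi & ~transcribed))],
        ]
    )
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    return {
        "rho_length_vs_expression": rho_expr,
        "rho_length_vs_profile_r": rho_prof,
        "fisher_one_sided_p": p,
        "table": table,
        "degenerate_margins": bool(degenerate),
    }
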