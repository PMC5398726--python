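"""Expression-matrix transforms and transcriptome-secretome integration.

Matrices are pandas DataFrames with genes as rows and samples as columns;
sample metadata is a DataFrame indexed by sample id with at least
``condition`` and ``batch`` columns. The functions here implement the
standard bulk-expression workflow used around a secretome study —
log2(x+1) transform, per-gene batch-mean removal, quantile normalization,
Spearman sample-similarity with k-means grouping, PCA — plus the
integration statistics: differential-expression threshold calls on
externally computed (fold change, FDR) tables, Venn overlap of DE sets,
genomic-proximity (operon-like) gene grouping, and the RNA-protein
rank correlation of the most abundant venom proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from venomkit.errors import ValidationError


def _check_matrix(m: pd.DataFrame) -> None:
    if (m.values < 0).any():
        raise ValidationError("expression matrix contains negative values")


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), elementwise."""
    _check_matrix(m)
    return np.log2(m + 1.0)


def remove_batch_means(m: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene batch-mean centering on a log-scale matrix.

    For each gene, every batch's mean is shifted to the gene's grand mean
    (the mean over all samples); within-batch deviations are untouched.
    Equivalent to regressing out a batch indicator with no other covariates.
    """
    missing = [s for s in m.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    batches = meta.loc[m.columns, "batch"]
    if batches.nunique() < 2:
        return m.copy()
    grand = m.mean(axis=1)
    out = m.copy()
    for batch, samples in batches.groupby(batches).groups.items():
        cols = list(samples)
        batch_mean = m[cols].mean(axis=1)
        out[cols] = m[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the per-sample sorted value
    vectors; each sample's values are replaced by the reference value at
    their rank. Ties within a sample receive the mean of the reference
    values at their tied ranks (average-rank interpolation).
    """
    if m.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    vals = m.to_numpy(dtype=float)
    n = vals.shape[0]
    reference = np.sort(vals, axis=0).mean(axis=1)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def sample_correlation_clusters(
    m: pd.DataFrame, k: int, random_state: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman sample-sample correlation matrix and k-means sample groups.

    Correlations are computed over genes; samples are then clustered by
    k-means (50 restarts, seeded) on the rows of the correlation matrix.
    """
    if k > m.shape[1]:
        raise ValidationError(f"k={k} exceeds the {m.shape[1]} samples")
    rho = stats.spearmanr(m.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=m.columns, columns=m.columns)
    km = KMeans(n_clusters=k, n_init=50, random_state=random_state)
    labels = pd.Series(km.fit_predict(corr.to_numpy()), index=m.columns, name="cluster")
    return corr, labels


def sample_pca(
    m: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA with samples as observations and genes as features.

    Returns (coordinates: samples x components, variance fractions).
    """
    X = m.to_numpy(dtype=float).T
    if np.allclose(X, X[0]):
        raise ValidationError("degenerate matrix: all samples identical")
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=m.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def mean_center_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (heatmap preprocessing)."""
    return m.sub(m.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# differential expression thresholds and overlap

def de_threshold_filter(
    results: pd.DataFrame,
    fdr_max: float = 0.05,
    fold_change_min: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Call DE genes from an external (log2 fold change, FDR) table.

    A gene is upregulated when fdr < fdr_max and log2fc > log2(fold_change_min),
    downregulated symmetrically (strict inequalities on both criteria).
    ``results`` needs columns ``gene_id``, ``log2fc``, ``fdr``.
    """
    required = {"gene_id", "log2fc", "fdr"}
    if not required.issubset(results.columns):
        raise ValidationError(f"DE table needs columns {sorted(required)}")
    lfc_min = np.log2(fold_change_min)
    sig = results["fdr"] < fdr_max
    up = set(results.loc[sig & (results["log2fc"] > lfc_min), "gene_id"])
    down = set(results.loc[sig & (results["log2fc"] < -lfc_min), "gene_id"])
    return up, down


@dataclass(frozen=True)
class OverlapStats:
    shared: int
    a_only: int
    b_only: int
    total_union: int
    pct_shared: int


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    """Venn statistics of two gene sets; pct_shared is |A∩B| / |A∪B| in %."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValidationError("both sets are empty")
    shared = len(a & b)
    pct = int(np.floor(100.0 * shared / len(union) + 0.5))
    return OverlapStats(
        shared=shared,
        a_only=len(a - b),
        b_only=len(b - a),
        total_union=len(union),
        pct_shared=pct,
    )


# ---------------------------------------------------------------------------
# genomic proximity (operon-like) grouping

@dataclass(frozen=True)
class ProximityGroup:
    scaffold_id: str
    gene_ids: tuple[str, ...]
    span: int


@dataclass(frozen=True)
class ProximitySummary:
    n_genes: int
    n_clustered: int
    fraction_clustered: float
    pct_clustered: int
    n_groups: int
    mean_group_size: float


def proximity_groups(
    genes: Iterable[str],
    positions: pd.DataFrame,
    window: int = 10,
) -> tuple[list[ProximityGroup], ProximitySummary]:
    """Chain query genes lying within ``window`` ordinal positions.

    ``positions`` maps gene_id -> (scaffold_id, ordinal_index), the gene's
    rank along its scaffold. Within a scaffold, query genes whose index gap
    to the nearest group member is <= window are merged transitively
    (single linkage); singletons are not groups. The summary counts genes
    in groups of size >= 2.
    """
    genes = set(genes)
    pos = positions.set_index("gene_id") if "gene_id" in positions.columns else positions
    missing = sorted(genes - set(pos.index))
    if missing:
        raise ValidationError(f"genes without positions: {missing[:10]}")

    sub = pos.loc[sorted(genes), ["scaffold_id", "ordinal_index"]]
    groups: list[ProximityGroup] = []
    for scaffold, block in sub.groupby("scaffold_id"):
        block = block.sort_values("ordinal_index")
        ids = block.index.to_list()
        idx = block["ordinal_index"].to_numpy()
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or idx[i] - idx[i - 1] > window:
                if i - start >= 2:
                    groups.append(
                        ProximityGroup(
                            scaffold_id=str(scaffold),
                            gene_ids=tuple(ids[start:i]),
                            span=int(idx[i - 1] - idx[start]),
                        )
                    )
                start = i

    n_clustered = sum(len(g.gene_ids) for g in groups)
    n_genes = len(genes)
    frac = n_clustered / n_genes if n_genes else 0.0
    summary = ProximitySummary(
        n_genes=n_genes,
        n_clustered=n_clustered,
        fraction_clustered=frac,
        pct_clustered=int(np.floor(100.0 * frac + 0.5)),
        n_groups=len(groups),
        mean_group_size=(n_clustered / len(groups)) if groups else 0.0,
    )
    return groups, summary


# ---------------------------------------------------------------------------
# RNA-protein correlation

def rna_protein_correlation(
    expression: Mapping[str, float] | pd.Series,
    abundance: Mapping[str, float] | pd.Series,
    gene_of_protein: Mapping[str, str],
    top_n: int = 100,
) -> float:
    """Spearman rho between transcript level and protein abundance.

    ``abundance`` maps protein id -> emPAI; the ``top_n`` most abundant
    proteins are paired with their gene's expression value and the rank
    correlation returned.
    """
    abundance = pd.Series(dict(abundance))
    expression = pd.Series(dict(expression))
    top = abundance.sort_values(ascending=False).head(top_n)
    missing_map = [p for p in top.index if p not in gene_of_protein]
    if missing_map:
        raise ValidationError(f"proteins without a gene mapping: {missing_map[:5]}")
    genes = [gene_of_protein[p] for p in top.index]
    missing_expr = [g for g in genes if g not in expression.index]
    if missing_expr:
        raise ValidationError(f"genes without expression: {missing_expr[:5]}")
    if len(top) < 3:
        raise ValidationError("need at least 3 RNA-protein pairs")
    rho = stats.spearmanr(expression.loc[genes].to_numpy(), top.to_numpy()).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# tabular I/O

def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_positions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "scaffold_id", "ordinal_index"}
    if not required.issubset(df.columns):
        raise ValidationError(f"positions table needs columns {sorted(required)}")
    dup = df.duplicated(subset=["scaffold_id", "ordinal_index"])
    if dup.any():
        raise ValidationError("duplicate (scaffold, ordinal_index) positions")
    return df


def read_de_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    if not required.issubset(df.columns):
        raise ValidationError(f"DE table needs columns {sorted(required)}")
    return df
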