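"""Single-cell Basal/Luminal signatures, preranked GSEA and signature-space
projection.

The signature workflow: QC-filter a log-scale single-cell matrix (genes seen
in < 3 cells and cells with < 200 detected genes are removed), derive
per-cluster markers by two-sided Wilcoxon rank-sum, compare a perturbation
ranking against the luminal/basal marker sets by preranked GSEA, take the
leading-edge genes as the perturbation-dependent plasticity signature, and
project bulk samples (plus perturbed queries) into the PCA space of the
signature genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("gene set must be non-empty")


@dataclass
class EnrichmentResult:
    ES: float
    NES: float
    p: float
    leading_edge: list[str]


# ---------------------------------------------------------------------------
# single-cell QC + markers
# ---------------------------------------------------------------------------


def sc_qc(matrix: pd.DataFrame, min_cells: int = 3, min_genes: int = 200
          ) -> pd.DataFrame:
    """QC filter on a cells x genes matrix (single fixed pass: genes
    expressed in < min_cells cells first, then cells with < min_genes
    detected genes)."""
    detected = (matrix > 0).sum(axis=0)
    matrix = matrix.loc[:, detected >= min_cells]
    per_cell = (matrix > 0).sum(axis=1)
    return matrix.loc[per_cell >= min_genes]


def sc_markers(
    matrix: pd.DataFrame,
    clusters: pd.Series,
    alpha: float = 0.05,
    min_cells_per_cluster: int = 3,
) -> pd.DataFrame:
    """Per-cluster marker genes by two-sided Wilcoxon rank-sum vs the rest.

    Markers are genes with BH-adjusted p < alpha and positive log fold
    change of means, ranked by logFC within cluster.
    """
    import warnings

    clusters = clusters.reindex(matrix.index).dropna()
    matrix = matrix.loc[clusters.index]
    frames = []
    for cluster in clusters.unique():
        in_c = (clusters == cluster).to_numpy()
        if in_c.sum() < min_cells_per_cluster:
            warnings.warn(f"cluster {cluster} has < {min_cells_per_cluster} cells")
            continue
        a = matrix.loc[in_c].to_numpy(float)
        b = matrix.loc[~in_c].to_numpy(float)
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        logfc = a.mean(axis=0) - b.mean(axis=0)
        q = multipletests(res.pvalue, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "cluster": cluster,
                "gene": matrix.columns,
                "logFC": logfc,
                "p": res.pvalue,
                "p_adj": q,
            }
        )
        df = df[(df["p_adj"] < alpha) & (df["logFC"] > 0)]
        frames.append(df.sort_values("logFC", ascending=False))
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene", "logFC", "p", "p_adj"])
    return pd.concat(frames, ignore_index=True)


def sc_qc_and_markers(
    matrix: pd.DataFrame, clusters: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    return sc_markers(sc_qc(matrix), clusters, alpha=alpha)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _running_es(
    genes: np.ndarray, scores: np.ndarray, hits: np.ndarray, weight: float
) -> tuple[float, int, np.ndarray]:
    """Signed extremum of the weighted KS running sum; returns (ES, extremum
    index, running sum)."""
    w = np.abs(scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        return 0.0, 0, np.zeros(len(genes))
    n_miss = len(genes) - hits.sum()
    inc = hit_w / total_hit - np.where(hits, 0.0, 1.0 / n_miss)
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i, run


def preranked_gsea(
    ranking: pd.Series,
    gene_set: GeneSet | Sequence[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a gene -> score ranking.

    The running sum increments by |score|^weight (normalised over set hits)
    at set genes and decrements by 1/(N - n_set) elsewhere; ES is the signed
    extremum, the leading edge the hits at or before (positive ES) / after
    (negative ES) the extremum, NES the ES over the mean |permuted ES| of
    matching sign, and p the fraction of gene-label permutations with an
    equal-or-more-extreme same-sign ES (lower bound 1/(n_perm + 1)).
    """
    genes_in_set = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    ranking = ranking.sort_values(ascending=False)
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(float)
    hits = np.isin(genes, list(genes_in_set))
    if hits.sum() < 3:
        raise ValueError("gene set overlaps the ranking by < 3 genes")
    es, i, _ = _running_es(genes, scores, hits, weight_exponent)
    if es >= 0:
        leading = [g for g, h in zip(genes[: i + 1], hits[: i + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i:], hits[i:]) if h]
    rng = np.random.default_rng(seed)
    n_hit = int(hits.sum())
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        ph = np.zeros(len(genes), dtype=bool)
        ph[rng.choice(len(genes), size=n_hit, replace=False)] = True
        perm_es[b], _, _ = _running_es(genes, scores, ph, weight_exponent)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
    # signed one-sided permutation p with add-one correction: floor at
    # 1/(n_perm + 1) for a set no permutation can match
    if es >= 0:
        more_extreme = int((perm_es >= es).sum())
    else:
        more_extreme = int((perm_es <= es).sum())
    p = (more_extreme + 1) / (n_perm + 1)
    return EnrichmentResult(ES=es, NES=float(nes), p=float(p),
                            leading_edge=leading)


def adapt_plasticity_signature(
    perturbation_ranking: pd.Series,
    luminal_set: GeneSet,
    basal_set: GeneSet,
    p_gate: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Perturbation-refined luminal/basal signature.

    ``perturbation_ranking`` scores genes by perturbation response (positive
    = up-regulated after perturbation).  The luminal set must be enriched
    among down-regulated genes and the basal set among up-regulated genes
    (both at p < p_gate); the leading edges are the adapted signatures.
    """
    down = preranked_gsea(
        -perturbation_ranking, luminal_set, n_perm=n_perm, seed=seed
    )
    up = preranked_gsea(
        perturbation_ranking, basal_set, n_perm=n_perm, seed=seed + 1
    )
    problems = []
    if not (down.ES > 0 and down.p < p_gate):
        problems.append(f"luminal-in-downregulated ES={down.ES:.3f} p={down.p:.4f}")
    if not (up.ES > 0 and up.p < p_gate):
        problems.append(f"basal-in-upregulated ES={up.ES:.3f} p={up.p:.4f}")
    if problems:
        raise ValueError("non-significant enrichment: " + "; ".join(problems))
    return down.leading_edge, up.leading_edge


# ---------------------------------------------------------------------------
# signature-space projection
# ---------------------------------------------------------------------------


class SignatureSpacePCA(BaseEstimator, TransformerMixin):
    """PCA of reference samples restricted to signature genes.

    Genes are centred and scaled with *reference* statistics; queries are
    projected with those same statistics, so a query identical to a
    reference centroid lands on that centroid.  Zero-variance signature
    genes are dropped (``n_dropped_``); a warning is issued when under half
    of the signature is present in the reference.
    """

    def __init__(self, signature_genes: Sequence[str], n_components: int = 2):
        self.signature_genes = list(signature_genes)
        self.n_components = n_components

    def fit(self, reference: pd.DataFrame, y=None):
        """``reference``: genes x samples expression."""
        import warnings

        present = [g for g in self.signature_genes if g in reference.index]
        if len(present) < 0.5 * len(self.signature_genes):
            warnings.warn("fewer than half the signature genes are present")
        if not present:
            raise ValueError("no signature genes in the reference")
        X = reference.loc[present]
        sd = X.std(axis=1, ddof=0)
        keep = sd > 0
        self.n_dropped_ = int((~keep).sum())
        self.genes_ = X.index[keep].tolist()
        self.mean_ = X.loc[self.genes_].mean(axis=1)
        self.scale_ = sd[keep]
        Z = ((X.loc[self.genes_].sub(self.mean_, axis=0))
             .div(self.scale_, axis=0)).T
        from sklearn.decomposition import PCA

        k = min(self.n_components, Z.shape[0] - 1, Z.shape[1])
        self.pca_ = PCA(n_components=k, svd_solver="full").fit(Z)
        self.reference_coords_ = pd.DataFrame(
            self.pca_.transform(Z),
            index=reference.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return self

    def transform(self, query: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "pca_")
        missing = [g for g in self.genes_ if g not in query.index]
        if missing:
            raise ValueError(f"{len(missing)} signature genes missing from query")
        Z = ((query.loc[self.genes_].sub(self.mean_, axis=0))
             .div(self.scale_, axis=0)).T
        return pd.DataFrame(
            self.pca_.transform(Z),
            index=query.columns,
            columns=self.reference_coords_.columns,
        )


def signature_space_projection(
    reference_expression: pd.DataFrame,
    sample_groups: Mapping[str, str] | pd.Series,
    signature_genes: Sequence[str],
    query_expression: pd.DataFrame,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Project reference and query into signature-gene PCA space.

    Returns (reference coords, query coords, group centroids).
    """
    model = SignatureSpacePCA(signature_genes, n_components).fit(
        reference_expression
    )
    ref = model.reference_coords_
    qry = model.transform(query_expression)
    groups = pd.Series(sample_groups).reindex(ref.index)
    centroids = ref.groupby(groups).mean()
    return ref, qry, centroids


# ---------------------------------------------------------------------------
# GMT / RNK I/O
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, GeneSet]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = GeneSet(parts[0], frozenset(parts[2:]))
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for name, gs in sets.items():
            fh.write("\t".join([name, "na", *sorted(gs.genes)]) + "\n")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return pd.Series(df["score"].to_numpy(), index=df["gene"]).sort_values(
        ascending=False
    )


def write_rnk(ranking: pd.Series, path) -> None:
    ranking.to_csv(path, sep="\t", header=False)
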