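"""Chromatin-state landscape analysis.

Consumes per-sample 6-state segmentations (E1..E6), builds the region-by-
sample categorical state matrix on the finest common partition, selects the
most informative regions (top Shannon-entropy, then top variance of a signed
numeric transform), and performs the unsupervised landscape analysis: MCA on
the categorical matrix, classical MDS on the numeric transform with a
mutual-nearest-neighbour (MNN) batch correction between tumours and cultured
lines, signed dimension loadings for gene ranking, basal-versus-non-basal
state-score differences, and segment-gene eQTL filtering.

The fixed signed transform encodes how activating each state is:
E2 (active enhancer/promoter) +3, E3 (bivalent) +2, E1 (quiescent/no mark)
+1, E5 (quiescent/weak repression) -1, E6 (heterochromatin) -2,
E4 (repressed) -3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .intervals import GenomicInterval, GenomeAnnotation, union_partition

STATE_SCORES = {"E2": 3, "E3": 2, "E1": 1, "E5": -1, "E6": -2, "E4": -3}
STATES = tuple(sorted(STATE_SCORES, key=lambda s: int(s[1:])))


def state_numeric_transform(state: str) -> int:
    """Signed activation score of one chromatin state (E2 -> +3 ... E4 -> -3)."""
    try:
        return STATE_SCORES[state]
    except KeyError:
        raise ValueError(f"unknown chromatin state {state!r}") from None


@dataclass
class LandscapeParams:
    entropy_top_fraction: float = 0.01
    variance_top_fraction: float = 0.01
    loading_alpha: float = 0.05
    exclude_sex_chroms: bool = True

    def __post_init__(self) -> None:
        for f in (self.entropy_top_fraction, self.variance_top_fraction):
            if not 0 < f <= 1:
                raise ValueError("top fractions must be in (0, 1]")


@dataclass
class StateMatrix:
    """Regions x samples categorical chromatin states + signed transform."""

    regions: list[GenomicInterval]
    categorical: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.categorical.columns)

    @property
    def numeric(self) -> pd.DataFrame:
        return self.categorical.apply(lambda col: col.map(STATE_SCORES))

    @property
    def region_entropy(self) -> pd.Series:
        return self.categorical.apply(_row_entropy, axis=1).rename("entropy")

    @property
    def region_variance(self) -> pd.Series:
        # summed in sorted order so the value is independent of sample order
        num = self.numeric.to_numpy(float)
        num = np.sort(num, axis=1)
        mean = num.mean(axis=1, keepdims=True)
        var = ((num - mean) ** 2).sum(axis=1) / (num.shape[1] - 1)
        return pd.Series(var, index=self.categorical.index, name="variance")

    def subset(self, mask: pd.Series) -> "StateMatrix":
        keep = mask.reindex(self.categorical.index).fillna(False).to_numpy(bool)
        return StateMatrix(
            regions=[r for r, k in zip(self.regions, keep) if k],
            categorical=self.categorical.loc[keep],
        )


def _row_entropy(row: pd.Series) -> float:
    counts = np.sort(row.value_counts().to_numpy(float))
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def build_state_matrix(
    segmentations: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    exclude_sex_chroms: bool = True,
) -> StateMatrix:
    """Finest-partition consensus sample-by-state matrix from segmentations."""
    regions, matrix = union_partition(
        segmentations, exclude_sex_chroms=exclude_sex_chroms
    )
    return StateMatrix(regions=regions, categorical=matrix)


def select_features(
    matrix: StateMatrix, params: LandscapeParams | None = None
) -> StateMatrix:
    """Informative-region selection.

    Drops regions that are the quiescent 'no mark' state (E1) in every
    sample, keeps the top ``entropy_top_fraction`` by Shannon entropy of the
    empirical state distribution across samples, then the top
    ``variance_top_fraction`` by variance of the signed numeric transform.
    Both cutoffs are inclusive at the quantile boundary.
    """
    params = params or LandscapeParams()
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    not_all_e1 = ~(matrix.categorical == "E1").all(axis=1)
    m = matrix.subset(not_all_e1)
    if m.categorical.empty:
        import warnings

        warnings.warn("all regions uniform E1; empty selection")
        return m
    # both cutoffs are counts relative to the full (post-exclusion) region
    # set: top n_e regions by entropy, then among those the top n_v by
    # numeric variance; boundary ties are kept (inclusive cutoffs)
    n_regions = m.categorical.shape[0]
    ent = m.region_entropy
    n_e = int(np.ceil(params.entropy_top_fraction * n_regions))
    ent_cut = ent.sort_values(ascending=False).iloc[min(n_e, n_regions) - 1]
    m = m.subset(ent >= ent_cut)
    var = m.region_variance
    n_v = int(np.ceil(params.variance_top_fraction * n_regions))
    if n_v < len(var):
        var_cut = var.sort_values(ascending=False).iloc[n_v - 1]
        m = m.subset(var >= var_cut)
    return m


# ---------------------------------------------------------------------------
# MCA
# ---------------------------------------------------------------------------


class MCA(BaseEstimator, TransformerMixin):
    """Multiple correspondence analysis of a categorical regions x samples
    matrix, with samples as observations and regions as variables.

    Computed as correspondence analysis of the complete indicator (disjunctive)
    matrix: one column per region-state level present in the data.  Fitted
    attributes follow the usual CA conventions; ``loading_`` holds per-region
    per-dimension signed correlation ratios (eta, oriented by the Pearson
    correlation between the region's signed state scores and the dimension
    coordinate) and ``loading_p_`` the one-way ANOVA p-value of the dimension
    coordinate on the region's categories.

    Parameters
    ----------
    n_components : number of principal dimensions retained.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        """``X``: regions x samples categorical DataFrame."""
        X = pd.DataFrame(X)
        if X.shape[1] < 3:
            raise ValueError("MCA needs >= 3 samples")
        if (X.nunique(axis=1) == 1).all():
            raise ValueError("constant categorical matrix")
        obs = X.T  # samples x regions
        Z = pd.get_dummies(obs, prefix_sep="=").astype(float)
        n, J = Z.shape
        Q = obs.shape[1]
        P = Z.to_numpy() / Z.to_numpy().sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        # drop trivial/null dimensions
        keep = sv > 1e-12
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        k = min(self.n_components, len(sv))
        self.singular_values_ = sv[:k]
        self.eigenvalues_ = sv[:k] ** 2
        self.all_eigenvalues_ = sv**2
        self.total_inertia_ = float(J / Q - 1)
        coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
        self.sample_coordinates_ = pd.DataFrame(
            coords,
            index=obs.index,
            columns=[f"Dim{i + 1}" for i in range(k)],
        )
        self.row_weights_ = r
        # per-region signed loadings + ANOVA p per dimension
        loadings = np.zeros((Q, k))
        pvals = np.ones((Q, k))
        scores = obs.apply(lambda col: col.map(STATE_SCORES))
        for qi, region in enumerate(obs.columns):
            cats = obs[region]
            groups_idx = [cats[cats == lv].index for lv in cats.unique()]
            for d in range(k):
                dim = self.sample_coordinates_.iloc[:, d]
                grand = dim.mean()
                ss_tot = ((dim - grand) ** 2).sum()
                if ss_tot <= 0:
                    continue
                ss_b = sum(
                    len(ix) * (dim.loc[ix].mean() - grand) ** 2 for ix in groups_idx
                )
                eta = np.sqrt(max(ss_b / ss_tot, 0.0))
                num = scores[region]
                if num.notna().all() and num.nunique() > 1 and dim.nunique() > 1:
                    sign = np.sign(np.corrcoef(num, dim)[0, 1])
                else:
                    sign = 1.0
                loadings[qi, d] = (sign if sign != 0 else 1.0) * eta
                if len(groups_idx) > 1 and all(len(ix) > 0 for ix in groups_idx):
                    try:
                        _, p = stats.f_oneway(
                            *[dim.loc[ix].to_numpy() for ix in groups_idx]
                        )
                        pvals[qi, d] = p if np.isfinite(p) else 1.0
                    except Exception:
                        pvals[qi, d] = 1.0
        dims = list(self.sample_coordinates_.columns)
        self.loading_ = pd.DataFrame(loadings, index=obs.columns, columns=dims)
        self.loading_p_ = pd.DataFrame(pvals, index=obs.columns, columns=dims)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        check_is_fitted(self, "sample_coordinates_")
        return self.sample_coordinates_


def mca(categorical: pd.DataFrame, n_components: int = 5):
    """Functional wrapper: returns (sample_coords, loadings, loading_p)."""
    model = MCA(n_components=n_components).fit(categorical)
    return model.sample_coordinates_, model.loading_, model.loading_p_


# ---------------------------------------------------------------------------
# MDS + MNN
# ---------------------------------------------------------------------------


def classical_mds(numeric: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Torgerson MDS of samples from Euclidean distances on the numeric
    matrix (regions x samples)."""
    Xs = numeric.T.to_numpy(float)  # samples x regions
    n = Xs.shape[0]
    D2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    k = min(n_components, int((w > 1e-10).sum()))
    coords = V[:, :k] * np.sqrt(np.maximum(w[:k], 0))
    if coords.shape[1] < n_components:
        coords = np.pad(coords, ((0, 0), (0, n_components - coords.shape[1])))
    return pd.DataFrame(
        coords,
        index=numeric.columns,
        columns=[f"Dim{i + 1}" for i in range(n_components)],
    )


def mnn_correct(
    coords: pd.DataFrame, batch: Mapping[str, str] | pd.Series, k: int = 3
) -> pd.DataFrame:
    """Mutual-nearest-neighbour batch correction in an existing embedding.

    For each sample of the smaller batch, its displacement from the mean of
    its mutual nearest neighbours in the larger batch is subtracted; samples
    without mutual neighbours get the average displacement of the corrected
    ones.  ``k`` is clipped (with a warning) when a batch is smaller than k.
    """
    import warnings

    batch = pd.Series(batch).reindex(coords.index)
    levels = batch.dropna().unique()
    if len(levels) != 2:
        raise ValueError("batch must have exactly two levels")
    g1 = coords.index[batch == levels[0]]
    g2 = coords.index[batch == levels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both batches must be non-empty")
    small, big = (g1, g2) if len(g1) <= len(g2) else (g2, g1)
    if k > min(len(small), len(big)):
        warnings.warn("k larger than a batch; reducing")
        k = min(len(small), len(big))
    Xs = coords.loc[small].to_numpy()
    Xb = coords.loc[big].to_numpy()
    d = ((Xs[:, None, :] - Xb[None, :, :]) ** 2).sum(-1)
    nn_sb = np.argsort(d, axis=1)[:, :k]          # small -> big
    nn_bs = np.argsort(d.T, axis=1)[:, :k]        # big -> small
    corrected = coords.copy().astype(float)
    displacements = []
    per_sample: dict[str, np.ndarray] = {}
    for i, s in enumerate(small):
        partners = [j for j in nn_sb[i] if i in nn_bs[j]]
        if partners:
            # pair displacements weighted by inverse squared distance, so a
            # coincident partner (no batch effect) dominates and the
            # correction vanishes
            wts = np.array([1.0 / (d[i, j] + 1e-12) for j in partners])
            diffs = np.array([Xs[i] - Xb[j] for j in partners])
            disp = (wts[:, None] * diffs).sum(axis=0) / wts.sum()
            per_sample[s] = disp
            displacements.append(disp)
    fallback = (
        np.mean(displacements, axis=0)
        if displacements
        else np.zeros(coords.shape[1])
    )
    for i, s in enumerate(small):
        corrected.loc[s] = Xs[i] - per_sample.get(s, fallback)
    return corrected


def mds_mnn(
    numeric: pd.DataFrame,
    batch: Mapping[str, str] | pd.Series,
    n_components: int = 2,
    k: int = 3,
) -> pd.DataFrame:
    """Classical MDS followed by MNN batch correction in the embedding."""
    return mnn_correct(classical_mds(numeric, n_components), batch, k=k)


# ---------------------------------------------------------------------------
# downstream landscape summaries
# ---------------------------------------------------------------------------


def rank_genes_by_loading(
    loadings: pd.Series,
    loading_p: pd.Series,
    region_gene_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.Series:
    """Signed gene ranking from dimension loadings.

    Regions are filtered at p < alpha; a gene covered by several regions
    takes the loading of largest magnitude.  Returns gene -> score sorted
    descending (an RNK-style ranking).
    """
    import warnings

    keep = loading_p < alpha
    scores: dict[str, float] = {}
    for region, val in loadings[keep].items():
        for gene in region_gene_map.get(region, ()):
            if gene not in scores or abs(val) > abs(scores[gene]):
                scores[gene] = float(val)
    if not scores:
        warnings.warn("no regions pass the loading filter")
        return pd.Series(dtype=float)
    return pd.Series(scores).sort_values(ascending=False)


def state_score_difference(
    numeric: pd.DataFrame, groups: Mapping[str, str] | pd.Series,
    group_a: str = "Basal",
) -> pd.Series:
    """Per-region mean signed-score difference, group_a minus the rest.

    With group_a = Basal this is the 'chromatin state score difference basal
    vs non-basal': negative means stronger activation in the non-basal group.
    """
    groups = pd.Series(groups).reindex(numeric.columns)
    in_a = (groups == group_a).to_numpy()
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise ValueError("both groups must be non-empty")
    X = numeric.to_numpy(float)
    return pd.Series(
        X[:, in_a].mean(axis=1) - X[:, ~in_a].mean(axis=1),
        index=numeric.index,
        name="score_difference",
    )


def segment_eqtl(
    numeric: pd.DataFrame,
    expression: pd.DataFrame,
    candidate_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Segment-gene eQTL filter: Pearson correlation across shared samples,
    keep pairs with two-sided p < alpha.  Pairs with constant score or
    expression are skipped (reported in the ``n_skipped`` attribute)."""
    shared = [s for s in numeric.columns if s in expression.columns]
    rows = []
    skipped = 0
    for region, gene in candidate_pairs:
        if region not in numeric.index or gene not in expression.index:
            raise KeyError(f"unknown pair ({region}, {gene})")
        x = numeric.loc[region, shared].to_numpy(float)
        y = expression.loc[gene, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            skipped += 1
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            rows.append((region, gene, r, p))
    out = pd.DataFrame(rows, columns=["region", "gene", "r", "p"])
    out.attrs["n_skipped"] = skipped
    return out


def tss_state_summary(
    segmentations: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    genome: GenomeAnnotation,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Median expression per TSS chromatin state per sample.

    Each gene's state in a sample is the segment state covering its TSS; for
    genes annotated with several TSSs the most frequent state wins, ties
    resolved toward the more active state (higher signed score).  Genes whose
    TSS falls outside the segmented territory are skipped (count in
    ``attrs['n_skipped']``).
    """
    rows = []
    skipped = 0
    for sample, segs in segmentations.items():
        if sample not in expression.columns:
            continue
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, lab in segs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, lab))
        for c in by_chrom:
            by_chrom[c].sort()
        gene_states: dict[str, str] = {}
        for gene in genome.genes:
            tss_list = list(gene.all_tss)
            states = []
            segs_c = by_chrom.get(gene.chrom, [])
            starts = [s for s, _, _ in segs_c]
            for tss in tss_list:
                i = int(np.searchsorted(starts, tss, side="right")) - 1
                if i >= 0 and segs_c[i][0] <= tss < segs_c[i][1]:
                    states.append(segs_c[i][2])
            if not states:
                skipped += 1
                continue
            counts = pd.Series(states).value_counts()
            top = counts[counts == counts.max()].index
            gene_states[gene.gene_id] = max(top, key=lambda s: STATE_SCORES[s])
        for state in STATES:
            genes_in = [g for g, s in gene_states.items() if s == state]
            genes_in = [g for g in genes_in if g in expression.index]
            if genes_in:
                rows.append(
                    (state, sample, float(expression.loc[genes_in, sample].median()))
                )
    out = pd.DataFrame(rows, columns=["state", "sample", "median_expression"])
    out.attrs["n_skipped"] = skipped
    return out
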