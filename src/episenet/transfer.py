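"""Tumour-reference similarity subtype transfer.

Cell lines cannot be subtyped by tumour-derived classifiers directly, so the
transfer works by similarity: reference tumours and query cell lines are
merged on shared genes after a per-dataset rank-based inverse-normal
transform, the 2000 most class-discriminative genes (one-way ANOVA F) are
kept, and each query is classified by majority vote of its k = 6 nearest
reference samples inside each of an ensemble of random 2-D embeddings
(1000 by default).  The per-class vote frequencies are the subtype
probability scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.utils.validation import check_is_fitted


@dataclass
class TransferParams:
    n_features: int = 2_000
    n_embeddings: int = 1_000
    k: int = 6
    embedding_dims: int = 2
    base_seed: int = 0
    embedding_method: str = "tsne"  # or "pca_rotation" (fast fallback)

    def __post_init__(self) -> None:
        if self.n_embeddings < 1 or self.k < 1 or self.embedding_dims < 1:
            raise ValueError("invalid TransferParams")


def rank_inverse_normal(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank-based inverse-normal transform (genes x samples).

    Platform-robust: any monotone per-sample scale (TPM, RLE, RMA...) maps to
    the same normal scores.
    """
    n = matrix.shape[0]
    ranks = matrix.rank(axis=0, method="average")
    return pd.DataFrame(
        stats.norm.ppf((ranks - 0.5) / n),
        index=matrix.index,
        columns=matrix.columns,
    )


def harmonize(
    reference: pd.DataFrame, query: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize each dataset, intersect genes and merge.

    Returns (genes x samples merged matrix, origin series with values
    'reference'/'query').  Errors on an empty gene intersection; warns below
    100 shared genes.
    """
    import warnings

    shared = reference.index.intersection(query.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between reference and query")
    if len(shared) < 100:
        warnings.warn(f"only {len(shared)} shared genes")
    ref = rank_inverse_normal(reference.loc[shared])
    qry = rank_inverse_normal(query.loc[shared])
    merged = pd.concat([ref, qry], axis=1)
    origin = pd.Series(
        ["reference"] * ref.shape[1] + ["query"] * qry.shape[1],
        index=merged.columns,
        name="origin",
    )
    return merged, origin


def select_features_ftest(
    merged: pd.DataFrame, labels: pd.Series, n_features: int = 2_000
) -> pd.DataFrame:
    """Top class-discriminative genes by one-way ANOVA F on the reference.

    ``labels`` indexes the reference samples only.  Classes with a single
    sample are dropped with a warning.  Ties in F are broken by gene id.
    """
    import warnings

    labels = labels.dropna()
    counts = labels.value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"dropping single-sample classes: {list(small)}")
        labels = labels[~labels.isin(small)]
    if labels.nunique() < 2:
        raise ValueError("need >= 2 classes with >= 2 reference samples")
    ref = merged[labels.index]
    F, _ = f_classif(ref.T.to_numpy(float), labels.to_numpy())
    F = np.where(np.isfinite(F), F, 0.0)
    order = sorted(zip(-F, merged.index), key=lambda t: (t[0], t[1]))
    keep = [g for _, g in order[: min(n_features, len(order))]]
    return merged.loc[keep]


class EnsembleKNNClassifier(BaseEstimator, ClassifierMixin):
    """KNN voting over an ensemble of random low-dimensional embeddings.

    Each embedding ``e`` is built jointly on reference + query with seed
    ``base_seed + e`` (joint embedding is required because the embeddings are
    non-parametric).  A query's class frequencies are the fraction of
    embeddings in which each class won the k-NN majority vote (ties broken
    by smallest summed neighbour distance).

    Parameters
    ----------
    n_embeddings, k, embedding_dims, base_seed : see :class:`TransferParams`.
    embedding_method : ``"pca_rotation"`` (random orthogonal projection of
        the top principal components; fast, neighbourhood-preserving) or
        ``"tsne"`` (scikit-learn TSNE with the per-embedding seed).
    n_pcs : PC space size for ``pca_rotation``.
    """

    def __init__(
        self,
        n_embeddings: int = 1_000,
        k: int = 6,
        embedding_dims: int = 2,
        base_seed: int = 0,
        embedding_method: str = "tsne",
        n_pcs: int = 10,
    ):
        self.n_embeddings = n_embeddings
        self.k = k
        self.embedding_dims = embedding_dims
        self.base_seed = base_seed
        self.embedding_method = embedding_method
        self.n_pcs = n_pcs

    def fit(self, X, y):
        """``X``: reference samples x genes array; ``y``: class labels."""
        X = np.asarray(X, float)
        y = np.asarray(y)
        if self.k >= len(y):
            raise ValueError("k must be smaller than the number of reference samples")
        self.classes_ = np.unique(y)
        self.X_ = X
        self.y_ = y
        return self

    def _embed(self, Z: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        if self.embedding_method == "tsne":
            from sklearn.manifold import TSNE

            perp = min(30.0, max(2.0, (len(Z) - 1) / 3))
            return TSNE(
                n_components=self.embedding_dims,
                random_state=int(seed) % (2**32),
                init="random",
                perplexity=perp,
            ).fit_transform(Z)
        if self.embedding_method != "pca_rotation":
            raise ValueError(f"unknown embedding_method {self.embedding_method!r}")
        k = min(self.n_pcs, Z.shape[0] - 1, Z.shape[1])
        pcs = PCA(n_components=k, svd_solver="full").fit_transform(Z)
        # random orthonormal frame: first dims of a QR-orthogonalised
        # Gaussian matrix, seeded per embedding
        A = rng.normal(size=(k, k))
        Q, _ = np.linalg.qr(A)
        return pcs @ Q[:, : self.embedding_dims]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        Xq = np.asarray(X, float)
        n_ref, n_query = len(self.X_), len(Xq)
        votes = np.zeros((n_query, len(self.classes_)))
        class_index = {c: i for i, c in enumerate(self.classes_)}
        Z = np.vstack([self.X_, Xq])
        for e in range(self.n_embeddings):
            emb = self._embed(Z, self.base_seed + e + 1)
            ref, qry = emb[:n_ref], emb[n_ref:]
            d = ((qry[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
            nn = np.argsort(d, axis=1)[:, : self.k]
            for qi in range(n_query):
                labels = self.y_[nn[qi]]
                counts = pd.Series(labels).value_counts()
                top = counts[counts == counts.max()].index
                if len(top) > 1:
                    sums = {
                        c: d[qi, nn[qi]][labels == c].sum() for c in top
                    }
                    winner = min(sums, key=lambda c: (sums[c], str(c)))
                else:
                    winner = top[0]
                votes[qi, class_index[winner]] += 1
        return votes / self.n_embeddings

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def ensemble_classify(
    merged: pd.DataFrame,
    labels: pd.Series,
    params: TransferParams | None = None,
) -> pd.DataFrame:
    """Classify every non-reference sample of ``merged`` (genes x samples).

    ``labels`` indexes reference samples.  Returns one row per query with
    the predicted class, per-class vote frequencies and the vote count.
    """
    params = params or TransferParams()
    ref_samples = [s for s in merged.columns if s in labels.index]
    query_samples = [s for s in merged.columns if s not in labels.index]
    clf = EnsembleKNNClassifier(
        n_embeddings=params.n_embeddings,
        k=params.k,
        embedding_dims=params.embedding_dims,
        base_seed=params.base_seed,
        embedding_method=params.embedding_method,
    ).fit(merged[ref_samples].T.to_numpy(), labels[ref_samples].to_numpy())
    proba = clf.predict_proba(merged[query_samples].T.to_numpy())
    out = pd.DataFrame(proba, index=query_samples, columns=clf.classes_)
    out.insert(0, "predicted", clf.classes_[np.argmax(proba, axis=1)])
    out["n_embeddings"] = params.n_embeddings
    return out
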