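"""ARACNe-style regulon inference, activity scoring and the TF-TF network.

``aracne_lite`` reverse-engineers TF -> target edges from expression by
mutual information (equal-frequency binning), a permutation significance
gate, data-processing-inequality (DPI) pruning of indirect triangles, and a
bootstrap-consensus vote.  ``regulon_activity`` is a variance-normalised
signed z-sum over the regulon — a deliberately simple enrichment scorer
whose scale supports the |mean activity| > 2 driver-TF gate used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .se_calling import differential_se  # noqa: F401  (shared DE gate)


@dataclass
class NetworkParams:
    mi_p_threshold: float = 1e-8
    n_bootstraps: int = 100
    dpi_tolerance: float = 0.0
    regulon_score_threshold: float = 2.0
    correlation_threshold: float = 0.5
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.mi_p_threshold < 1:
            raise ValueError("mi_p_threshold must be in (0, 1)")
        if self.n_bootstraps < 1 or self.n_permutations < 10:
            raise ValueError("bootstrap/permutation counts too small")


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning by rank."""
    order = stats.rankdata(x, method="ordinal") - 1
    return (order * n_bins // len(x)).astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (nats) on an equal-frequency 2-D histogram."""
    bx = _bin_indices(np.asarray(x, float), n_bins)
    by = _bin_indices(np.asarray(y, float), n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def _mi_matrix(X: np.ndarray, Y: np.ndarray, n_bins: int) -> np.ndarray:
    """MI between every row of X and every row of Y."""
    BX = np.stack([_bin_indices(row, n_bins) for row in X])
    BY = np.stack([_bin_indices(row, n_bins) for row in Y])
    n = X.shape[1]
    out = np.zeros((len(BX), len(BY)))
    for i, bx in enumerate(BX):
        base = bx * n_bins
        for j, by in enumerate(BY):
            joint = np.bincount(base + by, minlength=n_bins * n_bins).reshape(
                n_bins, n_bins
            ) / n
            px = joint.sum(axis=1, keepdims=True)
            py = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = joint * np.log(joint / (px * py))
            out[i, j] = np.nansum(terms)
    return out


def aracne_lite(
    expression: pd.DataFrame,
    tf_list: Sequence[str],
    params: NetworkParams | None = None,
    seed: int = 0,
) -> dict[str, list[tuple[str, float, float]]]:
    """Infer a TF -> target network from a genes x samples matrix.

    Returns TF -> list of (target, mode, weight):

    * significance — permutation null of MI shared across pairs (legitimate
      because equal-frequency binning gives every gene identical marginals),
      edges kept at ``mi_p_threshold``;
    * DPI — for each TF1-TF2-target triangle the weakest MI edge is removed
      when it is below the minimum of the other two minus ``dpi_tolerance``;
    * bootstrap consensus — the above repeated on ``n_bootstraps`` sample
      resamples; edges kept when present in > 50% of bootstraps, with the
      support fraction as weight;
    * mode — sign of the Spearman correlation between TF and target.
    """
    params = params or NetworkParams()
    rng = np.random.default_rng(seed)
    genes = list(expression.index)
    tfs = [t for t in tf_list if t in genes]
    n = expression.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    if n < 30:
        import warnings

        warnings.warn(f"only {n} samples; ARACNe-style inference is unstable")
    n_bins = min(10, max(2, int(np.floor(np.sqrt(n)))))
    X = expression.to_numpy(float)
    tf_idx = [genes.index(t) for t in tfs]

    def make_null(idx: np.ndarray) -> np.ndarray:
        # shared permutation null for the MI p-value (equal-frequency
        # binning gives every gene the same marginals, so one null serves
        # all pairs).  The gene vector is permuted BEFORE applying the
        # bootstrap index, so the null carries the same duplicated-pair
        # structure as the observed bootstrap MI.
        null = np.empty(params.n_permutations)
        base = X[tf_idx[0] if tf_idx else 0][idx]
        other = X[-1]
        for b in range(params.n_permutations):
            null[b] = mutual_information(
                base, rng.permutation(other)[idx], n_bins
            )
        null.sort()
        return null

    def significant_edges(M: np.ndarray, null: np.ndarray) -> np.ndarray:
        # p = (1 + #null >= mi) / (1 + n_perm), thresholded
        counts = len(null) - np.searchsorted(null, M, side="left")
        p = (1 + counts) / (1 + len(null))
        return p <= max(params.mi_p_threshold, 1.0 / (1 + len(null)))

    def run_once(idx: np.ndarray) -> set[tuple[str, str]]:
        Xb = X[:, idx]
        M = _mi_matrix(Xb[tf_idx], Xb, n_bins)
        sig = significant_edges(M, make_null(idx))
        edges: dict[tuple[str, str], float] = {}
        for i, tf in enumerate(tfs):
            for j, gene in enumerate(genes):
                if gene != tf and sig[i, j]:
                    edges[(tf, gene)] = M[i, j]
        # DPI on triangles TF1 - TF2 - target
        dropped: set[tuple[str, str]] = set()
        for tf1, tf2 in combinations(tfs, 2):
            if (tf1, tf2) not in edges and (tf2, tf1) not in edges:
                continue
            m12 = edges.get((tf1, tf2), edges.get((tf2, tf1), 0.0))
            for gene in genes:
                if gene in (tf1, tf2):
                    continue
                e1, e2 = (tf1, gene), (tf2, gene)
                if e1 in edges and e2 in edges:
                    trio = {e1: edges[e1], e2: edges[e2], (tf1, tf2): m12}
                    weakest = min(trio, key=trio.get)
                    others = [v for k, v in trio.items() if k != weakest]
                    if trio[weakest] < min(others) - params.dpi_tolerance:
                        dropped.add(weakest)
                        if weakest == (tf1, tf2):
                            dropped.add((tf2, tf1))
        return {e for e in edges if e not in dropped}

    support: dict[tuple[str, str], int] = {}
    for b in range(params.n_bootstraps):
        # a single "bootstrap" uses the data as-is (pure significance gate);
        # true resampling starts at n_bootstraps > 1
        if params.n_bootstraps == 1:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=n)
        for e in run_once(idx):
            support[e] = support.get(e, 0) + 1

    rho = {}
    network: dict[str, list[tuple[str, float, float]]] = {t: [] for t in tfs}
    for (tf, gene), count in sorted(support.items()):
        w = count / params.n_bootstraps
        if w <= 0.5:
            continue
        if (tf, gene) not in rho:
            r = stats.spearmanr(
                expression.loc[tf], expression.loc[gene]
            ).statistic
            rho[(tf, gene)] = 0.0 if not np.isfinite(r) else r
        mode = float(np.sign(rho[(tf, gene)])) or 1.0
        network[tf].append((gene, mode, w))
    return network


# ---------------------------------------------------------------------------


def regulon_activity(
    expression: pd.DataFrame,
    network: Mapping[str, Sequence[tuple]],
) -> pd.DataFrame:
    """Per-sample regulon activity (TFs x samples).

    Genes are z-scored across samples; the activity of TF t in sample s is
    ``sum_i mode_i w_i z(target_i, s) / sqrt(sum_i w_i^2)``, zero-mean and
    comparable across regulon sizes.  Network entries may be ``(target,
    mode)`` or ``(target, mode, weight)``.
    """
    z = expression.sub(expression.mean(axis=1), axis=0)
    sd = expression.std(axis=1, ddof=0).replace(0, np.nan)
    z = z.div(sd, axis=0).fillna(0.0)
    rows, index = [], []
    for tf, targets in network.items():
        entries = [
            (t[0], float(t[1]), float(t[2]) if len(t) > 2 else 1.0)
            for t in targets
            if t[0] in z.index
        ]
        if not entries:
            continue
        w = np.array([e[1] * e[2] for e in entries])
        Z = z.loc[[e[0] for e in entries]].to_numpy()
        denom = np.sqrt((np.array([e[2] for e in entries]) ** 2).sum())
        rows.append(w @ Z / denom)
        index.append(tf)
    return pd.DataFrame(rows, index=index, columns=expression.columns)


def select_network_tfs(
    links: pd.DataFrame,
    diff_regions: Sequence[str],
    tf_annotation: set[str],
    de_genes: set[str],
    activity: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    score_threshold: float = 2.0,
) -> pd.DataFrame:
    """Subtype driver-TF gate.

    Keeps genes that are (i) best-linked targets of differential SEs,
    (ii) annotated TFs, (iii) differentially expressed, and (iv) have
    |group-mean regulon activity| > ``score_threshold`` in some group; the
    subtype is the group of largest |mean activity|.
    """
    import warnings

    groups = pd.Series(groups).reindex(activity.columns)
    best = links[(links["is_best"]) & (links["region"].isin(set(diff_regions)))]
    candidates = sorted(set(best["gene"]) & tf_annotation & de_genes)
    rows = []
    for tf in candidates:
        if tf not in activity.index:
            continue
        means = activity.loc[tf].groupby(groups).mean()
        if means.abs().max() > score_threshold:
            subtype = means.abs().idxmax()
            rows.append((tf, subtype, *means.reindex(sorted(means.index))))
    if not rows:
        warnings.warn("no TFs pass the driver gate")
        return pd.DataFrame(columns=["TF", "subtype"])
    group_names = sorted(pd.Series(groups).dropna().unique())
    return pd.DataFrame(
        rows, columns=["TF", "subtype"] + [f"mean_{g}" for g in group_names]
    )


def build_correlation_network(
    expression: pd.DataFrame,
    selected_tfs: Sequence[str],
    correlation_threshold: float = 0.5,
) -> nx.Graph:
    """TF-TF Pearson graph: edges at r >= threshold; isolated TFs excluded.

    Connected components are the reported modules (``graph.graph['modules']``).
    """
    tfs = [t for t in selected_tfs if t in expression.index]
    if len(tfs) < 2:
        raise ValueError("need >= 2 selected TFs")
    X = expression.loc[tfs]
    corr = np.corrcoef(X.to_numpy(float))
    g = nx.Graph()
    for i, j in combinations(range(len(tfs)), 2):
        r = corr[i, j]
        if np.isfinite(r) and r >= correlation_threshold:
            g.add_edge(tfs[i], tfs[j], r=float(r))
    g.graph["modules"] = [sorted(c) for c in nx.connected_components(g)]
    return g
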