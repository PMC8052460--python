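"""Population structure: genetic distance, clustering, DAPC and Fst.

Nei's (1972) standard distance is computed directly on tetraploid allele
frequencies (dosage / 4 per clone). Hierarchical clustering follows the
classical Ward convention on unsquared distances ("ward.D" in the R dialect),
with the squared-distance variant available as a switch. The cluster-number
scan pairs K-means on retained principal components with a BIC criterion,
and between-group differentiation uses a Weir-Cockerham-type theta with
4 alleles counted per tetraploid clone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import ClonePanel, DosageMatrix, diploidize

__all__ = [
    "DistanceMatrix",
    "ClusterModel",
    "DapcModel",
    "nei_distance_matrix",
    "ward_tree",
    "linkage_to_newick",
    "detect_duplicates_and_mislabels",
    "kmeans_bic_scan",
    "dapc_fit",
    "dapc_crossval",
    "snpzip_select",
    "pairwise_fst",
]


@dataclass
class DistanceMatrix:
    clone_ids: list[str]
    values: np.ndarray
    metric: str = "nei1972"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.clone_ids), len(self.clone_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix not symmetric")
        if np.nanmin(v) < -1e-12:
            raise ValueError("negative distances")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        i, j = self.clone_ids.index(a), self.clone_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.clone_ids, columns=self.clone_ids)


@dataclass
class ClusterModel:
    k_values: list[int]
    bic: list[float]
    selected_k: int
    assignments: np.ndarray  # group index per clone at selected K
    clone_ids: list[str]


@dataclass
class DapcModel:
    n_pca: int
    variance_fraction: float
    n_da: int
    memberships: pd.DataFrame        # clones x groups, rows sum to 1
    marker_loadings: np.ndarray      # markers x n_da
    marker_ids: list[str]
    group_labels: list = field(default_factory=list)
    _pca: object | None = field(default=None, repr=False)
    _lda: object | None = field(default=None, repr=False)
    pc_scores: np.ndarray | None = field(default=None, repr=False)

    def posterior_from_scores(self, scores: np.ndarray) -> np.ndarray:
        """Group membership posteriors for points given in retained-PC space."""
        if self._lda is None:
            raise ValueError("model was not fit with prediction support")
        return self._lda.predict_proba(np.atleast_2d(scores))


def nei_distance_matrix(D: DosageMatrix) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between all clone pairs.

    Per clone, locus allele frequencies are x = dosage/ploidy and 1-x. With
    Jxy the mean over shared non-missing loci of sum_alleles(x*y), and Jx, Jy
    the analogous homozygosity terms, D = -ln(Jxy / sqrt(Jx*Jy)). A pair
    sharing no non-missing loci gets NaN.
    """
    X = D.dosage / D.ploidy
    n = D.n_clones
    out = np.zeros((n, n))
    valid = ~np.isnan(X)
    for i in range(n):
        xi = X[i]
        for j in range(i + 1, n):
            m = valid[i] & valid[j]
            if not m.any():
                out[i, j] = out[j, i] = np.nan
                continue
            x, y = xi[m], X[j][m]
            jxy = np.mean(x * y + (1 - x) * (1 - y))
            jx = np.mean(x**2 + (1 - x) ** 2)
            jy = np.mean(y**2 + (1 - y) ** 2)
            d = -np.log(jxy / np.sqrt(jx * jy))
            out[i, j] = out[j, i] = max(d, 0.0)
    return DistanceMatrix(list(D.clone_ids), out)


def ward_tree(dm: DistanceMatrix, variant: str = "ward.D") -> tuple[np.ndarray, str]:
    """Ward dendrogram from a distance matrix; returns (linkage, newick).

    ``variant="ward.D"`` applies the Lance-Williams Ward update to the
    distances as given (the classical convention); ``"ward.D2"`` applies it
    to squared distances. The ward.D tree is obtained by feeding sqrt(d) to
    the squared-distance algorithm and squaring the resulting heights.
    """
    v = dm.values
    if np.isnan(v).any():
        raise ValueError("distance matrix has missing cells")
    cond = squareform(v, checks=False)
    if variant == "ward.D":
        Z = hierarchy.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    elif variant == "ward.D2":
        Z = hierarchy.linkage(cond, method="ward")
    else:
        raise ValueError("variant must be 'ward.D' or 'ward.D2'")
    return Z, linkage_to_newick(Z, dm.clone_ids)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float | None) -> str:
        if node.is_leaf():
            name = labels[node.id]
        else:
            name = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
        if parent_height is None:
            return name + ";"
        return f"{name}:{max(parent_height - node.dist, 0.0):.6g}"

    return rec(tree, None)


def detect_duplicates_and_mislabels(
    dm: DistanceMatrix,
    panel: ClonePanel,
    dup_threshold: float = 0.001,
    tree: np.ndarray | None = None,
    n_clusters: int = 3,
    rare_below: float = 0.15,
    common_elsewhere: float = 0.25,
) -> pd.DataFrame:
    """Flag near-zero-distance duplicate pairs and market-class mislabels.

    Duplicates: unordered pairs with distance < ``dup_threshold``. Mislabel
    candidates: clones whose declared market class is rare (frequency below
    ``rare_below``) within their group when the Ward tree is cut at
    ``n_clusters`` while being common (frequency at least
    ``common_elsewhere``) in some other group — the pattern of a clone
    recorded under one market class but clustering with another. Genetic
    groups legitimately mix market classes, so mere disagreement with the
    group majority is not treated as evidence.
    Returns a report with columns (clone_id, flag, evidence).
    """
    records = []
    ids = dm.clone_ids
    iu = np.triu_indices(len(ids), k=1)
    for i, j in zip(*iu):
        if dm.values[i, j] < dup_threshold:
            records.append(
                {
                    "clone_id": ids[j],
                    "flag": "duplicate",
                    "evidence": f"distance {dm.values[i, j]:.2e} to {ids[i]}",
                }
            )
    if tree is None:
        tree, _ = ward_tree(dm)
    groups = hierarchy.fcluster(tree, t=n_clusters, criterion="maxclust")
    meta = panel.table.set_index("clone_id")["market_class"]
    classes = meta.reindex(ids)
    gdf = pd.DataFrame({"clone_id": ids, "group": groups, "market_class": classes.values})
    # class frequency within each tree group
    freq = (
        gdf.dropna(subset=["market_class"])
        .groupby(["group", "market_class"])
        .size()
        .unstack(fill_value=0)
    )
    freq = freq.div(freq.sum(axis=1), axis=0)
    for _, row in gdf.iterrows():
        mc = row["market_class"]
        if pd.isna(mc) or mc not in freq.columns:
            continue
        own = freq.loc[row["group"], mc]
        others = freq.loc[freq.index != row["group"], mc]
        if own < rare_below and (others >= common_elsewhere).any():
            home = others.idxmax()
            records.append(
                {
                    "clone_id": row["clone_id"],
                    "flag": "mislabel_candidate",
                    "evidence": (
                        f"declared {mc} is rare ({own:.0%}) in its cluster {row['group']} "
                        f"but common in cluster {home}"
                    ),
                }
            )
    return pd.DataFrame(records, columns=["clone_id", "flag", "evidence"])


def _numeric_matrix(D: DosageMatrix) -> np.ndarray:
    """Diploidized, mean-imputed, centered genotype matrix for PCA steps."""
    if D.ploidy == 4:
        D = diploidize(D)
    X = D.dosage.copy()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    return X - X.mean(axis=0)


def kmeans_bic_scan(
    D: DosageMatrix, k_max: int = 10, n_pca: int = 50, seed: int = 0, n_init: int = 25
) -> ClusterModel:
    """Scan cluster numbers with K-means on retained PCs; select K by BIC.

    BIC(K) = n*ln(WSS_K/n) + K*ln(n) on the retained principal-component
    scores; the selected K minimizes BIC, with ties broken toward smaller K.
    """
    n = D.n_clones
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of clones")
    X = _numeric_matrix(D)
    ncomp = min(n_pca, n - 1, X.shape[1])
    scores = PCA(n_components=ncomp, random_state=seed).fit_transform(X)
    ks, bics, assigns = [], [], {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        bic = n * np.log(wss / n) + k * np.log(n)
        ks.append(k)
        bics.append(float(bic))
        assigns[k] = labels
    best = ks[int(np.argmin(bics))]  # argmin returns first minimum -> smaller K on ties
    return ClusterModel(ks, bics, best, assigns[best], list(D.clone_ids))


def dapc_fit(
    D: DosageMatrix,
    assignments: np.ndarray,
    n_pca: int = 20,
    n_da: int | None = None,
) -> DapcModel:
    """Discriminant analysis of principal components.

    LDA is fit on the first ``n_pca`` PC scores of the (diploidized, centered)
    genotype matrix; group memberships Q are the discriminant-space Gaussian
    posteriors, and discriminant loadings are mapped back to markers through
    the PCA rotation.
    """
    assignments = np.asarray(assignments)
    groups = np.unique(assignments)
    g = len(groups)
    n = D.n_clones
    if n_pca >= n - g:
        raise ValueError("n_pca too large for the sample size (overfit guard)")
    if n_da is None:
        n_da = g - 1
    n_da = min(n_da, g - 1)
    X = _numeric_matrix(D)
    pca = PCA(n_components=n_pca, random_state=0).fit(X)
    scores = pca.transform(X)
    var_frac = float(pca.explained_variance_ratio_.sum())
    lda = LinearDiscriminantAnalysis(n_components=n_da, solver="svd").fit(scores, assignments)
    Q = pd.DataFrame(lda.predict_proba(scores), index=D.clone_ids, columns=lda.classes_)
    # markers x n_da: PC rotation (markers x n_pca) times LDA scalings
    loadings = pca.components_.T @ lda.scalings_[:, :n_da]
    return DapcModel(
        n_pca=n_pca,
        variance_fraction=var_frac,
        n_da=n_da,
        memberships=Q,
        marker_loadings=loadings,
        marker_ids=list(D.marker_ids),
        group_labels=list(lda.classes_),
        _pca=pca,
        _lda=lda,
        pc_scores=scores,
    )


def dapc_crossval(
    D: DosageMatrix,
    groups: np.ndarray,
    reps: int = 30,
    holdout: float = 0.10,
    seed: int = 0,
    n_pca_grid: list[int] | None = None,
) -> int:
    """Choose the number of retained PCs by stratified holdout validation.

    For each candidate n_pca, the mean root-mean-square assignment error
    (1 - holdout accuracy, averaged over ``reps`` stratified splits) is
    computed; the candidate with the lowest RMSE is returned, ties broken
    toward the smallest n_pca. Groups with a single member are pinned to the
    training set with a warning.
    """
    groups = np.asarray(groups)
    n = D.n_clones
    g = len(np.unique(groups))
    X = _numeric_matrix(D)
    if n_pca_grid is None:
        top = max(2, min(n - g - 1, X.shape[1], 60))
        n_pca_grid = sorted(set(np.linspace(1, top, num=min(top, 10), dtype=int)))
    rng = np.random.default_rng(seed)
    singletons = [lab for lab in np.unique(groups) if np.sum(groups == lab) == 1]
    if singletons:
        warnings.warn(
            f"groups {singletons} have one member; pinned to training set", UserWarning, stacklevel=2
        )
    errs = {p: [] for p in n_pca_grid}
    for _ in range(reps):
        test_idx: list[int] = []
        for lab in np.unique(groups):
            members = np.flatnonzero(groups == lab)
            if len(members) < 2:
                continue
            k = max(1, int(round(holdout * len(members))))
            k = min(k, len(members) - 1)  # keep at least one member in training
            test_idx.extend(rng.choice(members, size=k, replace=False))
        test = np.array(sorted(test_idx))
        train = np.setdiff1d(np.arange(n), test)
        for p in n_pca_grid:
            ncomp = min(p, len(train) - 1, X.shape[1])
            pca = PCA(n_components=ncomp, random_state=0).fit(X[train])
            lda = LinearDiscriminantAnalysis().fit(pca.transform(X[train]), groups[train])
            acc = float(np.mean(lda.predict(pca.transform(X[test])) == groups[test]))
            errs[p].append(1 - acc)
    rmse = {p: float(np.sqrt(np.mean(np.square(v)))) for p, v in errs.items()}
    best = min(n_pca_grid, key=lambda p: (round(rmse[p], 12), p))
    return best


def snpzip_select(model: DapcModel, axis: int = 0) -> list[str]:
    """Markers contributing most to one discriminant axis.

    The absolute loadings on the axis are split into two groups by Ward
    clustering; the markers in the higher-loading group are returned. If the
    loadings carry no structure (all equal), an empty list is returned with a
    warning.
    """
    if not 0 <= axis < model.marker_loadings.shape[1]:
        raise IndexError("axis out of range")
    load = np.abs(model.marker_loadings[:, axis])
    if np.allclose(load, load[0]):
        warnings.warn("degenerate loading split: all loadings equal", UserWarning, stacklevel=2)
        return []
    Z = hierarchy.linkage(load[:, None], method="ward")
    grp = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    means = [load[grp == g].mean() for g in (1, 2)]
    high = 1 + int(np.argmax(means))
    return [model.marker_ids[i] for i in np.flatnonzero(grp == high)]


def pairwise_fst(D: DosageMatrix, groups: np.ndarray) -> pd.DataFrame:
    """Pairwise Weir-Cockerham-type Fst between groups.

    Alleles are counted 4 per tetraploid clone (2 after diploidization). Per
    marker the between/within mean squares are combined across markers as a
    ratio of sums. Groups of fewer than 2 clones are excluded with a warning.
    Returns a table (group1, group2, fst).
    """
    groups = np.asarray(groups)
    labs = [g for g in pd.unique(groups)]
    sizes = {g: int(np.sum(groups == g)) for g in labs}
    small = [g for g in labs if sizes[g] < 2]
    if small:
        warnings.warn(f"groups {small} have <2 clones; excluded from Fst", UserWarning, stacklevel=2)
        labs = [g for g in labs if sizes[g] >= 2]
    if len(labs) < 2:
        raise ValueError("need at least two groups of size >= 2")
    X = D.dosage
    rows = []
    for a_i in range(len(labs)):
        for b_i in range(a_i + 1, len(labs)):
            a, b = labs[a_i], labs[b_i]
            Xa, Xb = X[groups == a], X[groups == b]
            fst = _wc_fst_two_groups(Xa, Xb, D.ploidy)
            rows.append({"group1": a, "group2": b, "fst": fst})
    return pd.DataFrame(rows)


def _wc_fst_two_groups(Xa: np.ndarray, Xb: np.ndarray, ploidy: int) -> float:
    na = ploidy * (~np.isnan(Xa)).sum(axis=0).astype(float)  # allele counts
    nb = ploidy * (~np.isnan(Xb)).sum(axis=0).astype(float)
    ok = (na >= 2) & (nb >= 2)
    na, nb = na[ok], nb[ok]
    pa = np.nansum(Xa, axis=0)[ok] / na
    pb = np.nansum(Xb, axis=0)[ok] / nb
    ntot = na + nb
    pbar = (na * pa + nb * pb) / ntot
    r = 2
    msp = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / (r - 1)
    msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (ntot - r)
    nc = (ntot - (na**2 + nb**2) / ntot) / (r - 1)
    num = msp - msg
    den = msp + (nc - 1) * msg
    poly = den > 0
    if not poly.any():
        return float("nan")
    return float(num[poly].sum() / den[poly].sum())
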