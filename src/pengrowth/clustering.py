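"""Phenotyping growth curves: PCA and hierarchical clustering on principal components.

The seven weakly correlated growth parameters (peak mass, relative mass
loss, sibling delta, guard duration, steepest slope, age at peak,
irregularity) are z-scored, missing cells (mostly the sibling delta of
singleton chicks) are completed by an iterative-PCA EM scheme, and the
completed matrix is decomposed by PCA.  Chicks are then grouped by
Ward-linkage hierarchical clustering on the retained principal-component
scores (HCPC), with the cluster count picked automatically from the
relative loss of within-cluster inertia between successive tree cuts,
and the partition optionally consolidated by k-means started from the
tree-cut centroids.

Clusters are finally mapped onto semantic phenotype names: *light* is
the cluster with the lowest mean peak mass; of the remaining two, *fast*
reaches peak mass earlier and *slow* later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .growthcurves import CLUSTERING_COLUMNS, PARAM_COLUMNS

SEMANTIC_LABELS = ("fast", "slow", "light")


@dataclass
class PCAModel:
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # columns = axes, rows = variables
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray
    ncp: int

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_ratio": self.explained_ratio.tolist(),
            "ncp": int(self.ncp),
        }


@dataclass
class ClusterAssignment:
    labels: pd.Series  # chick_id -> 1..k
    k: int
    inertia: dict[int, float]  # candidate k -> within-cluster inertia of the tree cut
    consolidated: bool
    semantic: dict[int, str] | None = None

    @property
    def semantic_labels(self) -> pd.Series:
        if self.semantic is None:
            raise ValueError("semantic mapping not set; run describe_clusters first")
        return self.labels.map(self.semantic)


@dataclass
class StabilityReport:
    k_counts: dict[int, int] = field(default_factory=dict)
    mean_coassignment_agreement: float = float("nan")
    n_boot: int = 0


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """z-score each column over its non-missing entries (sd with n-1 denominator)."""
    means = matrix.mean(axis=0, skipna=True).to_numpy()
    sds = matrix.std(axis=0, ddof=1, skipna=True).to_numpy()
    for col, sd, nobs in zip(matrix.columns, sds, matrix.notna().sum()):
        if nobs < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
    return (matrix - means) / sds, means, sds


def impute_iterative_pca(
    matrix: pd.DataFrame, ncp: int, tol: float = 1e-6, max_iter: int = 1000
) -> pd.DataFrame:
    """Complete missing cells by the iterative-PCA (EM) scheme.

    Missing cells start at the column mean; each iteration reconstructs
    the matrix from its rank-``ncp`` truncated SVD and overwrites only
    the missing cells, until the largest absolute change in an imputed
    cell falls below ``tol``.  Observed cells are never altered.
    """
    p = matrix.shape[1]
    if not (1 <= ncp < p):
        raise ValueError(f"ncp must be in [1, {p - 1}], got {ncp}")
    if (matrix.notna().sum(axis=1) == 0).any():
        raise ValueError("every row must have at least one observed value")
    X = matrix.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy()
    col_means = np.nanmean(X, axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :ncp] * s[:ncp]) @ Vt[:ncp]
        delta = np.max(np.abs(recon[miss] - X[miss]))
        X[miss] = recon[miss]
        if delta < tol:
            return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    raise RuntimeError(f"iterative PCA did not converge in {max_iter} iterations (last delta {delta:.3g})")


def choose_ncp_cv(
    matrix: pd.DataFrame,
    max_ncp: int = 5,
    n_repeats: int = 20,
    mask_frac: float = 0.05,
    seed: int = 0,
) -> int:
    """Pick the number of PCA axes by leave-out cross-validation.

    Repeatedly masks ``mask_frac`` of the observed cells, imputes them
    with each candidate axis count, and returns the count minimizing the
    mean squared reconstruction error.  Deterministic given ``seed``.
    """
    if max_ncp >= matrix.shape[1]:
        raise ValueError("max_ncp must be smaller than the number of columns")
    rng = np.random.default_rng(seed)
    z, _, _ = standardize(matrix)
    obs = np.argwhere(z.notna().to_numpy())
    errors = np.zeros(max_ncp)
    counts = np.zeros(max_ncp)
    for _ in range(n_repeats):
        n_mask = max(1, int(round(mask_frac * len(obs))))
        picked = obs[rng.choice(len(obs), size=n_mask, replace=False)]
        holed = z.to_numpy(dtype=float).copy()
        truth = holed[picked[:, 0], picked[:, 1]].copy()
        holed[picked[:, 0], picked[:, 1]] = np.nan
        holed_df = pd.DataFrame(holed, index=z.index, columns=z.columns)
        if (np.isnan(holed).sum(axis=1) == holed.shape[1]).any():
            continue  # a fully masked row cannot be scored
        for ncp in range(1, max_ncp + 1):
            try:
                filled = impute_iterative_pca(holed_df, ncp=ncp, max_iter=200)
            except RuntimeError:
                errors[ncp - 1] += np.inf
                counts[ncp - 1] += 1
                continue
            pred = filled.to_numpy()[picked[:, 0], picked[:, 1]]
            errors[ncp - 1] += float(np.mean((pred - truth) ** 2))
            counts[ncp - 1] += 1
    mse = errors / np.maximum(counts, 1)
    return int(np.argmin(mse)) + 1


def pca(matrix: pd.DataFrame) -> tuple[PCAModel, pd.DataFrame]:
    """PCA of the standardized, completed parameter matrix.

    Eigendecomposition of the correlation structure (the covariance of
    z-scored columns); scores are data x loadings.  Sign convention: the
    largest-magnitude entry of each loading vector is positive, so
    stored models are comparable across runs.
    """
    if matrix.isna().any().any():
        raise ValueError("PCA requires a complete matrix; impute first")
    z, means, sds = standardize(matrix)
    X = z.to_numpy(dtype=float)
    n = X.shape[0]
    corr = (X.T @ X) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    model = PCAModel(
        columns=list(matrix.columns),
        means=means,
        sds=sds,
        loadings=eigvec,
        eigenvalues=eigval,
        explained_ratio=eigval / eigval.sum(),
        ncp=matrix.shape[1],
    )
    scores = pd.DataFrame(
        X @ eigvec, index=matrix.index, columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])]
    )
    return model, scores


def _within_inertia(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def hcpc_cluster(scores: pd.DataFrame, max_k: int = 10, consolidate: bool = True) -> ClusterAssignment:
    """Ward-linkage clustering of PC scores with automatic cluster count.

    Cuts the Ward tree at k = 2..max_k, computes the within-cluster
    inertia W(k) of each cut, and selects the k (over k >= 3, with the
    k = 2 cut serving as the baseline) maximizing the relative inertia
    loss (W(k-1) - W(k)) / W(k-1).  With ``consolidate`` the cut labels
    are refined by k-means started from the cut centroids.
    """
    if not (2 <= max_k <= 10):
        raise ValueError("max_k must be between 2 and 10")
    X = scores.to_numpy(dtype=float)
    if X.shape[0] <= max_k:
        raise ValueError(f"need more than max_k={max_k} rows, got {X.shape[0]}")
    Z = linkage(X, method="ward")
    cuts = {k: fcluster(Z, t=k, criterion="maxclust") for k in range(2, max_k + 1)}
    inertia = {k: _within_inertia(X, lab) for k, lab in cuts.items()}
    rel_loss = {
        k: (inertia[k - 1] - inertia[k]) / inertia[k - 1] if inertia[k - 1] > 0 else 0.0
        for k in range(3, max_k + 1)
    }
    k = max(rel_loss, key=lambda kk: (rel_loss[kk], -kk))
    labels = cuts[k]
    if consolidate:
        centroids = np.vstack([X[labels == lab].mean(axis=0) for lab in range(1, k + 1)])
        km = KMeans(n_clusters=k, init=centroids, n_init=1, max_iter=300, random_state=0)
        labels = km.fit_predict(X) + 1
    return ClusterAssignment(
        labels=pd.Series(labels, index=scores.index, name="cluster"),
        k=int(k),
        inertia=inertia,
        consolidated=bool(consolidate),
    )


def run_cluster_pipeline(
    params: pd.DataFrame,
    ncp: int | None = None,
    n_axes: int = 5,
    max_k: int = 10,
    consolidate: bool = True,
    seed: int = 0,
) -> tuple[PCAModel, pd.DataFrame, ClusterAssignment]:
    """Standardize -> impute -> PCA -> HCPC on the seven clustering columns.

    ``ncp`` is the *imputation* rank (cross-validated when None); the
    clustering itself consumes the first ``n_axes`` principal components,
    the two roles the reference R workflow (missMDA + FactoMineR, whose
    PCA retains 5 axes by default) also keeps distinct.
    """
    matrix = params[CLUSTERING_COLUMNS].astype(float)
    if ncp is None:
        ncp = choose_ncp_cv(matrix, max_ncp=5, seed=seed)
    z, _, _ = standardize(matrix)
    complete_z = impute_iterative_pca(z, ncp=ncp)
    # undo the z-scoring so pca() re-derives its own standardization constants
    completed = complete_z * matrix.std(ddof=1) + matrix.mean()
    model, scores = pca(completed)
    model.ncp = ncp
    n_axes = min(n_axes, scores.shape[1])
    assignment = hcpc_cluster(scores.iloc[:, :n_axes], max_k=max_k, consolidate=consolidate)
    return model, scores, assignment


def cluster_stability(
    params: pd.DataFrame,
    n_boot: int = 50,
    seed: int = 0,
    ncp: int | None = None,
    max_k: int = 10,
) -> StabilityReport:
    """Bootstrap rows, rerun the pipeline, and summarize partition stability.

    Reports the distribution of chosen k and the mean pairwise
    co-assignment agreement between each bootstrap partition and the
    full-data partition (over pairs of rows present in the bootstrap).
    """
    report = StabilityReport(n_boot=n_boot)
    if n_boot == 0:
        return report
    rng = np.random.default_rng(seed)
    _, _, ref = run_cluster_pipeline(params, ncp=ncp, max_k=max_k, seed=seed)
    ref_labels = ref.labels
    agreements = []
    for _ in range(n_boot):
        idx = rng.choice(len(params), size=len(params), replace=True)
        boot = params.iloc[np.unique(idx)]
        _, _, asg = run_cluster_pipeline(boot, ncp=ncp, max_k=max_k, seed=seed)
        report.k_counts[asg.k] = report.k_counts.get(asg.k, 0) + 1
        common = boot.index
        sub = min(len(common), 200)
        pick = common[rng.choice(len(common), size=sub, replace=False)]
        a = ref_labels.loc[pick].to_numpy()
        b = asg.labels.loc[pick].to_numpy()
        same_a = a[:, None] == a[None, :]
        same_b = b[:, None] == b[None, :]
        iu = np.triu_indices(sub, k=1)
        agreements.append(float(np.mean(same_a[iu] == same_b[iu])))
    report.mean_coassignment_agreement = float(np.mean(agreements))
    return report


def describe_clusters(
    params: pd.DataFrame, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Per-cluster portraits of all eleven growth parameters.

    Returns a summary (mean and sd per cluster, one-way ANOVA F and p
    per parameter) and the semantic mapping {cluster id -> fast/slow/light}:
    *light* has the lowest mean peak mass; of the other two, *fast*
    reaches peak mass earlier.
    """
    if assignment.k < 2:
        raise ValueError("need at least two clusters to describe")
    labels = assignment.labels.loc[params.index]
    cols = [c for c in PARAM_COLUMNS if c in params.columns]
    rows = []
    for col in cols:
        entry: dict = {"parameter": col}
        groups = []
        for lab in range(1, assignment.k + 1):
            vals = params.loc[labels == lab, col].dropna().to_numpy()
            entry[f"mean_{lab}"] = float(np.mean(vals)) if len(vals) else np.nan
            entry[f"sd_{lab}"] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
            if len(vals):
                groups.append(vals)
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            F, p = f_oneway(*groups)
            entry["anova_F"], entry["anova_p"] = float(F), float(p)
        else:
            entry["anova_F"] = entry["anova_p"] = np.nan
        rows.append(entry)
    summary = pd.DataFrame(rows).set_index("parameter")

    mapping: dict[int, str] = {}
    if assignment.k == 3 and {"peak_mass", "age_at_peak"} <= set(params.columns):
        peak_means = {
            lab: params.loc[labels == lab, "peak_mass"].mean() for lab in range(1, 4)
        }
        light = min(peak_means, key=peak_means.get)
        rest = [lab for lab in range(1, 4) if lab != light]
        age_means = {lab: params.loc[labels == lab, "age_at_peak"].mean() for lab in rest}
        fast = min(age_means, key=age_means.get)
        slow = [lab for lab in rest if lab != fast][0]
        mapping = {fast: "fast", slow: "slow", light: "light"}
    else:
        mapping = {lab: f"cluster{lab}" for lab in range(1, assignment.k + 1)}
    assignment.semantic = mapping
    return summary, mapping


def recovery_ari(assignment: ClusterAssignment, truth: pd.Series) -> float:
    """Adjusted Rand index between a partition and ground-truth labels."""
    common = assignment.labels.index.intersection(truth.index)
    return float(adjusted_rand_score(truth.loc[common], assignment.labels.loc[common]))
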