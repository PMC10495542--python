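"""Cross-organism comparison: clustering, feature importance, regression.

Each organism is projected onto six scalar features — the signal size of
its between-region signal and of the five downstream within-region
constituents (5'UTR, CDS, 3'UTR, intron, 3'end; the upstream flank is
excluded).  Organisms are then grouped by Ward-linkage hierarchical
clustering, the cluster count chosen by the Calinski-Harabasz index with
the silhouette score as a cross-check, and each cluster's discriminating
features quantified with one-vs-all random-forest importances.  A
separate ordinary-least-squares analysis regresses the CDS within-region
signal size on its amino-acid-choice and synonymous-codon components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .decomposition import DecomposedSignal
from .genome_model import RegionLabel
from .metrics import signal_size

#: Within-region constituents used as clustering features (5'end excluded).
FEATURE_REGIONS = [
    RegionLabel.FIVE_UTR,
    RegionLabel.CDS,
    RegionLabel.THREE_UTR,
    RegionLabel.INTRON,
    RegionLabel.THREE_END,
]

FEATURE_COLUMNS = ["sigma_between"] + [
    f"sigma_within_{r.value}" for r in FEATURE_REGIONS
]


def build_feature_table(
    decompositions: dict[str, DecomposedSignal],
    metadata: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """One row per organism with the six signal-size features.

    *metadata* may map organism -> extra columns (e.g. taxonomic_class).
    A region entirely absent from an organism yields a zero constituent
    vector and hence a zero feature, with a warning.
    """
    rows = []
    for organism, d in decompositions.items():
        row: dict = {"organism": organism}
        row["sigma_between"] = signal_size(d.between).sigma
        for region in FEATURE_REGIONS:
            if region not in d.region_avg_gc:
                warnings.warn(
                    f"{organism}: region {region.value} absent; feature set to 0",
                    stacklevel=2,
                )
            row[f"sigma_within_{region.value}"] = signal_size(
                d.within_by_region[region]
            ).sigma
        if metadata and organism in metadata:
            row.update(metadata[organism])
        rows.append(row)
    return pd.DataFrame(rows).set_index("organism")


@dataclass
class ClusterResult:
    linkage: np.ndarray
    organisms: list[str]
    labels_k: dict[int, np.ndarray]
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    chosen_k: int
    chosen_k_silhouette: int
    scores_agree: bool
    importances: pd.DataFrame | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.labels_k[self.chosen_k]


def ward_cluster(
    table: pd.DataFrame,
    k_range: range = range(2, 11),
    scale: bool = False,
) -> ClusterResult:
    """Ward-linkage hierarchical clustering on the six signal-size features.

    Scores each candidate k with the Calinski-Harabasz index and the
    silhouette score; ``chosen_k`` maximises CH (ties broken toward the
    smaller k), with the silhouette argmax reported alongside and a flag
    when the two disagree.  Features are used unscaled by default (they
    share GC-fraction units); pass ``scale=True`` to z-score them.
    """
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n = len(X)
    Z = hierarchy.linkage(X, method="ward")
    labels_k: dict[int, np.ndarray] = {}
    ch: dict[int, float] = {}
    sil: dict[int, float] = {}
    for k in k_range:
        if k >= n or k < 2:
            continue
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        labels_k[k] = lab
        ch[k] = float(calinski_harabasz_score(X, lab))
        sil[k] = float(silhouette_score(X, lab))
    if not ch:
        raise ValueError("no feasible cluster count in k_range")
    chosen_k = min(ch, key=lambda k: (-ch[k], k))
    chosen_sil = min(sil, key=lambda k: (-sil[k], k))
    return ClusterResult(
        linkage=Z,
        organisms=list(table.index),
        labels_k=labels_k,
        ch_by_k=ch,
        silhouette_by_k=sil,
        chosen_k=chosen_k,
        chosen_k_silhouette=chosen_sil,
        scores_agree=chosen_k == chosen_sil,
    )


def feature_importance(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int,
    n_trees: int = 500,
) -> pd.DataFrame:
    """One-vs-all random-forest feature importances per cluster, in percent.

    For each cluster a forest is fit to the binary membership problem and
    its impurity-based (information-gain) importances are normalised to
    sum to 100.  The ``aggregate`` row is the member-weighted mean across
    clusters (also summing to 100).
    """
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("feature importance requires at least 2 clusters")
    small = [int(c) for c in clusters if (labels == c).sum() < 5]
    if small:
        warnings.warn(
            f"clusters {small} have fewer than 5 members; importances may be unstable",
            stacklevel=2,
        )
    rows = {}
    weights = {}
    for c in clusters:
        y = (labels == c).astype(int)
        # max_features=None: every split considers all six features, so the
        # impurity-based ranking reflects information gain over the full
        # feature set rather than the per-node subsampling used for
        # generalisation-oriented forests.
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, max_features=None
        )
        forest.fit(X, y)
        imp = forest.feature_importances_
        total = imp.sum()
        imp = imp / total * 100.0 if total > 0 else np.full_like(imp, 100.0 / len(imp))
        rows[f"cluster_{c}"] = imp
        weights[f"cluster_{c}"] = int((labels == c).sum())
    df = pd.DataFrame(rows, index=FEATURE_COLUMNS).T
    w = np.array([weights[i] for i in df.index], dtype=float)
    df.loc["aggregate"] = (df.to_numpy() * w[:, None]).sum(axis=0) / w.sum()
    return df


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage matrix as Newick with merge heights as branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            name = leaf_names[node.id].replace(" ", "_")
            return f"{name}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# Regression of the CDS within-region size on its two components


@dataclass
class RegressionResult:
    group: str
    n: int
    w_aa: float
    w_syn: float
    intercept: float
    p_aa: float
    p_syn: float
    p_intercept: float
    r_squared: float
    pearson_r: float
    pearson_p: float


def regress_cds_components(
    sizes: pd.DataFrame,
    group_column: str | None = "taxonomic_class",
    min_group: int = 4,
) -> list[RegressionResult]:
    """OLS of sigma(CDS within) on (sigma(aa choice), sigma(syn codon)) per group.

    *sizes* needs columns ``sigma_cds_within``, ``sigma_aa``, ``sigma_syn``
    and, when grouping, *group_column*.  Coefficient significance comes
    from two-tailed t-tests; the Pearson correlation between the two
    component sizes is reported alongside.  Rank-deficient designs yield
    NaN p-values rather than raising; groups below *min_group* are
    skipped.
    """
    results = []
    if group_column is None:
        grouped = [("all", sizes)]
    else:
        grouped = list(sizes.groupby(group_column, sort=True))
    for group, df in grouped:
        if len(df) < min_group:
            continue
        X = sm.add_constant(df[["sigma_aa", "sigma_syn"]].to_numpy(dtype=float))
        y = df["sigma_cds_within"].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        rank_ok = np.linalg.matrix_rank(X) == X.shape[1]
        p = fit.pvalues if rank_ok else np.full(3, np.nan)
        r, rp = stats.pearsonr(df["sigma_aa"], df["sigma_syn"]) if len(df) >= 3 else (np.nan, np.nan)
        results.append(
            RegressionResult(
                group=str(group),
                n=len(df),
                w_aa=float(fit.params[1]),
                w_syn=float(fit.params[2]),
                intercept=float(fit.params[0]),
                p_aa=float(p[1]),
                p_syn=float(p[2]),
                p_intercept=float(p[0]),
                r_squared=float(fit.rsquared),
                pearson_r=float(r),
                pearson_p=float(rp),
            )
        )
    return results


def regression_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
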