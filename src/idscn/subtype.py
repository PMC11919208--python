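"""Neuroanatomical subtyping on edge Z features.

Patients are clustered by Ward's minimum-variance agglomeration on Euclidean
distances (the Ward.D2 convention). The number of clusters is chosen by
majority vote of clustering validity indices over a k range, the robustness
of the solution is assessed by bootstrap mean Jaccard coefficients
(> 0.6 considered stable), and subtypes are contrasted edge-wise (t-test,
Benjamini-Hochberg FDR), clinically (t / chi-square), and for
subgroup x sex interactions (two-way ANOVA with simple-effects follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable

Edge = tuple[int, int]


@dataclass
class FeatureMatrix:
    """Patients x top-edge Z-score features."""

    patient_ids: list[str]
    edge_list: list[Edge]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.edge_list)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")


def hierarchical_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Ward clustering cut to k groups; labels are 1..k, deterministic."""
    X = _as_matrix(X)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} invalid for {n} patients")
    tree = linkage(X, method="ward")
    return fcluster(tree, t=k, criterion="maxclust")


# --- clustering validity indices -------------------------------------------

def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max within-cluster diameter."""
    d = squareform(pdist(X))
    uniq = np.unique(labels)
    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, d[np.ix_(idx, idx)].max())
    if max_diam == 0.0:
        return np.inf
    min_sep = np.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            ia = np.flatnonzero(labels == uniq[a])
            ib = np.flatnonzero(labels == uniq[b])
            min_sep = min(min_sep, d[np.ix_(ia, ib)].min())
    return float(min_sep / max_diam)


def _c_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C-index: (S - Smin) / (Smax - Smin), lower is better."""
    dists = pdist(X)
    cond = pdist(labels[:, None], metric=lambda a, b: float(a[0] == b[0]))
    within = dists[cond == 1.0]
    n_w = len(within)
    if n_w == 0:
        return 0.0
    ordered = np.sort(dists)
    s = within.sum()
    s_min = ordered[:n_w].sum()
    s_max = ordered[-n_w:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


# name -> (score(X, labels), higher_is_better)
VALIDITY_INDICES: dict[str, tuple[Callable[[np.ndarray, np.ndarray], float], bool]] = {
    "silhouette": (lambda X, lab: silhouette_score(X, lab), True),
    "calinski_harabasz": (lambda X, lab: calinski_harabasz_score(X, lab), True),
    "davies_bouldin": (lambda X, lab: davies_bouldin_score(X, lab), False),
    "dunn": (_dunn_index, True),
    "c_index": (_c_index, False),
}


def choose_k(
    X: np.ndarray, k_min: int = 2, k_max: int = 6,
    indices: Sequence[str] | None = None,
) -> tuple[int, dict[str, int]]:
    """Pick the number of clusters by index voting over Ward solutions.

    Each validity index votes for its best k in [k_min, k_max]; the most
    frequent vote wins, ties broken toward the smallest k.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n_patients")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate features: all patients identical")
    names = list(indices) if indices is not None else list(VALIDITY_INDICES)
    ks = list(range(k_min, k_max + 1))
    solutions = {k: hierarchical_cluster(X, k) for k in ks}
    votes: dict[str, int] = {}
    for name in names:
        score, higher = VALIDITY_INDICES[name]
        vals = []
        for k in ks:
            try:
                vals.append(float(score(X, solutions[k])))
            except ValueError:
                vals.append(-np.inf if higher else np.inf)
        arr = np.asarray(vals)
        votes[name] = ks[int(np.argmax(arr) if higher else np.argmin(arr))]
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return best, votes


def jaccard_stability(
    X: np.ndarray, k: int, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """Per-cluster mean bootstrap Jaccard coefficient.

    Patients are resampled with replacement, the resample is reclustered at
    the same k, and each original cluster (restricted to the resampled
    subjects) is matched to the bootstrap cluster maximizing the Jaccard
    coefficient; means over bootstraps are returned in cluster-label order
    (labels 1..k from the original Ward solution).
    """
    X = _as_matrix(X)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = hierarchical_cluster(X, k)
    clusters = [set(np.flatnonzero(labels == c)) for c in range(1, k + 1)]
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    sums = np.zeros(k)
    for _ in range(n_boot):
        sample = rng.integers(0, n, size=n)
        boot_labels = hierarchical_cluster(X[sample], k)
        present = set(sample.tolist())
        # map each unique original index to the cluster of its first occurrence
        boot_clusters: dict[int, set[int]] = {}
        seen: set[int] = set()
        for pos, orig in enumerate(sample.tolist()):
            if orig in seen:
                continue
            seen.add(orig)
            boot_clusters.setdefault(int(boot_labels[pos]), set()).add(orig)
        for ci, orig_cluster in enumerate(clusters):
            restricted = orig_cluster & present
            if not restricted:
                continue  # cluster absent from resample counts as 0
            best = max(
                len(restricted & bc) / len(restricted | bc)
                for bc in boot_clusters.values()
            )
            sums[ci] += best
    return sums / n_boot


@dataclass
class SubtypeSolution:
    k: int
    labels: np.ndarray
    index_votes: dict[str, int]
    jaccard: np.ndarray
    stable: np.ndarray  # per-cluster mean Jaccard > 0.6

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "index_votes": self.index_votes,
            "cluster_sizes": [int(np.sum(self.labels == c))
                              for c in range(1, self.k + 1)],
            "jaccard": self.jaccard.tolist(),
            "stable": self.stable.tolist(),
        }


class WardSubtyper(BaseEstimator, ClusterMixin):
    """Ward-linkage subtyper with index-voted k and bootstrap stability.

    Parameters
    ----------
    n_clusters : fixed number of clusters, or None to choose by index voting
        over [k_min, k_max].
    n_boot : bootstrap resamples for the Jaccard stability assessment
        (0 disables it).
    stability_threshold : mean Jaccard above which a cluster counts stable.

    Attributes (after fit)
    ----------------------
    labels_ : cluster assignment, 1..k_.
    k_ : chosen number of clusters.
    index_votes_ : per-index preferred k (empty when n_clusters is fixed).
    jaccard_ : per-cluster mean bootstrap Jaccard.
    stable_ : per-cluster stability flags.
    """

    def __init__(self, n_clusters: int | None = None, k_min: int = 2,
                 k_max: int = 6, n_boot: int = 1000,
                 stability_threshold: float = 0.6, random_state: int = 0):
        self.n_clusters = n_clusters
        self.k_min = k_min
        self.k_max = k_max
        self.n_boot = n_boot
        self.stability_threshold = stability_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.n_clusters is not None:
            self.k_ = int(self.n_clusters)
            self.index_votes_ = {}
        else:
            self.k_, self.index_votes_ = choose_k(X, self.k_min, self.k_max)
        self.labels_ = hierarchical_cluster(X, self.k_)
        if self.n_boot > 0:
            self.jaccard_ = jaccard_stability(X, self.k_, self.n_boot,
                                              self.random_state)
        else:
            self.jaccard_ = np.full(self.k_, np.nan)
        self.stable_ = self.jaccard_ > self.stability_threshold
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def solution(self) -> SubtypeSolution:
        return SubtypeSolution(self.k_, self.labels_, self.index_votes_,
                               self.jaccard_, self.stable_)


# --- subtype contrasts ------------------------------------------------------

CONTINUOUS_CLINICAL = ("caps", "pcl_c", "age", "education", "time_since_trauma")


@dataclass
class SubtypeContrasts:
    edge_table: pd.DataFrame       # edge, t, p, q, significant
    clinical_table: pd.DataFrame   # variable, test, statistic, p
    interaction_table: pd.DataFrame  # edge, F, p, post hoc simple effects
    alpha: float = 0.05


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def contrast_subtypes(
    features: FeatureMatrix,
    labels: np.ndarray,
    clinical: ClinicalTable | None = None,
    alpha: float = 0.05,
    yates: bool = False,
) -> SubtypeContrasts:
    """Contrast exactly two subtypes on edges, clinical variables and
    subgroup x sex interactions.

    Edge-wise two-sided pooled t-tests are BH-FDR corrected across edges.
    Continuous clinical variables use two-sample t; sex uses a Pearson
    chi-square (Yates correction optional). Per-edge two-way ANOVA tests the
    subgroup x sex interaction; simple effects (subgroup within each sex)
    are reported only when the interaction is significant.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 subtypes, got {len(uniq)}")
    g1 = features.values[labels == uniq[0]]
    g2 = features.values[labels == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each subtype needs at least 2 members")

    ts, ps = [], []
    for e in range(features.values.shape[1]):
        a, b = g1[:, e], g2[:, e]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        ts.append(float(t))
        ps.append(float(p))
    qs = bh_fdr(np.asarray(ps))
    edge_table = pd.DataFrame({
        "edge": [f"{i}-{j}" for i, j in features.edge_list],
        "region_i": [i for i, _ in features.edge_list],
        "region_j": [j for _, j in features.edge_list],
        "t": ts, "p": ps, "q": qs, "significant": qs < alpha,
    })

    clin_rows = []
    inter = pd.DataFrame(columns=["edge", "F", "p", "posthoc"])
    if clinical is not None:
        cf = clinical.frame.set_index("subject_id").loc[features.patient_ids]
        for var in CONTINUOUS_CLINICAL:
            if var not in cf.columns:
                continue
            vals = pd.to_numeric(cf[var], errors="coerce")
            if vals.isna().all():
                continue
            a = vals[labels == uniq[0]].dropna()
            b = vals[labels == uniq[1]].dropna()
            t, p = stats.ttest_ind(a, b, equal_var=True)
            clin_rows.append({"variable": var, "test": "t",
                              "statistic": float(t), "p": float(p)})
        if "sex" in cf.columns:
            table = pd.crosstab(cf["sex"], labels)
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
            clin_rows.append({"variable": "sex", "test": "chi2",
                              "statistic": float(chi2), "p": float(p)})
            inter = _interaction_anova(features, labels, cf["sex"].to_numpy(), alpha)
    clinical_table = pd.DataFrame(clin_rows, columns=["variable", "test",
                                                      "statistic", "p"])
    return SubtypeContrasts(edge_table, clinical_table, inter, alpha)


def _interaction_anova(features: FeatureMatrix, labels: np.ndarray,
                       sex: np.ndarray, alpha: float) -> pd.DataFrame:
    rows = []
    for e, (i, j) in enumerate(features.edge_list):
        df = pd.DataFrame({
            "z": features.values[:, e],
            "subgroup": labels.astype(str),
            "sex": sex.astype(str),
        })
        if df.groupby(["subgroup", "sex"]).size().min() < 2:
            rows.append({"edge": f"{i}-{j}", "F": np.nan, "p": np.nan,
                         "posthoc": ""})
            continue
        model = ols("z ~ C(subgroup) * C(sex)", data=df).fit()
        table = anova_lm(model, typ=2)
        f = float(table.loc["C(subgroup):C(sex)", "F"])
        p = float(table.loc["C(subgroup):C(sex)", "PR(>F)"])
        posthoc = ""
        if p < alpha:
            parts = []
            for s in sorted(df["sex"].unique()):
                sub = df[df["sex"] == s]
                groups = [sub[sub["subgroup"] == g]["z"]
                          for g in sorted(sub["subgroup"].unique())]
                if all(len(g) >= 2 for g in groups) and len(groups) == 2:
                    tt, pp = stats.ttest_ind(groups[0], groups[1], equal_var=True)
                    parts.append(f"{s}: t={tt:.3f}, p={pp:.4f}")
            posthoc = "; ".join(parts)
        rows.append({"edge": f"{i}-{j}", "F": f, "p": p, "posthoc": posthoc})
    return pd.DataFrame(rows, columns=["edge", "F", "p", "posthoc"])


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D patients x features matrix")
    return X
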