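"""Group-level SCN heterogeneity via jackknife pseudovalue networks.

Each subject's individualized network is the jackknife pseudovalue
``n * C(all) - (n - 1) * C(without subject)`` of the group Pearson matrix C,
the standard jackknife-bias construction attributing to each subject its
contribution to the group statistic. A subject's heterogeneity is the
Euclidean distance between its pseudovalue network and the group network,
taken over the strict upper triangle; groups are compared by a pooled
two-sample t-test with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import _pearson_matrix
from .io import ThicknessMatrix


def jackknife_subject_scn(group: ThicknessMatrix, subject_index: int) -> np.ndarray:
    """Jackknife pseudovalue network for one subject; diagonal forced to 1."""
    n = group.n_subjects
    if n < 5:
        raise ValueError("need at least 5 subjects for jackknife networks")
    if not 0 <= subject_index < n:
        raise IndexError(f"subject index {subject_index} out of range")
    c_all = _pearson_matrix(group.values, group.region_labels)
    mask = np.ones(n, dtype=bool)
    mask[subject_index] = False
    c_loo = _pearson_matrix(group.values[mask], group.region_labels)
    pseudo = n * c_all - (n - 1) * c_loo
    np.fill_diagonal(pseudo, 1.0)
    return pseudo


def heterogeneity_distance(subject_net: np.ndarray, group_net: np.ndarray) -> float:
    """Euclidean distance over the strict upper triangle of two networks."""
    subject_net = np.asarray(subject_net, dtype=float)
    group_net = np.asarray(group_net, dtype=float)
    if subject_net.shape != group_net.shape:
        raise ValueError("network shape mismatch")
    iu = np.triu_indices(subject_net.shape[0], k=1)
    diff = subject_net[iu] - group_net[iu]
    return float(np.sqrt(np.sum(diff ** 2)))


def group_distances(group: ThicknessMatrix) -> np.ndarray:
    """Per-subject pseudovalue distances against the group's own SCN."""
    n = group.n_subjects
    if n < 5:
        raise ValueError("need at least 5 subjects")
    c_all = _pearson_matrix(group.values, group.region_labels)
    iu = np.triu_indices(group.n_regions, k=1)
    out = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        c_loo = _pearson_matrix(group.values[mask], group.region_labels)
        pseudo = n * c_all - (n - 1) * c_loo
        diff = pseudo[iu] - c_all[iu]
        out[k] = np.sqrt(np.sum(diff ** 2))
    return out


@dataclass
class HeterogeneityResult:
    distances_a: np.ndarray
    distances_b: np.ndarray
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    cohens_d: float

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "t": self.t_stat,
            "p": self.p_value,
            "cohens_d": self.cohens_d,
        }


def compare_heterogeneity(
    group_a: ThicknessMatrix, group_b: ThicknessMatrix
) -> HeterogeneityResult:
    """Compare per-subject heterogeneity between two groups.

    Distances are computed within each group against that group's own
    group-level SCN; the groups are compared with a pooled-variance
    two-sided t-test, and Cohen's d uses the pooled SD (sign of
    mean_a - mean_b).
    """
    da = group_distances(group_a)
    db = group_distances(group_b)
    t, p = stats.ttest_ind(da, db, equal_var=True)
    na, nb = len(da), len(db)
    pooled_var = ((na - 1) * da.var(ddof=1) + (nb - 1) * db.var(ddof=1)) / (na + nb - 2)
    d = (da.mean() - db.mean()) / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    return HeterogeneityResult(
        distances_a=da, distances_b=db,
        mean_a=float(da.mean()), mean_b=float(db.mean()),
        t_stat=float(t), p_value=float(p), cohens_d=float(d),
    )


def two_sample_t_power(n_per_group: int, effect_d: float, alpha: float) -> float:
    """Exact power of a two-sided two-sample t-test (noncentral t)."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    ncp = effect_d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_sample_size(effect_d: float, alpha: float = 0.05,
                      power: float = 0.8, max_n: int = 10 ** 6) -> int:
    """Smallest even total n (two equal groups) reaching the requested power.

    Uses the exact noncentral-t power function; (d=0.5, alpha=0.05,
    power=0.8) gives a total of 128 participants.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect size must be positive")
    # bracket by doubling, then binary search on per-group n
    lo, hi = 2, 4
    while two_sample_t_power(hi, effect_d, alpha) < power:
        hi *= 2
        if hi > max_n:
            raise ValueError("requested power unattainable within max_n")
    while lo < hi:
        mid = (lo + hi) // 2
        if two_sample_t_power(mid, effect_d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return 2 * lo
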