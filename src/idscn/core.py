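"""Individualized differential structural covariance networks (IDSCN).

The reference structural covariance network (rSCN) is the region x region
Pearson correlation matrix over a control group. For each patient a
perturbed network (pSCN) is recomputed over controls-plus-patient, and the
edge-wise difference is scored as

    Z = (pSCN - rSCN) / [(1 - rSCN^2) / (n - 1)]

with n the control count. Negative Z means weaker structural covariance in
the patient than in controls. Two-sided p-values use the standard normal
reference, Bonferroni-corrected over the M(M-1)/2 distinct edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ThicknessMatrix

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical row-major upper-triangle ordering of the M(M-1)/2 edges."""

    M: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.rows)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))

    def linear_index(self, i: int, j: int) -> int:
        """Linear position of edge (i, j), i != j, in canonical order."""
        i, j = (i, j) if i < j else (j, i)
        if not (0 <= i < j < self.M):
            raise IndexError(f"edge ({i}, {j}) out of range for M={self.M}")
        # row-major offset over the upper triangle
        return i * self.M - i * (i + 1) // 2 + (j - i - 1)

    def vectorize(self, matrix: np.ndarray) -> np.ndarray:
        """Extract the strict upper triangle of ``matrix`` in canonical order."""
        return np.asarray(matrix)[self.rows, self.cols]


def build_edge_index(M: int) -> EdgeIndex:
    if M < 2:
        raise ValueError(f"need at least 2 regions, got M={M}")
    rows, cols = np.triu_indices(M, k=1)
    return EdgeIndex(M=M, rows=rows, cols=cols)


@dataclass
class ReferenceSCN:
    """Control-group Pearson correlation network and the n it was built from."""

    corr: np.ndarray
    n: int
    region_labels: list[str] | None = None


def _pearson_matrix(values: np.ndarray, region_labels: list[str] | None) -> np.ndarray:
    sd = values.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = region_labels[j] if region_labels else f"column {j}"
        raise ValueError(f"constant region column: {name}")
    return np.corrcoef(values, rowvar=False)


def build_rscn(controls: ThicknessMatrix) -> ReferenceSCN:
    """Reference SCN: sample Pearson correlations over all control subjects."""
    if controls.n_subjects < 4:
        raise ValueError("need at least 4 control subjects for a reference SCN")
    corr = _pearson_matrix(controls.values, controls.region_labels)
    return ReferenceSCN(corr=corr, n=controls.n_subjects,
                        region_labels=list(controls.region_labels))


def perturbed_scn(controls: ThicknessMatrix, patient_row: np.ndarray) -> np.ndarray:
    """Pearson network over the n+1 group formed by controls plus one patient."""
    patient_row = np.asarray(patient_row, dtype=float).ravel()
    if patient_row.shape[0] != controls.n_regions:
        raise ValueError("patient row length does not match region count")
    stacked = np.vstack([controls.values, patient_row])
    return _pearson_matrix(stacked, controls.region_labels)


@dataclass
class IDSCNResult:
    """One patient's edge-wise deviation from the reference network."""

    patient_id: str
    z: np.ndarray            # (M, M) symmetric, diagonal 0
    p: np.ndarray            # (M, M) two-sided normal p, diagonal 1
    significant: set[tuple[int, int]]
    degenerate: set[tuple[int, int]] = field(default_factory=set)
    alpha: float = 0.05
    n_tests: int = 0


def idscn_z(
    rscn: ReferenceSCN,
    pscn: np.ndarray,
    patient_id: str = "",
    alpha: float = 0.05,
) -> IDSCNResult:
    """Score the perturbed network against the reference.

    Off-diagonal edges where |rSCN| = 1 have an undefined Z; they are flagged
    degenerate, excluded from the Bonferroni test count, and carry z=0, p=1.
    """
    r = np.asarray(rscn.corr, dtype=float)
    pscn = np.asarray(pscn, dtype=float)
    if pscn.shape != r.shape:
        raise ValueError("pSCN shape does not match reference SCN")
    if rscn.n < 4:
        raise ValueError("reference SCN built from fewer than 4 controls")
    M = r.shape[0]
    edge_index = build_edge_index(M)

    delta = pscn - r
    denom = (1.0 - r ** 2) / (rscn.n - 1)
    off = ~np.eye(M, dtype=bool)
    degenerate_mask = off & (denom == 0.0)
    z = np.zeros_like(r)
    ok = off & ~degenerate_mask
    z[ok] = delta[ok] / denom[ok]

    p = np.ones_like(r)
    p[ok] = np.clip(2.0 * stats.norm.sf(np.abs(z[ok])), _TINY_P, 1.0)

    degenerate = {
        (i, j) for i, j in edge_index.pairs if degenerate_mask[i, j]
    }
    n_tests = edge_index.n_edges - len(degenerate)
    result = IDSCNResult(
        patient_id=patient_id, z=z, p=p, significant=set(),
        degenerate=degenerate, alpha=alpha, n_tests=n_tests,
    )
    result.significant = significant_edges(result, alpha, n_tests)
    return result


def significant_edges(
    result: IDSCNResult, alpha: float, n_tests: int
) -> set[tuple[int, int]]:
    """Edges with p strictly below the Bonferroni threshold alpha/n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    threshold = alpha / n_tests
    M = result.z.shape[0]
    edge_index = build_edge_index(M)
    out = set()
    for i, j in edge_index.pairs:
        if (i, j) in result.degenerate:
            continue
        if result.p[i, j] < threshold:
            out.add((i, j))
    return out


def share_threshold(n_patients: int, share_fraction: float = 0.05) -> int:
    """Minimum patient count for a shared edge.

    Round-half-away-from-zero of fraction x n, floored at 2 (0.05 x 89 = 4.45
    rounds to 4).
    """
    import math

    return max(2, int(math.floor(share_fraction * n_patients + 0.5)))


@dataclass
class EdgeTally:
    """Per-edge counts of patients with a significant deviation."""

    edge_index: EdgeIndex
    counts: np.ndarray            # (n_edges,) int
    mean_abs_z: np.ndarray        # (n_edges,) float
    threshold: int
    top_edges: list[tuple[int, int]]


def tally_and_select(
    results: list[IDSCNResult],
    n_patients: int | None = None,
    share_fraction: float = 0.05,
) -> EdgeTally:
    """Tally significant edges across patients and select shared top edges.

    Top edges are those significant in at least ``share_threshold`` patients,
    sorted by descending count, ties broken by descending mean |z| across
    patients, then canonical edge order.
    """
    if not results:
        raise ValueError("need at least one IDSCN result")
    if n_patients is None:
        n_patients = len(results)
    M = results[0].z.shape[0]
    edge_index = build_edge_index(M)
    counts = np.zeros(edge_index.n_edges, dtype=int)
    abs_z = np.zeros(edge_index.n_edges, dtype=float)
    for res in results:
        for (i, j) in res.significant:
            counts[edge_index.linear_index(i, j)] += 1
        abs_z += np.abs(edge_index.vectorize(res.z))
    mean_abs_z = abs_z / len(results)

    m = share_threshold(n_patients, share_fraction)
    hits = np.flatnonzero(counts >= m)
    order = sorted(hits, key=lambda e: (-counts[e], -mean_abs_z[e], e))
    pairs = edge_index.pairs
    top = [pairs[e] for e in order]
    return EdgeTally(edge_index=edge_index, counts=counts, mean_abs_z=mean_abs_z,
                     threshold=m, top_edges=top)


def top_edges_by_count(tally: EdgeTally, n_top: int) -> list[tuple[int, int]]:
    """The n_top most frequently altered edges regardless of the share rule."""
    order = sorted(
        range(tally.edge_index.n_edges),
        key=lambda e: (-tally.counts[e], -tally.mean_abs_z[e], e),
    )[:n_top]
    pairs = tally.edge_index.pairs
    return [pairs[e] for e in order]


class IDSCN(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer from thickness rows to edge Z features.

    ``fit`` consumes the control-group thickness matrix; ``transform`` maps
    each patient row to the canonical upper-triangle vector of IDSCN
    Z-scores. Compatible with sklearn pipelines and model selection.

    Parameters
    ----------
    alpha : familywise level for the Bonferroni-corrected per-edge test.

    Attributes (after fit)
    ----------------------
    reference_ : ReferenceSCN over the controls.
    edge_index_ : canonical edge ordering.
    n_features_in_ : region count M.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 4:
            raise ValueError("need at least 4 control subjects")
        labels = getattr(self, "_region_labels", None)
        self.reference_ = ReferenceSCN(
            corr=_pearson_matrix(X, labels), n=X.shape[0], region_labels=labels
        )
        self._controls = X
        self.edge_index_ = build_edge_index(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def fit_thickness(self, controls: ThicknessMatrix) -> "IDSCN":
        self._region_labels = list(controls.region_labels)
        return self.fit(controls.values)

    def transform(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("region count differs from the fitted controls")
        out = np.empty((X.shape[0], self.edge_index_.n_edges))
        for k, row in enumerate(X):
            res = self.result_for(row)
            out[k] = self.edge_index_.vectorize(res.z)
        return out

    def result_for(self, patient_row, patient_id: str = "") -> IDSCNResult:
        """Full per-patient result (Z/p matrices, Bonferroni edge set)."""
        self._check_fitted()
        stacked = np.vstack([self._controls, np.asarray(patient_row, float).ravel()])
        pscn = _pearson_matrix(stacked, self.reference_.region_labels)
        return idscn_z(self.reference_, pscn, patient_id=patient_id, alpha=self.alpha)

    def results_for(self, patients: ThicknessMatrix) -> list[IDSCNResult]:
        return [
            self.result_for(row, patient_id=sid)
            for sid, row in zip(patients.subject_ids, patients.values)
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise RuntimeError("IDSCN transformer is not fitted")

    @staticmethod
    def _validate(X) -> np.ndarray:
        if isinstance(X, ThicknessMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("expected a finite 2-D subjects x regions matrix")
        return X
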