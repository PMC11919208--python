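"""Synthetic cohorts with known covariance structure and planted subtypes.

Controls are drawn from a multivariate normal with a user-chosen base
correlation matrix on a plausible cortical-thickness scale (mean 2.5 mm,
SD 0.25 mm). Each patient is drawn from the base covariance modified by its
latent subtype's edge-level correlation shifts; an optional per-subject
correlation jitter models idiosyncratic covariance heterogeneity. Symptom
scores couple linearly to the patient's standardized cross-product deviation
on designated edges, plus Gaussian noise, so every downstream stage of the
pipeline has a known ground truth.

Subject-specific covariance heterogeneity (``subject_corr_mix`` = w) draws
each patient from the convex mixture (1 - w) * C + w * S_k, where S_k is a
random rank-one sign correlation matrix (a subject-specific global covariance
mode with random regional polarity). The mixture is a valid correlation
matrix by construction, so the full perturbation strength survives without
any PSD re-projection; each edge is shifted by about +/- w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ClinicalTable, NetworkOverlapTable, TermActivationTable, ThicknessMatrix
from .io import CANONICAL_NETWORKS

Edge = tuple[int, int]


class SpecError(ValueError):
    """Raised when a cohort specification cannot define a valid generator."""


def block_correlation(
    M: int, n_blocks: int, r_within: float, r_between: float
) -> np.ndarray:
    """Block-constant correlation matrix with unit diagonal.

    Regions are split into ``n_blocks`` contiguous blocks of (near-)equal
    size with correlation ``r_within`` inside a block and ``r_between``
    across blocks. Raises :class:`SpecError` if the result is not positive
    semidefinite, reporting the offending eigenvalue.
    """
    if not (-1 < r_between <= r_within < 1):
        raise SpecError(
            f"require -1 < r_between <= r_within < 1, got {r_between}, {r_within}"
        )
    if not 1 <= n_blocks <= M:
        raise SpecError(f"n_blocks must be in [1, {M}]")
    corr = np.full((M, M), float(r_between))
    sizes = [M // n_blocks + (1 if b < M % n_blocks else 0) for b in range(n_blocks)]
    start = 0
    for size in sizes:
        corr[start:start + size, start:start + size] = r_within
        start += size
    np.fill_diagonal(corr, 1.0)
    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig < -1e-10:
        raise SpecError(f"parameters give a non-PSD matrix (eigenvalue {min_eig:.3g})")
    return corr


def nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to PSD (eigenvalue clipping) and rescale
    to unit diagonal."""
    corr = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(corr)
    if w[0] >= 0:
        return corr
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def apply_edge_deltas(base: np.ndarray, edges: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """Shift selected correlations, then project back to a valid correlation
    matrix if the shifts broke positive semidefiniteness."""
    corr = base.copy()
    for i, j, delta in edges:
        if i == j:
            raise SpecError(f"cannot perturb the diagonal ({i}, {i})")
        new = corr[i, j] + delta
        if not -1.0 <= new <= 1.0:
            raise SpecError(
                f"edge ({i}, {j}): correlation {corr[i, j]:.3f} + {delta:+.3f} "
                "leaves [-1, 1]"
            )
        corr[i, j] = corr[j, i] = new
    return nearest_psd_correlation(corr)


@dataclass
class CohortSpec:
    """Generator recipe for a paired control/patient cohort.

    Defaults mirror the study design the package targets: 89 controls and 89
    patients over 148 cortical regions, thickness scale 2.5 +/- 0.25 mm, and
    demographics drawn independently of subtype (so subtype contrasts on
    demographics are null).
    """

    n_controls: int = 89
    n_patients: int = 89
    n_regions: int = 148
    base_corr: np.ndarray | None = None
    n_blocks: int = 4
    r_within: float = 0.3
    r_between: float = 0.0
    region_mean: float = 2.5
    region_sd: float = 0.25
    subtype_fractions: tuple[float, ...] = (1.0,)
    perturbed_edges: tuple[tuple[tuple[int, int, float], ...], ...] = ((),)
    symptom_intercept: float = 63.6
    symptom_weights: dict[Edge, float] = field(default_factory=dict)
    symptom_noise_sd: float = 9.0
    subject_corr_mix: float = 0.0
    seed: int = 0

    def resolve_base_corr(self) -> np.ndarray:
        if self.base_corr is not None:
            corr = np.asarray(self.base_corr, dtype=float)
            if corr.shape != (self.n_regions, self.n_regions):
                raise SpecError("base_corr shape does not match n_regions")
            if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
                raise SpecError("base_corr must be symmetric with unit diagonal")
            if float(np.linalg.eigvalsh(corr)[0]) < -1e-10:
                raise SpecError("base_corr is not positive semidefinite")
            return corr
        return block_correlation(self.n_regions, self.n_blocks,
                                 self.r_within, self.r_between)

    def validate(self) -> None:
        if self.n_controls < 4 or self.n_patients < 1 or self.n_regions < 3:
            raise SpecError("cohort too small (need >=4 controls, >=1 patient, M>=3)")
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-9:
            raise SpecError("subtype fractions must sum to 1")
        if len(self.perturbed_edges) != len(self.subtype_fractions):
            raise SpecError("one perturbed-edge list required per subtype")
        base = self.resolve_base_corr()
        for edges in self.perturbed_edges:
            apply_edge_deltas(base, edges)  # raises on invalid deltas

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_controls": self.n_controls,
            "n_patients": self.n_patients,
            "n_regions": self.n_regions,
            "n_blocks": self.n_blocks,
            "r_within": self.r_within,
            "r_between": self.r_between,
            "region_mean": self.region_mean,
            "region_sd": self.region_sd,
            "subtype_fractions": list(self.subtype_fractions),
            "perturbed_edges": [
                [[int(i), int(j), float(dl)] for i, j, dl in edges]
                for edges in self.perturbed_edges
            ],
            "symptom_intercept": self.symptom_intercept,
            "symptom_weights": [
                [int(i), int(j), float(w)] for (i, j), w in self.symptom_weights.items()
            ],
            "symptom_noise_sd": self.symptom_noise_sd,
            "subject_corr_mix": self.subject_corr_mix,
            "seed": self.seed,
        }
        if self.base_corr is not None:
            d["base_corr"] = np.asarray(self.base_corr).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        base = d.pop("base_corr", None)
        weights = {(int(i), int(j)): float(w)
                   for i, j, w in d.pop("symptom_weights", [])}
        edges = tuple(
            tuple((int(i), int(j), float(dl)) for i, j, dl in group)
            for group in d.pop("perturbed_edges", [[]])
        )
        fractions = tuple(float(f) for f in d.pop("subtype_fractions", [1.0]))
        return cls(
            base_corr=None if base is None else np.asarray(base, dtype=float),
            subtype_fractions=fractions,
            perturbed_edges=edges,
            symptom_weights=weights,
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _subtype_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n patients over subtype fractions."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw])
    for k in range(rem):
        sizes[order[k]] += 1
    return sizes


def _draw(rng: np.random.Generator, corr: np.ndarray, n: int,
          mean: float, sd: float) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return mean + sd * (rng.standard_normal((n, corr.shape[0])) @ root)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ThicknessMatrix, ThicknessMatrix, ClinicalTable, np.ndarray]:
    """Draw a control and a patient thickness matrix plus clinical table.

    Returns ``(controls, patients, clinical, truth)`` where ``truth`` holds
    each patient's latent subtype index. Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M = spec.n_regions
    base = spec.resolve_base_corr()
    labels = [f"region_{k:03d}" for k in range(M)]

    controls = _draw(rng, base, spec.n_controls, spec.region_mean, spec.region_sd)

    sizes = _subtype_sizes(spec.n_patients, spec.subtype_fractions)
    truth = np.concatenate([np.full(sz, s, dtype=int) for s, sz in enumerate(sizes)])
    subtype_corr = [apply_edge_deltas(base, edges) for edges in spec.perturbed_edges]

    rows = np.empty((spec.n_patients, M))
    if spec.subject_corr_mix > 0:
        w = spec.subject_corr_mix
        if not w < 1:
            raise SpecError("subject_corr_mix must be in [0, 1)")
        for k in range(spec.n_patients):
            sign = np.sign(rng.standard_normal(M))
            sign[sign == 0] = 1.0
            corr_k = (1 - w) * subtype_corr[truth[k]] + w * np.outer(sign, sign)
            np.fill_diagonal(corr_k, 1.0)
            rows[k] = _draw(rng, corr_k, 1, spec.region_mean, spec.region_sd)
    else:
        start = 0
        for s, sz in enumerate(sizes):
            if sz:
                rows[start:start + sz] = _draw(
                    rng, subtype_corr[s], sz, spec.region_mean, spec.region_sd
                )
            start += sz

    # symptom scores: linear in standardized cross-product deviations on the
    # designated edges (deviation measured against the base correlation)
    std = (rows - spec.region_mean) / spec.region_sd
    signal = np.full(spec.n_patients, float(spec.symptom_intercept))
    for (i, j), w in spec.symptom_weights.items():
        signal += w * (std[:, i] * std[:, j] - base[i, j])
    noise = (rng.standard_normal(spec.n_patients) * spec.symptom_noise_sd
             if spec.symptom_noise_sd > 0 else 0.0)
    caps_patients = np.maximum(signal + noise, 0.0)

    ctrl_ids = [f"ctrl_{k:03d}" for k in range(spec.n_controls)]
    pat_ids = [f"pat_{k:03d}" for k in range(spec.n_patients)]
    controls_tm = ThicknessMatrix(ctrl_ids, labels, controls)
    patients_tm = ThicknessMatrix(pat_ids, labels, rows)

    clinical = _clinical_frame(rng, ctrl_ids, pat_ids, caps_patients)
    return controls_tm, patients_tm, clinical, truth


def _clinical_frame(rng: np.random.Generator, ctrl_ids: list[str],
                    pat_ids: list[str], caps_patients: np.ndarray) -> ClinicalTable:
    """Demographics matched between groups and independent of subtype."""
    n_c, n_p = len(ctrl_ids), len(pat_ids)
    n = n_c + n_p

    age = np.clip(rng.normal(43.0, 10.0, n), 18, 70)
    sex = np.where(rng.random(n) < 0.69, "female", "male")
    education = np.clip(rng.normal(7.0, 3.2, n), 0, 16)
    tst = np.clip(rng.normal(11.4, 2.4, n), 8, 15)
    caps_ctrl = np.clip(rng.normal(22.5, 11.0, n_c), 0, 48)
    pcl = np.concatenate([
        np.clip(rng.normal(28.0, 6.9, n_c), 17, 54),
        np.clip(rng.normal(47.5, 12.5, n_p), 21, 85),
    ])
    frame = pd.DataFrame({
        "subject_id": ctrl_ids + pat_ids,
        "group": ["control"] * n_c + ["patient"] * n_p,
        "caps": np.concatenate([caps_ctrl, caps_patients]),
        "pcl_c": pcl,
        "age": age,
        "sex": sex,
        "education": education,
        "time_since_trauma": tst,
    })
    return ClinicalTable(frame)


def synthetic_network_overlap(
    region_labels: Sequence[str],
    seed: int = 0,
    networks: Sequence[str] = CANONICAL_NETWORKS,
) -> NetworkOverlapTable:
    """A synthetic region->network partition: each region lies wholly in one
    canonical network, with random voxel sizes. Stands in for a Yeo-derived
    voxel-overlap table in tests and synthetic pipeline runs."""
    rng = np.random.default_rng(seed)
    m = len(region_labels)
    sizes = rng.integers(800, 5000, size=m).astype(float)
    assignment = rng.integers(0, len(networks), size=m)
    overlap = np.zeros((m, len(networks)))
    overlap[np.arange(m), assignment] = sizes
    return NetworkOverlapTable(list(region_labels), list(networks), overlap, sizes)


def synthetic_term_table(
    region_labels: Sequence[str],
    n_terms: int = 20,
    seed: int = 0,
    enriched: dict[str, tuple[Sequence[int], float]] | None = None,
) -> TermActivationTable:
    """Synthetic term x region activations (lognormal background).

    ``enriched`` maps a term name to ``(region indices, factor)`` multiplying
    its activation on those regions, for planting known enrichments.
    """
    rng = np.random.default_rng(seed)
    m = len(region_labels)
    names = [f"term_{t:02d}" for t in range(n_terms)]
    activation = rng.lognormal(mean=0.0, sigma=0.4, size=(n_terms, m))
    if enriched:
        for term, (regions, factor) in enriched.items():
            if term not in names:
                names[0] = term  # replace the first background term
            idx = names.index(term)
            activation[idx, list(regions)] *= factor
    return TermActivationTable(names, list(region_labels), activation)
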