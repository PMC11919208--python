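"""Single-config orchestration of the full analysis.

Stages run in order — IDSCN, heterogeneity, edge tally, symptom prediction,
subtyping, subtype contrasts, annotation — each writing TSV/JSON reports
into a run directory, plus a manifest (config hash, seed, versions,
per-stage wall time) and a structured log. A master seed deterministically
derives the seed of every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import relative_distribution, term_annotation
from .core import IDSCN, tally_and_select, top_edges_by_count
from .heterogeneity import compare_heterogeneity
from .io import (
    ClinicalTable,
    ThicknessMatrix,
    read_clinical_table,
    read_network_overlap,
    read_term_activation,
    read_thickness_table,
    write_clinical_table,
    write_thickness_table,
)
from .predict import nested_cv_predict
from .simulate import (
    CohortSpec,
    generate_cohort,
    synthetic_network_overlap,
    synthetic_term_table,
)
from .subtype import FeatureMatrix, WardSubtyper, contrast_subtypes

logger = logging.getLogger("idscn")

STAGES = ("data", "idscn", "heterogeneity", "tally", "predict", "subtype",
          "annotate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    mode: str = "synthetic"                 # "synthetic" | "files"
    seed: int = 0
    alpha: float = 0.05
    share_fraction: float = 0.05
    n_top_fallback: int = 32
    k_min: int = 2
    k_max: int = 6
    n_boot: int = 1000
    outer_folds: int = 10
    inner_folds: int = 10
    repeats: int = 10
    n_estimators: int = 500
    n_perm: int = 1000
    synthetic: CohortSpec | None = None
    controls_path: str | None = None
    patients_path: str | None = None
    clinical_path: str | None = None
    overlap_path: str | None = None
    terms_path: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synthetic", None)
        files = d.pop("files", {}) or {}
        cfg = cls(
            synthetic=CohortSpec.from_dict(synth) if synth else None,
            controls_path=files.get("controls"),
            patients_path=files.get("patients"),
            clinical_path=files.get("clinical"),
            overlap_path=d.pop("overlap", None),
            terms_path=d.pop("terms", None),
            **{k: v for k, v in d.items() if k in cls.__dataclass_fields__},
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        blob = json.dumps(self._canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _canonical(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k not in ("synthetic", "extra")}
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Collect all validation errors (empty list means valid)."""
    errors: list[str] = []
    if config.mode not in ("synthetic", "files"):
        errors.append(f"unknown mode {config.mode!r}")
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if not 0 < config.share_fraction < 1:
        errors.append("share_fraction must be in (0, 1)")
    if not 2 <= config.k_min <= config.k_max:
        errors.append("need 2 <= k_min <= k_max")
    if config.n_boot < 1:
        errors.append("n_boot must be >= 1")
    if config.n_perm < 100:
        errors.append("n_perm must be >= 100")
    if min(config.outer_folds, config.inner_folds, config.repeats) < 2:
        errors.append("outer_folds, inner_folds and repeats must be >= 2")

    n_patients = None
    if config.mode == "synthetic":
        if config.synthetic is None:
            errors.append("synthetic mode requires a cohort spec")
        else:
            try:
                config.synthetic.validate()
                n_patients = config.synthetic.n_patients
            except Exception as exc:  # noqa: BLE001 - collect, don't raise
                errors.append(f"invalid cohort spec: {exc}")
    else:
        for name in ("controls_path", "patients_path", "clinical_path"):
            path = getattr(config, name)
            if path is None:
                errors.append(f"files mode requires {name}")
            elif not Path(path).exists():
                errors.append(f"{name} does not exist: {path}")
    for name in ("overlap_path", "terms_path"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name} does not exist: {path}")
    if n_patients is not None and config.k_max >= n_patients:
        errors.append(
            f"k_max={config.k_max} must be below the patient count {n_patients}"
        )
    return errors


def _write_idscn_long(results, region_labels, path: Path) -> None:
    frames = []
    for res in results:
        iu = np.triu_indices(res.z.shape[0], k=1)
        frames.append(pd.DataFrame({
            "patient_id": res.patient_id,
            "region_i": [region_labels[i] for i in iu[0]],
            "region_j": [region_labels[j] for j in iu[1]],
            "z": res.z[iu],
            "p": res.p[iu],
            "significant": [(i, j) in res.significant
                            for i, j in zip(iu[0], iu[1])],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages, writing reports and a manifest into ``out_dir``."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    boot_seed, cv_seed, perm_seed = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds[:3]
    )

    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "outputs": [],
    }
    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            try:
                runner = globals()[f"_stage_{stage}"]
                runner(config, out, state,
                       boot_seed=boot_seed, cv_seed=cv_seed, perm_seed=perm_seed)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                manifest["failed_stage"] = stage
                raise StageError(stage, exc) from exc
            finally:
                manifest["stages"].append(
                    {"name": stage, "seconds": round(time.perf_counter() - t0, 3)}
                )
        manifest["outputs"] = sorted(
            p.name for p in out.iterdir() if p.suffix in (".tsv", ".json", ".yaml")
        )
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(handler)
        handler.close()
    return out


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "idscn": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }


def _stage_data(config: RunConfig, out: Path, state: dict, **_) -> None:
    if config.mode == "synthetic":
        controls, patients, clinical, truth = generate_cohort(config.synthetic)
        write_thickness_table(controls, out / "controls_thickness.tsv")
        write_thickness_table(patients, out / "patients_thickness.tsv")
        write_clinical_table(clinical, out / "clinical.tsv")
        pd.DataFrame({"patient_id": patients.subject_ids,
                      "subtype_truth": truth}).to_csv(
            out / "subtype_truth.tsv", sep="\t", index=False)
        state["truth"] = truth
    else:
        controls = read_thickness_table(config.controls_path)
        patients = read_thickness_table(config.patients_path)
        clinical = read_clinical_table(config.clinical_path)
    state.update(controls=controls, patients=patients, clinical=clinical)


def _stage_idscn(config: RunConfig, out: Path, state: dict, **_) -> None:
    model = IDSCN(alpha=config.alpha).fit_thickness(state["controls"])
    results = model.results_for(state["patients"])
    _write_idscn_long(results, state["controls"].region_labels,
                      out / "idscn_edges.tsv")
    state.update(model=model, results=results)


def _stage_heterogeneity(config: RunConfig, out: Path, state: dict, **_) -> None:
    het = compare_heterogeneity(state["patients"], state["controls"])
    pd.DataFrame({
        "subject_id": state["patients"].subject_ids + state["controls"].subject_ids,
        "group": (["patient"] * len(het.distances_a)
                  + ["control"] * len(het.distances_b)),
        "distance": np.concatenate([het.distances_a, het.distances_b]),
    }).to_csv(out / "heterogeneity_distances.tsv", sep="\t", index=False)
    (out / "heterogeneity.json").write_text(json.dumps(het.to_dict(), indent=2))
    state["heterogeneity"] = het


def _stage_tally(config: RunConfig, out: Path, state: dict, **_) -> None:
    results = state["results"]
    tally = tally_and_select(results, n_patients=len(results),
                             share_fraction=config.share_fraction)
    labels = state["controls"].region_labels
    order = np.argsort(-tally.counts, kind="stable")
    nz = order[tally.counts[order] > 0]
    pairs = tally.edge_index.pairs
    pd.DataFrame({
        "region_i": [labels[pairs[e][0]] for e in nz],
        "region_j": [labels[pairs[e][1]] for e in nz],
        "n_patients": tally.counts[nz],
        "mean_abs_z": tally.mean_abs_z[nz],
    }).to_csv(out / "edge_tally.tsv", sep="\t", index=False)

    top = tally.top_edges
    if not top:
        logger.info("no edge met the >=%d-patient share rule; falling back to "
                    "the %d most frequently altered edges",
                    tally.threshold, config.n_top_fallback)
        top = top_edges_by_count(tally, config.n_top_fallback)
    state.update(tally=tally, top_edges=top)
    z = np.array([[res.z[i, j] for i, j in top] for res in results])
    state["features"] = FeatureMatrix(
        patient_ids=list(state["patients"].subject_ids),
        edge_list=top, values=z,
    )


def _stage_predict(config: RunConfig, out: Path, state: dict, *, cv_seed, **_) -> None:
    features = state["features"]
    clinical = state["clinical"]
    caps = clinical.frame.set_index("subject_id").loc[
        features.patient_ids, "caps"].to_numpy(dtype=float)
    report = nested_cv_predict(
        features.values, caps,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        repeats=config.repeats, seed=cv_seed,
        n_estimators=config.n_estimators,
    )
    pd.DataFrame({
        "patient_id": features.patient_ids,
        "observed": report.observed,
        "predicted": report.predicted,
    }).to_csv(out / "predictions.tsv", sep="\t", index=False)
    (out / "prediction_metrics.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    state["prediction"] = report


def _stage_subtype(config: RunConfig, out: Path, state: dict, *, boot_seed, **_) -> None:
    features = state["features"]
    subtyper = WardSubtyper(k_min=config.k_min, k_max=config.k_max,
                            n_boot=config.n_boot, random_state=boot_seed)
    subtyper.fit(features.values)
    solution = subtyper.solution()
    pd.DataFrame({
        "patient_id": features.patient_ids,
        "subtype": solution.labels,
    }).to_csv(out / "subtypes.tsv", sep="\t", index=False)
    (out / "subtype_solution.json").write_text(
        json.dumps(solution.to_dict(), indent=2))

    sizes = [int(np.sum(solution.labels == c)) for c in range(1, solution.k + 1)]
    if solution.k == 2 and min(sizes) >= 2:
        contrasts = contrast_subtypes(features, solution.labels,
                                      state["clinical"], alpha=config.alpha)
        contrasts.edge_table.to_csv(out / "subtype_edge_contrasts.tsv",
                                    sep="\t", index=False)
        contrasts.clinical_table.to_csv(out / "subtype_clinical_contrasts.tsv",
                                        sep="\t", index=False)
        contrasts.interaction_table.to_csv(out / "subtype_sex_interaction.tsv",
                                           sep="\t", index=False)
        state["contrasts"] = contrasts
    else:
        logger.info("contrasts skipped: need k=2 with >=2 members per subtype "
                    "(k=%d, sizes=%s)", solution.k, sizes)
    state["subtypes"] = solution


def _stage_annotate(config: RunConfig, out: Path, state: dict, *, perm_seed, **_) -> None:
    labels = state["controls"].region_labels
    if config.overlap_path:
        overlap = read_network_overlap(config.overlap_path)
    elif config.mode == "synthetic":
        overlap = synthetic_network_overlap(labels, seed=config.seed)
    else:
        logger.info("no overlap table supplied; annotation skipped")
        return
    if config.terms_path:
        terms = read_term_activation(config.terms_path)
    elif config.mode == "synthetic":
        terms = synthetic_term_table(labels, seed=config.seed)
    else:
        terms = None

    edges = state["top_edges"]
    rd = relative_distribution(edges, overlap, region_labels=labels)
    rd.rename_axis("network").reset_index().to_csv(
        out / "network_distribution.tsv", sep="\t", index=False)
    state["rd"] = rd
    if terms is not None:
        ann = term_annotation(edges, terms, n_perm=config.n_perm,
                              seed=perm_seed, alpha=config.alpha,
                              region_labels=labels)
        ann.table.to_csv(out / "term_annotation.tsv", sep="\t", index=False)
        state["terms"] = ann
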