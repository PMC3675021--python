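"""End-to-end orchestration: simulate/load → preprocess → outlier screen →
PCA → PLS-DA (+ permutation validation) → OPLS-DA → discriminant table.

A run is fully determined by a :class:`RunConfig` (serializable to YAML)
plus its seed: one global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so individual stages
can be rerun reproducibly.  Scaling follows biofluid convention: PCA on
mean-centered data; PLS-DA unit-variance scaled for serum and
mean-centered for urine; OPLS-DA unit-variance scaled for both.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .cohort import CohortConfig, CohortDataset, build_library, simulate_cohort
from .chemometrics import (
    Q2_ACCEPTABLE,
    autofit_components,
    cross_validated_q2,
    fit_opls,
    fit_pca,
    fit_pls,
)
from .interpretation import (
    DEFAULT_ASSIGN_TOLERANCE,
    assign_ppm,
    backscaled_profile,
    critical_r,
    discriminant_table,
)
from .preprocess import (
    DEFAULT_SCHEME_BY_FLUID,
    BucketTable,
    ScaledMatrix,
    assemble_matrix,
    get_scheme,
)
from .validation import classification_metrics, permutation_test, remove_outliers
from . import io as _io

__all__ = ["RunConfig", "RunReport", "PipelineStageError", "run_pipeline", "child_seed"]

PLS_SCALE_BY_FLUID = {"serum": "unit_variance", "urine": "mean_center"}
OPLS_SCALE = "unit_variance"

# stage indices for seed fan-out
_STAGE_SIMULATE, _STAGE_FOLDS, _STAGE_PERMUTATION = 0, 1, 2


class PipelineStageError(RuntimeError):
    """Failure wrapped with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def child_seed(seed: int, stage: int) -> int:
    """Derive a per-stage seed (< 2**31) from the global run seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    fluid: str
    scheme: str | None = None  # defaults to the fluid's standard scheme
    # simulation settings (used when no manifest is given)
    n_copd: int = 32
    n_control: int = 21
    points: int = 32768
    noise_sd: float = 5.0
    shift_jitter_sd: float = 0.001
    baseline_amplitude: float = 0.0
    effect_magnitude: float = 0.5
    # modeling
    autofit: bool = True
    n_components: int | None = None  # fixed PLS component count when autofit is off
    a_max: int = 5
    min_gain: float = 0.02
    k_folds: int = 10
    n_perm: int = 100
    alpha: float = 0.05
    # outlier screening
    outlier_alpha: float = 0.05
    outlier_components: int = 2
    # interpretation cutoff: "critical_r" or a fixed |r| value
    cutoff_policy: str | float = "critical_r"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = DEFAULT_SCHEME_BY_FLUID.get(self.fluid)
        if not self.autofit and self.n_components is None:
            raise ValueError("n_components required when autofit is off")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured record of one run; identical config+seed reproduces it
    byte for byte."""

    config: dict
    config_hash: str
    version: str
    n_samples: dict
    n_buckets: int
    outliers_removed: list
    pca: dict
    pls: dict
    opls: dict
    metrics: dict
    permutation: dict
    cutoff: float
    discriminants: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    def to_text(self) -> str:
        m = self.metrics
        lines = [
            f"metabopls run report (version {self.version}, config {self.config_hash})",
            f"fluid: {self.config['fluid']}   seed: {self.config['seed']}",
            f"samples: {self.n_samples['copd']} COPD vs {self.n_samples['control']} control"
            f" ({self.n_samples['total']} modeled; removed: {self.outliers_removed or 'none'})",
            f"buckets retained: {self.n_buckets}",
            "",
            f"PCA (2 comp, mean-centered): R2X = {self.pca['cumulative_r2x']:.3f}",
            f"PLS-DA  ({self.pls['n_components']} comp, {self.pls['scale']}): "
            f"R2X = {self.pls['r2x']:.3f}  R2Y = {self.pls['r2y']:.3f}  "
            f"Q2 = {self.pls['q2']:.3f}"
            f" ({'acceptable' if self.pls['q2_acceptable'] else 'below 0.1'})",
            f"OPLS-DA (1+{self.opls['n_ortho']} comp, {self.opls['scale']}): "
            f"R2X = {self.opls['r2x']:.3f}  Q2 = {self.opls['q2']:.3f}",
            "",
            "classification (out-of-fold PLS-DA predictions):",
            f"  COPD (n = {self.n_samples['copd']}) vs Control (n = {self.n_samples['control']})",
            f"  sensitivity {m['sensitivity']:.2f}%  specificity {m['specificity']:.2f}%  "
            f"classification rate {m['classification_rate']:.2f}%",
            "",
            f"permutation test ({self.permutation['n_perm']} permutations): "
            f"p = {self.permutation['p_value']:.4f}  "
            f"Q2 intercept = {self.permutation['q2_intercept']:.3f}  "
            f"R2Y intercept = {self.permutation['r2y_intercept']:.3f}  "
            f"valid = {self.permutation['valid']}",
            "",
            f"discriminant metabolites (|r| > {self.cutoff:.3f}):",
        ]
        if self.discriminants:
            for row in self.discriminants:
                lines.append(
                    f"  {row['metabolite']:<28s} {row['shifts']:<42s} "
                    f"r = {row['r']:+.3f}  {row['direction']}"
                )
        else:
            lines.append("  (none passed the cutoff)")
        return "\n".join(lines) + "\n"


def _y_from_groups(groups: list[str]) -> np.ndarray:
    return np.array([1.0 if g == "control" else -1.0 for g in groups])


def run_pipeline(
    config: RunConfig,
    manifest=None,
    outdir: str | None = None,
) -> RunReport:
    """Execute the full analysis; returns the report and, when ``outdir``
    is given, writes every intermediate artifact there."""

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, str(exc)) from exc
                return False

        return _Ctx()

    if outdir:
        os.makedirs(outdir, exist_ok=True)

    # --- stage: input -----------------------------------------------------
    with _stage("simulate" if manifest is None else "load"):
        if manifest is None:
            cc = CohortConfig(
                fluid=config.fluid,
                n_copd=config.n_copd,
                n_control=config.n_control,
                points=config.points,
                noise_sd=config.noise_sd,
                shift_jitter_sd=config.shift_jitter_sd,
                baseline_amplitude=config.baseline_amplitude,
                seed=child_seed(config.seed, _STAGE_SIMULATE),
            )
            library = build_library(config.fluid, config.effect_magnitude)
            dataset = simulate_cohort(cc, library)
            spectra = dataset.spectra
        else:
            if isinstance(manifest, (str, os.PathLike)):
                manifest = _io.read_manifest(manifest)
            spectra = manifest

    # --- stage: preprocess ------------------------------------------------
    with _stage("preprocess"):
        scheme = get_scheme(config.scheme)
        table = assemble_matrix(spectra, scheme)
        if outdir:
            _io.write_bucket_table(table, os.path.join(outdir, "bucket_table.tsv"))

    # --- stage: outlier screen -------------------------------------------
    with _stage("outlier_screen"):
        table, removed = remove_outliers(
            table, config.outlier_components, config.outlier_alpha
        )

    y = _y_from_groups(table.groups)
    n = table.n_samples
    fold_seed = child_seed(config.seed, _STAGE_FOLDS)
    pls_scale = PLS_SCALE_BY_FLUID[config.fluid]

    # --- stage: pca -------------------------------------------------------
    with _stage("pca"):
        A_pca = min(2, n - 1, table.matrix.shape[1])
        pca = fit_pca(ScaledMatrix.fit(table.matrix, "mean_center").values, A_pca)
        pca_block = {
            "n_components": A_pca,
            "explained_fraction": [float(v) for v in pca.explained_fraction],
            "cumulative_r2x": float(pca.cumulative_r2x[-1]),
        }

    # --- stage: pls -------------------------------------------------------
    with _stage("pls"):
        if config.autofit:
            A, _q2_path = autofit_components(
                table.matrix, y, k_folds=config.k_folds, seed=fold_seed,
                scale_method=pls_scale, a_max=config.a_max, min_gain=config.min_gain,
            )
        else:
            A = int(config.n_components)
        pls = fit_pls(ScaledMatrix.fit(table.matrix, pls_scale).values, y, A)
        q2, yhat_oof = cross_validated_q2(
            table.matrix, y, "pls", A, k_folds=config.k_folds, seed=fold_seed,
            scale_method=pls_scale,
        )
        counts, metrics = classification_metrics(y, yhat_oof)
        pls_block = {
            "n_components": A,
            "scale": pls_scale,
            "r2x": float(pls.r2x),
            "r2y": float(pls.r2y),
            "q2": float(q2),
            "q2_acceptable": bool(q2 > Q2_ACCEPTABLE),
        }
        metrics_block = {
            "tp": counts.tp, "fn": counts.fn, "tn": counts.tn, "fp": counts.fp,
            "sensitivity": float(metrics.sensitivity),
            "specificity": float(metrics.specificity),
            "classification_rate": float(metrics.classification_rate),
        }

    # --- stage: permutation ----------------------------------------------
    with _stage("permutation"):
        perm = permutation_test(
            table.matrix, y, "pls", A, n_perm=config.n_perm, k_folds=config.k_folds,
            seed=child_seed(config.seed, _STAGE_PERMUTATION), scale_method=pls_scale,
        )
        perm_block = {
            "n_perm": perm.n_perm,
            "p_value": float(perm.p_value),
            "q2_intercept": float(perm.q2_intercept),
            "r2y_intercept": float(perm.r2y_intercept),
            "valid": bool(perm.valid),
        }
        if outdir:
            with open(os.path.join(outdir, "permutation.tsv"), "w") as fh:
                fh.write("abs_corr\tr2y\tq2\n")
                for c, r2, q in zip(perm.correlations, perm.r2y, perm.q2):
                    fh.write(f"{c:.6f}\t{r2:.6f}\t{q:.6f}\n")

    # --- stage: opls ------------------------------------------------------
    with _stage("opls"):
        n_ortho = max(A - 1, 0)
        opls = fit_opls(ScaledMatrix.fit(table.matrix, OPLS_SCALE).values, y, n_ortho)
        opls_q2, _ = cross_validated_q2(
            table.matrix, y, "opls", n_ortho, k_folds=config.k_folds, seed=fold_seed,
            scale_method=OPLS_SCALE,
        )
        opls_block = {
            "n_ortho": n_ortho,
            "scale": OPLS_SCALE,
            "r2x": float(opls.r2x),
            "r2x_pred": float(opls.r2x_pred),
            "r2x_orth": float(opls.r2x_orth),
            "r2y": float(opls.r2y),
            "q2": float(opls_q2),
        }

    # --- stage: interpret -------------------------------------------------
    with _stage("interpret"):
        profile = backscaled_profile(opls, table)
        if config.cutoff_policy == "critical_r":
            cutoff = critical_r(n, config.alpha)
        else:
            cutoff = float(config.cutoff_policy)
        assignments = assign_ppm(profile.bucket_centers, config.fluid)
        disc = discriminant_table(profile, assignments, cutoff)
        if outdir:
            disc.to_csv(os.path.join(outdir, "discriminant_table.tsv"),
                        sep="\t", index=False, float_format="%.4f")

    report = RunReport(
        config=config.to_dict(),
        config_hash=config.content_hash(),
        version=__version__,
        n_samples={
            "copd": int(sum(g == "copd" for g in table.groups)),
            "control": int(sum(g == "control" for g in table.groups)),
            "total": n,
        },
        n_buckets=int(table.matrix.shape[1]),
        outliers_removed=removed,
        pca=pca_block,
        pls=pls_block,
        opls=opls_block,
        metrics=metrics_block,
        permutation=perm_block,
        cutoff=float(cutoff),
        discriminants=disc.to_dict(orient="records"),
    )
    if outdir:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(report.to_text())
    return report
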