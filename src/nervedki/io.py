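"""File IO, configuration, and the end-to-end pipeline.

Formats: 4-D NIfTI for diffusion-weighted images, 3-D NIfTI for masks and
scalar maps, FSL-style .bval/.bvec gradient tables, CSV for slice records
and statistics, JSON for the trained boundary, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gradients import B0_THRESHOLD, GradientScheme, read_bval_bvec
from .slicewise import SLICE_SCHEMA_VERSION

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_dwi",
    "save_nifti",
    "write_slice_records",
    "read_slice_records",
    "write_boundary",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults mirror the study design."""

    out_dir: str = "nervedki_out"
    seed: int = 0
    # inputs: either a DWI volume to fit, or a simulated tabular study
    dwi_path: str | None = None
    bval_path: str | None = None
    bvec_path: str | None = None
    mask_path: str | None = None
    simulate: bool = True
    # gradient scheme (used for simulation)
    n_directions: int = 20
    bvalues: list = field(default_factory=lambda: [2000.0, 4000.0])
    n_b0: int = 1
    # fit options
    wlls_passes: int = 2
    log_floor_frac: float = 1e-6
    n_radial: int = 64
    n_sphere: int = 256
    # outlier filter switches
    filter_before_training: bool = True
    filter_before_correlation: bool = True
    # classifier
    svm_cost: float = 1e6
    n_boot: int = 1000
    training_week: int = 4
    call_threshold: float = 0.5
    # stats
    equal_var: bool = False
    stats_parameters: list = field(
        default_factory=lambda: ["fa", "md", "ad", "rd", "mk", "ak", "rk"]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def read_dwi(dwi_path, bval_path, bvec_path):
    """Load a 4-D NIfTI with its FSL gradient tables into an image array
    and a GradientScheme.

    b=0 is detected by b < 50 s/mm^2; slightly off-unit b-vectors
    (|norm - 1| < 1e-3) are renormalized, larger deviations are an error.
    """
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected 4-D DWI, got {data.ndim}-D")
    bvals, bvecs = read_bval_bvec(bval_path, bvec_path)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"volume/gradient count mismatch: {data.shape[3]} vs {bvals.size}"
        )
    nonzero = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs[nonzero], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3 * (1 + 1e-6)):
        raise ValueError("b-vector norms deviate from 1 by more than 1e-3")
    bvecs = bvecs.copy()
    bvecs[nonzero] /= norms[:, None]
    bvecs[~nonzero] = 0.0
    scheme = GradientScheme(bvalues=bvals, directions=bvecs)
    return data, scheme, img.affine


def save_nifti(data: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def write_slice_records(records: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nervedki slice records schema v{SLICE_SCHEMA_VERSION}\n")
        records.to_csv(fh, index=False, float_format="%.10g")


def read_slice_records(path) -> pd.DataFrame:
    path = Path(path)
    header = path.open().readline()
    if not header.startswith("#") or "schema" not in header:
        raise ValueError(f"{path}: missing schema header")
    version = int(header.rstrip().rsplit("v", 1)[-1])
    if version != SLICE_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported slice-record schema v{version} "
            f"(expected v{SLICE_SCHEMA_VERSION})"
        )
    return pd.read_csv(path, comment="#")


def write_boundary(boundary, fa_thr, fa_sd, config, path) -> None:
    payload = {
        "slope": boundary.slope,
        "intercept": boundary.intercept,
        "slope_sd": boundary.slope_sd,
        "intercept_sd": boundary.intercept_sd,
        "w": list(map(float, boundary.w)),
        "offset": boundary.offset,
        "cost": boundary.cost,
        "seed": config.seed,
        "fa_threshold": fa_thr,
        "fa_threshold_sd": fa_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write every artifact to ``out_dir``.

    Stage order: fit (only when DWI inputs are configured) -> aggregate /
    simulate -> outlier filter -> train boundary at the training week ->
    classify all records -> group statistics.  Reruns with identical
    config and seed are bit-identical for all CSV/JSON outputs.
    """
    from . import classifier, stats, synthetic
    from .slicewise import filter_outliers

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "nervedki",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    def stage(name: str, status: str = "ok", **info):
        manifest["stages"].append({"stage": name, "status": status, **info})

    try:
        behavior = histology = None
        if config.dwi_path is not None:
            from .dki import fit_volume
            from .slicewise import aggregate_slices, label_slices

            image, scheme, _ = read_dwi(
                config.dwi_path, config.bval_path, config.bvec_path
            )
            mask = np.asarray(
                nib.load(str(config.mask_path)).dataobj
            ).astype(bool)
            maps = fit_volume(
                image, mask, scheme,
                n_radial=config.n_radial, n_sphere=config.n_sphere,
            )
            stage("fit", n_voxels=int(mask.sum()))
            labels = label_slices(mask.shape[2], 0, 0)
            records = aggregate_slices(maps, mask, labels)
            stage("aggregate", n_records=len(records))
        elif config.simulate:
            stage("fit", status="skipped", reason="tabular simulated study")
            study = synthetic.simulate_study(
                synthetic.StudyConfig(seed=config.seed)
            )
            records = study.records
            behavior, histology = study.behavior, study.histology
            behavior.to_csv(out / "behavior.csv", index=False)
            histology.to_csv(out / "histology.csv", index=False)
            study.ground_truth.to_csv(out / "ground_truth.csv", index=False)
            stage("aggregate", n_records=len(records), source="simulated")
        else:
            raise ValueError("config names neither DWI inputs nor simulation")
        write_slice_records(records, out / "slice_records.csv")

        kept, excluded = filter_outliers(records)
        excluded.to_csv(out / "excluded_records.csv", index=False)
        stage("filter", n_kept=len(kept), n_excluded=len(excluded))

        train_records = kept if config.filter_before_training else records
        boundary, platt, samples = classifier.train_from_records(
            train_records,
            cost=config.svm_cost,
            n_boot=config.n_boot,
            seed=config.seed,
            week=config.training_week,
        )
        fa_thr, fa_sd = classifier.fa_threshold(boundary, samples)
        logger.info(
            "FA threshold %.4f ignores the fitted intercept %.4f "
            "(zero-offset reduction)", fa_thr, boundary.intercept,
        )
        write_boundary(boundary, fa_thr, fa_sd, config, out / "boundary.json")
        stage("train", slope=boundary.slope, intercept=boundary.intercept,
              fa_threshold=fa_thr)

        assessments, nerve_summary = classifier.classify_study(
            records, boundary, platt, call_threshold=config.call_threshold
        )
        assessments.to_csv(out / "assessments.csv", index=False)
        nerve_summary.to_csv(out / "nerve_summary.csv", index=False)
        stage("classify", n_assessed=len(assessments))

        stats_input = kept if config.filter_before_correlation else records
        tests = stats.pairwise_ttests(
            stats_input, config.stats_parameters, equal_var=config.equal_var
        )
        tests.to_csv(out / "tests.csv", index=False)
        corr_rows = []
        if histology is not None:
            for name, res in stats.correlate_scalars_histology(
                stats_input, histology,
                apply_outlier_filter=config.filter_before_correlation,
            ).items():
                corr_rows.append({
                    "x": res.x_name, "y": res.y_name, "r": res.r,
                    "p": res.p, "n": res.n,
                })
        if behavior is not None:
            for name, res in stats.correlate_probability_behavior(
                nerve_summary, behavior
            ).items():
                corr_rows.append({
                    "x": res.x_name, "y": res.y_name, "r": res.r,
                    "p": res.p, "n": res.n,
                })
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
        stage("stats", n_tests=len(tests), n_correlations=len(corr_rows))
    except Exception as err:
        (out / "failed").write_text(
            f"pipeline halted at stage "
            f"{len(manifest['stages'])}: {err}\n"
        )
        manifest["failed"] = str(err)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
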