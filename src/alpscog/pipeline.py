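"""Run orchestration: subject-level feature extraction and cohort-level
statistics, with provenance and report artifacts."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alps import ALPSConfig, ROILocalizationError, subject_alps
from .cohort import CohortResults, CohortStudy, StatsConfig
from .dwi import load_dwi, load_volume
from .features import VolumetricsInput, lesion_metrics, normalize_volumes, wm_mask_stats
from .tensor import fit_tensor, tensor_scalars


@dataclass
class RunConfig:
    """One reproducible run: inputs, ALPS parameters, statistics knobs."""

    cohort_csv: str | None = None
    manifest: list[dict] = field(default_factory=list)
    band_y: tuple[int, int] | None = None  # inclusive voxel index range
    band_z: tuple[int, int] | None = None
    alps: ALPSConfig = field(default_factory=ALPSConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "alpscog_run"
    seed: int = 0
    fa_threshold: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        alps = ALPSConfig(**raw.pop("alps", {}))
        stats = StatsConfig(**raw.pop("stats", {}))
        return cls(alps=alps, stats=stats, **raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_subject(entry: dict, config: RunConfig) -> dict:
    """Extract the imaging features of one subject.

    ``entry`` maps input names to paths: ``dwi`` (NIfTI, with bval/bvec
    siblings or explicit ``bval``/``bvec`` keys), optional ``lesion_mask``
    (binary NIfTI) and optional volumetrics (``csfv``/``gmv``/``wmv``/
    ``tiv``/``cth`` numbers). Any failing stage marks the record failed
    with a stage-labeled reason; the run continues with other subjects.
    """
    rec: dict = {"id": entry.get("id", "unknown"), "failed": False, "qc": []}
    stage = "input"
    try:
        if "dwi" not in entry:
            raise ValueError("no DWI input in manifest entry")
        dwi = load_dwi(entry["dwi"], entry.get("bval"), entry.get("bvec"))
        stage = "tensor_fit"
        tensors = fit_tensor(dwi)
        stage = "scalars"
        fa, md, ad, rd = tensor_scalars(tensors)
        stage = "alps"
        if config.band_y is None or config.band_z is None:
            raise ValueError("search band (band_y, band_z) required")
        band = (
            np.arange(config.band_y[0], config.band_y[1] + 1),
            np.arange(config.band_z[0], config.band_z[1] + 1),
        )
        alps_res = subject_alps(tensors, fa, band, config.alps)
        rec["alps"] = alps_res.bilateral_alps
        rec["alps_left"] = alps_res.left.alps
        rec["alps_right"] = alps_res.right.alps
        rec["qc"].extend(alps_res.qc_flags)
        stage = "wm_stats"
        wm = wm_mask_stats(fa, md, ad, rd, config.fa_threshold)
        rec.update(wm)
        stage = "lesions"
        if "lesion_mask" in entry:
            mask, vs = load_volume(entry["lesion_mask"])
            lm = lesion_metrics(mask > 0.5, vs)
            rec["wmlv"] = lm.wmlv_ml
            rec["wmln"] = lm.wmln
        else:
            rec["qc"].append("no lesion mask provided")
        stage = "volumetrics"
        if all(k in entry for k in ("csfv", "gmv", "wmv", "tiv")):
            v = VolumetricsInput(
                entry["csfv"], entry["gmv"], entry["wmv"], entry["tiv"], entry.get("cth")
            )
            rec["ncsfv"], rec["ngmv"], rec["nwmv"] = normalize_volumes(v)
            rec["qc"].extend(v.flags)
            if entry.get("cth") is not None:
                rec["cth"] = entry["cth"]
            rec["tiv"] = entry["tiv"]
    except (ValueError, ROILocalizationError, OSError) as err:
        rec["failed"] = True
        rec["failure_stage"] = stage
        rec["failure_reason"] = str(err)
    return rec


@dataclass
class RunReport:
    """Cohort report with provenance."""

    features: pd.DataFrame | None
    results: CohortResults | None
    excluded: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.features is not None:
            self.features.to_csv(out / "features.tsv", sep="\t", index=False)
        if self.results is not None:
            r = self.results
            r.group_comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
            r.spearman_rho.to_csv(out / "spearman_rho.tsv", sep="\t")
            r.spearman_p.to_csv(out / "spearman_p.tsv", sep="\t")
            if r.adjusted_models:
                pd.concat(
                    {k: m.terms for k, m in r.adjusted_models.items()}, names=["outcome"]
                ).to_csv(out / "adjusted_models.tsv", sep="\t")
            if r.stepwise is not None:
                r.stepwise.params.to_csv(out / "stepwise.tsv", sep="\t")
            (out / "summary.txt").write_text(r.summary() + "\n")
        self.excluded.to_csv(out / "excluded.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out


def run_cohort(table: pd.DataFrame, config: RunConfig) -> RunReport:
    """Cohort statistics over a complete feature table (schema-validated),
    written to ``config.output_dir``."""
    study = CohortStudy(table, config.stats)
    results = study.fit()
    provenance = {
        "package": "alpscog",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_rows": len(table),
    }
    report = RunReport(
        features=None,
        results=results,
        excluded=pd.DataFrame(columns=["id", "failure_stage", "failure_reason"]),
        provenance=provenance,
    )
    report.write(config.output_dir)
    return report


def run(config: RunConfig) -> RunReport:
    """Full run: per-subject imaging extraction (when a manifest is given),
    merge into the cohort table, then cohort statistics."""
    features = None
    excluded = pd.DataFrame(columns=["id", "failure_stage", "failure_reason"])
    table = pd.read_csv(config.cohort_csv) if config.cohort_csv else None
    if config.manifest:
        recs = [run_subject(e, config) for e in config.manifest]
        features = pd.DataFrame(recs)
        failed = features[features["failed"]]
        excluded = failed.loc[:, ["id", "failure_stage", "failure_reason"]]
        good = features[~features["failed"]].drop(
            columns=["failed", "failure_stage", "failure_reason", "qc"], errors="ignore"
        )
        if table is not None:
            table = table.merge(good, on="id", how="left", suffixes=("", "_img"))
    report = RunReport(features=features, results=None, excluded=excluded, provenance={})
    if table is not None:
        cohort_report = run_cohort(table, config)
        report.results = cohort_report.results
        report.provenance = cohort_report.provenance
        report.features = features
        report.write(config.output_dir)
    return report
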