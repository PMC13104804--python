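"""End-to-end orchestration: simulate -> preprocess -> benchmark -> discover -> audit.

A RunConfig is fully serializable (YAML/JSON); a persisted config re-runs to
byte-identical artifacts because every source of randomness derives from the
seeds it records.  Artifacts are plain CSV (UTF-8, comma, dot decimal) and
JSON; scores print with 4 decimals, percentages with 2.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import BUILTIN, load_region_atlas
from .audit import audit_regions, bootstrap_profiles, dunn_posthoc
from .benchmark import CVResult, ModelSpec, default_specs, run_cv_benchmark
from .preprocess import atrophy_percentage, compute_csii, make_stratified_folds
from .scoring import AnchorSet, compute_iit_components, select_anchors
from .simulate import GeneratorConfig, simulate_cohorts

__all__ = ["RunConfig", "run_full_pipeline", "write_report_tables"]

logger = logging.getLogger("iit")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    atlas_path: str = BUILTIN
    k_folds: int = 5
    fold_seeds: list[int] = field(default_factory=lambda: list(range(10)))
    include_sex: bool = True
    model_overrides: dict = field(default_factory=dict)  # family -> {fixed, grid}
    k_anchors: int = 10
    normalize_borda: bool = False
    alpha: float = 0.05
    bootstrap_r: int = 10
    run_benchmark: bool = True

    def specs(self) -> list[ModelSpec]:
        out = []
        for spec in default_specs():
            o = self.model_overrides.get(spec.family, {})
            out.append(
                ModelSpec(
                    family=spec.family,
                    fixed={**spec.fixed, **o.get("fixed", {})},
                    grid=o.get("grid", spec.grid),
                )
            )
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        gen = d["generator"]
        gen["anchor_regions"] = sorted(gen["anchor_regions"])
        gen["bifurcation_regions"] = sorted(gen["bifurcation_regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        return cls(generator=GeneratorConfig(**gen), **d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, float_format: str = "%.4f", **kw) -> None:
    df.to_csv(path, float_format=float_format, lineterminator="\n", **kw)


def write_report_tables(
    outdir: Path,
    cv_results: dict[str, CVResult],
    components: pd.DataFrame,
    anchors: AnchorSet,
    audit_table: pd.DataFrame,
    volumetric_profile: pd.DataFrame,
) -> None:
    """Write the stable report tables (documented schemas, fixed precision).

    * ``metrics_<task>.csv`` — model, accuracy, f1_macro, roc_auc
    * ``confusion_<task>_<family>.csv`` — mean per-fold counts
    * ``iit_components.csv`` — feature, borda, rho, mean_ad, mean_pd,
      sigma_cn, delta, iit_score
    * ``anchors.csv`` / ``bifurcation_markers.csv`` — ranked selections
    * ``audit.csv`` — region, iit_score, p_pd_ad, effect_size, class
    * ``volumetric_profile.csv`` — region, cn/pd/ad means, pda, ada,
      p_cn_pd, p_cn_ad (percentages at 2 decimals)
    """
    outdir.mkdir(parents=True, exist_ok=True)
    for task, cv in cv_results.items():
        _write_csv(cv.metrics, outdir / f"metrics_{task}.csv", index_label="model")
        for family, mat in cv.confusion_mean.items():
            _write_csv(mat, outdir / f"confusion_{task}_{family}.csv", index_label="true")
        payload = {
            family: cv.confusion_mean[family].to_dict() for family in cv.confusion_mean
        }
        (outdir / f"confusion_{task}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    _write_csv(components, outdir / "iit_components.csv")
    _write_csv(anchors.anchors, outdir / "anchors.csv")
    _write_csv(anchors.bifurcation_markers, outdir / "bifurcation_markers.csv")
    (outdir / "anchors.json").write_text(
        json.dumps(
            {
                "anchors": anchors.anchor_names,
                "bifurcation_markers": anchors.bifurcation_names,
                "np_before": round(anchors.np_before, 4),
                "np_after": round(anchors.np_after, 4),
            },
            indent=2,
        )
    )

    required = {"iit_score", "p_pd_ad", "effect_size", "class"}
    missing = required - set(audit_table.columns)
    if missing:
        raise ValueError(f"audit table missing column(s): {sorted(missing)}")
    _write_csv(audit_table, outdir / "audit.csv")

    prof = volumetric_profile.copy()
    for col in ("pda", "ada"):
        if col not in prof.columns:
            raise ValueError(f"volumetric profile missing column: {col}")
    _write_csv(prof, outdir / "volumetric_profile.csv", float_format="%.2f")


def _volumetric_profile(features) -> pd.DataFrame:
    """Table-5-style per-region cohort means, atrophy percentages, p-values."""
    rows = []
    for region in features.feature_names:
        col = features.values[region]
        by = {
            g: col[np.asarray(features.cohort == g)].dropna().to_numpy()
            for g in ("CN", "PD", "AD")
        }
        means = {g: float(v.mean()) for g, v in by.items()}
        dunn = dunn_posthoc(
            [by["CN"], by["PD"], by["AD"]], labels=["CN", "PD", "AD"]
        ).set_index(["group_a", "group_b"])["p_adjusted"]
        rows.append(
            {
                "region": region,
                "cn_mean": means["CN"],
                "pd_mean": means["PD"],
                "ad_mean": means["AD"],
                "pda": atrophy_percentage(means["CN"], means["PD"]),
                "ada": atrophy_percentage(means["CN"], means["AD"]),
                "p_cn_pd": float(dunn[("CN", "PD")]),
                "p_cn_ad": float(dunn[("CN", "AD")]),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def run_full_pipeline(config: RunConfig, outdir: Union[str, Path]) -> Path:
    """Execute every stage in order and write all artifacts to ``outdir``.

    Stages: simulate -> CSII -> (optional) CV benchmark on the 3-way and
    binary tasks -> IIT discovery -> nonparametric audit -> report tables,
    plus a provenance manifest (config, hash, versions, seeds).  Any stage
    failure raises with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        atlas = load_region_atlas(config.atlas_path)
        table = simulate_cohorts(atlas, config.generator)
        table.write_long_csv(outdir / "cohorts_long.csv")
        logger.info(
            "simulate: n=%d subjects, p=%d regions, seed=%d",
            len(table.subjects), len(table.regions), config.generator.seed,
        )

        stage = "preprocess"
        features = compute_csii(table)
        clf_features = features.with_sex_feature() if config.include_sex else features

        stage = "benchmark"
        cv_results: dict[str, CVResult] = {}
        if config.run_benchmark:
            specs = config.specs()
            plan3 = make_stratified_folds(
                clf_features.cohort, k=config.k_folds, seeds=config.fold_seeds
            )
            cv_results["threeway"] = run_cv_benchmark(
                clf_features, plan3, specs, task="threeway"
            )
            binary = clf_features.subset(["PD", "AD"])
            plan2 = make_stratified_folds(
                binary.cohort, k=config.k_folds, seeds=config.fold_seeds
            )
            cv_results["binary"] = run_cv_benchmark(binary, plan2, specs, task="binary")
            for task, cv in cv_results.items():
                logger.info("benchmark %s: %s", task, cv.metrics.round(3).to_dict())

        stage = "discover"
        components = compute_iit_components(
            features,
            seed=config.generator.seed,
            specs=config.specs(),
            normalize_borda=config.normalize_borda,
        )
        anchors = select_anchors(
            components, k=config.k_anchors, n_subjects=features.n_subjects
        )
        logger.info(
            "discover: top-%d anchors %s (N/p %.1f -> %.1f)",
            config.k_anchors, anchors.anchor_names, anchors.np_before, anchors.np_after,
        )

        stage = "audit"
        audit_df = audit_regions(features, alpha=config.alpha)
        audit_table = (
            components[["iit_score"]]
            .join(audit_df[["p_ad_pd_direct", "effect_size", "classification"]])
            .rename(columns={"p_ad_pd_direct": "p_pd_ad", "classification": "class"})
            .sort_values("iit_score", ascending=False, kind="stable")
        )
        audit_table.index.name = "region"
        profiles = bootstrap_profiles(
            features,
            regions=anchors.anchor_names,
            n_realizations=config.bootstrap_r,
            seed=config.generator.seed,
        )
        boot_rows = [
            {"region": r, "cohort": g, "mean": p.means[g],
             "ci_low": p.intervals[g][0], "ci_high": p.intervals[g][1]}
            for r, p in profiles.items()
            for g in sorted(p.means)
        ]

        stage = "report"
        write_report_tables(
            outdir,
            cv_results,
            components,
            anchors,
            audit_table,
            _volumetric_profile(features),
        )
        _write_csv(pd.DataFrame(boot_rows).set_index("region"), outdir / "bootstrap_profiles.csv")
        manifest = {
            "config": config.to_dict(),
            "config_sha256": config.digest(),
            "package_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stages": ["simulate", "preprocess", "benchmark", "discover", "audit", "report"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete in %.1fs -> %s", time.time() - t0, outdir)
        return outdir
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
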