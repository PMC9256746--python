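"""End-to-end study workflow on a synthetic twin cohort.

Stages: simulate -> image QC -> scalar association statistics -> voxelwise
inference with ROI construction and sex-difference slope tests -> twin
correlations and ACE variance decomposition.  Each stage can be toggled;
all randomness is driven by explicit per-stage seeds derived from the run
seed, and a rerun with the same configuration produces an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, qc, stats, twin, voxels
from .cohort import (ClusterSpec, CohortConfig, ConfigurationError,
                     CovariateSpecs, TraitSpec, default_trait_specs,
                     generate_cohort, generate_volume_maps)

log = logging.getLogger("twinmorph")

SCALAR_COVARIATES = ["age_months", "site_id", "scanner_id"]
GMV_COVARIATES = SCALAR_COVARIATES + ["tiv"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_subjects=2000, n_mz_pairs=60, n_dz_pairs=280))
    stages: dict = field(default_factory=lambda: {
        "qc": True, "assoc": True, "voxelwise": True, "twin": True})
    alpha: float = 0.05
    bonferroni_m: int = 8
    qc_threshold: float = 0.70
    fwhm_mm: float = 8.0
    grid_shape: tuple = (24, 24, 24)
    voxel_size: float = 2.0
    n_perm: int = 300
    n_ur_rep: int = 100
    seed: int = 7
    effect_clusters: list = field(default_factory=lambda: [
        ClusterSpec(center=(7, 7, 7), radius=3.0, amplitude=-0.35,
                    trait="adhd_t"),
        ClusterSpec(center=(16, 16, 16), radius=2.5, amplitude=-0.30,
                    trait="adhd_t", sex="M"),
        ClusterSpec(center=(7, 16, 7), radius=2.0, amplitude=0.30,
                    trait="adhd_t"),
    ])
    out_dir: str = "twinmorph_run"
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            craw = dict(kwargs["cohort"])
            if "trait_specs" in craw:
                craw["trait_specs"] = [TraitSpec(**t) for t in craw["trait_specs"]]
            if "covariate_specs" in craw:
                craw["covariate_specs"] = CovariateSpecs(**craw["covariate_specs"])
            kwargs["cohort"] = CohortConfig(**craw)
        if "effect_clusters" in kwargs:
            kwargs["effect_clusters"] = [
                ClusterSpec(**c) if isinstance(c, dict) else c
                for c in kwargs["effect_clusters"]]
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        self.cohort.validate()
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.bonferroni_m < 1:
            raise ConfigurationError("bonferroni_m must be >= 1")
        for cl in self.effect_clusters:
            cl.validate(self.grid_shape)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        return enc(self)


def build_joint_rois(cluster_masks: dict) -> dict:
    """Combine per-sex significance masks into joint and sex-specific ROIs.

    joint ROI of a sex = union of that sex's clusters; specific ROI = that
    sex's voxels not present in the other sex's clusters.
    """
    shapes = {m.shape for m in cluster_masks.values()}
    if len(shapes) > 1:
        raise ValueError("cluster masks are on different grids")
    f = cluster_masks.get("F")
    m = cluster_masks.get("M")
    out = {}
    if f is not None:
        out["joint_F"] = f.copy()
        out["specific_F"] = voxels.exclusive_mask(f, m) if m is not None else f.copy()
    if m is not None:
        out["joint_M"] = m.copy()
        out["specific_M"] = voxels.exclusive_mask(m, f) if f is not None else m.copy()
    return out


def _seed_for(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _stage_assoc(table: pd.DataFrame, config: RunConfig) -> dict:
    cov = stats.build_covariate_matrix(table, SCALAR_COVARIATES)
    out: dict = {}

    for traitname in ("adhd_t", "nback2_acc"):
        res = stats.adjusted_two_sample_t(table[traitname], table["sex"], cov)
        d = stats.cohen_d_from_t(res.t, res.df)
        out[f"sex_difference_{traitname}"] = {
            **res.to_dict(), "cohen_d": d.d,
            "mean_F": float(table.loc[table.sex == "F", traitname].mean()),
            "mean_M": float(table.loc[table.sex == "M", traitname].mean()),
        }

    per_sex = {}
    for sx in ("F", "M"):
        sub = table[table.sex == sx]
        scov = stats.build_covariate_matrix(sub, SCALAR_COVARIATES)
        per_sex[sx] = stats.adjusted_regression(
            sub["nback2_acc"], sub["adhd_t"], scov)
    st = stats.slope_test(per_sex["M"], per_sex["F"])
    out["nback_vs_adhd"] = {
        "girls": per_sex["F"].to_dict(), "boys": per_sex["M"].to_dict(),
        "slope_test_boys_vs_girls": st.to_dict(),
    }

    out["diagnosis_rates"] = {str(cut): stats.diagnosis_rate(table, cut)
                              for cut in (65, 70)}

    if "med_stimulant" in table.columns:
        med_cov = stats.build_covariate_matrix(
            table, ["age_months", "sex", "site_id", "zygosity",
                    "scanner_id", "tiv"],
            categorical=("sex", "site_id", "zygosity", "scanner_id"))
        med = {}
        for rcol in [c for c in table.columns if c.startswith("roi_")]:
            F, p = stats.ancova(table[rcol], table["med_stimulant"], med_cov)
            med[rcol] = {"F": F, "p": p,
                         "mean_medicated": float(
                             table.loc[table.med_stimulant == 1, rcol].mean()),
                         "mean_unmedicated": float(
                             table.loc[table.med_stimulant == 0, rcol].mean())}
        adhd_F, adhd_p = stats.ancova(
            table["adhd_t"], table["med_stimulant"],
            stats.build_covariate_matrix(
                table, ["age_months", "sex", "site_id", "zygosity"],
                categorical=("sex", "site_id", "zygosity")))
        out["medication"] = {
            "prevalence": float(table["med_stimulant"].mean()),
            "adhd_ancova": {"F": adhd_F, "p": adhd_p},
            "roi_ancova": med,
        }
    return out


def _stage_voxelwise(table: pd.DataFrame, volumes, config: RunConfig,
                     out_dir: Path, seed: int) -> tuple[dict, pd.DataFrame]:
    vol_by_id = {v.subject_id: v for v in volumes}
    out: dict = {"groups": {}}
    masks = {}
    smoothed = {sid: voxels.smooth_volume(v, config.fwhm_mm)
                for sid, v in vol_by_id.items()}
    for gname, sel in (("all", np.ones(len(table), bool)),
                       ("F", (table.sex == "F").to_numpy()),
                       ("M", (table.sex == "M").to_numpy())):
        sub = table[sel]
        vols = [smoothed[s] for s in sub.subject_id]
        cov = stats.build_covariate_matrix(sub, GMV_COVARIATES)
        crit, sig, smap, _ = voxels.fwe_threshold(
            vols, sub["adhd_t"].to_numpy(), cov, alpha=config.alpha,
            n_perm=config.n_perm, seed=_seed_for(seed, f"fwe_{gname}"))
        clusters = voxels.extract_clusters(sig, smap)
        out["groups"][gname] = {
            "critical_t": crit, "df": smap.df,
            "n_significant_voxels": int(sig.sum()),
            "clusters": [c.to_dict() for c in clusters],
        }
        io.write_nifti(np.nan_to_num(smap.t), out_dir / f"tmap_{gname}.nii",
                       voxel_size=(config.voxel_size,) * 3)
        io.write_cluster_table(clusters, out_dir / f"clusters_{gname}.tsv",
                               voxel_size=(config.voxel_size,) * 3)
        if gname in ("F", "M"):
            masks[gname] = sig

    rois = build_joint_rois(masks)
    roi_stats = {}
    table = table.copy()
    ordered_vols = [smoothed[s] for s in table.subject_id]
    for rname, rmask in rois.items():
        roi_stats[rname] = {"n_voxels": int(rmask.sum())}
        if not rmask.any():
            continue
        table[f"gmv_{rname}"] = voxels.roi_extract(ordered_vols, rmask)
        per_sex = {}
        for sx in ("F", "M"):
            sub = table[table.sex == sx]
            scov = stats.build_covariate_matrix(sub, GMV_COVARIATES)
            per_sex[sx] = stats.adjusted_regression(
                sub[f"gmv_{rname}"], sub["adhd_t"], scov)
        st = stats.slope_test(per_sex["M"], per_sex["F"])
        alpha_corr = stats.bonferroni_alpha(config.alpha, config.bonferroni_m)
        roi_stats[rname].update({
            "girls": per_sex["F"].to_dict(), "boys": per_sex["M"].to_dict(),
            "slope_test_boys_vs_girls": st.to_dict(),
            "significant_bonferroni": bool(st.p < alpha_corr),
            "bonferroni_alpha": alpha_corr,
        })
        coef, p = stats.interaction_test(
            table[f"gmv_{rname}"], table["sex"], table["adhd_t"],
            table["family_id"],
            stats.build_covariate_matrix(table, GMV_COVARIATES))
        roi_stats[rname]["interaction"] = {"coef": coef, "p": p}
    out["rois"] = roi_stats
    return out, table


def _stage_twin(table: pd.DataFrame, config: RunConfig, seed: int) -> dict:
    out: dict = {}
    traits = ["adhd_t", "nback2_acc"]
    traits += [c for c in table.columns if c.startswith("gmv_") or
               c.startswith("roi_")]
    for traitname in traits:
        covs = SCALAR_COVARIATES if not (
            traitname.startswith("gmv_") or traitname.startswith("roi_")
        ) else GMV_COVARIATES
        entry: dict = {}
        try:
            mz = twin.make_pairs(table, "MZ", traitname, covs,
                                 seed=_seed_for(seed, f"mz_{traitname}"))
            dz = twin.make_pairs(table, "DZ", traitname, covs,
                                 seed=_seed_for(seed, f"dz_{traitname}"))
        except ValueError as exc:
            out[traitname] = {"error": str(exc)}
            continue
        tc_mz = twin.pair_correlation(mz)
        tc_dz = twin.pair_correlation(dz)
        ur = twin.ur_resample(table, traitname, covs, n_rep=config.n_ur_rep,
                              seed=_seed_for(seed, f"ur_{traitname}"))
        entry["correlations"] = {
            "MZ": tc_mz.to_dict(), "DZ": tc_dz.to_dict(),
            "UR": {"mean_r": ur["mean_r"], "mean_slope": ur["mean_slope"],
                   "n_rep": ur["n_rep"]},
        }
        entry["slope_tests"] = {
            "MZ_vs_DZ": twin.compare_pair_groups(tc_mz, tc_dz).to_dict(),
        }
        fit = twin.fit_ace(mz, dz, seed=_seed_for(seed, f"ace_{traitname}"))
        entry["ace"] = fit.to_dict()
        if fit.converged:
            entry["ace"]["fit_assessment"] = twin.assess_fit(fit)
        # sex-stratified fits (same-sex DZ pairs only)
        sex_fits = {}
        for sx in ("F", "M"):
            sub = table[table.sex == sx]
            try:
                mzs = twin.make_pairs(sub, "MZ", traitname, covs,
                                      seed=_seed_for(seed, f"mz_{traitname}_{sx}"),
                                      same_sex_only=True)
                dzs = twin.make_pairs(sub, "DZ", traitname, covs,
                                      seed=_seed_for(seed, f"dz_{traitname}_{sx}"),
                                      same_sex_only=True)
                sex_fits[sx] = twin.fit_ace(
                    mzs, dzs, seed=_seed_for(seed, f"ace_{traitname}_{sx}"))
                entry.setdefault("by_sex", {})[sx] = sex_fits[sx].to_dict()
            except ValueError as exc:
                entry.setdefault("by_sex", {})[sx] = {"error": str(exc)}
        if len(sex_fits) == 2:
            z, p = twin.compare_group_heritability(sex_fits["F"], sex_fits["M"])
            entry["sex_comparison_a2"] = {"z": z, "p": p}
        out[traitname] = entry
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write all outputs.

    Returns the study report (also written as JSON and Markdown under
    ``config.out_dir``).  Any stage failure raises with the stage name;
    outputs of completed stages remain on disk.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run %s -> %s", config.content_hash(), out_dir)

    report: dict = {"provenance": {
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
    }}
    stage = "simulate"
    try:
        cohort_cfg = config.cohort
        table = generate_cohort(cohort_cfg)
        io.write_cohort_csv(table, out_dir / "cohort.csv")
        need_vols = config.stages.get("qc", True) or \
            config.stages.get("voxelwise", True)
        volumes = None
        if need_vols:
            volumes = generate_volume_maps(
                table, grid_shape=config.grid_shape,
                voxel_size=config.voxel_size,
                effect_clusters=config.effect_clusters,
                seed=_seed_for(config.seed, "volumes"))
            if config.write_volumes:
                io.write_volumes(volumes, out_dir / "volumes")
        report["simulate"] = {
            "n_subjects": len(table),
            "n_mz_subjects": int((table.zygosity == "MZ").sum()),
            "n_dz_subjects": int((table.zygosity == "DZ").sum()),
            "n_girls": int((table.sex == "F").sum()),
        }

        if config.stages.get("qc", True):
            stage = "qc"
            qrep = qc.homogeneity_check(volumes, threshold=config.qc_threshold)
            io.write_json(qrep.to_dict(), out_dir / "qc_report.json")
            report["qc"] = {"threshold": qrep.threshold,
                            "n_input": qrep.n_input,
                            "n_excluded": qrep.n_excluded,
                            "flagged": list(qrep.flagged)}
            if qrep.flagged:
                keep = ~table.subject_id.isin(qrep.flagged)
                table = table[keep].reset_index(drop=True)
                volumes = [v for v in volumes
                           if v.subject_id not in set(qrep.flagged)]

        if config.stages.get("assoc", True):
            stage = "assoc"
            report["assoc"] = _stage_assoc(table, config)
            io.write_json(report["assoc"], out_dir / "assoc.json")

        if config.stages.get("voxelwise", True):
            stage = "voxelwise"
            res, table = _stage_voxelwise(
                table, volumes, config, out_dir,
                _seed_for(config.seed, "voxelwise"))
            report["voxelwise"] = res
            io.write_json(res, out_dir / "voxelwise.json")

        if config.stages.get("twin", True):
            stage = "twin"
            report["twin"] = _stage_twin(table, config,
                                         _seed_for(config.seed, "twin"))
            io.write_json(report["twin"], out_dir / "twin.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io.write_json(report, out_dir / "report.json")
    (out_dir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Human-readable summary mirroring the study's result structure."""
    lines = ["# Twin-informed morphometry study report", ""]
    prov = report.get("provenance", {})
    lines += [f"Config hash: `{prov.get('config_hash', '?')}`, "
              f"seed {prov.get('seed', '?')}", ""]
    sim = report.get("simulate", {})
    if sim:
        lines += ["## Cohort",
                  f"- {sim['n_subjects']} subjects "
                  f"({sim['n_girls']} girls); "
                  f"{sim['n_mz_subjects']} MZ and {sim['n_dz_subjects']} "
                  f"DZ/sibling twin subjects", ""]
    if "qc" in report:
        q = report["qc"]
        lines += ["## Image quality",
                  f"- {q['n_excluded']} of {q['n_input']} subjects excluded "
                  f"(mean cross-correlation < {q['threshold']})", ""]
    if "assoc" in report:
        a = report["assoc"]
        lines.append("## Trait statistics")
        for key in ("adhd_t", "nback2_acc"):
            sd = a.get(f"sex_difference_{key}")
            if sd:
                lines.append(
                    f"- {key}: boys {sd['mean_M']:.2f} vs girls "
                    f"{sd['mean_F']:.2f} (t = {sd['t']:.2f}, "
                    f"p = {sd['p']:.3g}, d = {sd['cohen_d']:.3f})")
        nb = a.get("nback_vs_adhd")
        if nb:
            lines.append(
                f"- 2-back vs ADHD partial r: girls "
                f"{nb['girls']['partial_r']:.3f}, boys "
                f"{nb['boys']['partial_r']:.3f} (slope test p = "
                f"{nb['slope_test_boys_vs_girls']['p']:.3g})")
        lines.append("")
    if "voxelwise" in report:
        lines.append("## Voxelwise GMV correlates")
        for g, res in report["voxelwise"]["groups"].items():
            lines.append(
                f"- {g}: critical |t| = {res['critical_t']:.2f}, "
                f"{res['n_significant_voxels']} significant voxels, "
                f"{len(res['clusters'])} clusters")
        for rname, rs in report["voxelwise"].get("rois", {}).items():
            if "slope_test_boys_vs_girls" in rs:
                st = rs["slope_test_boys_vs_girls"]
                lines.append(
                    f"- ROI {rname} ({rs['n_voxels']} voxels): slope test "
                    f"t = {st['t']:.2f}, p = {st['p']:.3g}")
        lines.append("")
    if "twin" in report:
        lines.append("## Heritability (ACE)")
        lines.append("| trait | a2 | c2 | e2 | class |")
        lines.append("|---|---|---|---|---|")
        for tname, entry in report["twin"].items():
            ace = entry.get("ace")
            if ace:
                lines.append(
                    f"| {tname} | {ace['a2']:.2f} "
                    f"[{ace['ci_a2'][0]:.2f}, {ace['ci_a2'][1]:.2f}] | "
                    f"{ace['c2']:.2f} | {ace['e2']:.2f} | "
                    f"{ace['classification']} |")
        lines.append("")
    return "\n".join(lines)
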