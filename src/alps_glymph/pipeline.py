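"""End-to-end orchestration: imaging -> ALPS -> scoring -> statistics.

Runs the full analysis chain on a fixture bundle or user-supplied inputs
and writes a report bundle mirroring the structure of a cohort study:
demographics comparison, covariate-adjusted cognitive comparison, imaging
markers + ALPS comparison, correlation matrices, and mediation models.
Every table is stamped with the configuration hash and seed so reruns are
auditable and byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alps as alps_mod
from . import cohort_scoring, group_stats, mediation
from .dti import fit_tensor
from .synthetic_data import GROUPS, read_fixture_bundle

logger = logging.getLogger("alps_glymph")

__all__ = ["RunConfig", "validate_inputs", "run_full_analysis"]

DEMOGRAPHIC_CONTINUOUS = ("age", "education")
RISK_FACTORS = ("hypertension", "diabetes", "hyperlipidemia", "smoking", "alcohol")
COGNITIVE_VARS = ("mmse", "moca", "z_episodic_memory", "z_language", "z_processing_speed",
                  "z_executive", "z_visuospatial")
MARKER_VARS = ("alps_index", "wmh_volume", "cmb_count", "li_count")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Covariate sets default to the published analysis plan: the adjusted
    group comparisons use gender, age, hypertension and education; the
    cognition partial correlations additionally adjust for WMH volume and
    microbleed count; mediation uses gender, age, education and
    hypertension with log-WMH exposure, ALPS mediator, and the cognitive
    composites as outcomes.
    """

    cohort_csv: str | None = None
    bundle_dir: str | None = None
    out_dir: str = "alps_report"
    imaging: bool = True
    glm_covariates: tuple = ("gender_num", "age", "hypertension_num", "education")
    cognition_corr_covariates: tuple = (
        "gender_num", "age", "education", "hypertension_num", "log_wmh", "log_cmb",
    )
    mediation_covariates: tuple = ("gender_num", "age", "education", "hypertension_num")
    mediation_exposure: str = "log_wmh"
    mediation_mediator: str = "alps_index"
    mediation_outcomes: tuple = ("z_episodic_memory",)
    mediation_groups: tuple = ("CSVD-MCI",)
    correlation_pairs: tuple = (
        ("age", "alps_index"),
        ("log_wmh", "alps_index"),
        ("log_cmb", "alps_index"),
        ("log_li", "alps_index"),
    )
    z_reference: str = "whole_sample"
    inversion_mode: str = "negate"
    alpha: float = 0.05
    bootstrap_k: int = 5000
    seed: int = 0
    roi_centers: dict | None = None  # {"projection": [x,y,z], "association": [x,y,z]}
    roi_voxel_count: int = 12

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in (k for k in raw if k.endswith(("_covariates", "_outcomes", "_groups"))):
            raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        """Short digest of the analysis-relevant settings.

        Input and output locations are excluded so the same analysis run
        against the same data hashes identically wherever it is written.
        """
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _numeric_helpers(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "gender" in out.columns:
        out["gender_num"] = (out["gender"].astype(str) == "F").astype(float)
    for rf in RISK_FACTORS:
        if rf in out.columns:
            out[f"{rf}_num"] = out[rf].astype(bool).astype(float)
    return out


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema/consistency checks; returns an itemized list of failures."""
    failures: list[str] = []
    cohort = None
    if config.bundle_dir is not None:
        bundle = Path(config.bundle_dir)
        if not (bundle / "manifest.json").exists():
            failures.append(f"bundle manifest missing: {bundle / 'manifest.json'}")
        else:
            try:
                loaded = read_fixture_bundle(bundle)
                cohort = loaded.get("cohort")
                dwi = loaded.get("dwi")
                if config.imaging and dwi is not None:
                    dw = dwi.bvals > 0
                    norms = np.linalg.norm(dwi.bvecs[dw], axis=1)
                    if not np.allclose(norms, 1.0, atol=1e-3):
                        failures.append("bvec: non-unit-norm b-vectors for b > 0 frames")
            except Exception as exc:  # surfaced, not swallowed
                failures.append(f"bundle load error: {exc}")
    if config.cohort_csv is not None:
        path = Path(config.cohort_csv)
        if not path.exists():
            failures.append(f"cohort CSV not found: {path}")
        else:
            cohort = pd.read_csv(path)
    if cohort is None:
        failures.append("no cohort table: set cohort_csv or bundle_dir")
        return failures

    required = {"group", "gender", "age", "education", "mmse", "moca", "cdr", "adl",
                "wmh_volume", "li_count", "cmb_count", "epvs_bg"}
    missing = sorted(required - set(cohort.columns))
    for col in missing:
        failures.append(f"cohort column missing: {col}")

    helper = _numeric_helpers(
        cohort_scoring.transform_markers(cohort) if not missing else cohort
    )
    derivable = set(helper.columns) | {f"z_{d}" for d in cohort_scoring.DOMAIN_COMPOSITES}
    for name, covs in (
        ("glm_covariates", config.glm_covariates),
        ("cognition_corr_covariates", config.cognition_corr_covariates),
        ("mediation_covariates", config.mediation_covariates),
    ):
        for cov in covs:
            if cov not in derivable:
                failures.append(f"{name}: covariate {cov!r} does not resolve to a cohort column")
    return failures


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.hash()
    df["seed"] = config.seed
    return df


def _group_vectors(df: pd.DataFrame, var: str) -> list[np.ndarray]:
    return [df.loc[df["group"] == g, var].dropna().to_numpy(float) for g in GROUPS
            if (df["group"] == g).any()]


def _comparison_table(df: pd.DataFrame, variables, config: RunConfig, adjusted: bool) -> pd.DataFrame:
    """One row per variable: per-group descriptives + the gating test."""
    rows = []
    cov_cols = list(config.glm_covariates)
    for var in variables:
        if var not in df.columns:
            continue
        summ = group_stats.summarize_groups(df, var)
        desc = {}
        for g in summ.table.index:
            r = summ.table.loc[g]
            desc[g] = (
                f"{r['mean']:.2f} ± {r['sd']:.2f}" if summ.normal
                else f"{r['median']:.2f} ({r['iqr']:.2f})"
            )
        sub = df.dropna(subset=[var] + (cov_cols if adjusted else []))
        logger.info("compare %s: n=%d covariates=%s", var, len(sub),
                    cov_cols if adjusted else [])
        if summ.normal:
            if adjusted:
                res = group_stats.glm_adjusted(
                    sub[var], sub["group"], sub[cov_cols], covariate_names=cov_cols
                )
            else:
                res = group_stats.anova_oneway(_group_vectors(sub, var))
        else:
            res = group_stats.kruskal_wallis(_group_vectors(sub, var))
        sig_pairs = ""
        if res.posthoc is not None:
            flags = res.posthoc[res.posthoc["p_bonferroni"] < config.alpha]["contrast"]
            sig_pairs = "; ".join(flags)
        rows.append({"variable": var, **desc, "test": res.test,
                     "statistic": res.statistic, "p": res.p_value,
                     "significant_contrasts": sig_pairs})
    return pd.DataFrame(rows)


def _categorical_table(df: pd.DataFrame, variables, config: RunConfig) -> pd.DataFrame:
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        counts = pd.crosstab(df[var].astype(bool) if df[var].dtype != object else df[var],
                             df["group"])
        counts = counts[[g for g in GROUPS if g in counts.columns]]
        res = group_stats.chi_square_test(counts.to_numpy())
        per_group = {g: f"{counts[g].iloc[-1]} ({100 * counts[g].iloc[-1] / counts[g].sum():.1f}%)"
                     for g in counts.columns}
        rows.append({"variable": var, **per_group, "test": res.test,
                     "statistic": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Sections: (1) demographics, (2) adjusted cognitive comparison,
    (3) markers + ALPS comparison, (4) correlations (pooled CSVD and per
    group), (5) mediation per configured outcome. Missing stages are
    skipped with an explicit entry in the skip log, never silently.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skip_log: list[str] = []
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "sections": {}}

    cohort = None
    bundle = None
    if config.bundle_dir is not None:
        bundle = read_fixture_bundle(config.bundle_dir)
        cohort = bundle.get("cohort")
    if config.cohort_csv is not None:
        cohort = pd.read_csv(config.cohort_csv)
    if cohort is None:
        raise ValueError("no cohort table available (set cohort_csv or bundle_dir)")

    # ----- imaging stage -------------------------------------------------
    if config.imaging and bundle is not None and "dwi" in bundle:
        tf = fit_tensor(bundle["dwi"])
        centers = config.roi_centers or bundle.get("roi_centers")
        if centers:
            roi_p = alps_mod.RoiSpec(tuple(centers["projection"]), "projection",
                                     config.roi_voxel_count)
            roi_a = alps_mod.RoiSpec(tuple(centers["association"]), "association",
                                     config.roi_voxel_count)
        else:
            roi_p, roi_a = alps_mod.suggest_roi_centers(tf, target_voxel_count=config.roi_voxel_count)
        meas = alps_mod.measure_alps(tf, roi_p, roi_a)
        report["sections"]["imaging"] = {
            "alps_index": meas.alps_index,
            "dx_proj": meas.dx_proj, "dy_proj": meas.dy_proj,
            "dx_asso": meas.dx_asso, "dz_asso": meas.dz_asso,
            "n_clamped_voxels": tf.n_clamped,
        }
    else:
        skip_log.append("imaging stage skipped (no DWI input or imaging disabled); "
                        "using alps_index column from the cohort table")

    # ----- scoring stage --------------------------------------------------
    scored = cohort_scoring.transform_markers(cohort)
    try:
        scored = cohort_scoring.z_transform_and_composite(
            scored, reference=config.z_reference, inversion_mode=config.inversion_mode
        )
    except (KeyError, ValueError) as exc:
        skip_log.append(f"z-composites unavailable: {exc}")
    scored = _numeric_helpers(scored)
    scored.to_csv(out_dir / "cohort_scored.csv", index=False)

    # ----- section 1: demographics ---------------------------------------
    demo = _comparison_table(scored, DEMOGRAPHIC_CONTINUOUS, config, adjusted=False)
    cat = _categorical_table(scored, ("gender",) + tuple(
        rf for rf in RISK_FACTORS if rf in scored.columns), config)
    table1 = pd.concat([cat, demo], ignore_index=True)
    _stamp(table1, config).to_csv(out_dir / "table1_demographics.tsv", sep="\t", index=False)
    report["sections"]["demographics"] = table1.to_dict(orient="records")

    # ----- section 2: cognition (adjusted) --------------------------------
    cog = _comparison_table(scored, COGNITIVE_VARS, config, adjusted=True)
    _stamp(cog, config).to_csv(out_dir / "table2_cognition.tsv", sep="\t", index=False)
    report["sections"]["cognition"] = cog.to_dict(orient="records")

    # ----- section 3: markers + ALPS (adjusted / rank / categorical) ------
    mark = _comparison_table(scored, MARKER_VARS, config, adjusted=True)
    if "epvs_bg" in scored.columns:
        mark = pd.concat([mark, _categorical_table(scored, ("epvs_bg",), config)],
                         ignore_index=True)
    _stamp(mark, config).to_csv(out_dir / "table3_markers.tsv", sep="\t", index=False)
    report["sections"]["markers"] = mark.to_dict(orient="records")

    # ----- section 4: correlations ---------------------------------------
    csvd = scored[scored["group"] != "NC"]
    corr_rows = []
    subsets = [("all_CSVD", csvd)] + [(g, scored[scored["group"] == g]) for g in GROUPS]
    for label, sub in subsets:
        for x, y in config.correlation_pairs:
            if x not in sub.columns or y not in sub.columns:
                skip_log.append(f"correlation {x}~{y} skipped in {label}: column missing")
                continue
            pair = sub[[x, y]].dropna()
            if len(pair) < 4 or pair[x].std() == 0 or pair[y].std() == 0:
                skip_log.append(f"correlation {x}~{y} skipped in {label}: degenerate data")
                continue
            res = group_stats.pearson_corr(pair[x], pair[y])
            corr_rows.append({"subset": label, "x": x, "y": y, "n": len(pair),
                              "r": res.statistic, "p": res.p_value, "type": "pearson"})
        # cognition partial correlations
        covs = [c for c in config.cognition_corr_covariates if c in sub.columns]
        for outcome in COGNITIVE_VARS:
            if outcome not in sub.columns or "alps_index" not in sub.columns:
                continue
            block = sub[[outcome, "alps_index", *covs]].dropna()
            if len(block) <= len(covs) + 3:
                skip_log.append(f"partial correlation alps~{outcome} skipped in {label}: n too small")
                continue
            try:
                res = group_stats.partial_corr(block["alps_index"], block[outcome], block[covs])
            except ValueError as exc:
                skip_log.append(f"partial correlation alps~{outcome} in {label}: {exc}")
                continue
            corr_rows.append({"subset": label, "x": "alps_index", "y": outcome,
                              "n": len(block), "r": res.statistic, "p": res.p_value,
                              "type": "partial"})
    corr = pd.DataFrame(corr_rows)
    _stamp(corr, config).to_csv(out_dir / "table4_correlations.tsv", sep="\t", index=False)
    report["sections"]["correlations"] = corr.to_dict(orient="records")

    # ----- section 5: mediation ------------------------------------------
    med_section = {}
    for gname in config.mediation_groups:
        sub = scored if gname == "all_CSVD" else scored[scored["group"] == gname]
        for outcome in config.mediation_outcomes:
            key = f"{gname}:{outcome}"
            covs = [c for c in config.mediation_covariates if c in sub.columns]
            needed = [config.mediation_exposure, config.mediation_mediator, outcome, *covs]
            if any(c not in sub.columns for c in needed):
                skip_log.append(f"mediation {key} skipped: missing columns")
                continue
            try:
                res = mediation.fit_mediation(
                    sub, config.mediation_exposure, config.mediation_mediator, outcome,
                    covariates=covs, k=config.bootstrap_k, seed=config.seed,
                )
            except ValueError as exc:
                skip_log.append(f"mediation {key}: {exc}")
                continue
            logger.info("mediation %s: n=%d covariates=%s seed=%d", key, res.n, covs, config.seed)
            med_section[key] = mediation.mediation_report(res)
    report["sections"]["mediation"] = med_section

    report["skip_log"] = skip_log
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
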