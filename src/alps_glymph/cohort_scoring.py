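"""Neuropsychological scoring and marker transforms.

Turns raw cohort data into the derived analysis variables:

* timed tests (Trail Making Test A/B, Stroop B/C) are sign-inverted so
  that larger always means better before standardization;
* every test is z-transformed against a reference population and averaged
  pairwise into five domain composites (episodic memory, language,
  processing speed, executive function, visuospatial function);
* subjects are assigned to diagnostic groups by education-adjusted
  MMSE/MoCA cutoffs combined with CDR and ADL criteria;
* small-vessel-disease markers are log10(x+1)-transformed and EPVS coded
  0/1 for the correlation and mediation models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TIMED_TESTS",
    "DOMAIN_COMPOSITES",
    "invert_timed_scores",
    "z_transform_and_composite",
    "classify_cognition",
    "classify_cohort",
    "classification_agreement",
    "transform_markers",
    "mmse_dementia_cutoff",
    "moca_normal_cutoff",
]

#: completion-time tests (seconds, lower = better)
TIMED_TESTS = ("tmt_a", "tmt_b", "scwt_b", "scwt_c")

#: cognitive domain -> its two constituent tests (post-inversion columns)
DOMAIN_COMPOSITES = {
    "episodic_memory": ("wms_vr_dr", "avlt_dr"),
    "language": ("bnt", "cvf"),
    "processing_speed": ("tmt_a_inv", "scwt_b_inv"),
    "executive": ("tmt_b_inv", "scwt_c_inv"),
    "visuospatial": ("cdt", "vrt"),
}


def invert_timed_scores(cohort: pd.DataFrame, mode: str = "negate") -> pd.DataFrame:
    """Add ``*_inv`` columns for the timed tests so larger means better.

    ``mode='negate'`` (default) uses the negative completion time, which
    reverses ranking while keeping z-score magnitudes symmetric;
    ``mode='reciprocal'`` uses 1/time. Non-timed columns are untouched.
    Non-positive completion times are invalid.
    """
    if mode not in ("negate", "reciprocal"):
        raise ValueError("mode must be 'negate' or 'reciprocal'")
    out = cohort.copy()
    for col in TIMED_TESTS:
        if col not in out.columns:
            continue
        t = out[col].astype(float)
        if (t <= 0).any():
            bad = out.index[t <= 0].tolist()
            raise ValueError(f"non-positive completion time in {col!r} at rows {bad}")
        out[f"{col}_inv"] = -t if mode == "negate" else 1.0 / t
    return out


def z_transform_and_composite(
    cohort: pd.DataFrame,
    reference: str = "whole_sample",
    inversion_mode: str = "negate",
) -> pd.DataFrame:
    """Z-transform test scores and build the five domain composites.

    ``reference`` selects the standardization population: the whole
    analyzed sample (default) or the normal-control group
    (``'nc_group'``, requires a ``group`` column with ``'NC'`` labels).
    Adds ``z_<test>`` columns and ``z_<domain>`` composites, each the mean
    of exactly its two constituent z-scores; a missing constituent makes
    the composite missing, never silently imputed.
    """
    if reference not in ("whole_sample", "nc_group"):
        raise ValueError("reference must be 'whole_sample' or 'nc_group'")
    out = invert_timed_scores(cohort, mode=inversion_mode)
    if reference == "nc_group":
        if "group" not in out.columns:
            raise ValueError("nc_group reference requires a 'group' column")
        ref_rows = out["group"] == "NC"
        if ref_rows.sum() < 2:
            raise ValueError("nc_group reference needs at least 2 NC subjects")
    else:
        ref_rows = pd.Series(True, index=out.index)

    tests = sorted({t for pair in DOMAIN_COMPOSITES.values() for t in pair})
    for test in tests:
        if test not in out.columns:
            continue
        ref = out.loc[ref_rows, test].astype(float)
        if ref.count() < 2:
            raise ValueError(f"reference population too small for test {test!r}")
        sd = ref.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero variance in reference population for test {test!r}")
        out[f"z_{test}"] = (out[test].astype(float) - ref.mean()) / sd

    for domain, (t1, t2) in DOMAIN_COMPOSITES.items():
        c1, c2 = f"z_{t1}", f"z_{t2}"
        if c1 in out.columns and c2 in out.columns:
            out[f"z_{domain}"] = (out[c1] + out[c2]) / 2.0
    return out


def mmse_dementia_cutoff(education_years: float) -> int:
    """Education-adjusted MMSE dementia cutoff: a score at or below it is
    in the dementia range. 17 for illiteracy, 20 for 1-6 years of
    education, 24 above 6 years."""
    if education_years < 0:
        raise ValueError("education_years must be >= 0")
    if education_years == 0:
        return 17
    if education_years <= 6:
        return 20
    return 24


_MOCA_EXTENSION_WARNED = set()


def moca_normal_cutoff(education_years: float) -> int:
    """Education-adjusted MoCA normality cutoff: a score above it is
    normal. 13 for illiteracy, 19 for 1-6 years, 24 for 7-12 years; the
    7-12-year rule is extended to >12 years (no published rule exists for
    that stratum — the extension is logged once per session)."""
    if education_years < 0:
        raise ValueError("education_years must be >= 0")
    if education_years == 0:
        return 13
    if education_years <= 6:
        return 19
    if education_years > 12 and "moca>12" not in _MOCA_EXTENSION_WARNED:
        _MOCA_EXTENSION_WARNED.add("moca>12")
        warnings.warn(
            "MoCA cutoff for >12 education years extends the 7-12-year rule (>24)",
            stacklevel=2,
        )
    return 24


def classify_cognition(record) -> str:
    """Assign a diagnostic label from screening scores.

    Rules (education-adjusted cutoffs from :func:`mmse_dementia_cutoff`
    and :func:`moca_normal_cutoff`):

    * ``VaD``      — MMSE at or below the dementia cutoff and CDR >= 1;
    * ``MCI``      — MMSE above the dementia cutoff, MoCA at or below the
      normality cutoff, CDR = 0.5 and ADL = 8;
    * ``non-CI``   — MMSE and MoCA both above their cutoffs, CDR = 0 and
      ADL = 8;
    * ``unclassifiable`` otherwise (returned, never coerced).

    ``record`` is any mapping (e.g. a DataFrame row) with keys ``mmse``,
    ``moca``, ``cdr``, ``adl`` and ``education``.
    """
    required = ("mmse", "moca", "cdr", "adl", "education")
    missing = [
        k
        for k in required
        if k not in record or record[k] is None or (isinstance(record[k], float) and np.isnan(record[k]))
    ]
    if missing:
        raise ValueError(f"classification requires fields {missing}")
    mmse, moca = float(record["mmse"]), float(record["moca"])
    cdr, adl = float(record["cdr"]), float(record["adl"])
    edu = float(record["education"])
    mmse_cut = mmse_dementia_cutoff(edu)
    moca_cut = moca_normal_cutoff(edu)

    if mmse <= mmse_cut and cdr >= 1:
        return "VaD"
    if mmse > mmse_cut and moca <= moca_cut and cdr == 0.5 and adl == 8:
        return "MCI"
    if mmse > mmse_cut and moca > moca_cut and cdr == 0 and adl == 8:
        return "non-CI"
    return "unclassifiable"


def classify_cohort(cohort: pd.DataFrame) -> pd.Series:
    """Row-wise :func:`classify_cognition`, returned as a Series."""
    return cohort.apply(classify_cognition, axis=1).rename("predicted_group")


def classification_agreement(cohort: pd.DataFrame) -> pd.DataFrame:
    """Compare generated group labels with reclassified labels.

    NC and CSVD-non-CI both map to the ``non-CI`` screening profile, so
    they are pooled for the comparison. Returns the cohort with
    ``predicted_group`` and ``label_agrees`` columns; the overall rate is
    ``result['label_agrees'].mean()``. Disagreements stay visible in the
    output rather than being dropped.
    """
    pred = classify_cohort(cohort)
    intended = cohort["group"].map(
        {"NC": "non-CI", "CSVD-non-CI": "non-CI", "CSVD-MCI": "MCI", "CSVD-VaD": "VaD"}
    )
    out = cohort.copy()
    out["predicted_group"] = pred
    out["label_agrees"] = (pred == intended).to_numpy()
    return out


def transform_markers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the transformed marker columns used by correlation/mediation.

    ``log_wmh = log10(wmh_volume + 1)``; likewise ``log_li`` and
    ``log_cmb`` for the counts (the +1 offset accommodates the many zero
    counts); ``epvs`` coded 1/0 for presence/absence.
    """
    out = cohort.copy()
    for raw, derived in (("wmh_volume", "log_wmh"), ("li_count", "log_li"), ("cmb_count", "log_cmb")):
        if raw in out.columns:
            v = out[raw].astype(float)
            if (v < 0).any():
                raise ValueError(f"negative values in {raw!r}")
            out[derived] = np.log10(v + 1.0)
    if "epvs_bg" in out.columns:
        out["epvs"] = out["epvs_bg"].astype(bool).astype(int)
    return out
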