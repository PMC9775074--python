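"""Covariate-adjusted single-mediator analysis with bootstrap intervals.

Implements the classic three-regression mediation model (the PROCESS
"model 4" layout) for an exposure X, mediator M and outcome Y with a
shared covariate set Z:

    M = i1 + a X + g1'Z          (path a)
    Y = i2 + c' X + b M + g2'Z   (paths b and c', the direct effect)
    Y = i3 + c X + g3'Z          (path c, the total effect)

All coefficients are non-standardized. For ordinary least squares with
identical covariates in every regression the decomposition
``c = c' + a*b`` holds exactly; the indirect (mediated) effect is the
product ``a*b``. Its sampling distribution is non-normal, so inference
uses a nonparametric bootstrap: subjects are resampled with replacement
``k`` times, the indirect effect recomputed on each resample, and a 95%
interval taken either as plain percentiles or with the bias-corrected
(BC) adjustment. The mediated effect is declared present when the
interval excludes zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MediationResult", "fit_mediation", "mediation_report"]


@dataclass
class MediationResult:
    """Point estimates and bootstrap interval for a single-mediator model."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    method: str
    k: int
    seed: int
    n: int
    covariates: tuple = ()
    conf_level: float = 0.95
    n_redrawn: int = 0
    standardized: bool = False  # coefficients are on the raw (non-standardized) scales
    p_values: dict = field(default_factory=dict)

    @property
    def mediation_present(self) -> bool:
        """True when the bootstrap CI for the indirect effect excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


def _ols_coef(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def _coef_pvalues(x: np.ndarray, y: np.ndarray, coef: np.ndarray) -> np.ndarray:
    resid = y - x @ coef
    dof = x.shape[0] - x.shape[1]
    if dof <= 0:
        return np.full(coef.shape, np.nan)
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    t = coef / np.sqrt(np.diag(cov))
    return 2.0 * stats.t.sf(np.abs(t), dof)


def fit_mediation(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates=(),
    k: int = 5000,
    method: str = "bias_corrected",
    seed: int = 0,
    conf_level: float = 0.95,
    force_small_k: bool = False,
) -> MediationResult:
    """Fit the mediation model and bootstrap the indirect effect.

    Complete cases only; rows with any missing value among the model
    variables are dropped. The resampling unit is the subject row, and the
    covariate set enters all three regressions. ``method`` is
    ``'bias_corrected'`` (default) or ``'percentile'``. Degenerate
    bootstrap resamples (collinear design, e.g. a binary covariate
    constant in the resample) are redrawn and counted in ``n_redrawn``.
    """
    if method not in ("percentile", "bias_corrected"):
        raise ValueError("method must be 'percentile' or 'bias_corrected'")
    if k < 100 and not force_small_k:
        raise ValueError("k < 100 gives unreliable bootstrap intervals; pass force_small_k=True to override")

    covariates = tuple(covariates)
    cols = [exposure, mediator, outcome, *covariates]
    df = data.loc[:, cols].apply(pd.to_numeric).dropna()
    n = len(df)
    if n <= len(covariates) + 3:
        raise ValueError(f"need n > covariates + 3 complete cases, got n = {n}")

    x = df[exposure].to_numpy(float)
    m = df[mediator].to_numpy(float)
    y = df[outcome].to_numpy(float)
    z = df[list(covariates)].to_numpy(float) if covariates else np.empty((n, 0))

    ones = np.ones((n, 1))
    xm_design = np.column_stack([ones, x, z])  # mediator ~ exposure + Z
    xy_design = np.column_stack([ones, x, m, z])  # outcome ~ exposure + mediator + Z

    for name, d in (("a-path", xm_design), ("b/c'-path", xy_design)):
        if np.linalg.matrix_rank(d) < d.shape[1]:
            raise ValueError(f"collinear design in the {name} regression")

    coef_m = _ols_coef(xm_design, m)
    coef_y = _ols_coef(xy_design, y)
    coef_t = _ols_coef(xm_design, y)  # total-effect model shares the a-path design
    a, b, c_prime, c = coef_m[1], coef_y[2], coef_y[1], coef_t[1]
    point = a * b

    p_values = {
        "a": float(_coef_pvalues(xm_design, m, coef_m)[1]),
        "b": float(_coef_pvalues(xy_design, y, coef_y)[2]),
        "c_prime": float(_coef_pvalues(xy_design, y, coef_y)[1]),
        "c": float(_coef_pvalues(xm_design, y, coef_t)[1]),
    }

    rng = np.random.default_rng(seed)
    boot = np.empty(k)
    filled = 0
    n_redrawn = 0
    max_rounds = 100
    while filled < k and max_rounds > 0:
        max_rounds -= 1
        need = k - filled
        idx = rng.integers(0, n, size=(need, n))
        xm_b = xm_design[idx]  # (need, n, p1)
        xy_b = xy_design[idx]  # (need, n, p2)
        m_b = m[idx]
        y_b = y[idx]
        # batched normal equations
        g1 = np.einsum("rni,rnj->rij", xm_b, xm_b)
        h1 = np.einsum("rni,rn->ri", xm_b, m_b)
        g2 = np.einsum("rni,rnj->rij", xy_b, xy_b)
        h2 = np.einsum("rni,rn->ri", xy_b, y_b)
        ok = (np.linalg.matrix_rank(g1) == g1.shape[1]) & (
            np.linalg.matrix_rank(g2) == g2.shape[1]
        )
        n_redrawn += int(np.count_nonzero(~ok))
        if not ok.any():
            continue
        a_b = np.linalg.solve(g1[ok], h1[ok][..., None])[:, 1, 0]
        b_b = np.linalg.solve(g2[ok], h2[ok][..., None])[:, 2, 0]
        vals = a_b * b_b
        vals = vals[np.isfinite(vals)]
        boot[filled : filled + len(vals)] = vals
        filled += len(vals)
    if filled < k:
        raise RuntimeError("could not complete the bootstrap: too many degenerate resamples")

    alpha = 1.0 - conf_level
    if method == "percentile":
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        # bias-corrected (BC, no acceleration): shift percentiles by the
        # normal quantile of the fraction of bootstrap draws below the point
        prop = np.mean(boot < point)
        prop = min(max(prop, 1.0 / (k + 1)), k / (k + 1.0))
        z0 = stats.norm.ppf(prop)
        z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
        p_lo = stats.norm.cdf(2 * z0 + z_lo)
        p_hi = stats.norm.cdf(2 * z0 + z_hi)
        lo, hi = np.percentile(boot, [100 * p_lo, 100 * p_hi])

    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        indirect=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        k=k,
        seed=seed,
        n=n,
        covariates=covariates,
        conf_level=conf_level,
        n_redrawn=n_redrawn,
        p_values=p_values,
    )


def mediation_report(result: MediationResult) -> dict:
    """Serializable path-diagram summary of a fitted mediation model.

    Returns a JSON-ready dict with each path's coefficient, significance
    star (at 0.05) and role (direct vs indirect), plus a rendered text
    diagram under ``'text'``. Round-trips through ``json`` unchanged.
    """
    def star(p):
        return "*" if (p is not None and p < 0.05) else ""

    pv = result.p_values or {}
    paths = {
        "a": {"coef": result.a, "p": pv.get("a"), "sig": star(pv.get("a")), "role": "exposure -> mediator"},
        "b": {"coef": result.b, "p": pv.get("b"), "sig": star(pv.get("b")), "role": "mediator -> outcome"},
        "c": {"coef": result.c, "p": pv.get("c"), "sig": star(pv.get("c")), "role": "total effect"},
        "c_prime": {"coef": result.c_prime, "p": pv.get("c_prime"), "sig": star(pv.get("c_prime")),
                    "role": "direct effect"},
    }
    report = {
        "paths": paths,
        "indirect": {
            "estimate": result.indirect,
            "ci": [result.ci_low, result.ci_high],
            "method": result.method,
            "k": result.k,
            "mediation_present": result.mediation_present,
        },
        "n": result.n,
        "covariates": list(result.covariates),
        "coefficients_standardized": result.standardized,
    }
    lines = [
        f"        mediator (b = {result.b:+.4f}{paths['b']['sig']})",
        f"       /        \\",
        f"  (a = {result.a:+.4f}{paths['a']['sig']})   \\",
        f"     /            v",
        f"exposure ------> outcome   (c' = {result.c_prime:+.4f}{paths['c_prime']['sig']}, "
        f"c = {result.c:+.4f}{paths['c']['sig']})",
        f"indirect a*b = {result.indirect:+.4f}, {int(result.conf_level*100)}% CI "
        f"[{result.ci_low:+.4f}, {result.ci_high:+.4f}] ({result.method}, k = {result.k})",
        f"mediation {'PRESENT' if result.mediation_present else 'not demonstrated'} "
        f"(CI {'excludes' if result.mediation_present else 'contains'} zero)",
    ]
    report["text"] = "\n".join(lines)
    # ensure JSON round-trip stability
    return json.loads(json.dumps(report))
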