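"""Intraclass correlation from an intercept-only two-level model.

Respondents within a recruitment component resemble each other, which
inflates the sampling variance of naive survey estimates.  The intraclass
correlation (ICC) quantifies this: for the one-way random-effects model

    y_ij = mu + u_i + e_ij,   u_i ~ N(0, s2_between),  e_ij ~ N(0, s2_within)

the ICC is s2_between / (s2_between + s2_within) — the expected correlation
between two randomly chosen members of the same component.  ICC 0 means
observations are effectively independent; ICC 1 means members of a component
respond identically.

Variance components are estimated by restricted maximum likelihood (REML)
for the unbalanced one-way layout, maximising the restricted log-likelihood
directly over (s2_between, s2_within) using the per-component closed forms
(each component's covariance is compound-symmetric, so determinants and
quadratic forms reduce to scalars).  A method-of-moments ANOVA estimator is
available as a cross-check; on balanced data the two agree whenever the
ANOVA estimate is interior.  Negative between-component estimates are
truncated at zero, giving ICC 0.

Binary and ordinal responses are fitted as numeric codes in the same linear
model, so their variances are on the coded scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize


def icc_from_components(sigma2_between: float, sigma2_within: float) -> float:
    """The two-level ICC: between-variance over total variance.

    Pure arithmetic on already-estimated components; raises when both are
    zero (the ratio is undefined) or either is negative.
    """
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_between + sigma2_within
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return sigma2_between / total


@dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    icc: float
    method: str
    converged: bool
    n_components: int
    n_individuals: int
    loglik: float = float("nan")


def _group_stats(values: np.ndarray, component_ids: np.ndarray):
    order = np.argsort(component_ids, kind="stable")
    v = values[order]
    g = component_ids[order]
    uniq, start = np.unique(g, return_index=True)
    groups = np.split(v, start[1:])
    n_i = np.array([len(grp) for grp in groups])
    means = np.array([grp.mean() for grp in groups])
    ss_within = np.array([((grp - grp.mean()) ** 2).sum() for grp in groups])
    return n_i, means, ss_within


def _neg2_reml(s2b: float, s2w: float, n_i, means, ss_within) -> float:
    """-2 x restricted log-likelihood for the one-way layout (with constants)."""
    d = s2w + n_i * s2b          # variance of each component mean times n_i
    w = n_i / d                  # GLS weights for the grand mean
    sw = w.sum()
    mu = (w * means).sum() / sw
    n = n_i.sum()
    logdet_v = (n_i - 1) @ np.log(np.full_like(d, s2w)) + np.log(d).sum()
    quad = ss_within.sum() / s2w + (w * (means - mu) ** 2).sum()
    return float((n - 1) * math.log(2 * math.pi) + logdet_v + math.log(sw) + quad)


def anova_components(values, component_ids) -> tuple[float, float]:
    """Method-of-moments (one-way ANOVA) estimates for unbalanced data.

    Uses expected mean squares with the standard unbalanced coefficient
    n0 = (N - sum n_i^2 / N) / (a - 1); the between estimate is truncated
    at zero.
    """
    values = np.asarray(values, dtype=float)
    component_ids = np.asarray(component_ids)
    n_i, means, ss_within = _group_stats(values, component_ids)
    a = len(n_i)
    n = n_i.sum()
    if a < 2:
        raise ValueError("need at least 2 components")
    grand = values.mean()
    ssb = (n_i * (means - grand) ** 2).sum()
    ssw = ss_within.sum()
    msw = ssw / (n - a) if n > a else 0.0
    msb = ssb / (a - 1)
    n0 = (n - (n_i**2).sum() / n) / (a - 1)
    s2b = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
    return float(s2b), float(msw)


def fit_variance_components(
    values: Sequence[float],
    component_ids: Sequence,
    method: str = "reml",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> VarianceComponents:
    """Estimate (s2_between, s2_within) and the ICC.

    Parameters
    ----------
    values
        Numeric response, one per individual (binary coded 0/1).
    component_ids
        Component label per individual, aligned with ``values``.
    method
        ``"reml"`` (default) or ``"anova_mom"`` for the moment estimator.
    tol
        Convergence tolerance on the -2 restricted log-likelihood.
    """
    values = np.asarray(values, dtype=float)
    component_ids = np.asarray(component_ids)
    if values.shape != component_ids.shape:
        raise ValueError("values and component_ids must align")
    mask = ~np.isnan(values)
    values, component_ids = values[mask], component_ids[mask]
    n_i, means, ss_within = _group_stats(values, component_ids)
    a, n = len(n_i), int(n_i.sum())
    if a < 2:
        raise ValueError("between-component variance unidentifiable with one component")

    if method == "anova_mom":
        s2b, s2w = anova_components(values, component_ids)
        return VarianceComponents(
            s2b, s2w, icc_from_components(s2b, s2w), "anova_mom", True, a, n
        )
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    total_var = values.var(ddof=1)
    if total_var == 0:
        raise ValueError("constant response; variance components undefined")
    s2b0, s2w0 = anova_components(values, component_ids)
    s2w0 = max(s2w0, 1e-8 * total_var)
    s2b0 = max(s2b0, 1e-8 * total_var)

    # profile over the ratio lam = s2b/s2w: for fixed lam the REML scale
    # estimate of s2w is closed-form, leaving a 1-D problem in log lam.
    def neg2_profile(log_lam: float) -> float:
        lam = math.exp(log_lam)
        d = 1.0 + n_i * lam
        w = n_i / d
        sw = w.sum()
        mu = (w * means).sum() / sw
        quad = ss_within.sum() + (w * (means - mu) ** 2).sum()
        s2w = quad / (n - 1)
        return float(
            (n - 1) * (math.log(2 * math.pi) + math.log(s2w) + 1)
            + np.log(d).sum()
            + math.log(sw)
        )

    res = optimize.minimize_scalar(
        neg2_profile,
        bounds=(-30.0, 30.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    lam = math.exp(res.x)
    d = 1.0 + n_i * lam
    w = n_i / d
    mu = (w * means).sum() / w.sum()
    s2w = (ss_within.sum() + (w * (means - mu) ** 2).sum()) / (n - 1)
    s2b = lam * s2w

    # boundary check: the profile may be minimised at lam -> 0
    if neg2_profile(-30.0) <= res.fun + tol:
        s2b = 0.0
        s2w = float(
            (ss_within.sum() + (n_i * (means - values.mean()) ** 2).sum()) / (n - 1)
        )
    converged = bool(res.success)
    m2ll = _neg2_reml(max(s2b, 0.0), s2w, n_i, means, ss_within)
    return VarianceComponents(
        sigma2_between=float(max(s2b, 0.0)),
        sigma2_within=float(s2w),
        icc=icc_from_components(max(s2b, 0.0), s2w),
        method="reml",
        converged=converged,
        n_components=a,
        n_individuals=n,
        loglik=-0.5 * m2ll,
    )


#: (row label, measures_frame column) pairs for the standard ICC table.
ICC_ROWS = (
    ("age", "age"),
    ("gender", "gender_code"),
    ("education", "education_code"),
    ("log_degree", "log_degree"),
    ("log_eating", "log_eating"),
    ("log_household", "log_household"),
    ("log_symptoms", "log_symptoms"),
    ("two_plus_symptoms", "two_plus_code"),
)


def icc_report(records, forest, **derive_kwargs):
    """ICC, between- and within-component variance for the standard rows."""
    import pandas as pd

    from .assortativity import _coded_frame

    df = _coded_frame(records, **derive_kwargs)
    comp = df["pid"].map(forest.component_id)
    rows = []
    for label, column in ICC_ROWS:
        vals = df[column].astype(float).to_numpy()
        try:
            vc = fit_variance_components(vals, comp.to_numpy())
            rows.append(
                {"attribute": label, "icc": vc.icc,
                 "sigma2_between": vc.sigma2_between,
                 "sigma2_within": vc.sigma2_within,
                 "n_components": vc.n_components,
                 "n_individuals": vc.n_individuals}
            )
        except ValueError as exc:
            rows.append({"attribute": label, "icc": float("nan"),
                         "sigma2_between": float("nan"),
                         "sigma2_within": float("nan"), "note": str(exc)})
    return pd.DataFrame(rows)
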