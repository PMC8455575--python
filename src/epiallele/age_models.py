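"""Methylation-versus-age models: correlations, an invertible linear clock,
age acceleration, and the age x group interaction.

The clock is a single-locus analogue of the classical epigenetic clocks:
ordinary least squares of percent methylation on chronological age fitted
in the control group, ``m = a + b*t``.  Inverting the line at a new
sample's methylation gives its *epigenetic age* ``t_hat = (m - a)/b``, and
*age acceleration* is ``delta = t_hat - age_at_autopsy`` — positive when a
donor is less methylated (with b < 0) than controls of the same age.

The age x group interaction is the standard analysis-of-covariance test of
whether the two groups share a methylation-age slope, fitted as
``m ~ age + group + age:group`` with an F-test (single df, equal to the
squared t) on the interaction coefficient.  All tests are two-sided; no
multiple-testing correction is applied, but the cohort report counts the
tests it ran.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "AgeRegressionFit",
    "AgeAcceleration",
    "pearson_age_correlation",
    "fit_methylation_age_regression",
    "methylation_age_acceleration",
    "acceleration_vs_clinical",
    "ancova_interaction",
    "age_analysis",
]


@dataclasses.dataclass(frozen=True)
class AgeRegressionFit:
    """OLS fit of percent methylation on age in the reference group."""

    intercept: float
    slope: float
    r: float
    p: float
    n: int
    residual_sd: float

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age

    def invert(self, methylation: float) -> float:
        """Epigenetic age at which the fitted line reaches ``methylation``."""
        if self.slope == 0:
            raise ValueError("clock slope is zero; the regression cannot be inverted")
        return (methylation - self.intercept) / self.slope


@dataclasses.dataclass(frozen=True)
class AgeAcceleration:
    sample_id: str
    epigenetic_age: float
    acceleration: float


def _paired(values, ages) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and ages must have the same length")
    keep = np.isfinite(v) & np.isfinite(a)
    return v[keep], a[keep]


def pearson_age_correlation(values, ages) -> tuple[float, float, int]:
    """Two-sided Pearson correlation over complete pairs: (r, p, n)."""
    v, a = _paired(values, ages)
    n = v.size
    if n < 3:
        raise ValueError(f"Pearson correlation needs at least 3 complete pairs, got {n}")
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = scipy.stats.pearsonr(v, a)
    return float(res.statistic), float(res.pvalue), n


def fit_methylation_age_regression(methylation, ages) -> AgeRegressionFit:
    """OLS of percent methylation on age; the control-group clock fit."""
    m, t = _paired(methylation, ages)
    n = m.size
    if n < 3:
        raise ValueError(f"regression needs at least 3 complete pairs, got {n}")
    if np.ptp(t) == 0:
        raise ValueError("ages are all equal; the design is degenerate")
    res = scipy.stats.linregress(t, m)
    resid = m - (res.intercept + res.slope * t)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return AgeRegressionFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
        residual_sd=residual_sd,
    )


def methylation_age_acceleration(
    sample_id: str, methylation: float, age: float, fit: AgeRegressionFit
) -> AgeAcceleration:
    """Epigenetic age and acceleration of one case against the control clock.

    With a demethylating clock (b < 0), lower-than-predicted methylation
    yields a positive acceleration (epigenetically older than chronology).
    """
    t_hat = fit.invert(methylation)
    return AgeAcceleration(
        sample_id=sample_id, epigenetic_age=t_hat, acceleration=t_hat - age
    )


def acceleration_vs_clinical(accelerations, clinical) -> tuple[float, float, int]:
    """Pearson correlation between age acceleration and a clinical variable
    (age at onset or disease duration); incomplete cases are dropped."""
    return pearson_age_correlation(accelerations, clinical)


def ancova_interaction(group_a, group_b) -> tuple[float, float, float]:
    """Age x group interaction from ``m ~ age * group``.

    ``group_a`` and ``group_b`` are sequences of (methylation, age) pairs.
    Returns (interaction slope difference, F, p); F is the single-df
    F-statistic (squared t) for the interaction coefficient.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    df = pd.DataFrame(
        {
            "m": np.concatenate([a[:, 0], b[:, 0]]),
            "age": np.concatenate([a[:, 1], b[:, 1]]),
            "grp": ["A"] * len(a) + ["B"] * len(b),
        }
    )
    if df.groupby("grp")["age"].agg(np.ptp).min() == 0:
        raise ValueError("singular design: a group has constant age")
    model = smf.ols("m ~ age * C(grp)", data=df).fit()
    term = "age:C(grp)[T.B]"
    est = float(model.params[term])
    tval = float(model.tvalues[term])
    p = float(model.pvalues[term])
    return est, tval**2, p


def age_analysis(
    summary: pd.DataFrame,
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    clock_region: str,
    clock_site: int | None = 1,
) -> dict:
    """Cohort-level age analysis over analysis outputs.

    ``clock_region`` names the region carrying the clock; ``clock_site`` is
    its 1-based CpG index (None means the region's mean methylation).
    Fits the control clock, computes case accelerations, the group-wise
    methylation-age and epipolymorphism-age correlations, correlations of
    acceleration with onset and duration, and the age x group interaction.
    """
    meta = metadata.set_index("sample_id")
    region_summary = summary[summary["region_id"] == clock_region].set_index("sample_id")

    if clock_site is None:
        clock_values = region_summary["mean_methylation"]
        clock_label = f"mean({clock_region})"
    else:
        sel = profiles[
            (profiles["region_id"] == clock_region) & (profiles["site_index"] == clock_site)
        ].set_index("sample_id")
        clock_values = sel["percent_methylation"]
        clock_label = f"{clock_region}:site{clock_site}"

    controls = meta[meta["group"] == "control"].index
    cases = meta[meta["group"] == "ALS"].index
    ctrl_m = clock_values.reindex(controls).to_numpy(dtype=float)
    ctrl_age = meta.loc[controls, "age_at_autopsy"].to_numpy(dtype=float)
    fit = fit_methylation_age_regression(ctrl_m, ctrl_age)

    accel_rows = []
    for sid in cases:
        m = clock_values.get(sid, math.nan)
        if not math.isfinite(m):
            continue
        acc = methylation_age_acceleration(sid, float(m), float(meta.loc[sid, "age_at_autopsy"]), fit)
        accel_rows.append(
            {
                "sample_id": sid,
                "group": "ALS",
                "clock": clock_label,
                "methylation": float(m),
                "age_at_autopsy": float(meta.loc[sid, "age_at_autopsy"]),
                "epigenetic_age": acc.epigenetic_age,
                "acceleration": acc.acceleration,
            }
        )
    accelerations = pd.DataFrame(
        accel_rows,
        columns=[
            "sample_id", "group", "clock", "methylation", "age_at_autopsy",
            "epigenetic_age", "acceleration",
        ],
    )

    corr_rows = []

    def _corr(name, values, against) -> None:
        try:
            r, p, n = pearson_age_correlation(values, against)
            corr_rows.append({"test": name, "r": r, "p": p, "n": n})
        except ValueError as exc:
            corr_rows.append({"test": name, "r": math.nan, "p": math.nan, "n": 0, "note": str(exc)})

    mean_meth = region_summary["mean_methylation"]
    epipoly = region_summary["epipolymorphism"]
    ages_all = meta["age_at_autopsy"]
    for group, idx in (("control", controls), ("ALS", cases)):
        _corr(
            f"{group}_mean_methylation_vs_age",
            mean_meth.reindex(idx).to_numpy(dtype=float),
            ages_all.reindex(idx).to_numpy(dtype=float),
        )
        _corr(
            f"{group}_epipolymorphism_vs_age",
            epipoly.reindex(idx).to_numpy(dtype=float),
            ages_all.reindex(idx).to_numpy(dtype=float),
        )
    if not accelerations.empty:
        onset = meta.loc[accelerations["sample_id"], "age_at_onset"].to_numpy(dtype=float)
        duration = meta.loc[accelerations["sample_id"], "disease_duration"].to_numpy(dtype=float)
        _corr("acceleration_vs_age_at_onset", accelerations["acceleration"].to_numpy(), onset)
        _corr("acceleration_vs_disease_duration", accelerations["acceleration"].to_numpy(), duration)

    interaction = None
    if len(controls) >= 3 and len(cases) >= 3:
        ga = np.column_stack([
            mean_meth.reindex(controls).to_numpy(dtype=float),
            ages_all.reindex(controls).to_numpy(dtype=float),
        ])
        gb = np.column_stack([
            mean_meth.reindex(cases).to_numpy(dtype=float),
            ages_all.reindex(cases).to_numpy(dtype=float),
        ])
        ga = ga[np.isfinite(ga).all(axis=1)]
        gb = gb[np.isfinite(gb).all(axis=1)]
        if len(ga) >= 3 and len(gb) >= 3:
            est, fstat, p = ancova_interaction(ga, gb)
            interaction = {"estimate": est, "F": fstat, "p": p}

    correlations = pd.DataFrame(corr_rows)
    correlations["n_tests_performed"] = len(corr_rows) + (1 if interaction else 0)
    return {
        "fit": fit,
        "clock": clock_label,
        "accelerations": accelerations,
        "correlations": correlations,
        "interaction": interaction,
    }
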