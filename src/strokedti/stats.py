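"""Group inference: GEE interaction gate, ANOVA + Tukey HSD, Pearson.

The longitudinal gate is a Gaussian GEE (identity link) of
``value ~ group * timepoint`` with subjects as clusters and a working
correlation (exchangeable by default; independence available), using the
robust sandwich covariance. The reported gate statistic is the joint Wald
chi-square over all group x timepoint interaction terms. Cross-sectional
contrasts at a single timepoint use one-way ANOVA followed by all-pairs
Tukey HSD (Tukey-Kramer for unequal n) on studentized-range quantiles. The
gate convention -- run the post-hoc only when the GEE interaction p < 0.05
-- is enforced by the pipeline driver, not here, so each piece stays
independently testable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "gee_interaction",
    "anova_tukey",
    "pearson",
    "simulate_longitudinal",
]


@dataclass
class ComparisonResult:
    """One test: label, estimate/se where meaningful, statistic and p-values."""

    contrast: str
    estimate: Optional[float]
    se: Optional[float]
    statistic: float
    p_value: float
    p_adjusted: Optional[float] = None
    df: Optional[tuple[float, ...]] = None


def _validate_longitudinal(data: pd.DataFrame) -> None:
    req = {"subject", "group", "timepoint", "value"}
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"longitudinal table missing column(s): {sorted(missing)}")
    dup = data.duplicated(subset=["subject", "timepoint"])
    if dup.any():
        raise ValueError("each (subject, timepoint) pair must appear at most once")
    if data["group"].nunique() < 2 or data["timepoint"].nunique() < 2:
        raise ValueError("interaction testing needs >= 2 groups and >= 2 timepoints")
    if not np.all(np.isfinite(data["value"].to_numpy(dtype=float))):
        raise ValueError("outcome values must be finite")


def gee_interaction(
    data: pd.DataFrame,
    working_correlation: str = "exchangeable",
    cov_type: str = "bias_reduced",
) -> ComparisonResult:
    """Joint Wald test of all group x timepoint terms in a Gaussian GEE.

    ``data`` columns: subject (cluster id), group, timepoint, value.
    Returns the chi-square statistic, its degrees of freedom, and the
    sandwich-covariance p-value for the interaction block. The default
    covariance is the Mancl-DeRouen bias-reduced sandwich: the plain robust
    sandwich is markedly anti-conservative with the few clusters per arm
    typical of animal cohorts (``cov_type="robust"`` restores it).
    """
    _validate_longitudinal(data)
    structs = {
        "independence": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
    }
    if working_correlation not in structs:
        raise ValueError(
            f"working_correlation must be one of {sorted(structs)}, got {working_correlation!r}"
        )
    model = smf.gee(
        "value ~ C(group) * C(timepoint)",
        groups="subject",
        data=data,
        family=sm.families.Gaussian(),
        cov_struct=structs[working_correlation](),
    )
    if cov_type not in ("robust", "bias_reduced", "naive"):
        raise ValueError(f"unknown cov_type {cov_type!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=100, cov_type=cov_type)
    inter = [name for name in result.model.exog_names if ":" in name]
    if not inter:
        raise ValueError("design has no interaction terms (singular or collapsed factors)")
    with warnings.catch_warnings():
        # small clusters can make the constraint covariance numerically
        # rank-deficient; statsmodels still returns the correct pinv-based test
        warnings.simplefilter("ignore")
        wald = result.wald_test(
            ", ".join(f"{name} = 0" for name in inter), scalar=True
        )
    return ComparisonResult(
        contrast="group x timepoint",
        estimate=None,
        se=None,
        statistic=float(wald.statistic),
        p_value=float(wald.pvalue),
        df=(float(len(inter)),),
    )


def gee_coefficients(data: pd.DataFrame, working_correlation: str = "independence"):
    """Fitted GEE parameter vector (exposed for the OLS-equivalence check)."""
    _validate_longitudinal(data)
    structs = {
        "independence": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
    }
    model = smf.gee(
        "value ~ C(group) * C(timepoint)",
        groups="subject",
        data=data,
        family=sm.families.Gaussian(),
        cov_struct=structs[working_correlation](),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100).params


def anova_tukey(
    values_by_group: dict[str, Sequence[float]],
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA F test plus all-pairs Tukey HSD at one timepoint.

    Returns ``(anova, pairwise)``. Pairwise adjusted p-values come from the
    studentized-range distribution with the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/ni + 1/nj))``; with two groups this reduces exactly to
    the pooled two-sample t-test. Zero within-group variance everywhere is
    degenerate: flagged with a warning, p reported as 0 when group means
    differ.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has < 2 observations")
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    df_within = n_total - k
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    msw = ss_within / df_within

    names = list(groups)
    if msw == 0:
        warnings.warn(
            "zero within-group variance: F is degenerate; p set to 0 where means differ",
            stacklevel=2,
        )
        means_differ = len({v.mean() for v in groups.values()}) > 1
        anova = ComparisonResult(
            contrast="one-way ANOVA", estimate=None, se=None,
            statistic=np.inf if means_differ else 0.0,
            p_value=0.0 if means_differ else 1.0,
            df=(float(k - 1), float(df_within)),
        )
        pairwise = []
        for a, b in itertools.combinations(names, 2):
            diff = groups[a].mean() - groups[b].mean()
            pairwise.append(ComparisonResult(
                contrast=f"{a} vs {b}", estimate=float(diff), se=0.0,
                statistic=np.inf if diff != 0 else 0.0,
                p_value=0.0 if diff != 0 else 1.0,
                p_adjusted=0.0 if diff != 0 else 1.0,
            ))
        return anova, pairwise

    f_stat = (ss_between / (k - 1)) / msw
    p_f = float(sps.f.sf(f_stat, k - 1, df_within))
    anova = ComparisonResult(
        contrast="one-way ANOVA", estimate=None, se=None,
        statistic=float(f_stat), p_value=p_f,
        df=(float(k - 1), float(df_within)),
    )
    pairwise = []
    for a, b in itertools.combinations(names, 2):
        va, vb = groups[a], groups[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(msw / 2 * (1 / len(va) + 1 / len(vb)))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_within))
        pairwise.append(ComparisonResult(
            contrast=f"{a} vs {b}", estimate=float(diff), se=float(se),
            statistic=float(q), p_value=p_adj, p_adjusted=min(1.0, p_adj),
            df=(float(k), float(df_within)),
        ))
    return anova, pairwise


def pearson(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Product-moment correlation r with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs >= 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    r, p = sps.pearsonr(x, y)
    return ComparisonResult(
        contrast="Pearson r", estimate=float(r), se=None,
        statistic=float(r), p_value=float(p), df=(float(len(x) - 2),),
    )


def simulate_longitudinal(
    group_means: dict[str, Sequence[float]],
    n_per_group: int,
    timepoints: Sequence[str],
    sd: float = 1.0,
    rho: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustered Gaussian outcomes with exchangeable within-subject correlation.

    Each subject's deviations are ``sqrt(rho)*b_subject +
    sqrt(1-rho)*e_obs`` around its group x timepoint mean, giving
    within-subject correlation ``rho`` and marginal sd ``sd``. Used by the
    type-I-error and power Monte-Carlos of the GEE gate.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for group, means in group_means.items():
        if len(means) != len(timepoints):
            raise ValueError(f"group {group!r}: need one mean per timepoint")
        for i in range(n_per_group):
            subject = f"{group}-{i}"
            b = rng.normal(0.0, 1.0)
            for tp, mu in zip(timepoints, means):
                e = rng.normal(0.0, 1.0)
                rows.append({
                    "subject": subject, "group": group, "timepoint": tp,
                    "value": mu + sd * (np.sqrt(rho) * b + np.sqrt(1 - rho) * e),
                })
    return pd.DataFrame(rows)
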