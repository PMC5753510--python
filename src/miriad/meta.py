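"""Random-effects meta-analysis of two-group expression summaries.

Each study contributes a standardized mean difference (Hedges' g) computed
from per-group sample size, mean and SD.  Studies are pooled with the
DerSimonian-Laird random-effects model; heterogeneity is summarised by
Cochran's Q, its chi-square p-value, I-squared and tau-squared.

Two significance calls are reported side by side:

* the conventional zero-crossing normal test (``z``/``p``), and
* a unit-interval stability rule that accepts the pooled effect only when
  the 95% CI excludes both +1 and -1 (closed interval: touching a boundary
  counts as overlap).  ``PooledResult.significance_flag`` combines the two:
  the CI must exclude 0 and both unit values.

The sign convention is control minus case, so a gene *down*-regulated in
the disease group yields a *positive* SMD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "StudyRecord",
    "EffectEstimate",
    "PooledResult",
    "STRATA",
    "hedges_g",
    "pool_random_effects",
    "significance_rule",
    "leave_one_out",
    "subgroup_compare",
    "forest_table",
]

#: Recognized clinico-pathological comparison strata.
STRATA = frozenset({"tissue", "vascular_invasion", "cirrhosis", "metastasis"})

#: Normal quantile for a 95% two-sided interval.
Z_95 = 1.959964


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one arm of a two-group comparison."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class StudyRecord:
    """One study's two-group summary (case = disease, control = reference)."""

    study_id: str
    case: GroupSummary
    control: GroupSummary
    stratum: str = "tissue"

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(
                f"unknown stratum {self.stratum!r}; expected one of {sorted(STRATA)}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study Hedges' g with its sampling variance and 95% CI."""

    study_id: str
    g: float
    variance: float
    ci_low: float
    ci_high: float
    weight: float = float("nan")  # filled during pooling (percent)


@dataclass(frozen=True)
class PooledResult:
    """Pooled SMD with heterogeneity statistics and decision flags."""

    smd: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: float
    df: int
    p_het: float
    i2: float
    tau2: float
    model: str
    heterogeneity_flag: bool
    significance_flag: bool
    n_studies: int
    omitted: str | None = None

    def as_dict(self) -> dict:
        return {
            "smd": self.smd,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "Q": self.Q,
            "df": self.df,
            "p_het": self.p_het,
            "i2": self.i2,
            "tau2": self.tau2,
            "model": self.model,
            "heterogeneity_flag": self.heterogeneity_flag,
            "significance_flag": self.significance_flag,
            "n_studies": self.n_studies,
            "omitted": self.omitted,
        }


def hedges_g(case: GroupSummary, control: GroupSummary, study_id: str = "") -> EffectEstimate:
    """Standardized mean difference (control minus case) with small-sample bias
    correction.

    d = (control.mean - case.mean) / s_p with the pooled SD
    s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)); the correction factor
    J = 1 - 3/(4 (n1+n2-2) - 1) gives g = J d.  The large-sample variance is
    var(g) = (n1+n2)/(n1 n2) + g^2 / (2 (n1+n2)).

    Raises
    ------
    ValueError
        If the pooled SD is zero while the group means differ (the effect is
        then undefined), or if either group has n < 2.
    """
    n1, n2 = case.n, control.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * case.sd**2 + (n2 - 1) * control.sd**2) / df
    diff = control.mean - case.mean
    if sp2 == 0:
        if diff != 0:
            raise ValueError(
                f"degenerate effect in study {study_id!r}: pooled SD is 0 "
                "but group means differ"
            )
        d = 0.0
    else:
        d = diff / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    n_tot = n1 + n2
    variance = n_tot / (n1 * n2) + g**2 / (2.0 * n_tot)
    half = Z_95 * math.sqrt(variance)
    return EffectEstimate(study_id=study_id, g=g, variance=variance,
                          ci_low=g - half, ci_high=g + half)


def _ci_excludes_units(ci_low: float, ci_high: float) -> bool:
    """True iff neither +1 nor -1 lies in the closed interval [ci_low, ci_high]."""
    return not (ci_low <= 1.0 <= ci_high) and not (ci_low <= -1.0 <= ci_high)


def significance_rule(result: PooledResult) -> bool:
    """Unit-interval significance: the 95% CI must exclude both +1 and -1.

    A CI that merely touches a boundary counts as overlapping it.
    """
    return _ci_excludes_units(result.ci_low, result.ci_high)


def pool_random_effects(effects: Sequence[EffectEstimate], model: str = "random") -> PooledResult:
    """Pool per-study effects with DerSimonian-Laird random-effects weights.

    Fixed-effect weights w = 1/v give Cochran's Q; the method-of-moments
    between-study variance is tau^2 = max(0, (Q - df)/C) with
    C = sum(w) - sum(w^2)/sum(w).  Random weights are w* = 1/(v + tau^2).
    With ``model="fixed"`` tau^2 is forced to 0 (Q, I2 still reported).

    A single study is returned unchanged (Q = 0, df = 0, p_het = 1).
    """
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    if model not in ("random", "fixed"):
        raise ValueError(f"unknown model {model!r}")

    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all effect variances must be > 0")

    w = 1.0 / v
    sw = w.sum()
    g_fe = float(np.sum(w * g) / sw)
    q = float(np.sum(w * (g - g_fe) ** 2))
    df = len(effects) - 1

    if df == 0:
        tau2 = 0.0
        p_het = 1.0
        i2 = 0.0
    else:
        c = sw - float(np.sum(w**2)) / sw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        p_het = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    if model == "fixed":
        tau2_used = 0.0
    else:
        tau2_used = tau2
    w_star = 1.0 / (v + tau2_used)
    sw_star = w_star.sum()
    smd = float(np.sum(w_star * g) / sw_star)
    se = math.sqrt(1.0 / sw_star)
    ci_low, ci_high = smd - Z_95 * se, smd + Z_95 * se
    z = smd / se
    p = 2.0 * float(stats.norm.sf(abs(z)))

    return PooledResult(
        smd=smd,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p=p,
        Q=q,
        df=df,
        p_het=p_het,
        i2=i2,
        tau2=tau2 if model == "random" else tau2,
        model=model,
        heterogeneity_flag=(p_het < 0.05 or i2 > 50.0),
        # paper-faithful decision: conventionally significant (CI excludes 0)
        # AND stable under the unit-interval screen (CI excludes +1 and -1)
        significance_flag=(_ci_excludes_units(ci_low, ci_high)
                           and not (ci_low <= 0.0 <= ci_high)),
        n_studies=len(effects),
    )


def leave_one_out(effects: Sequence[EffectEstimate], model: str = "random") -> list[PooledResult]:
    """Sensitivity analysis: re-pool with each study omitted in turn.

    Returns one :class:`PooledResult` per omitted study, labelled via
    ``omitted``; requires at least two studies.
    """
    if len(effects) < 2:
        raise ValueError("leave-one-out needs at least 2 effects")
    out = []
    for i, e in enumerate(effects):
        rest = [x for j, x in enumerate(effects) if j != i]
        out.append(replace(pool_random_effects(rest, model=model), omitted=e.study_id))
    return out


def effects_from_studies(studies: Iterable[StudyRecord]) -> list[EffectEstimate]:
    """Compute per-study Hedges' g for every record."""
    return [hedges_g(s.case, s.control, study_id=s.study_id) for s in studies]


def subgroup_compare(studies: Sequence[StudyRecord], stratum: str,
                     model: str = "random") -> PooledResult:
    """Pool only the studies belonging to one clinico-pathological stratum."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {sorted(STRATA)}")
    sub = [s for s in studies if s.stratum == stratum]
    if not sub:
        raise ValueError(f"no studies in stratum {stratum!r}")
    return pool_random_effects(effects_from_studies(sub), model=model)


def forest_table(effects: Sequence[EffectEstimate], pooled: PooledResult) -> "list[dict]":
    """Forest-plot data rows: per-study g, CI and random-effects weight (%)."""
    v = np.array([e.variance for e in effects], dtype=float)
    w = 1.0 / (v + pooled.tau2)
    pct = 100.0 * w / w.sum()
    return [
        {
            "study_id": e.study_id,
            "g": e.g,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_percent": float(p),
        }
        for e, p in zip(effects, pct)
    ]
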