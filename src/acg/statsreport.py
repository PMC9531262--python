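"""Group-comparison and correlation reporting.

Continuous clinical parameters are summarised per arm as median with
0.25–0.75 quartiles (linear-interpolation quantiles) and compared by the
Kruskal–Wallis test followed by the Mann–Whitney U test; the binary
CAM-ICU status is compared by the chi-squared test on the 2×2 contingency
table.  The correlation table reports, per clinical parameter, the
absolute Pearson correlation with (a) the dimensionality summary (mean of
the TOF and ATT dimensionalities; per-modality values also emitted) and
(b) the GA-derived first principal component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = ["GroupComparisonRow", "CorrelationRow", "group_compare",
           "correlation_table", "abs_pearson"]

log = logging.getLogger(__name__)

CONTINUOUS_PARAMS = ("sofa", "icdsc", "lactate", "pct", "creatinine", "bilirubin")


@dataclass
class GroupComparisonRow:
    parameter: str
    cg_median: float
    cg_q25: float
    cg_q75: float
    sg_median: float
    sg_q25: float
    sg_q75: float
    p_value: float
    test: str
    significant: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class CorrelationRow:
    parameter: str
    r_dimensionality: float
    r_dim_tof: float
    r_dim_att: float
    r_ga: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _rank_p(cg: np.ndarray, sg: np.ndarray) -> float:
    """Kruskal–Wallis gate, Mann–Whitney U pairwise p.

    Exact U distribution for small tie-free samples (n <= 10 per arm),
    normal approximation with tie correction otherwise.
    """
    stats.kruskal(cg, sg)  # omnibus gate; two groups, reported p is pairwise
    pooled = np.concatenate([cg, sg])
    exact = (len(cg) <= 10 and len(sg) <= 10
             and len(np.unique(pooled)) == len(pooled))
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(cg, sg, alternative="two-sided", method=method).pvalue)


def group_compare(cohort: Cohort, parameters=CONTINUOUS_PARAMS, day: int = 1,
                  alpha: float = 0.05) -> list[GroupComparisonRow]:
    """Arm-vs-arm comparison on one study day, one row per parameter."""
    cg = cohort.subset(group="CG", day=day)
    sg = cohort.subset(group="SG", day=day)
    if not cg or not sg:
        raise ValueError(f"day {day}: both arms must be non-empty")
    rows: list[GroupComparisonRow] = []
    for param in parameters:
        if param == "cam_icu":
            a = np.array([r.cam_icu for r in cg]); b = np.array([r.cam_icu for r in sg])
            table = np.array([[np.sum(a), np.sum(~a)], [np.sum(b), np.sum(~b)]])
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table).pvalue)
            rows.append(GroupComparisonRow(
                parameter=param,
                cg_median=float(np.mean(a)), cg_q25=float("nan"), cg_q75=float("nan"),
                sg_median=float(np.mean(b)), sg_q25=float("nan"), sg_q75=float("nan"),
                p_value=p, test="chi-squared", significant=p < alpha,
            ))
            continue
        try:
            va = np.array([float(getattr(r, param)) for r in cg])
            vb = np.array([float(getattr(r, param)) for r in sg])
        except AttributeError:
            log.warning("parameter %r absent; row skipped", param)
            continue
        qa = np.percentile(va, [25, 50, 75])
        qb = np.percentile(vb, [25, 50, 75])
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        else:
            p = _rank_p(va, vb)
        rows.append(GroupComparisonRow(
            parameter=param,
            cg_median=float(qa[1]), cg_q25=float(qa[0]), cg_q75=float(qa[2]),
            sg_median=float(qb[1]), sg_q25=float(qb[0]), sg_q75=float(qb[2]),
            p_value=p, test="kruskal-wallis→mann-whitney", significant=p < alpha,
        ))
    return rows


def abs_pearson(x, y) -> float:
    """|Pearson r|; missing (nan) when either argument has zero variance."""
    x = np.asarray(x, dtype=float); y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        log.warning("zero-variance input; correlation reported as missing")
        return float("nan")
    return float(abs(stats.pearsonr(x, y).statistic))


def correlation_table(dim_results, ga_components, targets) -> list[CorrelationRow]:
    """Absolute-correlation table of clinical parameters vs. ACG features.

    ``dim_results`` is the patient-day dimensionality list; ``ga_components``
    maps parameter name → per-row GA PC1 scores (a single vector is used for
    every parameter); ``targets`` is a DataFrame aligned with the rows,
    carrying the clinical columns.
    """
    dim_tof = np.array([d.dim_tof for d in dim_results])
    dim_att = np.array([d.dim_att for d in dim_results])
    composite = (dim_tof + dim_att) / 2.0
    rows: list[CorrelationRow] = []
    for param in CONTINUOUS_PARAMS:
        if param not in targets:
            log.warning("target %r missing from table; row skipped", param)
            continue
        y = targets[param].to_numpy(dtype=float)
        if isinstance(ga_components, dict):
            ga = ga_components.get(param)
        else:
            ga = ga_components
        rows.append(CorrelationRow(
            parameter=param,
            r_dimensionality=abs_pearson(composite, y),
            r_dim_tof=abs_pearson(dim_tof, y),
            r_dim_att=abs_pearson(dim_att, y),
            r_ga=abs_pearson(ga, y) if ga is not None else float("nan"),
        ))
    return rows
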