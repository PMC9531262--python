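"""The explained-variance "dimensionality" statistic.

For a T×F matrix of frequency-resolved TOF or ATT time series, the
dimensionality is the minimal number of principal components whose
cumulative explained variance reaches a threshold (90 % in the figure
conventions, 95 % in the worked definition).  It ranges from 1 — all
frequency channels move as one linear combination — to F, one distinct
dynamic per channel, and is read as a measure of asynchronicity of the
frequency channels.

Columns are mean-centred but not variance-scaled before the singular value
decomposition; the threshold comparison uses ``>=`` with an absolute
tolerance of 1e-12 so the count is stable across linear-algebra backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "VarianceProfile",
    "DimensionalityResult",
    "explained_variance_profile",
    "dimensionality",
    "patient_day_dimensionality",
]

log = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass(frozen=True)
class VarianceProfile:
    """Descending explained-variance fractions, one per component."""

    ratios: tuple[float, ...]
    degenerate: bool = False  # all-constant input; profile defined as (1, 0, ...)


@dataclass(frozen=True)
class DimensionalityResult:
    patient_id: str
    day: int
    threshold: float
    dim_tof: float
    dim_att: float
    per_measurement: tuple[tuple[int, int, int], ...] = ()


def _validate(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D T×F array")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need T >= 2 and F >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in data matrix")
    return x


def explained_variance_profile(data: np.ndarray) -> VarianceProfile:
    """Explained-variance fractions of the column-centred data matrix.

    Computed from the singular values of the centred matrix: fraction_i =
    s_i² / Σ s².  All-constant input has no variance to attribute; it is
    flagged degenerate with the conventional profile (1, 0, ..., 0).
    """
    x = _validate(data)
    xc = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    total = float(np.sum(s**2))
    k = min(x.shape)
    if total == 0.0:
        log.warning("zero total variance: all-constant data matrix")
        ratios = np.zeros(k)
        ratios[0] = 1.0
        return VarianceProfile(tuple(ratios), degenerate=True)
    ratios = np.sort(s**2 / total)[::-1]
    return VarianceProfile(tuple(float(r) for r in ratios))


def dimensionality(data: np.ndarray, threshold: float = 0.90) -> int:
    """Minimal number of components reaching the explained-variance threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    profile = explained_variance_profile(data)
    cum = np.cumsum(profile.ratios)
    hit = np.nonzero(cum >= threshold - _TOL)[0]
    # cum[-1] == 1 within rounding, so the search always terminates
    return int(hit[0]) + 1 if hit.size else len(profile.ratios)


def patient_day_dimensionality(
    cohort: Cohort,
    modality: str = "att",
    threshold: float = 0.90,
    stack_session: bool = False,
) -> list[DimensionalityResult]:
    """Dimensionality per patient-day: per-measurement values and their mean.

    ``modality`` selects TOF or ATT for the per-measurement breakdown; both
    per-day means are always reported.  With ``stack_session`` the 10 single
    measurements are stacked in time and analysed as one matrix instead.
    """
    if modality.lower() not in ("tof", "att"):
        raise ValueError("modality must be 'tof' or 'att'")
    results: list[DimensionalityResult] = []
    for rec in cohort.records:
        if not rec.sessions:
            log.warning("patient %s day %d has no sessions; skipped", rec.patient_id, rec.day)
            continue
        if stack_session:
            tof = np.vstack([m.tof for m in rec.sessions])
            att = np.vstack([m.att for m in rec.sessions])
            d_tof = [dimensionality(tof, threshold)]
            d_att = [dimensionality(att, threshold)]
            per = ((0, d_tof[0], d_att[0]),)
        else:
            d_tof = [dimensionality(m.tof, threshold) for m in rec.sessions]
            d_att = [dimensionality(m.att, threshold) for m in rec.sessions]
            per = tuple(
                (m.measurement_index, dt, da)
                for m, dt, da in zip(rec.sessions, d_tof, d_att)
            )
        results.append(DimensionalityResult(
            patient_id=rec.patient_id, day=rec.day, threshold=threshold,
            dim_tof=float(np.mean(d_tof)), dim_att=float(np.mean(d_att)),
            per_measurement=per,
        ))
    return results
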