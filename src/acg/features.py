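"""Feature table construction for GA selection and classification.

Each ACG measurement yields 20 time series (TOF and ATT at 10 frequencies).
The feature vocabulary summarises every channel, every within-modality
frequency pair, and every TOF×ATT frequency pair — deliberately including
the two families reported to carry the signal (attenuation-based summaries
and TOF–ATT interaction terms) — plus spectral slopes and both
explained-variance dimensionality values.  With the default 10-frequency
grid this yields 1,096 deterministic, uniquely named columns, comfortably
above the >1,000 the selection stage assumes.

Feature names follow ``{modality}_{f_i}[_{f_j}]_{stat}`` with ``tofatt``
marking cross-modality pairs.  Patient-day rows are the arithmetic mean of
the 10 measurement-level feature vectors; a measurement-level table is
available for the per-measurement classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, MeasurementSeries
from .dimensionality import dimensionality

__all__ = ["FeatureTable", "build_feature_table", "standardize", "feature_names"]

log = logging.getLogger(__name__)

TARGET_COLUMNS = ("sofa", "icdsc", "lactate", "pct", "creatinine", "bilirubin")
_CHANNEL_STATS = ("mean", "sd", "median", "iqr", "min", "max", "range",
                  "slope", "ac1", "diffrms", "skew", "kurt")
_PAIR_STATS = ("corr", "xcorr1", "meandiff", "meanratio", "sdratio")
_CROSS_STATS = ("corr", "meanprod", "meanratio", "meandiff")


@dataclass
class FeatureTable:
    """N×P feature matrix with aligned clinical targets and row metadata."""

    values: np.ndarray
    feature_names: list[str]
    row_index: list[tuple]          # (patient_id, day) or (patient_id, day, measurement)
    targets: pd.DataFrame           # clinical columns aligned to rows
    meta: pd.DataFrame              # group, severity, cam_icu per row
    standardized: bool = False

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature name count does not match columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(self.row_index) != n or len(self.targets) != n or len(self.meta) != n:
            raise ValueError("row index / targets / meta misaligned with values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.row_index)
        return pd.DataFrame(self.values, index=idx, columns=self.feature_names)


def feature_names(n_frequencies: int) -> list[str]:
    """The deterministic column vocabulary for an F-frequency grid."""
    f = [f"f{i + 1:02d}" for i in range(n_frequencies)]
    names: list[str] = []
    for mod in ("tof", "att"):
        for fi in f:
            names += [f"{mod}_{fi}_{s}" for s in _CHANNEL_STATS]
    for mod in ("tof", "att"):
        for i in range(n_frequencies):
            for j in range(i + 1, n_frequencies):
                names += [f"{mod}_{f[i]}_{f[j]}_{s}" for s in _PAIR_STATS]
    for i in range(n_frequencies):
        for j in range(n_frequencies):
            names += [f"tofatt_{f[i]}_{f[j]}_{s}" for s in _CROSS_STATS]
    for mod in ("tof", "att"):
        names += [f"{mod}_spectrum_meanslope", f"{mod}_spectrum_sdslope"]
    names += ["dim_tof", "dim_att"]
    return names


def _safe_corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix corr(a_i, b_j); zero-variance columns give 0."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    asd = az.std(axis=0)
    bsd = bz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (az.T @ bz) / a.shape[0] / np.outer(asd, bsd)
    c[~np.isfinite(c)] = 0.0
    return c


def _channel_stats(x: np.ndarray) -> np.ndarray:
    """12 summary statistics per column of a T×F matrix, stacked per column."""
    t = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    median = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    mn, mx = x.min(axis=0), x.max(axis=0)
    ti = np.arange(t) - (t - 1) / 2.0
    slope = (ti @ (x - mean)) / (ti @ ti)
    d = np.diff(x, axis=0)
    diffrms = np.sqrt((d**2).mean(axis=0))
    ac1 = np.array([_safe_corr_matrix(x[:-1, [k]], x[1:, [k]])[0, 0] for k in range(x.shape[1])])
    xc = x - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = (xc**2).mean(axis=0)
        skew = (xc**3).mean(axis=0) / m2**1.5
        kurt = (xc**4).mean(axis=0) / m2**2 - 3.0
    skew[~np.isfinite(skew)] = 0.0
    kurt[~np.isfinite(kurt)] = 0.0
    cols = np.vstack([mean, sd, median, q75 - q25, mn, mx, mx - mn,
                      slope, ac1, diffrms, skew, kurt])
    return cols.T.ravel()  # channel-major, stat-minor: matches feature_names


def _pair_feats(x: np.ndarray) -> np.ndarray:
    nf = x.shape[1]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    corr = _safe_corr_matrix(x, x)
    xcorr1 = _safe_corr_matrix(x[:-1], x[1:])
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(nf):
            for j in range(i + 1, nf):
                mr = mean[i] / mean[j] if mean[j] != 0 else 0.0
                sr = sd[i] / sd[j] if sd[j] != 0 else 0.0
                out += [corr[i, j], xcorr1[i, j], mean[i] - mean[j], mr, sr]
    return np.asarray(out)


def _cross_feats(tof: np.ndarray, att: np.ndarray) -> np.ndarray:
    nf = tof.shape[1]
    mt, ma = tof.mean(axis=0), att.mean(axis=0)
    corr = _safe_corr_matrix(tof, att)
    out = []
    for i in range(nf):
        for j in range(nf):
            mr = mt[i] / ma[j] if ma[j] != 0 else 0.0
            out += [corr[i, j], mt[i] * ma[j], mr, mt[i] - ma[j]]
    return np.asarray(out)


def _spectrum_slopes(x: np.ndarray, freqs: np.ndarray) -> list[float]:
    fc = freqs - freqs.mean()
    denom = fc @ fc
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return [float(fc @ (mean - mean.mean()) / denom), float(fc @ (sd - sd.mean()) / denom)]


def measurement_features(m: MeasurementSeries, freqs: np.ndarray,
                         dim_threshold: float = 0.90) -> np.ndarray:
    parts = [
        _channel_stats(m.tof), _channel_stats(m.att),
        _pair_feats(m.tof), _pair_feats(m.att),
        _cross_feats(m.tof, m.att),
        np.asarray(_spectrum_slopes(m.tof, freqs) + _spectrum_slopes(m.att, freqs)),
        np.asarray([dimensionality(m.tof, dim_threshold),
                    dimensionality(m.att, dim_threshold)], dtype=float),
    ]
    v = np.concatenate(parts)
    return np.nan_to_num(v, nan=0.0, posinf=0.0, neginf=0.0)


def build_feature_table(cohort: Cohort, per_measurement: bool = False,
                        dim_threshold: float = 0.90) -> FeatureTable:
    """Assemble the feature table (patient-day rows by default).

    Patient-day rows average the measurement-level feature vectors of the
    session's 10 single measurements, matching the study's per-day averaging
    convention; ``per_measurement=True`` keeps one row per single measurement.
    """
    freqs = cohort.frequency_grid.array
    names = feature_names(len(freqs))
    rows, index, tgt, meta = [], [], [], []
    for rec in cohort.records:
        if not rec.sessions:
            log.warning("patient %s day %d has no sessions; skipped", rec.patient_id, rec.day)
            continue
        per_meas = np.vstack([measurement_features(m, freqs, dim_threshold)
                              for m in rec.sessions])
        t_row = {c: getattr(rec, c) for c in TARGET_COLUMNS}
        m_row = {"group": rec.group, "severity": rec.severity, "cam_icu": rec.cam_icu}
        if per_measurement:
            for m, v in zip(rec.sessions, per_meas):
                rows.append(v)
                index.append((rec.patient_id, rec.day, m.measurement_index))
                tgt.append(t_row)
                meta.append(m_row)
        else:
            rows.append(per_meas.mean(axis=0))
            index.append((rec.patient_id, rec.day))
            tgt.append(t_row)
            meta.append(m_row)
    return FeatureTable(
        values=np.vstack(rows), feature_names=names, row_index=index,
        targets=pd.DataFrame(tgt), meta=pd.DataFrame(meta),
    )


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score every column (sample SD); constant columns become all-zero.

    Idempotent, and makes any affine image of a column numerically identical
    to the column itself — so subset-PCA fitness is unit-invariant.
    """
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    # numerically constant columns (float dust around a fixed value) count as constant
    varying = sd > 1e-9 * np.maximum(np.abs(mean), 1.0)
    z = np.where(varying, (x - mean) / np.where(varying, sd, 1.0), 0.0)
    return replace(table, values=z, standardized=True)
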