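"""Control statistics, plate quality control and the normalization formulas.

Plate quality is gated on the Z' factor

    Z' = 1 - 3 (SDp + SDn) / (mu_n - mu_p)

where mu_n/SDn summarize the negative (vehicle) controls and mu_p/SDp the
positive (inhibitor) controls.  Plates below the Z' threshold go through a
greedy leave-one-out control-outlier removal; plates that cannot be recovered
within the allowed number of removals are flagged for retest.

Per-well normalization produces three quantities:

    % INHIBITION = (1 - (x - mu_p) / (mu_n - mu_p)) * 100
    % N_VALUE    = x / mu_n * 100          (residual signal vs vehicle)
    % N_SCh      = (x - mu_n) / mu_n * 100 (signal change; = N_VALUE - 100)

Sample standard deviations (n-1 denominator) are used throughout, for the
control SDs feeding Z' as well as for CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateControls, MissingControls, ZeroMean
from .plate import AssayConfig, N_COLS, ROWS

PASS = "PASS"
PASS_AFTER_REMOVAL = "PASS_AFTER_REMOVAL"
RETEST = "RETEST"


@dataclass
class ControlStats:
    """Means and sample SDs of the negative and positive control wells."""

    mu_n: float
    mu_p: float
    sd_n: float
    sd_p: float
    n_n: int
    n_p: int


@dataclass
class PlateQC:
    """Outcome of the Z'-gated plate QC."""

    plate_id: str
    zprime_initial: float
    zprime_final: float
    s_over_b: float
    cv_n: float
    cv_p: float
    outliers_removed: list[str] = field(default_factory=list)
    status: str = PASS

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "zprime_initial": self.zprime_initial,
            "zprime_final": self.zprime_final,
            "s_over_b": self.s_over_b,
            "cv_n": self.cv_n,
            "cv_p": self.cv_p,
            "outliers_removed": list(self.outliers_removed),
            "status": self.status,
        }


@dataclass
class PlateEffectReport:
    """Linear-trend summary of the % INHIBITION heatmap of one plate."""

    inhibition_matrix: np.ndarray  # 16 x 24, NaN where unmapped
    row_means: np.ndarray
    col_means: np.ndarray
    row_trend_slope: float  # % inhibition per row index step
    col_trend_slope: float  # % inhibition per column index step
    flagged: bool


def control_stats(wells: pd.DataFrame) -> ControlStats:
    """Means and sample SDs of controls from an annotated well table."""
    neg = wells.loc[wells["role"] == "negative_control", "raw_signal"].to_numpy(float)
    pos = wells.loc[wells["role"] == "positive_control", "raw_signal"].to_numpy(float)
    if len(neg) < 2 or len(pos) < 2:
        raise MissingControls(
            f"need >=2 wells per control group, got {len(neg)} negative / {len(pos)} positive"
        )
    return ControlStats(
        mu_n=float(np.mean(neg)),
        mu_p=float(np.mean(pos)),
        sd_n=float(np.std(neg, ddof=1)),
        sd_p=float(np.std(pos, ddof=1)),
        n_n=len(neg),
        n_p=len(pos),
    )


def zprime(stats: ControlStats) -> float:
    """Z' factor; 1 in the zero-spread limit, may be negative, never > 1."""
    if stats.mu_n == stats.mu_p:
        raise DegenerateControls("mu_n == mu_p: Z' undefined")
    return 1.0 - 3.0 * (stats.sd_p + stats.sd_n) / abs(stats.mu_n - stats.mu_p)


def s_over_b(stats: ControlStats) -> float:
    """Signal-to-background ratio mu_n / mu_p."""
    if stats.mu_p == 0:
        raise ZeroDivisionError("mu_p == 0: S/B undefined")
    return stats.mu_n / stats.mu_p


def cv(values) -> float:
    """Coefficient of variation, % (sample SD / mean * 100)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ZeroMean("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroMean("CV undefined for zero mean")
    return float(np.std(arr, ddof=1) / mean * 100.0)


def _zprime_raw(neg: np.ndarray, pos: np.ndarray) -> float:
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        return -np.inf
    return 1.0 - 3.0 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / abs(mu_n - mu_p)


def qc_plate(wells: pd.DataFrame, config: AssayConfig) -> PlateQC:
    """Z'-gated plate QC with greedy leave-one-out control-outlier removal.

    If the initial Z' clears the threshold the plate passes untouched.
    Otherwise the single control well (either group) whose removal most
    increases Z' is discarded, repeatedly, up to ``config.max_outliers``
    removals; a plate recovering to Z' >= threshold passes with the removed
    wells listed, anything else is flagged ``RETEST``.  A group is never
    reduced below two wells.
    """
    plate_id = str(wells["plate_id"].iloc[0]) if len(wells) else ""
    neg_df = wells[wells["role"] == "negative_control"]
    pos_df = wells[wells["role"] == "positive_control"]
    if len(neg_df) < 2 or len(pos_df) < 2:
        raise MissingControls("plate lacks control wells")

    groups = {
        "negative_control": [neg_df["well"].tolist(), neg_df["raw_signal"].to_numpy(float)],
        "positive_control": [pos_df["well"].tolist(), pos_df["raw_signal"].to_numpy(float)],
    }

    def current_z() -> float:
        return _zprime_raw(groups["negative_control"][1], groups["positive_control"][1])

    z_initial = current_z()
    removed: list[str] = []
    z = z_initial
    status = PASS
    if z < config.zprime_threshold:
        while z < config.zprime_threshold and len(removed) < config.max_outliers:
            best = None  # (z_after, role, index)
            for role, (names, vals) in groups.items():
                if len(vals) <= 2:
                    continue
                for i in range(len(vals)):
                    trial = np.delete(vals, i)
                    if role == "negative_control":
                        z_after = _zprime_raw(trial, groups["positive_control"][1])
                    else:
                        z_after = _zprime_raw(groups["negative_control"][1], trial)
                    if best is None or z_after > best[0]:
                        best = (z_after, role, i)
            if best is None or best[0] <= z:
                break  # no removal improves Z'
            z = best[0]
            names, vals = groups[best[1]]
            removed.append(names.pop(best[2]))
            groups[best[1]][1] = np.delete(vals, best[2])
        status = PASS_AFTER_REMOVAL if z >= config.zprime_threshold else RETEST
        if status == RETEST:
            # removals that did not recover the plate are not applied
            pass

    neg = groups["negative_control"][1]
    pos = groups["positive_control"][1]
    return PlateQC(
        plate_id=plate_id,
        zprime_initial=float(z_initial),
        zprime_final=float(z),
        s_over_b=float(neg.mean() / pos.mean()),
        cv_n=cv(neg),
        cv_p=cv(pos),
        outliers_removed=removed,
        status=status,
    )


def normalize(
    wells: pd.DataFrame,
    stats: ControlStats,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Attach % INHIBITION, % N_VALUE and % N_SCh columns.

    Values outside [0, 100] are permitted (stimulation, over-quenching).
    Controls are normalized too by default, for diagnostics and for the
    t-tests against negative controls downstream.
    """
    if stats.mu_n == stats.mu_p:
        raise DegenerateControls("mu_n == mu_p")
    if stats.mu_n == 0:
        raise DegenerateControls("mu_n == 0")
    out = wells if include_controls else wells[wells["role"] == "sample"]
    out = out.copy()
    x = out["raw_signal"].to_numpy(float)
    out["pct_inhibition"] = (1.0 - (x - stats.mu_p) / (stats.mu_n - stats.mu_p)) * 100.0
    out["pct_n_value"] = x / stats.mu_n * 100.0
    out["pct_n_sch"] = (x - stats.mu_n) / stats.mu_n * 100.0
    return out


def plate_effect_summary(
    normalized: pd.DataFrame,
    iqr_fraction: float = 0.05,
    value_column: str = "pct_inhibition",
) -> PlateEffectReport:
    """Least-squares row/column trend of the % INHIBITION heatmap.

    A plate is flagged when either trend slope exceeds ``iqr_fraction`` of
    the plate's interquartile range per well-index step (with a floor of one
    percentage point on the IQR, so an exactly uniform plate never flags and
    a single hot well among 384 stays below threshold).
    """
    mat = np.full((len(ROWS), N_COLS), np.nan)
    for well, value in zip(normalized["well"], normalized[value_column]):
        r = ROWS.index(well[0])
        c = int(well[1:]) - 1
        mat[r, c] = value

    flat = mat[np.isfinite(mat)]

    def _axis_means(m: np.ndarray, axis: int) -> np.ndarray:
        counts = np.isfinite(m).sum(axis=axis)
        sums = np.nansum(np.where(np.isfinite(m), m, 0.0), axis=axis)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    row_means = _axis_means(mat, 1)
    col_means = _axis_means(mat, 0)

    def slope(values: np.ndarray) -> float:
        idx = np.arange(len(values), dtype=float)
        ok = np.isfinite(values)
        if ok.sum() < 2:
            return 0.0
        return float(np.polyfit(idx[ok], values[ok], 1)[0])

    row_slope = slope(row_means)
    col_slope = slope(col_means)
    iqr = float(np.percentile(flat, 75) - np.percentile(flat, 25)) if flat.size else 0.0
    threshold = iqr_fraction * max(iqr, 1.0)
    flagged = abs(row_slope) > threshold or abs(col_slope) > threshold
    return PlateEffectReport(
        inhibition_matrix=mat,
        row_means=row_means,
        col_means=col_means,
        row_trend_slope=row_slope,
        col_trend_slope=col_slope,
        flagged=flagged,
    )
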