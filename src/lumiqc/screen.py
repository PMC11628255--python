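"""Screen-level outputs: residual-signal tables with colour bands and
significance stars, IC50 grids across assays, modifier-effect comparisons and
potency-order consistency checks.

Residual signal is the bioluminescence remaining after metal addition as a
percentage of the negative control (100%: no effect, 0%: full quenching).
Cells are banded strong / moderate / weak / none on the half-open partition
[0,10) / [10,50) / [50,80) / [80,inf) and starred by a two-tailed Student's
t-test against the plate's negative controls at p < 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dose_response import (
    GREATER_THAN,
    INTERVAL,
    LESS_THAN,
    NONE,
    OK,
    POINT,
    CensoredIC50,
    FitResult,
)
from .errors import InsufficientOverlap, NegativeResidual, UnmatchedCells

#: half-open residual-% bands; upper edge excluded, last band unbounded
BAND_EDGES: list[tuple[float, float, str]] = [
    (0.0, 10.0, "strong"),
    (10.0, 50.0, "moderate"),
    (50.0, 80.0, "weak"),
    (80.0, float("inf"), "none"),
]

#: reference potency order of divalent metal-ligand complex stabilities
IRVING_WILLIAMS = ("Cu", "Zn", "Fe", "Mn", "Ca", "Mg")


@dataclass(frozen=True)
class Band:
    label: str
    lo: float
    hi: float


@dataclass
class ComparisonResult:
    """Baseline-vs-modifier contrast for one metal/concentration cell."""

    condition_id: str
    baseline_mean: float
    condition_mean: float
    delta: float
    p_value: float
    significant: bool


def band(residual_pct: float) -> Band:
    """Colour band for a residual-signal percentage (>= 0)."""
    if residual_pct < 0:
        raise NegativeResidual(f"residual {residual_pct}% is negative")
    for lo, hi, label in BAND_EDGES:
        if lo <= residual_pct < hi:
            return Band(label, lo, hi)
    raise AssertionError("unreachable: bands partition [0, inf)")


def ttest_vs_negative(sample, negative) -> tuple[float, bool]:
    """Two-tailed Student's (equal-variance) t-test; significant at p < 0.05.

    Degenerate zero-variance groups are resolved deterministically: both
    groups constant and equal -> p = 1; constant and unequal -> p = 0.
    """
    a = np.asarray(sample, dtype=float)
    b = np.asarray(negative, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    return p, p < 0.05


def residual_table(
    normalized: pd.DataFrame,
    value_column: str = "pct_n_value",
) -> pd.DataFrame:
    """Per-(compound, assay, concentration) residual-signal summary.

    Expects a normalized well table (multiple plates allowed) that still
    carries the control rows.  Returns mean, SD, n, colour band, t-test
    p-value vs the same plate's negative controls and the low-replicate flag.
    Means below 0 (noise on a fully quenched well) are clamped to 0 for
    banding only.
    """
    samples = normalized[normalized["role"] == "sample"]
    rows = []
    for (compound, assay, conc), grp in samples.groupby(
        ["compound_id", "assay_id", "concentration_um"], sort=True
    ):
        values = grp[value_column].to_numpy(float)
        plate_ids = grp["plate_id"].unique()
        negatives = normalized[
            (normalized["role"] == "negative_control")
            & normalized["plate_id"].isin(plate_ids)
        ][value_column].to_numpy(float)
        p_value, significant = ttest_vs_negative(values, negatives)
        mean = float(values.mean())
        rows.append(
            {
                "compound_id": compound,
                "assay_id": assay,
                "concentration_um": conc,
                "mean": mean,
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
                "n": len(values),
                "band": band(max(mean, 0.0)).label,
                "p_value": p_value,
                "significant": significant,
                "low_n": len(values) < 3,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IC50 grid rendering
# ---------------------------------------------------------------------------

def render_ic50(value: CensoredIC50, quality: str = OK) -> str:
    """Render a censored IC50 the way screening tables print it.

    Point -> "0.24"; bounds -> ">5000" / "<0.01"; interval ->
    "0.016 < IC50 < 0.063"; empty -> "n/a".  Unsuitable or failed fits carry
    a trailing "*".
    """
    fmt = lambda v: f"{v:.6g}"
    if value.kind == POINT:
        cell = fmt(value.value_um)
    elif value.kind == GREATER_THAN:
        cell = f">{fmt(value.lo_um)}"
    elif value.kind == LESS_THAN:
        cell = f"<{fmt(value.hi_um)}"
    elif value.kind == INTERVAL:
        cell = f"{fmt(value.lo_um)} < IC50 < {fmt(value.hi_um)}"
    else:
        cell = "n/a"
    if quality != OK and value.kind != NONE:
        cell += "*"
    return cell


_INTERVAL_RE = re.compile(r"^\s*([\d.eE+-]+)\s*<\s*IC50\s*<\s*([\d.eE+-]+)\s*$")


def parse_ic50(cell: str) -> CensoredIC50:
    """Inverse of :func:`render_ic50` (the quality star is dropped)."""
    s = cell.strip().rstrip("*").strip()
    if s in ("", "n/a"):
        return CensoredIC50.none()
    if s.startswith(">"):
        return CensoredIC50.greater_than(float(s[1:]))
    if s.startswith("<"):
        return CensoredIC50.less_than(float(s[1:]))
    m = _INTERVAL_RE.match(s)
    if m:
        return CensoredIC50.interval(float(m.group(1)), float(m.group(2)))
    return CensoredIC50.point(float(s))


def ic50_grid(fits: dict[tuple[str, str], FitResult]) -> pd.DataFrame:
    """Compound x assay grid of rendered IC50 cells.

    ``fits`` maps (compound_id, assay_id) to a :class:`FitResult`; missing
    cells render as "n/a".
    """
    compounds = sorted({k[0] for k in fits})
    assays = sorted({k[1] for k in fits})
    grid = pd.DataFrame(index=compounds, columns=assays, data="n/a")
    grid.index.name = "compound_id"
    for (compound, assay), fit in fits.items():
        grid.loc[compound, assay] = render_ic50(fit.ic50, fit.quality)
    return grid


# ---------------------------------------------------------------------------
# potency ordering
# ---------------------------------------------------------------------------

def potency_ranking(ic50s: dict[str, CensoredIC50]) -> list[str]:
    """Compound ids ordered by ascending potency-rank IC50.

    Left-censored values (``<bound``) sort before all point estimates,
    right-censored (``>bound``) after; within a censoring class the bound or
    value decides, and ties fall back to the id for determinism.
    """
    def key(item):
        cid, v = item
        if v.kind == LESS_THAN:
            return (0, v.hi_um, cid)
        if v.kind == POINT:
            return (1, v.value_um, cid)
        if v.kind == INTERVAL:
            return (1, float(np.sqrt(v.lo_um * v.hi_um)), cid)
        if v.kind == GREATER_THAN:
            return (2, v.lo_um, cid)
        return (3, 0.0, cid)
    return [cid for cid, _ in sorted(ic50s.items(), key=key)]


def rank_consistency(
    observed_order,
    reference_order=IRVING_WILLIAMS,
) -> float:
    """Spearman rank correlation between an observed potency order and a
    reference order, over their shared compounds (>= 3 required)."""
    shared = [c for c in observed_order if c in reference_order]
    if len(shared) < 3:
        raise InsufficientOverlap(
            f"only {len(shared)} shared compounds between orders"
        )
    obs_rank = [shared.index(c) for c in shared]
    ref_rank = [sorted(shared, key=list(reference_order).index).index(c) for c in shared]
    rho = sps.spearmanr(obs_rank, ref_rank).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# modifier comparisons (EDTA / GSH / pre-incubation)
# ---------------------------------------------------------------------------

def modifier_effect(
    baseline_values,
    modifier_values,
    condition_id: str,
) -> ComparisonResult:
    """Contrast one cell (metal x concentration) between the original
    screening condition and a modifier condition (e.g. "EDTA 0.5 mM").

    Both inputs must already be normalized against the baseline condition's
    negative control so the delta is on a common % scale.
    """
    a = np.asarray(baseline_values, dtype=float)
    b = np.asarray(modifier_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UnmatchedCells(f"condition {condition_id!r}: empty cell")
    p_value, significant = ttest_vs_negative(b, a)
    return ComparisonResult(
        condition_id=condition_id,
        baseline_mean=float(a.mean()),
        condition_mean=float(b.mean()),
        delta=float(b.mean() - a.mean()),
        p_value=p_value,
        significant=significant,
    )
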