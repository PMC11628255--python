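"""Synthetic 384-well plates and dose-response experiments.

The generator reproduces the statistical structure the analysis assumes:
negative/positive control wells drawn from truncated normal distributions
whose closed-form Z' and S/B match the published per-assay quality
parameters, triplicate sample wells following LL.4 inhibition truths taken
from the published per-assay IC50 grid, multiplicative replicate noise, and
optional artefacts (linear plate gradients, aberrant control wells) to
exercise the QC path.

Raw sample counts are built on the control-defined window:

    raw = mu_p + f(dose)/100 * (mu_n - mu_p),   f = LL.4 truth in residual %

then multiplied by ``max(0, Normal(1, cv))`` noise.  Every stream is seeded;
a per-plate stream is derived from (master seed, plate_id) via CRC32 so plate
generation is reproducible independent of order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .dose_response import DoseResponseData, LL4Params, ll4
from .errors import InvalidRange, LayoutOverflow, UnknownScenario
from .plate import (
    AssayConfig,
    N_COLS,
    Plate,
    PlateMap,
    ROWS,
    WellAddress,
    WellRole,
)


@dataclass
class SimulationSpec:
    """Generator configuration for one assay's plates."""

    assay: AssayConfig
    mu_n: float
    sd_n: float
    mu_p: float
    sd_p: float
    n_neg: int = 16
    n_pos: int = 16
    noise_cv: float = 10.0  # % multiplicative noise on sample wells
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_n > self.mu_p > 0):
            raise ValueError("need mu_n > mu_p > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class TrueResponse:
    """Ground-truth LL.4 curve for one compound, residual-%-signal scale."""

    compound_id: str
    params: LL4Params


@dataclass
class ArtifactSpec:
    """Optional plate artefacts: a linear gradient and/or control outliers."""

    gradient_axis: str | None = None  # "row" or "col"
    gradient_slope_pct: float = 0.0  # % signal change per index step
    outlier_count: int = 0
    outlier_multiplier: float = 0.1  # factor applied to the outlier wells
    outlier_role: str = "negative_control"


def closed_form_zprime(spec: SimulationSpec) -> float:
    """Z' implied by the generating control distributions."""
    return 1.0 - 3.0 * (spec.sd_p + spec.sd_n) / (spec.mu_n - spec.mu_p)


def closed_form_sb(spec: SimulationSpec) -> float:
    """S/B implied by the generating control distributions."""
    return spec.mu_n / spec.mu_p


def plate_rng(master_seed: int, plate_id: str) -> np.random.Generator:
    """Per-plate stream derived from (master seed, plate_id) via CRC32."""
    tag = zlib.crc32(f"{master_seed}:{plate_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((master_seed, tag)))


def build_platemap(
    truths: list[TrueResponse],
    doses_um: list[float] | dict[str, list[float]],
    n_rep: int = 3,
    n_neg: int = 16,
    n_pos: int = 16,
) -> PlateMap:
    """Default layout: negative controls fill column 23 top-down, positive
    controls column 24; sample triplicates fill columns 1-22 row-major.

    ``doses_um`` is either one shared dose list or a per-compound mapping.
    """
    if n_neg > len(ROWS) or n_pos > len(ROWS):
        raise LayoutOverflow("more control wells than rows")
    if not isinstance(doses_um, dict):
        doses_um = {t.compound_id: list(doses_um) for t in truths}
    entries: dict[WellAddress, WellRole] = {}
    for i in range(n_neg):
        entries[WellAddress(ROWS[i], 23)] = WellRole(kind="negative_control")
    for i in range(n_pos):
        entries[WellAddress(ROWS[i], 24)] = WellRole(kind="positive_control")

    sample_slots = [
        WellAddress(r, c) for r in ROWS for c in range(1, N_COLS - 1)
    ]
    needed = sum(len(doses_um[t.compound_id]) for t in truths) * n_rep
    if needed > len(sample_slots):
        raise LayoutOverflow(
            f"{needed} sample wells requested, {len(sample_slots)} available"
        )
    it = iter(sample_slots)
    for truth in truths:
        for dose in doses_um[truth.compound_id]:
            for rep in range(n_rep):
                entries[next(it)] = WellRole(
                    kind="sample",
                    compound_id=truth.compound_id,
                    concentration_um=float(dose),
                    replicate_group=f"{truth.compound_id}@{dose:g}µM",
                )
    for addr in it:
        entries[addr] = WellRole(kind="empty")
    # remaining control-column rows stay empty
    for i in range(n_neg, len(ROWS)):
        entries[WellAddress(ROWS[i], 23)] = WellRole(kind="empty")
    for i in range(n_pos, len(ROWS)):
        entries[WellAddress(ROWS[i], 24)] = WellRole(kind="empty")
    return PlateMap(entries=entries)


def simulate_plate(
    spec: SimulationSpec,
    truths: list[TrueResponse],
    doses_um: list[float] | dict[str, list[float]],
    artifacts: ArtifactSpec | None = None,
    plate_id: str = "SIM-001",
    n_rep: int = 3,
    platemap: PlateMap | None = None,
) -> tuple[Plate, PlateMap]:
    """Generate one raw plate and its platemap.

    Control wells ~ Normal(mu, sd) clipped at 0; sample wells follow the
    LL.4 truths on the control window with multiplicative noise; artefacts
    (gradient, outliers) are applied last.  Fully reproducible from
    (spec.seed, plate_id).
    """
    rng = plate_rng(spec.seed, plate_id)
    if platemap is None:
        platemap = build_platemap(
            truths, doses_um, n_rep=n_rep, n_neg=spec.n_neg, n_pos=spec.n_pos
        )
    truth_by_id = {t.compound_id: t for t in truths}

    wells: dict[WellAddress, float] = {}
    for addr in sorted(platemap.entries):
        role = platemap.entries[addr]
        if role.kind == "negative_control":
            value = max(0.0, rng.normal(spec.mu_n, spec.sd_n))
        elif role.kind == "positive_control":
            value = max(0.0, rng.normal(spec.mu_p, spec.sd_p))
        elif role.kind == "sample":
            truth = truth_by_id[role.compound_id]
            frac = float(ll4(role.concentration_um, truth.params)) / 100.0
            clean = spec.mu_p + frac * (spec.mu_n - spec.mu_p)
            value = max(0.0, clean * max(0.0, rng.normal(1.0, spec.noise_cv / 100.0)))
        else:  # empty
            value = 0.0
        wells[addr] = value

    if artifacts is not None:
        if artifacts.gradient_axis:
            for addr in wells:
                idx = ROWS.index(addr.row) if artifacts.gradient_axis == "row" else addr.col - 1
                wells[addr] *= 1.0 + artifacts.gradient_slope_pct / 100.0 * idx
        if artifacts.outlier_count:
            candidates = sorted(
                a for a, r in platemap.entries.items() if r.kind == artifacts.outlier_role
            )
            picks = rng.choice(len(candidates), size=artifacts.outlier_count, replace=False)
            for i in picks:
                wells[candidates[i]] *= artifacts.outlier_multiplier

    plate = Plate(plate_id=plate_id, wells=wells, assay_id=spec.assay.assay_id)
    return plate, platemap


def simulate_experiment(
    truth: TrueResponse,
    n_conc: int = 11,
    n_rep: int = 3,
    crange: tuple[float, float] = (0.001, 100.0),
    noise_cv: float = 10.0,
    seed: int = 0,
) -> DoseResponseData:
    """Dose-response observations already on the residual-%-signal scale.

    ``n_conc`` log-spaced concentrations over ``crange`` x ``n_rep``
    replicates, each multiplied by max(0, Normal(1, cv)) noise.
    """
    cmin, cmax = crange
    if not (0 < cmin < cmax):
        raise InvalidRange(f"bad concentration range {crange}")
    if n_conc < 2:
        raise InvalidRange("need >= 2 concentrations")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    concs = np.geomspace(cmin, cmax, n_conc)
    conc = np.repeat(concs, n_rep)
    clean = ll4(conc, truth.params)
    noise = np.maximum(0.0, rng.normal(1.0, noise_cv / 100.0, size=conc.shape))
    return DoseResponseData(
        compound_id=truth.compound_id,
        concentration_um=conc,
        response=clean * noise,
        replicate=np.tile(np.arange(n_rep), n_conc),
    )


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

#: published per-assay quality parameters (Z', S/B) the control
#: distributions are calibrated to reproduce in closed form
ASSAY_QUALITY: dict[str, tuple[float, float]] = {
    "FLuc_SC": (0.64, 136.0),
    "FLuc_H": (0.56, 85.0),
    "NLuc_SC": (0.82, 18.0),
    "NLuc_H": (0.88, 40.0),
    "RLuc_SC": (0.62, 11.0),
    "RLuc_H": (0.53, 11.0),
}

#: typical raw negative-control intensities per luciferase (arbitrary counts;
#: NLuc is by far the brightest reporter)
_MU_N = {"FLuc": 1.0e6, "NLuc": 5.0e6, "RLuc": 2.0e5}

_POSITIVE_CONTROLS = {
    "FLuc": ("PTC-124", 1.0, 0.04),
    "NLuc": ("isradipine", 10.0, 0.4),
    "RLuc": ("BTS", 10.0, 0.08),
}

#: published IC50 grid (µM) per metal salt and assay; strings encode the
#: published censoring ( ">5000", "<0.01", intervals )
IC50_TABLE: dict[str, dict[str, str]] = {
    "Ag":       {"FLuc_SC": "0.24", "FLuc_H": "<0.01", "NLuc_SC": "4.50", "NLuc_H": "46.63", "RLuc_SC": "68.44", "RLuc_H": "26.98"},
    "Cd":       {"FLuc_SC": "568.55", "FLuc_H": "1.21", "NLuc_SC": "1633.95", "NLuc_H": "88.31", "RLuc_SC": "536.75", "RLuc_H": "294.56"},
    "Co(II)":   {"FLuc_SC": "726.99", "FLuc_H": "31.54", "NLuc_SC": "3996.84", "NLuc_H": ">5000", "RLuc_SC": "688.50", "RLuc_H": ">5000"},
    "Cu(I)":    {"FLuc_SC": "408.12", "FLuc_H": "0.016 < IC50 < 0.063", "NLuc_SC": "46.64", "NLuc_H": "56.45", "RLuc_SC": "363.64", "RLuc_H": "18.51"},
    "Cu(II)":   {"FLuc_SC": "125.35", "FLuc_H": "0.07", "NLuc_SC": "31.08", "NLuc_H": "22.38", "RLuc_SC": "132.36", "RLuc_H": "7.79"},
    "Fe(II)-1": {"FLuc_SC": "180.67", "FLuc_H": "23.76", "NLuc_SC": "294.34", "NLuc_H": "336.44", "RLuc_SC": "107.62", "RLuc_H": "43.08"},
    "Fe(II)-2": {"FLuc_SC": "264.05", "FLuc_H": "22.89", "NLuc_SC": "883.48", "NLuc_H": "364.32", "RLuc_SC": "117.53", "RLuc_H": "40.47"},
    "Fe(II)-3": {"FLuc_SC": "256.96", "FLuc_H": "2.73", "NLuc_SC": "438.79", "NLuc_H": "316.77", "RLuc_SC": "114.89", "RLuc_H": "47.27"},
    "Fe(III)":  {"FLuc_SC": "23.91", "FLuc_H": "22.32", "NLuc_SC": "816.32", "NLuc_H": "130.01", "RLuc_SC": "535.61", "RLuc_H": "62.54"},
    "Ga":       {"FLuc_SC": "14.94", "FLuc_H": "10.54", "NLuc_SC": "1815.21", "NLuc_H": "2125.75", "RLuc_SC": "4285.96", "RLuc_H": "397.97"},
    "Pb(II)":   {"FLuc_SC": "737.41", "FLuc_H": "2.74", "NLuc_SC": ">5000", "NLuc_H": "541.60", "RLuc_SC": "2558.78", "RLuc_H": "598.29"},
    "Pt(II)":   {"FLuc_SC": "42.97", "FLuc_H": "39.93", "NLuc_SC": "258.81", "NLuc_H": "246.10", "RLuc_SC": "350.43", "RLuc_H": "723.68"},
    "Sn(II)":   {"FLuc_SC": "85.45", "FLuc_H": ">5000", "NLuc_SC": "2099.27", "NLuc_H": ">5000", "RLuc_SC": ">5000", "RLuc_H": ">5000"},
    "Zn":       {"FLuc_SC": "1200.65", "FLuc_H": "0.88", "NLuc_SC": "106.40", "NLuc_H": "128.18", "RLuc_SC": "4268.64", "RLuc_H": "196.40"},
}

#: concentration ceiling of the widest tested grids (µM)
GRID_MAX_UM = 5000.0

#: metals carried into the modifier (EDTA / GSH / pre-incubation) follow-ups
MODIFIER_METALS = ("Ag", "Cu(II)", "Fe(II)-1", "Fe(II)-2", "Fe(III)", "Zn")


def _truth_from_entry(compound_id: str, entry: str) -> TrueResponse:
    """LL.4 truth for one published IC50 cell.

    Right-censored entries are modelled with the inflection at 5x the grid
    maximum and a raised lower plateau (the response never reaches 50%
    inhibition in range), so the censoring path is exercised; left-censored
    entries put the inflection well below the smallest tested concentration;
    interval entries use the geometric midpoint.
    """
    s = entry.strip()
    if s.startswith(">"):
        params = LL4Params(b=1.0, c=60.0, d=100.0, e=5.0 * float(s[1:]))
    elif s.startswith("<"):
        params = LL4Params(b=1.0, c=0.0, d=100.0, e=float(s[1:]) / 5.0)
    elif "<" in s:  # "lo < IC50 < hi"
        lo, hi = (float(p.strip()) for p in s.replace("IC50", "").split("<") if p.strip())
        params = LL4Params(b=1.0, c=0.0, d=100.0, e=float(np.sqrt(lo * hi)))
    else:
        params = LL4Params(b=1.0, c=0.0, d=100.0, e=float(s))
    return TrueResponse(compound_id=compound_id, params=params)


def _assay_spec(assay_id: str, seed: int = 0) -> SimulationSpec:
    luciferase, buffer = assay_id.split("_")
    zp, sb = ASSAY_QUALITY[assay_id]
    mu_n = _MU_N[luciferase]
    mu_p = mu_n / sb
    sd_total = (1.0 - zp) * (mu_n - mu_p) / 3.0
    # apportion the SD budget in proportion to the means (similar CVs)
    sd_n = sd_total * mu_n / (mu_n + mu_p)
    sd_p = sd_total * mu_p / (mu_n + mu_p)
    name, conc, dmso = _POSITIVE_CONTROLS[luciferase]
    return SimulationSpec(
        assay=AssayConfig(
            luciferase=luciferase,
            buffer=buffer,
            positive_control_name=name,
            positive_control_um=conc,
            dmso_fraction_pct=dmso,
        ),
        mu_n=mu_n,
        sd_n=sd_n,
        mu_p=mu_p,
        sd_p=sd_p,
        seed=seed,
    )


def default_range(truth: TrueResponse) -> tuple[float, float]:
    """A sensible 11-point grid span for a truth: centred on the inflection,
    capped at the widest grid actually used for weak inhibitors."""
    e = truth.params.e
    if e > GRID_MAX_UM:  # right-censored truth: test up to the grid ceiling
        return (GRID_MAX_UM / 1e5, GRID_MAX_UM)
    lo = max(e / 300.0, 1e-5)
    hi = min(e * 300.0, GRID_MAX_UM * 4)
    return (lo, hi)


def scenario_library(name: str, seed: int = 0) -> tuple[SimulationSpec, list[TrueResponse]]:
    """Ready-to-run presets.

    Six assay presets ("FLuc_SC" ... "RLuc_H") carry control distributions
    whose closed-form Z'/S/B equal the published per-assay values and LL.4
    truths from the published IC50 grid.  Modifier presets reuse an assay
    preset with the follow-up metals and a perturbation:

    - "EDTA_0p5mM_RLuc" / "EDTA_0p5mM_NLuc": chelation restores the lower
      plateau to ~90% residual signal.
    - "GSH_2mM_FLuc": thiol quenching collapses the whole signal window
      (negative controls included) to near the positive-control floor.
    - "preincubation_EM_FLuc": 30-min enzyme+metal pre-incubation, modelled
      as a 3x potency increase (inflection / 3).
    """
    if name in ASSAY_QUALITY:
        spec = _assay_spec(name, seed=seed)
        truths = [_truth_from_entry(m, IC50_TABLE[m][name]) for m in IC50_TABLE]
        return spec, truths

    if name in ("EDTA_0p5mM_RLuc", "EDTA_0p5mM_NLuc"):
        base = "RLuc_SC" if name.endswith("RLuc") else "NLuc_SC"
        spec = _assay_spec(base, seed=seed)
        truths = []
        for m in MODIFIER_METALS:
            t = _truth_from_entry(m, IC50_TABLE[m][base])
            t.params.c = 90.0  # chelated metal no longer quenches
            truths.append(t)
        return spec, truths

    if name == "GSH_2mM_FLuc":
        spec = _assay_spec("FLuc_SC", seed=seed)
        # no signal in any well: the vehicle window collapses onto the floor
        spec.mu_n = spec.mu_p + 0.005 * (spec.mu_n - spec.mu_p)
        spec.sd_n = 0.1 * spec.mu_n
        truths = [_truth_from_entry(m, IC50_TABLE[m]["FLuc_SC"]) for m in MODIFIER_METALS]
        return spec, truths

    if name == "preincubation_EM_FLuc":
        spec = _assay_spec("FLuc_SC", seed=seed)
        truths = []
        for m in MODIFIER_METALS:
            t = _truth_from_entry(m, IC50_TABLE[m]["FLuc_SC"])
            t.params.e /= 3.0
            truths.append(t)
        return spec, truths

    raise UnknownScenario(
        f"unknown scenario {name!r}; known: {sorted(available_scenarios())}"
    )


def available_scenarios() -> list[str]:
    return sorted(ASSAY_QUALITY) + [
        "EDTA_0p5mM_NLuc",
        "EDTA_0p5mM_RLuc",
        "GSH_2mM_FLuc",
        "preincubation_EM_FLuc",
    ]
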