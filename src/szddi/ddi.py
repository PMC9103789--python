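"""Dynamic drug–drug interaction simulation stratified by CYP3A5 genotype.

A perpetrator compound inhibits the victim's CYP3A4/CYP3A5 clearance through
two mechanisms driven by its unbound liver concentration Iu:

* reversible (competitive) inhibition — each enzyme's intrinsic clearance is
  scaled by ``1/(1 + Iu/Ki)``;
* mechanism-based (time-dependent) inactivation — active enzyme is destroyed
  at ``kobs = kinact·Iu/(KI + Iu)`` and resynthesized at ``kdeg``, so the
  active fraction obeys ``df/dt = kdeg·(1-f) - kobs·f``.

CYP3A5 genotype enters through the abundance scalar (0 for *3/*3
non-expressers, 0.5 for *1/*3 expressers by default) and hence through the
victim's baseline fm split, which :func:`calibrate_baseline` pins to the
genotype-specific control exposures of the victim.

The headline output is the AUC ratio (AUCR): victim AUC with perpetrator
over victim AUC alone, over a 120-h window after the victim dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .exceptions import CalibrationError, ConfigurationError, DomainError
from .pbpk import (
    CYP_ENZYMES,
    CompoundParams,
    DoseRegimen,
    PhysiologyParams,
    pk_metrics,
    simulate,
)

__all__ = [
    "Mode",
    "EnzymeInhibition",
    "InteractionSpec",
    "ConstantExposure",
    "GenotypeScenario",
    "DDIResult",
    "load_interaction",
    "inhibition_terms",
    "enzyme_turnover_rhs",
    "calibrate_baseline",
    "run_ddi",
    "static_aucr_oracle",
    "scenario_table",
    "run_scenario_grid",
    "REFERENCE_DOSES",
    "VICTIM_DOSE_MG",
    "AUC_WINDOW_H",
    "default_scenarios",
]

Mode = Literal["RI_only", "TDI_only", "RI_and_TDI"]

#: Perpetrator dosing used in the reference DDI designs (mg): single dose and
#: twice-daily dose for the 13.5-day multiple-dose arm.
REFERENCE_DOSES = {"SZA": {"single": 33.6, "bid": 16.8}, "SZB": {"single": 10.8, "bid": 5.4}}
VICTIM_DOSE_MG = 2.0
AUC_WINDOW_H = 120.0
_BID_INTERVAL_H = 12.0
_BID_DOSES = 27  # 13.5 days b.i.d.; victim dosed 12 h after the last


class EnzymeInhibition(BaseModel):
    """Inhibition constants of the perpetrator on one enzyme (all µM/min⁻¹)."""

    ki: float | None = Field(default=None, gt=0)
    KI: float | None = Field(default=None, gt=0)
    kinact: float | None = Field(default=None, gt=0)


class InteractionSpec(BaseModel):
    """Perpetrator inhibition parameters and active mechanism mode."""

    perpetrator: str
    mode: Mode = "RI_and_TDI"
    enzymes: dict[str, EnzymeInhibition]

    @model_validator(mode="after")
    def _consistent(self):
        unknown = set(self.enzymes) - set(CYP_ENZYMES)
        if unknown:
            raise ValueError(f"unknown enzymes {sorted(unknown)}")
        if not self.enzymes:
            raise ValueError("interaction spec lists no enzymes")
        for name, e in self.enzymes.items():
            if self.mode in ("RI_only", "RI_and_TDI") and e.ki is None:
                raise ConfigurationError(
                    f"mode {self.mode} requires ki for {name}"
                )
            if self.mode in ("TDI_only", "RI_and_TDI") and (
                e.KI is None or e.kinact is None
            ):
                raise ConfigurationError(
                    f"mode {self.mode} requires KI and kinact for {name}"
                )
        return self

    def with_mode(self, mode: Mode) -> "InteractionSpec":
        """Restrict the spec to one mechanism; raises ConfigurationError if
        the required constants are absent."""
        return InteractionSpec(
            perpetrator=self.perpetrator, mode=mode, enzymes=self.enzymes
        )

    def terms(self, enzyme: str, iu_uM: float) -> tuple[float, float]:
        return inhibition_terms(iu_uM, self, enzyme)


@dataclass(frozen=True)
class ConstantExposure:
    """Wrap an :class:`InteractionSpec` with a fixed unbound inhibitor level
    (µM), for infusion-limit checks against the static AUCR oracle."""

    spec: InteractionSpec
    constant_iu_uM: float

    def terms(self, enzyme: str, iu_uM: float) -> tuple[float, float]:
        return self.spec.terms(enzyme, self.constant_iu_uM)


class GenotypeScenario(BaseModel):
    """CYP3A5 genotype stratum: abundance scalar and victim fm split."""

    label: Literal["expresser", "non_expresser"]
    cyp3a5_abundance_scalar: float = Field(ge=0)
    fm_cyp3a4: float = Field(ge=0, le=1)
    fm_cyp3a5: float = Field(ge=0, le=1)
    fm_other: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _fm(self):
        total = self.fm_cyp3a4 + self.fm_cyp3a5 + self.fm_other
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fm values must sum to 1, got {total}")
        if self.label == "non_expresser" and self.fm_cyp3a5 != 0:
            raise ValueError("non-expresser must have fm_cyp3a5 = 0")
        return self

    @property
    def fm(self) -> dict[str, float]:
        return {
            "CYP3A4": self.fm_cyp3a4,
            "CYP3A5": self.fm_cyp3a5,
            "other": self.fm_other,
        }


def default_scenarios() -> tuple[GenotypeScenario, GenotypeScenario]:
    """Pre-calibration genotype scenarios (placeholder fm splits)."""
    return (
        GenotypeScenario(
            label="non_expresser", cyp3a5_abundance_scalar=0.0,
            fm_cyp3a4=0.9, fm_cyp3a5=0.0, fm_other=0.1,
        ),
        GenotypeScenario(
            label="expresser", cyp3a5_abundance_scalar=0.5,
            fm_cyp3a4=0.6, fm_cyp3a5=0.3, fm_other=0.1,
        ),
    )


@dataclass(frozen=True)
class DDIResult:
    """Paired control/inhibited victim exposure for one scenario."""

    auc_control: float
    auc_inhibited: float
    aucr: float
    percent_increase: float
    scenario: tuple  # (inhibitor, regimen label, genotype label, mode)

    @classmethod
    def from_aucs(cls, auc_control, auc_inhibited, scenario) -> "DDIResult":
        if auc_control <= 0:
            raise DomainError("control AUC must be > 0")
        aucr = auc_inhibited / auc_control
        return cls(
            auc_control=float(auc_control), auc_inhibited=float(auc_inhibited),
            aucr=float(aucr), percent_increase=float((aucr - 1.0) * 100.0),
            scenario=tuple(scenario),
        )


def load_interaction(path: str | Path) -> InteractionSpec:
    """Read the ``interaction`` block of a perpetrator YAML config."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    block = data.get("interaction")
    if block is None:
        raise ConfigurationError(f"{path}: no interaction block")
    return InteractionSpec(
        perpetrator=data["name"],
        mode=block.get("mode", "RI_and_TDI"),
        enzymes={k: EnzymeInhibition(**v) for k, v in block["enzymes"].items()},
    )


# ---------------------------------------------------------------------------
# elementary terms
# ---------------------------------------------------------------------------
def inhibition_terms(
    iu_uM: float, spec: InteractionSpec, enzyme: str
) -> tuple[float, float]:
    """(reversible factor, kobs in h⁻¹) at unbound inhibitor level ``iu_uM``.

    The reversible factor ``1/(1+Iu/Ki)`` scales intrinsic clearance; kobs
    converts the per-minute inactivation rate to h⁻¹ (×60).  Enzymes absent
    from the spec are untouched: (1, 0).
    """
    if iu_uM < 0:
        raise DomainError("unbound inhibitor concentration must be >= 0")
    e = spec.enzymes.get(enzyme)
    if e is None:
        return 1.0, 0.0
    ri = 1.0
    kobs = 0.0
    if spec.mode in ("RI_only", "RI_and_TDI"):
        ri = 1.0 / (1.0 + iu_uM / e.ki)
    if spec.mode in ("TDI_only", "RI_and_TDI"):
        kobs = 60.0 * e.kinact * iu_uM / (e.KI + iu_uM)
    return ri, kobs


def enzyme_turnover_rhs(active_fraction: float, kdeg: float, kobs: float) -> float:
    """d(active fraction)/dt under zero-order synthesis, first-order
    degradation and inactivation; steady state = kdeg/(kdeg+kobs)."""
    return kdeg * (1.0 - active_fraction) - kobs * active_fraction


# ---------------------------------------------------------------------------
# baseline calibration
# ---------------------------------------------------------------------------
def _control_auc(
    victim: CompoundParams,
    phys: PhysiologyParams,
    clint_effective: float,
    *,
    dose_mg: float = VICTIM_DOSE_MG,
    window: float = AUC_WINDOW_H,
    matrix: str = "blood",
    grid_dt: float = 0.05,
) -> float:
    """Victim AUC for a single oral dose with a lumped effective CLint."""
    lumped = victim.model_copy(
        update={
            "clint_hlm": clint_effective,
            "enzyme_fractions": {"CYP3A4": 0.0, "CYP3A5": 0.0, "other": 1.0},
        }
    )
    reg = DoseRegimen(compound=victim.name, dose_mg=dose_mg, times=[0.0], label="control")
    res = simulate([lumped], [reg], phys, duration=window, grid_dt=grid_dt)
    return pk_metrics(res, victim.name, matrix=matrix).auc


def calibrate_baseline(
    victim: CompoundParams,
    phys: PhysiologyParams,
    scenarios: Sequence[GenotypeScenario],
    *,
    targets: dict[str, float] | None = None,
    fm_other: float = 0.05,
    tolerance: float = 0.01,
    clint_bounds: tuple[float, float] = (1e-2, 1e9),
) -> tuple[CompoundParams, list[GenotypeScenario], dict]:
    """Pin the victim's clearance magnitude and CYP3A5 split to the
    genotype-specific control AUCs.

    Two free parameters — total CLint,HLM ``T`` and the CYP3A5 fraction φ of
    it — are solved so the simulated single-dose victim AUC (blood, 120-h
    window) matches the target in each genotype.  Because the non-expresser
    sees effective CLint ``T·(1-φ)`` and the expresser ``T·(1-φ) + s·T·φ``
    (s = CYP3A5 abundance scalar), the problem reduces to two 1-D root
    findings on the same monotone CLint→AUC map plus an algebraic solve.
    ``fm_other`` (non-CYP3A share of T) is fixed.

    Returns the calibrated victim, scenarios with fm splits filled in, and a
    diagnostics dict.
    """
    targets = targets or {"non_expresser": 118.07, "expresser": 62.50}
    by_label = {s.label: s for s in scenarios}
    if set(by_label) != {"non_expresser", "expresser"}:
        raise CalibrationError("need exactly one expresser and one non_expresser scenario")
    s = by_label["expresser"].cyp3a5_abundance_scalar
    if s <= 0 or by_label["non_expresser"].cyp3a5_abundance_scalar != 0:
        raise CalibrationError(
            "CYP3A5 abundance scalars make the genotypes indistinguishable "
            "(expresser scalar must be > 0, non-expresser 0); the two AUC "
            "targets cannot both be met"
        )
    if targets["expresser"] >= targets["non_expresser"]:
        raise CalibrationError(
            "expresser control AUC target must be below the non-expresser's"
        )

    lo, hi = clint_bounds
    auc_hi, auc_lo = _control_auc(victim, phys, lo), _control_auc(victim, phys, hi)

    def solve(target: float) -> float:
        if not (auc_lo <= target <= auc_hi):
            raise CalibrationError(
                f"target AUC {target} outside achievable range",
                achievable=(auc_lo, auc_hi),
            )
        # oral AUC is ~ inversely proportional to CLint: one evaluation gives
        # a near-exact guess, Brent on a log bracket polishes it
        x0 = np.sqrt(lo * hi)
        a0 = _control_auc(victim, phys, x0)
        guess = x0 * a0 / target
        lo_b, hi_b = guess / 2.0, guess * 2.0
        return brentq(
            lambda x: _control_auc(victim, phys, x) - target,
            lo_b, hi_b, xtol=1e-6, rtol=1e-6,
        )

    u = solve(targets["non_expresser"])  # T·(1-φ)
    v = solve(targets["expresser"])  # T·(1-φ) + s·T·φ
    t_phi = (v - u) / s
    T = u + t_phi
    phi = t_phi / T
    f4 = 1.0 - phi - fm_other
    if f4 < 0:
        raise CalibrationError(
            f"CYP3A5 fraction {phi:.3f} leaves no room for fm_other={fm_other}"
        )
    calibrated = victim.model_copy(
        update={
            "clint_hlm": T,
            "enzyme_fractions": {"CYP3A4": f4, "CYP3A5": phi, "other": fm_other},
        }
    )
    ne = by_label["non_expresser"].model_copy(
        update={
            "fm_cyp3a4": f4 / (f4 + fm_other),
            "fm_cyp3a5": 0.0,
            "fm_other": fm_other / (f4 + fm_other),
        }
    )
    denom = f4 + s * phi + fm_other
    ex = by_label["expresser"].model_copy(
        update={
            "fm_cyp3a4": f4 / denom,
            "fm_cyp3a5": s * phi / denom,
            "fm_other": fm_other / denom,
        }
    )
    achieved = {"non_expresser": _control_auc(victim, phys, u),
                "expresser": _control_auc(victim, phys, v)}
    for label, auc in achieved.items():
        if abs(auc - targets[label]) > tolerance * targets[label]:
            raise CalibrationError(
                f"calibration residual too large for {label}: {auc} vs {targets[label]}"
            )
    diagnostics = {
        "clint_total": T, "cyp3a5_fraction": phi, "clint_nonexpresser": u,
        "clint_expresser": v, "achieved_auc": achieved, "targets": dict(targets),
    }
    return calibrated, [ne, ex], diagnostics


# ---------------------------------------------------------------------------
# scenario simulation
# ---------------------------------------------------------------------------
def _regimens(
    victim: CompoundParams,
    perpetrator: CompoundParams | None,
    regimen_pair: str,
    *,
    victim_dose: float,
    perp_single: float | None,
    perp_bid: float | None,
) -> tuple[list[DoseRegimen], float, float]:
    """Dose schedules, victim dose time and total duration for a design."""
    if regimen_pair == "single_dose":
        t_victim, duration = 0.0, AUC_WINDOW_H
        perp_times, perp_dose = [0.0], perp_single
    elif regimen_pair == "multiple_dose":
        t_last = _BID_INTERVAL_H * (_BID_DOSES - 1)
        t_victim = t_last + _BID_INTERVAL_H  # day 14
        duration = t_victim + AUC_WINDOW_H
        perp_times = [i * _BID_INTERVAL_H for i in range(_BID_DOSES)]
        perp_dose = perp_bid
    else:
        raise DomainError(f"regimen_pair must be single_dose or multiple_dose, got {regimen_pair!r}")
    regs = [
        DoseRegimen(
            compound=victim.name, dose_mg=victim_dose, times=[t_victim], label="victim"
        )
    ]
    if perpetrator is not None and perp_dose is not None and perp_dose > 0:
        regs.append(
            DoseRegimen(
                compound=perpetrator.name, dose_mg=perp_dose, times=perp_times,
                label="perpetrator",
            )
        )
    return regs, t_victim, duration


def run_ddi(
    victim: CompoundParams,
    perpetrator: CompoundParams,
    interaction: InteractionSpec,
    regimen_pair: str,
    genotype: GenotypeScenario,
    mode: Mode,
    phys: PhysiologyParams | None = None,
    *,
    victim_dose: float = VICTIM_DOSE_MG,
    perp_single: float | None = None,
    perp_bid: float | None = None,
    matrix: str = "blood",
    grid_dt: float = 0.05,
    control_auc: float | None = None,
) -> DDIResult:
    """Paired control/inhibited simulation for one scenario.

    The victim AUC window is the 120 h after the victim dose; ``matrix``
    selects the reporting matrix for the victim (whole blood by default).
    Perpetrator doses default to the packaged designs when the perpetrator
    name is known (:data:`REFERENCE_DOSES`).
    """
    phys = phys or PhysiologyParams()
    doses = REFERENCE_DOSES.get(perpetrator.name, {})
    perp_single = doses.get("single") if perp_single is None else perp_single
    perp_bid = doses.get("bid") if perp_bid is None else perp_bid
    spec = interaction.with_mode(mode)
    phys_g = phys.model_copy(
        update={
            "cyp_abundance": {
                **phys.cyp_abundance, "CYP3A5": genotype.cyp3a5_abundance_scalar
            }
        }
    )
    regs, t_victim, duration = _regimens(
        victim, perpetrator, regimen_pair,
        victim_dose=victim_dose, perp_single=perp_single, perp_bid=perp_bid,
    )
    window = (t_victim, t_victim + AUC_WINDOW_H)

    inhibited = simulate(
        [victim, perpetrator], regs, phys_g, interaction=spec,
        duration=duration, grid_dt=grid_dt,
    )
    auc_i = pk_metrics(inhibited, victim.name, window=window, matrix=matrix).auc

    if control_auc is None:
        control = simulate(
            [victim], [r for r in regs if r.compound == victim.name], phys_g,
            duration=duration, grid_dt=grid_dt,
        )
        control_auc = pk_metrics(control, victim.name, window=window, matrix=matrix).auc

    return DDIResult.from_aucs(
        control_auc, auc_i,
        scenario=(perpetrator.name, regimen_pair, genotype.label, mode),
    )


def static_aucr_oracle(
    iu_uM: float,
    spec: InteractionSpec,
    genotype: GenotypeScenario,
    kdeg: dict[str, float] | None = None,
) -> float:
    """Static mechanistic AUCR at a constant unbound inhibitor level.

    AUCR = 1 / ( Σ_e fm_e · ri_e · kdeg_e/(kdeg_e + kobs_e) + fm_other ).
    Exact for the dynamic model under constant exposure with enzymes at
    steady state, since oral AUC scales inversely with intrinsic clearance.
    """
    kdeg = kdeg or {e: 0.0193 for e in CYP_ENZYMES}
    denom = genotype.fm_other
    for e in CYP_ENZYMES:
        ri, kobs = inhibition_terms(iu_uM, spec, e)
        denom += genotype.fm[e] * ri * kdeg[e] / (kdeg[e] + kobs)
    return 1.0 / denom


def scenario_table(results: Sequence[DDIResult]) -> pd.DataFrame:
    """Tabulate DDI results (one row per scenario; duplicate scenarios are an
    error)."""
    seen = set()
    rows = []
    for r in results:
        if r.scenario in seen:
            raise DomainError(f"duplicate scenario {r.scenario}")
        seen.add(r.scenario)
        inhibitor, regimen, geno, mode = r.scenario
        rows.append(
            {
                "inhibitor": inhibitor, "regimen": regimen, "genotype": geno,
                "mode": mode, "auc_control": r.auc_control,
                "auc_inhibited": r.auc_inhibited, "aucr": r.aucr,
                "percent_increase": r.percent_increase,
            }
        )
    columns = [
        "inhibitor", "regimen", "genotype", "mode", "auc_control",
        "auc_inhibited", "aucr", "percent_increase",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_scenario_grid(
    victim: CompoundParams,
    perpetrators: dict[str, tuple[CompoundParams, InteractionSpec]],
    scenarios: Sequence[GenotypeScenario],
    phys: PhysiologyParams | None = None,
    *,
    grid_dt: float = 0.05,
) -> pd.DataFrame:
    """Run the full 2-genotype × 2-inhibitor × 2-regimen × 3-case grid.

    Cells whose mechanism mode is not supported by a perpetrator (e.g. a
    pure time-dependent inactivator asked for a reversible-only case) are
    emitted with empty AUC/AUCR values.  The victim must be pre-calibrated.
    """
    phys = phys or PhysiologyParams()
    rows = []
    control_cache: dict[tuple[str, str], float] = {}
    for geno in scenarios:
        for name, (perp, spec) in perpetrators.items():
            for regimen in ("single_dose", "multiple_dose"):
                for mode in ("RI_only", "TDI_only", "RI_and_TDI"):
                    base = {
                        "inhibitor": name, "regimen": regimen,
                        "genotype": geno.label, "mode": mode,
                    }
                    try:
                        spec.with_mode(mode)
                    except (ConfigurationError, ValueError):
                        rows.append(
                            {**base, "auc_control": np.nan, "auc_inhibited": np.nan,
                             "aucr": np.nan, "percent_increase": np.nan}
                        )
                        continue
                    key = (geno.label, regimen)
                    result = run_ddi(
                        victim, perp, spec, regimen, geno, mode, phys,
                        grid_dt=grid_dt, control_auc=control_cache.get(key),
                    )
                    control_cache[key] = result.auc_control
                    rows.append(
                        {**base, "auc_control": result.auc_control,
                         "auc_inhibited": result.auc_inhibited,
                         "aucr": result.aucr,
                         "percent_increase": result.percent_increase}
                    )
    return pd.DataFrame(rows)
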