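"""Minimal dynamic PBPK model with well-stirred hepatic elimination.

Structure (per compound): oral depot --ka--> gut wall --> portal blood -->
liver --> central plasma (optional peripheral), with first-order absorption
(fa, ka), a single representative subject, and hepatic elimination from the
unbound liver outflow concentration so that the steady-state clearance equals
the well-stirred model

    CLh = Qh · fu_b · CLint / (Qh + fu_b · CLint),        fu_b = fu_plasma / (B/P)

Microsomal intrinsic clearance (µL/min/mg protein) is scaled to whole-organ
CLint per enzyme with MPPGL and liver mass.  Enzyme active fractions for
CYP3A4/CYP3A5 are dynamic states obeying synthesis/degradation turnover and
can be depleted by a mechanism-based inactivator supplied through an
interaction object (see :mod:`szddi.ddi`).

Units: amounts mg, volumes L, flows L/h, times h, concentrations mg/L
internally and ng/mL (= µg/L·10⁻³... i.e. mg/L × 1000) on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.integrate import solve_ivp

from .exceptions import DomainError, SimulationError

__all__ = [
    "ENZYMES",
    "CYP_ENZYMES",
    "CompoundParams",
    "PhysiologyParams",
    "DoseRegimen",
    "SimulationResult",
    "PKMetrics",
    "load_compound",
    "load_physiology",
    "scale_clearance",
    "hepatic_clearance",
    "simulate",
    "pk_metrics",
    "fold_error",
]

#: Clearance pathways tracked per compound.
ENZYMES = ("CYP3A4", "CYP3A5", "other")
#: Enzymes with dynamic turnover states (inhibitable).
CYP_ENZYMES = ("CYP3A4", "CYP3A5")


class CompoundParams(BaseModel):
    """Drug-dependent model inputs (one compound).

    ``clint_hlm`` is the pooled human-liver-microsome intrinsic clearance in
    µL/min/mg protein; ``enzyme_fractions`` splits it across CYP3A4, CYP3A5
    and a lumped non-CYP3A "other" pathway.  ``vss`` (L/kg) and ``kp_scalar``
    set the central distribution volume ``vss·kp_scalar·body_weight``;
    ``peff`` (10⁻⁴ cm/s) is carried for bookkeeping but unused by the
    first-order absorption model.
    """

    name: str
    mw: float = Field(gt=0, description="molecular weight, g/mol")
    logp: float = 0.0
    fu_plasma: float = Field(gt=0, le=1)
    bp_ratio: float = Field(gt=0, description="blood-to-plasma ratio")
    fa: float = Field(gt=0, le=1, description="fraction absorbed")
    ka: float = Field(gt=0, description="absorption rate constant, 1/h")
    peff: float | None = Field(default=None, description="informational, 1e-4 cm/s")
    vss: float = Field(gt=0, description="steady-state volume, L/kg (plasma-referenced)")
    kp_scalar: float = Field(default=1.0, gt=0)
    clint_hlm: float = Field(ge=0, description="µL/min/mg microsomal protein")
    enzyme_fractions: dict[str, float]
    q_peripheral: float | None = Field(default=None, description="L/h; peripheral off if None")
    v_peripheral: float | None = Field(default=None, description="L")

    @field_validator("enzyme_fractions")
    @classmethod
    def _fractions(cls, v):
        unknown = set(v) - set(ENZYMES)
        if unknown:
            raise ValueError(f"unknown enzyme keys {sorted(unknown)}")
        if any(f < 0 for f in v.values()):
            raise ValueError("enzyme fractions must be >= 0")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"enzyme fractions must sum to 1, got {total}")
        return {e: v.get(e, 0.0) for e in ENZYMES}

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.bp_ratio

    def central_volume(self, body_weight: float) -> float:
        return self.vss * self.kp_scalar * body_weight


class PhysiologyParams(BaseModel):
    """Subject physiology for the representative individual.

    Defaults describe a healthy adult (60 kg) consistent with a Chinese
    reference subject: 1650 g liver, MPPGL 40 mg/g, hepatic blood flow
    90 L/h, CYP turnover half-life 36 h (kdeg 0.0193 h⁻¹).  The CYP3A5
    abundance scalar encodes genotype: 0.5 for *1/*3 expressers, 0 for
    *3/*3 non-expressers.  All values are overridable from config.
    """

    body_weight: float = Field(default=60.0, gt=0)  # kg
    liver_mass: float = Field(default=1650.0, gt=0)  # g
    mppgl: float = Field(default=40.0, gt=0)  # mg microsomal protein / g liver
    hepatic_blood_flow: float = Field(default=90.0, gt=0)  # L/h
    cyp_abundance: dict[str, float] = Field(
        default_factory=lambda: {"CYP3A4": 1.0, "CYP3A5": 0.5, "other": 1.0}
    )
    kdeg: dict[str, float] = Field(
        default_factory=lambda: {"CYP3A4": 0.0193, "CYP3A5": 0.0193}
    )
    portal_volume: float = Field(default=1.0, gt=0)  # L
    portal_flow_fraction: float = Field(default=0.75, gt=0, lt=1)
    liver_kp: float = Field(default=4.0, gt=0)  # liver:blood partition
    gut_transit: float = Field(default=20.0, gt=0)  # gut wall -> portal, 1/h

    @field_validator("cyp_abundance", "kdeg")
    @classmethod
    def _nonneg(cls, v):
        if any(x < 0 for x in v.values()):
            raise ValueError("physiology scalars must be >= 0")
        return v

    @property
    def liver_volume(self) -> float:
        """Liver volume in L (density ~1 g/mL)."""
        return self.liver_mass / 1000.0


class DoseRegimen(BaseModel):
    """Oral dosing schedule for one compound."""

    compound: str
    route: str = "oral"
    dose_mg: float = Field(gt=0)
    times: list[float]
    label: str = ""

    @field_validator("route")
    @classmethod
    def _route(cls, v):
        if v != "oral":
            raise ValueError("only oral dosing is modeled")
        return v

    @model_validator(mode="after")
    def _times(self):
        if not self.times:
            raise ValueError("times must be non-empty")
        if any(t < 0 for t in self.times):
            raise ValueError("dose times must be >= 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("dose times must be strictly increasing")
        return self


def load_compound(path: str | Path) -> CompoundParams:
    """Load a compound YAML config (interaction block, if any, is ignored
    here; :func:`szddi.ddi.load_interaction` reads it)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    data.pop("interaction", None)
    return CompoundParams(**data)


def load_physiology(path: str | Path) -> PhysiologyParams:
    return PhysiologyParams(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# clearance scaling
# ---------------------------------------------------------------------------
def scale_clearance(
    compound: CompoundParams, phys: PhysiologyParams
) -> dict[str, float]:
    """Whole-liver intrinsic clearance per pathway, in L/h.

    CLint,liver(e) = CLint,HLM · fraction(e) · MPPGL · liver mass ·
    abundance(e) · 60/10⁶  (µL/min → L/h).
    """
    out = {}
    for e in ENZYMES:
        out[e] = (
            compound.clint_hlm
            * compound.enzyme_fractions[e]
            * phys.mppgl
            * phys.liver_mass
            * phys.cyp_abundance.get(e, 1.0)
            * 60.0
            / 1e6
        )
    return out


def hepatic_clearance(
    clint: Mapping[str, float] | float,
    compound: CompoundParams,
    phys: PhysiologyParams,
) -> float:
    """Well-stirred hepatic blood clearance (L/h) for a given adjusted CLint."""
    total = float(sum(clint.values())) if isinstance(clint, Mapping) else float(clint)
    if total < 0:
        raise DomainError("CLint must be >= 0")
    qh = phys.hepatic_blood_flow
    x = compound.fu_blood * total
    return qh * x / (qh + x)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------
_N_SLOTS = 6  # depot, gut, portal, liver, central, peripheral (per compound)


@dataclass
class SimulationResult:
    """Dense simulation output.

    ``plasma`` maps compound name to its plasma concentration (ng/mL) on
    ``time``; ``amounts`` to the (n_time, 6) compartment-amount array
    (depot, gut wall, portal, liver, central, peripheral; mg);
    ``enzyme_fractions`` to active-fraction trajectories for CYP3A4/CYP3A5.
    ``mass_balance_residual`` is the max |absorbed - (in system + eliminated)|
    over the grid, in mg.
    """

    time: np.ndarray
    plasma: dict[str, np.ndarray]
    amounts: dict[str, np.ndarray]
    enzyme_fractions: dict[str, np.ndarray]
    compounds: dict[str, CompoundParams]
    mass_balance_residual: float

    def concentration(self, name: str, matrix: str = "plasma") -> np.ndarray:
        """Concentration profile in ng/mL; ``matrix`` 'plasma' or 'blood'
        (blood applies the compound's B/P ratio)."""
        c = self.plasma[name]
        if matrix == "plasma":
            return c
        if matrix == "blood":
            return c * self.compounds[name].bp_ratio
        raise ValueError(f"matrix must be 'plasma' or 'blood', got {matrix!r}")

    def to_frame(self):
        """Tidy export: columns time_h, compound, conc_ng_per_mL."""
        import pandas as pd

        frames = [
            pd.DataFrame(
                {"time_h": self.time, "compound": name, "conc_ng_per_mL": conc}
            )
            for name, conc in self.plasma.items()
        ]
        return pd.concat(frames, ignore_index=True)


def simulate(
    compounds: Sequence[CompoundParams],
    regimens: Sequence[DoseRegimen],
    phys: PhysiologyParams,
    interaction=None,
    duration: float = 24.0,
    *,
    grid_dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_enzyme_fractions: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Integrate the PBPK system over ``[0, duration]`` hours.

    Doses are instantaneous additions of ``fa · dose`` to the compound's
    depot at each scheduled time; integration restarts at every dose event.
    ``interaction``, if given, is an object with a ``terms(enzyme, iu_uM)``
    method returning ``(reversible factor, kobs h⁻¹)`` and either a
    ``perpetrator`` compound name (the inhibitor concentration driving the
    interaction is then its simulated unbound liver concentration) or a
    fixed ``constant_iu_uM`` exposure.
    """
    comp_list = list(compounds)
    names = [c.name for c in comp_list]
    if len(set(names)) != len(names):
        raise DomainError("compound names must be unique")
    for reg in regimens:
        if reg.compound not in names:
            raise DomainError(f"regimen references unknown compound {reg.compound!r}")

    qh = phys.hepatic_blood_flow
    qpv = qh * phys.portal_flow_fraction
    qha = qh - qpv
    vpo, vli, kp_li, ktr = (
        phys.portal_volume, phys.liver_volume, phys.liver_kp, phys.gut_transit,
    )

    perp_idx = None
    const_iu = None
    if interaction is not None:
        const_iu = getattr(interaction, "constant_iu_uM", None)
        perp = getattr(interaction, "perpetrator", None)
        if const_iu is None:
            if perp is None or perp not in names:
                raise DomainError(
                    "interaction must name a simulated perpetrator or a constant exposure"
                )
            perp_idx = names.index(perp)

    # per-compound constants
    consts = []
    for c in comp_list:
        clint = scale_clearance(c, phys)
        consts.append(
            (
                c.ka,
                c.fu_blood,
                c.bp_ratio,
                c.central_volume(phys.body_weight),
                np.array([clint[e] for e in ENZYMES]),
                c.q_peripheral or 0.0,
                c.v_peripheral or 1.0,
                c.mw,
            )
        )

    n_c = len(comp_list)
    n_states = n_c * _N_SLOTS + n_c + len(CYP_ENZYMES)  # + eliminated + enzymes
    enz_off = n_c * (_N_SLOTS + 1)
    kdeg = np.array([phys.kdeg.get(e, 0.0193) for e in CYP_ENZYMES])

    def rhs(t, y):
        dy = np.zeros_like(y)
        f_enz = y[enz_off : enz_off + len(CYP_ENZYMES)]

        # inhibitor exposure (unbound liver concentration, µM)
        if interaction is None:
            ri = np.ones(len(CYP_ENZYMES))
            kobs = np.zeros(len(CYP_ENZYMES))
        else:
            if const_iu is not None:
                iu = const_iu
            else:
                ka_, fub, bp, vc, clint_vec, qp, vp, mw = consts[perp_idx]
                Lp = y[perp_idx * _N_SLOTS + 3]
                iu = max(fub * (Lp / vli) / kp_li, 0.0) * 1000.0 / mw
            ri, kobs = np.empty(len(CYP_ENZYMES)), np.empty(len(CYP_ENZYMES))
            for k, e in enumerate(CYP_ENZYMES):
                ri[k], kobs[k] = interaction.terms(e, iu)

        activity = np.array([f_enz[0] * ri[0], f_enz[1] * ri[1], 1.0])
        for i, (ka_, fub, bp, vc, clint_vec, qp, vp, mw) in enumerate(consts):
            D, G, P, L, C, PP = y[i * _N_SLOTS : (i + 1) * _N_SLOTS]
            cp = C / vc
            cb = bp * cp
            cpo = P / vpo
            cout = (L / vli) / kp_li
            clint_eff = float(clint_vec @ activity)
            elim = fub * cout * clint_eff
            dy[i * _N_SLOTS + 0] = -ka_ * D
            dy[i * _N_SLOTS + 1] = ka_ * D - ktr * G
            dy[i * _N_SLOTS + 2] = ktr * G + qpv * cb - qpv * cpo
            dy[i * _N_SLOTS + 3] = qha * cb + qpv * cpo - qh * cout - elim
            dC = qh * cout - qh * cb
            if qp > 0:
                flux = qp * (cp - PP / vp)
                dC -= flux
                dy[i * _N_SLOTS + 5] = flux
            dy[i * _N_SLOTS + 4] = dC
            dy[n_c * _N_SLOTS + i] = elim  # eliminated amount
        dy[enz_off : enz_off + len(CYP_ENZYMES)] = kdeg * (1.0 - f_enz) - kobs * f_enz
        return dy

    # dose events
    events: dict[float, list[tuple[int, float]]] = {}
    for reg in regimens:
        idx = names.index(reg.compound)
        fa = comp_list[idx].fa
        for t in reg.times:
            if t <= duration:
                events.setdefault(float(t), []).append((idx, reg.dose_mg * fa))

    y0 = np.zeros(n_states)
    y0[enz_off : enz_off + len(CYP_ENZYMES)] = [
        (initial_enzyme_fractions or {}).get(e, 1.0) for e in CYP_ENZYMES
    ]

    grid = np.arange(0.0, duration + grid_dt / 2, grid_dt)
    boundaries = sorted({0.0, duration} | set(events))
    boundaries = [b for b in boundaries if b <= duration]

    times_out, states_out = [], []
    y = y0.copy()
    for k, t0 in enumerate(boundaries):
        for idx, amount in events.get(t0, []):
            y[idx * _N_SLOTS] += amount
        t1 = boundaries[k + 1] if k + 1 < len(boundaries) else duration
        if t1 <= t0:
            continue
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.concatenate([[t0], t_eval])
        if t_eval[-1] < t1:
            t_eval = np.concatenate([t_eval, [t1]])
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed: {sol.message}", last_state=y)
        y = sol.y[:, -1].copy()
        if times_out and sol.t[0] == times_out[-1][-1]:
            # boundary point appears in both segments; keep the post-dose state
            times_out[-1] = times_out[-1][:-1]
            states_out[-1] = states_out[-1][:, :-1]
        times_out.append(sol.t)
        states_out.append(sol.y)

    t = np.concatenate(times_out)
    Y = np.concatenate(states_out, axis=1)

    plasma, amounts = {}, {}
    for i, c in enumerate(comp_list):
        vc = consts[i][3]
        conc = Y[i * _N_SLOTS + 4] / vc * 1000.0  # mg/L -> ng/mL
        if conc.min() < -1e-9 * max(conc.max(), 1.0):
            raise SimulationError(
                f"negative concentration for {c.name}: {conc.min()}", last_state=y
            )
        plasma[c.name] = np.clip(conc, 0.0, None)
        amounts[c.name] = Y[i * _N_SLOTS : (i + 1) * _N_SLOTS].T

    # mass balance: absorbed (fa·dose released so far) vs in-system + eliminated
    dosed = np.zeros_like(t)
    for t_ev, items in events.items():
        dosed += np.where(t >= t_ev, sum(a for _, a in items), 0.0)
    in_system = sum(Y[i * _N_SLOTS : (i + 1) * _N_SLOTS].sum(axis=0) for i in range(n_c))
    eliminated = Y[n_c * _N_SLOTS : n_c * _N_SLOTS + n_c].sum(axis=0)
    residual = float(np.max(np.abs(dosed - in_system - eliminated))) if n_c else 0.0

    enzyme = {
        e: Y[enz_off + k] for k, e in enumerate(CYP_ENZYMES)
    }
    return SimulationResult(
        time=t, plasma=plasma, amounts=amounts, enzyme_fractions=enzyme,
        compounds={c.name: c for c in comp_list}, mass_balance_residual=residual,
    )


# ---------------------------------------------------------------------------
# PK metrics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PKMetrics:
    cmax: float  # ng/mL
    tmax: float  # h
    auc: float  # ng/mL·h
    auc_window: tuple[float, float]


def pk_metrics(
    result: SimulationResult,
    compound: str,
    window: tuple[float, float] | None = None,
    matrix: str = "plasma",
) -> PKMetrics:
    """Cmax/Tmax from the grid maximum, AUC by trapezoid (no extrapolation)."""
    t = result.time
    c = result.concentration(compound, matrix)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    if lo >= hi or lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise DomainError(f"window {window} not inside simulated span ({t[0]}, {t[-1]})")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise DomainError("empty window")
    tw, cw = t[mask], c[mask]
    imax = int(np.argmax(cw))
    return PKMetrics(
        cmax=float(cw[imax]), tmax=float(tw[imax]),
        auc=float(np.trapezoid(cw, tw)), auc_window=(float(lo), float(hi)),
    )


def fold_error(predicted: float, observed: float) -> float:
    """Symmetric prediction accuracy: max(p,o)/min(p,o), always >= 1;
    values below 2 are conventionally deemed acceptable."""
    if predicted <= 0 or observed <= 0:
        raise DomainError("fold_error requires positive values")
    return max(predicted, observed) / min(predicted, observed)
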