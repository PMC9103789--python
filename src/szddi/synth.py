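"""Synthetic assay and PK data with known ground truth.

Every generator is a pure function of its spec and seed, produces datasets
that pass :mod:`szddi.assay` validation, and at CV=0 reproduces its model
exactly, so generate→fit closure tests recover the truth parameters to
solver precision.

Noise is multiplicative lognormal by default (assay responses are strictly
positive); an additive-Gaussian variant is available behind a flag.  Default
designs copy the reference incubation layouts: IC50 concentration series of
10 inhibitor levels plus the zero control, Dixon 4×4 substrate×inhibitor
grids, and TDI preincubation times {0, 5, 10, 20, 30} min, all in
triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayDataset, AssayKind, VelocityRecord
from .exceptions import DomainError
from .pbpk import SimulationResult

__all__ = [
    "GeneratorSpec",
    "DIXON_DESIGN",
    "TDI_DESIGN",
    "IC50_DESIGN",
    "generate_dixon_dataset",
    "generate_tdi_dataset",
    "generate_ic50_dataset",
    "generate_ic50_pair",
    "generate_pk_observations",
]

#: Default reversible-inhibition design: tacrolimus substrate series (µM) ×
#: inhibitor series (µM, SZB pooled-HLM layout).
DIXON_DESIGN = {"substrate": (0.25, 0.5, 1.0, 2.0), "inhibitor": (0.0, 1.0, 2.0, 4.0)}
#: Default inactivation design: SZB pooled-HLM concentration series (µM) at
#: preincubation times (min).
TDI_DESIGN = {"inhibitor": (0.0, 0.1, 0.2, 0.5, 1.0, 2.0), "times": (0.0, 5.0, 10.0, 20.0, 30.0)}
#: Default IC50 design: SZB concentration series (µM) including the control.
IC50_DESIGN = {"inhibitor": (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0, 20.0)}


@dataclass(frozen=True)
class GeneratorSpec:
    """Truth parameters, design and noise for one synthetic experiment.

    Only the truth fields relevant to the assay kind need be set.  ``cv`` is
    the lognormal coefficient of variation of the multiplicative error;
    ``replicates`` the number of wells per design point.
    """

    vmax: float = 100.0  # pmol/min/mg
    km: float = 1.0  # µM
    ki: float | None = None  # µM
    KI: float | None = None  # µM
    kinact: float | None = None  # min⁻¹
    ic50: float | None = None  # µM
    hill: float = 1.0
    substrate_grid: tuple | None = None  # default: assay-specific design
    inhibitor_grid: tuple | None = None
    time_grid: tuple | None = None
    replicates: int = 3
    cv: float = 0.05
    noise: str = "lognormal"  # or "additive"
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        for grid in (self.substrate_grid, self.inhibitor_grid, self.time_grid):
            if grid is not None and len(grid) == 0:
                raise DomainError("design grids must be non-empty")


def _noise_factory(spec: GeneratorSpec):
    rng = np.random.default_rng(spec.seed)
    if spec.cv == 0:
        return lambda value: value
    if spec.noise == "lognormal":
        sigma = np.sqrt(np.log(1.0 + spec.cv**2))
        return lambda value: value * rng.lognormal(0.0, sigma)
    if spec.noise == "additive":
        return lambda value: max(value + rng.normal(0.0, spec.cv * value), 1e-12)
    raise DomainError(f"unknown noise model {spec.noise!r}")


def _metadata(spec: GeneratorSpec, **truth) -> dict:
    return {"generator_seed": spec.seed, "generator_cv": spec.cv, "truth": truth}


def generate_dixon_dataset(spec: GeneratorSpec) -> AssayDataset:
    """Noisy competitive-inhibition velocities on a substrate×inhibitor grid:

        v = Vmax·S / (Km·(1 + I/Ki) + S) × lognormal error.
    """
    if spec.ki is None:
        raise DomainError("dixon generator requires truth ki")
    noise = _noise_factory(spec)
    substrates = spec.substrate_grid or DIXON_DESIGN["substrate"]
    inhibitors = spec.inhibitor_grid or DIXON_DESIGN["inhibitor"]
    records = []
    for s in substrates:
        for i in inhibitors:
            v = spec.vmax * s / (spec.km * (1.0 + i / spec.ki) + s)
            for rep in range(1, spec.replicates + 1):
                records.append(
                    VelocityRecord(
                        substrate_conc=s, inhibitor_conc=i,
                        preincubation_min=0.0, replicate=rep, response=noise(v),
                    )
                )
    return AssayDataset(
        records=records, assay_kind=AssayKind.DIXON, normalized=False,
        metadata=_metadata(spec, ki=spec.ki, km=spec.km, vmax=spec.vmax),
    )


def generate_tdi_dataset(spec: GeneratorSpec) -> AssayDataset:
    """Normalized remaining activity exp(-kobs(I)·t) with saturable kobs and
    an inhibitor-free control series (kobs = 0)."""
    if spec.KI is None or spec.kinact is None:
        raise DomainError("tdi generator requires truth KI and kinact")
    inhibitors = spec.inhibitor_grid or TDI_DESIGN["inhibitor"]
    if 0.0 not in inhibitors:
        inhibitors = (0.0,) + tuple(inhibitors)
    times = spec.time_grid or TDI_DESIGN["times"]
    noise = _noise_factory(spec)
    records = []
    for i in inhibitors:
        kobs = spec.kinact * i / (spec.KI + i)
        for t in times:
            activity = np.exp(-kobs * t)
            for rep in range(1, spec.replicates + 1):
                records.append(
                    VelocityRecord(
                        substrate_conc=200.0, inhibitor_conc=i,
                        preincubation_min=t, replicate=rep,
                        response=float(noise(activity)),
                    )
                )
    return AssayDataset(
        records=records, assay_kind=AssayKind.TDI, normalized=True,
        metadata=_metadata(spec, KI=spec.KI, kinact=spec.kinact),
    )


def _ic50_records(spec: GeneratorSpec, ic50: float, noise, preinc: float):
    records = []
    for c in spec.inhibitor_grid or IC50_DESIGN["inhibitor"]:
        activity = 1.0 if c == 0 else 1.0 / (1.0 + (c / ic50) ** spec.hill)
        for rep in range(1, spec.replicates + 1):
            records.append(
                VelocityRecord(
                    substrate_conc=200.0, inhibitor_conc=c,
                    preincubation_min=preinc, replicate=rep,
                    response=float(noise(activity)),
                )
            )
    return records


def generate_ic50_dataset(spec: GeneratorSpec, *, preincubation_min: float = 0.0) -> AssayDataset:
    """Normalized logistic inhibition curve with noise."""
    if spec.ic50 is None:
        raise DomainError("ic50 generator requires truth ic50")
    noise = _noise_factory(spec)
    records = _ic50_records(spec, spec.ic50, noise, preincubation_min)
    return AssayDataset(
        records=records, assay_kind=AssayKind.IC50, normalized=True,
        metadata=_metadata(spec, ic50=spec.ic50, hill=spec.hill),
    )


def generate_ic50_pair(
    spec: GeneratorSpec, ic50_no_preinc: float, ic50_preinc: float
) -> tuple[AssayDataset, AssayDataset]:
    """Paired curves without/with NADPH preincubation (two IC50 truths,
    one shared design and noise stream)."""
    noise = _noise_factory(spec)
    no_pre = AssayDataset(
        records=_ic50_records(spec, ic50_no_preinc, noise, 0.0),
        assay_kind=AssayKind.IC50, normalized=True,
        metadata=_metadata(spec, ic50=ic50_no_preinc),
    )
    pre = AssayDataset(
        records=_ic50_records(spec, ic50_preinc, noise, 30.0),
        assay_kind=AssayKind.IC50, normalized=True,
        metadata=_metadata(spec, ic50=ic50_preinc),
    )
    return no_pre, pre


def generate_pk_observations(
    profile: SimulationResult,
    compound: str,
    cv: float = 0.1,
    seed: int = 0,
    *,
    sample_times: tuple | None = None,
    matrix: str = "plasma",
) -> pd.DataFrame:
    """Sample a simulated profile at observation times with multiplicative
    lognormal noise, as a tidy table (time_h, compound, conc_ng_per_mL)."""
    if cv < 0:
        raise DomainError("cv must be >= 0")
    t = profile.time
    c = profile.concentration(compound, matrix)
    if sample_times is None:
        sample_times = tuple(t[:: max(len(t) // 12, 1)])
    obs_t = np.asarray(sample_times, dtype=float)
    obs_c = np.interp(obs_t, t, c)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + cv**2))
        obs_c = obs_c * rng.lognormal(0.0, sigma, size=obs_c.shape)
    return pd.DataFrame(
        {"time_h": obs_t, "compound": compound, "conc_ng_per_mL": obs_c}
    )
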