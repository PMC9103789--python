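"""szddi: CYP3A4/5 inhibition kinetics and PBPK drug-drug interaction
simulation for schizandrol A/B as perpetrators and tacrolimus as victim.

The package covers the full pipeline: in vitro incubation data handling
(:mod:`szddi.assay`), IC50-shift / Dixon-Ki / time-dependent-inactivation
estimation (:mod:`szddi.kinetics`), a minimal dynamic PBPK model with
well-stirred hepatic clearance (:mod:`szddi.pbpk`), genotype-stratified DDI
simulation with enzyme turnover (:mod:`szddi.ddi`), ground-truth synthetic
data generation (:mod:`szddi.synth`) and table/report builders
(:mod:`szddi.report`).
"""

from importlib import resources as _resources
from pathlib import Path

from .assay import (
    AssayDataset,
    AssayKind,
    DilutionSpec,
    EnzymeSource,
    VelocityRecord,
    applied_inhibitor_conc,
    normalize_to_control,
    read_assay_csv,
    write_assay_csv,
)
from .ddi import (
    ConstantExposure,
    DDIResult,
    GenotypeScenario,
    InteractionSpec,
    calibrate_baseline,
    default_scenarios,
    enzyme_turnover_rhs,
    inhibition_terms,
    load_interaction,
    run_ddi,
    run_scenario_grid,
    scenario_table,
    static_aucr_oracle,
)
from .kinetics import (
    DixonKiEstimator,
    IC50Regressor,
    InactivationKineticsEstimator,
    TDIActivityEstimator,
    efficiency,
    fit_dixon,
    fit_ic50,
    fit_inactivation,
    fit_kobs,
    fit_tdi,
    ic50_shift,
)
from .pbpk import (
    CompoundParams,
    DoseRegimen,
    PhysiologyParams,
    PKMetrics,
    SimulationResult,
    fold_error,
    hepatic_clearance,
    load_compound,
    load_physiology,
    pk_metrics,
    scale_clearance,
    simulate,
)
from .report import build_table1, build_table2
from .synth import (
    GeneratorSpec,
    generate_dixon_dataset,
    generate_ic50_dataset,
    generate_ic50_pair,
    generate_pk_observations,
    generate_tdi_dataset,
)

__version__ = "0.1.0"


def packaged_config(name: str) -> Path:
    """Path to a packaged YAML config (e.g. 'szb.yaml', 'physiology.yaml')."""
    return Path(_resources.files("szddi.data") / name)
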