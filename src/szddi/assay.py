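"""In vitro incubation data: domain types, CSV I/O and unit conventions.

An incubation experiment is a flat table of velocity records (substrate and
inhibitor concentration, preincubation time, replicate, measured response)
plus metadata identifying the enzyme source and probe reaction.  Three assay
designs are supported:

``ic50``
    activity vs a single inhibitor concentration series (with and without
    NADPH preincubation).
``dixon``
    velocity over a substrate x inhibitor grid for reversible-inhibition Ki
    estimation from 1/v-vs-[I] lines.
``tdi``
    two-step dilution design: preincubation of inhibitor with microsomes and
    NADPH, then a diluted activity read at several preincubation times, for
    time-dependent-inactivation kinetics.

Responses may be raw metabolite formation rates (pmol/min/mg protein) or
activity normalized to the zero-inhibitor control; ``AssayDataset.normalized``
records which, and the TDI fitters require normalized input.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import AssayParseError, AssayValidationError

__all__ = [
    "AssayKind",
    "EnzymeSource",
    "VelocityRecord",
    "DilutionSpec",
    "AssayDataset",
    "CSV_COLUMNS",
    "TDI_PREINCUBATION_TIMES",
    "read_assay_csv",
    "write_assay_csv",
    "applied_inhibitor_conc",
    "normalize_to_control",
]

#: Canonical CSV header, in order.
CSV_COLUMNS = (
    "substrate_conc_uM",
    "inhibitor_conc_uM",
    "preincubation_min",
    "replicate",
    "response",
)

#: Preincubation sampling times (min) allowed in a TDI design.
TDI_PREINCUBATION_TIMES = frozenset({0.0, 5.0, 10.0, 20.0, 30.0})


class AssayKind(str, Enum):
    IC50 = "ic50"
    DIXON = "dixon"
    TDI = "tdi"


class EnzymeSource(str, Enum):
    """Microsomal enzyme source.

    ``CYP3A4_VIA_3A5_STAR3STAR3`` isolates CYP3A4 using CYP3A5*3/*3 (non
    expresser) microsomes; ``CYP3A5_VIA_STAR1STAR3_PLUS_CYP3CIDE`` isolates
    CYP3A5 in *1/*3 microsomes by first inactivating CYP3A4 with CYP3cide.
    """

    POOLED_HLM = "pooled_HLM"
    CYP3A4_VIA_3A5_STAR3STAR3 = "CYP3A4_via_3A5_star3star3"
    CYP3A5_VIA_STAR1STAR3_PLUS_CYP3CIDE = "CYP3A5_via_star1star3_plus_CYP3cide"


@dataclass(frozen=True)
class VelocityRecord:
    """One well: concentrations in µM, preincubation time in minutes.

    ``response`` is a metabolite formation rate (pmol/min/mg protein) or a
    normalized activity (fraction of control), per the dataset's
    ``normalized`` flag.
    """

    substrate_conc: float
    inhibitor_conc: float
    preincubation_min: float
    replicate: int
    response: float

    def __post_init__(self) -> None:
        if self.substrate_conc < 0 or self.inhibitor_conc < 0:
            raise AssayValidationError(
                "concentrations must be >= 0, got "
                f"S={self.substrate_conc}, I={self.inhibitor_conc}"
            )
        if self.preincubation_min < 0:
            raise AssayValidationError(
                f"preincubation_min must be >= 0, got {self.preincubation_min}"
            )
        if self.replicate < 1 or int(self.replicate) != self.replicate:
            raise AssayValidationError(
                f"replicate must be a positive integer, got {self.replicate}"
            )
        if self.response < 0:
            raise AssayValidationError(
                f"response must be >= 0, got {self.response}"
            )


@dataclass(frozen=True)
class DilutionSpec:
    """Two-step TDI dilution: an aliquot transferred into a larger volume.

    The default (20 µL into a 200 µL final activity read) is a 10-fold
    dilution, so only 1/10 of the nominal preincubation inhibitor
    concentration is carried into the activity read.
    """

    aliquot_volume: float = 20.0
    final_volume: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.aliquot_volume < self.final_volume:
            raise AssayValidationError(
                "require 0 < aliquot_volume < final_volume, got "
                f"{self.aliquot_volume} -> {self.final_volume}"
            )

    @property
    def dilution_factor(self) -> float:
        return self.final_volume / self.aliquot_volume


@dataclass
class AssayDataset:
    """A validated incubation experiment."""

    records: list[VelocityRecord]
    assay_kind: AssayKind
    enzyme_source: EnzymeSource = EnzymeSource.POOLED_HLM
    probe: str = "testosterone_6b_hydroxylation"
    protein_conc: float = 0.5  # mg/mL
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assay_kind = AssayKind(self.assay_kind)
        self.enzyme_source = EnzymeSource(self.enzyme_source)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.records:
            raise AssayValidationError("dataset is empty")
        if self.protein_conc <= 0:
            raise AssayValidationError("protein_conc must be > 0")
        if self.assay_kind is AssayKind.DIXON:
            subs = {r.substrate_conc for r in self.records}
            inhs = {r.inhibitor_conc for r in self.records}
            if len(subs) < 3:
                raise AssayValidationError(
                    f"dixon dataset needs >=3 distinct substrate levels, got {len(subs)}"
                )
            if len(inhs) < 3 or 0.0 not in inhs:
                raise AssayValidationError(
                    "dixon dataset needs >=3 distinct inhibitor levels including 0"
                )
        elif self.assay_kind is AssayKind.TDI:
            times = {r.preincubation_min for r in self.records}
            bad = times - TDI_PREINCUBATION_TIMES
            if bad:
                raise AssayValidationError(
                    f"tdi preincubation times must lie in {sorted(TDI_PREINCUBATION_TIMES)}, "
                    f"got extraneous {sorted(bad)}"
                )
            if len(times) < 4 or 0.0 not in times:
                raise AssayValidationError(
                    "tdi dataset needs >=4 preincubation times including 0"
                )
            if not any(r.inhibitor_conc == 0.0 for r in self.records):
                raise AssayValidationError(
                    "tdi dataset needs an inhibitor_conc=0 control series"
                )

    # -- convenience -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate_conc_uM": [r.substrate_conc for r in self.records],
                "inhibitor_conc_uM": [r.inhibitor_conc for r in self.records],
                "preincubation_min": [r.preincubation_min for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "response": [r.response for r in self.records],
            }
        )

    def inhibitor_levels(self) -> list[float]:
        return sorted({r.inhibitor_conc for r in self.records})

    def substrate_levels(self) -> list[float]:
        return sorted({r.substrate_conc for r in self.records})

    def preincubation_times(self) -> list[float]:
        return sorted({r.preincubation_min for r in self.records})


def _parse_cell(text: str, row: int, column: str, caster) -> float:
    try:
        return caster(text)
    except (TypeError, ValueError) as exc:
        raise AssayParseError(
            f"row {row}, column '{column}': cannot parse {text!r}"
        ) from exc


def read_assay_csv(
    path: str | Path,
    assay_kind: AssayKind | str,
    *,
    normalized: bool = False,
    **dataset_kwargs,
) -> AssayDataset:
    """Read an incubation CSV into a validated :class:`AssayDataset`.

    The dialect is fixed: comma-separated, period decimal, UTF-8, one header
    line whose names are exactly :data:`CSV_COLUMNS`.  Rows with a missing
    response are rejected with their row index; malformed numeric cells raise
    :class:`~szddi.exceptions.AssayParseError` naming row and column.

    A JSON metadata sidecar ``<path>.meta.json``, if present, is merged into
    the dataset metadata (and may set ``normalized``/``enzyme_source`` etc.).
    """
    path = Path(path)
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        normalized = meta.pop("normalized", normalized)
        for key in ("enzyme_source", "probe", "protein_conc"):
            if key in meta and key not in dataset_kwargs:
                dataset_kwargs[key] = meta.pop(key)
        dataset_kwargs.setdefault("metadata", {}).update(meta)

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise AssayParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != CSV_COLUMNS:
            raise AssayParseError(
                f"{path}: header must be {','.join(CSV_COLUMNS)}, got {','.join(header)}"
            )
        records = []
        for idx, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                raise AssayParseError(
                    f"row {idx}: expected {len(CSV_COLUMNS)} cells, got {len(row)}"
                )
            if not row[4].strip():
                raise AssayParseError(f"row {idx}: missing response")
            values = {
                "substrate_conc": _parse_cell(row[0], idx, CSV_COLUMNS[0], float),
                "inhibitor_conc": _parse_cell(row[1], idx, CSV_COLUMNS[1], float),
                "preincubation_min": _parse_cell(row[2], idx, CSV_COLUMNS[2], float),
                "replicate": _parse_cell(row[3], idx, CSV_COLUMNS[3], int),
                "response": _parse_cell(row[4], idx, CSV_COLUMNS[4], float),
            }
            for name in ("substrate_conc", "inhibitor_conc", "response"):
                if not math.isfinite(values[name]):
                    raise AssayParseError(
                        f"row {idx}: non-finite value in '{name}'"
                    )
            records.append(VelocityRecord(**values))
    return AssayDataset(
        records=records, assay_kind=assay_kind, normalized=normalized, **dataset_kwargs
    )


def write_assay_csv(dataset: AssayDataset, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a dataset in the canonical dialect (floats via ``repr``, so a
    read→write→read round trip is bit-exact)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for r in dataset.records:
            writer.writerow(
                [
                    repr(r.substrate_conc),
                    repr(r.inhibitor_conc),
                    repr(r.preincubation_min),
                    r.replicate,
                    repr(r.response),
                ]
            )
    if sidecar:
        meta = {
            "normalized": dataset.normalized,
            "enzyme_source": dataset.enzyme_source.value,
            "probe": dataset.probe,
            "protein_conc": dataset.protein_conc,
            **dataset.metadata,
        }
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )


def applied_inhibitor_conc(
    nominal: float,
    dilution: DilutionSpec,
    stage: str = "preincubation",
) -> float:
    """Inhibitor concentration actually experienced at a given assay stage.

    During the preincubation the nominal concentration applies; during the
    diluted activity read only the carryover ``nominal x aliquot/final``
    remains.  Linear in ``nominal``.
    """
    if nominal < 0:
        raise AssayValidationError(f"nominal concentration must be >= 0, got {nominal}")
    if stage == "preincubation":
        return nominal
    if stage == "activity":
        return nominal * dilution.aliquot_volume / dilution.final_volume
    raise ValueError(f"stage must be 'preincubation' or 'activity', got {stage!r}")


def normalize_to_control(dataset: AssayDataset) -> AssayDataset:
    """Rescale responses so the control mean equals 1.0.

    The control is the zero-inhibitor series (additionally zero-preincubation
    for TDI designs): its 6β-hydroxytestosterone formation is the surrogate
    for uninhibited enzyme activity.  Idempotent: normalizing a normalized
    dataset divides by a control mean of exactly 1.
    """
    if dataset.assay_kind is AssayKind.TDI:
        control = [
            r.response
            for r in dataset.records
            if r.inhibitor_conc == 0.0 and r.preincubation_min == 0.0
        ]
    else:
        control = [r.response for r in dataset.records if r.inhibitor_conc == 0.0]
    if not control:
        raise AssayValidationError("no zero-inhibitor control rows to normalize against")
    mean = sum(control) / len(control)
    if mean <= 0:
        raise AssayValidationError(f"control mean must be > 0, got {mean}")
    records = [replace(r, response=r.response / mean) for r in dataset.records]
    metadata = dict(dataset.metadata)
    if not dataset.normalized:
        metadata["original_units"] = metadata.get("original_units", "pmol/min/mg")
        metadata["control_mean_raw"] = mean
    return AssayDataset(
        records=records,
        assay_kind=dataset.assay_kind,
        enzyme_source=dataset.enzyme_source,
        probe=dataset.probe,
        protein_conc=dataset.protein_conc,
        normalized=True,
        metadata=metadata,
    )
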