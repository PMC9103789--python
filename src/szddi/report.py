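"""Report builders shaped like the study's summary tables.

``build_table1`` compares predicted vs observed PK metrics per compound with
the symmetric fold error; ``build_table2`` lays out the DDI scenario grid
(genotype × inhibitor × regimen, one column per mechanism case) with
"control/inhibited AUC" pair strings and AUC ratios.  Display values are
rounded half-up on the formatted string only; underlying numbers keep full
precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddi import DDIResult, scenario_table
from .exceptions import DomainError
from .pbpk import PKMetrics, fold_error

__all__ = ["round_half_up", "build_table1", "build_table2", "EM_DASH"]

EM_DASH = "—"

_MODES = ("RI_only", "TDI_only", "RI_and_TDI")


def round_half_up(value: float, ndigits: int = 2) -> str:
    """Format with half-up rounding (matching hand-tabulated values, unlike
    banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def build_table1(
    pred: Mapping[str, PKMetrics], obs: Mapping[str, PKMetrics]
) -> pd.DataFrame:
    """Predicted vs observed Cmax/Tmax/AUC with fold errors.

    ``pred`` and ``obs`` map compound name to its metrics; AUC windows must
    match between the two, otherwise the AUCs are not comparable.
    """
    if set(pred) != set(obs):
        raise DomainError("pred and obs must cover the same compounds")
    rows = []
    for name in pred:
        p, o = pred[name], obs[name]
        if p.auc_window != o.auc_window:
            raise DomainError(
                f"{name}: AUC windows differ ({p.auc_window} vs {o.auc_window})"
            )
        for param, pv, ov in (
            ("Cmax_ng_per_mL", p.cmax, o.cmax),
            ("Tmax_h", p.tmax, o.tmax),
            ("AUC_ng_per_mL_h", p.auc, o.auc),
        ):
            rows.append(
                {
                    "compound": name, "parameter": param, "predicted": pv,
                    "observed": ov, "fold_error": fold_error(pv, ov),
                    "fold_error_display": round_half_up(fold_error(pv, ov), 2),
                }
            )
    return pd.DataFrame(rows)


def _cell(ctrl, inh, aucr, rendered: bool) -> str:
    if aucr is None or (isinstance(aucr, float) and np.isnan(aucr)):
        return EM_DASH if rendered else ""
    return (
        f"{round_half_up(ctrl, 2)}/{round_half_up(inh, 2)} "
        f"(AUCR {round_half_up(aucr, 2)})"
    )


def build_table2(
    results: Sequence[DDIResult] | pd.DataFrame, *, rendered: bool = True
) -> pd.DataFrame:
    """DDI scenario grid, one row per (genotype, inhibitor, regimen) and one
    column per mechanism case.

    Accepts a list of :class:`DDIResult` or the long-form frame from
    :func:`szddi.ddi.run_scenario_grid` (which may contain NaN gaps for
    unsupported mechanism cases).  Gap cells render as an em-dash
    (``rendered=True``) or an empty string (CSV-friendly).
    """
    if isinstance(results, pd.DataFrame):
        long = results.copy()
    else:
        long = scenario_table(results)
    if long.empty:
        return pd.DataFrame(columns=["genotype", "inhibitor", "regimen", *_MODES])
    rows = []
    keys = long[["genotype", "inhibitor", "regimen"]].drop_duplicates()
    for _, key in keys.iterrows():
        sub = long[
            (long["genotype"] == key["genotype"])
            & (long["inhibitor"] == key["inhibitor"])
            & (long["regimen"] == key["regimen"])
        ]
        row = dict(key)
        for mode in _MODES:
            hit = sub[sub["mode"] == mode]
            if hit.empty:
                row[mode] = EM_DASH if rendered else ""
            else:
                r = hit.iloc[0]
                row[mode] = _cell(
                    r["auc_control"], r["auc_inhibited"], r["aucr"], rendered
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=["genotype", "inhibitor", "regimen", *_MODES])
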