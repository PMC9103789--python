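"""Inhibition-kinetics estimation: IC50 shift, Dixon Ki, and TDI parameters.

Three regression problems underlie CYP inhibition screening, and each is
exposed both as a scikit-learn style estimator (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing underscore)
and as a convenience function operating on an :class:`~szddi.assay.AssayDataset`:

* **IC50** — four-parameter logistic of normalized activity on log10
  inhibitor concentration (top fixed at 1 and bottom at 0 by default, since
  activity is expressed as fraction of control).  The *IC50 shift* is the
  ratio of the IC50 without NADPH preincubation to the IC50 with it; a shift
  above 1.5 flags time-dependent inhibition.

* **Dixon Ki** — for a competitive inhibitor, 1/v is linear in [I] at each
  substrate level and the lines share an intersection at [I] = -Ki.  Each
  substrate level is fit by ordinary least squares; pairwise intersection
  abscissae are averaged, weighted by the product of the two slopes'
  |t|-statistics, and Ki = -(weighted mean).

* **TDI (mechanism-based inactivation)** — activity remaining after
  preincubation decays as exp(-kobs·t); kobs is the negated slope of
  ln(activity) vs preincubation time (control-corrected by default), and
  kobs saturates in inhibitor concentration as

      kobs = kinact · [I] / (KI + [I])

  fit by nonlinear least squares, with the Kitz–Wilson double-reciprocal
  linearization (1/kobs vs 1/[I]) retained as a diagnostic cross-check.
  The inactivation efficiency kinact/KI is reported in mL/min/µmol
  (min⁻¹/µM × 1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .assay import AssayDataset, AssayKind
from .exceptions import (
    AssayValidationError,
    DomainError,
    FitError,
    NoInhibitionError,
)

__all__ = [
    "IC50Fit",
    "ShiftResult",
    "DixonFit",
    "InactivationFit",
    "IC50Regressor",
    "DixonKiEstimator",
    "InactivationKineticsEstimator",
    "TDIActivityEstimator",
    "fit_ic50",
    "ic50_shift",
    "fit_dixon",
    "fit_kobs",
    "fit_inactivation",
    "efficiency",
    "TDI_SHIFT_THRESHOLD",
]

#: IC50-shift value above which time-dependent inhibition is flagged.
TDI_SHIFT_THRESHOLD = 1.5

_SLOPE_T_CAP = 1e6  # |t| cap so noiseless (zero-SE) slopes keep finite weights


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class IC50Fit:
    """Logistic inhibition-curve fit; concentrations in µM."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    se_ic50: float
    converged: bool

    def __post_init__(self):
        if self.ic50 <= 0:
            raise DomainError(f"ic50 must be > 0, got {self.ic50}")
        if self.bottom > self.top:
            raise DomainError("bottom must not exceed top")


@dataclass(frozen=True)
class ShiftResult:
    ic50_no_preinc: float
    ic50_preinc: float
    shift: float
    tdi_flag: bool


@dataclass(frozen=True)
class DixonFit:
    """Dixon-plot analysis of one reversible-inhibition dataset.

    ``lines`` maps substrate concentration (µM) to a dict with the OLS
    ``slope``, ``intercept``, ``slope_se`` and ``slope_t`` of 1/v on [I].
    ``ki`` is ``None`` when ``mechanism_label == 'none_detected'``.
    """

    ki: float | None
    lines: dict
    intersection_x: float | None
    intersection_spread: float | None
    mechanism_label: str

    def __post_init__(self):
        if self.mechanism_label == "competitive":
            if self.ki is None or self.ki <= 0:
                raise DomainError("competitive label requires ki > 0")


@dataclass(frozen=True)
class InactivationFit:
    """Saturable inactivation kinetics.

    ``efficiency`` = (kinact/KI)·1000, in mL/min/µmol with kinact in min⁻¹
    and KI in µM.  ``kitz_wilson`` holds the linearized (kinact, KI)
    cross-check; ``r2_per_decay`` the log-linear decay fits feeding kobs.
    """

    kobs_by_conc: dict
    KI: float
    kinact: float
    efficiency: float
    r2_per_decay: list = field(default_factory=list)
    kitz_wilson: dict | None = None

    def __post_init__(self):
        if self.KI <= 0 or self.kinact <= 0:
            raise DomainError("KI and kinact must be > 0")
        if any(v < 0 for v in self.kobs_by_conc.values()):
            raise DomainError("kobs values must be >= 0")


# ---------------------------------------------------------------------------
# IC50
# ---------------------------------------------------------------------------
def _logistic(log_c, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50)))


class IC50Regressor(RegressorMixin, BaseEstimator):
    """Four-parameter logistic inhibition curve on log10 concentration.

    Parameters
    ----------
    top, bottom : float
        Plateaus of the activity curve; fixed at 1 and 0 by default, which is
        appropriate for data normalized to the uninhibited control.
    free_bottom : bool
        If True, the bottom plateau is estimated rather than fixed.
    flat_tolerance : float
        Minimum activity range (max-min of per-level means) below which the
        data are declared flat and :class:`NoInhibitionError` is raised.

    Attributes
    ----------
    ic50_ : float  (µM)
    hill_slope_, top_, bottom_, se_ic50_, converged_ : fit results
    """

    def __init__(self, top=1.0, bottom=0.0, free_bottom=False, flat_tolerance=0.05):
        self.top = top
        self.bottom = bottom
        self.free_bottom = free_bottom
        self.flat_tolerance = flat_tolerance

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        conc = np.asarray(X[:, 0], dtype=float)
        if np.any(conc < 0):
            raise DomainError("inhibitor concentrations must be >= 0")
        pos = conc > 0
        if np.unique(conc[pos]).size < 4:
            raise AssayValidationError(
                "need >=4 distinct positive inhibitor levels for an IC50 fit"
            )
        # flatness check on per-level means
        means = [y[conc == c].mean() for c in np.unique(conc)]
        if max(means) - min(means) < self.flat_tolerance:
            raise NoInhibitionError(
                "no inhibition detected: activity range "
                f"{max(means) - min(means):.4g} < {self.flat_tolerance}"
            )
        log_c, act = np.log10(conc[pos]), np.asarray(y, dtype=float)[pos]

        guess_idx = int(np.argmin(np.abs(act - 0.5 * (self.top + self.bottom))))
        p0 = [log_c[guess_idx], 1.0]
        lo, hi = [log_c.min() - 6.0, 0.01], [log_c.max() + 6.0, 10.0]
        if self.free_bottom:
            model = lambda lc, li, h, b: _logistic(lc, li, h, self.top, b)
            p0, lo, hi = p0 + [0.0], lo + [0.0], hi + [0.9]
        else:
            model = lambda lc, li, h: _logistic(lc, li, h, self.top, self.bottom)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, log_c, act, p0=p0, bounds=(lo, hi),
                    maxfev=20000, xtol=1e-13, ftol=1e-13, gtol=1e-13,
                )
        except (RuntimeError, ValueError) as exc:
            raise FitError(
                f"IC50 fit failed to converge: {exc}",
                residuals=act - model(log_c, *p0),
            ) from exc
        se_log = float(np.sqrt(np.abs(pcov[0, 0]))) if np.all(np.isfinite(pcov)) else np.nan
        self.ic50_ = float(10.0 ** popt[0])
        self.hill_slope_ = float(popt[1])
        self.top_ = float(self.top)
        self.bottom_ = float(popt[2]) if self.free_bottom else float(self.bottom)
        self.se_ic50_ = float(np.log(10.0) * self.ic50_ * se_log)
        self.converged_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "ic50_")
        conc = check_array(X)[:, 0]
        with np.errstate(divide="ignore"):
            log_c = np.log10(conc)
        out = _logistic(log_c, np.log10(self.ic50_), self.hill_slope_, self.top_, self.bottom_)
        return np.where(conc == 0, self.top_, out)

    def result_(self) -> IC50Fit:
        check_is_fitted(self, "ic50_")
        return IC50Fit(
            ic50=self.ic50_, hill_slope=self.hill_slope_, top=self.top_,
            bottom=self.bottom_, se_ic50=self.se_ic50_, converged=self.converged_,
        )


def fit_ic50(dataset: AssayDataset, **estimator_kwargs) -> IC50Fit:
    """Fit a normalized IC50 dataset (>=5 distinct inhibitor levels)."""
    if dataset.assay_kind is not AssayKind.IC50:
        raise AssayValidationError("fit_ic50 requires an ic50-kind dataset")
    if not dataset.normalized:
        raise AssayValidationError("fit_ic50 requires normalized activity data")
    if len(dataset.inhibitor_levels()) < 5:
        raise AssayValidationError("need >=5 distinct inhibitor levels")
    df = dataset.to_frame()
    est = IC50Regressor(**estimator_kwargs)
    est.fit(df[["inhibitor_conc_uM"]].to_numpy(), df["response"].to_numpy())
    return est.result_()


def ic50_shift(no_preinc, preinc) -> ShiftResult:
    """IC50 shift = IC50(no preincubation) / IC50(with NADPH preincubation).

    A shift above 1.5 flags time-dependent inhibition.  Accepts
    :class:`IC50Fit` objects or plain values in µM.
    """
    a = no_preinc.ic50 if isinstance(no_preinc, IC50Fit) else float(no_preinc)
    b = preinc.ic50 if isinstance(preinc, IC50Fit) else float(preinc)
    if a <= 0 or b <= 0:
        raise DomainError(f"IC50 values must be > 0, got {a}, {b}")
    shift = a / b
    return ShiftResult(
        ic50_no_preinc=a, ic50_preinc=b, shift=shift,
        tdi_flag=shift > TDI_SHIFT_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# Dixon Ki
# ---------------------------------------------------------------------------
class DixonKiEstimator(BaseEstimator):
    """Competitive Ki from Dixon-plot line intersections.

    ``fit(X, y)`` takes ``X`` with columns (substrate µM, inhibitor µM) and
    ``y`` strictly positive velocities.  For each substrate level an OLS line
    of 1/v on [I] is fit; a competitive inhibitor yields lines crossing at
    [I] = -Ki.  All pairwise intersection abscissae are combined by a
    weighted mean (weights: product of the two slopes' |t|-statistics), and
    a common intersection is accepted when the weighted SD of the abscissae
    is below ``spread_tolerance`` of |mean| and the mean lies left of zero.

    Parameters
    ----------
    spread_tolerance : float
        Maximum weighted SD of intersection abscissae, as a fraction of the
        |weighted mean|, for the "competitive" label.
    effect_tolerance : float
        Minimum relative increase of 1/v across the inhibitor range
        (slope·Imax/intercept) for a line to count as showing inhibition;
        if no line does, the label is "none_detected".  The default is
        small because a weak but noiseless competitive signal (Ki far above
        the inhibitor range) is still an exact intersection.
    """

    def __init__(self, spread_tolerance=0.25, effect_tolerance=0.01):
        self.spread_tolerance = spread_tolerance
        self.effect_tolerance = effect_tolerance

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have columns (substrate_conc, inhibitor_conc)")
        if np.any(y <= 0):
            raise DomainError("velocities must be strictly positive (1/v is used)")
        S, I = X[:, 0], X[:, 1]
        levels = np.unique(S)
        if levels.size < 2:
            raise AssayValidationError("need >=2 distinct substrate levels")
        lines = {}
        for s in levels:
            mask = S == s
            # replicate wells are averaged per design point before taking the
            # reciprocal, as on a conventional Dixon plot of triplicate means
            xi = np.unique(I[mask])
            yi = 1.0 / np.array([y[mask & (I == i)].mean() for i in xi])
            if np.unique(xi).size < 3:
                raise AssayValidationError(
                    f"substrate level {s}: need >=3 distinct inhibitor levels"
                )
            res = stats.linregress(xi, yi)
            se = res.stderr if np.isfinite(res.stderr) else 0.0
            tval = abs(res.slope) / se if se > 0 else (
                _SLOPE_T_CAP if abs(res.slope) > 0 else 0.0
            )
            rel_effect = res.slope * xi.max() / res.intercept if res.intercept != 0 else 0.0
            lines[float(s)] = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "slope_se": float(se),
                "slope_t": float(min(tval, _SLOPE_T_CAP)),
                "rel_effect": float(rel_effect),
            }
        self.lines_ = lines

        significant = [
            ln for ln in lines.values()
            if ln["slope_t"] >= 2.0 and ln["rel_effect"] >= self.effect_tolerance
        ]
        if not significant:
            self._label_none()
            return self

        keys = sorted(lines)
        xs, ws = [], []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                li, lj = lines[keys[i]], lines[keys[j]]
                db = li["slope"] - lj["slope"]
                scale = max(abs(li["slope"]), abs(lj["slope"]), 1e-300)
                if abs(db) < 1e-9 * scale:
                    continue  # effectively parallel pair
                xs.append((lj["intercept"] - li["intercept"]) / db)
                ws.append(li["slope_t"] * lj["slope_t"])
        if not xs:
            self._label_none()
            return self
        xs, ws = np.asarray(xs), np.asarray(ws)
        mean = float(np.average(xs, weights=ws))
        spread = float(np.sqrt(np.average((xs - mean) ** 2, weights=ws)))
        self.intersection_x_ = mean
        self.intersection_spread_ = spread
        if mean < 0 and spread <= self.spread_tolerance * abs(mean):
            self.mechanism_label_ = "competitive"
            self.ki_ = -mean
        else:
            self.mechanism_label_ = "none_detected"
            self.ki_ = None
        return self

    def _label_none(self):
        self.mechanism_label_ = "none_detected"
        self.ki_ = None
        self.intersection_x_ = None
        self.intersection_spread_ = None

    def result_(self) -> DixonFit:
        check_is_fitted(self, "mechanism_label_")
        return DixonFit(
            ki=self.ki_, lines=self.lines_, intersection_x=self.intersection_x_,
            intersection_spread=self.intersection_spread_,
            mechanism_label=self.mechanism_label_,
        )


def fit_dixon(dataset: AssayDataset, **estimator_kwargs) -> DixonFit:
    """Dixon-plot Ki estimation on a validated reversible-inhibition dataset."""
    if dataset.assay_kind is not AssayKind.DIXON:
        raise AssayValidationError("fit_dixon requires a dixon-kind dataset")
    df = dataset.to_frame()
    est = DixonKiEstimator(**estimator_kwargs)
    est.fit(
        df[["substrate_conc_uM", "inhibitor_conc_uM"]].to_numpy(),
        df["response"].to_numpy(),
    )
    return est.result_()


# ---------------------------------------------------------------------------
# TDI: kobs and saturable inactivation
# ---------------------------------------------------------------------------
def _log_decay_slope(times, activities):
    if np.any(np.asarray(activities) <= 0):
        raise DomainError("activity must be > 0 to take logs for kobs fitting")
    res = stats.linregress(times, np.log(activities))
    return res.slope, res.rvalue ** 2


def fit_kobs(dataset: AssayDataset, conc: float, *, control_correct: bool = True) -> float:
    """Observed inactivation rate (min⁻¹) at one preincubation concentration.

    The negated least-squares slope of ln(normalized activity) vs
    preincubation time.  With ``control_correct`` (default) the slope of the
    zero-inhibitor control series is subtracted first, removing
    NADPH-independent activity loss; the result is clipped at 0.
    """
    if dataset.assay_kind is not AssayKind.TDI:
        raise AssayValidationError("fit_kobs requires a tdi-kind dataset")
    if not dataset.normalized:
        raise AssayValidationError("fit_kobs requires normalized activity data")
    rows = [r for r in dataset.records if r.inhibitor_conc == conc]
    if len({r.preincubation_min for r in rows}) < 3:
        raise AssayValidationError(
            f"need >=3 preincubation times at inhibitor {conc} µM"
        )
    slope, _ = _log_decay_slope(
        [r.preincubation_min for r in rows], [r.response for r in rows]
    )
    if control_correct and conc != 0.0:
        ctl = [r for r in dataset.records if r.inhibitor_conc == 0.0]
        slope0, _ = _log_decay_slope(
            [r.preincubation_min for r in ctl], [r.response for r in ctl]
        )
        slope -= slope0
    return max(-slope, 0.0)


def _kobs_model(I, kinact, KI):
    return kinact * I / (KI + I)


class InactivationKineticsEstimator(RegressorMixin, BaseEstimator):
    """Saturable inactivation fit kobs = kinact·[I]/(KI+[I]).

    ``fit(X, y)``: X is inhibitor concentration (µM), y the observed
    inactivation rates (min⁻¹).  Fitted attributes ``kinact_`` (min⁻¹),
    ``KI_`` (µM), ``efficiency_`` (mL/min/µmol) and ``kitz_wilson_`` (the
    double-reciprocal linearization diagnostic).
    """

    def __init__(self, min_positive_levels=4):
        self.min_positive_levels = min_positive_levels

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        I, kobs = X[:, 0].astype(float), np.asarray(y, dtype=float)
        pos = I > 0
        if np.unique(I[pos]).size < self.min_positive_levels:
            raise AssayValidationError(
                f"need >={self.min_positive_levels} positive concentrations with kobs"
            )
        if np.all(kobs[pos] <= 0):
            raise FitError("no inactivation: all kobs are zero")
        kw = self._kitz_wilson(I[pos], kobs[pos])
        kmax = kobs[pos].max()
        half = kobs[pos] >= 0.5 * kmax
        p0 = [kmax * 1.2, max(float(I[pos][half].min()) * 0.5, 1e-3)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _kobs_model, I[pos], kobs[pos], p0=p0,
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    maxfev=20000, xtol=1e-13, ftol=1e-13, gtol=1e-13,
                )
        except (RuntimeError, ValueError) as exc:
            raise FitError(
                f"inactivation fit failed to converge: {exc}", fallback=kw
            ) from exc
        self.kinact_ = float(popt[0])
        self.KI_ = float(popt[1])
        self.efficiency_ = efficiency(self.kinact_, self.KI_)
        self.kitz_wilson_ = kw
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _kitz_wilson(I, kobs):
        ok = kobs > 0
        if ok.sum() < 2:
            return None
        res = stats.linregress(1.0 / I[ok], 1.0 / kobs[ok])
        if res.intercept <= 0:
            return None
        kinact = 1.0 / res.intercept
        return {"kinact": float(kinact), "KI": float(res.slope * kinact),
                "r2": float(res.rvalue ** 2)}

    def predict(self, X):
        check_is_fitted(self, "kinact_")
        return _kobs_model(check_array(X)[:, 0], self.kinact_, self.KI_)


class TDIActivityEstimator(BaseEstimator):
    """Full TDI pipeline on (concentration, time) -> activity observations.

    ``fit(X, y)``: X columns (inhibitor µM, preincubation min), y normalized
    activity.  Computes kobs per inhibitor level from the log-linear decay
    (control-corrected via the zero-inhibitor series when present), then the
    saturable inactivation parameters.
    """

    def __init__(self, control_correct=True, min_positive_levels=4):
        self.control_correct = control_correct
        self.min_positive_levels = min_positive_levels

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        I, t, act = X[:, 0], X[:, 1], np.asarray(y, dtype=float)
        slope0 = 0.0
        r2s = []
        if self.control_correct and np.any(I == 0):
            slope0, r2 = _log_decay_slope(t[I == 0], act[I == 0])
            r2s.append(r2)
        kobs_by_conc = {}
        for c in np.unique(I[I > 0]):
            mask = I == c
            slope, r2 = _log_decay_slope(t[mask], act[mask])
            if self.control_correct and np.any(I == 0):
                slope -= slope0
            kobs_by_conc[float(c)] = max(-slope, 0.0)
            r2s.append(r2)
        self.kobs_by_conc_ = kobs_by_conc
        self.r2_per_decay_ = r2s
        inner = InactivationKineticsEstimator(
            min_positive_levels=self.min_positive_levels
        )
        inner.fit(
            np.array(sorted(kobs_by_conc)).reshape(-1, 1),
            np.array([kobs_by_conc[c] for c in sorted(kobs_by_conc)]),
        )
        self.kinact_, self.KI_ = inner.kinact_, inner.KI_
        self.efficiency_, self.kitz_wilson_ = inner.efficiency_, inner.kitz_wilson_
        return self

    def result_(self) -> InactivationFit:
        check_is_fitted(self, "kinact_")
        return InactivationFit(
            kobs_by_conc=self.kobs_by_conc_, KI=self.KI_, kinact=self.kinact_,
            efficiency=self.efficiency_, r2_per_decay=self.r2_per_decay_,
            kitz_wilson=self.kitz_wilson_,
        )


def fit_inactivation(kobs_by_conc: dict) -> InactivationFit:
    """Fit kinact and KI from a map of inhibitor µM -> kobs (min⁻¹)."""
    I = np.array(sorted(kobs_by_conc), dtype=float).reshape(-1, 1)
    kobs = np.array([kobs_by_conc[c] for c in sorted(kobs_by_conc)], dtype=float)
    est = InactivationKineticsEstimator()
    est.fit(I, kobs)
    return InactivationFit(
        kobs_by_conc={float(k): float(v) for k, v in kobs_by_conc.items()},
        KI=est.KI_, kinact=est.kinact_, efficiency=est.efficiency_,
        kitz_wilson=est.kitz_wilson_,
    )


def fit_tdi(dataset: AssayDataset, **estimator_kwargs) -> InactivationFit:
    """Run the full TDI pipeline on a normalized tdi-kind dataset."""
    if dataset.assay_kind is not AssayKind.TDI:
        raise AssayValidationError("fit_tdi requires a tdi-kind dataset")
    if not dataset.normalized:
        raise AssayValidationError("fit_tdi requires normalized activity data")
    df = dataset.to_frame()
    est = TDIActivityEstimator(**estimator_kwargs)
    est.fit(
        df[["inhibitor_conc_uM", "preincubation_min"]].to_numpy(),
        df["response"].to_numpy(),
    )
    return est.result_()


def efficiency(kinact: float, KI: float) -> float:
    """Inactivation efficiency (kinact/KI)·1000 in mL/min/µmol.

    kinact in min⁻¹, KI in µM; min⁻¹/(µmol/L) = L/min/µmol, and the ×1000
    converts L to mL.
    """
    if kinact <= 0 or KI <= 0:
        raise DomainError(f"kinact and KI must be > 0, got {kinact}, {KI}")
    return kinact / KI * 1000.0
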