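"""Chou-Talalay median-effect fitting and combination-index analysis.

The median-effect model describes a dose-response as

    fa / fu = (D / Dm)^m

where ``fa`` is the fraction of cells affected at dose D, ``fu = 1 - fa``,
``Dm`` is the median-effect dose (the IC50) and ``m`` the sigmoidicity.
Taking logs linearizes the model, so (m, Dm) come from ordinary least
squares on (log D, log(fa/fu)) and r is the correlation of that line.

For a fixed-ratio drug combination observed at effect level fa, the
combination index in the mutually exclusive (two-term) form is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where d1, d2 are the doses present in the combination and Dx_i(fa) is the
dose of drug i alone that would produce the same effect. CI < 1 indicates
synergism, CI = 1 additivity, and CI > 1 antagonism; a Fa-CI curve
evaluates CI at every observed combination effect level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator

__all__ = [
    "MedianEffectError",
    "DoseResponseSeries",
    "MedianEffectFit",
    "CombinationIndexResult",
    "fit_median_effect",
    "dose_for_effect",
    "fa_from_dose",
    "combination_index",
    "fa_ci_curve",
    "viability_to_fa",
    "simulate_dose_response",
    "simulate_combination",
    "read_dose_response",
    "MedianEffectModel",
]


class MedianEffectError(ValueError):
    """The median-effect fit is undefined for the given data."""


def viability_to_fa(viability, control: float = 1.0) -> np.ndarray:
    """Convert relative viability to fraction affected, fa = 1 - v/control.

    Values outside [0, 1] (assay noise above control, or complete kill)
    are clipped with a warning; exact 0/1 values are then excluded by the
    fit itself.
    """
    fa = 1.0 - np.asarray(viability, dtype=float) / control
    if np.any((fa < 0) | (fa > 1)):
        warnings.warn("fraction affected clipped to [0, 1]", stacklevel=2)
    return np.clip(fa, 0.0, 1.0)


@dataclass
class DoseResponseSeries:
    """One drug's (dose, fraction-affected) measurements.

    Doses are concentrations (conventionally uM) and must be positive and
    strictly increasing; fa values must pair one-to-one with doses.
    """

    drug_id: str
    doses: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.doses.shape != self.fa.shape or self.doses.ndim != 1:
            raise ValueError("doses and fa must be equal-length 1-d arrays")
        if len(self.doses) < 2:
            raise ValueError("a dose-response series needs >= 2 points")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")


@dataclass(frozen=True)
class MedianEffectFit:
    """(m, Dm, r) of one drug's median-effect line."""

    m: float
    dm: float
    r: float
    drug_id: str = ""
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.dm > 0):
            raise ValueError("Dm must be positive")


@dataclass(frozen=True)
class CombinationIndexResult:
    """CI at one combination observation."""

    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    verdict: str


def fit_median_effect(series: DoseResponseSeries) -> MedianEffectFit:
    """OLS fit of the median-effect line log(fa/fu) = m log D - m log Dm.

    fa values of exactly 0 or 1 are log-infinite and excluded with a
    warning; fewer than 3 usable points triggers a small-sample warning,
    fewer than 2 (or zero dose spread / a flat response) is an error.
    """
    mask = (series.fa > 0.0) & (series.fa < 1.0)
    if not mask.all():
        warnings.warn(
            f"{int((~mask).sum())} boundary fa value(s) (0 or 1) excluded "
            f"from the median-effect fit of {series.drug_id}",
            stacklevel=2,
        )
    doses = series.doses[mask]
    fa = series.fa[mask]
    if len(doses) < 2:
        raise MedianEffectError(
            f"{series.drug_id}: fewer than 2 usable points after excluding "
            "boundary fa values"
        )
    if len(doses) < 3:
        warnings.warn(
            f"{series.drug_id}: median-effect fit on only {len(doses)} points",
            stacklevel=2,
        )
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    if np.ptp(x) == 0:
        raise MedianEffectError(f"{series.drug_id}: zero dose spread")
    res = linregress(x, y)
    m = float(res.slope)
    if not np.isfinite(m) or m == 0:
        raise MedianEffectError(
            f"{series.drug_id}: degenerate (flat) dose-response"
        )
    dm = float(10.0 ** (-res.intercept / m))
    r = float(res.rvalue)
    return MedianEffectFit(m=m, dm=dm, r=r, drug_id=series.drug_id,
                           n_points=len(doses))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx = Dm (fa/(1-fa))^(1/m): the single-agent dose producing effect
    fa. Dx(0.5) == Dm by definition of the median effect."""
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def fa_from_dose(fit: MedianEffectFit, dose) -> np.ndarray:
    """Forward model fa(D) = 1 / (1 + (Dm/D)^m)."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (fit.dm / dose) ** fit.m)


def _verdict(ci: float, additive_tol: float) -> str:
    if ci < 1.0 - additive_tol:
        return "synergism"
    if ci > 1.0 + additive_tol:
        return "antagonism"
    return "additive"


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float, fa_combo: float,
                      additive_tol: float = 0.0) -> CombinationIndexResult:
    """Two-term (mutually exclusive) CI at the observed combination effect.

    ``additive_tol`` widens the "additive" verdict band around CI = 1;
    the default 0 applies the strict <1 / =1 / >1 rule.
    """
    if not (0.0 < fa_combo < 1.0):
        raise ValueError(f"fa_combo must lie strictly in (0, 1), got {fa_combo}")
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("combination doses must be >= 0 and not both zero")
    dx1 = dose_for_effect(fit1, fa_combo)
    dx2 = dose_for_effect(fit2, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    return CombinationIndexResult(fa=fa_combo, d1=d1, d2=d2, dx1=dx1,
                                  dx2=dx2, ci=float(ci),
                                  verdict=_verdict(ci, additive_tol))


def fa_ci_curve(series1: DoseResponseSeries, series2: DoseResponseSeries,
                combo_series: DoseResponseSeries,
                ratio: tuple[float, float],
                additive_tol: float = 0.0) -> list[CombinationIndexResult]:
    """Fa-CI curve for a fixed-ratio combination.

    ``combo_series`` holds (total dose, observed fa) for the mixture; each
    total dose is split by ``ratio`` into the component doses, and CI is
    evaluated at the observed fa with the two single-agent fits. A zero
    ratio component degenerates gracefully to the single-agent CI (the
    other drug's term vanishes). The curve is returned sorted by fa.
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 < 0 or r2 < 0 or r1 + r2 == 0:
        raise ValueError("ratio components must be >= 0 and not both zero")
    fit1 = fit_median_effect(series1)
    fit2 = fit_median_effect(series2)
    w1, w2 = r1 / (r1 + r2), r2 / (r1 + r2)
    out = []
    for total, fa in zip(combo_series.doses, combo_series.fa):
        if not (0.0 < fa < 1.0):
            warnings.warn(
                f"combination point at dose {total} has boundary fa {fa}; "
                "skipped", stacklevel=2)
            continue
        out.append(combination_index(fit1, fit2, total * w1, total * w2,
                                     float(fa), additive_tol=additive_tol))
    return sorted(out, key=lambda r: r.fa)


def design_doses(m: float, dm: float, n: int = 6,
                 max_odds: float = 9.0) -> np.ndarray:
    """Serial-dilution dose design bracketing the IC50 in effect space.

    Returns ``n`` geometrically spaced doses whose model effects span
    fa from 1/(1+max_odds) to max_odds/(1+max_odds) (0.1 to 0.9 by
    default) symmetrically around Dm. Keeping observations off the fa
    saturation plateaus is what makes the linearized fit well conditioned
    for any sigmoidicity m.
    """
    if n < 2:
        raise ValueError("need at least 2 doses")
    odds_exponents = np.linspace(-1.0, 1.0, n) / m
    return dm * max_odds ** odds_exponents


def simulate_dose_response(m: float, dm: float, doses,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None,
                           drug_id: str = "SIM") -> DoseResponseSeries:
    """Dose-response data from the forward median-effect model, optionally
    with multiplicative Gaussian noise on fa (fa * (1 + eps), clipped to
    the open unit interval)."""
    doses = np.asarray(doses, dtype=float)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        fa = fa * (1.0 + rng.normal(0.0, noise_sd, size=fa.shape))
        fa = np.clip(fa, 1e-6, 1.0 - 1e-6)
    return DoseResponseSeries(drug_id=drug_id, doses=doses, fa=fa)


def simulate_combination(fit1: MedianEffectFit, fit2: MedianEffectFit,
                         ratio: tuple[float, float], fa_values,
                         potency_factor: float = 1.0,
                         drug_id: str = "COMBO") -> DoseResponseSeries:
    """Construct a fixed-ratio combination series with known CI.

    For each requested effect level the Loewe-additive total dose is
    D_add(fa) = 1 / (w1/Dx1(fa) + w2/Dx2(fa)) with w the normalized dose
    ratio; emitting D = potency_factor * D_add makes the true CI equal
    ``potency_factor`` at every point (1 = additive, <1 = synergistic).
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    w1, w2 = r1 / (r1 + r2), r2 / (r1 + r2)
    fa_values = np.sort(np.asarray(fa_values, dtype=float))
    doses = []
    for fa in fa_values:
        dx1 = dose_for_effect(fit1, float(fa))
        dx2 = dose_for_effect(fit2, float(fa))
        doses.append(potency_factor / (w1 / dx1 + w2 / dx2))
    return DoseResponseSeries(drug_id=drug_id, doses=np.asarray(doses),
                              fa=fa_values)


def read_dose_response(path, response: str = "fa") -> list[DoseResponseSeries]:
    """Read per-drug series from a TSV with columns drug_id, dose,
    response. ``response`` names the measurement: ``fa`` (fraction
    affected, default) or ``viability`` (converted as fa = 1 - v)."""
    if response not in ("fa", "viability"):
        raise ValueError(f"unknown response type {response!r}")
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "dose", "response"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    out = []
    for drug_id, grp in df.groupby("drug_id", sort=True):
        grp = grp.sort_values("dose")
        vals = grp["response"].to_numpy(dtype=float)
        fa = viability_to_fa(vals) if response == "viability" else vals
        out.append(DoseResponseSeries(drug_id=str(drug_id),
                                      doses=grp["dose"].to_numpy(dtype=float),
                                      fa=fa))
    return out


class MedianEffectModel(BaseEstimator):
    """Estimator interface to the median-effect fit.

    ``fit(doses, fa)`` estimates the fitted attributes ``m_`` (slope),
    ``dm_`` (median-effect dose, the IC50 in the dose units supplied) and
    ``r_`` (correlation of the linearized fit). ``predict(doses)`` returns
    the modelled fraction affected; ``dose_for_effect(fa)`` inverts it.
    """

    def __init__(self, drug_id: str = ""):
        self.drug_id = drug_id

    def fit(self, doses, fa) -> "MedianEffectModel":
        series = DoseResponseSeries(drug_id=self.drug_id or "drug",
                                    doses=np.asarray(doses, dtype=float),
                                    fa=np.asarray(fa, dtype=float))
        self.fit_ = fit_median_effect(series)
        self.m_ = self.fit_.m
        self.dm_ = self.fit_.dm
        self.r_ = self.fit_.r
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "fit_"):
            raise RuntimeError("MedianEffectModel is not fitted; call fit first")

    def predict(self, doses) -> np.ndarray:
        self._check_fitted()
        return fa_from_dose(self.fit_, doses)

    def dose_for_effect(self, fa: float) -> float:
        self._check_fitted()
        return dose_for_effect(self.fit_, fa)
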