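"""Dose-response curve analysis for organoid viability screens.

Raw ATP-luminescence readouts from a dilution series (by default a 7-point,
3-fold series from 50 uM plus a DMSO vehicle control) are normalized to the
DMSO control mean, fitted with a four-parameter logistic (4PL) curve, and
summarized as a normalized area under the viability-vs-log10-concentration
curve (AUC).  The AUC is dimensionless in [0, 1]: 1 means no drug effect over
the tested range (fully resistant), 0 means complete kill at every dose.

Conventions pinned here (the upstream assay software leaves them open):

* viability(c) = mean(replicates at c) / mean(DMSO readouts);
* the 4PL is ``v(c) = bottom + (top - bottom) / (1 + 10**(hill * (log10 c -
  log10_ec50)))`` with ``hill > 0``, i.e. viability is non-increasing in
  concentration;
* AUC integrates viability clipped to [0, 1] over log10 concentration and
  divides by the width of the tested range, so cohorts screened on different
  dose grids stay comparable;
* if the fit fails, or the data are flat or non-monotone beyond tolerance,
  the AUC falls back to the trapezoid on the observed per-dose means and the
  result is flagged (``method="trapezoid_raw"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import least_squares

from .errors import ControlError, SchemaError, ValidationError

__all__ = [
    "DoseSeries",
    "DoseResponseProfile",
    "FourPL",
    "AUCResult",
    "make_dilution_series",
    "normalize_viability",
    "four_pl",
    "fit_four_pl",
    "compute_auc",
    "load_plate",
    "write_plate",
]

#: viability range below which a profile is treated as showing no dose effect
FLAT_TOLERANCE = 0.05
#: largest tolerated uphill step (in viability fraction) between consecutive
#: dose means before the profile is declared non-monotone and sent to the
#: trapezoid fallback
MONOTONE_TOLERANCE = 0.25

PLATE_COLUMNS = ["patient_id", "drug", "conc_uM", "replicate", "readout"]


@dataclass(frozen=True)
class DoseSeries:
    """A serial dilution design: ``top_conc`` uM diluted ``fold``-fold, ``n_points`` times."""

    top_conc: float = 50.0
    fold: float = 3.0
    n_points: int = 7

    def __post_init__(self) -> None:
        if self.top_conc <= 0:
            raise ValidationError(f"top_conc must be > 0, got {self.top_conc}")
        if self.fold <= 1:
            raise ValidationError(f"dilution fold must be > 1, got {self.fold}")
        if self.n_points < 2:
            raise ValidationError(f"n_points must be >= 2, got {self.n_points}")

    def concentrations(self) -> np.ndarray:
        return make_dilution_series(self.top_conc, self.fold, self.n_points)


def make_dilution_series(top_conc: float, fold: float, n_points: int) -> np.ndarray:
    """Return the strictly decreasing concentration grid ``[top, top/fold, ...]`` in uM."""
    series = DoseSeries(top_conc, fold, n_points)
    return series.top_conc / series.fold ** np.arange(series.n_points, dtype=float)


@dataclass
class DoseResponseProfile:
    """One patient x drug dilution series with per-concentration replicate readouts."""

    patient_id: str
    drug: str
    concentrations: np.ndarray  # uM, strictly decreasing
    replicates: list[np.ndarray]  # raw readouts, one array per concentration
    dmso_readouts: np.ndarray  # raw vehicle-control readouts

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        self.dmso_readouts = np.asarray(self.dmso_readouts, dtype=float)
        if len(self.replicates) != len(self.concentrations):
            raise ValidationError(
                f"{self.patient_id}/{self.drug}: {len(self.concentrations)} concentrations "
                f"but {len(self.replicates)} replicate groups"
            )
        if any(len(r) == 0 for r in self.replicates):
            raise ValidationError(f"{self.patient_id}/{self.drug}: empty replicate group")
        if self.dmso_readouts.size == 0:
            raise ValidationError(f"{self.patient_id}/{self.drug}: no DMSO control readouts")
        if np.any(np.diff(self.concentrations) >= 0):
            raise ValidationError(
                f"{self.patient_id}/{self.drug}: concentrations must be strictly decreasing"
            )


def normalize_viability(profile: DoseResponseProfile) -> np.ndarray:
    """Per-concentration mean viability fractions relative to the DMSO control mean.

    Values are >= 0 and may exceed 1 (wells outgrowing the control); clipping
    to [0, 1] happens only inside the AUC integral.
    """
    control = float(np.mean(profile.dmso_readouts))
    if control <= 0:
        raise ControlError(
            f"{profile.patient_id}/{profile.drug}: DMSO control mean is {control}, must be > 0"
        )
    return np.array([float(np.mean(r)) for r in profile.replicates]) / control


def four_pl(log10_conc, top: float, bottom: float, log10_ec50: float, hill: float):
    """Decreasing four-parameter logistic evaluated at log10 concentration."""
    x = np.asarray(log10_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log10_ec50)))


@dataclass
class FourPL:
    """Fitted 4PL parameters (viability fractions; ``hill > 0`` means decreasing)."""

    top: float
    bottom: float
    log10_ec50: float
    hill: float
    converged: bool = True
    fallback_used: bool = False

    def predict(self, conc_uM) -> np.ndarray:
        return four_pl(np.log10(np.asarray(conc_uM, dtype=float)), self.top,
                       self.bottom, self.log10_ec50, self.hill)

    def predict_log10(self, log10_conc) -> np.ndarray:
        return four_pl(log10_conc, self.top, self.bottom, self.log10_ec50, self.hill)


@dataclass
class AUCResult:
    patient_id: str
    drug: str
    auc: float
    method: str  # "fitted_curve" | "trapezoid_raw"

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")
        self.auc = min(self.auc, 1.0)


def fit_four_pl(concentrations: Sequence[float], viabilities: Sequence[float]) -> FourPL:
    """Least-squares 4PL fit of mean viability fractions against concentration.

    Constraints: ``bottom`` in [0, 1], ``top`` in [0.5, 1.5], ``hill`` in
    (0, 10], ``log10_ec50`` within the dose grid +/- 1 decade.  Initialization
    reads top/bottom off the raw curve and places the EC50 at the dose whose
    mean is nearest the half-range; three Hill-slope starts guard against
    local minima.  Flat profiles, non-monotone profiles (beyond
    ``MONOTONE_TOLERANCE``) and optimizer failures return a fit with
    ``fallback_used=True`` so the AUC stage uses the raw trapezoid.
    """
    conc = np.asarray(concentrations, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if conc.shape != v.shape:
        raise ValidationError("concentrations and viabilities must have equal length")
    if np.unique(conc).size < 2:
        raise ValidationError("need at least 2 distinct concentrations")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be > 0 (0 encodes the DMSO control)")

    order = np.argsort(conc)
    x = np.log10(conc[order])
    y = v[order]

    top0 = float(np.clip(y.max(), 0.5, 1.5))
    bottom0 = float(np.clip(y.min(), 0.0, 1.0))
    flat = (y.max() - y.min()) < FLAT_TOLERANCE
    non_monotone = np.any(np.diff(y) > MONOTONE_TOLERANCE)

    def _fallback() -> FourPL:
        return FourPL(top=top0, bottom=bottom0, log10_ec50=float(np.median(x)),
                      hill=1.0, converged=False, fallback_used=True)

    if flat or non_monotone or np.unique(conc).size < 4:
        return _fallback()

    half = 0.5 * (top0 + bottom0)
    ec50_0 = float(x[np.argmin(np.abs(y - half))])
    lo = [0.5, 0.0, x.min() - 1.0, 1e-3]
    hi = [1.5, 1.0, x.max() + 1.0, 10.0]

    def residuals(p):
        return four_pl(x, *p) - y

    best = None
    for hill0 in (0.7, 1.0, 2.0):
        p0 = np.clip([top0, bottom0, ec50_0, hill0], lo, hi)
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return _fallback()
    top, bottom, log10_ec50, hill = (float(q) for q in best.x)
    if bottom > top:  # degenerate optimum; data do not support a 4PL shape
        return _fallback()
    return FourPL(top=top, bottom=bottom, log10_ec50=log10_ec50, hill=hill,
                  converged=True, fallback_used=False)


def compute_auc(
    fit: FourPL,
    concentrations: Sequence[float],
    observed_viability: Sequence[float] | None = None,
    patient_id: str = "",
    drug: str = "",
) -> AUCResult:
    """Normalized AUC over log10 concentration, in [0, 1].

    ``AUC = (1 / (log10 c_max - log10 c_min)) * integral of clip(v, 0, 1)``.
    A converged fit is integrated by adaptive quadrature; a fallback fit
    integrates the observed per-dose means by the trapezoid rule
    (``observed_viability`` is then required).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.unique(conc).size < 2:
        raise ValidationError("AUC needs at least 2 distinct concentrations")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be > 0")
    x = np.sort(np.log10(conc))
    width = x[-1] - x[0]

    if fit is not None and not fit.fallback_used:
        val, _ = quad(lambda t: float(np.clip(fit.predict_log10(t), 0.0, 1.0)),
                      x[0], x[-1], limit=200, epsabs=1e-10, epsrel=1e-10)
        return AUCResult(patient_id, drug, float(np.clip(val / width, 0.0, 1.0)),
                         "fitted_curve")

    if observed_viability is None:
        raise ValidationError("fallback AUC requires the observed viability means")
    v = np.asarray(observed_viability, dtype=float)
    order = np.argsort(conc)
    xv = np.log10(conc[order])
    yv = np.clip(v[order], 0.0, 1.0)
    val = float(np.trapezoid(yv, xv))
    return AUCResult(patient_id, drug, float(np.clip(val / width, 0.0, 1.0)),
                     "trapezoid_raw")


def profile_auc(profile: DoseResponseProfile) -> AUCResult:
    """Full per-profile path: normalize, fit, integrate."""
    v = normalize_viability(profile)
    fit = fit_four_pl(profile.concentrations, v)
    return compute_auc(fit, profile.concentrations, observed_viability=v,
                       patient_id=profile.patient_id, drug=profile.drug)


# ---------------------------------------------------------------------------
# plate.csv I/O (long format; conc_uM == 0 encodes the DMSO control well)
# ---------------------------------------------------------------------------

def load_plate(path) -> dict[tuple[str, str], DoseResponseProfile]:
    """Read a long-format plate table into per-(patient, drug) profiles."""
    df = pd.read_csv(path, dtype={"patient_id": str, "drug": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    profiles: dict[tuple[str, str], DoseResponseProfile] = {}
    for (pid, drug), grp in df.groupby(["patient_id", "drug"], sort=True):
        dmso = grp.loc[grp["conc_uM"] == 0, "readout"].to_numpy(float)
        dosed = grp[grp["conc_uM"] > 0]
        conc = np.sort(dosed["conc_uM"].unique())[::-1]
        reps = [dosed.loc[dosed["conc_uM"] == c, "readout"].to_numpy(float) for c in conc]
        profiles[(pid, drug)] = DoseResponseProfile(pid, drug, conc, reps, dmso)
    return profiles


def write_plate(rows: pd.DataFrame, path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    rows.to_csv(path, index=False)
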