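"""Non-compartmental PK summaries and the residual-blood tissue correction.

Works on mean concentration-time curves per matrix (plasma, blood, muscle
homogenate).  AUC is the linear trapezoid over the observed points with no
extrapolation beyond the last sample; muscle-homogenate concentrations are
converted to tissue concentration (ng/g) by scaling to the homogenate volume
and subtracting the drug carried in the blood trapped within the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MATRICES",
    "ConcSeries",
    "NCAResult",
    "TissueCorrectionParams",
    "TissueConcentration",
    "InsufficientSeriesError",
    "InvalidMassError",
    "UndefinedRatioError",
    "nca",
    "correct_muscle_concentration",
    "auc_ratio",
    "dose_response_summary",
    "mean_curve",
]

MATRICES = ("plasma", "blood", "muscle_homogenate")


class InsufficientSeriesError(ValueError):
    """Fewer than two concentration-time points."""


class InvalidMassError(ValueError):
    """Non-positive muscle mass."""


class UndefinedRatioError(ZeroDivisionError):
    """AUC ratio with a zero denominator."""


@dataclass(frozen=True)
class ConcSeries:
    """A concentration-time curve for one matrix at one dose.

    times in hours (strictly increasing, first >= 0), concentrations in
    ng/mL (ng/g once tissue-corrected).
    """

    matrix: str
    times: np.ndarray
    concs: np.ndarray
    dose_mg_per_kg: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concs, dtype=float)
        if times.ndim != 1 or times.shape != concs.shape:
            raise ValueError("times and concs must be aligned 1-D arrays")
        if times.size < 2:
            raise InsufficientSeriesError("need at least 2 time points")
        if times[0] < 0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing, starting >= 0")
        if np.any(concs < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concs", concs)

    def with_zero_anchor(self) -> "ConcSeries":
        """Prepend a (0, 0) point when the series starts after time zero."""
        if self.times[0] == 0.0:
            return self
        return ConcSeries(
            self.matrix,
            np.concatenate(([0.0], self.times)),
            np.concatenate(([0.0], self.concs)),
            self.dose_mg_per_kg,
        )


@dataclass(frozen=True)
class NCAResult:
    """Cmax (ng/mL), Tmax (h, earliest on ties) and AUC0-tlast (ng*h/mL)."""

    cmax: float
    tmax: float
    auc_last: float
    matrix: str = ""
    dose_mg_per_kg: float | None = None

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix,
            "dose_mg_per_kg": self.dose_mg_per_kg,
            "cmax": self.cmax,
            "tmax": self.tmax,
            "auc_last": self.auc_last,
        }


@dataclass(frozen=True)
class TissueCorrectionParams:
    """Parameters of the homogenate-to-tissue conversion.

    homogenate_dilution: mL of homogenisation buffer per g tissue (1:10 w/v
    homogenisation gives 10).  residual_blood_mL_per_g: blood volume trapped
    per gram of muscle; no universally agreed value exists, the 0.01 mL/g
    default is a literature-scale placeholder and should be set explicitly.
    """

    homogenate_dilution: float = 10.0
    residual_blood_mL_per_g: float = 0.01

    def __post_init__(self) -> None:
        if self.homogenate_dilution <= 0 or self.residual_blood_mL_per_g <= 0:
            raise ValueError("correction parameters must be positive")


@dataclass(frozen=True)
class TissueConcentration:
    """Residual-blood-corrected tissue concentration, ng per g of muscle."""

    value_ng_per_g: float
    clamped: bool = False


def nca(series: ConcSeries) -> NCAResult:
    """Non-compartmental summary of one curve.

    Cmax/Tmax are the observed maximum (earliest time on ties); AUC0-tlast
    is the linear trapezoid over the observed points, with no extrapolation
    to infinity and no (0, 0) anchor unless the series carries one.
    """
    i = int(np.argmax(series.concs))  # argmax returns the first maximum
    auc = float(np.trapezoid(series.concs, series.times))
    return NCAResult(
        cmax=float(series.concs[i]),
        tmax=float(series.times[i]),
        auc_last=auc,
        matrix=series.matrix,
        dose_mg_per_kg=series.dose_mg_per_kg,
    )


def correct_muscle_concentration(
    homog_conc_ng_ml: float,
    muscle_mass_g: float,
    blood_conc_ng_ml: float,
    params: TissueCorrectionParams | None = None,
) -> TissueConcentration:
    """Convert a muscle-homogenate concentration to tissue ng/g.

    Gross drug amount = homogenate concentration x homogenate volume
    (dilution x mass); the amount in residual blood
    (blood concentration x residual volume per g x mass) is subtracted and
    the net divided by the muscle mass.  A correction exceeding the gross
    amount clamps to 0 and flags the result.
    """
    params = params or TissueCorrectionParams()
    if muscle_mass_g <= 0:
        raise InvalidMassError("muscle mass must be positive")
    if homog_conc_ng_ml < 0 or blood_conc_ng_ml < 0:
        raise ValueError("concentrations must be non-negative")
    v_homog = params.homogenate_dilution * muscle_mass_g
    gross = homog_conc_ng_ml * v_homog
    residual = blood_conc_ng_ml * params.residual_blood_mL_per_g * muscle_mass_g
    net = (gross - residual) / muscle_mass_g
    if net < 0:
        return TissueConcentration(0.0, clamped=True)
    return TissueConcentration(float(net), clamped=False)


def auc_ratio(numerator: NCAResult, denominator: NCAResult) -> float:
    """Dimensionless AUC ratio between two matrices (e.g. blood/plasma)."""
    if denominator.auc_last == 0:
        raise UndefinedRatioError("denominator AUC is zero")
    return float(numerator.auc_last / denominator.auc_last)


def dose_response_summary(results: dict[float, NCAResult]) -> pd.DataFrame:
    """Cmax/AUC vs dose table with monotonicity flags.

    Rows sorted by dose; ``cmax_nonmonotone`` / ``auc_nonmonotone`` flag a
    strict decrease relative to the previous dose (ties are allowed, so
    identical curves at two doses raise no flag).
    """
    if len(results) < 2:
        raise ValueError("need results for at least 2 doses")
    doses = sorted(results)
    rows = []
    prev_cmax = prev_auc = -np.inf
    for dose in doses:
        r = results[dose]
        rows.append(
            {
                "dose_mg_per_kg": dose,
                "cmax": r.cmax,
                "tmax": r.tmax,
                "auc_last": r.auc_last,
                "cmax_nonmonotone": r.cmax < prev_cmax,
                "auc_nonmonotone": r.auc_last < prev_auc,
            }
        )
        prev_cmax, prev_auc = r.cmax, r.auc_last
    return pd.DataFrame(rows)


def mean_curve(series_list: list[ConcSeries]) -> ConcSeries:
    """Arithmetic mean curve across animals, per time point.

    All series must share the matrix and the sampling grid; NCA is run on
    mean curves rather than per animal by default.
    """
    if not series_list:
        raise ValueError("no series given")
    first = series_list[0]
    for s in series_list[1:]:
        if s.matrix != first.matrix or not np.array_equal(s.times, first.times):
            raise ValueError("series must share matrix and time grid")
    concs = np.mean([s.concs for s in series_list], axis=0)
    return ConcSeries(first.matrix, first.times.copy(), concs, first.dose_mg_per_kg)
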