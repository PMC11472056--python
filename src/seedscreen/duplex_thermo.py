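"""Two-state RNA duplex melting thermodynamics.

Model
-----
For a non-self-complementary duplex A·B formed from equimolar single strands
at total single-strand concentration ``Ct`` (mol/L), the two-state association
equilibrium ``A + B <-> AB`` has

    K(T) = x / ([A][B]) = x / (Ct/2 - x)^2,

where ``x`` is the duplex concentration and the duplex fraction is
``alpha = 2x/Ct``.  With the van't Hoff temperature dependence
``K(T) = exp(-(dH - T*dS)/(R*T))`` (association-signed dH < 0, dS < 0),
``alpha(Tm) = 1/2`` occurs exactly where ``K(Tm) = 4/Ct``, which rearranges to
the linear concentration dependence

    1/Tm = (R*ln(Ct/4) + dS) / dH,

so an ordinary least-squares regression of 1/Tm on log10(Ct/4) over a
concentration series recovers dH from the slope (slope = R*ln(10)/dH) and
dS from the intercept (intercept = dS/dH).

All enthalpies are kcal/mol, entropies cal/(mol*K), temperatures in K
internally and degrees C at the I/O boundary.  The gas constant is
R = 1.987204 cal/(mol*K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

#: Gas constant in cal/(mol*K).
GAS_CONSTANT_CAL = 1.987204

__all__ = [
    "GAS_CONSTANT_CAL",
    "MeltingCurve",
    "ThermoFit",
    "TmEstimate",
    "TmPrediction",
    "DuplexRecord",
    "PuckerResult",
    "NoTransitionError",
    "two_state_fraction",
    "predict_tm",
    "extract_tm",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "delta_tm",
    "c3_endo_percent",
]


class NoTransitionError(ValueError):
    """Raised when a melting curve shows no detectable sigmoid transition."""


@dataclass(frozen=True)
class MeltingCurve:
    """One UV-melting trace (A260 vs temperature) with its strand concentration.

    Parameters
    ----------
    temperature_C
        Strictly increasing temperature grid in degrees C, >= 10 points.
    absorbance_au
        A260 readings (arbitrary units), same length as the grid.
    total_strand_conc_M
        Total single-stranded concentration Ct (both strands summed), mol/L.
    label
        Free-text metadata (sequence, buffer, ...).
    """

    temperature_C: np.ndarray
    absorbance_au: np.ndarray
    total_strand_conc_M: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        a = np.asarray(self.absorbance_au, dtype=float)
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "absorbance_au", a)
        if t.ndim != 1 or t.size < 10:
            raise ValueError("melting curve needs >= 10 temperature points")
        if a.shape != t.shape:
            raise ValueError("temperature and absorbance lengths differ")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite values in melting curve")
        if not (math.isfinite(self.total_strand_conc_M) and self.total_strand_conc_M > 0):
            raise ValueError("total strand concentration must be positive")


@dataclass(frozen=True)
class ThermoFit:
    """Van't Hoff estimates from a concentration series of Tm values."""

    dH_kcal_per_mol: float
    dS_cal_per_mol_K: float
    dG37_kcal_per_mol: float
    n_points: int
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class TmEstimate:
    """Melting temperature extracted from a single curve."""

    tm_C: float
    method: Literal["derivative", "two_state_fit"]
    diagnostics: dict = field(default_factory=dict)


class TmPrediction(NamedTuple):
    """Analytic Tm from two-state parameters, in both temperature scales."""

    tm_K: float
    tm_C: float


@dataclass(frozen=True)
class DuplexRecord:
    """A measured duplex: strands (5'->3'), modification tags and Tm values."""

    top_seq: str
    bottom_seq: str
    tm_C: float
    delta_tm_C: float | None = None
    mod_positions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in (self.top_seq, self.bottom_seq):
            if set(s) - set("ACGU"):
                raise ValueError(f"non-RNA characters in duplex sequence {s!r}")
        for pos in self.mod_positions:
            if not 1 <= pos <= max(len(self.top_seq), len(self.bottom_seq)):
                raise ValueError(f"modification position {pos} outside strand")


@dataclass(frozen=True)
class PuckerResult:
    """Ribose pucker estimate from the H1'-H2' scalar coupling."""

    j_coupling_hz: float
    c3_endo_percent: float
    clamped: bool = False


def two_state_fraction(
    dH_kcal_per_mol: float,
    dS_cal_per_mol_K: float,
    total_strand_conc_M: float,
    temperature_K,
):
    """Duplex fraction alpha(T) of the two-state association equilibrium.

    Solves ``K(T) * (Ct/2 - x)**2 = x`` for the duplex concentration x and
    returns ``alpha = 2x/Ct``.  With ``b = K*Ct`` the physical root reduces to
    the numerically stable closed form ``alpha = b / (b + 1 + sqrt(2b + 1))``;
    very large b (deep below the transition) is handled in log space so the
    result never overflows.

    Parameters are association-signed: dH in kcal/mol (< 0 for a melting
    duplex), dS in cal/(mol*K), Ct in mol/L, temperature in K (scalar or
    array).  Returns a float or ndarray in [0, 1].
    """
    if not (math.isfinite(total_strand_conc_M) and total_strand_conc_M > 0):
        raise ValueError("Ct must be a positive, finite concentration")
    if not (math.isfinite(dH_kcal_per_mol) and math.isfinite(dS_cal_per_mol_K)):
        raise ValueError("non-finite thermodynamic parameters")
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")

    dH_cal = dH_kcal_per_mol * 1000.0
    log_K = -(dH_cal - T * dS_cal_per_mol_K) / (GAS_CONSTANT_CAL * T)
    log_b = log_K + np.log(total_strand_conc_M)

    alpha = np.empty_like(log_b)
    small = log_b <= 0
    b = np.exp(log_b[small])
    alpha[small] = b / (b + 1.0 + np.sqrt(2.0 * b + 1.0))
    inv_b = np.exp(-log_b[~small])
    alpha[~small] = 1.0 / (1.0 + inv_b + np.sqrt(2.0 * inv_b + inv_b * inv_b))
    if np.ndim(temperature_K) == 0:
        return float(alpha)
    return alpha


def predict_tm(
    dH_kcal_per_mol: float,
    dS_cal_per_mol_K: float,
    total_strand_conc_M: float,
) -> TmPrediction:
    """Analytic melting temperature Tm = dH / (dS + R*ln(Ct/4)).

    Tm is the temperature at which the two-state duplex fraction is exactly
    one half (K(Tm) = 4/Ct for a non-self-complementary duplex at equimolar
    strand concentrations).  Raises ``ValueError`` for parameter sets that do
    not produce a physical (positive-kelvin) melting temperature.
    """
    if not (math.isfinite(total_strand_conc_M) and total_strand_conc_M > 0):
        raise ValueError("Ct must be a positive, finite concentration")
    if dH_kcal_per_mol == 0:
        raise ValueError("dH must be nonzero")
    denom = dS_cal_per_mol_K + GAS_CONSTANT_CAL * math.log(total_strand_conc_M / 4.0)
    if denom == 0:
        raise ValueError("non-melting parameter set (zero denominator)")
    tm_K = dH_kcal_per_mol * 1000.0 / denom
    if tm_K <= 0:
        raise ValueError("non-melting parameter set (negative Tm)")
    return TmPrediction(tm_K=tm_K, tm_C=tm_K - 273.15)


def _derivative_tm(curve: MeltingCurve) -> TmEstimate:
    t, a = curve.temperature_C, curve.absorbance_au
    if np.ptp(a) == 0:
        raise NoTransitionError("no transition detected: absorbance is constant")
    # GCV-selected smoothing spline; derivative maximum = inflection point.
    spline = make_smoothing_spline(t, a, lam=None)
    fine = np.linspace(t[0], t[-1], 2001)
    deriv = spline.derivative()(fine)
    idx = int(np.argmax(deriv))
    span = t[-1] - t[0]
    if fine[idx] - t[0] < 0.01 * span or t[-1] - fine[idx] < 0.01 * span:
        raise NoTransitionError(
            "no transition detected: maximum slope at grid boundary"
        )
    if deriv[idx] <= 0:
        raise NoTransitionError("no transition detected: non-increasing trace")
    return TmEstimate(
        tm_C=float(fine[idx]),
        method="derivative",
        diagnostics={"max_dA_dT": float(deriv[idx])},
    )


def _two_state_fit_tm(curve: MeltingCurve) -> TmEstimate:
    t_C, a, ct = curve.temperature_C, curve.absorbance_au, curve.total_strand_conc_M
    t_K = t_C + 273.15
    # Baseline seeds from the outer 20% of the grid.
    k = max(3, len(t_C) // 5)
    m_ds, b_ds = np.polyfit(t_C[:k], a[:k], 1)
    m_ss, b_ss = np.polyfit(t_C[-k:], a[-k:], 1)
    try:
        tm0 = _derivative_tm(curve).tm_C + 273.15
    except NoTransitionError:
        tm0 = float(np.median(t_K))

    def model(theta: np.ndarray) -> np.ndarray:
        tm_K, dh, mds, bds, mss, bss = theta
        ds = dh * 1000.0 / tm_K - GAS_CONSTANT_CAL * math.log(ct / 4.0)
        alpha = two_state_fraction(dh, ds, ct, t_K)
        return alpha * (mds * t_C + bds) + (1 - alpha) * (mss * t_C + bss) - a

    theta0 = np.array([tm0, -80.0, m_ds, b_ds, m_ss, b_ss])
    lo = [t_K[0], -500.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t_K[-1], -1.0, np.inf, np.inf, np.inf, np.inf]
    res = least_squares(model, theta0, bounds=(lo, hi))
    tm_C = float(res.x[0] - 273.15)
    if tm_C - t_C[0] < 0.01 * (t_C[-1] - t_C[0]) or t_C[-1] - tm_C < 0.01 * (
        t_C[-1] - t_C[0]
    ):
        raise NoTransitionError("no transition detected: fitted Tm at grid boundary")
    return TmEstimate(
        tm_C=tm_C,
        method="two_state_fit",
        diagnostics={
            "dH_kcal_per_mol": float(res.x[1]),
            "residual_rms": float(np.sqrt(np.mean(res.fun**2))),
            "converged": bool(res.success),
        },
    )


def extract_tm(
    curve: MeltingCurve,
    method: Literal["derivative", "two_state_fit"] = "derivative",
) -> TmEstimate:
    """Extract Tm from a melting curve.

    ``derivative`` smooths the trace with a cubic smoothing spline (smoothing
    parameter chosen by generalized cross-validation) and returns the
    temperature of the maximum first derivative — the inflection point of the
    sigmoid.  ``two_state_fit`` performs nonlinear least squares of the
    dual-baseline two-state model ``A(T) = alpha(T)*ds(T) + (1-alpha(T))*ss(T)``
    with linear baselines and returns the fitted Tm.

    Raises :class:`NoTransitionError` for flat or boundary-transition curves.
    """
    if method == "derivative":
        return _derivative_tm(curve)
    if method == "two_state_fit":
        return _two_state_fit_tm(curve)
    raise ValueError(f"unknown Tm extraction method {method!r}")


def vant_hoff_fit(pairs: Sequence[tuple[float, float]]) -> ThermoFit:
    """Fit dH and dS from the concentration dependence of Tm.

    Parameters
    ----------
    pairs
        ``(Ct, Tm)`` tuples with Ct in mol/L (total single-strand
        concentration) and Tm in K.  At least two pairs with at least two
        distinct concentrations are required.

    Returns
    -------
    ThermoFit
        OLS regression of 1/Tm on log10(Ct/4): dH = R*ln(10)/slope (reported
        in kcal/mol), dS = intercept*dH (cal/(mol*K)), plus dG at 310.15 K
        and the r-squared of the line.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need >= 2 (Ct, Tm) pairs")
    ct = np.array([p[0] for p in pairs], dtype=float)
    tm = np.array([p[1] for p in pairs], dtype=float)
    if np.any(ct <= 0) or np.any(tm <= 0):
        raise ValueError("concentrations and temperatures must be positive")
    if np.unique(ct).size < 2:
        raise ValueError("singular design: all concentrations identical")
    x = np.log10(ct / 4.0)
    y = 1.0 / tm
    reg = stats.linregress(x, y)
    dH_cal = GAS_CONSTANT_CAL * math.log(10.0) / reg.slope
    dS = reg.intercept * dH_cal
    dH_kcal = dH_cal / 1000.0
    return ThermoFit(
        dH_kcal_per_mol=dH_kcal,
        dS_cal_per_mol_K=dS,
        dG37_kcal_per_mol=gibbs_free_energy(dH_kcal, dS, 310.15),
        n_points=len(pairs),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
    )


def gibbs_free_energy(
    dH_kcal_per_mol: float, dS_cal_per_mol_K: float, temperature_K: float
) -> float:
    """Standard Gibbs free energy dG = dH - T*dS, in kcal/mol.

    dH in kcal/mol, dS in cal/(mol*K), T in K.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return dH_kcal_per_mol - temperature_K * dS_cal_per_mol_K / 1000.0


def delta_tm(tm_test_C: float, tm_reference_C: float) -> float:
    """Tm difference (test minus reference) in degrees C, rounded to 1 d.p."""
    if not (math.isfinite(tm_test_C) and math.isfinite(tm_reference_C)):
        raise ValueError("non-finite Tm inputs")
    return round(tm_test_C - tm_reference_C, 1)


def c3_endo_percent(j_coupling_hz: float) -> PuckerResult:
    """C3'-endo population (%) from the H1'-H2' coupling constant.

    Uses the empirical affine relation ``C3'-endo(%) = 100 - 10*J``, clamped
    to [0, 100]; a large coupling (DNA-like C2'-endo sugar) gives a small
    C3'-endo percentage.  The result records whether clamping occurred.
    """
    if not math.isfinite(j_coupling_hz) or j_coupling_hz < 0:
        raise ValueError("J coupling must be a finite, nonnegative frequency")
    raw = 100.0 - 10.0 * j_coupling_hz
    clamped = raw < 0.0 or raw > 100.0
    return PuckerResult(
        j_coupling_hz=j_coupling_hz,
        c3_endo_percent=min(100.0, max(0.0, raw)),
        clamped=clamped,
    )
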