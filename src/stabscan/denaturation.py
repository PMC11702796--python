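"""Two-state denaturation analysis of fluorescence spectra.

A folded protein carrying tryptophans emits around 330 nm; unfolding red-shifts
the emission maximum and lowers its intensity.  Recording emission spectra over
a temperature ramp (thermal denaturation) or a denaturant titration (chemical
denaturation with GuHCl) yields a sigmoidal signal curve that a two-state
model describes with four parameters:

thermal::

    y(T) = Yn + Yd * e^u / (1 + e^u),   u = (dH_app / R) * (1/Tm - 1/T)

chemical::

    y(x) = Yn + Yd * e^v / (1 + e^v),   v = -(dG_app - m*x) / (R*T)

``Yn`` is the pre-transition signal level and ``Yd`` the transition amplitude,
so the post-transition level is ``Yn + Yd`` (the algebra of the model, even
though both are often loosely called "pre and post transition signal").
``Tm`` is the apparent melting temperature, ``dH_app`` the apparent van't Hoff
enthalpy, ``dG_app`` the unfolding free energy at zero denaturant, ``m`` the
denaturation slope, and ``D1/2 = dG_app / m`` the midpoint concentration.
Thermal unfolding of this system is irreversible, so every thermal parameter
is "apparent": no reversible-thermodynamics claim is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, NamedTuple, Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .constants import R_GAS
from .errors import ConvergenceError, DegenerateTransitionError, ValidationError

ConditionKind = Literal["temperature", "denaturant"]
Channel = Literal["lambda_max", "peak_intensity", "integrated_intensity"]
CHANNELS = ("lambda_max", "peak_intensity", "integrated_intensity")

ROOM_TEMPERATURE_K = 298.15


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class EmissionSpectrum:
    """A single fluorescence emission spectrum at one condition."""

    wavelengths: np.ndarray          # nm, strictly increasing
    intensities: np.ndarray          # arbitrary units
    condition: float                 # K (thermal) or M (chemical)
    direction: str = "unfolding"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValidationError("wavelength and intensity arrays differ in length")
        if self.wavelengths.size < 3:
            raise ValidationError("spectrum needs at least 3 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("non-monotonic wavelength grid")


@dataclass
class DenaturationSeries:
    """Spectra recorded across an ordered condition grid (one ramp/titration).

    ``intensities`` has shape (n_conditions, n_wavelengths); rows follow
    ``conditions``, which is kept sorted ascending.
    """

    condition_kind: ConditionKind
    conditions: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray
    direction: str = "unfolding"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.condition_kind not in ("temperature", "denaturant"):
            raise ValidationError(f"unknown condition kind: {self.condition_kind!r}")
        if self.conditions.size == 0:
            raise ValidationError("series with zero spectra")
        if self.intensities.shape != (self.conditions.size, self.wavelengths.size):
            raise ValidationError("ragged intensity matrix")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("non-monotonic wavelength grid")
        if np.any(~np.isfinite(self.intensities)):
            raise ValidationError("missing or non-finite intensity cells")
        order = np.argsort(self.conditions)
        self.conditions = self.conditions[order]
        self.intensities = self.intensities[order]

    def __len__(self) -> int:
        return self.conditions.size

    def spectra(self) -> Iterator[EmissionSpectrum]:
        for i, c in enumerate(self.conditions):
            yield EmissionSpectrum(self.wavelengths, self.intensities[i], c,
                                   self.direction)


@dataclass
class SignalCurve:
    """One scalar observable per condition, the input to the two-state fits."""

    x: np.ndarray                    # condition values, strictly increasing
    y: np.ndarray
    channel: Channel
    condition_kind: ConditionKind = "temperature"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValidationError("x and y differ in length")
        if not np.all(np.diff(self.x) > 0):
            raise ValidationError("condition values must be strictly increasing")


class LambdaMax(NamedTuple):
    wavelength_nm: float
    at_boundary: bool


@dataclass
class ThermalFit:
    """Eq-style two-state thermal fit result (all parameters apparent)."""

    dh_app: float                    # kcal/mol
    tm: float                        # K
    yn: float
    yd: float                        # transition amplitude; post level = yn + yd
    se: dict                         # parameter -> standard error
    rss: float
    converged: bool
    n_points: int

    @property
    def midpoint_signal(self) -> float:
        return self.yn + self.yd / 2.0


@dataclass
class ChemicalFit:
    """Two-state chemical (linear-extrapolation) fit at fixed temperature."""

    dg_app: float                    # kcal/mol
    m_value: float                   # kcal/(mol·M)
    yn: float
    yd: float
    temperature: float               # K
    se: dict
    rss: float
    converged: bool
    n_points: int

    @property
    def d_half(self) -> float:
        """Midpoint denaturant concentration D1/2 = dG_app / m, in M."""
        return self.dg_app / self.m_value

    @property
    def midpoint_signal(self) -> float:
        return self.yn + self.yd / 2.0


@dataclass
class StabilityDeltas:
    """Per-variant stability shifts relative to wild type.

    delta_tm = Tm(WT) - Tm(variant): positive for destabilising mutations.
    delta_d_half = D1/2(unfolding) - D1/2(refolding): hysteresis of one variant.
    delta_delta_d_half = delta_d_half(WT) - delta_d_half(variant).
    """

    label: str
    delta_tm: Optional[float] = None
    delta_d_half: Optional[float] = None
    delta_delta_d_half: Optional[float] = None


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points with equal or unequal x."""
    # Lagrange fit; x are three distinct abscissae
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
         + x[0] ** 2 * (y[1] - y[2])) / denom
    if a == 0.0:  # collinear: no curvature, keep the sample
        return float(x[1]), float(y[1])
    xv = -b / (2.0 * a)
    c = y[1] - a * x[1] ** 2 - b * x[1]
    return float(xv), float(a * xv ** 2 + b * xv + c)


def extract_lambda_max(spectrum: EmissionSpectrum) -> LambdaMax:
    """Wavelength of maximal emission, refined to sub-grid resolution.

    Fits a parabola through the maximal sample and its two neighbours.  When
    the maximum sits on the first or last grid point the boundary wavelength
    is returned with ``at_boundary=True``.
    """
    y = spectrum.intensities
    if np.all(y == y[0]):
        raise ValidationError("all-equal intensities: no unique maximum")
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return LambdaMax(float(spectrum.wavelengths[i]), True)
    xv, _ = _parabolic_vertex(spectrum.wavelengths[i - 1:i + 2], y[i - 1:i + 2])
    return LambdaMax(xv, False)


def _peak_intensity(spectrum: EmissionSpectrum) -> float:
    y = spectrum.intensities
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(y[i])
    _, yv = _parabolic_vertex(spectrum.wavelengths[i - 1:i + 2], y[i - 1:i + 2])
    return yv


def _integrated_intensity(spectrum: EmissionSpectrum) -> float:
    return float(np.trapezoid(spectrum.intensities, spectrum.wavelengths))


def build_signal_curve(series: DenaturationSeries, channel: Channel) -> SignalCurve:
    """Reduce each spectrum of a series to one observable.

    ``lambda_max`` tracks the red shift of the emission maximum,
    ``peak_intensity`` the (parabola-refined) maximal intensity, and
    ``integrated_intensity`` the area under the spectrum — the only channel
    that is exactly affine in the unfolded fraction of a two-basis mixture.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"unknown observable channel: {channel!r}")
    if len(series) < 6:
        raise ValidationError(
            f"need at least 6 conditions for a 4-parameter fit, got {len(series)}")
    extract = {
        "lambda_max": lambda s: extract_lambda_max(s).wavelength_nm,
        "peak_intensity": _peak_intensity,
        "integrated_intensity": _integrated_intensity,
    }[channel]
    y = np.array([extract(s) for s in series.spectra()])
    return SignalCurve(series.conditions.copy(), y, channel, series.condition_kind)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def eval_thermal_model(dh_app: float, tm: float, yn: float, yd: float,
                       x) -> np.ndarray | float:
    """Two-state thermal signal Yn + Yd·e^u/(1+e^u), u = (dH/R)(1/Tm − 1/x)."""
    x = np.asarray(x, dtype=float)
    u = (dh_app / R_GAS) * (1.0 / tm - 1.0 / x)
    out = yn + yd * expit(u)
    return out if out.ndim else float(out)


def eval_chemical_model(dg_app: float, m_value: float, yn: float, yd: float,
                        temperature: float, x) -> np.ndarray | float:
    """Two-state chemical signal Yn + Yd·e^v/(1+e^v), v = −(dG − m·x)/(R·T)."""
    x = np.asarray(x, dtype=float)
    v = -(dg_app - m_value * x) / (R_GAS * temperature)
    out = yn + yd * expit(v)
    return out if out.ndim else float(out)


def fraction_unfolded(curve: SignalCurve, yn: float, yd: float) -> np.ndarray:
    """Normalise a signal curve to unfolded fraction, clipped to [-0.1, 1.1]."""
    return np.clip((curve.y - yn) / yd, -0.1, 1.1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_N_RESTARTS = 5
_JITTER = 0.30


def _check_transition(y: np.ndarray) -> None:
    steps = np.abs(np.diff(y))
    med = float(np.median(steps))
    span = float(np.ptp(y))
    if span == 0.0 or (med > 0 and span <= 5.0 * med):
        raise DegenerateTransitionError(
            "degenerate transition: signal range does not exceed 5x the "
            "median successive difference")


def _midpoint_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """x at which y first crosses its midpoint level, by linear interpolation."""
    mid = (np.mean(y[:3]) + np.mean(y[-3:])) / 2.0
    d = y - mid
    sign = np.sign(d)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        # midpoint on a sample or no strict crossing; fall back to closest point
        return float(x[int(np.argmin(np.abs(d)))])
    i = int(idx[0])
    t = d[i] / (d[i] - d[i + 1])
    return float(x[i] + t * (x[i + 1] - x[i]))


def _fit_two_state(x: np.ndarray, y: np.ndarray, kind: str,
                   temperature: float) -> tuple[np.ndarray, dict, float, bool]:
    if x.size < 6:
        raise ValidationError("need at least 6 points for the two-state fit")
    _check_transition(y)

    yn0 = float(np.mean(y[:3]))
    yd0 = float(np.mean(y[-3:]) - yn0)
    xm0 = _midpoint_crossing(x, y)

    if kind == "thermal":
        # p = (dH_app, Tm, Yn, Yd)
        p0 = np.array([50.0, xm0, yn0, yd0])
        lo = np.array([1e-6, x.min() - 20.0, -np.inf, -np.inf])
        hi = np.array([np.inf, x.max() + 20.0, np.inf, np.inf])

        def resid(p):
            return eval_thermal_model(*p, x) - y
    else:
        # p = (dG_app, m, Yn, Yd); D1/2 = dG/m initialised at the crossing
        m0 = 2.0
        p0 = np.array([m0 * max(xm0, 1e-3), m0, yn0, yd0])
        lo = np.array([1e-9, 1e-9, -np.inf, -np.inf])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])

        def resid(p):
            return eval_chemical_model(p[0], p[1], p[2], p[3], temperature, x) - y

    rng = np.random.default_rng(0)
    best = None
    starts = [p0]
    for _ in range(_N_RESTARTS):
        jit = p0 * (1.0 + _JITTER * rng.uniform(-1.0, 1.0, size=4))
        starts.append(np.clip(jit, lo + 1e-12, None))
    for start in starts:
        start = np.minimum(np.maximum(start, lo + 1e-12),
                           np.where(np.isfinite(hi), hi - 1e-12, start))
        try:
            sol = least_squares(resid, start, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1] - 1e-15:
            best = (sol, rss)
    if best is None:
        raise ConvergenceError("every fit start failed")
    sol, rss = best
    converged = bool(sol.success)

    # standard errors from the Jacobian at the optimum
    dof = max(x.size - 4, 1)
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * (rss / dof)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except Exception:
        ses = np.full(4, np.nan)
        converged = False
    return sol.x, ses, rss, converged


def fit_thermal(curve: SignalCurve) -> ThermalFit:
    """Nonlinear least-squares fit of the two-state thermal model.

    Initialisation: Yn from the first 3 points, Yn+Yd from the last 3, Tm at
    the interpolated midpoint crossing, dH_app at 50 kcal/mol, followed by 5
    multi-start restarts with ±30% jitter.  Standard errors come from the
    Jacobian; ``converged`` reflects the optimizer's own verdict.
    """
    p, ses, rss, conv = _fit_two_state(curve.x, curve.y, "thermal", np.nan)
    se = dict(zip(("dh_app", "tm", "yn", "yd"), map(float, ses)))
    return ThermalFit(float(p[0]), float(p[1]), float(p[2]), float(p[3]),
                      se, rss, conv, curve.x.size)


def fit_chemical(curve: SignalCurve,
                 temperature: float = ROOM_TEMPERATURE_K) -> ChemicalFit:
    """Two-state chemical-denaturation fit at fixed temperature (default
    298.15 K, room temperature).  See :func:`fit_thermal` for the strategy."""
    p, ses, rss, conv = _fit_two_state(curve.x, curve.y, "chemical", temperature)
    se = dict(zip(("dg_app", "m_value", "yn", "yd"), map(float, ses)))
    return ChemicalFit(float(p[0]), float(p[1]), float(p[2]), float(p[3]),
                       temperature, se, rss, conv, curve.x.size)


# ---------------------------------------------------------------------------
# deltas
# ---------------------------------------------------------------------------

def stability_deltas(
    thermal: Optional[Mapping[str, ThermalFit]] = None,
    chemical_unfolding: Optional[Mapping[str, ChemicalFit]] = None,
    chemical_refolding: Optional[Mapping[str, ChemicalFit]] = None,
    wt_label: str = "WT",
) -> dict[str, StabilityDeltas]:
    """Signed stability shifts per variant, referenced to the wild type.

    Any of the three fit collections may be omitted; the corresponding deltas
    stay ``None``.  Hysteresis (delta_d_half) needs both chemical directions.
    """
    labels: list[str] = []
    for coll in (thermal, chemical_unfolding):
        if coll:
            for k in coll:
                if k not in labels:
                    labels.append(k)
    if not labels:
        raise ValidationError("no fits supplied")
    if thermal is not None and wt_label not in thermal:
        raise ValidationError(f"missing wild-type label {wt_label!r} in thermal fits")
    have_hyst = chemical_unfolding is not None and chemical_refolding is not None
    if have_hyst and wt_label not in chemical_unfolding:
        raise ValidationError(f"missing wild-type label {wt_label!r} in chemical fits")

    out: dict[str, StabilityDeltas] = {}
    wt_dd = None
    if have_hyst and wt_label in chemical_refolding:
        wt_dd = (chemical_unfolding[wt_label].d_half
                 - chemical_refolding[wt_label].d_half)
    for lab in labels:
        d = StabilityDeltas(lab)
        if thermal and lab in thermal:
            d.delta_tm = thermal[wt_label].tm - thermal[lab].tm
        if have_hyst and lab in chemical_unfolding and lab in chemical_refolding:
            d.delta_d_half = (chemical_unfolding[lab].d_half
                              - chemical_refolding[lab].d_half)
            if wt_dd is not None:
                d.delta_delta_d_half = wt_dd - d.delta_d_half
        out[lab] = d
    return out
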