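"""Thermodynamic analysis of replica-exchange trajectories.

Multiple replicas sampled at a ladder of temperatures are combined with the
weighted histogram analysis method (WHAM): iterating

    Omega(E_b) = sum_k n_k(E_b) / sum_k N_k * exp(f_k - E_b/(R*T_k))
    exp(-f_k)  = sum_b Omega(E_b) * exp(-E_b/(R*T_k))

to self-consistency yields a relative density of states Omega(E) and
per-temperature dimensionless free energies f_k (f_1 pinned to 0).  From the
solution any canonical average can be reweighted to an arbitrary temperature:
the energy moments give the specific heat

    Cv(T) = (<E^2> - <E>^2) / (R * T^2)

whose peak defines the melting temperature, and per-frame weights give free
energy landscapes (potentials of mean force) over order parameters such as
the radius of gyration Rg and the helix fraction:

    PMF(r) = -kB * T * ln P(r)

All energies are molar (kcal/mol), so kB and R are the same constant.

No autocorrelation/statistical-inefficiency correction is applied: frames at
one temperature enter with uniform weight.  Log-sum-exp arithmetic is used
throughout, so absolute energies may be large.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import R_GAS
from .denaturation import SignalCurve, ThermalFit, fit_thermal
from .errors import ValidationError

FRAME_COLUMNS = ("step", "replica_id", "temperature_K", "energy_kcal_mol",
                 "rg_angstrom", "helix_fraction")
EXCHANGE_COLUMNS = ("step", "replica_a", "replica_b", "accepted")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReplicaExchangeDataset:
    """Frames from a temperature-replica-exchange run, grouped by temperature.

    ``frames`` carries one row per recorded frame with columns
    step, replica_id, temperature_K, energy_kcal_mol, rg_angstrom,
    helix_fraction; ``ladder`` is the sorted unique temperature ladder;
    ``exchange`` (optional) logs swap attempts with columns step, replica_a,
    replica_b, accepted and, when available, temp_a_K / temp_b_K.
    """

    frames: pd.DataFrame
    ladder: np.ndarray = field(default=None)  # type: ignore[assignment]
    exchange: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValidationError(f"missing frame columns: {missing}")
        theta = self.frames["helix_fraction"].to_numpy(float)
        if np.any((theta < 0) | (theta > 1)):
            raise ValidationError("helix_fraction outside [0, 1]")
        temps = np.unique(self.frames["temperature_K"].to_numpy(float))
        if self.ladder is None:
            self.ladder = temps
        else:
            self.ladder = np.asarray(self.ladder, dtype=float)
            if not np.all(np.isin(temps, self.ladder)):
                raise ValidationError("frame temperature not on the ladder")
        if self.exchange is not None:
            miss = [c for c in EXCHANGE_COLUMNS if c not in self.exchange.columns]
            if miss:
                raise ValidationError(f"missing exchange-log columns: {miss}")

    def group_by_temperature(self) -> dict[float, pd.DataFrame]:
        return {float(t): g for t, g in self.frames.groupby("temperature_K")}


@dataclass
class WhamSolution:
    """Self-consistent WHAM output over an energy histogram."""

    bin_centers: np.ndarray
    bin_width: float
    ln_omega: np.ndarray             # -inf on empty bins; relative scale
    f: np.ndarray                    # per-temperature dimensionless free energies
    ladder: np.ndarray
    n_k: np.ndarray                  # frames per temperature
    n_iter: int
    residual: float
    converged: bool

    def ln_weight_denominator(self, energies: np.ndarray) -> np.ndarray:
        """ln sum_k N_k exp(f_k - beta_k E) per frame (MBAR-style mixture)."""
        beta = 1.0 / (R_GAS * self.ladder)
        a = (np.log(self.n_k)[:, None] + self.f[:, None]
             - beta[:, None] * energies[None, :])
        return logsumexp(a, axis=0)

    def frame_ln_weights(self, energies: np.ndarray, temperature: float) -> np.ndarray:
        """Unnormalised log-weights reweighting frames to ``temperature``."""
        beta = 1.0 / (R_GAS * temperature)
        return -beta * energies - self.ln_weight_denominator(energies)


@dataclass
class ThermoCurves:
    """Canonical energy curves on a temperature grid, with the Cv melting peak."""

    t_grid: np.ndarray
    mean_energy: np.ndarray          # kcal/mol
    cv: np.ndarray                   # kcal/(mol·K)
    tm: float                        # K, parabola-refined argmax of Cv


@dataclass
class PmfSurface:
    """Free-energy landscape over 1 or 2 order parameters at one temperature."""

    coords: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    values: np.ndarray               # kcal/mol, min over finite bins = 0; inf = unreachable
    temperature: float


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_solve(data: ReplicaExchangeDataset, bins: int = 200,
               tol: float = 1e-7, max_iter: int = 10000) -> WhamSolution:
    """Solve the WHAM self-consistency equations by direct iteration.

    Convergence is declared when max |delta f_k| <= ``tol``; on hitting
    ``max_iter`` first, the partial solution is returned with
    ``converged=False``.
    """
    if len(data.frames) == 0:
        raise ValidationError("empty dataset")
    groups = data.group_by_temperature()
    temps = np.array(sorted(groups))
    e_all = data.frames["energy_kcal_mol"].to_numpy(float)
    if np.any(~np.isfinite(e_all)):
        raise ValidationError("non-finite energies")

    emin, emax = float(e_all.min()), float(e_all.max())
    if emax == emin:
        emax = emin + 1.0  # single level: one occupied bin
    edges = np.linspace(emin, emax, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = float(edges[1] - edges[0])

    n_kb = np.zeros((temps.size, bins))
    for k, t in enumerate(temps):
        n_kb[k], _ = np.histogram(groups[t]["energy_kcal_mol"].to_numpy(float),
                                  bins=edges)
    n_k = n_kb.sum(axis=1)
    n_b = n_kb.sum(axis=0)
    occ = n_b > 0

    # represent each occupied bin by the mean energy of its samples, not the
    # geometric centre: removes the quantisation bias on coarse histograms
    # (discrete-level systems) while changing nothing in the dense limit
    idx = np.clip(np.digitize(e_all, edges) - 1, 0, bins - 1)
    sums = np.bincount(idx, weights=e_all, minlength=bins)
    centers = centers.copy()
    centers[occ] = sums[occ] / n_b[occ]

    beta = 1.0 / (R_GAS * temps)
    ln_nk = np.log(n_k)
    ln_nb_occ = np.log(n_b[occ])
    e_occ = centers[occ]

    f = np.zeros(temps.size)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # ln Omega on occupied bins
        denom = logsumexp(ln_nk[:, None] + f[:, None]
                          - beta[:, None] * e_occ[None, :], axis=0)
        ln_omega_occ = ln_nb_occ - denom
        f_new = -logsumexp(ln_omega_occ[None, :]
                           - beta[:, None] * e_occ[None, :], axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual <= tol:
            break
    converged = residual <= tol

    ln_omega = np.full(bins, -np.inf)
    denom = logsumexp(ln_nk[:, None] + f[:, None]
                      - beta[:, None] * e_occ[None, :], axis=0)
    ln_omega[occ] = ln_nb_occ - denom
    ln_omega[occ] -= ln_omega[occ][0]  # anchor first occupied bin

    return WhamSolution(centers, width, ln_omega, f, temps, n_k,
                        it, residual, converged)


def reweighted_energy_moments(wham: WhamSolution, temperature: float
                              ) -> tuple[float, float]:
    """Canonical <E> and Var(E) at ``temperature`` from the binned solution."""
    occ = np.isfinite(wham.ln_omega)
    e = wham.bin_centers[occ]
    lnp = wham.ln_omega[occ] - e / (R_GAS * temperature)
    lnp -= logsumexp(lnp)
    p = np.exp(lnp)
    mean = float(p @ e)
    var = float(p @ (e - mean) ** 2)
    return mean, var


def _parabolic_argmax(x: np.ndarray, y: np.ndarray) -> float:
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(x[i])
    x3, y3 = x[i - 1:i + 2], y[i - 1:i + 2]
    d2 = y3[0] - 2 * y3[1] + y3[2]
    if d2 >= 0:
        return float(x[i])
    h = x3[1] - x3[0]
    return float(x3[1] + 0.5 * h * (y3[0] - y3[2]) / d2)


def compute_cv(wham: WhamSolution, t_grid: Optional[np.ndarray] = None,
               allow_unconverged: bool = False) -> ThermoCurves:
    """Reweighted <E>(T) and Cv(T) = Var(E)/(R*T^2); Tm = argmax Cv.

    The default grid spans the temperature ladder at 0.5 K steps; requesting
    temperatures more than 25 K outside the ladder raises, since reweighting
    that far extrapolates beyond the sampled energy histograms.
    """
    if not wham.converged and not allow_unconverged:
        raise ValidationError("WHAM did not converge; pass allow_unconverged=True "
                              "to analyse the partial solution")
    if t_grid is None:
        t_grid = np.arange(wham.ladder.min(), wham.ladder.max() + 0.25, 0.5)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.min() < wham.ladder.min() - 25.0 or t_grid.max() > wham.ladder.max() + 25.0:
        raise ValidationError("temperature grid extrapolates more than 25 K "
                              "beyond the ladder")
    mean = np.empty(t_grid.size)
    var = np.empty(t_grid.size)
    for i, t in enumerate(t_grid):
        mean[i], var[i] = reweighted_energy_moments(wham, t)
    cv = var / (R_GAS * t_grid ** 2)
    tm = _parabolic_argmax(t_grid, cv)
    return ThermoCurves(t_grid, mean, cv, tm)


def delta_tm(curves: Mapping[str, ThermoCurves], wt_label: str = "WT"
             ) -> dict[str, float]:
    """Melting-point shifts Tm(WT) - Tm(variant); positive = destabilising."""
    if wt_label not in curves:
        raise ValidationError(f"missing wild-type label {wt_label!r}")
    wt = curves[wt_label].tm
    return {lab: wt - c.tm for lab, c in curves.items()}


def cv_peak_enthalpy(curves: ThermoCurves) -> float:
    """Melting enthalpy as the Cv-peak area above its half-maximum baseline.

    The Cv peak is integrated (trapezoid) between the two temperatures at
    which Cv crosses half its maximum, after subtracting that half-maximum as
    a flat baseline.  Units: kcal/mol.
    """
    cv, t = curves.cv, curves.t_grid
    i = int(np.argmax(cv))
    half = cv[i] / 2.0

    def crossing(lo_idx, hi_idx, step):
        j = lo_idx
        while 0 <= j + step <= cv.size - 1 and j != hi_idx:
            if (cv[j] - half) * (cv[j + step] - half) <= 0:
                frac = (cv[j] - half) / (cv[j] - cv[j + step])
                return t[j] + frac * (t[j + step] - t[j])
            j += step
        return t[hi_idx]

    t1 = crossing(i, 0, -1)
    t2 = crossing(i, cv.size - 1, +1)
    sel = (t >= t1) & (t <= t2)
    tt = np.concatenate(([t1], t[sel], [t2]))
    vv = np.concatenate(([half], cv[sel], [half]))
    order = np.argsort(tt)
    return float(np.trapezoid(vv[order] - half, tt[order]))


# ---------------------------------------------------------------------------
# PMF and melting sigmoids
# ---------------------------------------------------------------------------

_COORD_COLUMNS = {"rg": "rg_angstrom", "helix_fraction": "helix_fraction"}


def compute_pmf(data: ReplicaExchangeDataset, wham: WhamSolution,
                coords: Sequence[str], temperature: float,
                bins: int | Sequence[int] = 50) -> PmfSurface:
    """Potential of mean force over 1 or 2 order parameters at one temperature.

    Frames are reweighted to ``temperature`` with WHAM frame weights, their
    joint histogram over the chosen coordinates is normalised to a probability
    density P, and PMF = -kB*T*ln P with the minimum shifted to zero.  Empty
    bins are unreachable and carry +inf.
    """
    coords = tuple(coords)
    if not 1 <= len(coords) <= 2:
        raise ValidationError("PMF supports 1 or 2 coordinates")
    cols = []
    for c in coords:
        key = c.lower()
        if key not in _COORD_COLUMNS:
            raise ValidationError(f"unknown PMF coordinate {c!r}")
        cols.append(_COORD_COLUMNS[key])
    e = data.frames["energy_kcal_mol"].to_numpy(float)
    lnw = wham.frame_ln_weights(e, temperature)
    w = np.exp(lnw - lnw.max())
    sample = np.column_stack([data.frames[c].to_numpy(float) for c in cols])
    if isinstance(bins, int):
        bins = [bins] * len(coords)
    hist, edges = np.histogramdd(sample, bins=bins, weights=w)
    if np.count_nonzero(hist) <= 1:
        raise ValidationError("degenerate landscape: all frames in one bin")
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        pmf = -R_GAS * temperature * np.log(p)
    pmf -= pmf[np.isfinite(pmf)].min()
    return PmfSurface(coords, tuple(np.asarray(e) for e in edges), pmf, temperature)


def reweighted_observable(data: ReplicaExchangeDataset, wham: WhamSolution,
                          column: str, temperature: float) -> float:
    """Canonical average of a frame column at an arbitrary temperature."""
    e = data.frames["energy_kcal_mol"].to_numpy(float)
    lnw = wham.frame_ln_weights(e, temperature)
    w = np.exp(lnw - logsumexp(lnw))
    return float(w @ data.frames[column].to_numpy(float))


def rg_melting_fit(data: ReplicaExchangeDataset, wham: WhamSolution,
                   t_grid: Optional[np.ndarray] = None) -> ThermalFit:
    """Sigmoid fit of the reweighted <Rg>(T) melting curve.

    <Rg> is evaluated on a temperature grid by WHAM reweighting and fitted
    with the same two-state sigmoid used for thermal denaturation (x = T,
    signal = Rg), so ``tm`` is the Rg-melting midpoint and ``yd`` the
    amplitude of the Rg change.
    """
    if t_grid is None:
        t_grid = np.linspace(wham.ladder.min(), wham.ladder.max(), 31)
    t_grid = np.asarray(t_grid, dtype=float)
    rg = np.array([reweighted_observable(data, wham, "rg_angstrom", t)
                   for t in t_grid])
    curve = SignalCurve(t_grid, rg, "peak_intensity", "temperature")
    return fit_thermal(curve)


# ---------------------------------------------------------------------------
# exchange diagnostics
# ---------------------------------------------------------------------------

def exchange_rate_summary(data: ReplicaExchangeDataset
                          ) -> tuple[dict[tuple[float, float], float], float, float]:
    """Acceptance rate per adjacent temperature pair, plus (min, max).

    Pairs are keyed by the (lower, upper) temperatures of the attempted swap
    when the log carries temp_a_K/temp_b_K columns, otherwise by the replica
    id pair.
    """
    log = data.exchange
    if log is None or len(log) == 0:
        raise ValidationError("empty exchange log")
    if {"temp_a_K", "temp_b_K"}.issubset(log.columns):
        lo = np.minimum(log["temp_a_K"], log["temp_b_K"])
        hi = np.maximum(log["temp_a_K"], log["temp_b_K"])
        keys = list(zip(lo.to_numpy(float), hi.to_numpy(float)))
    else:
        a = np.minimum(log["replica_a"], log["replica_b"])
        b = np.maximum(log["replica_a"], log["replica_b"])
        keys = list(zip(a.to_numpy(), b.to_numpy()))
    acc = log["accepted"].to_numpy()
    rates: dict[tuple, list] = {}
    for k, v in zip(keys, acc):
        rates.setdefault(k, []).append(bool(v))
    summary = {k: float(np.mean(v)) for k, v in sorted(rates.items())}
    vals = list(summary.values())
    return summary, min(vals), max(vals)
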