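"""Synthetic data generators with analytically known ground truth.

Two generators back the whole pipeline with oracles:

* **Fluorescence spectra.** Each condition's spectrum is a two-basis mixture
  ``(1-fu)*Gn + fu*Gu`` of a native Gaussian band (higher, bluer) and an
  unfolded band (lower, red-shifted), where the unfolded fraction ``fu``
  follows the two-state thermal or chemical model with chosen ground-truth
  parameters, plus i.i.d. Gaussian noise.  Unfolding therefore red-shifts the
  emission maximum and lowers its intensity, the two observables the
  denaturation analysis reads out.

* **Zimm–Bragg replica exchange.** A helix/coil chain of N residues with
  nucleation parameter sigma and van't Hoff propagation weight

      s(T) = exp((dH_prop / R) * (1/T - 1/T_ref)),   s(T_ref) = 1,

  so helix is favoured below T_ref and melts on heating.  The stationary
  weight of a configuration x at temperature T is

      pi(x; T) ∝ sigma^runs(x) * s(T)^n_h(x) = g(x) * exp(-E(x)/(R*T)),

  with frame energy E = -dH_prop * n_h (n_h = helical residue count) and a
  temperature-independent degeneracy g, which makes the standard
  energy-based replica-swap Metropolis criterion exact for this model.
  Replicas perform single-residue flip Metropolis moves at their current
  ladder temperature; every ``exchange_period`` frames adjacent ladder pairs
  (alternating even/odd pairing) attempt a swap accepted with probability
  min(1, exp[(1/(R*Ti) - 1/(R*Tj)) * (Ei - Ej)]).  The radius of gyration is
  an affine readout of the helix fraction plus noise.  The 2x2 transfer
  matrix of the model gives closed-form <E>(T), Cv(T) and helix fraction, so
  every downstream estimate (WHAM reweighting, Cv peak, melting sigmoids)
  can be checked against exact numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .constants import R_GAS
from .denaturation import DenaturationSeries, eval_chemical_model, eval_thermal_model
from .errors import ValidationError
from .rex import ReplicaExchangeDataset


# ---------------------------------------------------------------------------
# fluorescence spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectraSimConfig:
    """Ground truth for one synthetic denaturation series.

    Thermal mode uses (tm, dh_app); chemical mode uses (dg_app, m_value,
    temperature).  Spectral bands are Gaussians in wavelength; the unfolded
    band must be red-shifted (lambda_u > lambda_n) and weaker
    (amp_u < amp_n).
    """

    mode: str = "thermal"                    # "thermal" | "chemical"
    # thermal ground truth
    tm: float = 333.0                        # K
    dh_app: float = 50.0                     # kcal/mol
    # chemical ground truth
    dg_app: float = 4.0                      # kcal/mol
    m_value: float = 2.0                     # kcal/(mol·M)
    temperature: float = 298.15              # K, fixed for chemical mode
    # spectral shape
    lambda_n: float = 330.0                  # nm, native band centre
    width_n: float = 12.0                    # nm
    amp_n: float = 100.0                     # a.u.
    lambda_u: float = 350.0                  # nm, unfolded band centre
    width_u: float = 14.0                    # nm
    amp_u: float = 55.0                      # a.u.
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(290.0, 361.0, 1.0))
    conditions: np.ndarray = field(default_factory=lambda: np.arange(293.0, 364.0, 5.0))
    noise_sigma: float = 1.0                 # a.u.
    direction: str = "unfolding"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("thermal", "chemical"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.lambda_u > self.lambda_n:
            raise ValidationError("unfolded band must be red-shifted (lambda_u > lambda_n)")
        if not self.amp_u < self.amp_n:
            raise ValidationError("unfolded amplitude must be below native amplitude")
        if self.width_n <= 0 or self.width_u <= 0:
            raise ValidationError("band widths must be positive")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=float)


def unfolded_fraction(config: SpectraSimConfig, x) -> np.ndarray:
    """Two-state unfolded fraction at condition(s) x under the config's truth."""
    if config.mode == "thermal":
        return np.asarray(eval_thermal_model(config.dh_app, config.tm, 0.0, 1.0, x))
    return np.asarray(eval_chemical_model(config.dg_app, config.m_value, 0.0, 1.0,
                                          config.temperature, x))


def simulate_spectra_series(config: SpectraSimConfig) -> DenaturationSeries:
    """Generate a denaturation series of noisy two-basis emission spectra."""
    if config.conditions.size == 0:
        raise ValidationError("empty condition grid")
    lam = config.wavelengths
    gn = config.amp_n * np.exp(-0.5 * ((lam - config.lambda_n) / config.width_n) ** 2)
    gu = config.amp_u * np.exp(-0.5 * ((lam - config.lambda_u) / config.width_u) ** 2)
    fu = unfolded_fraction(config, config.conditions)
    clean = (1.0 - fu)[:, None] * gn[None, :] + fu[:, None] * gu[None, :]
    rng = np.random.default_rng(config.seed)
    noisy = clean + rng.normal(0.0, config.noise_sigma, size=clean.shape) \
        if config.noise_sigma > 0 else clean
    kind = "temperature" if config.mode == "thermal" else "denaturant"
    return DenaturationSeries(kind, config.conditions.copy(), lam.copy(), noisy,
                              config.direction)


# ---------------------------------------------------------------------------
# Zimm–Bragg helix-coil chain
# ---------------------------------------------------------------------------

@dataclass
class ZimmBraggConfig:
    """Helix-coil chain and replica-exchange protocol parameters.

    Defaults describe the reference synthetic system: a 30-residue chain with
    independent sites (sigma = 1, keeping the transfer-matrix oracle closed
    form), propagation enthalpy 15 kcal/mol, melting midpoint T_ref = 330 K
    (matching the wild-type apparent Tm scale of the fluorescence study), an
    8-temperature ladder over 300–360 K and 20 000 frames per replica.
    """

    n_residues: int = 30
    sigma: float = 1.0                       # nucleation parameter, (0, 1]
    dh_prop: float = 15.0                    # kcal/mol per helical residue
    t_ref: float = 330.0                     # K where s = 1
    rg_helix: float = 17.0                   # Å, fully helical readout
    rg_coil: float = 30.0                    # Å, fully coil readout
    rg_noise: float = 0.5                    # Å
    ladder: np.ndarray = field(default_factory=lambda: np.linspace(300.0, 360.0, 8))
    n_frames: int = 20000
    sweeps_per_frame: int = 1                # one sweep = N attempted flips
    exchange_period: int = 10                # frames between swap attempts; 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValidationError("chain needs at least 2 residues")
        if not 0.0 < self.sigma <= 1.0:
            raise ValidationError("sigma must lie in (0, 1]")
        if not self.rg_coil > self.rg_helix:
            raise ValidationError("rg_coil must exceed rg_helix")
        self.ladder = np.asarray(self.ladder, dtype=float)
        # non-decreasing: a degenerate equal-temperature pair is allowed as a
        # diagnostic (its swaps are always accepted), decreasing is not
        if self.ladder.size > 1 and not np.all(np.diff(self.ladder) >= 0):
            raise ValidationError("temperature ladder must be non-decreasing")


class ZimmBraggPoint(NamedTuple):
    mean_energy: float               # kcal/mol
    cv: float                        # kcal/(mol·K)
    helix_fraction: float


def _transfer_moments(n: int, sigma: float, s: float) -> tuple[float, float]:
    """<n_h> and Var(n_h) from the transfer matrix, by d/d(ln s) propagation.

    Row/column order (helix, coil); residue 1 carries weight (sigma*s, 1).
    Z, dZ/dt and d2Z/dt2 (t = ln s) are propagated together with per-step
    renormalisation, so arbitrary N and s are safe.
    """
    m = np.array([[s, 1.0], [sigma * s, 1.0]])
    m1 = np.array([[s, 0.0], [sigma * s, 0.0]])     # dM/dt; d2M/dt2 identical
    v = np.array([sigma * s, 1.0])
    v1 = np.array([sigma * s, 0.0])
    v2 = np.array([sigma * s, 0.0])
    for _ in range(n - 1):
        v, v1, v2 = (v @ m,
                     v1 @ m + v @ m1,
                     v2 @ m + 2.0 * (v1 @ m1) + v @ m1)
        scale = np.abs(v).max()
        v, v1, v2 = v / scale, v1 / scale, v2 / scale
    z = v.sum()
    a = v1.sum() / z                 # <n_h>
    b = v2.sum() / z                 # <n_h^2>
    return float(a), float(b - a * a)


def propagation_weight(config: ZimmBraggConfig, t: float) -> float:
    """s(T) = exp((dH_prop/R)(1/T - 1/T_ref)); > 1 below T_ref."""
    return float(np.exp((config.dh_prop / R_GAS) * (1.0 / t - 1.0 / config.t_ref)))


def zimm_bragg_analytic(config: ZimmBraggConfig, t: float) -> ZimmBraggPoint:
    """Exact <E>, Cv and helix fraction of the chain at temperature ``t``.

    Because the stationary weight factors as g(x)·exp(-E/(R*T)) with g
    temperature independent, the fluctuation formula
    Cv = Var(E)/(R*T^2) equals d<E>/dT exactly.
    """
    if t <= 0:
        raise ValidationError("temperature must be positive")
    s = propagation_weight(config, t)
    nh_mean, nh_var = _transfer_moments(config.n_residues, config.sigma, s)
    mean_e = -config.dh_prop * nh_mean
    var_e = config.dh_prop ** 2 * nh_var
    cv = var_e / (R_GAS * t * t)
    return ZimmBraggPoint(mean_e, cv, nh_mean / config.n_residues)


def zimm_bragg_tm(config: ZimmBraggConfig,
                  bracket: tuple[float, float] | None = None) -> float:
    """Temperature of the analytic Cv maximum (golden-section search)."""
    from scipy.optimize import minimize_scalar
    if bracket is None:
        bracket = (config.ladder.min(), config.ladder.max())
    res = minimize_scalar(lambda t: -zimm_bragg_analytic(config, t).cv,
                          bounds=bracket, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


# ---------------------------------------------------------------------------
# replica-exchange Metropolis sampler (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rex_kernel(n_res, ln_sigma, dh, ladder, lns_ladder, n_frames,
                sweeps_per_frame, exchange_period, seed,
                out_nh, out_temp_idx, out_rg_noise,
                ex_step, ex_rep_a, ex_rep_b, ex_lad_lo, ex_acc):
    np.random.seed(seed)
    n_rep = ladder.shape[0]
    states = np.zeros((n_rep, n_res), dtype=np.int8)
    n_h = np.zeros(n_rep, dtype=np.int64)
    for k in range(n_rep):
        for i in range(n_res):
            if np.random.random() < 0.5:
                states[k, i] = 1
                n_h[k] += 1
    ladder_of = np.arange(n_rep)             # replica -> ladder index
    replica_at = np.arange(n_rep)            # ladder index -> replica
    beta = 1.0 / (R_GAS_NB * ladder)
    parity = 0
    n_ex = 0
    for frame in range(n_frames):
        for _ in range(sweeps_per_frame):
            for _ in range(n_res):
                for k in range(n_rep):
                    i = np.random.randint(n_res)
                    cur = states[k, i]
                    left = states[k, i - 1] if i > 0 else np.int8(0)
                    right = states[k, i + 1] if i < n_res - 1 else np.int8(0)
                    joins = left + right
                    if cur == 0:
                        dn = 1
                        druns = 1 - joins
                    else:
                        dn = -1
                        druns = joins - 1
                    ln_ratio = dn * lns_ladder[ladder_of[k]] + druns * ln_sigma
                    if ln_ratio >= 0.0 or np.log(np.random.random()) < ln_ratio:
                        states[k, i] = 1 - cur
                        n_h[k] += dn
        for k in range(n_rep):
            out_nh[k, frame] = n_h[k]
            out_temp_idx[k, frame] = ladder_of[k]
            out_rg_noise[k, frame] = np.random.normal()
        if exchange_period > 0 and n_rep >= 2 and (frame + 1) % exchange_period == 0:
            start = parity
            parity = 1 - parity
            for lo in range(start, n_rep - 1, 2):
                ra = replica_at[lo]
                rb = replica_at[lo + 1]
                ea = -dh * n_h[ra]
                eb = -dh * n_h[rb]
                arg = (beta[lo] - beta[lo + 1]) * (ea - eb)
                acc = arg >= 0.0 or np.log(np.random.random()) < arg
                ex_step[n_ex] = frame
                ex_rep_a[n_ex] = ra
                ex_rep_b[n_ex] = rb
                ex_lad_lo[n_ex] = lo
                ex_acc[n_ex] = 1 if acc else 0
                n_ex += 1
                if acc:
                    ladder_of[ra] = lo + 1
                    ladder_of[rb] = lo
                    replica_at[lo] = rb
                    replica_at[lo + 1] = ra
    return n_ex


# numba closes over module globals at compile time; keep R as a plain float
R_GAS_NB = R_GAS


def simulate_rex_zimm_bragg(config: ZimmBraggConfig) -> ReplicaExchangeDataset:
    """Run the replica-exchange Metropolis sampler; deterministic given seed."""
    ladder = config.ladder
    n_rep = ladder.size
    if config.exchange_period > 0 and n_rep < 2:
        raise ValidationError("exchanges need at least 2 replicas")
    lns = np.array([np.log(propagation_weight(config, t)) for t in ladder])
    nf = config.n_frames
    out_nh = np.zeros((n_rep, nf), dtype=np.int64)
    out_ti = np.zeros((n_rep, nf), dtype=np.int64)
    out_rgn = np.zeros((n_rep, nf))
    max_ex = (nf // config.exchange_period + 1) * max(n_rep // 2 + 1, 1) \
        if config.exchange_period > 0 else 1
    ex_step = np.zeros(max_ex, dtype=np.int64)
    ex_a = np.zeros(max_ex, dtype=np.int64)
    ex_b = np.zeros(max_ex, dtype=np.int64)
    ex_lo = np.zeros(max_ex, dtype=np.int64)
    ex_acc = np.zeros(max_ex, dtype=np.int64)

    n_ex = _rex_kernel(config.n_residues, float(np.log(config.sigma)),
                       float(config.dh_prop), ladder.astype(float), lns,
                       nf, config.sweeps_per_frame, config.exchange_period,
                       config.seed % (2 ** 31),
                       out_nh, out_ti, out_rgn,
                       ex_step, ex_a, ex_b, ex_lo, ex_acc)

    n = config.n_residues
    theta = out_nh / n
    rg = config.rg_coil - (config.rg_coil - config.rg_helix) * theta \
        + config.rg_noise * out_rgn
    frames = pd.DataFrame({
        "step": np.tile(np.arange(nf), n_rep),
        "replica_id": np.repeat(np.arange(n_rep), nf),
        "temperature_K": ladder[out_ti.reshape(-1)],
        "energy_kcal_mol": (-config.dh_prop * out_nh).reshape(-1).astype(float),
        "rg_angstrom": rg.reshape(-1),
        "helix_fraction": theta.reshape(-1),
    }).sort_values(["step", "replica_id"], ignore_index=True)

    exchange = None
    if config.exchange_period > 0:
        exchange = pd.DataFrame({
            "step": ex_step[:n_ex],
            "replica_a": ex_a[:n_ex],
            "replica_b": ex_b[:n_ex],
            "temp_a_K": ladder[ex_lo[:n_ex]],
            "temp_b_K": ladder[ex_lo[:n_ex] + 1],
            "accepted": ex_acc[:n_ex].astype(bool),
        })
    return ReplicaExchangeDataset(frames, ladder.copy(), exchange)
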