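"""WHAM self-consistency, Cv/Tm, PMF, melting sigmoids, exchange rates."""

import numpy as np
import pandas as pd
import pytest

from stabscan.constants import R_GAS
from stabscan.errors import ValidationError
from stabscan.rex import (ReplicaExchangeDataset, compute_cv, compute_pmf,
                          cv_peak_enthalpy, delta_tm, exchange_rate_summary,
                          reweighted_energy_moments, reweighted_observable,
                          rg_melting_fit, wham_solve)
from stabscan.synthetic import (ZimmBraggConfig, simulate_rex_zimm_bragg,
                                zimm_bragg_analytic, zimm_bragg_tm)


def _frames(step, temp, energy, rg=None, theta=None):
    n = len(energy)
    return pd.DataFrame({
        "step": step, "replica_id": np.zeros(n, int),
        "temperature_K": temp, "energy_kcal_mol": energy,
        "rg_angstrom": rg if rg is not None else np.full(n, 20.0),
        "helix_fraction": theta if theta is not None else np.full(n, 0.5),
    })


def _two_level_dataset(delta_e, temps, n_per_temp, seed):
    """Exact Boltzmann sampling of levels {0, -delta_e}, equal degeneracy."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in temps:
        p_low = 1.0 / (1.0 + np.exp(-delta_e / (R_GAS * t)))
        e = np.where(rng.uniform(size=n_per_temp) < p_low, -delta_e, 0.0)
        rows.append(_frames(np.arange(n_per_temp), np.full(n_per_temp, t), e))
    return ReplicaExchangeDataset(pd.concat(rows, ignore_index=True))


class TestWham:
    def test_single_temperature_reduces_to_raw_histogram(self):
        """One simulation: reweighted P(E) at T1 equals the raw histogram."""
        rng = np.random.default_rng(0)
        e = rng.normal(-50.0, 5.0, size=4000)
        ds = ReplicaExchangeDataset(_frames(np.arange(e.size),
                                            np.full(e.size, 320.0), e))
        sol = wham_solve(ds, bins=40)
        assert sol.converged
        occ = np.isfinite(sol.ln_omega)
        lnp = sol.ln_omega[occ] - sol.bin_centers[occ] / (R_GAS * 320.0)
        p = np.exp(lnp - lnp.max())
        p /= p.sum()
        hist, _ = np.histogram(e, bins=40, range=(e.min(), e.max()))
        raw = hist[hist > 0] / e.size
        np.testing.assert_allclose(p, raw, rtol=1e-10)

    def test_two_level_density_of_states_equal(self):
        """Non-degenerate two-level system: ln Omega gap ~ 0 within 3 SE."""
        gaps = []
        for seed in range(8):
            ds = _two_level_dataset(1.5, [290.0, 310.0, 330.0, 350.0],
                                    4000, seed)
            sol = wham_solve(ds, bins=2)
            occ = np.isfinite(sol.ln_omega)
            lnw = sol.ln_omega[occ]
            gaps.append(lnw[1] - lnw[0])
        gaps = np.asarray(gaps)
        se = gaps.std(ddof=1) / np.sqrt(gaps.size)
        assert abs(gaps.mean()) < 3 * se + 1e-3

    def test_translation_invariance(self):
        """Shifting all energies by c shifts f_k by c*(beta_k - beta_1) and
        leaves reweighted averages shifted by exactly c."""
        rng = np.random.default_rng(4)
        rows = []
        for t in (300.0, 330.0):
            e = rng.normal(-40 + t / 10, 4.0, size=2000)
            rows.append(_frames(np.arange(e.size), np.full(e.size, t), e))
        frames = pd.concat(rows, ignore_index=True)
        c = 123.456
        shifted = frames.copy()
        shifted["energy_kcal_mol"] += c
        sol_a = wham_solve(ReplicaExchangeDataset(frames), bins=60)
        sol_b = wham_solve(ReplicaExchangeDataset(shifted), bins=60)
        beta = 1.0 / (R_GAS * sol_a.ladder)
        np.testing.assert_allclose(sol_b.f - sol_a.f, c * (beta - beta[0]),
                                   atol=1e-8)
        for t in (305.0, 325.0):
            ma, _ = reweighted_energy_moments(sol_a, t)
            mb, _ = reweighted_energy_moments(sol_b, t)
            assert mb - ma == pytest.approx(c, abs=1e-8)

    def test_reweighting_reproduces_raw_ladder_means(self, zb_dataset, zb_wham):
        """WHAM at any ladder temperature matches that run's raw <E>."""
        groups = zb_dataset.group_by_temperature()
        for t, g in groups.items():
            e = g["energy_kcal_mol"].to_numpy()
            blocks = e[:e.size // 20 * 20].reshape(20, -1).mean(axis=1)
            se = blocks.std(ddof=1) / np.sqrt(blocks.size)
            m, _ = reweighted_energy_moments(zb_wham, t)
            assert abs(m - e.mean()) < 3 * se + 0.5 * zb_wham.bin_width

    def test_empty_dataset_rejected(self):
        ds = ReplicaExchangeDataset(_frames([], [], []))
        with pytest.raises(ValidationError):
            wham_solve(ds)


class TestThermoCurves:
    def test_degenerate_equal_energies_give_zero_cv(self):
        ds = ReplicaExchangeDataset(_frames(np.arange(100),
                                            np.full(100, 320.0),
                                            np.full(100, -7.0)))
        sol = wham_solve(ds, bins=10)
        tc = compute_cv(sol, np.array([320.0]), allow_unconverged=True)
        assert tc.cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_cv_peak_location(self):
        """Closed-form two-level Cv peaks where u*tanh(u/2) = 2.

        The root is found numerically (independent oracle); for
        delta_e = 1.5 kcal/mol it sits near 314.7 K.
        """
        from scipy.optimize import brentq
        delta_e = 1.5
        u_star = brentq(lambda u: u * np.tanh(u / 2) - 2, 1e-6, 50)
        t_star = delta_e / (R_GAS * u_star)
        assert t_star == pytest.approx(314.7, abs=0.2)

        ds = _two_level_dataset(delta_e, [260.0, 300.0, 340.0, 380.0],
                                30000, seed=1)
        sol = wham_solve(ds, bins=2)
        tc = compute_cv(sol, np.arange(260.0, 380.5, 0.5))
        assert tc.tm == pytest.approx(t_star, abs=3.0)

    def test_zimm_bragg_tm_matches_transfer_matrix(self, zb_config, zb_wham):
        tc = compute_cv(zb_wham)
        assert tc.tm == pytest.approx(zimm_bragg_tm(zb_config), abs=2.0)

    def test_cv_consistent_with_energy_derivative(self, zb_wham):
        """Fluctuation Cv tracks d<E>/dT within 1% where Cv is substantial."""
        tc = compute_cv(zb_wham)
        de_dt = np.gradient(tc.mean_energy, tc.t_grid)
        strong = tc.cv > 0.1 * tc.cv.max()
        strong[[0, -1]] = False  # np.gradient is only first-order at the edges
        np.testing.assert_allclose(de_dt[strong], tc.cv[strong], rtol=0.01)

    def test_extrapolation_guard(self, zb_wham):
        with pytest.raises(ValidationError):
            compute_cv(zb_wham, np.array([200.0]))

    def test_delta_tm_signs_and_oracle_shift(self):
        """Configs whose analytic melting points differ by 10 K yield
        delta Tm = 10 +- 2 K from independent REX runs; a more stable
        variant gets a negative shift."""
        curves = {}
        for label, t_ref, seed in (("WT", 330.0, 5), ("MUT", 320.0, 6)):
            cfg = ZimmBraggConfig(t_ref=t_ref, n_frames=6000, seed=seed,
                                  ladder=np.linspace(295.0, 355.0, 8))
            sol = wham_solve(simulate_rex_zimm_bragg(cfg))
            curves[label] = compute_cv(sol, allow_unconverged=True)
        shifts = delta_tm(curves)
        assert shifts["WT"] == 0.0
        assert shifts["MUT"] == pytest.approx(10.0, abs=2.0)
        curves["STAB"] = compute_cv(
            wham_solve(simulate_rex_zimm_bragg(
                ZimmBraggConfig(t_ref=340.0, n_frames=6000, seed=7,
                                ladder=np.linspace(295.0, 355.0, 8)))),
            allow_unconverged=True)
        assert delta_tm(curves)["STAB"] < 0

    def test_cv_peak_enthalpy_positive_and_bounded(self, zb_config, zb_wham):
        """The Cv-peak area is positive and below the full melting enthalpy."""
        tc = compute_cv(zb_wham)
        dh = cv_peak_enthalpy(tc)
        total = zb_config.dh_prop * zb_config.n_residues
        assert 0 < dh < total


class TestPmf:
    def test_uniform_two_bins_flat(self):
        rng = np.random.default_rng(0)
        n = 2000
        rg = np.where(rng.uniform(size=n) < 0.5, 15.0, 25.0)
        ds = ReplicaExchangeDataset(_frames(np.arange(n), np.full(n, 300.0),
                                            np.zeros(n), rg=rg))
        sol = wham_solve(ds, bins=4)
        surf = compute_pmf(ds, sol, ("rg",), 300.0, bins=2)
        finite = surf.values[np.isfinite(surf.values)]
        p = np.exp(-finite / (R_GAS * 300.0))
        p /= p.sum()
        # equal sampling probabilities -> PMF difference ~ 0 (binomial noise)
        assert abs(finite[0] - finite[1]) < 0.1

    def test_ninety_ten_split_formula(self):
        """P = 0.9/0.1 at 300 K gives dPMF = R*300*ln 9 ~ 1.310 kcal/mol."""
        n = 10000
        rg = np.where(np.arange(n) < int(0.9 * n), 15.0, 25.0)
        ds = ReplicaExchangeDataset(_frames(np.arange(n), np.full(n, 300.0),
                                            np.zeros(n), rg=rg))
        sol = wham_solve(ds, bins=4)
        surf = compute_pmf(ds, sol, ("rg",), 300.0, bins=2)
        finite = surf.values[np.isfinite(surf.values)]
        expected = R_GAS * 300.0 * np.log(9.0)
        assert expected == pytest.approx(1.310, abs=0.001)
        assert max(finite) - min(finite) == pytest.approx(expected, rel=1e-9)
        assert min(finite) == 0.0

    def test_minimum_bin_is_modal_bin(self, zb_dataset, zb_wham):
        surf = compute_pmf(zb_dataset, zb_wham, ("rg", "helix_fraction"),
                           330.0, bins=20)
        assert surf.values[np.isfinite(surf.values)].min() == 0.0
        # empty bins are +inf, never 0
        assert not np.any(surf.values[~np.isfinite(surf.values)] == 0)

    def test_bin_doubling_stability(self, zb_dataset, zb_wham):
        """Doubling bins moves the basin by less than one coarse bin width."""
        s1 = compute_pmf(zb_dataset, zb_wham, ("rg",), 330.0, bins=25)
        s2 = compute_pmf(zb_dataset, zb_wham, ("rg",), 330.0, bins=50)

        def basin(surface):
            c = 0.5 * (surface.edges[0][:-1] + surface.edges[0][1:])
            return c[np.nanargmin(np.where(np.isfinite(surface.values),
                                           surface.values, np.nan))]
        w1 = s1.edges[0][1] - s1.edges[0][0]
        assert abs(basin(s1) - basin(s2)) < w1

    def test_degenerate_landscape_rejected(self):
        n = 50
        ds = ReplicaExchangeDataset(_frames(np.arange(n), np.full(n, 300.0),
                                            np.zeros(n), rg=np.full(n, 20.0)))
        sol = wham_solve(ds, bins=2)
        with pytest.raises(ValidationError):
            compute_pmf(ds, sol, ("rg",), 300.0, bins=5)


class TestRgMelting:
    def test_midpoint_consistent_with_cv_peak(self, zb_config, zb_dataset,
                                              zb_wham):
        fit = rg_melting_fit(zb_dataset, zb_wham)
        tc = compute_cv(zb_wham)
        assert abs(fit.tm - tc.tm) < 3.0

    def test_rg_monotone_nondecreasing_in_t(self, zb_dataset, zb_wham):
        grid = np.linspace(302.0, 358.0, 15)
        rg = [reweighted_observable(zb_dataset, zb_wham, "rg_angstrom", t)
              for t in grid]
        assert np.all(np.diff(rg) > -1e-6)

    def test_flat_rg_rejected(self):
        from stabscan.errors import DegenerateTransitionError
        n = 3000
        rng = np.random.default_rng(1)
        e = rng.normal(-30, 3, size=n)
        ds = ReplicaExchangeDataset(_frames(np.arange(n), np.full(n, 320.0),
                                            e, rg=np.full(n, 20.0)))
        sol = wham_solve(ds, bins=30)
        with pytest.raises(DegenerateTransitionError):
            rg_melting_fit(ds, sol, np.linspace(300.0, 340.0, 15))


class TestExchangeRates:
    def test_counting(self):
        log = pd.DataFrame({"step": np.arange(10),
                            "replica_a": 0, "replica_b": 1,
                            "accepted": [True] * 3 + [False] * 7})
        frames = _frames(np.arange(4), np.full(4, 300.0), np.zeros(4))
        ds = ReplicaExchangeDataset(frames, exchange=log)
        summary, lo, hi = exchange_rate_summary(ds)
        assert lo == hi == pytest.approx(0.3)

    def test_empty_log_rejected(self):
        ds = ReplicaExchangeDataset(_frames(np.arange(4), np.full(4, 300.0),
                                            np.zeros(4)))
        with pytest.raises(ValidationError):
            exchange_rate_summary(ds)

    def test_rates_keyed_by_temperature_pair(self, zb_dataset):
        summary, lo, hi = exchange_rate_summary(zb_dataset)
        assert len(summary) == zb_dataset.ladder.size - 1
        assert 0 < lo <= hi <= 1
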