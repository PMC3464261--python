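"""Spectral densities, forward rates, tumbling estimation and model-free fits."""

import math

import numpy as np
import pytest

from relaxkit import (
    ModelFreeFitter,
    RelaxationTriple,
    SpinSystemConstants,
    TumblingRangeError,
    estimate_tau_m,
    fit_modelfree,
    forward_rates,
    generate_dataset,
    select_tumbling_subset,
    spectral_density,
)


def independent_forward(s2, tau_e_ps, rex, tau_m_ns, consts):
    """Literal from-scratch transcription of the relaxation equations.

    Kept deliberately separate from the library implementation (different
    structure, plain floats) to act as a dual-implementation oracle.
    """
    mu0 = 4e-7 * math.pi
    hbar = 1.054571817e-34
    gh, gn = 2.6752218744e8, -2.7126189e7
    r = consts.r_nh * 1e-10
    d = mu0 / (4 * math.pi) * hbar * gh * abs(gn) / r**3
    wh = 2 * math.pi * consts.proton_freq * 1e6
    wn = wh * abs(gn / gh)
    c = wn * consts.csa * 1e-6 / math.sqrt(3.0)
    tm = tau_m_ns * 1e-9
    te = tau_e_ps * 1e-12

    def J(w):
        out = 0.4 * s2 * tm / (1 + (w * tm) ** 2)
        if te > 0:
            tp = 1.0 / (1.0 / tm + 1.0 / te)
            out += 0.4 * (1 - s2) * tp / (1 + (w * tp) ** 2)
        return out

    r1 = d * d / 4 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) + c * c * J(wn)
    r2 = (
        d * d / 8 * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn))
        + c * c / 6 * (4 * J(0) + 3 * J(wn))
        + rex
    )
    noe = 1 + d * d / 4 * (gh / gn) * (6 * J(wh + wn) - J(wh - wn)) / r1
    return r1, r2, noe


class TestSpectralDensity:
    def test_rigid_zero_frequency_closed_form(self):
        tm = 7.9e-9
        assert spectral_density(0.0, 1.0, tm) == pytest.approx(0.4 * tm, rel=1e-14)

    def test_fully_flexible_fast_limit_vanishes(self):
        # J is bounded by 0.4 * tau_e when s2 = 0, so it vanishes with tau_e
        for w in (0.0, 1e8, 1e9):
            assert spectral_density(w, 0.0, 7.9e-9, 1e-18) <= 0.4e-18

    def test_value_against_literal_formula(self, consts):
        w = 2 * math.pi * 60.8e6
        tm, te, s2 = 7.9e-9, 50e-12, 0.8
        tp = 1 / (1 / tm + 1 / te)
        expected = 0.4 * (s2 * tm / (1 + (w * tm) ** 2) + (1 - s2) * tp / (1 + (w * tp) ** 2))
        assert spectral_density(w, s2, tm, te) == pytest.approx(expected, rel=1e-14)


class TestForwardRates:
    def test_matches_independent_oracle(self, consts):
        t = forward_rates(0.8, 50.0, 0.0, 7.9, consts)
        r1, r2, noe = independent_forward(0.8, 50.0, 0.0, 7.9, consts)
        assert t.r1 == pytest.approx(r1, rel=1e-10)
        assert t.r2 == pytest.approx(r2, rel=1e-10)
        assert t.noe == pytest.approx(noe, rel=1e-10)

    def test_rex_is_additive_on_r2_only(self, consts):
        base = forward_rates(0.8, 0.0, 0.0, 7.9, consts)
        with_rex = forward_rates(0.8, 0.0, 3.0, 7.9, consts)
        assert with_rex.r2 - base.r2 == pytest.approx(3.0, abs=1e-12)
        assert with_rex.r1 == base.r1
        assert with_rex.noe == base.noe

    def test_r2_over_r1_grows_with_tumbling_time(self, consts):
        slow = forward_rates(1.0, 0.0, 0.0, 7.9, consts)
        fast = forward_rates(1.0, 0.0, 0.0, 4.0, consts)
        assert slow.r2 / slow.r1 > fast.r2 / fast.r1

    def test_r2_not_less_than_r1_for_slow_tumbling(self, consts):
        for tm in (1.0, 4.0, 8.0, 15.0):
            t = forward_rates(0.85, 30.0, 0.0, tm, consts)
            assert t.r2 >= t.r1


class TestEstimateTauM:
    @pytest.mark.parametrize("tau_m", [1.0, 4.0, 6.9, 7.9, 20.0])
    def test_rigid_rotor_round_trip(self, consts, tau_m):
        triple = forward_rates(1.0, 0.0, 0.0, tau_m, consts)
        assert estimate_tau_m(triple, consts) == pytest.approx(tau_m, rel=1e-4)

    def test_r2_perturbation_increases_estimate(self, consts):
        t = forward_rates(1.0, 0.0, 0.0, 7.9, consts)
        bumped = RelaxationTriple(t.residue_index, t.r1, 1.05 * t.r2, t.noe)
        est = estimate_tau_m(bumped, consts)
        assert est > 7.9
        # brute-force scan oracle for the perturbed ratio
        grid = np.linspace(6.0, 10.0, 4001)
        ratios = [forward_rates(1.0, 0, 0, tm, consts).r2
                  / forward_rates(1.0, 0, 0, tm, consts).r1 for tm in grid]
        oracle = grid[int(np.argmin(np.abs(np.array(ratios) - 1.05 * t.r2 / t.r1)))]
        assert est == pytest.approx(oracle, abs=2e-3)

    def test_out_of_range_ratio_flagged(self, consts):
        with pytest.raises(TumblingRangeError):
            estimate_tau_m(RelaxationTriple(1, r1=2.0, r2=1.0, noe=0.8), consts)


class TestSelectTumblingSubset:
    @staticmethod
    def _noisy_triples(consts, n=20, tau_m=7.9):
        return [
            RelaxationTriple(
                i + 1,
                *(lambda t: (t.r1, t.r2, t.noe))(forward_rates(1.0, 0, 0, tau_m, consts)),
            )
            for i in range(n)
        ]

    def test_all_rigid_all_included(self, consts):
        triples = self._noisy_triples(consts)
        est = select_tumbling_subset(triples, consts=consts)
        assert len(est.included) == len(triples)
        assert est.average_tau_m == pytest.approx(7.9, rel=1e-4)

    def test_low_noe_residue_excluded(self, consts):
        triples = self._noisy_triples(consts)
        t0 = triples[0]
        triples[0] = RelaxationTriple(t0.residue_index, t0.r1, t0.r2, 0.3)
        est = select_tumbling_subset(triples, consts=consts)
        assert t0.residue_index not in est.included
        assert "NOE" in est.excluded[t0.residue_index]

    def test_recovery_on_noisy_114_residue_protein(self, consts, profile_114):
        ds = generate_dataset(list(profile_114), tau_m=7.9, seed=21)
        triples = []
        for p in ds.truth:
            t = forward_rates(p.s2, p.tau_e, p.rex, 7.9, consts, p.residue_index)
            rng = np.random.default_rng(p.residue_index)
            triples.append(
                RelaxationTriple(
                    p.residue_index,
                    t.r1 * (1 + rng.normal(0, 0.01)),
                    t.r2 * (1 + rng.normal(0, 0.01)),
                    t.noe + rng.normal(0, 0.01),
                )
            )
        est = select_tumbling_subset(triples, consts=consts)
        assert est.average_tau_m == pytest.approx(7.9, rel=0.02)

    def test_degenerate_subset_rejected(self, consts):
        triples = self._noisy_triples(consts, n=4)
        with pytest.raises(ValueError):
            select_tumbling_subset(triples, consts=consts)


def _noiseless_triple(s2, te, rex, consts, rel_err=0.01):
    t = forward_rates(s2, te, rex, 7.9, consts)
    return RelaxationTriple(
        1, t.r1, t.r2, t.noe, rel_err * t.r1, rel_err * t.r2, rel_err * abs(t.noe)
    )


class TestFitModelfree:
    @pytest.mark.parametrize(
        "s2,te,rex,model",
        [
            (0.8, 0.0, 0.0, "M1"),
            (0.8, 500.0, 0.0, "M2"),
            (0.8, 0.0, 3.0, "M3"),
            (0.3, 600.0, 0.0, "M2"),
            (0.55, 0.0, 1.5, "M3"),
        ],
    )
    def test_noiseless_exact_recovery(self, consts, s2, te, rex, model):
        r = fit_modelfree(_noiseless_triple(s2, te, rex, consts), 7.9, consts)
        assert r.model == model
        assert r.chi2 < 1e-8
        assert r.s2 == pytest.approx(s2, abs=1e-5)
        if te > 0:
            assert r.tau_e == pytest.approx(te, rel=1e-4)
        if rex > 0:
            assert r.rex == pytest.approx(rex, rel=1e-4)

    def test_noiseless_m3_against_grid_oracle(self, consts):
        triple = _noiseless_triple(0.8, 0.0, 3.0, consts)
        # brute-force 2-D grid over (s2, rex)
        best = (np.inf, None, None)
        for s2 in np.linspace(0.7, 0.9, 201):
            for rex in np.linspace(2.0, 4.0, 201):
                calc = forward_rates(s2, 0.0, rex, 7.9, consts)
                chi = (
                    ((calc.r1 - triple.r1) / triple.r1_err) ** 2
                    + ((calc.r2 - triple.r2) / triple.r2_err) ** 2
                    + ((calc.noe - triple.noe) / triple.noe_err) ** 2
                )
                if chi < best[0]:
                    best = (chi, s2, rex)
        r = fit_modelfree(triple, 7.9, consts)
        assert r.s2 == pytest.approx(best[1], abs=1e-3)
        assert r.rex == pytest.approx(best[2], abs=1e-2)

    def test_noisy_m2_selected_majority(self, consts):
        clean = forward_rates(0.8, 500.0, 0.0, 7.9, consts)
        n_m2 = 0
        n_rep = 200
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            t = RelaxationTriple(
                1,
                clean.r1 * (1 + rng.normal(0, 0.01)),
                clean.r2 * (1 + rng.normal(0, 0.01)),
                clean.noe * (1 + rng.normal(0, 0.01)),
                0.01 * clean.r1,
                0.01 * clean.r2,
                0.01 * abs(clean.noe),
            )
            if fit_modelfree(t, 7.9, consts).model == "M2":
                n_m2 += 1
        assert n_m2 / n_rep >= 0.8

    def test_selected_chi2_never_exceeds_simpler_model(self, consts):
        triple = _noiseless_triple(0.75, 300.0, 0.0, consts)
        full = ModelFreeFitter(tau_m=7.9, constants=consts)
        m1 = full._fit_one_model(triple, "M1", 7.9, consts)[3]
        selected = fit_modelfree(triple, 7.9, consts)
        assert selected.chi2 <= m1 + 1e-12

    def test_errors_required(self, consts):
        t = forward_rates(0.8, 0.0, 0.0, 7.9, consts)
        with pytest.raises(ValueError):
            ModelFreeFitter(tau_m=7.9).fit([t])
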