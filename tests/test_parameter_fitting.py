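import numpy as np
import pytest

from glycofit.dataset_curation import split
from glycofit.forcefield_io import Conformer, ConformerSet
from glycofit.parameter_fitting import (
    AdadeltaState,
    FitConfig,
    FitWorkspace,
    FreeParameterMask,
    adadelta_step,
    cost,
    fit,
)
from glycofit.synthetic_data import (
    DRIVEN_TORSION_TYPES,
    GeneratorConfig,
    make_dataset,
    perturb_parameters,
)
from oracles import golden_section_minimize


def relaxed_config(**kw):
    """Recovery-style config: only the neutrality penalty anchors."""
    defaults = dict(
        lambda_chg=0.0,
        lambda_dih=0.0,
        lambda_scee=0.0,
        mask=FreeParameterMask(torsion_types=list(DRIVEN_TORSION_TYPES), fit_phases=False),
    )
    defaults.update(kw)
    return FitConfig(**defaults)


class TestCost:
    def test_zero_at_truth_with_neutral_charges(
        self, small_dataset, truth_params, small_charge_stats
    ):
        cfg = FitConfig(lambda_chg=0.0, lambda_scee=0.0, lambda_dih=0.0)
        total, pen = cost(truth_params, small_dataset, truth_params, small_charge_stats, cfg)
        assert pen["data"] == pytest.approx(0.0, abs=1e-12)
        assert pen["chi2_csum"] == pytest.approx(0.0, abs=1e-16)
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_penalties_measure_deviation_from_reference(
        self, small_dataset, truth_params, start_params, small_charge_stats
    ):
        cfg = FitConfig()
        _, pen = cost(truth_params, small_dataset, start_params, small_charge_stats, cfg)
        v_dev = 0.0
        for t, terms in truth_params.torsion_terms.items():
            ref = {n: v for n, v, _ in start_params.torsion_terms.get(t, [])}
            v_dev += sum((v - ref.get(n, 0.0)) ** 2 for n, v, _ in terms)
            v_dev += sum(v**2 for n, v in ref.items() if n not in {n for n, _, _ in terms})
        assert pen["chi2_dih"] == pytest.approx(v_dev, rel=1e-9)
        assert pen["chi2_scee"] == pytest.approx((truth_params.scee - start_params.scee) ** 2)

    def test_single_structure_no_penalties_is_ree_squared(self, topology, chair_coords, truth_params):
        from glycofit.mm_energy import total_energy

        e = total_energy(topology, truth_params, chair_coords).total
        cs = ConformerSet(
            [Conformer("ref", chair_coords, 0.0), Conformer("s", chair_coords, 3.0)], topology
        )
        cfg = FitConfig(lambda_csum=0.0, lambda_chg=0.0, lambda_dih=0.0, lambda_scee=0.0)
        total, pen = cost(truth_params, cs, truth_params, None, cfg)
        # identical geometry: MM difference 0, QM difference 3 -> mean REE^2 = (0+9)/2
        assert total == pytest.approx(4.5, abs=1e-9)

    def test_sigma_floor_applied_with_warning(self, small_dataset, truth_params):
        from glycofit.dataset_curation import ChargeStatistics

        labels = [
            small_dataset.topology.atoms[i].label
            for i in small_dataset.topology.optimizable_atoms
        ]
        stats = ChargeStatistics(
            mean={l: truth_params.charges[l] for l in labels},
            sd={l: 0.0 for l in labels},
            sample_count=10,
        )
        with pytest.warns(UserWarning, match="floor"):
            FitWorkspace(small_dataset, truth_params, FitConfig(), stats)


class TestGradient:
    def test_matches_directional_finite_differences(
        self, small_dataset, truth_params, start_params, small_charge_stats, rng
    ):
        cfg = FitConfig()
        ws = FitWorkspace(small_dataset, start_params, cfg, small_charge_stats)
        sub = np.arange(len(small_dataset))
        p0 = ws.initial_vector(truth_params)
        free = ws.free_flags()
        h = 1e-6
        for _ in range(10):
            p = p0 + rng.normal(0, 0.05, p0.size)
            _, _, g = ws.cost_and_gradient(p, sub)
            d = rng.normal(0, 1, p.size) * free
            d /= np.linalg.norm(d)
            cp, _, _ = ws.cost_and_gradient(p + h * d, sub, want_gradient=False)
            cm, _, _ = ws.cost_and_gradient(p - h * d, sub, want_gradient=False)
            fd = (cp - cm) / (2 * h)
            assert abs(float(g @ d) - fd) / max(abs(fd), 1e-10) < 1e-5

    def test_scee_gradient_opposes_14_coulomb_sign(
        self, small_dataset, truth_params, small_charge_stats
    ):
        # dE/dscee = -E_C14/scee: raising scee weakens whatever the 1-4
        # electrostatics contribute
        cfg = FitConfig()
        ws = FitWorkspace(small_dataset, truth_params, cfg, small_charge_stats)
        p = ws.initial_vector(truth_params)
        rows = np.arange(len(small_dataset))
        e, (gq_nb, gq_14, ec_14, q, scee) = ws._energies(p, rows)
        d_scee = -ec_14 / scee
        assert np.all(np.sign(d_scee) == -np.sign(ec_14))

    def test_zero_at_symmetric_minimum(self, small_dataset, truth_params, small_charge_stats):
        cfg = FitConfig(lambda_chg=0.0, lambda_dih=0.0, lambda_scee=0.0)
        ws = FitWorkspace(small_dataset, truth_params, cfg, small_charge_stats)
        _, _, g = ws.cost_and_gradient(
            ws.initial_vector(truth_params), np.arange(len(small_dataset))
        )
        # data term exactly zero at the generating parameters; neutral truth
        assert np.linalg.norm(g[ws.free_flags()]) < 1e-6


class TestAdadelta:
    def test_zero_gradient_zero_update(self):
        state = AdadeltaState.zeros(4)
        np.testing.assert_array_equal(adadelta_step(np.zeros(4), state), np.zeros(4))

    def test_first_step_magnitude_matches_closed_form(self):
        g = np.array([0.5, -2.0, 10.0])
        c, rho = 1e-6, 0.95
        state = AdadeltaState.zeros(3)
        step = adadelta_step(g.copy(), state, rho, c)
        expected = np.sqrt(c / ((1 - rho) * g**2 + c)) * np.abs(g)
        np.testing.assert_allclose(np.abs(step), expected, rtol=1e-12)

    def test_update_opposes_gradient_componentwise(self, rng):
        state = AdadeltaState.zeros(20)
        for _ in range(5):
            g = rng.normal(0, 3, 20)
            step = adadelta_step(g, state)
            assert np.all(step * g <= 0)


class TestFit:
    def test_start_at_truth_stays_put(self, small_dataset, truth_params, small_charge_stats):
        cfg = relaxed_config(max_epochs=100)
        res = fit(small_dataset, truth_params, small_charge_stats, cfg)
        for t, terms in truth_params.torsion_terms.items():
            fitted = {n: v for n, v, _ in res.parameters.torsion_terms[t]}
            for n, v, _ in terms:
                assert abs(fitted[n] - v) < 1e-3
        assert abs(res.parameters.scee - truth_params.scee) < 1e-3

    def test_train_cost_decreases_and_aliphatic_h_stay_zero(
        self, small_dataset, truth_params, small_charge_stats
    ):
        start = perturb_parameters(truth_params, dv=0.5, dq=0.02)
        cfg = relaxed_config(max_epochs=300)
        res = fit(small_dataset, start, small_charge_stats, cfg)
        assert res.train_cost[-1] <= res.train_cost[0]
        for label in ("H1", "H2", "H3", "H4", "H5", "H61", "H62"):
            assert res.parameters.charges[label] == 0.0

    def test_one_free_parameter_matches_golden_section(
        self, small_dataset, truth_params, small_charge_stats
    ):
        # scee is the only free parameter and every penalty is off, so the
        # fit is a 1-D minimization comparable to a golden-section oracle
        start = truth_params.copy()
        start.scee = 1.25
        cfg = FitConfig(
            lambda_csum=0.0,
            lambda_chg=0.0,
            lambda_dih=0.0,
            lambda_scee=0.0,
            max_epochs=8000,
            tolerance=0.0,
            adadelta_eps=1e-8,  # deep convergence for the 1-D comparison
            mask=FreeParameterMask(
                fit_amplitudes=False, fit_phases=False, charge_atoms=[], fit_scee=True
            ),
        )
        ws = FitWorkspace(small_dataset, start, cfg, small_charge_stats)
        sub = np.arange(len(small_dataset))

        def cost_of_scee(s):
            p = ws.initial_vector(start)
            p[-1] = s
            return ws.cost_and_gradient(p, sub, want_gradient=False)[0]

        s_star = golden_section_minimize(cost_of_scee, 0.8, 1.6)
        res = fit(small_dataset, start, small_charge_stats, cfg)
        assert res.parameters.scee == pytest.approx(s_star, abs=1e-4)
        assert s_star == pytest.approx(truth_params.scee, abs=1e-6)

    def test_net_charge_scales_inversely_with_csum_weight(self, truth_params):
        # data generated from a deliberately non-neutral truth, so the data
        # term pulls the total charge to +0.05 e and the neutrality penalty
        # must fight it; the residual shrinks roughly like 1/lambda
        from glycofit.synthetic_data import (
            GeneratorConfig,
            emulate_resp_sets,
            generate_conformers,
            oracle_energies,
        )
        from glycofit.dataset_curation import charge_statistics

        nonneutral = truth_params.copy()
        nonneutral.charges = dict(nonneutral.charges)
        nonneutral.charges["O3"] += 0.05
        cs = generate_conformers(GeneratorConfig(n_structures=60, seed=2024))
        cs = oracle_energies(cs, nonneutral, 0.0, seed=1)
        cs = emulate_resp_sets(cs, nonneutral.charges, 0.03, seed=2)
        stats = charge_statistics(cs)
        sums = {}
        for lam in (1.0, 30.0):
            cfg = relaxed_config(lambda_csum=lam, max_epochs=4000, tolerance=0.0)
            res = fit(cs, nonneutral, stats, cfg)
            sums[lam] = abs(sum(res.parameters.charges.values()))
        assert sums[30.0] < sums[1.0]
        assert sums[1.0] / sums[30.0] > 8.0

    def test_deterministic_given_config(self, small_dataset, truth_params, small_charge_stats):
        start = perturb_parameters(truth_params, dv=0.3, dq=0.01)
        cfg = relaxed_config(max_epochs=50)
        r1 = fit(small_dataset, start, small_charge_stats, cfg)
        r2 = fit(small_dataset, start, small_charge_stats, cfg)
        assert r1.train_cost == r2.train_cost
        assert r1.parameters.charges == r2.parameters.charges

    def test_test_cost_tracked_per_epoch(self, small_dataset, truth_params, small_charge_stats):
        train, test = split(small_dataset, seed=0)
        start = perturb_parameters(truth_params, dv=0.2, dq=0.01)
        cfg = relaxed_config(max_epochs=40)
        res = fit(small_dataset, start, small_charge_stats, cfg, train, test)
        assert len(res.test_cost) == len(res.train_cost) == res.epochs
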