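"""Kinetic models: IO, steady states, MCMC evolution, coupling, essentiality."""

import copy
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metacons import synthetic
from metacons.kinetics import (
    ERYTHROCYTE_EXCLUDED_METABOLITES,
    EvolutionConfig,
    KineticModel,
    ModelFormatError,
    Reaction,
    Trajectory,
    evolve,
    fitness_coupling,
    insilico_mcs,
    mutant_ensemble,
    mutate,
    random_keyflux_scan,
    reaction_essentiality,
    selection_distance,
    steady_state,
)
from metacons.kinetics.analysis import coupling_from_ensemble
from metacons.kinetics.evolve import EvolutionError


def chain_model(k=2.0, v0=1.0):
    """Constant source into A, first-order consumption: A* = v0/k, flux v0."""
    return KineticModel(
        species={"A": 1.0},
        boundary={"Sink": 0.0},
        reactions=[
            Reaction("R_in", {"A": 1.0}, "v0", {"v0": v0}),
            Reaction("R_out", {"A": -1.0, "Sink": 1.0}, "k * A", {"k": k}),
        ],
    )


class TestModelIO:
    def test_toy_model_loads_with_8_reactions(self, toy_model):
        assert len(toy_model.reactions) == 8
        assert len(toy_model.species_ids) == 6

    def test_undeclared_rate_law_symbol_named(self):
        with pytest.raises(ModelFormatError, match="Bogus"):
            KineticModel(
                species={"A": 1.0},
                boundary={},
                reactions=[Reaction("R1", {"A": 1.0}, "k * Bogus", {"k": 1.0})],
            )

    def test_duplicate_parameter_ownership_rejected(self):
        with pytest.raises(ModelFormatError, match="owned by both"):
            KineticModel(
                species={"A": 1.0},
                boundary={},
                reactions=[
                    Reaction("R1", {"A": 1.0}, "k", {"k": 1.0}),
                    Reaction("R2", {"A": -1.0}, "k * A", {"k": 2.0}),
                ],
            )

    def test_native_round_trip_value_identical(self, toy_model):
        text = toy_model.to_native()
        again = KineticModel.from_native(text)
        assert np.array_equal(toy_model.p0, again.p0)
        assert again.to_native() == text

    def test_native_sbml_native_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        toy_model.to_sbml_file(path)
        back = KineticModel.from_sbml_file(path)
        assert set(back.species_ids) == set(toy_model.species_ids)
        for pname, idx in toy_model.parameter_index.items():
            assert back.p0[back.parameter_index[pname]] == toy_model.p0[idx]
        # and the two models agree dynamically
        ss1 = steady_state(toy_model)
        ss2 = steady_state(back)
        assert ss1.converged and ss2.converged
        f2 = {r: ss2.flux_of(back, r) for r in back.reaction_ids}
        for r in toy_model.reaction_ids:
            assert f2[r] == pytest.approx(ss1.flux_of(toy_model, r), rel=1e-6)


class TestSteadyState:
    def test_linear_chain_analytic(self):
        ss = steady_state(chain_model(k=2.0, v0=1.0))
        m = chain_model(k=2.0, v0=1.0)
        assert ss.converged
        assert ss.concentration_of(m, "A") == pytest.approx(0.5, abs=1e-8)
        assert ss.flux_of(m, "R_out") == pytest.approx(1.0, abs=1e-8)

    def test_rate_mutation_shifts_level_not_flux(self):
        m = chain_model(k=4.0, v0=1.0)
        ss = steady_state(m)
        assert ss.concentration_of(m, "A") == pytest.approx(0.25, abs=1e-8)
        assert ss.flux_of(m, "R_out") == pytest.approx(1.0, abs=1e-8)

    def test_unbounded_accumulation_reports_nonconvergence(self):
        # saturable consumption cannot absorb the source: no fixed point
        m = KineticModel(
            species={"A": 1.0},
            boundary={},
            reactions=[
                Reaction("R_in", {"A": 1.0}, "v0", {"v0": 1e6}),
                Reaction("R_out", {"A": -1.0}, "Vm * A / (Km + A)", {"Vm": 1.0, "Km": 1.0}),
            ],
        )
        ss = steady_state(m)
        assert not ss.converged

    def test_toy_wild_type_converges(self, toy_model, toy_wildtype):
        assert toy_wildtype.residual < 1e-9
        src = toy_wildtype.flux_of(toy_model, "R_src")
        sinks = toy_wildtype.flux_of(toy_model, "R_cexp") + toy_wildtype.flux_of(toy_model, "R_dexp")
        assert src == pytest.approx(sinks, abs=1e-8)

    def test_moiety_total_preserved(self, toy_model, toy_wildtype):
        i = toy_model.species_ids.index("ATP")
        j = toy_model.species_ids.index("ADP")
        total = toy_wildtype.concentrations[i] + toy_wildtype.concentrations[j]
        assert total == pytest.approx(2.0, abs=1e-7)

    def test_unique_fixed_point_from_random_starts(self, toy_model, toy_wildtype):
        rng = np.random.default_rng(77)
        sols = []
        for _ in range(20):
            x0 = rng.uniform(0.05, 3.0, size=len(toy_model.species_ids))
            # respect the ATP+ADP=2 moiety so the same fixed point is reachable
            i = toy_model.species_ids.index("ATP")
            j = toy_model.species_ids.index("ADP")
            tot = x0[i] + x0[j]
            x0[i] *= 2.0 / tot
            x0[j] *= 2.0 / tot
            ss = steady_state(toy_model, x0=x0)
            assert ss.converged
            sols.append(ss.concentrations)
        sols = np.array(sols)
        assert np.max(np.ptp(sols, axis=0)) < 1e-6


class TestMutation:
    def test_zero_alpha_is_identity(self, toy_model):
        class FixedRng:
            def integers(self, n):
                return 0

            def normal(self, mu, sd):
                return 0.0

        ev = mutate(toy_model, toy_model.p0, 0.01, FixedRng())
        assert ev.new_value == ev.old_value

    def test_unit_alpha_multiplies_by_ten(self, toy_model):
        class FixedRng:
            def integers(self, n):
                return 0

            def normal(self, mu, sd):
                return 1.0

        ev = mutate(toy_model, toy_model.p0, 0.01, FixedRng())
        assert ev.new_value == pytest.approx(10 * ev.old_value, rel=1e-15)

    def test_alpha_distribution_normal(self, toy_model):
        rng = np.random.default_rng(5)
        alphas = np.array(
            [mutate(toy_model, toy_model.p0, 0.01, rng).alpha for _ in range(20_000)]
        )
        stat = stats.kstest(alphas, "norm", args=(0.0, 0.01))
        assert stat.pvalue > 0.01

    def test_parameterless_reactions_resampled(self):
        m = synthetic.toy_monotone_model()
        rng = np.random.default_rng(6)
        for _ in range(50):
            ev = mutate(m, m.p0, 0.01, rng)
            assert ev.reaction_id == "R_in"


class TestSelectionDistance:
    def test_closed_forms(self, toy_model, toy_wildtype):
        keys = [toy_model.reaction_index(r) for r in synthetic.TOY_KEY_FLUXES]
        assert selection_distance(toy_wildtype, toy_wildtype, keys) == 0.0
        mut = copy.deepcopy(toy_wildtype)
        mut.fluxes = toy_wildtype.fluxes.copy()
        mut.fluxes[keys[0]] *= 2
        assert selection_distance(mut, toy_wildtype, keys) == pytest.approx(1.0, rel=1e-12)
        mut.fluxes = toy_wildtype.fluxes.copy()
        mut.fluxes[keys[0]] *= 1.1
        mut.fluxes[keys[1]] *= 1.1
        assert selection_distance(mut, toy_wildtype, keys) == pytest.approx(
            math.sqrt(0.02), rel=1e-9
        )

    def test_zero_wildtype_key_flux_rejected(self, toy_model, toy_wildtype):
        mut = copy.deepcopy(toy_wildtype)
        wt0 = copy.deepcopy(toy_wildtype)
        wt0.fluxes = toy_wildtype.fluxes.copy()
        wt0.fluxes[0] = 0.0
        with pytest.raises(ValueError):
            selection_distance(mut, wt0, [0])


class TestEvolve:
    def test_drift_accepts_every_steady_state_proposal(self, toy_model):
        cfg = EvolutionConfig(omega=math.inf, sigma_mut=1e-2, T=100, seed=1)
        traj = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        assert traj.acceptance_fraction == 1.0

    def test_selection_accepted_states_below_threshold(self, toy_model):
        cfg = EvolutionConfig(omega=1e-4, sigma_mut=1e-2, T=300, seed=2)
        traj = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        assert traj.accepted.any() and not traj.accepted.all()
        assert np.all(traj.z[traj.accepted] < cfg.omega)

    def test_vanishing_threshold_freezes_near_wild_type(self):
        # every parameter of this model moves the key flux, so omega -> 0+
        # rejects essentially all proposals and the state stays at wild type
        m = synthetic.toy_monotone_model()
        wt = steady_state(m)
        cfg = EvolutionConfig(omega=1e-12, sigma_mut=1e-2, T=200, seed=3)
        traj = evolve(m, ["R_out"], cfg)
        rel = np.abs(traj.concentrations / wt.concentrations - 1)
        assert np.max(rel) < 1e-3

    def test_flux_neutral_directions_stay_accepted(self, toy_model, toy_wildtype):
        # the toy network has parameters (e.g. the D-export rate constant)
        # that change a concentration but no steady-state flux; such strictly
        # neutral moves pass any threshold, so evolution never fully freezes
        cfg = EvolutionConfig(omega=1e-12, sigma_mut=1e-2, T=200, seed=3)
        traj = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        assert traj.accepted.any()
        assert np.all(traj.z[traj.accepted] < cfg.omega)

    def test_state_changes_only_at_accepted_iterations(self, toy_model):
        cfg = EvolutionConfig(omega=1e-4, sigma_mut=1e-2, T=200, seed=4)
        traj = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        diffs = np.abs(np.diff(traj.concentrations, axis=0)).max(axis=1)
        changed = diffs > 0
        assert not np.any(changed & ~traj.accepted[1:])

    def test_bit_reproducible(self, toy_model):
        cfg = EvolutionConfig(omega=1e-4, sigma_mut=1e-2, T=100, seed=5)
        a = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        b = evolve(toy_model, synthetic.TOY_KEY_FLUXES, cfg)
        assert np.array_equal(a.concentrations, b.concentrations)
        assert np.array_equal(a.z, b.z)

    def test_nonconverging_wild_type_fails_before_iterating(self):
        m = KineticModel(
            species={"A": 1.0},
            boundary={},
            reactions=[
                Reaction("R_in", {"A": 1.0}, "v0", {"v0": 1e6}),
                Reaction("R_out", {"A": -1.0}, "Vm * A / (Km + A)", {"Vm": 1.0, "Km": 1.0}),
            ],
        )
        with pytest.raises(EvolutionError, match="wild-type"):
            evolve(m, ["R_out"], EvolutionConfig(T=5, seed=1))


class TestInSilicoMCS:
    def _traj(self, ratios, x0=1.0):
        conc = np.asarray(ratios, float)[:, None] * x0
        T = len(ratios)
        wt = None
        traj = Trajectory(
            concentrations=conc,
            accepted=np.ones(T, dtype=bool),
            z=np.zeros(T),
            wildtype=None,
            final_parameters=np.zeros(0),
            species_ids=["M"],
        )
        from metacons.kinetics.solve import SteadyState

        wt = SteadyState(np.array([x0]), np.zeros(0), True, 0.0)
        traj.wildtype = wt
        return traj

    def test_constant_trajectory_flagged(self):
        res = insilico_mcs(self._traj([1.0, 1.0, 1.0]))
        assert bool(res.table["flagged"].iloc[0])
        assert res.table["evolution_rate"].iloc[0] == 0.0

    def test_sample_variance_oracle(self):
        # var([1.0, 1.1, 0.9], ddof=1) = 0.01; ER = 0.01/3; score = 300
        res = insilico_mcs(self._traj([1.0, 1.1, 0.9]))
        assert res.table["evolution_rate"].iloc[0] == pytest.approx(0.01 / 3, rel=1e-12)
        assert res.table["score"].iloc[0] == pytest.approx(300.0, rel=1e-12)

    def test_exclusion_list_applied(self):
        traj = self._traj([1.0, 1.1, 0.9])
        traj.species_ids = [ERYTHROCYTE_EXCLUDED_METABOLITES[0]]
        res = insilico_mcs(traj, exclude=ERYTHROCYTE_EXCLUDED_METABOLITES)
        assert bool(res.table["flagged"].iloc[0])

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            insilico_mcs(self._traj([1.0]))


class TestFitnessCoupling:
    def test_monotone_coupled_metabolite_is_one(self):
        m = synthetic.toy_monotone_model()
        table = fitness_coupling(m, ["R_out"], n_mut=300, seed=11)
        assert table.set_index("metabolite").loc["A", "coupling"] == pytest.approx(1.0)

    def test_decoupled_branch_metabolites_near_zero(self):
        m = synthetic.toy_decoupled_model(10)
        table = fitness_coupling(m, ["Rout1"], n_mut=2000, seed=12).set_index("metabolite")
        others = table.drop(index="A1")["coupling"]
        assert np.all(np.abs(others) < 0.1)

    def test_coupling_bounded(self, toy_model):
        table = fitness_coupling(toy_model, list(toy_model.reaction_ids), n_mut=200, seed=13)
        assert table["coupling"].between(-1, 1).all()

    def test_half_ensemble_reproducibility(self, toy_model):
        a = fitness_coupling(toy_model, synthetic.TOY_KEY_FLUXES, n_mut=2000, seed=21)
        b = fitness_coupling(toy_model, synthetic.TOY_KEY_FLUXES, n_mut=2000, seed=22)
        diff = (a.set_index("metabolite")["coupling"] - b.set_index("metabolite")["coupling"]).abs()
        assert diff.max() < 0.15


class TestEssentiality:
    def test_key_flux_carrier_essential(self, toy_model):
        rxn, met = reaction_essentiality(toy_model, synthetic.TOY_KEY_FLUXES)
        r = rxn.set_index("reaction")
        assert r.loc["R_cexp", "essential"] is True or r.loc["R_cexp", "essential"] == True
        assert met.set_index("metabolite").loc["C", "essential"] == True

    def test_side_branch_not_essential(self, toy_model):
        rxn, met = reaction_essentiality(toy_model, synthetic.TOY_KEY_FLUXES)
        r = rxn.set_index("reaction")
        assert r.loc["R_bd", "essential"] == False
        assert r.loc["R_dexp", "essential"] == False
        assert met.set_index("metabolite").loc["D", "essential"] == False

    def test_no_knockdown_no_essential(self, toy_model):
        rxn, _ = reaction_essentiality(toy_model, synthetic.TOY_KEY_FLUXES, knockdown=1.0)
        assert not rxn["essential"].fillna(False).any()


class TestRandomKeyfluxScan:
    def test_designated_set_consistent_with_direct_computation(self, toy_model):
        ens = mutant_ensemble(toy_model, n_mut=400, seed=31)
        abund = pd.Series(ens.wildtype.concentrations, index=toy_model.species_ids)
        res = random_keyflux_scan(
            toy_model, abund, synthetic.TOY_KEY_FLUXES, n_combos=30, ensemble=ens, seed=31
        )
        direct = coupling_from_ensemble(ens, synthetic.TOY_KEY_FLUXES).set_index("metabolite")["coupling"]
        rho = stats.spearmanr(abund.loc[direct.index], direct).statistic
        assert res["observed_rho"] == pytest.approx(rho, rel=1e-12)
        assert 0 < res["p_one_sided"] <= 1
        assert len(res["null_coupling_rho"]) == 30
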