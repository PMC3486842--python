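"""FBA engine: hand-checked LPs, vertex-enumeration oracle, invariants."""

import itertools

import numpy as np
import pytest

from catapot.fba import (
    FBAError,
    Medium,
    MetabolicModel,
    Reaction,
    format_equation,
    label_growth,
    load_model_tsv,
    maximize_biomass,
    measure_yield,
    parse_equation,
    remove_atp_maintenance,
    write_model_tsv,
)


def toy_chain(uptake_ub=10.0):
    """exchange -> G (bound), G -> 2 P, biomass consumes 1 P per unit."""
    return MetabolicModel(
        metabolites=("G", "P"),
        reactions=(
            Reaction("EX_G", {"G": 1.0}, 0.0, uptake_ub),
            Reaction("CONV", {"G": -1.0, "P": 2.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
        ),
        biomass_reaction_id="BIOMASS",
        exchange_reactions={"g_nut": "EX_G"},
    )


class TestMaximizeBiomass:
    def test_linear_chain_hand_lp(self):
        # 10 units uptake -> 20 P -> biomass flux 20
        sol = maximize_biomass(toy_chain(), Medium({"g_nut": 10.0}))
        assert sol.status == "optimal"
        assert sol.biomass_flux == pytest.approx(20.0, abs=1e-8)

    def test_empty_medium_gives_zero_biomass(self):
        sol = maximize_biomass(toy_chain(), Medium({}))
        assert sol.status == "optimal"
        assert sol.biomass_flux == pytest.approx(0.0, abs=1e-9)

    def test_structurally_blocked_source_gives_zero(self):
        model = MetabolicModel(
            metabolites=("G", "X", "P"),
            reactions=(
                Reaction("EX_G", {"G": 1.0}, 0.0, 10.0),
                Reaction("DEADEND", {"G": -1.0, "X": 1.0}, 0.0, 0.0),
                Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
            ),
            biomass_reaction_id="BIOMASS",
            exchange_reactions={"g_nut": "EX_G"},
        )
        sol = maximize_biomass(model, Medium({"g_nut": 10.0}))
        assert sol.biomass_flux == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_lp_reported(self):
        # mass-imbalanced loop able to create P from nothing
        model = MetabolicModel(
            metabolites=("P",),
            reactions=(
                Reaction("MAGIC", {"P": 1.0}, 0.0, np.inf),
                Reaction("BIOMASS", {"P": -1.0}, 0.0, np.inf),
            ),
            biomass_reaction_id="BIOMASS",
        )
        assert maximize_biomass(model, Medium({})).status == "unbounded"

    def test_steady_state_residual_within_tolerance(self):
        model = toy_chain()
        sol = maximize_biomass(model, Medium({"g_nut": 10.0}))
        S = model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r.id] for r in model.reactions])
        assert np.max(np.abs(v @ S)) < 1e-8


def _enumerate_vertices_optimum(model: MetabolicModel, medium: Medium) -> float:
    """Independent oracle: exhaustive vertex enumeration of the flux polytope.

    Project onto the null space of the steady-state constraints and
    enumerate all vertices defined by choosing dim-many active bound
    constraints; return the maximal biomass flux over feasible vertices.
    """
    from catapot.fba import _apply_medium

    S = model.stoichiometric_matrix()
    bounds = _apply_medium(model, medium)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    n = len(model.reactions)
    A = S.T  # metabolite balance rows
    # null-space basis of A
    if A.size:
        _, s, vt = np.linalg.svd(A)
        rank = int(np.sum(s > 1e-10))
        N = vt[rank:].T  # n x d
    else:
        N = np.eye(n)
    d = N.shape[1]
    c = np.zeros(n)
    c[model.reaction_index[model.biomass_reaction_id]] = 1.0
    if d == 0:
        v = np.zeros(n)
        if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
            return float(c @ v)
        return None
    best = None
    rows = [(i, "lb") for i in range(n)] + [(i, "ub") for i in range(n)]
    for combo in itertools.combinations(rows, d):
        M = np.array([N[i] for i, _ in combo])
        rhs = np.array([lb[i] if side == "lb" else ub[i] for i, side in combo])
        if np.linalg.matrix_rank(M, tol=1e-10) < d:
            continue
        t, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        v = N @ t
        if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
            val = float(c @ v)
            best = val if best is None else max(best, val)
    return best


def random_toy_model(rng):
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, 7))
    mets = tuple(f"m{j}" for j in range(n_mets))
    reactions = []
    for i in range(n_rxns):
        stoich = {}
        for j in range(n_mets):
            coef = int(rng.integers(-2, 3))
            if coef and rng.random() < 0.7:
                stoich[mets[j]] = float(coef)
        if not stoich:
            stoich[mets[0]] = 1.0
        lbnd = float(rng.choice([0.0, -5.0]))
        ubnd = float(rng.choice([3.0, 10.0]))
        reactions.append(Reaction(f"r{i}", stoich, lbnd, ubnd))
    return MetabolicModel(
        metabolites=mets,
        reactions=tuple(reactions),
        biomass_reaction_id="r0",
    )


class TestVertexOracle:
    def test_lp_matches_vertex_enumeration_on_random_small_models(self):
        """On >= 20 random bounded toy networks, HiGHS equals brute force."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            model = random_toy_model(rng)
            sol = maximize_biomass(model, Medium({}))
            assert sol.status == "optimal"  # 0 in box, finite bounds
            oracle = _enumerate_vertices_optimum(model, Medium({}))
            assert oracle is not None
            assert sol.biomass_flux == pytest.approx(oracle, abs=1e-8)
            checked += 1


class TestLabelGrowth:
    def test_chain_nutrient_is_g(self):
        assert label_growth(toy_chain(), Medium({}), "g_nut") == "G"

    def test_nutrient_without_exchange_is_ng(self):
        assert label_growth(toy_chain(), Medium({}), "unknown_nut") == "NG"

    def test_subthreshold_growth_is_ng(self):
        # biomass flux at bound 10 is 20; epsilon above that -> NG
        assert label_growth(toy_chain(), Medium({}), "g_nut", epsilon=40.0) == "NG"

    def test_growing_minimal_medium_is_rejected(self):
        with pytest.raises(FBAError, match="minimal medium"):
            label_growth(toy_chain(), Medium({"g_nut": 1.0}), "g_nut")


class TestMeasureYield:
    def test_chain_yield_is_two_per_mole(self):
        assert measure_yield(toy_chain(), Medium({}), "g_nut") == pytest.approx(2.0)

    def test_yield_invariant_to_uptake_bound(self):
        y1 = measure_yield(toy_chain(), Medium({}), "g_nut", uptake_bound=10.0)
        y2 = measure_yield(toy_chain(), Medium({}), "g_nut", uptake_bound=20.0)
        assert y1 == pytest.approx(y2, abs=1e-9)

    def test_isomers_entering_same_metabolite_have_equal_yield(self):
        model = MetabolicModel(
            metabolites=("A", "B", "I", "P"),
            reactions=(
                Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
                Reaction("EX_B", {"B": 1.0}, 0.0, 10.0),
                Reaction("TA", {"A": -1.0, "I": 1.0}, 0.0, 1000.0),
                Reaction("TB", {"B": -1.0, "I": 1.0}, 0.0, 1000.0),
                Reaction("CAT", {"I": -1.0, "P": 3.0}, 0.0, 1000.0),
                Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
            ),
            biomass_reaction_id="BIOMASS",
            exchange_reactions={"a": "EX_A", "b": "EX_B"},
        )
        ya = measure_yield(model, Medium({}), "a")
        yb = measure_yield(model, Medium({}), "b")
        assert ya == pytest.approx(yb) == pytest.approx(3.0)

    def test_zero_uptake_at_optimum_raises(self):
        model = MetabolicModel(
            metabolites=("G", "X", "P"),
            reactions=(
                Reaction("EX_G", {"G": 1.0}, 0.0, 10.0),
                Reaction("SINK", {"G": -1.0, "X": 1.0}, 0.0, 0.0),
                Reaction("BIOMASS", {"P": -1.0}, 0.0, 0.0),
            ),
            biomass_reaction_id="BIOMASS",
            exchange_reactions={"g_nut": "EX_G"},
        )
        with pytest.raises(FBAError, match="zero uptake"):
            measure_yield(model, Medium({}), "g_nut")


class TestMaintenanceRemoval:
    def _with_atpm(self, lbnd):
        base = toy_chain()
        return MetabolicModel(
            metabolites=base.metabolites,
            reactions=base.reactions + (Reaction("ATPM", {"P": -1.0}, lbnd, 1000.0),),
            biomass_reaction_id="BIOMASS",
            exchange_reactions=base.exchange_reactions,
        )

    def test_bounds_zeroed(self):
        model = remove_atp_maintenance(self._with_atpm(8.39))
        atpm = model.reaction("ATPM")
        assert (atpm.lower_bound, atpm.upper_bound) == (0.0, 0.0)

    def test_missing_maintenance_warns_and_returns_unchanged(self):
        model = toy_chain()
        with pytest.warns(UserWarning, match="no ATP-maintenance"):
            assert remove_atp_maintenance(model) is model

    def test_ambiguous_pattern_raises(self):
        base = self._with_atpm(1.0)
        model = MetabolicModel(
            metabolites=base.metabolites,
            reactions=base.reactions
            + (Reaction("ATPM2", {"P": -1.0}, 0.0, 1.0),),
            biomass_reaction_id="BIOMASS",
            exchange_reactions=base.exchange_reactions,
        )
        with pytest.raises(FBAError, match="ATPM"):
            remove_atp_maintenance(model, pattern="ATPM")

    def test_forced_maintenance_suppresses_growth_until_removed(self):
        # maintenance drain consumes the full 20 P supply -> biomass 0
        model = self._with_atpm(20.0)
        before = maximize_biomass(model, Medium({"g_nut": 10.0}))
        assert before.biomass_flux == pytest.approx(0.0, abs=1e-8)
        after = maximize_biomass(
            remove_atp_maintenance(model), Medium({"g_nut": 10.0})
        )
        assert after.biomass_flux == pytest.approx(20.0, abs=1e-8)


class TestMonotonicity:
    def test_enlarging_uptake_bound_never_decreases_biomass(self, catalog, organisms, logistic_model):
        from catapot.fixtures import organism_fba_model

        model, minimal = organism_fba_model(
            catalog, organisms["org_all"], logistic_model, 0.1
        )
        for nid in ["glc", "aa_ala", "pur_ade", "pyr_thy"]:
            fluxes = [
                maximize_biomass(model, minimal.with_nutrient(nid, b)).biomass_flux
                for b in (0.0, 5.0, 10.0, 20.0)
            ]
            assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(fluxes, fluxes[1:]))


class TestReactionDialect:
    @pytest.mark.parametrize(
        "equation, stoich",
        [
            ("A + 2 B -> C", {"A": -1.0, "B": -2.0, "C": 1.0}),
            ("-> X", {"X": 1.0}),
            ("X ->", {"X": -1.0}),
            ("2 A -> 0.5 B + A", {"A": -1.0, "B": 0.5}),
        ],
    )
    def test_equation_grammar(self, equation, stoich):
        assert parse_equation(equation) == stoich

    def test_equation_without_arrow_raises(self):
        with pytest.raises(FBAError):
            parse_equation("A + B")

    def test_format_parse_round_trip(self):
        stoich = {"A": -1.0, "B": -2.0, "C": 1.5}
        assert parse_equation(format_equation(stoich)) == stoich

    def test_model_tsv_round_trip_bit_exact(self, tmp_path, catalog, organisms, logistic_model):
        from catapot.fixtures import organism_fba_model

        model, _ = organism_fba_model(catalog, organisms["org_all"], logistic_model, 0.1)
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        write_model_tsv(model, p1)
        model2 = load_model_tsv(p1)
        write_model_tsv(model2, p2)
        assert p1.read_text() == p2.read_text()
        assert model2.biomass_reaction_id == model.biomass_reaction_id
        assert dict(model2.exchange_reactions) == dict(model.exchange_reactions)
        sol1 = maximize_biomass(model, Medium({"glc": 10.0}))
        sol2 = maximize_biomass(model2, Medium({"glc": 10.0}))
        assert sol1.biomass_flux == pytest.approx(sol2.biomass_flux, abs=1e-9)


class TestSBML:
    def test_read_sbml_model_written_by_cobra(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        from cobra import Metabolite, Model, Reaction as CReaction

        cmodel = Model("toy")
        g = Metabolite("glc_e", compartment="e")
        p = Metabolite("prec_c", compartment="c")
        ex = CReaction("EX_glc")
        ex.add_metabolites({g: -1.0})
        ex.lower_bound, ex.upper_bound = -10.0, 0.0
        conv = CReaction("CONV")
        conv.add_metabolites({g: -1.0, p: 2.0})
        conv.lower_bound, conv.upper_bound = 0.0, 1000.0
        bm = CReaction("BIOMASS_toy")
        bm.add_metabolites({p: -1.0})
        bm.lower_bound, bm.upper_bound = 0.0, 1000.0
        cmodel.add_reactions([ex, conv, bm])
        cmodel.objective = "BIOMASS_toy"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cmodel, str(path))

        from catapot.fba import read_sbml

        model = read_sbml(path)
        assert model.biomass_reaction_id == "BIOMASS_toy"
        assert "glc_e" in model.exchange_reactions
        sol = maximize_biomass(model, Medium({"glc_e": 10.0}))
        assert sol.biomass_flux == pytest.approx(20.0, abs=1e-6)
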