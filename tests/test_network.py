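import numpy as np
import pytest

from p53combo.network import (
    MissingParameterError,
    NORMAL,
    PTEN_CANCER,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SchemaError,
    Species,
    WIP1_CANCER,
    build_network,
    default_parameters,
    deterministic_rates,
    stochastic_propensities,
)


class TestBuildAndValidation:
    def test_nominal_transcription_rates(self, network):
        assert network.params["s1"] == pytest.approx(0.1)
        assert network.params["s2"] == pytest.approx(0.03)

    def test_missing_parameter_names_the_constant(self):
        params = dict(default_parameters())
        params.pop("k_pten")
        with pytest.raises(MissingParameterError, match="k_pten"):
            build_network(ParameterSet(params))

    def test_dangling_species_reference_is_schema_error(self):
        sp = [Species("A", "protein", 1.0)]
        rx = [Reaction("r", (("A", 1),), (("B", 1),), "k")]
        with pytest.raises(SchemaError, match="unknown species 'B'"):
            ReactionNetwork(sp, rx, ParameterSet({"k": 1.0}))

    def test_duplicate_species_rejected(self):
        sp = [Species("A", "protein"), Species("A", "mRNA")]
        with pytest.raises(SchemaError, match="duplicate"):
            ReactionNetwork(sp, [], ParameterSet({}))

    def test_parameters_must_be_finite_nonnegative(self):
        with pytest.raises(ValueError):
            ParameterSet({"k": -1.0})
        with pytest.raises(ValueError):
            ParameterSet({"k": float("inf")})

    def test_tsv_round_trip_identity(self, network):
        text = network.to_tsv()
        back = ReactionNetwork.from_tsv(text)
        assert back.species == network.species
        assert back.reactions == network.reactions
        assert dict(back.params) == dict(network.params)
        c1, c2 = network.compile(), back.compile()
        assert np.array_equal(c1.stoich, c2.stoich)
        assert np.allclose(c1.k, c2.k)
        assert np.allclose(c1.reg_K, c2.reg_K)


class TestPhenotypes:
    def test_wip1_cancer_is_fivefold_s1(self, network):
        net = network.apply_phenotype(WIP1_CANCER)
        assert net.params["s1"] == pytest.approx(0.5)
        assert net.params["s2"] == pytest.approx(0.03)

    def test_pten_cancer_is_fivefold_reduced_s2(self, network):
        net = network.apply_phenotype(PTEN_CANCER)
        assert net.params["s2"] == pytest.approx(0.006)
        assert net.params["s1"] == pytest.approx(0.1)

    def test_normal_phenotype_is_identity(self, network):
        net = network.apply_phenotype(NORMAL)
        assert dict(net.params) == dict(network.params)

    def test_original_network_untouched(self, network):
        s1 = network.params["s1"]
        network.apply_phenotype(WIP1_CANCER)
        assert network.params["s1"] == s1

    def test_phenotype_is_invertible(self, network):
        net = network.apply_phenotype(WIP1_CANCER)
        restored = net.with_params(s1=net.params["s1"] / 5.0)
        assert dict(restored.params) == dict(network.params)

    def test_uptake_specificity_divides_ka(self, network):
        from p53combo.network import CellPhenotype

        net = network.apply_phenotype(
            CellPhenotype("normal", uptake_specificity=10.0))
        assert net.params["k_a"] == pytest.approx(network.params["k_a"] / 10)

    def test_invalid_multipliers_rejected(self):
        from p53combo.network import CellPhenotype

        with pytest.raises(ValueError):
            CellPhenotype("custom", s1_multiplier=0.0)
        with pytest.raises(ValueError):
            CellPhenotype("normal", s1_multiplier=2.0)


class TestRateLaws:
    def test_zero_state_only_ungated_synthesis_positive(self, network,
                                                        compiled):
        """At the all-zero state every degradation/conversion flux vanishes;
        only constitutive p53 synthesis remains (HIPK2 synthesis is gated by
        damage, transcription by promoter state, infusion is off)."""
        flux = deterministic_rates(network, np.zeros(compiled.n_species))
        names = [r.name for r in network.reactions]
        positive = {names[j] for j in np.nonzero(flux > 0)[0]}
        assert positive == {"p53_synth"}

    def test_flux_matches_hand_coded_rate_laws(self, network, compiled):
        """Independent oracle: three rate laws evaluated from their formulas."""
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 5000, compiled.n_species)
        p = network.params
        flux = deterministic_rates(network, y)
        names = [r.name for r in network.reactions]
        i = compiled.index
        # mass action with two species: Mdm2-mediated p53 degradation
        j = names.index("p53_deg_mdm2")
        assert flux[j] == pytest.approx(
            p["d_p53_mdm2"] * y[i["p53"]] * y[i["Mdm2_nuc"]])
        # regulator 'pow': phosphorylation scaled by active-ATM fraction
        j = names.index("p53_phos1")
        assert flux[j] == pytest.approx(
            p["k_ph1"] * y[i["p53"]] * (y[i["ATMa"]] / 1.0e4))
        # regulator 'hill': saturating DNA repair (no mass-action part)
        j = names.index("dsb_repair")
        d = y[i["DSB"]]
        assert flux[j] == pytest.approx(
            p["rep_vmax"] * d / (p["rep_km"] + d))

    def test_mass_action_linearity(self, network, compiled):
        rng = np.random.default_rng(1)
        y = rng.uniform(10, 1000, compiled.n_species)
        y2 = y.copy()
        y2[compiled.index["Wip1_mRNA"]] *= 2
        names = [r.name for r in network.reactions]
        j = names.index("wip1_transl")
        f1 = deterministic_rates(network, y)[j]
        f2 = deterministic_rates(network, y2)[j]
        assert f2 == pytest.approx(2 * f1)

    def test_negative_state_rejected(self, network, compiled):
        y = np.zeros(compiled.n_species)
        y[0] = -1
        with pytest.raises(ValueError):
            deterministic_rates(network, y)

    def test_fluxes_finite_nonnegative_on_random_states(self, network,
                                                        compiled):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.uniform(0, 1e5, compiled.n_species)
            flux = deterministic_rates(network, y)
            assert np.all(np.isfinite(flux))
            assert np.all(flux >= 0)

    def test_phosphoform_interconversion_conserves_p53(self, network,
                                                       compiled):
        """Reactions that only interconvert p53 forms must have zero net
        p53 stoichiometry."""
        forms = [compiled.index[s] for s in
                 ("p53", "p53_arrester", "p53_killer")]
        for j, rxn in enumerate(network.reactions):
            if "phos" in rxn.name and "p53" in rxn.name:
                assert compiled.stoich[j][forms].sum() == 0


class TestPropensities:
    def test_empty_reactant_gives_zero_propensity(self, network, compiled):
        y = np.zeros(compiled.n_species)
        prop = stochastic_propensities(network, y)
        for j, rxn in enumerate(network.reactions):
            for sp, _ in rxn.reactants:
                if y[compiled.index[sp]] == 0:
                    assert prop[j] == 0.0

    def test_dimerization_combinatorics(self):
        sp = [Species("A", "protein", 1.0, scalable=False)]
        rx = [Reaction("dimer", (("A", 2),), (), "k")]
        net = ReactionNetwork(sp, rx, ParameterSet({"k": 1.0}))
        assert stochastic_propensities(net, np.array([1.0]))[0] == 0.0
        assert stochastic_propensities(net, np.array([3.0]))[0] == pytest.approx(6.0)

    def test_non_integer_copy_number_rejected(self, network, compiled):
        y = np.zeros(compiled.n_species)
        y[compiled.index["p53"]] = 1.5
        with pytest.raises(ValueError, match="non-integer"):
            stochastic_propensities(network, y)

    def test_propensity_approaches_flux_at_large_copy_number(self):
        """Law-of-large-numbers check on a conversion fixture."""
        sp = [Species("A", "protein", 0.0, scalable=False)]
        rx = [Reaction("decay", (("A", 1),), (), "k")]
        net = ReactionNetwork(sp, rx, ParameterSet({"k": 0.5}))
        for n in (10, 1000, 100000):
            y = np.array([float(n)])
            a = stochastic_propensities(net, y)[0]
            f = deterministic_rates(net, y)[0]
            assert abs(a - f) / f < 1e-12  # unary mass action: exact match
        # for a dimerization the relative gap shrinks like 1/N
        rx2 = [Reaction("dimer", (("A", 2),), (), "k")]
        net2 = ReactionNetwork(sp, rx2, ParameterSet({"k": 1.0}))
        gaps = []
        for n in (10, 100, 1000):
            y = np.array([float(n)])
            a = stochastic_propensities(net2, y)[0]
            f = deterministic_rates(net2, y)[0]
            gaps.append(abs(a - f) / f)
        assert gaps[0] > gaps[1] > gaps[2]

    def test_jitted_kernels_match_reference(self, network, compiled):
        """The numba twins must agree with the pure-python evaluators."""
        from p53combo import _kernels
        from p53combo.deterministic import _sparse_stoich

        rng = np.random.default_rng(3)
        y = np.floor(rng.uniform(0, 2000, compiled.n_species))
        ref_flux = deterministic_rates(network, y)
        out = np.empty(compiled.n_reactions)
        _kernels.flux_vector(y, compiled.k, compiled.ma_idx, compiled.reg_idx,
                             compiled.reg_kind, compiled.reg_K,
                             compiled.reg_n, out)
        np.testing.assert_allclose(out, ref_flux, rtol=1e-12)
        ref_prop = stochastic_propensities(network, y)
        discrete = np.ones(compiled.n_species, dtype=bool)
        _kernels.propensity_vector(y, compiled.k, compiled.ma_idx,
                                   compiled.reg_idx, compiled.reg_kind,
                                   compiled.reg_K, compiled.reg_n,
                                   discrete, out)
        np.testing.assert_allclose(out, ref_prop, rtol=1e-12)
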