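"""Descriptor families: pharmacophore typing, CATS2D, atom pairs,
Moran autocorrelation, 3D-MoRSE, pre-filtering and normalization."""

import numpy as np
import pandas as pd
import pytest

from redoxsar import (
    CorrelationFilter,
    DescriptorCalculator,
    DescriptorSpec,
    MinMaxNormalizer,
    assign_ppp_types,
    atom_pair_presence,
    build_graph,
    cats2d,
    embed_conformer,
    moran_autocorrelation,
    morse_descriptor,
    normalize,
    prefilter_correlated,
)
from redoxsar.dataset import Conformer
from redoxsar.descriptors import default_grid, final_model_specs


class TestSpecs:
    @pytest.mark.parametrize(
        "name",
        ["MATS4v", "Mor10u", "CATS2D_01_DN", "B04[C-Cl]", "B08[C-O]"],
    )
    def test_names_round_trip(self, name):
        assert DescriptorSpec.from_name(name).name == name

    def test_final_model_names(self):
        assert [s.name for s in final_model_specs()] == [
            "MATS4v", "Mor10u", "CATS2D_01_DN", "B04[C-Cl]", "B08[C-O]",
        ]

    def test_default_grid_has_several_hundred_unique_columns(self):
        names = [s.name for s in default_grid()]
        assert len(names) == len(set(names))
        # 8*4 MATS + 32*2 MoRSE + 15*10 CATS2D + 21*10 B0k
        assert len(names) == 32 + 64 + 150 + 210


class TestPharmacophoreTyping:
    def test_benzoic_acid_donor_negative_pair_at_distance_1(self):
        g = build_graph("OC(=O)c1ccccc1")
        types = assign_ppp_types(g)
        donors = [i for i, t in enumerate(types) if "D" in t]
        negatives = [i for i, t in enumerate(types) if "N" in t]
        assert [g.elements[i] for i in donors] == ["O"]  # the hydroxyl O
        assert [g.elements[i] for i in negatives] == ["C"]  # the carboxyl C
        assert g.dist[donors[0], negatives[0]] == 1
        assert cats2d(g, 1, ("D", "N")) == 1

    def test_phenol_has_one_donor_and_no_negative_center(self):
        g = build_graph("Oc1ccccc1")
        types = assign_ppp_types(g)
        assert sum("D" in t for t in types) == 1
        assert not any("N" in t for t in types)
        assert cats2d(g, 1, ("D", "N")) == 0

    def test_single_carbon_is_lipophilic_only(self):
        g = build_graph("C")
        types = assign_ppp_types(g)
        assert types[0] == frozenset({"L"})

    def test_sulfonic_acid_center_typed_negative(self):
        g = build_graph("Nc1ccc(cc1)S(O)(=O)=O")
        types = assign_ppp_types(g)
        s = g.atoms_of("S")[0]
        assert "N" in types[s]
        assert cats2d(g, 1, ("D", "N")) >= 1

    def test_basic_amine_positive_but_amide_and_aniline_not(self):
        g = build_graph("CN(C)CC(c1ccc(O)cc1)C1(O)CCCCC1")  # tertiary amine
        types = assign_ppp_types(g)
        assert any("P" in t for t in types)
        for smiles in ("CC(=O)Nc1ccccc1", "Nc1ccccc1"):  # amide N, aniline N
            g = build_graph(smiles)
            types = assign_ppp_types(g)
            assert not any("P" in t for t in types)


class TestCats2d:
    def test_lag0_counts_atoms_carrying_both_types(self):
        g = build_graph("OC(=O)c1ccccc1O")  # salicylic acid: 2 D-typed O
        assert cats2d(g, 0, ("D", "D")) == 2
        # the hydroxyl oxygens are both D and A
        assert cats2d(g, 0, ("D", "A")) == 2

    def test_symmetric_in_type_pair(self, compounds):
        for c in compounds[:8]:
            g = build_graph(c.smiles)
            types = assign_ppp_types(g)
            for lag in (1, 3):
                assert cats2d(g, lag, ("D", "N"), types) == cats2d(g, lag, ("N", "D"), types)

    def test_lag_out_of_range(self):
        g = build_graph("CC")
        with pytest.raises(ValueError):
            cats2d(g, 10, ("D", "N"))

    def test_carboxylic_fixture_compounds_have_donor_negative_pair(self, compounds):
        """-COOH (and the sulfonic analog) gives CATS2D_01_DN >= 1; compounds
        without acidic groups or charges give 0."""
        acids = {"BenzAc", "o-aminoBenzAc", "SalAc", "IBP", "DCF", "ETD", "CIP", "AMX", "SA"}
        for c in compounds:
            g = build_graph(c.smiles)
            count = cats2d(g, 1, ("D", "N"))
            if c.abbr in acids:
                assert count >= 1, c.abbr
            else:
                assert count == 0, c.abbr


class TestAtomPairs:
    def test_atrazine_B04_CCl_absent(self):
        g = build_graph("CCNc1nc(Cl)nc(NC(C)C)n1")
        assert atom_pair_presence(g, "C", "Cl", 4) == 0

    def test_dichlorophenol_B04_CCl_present(self):
        g = build_graph("Oc1ccc(Cl)cc1Cl")  # C5 sits 4 bonds from the 2-Cl
        assert atom_pair_presence(g, "C", "Cl", 4) == 1

    def test_phenol_B08_CO_absent(self):
        g = build_graph("Oc1ccccc1")
        assert atom_pair_presence(g, "C", "O", 8) == 0
        assert max(g.pair_distances("C", "O")) == 4

    def test_symmetric_in_elements(self, compounds):
        for c in compounds[:10]:
            g = build_graph(c.smiles)
            for k in (2, 4, 8):
                assert atom_pair_presence(g, "C", "O", k) == atom_pair_presence(g, "O", "C", k)

    def test_distance_out_of_range(self):
        g = build_graph("CC")
        with pytest.raises(ValueError):
            atom_pair_presence(g, "C", "C", 0)


class TestMoran:
    def test_two_atom_closed_form_is_minus_one(self):
        # two atoms with distinct weights: centered products give -c^2/c^2
        g = build_graph("CO")
        assert moran_autocorrelation(g, 1, "v", include_hydrogens=False) == pytest.approx(-1.0)
        assert moran_autocorrelation(
            g, 1, np.array([1.0, 5.0]), include_hydrogens=False
        ) == pytest.approx(-1.0)

    def test_equal_weights_give_zero(self):
        g = build_graph("CCCC")
        assert moran_autocorrelation(g, 1, "u") == 0.0
        assert moran_autocorrelation(g, 2, np.full(4, 2.5), include_hydrogens=False) == 0.0

    def test_empty_lag_gives_zero(self):
        g = build_graph("CCCO")  # heavy-atom 4-chain: max distance 3
        assert moran_autocorrelation(g, 4, "v", include_hydrogens=False) == 0.0

    def test_affine_invariance_of_weights(self, compounds):
        """MATS is unchanged by w -> a*w + b, so the carbon-scaling
        convention cannot alter Moran values."""
        rng = np.random.default_rng(42)
        for c in compounds[:10]:
            g = build_graph(c.smiles)
            w = rng.uniform(0.5, 3.0, g.n_atoms)
            base = moran_autocorrelation(g, 3, w, include_hydrogens=False)
            shifted = moran_autocorrelation(g, 3, 2.7 * w - 1.3, include_hydrogens=False)
            assert shifted == pytest.approx(base, rel=1e-10, abs=1e-12)

    def test_invariant_to_atom_reordering(self):
        # same molecule written with different atom orders
        a = build_graph("OC(=O)c1ccccc1O")
        b = build_graph("c1ccc(O)c(c1)C(O)=O")
        for k in (1, 2, 3, 4):
            assert moran_autocorrelation(a, k, "v") == pytest.approx(
                moran_autocorrelation(b, k, "v"), rel=1e-12
            )


class TestMorse:
    def test_signal_1_unweighted_is_pair_count(self):
        conf = embed_conformer("CCO", seed=3)
        n = conf.n_atoms
        assert morse_descriptor(conf, 1, "u") == pytest.approx(n * (n - 1) / 2)

    def test_two_atoms_at_pi_over_9_gives_zero_at_signal_10(self):
        conf = Conformer(
            elements=["C", "C"],
            coordinates=np.array([[0.0, 0.0, 0.0], [np.pi / 9, 0.0, 0.0]]),
            seed=0,
        )
        assert morse_descriptor(conf, 10, "u") == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        conf = embed_conformer("CC(C)Cc1ccc(cc1)C(C)C(=O)O", seed=5)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = Conformer(
            elements=conf.elements,
            coordinates=conf.coordinates @ rot.T + np.array([1.0, -2.0, 3.0]),
            seed=0,
        )
        assert morse_descriptor(moved, 10, "u") == pytest.approx(
            morse_descriptor(conf, 10, "u"), abs=1e-9
        )

    def test_coincident_atoms_rejected(self):
        conf = Conformer(["C", "C"], np.zeros((2, 3)), seed=0)
        with pytest.raises(ValueError):
            morse_descriptor(conf, 10, "u")


class TestMatrixPipeline:
    def test_final_model_matrix_is_dense_and_deterministic(self, compounds, model5_matrix):
        assert model5_matrix.shape == (30, 5)
        assert not model5_matrix.isna().any().any()
        again = DescriptorCalculator(specs="final-model", seed=7).fit().transform(compounds)
        pd.testing.assert_frame_equal(model5_matrix, again)

    def test_2d_descriptors_invariant_to_smiles_atom_order(self):
        specs = [DescriptorSpec.from_name(n) for n in ("MATS4v", "CATS2D_01_DN", "B04[C-Cl]")]
        from redoxsar import compute_matrix

        a = compute_matrix([("x", "Oc1ccc(Cl)cc1Cl")], specs)
        b = compute_matrix([("x", "Clc1cc(Cl)c(O)cc1")], specs)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_failure_carries_compound_id(self):
        from redoxsar import compute_matrix

        with pytest.raises(RuntimeError, match="badmol"):
            compute_matrix([("badmol", "C(")], final_model_specs())


class TestPrefilter:
    def test_duplicate_column_removed_original_kept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=20)
        reduced, log = prefilter_correlated(X)
        assert list(reduced.columns) == ["a", "c"]
        assert ("b", "a", pytest.approx(1.0)) in [(d, p, r) for d, p, r in log]

    def test_moderate_correlation_kept(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": b})
        reduced, log = prefilter_correlated(X)
        assert list(reduced.columns) == ["a", "b"]
        assert log == []

    def test_planted_collinear_pairs_all_removed(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(25, 16)), columns=[f"x{i}" for i in range(16)])
        for j in range(4):  # plant 4 exact collinear partners
            X[f"dup{j}"] = 2.0 * X[f"x{j}"] + 1.0
        reduced, log = prefilter_correlated(X)
        assert len(log) == 4
        assert reduced.shape[1] == 16

    def test_constant_columns_dropped_first(self):
        X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0)})
        reduced, log = prefilter_correlated(X)
        assert list(reduced.columns) == ["a"]
        assert log[0][0] == "const" and log[0][1] is None

    def test_filter_estimator_transform_matches_function(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        X["f"] = X["a"]
        filt = CorrelationFilter().fit(X)
        pd.testing.assert_frame_equal(filt.transform(X), prefilter_correlated(X)[0])


class TestNormalize:
    def test_training_columns_span_unit_interval_test_rows_may_exceed(self):
        X = pd.DataFrame({"a": [2.0, 3.0, 4.0, 5.0]}, index=list("wxyz"))
        Xn, scaler = normalize(X, ["w", "x", "y"])  # train range [2, 4]
        assert Xn.loc["w", "a"] == 0.0
        assert Xn.loc["y", "a"] == 1.0
        assert Xn.loc["z", "a"] == pytest.approx(1.5)

    def test_binary_column_unchanged(self):
        X = pd.DataFrame({"b": [0.0, 1.0, 0.0, 1.0]}, index=list("wxyz"))
        Xn, _ = normalize(X, list("wxyz"))
        assert np.array_equal(Xn["b"].to_numpy(), X["b"].to_numpy())

    def test_constant_training_column_maps_to_zero(self):
        X = pd.DataFrame({"c": [5.0, 5.0, 5.0, 7.0]}, index=list("wxyz"))
        Xn, _ = normalize(X, ["w", "x", "y"])
        assert np.all(Xn.loc[list("wxy"), "c"] == 0.0)

    def test_round_trip_identity(self, model5_matrix, train_ids):
        Xn, scaler = normalize(model5_matrix, train_ids)
        back = scaler.inverse_transform(Xn)
        assert np.allclose(back.to_numpy(), model5_matrix.to_numpy(), atol=1e-12)

    def test_scaler_serialization_round_trip(self, model5_matrix, train_ids):
        _, scaler = normalize(model5_matrix, train_ids)
        clone = MinMaxNormalizer.from_dict(scaler.to_dict())
        a = scaler.transform(model5_matrix)
        b = clone.transform(model5_matrix)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)
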