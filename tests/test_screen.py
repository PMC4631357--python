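"""Mutant enumeration, epistasis arithmetic, pair classification, exports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtlogic.screen import (
    GenePairProfile,
    MutationSpec,
    ScreenConfig,
    classify_pair,
    compute_epistasis,
    enumerate_mutants,
    interaction_network,
    mutant_clamps,
    mutant_label,
    mutant_landscape_coordinates,
    run_screen,
    write_sif,
)
from emtlogic.simulate import SimulationConfig


class TestEnumerateMutants:
    def test_two_gene_combinatorics(self, model):
        muts = enumerate_mutants(model, ["NICD", "p53"])
        singles = [m for m in muts if len(m) == 1]
        doubles = [m for m in muts if len(m) == 2]
        assert len(singles) == 4 and len(doubles) == 4

    def test_full_default_set(self, model):
        muts = enumerate_mutants(model)
        assert sum(1 for m in muts if len(m) == 1) == 52
        assert sum(1 for m in muts if len(m) == 2) == 1300
        assert len(set(muts)) == len(muts)

    def test_notch_p53_pair_appears_once(self, model):
        target = (MutationSpec("NICD", "GoF"), MutationSpec("p53", "LoF"))
        muts = enumerate_mutants(model, ["NICD", "p53"])
        assert muts.count(target) == 1

    def test_same_gene_twice_rejected(self):
        with pytest.raises(ValueError):
            mutant_clamps((MutationSpec("NICD", "GoF"), MutationSpec("NICD", "LoF")))

    def test_input_not_mutatable(self, model):
        with pytest.raises(ValueError):
            enumerate_mutants(model, ["ECMicroenv"])


class TestEpistasis:
    @pytest.mark.parametrize(
        "p1, p2, p12, expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.0, 0.0, 1.0, -1.0),
            (0.2, 0.3, 0.9, pytest.approx(-0.46)),
        ],
    )
    def test_worked_examples(self, p1, p2, p12, expected):
        assert compute_epistasis(p1, p2, p12) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_symmetric_and_bounded(self, p1, p2, p12):
        eps = compute_epistasis(p1, p2, p12)
        assert eps == compute_epistasis(p2, p1, p12)
        assert -1.0 <= eps <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_multiplicative_null_gives_zero(self, p1, p2):
        p12 = 1.0 - (1.0 - p1) * (1.0 - p2)
        assert compute_epistasis(p1, p2, p12) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, 0, 0), (0, 1.2, 0), (0, 0, 2)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_epistasis(*bad)


class TestClassifyPair:
    def test_synthetic_dosage_extreme_is_cluster_3(self):
        prof = GenePairProfile("p53", "NICD", 0.0, 1.0, 0.0, 0.0)
        assert classify_pair(prof) == "3"

    def test_flat_profile_is_other(self):
        prof = GenePairProfile("a", "b", 0.4, 0.4, 0.4, 0.4)
        assert prof.amplitude == 0.0
        assert classify_pair(prof) == "other"

    def test_double_gof_cancel_is_cluster_2a(self):
        prof = GenePairProfile("a", "b", 0.9, 0.5, 0.5, 0.0)
        assert classify_pair(prof) == "2a"

    def test_any_gof_cancel_is_cluster_1a(self):
        prof = GenePairProfile("a", "b", 0.8, 0.0, 0.0, 0.0)
        assert classify_pair(prof) == "1a"

    def test_each_pair_has_exactly_one_cluster(self):
        grid = [0.0, 0.5, 1.0]
        for four in itertools.product(grid, repeat=4):
            cluster = classify_pair(GenePairProfile("a", "b", *four))
            assert cluster in {"1a", "1b", "2a", "2b", "3", "other"}


@pytest.fixture(scope="module")
def result(model):
    cfg = ScreenConfig(
        simulation=SimulationConfig(n_trajectories=100, max_time=20.0, seed=0)
    )
    return run_screen(model, genes=["NICD", "p53", "AKT2", "ERK"], config=cfg)


class TestSmallScreen:
    def test_notch_p53_full_penetrance_and_synergy(self, result):
        table = result.mutant_table.set_index("mutant")
        assert table.loc["NICD+/p53-", "reaches_one"]
        rec = next(
            r for r in result.records
            if {r.mutant_a.label, r.mutant_b.label} == {"NICD+", "p53-"}
        )
        assert rec.p12 == 1.0 and rec.epsilon < 0

    def test_screen_reproducible_under_fixed_seed(self, model, result):
        cfg = ScreenConfig(
            simulation=SimulationConfig(n_trajectories=100, max_time=20.0, seed=0)
        )
        again = run_screen(model, genes=["NICD", "p53", "AKT2", "ERK"], config=cfg)
        pd.testing.assert_frame_equal(
            again.mutant_table.drop(columns="mutant_obj"),
            result.mutant_table.drop(columns="mutant_obj"),
        )

    def test_all_pairs_and_directions_scored(self, result):
        assert len(result.records) == 4 * 6  # C(4,2) pairs x 4 direction combos

    def test_network_export(self, result, tmp_path):
        g = interaction_network(result.records, result.config)
        for a, b, data in g.edges(data=True):
            eps = data["epsilon"]
            assert eps <= result.config.synergy_threshold or eps >= result.config.alleviation_threshold
        write_sif(g, tmp_path / "net.sif")
        lines = (tmp_path / "net.sif").read_text().splitlines()
        assert len([l for l in lines if "\t" in l]) == g.number_of_edges()

    def test_single_significant_record_gives_one_edge(self):
        from emtlogic.screen import EpistasisRecord

        rec = EpistasisRecord(
            MutationSpec("a", "GoF"), MutationSpec("b", "LoF"), 0.2, 0.3, 1.0
        )
        assert rec.epsilon == pytest.approx(-0.56)
        g = interaction_network([rec])
        assert g.number_of_edges() == 1
        assert g["a+"]["b-"]["weight"] == pytest.approx(0.56)


class TestLandscape:
    def test_identical_vectors_identical_coordinates(self):
        df = pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5], [0.1, 0.9], [0.9, 0.1]],
            index=["m1", "m2", "m3", "m4"],
            columns=["none", "Metastasis"],
        )
        coords = mutant_landscape_coordinates(df, min_prevalence=0.0)
        assert np.allclose(coords.loc["m1"], coords.loc["m2"])

    def test_three_point_embedding_matches_closed_form(self):
        df = pd.DataFrame(
            [[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]],
            index=["a", "b", "c"],
            columns=["x", "y"],
        )
        coords = mutant_landscape_coordinates(df, min_prevalence=0.0)
        # points are colinear along (1,-1)/sqrt(2); closed-form projections
        expected = np.array([-np.sqrt(2) / 2, np.sqrt(2) / 2, 0.0])
        got = coords["PC1"].to_numpy()
        assert np.allclose(sorted(got), sorted(expected), atol=1e-9)
        assert np.allclose(coords["PC2"], 0.0, atol=1e-9)

    def test_low_prevalence_columns_dropped(self):
        df = pd.DataFrame(
            {"common": [0.4, 0.6, 0.5], "rare": [0.001, 0.002, 0.0]},
            index=["a", "b", "c"],
        )
        coords = mutant_landscape_coordinates(df, min_prevalence=0.01)
        assert list(coords.columns) == ["PC1", "PC2"]

    def test_too_few_mutants(self):
        with pytest.raises(ValueError):
            mutant_landscape_coordinates(pd.DataFrame([[1.0]], index=["a"]))
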