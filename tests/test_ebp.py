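"""Expression-to-stable-state matching: mapping, binarization, EBP scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtlogic.ebp import (
    average_replicates,
    binarize,
    ebp_pipeline,
    ebp_score,
    map_genes_to_model,
    similarity_matrix,
)
from emtlogic.synth import default_timecourse_spec, generate_timecourse


def frame(rows: dict, columns):
    return pd.DataFrame(rows, index=columns).T


class TestMapping:
    def test_direct_alias_and_biomarker_mapping(self, model):
        expr = frame(
            {"CDH1": [1.0], "CDH2": [2.0], "CASP9": [3.0], "JUNK": [4.0]}, ["T0:1"]
        )
        mapped = map_genes_to_model(expr, model)
        assert set(mapped.index) == {"CDH1", "CDH2", "Apoptosis"}

    def test_vim_maps_to_vim_node(self, model):
        mapped = map_genes_to_model(frame({"VIM": [1.0]}, ["T0:1"]), model)
        assert list(mapped.index) == ["VIM"]

    def test_growth_factor_and_erk_proxies(self, model):
        mapped = map_genes_to_model(frame({"EGFR": [1.0], "MAPK1": [2.0]}, ["T0:1"]), model)
        assert set(mapped.index) == {"GF", "ERK"}

    def test_override_wins(self, model):
        mapped = map_genes_to_model(
            frame({"EGFR": [1.0]}, ["T0:1"]), model, overrides={"EGFR": "ERK"}
        )
        assert list(mapped.index) == ["ERK"]

    def test_empty_intersection_is_an_error(self, model):
        with pytest.raises(ValueError):
            map_genes_to_model(frame({"NOPE": [1.0]}, ["T0:1"]), model)


class TestAverageReplicates:
    def test_mean_of_three(self):
        expr = frame({"g": [1.0, 2.0, 3.0]}, ["T0:1", "T0:2", "T0:3"])
        out = average_replicates(expr)
        assert out.loc["g", "T0"] == 2.0

    def test_single_replicate_identity(self):
        expr = frame({"g": [5.0]}, ["T8:1"])
        assert average_replicates(expr).loc["g", "T8"] == 5.0

    def test_unequal_replicates_mean_over_available(self):
        expr = frame({"g": [1.0, 3.0, 10.0]}, ["T0:1", "T0:2", "T8:1"])
        out = average_replicates(expr)
        assert out.loc["g", "T0"] == 2.0 and out.loc["g", "T8"] == 10.0

    def test_timepoint_order_preserved(self):
        expr = frame({"g": [0, 1, 2, 3]}, ["T0:1", "T8:1", "T24:1", "T72:1"])
        assert list(average_replicates(expr).columns) == ["T0", "T8", "T24", "T72"]


class TestBinarize:
    def test_two_means_worked_example(self):
        expr = frame({"g": [1.0, 1.0, 9.0, 9.0]}, ["T0", "T8", "T24", "T72"])
        prof = binarize(expr)
        assert list(prof.bits.loc["g"]) == [0, 0, 1, 1]
        assert prof.thresholds["g"] == 5.0
        assert prof.flags["g"] == "dynamic"

    def test_constant_gene_flagged_not_errored(self):
        expr = frame(
            {"hi": [8.0, 8.0, 8.0, 8.0], "lo": [1.0, 1.0, 1.0, 1.0]},
            ["T0", "T8", "T24", "T72"],
        )
        prof = binarize(expr)
        assert prof.flags["hi"] == "always-ON"
        assert prof.flags["lo"] == "always-OFF"
        assert set(prof.bits.loc["hi"]) == {1}

    def test_planted_dynamic_genes_recovered(self, model):
        expr, truth = generate_timecourse(default_timecourse_spec(seed=3))
        mapped = map_genes_to_model(expr, model)
        prof = binarize(average_replicates(mapped))
        # the 11 induced/repressed genes, under their model-node names
        expected = {"CDH1", "CDH2", "CTNNB1", "GF", "ERK", "Invasion",
                    "SMAD", "SNAI2", "TGFbeta", "VIM", "ZEB1"}
        assert set(prof.dynamic_genes()) == expected

    def test_quantile_method_monotone_invariance(self):
        base = frame({"g": [1.0, 2.0, 8.0, 9.0], "h": [9.0, 8.0, 2.0, 1.0]},
                     ["T0", "T8", "T24", "T72"])
        transformed = np.exp(base / 3.0)  # strictly monotone
        b1 = binarize(base, method="quantile")
        b2 = binarize(transformed, method="quantile", min_dynamic_range=0.5)
        pd.testing.assert_frame_equal(b1.bits, b2.bits)


class TestScoring:
    def test_similarity_rule(self, model, wildtype_states):
        bits = frame({"CDH1": [1, 0], "VIM": [0, 1]}, ["T0", "T72"])
        sim = similarity_matrix(bits, {"HS": wildtype_states["HS"], "M1": wildtype_states["M1"]})
        # HS: CDH1=1, VIM=0 -> matches at T0, not at T72
        assert sim["T0"].loc["CDH1", "HS"] == 1 and sim["T0"].loc["VIM", "HS"] == 1
        assert sim["T72"].loc["CDH1", "HS"] == 0 and sim["T72"].loc["VIM", "HS"] == 0
        assert sim["T72"].loc["CDH1", "M1"] == 1

    def test_perfect_match_and_complement(self, model, wildtype_states):
        nodes = [n for n in model.nodes if n not in model.inputs]
        m1 = wildtype_states["M1"]
        bits = pd.DataFrame({"match": [m1[n] for n in nodes],
                             "complement": [1 - m1[n] for n in nodes]},
                            index=nodes)
        sim = similarity_matrix(bits, wildtype_states)
        res = ebp_score(sim, wildtype_states)
        assert res.scores.loc["match", "M1"] == len(nodes)
        assert res.scores.loc["complement", "M1"] == 0
        assert "M1" in res.best["match"]
        # M2 differs from M1 only at the unmapped input, so it ties
        assert set(res.best["match"]) == {"M1", "M2"}

    def test_three_gene_toy_counts_agreements(self, model, wildtype_states):
        genes = ["CDH1", "VIM", "SNAI1"]
        m1 = wildtype_states["M1"]  # bits (0, 1, 1)
        bits = pd.DataFrame({"T0": [1, 1, 1]}, index=genes)
        sim = similarity_matrix(bits, {"M1": m1})
        assert int(sim["T0"]["M1"].sum()) == 2

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=5, max_size=5))
    def test_score_plus_complement_score_is_gene_count(self, model, wildtype_states, profile):
        genes = ["CDH1", "VIM", "SNAI1", "CDH2", "ZEB1"]
        bits = pd.DataFrame({"T0": profile}, index=genes)
        comp = pd.DataFrame({"T0": [1 - b for b in profile]}, index=genes)
        s = ebp_score(similarity_matrix(bits, wildtype_states), wildtype_states)
        c = ebp_score(similarity_matrix(comp, wildtype_states), wildtype_states)
        for col in s.scores.columns:
            assert s.scores.loc["T0", col] + c.scores.loc["T0", col] == len(genes)


class TestPipeline:
    @pytest.mark.parametrize("noise", [0.0, 0.3])
    def test_emt_induction_drifts_from_apoptotic_to_metastatic(
        self, model, wildtype_states, noise
    ):
        """The per-timepoint argmax phenotype moves monotonically from an
        apoptotic to a metastatic stable state as induction progresses."""
        expr, _ = generate_timecourse(default_timecourse_spec(noise_sd=noise, seed=11))
        res, _ = ebp_pipeline(expr, model, wildtype_states)
        rank = {"Apoptosis+CellCycleArrest": 0, "HS": 0, "EMT+CellCycleArrest": 1,
                "Metastasis": 2, "other": 1}
        ranks = [max(rank[p] for p in res.phenotypes[tp]) for tp in res.scores.index]
        assert ranks == sorted(ranks)
        assert "Apoptosis+CellCycleArrest" in res.phenotypes[res.scores.index[0]]
        assert res.phenotypes[res.scores.index[-1]] == ["Metastasis"] * len(
            res.best[res.scores.index[-1]]
        )

    def test_dynamic_only_restriction(self, model, wildtype_states):
        expr, _ = generate_timecourse(default_timecourse_spec(seed=2))
        res, prof = ebp_pipeline(expr, model, wildtype_states, dynamic_only=True)
        assert res.scores.to_numpy().max() <= len(prof.dynamic_genes())
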