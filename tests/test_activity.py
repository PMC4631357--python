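"""Module-activity scoring and differential-activity testing."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from emtlogic.activity import activity_scores, differential_activity, read_gmt, write_gmt
from emtlogic.library import ModuleDefinition, load_modules
from emtlogic.synth import CohortSpec, generate_cohort


def module(name, genes):
    return ModuleDefinition(name, tuple(genes), tuple(genes))


class TestActivityScores:
    def test_single_gene_module_is_centred_expression(self, rng):
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(1, 20)), index=["G1"],
            columns=[f"S{i}" for i in range(20)],
        )
        scores = activity_scores(expr, [module("m", ["G1"])])
        centred = expr.loc["G1"] - expr.loc["G1"].mean()
        assert np.allclose(scores.scores["m"].to_numpy(), centred.to_numpy())

    def test_perfectly_correlated_genes(self, rng):
        base = rng.normal(0, 1, size=30)
        expr = pd.DataFrame(
            [5 + base, 7 + base], index=["A", "B"],
            columns=[f"S{i}" for i in range(30)],
        )
        scores = activity_scores(expr, [module("m", ["A", "B"])])
        r = np.corrcoef(scores.scores["m"], base)[0, 1]
        assert r > 0.999999

    def test_two_gene_module_matches_eigendecomposition(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(2, 40)), index=["A", "B"],
            columns=[f"S{i}" for i in range(40)],
        )
        scores = activity_scores(expr, [module("m", ["A", "B"])])
        centred = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
        cov = np.cov(centred)
        w, v = np.linalg.eigh(cov)
        pc1 = centred.T @ v[:, np.argmax(w)]
        got = scores.scores["m"].to_numpy()
        r = np.corrcoef(got, pc1)[0, 1]
        assert abs(r) > 0.999999

    def test_shift_invariance_and_scale_equivariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(3, 25)), index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(25)],
        )
        mods = [module("m", ["A", "B", "C"])]
        s0 = activity_scores(expr, mods).scores["m"].to_numpy()
        shifted = expr.add(pd.Series({"A": 10.0, "B": -3.0, "C": 0.5}), axis=0)
        s1 = activity_scores(shifted, mods).scores["m"].to_numpy()
        assert np.allclose(s0, s1)
        s2 = activity_scores(expr * 2.5, mods).scores["m"].to_numpy()
        assert np.allclose(s2, 2.5 * s0)

    def test_orientation_follows_mean_expression(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(4, 30)), index=list("ABCD"),
            columns=[f"S{i}" for i in range(30)],
        )
        scores = activity_scores(expr, [module("m", list("ABCD"))])
        mean_centred = (expr - expr.mean(axis=1).to_numpy()[:, None]).mean(axis=0)
        assert np.dot(scores.scores["m"], mean_centred) >= 0

    def test_empty_module_skipped(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(1, 5)), index=["A"],
                            columns=list("vwxyz"))
        scores = activity_scores(expr, [module("m", ["A"]), module("ghost", ["Q"])])
        assert list(scores.scores.columns) == ["m"]


class TestDifferentialActivity:
    def test_planted_cohort_design_recovers_signs(self):
        """Emulated 88 vs 17 tumour cohort: AKT2 module planted up, miRNA
        module planted down in the metastatic group.  With only 17 samples in
        the metastatic group a single replicate can miss significance, so the
        check runs over repeated cohorts."""
        modules = load_modules()
        sign_ok = {"AKT2": 0, "miRNA": 0}
        significant = {"AKT2": 0, "miRNA": 0}
        n_rep = 12
        for seed in range(n_rep):
            spec = CohortSpec(effects={"AKT2": 1.0, "miRNA": -1.0}, seed=seed)
            expr, labels, _ = generate_cohort(spec, modules)
            res = differential_activity(activity_scores(expr, modules), labels)
            sign_ok["AKT2"] += int(res.loc["AKT2", "t"] > 0)
            sign_ok["miRNA"] += int(res.loc["miRNA", "t"] < 0)
            significant["AKT2"] += int(res.loc["AKT2", "significant"] and res.loc["AKT2", "t"] > 0)
            significant["miRNA"] += int(res.loc["miRNA", "significant"] and res.loc["miRNA", "t"] < 0)
        for mod in ("AKT2", "miRNA"):
            assert sign_ok[mod] >= n_rep - 2
            assert significant[mod] >= 0.75 * n_rep

    def test_power_above_090_for_one_sd_effect(self):
        """1 pooled-SD shift on a 10-gene module, n = 50 vs 50."""
        genes = [f"G{i}" for i in range(10)]
        mod = {"m": module("m", genes)}
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            spec = CohortSpec(n_group0=50, n_group1=50, effects={"m": 1.0},
                              n_background_genes=0, seed=seed)
            expr, labels, _ = generate_cohort(spec, mod)
            res = differential_activity(activity_scores(expr, mod), labels)
            hits += int(res.loc["m", "significant"])
        assert hits / n_sim > 0.9

    def test_null_module_p_values_uniform(self):
        """Pure-noise module: p-values across simulations are uniform."""
        genes = [f"G{i}" for i in range(8)]
        mod = {"m": module("m", genes)}
        pvals = []
        for seed in range(200):
            spec = CohortSpec(n_group0=20, n_group1=20, effects={},
                              n_background_genes=0, seed=seed)
            expr, labels, _ = generate_cohort(spec, mod)
            res = differential_activity(activity_scores(expr, mod), labels)
            pvals.append(res.loc["m", "p_value"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_label_permutation_mostly_non_significant(self, rng):
        modules = load_modules()
        spec = CohortSpec(effects={}, seed=9)
        expr, labels, _ = generate_cohort(spec, modules)
        scores = activity_scores(expr, modules)
        flags = []
        for _ in range(25):
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            res = differential_activity(scores, permuted)
            flags.extend(res["significant"].tolist())
        assert np.mean(flags) < 0.10  # nominal 5% false-positive rate

    def test_group_size_guard(self):
        scores = pd.DataFrame({"m": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            differential_activity(scores, pd.Series({"a": "M0", "b": "M0", "c": "M1"}))


class TestGMT:
    def test_round_trip(self, tmp_path):
        mods = {"setA": module("setA", ["G1", "G2"]), "setB": module("setB", ["G3"])}
        path = tmp_path / "sets.gmt"
        write_gmt(mods, path)
        again = read_gmt(path)
        assert {k: v.target_genes for k, v in again.items()} == {
            "setA": ("G1", "G2"), "setB": ("G3",)
        }
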