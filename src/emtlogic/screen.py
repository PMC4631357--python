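"""Systematic single/double mutant screen, epistasis scores, gene-pair
classification and interaction-network export.

Mutants are clamp sets (GoF = ON, LoF = OFF) over a configurable gene
allowlist (default: every non-input, non-output node).  For each mutant the
screen estimates endpoint phenotype probabilities by continuous-time
simulation; for every gene pair and every direction combination it computes
the epistasis score on the event of *not* reaching metastasis,

    epsilon = (1 - p12) - (1 - p1) (1 - p2),

negative for synergy, positive for alleviation/masking.  A mutant "reaches
100% metastasis" when its estimated probability clears a near-one threshold
*and* every stable state of the clamped model is metastatic (an exact
confirmation that turns the stochastic claim into a checkable one; slowly
absorbing mutants whose probability has not converged by the simulation
horizon, and mutants trapped in cyclic attractors, do not qualify).

The screen's default study conditions start every trajectory from a resting
state (all non-input nodes OFF, environment inputs random) and read
endpoints at a horizon of 20 time units with all rates 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .library import PHENOTYPE_NODES, default_mutatable_genes
from .model import BooleanModel
from .simulate import SimulationConfig, exact_phenotype_probabilities, simulate_endpoints

logger = logging.getLogger(__name__)

__all__ = [
    "MutationSpec",
    "EpistasisRecord",
    "GenePairProfile",
    "ScreenConfig",
    "ScreenResult",
    "enumerate_mutants",
    "compute_epistasis",
    "run_screen",
    "classify_pair",
    "interaction_network",
    "write_sif",
    "mutant_landscape_coordinates",
]

_DIRECTIONS = ("LoF", "GoF")


@dataclass(frozen=True)
class MutationSpec:
    gene: str
    direction: str  # "GoF" -> clamp 1, "LoF" -> clamp 0

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError("direction must be 'GoF' or 'LoF'")

    @property
    def value(self) -> int:
        return 1 if self.direction == "GoF" else 0

    @property
    def label(self) -> str:
        return f"{self.gene}{'+' if self.direction == 'GoF' else '-'}"


Mutant = tuple[MutationSpec, ...]


def mutant_label(mutant: Mutant) -> str:
    return "/".join(m.label for m in mutant) if mutant else "WT"


def mutant_clamps(mutant: Mutant) -> dict[str, int]:
    clamps: dict[str, int] = {}
    for m in mutant:
        if m.gene in clamps:
            raise ValueError(f"mutant clamps gene {m.gene!r} twice")
        clamps[m.gene] = m.value
    return clamps


@dataclass(frozen=True)
class EpistasisRecord:
    mutant_a: MutationSpec
    mutant_b: MutationSpec
    p1: float
    p2: float
    p12: float

    @property
    def epsilon(self) -> float:
        return compute_epistasis(self.p1, self.p2, self.p12)


@dataclass(frozen=True)
class GenePairProfile:
    """The four double-mutant phenotype probabilities of one gene pair."""

    gene_a: str
    gene_b: str
    p_lof_lof: float
    p_lof_gof: float
    p_gof_lof: float
    p_gof_gof: float

    @property
    def amplitude(self) -> float:
        four = (self.p_lof_lof, self.p_lof_gof, self.p_gof_lof, self.p_gof_gof)
        return max(four) - min(four)


@dataclass
class ScreenConfig:
    synergy_threshold: float = -0.2
    alleviation_threshold: float = 0.3
    phenotype: str = "Metastasis"
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_trajectories=200, max_time=20.0, seed=0)
    )
    #: start trajectories from the resting state (non-input nodes OFF)
    resting_start: bool = True
    #: estimated probability needed before a mutant may count as "reaches 1"
    reach_one_threshold: float = 0.995
    #: additionally require every stable state of the clamped model to show
    #: the phenotype before declaring probability 1
    exact_confirmation: bool = True
    #: "cancelled" tolerance for gene-pair cluster patterns
    cancelled_tolerance: float = 0.05
    #: free-node limit under which the exact absorption solve replaces sampling
    exact_solve_max_free: int = 12

    def __post_init__(self):
        if not (self.synergy_threshold < 0 < self.alleviation_threshold):
            raise ValueError("thresholds must satisfy synergy < 0 < alleviation")


def enumerate_mutants(model: BooleanModel, genes: Sequence[str] | None = None) -> list[Mutant]:
    """All single and double mutants over ``genes``: 2n singles, 4*C(n,2)
    doubles, in deterministic gene order (LoF before GoF)."""
    if genes is None:
        genes = default_mutatable_genes(model)
    for g in genes:
        if g not in model.index:
            raise KeyError(f"unknown gene {g!r}")
        if g in model.inputs:
            raise ValueError(f"input node {g!r} cannot be mutated")
    mutants: list[Mutant] = [
        (MutationSpec(g, d),) for g in genes for d in _DIRECTIONS
    ]
    for g1, g2 in itertools.combinations(genes, 2):
        for d1 in _DIRECTIONS:
            for d2 in _DIRECTIONS:
                mutants.append((MutationSpec(g1, d1), MutationSpec(g2, d2)))
    return mutants


def compute_epistasis(p1: float, p2: float, p12: float) -> float:
    """epsilon = (1-p12) - (1-p1)(1-p2); requires probabilities in [0,1]."""
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0,1]")
    return (1.0 - p12) - (1.0 - p1) * (1.0 - p2)


@dataclass
class ScreenResult:
    mutant_table: pd.DataFrame       # one row per mutant (and WT)
    records: list[EpistasisRecord]   # all pairs x direction combinations
    pair_profiles: dict[tuple[str, str], GenePairProfile]
    combo_table: pd.DataFrame        # phenotype-combination distribution per mutant
    config: ScreenConfig
    genes: tuple[str, ...]

    def epistasis_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            eps = r.epsilon
            rows.append(
                {
                    "gene_a": r.mutant_a.gene,
                    "dir_a": r.mutant_a.direction,
                    "gene_b": r.mutant_b.gene,
                    "dir_b": r.mutant_b.direction,
                    "p1": r.p1,
                    "p2": r.p2,
                    "p12": r.p12,
                    "epsilon": eps,
                    "interaction": (
                        "synergy"
                        if eps < self.config.synergy_threshold
                        else "alleviation"
                        if eps > self.config.alleviation_threshold
                        else ""
                    ),
                }
            )
        df = pd.DataFrame(rows)
        clusters = {
            (p.gene_a, p.gene_b): classify_pair(p, self.config.cancelled_tolerance)
            for p in self.pair_profiles.values()
        }
        if not df.empty:
            df["cluster"] = [clusters[(a, b)] for a, b in zip(df.gene_a, df.gene_b)]
        return df

    def reaches_one(self) -> pd.DataFrame:
        return self.mutant_table[self.mutant_table["reaches_one"]]

    def synergistic_full_penetrance_pairs(self) -> list[Mutant]:
        """Double mutants at probability 1 with neither single at 1."""
        t = self.mutant_table.set_index("mutant")
        out: list[Mutant] = []
        for _, row in t[(t["order"] == 2) & t["reaches_one"]].iterrows():
            mut: Mutant = row["mutant_obj"]
            if not any(t.loc[m.label, "reaches_one"] for m in mut):
                out.append(mut)
        return out


def _resting_policy(model: BooleanModel) -> dict[str, int]:
    return {n: 0 for n in model.nodes if n not in model.inputs}


def run_screen(
    model: BooleanModel,
    genes: Sequence[str] | None = None,
    config: ScreenConfig | None = None,
    batch_conditions: int = 128,
) -> ScreenResult:
    """Simulate every single/double mutant (plus wild type) and assemble the
    probability table, epistasis records and pair profiles.

    Conditions are simulated in batches for memory; each mutant's trajectory
    streams are derived from the master seed and the mutant's position, so
    results are reproducible bit-for-bit and independent of batching.
    """
    config = config or ScreenConfig()
    if genes is None:
        genes = tuple(default_mutatable_genes(model))
    genes = tuple(genes)
    mutants: list[Mutant] = [()] + enumerate_mutants(model, genes)

    sim = config.simulation
    if config.resting_start and not sim.initial_policy:
        sim = replace(sim, initial_policy=_resting_policy(model))

    ph = config.phenotype
    ph_idx = [model.index[p] for p in PHENOTYPE_NODES]

    rows = []
    combo_counts: list[dict[str, float]] = []
    for start in range(0, len(mutants), batch_conditions):
        chunk = mutants[start:start + batch_conditions]
        clamp_sets = [mutant_clamps(mu) for mu in chunk]
        X, absorbed, cond = simulate_endpoints(
            model, clamp_sets, sim,
            seed_seq=None, cond_offset=start,
        )
        for j, mu in enumerate(chunk):
            sel = cond == j
            Xj = X[sel]
            probs = {p: float(Xj[:, model.index[p]].mean()) for p in PHENOTYPE_NODES}
            if len(model.nodes) - len(clamp_sets[j]) <= config.exact_solve_max_free:
                try:
                    probs.update(
                        exact_phenotype_probabilities(
                            model, clamp_sets[j], PHENOTYPE_NODES,
                            initial_policy=sim.initial_policy,
                        )
                    )
                except ValueError:
                    pass
            combos = {}
            for row in Xj[:, ph_idx]:
                key = "+".join(p for p, b in zip(PHENOTYPE_NODES, row) if b) or "none"
                combos[key] = combos.get(key, 0.0) + 1.0 / len(Xj)
            combo_counts.append(combos)
            p_hat = probs[ph]
            reaches = p_hat >= config.reach_one_threshold
            all_stable_ph = None
            if reaches and config.exact_confirmation:
                try:
                    stab = model.enumerate_stable_states(clamp_sets[j])
                    all_stable_ph = bool(stab) and all(s[ph] == 1 for s in stab)
                    reaches = reaches and all_stable_ph
                except Exception:
                    logger.exception("exact confirmation failed for %s", mutant_label(mu))
                    all_stable_ph = None
            rows.append(
                {
                    "mutant": mutant_label(mu),
                    "mutant_obj": mu,
                    "order": len(mu),
                    **{f"P({p})": probs[p] for p in PHENOTYPE_NODES},
                    "fraction_absorbed": float(absorbed[sel].mean()),
                    "n": sim.n_trajectories,
                    "reaches_one": bool(reaches),
                    "all_stable_metastatic": all_stable_ph,
                }
            )

    table = pd.DataFrame(rows)
    combo_table = pd.DataFrame(combo_counts).fillna(0.0)
    combo_table.index = table["mutant"]

    p_of = dict(zip(table["mutant"], table[f"P({ph})"]))
    reach = dict(zip(table["mutant"], table["reaches_one"]))

    def p_final(label: str) -> float:
        # exact confirmation promotes near-one estimates to exactly 1
        return 1.0 if reach[label] else min(p_of[label], 1.0)

    records = []
    profiles = {}
    for g1, g2 in itertools.combinations(genes, 2):
        four = {}
        for d1 in _DIRECTIONS:
            for d2 in _DIRECTIONS:
                a, b = MutationSpec(g1, d1), MutationSpec(g2, d2)
                label = mutant_label((a, b))
                records.append(
                    EpistasisRecord(a, b, p_final(a.label), p_final(b.label), p_final(label))
                )
                four[(d1, d2)] = p_final(label)
        profiles[(g1, g2)] = GenePairProfile(
            g1, g2,
            four[("LoF", "LoF")], four[("LoF", "GoF")],
            four[("GoF", "LoF")], four[("GoF", "GoF")],
        )
    return ScreenResult(table, records, profiles, combo_table, config, genes)


def classify_pair(profile: GenePairProfile, cancelled_tolerance: float = 0.05) -> str:
    """Gene-pair cluster from the cancellation pattern of its four mutants.

    1a: any GoF cancels the phenotype (double LoF can amplify);
    1b: any LoF cancels (double GoF can amplify);
    2a: double GoF cancels, double LoF or mixed amplify;
    2b: double LoF cancels, double GoF or mixed amplify;
    3:  both same-direction doubles cancel, only mixed (synthetic dosage)
        amplifies.  Unmatched patterns -> "other".
    """
    tol = cancelled_tolerance
    ll, gg = profile.p_lof_lof, profile.p_gof_gof
    mixed = (profile.p_lof_gof, profile.p_gof_lof)
    c_ll, c_gg = ll < tol, gg < tol
    c_mixed = all(p < tol for p in mixed)
    any_mixed_high = any(p >= tol for p in mixed)
    if c_ll and c_gg and c_mixed:
        return "other"  # phenotype never appears
    if c_gg and c_mixed and not c_ll:
        return "1a"
    if c_ll and c_mixed and not c_gg:
        return "1b"
    if c_ll and c_gg and any_mixed_high:
        return "3"
    if c_gg and not c_ll:
        return "2a"
    if c_ll and not c_gg:
        return "2b"
    return "other"


def interaction_network(
    records: Sequence[EpistasisRecord],
    config: ScreenConfig | None = None,
) -> nx.Graph:
    """Genetic-interaction network of the significant records: nodes are
    single mutants sized by their phenotype probability, edges weighted by
    |epsilon| and signed synergy/alleviation."""
    config = config or ScreenConfig()
    g = nx.Graph()
    for r in records:
        eps = r.epsilon
        if config.synergy_threshold < eps < config.alleviation_threshold:
            continue
        for spec, p in ((r.mutant_a, r.p1), (r.mutant_b, r.p2)):
            g.add_node(spec.label, probability=float(p), gene=spec.gene, direction=spec.direction)
        kind = "synergy" if eps < 0 else "alleviation"
        a, b = r.mutant_a.label, r.mutant_b.label
        if not g.has_edge(a, b) or abs(eps) > g[a][b]["weight"]:
            g.add_edge(a, b, weight=abs(float(eps)), epsilon=float(eps), interaction=kind)
    return g


def write_sif(graph: nx.Graph, path) -> None:
    """Simple-interaction-format export (one edge per line)."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('interaction', 'interacts')}\t{b}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\n")


def mutant_landscape_coordinates(
    combo_table: pd.DataFrame,
    min_prevalence: float = 0.01,
) -> pd.DataFrame:
    """2-D embedding of mutants from their phenotype-combination probability
    vectors (principal components; combination columns whose mean prevalence
    over the mutant set exceeds ``min_prevalence`` are retained)."""
    if len(combo_table) < 3:
        raise ValueError("need at least 3 mutants to embed")
    kept = combo_table.loc[:, combo_table.mean(axis=0) > min_prevalence]
    if kept.shape[1] == 0:
        kept = combo_table
    mat = kept.to_numpy(dtype=float)
    centred = mat - mat.mean(axis=0)
    if np.allclose(centred, 0) or min(centred.shape) < 2:
        coords = np.zeros((len(kept), 2))
        coords[:, : min(2, mat.shape[1])] = mat[:, :2] if mat.shape[1] >= 2 else mat[:, :1]
    else:
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(centred)
        # deterministic sign: largest-|loading| entry of each axis positive
        for k in range(2):
            load = pca.components_[k]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, k] *= -1
    return pd.DataFrame(coords, index=kept.index, columns=["PC1", "PC2"])
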