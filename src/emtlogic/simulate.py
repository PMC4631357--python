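"""Continuous-time Markov simulation of the asynchronous Boolean dynamics.

The dynamics is the standard stochastic interpretation of asynchronous
Boolean networks: every unclamped node whose rule disagrees with its current
value is eligible to flip, each flip carries a rate (all 1 by default, per
time unit), the waiting time is exponential in the total rate and the flip is
chosen proportionally to its rate (Gillespie).  A trajectory stops when no
flip is eligible (absorbed in a stable state) or when simulated time exceeds
the horizon.  Phenotype probabilities are endpoint averages of the phenotype
nodes' ON indicators over many trajectories.

Randomness discipline: one master seed spawns an independent child stream
per trajectory, so estimates are bitwise reproducible and independent of
batching, and growing ``n_trajectories`` extends rather than reshuffles the
trajectory set.  Each trajectory consumes two uniforms per step (waiting
time, then flip choice), identically in the scalar and the vectorised
engine.

For small clamped models (free-node state space up to ``2**12`` by default)
``exact_phenotype_probabilities`` solves the absorption problem exactly on
the full transition graph instead of sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

from .library import PHENOTYPE_NODES
from .model import BooleanModel, NetworkState, validate_clamps

__all__ = [
    "SimulationConfig",
    "PhenotypeProbabilities",
    "sample_initial_state",
    "simulate_trajectory",
    "estimate_phenotype_probabilities",
    "simulate_endpoints",
    "exact_phenotype_probabilities",
]


@dataclass
class SimulationConfig:
    """Parameters of the continuous-time simulation.

    rate_up / rate_down are per-node transition rates in inverse time units;
    the published analyses set every rate to 1.  ``initial_policy`` maps node
    names to fixed initial bits; unlisted nodes start i.i.d. uniform on {0,1}
    (``{}`` = all random).
    """

    rate_up: float = 1.0
    rate_down: float = 1.0
    n_trajectories: int = 1000
    max_time: float = 100.0
    seed: int = 0
    initial_policy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.rate_up <= 0 or self.rate_down <= 0:
            raise ValueError("rates must be positive")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


@dataclass
class PhenotypeProbabilities:
    """Endpoint ON-probabilities of the phenotype nodes.

    Probabilities are not mutually exclusive and need not sum to 1 (an
    endpoint can activate several read-outs at once).  The Monte-Carlo
    standard error of each estimate is sqrt(p(1-p)/n).
    """

    probabilities: dict[str, float]
    n_trajectories: int
    fraction_absorbed: float

    def __getitem__(self, phenotype: str) -> float:
        return self.probabilities[phenotype]

    def standard_error(self, phenotype: str) -> float:
        p = self.probabilities[phenotype]
        return math.sqrt(p * (1.0 - p) / self.n_trajectories)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phenotype": k,
                "probability": p,
                "mc_error": self.standard_error(k),
                "n": self.n_trajectories,
                "fraction_absorbed": self.fraction_absorbed,
            }
            for k, p in self.probabilities.items()
        ]
        return pd.DataFrame(rows)


def sample_initial_state(
    model: BooleanModel,
    policy: Mapping[str, int],
    rng: np.random.Generator,
    clamps: Mapping[str, int] | None = None,
) -> NetworkState:
    """Draw an initial state: clamp values win, then policy-fixed values,
    remaining nodes i.i.d. uniform."""
    clamps = validate_clamps(model, clamps or {})
    for node in policy:
        if node not in model.index:
            raise KeyError(f"initial-policy node {node!r} is not a model node")
    bits = rng.integers(0, 2, size=len(model.nodes))
    assignment = dict(zip(model.nodes, (int(b) for b in bits)))
    assignment.update({k: int(v) for k, v in policy.items()})
    assignment.update(clamps)
    return model.state(assignment)


def simulate_trajectory(
    model: BooleanModel,
    clamps: Mapping[str, int] | None,
    config: SimulationConfig,
    rng: np.random.Generator,
    initial: NetworkState | None = None,
) -> tuple[NetworkState, float, bool]:
    """One Gillespie trajectory; returns (final state, end time, absorbed)."""
    clamps = validate_clamps(model, clamps or {})
    state = initial if initial is not None else sample_initial_state(
        model, config.initial_policy, rng, clamps
    )
    assignment = state.as_dict()
    t = 0.0
    free = [n for n in model.ruled_nodes if n not in clamps]
    while True:
        flips = []
        total_rate = 0.0
        for node in free:
            target = model.evaluate_rule(node, assignment)
            if target != assignment[node]:
                rate = config.rate_up if target == 1 else config.rate_down
                flips.append((node, rate))
                total_rate += rate
        if not flips:
            return model.state(assignment), t, True
        dt = -math.log(rng.random()) / total_rate
        if t + dt > config.max_time:
            return model.state(assignment), config.max_time, False
        t += dt
        u = rng.random() * total_rate
        acc = 0.0
        for node, rate in flips:
            acc += rate
            if u < acc:
                assignment[node] = 1 - assignment[node]
                break
        else:
            node = flips[-1][0]
            assignment[node] = 1 - assignment[node]


def _spawn_generators(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in seed_seq.spawn(n)]


def simulate_endpoints(
    model: BooleanModel,
    clamp_sets: Sequence[Mapping[str, int]],
    config: SimulationConfig,
    seed_seq: np.random.SeedSequence | None = None,
    chunk: int = 16,
    cond_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised endpoint simulation for a batch of clamp conditions.

    Runs ``config.n_trajectories`` trajectories for *each* clamp set in one
    numpy batch (rows = trajectories).  Returns ``(X, absorbed, cond)``:
    endpoint bit matrix, absorption flags, and the clamp-set index of each
    row.  Bitwise identical to running ``simulate_trajectory`` with the same
    per-trajectory streams.

    Each condition's trajectory streams derive from ``(config.seed,
    cond_offset + condition index)``, so splitting a batch of conditions into
    smaller batches (with matching offsets) reproduces the same endpoints.
    """
    n_per = config.n_trajectories
    n_rows = n_per * len(clamp_sets)
    n_nodes = len(model.nodes)
    if seed_seq is not None:
        gens = _spawn_generators(seed_seq, n_rows)
    else:
        gens = []
        for j in range(len(clamp_sets)):
            ss = np.random.SeedSequence(config.seed, spawn_key=(cond_offset + j,))
            gens.extend(_spawn_generators(ss, n_per))

    cond = np.repeat(np.arange(len(clamp_sets)), n_per)
    # initial states: per-row draws (consumes one uniform block per row,
    # matching sample_initial_state's integers() call on the same stream)
    X = np.empty((n_rows, n_nodes), dtype=np.uint8)
    for i, g in enumerate(gens):
        X[i] = g.integers(0, 2, size=n_nodes)
    free_mask = np.ones((len(clamp_sets), n_nodes), dtype=bool)
    for j, clamps in enumerate(clamp_sets):
        clamps = validate_clamps(model, clamps)
        for node in model.inputs:
            free_mask[j, model.index[node]] = False
        for node, bit in clamps.items():
            X[cond == j, model.index[node]] = bit
            free_mask[j, model.index[node]] = False
        for node, bit in config.initial_policy.items():
            if node not in clamps:
                X[cond == j, model.index[node]] = int(bit)
    row_free = free_mask[cond]

    uniform_rates = config.rate_up == config.rate_down
    t = np.zeros(n_rows)
    absorbed = np.zeros(n_rows, dtype=bool)
    active = np.ones(n_rows, dtype=bool)
    # pre-drawn per-row uniforms, refilled in chunks from each row's stream
    buf = np.empty((n_rows, chunk, 2))
    for i, g in enumerate(gens):
        buf[i] = g.random((chunk, 2))
    ptr = np.zeros(n_rows, dtype=np.int64)

    node_list = list(model.ruled_nodes)
    while active.any():
        rows = np.nonzero(active)[0]
        Xa = X[rows]
        F = Xa.copy()
        for node in node_list:
            F[:, model.index[node]] = model.rule_values(Xa, node)
        U = (F != Xa) & row_free[rows]
        k = U.sum(axis=1)
        # rates: uniform case keeps total = k; otherwise weight by direction
        if uniform_rates:
            rates = U.astype(np.float64) * config.rate_up
        else:
            up = (F == 1) & U
            rates = up * config.rate_up + (U & ~up) * config.rate_down
        total = rates.sum(axis=1)
        newly_stable = k == 0
        if newly_stable.any():
            idx = rows[newly_stable]
            absorbed[idx] = True
            active[idx] = False
        live = ~newly_stable
        if not live.any():
            continue
        lrows = rows[live]
        need_refill = ptr[lrows] >= chunk
        for i in lrows[need_refill]:
            buf[i] = gens[i].random((chunk, 2))
            ptr[i] = 0
        u = buf[lrows, ptr[lrows]]
        ptr[lrows] += 1
        dt = -np.log(u[:, 0]) / total[live]
        over = t[lrows] + dt > config.max_time
        if over.any():
            idx = lrows[over]
            t[idx] = config.max_time
            active[idx] = False
        go = ~over
        if not go.any():
            continue
        grows = lrows[go]
        t[grows] += dt[go]
        target = u[go, 1][:, None] * total[live][go, None]
        csum = np.cumsum(rates[live][go], axis=1)
        flip = np.argmax(csum > target, axis=1)
        X[grows, flip] ^= 1
    return X, absorbed, cond


def estimate_phenotype_probabilities(
    model: BooleanModel,
    clamps: Mapping[str, int] | None,
    config: SimulationConfig,
    phenotypes: Sequence[str] = PHENOTYPE_NODES,
) -> PhenotypeProbabilities:
    """Monte-Carlo estimate of endpoint phenotype probabilities."""
    clamps = validate_clamps(model, clamps or {})
    X, absorbed, _ = simulate_endpoints(model, [clamps], config)
    probs = {
        ph: float(X[:, model.index[ph]].mean()) for ph in phenotypes if ph in model.index
    }
    return PhenotypeProbabilities(probs, config.n_trajectories, float(absorbed.mean()))


def exact_phenotype_probabilities(
    model: BooleanModel,
    clamps: Mapping[str, int] | None = None,
    phenotypes: Sequence[str] = PHENOTYPE_NODES,
    initial_policy: Mapping[str, int] | None = None,
    max_free_nodes: int = 12,
) -> dict[str, float]:
    """Exact absorption probabilities by linear solve on the full transition
    graph (embedded jump chain; valid when every attractor is a stable state).

    The initial distribution is uniform over unconstrained nodes, matching the
    all-random simulation policy.  Raises if the free-node state space exceeds
    ``2**max_free_nodes`` or if a cyclic attractor is present.
    """
    clamps = validate_clamps(model, clamps or {})
    policy = dict(initial_policy or {})
    free = [n for n in model.nodes if n not in clamps]
    flippable = [n for n in model.ruled_nodes if n not in clamps]
    if len(free) > max_free_nodes:
        raise ValueError(f"{len(free)} free nodes exceed the 2**{max_free_nodes} exact-solve limit")

    n_states = 1 << len(free)
    pos = {n: j for j, n in enumerate(free)}

    def bits_of(code: int) -> dict[str, int]:
        d = {n: (code >> pos[n]) & 1 for n in free}
        d.update(clamps)
        return d

    succ: list[list[int]] = []
    for code in range(n_states):
        assign = bits_of(code)
        nxt = []
        for node in flippable:
            if model.evaluate_rule(node, assign) != assign[node]:
                nxt.append(code ^ (1 << pos[node]))
        succ.append(nxt)

    transient = [c for c in range(n_states) if succ[c]]
    absorbing = {c for c in range(n_states) if not succ[c]}
    # cyclic-attractor guard: every transient state must reach an absorbing one
    reach = set(absorbing)
    changed = True
    while changed:
        changed = False
        for c in transient:
            if c not in reach and any(s in reach for s in succ[c]):
                reach.add(c)
                changed = True
    if any(c not in reach for c in transient):
        raise ValueError("cyclic attractor present; exact absorption solve is undefined")

    tindex = {c: i for i, c in enumerate(transient)}
    results = {}
    # h(c) = expected endpoint indicator; one linear solve per phenotype
    for ph in phenotypes:
        if ph not in model.index:
            continue
        def endpoint_value(code: int) -> float:
            assign = bits_of(code)
            return float(assign[ph])

        if transient:
            rows, cols, vals = [], [], []
            b = np.zeros(len(transient))
            for c in transient:
                i = tindex[c]
                kdeg = len(succ[c])
                for s in succ[c]:
                    if s in tindex:
                        rows.append(i)
                        cols.append(tindex[s])
                        vals.append(1.0 / kdeg)
                    else:
                        b[i] += endpoint_value(s) / kdeg
            Q = scipy.sparse.csr_matrix(
                (vals, (rows, cols)), shape=(len(transient), len(transient))
            )
            A = scipy.sparse.eye(len(transient), format="csr") - Q
            h_trans = scipy.sparse.linalg.spsolve(A.tocsc(), b)
        h = np.empty(n_states)
        for c in range(n_states):
            h[c] = h_trans[tindex[c]] if c in tindex else endpoint_value(c)

        # uniform initial distribution over nodes not fixed by the policy
        fixed = {n: int(v) for n, v in policy.items() if n in pos}
        weight = np.zeros(n_states)
        for c in range(n_states):
            if all((c >> pos[n]) & 1 == v for n, v in fixed.items()):
                weight[c] = 1.0
        weight /= weight.sum()
        results[ph] = float(h @ weight)
    return results
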