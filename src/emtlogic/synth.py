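"""Synthetic data generators: EMT-induction time courses, two-group tumour
cohorts, and random Boolean models for oracle testing.

The time-course generator emulates a TGF-beta EMT induction experiment in an
epithelial cancer cell line sampled at 0/8/24/72 h with 3 replicates:
epithelial markers (E-cadherin) decay and mesenchymal/invasion markers
(N-cadherin, vimentin, ZEB1, SNAI2, MMP2, TGFB1, ...) rise along sigmoid
trajectories on a log2 expression scale, with additive Gaussian noise
(multiplicative on the raw scale, as for microarrays).  Early timepoints
binarize towards the epithelial/apoptotic stable-state patterns and late
timepoints towards the metastatic pattern.  The cohort generator emulates a
tumour expression cohort split into non-metastatic/metastatic groups (88 vs
17 by default) with module-level activity shifts planted in pooled-SD units.

Everything is deterministic under a fixed seed, and every generator returns
ground-truth annotations sufficient to check downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import ModuleDefinition
from .model import BooleanModel, parse_model

__all__ = [
    "SigmoidGene",
    "TimecourseSpec",
    "CohortSpec",
    "default_timecourse_spec",
    "generate_timecourse",
    "generate_cohort",
    "generate_random_model",
]


@dataclass(frozen=True)
class SigmoidGene:
    """log2 trajectory: baseline + amplitude * sigmoid(slope * (t - midpoint)).
    Negative amplitude encodes repression."""

    baseline: float
    amplitude: float
    midpoint: float  # hours
    slope: float     # per hour

    def value(self, t: float) -> float:
        return self.baseline + self.amplitude / (1.0 + np.exp(-self.slope * (t - self.midpoint)))

    def true_bit(self, t: float) -> int:
        """ON/OFF against the trajectory's own half-amplitude threshold."""
        thr = self.baseline + self.amplitude / 2.0
        return int(self.value(t) >= thr) if self.amplitude > 0 else int(self.value(t) > thr)


@dataclass
class TimecourseSpec:
    timepoints: tuple[float, ...] = (0.0, 8.0, 24.0, 72.0)
    n_replicates: int = 3
    dynamic_genes: dict[str, SigmoidGene] = field(default_factory=dict)
    static_genes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for g, s in self.dynamic_genes.items():
            if s.slope <= 0:
                raise ValueError(f"gene {g}: slope must be positive")
            if s.amplitude == 0:
                raise ValueError(f"gene {g}: amplitude must be non-zero")


_LO, _HI = 4.0, 8.0

#: induction (+) / repression (-) of the 11 dynamically responding genes
_DYNAMIC_DIRECTIONS = {
    "CDH1": -1, "CDH2": +1, "CTNNB1": +1, "EGFR": +1, "MAPK1": +1,
    "MMP2": +1, "SMAD3": +1, "SNAI2": +1, "TGFB1": +1, "VIM": +1, "ZEB1": +1,
}

#: constitutive genes: half resemble the apoptotic stable-state pattern,
#: half the metastatic one, so neither is favoured by the constant background
_STATIC_LEVELS = {
    "AKT1": _LO, "TP63": _LO, "TP73": _LO,           # OFF in both patterns
    "AKT2": _LO, "DKK1": _LO, "CDKN1A": _HI, "TP53": _HI, "CASP9": _HI,
    "NOTCH1": _HI, "TWIST1": _HI, "SNAI1": _HI, "ZEB2": _HI, "CDC42": _HI,
}


def default_timecourse_spec(noise_sd: float = 0.3, seed: int = 0) -> TimecourseSpec:
    """The default EMT-induction design: 11 dynamic genes with midpoints in
    the 8-24 h window (so the 8 h sample sits near the decision boundary)."""
    dynamic = {}
    for i, (gene, direction) in enumerate(sorted(_DYNAMIC_DIRECTIONS.items())):
        midpoint = 12.0 if i % 2 == 0 else 18.0
        if direction > 0:
            dynamic[gene] = SigmoidGene(_LO, _HI - _LO, midpoint, 0.35)
        else:
            dynamic[gene] = SigmoidGene(_HI, -( _HI - _LO), midpoint, 0.35)
    return TimecourseSpec(
        dynamic_genes=dynamic,
        static_genes=dict(_STATIC_LEVELS),
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_timecourse(spec: TimecourseSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Replicate-annotated expression matrix plus ground truth.

    Columns are labelled ``T<t>:<replicate>``; ground truth carries the list
    of dynamic genes and the noiseless ON/OFF bit of every gene per
    timepoint.
    """
    spec = spec or default_timecourse_spec()
    rng = np.random.default_rng(spec.seed)
    columns = [
        f"T{int(t) if float(t).is_integer() else t}:{r + 1}"
        for t in spec.timepoints
        for r in range(spec.n_replicates)
    ]
    genes = list(spec.dynamic_genes) + list(spec.static_genes)
    data = np.empty((len(genes), len(columns)))
    for i, gene in enumerate(genes):
        j = 0
        for t in spec.timepoints:
            mu = (
                spec.dynamic_genes[gene].value(t)
                if gene in spec.dynamic_genes
                else spec.static_genes[gene]
            )
            for _ in range(spec.n_replicates):
                data[i, j] = mu + rng.normal(0.0, spec.noise_sd)
                j += 1
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)

    tp_labels = [c.split(":")[0] for c in columns[:: spec.n_replicates]]
    true_bits = pd.DataFrame(
        {
            tp: [
                spec.dynamic_genes[g].true_bit(t)
                if g in spec.dynamic_genes
                else int(spec.static_genes[g] >= (_LO + _HI) / 2)
                for g in genes
            ]
            for tp, t in zip(tp_labels, spec.timepoints)
        },
        index=genes,
    )
    truth = {
        "dynamic_genes": sorted(spec.dynamic_genes),
        "true_bits": true_bits,
        "timepoints": list(spec.timepoints),
    }
    return expr, truth


@dataclass
class CohortSpec:
    n_group0: int = 88   # non-metastatic
    n_group1: int = 17   # metastatic
    #: module name -> planted group-1 shift in pooled-SD units (sign = direction)
    effects: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 6.0
    gene_sd: float = 1.0
    n_background_genes: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_group0 < 2 or self.n_group1 < 2:
            raise ValueError("each group needs at least 2 samples")
        for mod, e in self.effects.items():
            if not np.isfinite(e):
                raise ValueError(f"effect for {mod} must be finite")


def generate_cohort(
    spec: CohortSpec,
    modules: Mapping[str, ModuleDefinition] | Sequence[ModuleDefinition],
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Two-group cohort with planted module-activity shifts.

    Returns (genes x samples matrix, sample->group labels ('M0'/'M1'),
    ground truth with the planted per-module effects).
    """
    if not isinstance(modules, Mapping):
        modules = {m.name: m for m in modules}
    for mod in spec.effects:
        if mod not in modules:
            raise KeyError(f"planted effect on undefined module {mod!r}")
    rng = np.random.default_rng(spec.seed)

    genes: list[str] = []
    for m in modules.values():
        for g in m.target_genes:
            if g not in genes:
                genes.append(g)
    background = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    all_genes = genes + background

    samples = [f"S{i:03d}" for i in range(spec.n_group0 + spec.n_group1)]
    labels = pd.Series(
        ["M0"] * spec.n_group0 + ["M1"] * spec.n_group1, index=samples, name="group"
    )
    gene_means = spec.baseline_mean + rng.normal(0.0, 1.0, size=len(all_genes))
    data = gene_means[:, None] + rng.normal(
        0.0, spec.gene_sd, size=(len(all_genes), len(samples))
    )
    expr = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"), columns=samples)
    for mod, effect in spec.effects.items():
        shift = effect * spec.gene_sd
        for g in modules[mod].target_genes:
            expr.loc[g, labels == "M1"] += shift
    truth = {"effects": dict(spec.effects), "module_genes": {
        m.name: list(m.target_genes) for m in modules.values()}}
    return expr, labels, truth


def generate_random_model(
    n_nodes: int,
    max_regulators: int = 3,
    seed: int = 0,
    p_negate: float = 0.4,
) -> BooleanModel:
    """Random Boolean model over nodes X0..X{n-1}: every node carries a rule
    over 1..max_regulators random regulators joined by random AND/OR, with
    random negations.  Emitted through the rule-file grammar, so the result
    is by construction parseable and serialisable."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    lines = []
    for name in names:
        k = int(rng.integers(1, max_regulators + 1))
        regs = rng.choice(names, size=min(k, n_nodes), replace=False)
        literals = [
            f"!{r}" if rng.random() < p_negate else str(r) for r in regs
        ]
        expr = literals[0]
        for lit in literals[1:]:
            op = "&" if rng.random() < 0.5 else "|"
            expr = f"{expr} {op} {lit}"
        lines.append(f"{name} = {expr}")
    return parse_model("\n".join(lines))
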