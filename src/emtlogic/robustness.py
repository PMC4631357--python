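"""Robustness of the model to AND<->OR swaps in the logical rules.

Model variants differ from the wild type by at most two operator swaps, in
three classes: one swap in one rule; two swaps in the same rule; one swap in
each of two distinct rules.  The bundled model has 126 binary operator sites,
yielding 126 + 283 + 7592 = 8001 variants.  The census enumerates every
variant's stable states (inputs free), pools them with multiplicity, and
measures each distinct state's Hamming distance to the nearest wild-type
stable state (DIST_TO_WT).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expr import parse_expr
from .model import BooleanModel, NetworkState, OperatorSite
from .simulate import SimulationConfig, estimate_phenotype_probabilities

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSpec",
    "VariantCensus",
    "enumerate_variants",
    "apply_variant",
    "census_stable_states",
    "phenotype_probability_sweep",
]


@dataclass(frozen=True)
class VariantSpec:
    """1 or 2 operator swaps; two swaps must sit in the same rule at distinct
    sites or in two distinct rules (one each)."""

    swaps: tuple[OperatorSite, ...]

    def __post_init__(self):
        if len(self.swaps) not in (1, 2):
            raise ValueError("a variant carries exactly 1 or 2 swaps")
        if len(self.swaps) == 2:
            a, b = self.swaps
            if a.node == b.node and a.index == b.index:
                raise ValueError("two swaps at the same site restore the wild type")

    @property
    def rules_touched(self) -> tuple[str, ...]:
        return tuple(sorted({s.node for s in self.swaps}))


def enumerate_variants(model: BooleanModel) -> list[VariantSpec]:
    """All operator-swap variants in deterministic order: singles first, then
    same-rule pairs, then cross-rule pairs.  The wild type is excluded."""
    sites = model.operator_sites()
    by_rule: dict[str, list[OperatorSite]] = {}
    for s in sites:
        by_rule.setdefault(s.node, []).append(s)

    variants = [VariantSpec((s,)) for s in sites]
    for node in model.ruled_nodes:
        for a, b in itertools.combinations(by_rule.get(node, []), 2):
            variants.append(VariantSpec((a, b)))
    ruled = list(model.ruled_nodes)
    for i, r in enumerate(ruled):
        for s in ruled[i + 1:]:
            for a in by_rule.get(r, []):
                for b in by_rule.get(s, []):
                    variants.append(VariantSpec((a, b)))
    return variants


def swapped_rule_text(model: BooleanModel, node: str, indices: Iterable[int]) -> str:
    """Rule text of ``node`` with the given operator occurrences flipped.

    The swap is performed on the rule *as written* (minimal parentheses) and
    the result re-read under standard precedence (NOT > AND > OR), so a
    flipped operator regroups its chain the way the written expression
    dictates.  This is the convention under which the variant census best
    matches the published reproducibility analysis; flipping at a fixed site
    of the frozen binary tree gives a systematically different (larger)
    census.
    """
    text = str(model.rules[node])
    positions = [i for i, ch in enumerate(text) if ch in "&|"]
    chars = list(text)
    for idx in indices:
        p = positions[idx]
        chars[p] = "&" if chars[p] == "|" else "|"
    return "".join(chars)


def apply_variant(model: BooleanModel, variant: VariantSpec) -> BooleanModel:
    """The model with the variant's operators flipped (text-level swap)."""
    by_node: dict[str, list[int]] = {}
    for site in variant.swaps:
        by_node.setdefault(site.node, []).append(site.index)
    replacements = {
        node: parse_expr(swapped_rule_text(model, node, idxs))
        for node, idxs in by_node.items()
    }
    return model.with_rules(replacements)


@dataclass
class VariantCensus:
    """Pooled stable states of a variant family."""

    n_variants: int
    per_variant_states: list[tuple[tuple[int, ...], ...]]  # bit vectors per variant
    state_counts: Counter  # distinct bit vector -> occurrences with multiplicity
    dist_to_wt: dict[tuple[int, ...], int]
    nodes: tuple[str, ...]

    @property
    def total_occurrences(self) -> int:
        return sum(self.state_counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.state_counts)

    def occurrence_share_at_distance(self, d: int) -> float:
        """Share of occurrences (with multiplicity) at DIST_TO_WT == d."""
        hits = sum(c for s, c in self.state_counts.items() if self.dist_to_wt[s] == d)
        return hits / self.total_occurrences

    @property
    def max_dist_to_wt(self) -> int:
        return max(self.dist_to_wt.values())

    def summary(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "total_stable_state_occurrences": self.total_occurrences,
            "n_distinct_stable_states": self.n_distinct,
            "pct_occurrences_identical_to_wt": round(100 * self.occurrence_share_at_distance(0)),
            "pct_occurrences_at_dist_1": round(100 * self.occurrence_share_at_distance(1)),
            "max_dist_to_wt": self.max_dist_to_wt,
        }

    def distinct_state_table(self) -> pd.DataFrame:
        rows = [
            {
                "state": "".join(map(str, s)),
                "occurrences": c,
                "dist_to_wt": self.dist_to_wt[s],
            }
            for s, c in self.state_counts.most_common()
        ]
        return pd.DataFrame(rows)


def census_stable_states(
    model: BooleanModel,
    variants: Sequence[VariantSpec] | None = None,
    wildtype_states: Iterable[NetworkState] | None = None,
) -> VariantCensus:
    """Enumerate stable states for every variant and pool them.

    Only the 1-2 touched rules are recompiled per variant; the determining
    set and topological order are shared with the wild type because swaps
    preserve the regulatory structure.
    """
    if variants is None:
        variants = enumerate_variants(model)
    wt = list(wildtype_states) if wildtype_states is not None else model.enumerate_stable_states()
    wt_bits = np.array([s.bits for s in wt], dtype=np.uint8)

    base = dict(model._compiled)
    counts: Counter = Counter()
    per_variant: list[tuple[tuple[int, ...], ...]] = []
    for variant in variants:
        try:
            vm = apply_variant(model, variant)
            tables = dict(base)
            for node in variant.rules_touched:
                tables[node] = model._compile_rule(vm.rules[node])
            states = model.enumerate_stable_states(compiled=tables)
        except Exception:  # pragma: no cover - none expected
            logger.exception("variant %s failed; skipped", variant)
            per_variant.append(())
            continue
        keys = tuple(s.bits for s in states)
        per_variant.append(keys)
        counts.update(keys)

    dist = {}
    for s in counts:
        arr = np.array(s, dtype=np.uint8)
        dist[s] = int(np.min((wt_bits != arr).sum(axis=1)))
    return VariantCensus(len(variants), per_variant, counts, dist, model.nodes)


def phenotype_probability_sweep(
    model: BooleanModel,
    variants: Sequence[VariantSpec],
    config: SimulationConfig,
    subsample: int | None = None,
    phenotypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Estimated phenotype probabilities per variant (optionally a seeded
    random subsample), one row per variant, for distribution summaries."""
    variants = list(variants)
    if subsample is not None and subsample < len(variants):
        rng = np.random.default_rng(config.seed)
        pick = rng.choice(len(variants), size=subsample, replace=False)
        variants = [variants[i] for i in sorted(pick)]
    rows = []
    for variant in variants:
        vm = apply_variant(model, variant)
        kwargs = {} if phenotypes is None else {"phenotypes": phenotypes}
        probs = estimate_phenotype_probabilities(vm, {}, config, **kwargs)
        row = {"variant": "; ".join(f"{s.node}[{s.index}]" for s in variant.swaps)}
        row.update(probs.probabilities)
        rows.append(row)
    return pd.DataFrame(rows)
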