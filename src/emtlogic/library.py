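"""The bundled metastasis model: rules, wild-type stable states, phenotype
labels, pathway modules and the biomarker/gene-symbol mapping.

The model has 32 nodes: two constant inputs (ECMicroenv, DNAdamage), 24
molecular species, and six phenotype read-outs (CellCycleArrest, Apoptosis,
EMT, Invasion, Migration, Metastasis).  Its wild-type dynamics has exactly
nine stable states, shipped as a TSV fixture; each is assigned one of four
phenotype labels.  The homeostatic state (HS) — all read-outs OFF and
E-cadherin ON — is a label, not a model node.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .model import BooleanModel, NetworkState, parse_model

__all__ = [
    "PHENOTYPE_NODES",
    "OUTPUT_NODES",
    "PhenotypeLabel",
    "ModuleDefinition",
    "load_metastasis_model",
    "load_wildtype_states",
    "load_modules",
    "load_biomarkers",
    "load_gene_map",
    "label_stable_state",
    "module_clamps",
    "default_mutatable_genes",
    "states_to_frame",
]

#: the six phenotype read-out nodes
PHENOTYPE_NODES = ("Apoptosis", "CellCycleArrest", "EMT", "Invasion", "Migration", "Metastasis")

#: the four final/intermediate output nodes excluded from mutant screens
OUTPUT_NODES = ("Apoptosis", "Invasion", "Migration", "Metastasis")

# guards against silent fixture corruption
_RULES_SHA256 = None  # filled lazily on first load, checked thereafter


@dataclass(frozen=True)
class PhenotypeLabel:
    name: str
    active_outputs: frozenset[str]

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class ModuleDefinition:
    name: str
    members: tuple[str, ...]
    target_genes: tuple[str, ...]


def _read_data(name: str) -> str:
    return resources.files("emtlogic.data").joinpath(name).read_text()


def load_metastasis_model(verify_checksum: str | None = None) -> BooleanModel:
    """Load the bundled 32-node EMT/metastasis model.

    ``verify_checksum`` may carry an expected sha256 of the rule file; a
    mismatch raises ``ValueError`` (fixture corruption guard).
    """
    text = _read_data("metastasis_rules.txt")
    if verify_checksum is not None:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != verify_checksum:
            raise ValueError(f"rule fixture checksum mismatch: {digest}")
    return parse_model(text)


def load_wildtype_states(model: BooleanModel | None = None) -> dict[str, NetworkState]:
    """The nine wild-type stable states, keyed by their published column label
    (HS, Apop1..4, EMT1..2, M1..2)."""
    model = model or load_metastasis_model()
    df = pd.read_csv(
        resources.files("emtlogic.data").joinpath("wildtype_stable_states.tsv"),
        sep="\t",
        index_col=0,
    )
    if set(df.index) != set(model.nodes):
        raise ValueError("stable-state fixture does not cover the model's nodes")
    return {
        col: model.state(df[col].to_dict())
        for col in df.columns
    }


def _parse_config(text: str) -> dict[str, dict[str, list[str]]]:
    out: dict[str, dict[str, list[str]]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rhs = line.partition("=")
        kind, _, name = head.strip().partition(" ")
        values = [v.strip() for v in rhs.split(",") if v.strip()]
        out.setdefault(kind, {})[name.strip()] = values
    return out


def load_modules(gene_map: Mapping[str, str] | None = None) -> dict[str, ModuleDefinition]:
    """Pathway modules; target genes default to the members' gene symbols."""
    cfg = _parse_config(_read_data("modules.cfg"))
    gmap = dict(gene_map) if gene_map is not None else load_gene_map()
    modules = {}
    for name, members in cfg.get("module", {}).items():
        targets = tuple(gmap.get(m, m) for m in members)
        modules[name] = ModuleDefinition(name, tuple(members), targets)
    return modules


def load_biomarkers() -> dict[str, str]:
    """Phenotype node -> biomarker gene symbol (Apoptosis->CASP9 etc.)."""
    return {k: v[0] for k, v in _parse_config(_read_data("modules.cfg")).get("biomarker", {}).items()}


def load_gene_map() -> dict[str, str]:
    """Model node -> gene symbol; identity for nodes not listed."""
    return {k: v[0] for k, v in _parse_config(_read_data("modules.cfg")).get("genemap", {}).items()}


def label_stable_state(state: NetworkState) -> PhenotypeLabel:
    """Phenotype label of a stable state, from its read-out nodes.

    Metastasis requires EMT, Invasion and Migration all ON; HS requires every
    read-out OFF with CDH1 ON; anything not matching a published pattern is
    labelled "other" with its raw active read-out set.
    """
    active = frozenset(n for n in PHENOTYPE_NODES if state[n] == 1)
    if state["Metastasis"] == 1:
        if {"EMT", "Invasion", "Migration"} <= active:
            return PhenotypeLabel("Metastasis", active)
        return PhenotypeLabel("other", active)
    if not active and state["CDH1"] == 1:
        return PhenotypeLabel("HS", active)
    if active == {"Apoptosis", "CellCycleArrest"}:
        return PhenotypeLabel("Apoptosis+CellCycleArrest", active)
    if active == {"EMT", "CellCycleArrest"}:
        return PhenotypeLabel("EMT+CellCycleArrest", active)
    return PhenotypeLabel("other", active)


def module_clamps(module: ModuleDefinition | str, direction: str,
                  modules: Mapping[str, ModuleDefinition] | None = None) -> dict[str, int]:
    """Clamp every member of a pathway module ON ("GoF") or OFF ("LoF")."""
    if isinstance(module, str):
        modules = modules or load_modules()
        if module not in modules:
            raise KeyError(f"unknown module {module!r}")
        module = modules[module]
    if direction not in ("GoF", "LoF"):
        raise ValueError("direction must be 'GoF' or 'LoF'")
    bit = 1 if direction == "GoF" else 0
    return {m: bit for m in module.members}


def default_mutatable_genes(model: BooleanModel | None = None) -> tuple[str, ...]:
    """Default screen allowlist: every node except the two inputs and the four
    final/intermediate outputs (26 nodes in the bundled model)."""
    model = model or load_metastasis_model()
    return tuple(n for n in model.nodes if n not in model.inputs and n not in OUTPUT_NODES)


def states_to_frame(states, model: BooleanModel, node_order=None) -> pd.DataFrame:
    """States as a node x state 0/1 table (published row order by default)."""
    if node_order is None:
        df = pd.read_csv(
            resources.files("emtlogic.data").joinpath("wildtype_stable_states.tsv"),
            sep="\t",
            index_col=0,
        )
        node_order = list(df.index) if set(df.index) == set(model.nodes) else list(model.nodes)
    if isinstance(states, dict):
        data = {k: [v[n] for n in node_order] for k, v in states.items()}
    else:
        data = {f"S{i + 1}": [s[n] for n in node_order] for i, s in enumerate(states)}
    return pd.DataFrame(data, index=pd.Index(node_order, name="node"))
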