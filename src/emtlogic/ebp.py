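"""Expression-based phenotype (EBP) matching of transcriptome profiles to
the model's stable states.

Six steps: (1) map measured genes to model species (phenotype read-outs map
through biomarkers: Apoptosis->CASP9, Migration->CDC42, Invasion->MMP2);
(2) average replicates per timepoint; (3) binarize each gene against a
threshold, flagging genes that never cross it as always-ON/always-OFF;
(4) label the stable states; (5) build the 0/1 agreement (similarity) matrix
between the binarized profile and each stable state; (6) sum agreements into
an integer EBP score per (timepoint, stable state).  The state(s) with the
highest score are the closest phenotype at that timepoint; ties are
reported as ties.

Expression tables are pandas DataFrames, genes in rows (symbols), samples in
columns labelled ``timepoint:replicate`` (e.g. ``T8:2``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import label_stable_state, load_biomarkers, load_gene_map
from .model import BooleanModel, NetworkState

logger = logging.getLogger(__name__)

__all__ = [
    "BinarizedProfile",
    "EBPResult",
    "map_genes_to_model",
    "average_replicates",
    "binarize",
    "similarity_matrix",
    "ebp_score",
    "ebp_pipeline",
    "read_expression_tsv",
    "write_expression_tsv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def map_genes_to_model(
    expr: pd.DataFrame,
    model: BooleanModel,
    biomarkers: Mapping[str, str] | None = None,
    gene_map: Mapping[str, str] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Restrict an expression matrix to model-mappable genes; rows are
    re-indexed by model node name.  Matching is case-insensitive.  Unmapped
    measured genes are dropped (logged); an empty intersection is an error.
    ``overrides`` maps gene symbol -> node name and wins over the defaults.
    """
    biomarkers = dict(load_biomarkers() if biomarkers is None else biomarkers)
    gene_map = dict(load_gene_map() if gene_map is None else gene_map)
    symbol_to_node: dict[str, str] = {}
    for node in model.nodes:
        if node in model.inputs:
            continue
        symbol_to_node[gene_map.get(node, node).upper()] = node
    for phenotype, symbol in biomarkers.items():
        symbol_to_node[symbol.upper()] = phenotype
    for symbol, node in (overrides or {}).items():
        symbol_to_node[symbol.upper()] = node

    rows, index = [], []
    dropped = []
    for gene in expr.index:
        node = symbol_to_node.get(str(gene).upper())
        if node is None or node in index:
            dropped.append(gene)
            continue
        rows.append(expr.loc[gene])
        index.append(node)
    if not rows:
        raise ValueError("no measured gene maps to a model node")
    if dropped:
        logger.info("dropped %d unmapped gene(s): %s", len(dropped), dropped[:10])
    return pd.DataFrame(rows, index=pd.Index(index, name="node"))


def _timepoint_of(column: str) -> str:
    return str(column).split(":", 1)[0]


def average_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicates per timepoint; timepoint order follows
    first appearance in the columns."""
    tps = []
    for c in expr.columns:
        tp = _timepoint_of(c)
        if tp not in tps:
            tps.append(tp)
    counts = {tp: sum(_timepoint_of(c) == tp for c in expr.columns) for tp in tps}
    if len(set(counts.values())) > 1:
        logger.warning("unequal replicate counts per timepoint: %s", counts)
    out = {tp: expr.loc[:, [c for c in expr.columns if _timepoint_of(c) == tp]].mean(axis=1)
           for tp in tps}
    return pd.DataFrame(out)


def _two_means_threshold(values: np.ndarray) -> float:
    """Exact 1-D 2-means: best split of the sorted values; threshold is the
    midpoint of the two cluster means."""
    v = np.sort(values.astype(float))
    best, best_sse = None, np.inf
    for cut in range(1, len(v)):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = (lo.mean() + hi.mean()) / 2.0
    return float(best)


@dataclass
class BinarizedProfile:
    """Per-gene bits over the series plus a dynamic/always-ON/always-OFF flag."""

    bits: pd.DataFrame        # genes x timepoints, 0/1
    flags: pd.Series          # "dynamic" | "always-ON" | "always-OFF"
    thresholds: pd.Series     # per-gene threshold used

    def dynamic_genes(self) -> list[str]:
        return list(self.flags.index[self.flags == "dynamic"])


def binarize(
    expr: pd.DataFrame,
    method: str = "two-means",
    min_dynamic_range: float = 1.0,
    quantile: float = 0.5,
) -> BinarizedProfile:
    """Threshold each gene's series into bits.

    A gene is *dynamic* when its range across the series exceeds
    ``min_dynamic_range`` (log-scale units); dynamic genes get a per-gene
    two-means threshold (or a global quantile threshold with
    ``method='quantile'``).  Other genes are flagged always-ON/always-OFF by
    their mean against the global two-means threshold of the whole matrix.
    """
    if method not in ("two-means", "quantile"):
        raise ValueError(f"unknown binarization method {method!r}")
    global_thr = (
        float(np.quantile(expr.to_numpy().ravel(), quantile))
        if method == "quantile"
        else _two_means_threshold(expr.to_numpy().ravel())
    )
    bits, flags, thresholds = {}, {}, {}
    for gene in expr.index:
        series = expr.loc[gene].to_numpy(dtype=float)
        if series.max() - series.min() > min_dynamic_range:
            thr = global_thr if method == "quantile" else _two_means_threshold(series)
            b = (series >= thr).astype(int)
            flags[gene] = "dynamic" if 0 < b.sum() < len(b) else (
                "always-ON" if b.all() else "always-OFF"
            )
            bits[gene] = b
            thresholds[gene] = thr
        else:
            on = series.mean() >= global_thr
            bits[gene] = np.full(len(series), int(on))
            flags[gene] = "always-ON" if on else "always-OFF"
            thresholds[gene] = global_thr
    return BinarizedProfile(
        pd.DataFrame(bits, index=expr.columns).T.astype(int),
        pd.Series(flags, name="flag"),
        pd.Series(thresholds, name="threshold"),
    )


def similarity_matrix(
    profile: BinarizedProfile | pd.DataFrame,
    states: Mapping[str, NetworkState],
    genes: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per timepoint: genes x states 0/1 agreement matrix (1 iff the
    binarized bit equals the state's bit for that node)."""
    bits = profile.bits if isinstance(profile, BinarizedProfile) else profile
    if genes is not None:
        bits = bits.loc[[g for g in bits.index if g in set(genes)]]
    out = {}
    for tp in bits.columns:
        mat = {
            label: [int(bits.loc[g, tp] == state[g]) for g in bits.index]
            for label, state in states.items()
        }
        out[tp] = pd.DataFrame(mat, index=bits.index)
    return out


@dataclass
class EBPResult:
    scores: pd.DataFrame                 # timepoints x states, integer sums
    best: dict[str, list[str]]           # timepoint -> argmax state labels (ties kept)
    phenotypes: dict[str, list[str]]     # timepoint -> phenotype labels of the argmax set

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "timepoint": tp,
                "best_states": ",".join(self.best[tp]),
                "phenotypes": ",".join(sorted(set(self.phenotypes[tp]))),
                "score": int(self.scores.loc[tp, self.best[tp][0]]),
            }
            for tp in self.scores.index
        ]
        return pd.DataFrame(rows)


def ebp_score(
    similarity: Mapping[str, pd.DataFrame],
    states: Mapping[str, NetworkState],
) -> EBPResult:
    """Sum each similarity matrix column into the integer EBP score."""
    scores = pd.DataFrame(
        {tp: sim.sum(axis=0) for tp, sim in similarity.items()}
    ).T.astype(int)
    best, phenos = {}, {}
    for tp in scores.index:
        top = scores.loc[tp].max()
        winners = list(scores.columns[scores.loc[tp] == top])
        best[tp] = winners
        phenos[tp] = [str(label_stable_state(states[w])) for w in winners]
    return EBPResult(scores, best, phenos)


def ebp_pipeline(
    expr: pd.DataFrame,
    model: BooleanModel,
    states: Mapping[str, NetworkState],
    dynamic_only: bool = False,
    **binarize_kwargs,
) -> tuple[EBPResult, BinarizedProfile]:
    """All six steps on a replicate-annotated expression table.

    With ``dynamic_only`` the score is restricted to the genes flagged
    dynamic; by default constant genes contribute their constant bit.
    """
    mapped = map_genes_to_model(expr, model)
    averaged = average_replicates(mapped)
    profile = binarize(averaged, **binarize_kwargs)
    genes = profile.dynamic_genes() if dynamic_only else None
    sim = similarity_matrix(profile, states, genes=genes)
    return ebp_score(sim, states), profile
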