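"""Biological annotation of learned chromatin states and model robustness.

The 13-state vocabulary follows the conventional naming for 5-mark models:
active promoters (PrAct) and their flanks (PrFlk), intergenic (EhAct) and
genic (EhGen) enhancers, active transcription (TxAct) and flanks (TxFlk),
strong (RepPC) and weak (WkRep) polycomb repression, bivalent promoters
(PrBiv) and enhancers (EhBiv), repeat/ZNF clusters (RpZNF), heterochromatin
(Htchr) and quiescent/low (QsLow). A learned state is labeled by the nearest
archetypal emission vector, with genomic fold-enrichment used to break near
ties; robustness of a jointly trained model is assessed by average-linkage
clustering of emission rows pooled with independently trained per-sample
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome import BinGrid, GenomicInterval, Segmentation
from .hmm import ChromatinStateModel

CORE_MARKS = ["H3K4me1", "H3K4me3", "H3K9me3", "H3K27me3", "H3K36me3"]

# Archetypal emission levels: a mark is "high" (0.8), "mid" (0.4) or low (0.1)
# in each state. Order of values follows CORE_MARKS.
_H, _M, _L = 0.8, 0.4, 0.1
DEFAULT_VOCABULARY: dict[str, np.ndarray] = {
    "PrAct": np.array([_L, _H, _L, _L, _L]),
    "PrFlk": np.array([_M, _M, _L, _L, _L]),
    "EhAct": np.array([_H, _L, _L, _L, _L]),
    "EhGen": np.array([_H, _L, _L, _L, _M]),
    "TxAct": np.array([_L, _L, _L, _L, _H]),
    "TxFlk": np.array([_L, _L, _L, _L, _M]),
    "RepPC": np.array([_L, _L, _L, _H, _L]),
    "WkRep": np.array([_L, _L, _L, _M, _L]),
    "PrBiv": np.array([_L, _H, _L, _H, _L]),
    "EhBiv": np.array([_H, _L, _L, _H, _L]),
    "RpZNF": np.array([_L, _L, _H, _L, _H]),
    "Htchr": np.array([_L, _L, _H, _L, _L]),
    "QsLow": np.array([_L, _L, _L, _L, _L]),
}

PROMOTER_LABELS = ("PrAct", "PrFlk", "PrBiv")
GENIC_LABELS = ("TxAct", "TxFlk", "EhGen")


# ------------------------------------------------------------ fold enrichment

def fold_enrichment(
    seg: Segmentation,
    categories: dict[str, list[GenomicInterval]],
    grid: BinGrid,
    include_genome_fraction: bool = True,
) -> pd.DataFrame:
    """State x category fold-enrichment table.

    enrichment(s, c) = [n(s & c) / n(s)] / [n(c) / N] with n counting bins on
    the grid; a state absent from the segmentation gets 0 (flagged via the
    ``genome_fraction`` column being 0).
    """
    seg.check_grid(grid)
    if all(v.size == 0 for v in seg.states.values()):
        raise ValueError("empty segmentation")
    K = seg.n_states
    N = grid.total_bins
    flat = np.concatenate([seg.states[c] for c in grid.chroms])
    state_counts = np.bincount(flat, minlength=K).astype(float)

    offsets = {}
    pos = 0
    for c in grid.chroms:
        offsets[c] = pos
        pos += grid.n_bins(c)

    table = {}
    for cat, intervals in categories.items():
        mask = np.zeros(N, dtype=bool)
        for iv in intervals:
            b0, b1 = grid.bin_range(iv.chrom, iv.start, iv.end)
            mask[offsets[iv.chrom] + b0 : offsets[iv.chrom] + b1] = True
        n_c = mask.sum()
        joint = np.bincount(flat[mask], minlength=K).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            enr = (joint / state_counts) / (n_c / N)
        table[cat] = np.nan_to_num(enr, nan=0.0, posinf=0.0)
    df = pd.DataFrame(table, index=seg.labels)
    if include_genome_fraction:
        df.insert(0, "genome_fraction", state_counts / N)
    return df


# ------------------------------------------------------------ state labeling

def assign_state_labels(
    model: ChromatinStateModel,
    enrichment: pd.DataFrame | None = None,
    vocabulary: dict[str, np.ndarray] | None = None,
    tie_margin: float = 0.1,
) -> dict[int, str]:
    """Label each state with the nearest emission archetype.

    If an enrichment table is given (rows in state order, with ``tss`` and/or
    ``genebody`` columns) and the two nearest archetypes are within
    ``tie_margin`` of each other, the tie is broken by genomic context:
    promoter-enriched states prefer Pr* labels, genic states prefer
    Tx*/EhGen. Duplicate labels get a numeric suffix and a warning.
    """
    vocab = vocabulary or DEFAULT_VOCABULARY
    arch = np.vstack(list(vocab.values()))
    names = list(vocab)
    out: dict[int, str] = {}
    for k in range(model.n_states):
        d = np.linalg.norm(arch - model.emission[k], axis=1)
        order = np.argsort(d, kind="stable")
        label = names[order[0]]
        if (
            enrichment is not None
            and len(order) > 1
            and d[order[1]] - d[order[0]] <= tie_margin
        ):
            pair = [names[order[0]], names[order[1]]]
            row = enrichment.iloc[k]
            tss = row.get("tss", 0.0)
            body = row.get("genebody", 0.0)
            if tss > max(body, 1.0):
                pref = [p for p in pair if p in PROMOTER_LABELS]
            elif body > max(tss, 1.0):
                pref = [p for p in pair if p in GENIC_LABELS]
            else:
                pref = []
            if pref:
                label = pref[0]
        out[k] = label

    used: dict[str, int] = {}
    for k in sorted(out):
        lab = out[k]
        used[lab] = used.get(lab, 0) + 1
        if used[lab] > 1:
            warnings.warn(f"label {lab} assigned to multiple states; suffixing")
            out[k] = f"{lab}.{used[lab]}"
    return out


# ---------------------------------------------------------- model robustness

@dataclass
class ModelMatch:
    """Result of clustering a reference model's states with per-sample models."""

    assignments: pd.DataFrame  # one row per pooled state: model, state, cluster
    reproducibility_score: float
    linkage: np.ndarray
    cophenetic_correlation: float

    def cluster_members(self, cluster: int) -> pd.DataFrame:
        return self.assignments[self.assignments.cluster == cluster]


def match_models(
    reference: ChromatinStateModel,
    others: dict[str, ChromatinStateModel],
) -> ModelMatch:
    """Cluster emission rows of the reference and per-sample models jointly.

    All states' emission vectors are pooled and clustered (average linkage,
    Euclidean); the tree is cut at K_reference clusters. The reproducibility
    score is the fraction of reference states whose cluster contains at least
    one state from every other model — 1.0 means every reference state is
    reproduced by every independently trained model.
    """
    for name, m in others.items():
        if m.mark_names != reference.mark_names:
            raise ValueError(f"model {name!r} has a different mark set")
    rows = [("reference", k, reference.emission[k]) for k in range(reference.n_states)]
    for name, m in others.items():
        rows += [(name, k, m.emission[k]) for k in range(m.n_states)]
    X = np.vstack([r[2] for r in rows])
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    clusters = hierarchy.fcluster(Z, t=reference.n_states, criterion="maxclust")
    coph = hierarchy.cophenet(Z, pdist(X))[0]
    df = pd.DataFrame(
        {
            "model": [r[0] for r in rows],
            "state": [r[1] for r in rows],
            "cluster": clusters,
        }
    )
    model_names = list(others)
    n_ok = 0
    ref_rows = df[df.model == "reference"]
    for _, row in ref_rows.iterrows():
        members = df[df.cluster == row.cluster]
        if all((members.model == name).any() for name in model_names):
            n_ok += 1
    score = n_ok / reference.n_states
    return ModelMatch(df, score, Z, float(coph))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
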