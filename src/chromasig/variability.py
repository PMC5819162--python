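"""Chromatin-state variability, variable-region clustering, QC and expression.

Variability of a state is summarized by how many of the N samples share it
at each locus where it occurs at all: the cumulative fraction F(n) of
occupied loci covered by <= n samples, and its area under the curve
AUC = (1/N) * sum_n F(n). A state private to single samples has AUC -> 1,
a state shared by all samples has AUC = 1/N, so larger AUC means more
cross-sample variability.

Expression support: FPKM normalization (reads / millions mapped / kb of gene
length), per-state expression distributions for genes grouped by their
dominant gene-body state, and rank correlation of gene-body mark signal with
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from .genome import BinGrid, GeneAnnotation, Segmentation
from .simulate import gene_majority_state


@dataclass
class VariabilityCurve:
    """Sharing profile of one chromatin state across N samples."""

    state: str
    n_samples: int
    counts: np.ndarray  # counts[n-1] = loci where the state occurs in exactly n samples

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_samples,):
            raise ValueError("counts must have one entry per 1..N")

    @property
    def cumulative_fraction(self) -> np.ndarray:
        total = self.counts.sum()
        return np.cumsum(self.counts) / total

    @property
    def auc(self) -> float:
        return float(self.cumulative_fraction.mean())


def state_variability(
    segmentations: dict[str, Segmentation], state: int | str
) -> VariabilityCurve:
    """Sharing curve of one state over a cohort of segmentations."""
    if len(segmentations) < 2:
        raise ValueError("need at least 2 samples")
    segs = list(segmentations.values())
    labels = segs[0].labels
    k = labels.index(state) if isinstance(state, str) else int(state)
    chroms = list(segs[0].states)
    occupancy = np.concatenate(
        [np.sum([s.states[c] == k for s in segs], axis=0) for c in chroms]
    )
    occupied = occupancy[occupancy > 0]
    if occupied.size == 0:
        raise ValueError(f"state {state!r} occurs in no sample")
    N = len(segs)
    counts = np.bincount(occupied, minlength=N + 1)[1 : N + 1]
    return VariabilityCurve(labels[k], N, counts)


def variability_table(segmentations: dict[str, Segmentation]) -> pd.DataFrame:
    """AUC and occupied-locus count for every state present in the cohort."""
    labels = next(iter(segmentations.values())).labels
    rows = []
    for k, lab in enumerate(labels):
        try:
            curve = state_variability(segmentations, k)
        except ValueError:
            continue
        rows.append({"state": lab, "auc": curve.auc, "n_loci": int(curve.counts.sum())})
    return pd.DataFrame(rows).set_index("state")


# ------------------------------------------------------------ region clustering

def top_variable_regions(
    matrix: pd.DataFrame,
    n_top: int = 1000,
    sample_k: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Select the most variable rows and standardize each to mean 0, sd 1.

    Optionally pre-samples ``sample_k`` rows at random (seeded) before the
    variance ranking, mirroring a two-stage peak-sampling protocol. Constant
    rows (sd 0) cannot be standardized and are excluded with a warning.
    """
    if matrix.empty:
        raise ValueError("empty intensity matrix")
    df = matrix
    if sample_k is not None and sample_k < len(df):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(df), size=sample_k, replace=False))
        df = df.iloc[keep]
    sd = df.std(axis=1, ddof=1)
    nonconst = sd > 0
    if not nonconst.all():
        warnings.warn(f"{int((~nonconst).sum())} constant rows excluded from selection")
    df = df.loc[nonconst]
    sd = sd.loc[nonconst]
    var = sd**2
    order = np.argsort(-var.to_numpy(), kind="stable")[:n_top]
    sel = df.iloc[np.sort(order)]
    return sel.sub(sel.mean(axis=1), axis=0).div(sel.std(axis=1, ddof=1), axis=0)


def cluster_regions(matrix: pd.DataFrame, method: str = "average", metric: str = "euclidean"):
    """Agglomerative clustering of standardized region rows.

    Returns ``(linkage, leaf_order)``; merge heights are non-decreasing for
    average linkage and the leaf order is deterministic.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(matrix.to_numpy(), method=method, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    return Z, list(matrix.index[leaves])


# ----------------------------------------------------------------- QC metrics

def replicate_correlation(rep1, rep2) -> float | None:
    """Pearson correlation of replicate peak intensities; None if undefined."""
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("replicates must be equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant replicate vector; correlation undefined")
        return None
    return float(pearsonr(x, y).statistic)


# ----------------------------------------------------------------- expression

def fpkm(count: float, total_reads: float, gene_length_bp: float) -> float:
    """Fragments per kilobase per million mapped reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if gene_length_bp < 1:
        raise ValueError("gene length must be >= 1 bp")
    return count / (total_reads / 1e6) / (gene_length_bp / 1e3)


def fpkm_table(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM for a gene x sample count table; library size = column sum."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total read count")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    return counts.div(totals / 1e6, axis=1).div(lengths / 1e3, axis=0)


def gene_state_expression(
    seg: Segmentation,
    genes: GeneAnnotation,
    expression: pd.Series,
    grid: BinGrid,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression distribution per dominant gene-body chromatin state.

    Returns ``(per_gene, summary)``: per-gene state assignment with its
    expression value, and a per-state summary with median expression plus
    one-sided rank-sum comparisons of every state against QsLow-like baseline
    columns are (n_genes, median, rank-sum p vs pooled rest).
    """
    rows = []
    for g in genes:
        if g.gene_id not in expression.index:
            continue
        k = gene_majority_state(seg, g, grid)
        rows.append({"gene_id": g.gene_id, "state": seg.labels[k], "value": expression[g.gene_id]})
    per_gene = pd.DataFrame(rows).set_index("gene_id")
    summary_rows = []
    for state, grp in per_gene.groupby("state"):
        rest = per_gene.loc[per_gene.state != state, "value"]
        if len(grp) and len(rest):
            p = mannwhitneyu(grp.value, rest, alternative="greater").pvalue
        else:
            p = np.nan
        summary_rows.append(
            {
                "state": state,
                "n_genes": len(grp),
                "median": float(grp.value.median()),
                "p_greater_than_rest": float(p),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("state")
    return per_gene, summary


def mark_expression_correlation(signal: pd.Series, expression: pd.Series) -> float | None:
    """Spearman rank correlation (midrank ties) of per-gene signal vs expression."""
    joined = pd.concat([signal, expression], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 genes with both values")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.nunique() == 1 or y.nunique() == 1:
        warnings.warn("constant input; Spearman correlation undefined")
        return None
    return float(spearmanr(x, y).statistic)
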