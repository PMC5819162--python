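"""Synthetic multi-cell-line cohort generator with known ground truth.

The generator emulates the structure of a 13-cell-line breast-cancer panel:
two normal-immortalized lines plus five cancer subtypes (luminal A/B, HER2,
TNBC-basal, TNBC-claudin-low), five core histone marks binarized at 200 bp
bins. All lines share a backbone segmentation drawn from a generating
chromatin-state HMM; differential biology is planted as disjoint regions
where one subtype (or group: all cancers, the TNBC side) carries a state the
others do not. Mark vectors are then emitted per bin from the state's
Bernoulli emission parameters, counts from state-dependent Poisson rates,
and gene expression from state-dependent rates — so every downstream stage
has a recoverable planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CORE_MARKS, DEFAULT_VOCABULARY
from .genome import BinGrid, Gene, GeneAnnotation, Segmentation, SubtypeDesign
from .hmm import ChromatinStateModel

STATE_LABELS = list(DEFAULT_VOCABULARY)

SIGNATURE_CLASSES = ("subtype-present", "subtype-absent", "pan-cancer", "tnbc")

# The cohort the generator emulates: 13 lines, 2 normal-immortalized + 5
# cancer subtypes, TNBC side = basal + claudin-low.
BREAST_PANEL_LINES: dict[str, str] = {
    "76NF2V": "Normal",
    "MCF10A": "Normal",
    "MCF7": "LuminalA",
    "ZR751": "LuminalA",
    "MB361": "LuminalB",
    "UACC812": "LuminalB",
    "SKBR3": "HER2",
    "AU565": "HER2",
    "HCC1954": "HER2",
    "MB468": "Basal",
    "HCC1937": "Basal",
    "MB231": "ClaudinLow",
    "MB436": "ClaudinLow",
}


def default_design() -> SubtypeDesign:
    return SubtypeDesign(
        lines=list(BREAST_PANEL_LINES),
        subtype_of=dict(BREAST_PANEL_LINES),
        normal_subtypes=frozenset({"Normal"}),
        tnbc_subtypes=frozenset({"Basal", "ClaudinLow"}),
    )


def default_model(
    high: float = 0.9,
    mid: float = 0.45,
    low: float = 0.05,
    self_transition: float = 0.9,
    state_labels: list[str] | None = None,
) -> ChromatinStateModel:
    """Generating 13-state model: archetype patterns with sharp emissions.

    Emission levels are deliberately sharper than the annotation archetypes
    (0.9/0.45/0.05 vs 0.8/0.4/0.1) so the generator and the labeler stay
    independent. Transitions are sticky and otherwise uniform.
    """
    labels = state_labels or STATE_LABELS
    level = {0.8: high, 0.4: mid, 0.1: low}
    E = np.array([[level[v] for v in DEFAULT_VOCABULARY[lab]] for lab in labels])
    K = len(labels)
    A = np.full((K, K), (1.0 - self_transition) / (K - 1))
    np.fill_diagonal(A, self_transition)
    pi = np.full(K, 1.0 / K)
    return ChromatinStateModel(E, A, pi, list(CORE_MARKS), list(labels))


# Expression rates (expected reads per kb of gene body) by dominant gene-body
# state. Rates follow transcription-elongation biology: gene bodies dominated
# by H3K36me3-marked states (TxAct, TxFlk, genic enhancers, ZNF clusters) are
# the productively transcribed ones; promoter-only bodies are modest and
# repressed/quiescent bodies near silent.
DEFAULT_EXPRESSION_RATES: dict[str, float] = {
    "PrAct": 10.0,
    "PrFlk": 5.0,
    "EhAct": 2.0,
    "EhGen": 30.0,
    "TxAct": 100.0,
    "TxFlk": 50.0,
    "RepPC": 1.0,
    "WkRep": 2.0,
    "PrBiv": 2.0,
    "EhBiv": 2.0,
    "RpZNF": 40.0,
    "Htchr": 1.0,
    "QsLow": 1.0,
}


@dataclass(frozen=True)
class PlantedRegion:
    """One planted differential region, in bin coordinates."""

    chrom: str
    start_bin: int
    end_bin: int
    target: str  # focal subtype, or group name for pan-cancer / tnbc
    replaced_state: int
    replacement_state: int
    signature_class: str

    def to_dict(self, grid: BinGrid, labels: list[str]) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start_bin * grid.bin_size,
            "end": min(self.end_bin * grid.bin_size, grid.chrom_sizes[self.chrom]),
            "start_bin": self.start_bin,
            "end_bin": self.end_bin,
            "target": self.target,
            "replaced_state": labels[self.replaced_state],
            "replacement_state": labels[self.replacement_state],
            "class": self.signature_class,
        }


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    backbone: dict[str, np.ndarray]
    planted: list[PlantedRegion]
    noise_rate: float
    model: ChromatinStateModel
    expression_rates: dict[str, float]
    seed: int

    def planted_by_class(self, signature_class: str) -> list[PlantedRegion]:
        return [p for p in self.planted if p.signature_class == signature_class]

    def save_json(self, path, grid: BinGrid) -> None:
        labels = self.model.labels_or_default()
        payload = {
            "seed": self.seed,
            "noise_rate": self.noise_rate,
            "bin_size": grid.bin_size,
            "planted": [p.to_dict(grid, labels) for p in self.planted],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class PlantingError(ValueError):
    """Genome too small to host all requested planted regions disjointly."""


def _sample_chain(model: ChromatinStateModel, T: int, rng: np.random.Generator) -> np.ndarray:
    cum_pi = model.start.cumsum()
    cum_A = model.transition.cumsum(axis=1)
    u = rng.random(T)
    s = np.empty(T, dtype=np.int32)
    s[0] = np.searchsorted(cum_pi, u[0])
    for t in range(1, T):
        s[t] = np.searchsorted(cum_A[s[t - 1]], u[t])
    return s


def simulate_cohort(
    design: SubtypeDesign,
    grid: BinGrid,
    model: ChromatinStateModel | None = None,
    n_planted_per_class: int = 4,
    noise_rate: float = 0.0,
    seed: int = 0,
    region_len_bins: int = 10,
    classes: tuple[str, ...] = SIGNATURE_CLASSES,
    backbone: str = "shared",
):
    """Simulate segmentations and binarized mark tracks for a cohort.

    Returns ``(truth, segmentations, marks)`` with ``segmentations[line]`` a
    :class:`Segmentation` and ``marks[line][mark][chrom]`` an int8 0/1 array.

    The backbone is drawn from the model's Markov chain and shared by every
    line (``backbone="shared"``, the cohort structure differential calling
    assumes); each planted region overrides it (target lines carry the
    replacement state, all other lines the replaced state); every line's
    remaining bins are independently resampled to a uniform random state
    with probability ``noise_rate``; finally each bin's mark vector is drawn
    from the Bernoulli emissions of that line's state. With
    ``backbone="independent"`` each line draws its own chain from the model
    (no planting allowed) — the faithful setup for parameter-recovery
    experiments, where the data must be i.i.d. sequences of the model. A
    single master seed spawns per-line and per-line-per-mark substreams, so
    outputs are bit-reproducible.
    """
    if backbone not in ("shared", "independent"):
        raise ValueError(f"unknown backbone mode {backbone!r}")
    if backbone == "independent" and n_planted_per_class > 0:
        raise ValueError("planting requires the shared backbone")
    if model is None:
        model = default_model()
    if model.n_states < 2:
        raise ValueError("generating model needs at least 2 states")
    if not 0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    K = model.n_states
    M = model.n_marks
    labels = model.labels_or_default()
    ss = np.random.SeedSequence(seed)
    n_lines = len(design.lines)
    children = ss.spawn(1 + n_lines + n_lines * M)
    rng_master = np.random.default_rng(children[0])
    rng_noise = {ln: np.random.default_rng(children[1 + i]) for i, ln in enumerate(design.lines)}
    rng_marks = {
        (ln, mk): np.random.default_rng(children[1 + n_lines + i * M + m])
        for i, ln in enumerate(design.lines)
        for m, mk in enumerate(model.mark_names)
    }

    shared_backbone = {
        c: _sample_chain(model, grid.n_bins(c), rng_master) for c in grid.chroms
    }

    # --- plant disjoint regions: candidate slots spaced region_len apart
    gap = max(2, region_len_bins // 2)
    slots = []
    for c in grid.chroms:
        b = gap
        while b + region_len_bins + gap <= grid.n_bins(c):
            slots.append((c, b))
            b += region_len_bins + gap
    n_needed = n_planted_per_class * len(classes)
    if n_needed > len(slots):
        raise PlantingError(
            f"genome hosts only {len(slots)} regions of {region_len_bins} bins, "
            f"need {n_needed}"
        )
    chosen = rng_master.choice(len(slots), size=n_needed, replace=False)
    chosen_slots = [slots[i] for i in sorted(chosen)]

    planted: list[PlantedRegion] = []
    subtype_cycle = design.subtypes
    idx = 0
    for klass in classes:
        for j in range(n_planted_per_class):
            chrom, b0 = chosen_slots[idx]
            idx += 1
            r0, r1 = rng_master.choice(K, size=2, replace=False)
            if klass in ("subtype-present", "subtype-absent"):
                target = subtype_cycle[j % len(subtype_cycle)]
            elif klass == "pan-cancer":
                target = "cancer"
            else:
                target = "tnbc"
            planted.append(
                PlantedRegion(chrom, b0, b0 + region_len_bins, target, int(r0), int(r1), klass)
            )

    planted_mask = {c: np.zeros(grid.n_bins(c), dtype=bool) for c in grid.chroms}
    for p in planted:
        planted_mask[p.chrom][p.start_bin : p.end_bin] = True

    tnbc_lines = {ln for s in design.tnbc_subtypes for ln in design.lines_of(s)}
    normal_lines = {ln for s in design.normal_subtypes for ln in design.lines_of(s)}

    def carries_replacement(line: str, p: PlantedRegion) -> bool:
        if p.signature_class in ("subtype-present", "subtype-absent"):
            return design.subtype_of[line] == p.target
        if p.signature_class == "pan-cancer":
            return line not in normal_lines
        return line in tnbc_lines  # tnbc contrast: luminal/HER2 and normals keep r0

    segs: dict[str, Segmentation] = {}
    marks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for line in design.lines:
        if backbone == "shared":
            states = {c: shared_backbone[c].copy() for c in grid.chroms}
        else:
            states = {
                c: _sample_chain(model, grid.n_bins(c), rng_noise[line])
                for c in grid.chroms
            }
        if noise_rate > 0:
            rng = rng_noise[line]
            for c in grid.chroms:
                T = grid.n_bins(c)
                flip = (rng.random(T) < noise_rate) & ~planted_mask[c]
                states[c][flip] = rng.integers(0, K, size=int(flip.sum()))
        for p in planted:
            states[p.chrom][p.start_bin : p.end_bin] = (
                p.replacement_state if carries_replacement(line, p) else p.replaced_state
            )
        seg = Segmentation(states, list(labels))
        segs[line] = seg
        marks[line] = {}
        for m, mk in enumerate(model.mark_names):
            rng = rng_marks[(line, mk)]
            marks[line][mk] = {
                c: (rng.random(grid.n_bins(c)) < model.emission[states[c], m]).astype(np.int8)
                for c in grid.chroms
            }

    truth = CohortTruth(
        shared_backbone, planted, noise_rate, model, dict(DEFAULT_EXPRESSION_RATES), seed
    )
    return truth, segs, marks


def simulate_counts(
    binary: dict[str, np.ndarray],
    lambda_on: float = 20.0,
    lambda_off: float = 0.5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-bin Poisson read counts from a 0/1 presence track.

    Counts are Poisson(lambda_on) where the mark is present and
    Poisson(lambda_off) elsewhere; lambda_on must exceed lambda_off.
    """
    if not lambda_on > lambda_off >= 0:
        raise ValueError("require lambda_on > lambda_off >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, b in binary.items():
        b = np.asarray(b)
        lam = np.where(b > 0, lambda_on, lambda_off)
        out[chrom] = rng.poisson(lam).astype(np.int64)
    return out


def gene_majority_state(seg: Segmentation, gene: Gene, grid: BinGrid) -> int:
    """Majority state over a gene body's bins; ties go to the lowest index."""
    b0, b1 = grid.bin_range(gene.chrom, gene.start, gene.end)
    if b1 <= b0:
        raise ValueError(f"gene {gene.gene_id} covers no bins")
    counts = np.bincount(seg.states[gene.chrom][b0:b1], minlength=seg.n_states)
    return int(counts.argmax())


def simulate_expression(
    genes: GeneAnnotation,
    seg: Segmentation,
    grid: BinGrid,
    rate_map: dict[str, float] | None = None,
    library_scale: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Per-gene Poisson read counts driven by the dominant gene-body state.

    count ~ Poisson(rate_map[state] * gene_length_kb * library_scale).
    """
    rates = rate_map or DEFAULT_EXPRESSION_RATES
    rng = np.random.default_rng(seed)
    counts = {}
    for g in genes:
        k = gene_majority_state(seg, g, grid)
        label = seg.labels[k]
        if label not in rates:
            raise KeyError(f"state {label!r} missing from expression rate map")
        lam = rates[label] * (g.length / 1000.0) * library_scale
        counts[g.gene_id] = int(rng.poisson(lam))
    return pd.Series(counts, name="count")


def make_genes(
    grid: BinGrid,
    n_genes: int,
    seed: int = 0,
    min_len_bins: int = 3,
    max_len_bins: int = 20,
) -> GeneAnnotation:
    """Synthetic gene annotation: non-overlapping stranded genes on the grid."""
    rng = np.random.default_rng(seed)
    genes = []
    per_chrom = -(-n_genes // len(grid.chroms))
    gid = 0
    for chrom in grid.chroms:
        n_bins = grid.n_bins(chrom)
        pos = 1
        for _ in range(per_chrom):
            if gid >= n_genes:
                break
            length = int(rng.integers(min_len_bins, max_len_bins + 1))
            if pos + length + 1 >= n_bins:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    chrom,
                    pos * grid.bin_size,
                    (pos + length) * grid.bin_size,
                    strand,
                    f"G{gid + 1:05d}",
                )
            )
            gid += 1
            pos += length + int(rng.integers(2, 6))
    return GeneAnnotation(genes)
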