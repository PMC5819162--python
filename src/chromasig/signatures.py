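"""Subtype-specific, pan-cancer and TNBC chromatin-state signature calling.

The caller works on per-cell-line segmentations that share one bin grid:

1. within-subtype consensus: a subtype has a state at a bin only if all of
   its lines agree (otherwise the bin is discordant for that subtype);
2. candidate bins: every subtype has a consensus and the subtypes do not all
   share one state;
3. subtype-specific calls: at a candidate bin a focal subtype is
   uniquely-present if its state occurs in no other subtype, and
   uniquely-absent if in addition all other subtypes share a single state the
   focal subtype lacks (the absent condition implies the present one, so
   calls are reported present-dominant with an ``uniquely_absent`` flag);
4. group contrasts: a bin is a pan-cancer signature when all normal-like
   subtypes share one state and all cancer subtypes share a different one,
   and a TNBC signature when the basal/claudin-low side differs likewise
   from the luminal/HER2 side;
5. contiguous bins with the identical call and consensus pattern are merged
   to regions, dropping runs shorter than ``min_bins``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, Gene, GeneAnnotation, GenomicInterval, Segmentation, SubtypeDesign

log = logging.getLogger(__name__)

DISCORDANT = -1

PROMOTER_FAMILY = ("PrAct", "PrFlk", "PrBiv")

# Representative histone-mark signal per state family: which mark to profile
# and over which window (gene body, TSS +/- flank, or the region itself for
# enhancer states).
DEFAULT_SIGNAL_RULES: dict[str, tuple[str, str]] = {
    "TxAct": ("H3K36me3", "genebody"),
    "TxFlk": ("H3K36me3", "genebody"),
    "RepPC": ("H3K27me3", "genebody"),
    "WkRep": ("H3K27me3", "genebody"),
    "PrAct": ("H3K4me3", "tss"),
    "PrFlk": ("H3K4me3", "tss"),
    "PrBiv": ("H3K4me3", "tss"),
    "EhAct": ("H3K4me1", "enhancer"),
    "EhGen": ("H3K4me1", "enhancer"),
    "EhBiv": ("H3K4me1", "enhancer"),
    "Htchr": ("H3K9me3", "genebody"),
}


@dataclass
class ConsensusMap:
    """Per-bin consensus state per subtype (DISCORDANT where lines disagree)."""

    subtypes: list[str]
    states: dict[str, np.ndarray]  # chrom -> (n_subtypes, n_bins) int32
    labels: list[str]

    def pattern(self, chrom: str, bin_index: int) -> tuple[int, ...]:
        return tuple(int(v) for v in self.states[chrom][:, bin_index])


@dataclass(frozen=True)
class SignatureCall:
    """A merged signature region with its per-subtype consensus pattern."""

    chrom: str
    start: int
    end: int
    start_bin: int
    end_bin: int
    signature_class: str  # subtype-present | pan-cancer | tnbc
    focal: str  # focal subtype, or "cancer"/"tnbc" for group contrasts
    state: str  # focal-side state label
    other_state: str | None  # shared opposite-side state (contrasts / absent)
    uniquely_absent: bool
    pattern: dict[str, str]  # subtype -> consensus state label

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.focal)


# ------------------------------------------------------------------ consensus

def subtype_consensus(
    segmentations: dict[str, Segmentation], design: SubtypeDesign, grid: BinGrid
) -> ConsensusMap:
    """Within-subtype consensus state per bin; disagreement -> DISCORDANT."""
    missing = [ln for ln in design.lines if ln not in segmentations]
    if missing:
        raise ValueError(f"missing segmentations for lines: {missing}")
    labels = segmentations[design.lines[0]].labels
    for ln in design.lines:
        segmentations[ln].check_grid(grid)
        if segmentations[ln].labels != labels:
            raise ValueError(f"line {ln} uses a different state vocabulary")
    subtypes = design.subtypes
    out: dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        cons = np.empty((len(subtypes), grid.n_bins(chrom)), dtype=np.int32)
        for i, st in enumerate(subtypes):
            arr = np.vstack([segmentations[ln].states[chrom] for ln in design.lines_of(st)])
            agree = (arr == arr[0]).all(axis=0)
            cons[i] = np.where(agree, arr[0], DISCORDANT)
        out[chrom] = cons
    return ConsensusMap(list(subtypes), out, list(labels))


def find_signature_bins(consensus: ConsensusMap) -> dict[str, np.ndarray]:
    """Candidate mask: all subtypes concordant and not all in one state."""
    out = {}
    for chrom, cons in consensus.states.items():
        defined = (cons != DISCORDANT).all(axis=0)
        all_same = (cons == cons[0]).all(axis=0)
        out[chrom] = defined & ~all_same
    return out


# --------------------------------------------------------------- bin classing

def classify_subtype_signature(pattern, focal: int) -> tuple[str, bool]:
    """Classify one qualifying bin pattern for a focal subtype.

    Returns ``(class, uniquely_absent)`` where class is ``present`` (the
    focal state occurs in no other subtype; reported present-dominant even
    when the absent condition co-holds) or ``none``.
    """
    pattern = list(pattern)
    mine = pattern[focal]
    others = pattern[:focal] + pattern[focal + 1 :]
    if DISCORDANT in pattern:
        return "none", False
    present = mine not in others
    absent = present and len(set(others)) == 1
    return ("present" if present else "none"), absent


def _subtype_masks(cons: np.ndarray, focal: int):
    """Vectorized present/absent masks for one focal subtype on (S, T) cons."""
    others = np.delete(cons, focal, axis=0)
    present = (others != cons[focal]).all(axis=0)
    uniform_others = (others == others[0]).all(axis=0)
    return present, present & uniform_others


def group_contrast_signature(
    consensus: ConsensusMap, side_a: list[str], side_b: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-bin group contrast: both sides internally uniform, mutually distinct.

    Returns per chrom ``(qualifies, state_a, state_b)``. Bins where any
    cohort subtype is discordant, or where all subtypes share one state, are
    never called (the global candidate filter applies).
    """
    if not side_a or not side_b:
        raise ValueError("both partition sides must be non-empty")
    idx_a = [consensus.subtypes.index(s) for s in side_a]
    idx_b = [consensus.subtypes.index(s) for s in side_b]
    candidate = find_signature_bins(consensus)
    out = {}
    for chrom, cons in consensus.states.items():
        a = cons[idx_a]
        b = cons[idx_b]
        a_uniform = (a == a[0]).all(axis=0)
        b_uniform = (b == b[0]).all(axis=0)
        qual = candidate[chrom] & a_uniform & b_uniform & (a[0] != b[0])
        out[chrom] = (qual, a[0], b[0])
    return out


# ------------------------------------------------------------------- merging

def _runs_of(mask: np.ndarray, pattern_rows: np.ndarray):
    """Maximal runs where mask holds and every pattern row is constant."""
    T = mask.size
    if T == 0:
        return
    change = np.zeros(T, dtype=bool)
    change[1:] = (pattern_rows[:, 1:] != pattern_rows[:, :-1]).any(axis=0) | (
        mask[1:] != mask[:-1]
    )
    starts = np.flatnonzero(np.concatenate([[True], change[1:]]))
    ends = np.concatenate([starts[1:], [T]])
    for s, e in zip(starts, ends):
        if mask[s]:
            yield int(s), int(e)


def merge_signature_regions(
    per_bin_mask: dict[str, np.ndarray],
    consensus: ConsensusMap,
    grid: BinGrid,
    min_bins: int = 2,
    *,
    signature_class: str,
    focal: str,
    focal_state_of,
    other_state_of=None,
    absent_of=None,
) -> list[SignatureCall]:
    """Merge per-bin calls into maximal constant-pattern regions.

    ``focal_state_of(chrom, bin)`` (and friends) provide the per-bin call
    attributes; runs shorter than ``min_bins`` are dropped.
    """
    calls = []
    labels = consensus.labels
    for chrom, mask in per_bin_mask.items():
        cons = consensus.states[chrom]
        for s, e in _runs_of(mask, cons):
            if e - s < min_bins:
                continue
            pattern = {
                st: (labels[v] if v >= 0 else "discordant")
                for st, v in zip(consensus.subtypes, cons[:, s])
            }
            start_bp = s * grid.bin_size
            end_bp = min(e * grid.bin_size, grid.chrom_sizes[chrom])
            calls.append(
                SignatureCall(
                    chrom,
                    start_bp,
                    end_bp,
                    s,
                    e,
                    signature_class,
                    focal,
                    labels[focal_state_of(chrom, s)],
                    labels[other_state_of(chrom, s)] if other_state_of else None,
                    bool(absent_of(chrom, s)) if absent_of else False,
                    pattern,
                )
            )
    return calls


# ------------------------------------------------------------------ top level

def call_signatures(
    segmentations: dict[str, Segmentation],
    design: SubtypeDesign,
    grid: BinGrid,
    min_bins: int = 2,
    contrasts: tuple[str, ...] = ("pan-cancer", "tnbc"),
) -> list[SignatureCall]:
    """Run the full signature caller over a cohort of segmentations."""
    consensus = subtype_consensus(segmentations, design, grid)
    candidate = find_signature_bins(consensus)
    calls: list[SignatureCall] = []

    for i, subtype in enumerate(consensus.subtypes):
        mask = {}
        absent = {}
        for chrom, cons in consensus.states.items():
            present_m, absent_m = _subtype_masks(cons, i)
            mask[chrom] = candidate[chrom] & present_m
            absent[chrom] = absent_m
        other_state = {
            chrom: np.delete(consensus.states[chrom], i, axis=0)[0]
            for chrom in consensus.states
        }
        calls += merge_signature_regions(
            mask,
            consensus,
            grid,
            min_bins,
            signature_class="subtype-present",
            focal=subtype,
            focal_state_of=lambda c, t, i=i: consensus.states[c][i, t],
            other_state_of=lambda c, t, i=i: (
                other_state[c][t] if absent[c][t] else consensus.states[c][i, t]
            ),
            absent_of=lambda c, t: absent[c][t],
        )
        # other_state is only meaningful when the absent condition holds;
        # patch it back to None elsewhere.
    for call in calls:
        if not call.uniquely_absent and call.other_state == call.state:
            object.__setattr__(call, "other_state", None)

    for contrast in contrasts:
        side_a, side_b = design.partition(contrast)
        if not side_a or not side_b:
            log.info("skipping %s contrast: empty side", contrast)
            continue
        # focal side is the cancer side for pan-cancer, the TNBC side for tnbc
        if contrast == "pan-cancer":
            focal_side, other_side = side_b, side_a
            focal_name = "cancer"
        else:
            focal_side, other_side = side_a, side_b
            focal_name = "tnbc"
        per_bin = group_contrast_signature(consensus, focal_side, other_side)
        mask = {c: v[0] for c, v in per_bin.items()}
        calls += merge_signature_regions(
            mask,
            consensus,
            grid,
            min_bins,
            signature_class=contrast,
            focal=focal_name,
            focal_state_of=lambda c, t: per_bin[c][1][t],
            other_state_of=lambda c, t: per_bin[c][2][t],
        )
    return calls


def calls_to_frame(calls: list[SignatureCall]) -> pd.DataFrame:
    """Tabular view of calls (one row per region, pattern serialized)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "class": c.signature_class,
                "focal": c.focal,
                "state": c.state,
                "other_state": c.other_state or "",
                "uniquely_absent": c.uniquely_absent,
                "n_bins": c.n_bins,
                "pattern": ";".join(f"{k}={v}" for k, v in c.pattern.items()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "class",
            "focal",
            "state",
            "other_state",
            "uniquely_absent",
            "n_bins",
            "pattern",
        ],
    )


# --------------------------------------------------- representative signals

def _window_max(track: dict[str, np.ndarray], grid: BinGrid, iv: GenomicInterval) -> float:
    b0, b1 = grid.bin_range(iv.chrom, iv.start, iv.end)
    if b1 <= b0:
        return 0.0
    return float(np.max(track[iv.chrom][b0:b1]))


def _overlapping_genes(genes: GeneAnnotation, call: SignatureCall) -> list[Gene]:
    return [
        g
        for g in genes
        if g.chrom == call.chrom and g.start < call.end and g.end > call.start
    ]


def representative_signal(
    calls: list[SignatureCall],
    tracks: dict[str, dict[str, dict[str, np.ndarray]]],
    genes: GeneAnnotation,
    grid: BinGrid,
    rules: dict[str, tuple[str, str]] | None = None,
    enhancers: list[GenomicInterval] | None = None,
    flank: int = 1000,
) -> pd.DataFrame:
    """Max peak-height matrix (region-or-gene x cell line) per the state rules.

    ``tracks[line][mark][chrom]`` are per-bin peak-height values. For
    gene-body rules the window is each overlapping gene's body (calls with no
    overlapping gene are omitted and logged); for promoter rules it is the
    overlapping genes' TSS +/- ``flank``; for enhancer rules the call region
    itself +/- ``flank`` (or supplied enhancer intervals overlapping it).
    """
    rules = rules or DEFAULT_SIGNAL_RULES
    lines = list(tracks)
    rows = {}
    for call in calls:
        base_state = call.state.split(".")[0]
        if base_state not in rules:
            continue
        mark, kind = rules[base_state]
        windows: list[tuple[str, GenomicInterval]] = []
        if kind in ("genebody", "tss"):
            hit_genes = _overlapping_genes(genes, call)
            if not hit_genes:
                log.info(
                    "call %s:%d-%d (%s) overlaps no gene; omitted",
                    call.chrom,
                    call.start,
                    call.end,
                    call.state,
                )
                continue
            for g in hit_genes:
                if kind == "genebody":
                    windows.append((g.gene_id, g.interval()))
                else:
                    windows.append((g.gene_id, genes.tss_window(g.gene_id, flank)))
        else:  # enhancer
            region = None
            if enhancers:
                for iv in enhancers:
                    if iv.chrom == call.chrom and iv.start < call.end and iv.end > call.start:
                        region = iv
                        break
            if region is None:
                region = call.interval()
            windows.append(
                (
                    "region",
                    GenomicInterval(
                        region.chrom,
                        max(0, region.start - flank),
                        min(grid.chrom_sizes[region.chrom], region.end + flank),
                    ),
                )
            )
        for wname, iv in windows:
            key = f"{call.chrom}:{call.start}-{call.end}|{call.focal}|{call.state}|{wname}|{mark}"
            rows[key] = [
                _window_max(tracks[ln][mark], grid, iv) if mark in tracks[ln] else np.nan
                for ln in lines
            ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=lines)


def signature_genes(
    calls: list[SignatureCall],
    genes: GeneAnnotation,
    grid: BinGrid,
    flank: int = 1000,
) -> pd.DataFrame:
    """Genes hit by each call: gene-body overlap, or TSS-window overlap for
    promoter-state calls. One row per (call, gene)."""
    rows = []
    for call in calls:
        base_state = call.state.split(".")[0]
        for g in genes:
            if g.chrom != call.chrom:
                continue
            if base_state in PROMOTER_FAMILY:
                iv = genes.tss_window(g.gene_id, flank)
                hit = iv.start < call.end and iv.end > call.start
            else:
                hit = g.start < call.end and g.end > call.start
            if hit:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "class": call.signature_class,
                        "focal": call.focal,
                        "state": call.state,
                        "chrom": call.chrom,
                        "start": call.start,
                        "end": call.end,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "class", "focal", "state", "chrom", "start", "end"]
    )
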