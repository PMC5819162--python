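"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: BED4 segmentations (ChromHMM ``_segments.bed`` dialect), bedGraph
count/peak-height tracks plus a two-column fixed-step dialect, BED6 gene
annotations, the tab-separated cohort design table, ChromHMM-style binarized
mark files, and gene x cell-line expression tables. All coordinates are
0-based half-open on disk and in memory.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import (
    BinGrid,
    Gene,
    GeneAnnotation,
    GenomeError,
    Segmentation,
    SubtypeDesign,
)


class FormatError(GenomeError):
    """Malformed on-disk file; the message names the offending row."""


# ---------------------------------------------------------------- segmentations

def write_segmentation_bed(seg: Segmentation, grid: BinGrid, path: str | os.PathLike) -> None:
    """Write a segmentation as BED4, merging equal-state bins to maximal runs."""
    seg.check_grid(grid)
    bs = grid.bin_size
    with open(path, "w") as fh:
        for chrom in grid.chroms:
            size = grid.chrom_sizes[chrom]
            for s, e, k in seg.runs(chrom):
                fh.write(f"{chrom}\t{s * bs}\t{min(e * bs, size)}\t{seg.labels[k]}\n")


def read_segmentation_bed(
    path: str | os.PathLike, grid: BinGrid, labels: list[str] | None = None
) -> Segmentation:
    """Read a BED4 segmentation that tiles every grid chromosome.

    Rows must be sorted within each chromosome, non-overlapping, gap-free and
    aligned to bin boundaries (except at chromosome ends). If ``labels`` is
    omitted the vocabulary is the sorted set of labels seen in the file.
    """
    rows: dict[str, list[tuple[int, int, str]]] = {}
    seen_labels: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns, got {len(parts)}")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom not in grid.chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            rows.setdefault(chrom, []).append((start, end, label))
            seen_labels.add(label)

    if labels is None:
        labels = sorted(seen_labels, key=_state_sort_key)
    index_of = {lab: i for i, lab in enumerate(labels)}

    states: dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        vec = np.full(n, -1, dtype=np.int32)
        pos = 0
        for start, end, label in rows.get(chrom, []):
            if start != pos:
                kind = "gap" if start > pos else "overlap"
                raise FormatError(
                    f"{path}: {kind} before row {chrom}:{start}-{end} (expected start {pos})"
                )
            if label not in index_of:
                raise FormatError(f"{path}: unknown state label {label!r} at {chrom}:{start}")
            b0, b1 = grid.bin_range(chrom, start, end)
            if b0 * grid.bin_size != start:
                raise FormatError(f"{path}: row {chrom}:{start}-{end} not bin-aligned")
            vec[b0:b1] = index_of[label]
            pos = end
        if pos != grid.chrom_sizes[chrom]:
            raise FormatError(
                f"{path}: {chrom} ends at {pos}, expected {grid.chrom_sizes[chrom]}"
            )
        states[chrom] = vec
    return Segmentation(states, list(labels))


def _state_sort_key(label: str):
    # "E2" < "E10"; non-numeric labels sort lexicographically after.
    if label[:1] == "E" and label[1:].isdigit():
        return (0, int(label[1:]), label)
    return (1, 0, label)


# ---------------------------------------------------------------------- tracks

def write_track(track: dict[str, np.ndarray], grid: BinGrid, path: str | os.PathLike) -> None:
    """Write a per-bin track as bedGraph, merging equal-value runs, skipping 0."""
    bs = grid.bin_size
    with open(path, "w") as fh:
        for chrom in grid.chroms:
            v = np.asarray(track[chrom])
            size = grid.chrom_sizes[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [v.size]])
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                txt = f"{val:g}" if isinstance(val, (float, np.floating)) else str(val)
                fh.write(f"{chrom}\t{s * bs}\t{min(e * bs, size)}\t{txt}\n")


def read_track(path: str | os.PathLike, grid: BinGrid, dtype=np.float64) -> dict[str, np.ndarray]:
    """Read a bedGraph or two-column fixed-step file onto the grid.

    bedGraph rows carry (chrom, start, end, value); a row spanning several
    bins assigns its value to every overlapped bin (step-function coverage
    semantics). The fixed-step dialect has two columns (chrom, value), one row
    per bin in grid order. Bins absent from the file are 0; negative values
    are rejected.
    """
    track = grid.zeros(dtype=dtype)
    cursor: dict[str, int] = {c: 0 for c in grid.chroms}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) == 2:  # fixed-step: chrom, value
                chrom, val = parts[0], float(parts[1])
                if chrom not in track:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if val < 0:
                    raise FormatError(f"{path}:{lineno}: negative value {val}")
                i = cursor[chrom]
                if i >= grid.n_bins(chrom):
                    raise FormatError(f"{path}:{lineno}: more rows than bins on {chrom}")
                track[chrom][i] = val
                cursor[chrom] = i + 1
            elif len(parts) >= 4:  # bedGraph
                chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in track:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if val < 0:
                    raise FormatError(f"{path}:{lineno}: negative value {val}")
                b0, b1 = grid.bin_range(chrom, start, end)
                track[chrom][b0:b1] = val
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 4 columns, got {len(parts)}")
    return track


# ------------------------------------------------------- binarized mark files

def write_binary_marks(
    binary: dict[str, dict[str, np.ndarray]],
    grid: BinGrid,
    cell_line: str,
    chrom: str,
    path: str | os.PathLike,
) -> None:
    """ChromHMM-style binarized file: header ``cell<TAB>chrom``, mark columns."""
    marks = list(binary)
    mat = np.column_stack([np.asarray(binary[m][chrom], dtype=np.int8) for m in marks])
    with open(path, "w") as fh:
        fh.write(f"{cell_line}\t{chrom}\n")
        fh.write("\t".join(marks) + "\n")
        np.savetxt(fh, mat, fmt="%d", delimiter="\t")


def read_binary_marks(path: str | os.PathLike) -> tuple[str, str, list[str], np.ndarray]:
    """Read a ChromHMM-style binarized file -> (cell, chrom, marks, T x M array)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise FormatError(f"{path}: first line must be 'cell<TAB>chrom'")
        marks = fh.readline().rstrip("\n").split("\t")
        mat = np.loadtxt(fh, dtype=np.int8, ndmin=2)
    if mat.size and not np.isin(mat, (0, 1)).all():
        raise FormatError(f"{path}: non-binary entries")
    return header[0], header[1], marks, mat


# ------------------------------------------------------------- design & genes

def write_design(design: SubtypeDesign, path: str | os.PathLike) -> None:
    rows = []
    for ln in design.lines:
        st = design.subtype_of[ln]
        is_normal = st in design.normal_subtypes
        side = "na" if is_normal else ("tnbc" if st in design.tnbc_subtypes else "luminal")
        rows.append((ln, st, int(is_normal), side))
    pd.DataFrame(rows, columns=["cell_line", "subtype", "is_normal", "tnbc_side"]).to_csv(
        path, sep="\t", index=False
    )


def read_design(path: str | os.PathLike) -> SubtypeDesign:
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "subtype": str})
    required = {"cell_line", "subtype", "is_normal", "tnbc_side"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: design table needs columns {sorted(required)}")
    normals = frozenset(df.loc[df.is_normal.astype(int) == 1, "subtype"])
    tnbc = frozenset(df.loc[df.tnbc_side == "tnbc", "subtype"])
    return SubtypeDesign(
        lines=list(df.cell_line),
        subtype_of=dict(zip(df.cell_line, df.subtype)),
        normal_subtypes=normals,
        tnbc_subtypes=tnbc,
    )


def write_genes_bed(genes: GeneAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path: str | os.PathLike) -> GeneAnnotation:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6, got {len(p)} columns")
            genes.append(Gene(p[0], int(p[1]), int(p[2]), p[5], p[3]))
    return GeneAnnotation(genes)


# ------------------------------------------------------------------ expression

def write_expression(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Gene x cell-line integer read counts, genes as the index."""
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------- model tables

def write_matrix_tsv(mat: np.ndarray, row_names: Iterable, col_names: Iterable, path) -> None:
    pd.DataFrame(np.asarray(mat), index=list(row_names), columns=list(col_names)).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
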