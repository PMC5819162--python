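"""End-to-end driver: simulate -> binarize -> train -> segment -> annotate ->
signatures -> variability -> expression, from one YAML config.

Every stage writes plain-text outputs under the run directory and registers
them in ``manifest.json`` (stage, files, sha256 checksums, seeds), so a rerun
with the same config is checkably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .annotate import assign_state_labels, fold_enrichment, linkage_to_newick
from .binarize import BinarizationSpec, binarize_track
from .genome import BinGrid, Segmentation, SubtypeDesign
from .hmm import baum_welch, decode, save_model, select_model
from .signatures import call_signatures, calls_to_frame, representative_signal, signature_genes
from .simulate import (
    DEFAULT_EXPRESSION_RATES,
    default_design,
    default_model,
    make_genes,
    simulate_cohort,
    simulate_counts,
    simulate_expression,
)
from .variability import (
    cluster_regions,
    fpkm_table,
    gene_state_expression,
    mark_expression_correlation,
    top_variable_regions,
    variability_table,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Fully defaulted run configuration (YAML-serializable)."""

    out_dir: str = "chromasig_run"
    seed: int = 0
    bin_size: int = 200
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_500_000, "chr2": 1_500_000}
    )
    design: str | None = None  # path to a design TSV; None -> the 13-line default
    n_planted_per_class: int = 4
    noise_rate: float = 0.02
    region_len_bins: int = 10
    lambda_on: float = 20.0
    lambda_off: float = 0.5
    p_threshold: float = 1e-4
    n_states: int | None = 13  # force K; None -> scan k_range
    k_range: list[int] = field(default_factory=lambda: [10, 20])
    train_max_iter: int = 300
    train_n_init: int = 3
    min_bins: int = 2
    n_genes: int = 300
    n_top_variable: int = 1000
    demo_states: int | None = None  # use a reduced generating model of this size

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Small end-to-end demo: 3 subtypes x 2 lines, ~20k bins, 6 states."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        chrom_sizes={"chr1": 2_500_000, "chr2": 1_500_000},
        n_states=6,
        demo_states=6,
        n_genes=200,
        n_top_variable=200,
        design="__demo__",
    )


def _demo_design() -> SubtypeDesign:
    lines = {
        "NORM1": "Normal",
        "NORM2": "Normal",
        "LUMA1": "LuminalA",
        "LUMA2": "LuminalA",
        "BAS1": "Basal",
        "BAS2": "Basal",
    }
    return SubtypeDesign(
        lines=list(lines),
        subtype_of=lines,
        normal_subtypes=frozenset({"Normal"}),
        tnbc_subtypes=frozenset({"Basal"}),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, root: Path, config: PipelineConfig):
        self.root = root
        self.data = {"config": asdict(config), "stages": []}

    def stage(self, name: str, files: list[Path], seed: int | None = None, **extra):
        self.data["stages"].append(
            {
                "stage": name,
                "seed": seed,
                "files": {str(p.relative_to(self.root)): _sha256(p) for p in sorted(files)},
                **extra,
            }
        )

    def write(self):
        with open(self.root / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict. Fails fast, naming the stage."""
    t0 = time.time()
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(root, config)
    stage = "setup"
    try:
        grid = BinGrid(config.chrom_sizes, config.bin_size)
        if config.design == "__demo__":
            design = _demo_design()
        elif config.design:
            if not Path(config.design).exists():
                raise PipelineError(f"design table not found: {config.design}")
            design = io.read_design(config.design)
        else:
            design = default_design()

        if config.demo_states:
            labels = ["PrAct", "EhAct", "TxAct", "RepPC", "Htchr", "QsLow"][: config.demo_states]
            model_gen = default_model(state_labels=labels)
        else:
            model_gen = default_model()

        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        sim_dir = root / "simulated"
        sim_dir.mkdir(exist_ok=True)
        truth, segs, marks = simulate_cohort(
            design,
            grid,
            model_gen,
            n_planted_per_class=config.n_planted_per_class,
            noise_rate=config.noise_rate,
            seed=config.seed,
            region_len_bins=config.region_len_bins,
        )
        files = [sim_dir / "design.tsv", sim_dir / "truth.json", sim_dir / "genes.bed"]
        io.write_design(design, files[0])
        truth.save_json(files[1], grid)
        genes = make_genes(grid, config.n_genes, seed=config.seed + 1)
        io.write_genes_bed(genes, files[2])
        counts: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        rng_counts = np.random.SeedSequence(config.seed).spawn(1)[0].spawn(
            len(design.lines) * len(model_gen.mark_names)
        )
        ci = 0
        for line in design.lines:
            p = sim_dir / f"{line}_segments.bed"
            io.write_segmentation_bed(segs[line], grid, p)
            files.append(p)
            counts[line] = {}
            for mark in model_gen.mark_names:
                sub_seed = int(rng_counts[ci].generate_state(1)[0] % (2**31))
                ci += 1
                counts[line][mark] = simulate_counts(
                    marks[line][mark], config.lambda_on, config.lambda_off, seed=sub_seed
                )
                p = sim_dir / f"{line}_{mark}.bedgraph"
                io.write_track(counts[line][mark], grid, p)
                files.append(p)
        expr_dir = sim_dir
        expr = pd.DataFrame(
            {
                line: simulate_expression(
                    genes, segs[line], grid, truth.expression_rates, seed=config.seed + 17 + i
                )
                for i, line in enumerate(design.lines)
            }
        )
        io.write_expression(expr, expr_dir / "expression.tsv")
        files.append(expr_dir / "expression.tsv")
        manifest.stage("simulate", files, seed=config.seed, n_planted=len(truth.planted))

        # ---- binarize ------------------------------------------------------
        stage = "binarize"
        bin_dir = root / "binarized"
        bin_dir.mkdir(exist_ok=True)
        spec = BinarizationSpec(p_threshold=config.p_threshold)
        binary = {
            line: {mark: binarize_track(counts[line][mark], spec) for mark in model_gen.mark_names}
            for line in design.lines
        }
        files = []
        for line in design.lines:
            for chrom in grid.chroms:
                p = bin_dir / f"{line}_{chrom}_binary.txt"
                io.write_binary_marks(binary[line], grid, line, chrom, p)
                files.append(p)
        manifest.stage("binarize", files, p_threshold=config.p_threshold)

        # ---- train ---------------------------------------------------------
        stage = "train"
        model_dir = root / "model"
        model_dir.mkdir(exist_ok=True)
        sequences = [
            np.column_stack([binary[line][m][chrom] for m in model_gen.mark_names])
            for line in design.lines
            for chrom in grid.chroms
        ]
        if config.n_states:
            model, _ = baum_welch(
                sequences,
                config.n_states,
                seed=config.seed,
                max_iter=config.train_max_iter,
                n_init=config.train_n_init,
                mark_names=model_gen.mark_names,
            )
            diag = None
        else:
            lo, hi = config.k_range
            model, diag = select_model(
                sequences,
                range(lo, hi + 1),
                seed=config.seed,
                max_iter=config.train_max_iter,
                n_init=config.train_n_init,
                mark_names=model_gen.mark_names,
            )
        files = [model_dir / "emissions.tsv", model_dir / "transitions.tsv"]
        save_model(model, files[0], files[1])
        if diag is not None:
            diag.to_csv(model_dir / "model_selection.tsv", sep="\t")
            files.append(model_dir / "model_selection.tsv")
        manifest.stage("train", files, seed=config.seed, K=model.n_states)

        # ---- segment -------------------------------------------------------
        stage = "segment"
        seg_dir = root / "segmentation"
        seg_dir.mkdir(exist_ok=True)
        decoded: dict[str, Segmentation] = {}
        tmp_labels = model.labels_or_default()
        files = []
        for line in design.lines:
            states = {}
            for chrom in grid.chroms:
                X = np.column_stack([binary[line][m][chrom] for m in model_gen.mark_names])
                states[chrom] = decode(model, X, mode="viterbi")
            decoded[line] = Segmentation(states, tmp_labels)

        # ---- annotate ------------------------------------------------------
        stage = "annotate"
        categories = {
            "tss": [genes.tss_window(g.gene_id) for g in genes],
            "genebody": [g.interval() for g in genes],
        }
        ref_line = design.lines[0]
        enrich = fold_enrichment(decoded[ref_line], categories, grid)
        label_map = assign_state_labels(model, enrich)
        labels = [label_map[k] for k in range(model.n_states)]
        model.state_labels = labels
        for line in design.lines:
            decoded[line] = Segmentation(decoded[line].states, labels)
            p = seg_dir / f"{line}_segments.bed"
            io.write_segmentation_bed(decoded[line], grid, p)
            files.append(p)
        ann_dir = root / "annotation"
        ann_dir.mkdir(exist_ok=True)
        enrich.index = labels
        enrich.to_csv(ann_dir / "enrichment.tsv", sep="\t")
        pd.Series(labels, name="label").rename_axis("state").to_csv(
            ann_dir / "state_labels.tsv", sep="\t"
        )
        files += [ann_dir / "enrichment.tsv", ann_dir / "state_labels.tsv"]
        manifest.stage("segment+annotate", files, K=model.n_states)

        # ---- signatures ----------------------------------------------------
        stage = "signatures"
        sig_dir = root / "signatures"
        sig_dir.mkdir(exist_ok=True)
        calls = call_signatures(decoded, design, grid, min_bins=config.min_bins)
        frame = calls_to_frame(calls)
        frame.to_csv(sig_dir / "signature_calls.tsv", sep="\t", index=False)
        genes_hit = signature_genes(calls, genes, grid)
        genes_hit.to_csv(sig_dir / "signature_genes.tsv", sep="\t", index=False)
        heights = {line: counts[line] for line in design.lines}
        signal = representative_signal(calls, heights, genes, grid)
        signal.to_csv(sig_dir / "representative_signal.tsv", sep="\t")
        files = [
            sig_dir / "signature_calls.tsv",
            sig_dir / "signature_genes.tsv",
            sig_dir / "representative_signal.tsv",
        ]
        manifest.stage("signatures", files, n_calls=len(calls))

        # ---- variability ---------------------------------------------------
        stage = "variability"
        var_dir = root / "variability"
        var_dir.mkdir(exist_ok=True)
        vtab = variability_table(decoded)
        vtab.to_csv(var_dir / "state_variability.tsv", sep="\t")
        files = [var_dir / "state_variability.tsv"]
        if len(signal) >= 2:
            std = top_variable_regions(signal.dropna(axis=1), n_top=config.n_top_variable)
            if len(std) >= 2:
                Z, leaves = cluster_regions(std)
                (var_dir / "region_dendrogram.nwk").write_text(
                    linkage_to_newick(Z, list(std.index))
                )
                std.to_csv(var_dir / "top_variable_regions.tsv", sep="\t")
                files += [var_dir / "region_dendrogram.nwk", var_dir / "top_variable_regions.tsv"]
        manifest.stage("variability", files)

        # ---- expression ----------------------------------------------------
        stage = "expression"
        ex_dir = root / "expression"
        ex_dir.mkdir(exist_ok=True)
        lengths = pd.Series({g.gene_id: g.length for g in genes})
        fpkms = fpkm_table(expr, lengths)
        fpkms.to_csv(ex_dir / "fpkm.tsv", sep="\t", float_format="%.4f")
        per_gene, summary = gene_state_expression(
            decoded[ref_line], genes, fpkms[ref_line], grid
        )
        summary.to_csv(ex_dir / "state_expression_summary.tsv", sep="\t")
        def _genebody_occupancy(track, g):
            b0, b1 = grid.bin_range(g.chrom, g.start, g.end)
            return float(np.mean(track[g.chrom][b0:b1])) if b1 > b0 else 0.0

        k36 = {}
        for line in design.lines:
            sig = pd.Series(
                {g.gene_id: _genebody_occupancy(counts[line]["H3K36me3"], g) for g in genes}
            )
            k36[line] = mark_expression_correlation(sig, fpkms[line])
        pd.Series(k36, name="spearman_rho").rename_axis("cell_line").to_csv(
            ex_dir / "h3k36me3_expression_spearman.tsv", sep="\t"
        )
        files = [
            ex_dir / "fpkm.tsv",
            ex_dir / "state_expression_summary.tsv",
            ex_dir / "h3k36me3_expression_spearman.tsv",
        ]
        manifest.stage("expression", files)

        manifest.data["elapsed_seconds"] = round(time.time() - t0, 2)
        manifest.write()
        config.to_yaml(root / "config.yaml")
        return manifest.data
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with failing stage
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
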