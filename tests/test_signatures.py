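"""Signature caller vs independent brute-force classification, plus windows."""

import numpy as np
import pandas as pd
import pytest

from chromasig.genome import (
    BinGrid,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    Segmentation,
    SubtypeDesign,
)
from chromasig.signatures import (
    DISCORDANT,
    call_signatures,
    classify_subtype_signature,
    find_signature_bins,
    group_contrast_signature,
    merge_signature_regions,
    representative_signal,
    signature_genes,
    subtype_consensus,
)
from chromasig.simulate import default_design, simulate_cohort


def make_segs(grid, design, per_line_states, labels):
    return {
        line: Segmentation({"chr1": np.asarray(per_line_states[line])}, labels)
        for line in design.lines
    }


# ------------------------------------------------- independent oracle helpers

def oracle_consensus(states_by_line, design):
    """Bin-by-bin pure-Python re-evaluation of the subtype consensus."""
    n_bins = len(next(iter(states_by_line.values())))
    out = {}
    for st in design.subtypes:
        lines = design.lines_of(st)
        vals = []
        for b in range(n_bins):
            seen = {states_by_line[ln][b] for ln in lines}
            vals.append(seen.pop() if len(seen) == 1 else DISCORDANT)
        out[st] = vals
    return out


def oracle_bin_calls(cons, design):
    """Per-bin qualifying flag + per-focal present/absent + group contrasts."""
    subtypes = design.subtypes
    n_bins = len(cons[subtypes[0]])
    result = []
    for b in range(n_bins):
        pattern = [cons[s][b] for s in subtypes]
        defined = DISCORDANT not in pattern
        qualifies = defined and len(set(pattern)) > 1
        per_focal = {}
        for i, s in enumerate(subtypes):
            others = pattern[:i] + pattern[i + 1 :]
            present = qualifies and pattern[i] not in others
            absent = present and len(set(others)) == 1
            per_focal[s] = (present, absent)
        contrasts = {}
        for name in ("pan-cancer", "tnbc"):
            a, bb = design.partition(name)
            if not a or not bb:
                continue
            sa = {cons[s][b] for s in a}
            sb = {cons[s][b] for s in bb}
            contrasts[name] = (
                qualifies and len(sa) == 1 and len(sb) == 1 and sa != sb
            )
        result.append((qualifies, per_focal, contrasts))
    return result


class TestConsensus:
    def test_agreement_and_discord(self, design3):
        grid = BinGrid({"chr1": 600}, 200)
        labels = ["E1", "E2"]
        states = {
            "N1": [0, 0, 1],
            "N2": [0, 1, 1],
            "L1": [1, 1, 0],
            "L2": [1, 1, 0],
            "T1": [0, 0, 0],
            "T2": [0, 0, 0],
        }
        cons = subtype_consensus(make_segs(grid, design3, states, labels), design3, grid)
        np.testing.assert_array_equal(cons.states["chr1"][0], [0, DISCORDANT, 1])
        np.testing.assert_array_equal(cons.states["chr1"][1], [1, 1, 0])
        np.testing.assert_array_equal(cons.states["chr1"][2], [0, 0, 0])

    def test_single_line_subtype_vacuous(self):
        design = SubtypeDesign(
            ["a", "b"], {"a": "X", "b": "Y"}, frozenset({"X"}), frozenset()
        )
        grid = BinGrid({"chr1": 400}, 200)
        segs = {
            "a": Segmentation({"chr1": np.array([0, 1])}, ["E1", "E2"]),
            "b": Segmentation({"chr1": np.array([1, 1])}, ["E1", "E2"]),
        }
        cons = subtype_consensus(segs, design, grid)
        np.testing.assert_array_equal(cons.states["chr1"][0], [0, 1])

    def test_missing_line_rejected(self, design3):
        grid = BinGrid({"chr1": 400}, 200)
        with pytest.raises(ValueError, match="missing"):
            subtype_consensus({}, design3, grid)


class TestFindSignatureBins:
    def test_all_same_filtered_and_mixed_qualifies(self, design3):
        grid = BinGrid({"chr1": 600}, 200)
        labels = ["A", "B"]
        # bins: (A,A,A) -> out; (A,B,B) -> in; discordant Normal -> out
        states = {
            "N1": [0, 0, 0],
            "N2": [0, 0, 1],
            "L1": [0, 1, 1],
            "L2": [0, 1, 1],
            "T1": [0, 1, 0],
            "T2": [0, 1, 0],
        }
        cons = subtype_consensus(make_segs(grid, design3, states, labels), design3, grid)
        np.testing.assert_array_equal(find_signature_bins(cons)["chr1"], [False, True, False])


class TestClassifyPattern:
    def test_present_and_absent_co_occur(self):
        # focal state unique and all others share one state: present-dominant
        klass, absent = classify_subtype_signature([1, 0, 0, 0, 0, 0], focal=0)
        assert (klass, absent) == ("present", True)

    def test_shared_focal_state_is_none(self):
        klass, absent = classify_subtype_signature([1, 1, 0, 0, 0, 0], focal=0)
        assert (klass, absent) == ("none", False)

    def test_all_distinct_every_focal_present(self):
        pattern = [0, 1, 2, 3, 4, 5]
        for focal in range(6):
            klass, absent = classify_subtype_signature(pattern, focal)
            assert klass == "present"
            assert not absent

    def test_discordant_disqualifies(self):
        assert classify_subtype_signature([1, DISCORDANT, 0], 0) == ("none", False)


class TestGroupContrast:
    def test_example_and_swap(self, design3):
        grid = BinGrid({"chr1": 600}, 200)
        labels = ["QsLow", "RepPC"]
        states = {
            "N1": [0, 0, 1],
            "N2": [0, 0, 1],
            "L1": [1, 0, 1],
            "L2": [1, 0, 1],
            "T1": [1, 0, 0],
            "T2": [1, 1, 0],
        }
        cons = subtype_consensus(make_segs(grid, design3, states, labels), design3, grid)
        out = group_contrast_signature(cons, ["Normal"], ["Luminal", "Basal"])
        qual, a, b = out["chr1"]
        # bin0: normals QsLow, cancers RepPC -> qualifies; bin1: all same;
        # bin2: cancer sides disagree
        np.testing.assert_array_equal(qual, [True, False, False])
        assert (a[0], b[0]) == (0, 1)
        # swapping sides preserves the region set and swaps the states
        out2 = group_contrast_signature(cons, ["Luminal", "Basal"], ["Normal"])
        qual2, a2, b2 = out2["chr1"]
        np.testing.assert_array_equal(qual, qual2)
        assert (a2[0], b2[0]) == (1, 0)

    def test_empty_side_rejected(self, design3):
        grid = BinGrid({"chr1": 400}, 200)
        states = {ln: [0, 0] for ln in design3.lines}
        cons = subtype_consensus(make_segs(grid, design3, states, ["A"]), design3, grid)
        with pytest.raises(ValueError):
            group_contrast_signature(cons, [], ["Normal"])


class TestMergeRegions:
    def test_contiguous_run_merges(self, design3):
        grid = BinGrid({"chr1": 2000}, 200)  # 10 bins
        labels = ["A", "B"]
        states = {
            ln: ([1] * 10 if design3.subtype_of[ln] == "Basal" else [0] * 10)
            for ln in design3.lines
        }
        calls = call_signatures(make_segs(grid, design3, states, labels), design3, grid)
        basal = [c for c in calls if c.focal == "Basal"]
        assert len(basal) == 1
        assert (basal[0].start, basal[0].end, basal[0].n_bins) == (0, 2000, 10)
        assert basal[0].uniquely_absent  # Normal+Luminal share state A

    def test_single_bin_dropped_by_min_bins(self, design3):
        grid = BinGrid({"chr1": 1000}, 200)
        labels = ["A", "B"]
        base = [0, 0, 0, 0, 0]
        basal = [0, 0, 1, 0, 0]  # isolated single qualifying bin
        states = {
            ln: (basal if design3.subtype_of[ln] == "Basal" else base)
            for ln in design3.lines
        }
        calls = call_signatures(make_segs(grid, design3, states, labels), design3, grid, min_bins=2)
        assert calls == []
        calls1 = call_signatures(
            make_segs(grid, design3, states, labels), design3, grid, min_bins=1
        )
        assert len([c for c in calls1 if c.signature_class == "subtype-present"]) == 1

    def test_run_length_encoding_oracle(self, design3, rng):
        # random per-line states; region starts/ends must match a pure-Python
        # run-length encoding over (qualify, full pattern)
        grid = BinGrid({"chr1": 100 * 200}, 200)
        labels = ["A", "B", "C"]
        for _ in range(10):
            states = {ln: rng.integers(0, 3, 100).tolist() for ln in design3.lines}
            segs = make_segs(grid, design3, states, labels)
            calls = call_signatures(segs, design3, grid, min_bins=1, contrasts=())
            cons = oracle_consensus(states, design3)
            bins = oracle_bin_calls(cons, design3)
            expected = []
            for i, st in enumerate(design3.subtypes):
                runs = []
                prev_key = None
                for b in range(100):
                    present = bins[b][1][st][0]
                    pattern = tuple(cons[s][b] for s in design3.subtypes)
                    key = (present, pattern) if present else None
                    if key is not None and key == prev_key:
                        runs[-1][1] = b + 1
                    elif key is not None:
                        runs.append([b, b + 1, st])
                    prev_key = key
                expected += [tuple(r) for r in runs]
            got = sorted((c.start_bin, c.end_bin, c.focal) for c in calls)
            assert got == sorted(expected)


class TestCallerMatchesOracle:
    def test_random_cohorts(self, rng):
        design = default_design()
        grid = BinGrid({"chr1": 60 * 200}, 200)
        labels = ["A", "B", "C", "D"]
        for _ in range(50):
            states = {ln: rng.integers(0, 4, 60).tolist() for ln in design.lines}
            segs = make_segs(grid, design, states, labels)
            calls = call_signatures(segs, design, grid, min_bins=1)
            cons = oracle_consensus(states, design)
            bins = oracle_bin_calls(cons, design)
            # collapse calls back to per-bin flags and compare exhaustively
            got_present = {
                (b, c.focal)
                for c in calls
                if c.signature_class == "subtype-present"
                for b in range(c.start_bin, c.end_bin)
            }
            exp_present = {
                (b, st)
                for b, (_, per_focal, _) in enumerate(bins)
                for st, (present, _) in per_focal.items()
                if present
            }
            assert got_present == exp_present
            for name, focal in (("pan-cancer", "cancer"), ("tnbc", "tnbc")):
                got = {
                    b
                    for c in calls
                    if c.signature_class == name
                    for b in range(c.start_bin, c.end_bin)
                }
                exp = {b for b, (_, _, con) in enumerate(bins) if con.get(name)}
                assert got == exp, name

    def test_line_order_within_subtype_irrelevant(self, design3, rng):
        grid = BinGrid({"chr1": 50 * 200}, 200)
        labels = ["A", "B"]
        states = {ln: rng.integers(0, 2, 50).tolist() for ln in design3.lines}
        segs = make_segs(grid, design3, states, labels)
        calls1 = call_signatures(segs, design3, grid)
        swapped = SubtypeDesign(
            ["N2", "N1", "L2", "L1", "T2", "T1"],
            design3.subtype_of,
            design3.normal_subtypes,
            design3.tnbc_subtypes,
        )
        calls2 = call_signatures(segs, swapped, grid)
        key = lambda c: (c.chrom, c.start, c.end, c.signature_class, c.focal, c.state)
        assert sorted(map(key, calls1)) == sorted(map(key, calls2))

    def test_filtered_bins_never_called(self, design3, rng):
        grid = BinGrid({"chr1": 80 * 200}, 200)
        labels = ["A", "B", "C"]
        states = {ln: rng.integers(0, 3, 80).tolist() for ln in design3.lines}
        segs = make_segs(grid, design3, states, labels)
        cons = subtype_consensus(segs, design3, grid)
        qualify = find_signature_bins(cons)["chr1"]
        calls = call_signatures(segs, design3, grid, min_bins=1)
        for c in calls:
            assert qualify[c.start_bin : c.end_bin].all()


class TestPlantedRecovery:
    def test_noise_free_cohort_full_recovery(self):
        design = default_design()
        grid = BinGrid({"chr1": 500_000, "chr2": 300_000}, 200)
        truth, segs, _ = simulate_cohort(
            design, grid, n_planted_per_class=3, noise_rate=0.0, seed=21
        )
        calls = call_signatures(segs, design, grid)

        def hit(p):
            for c in calls:
                if c.chrom == p.chrom and c.start_bin < p.end_bin and c.end_bin > p.start_bin:
                    if p.signature_class in ("subtype-present", "subtype-absent"):
                        if c.signature_class == "subtype-present" and c.focal == p.target:
                            return True
                    elif c.signature_class == p.signature_class:
                        return True
            return False

        assert all(hit(p) for p in truth.planted)
        planted_bins = {
            (p.chrom, b) for p in truth.planted for b in range(p.start_bin, p.end_bin)
        }
        for c in calls:
            assert any(
                (c.chrom, b) in planted_bins for b in range(c.start_bin, c.end_bin)
            ), "false-positive region outside planted truth"


class TestRepresentativeSignal:
    @pytest.fixture
    def setup(self, design3):
        grid = BinGrid({"chr1": 4000}, 200)  # 20 bins
        genes = GeneAnnotation([Gene("chr1", 800, 2000, "+", "g1")])
        return grid, genes

    def _call(self, state, start=800, end=1600):
        from chromasig.signatures import SignatureCall

        return SignatureCall(
            "chr1", start, end, start // 200, end // 200,
            "subtype-present", "Basal", state, None, False, {},
        )

    def test_constant_track(self, setup, design3):
        grid, genes = setup
        tracks = {
            ln: {"H3K36me3": {"chr1": np.full(20, 7.0)}} for ln in design3.lines
        }
        out = representative_signal([self._call("TxAct")], tracks, genes, grid)
        assert out.shape == (1, 6)
        assert (out.to_numpy() == 7.0).all()

    def test_single_spike(self, setup, design3):
        grid, genes = setup
        track = np.zeros(20)
        track[6] = 17.0  # inside g1's body (bins 4..9)
        tracks = {ln: {"H3K36me3": {"chr1": track}} for ln in design3.lines}
        out = representative_signal([self._call("TxAct")], tracks, genes, grid)
        assert (out.to_numpy() == 17.0).all()

    def test_promoter_rule_uses_tss_window(self, setup, design3):
        grid, genes = setup
        track = np.zeros(20)
        track[1] = 5.0  # bin 1 is inside TSS(800) +/- 1000 = [0, 1800)
        track[12] = 9.0  # outside the window
        tracks = {ln: {"H3K4me3": {"chr1": track}} for ln in design3.lines}
        out = representative_signal([self._call("PrAct")], tracks, genes, grid)
        assert (out.to_numpy() == 5.0).all()

    def test_no_overlapping_gene_omitted(self, design3):
        grid = BinGrid({"chr1": 4000}, 200)
        genes = GeneAnnotation([Gene("chr1", 3000, 3800, "+", "far")])
        tracks = {ln: {"H3K36me3": {"chr1": np.ones(20)}} for ln in design3.lines}
        out = representative_signal([self._call("TxAct")], tracks, genes, grid)
        assert out.empty

    def test_matches_brute_force_window_max(self, design3, rng):
        grid = BinGrid({"chr1": 100 * 200}, 200)
        genes = GeneAnnotation([Gene("chr1", 4000, 10_000, "+", "g")])
        for _ in range(50):
            track = rng.random(100) * 10
            tracks = {ln: {"H3K36me3": {"chr1": track}} for ln in design3.lines}
            s = int(rng.integers(0, 95))
            call = self._call("TxAct", s * 200, (s + 3) * 200)
            out = representative_signal([call], tracks, genes, grid)
            if call.end <= 4000 or call.start >= 10_000:
                assert out.empty
            else:
                assert out.iloc[0, 0] == pytest.approx(track[20:50].max())


class TestSignatureGenes:
    def test_region_inside_gene_listed(self, design3):
        grid = BinGrid({"chr1": 4000}, 200)
        genes = GeneAnnotation([Gene("chr1", 400, 2000, "+", "g1")])
        from chromasig.signatures import SignatureCall

        call = SignatureCall(
            "chr1", 800, 1200, 4, 6, "subtype-present", "Basal", "TxAct", None, False, {}
        )
        out = signature_genes([call], genes, grid)
        assert list(out.gene_id) == ["g1"]

    def test_intergenic_region_empty(self, design3):
        grid = BinGrid({"chr1": 4000}, 200)
        genes = GeneAnnotation([Gene("chr1", 3000, 3600, "+", "g1")])
        from chromasig.signatures import SignatureCall

        call = SignatureCall(
            "chr1", 0, 400, 0, 2, "subtype-present", "Basal", "TxAct", None, False, {}
        )
        assert signature_genes([call], genes, grid).empty

    def test_matches_overlap_oracle(self, rng):
        grid = BinGrid({"chr1": 200 * 200}, 200)
        from chromasig.signatures import PROMOTER_FAMILY, SignatureCall

        genes = []
        pos = 0
        i = 0
        while pos < 190:
            length = int(rng.integers(2, 10))
            genes.append(
                Gene("chr1", pos * 200, (pos + length) * 200, "+" if rng.random() < 0.5 else "-", f"g{i}")
            )
            pos += length + int(rng.integers(1, 4))
            i += 1
        ann = GeneAnnotation(genes)
        for _ in range(100):
            s = int(rng.integers(0, 195))
            e = s + int(rng.integers(1, 6))
            state = ["TxAct", "PrAct", "RepPC"][int(rng.integers(0, 3))]
            call = SignatureCall(
                "chr1", s * 200, e * 200, s, e, "subtype-present", "X", state, None, False, {}
            )
            got = set(signature_genes([call], ann, grid).gene_id)
            exp = set()
            for g in genes:
                if state in PROMOTER_FAMILY:
                    lo, hi = max(0, g.tss - 1000), g.tss + 1000
                else:
                    lo, hi = g.start, g.end
                if lo < e * 200 and hi > s * 200:
                    exp.add(g.gene_id)
            assert got == exp
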