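"""Max-gap merging, Simes/BH, gene assignment and feature annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tadascope.genome import Fragment, GatcMap, Gene, GeneSet
from tadascope.peaks import (
    annotate_peak_features,
    assign_genes,
    bh_adjust,
    call_peaks,
    feature_proportions,
    merge_gatcs,
    peaks_to_frame,
    score_peaks,
    simes_combine,
    Peak,
)


def toy_map(intervals, contig="c", length=100_000):
    """Build a GatcMap-like object holding arbitrary fragments for merging."""
    frags = [
        Fragment(f"{contig}:{a}-{b}", contig, a, b) for a, b in intervals
    ]
    sites = np.array([a for a, _ in intervals], dtype=np.int64)
    return GatcMap(
        sites={contig: sites}, fragments=frags, contig_lengths={contig: length}
    )


def stats_for(gmap, logfc=None, p=None):
    ids = gmap.fragment_ids
    n = len(ids)
    return pd.DataFrame(
        {
            "fragment_id": ids,
            "logFC": logfc if logfc is not None else np.ones(n),
            "p": p if p is not None else np.full(n, 1e-6),
        }
    ).set_index("fragment_id", drop=False)


class TestMergeGatcs:
    def test_hand_clustering_at_gaps_300_and_500(self):
        gmap = toy_map([(0, 100), (400, 500), (1000, 1100)])
        stats = stats_for(gmap)
        peaks = merge_gatcs(stats, gmap, tolerance=350)
        members = [pk.members for pk in peaks]
        assert members == [["c:0-100", "c:400-500"], ["c:1000-1100"]]

    def test_single_fragment_single_peak(self):
        gmap = toy_map([(10, 60)])
        peaks = merge_gatcs(stats_for(gmap), gmap, tolerance=350)
        assert len(peaks) == 1 and peaks[0].n_gatc == 1

    def test_empty_input_empty_output(self):
        gmap = toy_map([(10, 60)])
        stats = stats_for(gmap).iloc[:0]
        assert merge_gatcs(stats, gmap, tolerance=100) == []

    def test_mean_logfc_within_member_range_and_mixed_flag(self):
        gmap = toy_map([(0, 100), (150, 250)])
        stats = stats_for(gmap, logfc=np.array([2.0, -1.0]))
        (pk,) = merge_gatcs(stats, gmap, tolerance=350)
        assert -1.0 <= pk.mean_logfc <= 2.0
        assert pk.mixed_sign

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(50_000, size=200, replace=False))
        intervals = [(int(s), int(s) + int(rng.integers(10, 200))) for s in starts]
        # drop overlapping intervals to respect the tiling assumption
        pruned = []
        for a, b in intervals:
            if not pruned or a >= pruned[-1][1]:
                pruned.append((a, b))
        gmap = toy_map(pruned)
        tol = int(rng.integers(0, 500))
        peaks = merge_gatcs(stats_for(gmap), gmap, tolerance=tol)
        got = [pk.members for pk in peaks]

        # O(n^2) transitive closure on the 'gap <= tol' adjacency
        n = len(pruned)
        adj = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            gap = max(pruned[j][0] - pruned[i][1], pruned[i][0] - pruned[j][1])
            adj[i, j] = adj[j, i] = gap <= tol
        seen, expected = set(), []
        for i in range(n):
            if i in seen:
                continue
            comp, stack = [], [i]
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                comp.append(k)
                stack.extend(np.flatnonzero(adj[k]))
            expected.append(sorted(comp))
        expected_members = [
            [f"c:{pruned[k][0]}-{pruned[k][1]}" for k in comp] for comp in expected
        ]
        assert got == expected_members


class TestSimes:
    def test_single_p(self):
        assert simes_combine([0.37]) == pytest.approx(0.37)

    def test_all_equal_collapse(self):
        assert simes_combine([0.2, 0.2, 0.2]) == pytest.approx(0.2)

    def test_worked_example(self):
        assert simes_combine([0.01, 0.04]) == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simes_combine([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_min_p_and_m_times_min(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 20))
        s = simes_combine(p)
        assert p.min() <= s <= min(1.0, len(p) * p.min()) + 1e-12


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.2]).tolist() == [pytest.approx(0.2)]

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        m = p.size
        order = np.argsort(p)
        oracle = np.empty(m)
        for rank0, idx in enumerate(order):
            i = rank0 + 1
            oracle[idx] = min(
                min(m * p[order[j]] / (j + 1) for j in range(rank0, m)), 1.0
            )
        np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)


def gene(gid, start, end, strand="+", contig="c"):
    return Gene(gid, gid, contig, strand, start, end, exons=[(start, end)])


class TestAssignGenes:
    def test_minimum_fdr_rule(self):
        peaks = [
            Peak("p0", "c", 100, 200, ["a"], 1.0, p=0.04, q=0.05),
            Peak("p1", "c", 300, 400, ["b"], 2.0, p=0.0005, q=0.001),
        ]
        genes = GeneSet([gene("g1", 150, 350)])
        out = assign_genes(peaks, genes)
        row = out.loc["g1"]
        assert row.peak_id == "p1" and row.FDR == 0.001 and row.significant

    def test_gene_without_overlap_gets_none(self):
        peaks = [Peak("p0", "c", 0, 10, ["a"], 1.0, p=0.001, q=0.001)]
        out = assign_genes(peaks, GeneSet([gene("g1", 500, 600)]))
        row = out.loc["g1"]
        assert row.peak_id == "" and not row.significant and np.isnan(row.FDR)

    def test_tie_breaks_by_abs_logfc_then_position(self):
        peaks = [
            Peak("p0", "c", 100, 200, ["a"], 1.0, p=0.01, q=0.02),
            Peak("p1", "c", 250, 300, ["b"], -3.0, p=0.01, q=0.02),
            Peak("p2", "c", 350, 400, ["d"], 3.0, p=0.01, q=0.02),
        ]
        out = assign_genes(peaks, GeneSet([gene("g1", 0, 1000)]))
        assert out.loc["g1"].peak_id == "p1"  # |logFC| tie -> leftmost

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = []
        for i in range(30):
            a = int(rng.integers(0, 9_000))
            peaks.append(
                Peak(
                    f"p{i}",
                    "c",
                    a,
                    a + int(rng.integers(50, 600)),
                    ["x"],
                    float(rng.normal()),
                    p=float(rng.uniform()),
                    q=float(rng.uniform()),
                )
            )
        genes = GeneSet(
            [gene(f"g{i}", int(a), int(a) + int(rng.integers(100, 1500)))
             for i, a in enumerate(rng.integers(0, 9_000, size=50))]
        )
        out = assign_genes(peaks, genes)
        for g in genes:
            hits = [pk for pk in peaks if pk.start < g.end and g.start < pk.end]
            if not hits:
                assert out.loc[g.id].peak_id == ""
            else:
                best = min(hits, key=lambda pk: (pk.q, -abs(pk.mean_logfc), pk.start))
                assert out.loc[g.id].peak_id == best.id

    def test_significant_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        peaks = [
            Peak(f"p{i}", "c", i * 100, i * 100 + 50, ["x"], 1.0,
                 p=float(rng.uniform()), q=float(rng.uniform()))
            for i in range(40)
        ]
        genes = GeneSet([gene(f"g{i}", i * 100, i * 100 + 60) for i in range(40)])
        counts = [
            int(assign_genes(peaks, genes, fdr_threshold=thr)["significant"].sum())
            for thr in (0.2, 0.1, 0.05, 0.01, 0.001)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAnnotateFeatures:
    def make_genes(self):
        g = Gene("g1", "g1", "c", "+", 2000, 5000,
                 exons=[(2000, 2600), (4000, 5000)])
        return GeneSet([g])

    def test_promoter_upstream_of_tss(self):
        pk = Peak("p", "c", 1750, 1850, ["x"], 1.0)
        out = annotate_peak_features([pk], self.make_genes())
        assert out.feature.iloc[0] == "promoter"

    def test_intron_priority_below_exon(self):
        pk = Peak("p", "c", 3000, 3100, ["x"], 1.0)
        out = annotate_peak_features([pk], self.make_genes())
        assert out.feature.iloc[0] == "intron"

    def test_distal_intergenic_and_proportions(self):
        pks = [
            Peak("p1", "c", 1750, 1850, ["x"], 1.0),
            Peak("p2", "c", 9000, 9100, ["x"], 1.0),
        ]
        out = annotate_peak_features(pks, self.make_genes())
        assert set(out.feature) == {"promoter", "distal_intergenic"}
        props = feature_proportions(out)
        assert props["proportion"].sum() == pytest.approx(1.0)


class TestPipelineDeterminism:
    def test_identical_inputs_give_byte_identical_outputs(self, small_sim, tmp_path):
        from tadascope.pipeline import run_pipeline

        outs = []
        for i in range(2):
            stats, peaks, assign = run_pipeline(
                small_sim["counts"],
                small_sim["samples"],
                small_sim["gatc"],
                small_sim["genes"],
                treatment="DN",
            )
            p = tmp_path / f"run{i}.tsv"
            peaks_to_frame(peaks).to_csv(p, sep="\t", index=False)
            a = tmp_path / f"genes{i}.tsv"
            assign.to_csv(a, sep="\t", index=False)
            outs.append(p.read_bytes() + a.read_bytes())
        assert outs[0] == outs[1]
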