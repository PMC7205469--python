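import math

import numpy as np
import pytest

from apa import annotation as A
from apa import quantify as Q
from apa import synthetic_data as S


def feat(gene_id, kind, iv, chrom="chr1", strand="+"):
    return A.SplitFeature(gene_id, kind, chrom, strand, iv)


def brute_force_counts(reads, features):
    """Independent oracle: exhaustive per-read containment check."""
    counts = {f.feature_id: 0 for f in features}
    for r in reads:
        for f in features:
            if (
                r.chrom == f.chrom
                and f.interval[0] <= r.interval[0]
                and r.interval[1] <= f.interval[1]
            ):
                counts[f.feature_id] += 1
    return counts


class TestCountContainedReads:
    def test_contained_counted_overlapping_not(self):
        f = feat("g", A.UPSTREAM, (100, 300))
        reads = [
            Q.AlignedRead("chr1", "+", (150, 200)),
            Q.AlignedRead("chr1", "+", (90, 140)),
        ]
        table = Q.count_contained_reads(reads, [f])
        assert table.counts[f.feature_id] == 1

    def test_boundary_containment(self):
        f = feat("g", A.UPSTREAM, (100, 300))
        reads = [
            Q.AlignedRead("chr1", "+", (100, 300)),  # exact: contained
            Q.AlignedRead("chr1", "+", (100, 301)),  # one past end: not
            Q.AlignedRead("chr1", "+", (99, 200)),  # one before start: not
        ]
        table = Q.count_contained_reads(reads, [f])
        assert table.counts[f.feature_id] == 1

    def test_strand_agnostic(self):
        f = feat("g", A.UPSTREAM, (100, 300), strand="+")
        reads = [Q.AlignedRead("chr1", "-", (150, 200))]
        assert Q.count_contained_reads(reads, [f]).counts[f.feature_id] == 1

    def test_empty_read_list(self):
        f = feat("g", A.UPSTREAM, (100, 300))
        table = Q.count_contained_reads([], [f])
        assert table.counts[f.feature_id] == 0
        assert table.library_size == 0

    def test_counts_match_brute_force_oracle(self, rng):
        for _ in range(20):
            features = []
            for i in range(5):
                s = int(rng.integers(0, 5000))
                features.append(feat(f"g{i}", A.OTHER, (s, s + int(rng.integers(50, 800)))))
            reads = []
            for _ in range(200):
                chrom = "chr1" if rng.random() < 0.9 else "chr2"
                s = int(rng.integers(0, 5500))
                reads.append(Q.AlignedRead(chrom, "+", (s, s + int(rng.integers(20, 120)))))
            table = Q.count_contained_reads(reads, features)
            assert table.counts == brute_force_counts(reads, features)

    def test_dedup_collapses_and_is_idempotent(self):
        reads = [
            Q.AlignedRead("chr1", "+", (100, 150)),
            Q.AlignedRead("chr1", "+", (100, 150)),
            Q.AlignedRead("chr1", "-", (100, 150)),  # other strand kept
            Q.AlignedRead("chr1", "+", (101, 151)),
        ]
        rs = Q.ReadSet.from_reads(reads)
        d1 = rs.dedup()
        assert d1.n_reads == 3
        d2 = d1.dedup()
        assert d2.n_reads == 3
        assert [r.interval for r in d2.iter_reads()] == [r.interval for r in d1.iter_reads()]

    def test_dedup_uses_five_prime_end_on_minus(self):
        # same 3' start but different 5' ends on -: both kept
        reads = [
            Q.AlignedRead("chr1", "-", (100, 150)),
            Q.AlignedRead("chr1", "-", (100, 160)),
        ]
        assert Q.ReadSet.from_reads(reads).dedup().n_reads == 2


class TestRpkm:
    def test_hand_arithmetic(self):
        f = feat("g", A.UPSTREAM, (0, 500))
        table = Q.CountTable({f.feature_id: 100}, library_size=1_000_000)
        assert Q.compute_rpkm(table, [f])[f.feature_id] == pytest.approx(200.0)

    def test_zero_count(self):
        f = feat("g", A.UPSTREAM, (0, 500))
        table = Q.CountTable({f.feature_id: 0}, library_size=1_000_000)
        assert Q.compute_rpkm(table, [f])[f.feature_id] == 0.0

    def test_library_scale_equivariance(self):
        f = feat("g", A.UPSTREAM, (0, 500))
        t1 = Q.CountTable({f.feature_id: 100}, library_size=1_000_000)
        t2 = Q.CountTable({f.feature_id: 100}, library_size=2_000_000)
        assert Q.compute_rpkm(t1, [f])[f.feature_id] == pytest.approx(
            2 * Q.compute_rpkm(t2, [f])[f.feature_id]
        )

    def test_zero_library_errors(self):
        f = feat("g", A.UPSTREAM, (0, 500))
        with pytest.raises(ValueError):
            Q.compute_rpkm(Q.CountTable({}, library_size=0), [f])


class TestD3utrRatios:
    def make_pair(self):
        up = feat("g", A.UPSTREAM, (0, 500))
        d3 = feat("g", A.D3UTR, (500, 800))
        return up, d3

    def test_hand_arithmetic(self):
        up, d3 = self.make_pair()
        table = Q.CountTable(
            {up.feature_id: 100, d3.feature_id: 30}, library_size=1_000_000
        )
        (rec,) = Q.ratios_from_counts(table, [up, d3])
        assert rec.upstream_rpkm == pytest.approx(200.0)
        assert rec.d3utr_rpkm == pytest.approx(100.0)
        assert rec.ratio == pytest.approx(0.5)

    def test_zero_upstream_is_na(self):
        up, d3 = self.make_pair()
        table = Q.CountTable({up.feature_id: 0, d3.feature_id: 5}, library_size=1000)
        (rec,) = Q.ratios_from_counts(table, [up, d3])
        assert rec.is_na

    def test_equal_rpkm_gives_one(self):
        up, d3 = self.make_pair()
        table = Q.CountTable(
            {up.feature_id: 500, d3.feature_id: 300}, library_size=1_000_000
        )
        (rec,) = Q.ratios_from_counts(table, [up, d3])
        assert rec.ratio == pytest.approx(1.0)

    def test_unpaired_gene_skipped(self):
        up = feat("g", A.UPSTREAM, (0, 500))
        table = Q.CountTable({up.feature_id: 10}, library_size=1000)
        assert Q.ratios_from_counts(table, [up]) == []

    def test_na_survives_table_round_trip(self, tmp_path):
        up, d3 = self.make_pair()
        table = Q.CountTable({up.feature_id: 0, d3.feature_id: 5}, library_size=1000)
        recs = Q.ratios_from_counts(table, [up, d3])
        path = tmp_path / "r.tsv"
        Q.write_ratio_table(recs, path)
        assert "NA" in path.read_text()
        (back,) = Q.read_ratio_table(path)
        assert back.is_na


class TestDifferentialExpression:
    def _tables(self, ca, cb):
        genes = [f"g{i}" for i in range(len(ca))]
        a = Q.CountTable(dict(zip(genes, ca)), library_size=max(1, sum(ca)))
        b = Q.CountTable(dict(zip(genes, cb)), library_size=max(1, sum(cb)))
        return a, b

    def test_identical_tables(self):
        counts = list(range(10, 70))
        a, b = self._tables(counts, counts)
        recs = Q.differential_expression(a, b, min_genes=10)
        assert all(r.fc == pytest.approx(1.0) for r in recs)

    def test_size_factors_identity_for_identical(self):
        ka = np.arange(10, 70, dtype=float)
        sa, sb = Q.median_of_ratios_size_factors(ka, ka, min_genes=10)
        assert sa == pytest.approx(1.0)
        assert sb == pytest.approx(1.0)

    def test_size_factors_hand_oracle(self):
        # oracle: hand-computed median of count/geometric-mean
        ka = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        kb = 2 * ka
        sa, sb = Q.median_of_ratios_size_factors(ka, kb, min_genes=3)
        gm = np.sqrt(ka * kb)
        assert sa == pytest.approx(np.median(ka / gm))
        assert sb == pytest.approx(np.median(kb / gm))
        assert sb / sa == pytest.approx(2.0)

    def test_tripled_gene_fc_about_three(self):
        ca = [100, 200, 300, 400, 500, 600]
        cb = [100, 200, 300, 400, 500, 1800]
        a, b = self._tables(ca, cb)
        recs = Q.differential_expression(a, b, min_genes=5, n_bins=1)
        fc = {r.gene_id: r.fc for r in recs}
        assert fc["g5"] == pytest.approx(3.0, rel=0.02)
        assert fc["g0"] == pytest.approx(1.0, rel=0.02)

    def test_zero_in_a_finite_fc(self):
        ca = [0] + list(range(10, 120, 2))
        cb = [50] + list(range(10, 120, 2))
        a, b = self._tables(ca, cb)
        recs = Q.differential_expression(a, b, min_genes=10)
        r0 = next(r for r in recs if r.gene_id == "g0")
        assert math.isfinite(r0.fc) and r0.fc > 1

    def test_too_few_genes_errors(self):
        a, b = self._tables([5, 5, 5], [5, 5, 5])
        with pytest.raises(ValueError):
            Q.differential_expression(a, b)


class TestClassify:
    def _rec(self, fc, p=0.5):
        return Q.DiffExprRecord("g", 1.0, 1.0, fc, 0.0, p)

    def test_sensitive(self):
        (r,) = Q.classify_aire_sensitivity([self._rec(3.5, 0.001)])
        assert r.label == "sensitive"

    def test_neutral(self):
        (r,) = Q.classify_aire_sensitivity([self._rec(1.5)])
        assert r.label == "neutral"

    def test_between_thresholds_unassigned(self):
        (r,) = Q.classify_aire_sensitivity([self._rec(2.5, 0.5)])
        assert r.label == "unassigned"

    def test_high_fc_without_significance_unassigned(self):
        (r,) = Q.classify_aire_sensitivity([self._rec(4.0, 0.5)])
        assert r.label == "unassigned"

    def test_boundaries(self):
        (r,) = Q.classify_aire_sensitivity([self._rec(3.0, 0.009)])
        assert r.label == "sensitive"  # fc >= 3 inclusive
        (r,) = Q.classify_aire_sensitivity([self._rec(2.0)])
        assert r.label == "unassigned"  # fc < 2 strict
        (r,) = Q.classify_aire_sensitivity([self._rec(0.5)])
        assert r.label == "unassigned"  # fc > 0.5 strict


class TestParameterRecovery:
    def test_ratio_converges_to_pi(self):
        cfg = S.SimulationConfig(
            seed=11, n_genes=12, pa_fraction=1.0, mean_reads_per_gene=20000.0,
            log_expr_sd=0.0,
        )
        ann = S.simulate_annotation(cfg)
        feats = A.build_split_annotation(ann.genes, ann.sites)
        reads = S.simulate_reads(cfg, ann, "a")
        table = Q.count_contained_reads(reads, feats)
        recs = Q.ratios_from_counts(table, feats)
        errs = [
            abs(r.ratio - ann.truth.loc[r.gene_id, "pi"]) for r in recs if not r.is_na
        ]
        assert len(errs) == 12
        assert max(errs) < 0.03

    def test_subsampling_invariance(self, rng):
        cfg = S.SimulationConfig(
            seed=5, n_genes=30, pa_fraction=1.0, mean_reads_per_gene=5000.0
        )
        ann = S.simulate_annotation(cfg)
        feats = A.build_split_annotation(ann.genes, ann.sites)
        reads = S.simulate_reads(cfg, ann, "a")
        all_reads = list(reads.iter_reads())
        keep = rng.random(len(all_reads)) < 0.5
        half = [r for r, k in zip(all_reads, keep) if k]
        full_recs = {
            r.gene_id: r.ratio
            for r in Q.ratios_from_counts(Q.count_contained_reads(reads, feats), feats)
            if not r.is_na
        }
        half_recs = {
            r.gene_id: r.ratio
            for r in Q.ratios_from_counts(Q.count_contained_reads(half, feats), feats)
            if not r.is_na
        }
        diffs = [half_recs[g] - full_recs[g] for g in full_recs if g in half_recs]
        assert abs(np.median(diffs)) < 0.02


class TestSamIO:
    def test_sam_round_trip(self, tmp_path):
        cfg = S.SimulationConfig(seed=2, n_genes=10, mean_reads_per_gene=100.0)
        ann = S.simulate_annotation(cfg)
        reads = S.simulate_reads(cfg, ann, "a")
        path = tmp_path / "r.sam"
        S.write_sam(reads, ann.chrom_sizes, path)
        back = Q.ReadSet.from_sam(path)
        assert back.n_reads == reads.n_reads
        for chrom in reads.chroms():
            a, b = reads.arrays(chrom), back.arrays(chrom)
            # both coordinate-sorted by construction
            assert np.array_equal(a["start"], b["start"])
            assert np.array_equal(a["end"], b["end"])
            assert np.array_equal(a["fwd"], b["fwd"])

    def test_bed_reader(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t100\t150\tr0\t0\t+\nchr1\t200\t260\tr1\t0\t-\n")
        rs = Q.ReadSet.from_bed(path)
        assert rs.n_reads == 2
        assert list(rs.arrays("chr1")["fwd"]) == [True, False]

    def test_count_table_round_trip(self, tmp_path):
        t = Q.CountTable({"f1": 3, "f2": 0}, library_size=10, sample_id="s")
        path = tmp_path / "c.tsv"
        Q.write_count_table(t, path)
        back = Q.read_count_table(path)
        assert back.counts == t.counts
        assert back.library_size == 10
        assert back.sample_id == "s"
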