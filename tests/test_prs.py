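import numpy as np
import pytest

import pgscov as pg
from pgscov.prs import EmptyScoreError, IndexSnp

from conftest import make_panel, make_stats


def brute_force_clump(stats, panel, r2_min, window_bp, p1=1.0):
    """Literal greedy clumping, written independently: sort records by
    (p, chrom, pos); promote the first unclaimed record with p <= p1; claim
    all unclaimed records within the window at r2 >= r2_min; repeat."""
    recs = []
    for i, key in enumerate(stats.keys()):
        j = panel.find(key)
        if j is not None:
            row = stats.df.iloc[i]
            recs.append((float(row.pvalue), str(row.chrom), int(row.pos), j))
    recs.sort()
    claimed = set()
    indices = []
    while True:
        head = next((r for r in recs if r[3] not in claimed and r[0] <= p1), None)
        if head is None:
            break
        claimed.add(head[3])
        indices.append(head[3])
        a = panel.dosages[:, head[3]]
        for p, c, pos, j in recs:
            if j in claimed or c != head[1] or abs(pos - head[2]) > window_bp:
                continue
            b = panel.dosages[:, j]
            m = ~(np.isnan(a) | np.isnan(b))
            if m.sum() < 2 or np.std(a[m]) == 0 or np.std(b[m]) == 0:
                continue
            if min(float(np.corrcoef(a[m], b[m])[0, 1] ** 2), 1.0) >= r2_min:
                claimed.add(j)
    return [panel.variants[j] for j in indices]


def _stats_for(panel, pvals, betas=None):
    betas = betas if betas is not None else [0.1] * len(pvals)
    rows = [(v.chrom, v.pos, v.rsid, v.alt, v.ref, b, p)
            for v, b, p in zip(panel.variants, betas, pvals)]
    return make_stats(rows)


class TestClump:
    def test_single_variant_is_sole_index(self):
        panel = make_panel([np.tile([0, 1, 2], 20)])
        stats = _stats_for(panel, [0.01])
        res = pg.clump(stats, panel)
        assert [s.key for s in res.index_snps] == [panel.variants[0]]

    def test_perfect_ld_keeps_smaller_pvalue(self):
        rng = np.random.default_rng(21)
        base = rng.binomial(2, 0.5, 100).astype(float)
        panel = make_panel([base, base.copy()])
        stats = _stats_for(panel, [1e-4, 1e-8])
        res = pg.clump(stats, panel, pg.ClumpConfig(clump_r2=0.10))
        assert [s.key.rsid for s in res.index_snps] == ["rs2"]
        assert res.index_snps[0].pvalue == 1e-8
        assert [v.rsid for v in res.clumped_away[res.index_snps[0].key]] == ["rs1"]

    def test_matches_brute_force_on_block_panel(self, small_panel):
        rng = np.random.default_rng(22)
        pvals = rng.uniform(1e-10, 1, size=small_panel.n_variants)
        stats = _stats_for(small_panel, pvals)
        for r2_min, window in [(0.1, 250_000), (0.5, 20_000), (0.9, 5_000)]:
            got = pg.clump(stats, small_panel,
                           pg.ClumpConfig(clump_r2=r2_min, clump_window_bp=window))
            want = brute_force_clump(stats, small_panel, r2_min, window)
            assert [s.key for s in got.index_snps] == want

    def test_random_scenarios_match_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            m = int(rng.integers(6, 51))
            n = int(rng.integers(20, 60))
            base = rng.binomial(2, rng.uniform(0.1, 0.5), size=(n, m)).astype(float)
            # induce LD by copying some columns with noise
            for j in range(1, m):
                if rng.random() < 0.5:
                    src = int(rng.integers(0, j))
                    flip = rng.random(n) < 0.1
                    base[:, j] = np.where(flip, 2 - base[:, src], base[:, src])
            panel = make_panel(list(base.T), spacing=int(rng.integers(500, 5_000)))
            stats = _stats_for(panel, rng.uniform(1e-12, 1, size=m))
            r2_min = float(rng.uniform(0.05, 0.95))
            window = int(rng.integers(1_000, 100_000))
            p1 = float(rng.choice([0.5, 1.0]))
            got = pg.clump(stats, panel, pg.ClumpConfig(
                clump_r2=r2_min, clump_window_bp=window, p1=p1))
            assert [s.key for s in got.index_snps] == brute_force_clump(
                stats, panel, r2_min, window, p1)

    def test_row_order_invariance(self, small_panel):
        rng = np.random.default_rng(24)
        pvals = rng.uniform(0, 1, size=small_panel.n_variants)
        stats = _stats_for(small_panel, pvals)
        shuffled = pg.SummaryStats(
            stats.df.sample(frac=1, random_state=1).reset_index(drop=True))
        a = pg.clump(stats, small_panel)
        b = pg.clump(shuffled, small_panel)
        assert [s.key for s in a.index_snps] == [s.key for s in b.index_snps]

    def test_absent_variants_counted(self, small_panel):
        stats = _stats_for(small_panel, [0.1] * small_panel.n_variants)
        extra = make_stats([("9", 1, "rs_ghost", "G", "A", 0.1, 0.5)])
        merged = pg.SummaryStats(
            stats.df.head(5)._append(extra.df, ignore_index=True))
        res = pg.clump(merged, small_panel)
        assert res.n_absent_from_panel == 1

    def test_empty_intersection_raises(self, small_panel):
        ghost = make_stats([("9", 1, "rs_ghost", "G", "A", 0.1, 0.5)])
        with pytest.raises(EmptyScoreError):
            pg.clump(ghost, small_panel)


class TestThreshold:
    def _clumped(self, small_panel):
        pvals = np.array([1e-9, 1e-5, 0.2] + [0.9] * (small_panel.n_variants - 3))
        return pg.clump(_stats_for(small_panel, pvals), small_panel,
                        pg.ClumpConfig(clump_r2=0.999, clump_window_bp=1))

    def test_threshold_one_is_identity(self, small_panel):
        res = self._clumped(small_panel)
        assert len(pg.threshold(res, 1.0)) == len(res)

    def test_genome_wide_threshold_keeps_one(self, small_panel):
        res = self._clumped(small_panel)
        kept = pg.threshold(res, 5e-8)
        assert [s.pvalue for s in kept.index_snps] == [1e-9]

    def test_nested_and_monotone_counts(self, small_panel, small_scenario):
        stats, _ = pg.simulate_sumstats(small_panel, small_scenario)
        res = pg.clump(stats, small_panel)
        counts = []
        prev_keys = set()
        for t in sorted(pg.DEFAULT_THRESHOLDS):
            kept = pg.threshold(res, t)
            keys = {s.key for s in kept.index_snps}
            assert prev_keys <= keys  # nesting
            # filter oracle
            assert len(kept) == sum(s.pvalue <= t for s in res.index_snps)
            counts.append(len(kept))
            prev_keys = keys
        assert counts == sorted(counts)


class TestMatchAlleles:
    @pytest.mark.parametrize("eff,oth,ref,alt,expected", [
        ("A", "G", "G", "A", "same"),
        ("A", "G", "A", "G", "flip"),
        ("A", "T", "A", "T", "ambiguous"),
        ("C", "G", "G", "C", "ambiguous"),
        ("A", "C", "G", "T", "mismatch"),
    ])
    def test_orientations(self, eff, oth, ref, alt, expected):
        v = pg.VariantKey("1", 100, "rs1", ref, alt)
        assert pg.match_alleles(eff, oth, v) == expected


class TestScore:
    def _weights(self, panel, betas, pvals=None):
        pvals = pvals or [1e-8] * len(betas)
        return pg.ClumpResult(index_snps=[
            IndexSnp(key=v, effect_allele=v.alt, other_allele=v.ref,
                     beta=b, pvalue=p)
            for v, b, p in zip(panel.variants, betas, pvals)])

    def test_zero_betas_zero_scores(self, small_panel):
        sv = pg.score(small_panel, self._weights(small_panel,
                                                 [0.0] * small_panel.n_variants))
        assert np.all(sv.scores == 0.0)

    def test_hand_computed_two_snp_score(self):
        panel = make_panel([[2, 0], [1, 1]])
        sv = pg.score(panel, self._weights(panel, [0.5, -0.2]))
        assert sv.scores[0] == pytest.approx(0.5 * 2 + (-0.2) * 1)
        assert sv.n_snps_used == 2

    def test_flip_consistency(self):
        # swapping panel ref/alt and recoding dosage leaves scores unchanged
        panel = make_panel([[0, 1, 2, 2]])
        v = panel.variants[0]
        flipped = pg.GenotypePanel(
            variants=[pg.VariantKey(v.chrom, v.pos, v.rsid, v.alt, v.ref)],
            samples=panel.samples, dosages=2 - panel.dosages)
        w = self._weights(panel, [0.3])
        np.testing.assert_allclose(pg.score(panel, w).scores,
                                   pg.score(flipped, w).scores)

    def test_linear_in_betas(self, small_panel):
        rng = np.random.default_rng(31)
        betas = rng.normal(size=small_panel.n_variants)
        s1 = pg.score(small_panel, self._weights(small_panel, betas))
        s3 = pg.score(small_panel, self._weights(small_panel, 3 * betas))
        np.testing.assert_allclose(s3.scores, 3 * s1.scores, rtol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        col = np.array([0.0, 2.0, np.nan, 2.0])
        panel = make_panel([col])
        sv = pg.score(panel, self._weights(panel, [1.0]))
        # effect-allele frequency 4/6 -> imputed dosage 4/3
        assert sv.scores[2] == pytest.approx(4 / 3)

    def test_ambiguous_snps_excluded_and_counted(self):
        rng = np.random.default_rng(32)
        base = rng.binomial(2, 0.5, 50).astype(float)
        panel = pg.GenotypePanel(
            variants=[pg.VariantKey("1", 100, "rs1", "A", "T"),
                      pg.VariantKey("1", 200, "rs2", "A", "G")],
            samples=[f"S{i}" for i in range(50)],
            dosages=np.column_stack([base, base]))
        w = pg.ClumpResult(index_snps=[
            IndexSnp(pg.VariantKey("1", 100, "rs1", "A", "T"), "T", "A", 0.5, 1e-8),
            IndexSnp(pg.VariantKey("1", 200, "rs2", "A", "G"), "G", "A", 0.5, 1e-8)])
        sv = pg.score(panel, w)
        assert sv.n_snps_used == 1 and sv.n_excluded_ambiguous == 1

    def test_low_info_variants_excluded(self):
        rng = np.random.default_rng(33)
        cols = [rng.binomial(2, 0.5, 50).astype(float) for _ in range(2)]
        panel = make_panel(cols, info=np.array([1.0, 0.6]))
        sv = pg.score(panel, self._weights(panel, [0.5, 0.5]))
        assert sv.n_snps_used == 1

    def test_zero_usable_snps_raises(self):
        panel = make_panel([[0, 1, 2]])
        w = pg.ClumpResult(index_snps=[])
        with pytest.raises(EmptyScoreError):
            pg.score(panel, w)
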