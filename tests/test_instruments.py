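import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrlink.instruments import (EmptyInstrumentError, InstrumentConfig,
                                apply_instrument_filters, f_statistic,
                                find_proxy, ld_clump, select_significant,
                                variance_explained)
from mrlink.ld import LDReference
from mrlink.simulate import MRSimConfig, simulate_ld_reference, simulate_mr_sumstats
from tests.conftest import make_sumstats


def _stats_from(pvals, pos=None, chrom=None):
    pos = pos or [100 * (i + 1) for i in range(len(pvals))]
    chrom = chrom or ["1"] * len(pvals)
    return make_sumstats([
        (f"rs{i + 1}", chrom[i], pos[i], "A", "G", 0.3, 0.1, 0.01, p, 10000)
        for i, p in enumerate(pvals)])


def _ld_from_matrix(snp_ids, pos, r2_matrix, chrom=None):
    chrom = chrom or ["1"] * len(snp_ids)
    index = pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "pos": pos,
                          "ld_score": 1.0})
    rows = []
    for i in range(len(snp_ids)):
        for j in range(i + 1, len(snp_ids)):
            if r2_matrix[i][j] > 0:
                rows.append((snp_ids[i], snp_ids[j], r2_matrix[i][j]))
    pairs = pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"]) if rows else None
    return LDReference(index, pairs)


class TestSelectSignificant:
    def test_strict_inequality_at_threshold(self):
        ss = _stats_from([4e-8, 5e-8, 6e-8])
        assert select_significant(ss) == ["rs1"]

    def test_empty_stats_empty_list(self):
        ss = _stats_from([0.5])
        assert select_significant(ss, 1e-10) == []

    def test_tie_break_lexicographic(self):
        ss = _stats_from([1e-9, 1e-9])
        assert select_significant(ss) == ["rs1", "rs2"]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-12, 0.99), min_size=1, max_size=20),
           st.floats(1e-10, 0.5), st.floats(1e-10, 0.5))
    def test_monotone_in_threshold(self, pvals, t1, t2):
        ss = _stats_from(pvals)
        lo, hi = sorted([t1, t2])
        assert set(select_significant(ss, lo)) <= set(select_significant(ss, hi))


def greedy_clump_oracle(cands, pvals, pos, r2, r2_max, window):
    """Step-by-step greedy removal enumeration, written independently of
    the library's clumping loop."""
    alive = {c: True for c in cands}
    order = sorted(cands, key=lambda c: (pvals[c], pos[c], c))
    kept = []
    for c in order:
        if not alive[c]:
            continue
        kept.append(c)
        alive[c] = False
        for d in order:
            if alive[d] and abs(pos[d] - pos[c]) <= window and r2[(c, d)] >= r2_max:
                alive[d] = False
    return kept


class TestLDClump:
    def test_dominant_snp_absorbs_neighbour(self):
        ld = _ld_from_matrix(["rs1", "rs2"], [1000, 2000],
                             [[1, 0.5], [0.5, 1]])
        ss = _stats_from([1e-10, 1e-9], pos=[1000, 2000])
        assert ld_clump(["rs1", "rs2"], ss, ld) == ["rs1"]

    def test_r2_below_threshold_keeps_both(self):
        ld = _ld_from_matrix(["rs1", "rs2"], [1000, 2000],
                             [[1, 0.0005], [0.0005, 1]])
        ss = _stats_from([1e-10, 1e-9], pos=[1000, 2000])
        assert ld_clump(["rs1", "rs2"], ss, ld) == ["rs1", "rs2"]

    def test_distant_same_chromosome_never_removed(self):
        ld = _ld_from_matrix(["rs1", "rs2"], [1000, 50_000_000],
                             [[1, 0.99], [0.99, 1]])
        ss = _stats_from([1e-10, 1e-9], pos=[1000, 50_000_000])
        assert ld_clump(["rs1", "rs2"], ss, ld) == ["rs1", "rs2"]

    def test_absent_from_reference_treated_independent(self):
        ld = _ld_from_matrix(["rs1"], [1000], [[1]])
        ss = _stats_from([1e-10, 1e-9], pos=[1000, 2000])
        assert ld_clump(["rs1", "rs2"], ss, ld) == ["rs1", "rs2"]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        names = [f"rs{i + 1}" for i in range(k)]
        pos = sorted(rng.integers(1, 5_000_000, size=k).tolist())
        pvals = {n: float(rng.uniform(1e-12, 1e-6)) for n in names}
        mat = rng.uniform(0, 1, size=(k, k))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        mat[mat < 0.3] = 0.0  # sparsify
        r2 = {(a, b): mat[i, j] for i, a in enumerate(names)
              for j, b in enumerate(names)}
        ld = _ld_from_matrix(names, pos, mat)
        ss = make_sumstats([
            (n, "1", pos[i], "A", "G", 0.3, 0.1, 0.01, pvals[n], 10000)
            for i, n in enumerate(names)])
        r2_max, window = 0.25, 2_000_000
        got = ld_clump(names, ss, ld, r2_max=r2_max, window_kb=window // 1000)
        want = greedy_clump_oracle(names, pvals, dict(zip(names, pos)), r2,
                                   r2_max, window)
        assert got == want

    @pytest.mark.parametrize("seed", range(10))
    def test_output_pairwise_independent(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = 8
        names = [f"rs{i + 1}" for i in range(k)]
        pos = sorted(rng.integers(1, 3_000_000, size=k).tolist())
        mat = rng.uniform(0, 1, size=(k, k))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = _ld_from_matrix(names, pos, mat)
        ss = make_sumstats([
            (n, "1", pos[i], "A", "G", 0.3, 0.1, 0.01,
             float(rng.uniform(1e-12, 1e-6)), 10000)
            for i, n in enumerate(names)])
        kept = ld_clump(names, ss, ld, r2_max=0.3, window_kb=1000)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                pa, pb = ld.position(a), ld.position(b)
                assert abs(pa - pb) > 1_000_000 or ld.r2(a, b) < 0.3


class TestScalarFormulas:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.1, 0.01, 100.0), (0.0, 0.01, 0.0), (-0.05, 0.005, 100.0)])
    def test_f_statistic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_f_statistic_rejects_bad_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    @pytest.mark.parametrize("maf,beta,expected", [
        (0.5, 0.1, 0.005), (0.3, 0.0, 0.0)])
    def test_variance_explained(self, maf, beta, expected):
        assert variance_explained(maf, beta) == pytest.approx(expected)

    def test_variance_explained_additivity(self):
        assert sum(variance_explained(0.5, 0.1) for _ in range(10)) \
            == pytest.approx(0.05)

    def test_variance_explained_domain(self):
        with pytest.raises(ValueError):
            variance_explained(0.7, 0.1)


class TestFindProxy:
    def _ld(self):
        return _ld_from_matrix(
            ["rs1", "rs2", "rs3", "rs4"], [120, 100, 500, 900],
            [[1, 0.9, 0.85, 0.5],
             [0.9, 1, 0, 0],
             [0.85, 0, 1, 0],
             [0.5, 0, 0, 1]])

    def test_highest_r2_wins(self):
        assert find_proxy("rs1", {"rs2", "rs3", "rs4"}, self._ld()) == "rs2"

    def test_strict_inequality_none(self):
        ld = _ld_from_matrix(["rs1", "rs2"], [100, 200], [[1, 0.8], [0.8, 1]])
        assert find_proxy("rs1", {"rs2"}, ld) is None

    def test_tie_breaks_on_nearest_position(self):
        ld = _ld_from_matrix(["rsA", "rsB", "rsC"], [120, 100, 500],
                             [[1, 0.9, 0.9], [0.9, 1, 0], [0.9, 0, 1]])
        assert find_proxy("rsA", {"rsB", "rsC"}, ld) == "rsB"

    def test_absent_target_returns_none(self):
        assert find_proxy("rsX", {"rs1"}, self._ld()) is None


class TestApplyFilters:
    def test_composition_counts_weak_instrument(self):
        ld = _ld_from_matrix(["rs1", "rs2", "rs3"],
                             [1000, 20_000_000, 40_000_000],
                             [[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        ss = make_sumstats([
            ("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.010, 1e-20, 10000),
            ("rs2", "1", 20_000_000, "A", "G", 0.3, 0.08, 0.012, 1e-12, 10000),
            ("rs3", "1", 40_000_000, "A", "G", 0.3, 0.03, 0.010, 1e-9, 10000),
        ])
        kept, metrics, audit = apply_instrument_filters(ss, ld)
        assert kept == ["rs1", "rs2"]  # rs3 has F = 9 < 10
        assert audit["removed_weak_f"] == 1
        assert metrics["rs3"].f_stat == pytest.approx(9.0)

    def test_no_significant_snp_raises(self):
        ld = _ld_from_matrix(["rs1"], [1000], [[1]])
        ss = _stats_from([0.5])
        with pytest.raises(EmptyInstrumentError, match="significance"):
            apply_instrument_filters(ss, ld)

    def test_planted_instruments_recovered(self):
        # strong planted instruments: nearly all survive selection on average
        recovered = []
        for seed in range(3):
            cfg = MRSimConfig(n_snp=100, causal_beta=0.0, n_exposure=20_000_000,
                              exposure_r2_total=0.1, seed=seed)
            exposure, _, _ = simulate_mr_sumstats(cfg)
            ld = simulate_ld_reference(n_block=100, block_size=1, seed=seed)
            kept, _, _ = apply_instrument_filters(exposure, ld)
            recovered.append(len(kept))
        assert np.mean(recovered) >= 95
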