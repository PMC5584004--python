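import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chicogs import blockshifter as bs
from chicogs.genome_model import Fragment, FragmentMap, PIRSet


def contiguous_map(n):
    return FragmentMap(
        [Fragment(i + 1, "chr1", i * 100, (i + 1) * 100) for i in range(n)]
    )


def sets_from_labels(labels):
    test = PIRSet("test", frozenset(i + 1 for i, l in enumerate(labels) if l & 1))
    control = PIRSet("control", frozenset(i + 1 for i, l in enumerate(labels) if l & 2))
    return test, control


def oracle_superblocks(labels, gap):
    """Linear scan with an explicit gap counter over a label string."""
    runs, current, gap_count = [], [], None
    for i, lab in enumerate(labels):
        if lab == 0:
            if current is not None and current:
                gap_count += 1
        else:
            if current and gap_count > gap:
                runs.append(current)
                current = []
            current.append((i + 1, lab))
            gap_count = 0
    if current:
        runs.append(current)
    return runs


class TestSuperblocks:
    def test_single_gap_bridged(self):
        labels = [1, 0, 1]
        fmap = contiguous_map(3)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=1)
        assert len(blocks) == 1
        assert list(blocks[0].fragment_ids) == [1, 3]

    def test_gap_exceeded_splits(self):
        labels = [1, 0, 0, 1]
        fmap = contiguous_map(4)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=1)
        assert len(blocks) == 2

    def test_kind_classification(self):
        labels = [1, 2, 0, 0, 1, 0, 0, 3]
        fmap = contiguous_map(8)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=0)
        kinds = [b.kind for b in blocks]
        # T|C adjacent -> mixed; lone T -> unmixed; a lone "both" fragment
        # carries both labels so the block is mixed
        assert kinds == ["mixed", "unmixed_test", "mixed"]

    @given(
        labels=st.lists(st.integers(0, 3), min_size=1, max_size=40),
        gap=st.sampled_from([0, 1, 5]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_run_finder_oracle(self, labels, gap):
        fmap = contiguous_map(len(labels))
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=gap)
        expected = oracle_superblocks(labels, gap)
        assert len(blocks) == len(expected)
        for b, run in zip(blocks, expected):
            assert list(b.fragment_ids) == [fid for fid, _ in run]
            assert list(b.labels) == [lab for _, lab in run]


class TestStatistic:
    def test_mean_difference(self):
        labels = [1, 1, 2, 2]
        fmap = contiguous_map(4)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=0)
        ppi = pd.DataFrame(
            {"fragment_id": [1, 2, 3, 4], "ppi": [0.2, 0.4, 0.1, 0.1]}
        )
        assert bs.enrichment_statistic(blocks, ppi) == pytest.approx(0.2)

    def test_identical_sets_zero(self):
        labels = [3, 3, 3]
        fmap = contiguous_map(3)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=0)
        ppi = pd.DataFrame({"fragment_id": [1, 2, 3], "ppi": [0.5, 0.1, 0.2]})
        assert bs.enrichment_statistic(blocks, ppi) == 0.0

    def test_both_label_counts_on_both_sides(self):
        labels = [1, 3, 2]
        fmap = contiguous_map(3)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=0)
        ppi = pd.DataFrame({"fragment_id": [1, 2, 3], "ppi": [0.6, 0.3, 0.0]})
        # test mean over frags {1,2}: 0.45 ; control over {2,3}: 0.15
        assert bs.enrichment_statistic(blocks, ppi) == pytest.approx(0.3)

    def test_empty_side_errors(self):
        labels = [1, 1]
        fmap = contiguous_map(2)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=0)
        ppi = pd.DataFrame({"fragment_id": [1, 2], "ppi": [0.1, 0.1]})
        with pytest.raises(ValueError, match="test/control"):
            bs.enrichment_statistic(blocks, ppi)

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=20, deadline=None)
    def test_matches_flat_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        labels = rng.integers(0, 4, size=n)
        if not (labels & 1).any():
            labels[0] = 1
        if not (labels & 2).any():
            labels[1] = 2
        fmap = contiguous_map(n)
        blocks = bs.build_superblocks(fmap, *sets_from_labels(labels), gap=5)
        frag_of = rng.integers(1, n + 1, size=50)
        vals = rng.random(50)
        ppi = pd.DataFrame({"fragment_id": frag_of, "ppi": vals})
        t_mask = np.array([labels[f - 1] & 1 > 0 for f in frag_of])
        c_mask = np.array([labels[f - 1] & 2 > 0 for f in frag_of])
        expect = vals[t_mask].mean() - vals[c_mask].mean()
        assert bs.enrichment_statistic(blocks, ppi) == pytest.approx(expect)


class TestPermutation:
    def _blocks(self, labels, gap=0):
        fmap = contiguous_map(len(labels))
        return bs.build_superblocks(fmap, *sets_from_labels(labels), gap=gap)

    def test_conservation(self):
        labels = [1, 2, 1, 0, 0, 1, 0, 0, 2, 0, 0, 3, 2]
        blocks = self._blocks(labels, gap=1)
        rng = np.random.default_rng(0)
        n_t = sum(1 for b in blocks if b.kind == "unmixed_test")
        n_c = sum(1 for b in blocks if b.kind == "unmixed_control")
        for _ in range(50):
            permuted = bs.permute_labels(blocks, rng)
            assert sum(1 for b in permuted if b.kind == "unmixed_test") == n_t
            assert sum(1 for b in permuted if b.kind == "unmixed_control") == n_c
            for orig, perm in zip(blocks, permuted):
                if orig.kind == "mixed":
                    assert sorted(orig.labels) == sorted(perm.labels)

    def test_rotation_by_length_is_identity(self):
        blocks = self._blocks([1, 2, 1])
        b = blocks[0]
        assert list(np.roll(b.labels, len(b))) == list(b.labels)

    def test_two_point_null_for_single_mixed_block(self):
        blocks = self._blocks([1, 2])
        ppi = pd.DataFrame({"fragment_id": [1, 2], "ppi": [0.8, 0.2]})
        eng = bs.PermutationEngine(blocks)
        fs, fc = bs._fragment_signal(blocks, ppi)
        eng.set_signal(fs, fc)
        stats = eng.null_statistics(4000, np.random.default_rng(1))
        support = sorted(set(np.round(stats, 12)))
        np.testing.assert_allclose(support, [-0.6, 0.6], atol=1e-12)
        # both rotations equally likely
        frac = np.mean(stats > 0)
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 4000)


class TestBlockshifterTest:
    def test_degenerate_constant_ppi(self):
        labels = [1, 2, 0, 1, 0, 0, 2]
        fmap = contiguous_map(len(labels))
        test, control = sets_from_labels(labels)
        ppi = pd.DataFrame(
            {"fragment_id": np.arange(1, 8), "ppi": np.full(7, 0.3)}
        )
        res = bs.blockshifter_test(fmap, test, control, ppi, gap=1, n_perm=500, seed=0)
        assert res.observed_stat == pytest.approx(0.0)
        assert res.empirical_p == 1.0
        assert res.degenerate_null

    def test_enriched_instance_positive_z(self, genome_small):
        g = genome_small
        rng = np.random.default_rng(3)
        test_only = g.pirs_test.fragment_ids - g.pirs_control.fragment_ids
        ppi_vals = np.full(len(g.panel), 1e-4)
        in_test = g.panel["fragment_id"].isin(test_only).to_numpy()
        ppi_vals[in_test] = 0.5
        ppi = pd.DataFrame({"fragment_id": g.panel["fragment_id"], "ppi": ppi_vals})
        res = bs.blockshifter_test(
            g.fmap, g.pirs_test, g.pirs_control, ppi, gap=5, n_perm=500, seed=0
        )
        assert res.z > 0
        assert res.empirical_p < 0.05

    def test_empirical_null_matches_exhaustive_enumeration(self):
        # 8 fragments: mixed block [T,C,T], unmixed test [6], unmixed control [8]
        labels = [1, 2, 1, 0, 0, 1, 0, 2]
        fmap = contiguous_map(8)
        test, control = sets_from_labels(labels)
        blocks = bs.build_superblocks(fmap, test, control, gap=0)
        assert [b.kind for b in blocks] == ["mixed", "unmixed_test", "unmixed_control"]
        ppi = pd.DataFrame(
            {
                "fragment_id": [1, 2, 2, 3, 6, 8],
                "ppi": [0.3, 0.1, 0.2, 0.05, 0.4, 0.15],
            }
        )
        frag_ppi = {1: [0.3], 2: [0.1, 0.2], 3: [0.05], 6: [0.4], 8: [0.15]}

        # oracle: enumerate all rotations x unmixed label assignments
        mixed_labels = [1, 2, 1]
        exact = []
        for off, assign in itertools.product(range(3), [(1, 2), (2, 1)]):
            lab = {}
            rolled = np.roll(mixed_labels, off)
            for fid, l in zip([1, 2, 3], rolled):
                lab[fid] = l
            lab[6], lab[8] = assign
            tvals = [v for f, l in lab.items() if l & 1 for v in frag_ppi[f]]
            cvals = [v for f, l in lab.items() if l & 2 for v in frag_ppi[f]]
            exact.append(np.mean(tvals) - np.mean(cvals))
        exact = np.array(sorted(exact))

        eng = bs.PermutationEngine(blocks)
        fs, fc = bs._fragment_signal(blocks, ppi)
        eng.set_signal(fs, fc)
        n = 30_000
        stats = eng.null_statistics(n, np.random.default_rng(5))
        # support agrees
        assert set(np.round(stats, 10)) == set(np.round(exact, 10))
        # each of the 6 equally likely outcomes appears at frequency ~1/6
        for value in np.unique(np.round(exact, 10)):
            freq = np.mean(np.round(stats, 10) == value)
            weight = np.mean(np.round(exact, 10) == value)
            assert abs(freq - weight) < 4 * np.sqrt(weight * (1 - weight) / n)

        # the Monte Carlo p-value agrees with the exact enumeration p
        obs = eng.observed()
        res = bs.blockshifter_test(
            fmap, test, control, ppi, gap=0, n_perm=5000, seed=2
        )
        p_exact = np.mean(exact >= obs - 1e-15)
        assert res.empirical_p == pytest.approx(p_exact, abs=0.03)

    def test_type_one_error_under_iid_signal(self, genome_small):
        """With ppi i.i.d. across variants the empirical p is uniform."""
        g = genome_small
        rng = np.random.default_rng(11)
        ppi_df = pd.DataFrame({"fragment_id": g.panel["fragment_id"], "ppi": 0.0})
        with_data = frozenset(
            int(f) for f in g.panel["fragment_id"].unique() if f >= 0
        )
        test = PIRSet("test", g.pirs_test.fragment_ids & with_data)
        control = PIRSet("control", g.pirs_control.fragment_ids & with_data)
        eng = bs.PermutationEngine(
            bs.build_superblocks(g.fmap, test, control, gap=5)
        )
        rej = 0
        n_data = 1000
        for _ in range(n_data):
            ppi_df["ppi"] = rng.random(len(ppi_df))
            res = bs.blockshifter_test(
                g.fmap, test, control, ppi_df, gap=5, n_perm=200,
                rng=rng, engine=eng,
            )
            rej += res.empirical_p <= 0.05
        assert 0.032 <= rej / n_data <= 0.068


class TestFisherComparator:
    def _variants(self, n_t_hi, n_t_lo, n_c_hi, n_c_lo):
        rows = []
        rows += [{"fragment_id": 1, "ppi": 0.5}] * n_t_hi
        rows += [{"fragment_id": 1, "ppi": 0.0}] * n_t_lo
        rows += [{"fragment_id": 2, "ppi": 0.5}] * n_c_hi
        rows += [{"fragment_id": 2, "ppi": 0.0}] * n_c_lo
        return pd.DataFrame(rows)

    def test_symmetric_table(self):
        test = PIRSet("test", frozenset({1}))
        control = PIRSet("control", frozenset({2}))
        odds, p = bs.fisher_naive_test(self._variants(10, 90, 10, 90), test, control)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_extreme_table_hypergeometric(self):
        test = PIRSet("test", frozenset({1}))
        control = PIRSet("control", frozenset({2}))
        odds, p = bs.fisher_naive_test(self._variants(5, 0, 0, 5), test, control)
        assert np.isinf(odds)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_empty_margin_flagged(self):
        test = PIRSet("test", frozenset({1}))
        control = PIRSet("control", frozenset({2}))
        variants = pd.DataFrame({"fragment_id": [1, 1], "ppi": [0.5, 0.6]})
        odds, p = bs.fisher_naive_test(variants, test, control)
        assert np.isnan(odds) and p == 1.0
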