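import itertools

import numpy as np
import pandas as pd
import pytest

from chicogs.cogs import (
    categorize_variants,
    combine_gene_score,
    decision_tree_assign,
    gene_block_score,
    node_counts,
    prioritize_genes,
    score_gene,
    score_genes,
)
from chicogs.genome_model import (
    Fragment,
    FragmentMap,
    GeneAnnotation,
    InteractionSet,
)

STATES = ["activated", "non_activated"]


@pytest.fixture
def small_world():
    """Ten fragments; gene baited on fragment 5, coding exon inside
    fragment 8, PIR on fragment 2 (activated only) and 9 (both states)."""
    fmap = FragmentMap(
        [Fragment(i, "chr1", (i - 1) * 1000, i * 1000) for i in range(1, 11)]
    )
    gene = GeneAnnotation(
        "GENE_A", bait_ids={5}, coding_intervals=[("chr1", 7200, 7800)]
    )
    ints = InteractionSet(
        pd.DataFrame(
            {
                "bait_id": [5, 5],
                "oe_id": [2, 9],
                "activated": [5.2, 8.0],
                "non_activated": [1.0, 7.0],
            }
        ),
        STATES,
    )
    return fmap, gene, ints


def variants_at(positions, ids=None):
    ids = ids or [f"v{i}" for i in range(len(positions))]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "chr1",
            "pos": positions,
            "fragment_id": [(p - 1) // 1000 + 1 for p in positions],
            "block_id": 0,
        }
    )
    return df


class TestCategorize:
    def test_precedence_coding_over_pir(self, small_world):
        fmap, gene, ints = small_world
        # fragment 8 is not a PIR here, so plant the exon inside fragment 9
        gene = GeneAnnotation(
            "GENE_A", bait_ids={5}, coding_intervals=[("chr1", 8200, 8800)]
        )
        v = variants_at([8500])
        out = categorize_variants(v, gene, fmap, ints, STATES)
        assert out[0].category == "coding"

    def test_bait_adjacent_is_promoter(self, small_world):
        fmap, gene, ints = small_world
        v = variants_at([4500, 5500, 6500, 3500])
        cats = [a.category for a in categorize_variants(v, gene, fmap, ints, STATES)]
        # fragments 4,5,6 are promoter (bait 5 +/- 1); fragment 4's left
        # neighbour 3 is not
        assert cats == ["promoter", "promoter", "promoter"]

    def test_pir_records_state_support(self, small_world):
        fmap, gene, ints = small_world
        out = categorize_variants(variants_at([1500]), gene, fmap, ints, STATES)
        assert out[0].category == "pir"
        assert out[0].state_support == frozenset({"activated"})

    def test_uncategorised_variant_skipped(self, small_world):
        fmap, gene, ints = small_world
        assert categorize_variants(variants_at([2500]), gene, fmap, ints, STATES) == []


class TestScores:
    def test_block_score_sums_ppi(self, small_world):
        fmap, gene, ints = small_world
        v = variants_at([1500, 7500], ids=["A", "B"])
        asg = categorize_variants(v, gene, fmap, ints, STATES)
        ppi = pd.Series({"A": 0.3, "B": 0.2})
        assert gene_block_score(asg, ppi, ("pir",)) == pytest.approx(0.3)
        assert gene_block_score(asg, ppi, ("coding",)) == pytest.approx(0.2)
        assert gene_block_score(asg, ppi, ("promoter",)) == 0.0

    def test_combine_formula(self):
        assert combine_gene_score([0.5, 0.5]) == 0.75
        assert combine_gene_score([0.4]) == pytest.approx(0.4)
        assert combine_gene_score([0.9, 0.9, 0.9]) == pytest.approx(0.999)
        assert combine_gene_score([]) == 0.0
        with pytest.raises(ValueError):
            combine_gene_score([1.2])

    def test_monotone_in_added_pir(self, small_world):
        """Adding a PIR to the gene's interaction set never lowers its score."""
        fmap, gene, _ = small_world
        v = variants_at([1500, 2500, 9500], ids=["A", "B", "C"])
        post = {0: pd.Series({"A": 0.2, "B": 0.3, "C": 0.1})}
        base_ints = InteractionSet(
            pd.DataFrame(
                {"bait_id": [5], "oe_id": [2], "activated": [6.0], "non_activated": [6.0]}
            ),
            STATES,
        )
        more_ints = InteractionSet(
            pd.DataFrame(
                {
                    "bait_id": [5, 5],
                    "oe_id": [2, 3],
                    "activated": [6.0, 7.0],
                    "non_activated": [6.0, 7.0],
                }
            ),
            STATES,
        )
        s0 = score_gene(gene, v, post, fmap, base_ints, STATES).overall_score
        s1 = score_gene(gene, v, post, fmap, more_ints, STATES).overall_score
        assert s1 >= s0

    def test_multi_block_equals_direct_enumeration(self, small_world):
        """Gene score equals the enumerated probability that at least one
        block's causal model hits the gene's regions (independent blocks)."""
        fmap, gene, ints = small_world
        rng = np.random.default_rng(4)
        v = pd.DataFrame(
            {
                "variant_id": [f"b{b}v{i}" for b in range(3) for i in range(4)],
                "chrom": "chr1",
                "pos": [1500, 4500, 8500, 2500] * 3,
                "fragment_id": [2, 5, 9, 3] * 3,
                "block_id": np.repeat([0, 1, 2], 4),
            }
        )
        post = {}
        for b in range(3):
            ids = [f"b{b}v{i}" for i in range(4)]
            models = [frozenset([ids[0]]), frozenset(ids[1:3]), frozenset([ids[3]])]
            probs = rng.dirichlet(np.ones(4))[:3] * 0.9
            post[b] = pd.DataFrame({"model": models, "posterior": probs})
        rec = score_gene(gene, v, post, fmap, ints, STATES)

        # oracle: joint enumeration over blocks incl. the "no causal" outcome
        hit_sets = []
        for b in range(3):
            asg = categorize_variants(
                v[v["block_id"] == b], gene, fmap, ints, STATES
            )
            hit_vars = {a.variant_id for a in asg}
            tbl = post[b]
            p_hit = sum(
                p for m, p in zip(tbl["model"], tbl["posterior"]) if m & hit_vars
            )
            p_miss_listed = sum(
                p for m, p in zip(tbl["model"], tbl["posterior"]) if not (m & hit_vars)
            )
            hit_sets.append((p_hit, p_miss_listed + (1 - p_hit - p_miss_listed)))
        p_none = 1.0
        for p_hit, p_not in hit_sets:
            p_none *= p_not
        assert rec.overall_score == pytest.approx(1 - p_none, abs=1e-12)

    def test_shared_pir_credits_every_gene(self):
        fmap = FragmentMap(
            [Fragment(i, "chr1", (i - 1) * 1000, i * 1000) for i in range(1, 11)]
        )
        g1 = GeneAnnotation("G1", bait_ids={2})
        g2 = GeneAnnotation("G2", bait_ids={8})
        ints = InteractionSet(
            pd.DataFrame(
                {
                    "bait_id": [2, 8],
                    "oe_id": [5, 5],
                    "activated": [6.0, 6.0],
                    "non_activated": [6.0, 6.0],
                }
            ),
            STATES,
        )
        v = variants_at([4500], ids=["shared"])
        post = {0: pd.Series({"shared": 0.8})}
        s1 = score_gene(g1, v, post, fmap, ints, STATES).overall_score
        s2 = score_gene(g2, v, post, fmap, ints, STATES).overall_score
        assert s1 == s2 == pytest.approx(0.8)


class TestDecisionTree:
    def test_genic_branch(self):
        comps = {"genic": 0.9, "pir_all": 0.1, "coding": 0.9, "promoter": 0.05}
        assert decision_tree_assign(comps) == "coding"

    def test_root_unresolved(self):
        comps = {"genic": 0.5, "pir_all": 0.4}
        assert decision_tree_assign(comps) == "mechanism_unresolved"

    def test_pir_state_split(self):
        comps = {
            "genic": 0.05,
            "pir_all": 0.6,
            "pir_activated": 0.6,
            "pir_non_activated": 0.1,
        }
        assert (
            decision_tree_assign(comps, state_labels=("activated", "non_activated"))
            == "pir_activated"
        )

    def test_pir_unresolved_when_states_comparable(self):
        comps = {
            "genic": 0.05,
            "pir_all": 0.6,
            "pir_activated": 0.5,
            "pir_non_activated": 0.4,
        }
        assert decision_tree_assign(comps) == "pir_unresolved"

    def test_zero_competitor_is_infinite_ratio(self):
        comps = {"genic": 0.4, "pir_all": 0.0, "coding": 0.0, "promoter": 0.4}
        assert decision_tree_assign(comps) == "promoter"

    def test_both_zero_unresolved(self):
        assert decision_tree_assign({"genic": 0.0, "pir_all": 0.0}) == "unresolved"

    def test_log10_ratio_mode_is_stricter(self):
        comps = {"genic": 0.9, "pir_all": 0.1, "coding": 0.9, "promoter": 0.01}
        assert decision_tree_assign(comps) == "coding"
        # ratio 9 -> log10 ~ 0.95 < 3: stuck at root under the log10 reading
        assert decision_tree_assign(comps, log10_ratio=True) == "mechanism_unresolved"


class TestPrioritisation:
    def _scores(self, values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(values))],
                "trait": "T",
                "overall_score": values,
                "node": "pir_activated",
                "top_block": [0] * len(values),
            }
        )

    def test_threshold_split(self):
        reported, prioritised, region = prioritize_genes(self._scores([0.6, 0.4, 0.005]))
        assert set(reported["overall_score"]) == {0.6, 0.4}
        assert set(prioritised["overall_score"]) == {0.6}
        assert region["n_genes"].iloc[0] == 1

    def test_empty_input(self):
        reported, prioritised, region = prioritize_genes(self._scores([]))
        assert len(reported) == len(prioritised) == len(region) == 0

    def test_fractional_node_counts(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "trait": ["T1", "T2", "T1"],
                "overall_score": [0.8, 0.7, 0.9],
                "node": ["coding", "pir_activated", "coding"],
                "top_block": [0, 0, 1],
            }
        )
        counts = node_counts(df)
        assert counts["coding"] == pytest.approx(1.5)
        assert counts["pir_activated"] == pytest.approx(0.5)


def test_planted_signal_recovery(genome_small):
    """A gene whose PIR holds the sole causal variant is recovered with a
    COGS score matching the planted ppi; untouched genes score ~0."""
    g = genome_small
    panel = g.panel
    # find a PIR fragment (of some gene, in any CD4 state) containing a variant
    target_gene, target_fid, target_vid = None, None, None
    for gene in g.genes:
        pirs = g.interactions.pir_fragments("activated", 5.0, bait_ids=gene.bait_ids)
        for fid in pirs:
            hit = panel[panel["fragment_id"] == fid]
            if len(hit):
                target_gene, target_fid = gene, fid
                target_vid = hit["variant_id"].iloc[0]
                break
        if target_gene:
            break
    assert target_gene is not None
    ppi = pd.Series(1e-6, index=panel["variant_id"])
    ppi.loc[target_vid] = 0.95
    block_of = dict(zip(panel["variant_id"], panel["block_id"]))
    post = {
        int(b): ppi[[v for v in ppi.index if block_of[v] == b]]
        for b in panel["block_id"].unique()
    }
    scores = score_genes(
        g.genes, panel, post, g.fmap, g.interactions, STATES
    )
    top = scores.iloc[0]
    assert top["overall_score"] >= 0.9
    planted = scores[scores["gene_id"] == target_gene.gene_id]
    assert planted["overall_score"].iloc[0] >= 0.9
    assert planted["overall_score"].iloc[0] == scores["overall_score"].max()
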