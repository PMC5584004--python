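"""COGS gene prioritisation scores from fine-mapped posteriors and
promoter capture Hi-C interaction calls.

For each gene, variants are assigned to the first matching category:

1. *coding* — the variant overlaps a coding interval of the gene;
2. *promoter* — the variant lies in a fragment baited for the gene's
   promoter or its immediately adjacent fragments (proximal interactions
   are poorly detected by capture Hi-C, so one flank either side is
   credited to the promoter);
3. *pir* — the variant lies in any fragment with a confident interaction
   to one of the gene's baits.

Within each LD block the posterior mass of models containing a variant in
the chosen category set is aggregated (for single-causal posteriors this
is a sum of per-variant ppi), and block-level probabilities are combined
assuming independence across blocks:

    gene score = 1 − Π_blocks (1 − block score)

— the approximate posterior probability that at least one block harbours a
causal variant in the gene's regions.  A ratio-based decision tree then
labels each prioritised gene with its most likely mechanism (coding /
promoter / PIR, and for PIRs the supporting activation state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .finemap import aggregate_model_posteriors
from .genome_model import FragmentMap, GeneAnnotation, InteractionSet

__all__ = [
    "CategoryAssignment",
    "GeneScoreRecord",
    "categorize_variants",
    "gene_block_score",
    "combine_gene_score",
    "decision_tree_assign",
    "score_gene",
    "score_genes",
    "prioritize_genes",
    "node_counts",
]


@dataclass(frozen=True)
class CategoryAssignment:
    variant_id: str
    gene_id: str
    category: str  # coding | promoter | pir
    state_support: frozenset = frozenset()


@dataclass
class GeneScoreRecord:
    gene_id: str
    trait: str
    overall_score: float
    component_scores: Dict[str, float]
    node: str
    block_scores: Dict[int, float] = field(default_factory=dict)

    @property
    def top_block(self) -> Optional[int]:
        if not self.block_scores:
            return None
        return max(self.block_scores, key=self.block_scores.get)


def _gene_pir_fragments(
    gene: GeneAnnotation,
    interactions: InteractionSet,
    states: Sequence[str],
    threshold: float = 5.0,
) -> Dict[str, Set[int]]:
    """Other-end fragments interacting with the gene's baits, per state."""
    return {
        s: interactions.pir_fragments(s, threshold, bait_ids=gene.bait_ids)
        for s in states
    }


def _promoter_fragments(gene: GeneAnnotation, fmap: FragmentMap) -> Set[int]:
    frags: Set[int] = set()
    for b in gene.bait_ids:
        if b in fmap:
            frags.add(b)
            frags.update(fmap.neighbors(b, k=1))
    return frags


def categorize_variants(
    variants: pd.DataFrame,
    gene: GeneAnnotation,
    fmap: FragmentMap,
    interactions: InteractionSet,
    states: Sequence[str],
    score_threshold: float = 5.0,
) -> List[CategoryAssignment]:
    """Assign each variant to its first matching category for one gene.

    Precedence is coding > promoter > pir; a variant matching none is
    skipped.  PIR assignments record which states call the supporting
    interaction.  ``variants`` needs columns variant_id, chrom, pos
    (1-based) and fragment_id.
    """
    pir_by_state = _gene_pir_fragments(gene, interactions, states, score_threshold)
    promoter = _promoter_fragments(gene, fmap)
    out: List[CategoryAssignment] = []
    for row in variants.itertuples():
        p0 = int(row.pos) - 1
        if any(
            c == row.chrom and s <= p0 < e for c, s, e in gene.coding_intervals
        ):
            out.append(CategoryAssignment(str(row.variant_id), gene.gene_id, "coding"))
            continue
        fid = int(row.fragment_id)
        if fid in promoter:
            out.append(CategoryAssignment(str(row.variant_id), gene.gene_id, "promoter"))
            continue
        support = frozenset(s for s, frags in pir_by_state.items() if fid in frags)
        if support:
            out.append(
                CategoryAssignment(str(row.variant_id), gene.gene_id, "pir", support)
            )
    return out


def gene_block_score(
    assignments: Iterable[CategoryAssignment],
    posteriors,
    categories: Sequence[str] = ("coding", "promoter", "pir"),
    states: Optional[Sequence[str]] = None,
) -> float:
    """Posterior mass on "a causal variant hits the gene" within one block.

    ``posteriors`` is either a per-variant ppi mapping/Series (single
    causal) or a model-posterior DataFrame (columns model, posterior), in
    which case the model-aggregation rule applies.  ``states`` restricts
    PIR assignments to those supported in at least one listed state.
    """
    wanted: Set[str] = set()
    for a in assignments:
        if a.category not in categories:
            continue
        if a.category == "pir" and states is not None:
            if not (a.state_support & set(states)):
                continue
        wanted.add(a.variant_id)
    if not wanted:
        return 0.0
    if isinstance(posteriors, pd.DataFrame) and "model" in posteriors.columns:
        return aggregate_model_posteriors(posteriors, wanted)
    if isinstance(posteriors, pd.Series):
        ppi = posteriors
    else:
        ppi = pd.Series(dict(posteriors))
    present = [v for v in wanted if v in ppi.index]
    return float(ppi.loc[present].sum())


def combine_gene_score(block_scores: Iterable[float]) -> float:
    """1 − Π(1 − s): probability at least one block contributes a causal
    variant, assuming independence across LD blocks."""
    total = 1.0
    for s in block_scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"block score {s} outside [0, 1]")
        total *= 1.0 - s
    return 1.0 - total


def _ratio(a: float, b: float) -> float:
    if b == 0.0:
        return float("inf") if a > 0 else float("nan")
    return a / b


def decision_tree_assign(
    component_scores: Mapping[str, float],
    ratio_threshold: float = 3.0,
    log10_ratio: bool = False,
    state_labels: Tuple[str, str] = ("activated", "non_activated"),
) -> str:
    """Label a gene's most likely mechanism by successive score-ratio splits.

    Root: genic (coding + promoter) vs PIR; the winner must exceed the
    competitor by ``ratio_threshold`` (on the raw ratio by default, or on
    its log10 with ``log10_ratio``), else the gene is returned at the
    parent node.  The genic branch splits coding vs promoter; the PIR
    branch splits the two activation states using scores computed from
    each state's PIR calls alone.
    """

    def prefer(a: float, b: float) -> int:
        # 1 if a preferred, -1 if b preferred, 0 undecided
        r_ab, r_ba = _ratio(a, b), _ratio(b, a)
        thr = ratio_threshold
        if log10_ratio:
            r_ab = np.log10(r_ab) if r_ab > 0 else -np.inf
            r_ba = np.log10(r_ba) if r_ba > 0 else -np.inf
        if np.isnan(r_ab) and np.isnan(r_ba):
            return 0
        if r_ab > thr:
            return 1
        if r_ba > thr:
            return -1
        return 0

    genic = component_scores.get("genic", 0.0)
    pir = component_scores.get("pir_all", 0.0)
    if genic == 0.0 and pir == 0.0:
        return "unresolved"
    root = prefer(genic, pir)
    if root == 0:
        return "mechanism_unresolved"
    if root > 0:
        sub = prefer(
            component_scores.get("coding", 0.0), component_scores.get("promoter", 0.0)
        )
        if sub > 0:
            return "coding"
        if sub < 0:
            return "promoter"
        return "genic_unresolved"
    s_a, s_b = state_labels
    sub = prefer(
        component_scores.get(f"pir_{s_a}", 0.0), component_scores.get(f"pir_{s_b}", 0.0)
    )
    if sub > 0:
        return f"pir_{s_a}"
    if sub < 0:
        return f"pir_{s_b}"
    return "pir_unresolved"


def score_gene(
    gene: GeneAnnotation,
    variants: pd.DataFrame,
    posteriors_by_block: Mapping[int, object],
    fmap: FragmentMap,
    interactions: InteractionSet,
    states: Sequence[str],
    trait: str = "trait",
    score_threshold: float = 5.0,
    ratio_threshold: float = 3.0,
    log10_ratio: bool = False,
) -> GeneScoreRecord:
    """Full COGS record for one gene.

    ``variants`` needs variant_id, chrom, pos, fragment_id and block_id;
    ``posteriors_by_block`` maps block_id to a ppi Series (indexed by
    variant_id) or a model-posterior DataFrame.
    """
    assignments = categorize_variants(
        variants, gene, fmap, interactions, states, score_threshold
    )
    by_block: Dict[int, List[CategoryAssignment]] = {}
    vid_block = dict(zip(variants["variant_id"].astype(str), variants["block_id"]))
    for a in assignments:
        by_block.setdefault(int(vid_block[a.variant_id]), []).append(a)

    def component(categories, state_filter=None) -> Tuple[float, Dict[int, float]]:
        per_block = {}
        for block_id, asg in by_block.items():
            post = posteriors_by_block.get(block_id)
            if post is None:
                continue
            s = gene_block_score(asg, post, categories, state_filter)
            if s > 0:
                per_block[block_id] = s
        return combine_gene_score(per_block.values()), per_block

    overall, overall_blocks = component(("coding", "promoter", "pir"))
    coding, _ = component(("coding",))
    promoter, _ = component(("promoter",))
    genic, _ = component(("coding", "promoter"))
    pir_all, _ = component(("pir",))
    comps = {
        "coding": coding,
        "promoter": promoter,
        "genic": genic,
        "pir_all": pir_all,
    }
    for s in states:
        comps[f"pir_{s}"], _ = component(("pir",), state_filter=[s])
    node = decision_tree_assign(
        comps,
        ratio_threshold=ratio_threshold,
        log10_ratio=log10_ratio,
        state_labels=tuple(states[:2]) if len(states) >= 2 else ("activated", "non_activated"),
    )
    return GeneScoreRecord(
        gene_id=gene.gene_id,
        trait=trait,
        overall_score=overall,
        component_scores=comps,
        node=node,
        block_scores=overall_blocks,
    )


def score_genes(
    genes: Sequence[GeneAnnotation],
    variants: pd.DataFrame,
    posteriors_by_block: Mapping[int, object],
    fmap: FragmentMap,
    interactions: InteractionSet,
    states: Sequence[str],
    trait: str = "trait",
    **kwargs,
) -> pd.DataFrame:
    """Score every gene; returns a tidy table sorted by overall score."""
    rows = []
    for gene in genes:
        rec = score_gene(
            gene, variants, posteriors_by_block, fmap, interactions, states,
            trait=trait, **kwargs,
        )
        row = {
            "gene_id": rec.gene_id,
            "trait": rec.trait,
            "overall_score": rec.overall_score,
            "node": rec.node,
            "n_blocks": len(rec.block_scores),
            "top_block": rec.top_block if rec.top_block is not None else -1,
        }
        for k, v in rec.component_scores.items():
            row[f"score_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("overall_score", ascending=False).reset_index(drop=True)


def prioritize_genes(
    scores: pd.DataFrame,
    report_threshold: float = 0.01,
    priority_threshold: float = 0.5,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Filter the score table into reported and prioritised subsets.

    Returns (reported, prioritised, per-region summary).  The per-region
    summary counts prioritised genes per top contributing LD block —
    quantifying how many genes a typical signal region nominates.
    """
    if len(scores) == 0:
        empty = scores.copy()
        return empty, empty.copy(), pd.DataFrame(columns=["top_block", "n_genes"])
    reported = scores[scores["overall_score"] > report_threshold].copy()
    prioritised = scores[scores["overall_score"] > priority_threshold].copy()
    if len(prioritised):
        region = (
            prioritised.groupby("top_block")
            .size()
            .rename("n_genes")
            .reset_index()
        )
    else:
        region = pd.DataFrame(columns=["top_block", "n_genes"])
    return reported, prioritised, region


def node_counts(prioritised: pd.DataFrame) -> pd.Series:
    """Fractional per-node counts: a gene prioritised for n traits adds 1/n
    per (trait, node) occurrence, so each gene contributes unit mass."""
    if len(prioritised) == 0:
        return pd.Series(dtype=float)
    per_gene = prioritised.groupby("gene_id").size()
    weights = prioritised["gene_id"].map(lambda g: 1.0 / per_gene[g])
    return weights.groupby(prioritised["node"]).sum().sort_values(ascending=False)
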