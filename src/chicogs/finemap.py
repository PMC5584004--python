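"""Single-causal-variant Bayesian fine-mapping from GWAS summary statistics.

Per LD block, each variant's evidence is summarised by a Wakefield
approximate Bayes factor computed from its Z score and the estimated
variance of its effect estimate.  Under the assumption of at most one
causal variant per block, with a per-variant prior probability ``pi`` of
causality, the block-level model space is {null} ∪ {variant i causal} and
posterior probabilities follow from the prior-weighted Bayes factors.

Also provided: the input filters applied before fine-mapping (removal of
unsupported genome-wide-significant signals, masking of the extended MHC),
and aggregation of model posteriors from an external multi-causal
fine-mapper over arbitrary variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri_exp

from .genome_model import PairwiseR2

__all__ = [
    "FineMapConfig",
    "wakefield_labf",
    "estimate_V",
    "zscore_from_p",
    "pvalue_from_z",
    "single_causal_posteriors",
    "finemap_blocks",
    "filter_spurious",
    "mask_region",
    "binom_model_prior",
    "aggregate_model_posteriors",
    "parse_model_table",
    "MHC_MASK",
]

#: Extended MHC mask (GRCh37): chr6:25-35 Mb.
MHC_MASK: Tuple[str, int, int] = ("chr6", 25_000_000, 35_000_000)


@dataclass
class FineMapConfig:
    """Priors and block geometry for single-causal fine-mapping.

    W
        Prior variance of the log relative risk at a causal variant
        (default 0.04, i.e. a 95% prior belief that the relative risk lies
        in roughly 0.68-1.48).
    pi
        Prior probability that any one variant is causal (default 1e-4).
    block_cM
        Genetic block width in centimorgans: 1.0 for enrichment-oriented
        posteriors, 0.1 for gene-score-oriented posteriors.
    mhc_mask
        Region excluded from all analysis.
    """

    W: float = 0.04
    pi: float = 1e-4
    block_cM: float = 1.0
    mhc_mask: Tuple[str, int, int] = MHC_MASK

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("W must be positive")
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")


def wakefield_labf(z, V, W: float = 0.04):
    """Log approximate Bayes factor (alternative over null) for a variant.

    lABF = 0.5*ln(V/(V+W)) + (z²/2) * W/(V+W), where V is the variance of
    the estimated effect and W the prior effect variance.  Vectorised over
    ``z`` and ``V``.
    """
    z = np.asarray(z, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    if W <= 0:
        raise ValueError("W must be positive")
    shrink = W / (V + W)
    out = 0.5 * np.log(V / (V + W)) + 0.5 * z * z * shrink
    return out if out.ndim else float(out)


def estimate_V(
    maf,
    n_cases: float,
    n_controls: Optional[float] = None,
    se=None,
):
    """Approximate the variance of the effect estimate from study design.

    When a standard error is supplied it takes precedence (V = se²).
    Case-control: V = 1/(2·N·f·(1-f)·s·(1-s)) with N the total sample size,
    f the minor allele frequency and s the case fraction.  Quantitative
    traits (``n_controls`` None): V = 1/(2·N·f·(1-f)).
    """
    if se is not None:
        se = np.asarray(se, dtype=np.float64)
        return se * se if se.ndim else float(se * se)
    f = np.asarray(maf, dtype=np.float64)
    if np.any((f <= 0) | (f > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if n_cases <= 0 or (n_controls is not None and n_controls <= 0):
        raise ValueError("sample sizes must be positive")
    if n_controls is None:
        N = float(n_cases)
        out = 1.0 / (2.0 * N * f * (1.0 - f))
    else:
        N = float(n_cases) + float(n_controls)
        s = float(n_cases) / N
        out = 1.0 / (2.0 * N * f * (1.0 - f) * s * (1.0 - s))
    return out if out.ndim else float(out)


def zscore_from_p(p):
    """|Z| from a two-sided p-value, stable down to log-underflow scale.

    Uses the inverse of the log normal CDF, so p-values far below the
    smallest normal double (provided as exact zeros they are rejected)
    convert without intermediate underflow.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    out = -ndtri_exp(np.log(p) - np.log(2.0))
    return out if out.ndim else float(out)


def pvalue_from_z(z):
    """Two-sided normal p-value from a Z score."""
    z = np.asarray(z, dtype=np.float64)
    out = 2.0 * ndtr(-np.abs(z))
    return out if out.ndim else float(out)


def log_pvalue_from_z(z):
    """Natural-log two-sided normal p-value (no underflow for large |z|)."""
    z = np.asarray(z, dtype=np.float64)
    out = np.log(2.0) + log_ndtr(-np.abs(z))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------

def _posteriors_from_labf(labf: np.ndarray, pi: float) -> Tuple[np.ndarray, float]:
    """Posterior over {null} ∪ {i causal} from per-variant lABFs.

    Prior weights are exact binomial: w0 = (1-pi)^n for the null and
    wi = pi*(1-pi)^(n-1) per single-causal model, so the posterior vector
    sums to one exactly.  Computed in log space.
    """
    n = len(labf)
    if n == 0:
        raise ValueError("empty block")
    log1m = np.log1p(-pi)
    log_w0 = n * log1m
    log_wi = np.log(pi) + (n - 1) * log1m
    terms = np.concatenate(([log_w0], log_wi + labf))
    denom = logsumexp(terms)
    post = np.exp(terms - denom)
    return post[1:], float(post[0])


def single_causal_posteriors(
    block: pd.DataFrame, config: FineMapConfig = FineMapConfig()
) -> Tuple[pd.DataFrame, float]:
    """Fine-map one LD block under the at-most-one-causal-variant model.

    ``block`` needs a ``z`` column (or ``p``, converted via the two-sided
    normal quantile — the lABF depends on z² only, so the sign is
    irrelevant) and a ``V`` column (or ``maf`` + sample-size columns handled
    upstream).  Returns the block with ``labf`` and ``ppi`` columns added,
    and the posterior probability that the block contains no causal variant.
    """
    if len(block) == 0:
        raise ValueError("empty block")
    out = block.copy()
    if "z" in out.columns and out["z"].notna().all():
        z = out["z"].to_numpy(dtype=np.float64)
    else:
        z = zscore_from_p(out["p"].to_numpy(dtype=np.float64))
    V = out["V"].to_numpy(dtype=np.float64)
    labf = wakefield_labf(z, V, config.W)
    ppi, pp_null = _posteriors_from_labf(np.asarray(labf, dtype=np.float64), config.pi)
    out["labf"] = labf
    out["ppi"] = ppi
    return out, pp_null


def finemap_blocks(
    variants: pd.DataFrame, config: FineMapConfig = FineMapConfig()
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fine-map every LD block in a variant table (``block_id`` column).

    Returns (per-variant table with labf/ppi, per-block summary with
    pp_null and n_variants).
    """
    parts = []
    summaries = []
    for block_id, sub in variants.groupby("block_id", sort=True):
        scored, pp_null = single_causal_posteriors(sub, config)
        parts.append(scored)
        summaries.append((block_id, pp_null, len(sub)))
    out = pd.concat(parts) if parts else variants.copy()
    summary = pd.DataFrame(summaries, columns=["block_id", "pp_null", "n_variants"])
    return out, summary


# ---------------------------------------------------------------------------
# Input filters
# ---------------------------------------------------------------------------

def filter_spurious(
    variants: pd.DataFrame,
    r2: PairwiseR2,
    p_signif: float = 5e-8,
    p_support: float = 1e-5,
    window_bp: int = 50_000,
    r2_min: float = 0.6,
) -> pd.DataFrame:
    """Drop unsupported genome-wide-significant variants.

    A variant with p < ``p_signif`` is retained only if some other variant
    with p < ``p_support`` is either within ``window_bp`` on the same
    chromosome or in LD with it (r² > ``r2_min``).  All variants with
    p >= ``p_signif`` are retained.
    """
    keep = np.ones(len(variants), dtype=bool)
    sig = variants["p"].to_numpy() < p_signif
    if not sig.any():
        return variants.copy()
    support = variants[variants["p"].to_numpy() < p_support]
    for idx in np.nonzero(sig)[0]:
        row = variants.iloc[idx]
        cand = support[support["variant_id"] != row["variant_id"]]
        same = cand[cand["chrom"] == row["chrom"]]
        if ((same["pos"] - row["pos"]).abs() <= window_bp).any():
            continue
        if any(r2.r2(row["variant_id"], u) > r2_min for u in same["variant_id"]):
            continue
        keep[idx] = False
    return variants.loc[keep].copy()


def mask_region(
    variants: pd.DataFrame, region: Tuple[str, int, int] = MHC_MASK
) -> Tuple[pd.DataFrame, int]:
    """Drop variants inside a half-open bp region (default: extended MHC).

    Returns the filtered table and the number of variants removed.
    """
    chrom, start, end = region
    p0 = variants["pos"] - 1
    inside = (variants["chrom"] == chrom) & (p0 >= start) & (p0 < end)
    return variants.loc[~inside].copy(), int(inside.sum())


# ---------------------------------------------------------------------------
# Multi-causal model posteriors (external fine-mapper output)
# ---------------------------------------------------------------------------

def binom_model_prior(k: int, n: int, pi: float = 1e-4) -> float:
    """Prior for a specific k-variant causal model among n variants:
    pi^k * (1-pi)^(n-k)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(pi**k * (1.0 - pi) ** (n - k))


def parse_model_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a model-posterior table: ``model`` becomes a frozenset of
    variant ids (comma-joined on disk)."""
    out = df.copy()
    out["model"] = out["model"].map(
        lambda m: m if isinstance(m, frozenset) else frozenset(str(m).split(","))
    )
    if ((out["posterior"] < 0) | (out["posterior"] > 1)).any():
        raise ValueError("model posteriors must lie in [0, 1]")
    return out


def aggregate_model_posteriors(table: pd.DataFrame, variant_set: Iterable[str]) -> float:
    """Total posterior mass of models containing any variant in the set.

    For a single-causal PosteriorSet expressed as one model per variant this
    reduces to the sum of ppi over the set.  Empty set returns 0.
    """
    vset: Set[str] = set(map(str, variant_set))
    if not vset:
        return 0.0
    table = parse_model_table(table)
    hit = table["model"].map(lambda m: bool(m & vset))
    return float(table.loc[hit, "posterior"].sum())
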