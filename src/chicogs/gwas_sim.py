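"""Simulation of GWAS summary statistics over LD blocks and the
blockshifter calibration study.

Under a single causal variant per block with non-centrality parameter
``ncp`` at the causal variant i, the expected 1-df association chi-square
at any variant j is ncp·r²(i,j), so Z scores are multivariate normal with
mean μ_j = sqrt(ncp·r²(i,j)) and covariance the LD correlation matrix Σ.
Null blocks have μ = 0.  The calibration study plants causal variants
under three enrichment scenarios (null / power1 / power2), optionally
thins variants to emulate lower genotyping density (backfilled by PMI),
fine-maps each simulated GWAS, and records blockshifter rejection rates
across superblock gap sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import blockshifter as bs
from .finemap import FineMapConfig, estimate_V, pvalue_from_z, wakefield_labf
from .genome_model import PIRSet

__all__ = [
    "ScenarioConfig",
    "DENSITY_RETENTION",
    "BlockSampler",
    "simulate_block_z",
    "place_causals",
    "thin_to_density",
    "calibration_run",
]

#: Retention fractions emulating genotyping densities.  ``full`` keeps every
#: panel variant; the sparser settings are synthetic stand-ins for
#: HapMap-imputation-like and genotyping-array-like coverage.
DENSITY_RETENTION: Dict[str, float] = {
    "full": 1.0,
    "hapmap_like": 0.3,
    "array_like": 0.15,
}


@dataclass
class ScenarioConfig:
    """One cell of the calibration study design.

    scenario
        ``null`` (causal PIR placement indifferent to test/control),
        ``power1`` (PIR-localised causals drawn from test PIRs with
        probability 0.5, else any PIR) or ``power2`` (always test PIRs).
    n_blocks_alt
        Number of blocks carrying one causal variant each (study design:
        50 of 269 1-cM blocks; scaled proportionally on smaller genomes).
    ncp_causal
        Non-centrality parameter at the causal variant (80, making each
        causal variant genome-wide significant in expectation).
    p_causal_in_pir
        Probability the causal variant lies within a PIR at all (0.5).
    n_cases, n_controls
        Case-control sample sizes used for the effect-variance
        approximation in fine-mapping (defaults from a large rheumatoid
        arthritis meta-analysis).
    """

    scenario: str = "null"
    n_blocks_alt: int = 6
    ncp_causal: float = 80.0
    p_causal_in_pir: float = 0.5
    density: str = "full"
    n_cases: int = 5539
    n_controls: int = 20169
    n_sims: int = 500
    n_perm: int = 200
    seed: int = 0
    retention: Mapping[str, float] = field(default_factory=lambda: dict(DENSITY_RETENTION))

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "power1", "power2"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.p_causal_in_pir <= 1:
            raise ValueError("p_causal_in_pir must lie in [0, 1]")
        if self.density not in self.retention:
            raise ValueError(f"unknown density {self.density!r}")


class BlockSampler:
    """MVN sampler for one LD block's Z scores.

    Factorises Σ once (symmetric eigendecomposition with tiny negative
    eigenvalues clipped at -1e-8; more negative values are rejected) so
    repeated draws are a matrix-vector product.
    """

    def __init__(self, sigma: np.ndarray, tol: float = 1e-8):
        sigma = np.asarray(sigma, dtype=np.float64)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        w, v = np.linalg.eigh(sigma)
        if w.min() < -tol:
            raise ValueError(f"sigma not PSD: min eigenvalue {w.min():.3g}")
        w = np.clip(w, 0.0, None)
        self.factor = v * np.sqrt(w)  # factor @ factor.T == sigma (clipped)
        self.sigma = sigma
        self.n = sigma.shape[0]

    def mean_vector(self, causal_index: Optional[int], ncp: float) -> np.ndarray:
        """μ_j = sqrt(ncp · r²(causal, j)); zero vector for null blocks.

        The construction squares the correlation, so the sign of r is
        discarded (μ_i = sqrt(ncp) at the causal variant itself).
        """
        if causal_index is None:
            return np.zeros(self.n)
        r = self.sigma[causal_index]
        return np.sqrt(ncp * r * r)

    def signed_mean_vector(self, causal_index: Optional[int], ncp: float) -> np.ndarray:
        """Alternative mean μ_j = sqrt(ncp)·r(causal, j) — the internally
        consistent MVN mean, keeping the sign of r."""
        if causal_index is None:
            return np.zeros(self.n)
        return np.sqrt(ncp) * self.sigma[causal_index]

    def draw(
        self,
        causal_index: Optional[int],
        ncp: float,
        rng: np.random.Generator,
        eps: Optional[np.ndarray] = None,
        signed: bool = False,
    ) -> np.ndarray:
        """One Z-score vector; ``eps`` allows reuse of standard-normal noise
        across scenarios (common random numbers)."""
        if eps is None:
            eps = rng.standard_normal(self.n)
        mu = (
            self.signed_mean_vector(causal_index, ncp)
            if signed
            else self.mean_vector(causal_index, ncp)
        )
        return mu + self.factor @ eps


def simulate_block_z(
    sigma: np.ndarray,
    causal_index: Optional[int],
    ncp: float,
    rng: np.random.Generator,
    signed: bool = False,
) -> np.ndarray:
    """Simulate one block's Z scores ~ MVN(μ, Σ); see ``BlockSampler``."""
    return BlockSampler(sigma).draw(causal_index, ncp, rng, signed=signed)


def _stratum_indices(
    block_variants: pd.DataFrame,
    pirs_test: PIRSet,
    pirs_control: PIRSet,
) -> Dict[str, np.ndarray]:
    fid = block_variants["fragment_id"].to_numpy()
    in_t = np.array([int(f) in pirs_test for f in fid])
    in_c = np.array([int(f) in pirs_control for f in fid])
    any_pir = in_t | in_c
    return {
        "pir_any": np.nonzero(any_pir)[0],
        "pir_test": np.nonzero(in_t)[0],
        "non_pir": np.nonzero(~any_pir)[0],
    }


def place_causals(
    variants: pd.DataFrame,
    alt_blocks: Sequence[int],
    pirs_test: PIRSet,
    pirs_control: PIRSet,
    scenario: str,
    p_causal_in_pir: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose one causal variant per alt block according to the scenario.

    With probability ``p_causal_in_pir`` the causal variant is drawn from
    PIR-overlapping variants of the block — from test-set PIRs always
    (power2), with probability 0.5 (power1), or from any PIR without regard
    to set (null) — otherwise from non-PIR variants.  Note test-set PIRs
    may also belong to the control set, so not every PIR-placed causal is
    informative for enrichment.  Returns a truth table
    (block_id, variant_index, variant_id, stratum).
    """
    rows = []
    for block_id in alt_blocks:
        sub = variants[variants["block_id"] == block_id]
        strata = _stratum_indices(sub, pirs_test, pirs_control)
        in_pir = rng.random() < p_causal_in_pir
        if in_pir:
            if scenario == "power2":
                stratum = "pir_test"
            elif scenario == "power1":
                stratum = "pir_test" if rng.random() < 0.5 else "pir_any"
            else:
                stratum = "pir_any"
        else:
            stratum = "non_pir"
        pool = strata[stratum]
        if len(pool) == 0:
            raise ValueError(
                f"block {block_id}: no variants in stratum {stratum!r}"
            )
        local = int(pool[rng.integers(0, len(pool))])
        rows.append(
            {
                "block_id": block_id,
                "variant_index": local,
                "variant_id": sub["variant_id"].iloc[local],
                "stratum": stratum,
            }
        )
    return pd.DataFrame(
        rows, columns=["block_id", "variant_index", "variant_id", "stratum"]
    )


def eligible_alt_blocks(
    variants: pd.DataFrame,
    pirs_test: PIRSet,
    pirs_control: PIRSet,
    scenario: str = "null",
) -> np.ndarray:
    """Blocks with at least one variant in every stratum the scenario can
    draw from.  All scenarios need PIR-overlapping and non-PIR variants;
    the power scenarios additionally need test-PIR variants.  Requiring
    test-PIR variants under the null would skew signal placement toward
    test-rich blocks and spoil the type-1-error study.
    """
    needed = ["pir_any", "non_pir"]
    if scenario in ("power1", "power2"):
        needed.append("pir_test")
    ok = []
    for block_id, sub in variants.groupby("block_id"):
        strata = _stratum_indices(sub, pirs_test, pirs_control)
        if all(len(strata[k]) for k in needed):
            ok.append(block_id)
    return np.array(sorted(ok))


def thin_to_density(
    variants: pd.DataFrame,
    density: str,
    rng: np.random.Generator,
    retention: Mapping[str, float] = DENSITY_RETENTION,
) -> pd.DataFrame:
    """Bernoulli-thin a variant table to a genotyping-density fraction."""
    frac = retention[density]
    if frac >= 1.0:
        return variants.copy()
    keep = rng.random(len(variants)) < frac
    return variants.loc[keep].copy()


# ---------------------------------------------------------------------------
# Calibration study
# ---------------------------------------------------------------------------

def _finemap_fast(
    z: np.ndarray,
    V: np.ndarray,
    block_starts: np.ndarray,
    block_sizes: np.ndarray,
    W: float,
    pi: float,
) -> np.ndarray:
    """Vectorised single-causal posteriors for block-sorted variants.

    Equivalent to running ``single_causal_posteriors`` per block; used in
    the simulation loop where the exact binomial prior weights and the
    log-sum-exp reduction are applied with ``np.reduceat``.
    """
    labf = wakefield_labf(z, V, W)
    log1m = np.log1p(-pi)
    t = np.log(pi) + (block_sizes.repeat(block_sizes) - 1) * log1m + labf
    log_w0 = block_sizes * log1m
    m = np.maximum.reduceat(t, block_starts)
    m = np.maximum(m, log_w0)
    sums = np.add.reduceat(np.exp(t - m.repeat(block_sizes)), block_starts)
    denom = np.log(np.exp(log_w0 - m) + sums) + m
    return np.exp(t - denom.repeat(block_sizes))


def calibration_run(
    genome,
    scenarios: Sequence[str] = ("null", "power1", "power2"),
    gaps: Sequence[int] = (1, 5, 10),
    densities: Sequence[str] = ("full",),
    n_sims: int = 500,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    base_config: Optional[ScenarioConfig] = None,
    run_fisher: bool = False,
) -> pd.DataFrame:
    """Empirical type-1 error / power of blockshifter over a scenario grid.

    ``genome`` is a ``SyntheticGenome``.  For each simulated GWAS the
    standard-normal noise is shared across scenarios (common random
    numbers), so power comparisons between scenarios are paired.  Returns a
    tidy table with one row per (scenario, density, gap): rejection rate at
    ``alpha`` (one-sided empirical p), mean blockshifter Z and Monte Carlo
    standard error; optionally the naive Fisher comparator's rejection
    rate.
    """
    cfg = base_config or ScenarioConfig()
    panel = genome.panel.sort_values(["block_id", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    block_ids = panel["block_id"].to_numpy()
    uniq, block_starts = np.unique(block_ids, return_index=True)
    block_sizes = np.diff(np.append(block_starts, len(panel)))
    V = estimate_V(panel["maf"].to_numpy(), cfg.n_cases, cfg.n_controls)
    samplers = {int(b): genome.samplers[int(b)] for b in uniq}
    test, control = genome.pirs_test, genome.pirs_control

    # permutation topology is fixed across sims: superblocks over
    # variant-bearing PIR fragments of the reference panel
    with_data = frozenset(
        int(f) for f in panel["fragment_id"].unique() if int(f) >= 0
    )
    test_inf = PIRSet(test.state, test.fragment_ids & with_data)
    control_inf = PIRSet(control.state, control.fragment_ids & with_data)
    engines = {
        g: bs.PermutationEngine(
            bs.build_superblocks(genome.fmap, test_inf, control_inf, gap=g)
        )
        for g in gaps
    }
    # fragment slot index for fast per-sim signal aggregation
    frag_slot = {}
    for g, eng in engines.items():
        slots = np.concatenate([b.fragment_ids for b in eng.blocks]) if eng.blocks else []
        lookup = {int(f): i for i, f in enumerate(slots)}
        fidx = np.array(
            [lookup.get(int(f), -1) for f in panel["fragment_id"]], dtype=np.int64
        )
        frag_slot[g] = (fidx, len(slots))

    eligible = {
        s: eligible_alt_blocks(panel, test, control, scenario=s) for s in scenarios
    }
    if any(len(e) < cfg.n_blocks_alt for e in eligible.values()):
        raise ValueError("not enough blocks with populated placement strata")

    master = np.random.default_rng(seed)
    rej = {
        (s, d, g): 0 for s in scenarios for d in densities for g in gaps
    }
    zsum = {k: 0.0 for k in rej}
    zsq = {k: 0.0 for k in rej}
    fisher_rej = {(s, d): 0 for s in scenarios for d in densities}

    from .pmi import pmi_impute  # local import to avoid cycle at module load

    for _ in range(n_sims):
        sim_seed = int(master.integers(0, 2**31 - 1))
        rng_common = np.random.default_rng(sim_seed)
        eps = {int(b): rng_common.standard_normal(samplers[int(b)].n) for b in uniq}
        for s_i, scenario in enumerate(scenarios):
            rng = np.random.default_rng((sim_seed, s_i))
            alt = rng.choice(eligible[scenario], size=cfg.n_blocks_alt, replace=False)
            truth = place_causals(
                panel, alt, test, control, scenario, cfg.p_causal_in_pir, rng
            )
            causal_of = dict(zip(truth["block_id"], truth["variant_index"]))
            z = np.empty(len(panel))
            for b, start, size in zip(uniq, block_starts, block_sizes):
                smp = samplers[int(b)]
                z[start : start + size] = smp.draw(
                    causal_of.get(b), cfg.ncp_causal, rng, eps=eps[int(b)]
                )
            for d_i, density in enumerate(densities):
                full_path = cfg.retention.get(density, 1.0) >= 1.0
                if full_path:
                    ppi = _finemap_fast(z, V, block_starts, block_sizes, 0.04, 1e-4)
                    scored = panel[["variant_id", "fragment_id"]].copy()
                    scored["ppi"] = ppi
                else:
                    rng_d = np.random.default_rng((sim_seed, s_i, d_i))
                    obs = panel.copy()
                    obs["z"] = z
                    obs["p"] = pvalue_from_z(z)
                    thinned = thin_to_density(obs, density, rng_d, cfg.retention)
                    dense = pmi_impute(thinned, panel, genome.r2, r2_min=0.6)
                    dense = dense.merge(
                        panel[["variant_id", "block_id", "maf"]],
                        on="variant_id",
                        how="left",
                        suffixes=("", "_panel"),
                    )
                    dense = dense.sort_values(
                        ["block_id", "pos"], kind="mergesort"
                    ).reset_index(drop=True)
                    bid = dense["block_id"].to_numpy()
                    ub, st = np.unique(bid, return_index=True)
                    sz = np.diff(np.append(st, len(dense)))
                    from .finemap import zscore_from_p

                    zz = zscore_from_p(dense["p"].to_numpy())
                    VV = estimate_V(
                        dense["maf"].to_numpy(), cfg.n_cases, cfg.n_controls
                    )
                    ppi = _finemap_fast(zz, VV, st, sz, 0.04, 1e-4)
                    scored = dense[["variant_id", "fragment_id"]].copy()
                    scored["ppi"] = ppi
                for g in gaps:
                    eng = engines[g]
                    fidx, n_slots = frag_slot[g]
                    if full_path:
                        vals = scored["ppi"].to_numpy()
                        fi = fidx
                    else:
                        order = {v: i for i, v in enumerate(panel["variant_id"])}
                        rows = scored["variant_id"].map(order).to_numpy()
                        fi = fidx[rows]
                        vals = scored["ppi"].to_numpy()
                    ok = fi >= 0
                    frag_sum = np.bincount(fi[ok], weights=vals[ok], minlength=n_slots)
                    frag_cnt = np.bincount(fi[ok], minlength=n_slots).astype(float)
                    eng.set_signal(frag_sum, frag_cnt)
                    obs_stat = eng.observed()
                    rng_p = np.random.default_rng((sim_seed, s_i, d_i, g))
                    null = eng.null_statistics(n_perm, rng_p)
                    p_emp = (1.0 + np.sum(null >= obs_stat - 1e-15)) / (1.0 + n_perm)
                    sd = null.std(ddof=1)
                    zval = (obs_stat - null.mean()) / sd if sd > 0 else np.nan
                    key = (scenario, density, g)
                    if p_emp <= alpha:
                        rej[key] += 1
                    if np.isfinite(zval):
                        zsum[key] += zval
                        zsq[key] += zval * zval
                if run_fisher:
                    ft = scored.copy()
                    _, p_f = bs.fisher_naive_test(ft, test, control)
                    if p_f <= alpha:
                        fisher_rej[(scenario, density)] += 1

    rows = []
    for (s, d, g), k in rej.items():
        rate = k / n_sims
        mean_z = zsum[(s, d, g)] / n_sims
        rows.append(
            {
                "scenario": s,
                "density": d,
                "gap": g,
                "n_sims": n_sims,
                "n_perm": n_perm,
                "rejection_rate": rate,
                "mean_z": mean_z,
                "mc_se": float(np.sqrt(rate * (1 - rate) / n_sims)),
                "fisher_rejection_rate": (
                    fisher_rej[(s, d)] / n_sims if run_fisher else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
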