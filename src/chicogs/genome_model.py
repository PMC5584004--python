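"""Core genomic data model for capture Hi-C / GWAS integration.

Internal coordinates are 0-based half-open (BED convention) throughout.
GWAS variant positions are read as 1-based and converted on ingest, so a
variant at 1-based position ``p`` lies in fragment ``[start, end)`` iff
``p - 1`` is in ``[start, end)``.  Chromosome names are normalised to the
``chr``-prefixed form on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "FragmentMap",
    "InteractionSet",
    "PIRSet",
    "GeneAnnotation",
    "RecombMap",
    "PairwiseR2",
    "normalize_chrom",
    "read_fragment_map",
    "read_interactions",
    "read_gwas",
    "read_recomb_map",
    "read_genes",
    "call_pirs",
    "assign_variants_to_fragments",
    "ld_blocks_from_recomb",
    "assign_variants_to_blocks",
]

#: Canonical column order for GWAS variant tables.
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "p"]


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome label to the ``chr``-prefixed form."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: half-open interval ``[start, end)`` on a chromosome."""

    fragment_id: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.fragment_id}: degenerate interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class FragmentMap:
    """An ordered, non-overlapping genome-wide restriction fragment map.

    Fragments are indexed per chromosome by sorted start coordinate, giving
    O(log n) point lookup via binary search.  Fragment ids are unique
    genome-wide.
    """

    def __init__(self, fragments: Iterable[Fragment]):
        by_chrom: Dict[str, List[Fragment]] = {}
        self._by_id: Dict[int, Fragment] = {}
        for frag in fragments:
            if frag.fragment_id in self._by_id:
                raise ValueError(f"duplicate fragment id {frag.fragment_id}")
            self._by_id[frag.fragment_id] = frag
            by_chrom.setdefault(frag.chrom, []).append(frag)

        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._ids: Dict[str, np.ndarray] = {}
        self._index: Dict[int, Tuple[str, int]] = {}
        for chrom, frags in by_chrom.items():
            frags.sort(key=lambda f: f.start)
            for a, b in zip(frags, frags[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping fragments on {chrom}: "
                        f"{a.fragment_id} [{a.start},{a.end}) and "
                        f"{b.fragment_id} [{b.start},{b.end})"
                    )
            self._starts[chrom] = np.array([f.start for f in frags], dtype=np.int64)
            self._ends[chrom] = np.array([f.end for f in frags], dtype=np.int64)
            self._ids[chrom] = np.array([f.fragment_id for f in frags], dtype=np.int64)
            for i, f in enumerate(frags):
                self._index[f.fragment_id] = (chrom, i)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, fragment_id: int) -> bool:
        return fragment_id in self._by_id

    def __iter__(self) -> Iterator[Fragment]:
        for chrom in self.chroms:
            for fid in self._ids[chrom]:
                yield self._by_id[int(fid)]

    @property
    def chroms(self) -> List[str]:
        return sorted(self._starts)

    @property
    def fragment_ids(self) -> Set[int]:
        return set(self._by_id)

    def fragment(self, fragment_id: int) -> Fragment:
        return self._by_id[fragment_id]

    def chrom_fragment_ids(self, chrom: str) -> np.ndarray:
        """Fragment ids on a chromosome, in genomic order."""
        return self._ids[chrom]

    def locate(self, chrom: str, pos0: int) -> Optional[int]:
        """Fragment id containing 0-based position ``pos0``, or None."""
        if chrom not in self._starts:
            return None
        i = int(np.searchsorted(self._starts[chrom], pos0, side="right")) - 1
        if i < 0 or pos0 >= self._ends[chrom][i]:
            return None
        return int(self._ids[chrom][i])

    def locate_many(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Vectorised locate; returns -1 for unassigned positions."""
        out = np.full(len(pos0), -1, dtype=np.int64)
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        for c in np.unique(chrom):
            if c not in self._starts:
                continue
            m = chrom == c
            p = pos0[m]
            i = np.searchsorted(self._starts[c], p, side="right") - 1
            ok = (i >= 0) & (p < self._ends[c][np.clip(i, 0, None)])
            res = np.full(len(p), -1, dtype=np.int64)
            res[ok] = self._ids[c][i[ok]]
            out[m] = res
        return out

    def neighbors(self, fragment_id: int, k: int = 1) -> List[int]:
        """Ids of up to ``k`` flanking fragments either side, truncated at
        chromosome ends."""
        chrom, i = self._index[fragment_id]
        ids = self._ids[chrom]
        lo, hi = max(0, i - k), min(len(ids), i + k + 1)
        return [int(f) for f in ids[lo:hi] if f != fragment_id]

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_bed(cls, path) -> "FragmentMap":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "fragment_id"],
        )
        frags = [
            Fragment(int(r.fragment_id), normalize_chrom(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        ]
        return cls(frags)

    def to_bed(self, path) -> None:
        rows = [(f.chrom, f.start, f.end, f.fragment_id) for f in self]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.fragment_id, f.chrom, f.start, f.end) for f in self],
            columns=["fragment_id", "chrom", "start", "end"],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentMap):
            return NotImplemented
        return self._by_id == other._by_id


def read_fragment_map(path) -> FragmentMap:
    """Read a BED4 fragment map (chrom, start, end, fragment_id)."""
    return FragmentMap.read_bed(path)


@dataclass(frozen=True)
class PIRSet:
    """Promoter-interacting fragments called in one cell state."""

    state: str
    fragment_ids: frozenset
    score_threshold: float = 5.0

    def __contains__(self, fragment_id: int) -> bool:
        return fragment_id in self.fragment_ids

    def __len__(self) -> int:
        return len(self.fragment_ids)


class InteractionSet:
    """Bait/other-end interaction calls with per-state confidence scores.

    Backed by a DataFrame with columns ``bait_id``, ``oe_id`` and one score
    column per state.  Mirrors the wide "peak matrix" layout of CHiCAGO
    output tables; a long 4-column dialect (bait_id, oe_id, state, score) is
    accepted on read.
    """

    def __init__(self, df: pd.DataFrame, states: Sequence[str]):
        states = list(states)
        missing = [s for s in states if s not in df.columns]
        if missing:
            raise ValueError(f"score columns missing for states: {missing}")
        if (df["bait_id"] == df["oe_id"]).any():
            bad = df.loc[df["bait_id"] == df["oe_id"], "bait_id"].iloc[0]
            raise ValueError(f"self-interaction on fragment {bad}")
        self.df = df.reset_index(drop=True)
        self.states = states

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        if self.states != other.states:
            return False
        a = self.df.sort_values(["bait_id", "oe_id"]).reset_index(drop=True)
        b = other.df.sort_values(["bait_id", "oe_id"]).reset_index(drop=True)
        return a[["bait_id", "oe_id"] + self.states].equals(
            b[["bait_id", "oe_id"] + self.states]
        )

    def scores_for(self, state: str) -> pd.Series:
        if state not in self.states:
            raise KeyError(
                f"unknown state {state!r}; available states: {self.states}"
            )
        return self.df[state]

    def pir_fragments(
        self, state: str, threshold: float = 5.0, bait_ids: Optional[Set[int]] = None
    ) -> Set[int]:
        """Other-end fragments with score strictly above ``threshold`` in
        ``state``, optionally restricted to a set of baits."""
        scores = self.scores_for(state)
        mask = scores > threshold
        if bait_ids is not None:
            mask &= self.df["bait_id"].isin(bait_ids)
        return set(self.df.loc[mask, "oe_id"].astype(int))

    @classmethod
    def read_tsv(cls, path, states: Optional[Sequence[str]] = None) -> "InteractionSet":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        df = df.rename(columns={"baitID": "bait_id", "oeID": "oe_id"})
        if {"state", "score"} <= set(df.columns):
            # long dialect -> pivot wide
            wide = df.pivot_table(
                index=["bait_id", "oe_id"], columns="state", values="score", fill_value=0.0
            ).reset_index()
            wide.columns.name = None
            found = [c for c in wide.columns if c not in ("bait_id", "oe_id")]
            return cls(wide, states or found)
        found = [c for c in df.columns if c not in ("bait_id", "oe_id")]
        return cls(df, states or found)

    def to_tsv(self, path) -> None:
        out = self.df[["bait_id", "oe_id"] + self.states]
        # %.17g guarantees binary round-trip of the scores through text
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_interactions(path, states: Optional[Sequence[str]] = None) -> InteractionSet:
    return InteractionSet.read_tsv(path, states=states)


def call_pirs(
    interactions: InteractionSet, state: str, threshold: float = 5.0
) -> PIRSet:
    """Call the promoter-interacting fragment set for one state.

    A fragment is a PIR when any interaction involving it as other end has a
    confidence score strictly greater than ``threshold`` (default 5).
    """
    frags = interactions.pir_fragments(state, threshold)
    return PIRSet(state=state, fragment_ids=frozenset(frags), score_threshold=threshold)


@dataclass
class GeneAnnotation:
    """A gene with its baited promoter fragments and coding intervals."""

    gene_id: str
    bait_ids: Set[int]
    coding_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"


def read_genes(path) -> List[GeneAnnotation]:
    """Read gene annotation TSV: gene_id, bait_ids (semicolon separated),
    coding_intervals (comma-separated chrom:start-end, optional), biotype."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        baits = {int(x) for x in str(r.bait_ids).split(";") if x not in ("", "nan")}
        intervals: List[Tuple[str, int, int]] = []
        raw = getattr(r, "coding_intervals", "")
        if isinstance(raw, str) and raw.strip():
            for item in raw.split(","):
                chrom, span = item.split(":")
                start, end = span.split("-")
                intervals.append((normalize_chrom(chrom), int(start), int(end)))
        genes.append(
            GeneAnnotation(
                gene_id=str(r.gene_id),
                bait_ids=baits,
                coding_intervals=intervals,
                biotype=str(getattr(r, "biotype", "protein_coding")),
            )
        )
    return genes


def write_genes(genes: Sequence[GeneAnnotation], path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "bait_ids": ";".join(str(b) for b in sorted(g.bait_ids)),
                "coding_intervals": ",".join(
                    f"{c}:{s}-{e}" for c, s, e in g.coding_intervals
                ),
                "biotype": g.biotype,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS variant tables
# ---------------------------------------------------------------------------

def read_gwas(path) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV.

    Required columns: chrom, pos (1-based), a1, a2, p.  Optional: variant_id,
    beta, se, n_cases, n_controls, maf.  Returns a DataFrame with normalised
    chromosome names and a ``source`` column (``observed``).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    if "variant_id" not in df.columns:
        df["variant_id"] = df["chrom"] + ":" + df["pos"].astype(str)
    if "source" not in df.columns:
        df["source"] = "observed"
    bad = df["p"] <= 0
    if bad.any():
        raise ValueError(f"{int(bad.sum())} variants with p <= 0")
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def assign_variants_to_fragments(
    variants: pd.DataFrame, fmap: FragmentMap
) -> pd.DataFrame:
    """Assign each variant (1-based ``pos``) to its containing fragment.

    A variant at 1-based position p belongs to fragment [start, end) iff
    p - 1 is in [start, end).  Unassigned variants get fragment_id -1.
    """
    out = variants.copy()
    out["fragment_id"] = fmap.locate_many(
        out["chrom"].to_numpy(), out["pos"].to_numpy() - 1
    )
    return out


# ---------------------------------------------------------------------------
# Recombination maps and LD blocks
# ---------------------------------------------------------------------------

class RecombMap:
    """Per-chromosome genetic map: sorted (bp position, cumulative cM).

    Cumulative cM is linearly interpolated between map points and held flat
    outside the mapped range.
    """

    def __init__(self, per_chrom: Mapping[str, Tuple[np.ndarray, np.ndarray]]):
        if not per_chrom:
            raise ValueError("empty recombination map")
        self._map: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in per_chrom.items():
            pos = np.asarray(pos, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if len(pos) == 0:
                raise ValueError(f"empty map for {chrom}")
            order = np.argsort(pos)
            pos, cm = pos[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM not non-decreasing on {chrom}")
            self._map[normalize_chrom(chrom)] = (pos, cm)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._map)

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at bp position(s), flat extrapolation outside map."""
        p, c = self._map[normalize_chrom(chrom)]
        return np.interp(np.asarray(pos, dtype=np.float64), p, c)

    def pos_at(self, chrom: str, cm) -> np.ndarray:
        """Inverse interpolation: bp position at cumulative cM value(s)."""
        p, c = self._map[normalize_chrom(chrom)]
        return np.interp(np.asarray(cm, dtype=np.float64), c, p)

    @classmethod
    def read_hapmap(cls, path) -> "RecombMap":
        """Read a HapMap-dialect map: columns chrom, pos,
        rate_cM_per_Mb, cumulative_cM (header required)."""
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.lower(): c for c in df.columns}
        chrom_col = cols.get("chrom") or cols.get("chr")
        pos_col = cols.get("pos") or cols.get("position")
        cm_col = None
        for key in cols:
            if "cm" in key and "mb" not in key and "rate" not in key:
                cm_col = cols[key]
        if pos_col is None or cm_col is None:
            raise ValueError("recombination map needs position and cumulative-cM columns")
        per_chrom = {}
        if chrom_col is None:
            raise ValueError("recombination map needs a chrom column")
        for chrom, sub in df.groupby(chrom_col):
            per_chrom[normalize_chrom(chrom)] = (
                sub[pos_col].to_numpy(),
                sub[cm_col].to_numpy(),
            )
        return cls(per_chrom)

    def to_tsv(self, path) -> None:
        rows = []
        for chrom in self.chroms:
            pos, cm = self._map[chrom]
            rate = np.empty_like(cm)
            dp = np.diff(pos)
            with np.errstate(divide="ignore", invalid="ignore"):
                rate[:-1] = np.where(dp > 0, np.diff(cm) / dp * 1e6, 0.0)
            rate[-1] = 0.0
            for p, r, c in zip(pos, rate, cm):
                rows.append((chrom, int(p), r, c))
        pd.DataFrame(
            rows, columns=["chrom", "pos", "rate_cM_per_Mb", "cumulative_cM"]
        ).to_csv(path, sep="\t", index=False)


def read_recomb_map(path) -> RecombMap:
    return RecombMap.read_hapmap(path)


def ld_blocks_from_recomb(
    rmap: RecombMap, variants: pd.DataFrame, block_cM: float
) -> pd.DataFrame:
    """Partition each chromosome into blocks of ``block_cM`` centimorgans.

    Block boundaries are the bp positions at which the cumulative genetic
    distance crosses successive multiples of ``block_cM`` (linear inverse
    interpolation of the map).  Returns a DataFrame (chrom, start, end,
    block_id) of half-open bp intervals jointly covering every variant; the
    last block per chromosome may be genetically shorter.
    """
    if block_cM <= 0:
        raise ValueError("block_cM must be positive")
    rows = []
    bid = 0
    for chrom in rmap.chroms:
        pos, cm = rmap._map[chrom]
        vpos = variants.loc[variants["chrom"] == chrom, "pos"].to_numpy()
        lo = min(float(pos[0]), float(vpos.min()) if len(vpos) else np.inf)
        hi = max(float(pos[-1]), float(vpos.max()) if len(vpos) else -np.inf)
        cm_lo, cm_hi = float(cm[0]), float(cm[-1])
        n_full = int(np.floor((cm_hi - cm_lo) / block_cM))
        targets = cm_lo + block_cM * np.arange(1, n_full + 1)
        # drop a final boundary that coincides with the end of the map
        targets = targets[targets < cm_hi - 1e-12]
        cuts = rmap.pos_at(chrom, targets)
        edges = np.concatenate(([lo], cuts, [hi + 1.0]))
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append((chrom, int(np.floor(a)), int(np.ceil(b)), bid))
            bid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])


def assign_variants_to_blocks(
    variants: pd.DataFrame, blocks: pd.DataFrame
) -> pd.DataFrame:
    """Attach a ``block_id`` column; every variant falls in exactly one block."""
    out = variants.copy()
    out["block_id"] = -1
    for chrom, sub in blocks.groupby("chrom"):
        m = out["chrom"] == chrom
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ids = sub["block_id"].to_numpy()
        # variant pos is 1-based; block intervals are 0-based half-open
        p0 = out.loc[m, "pos"].to_numpy() - 1
        i = np.searchsorted(starts, p0, side="right") - 1
        i = np.clip(i, 0, len(ids) - 1)
        out.loc[m, "block_id"] = ids[i]
    if (out["block_id"] < 0).any():
        raise ValueError("some variants fall on chromosomes absent from the block map")
    return out


# ---------------------------------------------------------------------------
# Pairwise r-squared lookup
# ---------------------------------------------------------------------------

class PairwiseR2:
    """Pairwise r² between variants, organised by LD block.

    Variants in different blocks are treated as unlinked (r² = 0).  Built
    either from per-block correlation matrices or from a long-format table of
    (id1, id2, r2) pairs.
    """

    def __init__(self):
        self._block_of: Dict[str, Tuple[int, int]] = {}  # id -> (block, index)
        self._mats: Dict[int, np.ndarray] = {}
        self._ids: Dict[int, List[str]] = {}

    @classmethod
    def from_blocks(
        cls, blocks: Mapping[int, Tuple[Sequence[str], np.ndarray]]
    ) -> "PairwiseR2":
        """``blocks`` maps block_id -> (variant ids, correlation matrix r)."""
        self = cls()
        for block_id, (ids, r) in blocks.items():
            r = np.asarray(r, dtype=np.float64)
            if r.shape != (len(ids), len(ids)):
                raise ValueError(f"block {block_id}: matrix/id shape mismatch")
            self._mats[block_id] = r * r
            self._ids[block_id] = list(ids)
            for i, vid in enumerate(ids):
                self._block_of[str(vid)] = (block_id, i)
        return self

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "PairwiseR2":
        """Build from long-format (id1, id2, r2); one synthetic block per
        connected vocabulary is not inferred — all listed pairs are kept in a
        single dense symmetric structure."""
        ids = sorted(set(pairs["id1"]).union(pairs["id2"]))
        index = {v: i for i, v in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(mat, 1.0)
        for r in pairs.itertuples():
            i, j = index[r.id1], index[r.id2]
            mat[i, j] = mat[j, i] = float(r.r2)
        self = cls()
        self._mats[0] = mat
        self._ids[0] = ids
        for v, i in index.items():
            self._block_of[str(v)] = (0, i)
        return self

    def r2(self, u: str, v: str) -> float:
        if u == v:
            return 1.0
        a = self._block_of.get(str(u))
        b = self._block_of.get(str(v))
        if a is None or b is None or a[0] != b[0]:
            return 0.0
        return float(self._mats[a[0]][a[1], b[1]])

    def proxies(self, v: str, r2_min: float = 0.0) -> Dict[str, float]:
        """All same-block variants with r² strictly above ``r2_min``."""
        loc = self._block_of.get(str(v))
        if loc is None:
            return {}
        block_id, i = loc
        row = self._mats[block_id][i]
        ids = self._ids[block_id]
        return {
            ids[j]: float(row[j])
            for j in np.nonzero(row > r2_min)[0]
            if ids[j] != str(v)
        }
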