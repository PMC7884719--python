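"""Consensus portrait construction from many harmonized DGE tables.

A *portrait* is a consensus ranking of all genes from most to least
dysregulated across a collection of studies, with a sign giving the
consensus direction of change.  The construction is rank-based and
deterministic:

1. Within each study, genes are ranked twice — once from most
   significantly upregulated (rank 1) down, and once from most
   significantly downregulated (rank 1) down.
2. Genes missing from more than a third of the studies are dropped;
   remaining missing cells are imputed with the neutral midpoint rank of
   the retained universe, so they cannot land in any top tier of a
   normally sized study.
3. For a ladder of cumulative rank tiers (by default the top 1000, 2000,
   ..., 8000), each gene's per-tier count is the number of studies in
   which it falls at or inside the cutoff, separately for the up and the
   down ranking.
4. The signed consensus score is the tier-wise difference (up count minus
   down count) combined with geometrically decaying weights
   ``w_k = 0.1**(k-1)``, so each deeper tier matters tenfold less; the
   final list is sorted by absolute score.

A gene in the top 1000 upregulated in 13 studies and never in the top
1000 downregulated starts at +13.0; deeper tiers then add refinements
after the decimal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .dge_io import DGETable

__all__ = [
    "DEFAULT_TIERS",
    "default_weights",
    "RankMatrix",
    "TierCounts",
    "Portrait",
    "rank_directional",
    "assemble_rank_matrix",
    "tier_counts",
    "portrait_score",
    "build_portrait",
]

DEFAULT_TIERS: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000)


def default_weights(n_tiers: int, decay: float = 0.1) -> np.ndarray:
    """Geometric tier weights ``decay**(k-1)``, k = 1..n_tiers.

    Built by repeated multiplication (each deeper tier weighs ``decay``
    times the one above it), the way the scheme is defined.
    """
    w = np.empty(n_tiers)
    acc = 1.0
    for k in range(n_tiers):
        w[k] = acc
        acc *= decay
    return w


def rank_directional(table: DGETable, direction: str) -> pd.Series:
    """Rank a study's genes by signed score in one direction.

    ``direction="up"``: rank 1 is the most significantly upregulated gene
    (largest signed score); ``"down"``: rank 1 is the most significantly
    downregulated (most negative).  Genes with score exactly 0 rank after
    every nonzero-score gene in *both* directions, so a directionless gene
    never competes for a top tier.  Ties are broken by source order, then
    symbol — ranks are a deterministic permutation of 1..G.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(table) == 0:
        raise ValueError("cannot rank an empty table")
    df = table.data
    score = df["signed_score"].to_numpy(dtype=float)
    symbols = df["symbol"].to_numpy()
    key = -score if direction == "up" else score
    is_zero = score == 0.0
    order = np.lexsort((symbols, np.arange(len(df)), key, is_zero))
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(1, len(df) + 1)
    return pd.Series(ranks, index=symbols, name=f"{table.study_id}:{direction}")


@dataclass
class RankMatrix:
    """Per-study directional ranks over a shared, filtered gene universe.

    ``up_ranks`` / ``down_ranks`` are (G x n) integer arrays; rank 1 is the
    most significantly up- (down-) regulated gene of that study within the
    retained universe.  Cells that were missing in the source are marked in
    ``missing_mask`` and carry the imputed midpoint rank.
    """

    genes: list[str]
    up_ranks: np.ndarray
    down_ranks: np.ndarray
    missing_mask: np.ndarray
    dataset_ids: list[str]
    midpoint: int

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)


def assemble_rank_matrix(tables: Sequence[DGETable]) -> RankMatrix:
    """Combine studies by gene symbol into a filtered, imputed rank matrix.

    A gene is retained only if it is missing from at most a third of the
    studies (strictly more than 1/3 missing drops it).  Each study is then
    ranked over its own genes restricted to the retained universe, and
    missing cells are imputed with the midpoint rank
    ``ceil((G_final + 1) / 2)`` of the retained universe — a neutral value
    that keeps imputed genes out of the top tiers of both directions in
    the intended regime.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to assemble a rank matrix")
    ids = [t.study_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study_ids in input tables")
    n = len(tables)
    presence: dict[str, int] = {}
    for t in tables:
        syms = t.data["symbol"]
        if syms.duplicated().any():
            raise ValueError(
                f"table {t.study_id!r} has duplicate symbols; "
                "run collapse_duplicates first"
            )
        for s in syms:
            presence[s] = presence.get(s, 0) + 1
    max_missing = n / 3.0  # "more than a third missing" drops the gene
    genes = sorted(s for s, c in presence.items() if (n - c) <= max_missing)
    if not genes:
        raise ValueError("no genes survive the missingness filter")
    g_final = len(genes)
    midpoint = ceil((g_final + 1) / 2)
    gene_idx = {s: i for i, s in enumerate(genes)}
    universe = set(genes)

    up = np.full((g_final, n), midpoint, dtype=np.int64)
    down = np.full((g_final, n), midpoint, dtype=np.int64)
    missing = np.ones((g_final, n), dtype=bool)
    for j, t in enumerate(tables):
        keep = t.data["symbol"].isin(universe).to_numpy()
        restricted = DGETable(
            study_id=t.study_id,
            data=t.data.loc[keep],
            metadata=t.metadata,
        )
        if len(restricted) == 0:
            continue
        rows = np.fromiter(
            (gene_idx[s] for s in restricted.data["symbol"]),
            dtype=np.int64,
            count=len(restricted),
        )
        up[rows, j] = rank_directional(restricted, "up").to_numpy()
        down[rows, j] = rank_directional(restricted, "down").to_numpy()
        missing[rows, j] = False
    return RankMatrix(
        genes=genes,
        up_ranks=up,
        down_ranks=down,
        missing_mask=missing,
        dataset_ids=ids,
        midpoint=midpoint,
    )


@dataclass
class TierCounts:
    """Cumulative per-tier membership counts for each gene.

    ``U[g, k]`` is the number of studies in which gene ``g`` ranks at or
    inside ``tiers[k]`` in the upregulated ordering; ``D`` is the same for
    the downregulated ordering.  Tiers are cumulative: the top-2000 count
    includes the top 1000.
    """

    genes: list[str]
    tiers: tuple[int, ...]
    U: np.ndarray
    D: np.ndarray
    n_datasets: int


def tier_counts(
    rm: RankMatrix, tiers: Sequence[int] = DEFAULT_TIERS
) -> TierCounts:
    """Count per-gene tier memberships across studies, both directions."""
    tiers = tuple(int(t) for t in tiers)
    if any(t <= 0 for t in tiers) or any(
        b <= a for a, b in zip(tiers, tiers[1:])
    ):
        raise ValueError("tiers must be strictly increasing and positive")
    if rm.n_genes < 2 * max(tiers):
        warnings.warn(
            f"retained universe ({rm.n_genes} genes) is smaller than twice "
            f"the deepest tier ({max(tiers)}); imputed midpoint ranks can "
            "fall inside a tier",
            stacklevel=2,
        )
    cuts = np.asarray(tiers)[None, None, :]
    U = (rm.up_ranks[:, :, None] <= cuts).sum(axis=1)
    D = (rm.down_ranks[:, :, None] <= cuts).sum(axis=1)
    return TierCounts(
        genes=rm.genes,
        tiers=tiers,
        U=U.astype(np.int64),
        D=D.astype(np.int64),
        n_datasets=rm.n_datasets,
    )


def portrait_score(
    tc: TierCounts, weights: Sequence[float] | None = None
) -> pd.Series:
    """Decay-weighted signed consensus score per gene.

    ``score(g) = sum_k w_k * (U[g,k] - D[g,k])`` with default weights
    ``0.1**(k-1)``: the tier-1 term is the whole-number part (e.g. a gene
    in the top tier upregulated in 13 studies and downregulated in none
    starts at 13.0) and deeper tiers refine the decimals.  A gene equally
    often in the top tier of both directions cancels to zero there.
    """
    if weights is None:
        w = default_weights(len(tc.tiers))
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(tc.tiers):
            raise ValueError(
                f"got {len(w)} weights for {len(tc.tiers)} tiers"
            )
    # accumulate tier by tier, shallowest first — the definitional
    # summation order, reproducible against a per-gene loop bit-for-bit
    net = tc.U - tc.D
    score = np.zeros(net.shape[0])
    for k in range(net.shape[1]):
        score += w[k] * net[:, k]
    return pd.Series(score, index=pd.Index(tc.genes, name="symbol"), name="score")


@dataclass
class Portrait:
    """A signed consensus portrait: genes ordered by |score| descending.

    ``entries`` has columns ``symbol``, ``score``, ``sign``, ``rank``.
    ``provenance`` records the datasets, tiers, weights and filter counts
    that produced it.
    """

    portrait_id: str
    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def signed_scores(self) -> pd.Series:
        """Signed scores indexed by symbol, in |score|-descending order."""
        return pd.Series(
            self.entries["score"].to_numpy(),
            index=self.entries["symbol"].to_numpy(),
            name=self.portrait_id,
        )

    def to_tsv(self, dest: str | Path | IO[str]) -> None:
        self.entries.to_csv(dest, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, source: str | Path | IO[str], portrait_id: str | None = None
    ) -> "Portrait":
        df = pd.read_csv(source, sep="\t")
        if not {"symbol", "score"} <= set(df.columns):
            # accept the two-column sign1 dialect as well
            if {"Gene.symbol", "sign1"} <= set(df.columns):
                df = df.rename(columns={"Gene.symbol": "symbol", "sign1": "score"})
            else:
                raise ValueError("portrait TSV needs 'symbol' and 'score' columns")
        df = df[["symbol", "score"]].copy()
        df["sign"] = np.sign(df["score"]).astype(int)
        df["rank"] = np.arange(1, len(df) + 1)
        if portrait_id is None:
            portrait_id = (
                Path(source).stem if isinstance(source, (str, Path)) else "portrait"
            )
        return cls(portrait_id=portrait_id, entries=df.reset_index(drop=True))


def build_portrait(
    tables: Sequence[DGETable],
    tiers: Sequence[int] = DEFAULT_TIERS,
    weights: Sequence[float] | None = None,
    portrait_id: str = "portrait",
) -> Portrait:
    """Build a signed consensus portrait from harmonized DGE tables.

    Deterministic for fixed inputs: rank, filter and impute
    (:func:`assemble_rank_matrix`), count cumulative tier memberships
    (:func:`tier_counts`), combine with decaying weights
    (:func:`portrait_score`), then sort by absolute score descending with
    lexicographic symbol tie-break.
    """
    rm = assemble_rank_matrix(tables)
    tc = tier_counts(rm, tiers)
    scores = portrait_score(tc, weights)
    df = pd.DataFrame(
        {"symbol": scores.index.to_numpy(), "score": scores.to_numpy()}
    )
    order = np.lexsort((df["symbol"].to_numpy(), -df["score"].abs().to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    df["sign"] = np.sign(df["score"]).astype(int)
    df["rank"] = np.arange(1, len(df) + 1)
    w = (
        default_weights(len(tc.tiers))
        if weights is None
        else np.asarray(list(weights), dtype=float)
    )
    provenance = {
        "dataset_ids": list(rm.dataset_ids),
        "tiers": list(tc.tiers),
        "weights": [float(x) for x in w],
        "n_genes_retained": rm.n_genes,
        "imputed_midpoint_rank": rm.midpoint,
        "n_imputed_cells": int(rm.missing_mask.sum()),
    }
    return Portrait(portrait_id=portrait_id, entries=df, provenance=provenance)
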