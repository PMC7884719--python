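"""Quadrant-signed hypergeometric overlap between two signed gene lists.

Two signed ranked gene lists (a study and a portrait, a treatment and a
portrait, or two portraits) are compared through their top-N upregulated
and top-N downregulated gene sets.  Each of the four set pairs forms a
quadrant, labelled as in the rank-rank hypergeometric overlap (RRHO)
literature:

* **A** — up in the first list, up in the second (concordant);
* **B** — up in the first, down in the second (discordant);
* **C** — down in the first, up in the second (discordant);
* **D** — down in both (concordant).

Each quadrant is scored by the upper-tail hypergeometric p-value of its
overlap count on the shared gene universe, reported as ``-log10 p``.  The
*match score* ``(A + D) - (B + C)`` measures concordance of two disorder
signatures; the *reversal score* ``(B + C) - (A + D)``, with the treatment
as the first list, measures a treatment's capacity to push a disorder's
expression back toward normal.  The two are linked by an exact identity:
reversing a treatment's signs turns its reversal score into a match score.

:func:`rrho_map` generalises the single 2x2 comparison to a grid of
prefix overlaps over sliding rank thresholds, the RRHO heat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge_io import NEGLOG10_CLAMP, DGETable
from .portrait import Portrait

__all__ = [
    "GeneSetPair",
    "QuadrantCell",
    "QuadrantScores",
    "top_sets",
    "quadrant_overlap",
    "match_score",
    "reversal_score",
    "sign_flip",
    "rrho_map",
    "hypergeom_upper_tail",
    "neglog10_upper_tail",
]

SignedList = "DGETable | Portrait | pd.Series"


def _as_signed_series(source) -> pd.Series:
    """Coerce a DGETable, Portrait or symbol->score Series to a Series."""
    if isinstance(source, (DGETable, Portrait)):
        return source.signed_scores
    if isinstance(source, pd.Series):
        return source
    raise TypeError(
        f"expected DGETable, Portrait or Series, got {type(source).__name__}"
    )


@dataclass(frozen=True)
class GeneSetPair:
    """Top-N upregulated and top-N downregulated gene sets of one list."""

    up: frozenset
    down: frozenset
    N: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")
        if len(self.up) > self.N or len(self.down) > self.N:
            raise ValueError("set sizes exceed the stated cutoff N")

    def flipped(self) -> "GeneSetPair":
        """The pair with up and down exchanged (the sign-flipped list)."""
        return GeneSetPair(
            up=self.down, down=self.up, N=self.N,
            source_id=f"{self.source_id}:flipped",
        )


def top_sets(source, N: int = 1000) -> GeneSetPair:
    """Extract the top-N upregulated and top-N downregulated gene sets.

    Only genes with a strictly positive score can enter ``up`` and only
    strictly negative ones ``down``; if fewer than N exist on a side the
    available genes are taken and a warning is emitted.  Ties at the
    cutoff resolve by list order then symbol, matching the global
    determinism rule.
    """
    scores = _as_signed_series(source)
    name = scores.name or ""
    vals = scores.to_numpy(dtype=float)
    syms = scores.index.to_numpy()
    pos = vals > 0
    neg = vals < 0
    order_up = np.lexsort((syms, np.arange(len(vals)), -vals))
    order_down = np.lexsort((syms, np.arange(len(vals)), vals))
    up_idx = [i for i in order_up if pos[i]][:N]
    down_idx = [i for i in order_down if neg[i]][:N]
    if len(up_idx) < N or len(down_idx) < N:
        warnings.warn(
            f"{name or 'list'}: only {len(up_idx)} upregulated / "
            f"{len(down_idx)} downregulated genes available for N={N}",
            stacklevel=2,
        )
    return GeneSetPair(
        up=frozenset(syms[up_idx]),
        down=frozenset(syms[down_idx]),
        N=N,
        source_id=str(name),
    )


def hypergeom_upper_tail(k: int, universe: int, n1: int, n2: int) -> float:
    """P(X >= k) for the overlap of a size-``n1`` and a size-``n2`` set
    drawn from ``universe`` genes (one-sided over-representation test).
    ``k = 0`` gives exactly 1."""
    if universe <= 0:
        raise ValueError("universe must be non-empty")
    return float(hypergeom.sf(k - 1, universe, n1, n2))


def neglog10_upper_tail(
    k: int, universe: int, n1: int, n2: int, clamp: float = NEGLOG10_CLAMP
) -> float:
    """``-log10`` of the upper-tail p, clamped to keep huge overlaps finite."""
    p = hypergeom_upper_tail(k, universe, n1, n2)
    if p <= 0.0:
        return clamp
    return float(min(-np.log10(p), clamp))


@dataclass(frozen=True)
class QuadrantCell:
    """Overlap count and -log10 upper-tail p for one quadrant."""

    k: int
    neg_log_p: float


@dataclass(frozen=True)
class QuadrantScores:
    """The four quadrant overlap statistics for a pair of signed lists."""

    A: QuadrantCell
    B: QuadrantCell
    C: QuadrantCell
    D: QuadrantCell
    universe_size: int
    first_id: str = ""
    second_id: str = ""

    def to_dict(self) -> dict:
        return {
            "first_id": self.first_id,
            "second_id": self.second_id,
            "universe_size": self.universe_size,
            **{
                q: {"k": cell.k, "neg_log_p": cell.neg_log_p}
                for q, cell in zip("ABCD", (self.A, self.B, self.C, self.D))
            },
        }


def quadrant_overlap(
    first: GeneSetPair,
    second: GeneSetPair,
    universe: Iterable[str],
    clamp: float = NEGLOG10_CLAMP,
) -> QuadrantScores:
    """Score the four signed-set overlaps on a shared gene universe.

    All sets are first intersected with the universe; each quadrant's
    p-value is the hypergeometric upper tail of its overlap count given
    the two intersected set sizes and the universe size.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    f_up, f_dn = first.up & uni, first.down & uni
    s_up, s_dn = second.up & uni, second.down & uni
    M = len(uni)

    def cell(a: frozenset, b: frozenset) -> QuadrantCell:
        k = len(a & b)
        return QuadrantCell(
            k=k, neg_log_p=neglog10_upper_tail(k, M, len(a), len(b), clamp)
        )

    return QuadrantScores(
        A=cell(f_up, s_up),
        B=cell(f_up, s_dn),
        C=cell(f_dn, s_up),
        D=cell(f_dn, s_dn),
        universe_size=M,
        first_id=first.source_id,
        second_id=second.source_id,
    )


def match_score(q: QuadrantScores) -> float:
    """Concordance of two signed lists: ``(A + D) - (B + C)`` on the
    -log10 p scale.  Positive when the lists agree in direction."""
    return (q.A.neg_log_p + q.D.neg_log_p) - (q.B.neg_log_p + q.C.neg_log_p)


def reversal_score(q: QuadrantScores) -> float:
    """Treatment-reversal potential: ``(B + C) - (A + D)`` with the
    treatment as the first list.  B and C collect genes the treatment
    pushes opposite to the disorder; A and D collect "worsening" genes
    the treatment pushes the same way.  Higher is better."""
    return (q.B.neg_log_p + q.C.neg_log_p) - (q.A.neg_log_p + q.D.neg_log_p)


def sign_flip(source) -> pd.Series:
    """Negate every signed score of a list (DGETable, Portrait or Series)."""
    s = _as_signed_series(source)
    out = -s
    out.name = f"{s.name}:flipped" if s.name else "flipped"
    return out


def rrho_map(
    first,
    second,
    step: int = 100,
    clamp: float = NEGLOG10_CLAMP,
) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap grid of two signed lists.

    Both lists are restricted to their shared gene universe and ordered
    from most upregulated to most downregulated; thresholds advance in
    ``step``-sized strides along each list.  Each cell lies in one of
    four quadrants depending on which side of its list's up/down boundary
    each threshold falls, and compares segments anchored at the relevant
    end of each list — the top of the list for an up-side threshold i
    (the i most upregulated genes), the bottom for a down-side threshold
    (the genes from position i to the end, i.e. the most downregulated).
    Each segment pair is scored by the hypergeometric upper-tail
    ``-log10 p`` of its overlap on the shared universe, positive in the
    concordant (up-up, down-down) quadrants and negative in the
    discordant ones.  A sign-flipped second list therefore mirrors the
    map with negated values.  Rows index the first list, columns the
    second.
    """
    s1 = _as_signed_series(first)
    s2 = _as_signed_series(second)
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise ValueError("lists share no genes")
    s1 = s1.loc[shared]
    s2 = s2.loc[shared]
    G = len(shared)
    if step < 1 or step > G:
        raise ValueError(f"step must be in [1, {G}]")

    def ordered(s: pd.Series) -> np.ndarray:
        syms = s.index.to_numpy()
        vals = s.to_numpy(dtype=float)
        return syms[np.lexsort((syms, np.arange(len(s)), -vals))]

    o1, o2 = ordered(s1), ordered(s2)
    n_pos1 = int((s1 > 0).sum())
    n_pos2 = int((s2 > 0).sum())
    cuts = list(range(step, G + 1, step))
    if cuts[-1] != G:
        cuts.append(G)

    def segment(order: np.ndarray, cut: int, n_pos: int) -> tuple[set, bool]:
        if cut <= n_pos:
            return set(order[:cut]), True  # up-anchored prefix
        return set(order[cut - 1 :]), False  # down-anchored suffix

    grid = np.zeros((len(cuts), len(cuts)))
    for i, ci in enumerate(cuts):
        seg1, up1 = segment(o1, ci, n_pos1)
        for j, cj in enumerate(cuts):
            seg2, up2 = segment(o2, cj, n_pos2)
            k = len(seg1 & seg2)
            v = neglog10_upper_tail(k, G, len(seg1), len(seg2), clamp)
            grid[i, j] = v if up1 == up2 else -v
    return pd.DataFrame(grid, index=cuts, columns=cuts)
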