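"""Ranking treatment signatures by reversal of consensus portraits.

Signature matching for drug repurposing: a treatment whose expression
changes oppose a disorder portrait's changes (upregulating what the
disorder downregulates and vice versa) is a reversal candidate.  Every
treatment DGE table is scored against every portrait with the quadrant
reversal score on fixed top-N sets, so scores are uniform across
treatments; the bottom of the ranking flags signatures that mimic
(worsen) the portrait.

Also exported here: the per-gene reversal report (exactly which portrait
genes a treatment moves, per quadrant) and the wide signed-score feature
matrix over the portraits' top genes used for 2-D embedding, with
portrait rows sign-reversed so a perfect reverser sits on top of its
portrait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dge_io import DGETable
from .overlap import (
    QuadrantScores,
    quadrant_overlap,
    reversal_score,
    top_sets,
)
from .portrait import Portrait

__all__ = [
    "LOW_OVERLAP_THRESHOLD",
    "ReversalReport",
    "screen_treatments",
    "reversed_genes",
    "build_embedding_matrix",
]

# Hypergeometric scores on tiny shared universes are unstable; pairs with
# fewer shared genes than this are still scored but flagged.
LOW_OVERLAP_THRESHOLD = 100


def _score_pair(
    treatment: DGETable, portrait: Portrait, N: int
) -> tuple[QuadrantScores, float, int]:
    universe = frozenset(treatment.symbols) & frozenset(
        portrait.entries["symbol"]
    )
    t_sets = top_sets(treatment, N)
    p_sets = top_sets(portrait, N)
    q = quadrant_overlap(t_sets, p_sets, universe)
    return q, reversal_score(q), len(universe)


def screen_treatments(
    treatments: Sequence[DGETable],
    portraits: Sequence[Portrait],
    N: int = 1000,
) -> pd.DataFrame:
    """Score and rank a treatment library against one or more portraits.

    Returns one row per treatment with, for every portrait, the reversal
    score, the dense rank (1 = strongest reverser), and a low-confidence
    flag when treatment and portrait share fewer than
    ``LOW_OVERLAP_THRESHOLD`` genes.  Scores are pairwise independent, so
    adding a treatment never reorders the others.
    """
    if not treatments or not portraits:
        raise ValueError("need at least one treatment and one portrait")
    rows = []
    for t in treatments:
        row: dict = {
            "treatment_id": t.study_id,
            "category": t.metadata.get("category", ""),
        }
        for p in portraits:
            q, score, n_shared = _score_pair(t, p, N)
            row[f"reversal_score__{p.portrait_id}"] = score
            row[f"low_confidence__{p.portrait_id}"] = (
                n_shared < LOW_OVERLAP_THRESHOLD
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    for p in portraits:
        col = f"reversal_score__{p.portrait_id}"
        order = np.lexsort(
            (out["treatment_id"].to_numpy(), -out[col].to_numpy())
        )
        ranks = np.empty(len(out), dtype=np.int64)
        ranks[order] = np.arange(1, len(out) + 1)
        out[f"rank__{p.portrait_id}"] = ranks
    lead = next(
        c for c in out.columns if c.startswith("reversal_score__")
    )
    return out.sort_values(
        lead, ascending=False, kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class ReversalReport:
    """Per-gene quadrant membership for one treatment-portrait pair.

    ``genes_B`` (up in treatment, down in portrait) and ``genes_C`` (down
    in treatment, up in portrait) are the reversed genes; ``genes_A`` and
    ``genes_D`` are concordant ("worsening") genes.  Counts reconcile
    exactly with the k values of ``quadrants``.
    """

    treatment_id: str
    portrait_id: str
    genes_A: list[str]
    genes_B: list[str]
    genes_C: list[str]
    genes_D: list[str]
    quadrants: QuadrantScores | None = None

    def to_dict(self) -> dict:
        d = {
            "treatment_id": self.treatment_id,
            "portrait_id": self.portrait_id,
            "genes_A": self.genes_A,
            "genes_B": self.genes_B,
            "genes_C": self.genes_C,
            "genes_D": self.genes_D,
        }
        if self.quadrants is not None:
            d["quadrants"] = self.quadrants.to_dict()
        return d


def reversed_genes(
    treatment: DGETable, portrait: Portrait, N: int = 1000
) -> ReversalReport:
    """List the specific portrait genes a treatment moves, per quadrant."""
    universe = frozenset(treatment.symbols) & frozenset(
        portrait.entries["symbol"]
    )
    t_sets = top_sets(treatment, N)
    p_sets = top_sets(portrait, N)
    q = quadrant_overlap(t_sets, p_sets, universe) if universe else None
    t_up, t_dn = t_sets.up & universe, t_sets.down & universe
    p_up, p_dn = p_sets.up & universe, p_sets.down & universe
    return ReversalReport(
        treatment_id=treatment.study_id,
        portrait_id=portrait.portrait_id,
        genes_A=sorted(t_up & p_up),
        genes_B=sorted(t_up & p_dn),
        genes_C=sorted(t_dn & p_up),
        genes_D=sorted(t_dn & p_dn),
        quadrants=q,
    )


def build_embedding_matrix(
    portraits: Sequence[Portrait],
    treatments: Sequence[DGETable],
    N: int = 1000,
) -> pd.DataFrame:
    """Signed-score feature matrix over the portraits' top genes.

    Features are the union of the top-N up and top-N down genes of every
    portrait (with three portraits of 1000+1000 genes each and realistic
    overlap this lands in the few-thousand range).  Rows are the
    treatments (raw signed scores) followed by the portraits with their
    signs negated, so a treatment that perfectly reverses a portrait has
    an identical feature profile to that portrait's row.  Genes a row
    never measured are 0.  The matrix is exported for an external 2-D
    embedding (e.g. UMAP); no transformation is applied here.
    """
    if not portraits:
        raise ValueError("need at least one portrait")
    features: set[str] = set()
    for p in portraits:
        sets = top_sets(p, N)
        features |= sets.up | sets.down
    if not features:
        raise ValueError("portraits contribute no feature genes")
    cols = sorted(features)
    rows = []
    index = []
    for t in treatments:
        s = t.signed_scores
        rows.append(s.reindex(cols).fillna(0.0).to_numpy())
        index.append(t.study_id)
    for p in portraits:
        s = -p.signed_scores
        rows.append(s.reindex(cols).fillna(0.0).to_numpy())
        index.append(p.portrait_id)
    return pd.DataFrame(rows, index=index, columns=cols)
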