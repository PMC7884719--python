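"""Self-consistency checks: match matrices and the randomized-control portrait.

Two procedures probe whether a portrait captures a real, shared biological
signal rather than an artifact of the scoring scheme:

* the **match matrix** scores every input study against every portrait
  with the quadrant match score — studies should match the portrait built
  from them, and group-specific portraits should match their own group's
  studies best;
* the **randomized control** rebuilds the portrait after permuting the
  gene-score association *within* each input study (preserving every
  study's score distribution but destroying cross-study gene agreement),
  repeats this several times, and compares real versus random matching
  scores with a one-way ANOVA.  A real biological signature shows up as a
  significantly higher mean match for the real portrait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dge_io import DGETable
from .overlap import match_score, quadrant_overlap, top_sets
from .portrait import DEFAULT_TIERS, Portrait, build_portrait

__all__ = [
    "RandomizationResult",
    "match_matrix",
    "shuffle_dataset",
    "one_way_anova",
    "randomization_control",
]


def _match_one(dataset: DGETable, portrait: Portrait, N: int) -> dict:
    universe = frozenset(dataset.symbols) & frozenset(
        portrait.entries["symbol"]
    )
    q = quadrant_overlap(top_sets(dataset, N), top_sets(portrait, N), universe)
    return {
        "score": match_score(q),
        "A": q.A.neg_log_p,
        "B": q.B.neg_log_p,
        "C": q.C.neg_log_p,
        "D": q.D.neg_log_p,
    }


def match_matrix(
    datasets: Sequence[DGETable],
    portraits: Sequence[Portrait],
    N: int = 1000,
) -> pd.DataFrame:
    """Match score of every dataset (rows) against every portrait (columns)."""
    if not datasets or not portraits:
        raise ValueError("need at least one dataset and one portrait")
    out = pd.DataFrame(
        {
            p.portrait_id: [
                _match_one(d, p, N)["score"] for d in datasets
            ]
            for p in portraits
        },
        index=pd.Index([d.study_id for d in datasets], name="dataset"),
    )
    return out


def shuffle_dataset(table: DGETable, rng: np.random.Generator | int) -> DGETable:
    """Randomize the gene-score association within one study.

    The score triples (p, direction, signed score) are permuted uniformly
    against the symbol column, then rows are re-sorted into significance
    order so the shuffled table is a well-formed DGE table.  Symbol set
    and score multiset are both preserved; deterministic for a fixed
    seed/generator state.
    """
    rng = np.random.default_rng(rng)
    out = table.copy()
    perm = rng.permutation(len(out))
    for col in ("p", "direction", "signed_score"):
        out.data[col] = out.data[col].to_numpy()[perm]
    order = np.lexsort(
        (np.arange(len(out)), -out.data["signed_score"].abs().to_numpy())
    )
    out.data = out.data.iloc[order].reset_index(drop=True)
    out.study_id = f"{table.study_id}:shuffled"
    return out


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value from the closed formula.

    With two groups this reduces to the squared two-sample t statistic.
    Implemented directly from the between/within mean-square ratio and
    checked against the standard F distribution.
    """
    from scipy.stats import f as f_dist

    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 1 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n_total = len(all_vals)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if df2 <= 0 or ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0, float("nan")
    F = (ss_between / df1) / (ss_within / df2)
    p = float(f_dist.sf(F, df1, df2))
    return float(F), p


@dataclass
class RandomizationResult:
    """Real-vs-random portrait matching scores and their ANOVA."""

    real_scores: pd.Series
    random_scores: pd.DataFrame  # rows = datasets, columns = replicates
    n_reps: int
    summary: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "real_scores": self.real_scores.to_dict(),
            "random_scores": {
                c: self.random_scores[c].to_dict()
                for c in self.random_scores.columns
            },
            "n_reps": self.n_reps,
            "summary": self.summary,
            "anova": self.anova,
        }


def randomization_control(
    datasets: Sequence[DGETable],
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
    N: int = 1000,
    tiers: Sequence[int] = DEFAULT_TIERS,
    anova_mode: str = "replicate_mean",
) -> RandomizationResult:
    """Compare real-portrait matching against shuffled-control portraits.

    The real portrait is built once from ``datasets`` and each dataset is
    scored against it.  For each of ``n_reps`` replicates, every dataset
    is freshly shuffled (:func:`shuffle_dataset`), a control portrait is
    built from the shuffled set, and each shuffled dataset is scored
    against that control.  Alongside overall scores, the concordant
    up-quadrant (A) and down-quadrant (D) components are averaged
    separately, since a disorder may show stronger consistency in one
    direction.

    ``anova_mode`` selects the units of the one-way ANOVA (two groups,
    real vs random): ``"replicate_mean"`` compares per-dataset real scores
    with per-dataset random scores averaged over replicates;
    ``"pooled"`` pools all per-replicate random scores.

    Replicate random states are split from the master seed, so results
    are reproducible end to end.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if anova_mode not in ("replicate_mean", "pooled"):
        raise ValueError("anova_mode must be 'replicate_mean' or 'pooled'")
    ids = [d.study_id for d in datasets]
    real_portrait = build_portrait(datasets, tiers=tiers, portrait_id="real")
    real_detail = [_match_one(d, real_portrait, N) for d in datasets]
    real_scores = pd.Series(
        [r["score"] for r in real_detail], index=ids, name="real"
    )

    master = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    child_seeds = master.spawn(n_reps)
    rand_cols = {}
    rand_A = np.zeros((len(ids), n_reps))
    rand_D = np.zeros((len(ids), n_reps))
    for r, child in enumerate(child_seeds):
        shuffled = [shuffle_dataset(d, child) for d in datasets]
        control = build_portrait(
            shuffled, tiers=tiers, portrait_id=f"random_{r}"
        )
        detail = [_match_one(s, control, N) for s in shuffled]
        rand_cols[f"rep_{r}"] = [x["score"] for x in detail]
        rand_A[:, r] = [x["A"] for x in detail]
        rand_D[:, r] = [x["D"] for x in detail]
    random_scores = pd.DataFrame(rand_cols, index=ids)

    if anova_mode == "replicate_mean":
        random_arm = random_scores.mean(axis=1).to_numpy()
    else:
        random_arm = random_scores.to_numpy().ravel()
    F, p = one_way_anova(real_scores.to_numpy(), random_arm)

    summary = {
        "real_mean": float(real_scores.mean()),
        "random_mean": float(random_scores.to_numpy().mean()),
        "real_up_component_mean": float(
            np.mean([r["A"] for r in real_detail])
        ),
        "real_down_component_mean": float(
            np.mean([r["D"] for r in real_detail])
        ),
        "random_up_component_mean": float(rand_A.mean()),
        "random_down_component_mean": float(rand_D.mean()),
    }
    return RandomizationResult(
        real_scores=real_scores,
        random_scores=random_scores,
        n_reps=n_reps,
        summary=summary,
        anova={"F": F, "p": p, "mode": anova_mode},
    )
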