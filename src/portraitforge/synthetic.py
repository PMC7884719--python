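"""Synthetic study sets with planted dysregulation signal and ground truth.

The generator emulates the statistical structure the portrait method
assumes about a collection of case-control DGE studies of one disorder:

* a **consistent** fraction of genes carries a true dysregulation with a
  fixed direction shared by every study (with a configurable bias toward
  downregulation, the dominance the disorder shows);
* an **inconsistent** fraction is perturbed in every study but with a
  direction re-drawn per study (real but direction-unstable effects);
* the remaining **null** genes have uniform p-values and random signs.

Signal-gene p-values follow a Beta(a, 1) law — the standard
one-parameter enrichment family for p-value simulation, uniform at
``a = 1`` and concentrated near 0 as ``a`` shrinks.  Cells go missing
completely at random to exercise the missingness filter and midpoint
imputation.  Planted treatment signatures reverse (or mimic) a chosen
fraction of the consistent signal, providing ground truth for the
screening recovery claims.  A truth table accompanies every simulated
set; tests recover it rather than inferring it from outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dge_io import DGETable, signed_score

__all__ = ["SyntheticConfig", "simulate_study_set", "simulate_treatment"]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-signal study-set generator.

    Defaults mirror a mid-sized meta-analysis: 12 studies of 2000 genes,
    5% of genes consistently dysregulated with 70% of those downregulated,
    5% direction-unstable, strong signal (Beta(0.05, 1) p-values) and 10%
    missing cells.
    """

    n_genes: int = 2000
    n_studies: int = 12
    frac_consistent: float = 0.05
    frac_inconsistent: float = 0.05
    frac_down_among_consistent: float = 0.7
    signal_strength: float = 0.05  # Beta(a, 1) shape; smaller = stronger
    missing_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_studies < 1:
            raise ValueError("n_genes and n_studies must be positive")
        for name in (
            "frac_consistent",
            "frac_inconsistent",
            "frac_down_among_consistent",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_consistent + self.frac_inconsistent > 1.0:
            raise ValueError("frac_consistent + frac_inconsistent must be <= 1")
        if not 0.0 < self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in (0, 1]")


def _gene_symbols(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_study_set(
    cfg: SyntheticConfig,
) -> tuple[list[DGETable], pd.DataFrame]:
    """Simulate a set of DGE studies plus the planted truth table.

    Returns the studies (each sorted most-significant-first, as a real
    DGE export would be) and a truth table with one row per gene:
    ``class`` in {consistent, inconsistent, null} and ``true_direction``
    in {+1, -1, 0}.  Byte-deterministic for a fixed config (the seed is
    part of the config).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, S = cfg.n_genes, cfg.n_studies
    symbols = np.array(_gene_symbols(G))

    n_cons = round(cfg.frac_consistent * G)
    n_incons = round(cfg.frac_inconsistent * G)
    classes = np.array(["null"] * G, dtype=object)
    perm = rng.permutation(G)
    cons_idx = perm[:n_cons]
    incons_idx = perm[n_cons : n_cons + n_incons]
    classes[cons_idx] = "consistent"
    classes[incons_idx] = "inconsistent"

    true_dir = np.zeros(G, dtype=int)
    n_down = round(cfg.frac_down_among_consistent * n_cons)
    down_choice = rng.permutation(n_cons)
    true_dir[cons_idx[down_choice[:n_down]]] = -1
    true_dir[cons_idx[down_choice[n_down:]]] = +1

    truth = pd.DataFrame(
        {"symbol": symbols, "class": classes, "true_direction": true_dir}
    )

    a = cfg.signal_strength
    is_signal = classes != "null"
    tables = []
    for s in range(S):
        p = rng.uniform(size=G)
        p[is_signal] = rng.beta(a, 1.0, size=int(is_signal.sum()))
        direction = np.where(rng.uniform(size=G) < 0.5, 1, -1)
        direction[cons_idx] = true_dir[cons_idx]
        resampled = np.where(rng.uniform(size=len(incons_idx)) < 0.5, 1, -1)
        direction[incons_idx] = resampled
        observed = rng.uniform(size=G) >= cfg.missing_rate
        df = pd.DataFrame(
            {
                "symbol": symbols[observed],
                "p": p[observed],
                "direction": direction[observed],
                "signed_score": signed_score(p[observed], direction[observed]),
            }
        )
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
        tables.append(
            DGETable(
                study_id=f"study_{s:02d}",
                data=df,
                metadata={"synthetic": True, "seed": cfg.seed},
            )
        )
    return tables, truth


def simulate_treatment(
    truth: pd.DataFrame,
    reversal_fraction: float,
    mimic_fraction: float = 0.0,
    cfg: SyntheticConfig | None = None,
    treatment_id: str | None = None,
    seed: int | None = None,
) -> DGETable:
    """Simulate a treatment signature against a planted disorder truth.

    A ``reversal_fraction`` of the consistent disorder genes receive a
    strong p-value and the direction *opposite* to their true disorder
    direction (therapeutic reversal); a further ``mimic_fraction`` move in
    the *same* direction (worsening).  All other genes are null.  The
    affected-gene selection is nested: raising the fraction only adds
    genes, so at a fixed seed the planted reversal grows monotonically.
    """
    if reversal_fraction < 0 or mimic_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if reversal_fraction + mimic_fraction > 1.0:
        raise ValueError("reversal_fraction + mimic_fraction must be <= 1")
    cfg = cfg or SyntheticConfig()
    if seed is None:
        seed = cfg.seed + 1_000_003
    rng = np.random.default_rng(seed)

    symbols = truth["symbol"].to_numpy()
    G = len(symbols)
    cons_mask = (truth["class"] == "consistent").to_numpy()
    cons_pos = np.flatnonzero(cons_mask)
    order = rng.permutation(len(cons_pos))  # nested selection
    n_rev = round(reversal_fraction * len(cons_pos))
    n_mim = round(mimic_fraction * len(cons_pos))
    rev_idx = cons_pos[order[:n_rev]]
    mim_idx = cons_pos[order[n_rev : n_rev + n_mim]]

    p = rng.uniform(size=G)
    direction = np.where(rng.uniform(size=G) < 0.5, 1, -1)
    a = cfg.signal_strength
    true_dir = truth["true_direction"].to_numpy()
    p[rev_idx] = rng.beta(a, 1.0, size=len(rev_idx))
    direction[rev_idx] = -true_dir[rev_idx]
    p[mim_idx] = rng.beta(a, 1.0, size=len(mim_idx))
    direction[mim_idx] = true_dir[mim_idx]

    df = pd.DataFrame(
        {
            "symbol": symbols,
            "p": p,
            "direction": direction,
            "signed_score": signed_score(p, direction),
        }
    )
    df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    if treatment_id is None:
        treatment_id = f"treatment_rev{reversal_fraction:g}_mim{mimic_fraction:g}"
    return DGETable(
        study_id=treatment_id,
        data=df,
        metadata={
            "synthetic": True,
            "reversal_fraction": reversal_fraction,
            "mimic_fraction": mimic_fraction,
        },
    )
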