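"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from portraitforge import DGETable, SyntheticConfig, simulate_study_set


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never share code with the
# implementation they check)
# ---------------------------------------------------------------------------


def hypergeom_tail_oracle(k: int, universe: int, n1: int, n2: int) -> float:
    """Exact upper-tail P(X >= k) by exhaustive rational tail summation."""
    total = Fraction(0)
    denom = comb(universe, n2)
    for i in range(k, min(n1, n2) + 1):
        if n2 - i <= universe - n1:
            total += Fraction(comb(n1, i) * comb(universe - n1, n2 - i), denom)
    return float(total)


def portrait_scores_oracle(
    tables: list[DGETable], tiers: tuple[int, ...]
) -> dict[str, float]:
    """Triple-loop (gene x dataset x tier) recount of consensus scores.

    Re-derives the whole construction from the raw tables: missingness
    filter, per-dataset directional ranking restricted to the retained
    universe (ties by source order), midpoint imputation, cumulative tier
    counting and decay-weighted summation — all with explicit loops.
    """
    n = len(tables)
    present: dict[str, int] = {}
    for t in tables:
        for s in t.data["symbol"]:
            present[s] = present.get(s, 0) + 1
    universe = sorted(s for s, c in present.items() if (n - c) * 3 <= n)
    g_final = len(universe)
    midpoint = -(-(g_final + 1) // 2)  # ceil
    uni_set = set(universe)

    per_dataset_up: list[dict[str, int]] = []
    per_dataset_down: list[dict[str, int]] = []
    for t in tables:
        rows = [
            (float(sc), pos, sym)
            for pos, (sym, sc) in enumerate(
                zip(t.data["symbol"], t.data["signed_score"])
            )
            if sym in uni_set
        ]
        up_sorted = sorted(rows, key=lambda r: (r[0] == 0.0, -r[0], r[1]))
        down_sorted = sorted(rows, key=lambda r: (r[0] == 0.0, r[0], r[1]))
        per_dataset_up.append(
            {sym: i + 1 for i, (_, _, sym) in enumerate(up_sorted)}
        )
        per_dataset_down.append(
            {sym: i + 1 for i, (_, _, sym) in enumerate(down_sorted)}
        )

    scores: dict[str, float] = {}
    for g in universe:
        score = 0.0
        weight = 1.0  # each deeper tier weighs tenfold less
        for cutoff in tiers:
            u = d = 0
            for j in range(n):
                ur = per_dataset_up[j].get(g, midpoint)
                dr = per_dataset_down[j].get(g, midpoint)
                if ur <= cutoff:
                    u += 1
                if dr <= cutoff:
                    d += 1
            score += weight * (u - d)
            weight *= 0.1
        scores[g] = score
    return scores


def make_table(study_id: str, rows: list[tuple[str, float]]) -> DGETable:
    """Build a DGETable straight from (symbol, signed_score) pairs."""
    return DGETable(
        study_id=study_id,
        data=pd.DataFrame(
            {
                "symbol": [r[0] for r in rows],
                "signed_score": [float(r[1]) for r in rows],
            }
        ),
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

TOY_TIERS = (10, 20, 30, 40, 50, 60, 70, 80)


@pytest.fixture(scope="session")
def planted_set():
    """A 300-gene, 6-study planted-signal set with its truth table."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_studies=6,
        frac_consistent=0.1,
        frac_inconsistent=0.05,
        signal_strength=0.05,
        missing_rate=0.1,
        seed=11,
    )
    tables, truth = simulate_study_set(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def oracle_set():
    """The 200-gene, 10-study fixture used for oracle-equivalence checks."""
    cfg = SyntheticConfig(
        n_genes=200,
        n_studies=10,
        frac_consistent=0.08,
        frac_inconsistent=0.05,
        signal_strength=0.1,
        missing_rate=0.12,
        seed=23,
    )
    tables, truth = simulate_study_set(cfg)
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
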