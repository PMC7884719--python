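"""Cross-portrait and external gene-list comparisons.

Two small analyses built on the shared overlap machinery: genes
dysregulated in *opposite* directions in two portraits (e.g. up in the
male portrait but down in the female one), and a plain hypergeometric
overlap test between a portrait's top genes and an external list such as
GWAS hits for the disorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .overlap import hypergeom_upper_tail, top_sets
from .portrait import Portrait

__all__ = ["DivergenceResult", "OverlapTestResult", "divergent_genes", "list_overlap_test"]


@dataclass
class DivergenceResult:
    """Genes in opposite top-N sets of two portraits."""

    first_id: str
    second_id: str
    N: int
    up_first_down_second: list[str]
    down_first_up_second: list[str]

    def to_dict(self) -> dict:
        return {
            "first_id": self.first_id,
            "second_id": self.second_id,
            "N": self.N,
            "up_first_down_second": self.up_first_down_second,
            "down_first_up_second": self.down_first_up_second,
        }


def divergent_genes(
    first: Portrait, second: Portrait, N: int = 1000
) -> DivergenceResult:
    """Genes moving in opposite directions in two portraits.

    Returns the intersection of the first portrait's top-N up set with
    the second's top-N down set, and vice versa.  Swapping the arguments
    swaps the two lists.
    """
    f = top_sets(first, N)
    s = top_sets(second, N)
    return DivergenceResult(
        first_id=first.portrait_id,
        second_id=second.portrait_id,
        N=N,
        up_first_down_second=sorted(f.up & s.down),
        down_first_up_second=sorted(f.down & s.up),
    )


@dataclass
class OverlapTestResult:
    """Hypergeometric overlap of two gene lists on a stated universe."""

    common: list[str]
    k: int
    p: float
    universe_size: int
    query_size: int
    reference_size: int
    attrition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "common": self.common,
            "k": self.k,
            "p": self.p,
            "universe_size": self.universe_size,
            "query_size": self.query_size,
            "reference_size": self.reference_size,
            "attrition": self.attrition,
        }


def list_overlap_test(
    query: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
) -> OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists.

    Both lists are intersected with the universe first (the number of
    genes lost is recorded) and the exact upper-tail p is computed on the
    intersected counts; the test is symmetric in query and reference.
    Typical use: an external GWAS gene list versus a portrait's top 1000
    dysregulated genes, on the portrait's full gene universe.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q_raw, r_raw = frozenset(query), frozenset(reference)
    q, r = q_raw & uni, r_raw & uni
    common = sorted(q & r)
    p = hypergeom_upper_tail(len(common), len(uni), len(q), len(r))
    return OverlapTestResult(
        common=common,
        k=len(common),
        p=p,
        universe_size=len(uni),
        query_size=len(q),
        reference_size=len(r),
        attrition={
            "query_dropped": len(q_raw) - len(q),
            "reference_dropped": len(r_raw) - len(r),
        },
    )
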