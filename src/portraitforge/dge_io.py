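"""Reading, validation and harmonization of per-study DGE tables.

A differential-gene-expression (DGE) table, as exported by GEO2R-style
tools, lists genes ordered from most to least significant, with a p-value
and a direction of change versus controls.  Every downstream stage of the
portrait pipeline consumes a single unified per-gene representation: the
*signed score* ``sign1 = -log10(p) * sign(direction)``, so an upregulated
gene with p = 1e-6 scores +6 and a downregulated one -6.

This module reads the two supported tab-separated dialects (raw
``Gene.symbol`` / ``P.Value`` / ``logFC`` exports, or precomputed
``Gene.symbol`` / ``sign1`` files), repairs spreadsheet-mangled and
outdated gene symbols, collapses multi-probe duplicates, and writes the
two-column sign1 intermediate format.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DGE_P_FLOOR",
    "NEGLOG10_CLAMP",
    "DGETable",
    "SymbolMap",
    "FormatError",
    "signed_score",
    "read_dge_table",
    "write_dge_table",
    "update_symbols",
    "collapse_duplicates",
    "load_builtin_symbol_map",
]

# Clamp for p = 0 (underflow in exported tables): keeps scores finite and
# the significance ordering stable.
DGE_P_FLOOR = 1e-320

# Cap on any -log10(p) value produced by the pipeline.
NEGLOG10_CLAMP = 320.0

#: Default column mapping for the raw GEO2R export dialect.
GEO2R_FORMAT: Mapping[str, str] = {
    "symbol": "Gene.symbol",
    "p": "P.Value",
    "logfc": "logFC",
}

#: Column mapping for the precomputed signed-score dialect.
SIGN1_FORMAT: Mapping[str, str] = {"symbol": "Gene.symbol", "sign1": "sign1"}


class FormatError(ValueError):
    """Raised when an input table is missing required columns or is empty."""


def signed_score(
    p: float | np.ndarray,
    direction: int | np.ndarray,
    p_floor: float = DGE_P_FLOOR,
) -> float | np.ndarray:
    """Signed significance score ``-log10(max(p, p_floor)) * direction``.

    Parameters
    ----------
    p
        p-value(s) in [0, 1].
    direction
        Direction of expression change: +1 (up in disorder), -1 (down),
        or 0 (no direction; the score is 0).
    p_floor
        Clamp applied before the logarithm so p = 0 stays finite.

    Returns
    -------
    The signed score; scalar in, scalar out.

    Examples
    --------
    >>> signed_score(1e-6, +1)
    6.0
    >>> signed_score(0.01, -1)
    -2.0
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1) | ~np.isfinite(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    d_arr = np.asarray(direction, dtype=float)
    score = -np.log10(np.maximum(p_arr, p_floor)) * np.sign(d_arr)
    # -0.0 from direction 0 or p = 1 is normalised to +0.0
    score = score + 0.0
    if np.isscalar(p) or p_arr.ndim == 0:
        return float(score)
    return score


@dataclass
class DGETable:
    """One study's gene list with signed significance scores.

    ``data`` holds one row per gene in the source's significance order
    (most significant first) with columns ``symbol``, ``p``, ``direction``
    and ``signed_score``.  Tables built from a sign1 file carry NaN in
    ``p`` and the sign of the score in ``direction``.
    """

    study_id: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"symbol", "signed_score"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DGETable data missing columns: {sorted(missing)}")
        if "direction" not in self.data.columns:
            self.data = self.data.assign(
                direction=np.sign(self.data["signed_score"]).astype(int)
            )
        if "p" not in self.data.columns:
            self.data = self.data.assign(p=np.nan)
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def symbols(self) -> pd.Series:
        return self.data["symbol"]

    @property
    def signed_scores(self) -> pd.Series:
        """Signed scores indexed by symbol, in source significance order."""
        return pd.Series(
            self.data["signed_score"].to_numpy(),
            index=self.data["symbol"].to_numpy(),
            name=self.study_id,
        )

    def copy(self) -> "DGETable":
        return DGETable(
            study_id=self.study_id,
            data=self.data.copy(),
            metadata=dict(self.metadata),
            load_report=dict(self.load_report),
        )


def _clean_symbols(raw: pd.Series) -> pd.Series:
    s = raw.astype("string").str.strip()
    s = s.mask(s == "", pd.NA)
    return s


def read_dge_table(
    source: str | Path | IO[str],
    fmt: Mapping[str, str] | None = None,
    study_id: str | None = None,
    p_floor: float = DGE_P_FLOOR,
    metadata: dict | None = None,
) -> DGETable:
    """Read a tab-separated DGE table into a :class:`DGETable`.

    ``fmt`` maps logical roles to column names.  Two dialects are
    supported: ``{"symbol": ..., "p": ..., "logfc": ...}`` (signed scores
    computed via :func:`signed_score` with direction = sign(logFC)), and
    ``{"symbol": ..., "sign1": ...}`` (precomputed scores used verbatim).
    With ``fmt=None`` the dialect is inferred from the header.

    Rows with an empty/missing symbol or an unparseable p-value are
    dropped and counted in ``table.load_report``.

    Raises
    ------
    FormatError
        If the file is empty or a required column is absent.
    """
    try:
        raw = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError("empty DGE table") from None
    if raw.empty:
        raise FormatError("DGE table has a header but no rows")

    if fmt is None:
        if set(SIGN1_FORMAT.values()) <= set(raw.columns):
            fmt = SIGN1_FORMAT
        else:
            fmt = GEO2R_FORMAT
    for role, col in fmt.items():
        if col not in raw.columns:
            raise FormatError(
                f"required column {col!r} (role {role!r}) not found; "
                f"available: {list(raw.columns)}"
            )

    report: dict = {"n_rows_in": len(raw)}
    symbols = _clean_symbols(raw[fmt["symbol"]])
    keep = symbols.notna()
    report["n_dropped_empty_symbol"] = int((~keep).sum())

    if "sign1" in fmt:
        score = pd.to_numeric(raw[fmt["sign1"]], errors="coerce")
        bad = score.isna() & keep
        report["n_dropped_bad_value"] = int(bad.sum())
        keep &= score.notna()
        df = pd.DataFrame(
            {
                "symbol": symbols[keep].astype(str).to_numpy(),
                "p": np.nan,
                "direction": np.sign(score[keep]).astype(int).to_numpy(),
                "signed_score": score[keep].to_numpy(dtype=float),
            }
        )
        report["n_p_clamped"] = 0
    else:
        p = pd.to_numeric(raw[fmt["p"]], errors="coerce")
        logfc = pd.to_numeric(raw[fmt["logfc"]], errors="coerce")
        bad = (p.isna() | logfc.isna() | (p < 0) | (p > 1)) & keep
        report["n_dropped_bad_value"] = int(bad.sum())
        keep &= ~bad
        p_kept = p[keep].to_numpy(dtype=float)
        direction = np.sign(logfc[keep]).astype(int).to_numpy()
        report["n_p_clamped"] = int((p_kept < p_floor).sum())
        df = pd.DataFrame(
            {
                "symbol": symbols[keep].astype(str).to_numpy(),
                "p": p_kept,
                "direction": direction,
                "signed_score": signed_score(p_kept, direction, p_floor=p_floor),
            }
        )
    report["n_rows_out"] = len(df)
    if study_id is None:
        study_id = Path(source).stem if isinstance(source, (str, Path)) else "study"
    return DGETable(
        study_id=study_id,
        data=df,
        metadata=metadata or {},
        load_report=report,
    )


def write_dge_table(table: DGETable, dest: str | Path | IO[str]) -> None:
    """Write the two-column (Gene.symbol, sign1) intermediate format."""
    out = pd.DataFrame(
        {
            "Gene.symbol": table.data["symbol"],
            "sign1": table.data["signed_score"].map(lambda v: format(v, ".17g")),
        }
    )
    out.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Symbol harmonization
# ---------------------------------------------------------------------------


@dataclass
class SymbolMap:
    """Gene-symbol update map with spreadsheet-date repair.

    ``alias_to_current`` rewrites outdated symbols (e.g. ``MARCH3`` ->
    ``MARCHF3``).  ``date_repairs`` maps spreadsheet-date strings
    (``"3-Mar"``) back to the symbol they came from; dates that could have
    come from more than one gene go in ``ambiguous_dates`` and are left
    untouched but flagged.  Symbols in ``protected`` (currently valid) are
    never rewritten, which also makes application idempotent: no rewrite
    target may itself be an alias key.
    """

    alias_to_current: dict[str, str] = field(default_factory=dict)
    date_repairs: dict[str, str] = field(default_factory=dict)
    ambiguous_dates: set[str] = field(default_factory=set)
    protected: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.alias_to_current) & self.protected
        if bad:
            raise ValueError(
                f"protected symbols may not appear as alias keys: {sorted(bad)[:5]}"
            )
        chained = {v for v in self.alias_to_current.values()} & set(
            self.alias_to_current
        )
        if chained:
            raise ValueError(
                f"alias map is not idempotent; targets that are also keys: "
                f"{sorted(chained)[:5]}"
            )
        dated = {v for v in self.date_repairs.values()} & set(self.date_repairs)
        if dated:
            raise ValueError("date repair targets may not be date strings")

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "SymbolMap":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            obj = json.loads(Path(source).read_text())
        return cls(
            alias_to_current=dict(obj.get("alias_to_current", {})),
            date_repairs=dict(obj.get("date_repairs", {})),
            ambiguous_dates=set(obj.get("ambiguous_dates", [])),
            protected=set(obj.get("protected", [])),
        )

    def to_json(self, dest: str | Path) -> None:
        Path(dest).write_text(
            json.dumps(
                {
                    "alias_to_current": self.alias_to_current,
                    "date_repairs": self.date_repairs,
                    "ambiguous_dates": sorted(self.ambiguous_dates),
                    "protected": sorted(self.protected),
                },
                indent=1,
            )
        )


def load_builtin_symbol_map() -> SymbolMap:
    """Load the small symbol-update map shipped with the package.

    The shipped file is a synthetic, demonstration-scale stand-in covering
    the classic spreadsheet-date families (MARCH/MARCHF, SEPT/SEPTIN,
    DEC1) rather than a complete nomenclature history; production use
    should supply a full, versioned map via :meth:`SymbolMap.from_json`.
    """
    ref = resources.files("portraitforge.data").joinpath(
        "symbol_map_synthetic.json"
    )
    with ref.open("r") as fh:
        return SymbolMap.from_json(fh)


def update_symbols(
    table: DGETable, symbol_map: SymbolMap
) -> tuple[DGETable, dict]:
    """Rewrite outdated and date-mangled symbols; report every change.

    Protected (currently valid) symbols are never rewritten.  Ambiguous
    date strings are left unchanged and listed in the report.  The
    operation is idempotent.
    """
    report: dict = {"alias_updates": {}, "date_repairs": {}, "ambiguous": []}
    out = table.copy()
    new_symbols = []
    for sym in out.data["symbol"]:
        if sym in symbol_map.protected:
            new_symbols.append(sym)
        elif sym in symbol_map.ambiguous_dates:
            report["ambiguous"].append(sym)
            new_symbols.append(sym)
        elif sym in symbol_map.date_repairs:
            tgt = symbol_map.date_repairs[sym]
            tgt = symbol_map.alias_to_current.get(tgt, tgt)
            report["date_repairs"][sym] = tgt
            new_symbols.append(tgt)
        elif sym in symbol_map.alias_to_current:
            tgt = symbol_map.alias_to_current[sym]
            report["alias_updates"][sym] = tgt
            new_symbols.append(tgt)
        else:
            new_symbols.append(sym)
    out.data["symbol"] = new_symbols
    report["n_changed"] = len(report["alias_updates"]) + len(report["date_repairs"])
    return out, report


def collapse_duplicates(table: DGETable) -> tuple[DGETable, dict]:
    """Keep one record per symbol: smallest p, ties by larger ``|score|``,
    then first occurrence.  Arrays with multiple probes per gene produce
    such duplicates; symbol updating can create them too.
    """
    df = table.data
    # sort key: p ascending (NaN last), |score| descending, original order;
    # mergesort keeps the first-occurrence tie-break stable
    order = df.assign(
        _p=df["p"].fillna(np.inf),
        _abs=-df["signed_score"].abs(),
        _pos=np.arange(len(df)),
    ).sort_values(["_p", "_abs", "_pos"], kind="mergesort")
    best = order.drop_duplicates("symbol", keep="first").sort_values("_pos")
    collapsed = best.drop(columns=["_p", "_abs", "_pos"]).reset_index(drop=True)
    report = {
        "n_rows_in": len(df),
        "n_rows_out": len(collapsed),
        "n_collapsed": len(df) - len(collapsed),
    }
    out = table.copy()
    out.data = collapsed
    return out, report
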