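"""Conversion of 16S rRNA gene copy numbers to cell estimates.

Gene copy counts are divided by the domain-average 16S copy number per cell
(rrnDB-derived defaults: 4.19 for Bacteria, 1.71 for Archaea).  The divisor
is treated as exact, so sd_cells = sd_copies / divisor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .catalogue import COPIES_PER_CELL

__all__ = ["CopyRecord", "CellEstimate", "copies_to_cells", "summarize_cells"]


@dataclass(frozen=True)
class CopyRecord:
    domain: str  # "Bacteria" | "Archaea"
    temperature: float
    time: float
    copies_per_ml: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.copies_per_ml < 0:
            raise ValueError("copies must be >= 0")


@dataclass(frozen=True)
class CellEstimate:
    domain: str
    temperature: float
    time: float
    cells_per_ml: float
    sd: float
    divisor_used: float
    n: int = 1
    single_replicate: bool = False


def copies_to_cells(
    rec: CopyRecord, divisors: Mapping[str, float] = COPIES_PER_CELL
) -> CellEstimate:
    """Deterministic copies -> cells conversion for one record."""
    if rec.domain not in divisors:
        raise KeyError(f"unknown domain {rec.domain!r}; have {sorted(divisors)}")
    d = divisors[rec.domain]
    if d <= 0:
        raise ValueError("divisor must be positive")
    return CellEstimate(rec.domain, rec.temperature, rec.time, rec.copies_per_ml / d, 0.0, d)


def summarize_cells(
    records: pd.DataFrame | list[CopyRecord],
    divisors: Mapping[str, float] = COPIES_PER_CELL,
) -> pd.DataFrame:
    """Mean +- sample sd of cell estimates per (domain, temperature, time).

    Accepts a qPCR table (columns domain, temperature, time, replicate,
    copies_per_ml) or a list of CopyRecord.  The returned frame also
    carries the archaeal share of total mean cells per (temperature, time)
    in the ``archaeal_share`` column (as a fraction, repeated on both
    domain rows).
    """
    if isinstance(records, list):
        df = pd.DataFrame(
            [
                {
                    "domain": r.domain,
                    "temperature": r.temperature,
                    "time": r.time,
                    "replicate": r.replicate,
                    "copies_per_ml": r.copies_per_ml,
                }
                for r in records
            ]
        )
    else:
        df = records.copy()
    unknown = set(df["domain"]) - set(divisors)
    if unknown:
        raise KeyError(f"unknown domains {sorted(unknown)}")
    df["cells"] = df.apply(lambda r: r["copies_per_ml"] / divisors[r["domain"]], axis=1)
    g = df.groupby(["domain", "temperature", "time"])["cells"]
    out = g.agg(cells_per_ml="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["single_replicate"] = out["n"] == 1
    out["divisor_used"] = out["domain"].map(divisors)

    means = out.pivot_table(index=["temperature", "time"], columns="domain",
                            values="cells_per_ml", aggfunc="mean")
    share = means.get("Archaea", 0.0) / means.sum(axis=1)
    out = out.merge(share.rename("archaeal_share").reset_index(), on=["temperature", "time"])
    return out
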