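"""Batch-vs-field comparison of biochar--water partition coefficients.

Field-fitted K_bc values from pilot filters are typically far lower than
batch-screening values for the same compound--sorbent pair because of
matrix effects, fouling and non-ideal flow.  This module computes per-pair
ratios (batch / field) with explicit handling of left-censored field
values ("<0.1" becomes a right-censored ratio bound, excluded from the
min/max summary but itemised, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import load_field_batch_table

__all__ = ["Censored", "CoefficientPair", "load_reference_pairs", "ratio_table"]


@dataclass(frozen=True)
class Censored:
    """A left-censored measurement: value < bound."""

    bound: float

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValidationError("censoring bound must be positive")

    def __str__(self) -> str:
        return f"<{self.bound:g}"


def _parse_value(token) -> float | Censored:
    if isinstance(token, (int, float)):
        return float(token)
    token = str(token).strip()
    if token.startswith("<"):
        return Censored(float(token[1:]))
    return float(token)


@dataclass(frozen=True)
class CoefficientPair:
    """Batch and field partition coefficients for one compound--sorbent pair."""

    compound: str
    sorbent: str
    kbc_batch: float
    kbc_field: float | Censored

    def __post_init__(self) -> None:
        if self.kbc_batch <= 0:
            raise ValidationError(f"{self.compound}/{self.sorbent}: batch K_bc must be positive")
        if isinstance(self.kbc_field, (int, float)) and self.kbc_field <= 0:
            raise ValidationError(f"{self.compound}/{self.sorbent}: field K_bc must be positive")

    @property
    def censored(self) -> bool:
        return isinstance(self.kbc_field, Censored)

    @property
    def ratio(self) -> float:
        """Batch/field ratio; for censored field values this is a lower bound."""
        if self.censored:
            return self.kbc_batch / self.kbc_field.bound
        return self.kbc_batch / self.kbc_field


def load_reference_pairs():
    """Packaged field-vs-batch fixture as (pairs, sand K_s table).

    The K_bc rows become :class:`CoefficientPair` objects; K_s rows (no
    batch analogue) are returned separately so nothing is dropped.
    """
    frame = load_field_batch_table()
    pairs = []
    ks_rows = []
    for _, row in frame.iterrows():
        field_value = _parse_value(row["field_L_kg"])
        if row["coefficient"] == "K_bc":
            pairs.append(
                CoefficientPair(
                    compound=row["compound"],
                    sorbent=row["sorbent"],
                    kbc_batch=float(row["batch_L_kg"]),
                    kbc_field=field_value,
                )
            )
        else:
            ks_rows.append(
                {
                    "compound": row["compound"],
                    "ks_field_L_kg": str(field_value),
                    "censored": isinstance(field_value, Censored),
                }
            )
    return pairs, pd.DataFrame(ks_rows)


def ratio_table(pairs) -> tuple[pd.DataFrame, dict]:
    """Per-pair batch/field ratios plus a finite-ratio summary.

    Returns (table, summary).  The summary's ``ratio_min``/``ratio_max``
    cover finite ratios only; censored pairs are listed under
    ``censored_ratios`` as lower bounds (e.g. ``"> 2790"``).
    """
    if not pairs:
        raise ValidationError("need at least one coefficient pair")
    rows = []
    for pair in pairs:
        rows.append(
            {
                "compound": pair.compound,
                "sorbent": pair.sorbent,
                "kbc_batch_L_kg": pair.kbc_batch,
                "kbc_field_L_kg": str(pair.kbc_field) if pair.censored else pair.kbc_field,
                "ratio": pair.ratio,
                "censored": pair.censored,
            }
        )
    table = pd.DataFrame(rows)
    finite = table.loc[~table["censored"], "ratio"]
    if finite.empty:
        raise ValidationError("no pair has finite batch and field values")
    summary = {
        "n_pairs": len(table),
        "n_finite": int(finite.size),
        "ratio_min": float(finite.min()),
        "ratio_max": float(finite.max()),
        "censored_ratios": [
            f"{r.compound}/{r.sorbent} > {r.ratio:.4g}"
            for r in pairs
            if r.censored
        ],
    }
    return table, summary
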