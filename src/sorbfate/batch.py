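"""Mass-balance computation of sorbed concentrations, single-point sorption
coefficients K_bc, removal percentages, K_bc matrices and salinity-series
trend classification.

The single-point coefficient is the standard batch quantity

    q    = (C0 - Ce) * V / m          (mg/kg)
    K_bc = q / Ce                     (L/kg)
    removal = 100 * (C0 - Ce) / C0    (%)

Complete-removal observations (Ce = 0) carry no finite K_bc; they are
reported as censored lower bounds K_bc >= q / LOQ for a configurable
limit of quantification, never as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import BatchDataset, BatchRecord

__all__ = [
    "SorptionPoint",
    "KbcMatrix",
    "SalinitySeries",
    "sorption_point",
    "compute_points",
    "build_kbc_matrix",
    "classify_salinity_trend",
    "DEFAULT_LOQ",
    "TREND_DEADBAND",
]

#: default analytical limit of quantification, mg/L (used for censored bounds)
DEFAULT_LOQ = 0.01
#: relative dead-band for salinity trend classification
TREND_DEADBAND = 0.05
#: relative tolerance when matching records to a requested loading
LOADING_TOLERANCE = 0.02


@dataclass(frozen=True)
class SorptionPoint:
    """One computed sorption observation.

    ``kbc`` is None when removal is complete; ``kbc_lower_bound`` then
    carries the censoring bound q / LOQ.
    """

    compound: str
    sorbent: str
    q: float  # sorbed-phase concentration, mg/kg
    ce: float  # equilibrium aqueous concentration, mg/L
    kbc: float | None  # L/kg
    removal: float  # %
    complete_removal: bool = False
    kbc_lower_bound: float | None = None
    nacl_molarity: float = 0.0
    loading: float = 0.0  # mg/L


def sorption_point(record: BatchRecord, loq: float = DEFAULT_LOQ) -> SorptionPoint:
    """Mass-balance evaluation of one batch record.

    Records whose Ce marginally exceeds C0 (within the read-time tolerance)
    are treated as zero sorption: Ce is clipped to C0 so removal stays in
    [0, 100] and the per-record mass balance holds by construction.
    """
    ce = min(record.ce, record.c0)
    q = (record.c0 - ce) * record.volume / record.mass
    removal = 100.0 * (record.c0 - ce) / record.c0 if record.c0 > 0 else 0.0
    # mass conservation by construction: C0*V = Ce*V + q*m
    assert abs(record.c0 * record.volume - (ce * record.volume + q * record.mass)) <= (
        1e-12 * max(record.c0 * record.volume, 1.0)
    )
    if ce > 0:
        return SorptionPoint(
            compound=record.compound,
            sorbent=record.sorbent,
            q=q,
            ce=ce,
            kbc=q / ce,
            removal=removal,
            nacl_molarity=record.nacl_molarity,
            loading=record.loading,
        )
    return SorptionPoint(
        compound=record.compound,
        sorbent=record.sorbent,
        q=q,
        ce=0.0,
        kbc=None,
        removal=100.0,
        complete_removal=True,
        kbc_lower_bound=q / loq,
        nacl_molarity=record.nacl_molarity,
        loading=record.loading,
    )


def compute_points(dataset: BatchDataset, loq: float = DEFAULT_LOQ) -> list[SorptionPoint]:
    return [sorption_point(record, loq=loq) for record in dataset]


@dataclass
class KbcMatrix:
    """Compounds x sorbents table of mean single-point K_bc at one loading.

    ``values`` holds replicate means (L/kg); ``counts`` the replicate
    number per cell, ``sds`` the sample standard deviation, ``censored``
    flags cells where every replicate showed complete removal (the value
    column then carries the mean lower bound).
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    sds: pd.DataFrame
    censored: pd.DataFrame
    loading: float  # mg/L

    @property
    def compounds(self):
        return list(self.values.index)

    @property
    def sorbents(self):
        return list(self.values.columns)

    def drop_censored(self, axis: str = "sorbents") -> "KbcMatrix":
        """Drop sorbents (columns) or compounds (rows) containing censored cells."""
        if axis == "sorbents":
            keep = [s for s in self.values.columns if not self.censored[s].any()]
            return KbcMatrix(
                self.values[keep], self.counts[keep], self.sds[keep], self.censored[keep], self.loading
            )
        keep = [c for c in self.values.index if not self.censored.loc[c].any()]
        return KbcMatrix(
            self.values.loc[keep],
            self.counts.loc[keep],
            self.sds.loc[keep],
            self.censored.loc[keep],
            self.loading,
        )


def build_kbc_matrix(
    dataset: BatchDataset,
    loading: float,
    rel_tol: float = LOADING_TOLERANCE,
    loq: float = DEFAULT_LOQ,
) -> KbcMatrix:
    """Assemble the compounds x sorbents K_bc matrix at one sorbent loading.

    Cells are arithmetic means of the replicate K_bc values whose record
    loading lies within ``rel_tol`` of the request.  Pairs present in the
    dataset but absent at the requested loading raise a ValidationError
    listing them.  Cells where all replicates show complete removal are
    flagged censored and carry the mean lower bound.
    """
    if loading <= 0:
        raise ValidationError("loading must be positive")
    universe = sorted({(r.compound, r.sorbent) for r in dataset})
    if not universe:
        raise ValidationError("dataset is empty")
    selected: dict[tuple, list[SorptionPoint]] = {}
    for record in dataset:
        if abs(record.loading - loading) <= rel_tol * loading:
            selected.setdefault((record.compound, record.sorbent), []).append(
                sorption_point(record, loq=loq)
            )
    absent = [pair for pair in universe if pair not in selected]
    if absent:
        raise ValidationError(
            f"no record at loading {loading} mg/L for pairs: "
            + ", ".join(f"{c}/{s}" for c, s in absent)
        )
    compounds = sorted({c for c, _ in universe})
    sorbents = sorted({s for _, s in universe})
    values = pd.DataFrame(np.nan, index=compounds, columns=sorbents)
    counts = pd.DataFrame(0, index=compounds, columns=sorbents)
    sds = pd.DataFrame(np.nan, index=compounds, columns=sorbents)
    censored = pd.DataFrame(False, index=compounds, columns=sorbents)
    for (compound, sorbent), points in selected.items():
        finite = [p.kbc for p in points if p.kbc is not None]
        counts.loc[compound, sorbent] = len(points)
        if finite:
            values.loc[compound, sorbent] = float(np.mean(finite))
            sds.loc[compound, sorbent] = float(np.std(finite, ddof=1)) if len(finite) > 1 else np.nan
        else:  # every replicate at complete removal -> censored lower bound
            censored.loc[compound, sorbent] = True
            values.loc[compound, sorbent] = float(np.mean([p.kbc_lower_bound for p in points]))
    return KbcMatrix(values=values, counts=counts, sds=sds, censored=censored, loading=loading)


@dataclass(frozen=True)
class SalinitySeries:
    """K_bc of one compound--sorbent pair across NaCl molarities."""

    compound: str
    sorbent: str
    levels: tuple  # mol/L, strictly increasing
    kbc: tuple  # L/kg per level

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.kbc):
            raise ValidationError("levels and kbc must have equal length")
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError("salinity levels must be strictly increasing")
        if min(self.kbc) <= 0:
            raise ValidationError("K_bc values must be positive to classify a trend")


def classify_salinity_trend(series: SalinitySeries, deadband: float = TREND_DEADBAND) -> str:
    """Classify the ionic-strength response of K_bc.

    ``decrease`` if every successive ratio <= 1 - deadband, ``increase`` if
    every ratio >= 1 + deadband, ``flat`` if all ratios are within the
    dead-band, otherwise ``non-monotone``.
    """
    if len(series.levels) < 3:
        raise ValidationError("need at least 3 salinity levels to classify a trend")
    kbc = np.asarray(series.kbc, dtype=float)
    ratios = kbc[1:] / kbc[:-1]
    if np.all(ratios <= 1.0 - deadband):
        return "decrease"
    if np.all(ratios >= 1.0 + deadband):
        return "increase"
    if np.all((ratios >= 1.0 - deadband) & (ratios <= 1.0 + deadband)):
        return "flat"
    return "non-monotone"
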