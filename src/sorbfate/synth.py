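"""Synthetic-data generators with known ground truth.

Because no raw batch or field measurements are deposited with the study
this package emulates, every pipeline stage is exercised on synthetic
data generated under the published experimental designs:

* batch series: 50 mL of solution at 1 mg/L per compound over sorbent
  masses of 5, 10, 25, 50, 100 and 250 mg, in triplicate;
* salinity series: NaCl at 0, 0.01, 0.1 and 1 M;
* field filtration: the layered bucket filter at 1 L/min with 24
  composite 1 L effluent samples after 15 min of conditioning.

Noise is multiplicative lognormal on concentrations (default CV 5%,
mean-preserving, truncated at physical bounds) - concentration
quantification error scales roughly with signal.  Every generator is a
pure function of (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .batch import KbcMatrix, SalinitySeries
from .exceptions import GenerationError, ValidationError
from .io import BatchDataset, BatchRecord
from .isotherms import IsothermModel
from .transport import (
    BreakthroughCurve,
    FilterColumn,
    SoluteTransportParams,
    SolverSettings,
    field_filter,
    simulate_breakthrough,
)

__all__ = [
    "BatchTruth",
    "ColumnTruth",
    "generate_batch",
    "generate_salinity_series",
    "generate_kbc_matrix",
    "generate_breakthrough",
]

#: batch design defaults: 1 mg/L in 50 mL over masses 5-250 mg, triplicate
DEFAULT_MASSES_KG = (5e-6, 10e-6, 25e-6, 50e-6, 100e-6, 250e-6)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


@dataclass(frozen=True)
class BatchTruth:
    """Ground truth for one synthetic batch series."""

    isotherm: IsothermModel
    c0: float = 1.0  # mg/L
    volume: float = 0.05  # L
    masses: tuple = DEFAULT_MASSES_KG  # kg
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0
    compound: str = "synthetic"
    sorbent: str = "BC"


def _equilibrium_ce(isotherm: IsothermModel, c0: float, volume: float, mass: float) -> float:
    """Solve the implicit batch mass balance C0 V = Ce V + q(Ce) m for Ce.

    The residual is strictly increasing in Ce for every supported isotherm,
    so bisection on (0, C0] (capped below C_s for BET) finds the unique root.
    """
    upper = c0
    if isotherm.kind == "bet":
        upper = min(c0, isotherm.params["c_s"] * (1.0 - 1e-9))

    def residual(ce: float) -> float:
        return ce * volume + float(isotherm.predict(ce)) * mass - c0 * volume

    lo = upper * 1e-15
    if residual(lo) >= 0 or residual(upper) < 0:
        raise GenerationError(
            f"no equilibrium Ce in (0, {upper:g}] for mass {mass:g} kg and this isotherm"
        )
    return brentq(residual, lo, upper, xtol=1e-15, rtol=1e-14)


def generate_batch(truth: BatchTruth, seed: int | None = None) -> BatchDataset:
    """Generate a batch dataset from a truth isotherm.

    For each sorbent mass and replicate the exact equilibrium Ce is found
    from the mass balance, then multiplicative lognormal noise with
    CV = ``truth.noise_cv`` is applied and clipped to [0, C0].
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records = []
    for mass in truth.masses:
        ce_true = _equilibrium_ce(truth.isotherm, truth.c0, truth.volume, mass)
        factors = _lognormal_factor(rng, truth.noise_cv, truth.replicates)
        for factor in factors:
            ce_obs = float(np.clip(ce_true * factor, 0.0, truth.c0))
            records.append(
                BatchRecord(
                    compound=truth.compound,
                    sorbent=truth.sorbent,
                    c0=truth.c0,
                    ce=ce_obs,
                    volume=truth.volume,
                    mass=mass,
                )
            )
    return BatchDataset(records)


def generate_salinity_series(
    base_kbc: float,
    factor_per_decade: float,
    levels=(0.0, 0.01, 0.1, 1.0),
    noise_cv: float = 0.0,
    seed: int | None = None,
    compound: str = "synthetic",
    sorbent: str = "BC",
) -> SalinitySeries:
    """Synthetic ionic-strength series: K_bc changes by a fixed factor per decade.

    0 M is the reference level; each successive stated molarity is one
    decade step, so levels (0, 0.01, 0.1, 1) give base * factor**(0..3).
    """
    if base_kbc <= 0:
        raise ValidationError("base K_bc must be positive")
    if factor_per_decade <= 0:
        raise ValidationError("factor per decade must be positive")
    levels = tuple(float(l) for l in levels)
    if np.any(np.diff(levels) <= 0):
        raise ValidationError("levels must be strictly increasing")
    nonzero = [l for l in levels if l > 0]
    if not nonzero:
        raise ValidationError("need at least one non-zero salinity level")
    ref = nonzero[0]
    offset = 1.0 if levels[0] == 0.0 else 0.0
    decades = np.array(
        [0.0 if l == 0.0 else offset + np.log10(l / ref) for l in levels]
    )
    kbc = base_kbc * factor_per_decade ** decades
    rng = np.random.default_rng(seed)
    kbc = kbc * _lognormal_factor(rng, noise_cv, kbc.size)
    return SalinitySeries(compound=compound, sorbent=sorbent, levels=levels, kbc=tuple(kbc))


def generate_kbc_matrix(
    n_compounds: int = 7,
    n_sorbents: int = 10,
    block_means=(2000.0, 200.0),
    block_sizes=None,
    noise_cv: float = 0.10,
    loading: float = 200.0,
    seed: int | None = None,
):
    """K_bc matrix with a planted two-block structure over sorbents.

    Each sorbent belongs to one block whose mean K_bc is taken from
    ``block_means``; compounds modulate cells by a fixed geometric spread
    so rows differ but block membership stays recoverable.  Returns
    (KbcMatrix, true block labels by sorbent).
    """
    import pandas as pd

    if block_sizes is None:
        half = n_sorbents // 2
        block_sizes = (half, n_sorbents - half)
    if sum(block_sizes) != n_sorbents or len(block_sizes) != len(block_means):
        raise ValidationError("block sizes must partition the sorbents, one per block mean")
    rng = np.random.default_rng(seed)
    compounds = [f"compound_{i + 1}" for i in range(n_compounds)]
    sorbents = [f"sorbent_{j + 1}" for j in range(n_sorbents)]
    block_of = np.repeat(np.arange(len(block_sizes)), block_sizes)
    compound_factor = np.geomspace(0.5, 2.0, n_compounds)
    means = np.array([block_means[b] for b in block_of])
    cells = np.outer(compound_factor, means)
    cells = cells * _lognormal_factor(rng, noise_cv, cells.shape)
    values = pd.DataFrame(cells, index=compounds, columns=sorbents)
    shape = pd.DataFrame(np.full(cells.shape, 3), index=compounds, columns=sorbents)
    matrix = KbcMatrix(
        values=values,
        counts=shape,
        sds=values * 0.0,
        censored=pd.DataFrame(False, index=compounds, columns=sorbents),
        loading=loading,
    )
    labels = dict(zip(sorbents, (int(b) for b in block_of)))
    return matrix, labels


@dataclass(frozen=True)
class ColumnTruth:
    """Ground truth for one synthetic field-filtration run."""

    column: FilterColumn = field(default_factory=field_filter)
    params: SoluteTransportParams = field(default_factory=SoluteTransportParams)
    c_in: float = 1.0  # mg/L (units cancel in C/C_in)
    sample_volumes: tuple = tuple(float(v) for v in range(1, 25))  # L
    noise_cv: float = 0.05
    seed: int = 0


def generate_breakthrough(
    truth: ColumnTruth,
    seed: int | None = None,
    settings: SolverSettings | None = None,
) -> BreakthroughCurve:
    """Simulate the truth column and emit noisy composite 1 L samples.

    The fine solver output is averaged over each sampling interval (grab
    samples integrate the effluent over the litre they collect), then
    multiplicative lognormal noise with CV = ``truth.noise_cv`` is applied.
    """
    volumes = np.asarray(truth.sample_volumes, dtype=float)
    if truth.c_in == 0:
        return BreakthroughCurve(
            volumes=volumes,
            c_over_cin=np.zeros_like(volumes),
            provenance="observed",
            label="synthetic",
            c_in=0.0,
        )
    fine = simulate_breakthrough(
        truth.column,
        truth.params,
        c_in=truth.c_in,
        duration_volume=float(volumes[-1]),
        settings=settings,
    )
    sampled = fine.interval_means(volumes)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    noisy = np.maximum(sampled * _lognormal_factor(rng, truth.noise_cv, sampled.size), 0.0)
    return BreakthroughCurve(
        volumes=volumes,
        c_over_cin=noisy,
        provenance="observed",
        label="synthetic",
        c_in=truth.c_in,
        mass_balance=fine.mass_balance,
    )
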