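"""Inference of the sympatric-speciation fraction and age-range correlations.

Observed summary indices (counts of completely sympatric and completely
allopatric pairs, and bimodality) are compared with simulated index
distributions by a two-tailed percentile rule: a simulation cell is
consistent with the data when the observed value lies within the 2.5th
and 97.5th percentiles of the simulated distribution.  The reported
estimate of how often speciation was sympatric is the range of sympatric
fractions over cells consistent with all three indices simultaneously.

Age-range correlations (ARC) regress the angular-transformed overlap
index, arcsin(sqrt(p)), on phylogenetic branch length by ordinary least
squares; only sister pairs enter, avoiding ancestral-range
reconstruction.  The back-transformed intercept, sin^2(intercept), is a
crude estimate of the fraction of speciation that was sympatric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geometry import OverlapSummary

__all__ = [
    "PARAMETER_COLUMNS",
    "ArcFit",
    "ConsistencyResult",
    "percentile_consistency",
    "sweep_percentile_bounds",
    "consistent_sympatric_range",
    "parameter_recovery",
    "angular_transform",
    "back_transform",
    "arc_regression",
]

#: Sweep-table columns identifying one simulation parameter combination.
PARAMETER_COLUMNS = ["ancestral_fraction", "movement_sd", "movement_mean", "geometry"]

_INDEX_COLUMNS = ["z", "c", "bimodality"]


def percentile_consistency(observed: float, simulated) -> bool:
    """Two-tailed percentile test of one observed index against simulations.

    True iff the observed value lies within [P2.5, P97.5] of the
    simulated distribution (linear-interpolation quantiles); equality at
    a boundary counts as consistent.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.size == 0:
        raise ValueError("simulated distribution is empty")
    if sim.size < 40:
        warnings.warn(
            f"only {sim.size} simulated values; 2.5/97.5 percentiles are unstable",
            stacklevel=2,
        )
    lo, hi = np.percentile(sim, [2.5, 97.5])
    return bool(lo <= observed <= hi)


@dataclass(frozen=True)
class ConsistencyResult:
    """Sympatric-fraction ranges consistent with the observed indices.

    ``joint`` is the (min, max) fraction of sympatric speciation over
    cells where all three indices pass the percentile test in the same
    parameter combination; ``per_index`` holds the analogous union-over-
    combinations range for each index alone.  ``cells`` is the per-cell
    boolean table behind both.
    """

    joint: tuple[float, float] | None
    per_index: dict[str, tuple[float, float] | None]
    cells: pd.DataFrame
    n_pairs: int


def sweep_percentile_bounds(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-cell 2.5/97.5 percentile bounds of each index in a sweep table.

    One row per (parameter combination, n_sympatric) cell with columns
    ``<index>_lo`` and ``<index>_hi``.  Precomputing the bounds lets many
    observed summaries be tested against one sweep cheaply.
    """
    missing = [c for c in PARAMETER_COLUMNS + ["n_sympatric"] + _INDEX_COLUMNS
               if c not in sweep.columns]
    if missing:
        raise ValueError(f"sweep table lacks columns: {missing}")
    rows = []
    for key, cell in sweep.groupby(PARAMETER_COLUMNS + ["n_sympatric"], sort=True):
        rec = dict(zip(PARAMETER_COLUMNS + ["n_sympatric"], key))
        if len(cell) < 40:
            warnings.warn(
                f"cell {key} has only {len(cell)} replicates; "
                "2.5/97.5 percentiles are unstable",
                stacklevel=2,
            )
        for name in _INDEX_COLUMNS:
            lo, hi = np.percentile(cell[name].to_numpy(), [2.5, 97.5])
            rec[f"{name}_lo"], rec[f"{name}_hi"] = lo, hi
        rows.append(rec)
    return pd.DataFrame(rows)


def consistent_sympatric_range(
    observed: OverlapSummary, sweep: pd.DataFrame
) -> ConsistencyResult:
    """Range of sympatric-speciation fractions consistent with the data.

    ``sweep`` is either the tidy replicate table from
    :func:`sympatry.simulator.run_sweep` or the precomputed bounds table
    from :func:`sweep_percentile_bounds`.  For each (parameter
    combination, n_sympatric) cell and index, consistency follows the
    two-tailed percentile rule; fractions are n_sympatric / n pairs.
    """
    if "z_lo" not in sweep.columns:
        sweep = sweep_percentile_bounds(sweep)
    obs = {"z": observed.z, "c": observed.c, "bimodality": observed.bimodality}
    cells = sweep[PARAMETER_COLUMNS + ["n_sympatric"]].copy()
    for name in _INDEX_COLUMNS:
        cells[f"consistent_{name}"] = (
            (sweep[f"{name}_lo"] <= obs[name]) & (obs[name] <= sweep[f"{name}_hi"])
        )
    cells["consistent_all"] = np.logical_and.reduce(
        [cells[f"consistent_{name}"] for name in _INDEX_COLUMNS]
    )
    n = observed.n

    def _range(mask: pd.Series) -> tuple[float, float] | None:
        ks = cells.loc[mask, "n_sympatric"]
        if ks.empty:
            return None
        return (float(ks.min()) / n, float(ks.max()) / n)

    per_index = {name: _range(cells[f"consistent_{name}"]) for name in _INDEX_COLUMNS}
    return ConsistencyResult(
        joint=_range(cells["consistent_all"]),
        per_index=per_index,
        cells=cells,
        n_pairs=n,
    )


def parameter_recovery(
    true_fractions,
    n_pairs: int,
    n_runs: int,
    config_grid,
    observed_config,
    n_replicates: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Coverage of the joint consistency interval in a recovery experiment.

    For each true sympatric fraction, ``n_runs`` observed datasets of
    ``n_pairs`` sister pairs are simulated under ``observed_config``
    with round(fraction * n_pairs) sympatric events, and each is pushed
    through the full percentile inference against one shared sweep over
    ``config_grid``.  Because the realized mixture is a count, coverage
    is judged against the realizable truth k / n_pairs.  Returns one row
    per fraction with the realized truth and the fraction of runs whose
    jointly consistent interval covers it.
    """
    from .synthetic import gen_branch_lengths, gen_pair_table
    from .geometry import summarize_overlaps
    from .simulator import run_sweep

    ss = np.random.SeedSequence(seed)
    seed_sweep, seed_obs = ss.spawn(2)
    rng = np.random.default_rng(seed_obs)
    branch_lengths = gen_branch_lengths(n_pairs, rng=np.random.default_rng(seed_sweep))
    sweep = run_sweep(
        branch_lengths, config_grid, n_replicates=n_replicates,
        seed=int(seed_sweep.generate_state(1)[0] % 2**31),
    )
    bounds = sweep_percentile_bounds(sweep)
    rows = []
    for frac in true_fractions:
        k_true = int(round(frac * n_pairs))
        truth = k_true / n_pairs
        covered = 0
        for _ in range(n_runs):
            table, _ = gen_pair_table(
                n_pairs, frac, observed_config, rng, branch_lengths=branch_lengths
            )
            observed = summarize_overlaps(table["overlap_index"])
            result = consistent_sympatric_range(observed, bounds)
            if result.joint is not None:
                lo, hi = result.joint
                covered += lo - 1e-9 <= truth <= hi + 1e-9
        rows.append(
            {
                "true_fraction": frac,
                "realized_truth": truth,
                "n_runs": n_runs,
                "coverage": covered / n_runs,
            }
        )
    return pd.DataFrame(rows)


def angular_transform(p) -> np.ndarray | float:
    """Variance-stabilising angular transform arcsin(sqrt(p)), p in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


def back_transform(theta) -> np.ndarray | float:
    """Inverse of the angular transform: sin^2(theta), theta in [0, pi/2]."""
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < 0) | (arr > np.pi / 2 + 1e-12)):
        raise ValueError("angles must lie in [0, pi/2]")
    out = np.sin(arr) ** 2
    return float(out) if np.isscalar(theta) else out


@dataclass(frozen=True)
class ArcFit:
    """Age-range correlation fit on the angular scale."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    slope_p: float
    intercept_backtransformed: float
    n: int


def arc_regression(branch_lengths, overlaps) -> ArcFit:
    """OLS of angular-transformed range overlap on branch length.

    The slope p-value is the standard two-sided t-test with n - 2
    degrees of freedom.  The intercept is back-transformed through
    sin^2 after truncation into [0, pi/2].
    """
    t = np.asarray(branch_lengths, dtype=float)
    y = angular_transform(np.asarray(overlaps, dtype=float))
    if t.size != y.size:
        raise ValueError("branch_lengths and overlaps differ in length")
    if t.size < 3:
        raise ValueError("need at least 3 sister pairs for the regression")
    if np.ptp(t) == 0:
        raise ValueError("constant predictor: branch lengths show no variation")
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    intercept, slope = fit.params
    bt = float(np.sin(np.clip(intercept, 0.0, np.pi / 2)) ** 2)
    return ArcFit(
        intercept=float(intercept),
        slope=float(slope),
        intercept_se=float(fit.bse[0]),
        slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        intercept_backtransformed=bt,
        n=int(t.size),
    )
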