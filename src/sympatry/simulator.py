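"""Stochastic simulation of speciation geometry and post-speciation range movement.

The model follows the null-model tradition for inferring the geography of
speciation from present-day range overlap.  An ancestral range of known
size, living on a square domain of 100 x 100 length units, is divided
into two square daughter ranges whose initial configuration depends on
the speciation mode:

* sympatric  — the smaller daughter is placed uniformly at random inside
  the larger (initial overlap index 1);
* vicariant  — the smaller daughter sits 2 units to the right of the
  larger, its vertical placement uniform along the larger's extent;
* parapatric — as vicariant but abutting (gap 0);
* peripatric — the split is 95:5 and both daughters are placed uniformly
  on the domain subject to not overlapping.

Ranges then drift: at each time step four independent normal deviates
are added outward to the top, bottom, left and right edges of each box,
so a positive mean gives ranges a tendency to grow.  Boxes are clipped
to the domain.  A box whose width or height collapses to zero is extinct
and the whole pair is re-simulated from the split.  The number of steps
for a pair is its phylogenetic branch length (My) times 10.

The per-pair final overlap indices are summarised with the same
0.05 / 0.95 classification and bimodality score applied to observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import OverlapSummary, summarize_overlaps

__all__ = [
    "MODES",
    "RangeBox",
    "SimConfig",
    "SimReplicateResult",
    "PlacementError",
    "RestartLimitError",
    "split_area",
    "place_daughters",
    "step_move",
    "simulate_pair",
    "run_replicate",
    "run_sweep",
    "default_config_grid",
]

#: The four speciation geometries.
MODES = ("sympatric", "vicariant", "parapatric", "peripatric")


class PlacementError(RuntimeError):
    """Initial placement is persistently infeasible for the configuration."""


class RestartLimitError(RuntimeError):
    """Extinction-triggered restarts exceeded the configured cap."""


@dataclass(frozen=True)
class RangeBox:
    """An axis-aligned rectangular species range.

    A box with ``right <= left`` or ``top <= bottom`` denotes a species
    whose range has dwindled to zero size (extinction).
    """

    left: float
    right: float
    bottom: float
    top: float

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.top - self.bottom

    @property
    def area(self) -> float:
        return max(self.width, 0.0) * max(self.height, 0.0)

    @property
    def alive(self) -> bool:
        return self.width > 0 and self.height > 0

    def intersection_area(self, other: "RangeBox") -> float:
        w = min(self.right, other.right) - max(self.left, other.left)
        h = min(self.top, other.top) - max(self.bottom, other.bottom)
        return max(w, 0.0) * max(h, 0.0)

    def overlap_index(self, other: "RangeBox") -> float:
        smaller = min(self.area, other.area)
        if smaller <= 0:
            raise ValueError("overlap index undefined for an extinct range")
        return min(self.intersection_area(other) / smaller, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation condition.

    ``ancestral_fraction`` is the ancestral range area as a fraction of
    the domain area; observed heliconiine medians motivate 0.082 / 0.108
    (relaxed BSC) and 0.135 / 0.16 (strict BSC), plus doubled values,
    the default being the medium-sized 0.16.  ``movement_sd`` is the
    standard deviation of the per-step edge deviates, in length units,
    explored over 0.25-2; ``movement_mean`` 0 or 0.1 (growth tendency).
    """

    domain_size: float = 100.0
    ancestral_fraction: float = 0.16
    movement_sd: float = 0.5
    movement_mean: float = 0.0
    steps_per_branch_unit: float = 10.0
    n_replicates: int = 1000
    nonsympatric_geometry: str = "vicariant"
    peripatric_small_fraction: float = 0.05
    vicariant_gap: float = 2.0
    boundary: str = "clip"  # or "reflect"
    placement_retry_cap: int = 1000
    restart_cap: int = 1000
    split_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ancestral_fraction < 1:
            raise ValueError("ancestral_fraction must lie in (0, 1)")
        if self.movement_sd < 0:
            raise ValueError("movement_sd must be nonnegative")
        if self.nonsympatric_geometry not in ("vicariant", "parapatric", "peripatric"):
            raise ValueError(
                f"unknown non-sympatric geometry {self.nonsympatric_geometry!r}"
            )
        if self.boundary not in ("clip", "reflect"):
            raise ValueError("boundary must be 'clip' or 'reflect'")

    @property
    def ancestral_area(self) -> float:
        return self.ancestral_fraction * self.domain_size**2


@dataclass(frozen=True)
class SimReplicateResult:
    """Per-pair final overlap indices and their summary for one replicate."""

    overlaps: np.ndarray
    summary: OverlapSummary


# ---------------------------------------------------------------------------
# splitting and placement


def _split_fractions(mode: str, m: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fraction of the ancestral area taken by the *larger* daughter, shape (m,)."""
    if mode == "peripatric":
        return np.full(m, 1.0 - config.peripatric_small_fraction)
    if config.split_sampler is not None:
        u = np.asarray(config.split_sampler(rng, m), dtype=float)
    else:
        u = rng.uniform(0.0, 1.0, size=m)
    return np.maximum(u, 1.0 - u)


def split_area(
    total_area: float, mode: str, rng: np.random.Generator, config: SimConfig | None = None
) -> tuple[float, float]:
    """Divide an ancestral area into two daughter areas, larger first.

    Non-peripatric modes draw the split fraction Uniform(0, 1); the
    peripatric mode always splits 95:5.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    config = config or SimConfig()
    f = float(_split_fractions(mode, 1, config, rng)[0])
    large = total_area * f
    return large, total_area - large


def _place_batch(
    mode: str,
    area_large: np.ndarray,
    area_small: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial boxes for m pairs, shape (m, 8): larger box cols 0-3, smaller 4-7.

    Column layout per box is (left, right, bottom, top).  Infeasible
    draws are rejected and redrawn up to ``placement_retry_cap`` rounds.
    """
    m = len(area_large)
    L = config.domain_size
    sl = np.sqrt(area_large)
    ss = np.sqrt(area_small)
    if np.any(sl > L) or np.any(ss > L):
        raise PlacementError("daughter range exceeds the domain")
    out = np.empty((m, 8))

    if mode == "sympatric":
        lx = rng.uniform(0.0, 1.0, size=m) * (L - sl)
        ly = rng.uniform(0.0, 1.0, size=m) * (L - sl)
        sx = lx + rng.uniform(0.0, 1.0, size=m) * (sl - ss)
        sy = ly + rng.uniform(0.0, 1.0, size=m) * (sl - ss)
        out[:, 0], out[:, 1], out[:, 2], out[:, 3] = lx, lx + sl, ly, ly + sl
        out[:, 4], out[:, 5], out[:, 6], out[:, 7] = sx, sx + ss, sy, sy + ss
        return out

    if mode in ("vicariant", "parapatric"):
        gap = config.vicariant_gap if mode == "vicariant" else 0.0
        slack = L - sl - gap - ss
        if np.any(slack < 0):
            raise PlacementError(
                f"{mode} placement infeasible: larger side + gap + smaller side "
                f"exceeds the domain ({config})"
            )
        lx = rng.uniform(0.0, 1.0, size=m) * slack
        ly = rng.uniform(0.0, 1.0, size=m) * (L - sl)
        # smaller box: vertical interval must intersect the larger's extent
        pending = np.arange(m)
        sy = np.empty(m)
        for _ in range(config.placement_retry_cap):
            cand = ly[pending] - ss[pending] + rng.uniform(0.0, 1.0, size=len(pending)) * (
                sl[pending] + ss[pending]
            )
            ok = (cand >= 0.0) & (cand <= L - ss[pending])
            sy[pending[ok]] = cand[ok]
            pending = pending[~ok]
            if len(pending) == 0:
                break
        else:
            raise PlacementError(
                f"{mode} vertical placement persistently infeasible ({config})"
            )
        sx = lx + sl + gap
        out[:, 0], out[:, 1], out[:, 2], out[:, 3] = lx, lx + sl, ly, ly + sl
        out[:, 4], out[:, 5], out[:, 6], out[:, 7] = sx, sx + ss, sy, sy + ss
        return out

    if mode == "peripatric":
        pending = np.arange(m)
        for _ in range(config.placement_retry_cap):
            k = len(pending)
            lx = rng.uniform(0.0, 1.0, size=k) * (L - sl[pending])
            ly = rng.uniform(0.0, 1.0, size=k) * (L - sl[pending])
            sx = rng.uniform(0.0, 1.0, size=k) * (L - ss[pending])
            sy = rng.uniform(0.0, 1.0, size=k) * (L - ss[pending])
            ox = np.minimum(lx + sl[pending], sx + ss[pending]) - np.maximum(lx, sx)
            oy = np.minimum(ly + sl[pending], sy + ss[pending]) - np.maximum(ly, sy)
            ok = ~((ox > 0) & (oy > 0))
            rows = pending[ok]
            out[rows, 0], out[rows, 1] = lx[ok], lx[ok] + sl[rows]
            out[rows, 2], out[rows, 3] = ly[ok], ly[ok] + sl[rows]
            out[rows, 4], out[rows, 5] = sx[ok], sx[ok] + ss[rows]
            out[rows, 6], out[rows, 7] = sy[ok], sy[ok] + ss[rows]
            pending = pending[~ok]
            if len(pending) == 0:
                return out
        raise PlacementError(
            f"peripatric non-overlapping placement persistently infeasible ({config})"
        )

    raise ValueError(f"unknown speciation mode {mode!r}")


def place_daughters(
    mode: str,
    area_large: float,
    area_small: float,
    domain_size: float,
    rng: np.random.Generator,
    config: SimConfig | None = None,
) -> tuple[RangeBox, RangeBox]:
    """Place two square daughter ranges on the domain for the given mode."""
    config = config or SimConfig()
    if domain_size != config.domain_size:
        config = replace(config, domain_size=domain_size)
    row = _place_batch(
        mode, np.array([area_large]), np.array([area_small]), config, rng
    )[0]
    return (
        RangeBox(left=row[0], right=row[1], bottom=row[2], top=row[3]),
        RangeBox(left=row[4], right=row[5], bottom=row[6], top=row[7]),
    )


# ---------------------------------------------------------------------------
# movement


def _apply_boundary(b: np.ndarray, L: float, boundary: str) -> np.ndarray:
    if boundary == "clip":
        np.clip(b, 0.0, L, out=b)
    else:  # reflect: fold coordinates back into the domain
        b = np.abs(b)
        b = L - np.abs(L - b)
        np.clip(b, 0.0, L, out=b)  # guard against deviates larger than L
    return b

#: outward sign convention per box column (left, right, bottom, top)
_SIGNS = np.array([-1.0, 1.0, -1.0, 1.0])


def step_move(
    box: RangeBox,
    movement_mean: float,
    movement_sd: float,
    rng: np.random.Generator,
    domain_size: float = 100.0,
    boundary: str = "clip",
) -> RangeBox:
    """Advance one range by one time step of edge movement.

    Four independent N(mean, sd^2) deviates are applied outward (top and
    right increase, bottom and left decrease), then the box is confined
    to the domain.  The returned box may be extinct (``alive`` False).
    """
    d = rng.normal(movement_mean, movement_sd, size=4)
    b = np.array([box.left, box.right, box.bottom, box.top]) + _SIGNS * d
    b = _apply_boundary(b, domain_size, boundary)
    return RangeBox(left=b[0], right=b[1], bottom=b[2], top=b[3])


def _simulate_pairs_batch(
    modes: np.ndarray,
    steps: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Final overlap indices for many independently simulated pairs.

    Pairs losing a daughter to extinction are restarted from the split
    until both daughters survive, up to ``restart_cap`` restarts each.
    """
    N = len(modes)
    boxes = np.empty((N, 8))
    overlaps = np.empty(N)
    restarts = np.zeros(N, dtype=int)
    pending = np.arange(N)
    signs8 = np.concatenate([_SIGNS, _SIGNS])

    while len(pending) > 0:
        over = restarts[pending] > config.restart_cap
        if np.any(over):
            i = pending[over][0]
            raise RestartLimitError(
                f"pair exceeded {config.restart_cap} extinction restarts "
                f"(mode={modes[i]}, steps={steps[i]}, movement_sd={config.movement_sd}, "
                f"movement_mean={config.movement_mean}, "
                f"ancestral_fraction={config.ancestral_fraction})"
            )
        # split and place each pending pair
        for mode in np.unique(modes[pending]):
            rows = pending[modes[pending] == mode]
            f = _split_fractions(mode, len(rows), config, rng)
            area = config.ancestral_area
            boxes[rows] = _place_batch(mode, area * f, area * (1.0 - f), config, rng)

        remaining = steps[pending].copy()
        failed_local = np.zeros(len(pending), dtype=bool)
        active = remaining > 0
        while np.any(active):
            idx = np.flatnonzero(active)
            rows = pending[idx]
            d = rng.normal(config.movement_mean, config.movement_sd, size=(len(rows), 8))
            b = boxes[rows] + signs8 * d
            b = _apply_boundary(b, config.domain_size, config.boundary)
            boxes[rows] = b
            extinct = (
                (b[:, 1] <= b[:, 0])
                | (b[:, 3] <= b[:, 2])
                | (b[:, 5] <= b[:, 4])
                | (b[:, 7] <= b[:, 6])
            )
            failed_local[idx[extinct]] = True
            remaining[idx] -= 1
            active = (remaining > 0) & ~failed_local

        done = pending[~failed_local]
        b = boxes[done]
        inter = np.maximum(
            np.minimum(b[:, 1], b[:, 5]) - np.maximum(b[:, 0], b[:, 4]), 0.0
        ) * np.maximum(np.minimum(b[:, 3], b[:, 7]) - np.maximum(b[:, 2], b[:, 6]), 0.0)
        smaller = np.minimum(
            (b[:, 1] - b[:, 0]) * (b[:, 3] - b[:, 2]),
            (b[:, 5] - b[:, 4]) * (b[:, 7] - b[:, 6]),
        )
        overlaps[done] = np.minimum(inter / smaller, 1.0)
        restarts[pending[failed_local]] += 1
        pending = pending[failed_local]

    return overlaps


def _step_counts(branch_lengths: np.ndarray, config: SimConfig) -> np.ndarray:
    steps = np.rint(np.asarray(branch_lengths, dtype=float) * config.steps_per_branch_unit)
    return np.maximum(steps, 1).astype(int)


def simulate_pair(
    mode: str,
    branch_length: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> float:
    """Simulate one sister pair and return its final overlap index.

    The pair takes round(branch_length x steps_per_branch_unit) movement
    steps (minimum 1); extinction of either daughter restarts the pair
    from the split.
    """
    if branch_length <= 0:
        raise ValueError("branch_length must be positive")
    if mode not in MODES:
        raise ValueError(f"unknown speciation mode {mode!r}")
    steps = _step_counts(np.array([branch_length]), config)
    return float(_simulate_pairs_batch(np.array([mode]), steps, config, rng)[0])


def run_replicate(
    branch_lengths: Sequence[float],
    n_sympatric: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimReplicateResult:
    """Simulate one replicate set of sister pairs under a mode mixture.

    Branch lengths are assigned to pairs by permutation without
    replacement; ``n_sympatric`` pairs speciate sympatrically and the
    remainder under ``config.nonsympatric_geometry``.
    """
    bl = np.asarray(branch_lengths, dtype=float)
    if bl.size == 0:
        raise ValueError("branch_lengths must be non-empty")
    if not 0 <= n_sympatric <= bl.size:
        raise ValueError(f"n_sympatric={n_sympatric} outside 0..{bl.size}")
    bl = rng.permutation(bl)
    modes = np.array(
        ["sympatric"] * n_sympatric
        + [config.nonsympatric_geometry] * (bl.size - n_sympatric)
    )
    overlaps = _simulate_pairs_batch(modes, _step_counts(bl, config), config, rng)
    return SimReplicateResult(overlaps=overlaps, summary=summarize_overlaps(overlaps))


def _run_cell(
    branch_lengths: np.ndarray,
    n_sympatric: int,
    config: SimConfig,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_replicates, 3) array of (z, c, bimodality) for one sweep cell.

    All replicates of the cell are simulated as one flat batch for speed.
    """
    n = branch_lengths.size
    bl = rng.permuted(np.tile(branch_lengths, (n_replicates, 1)), axis=1)
    modes = np.tile(
        np.array(
            ["sympatric"] * n_sympatric
            + [config.nonsympatric_geometry] * (n - n_sympatric)
        ),
        n_replicates,
    )
    overlaps = _simulate_pairs_batch(
        modes, _step_counts(bl.ravel(), config), config, rng
    ).reshape(n_replicates, n)
    out = np.empty((n_replicates, 3))
    for r in range(n_replicates):
        s = summarize_overlaps(overlaps[r])
        out[r] = (s.z, s.c, s.bimodality)
    return out


def default_config_grid(
    ancestral_fractions: Iterable[float] = (0.16,),
    movement_sds: Iterable[float] = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    movement_means: Iterable[float] = (0.0, 0.1),
    geometries: Iterable[str] = ("vicariant", "parapatric", "peripatric"),
    **common,
) -> list[SimConfig]:
    """Cartesian grid of simulation conditions, one SimConfig per cell."""
    grid = []
    for a in ancestral_fractions:
        for sd in movement_sds:
            for mu in movement_means:
                for g in geometries:
                    grid.append(
                        SimConfig(
                            ancestral_fraction=a,
                            movement_sd=sd,
                            movement_mean=mu,
                            nonsympatric_geometry=g,
                            **common,
                        )
                    )
    return grid


def run_sweep(
    branch_lengths: Sequence[float],
    config_grid: Sequence[SimConfig],
    n_sympatric_values: Sequence[int] | None = None,
    n_replicates: int = 1000,
    seed: int | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Simulate index distributions over a parameter grid and mode mixtures.

    Returns a tidy table with one row per replicate per cell: the
    parameter columns, ``n_sympatric`` and the three indices ``z``,
    ``c`` and ``bimodality``.  Deterministic given ``seed``: each cell
    draws from its own child RNG spawned from the seed in grid order.
    """
    bl = np.asarray(branch_lengths, dtype=float)
    if bl.size == 0 or len(config_grid) == 0:
        raise ValueError("branch_lengths and config_grid must be non-empty")
    if n_sympatric_values is None:
        n_sympatric_values = range(bl.size + 1)
    n_sympatric_values = list(n_sympatric_values)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config_grid) * len(n_sympatric_values))
    frames = []
    i = 0
    for config in config_grid:
        for k in n_sympatric_values:
            idx = _run_cell(bl, k, config, n_replicates, np.random.default_rng(children[i]))
            i += 1
            frames.append(
                pd.DataFrame(
                    {
                        "ancestral_fraction": config.ancestral_fraction,
                        "movement_sd": config.movement_sd,
                        "movement_mean": config.movement_mean,
                        "geometry": config.nonsympatric_geometry,
                        "n_sympatric": k,
                        "replicate": np.arange(n_replicates),
                        "z": idx[:, 0].astype(int),
                        "c": idx[:, 1].astype(int),
                        "bimodality": idx[:, 2],
                    }
                )
            )
            if progress is not None:
                progress(
                    f"cell sd={config.movement_sd} mean={config.movement_mean} "
                    f"geom={config.nonsympatric_geometry} "
                    f"frac={config.ancestral_fraction} k={k}: "
                    f"{n_replicates} replicates"
                )
    return pd.concat(frames, ignore_index=True)
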