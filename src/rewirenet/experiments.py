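"""Parameter sweeps over (τ, p_random), aggregation and phase-transition analysis.

A sweep runs the adaptive-rewiring simulator repeatedly over a grid of
rewiring rates and random-rewiring probabilities, evaluates the metric suite
on each final network, and aggregates per-cell means and standard errors.
The modular→centralized transition point τ_transition is the inflection of a
four-parameter logistic fitted to the outlier-proportion-vs-τ curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .graph import WeightedGraph, fiedler_order, normalized_laplacian, spectral_decomposition
from .metrics import (
    NullEnsembleConfig,
    assortativity,
    clustering_coefficient,
    efficiency,
    modularity_spectral,
    outlier_proportion,
    small_worldness,
)
from .rewiring import RewiringConfig, RewiringTrace, run_rewiring

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "run_cell",
    "transition_tau",
    "LogisticFit",
    "metric_correlation",
    "snapshot_figure_data",
    "derive_seed",
]

#: per-run scalar metrics computed by sweeps
SCALAR_METRICS = ("C", "E", "S", "Q", "outlier_proportion", "r")


@dataclass
class SweepSpec:
    """Grid of simulator settings with replicated seeded runs per cell."""

    tau_grid: Sequence[float]
    p_random_grid: Sequence[float] = (0.2,)
    weight_regimes: Sequence[str] = ("normal",)
    runs_per_cell: int = 100
    base_seed: int = 0
    node_count: int = 100
    edge_count: int | None = None
    total_rewirings: int = 4000
    null: NullEnsembleConfig = field(default_factory=lambda: NullEnsembleConfig(n_nulls=30))

    def __post_init__(self) -> None:
        if len(self.tau_grid) == 0 or len(self.p_random_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.runs_per_cell < 1:
            raise ValueError("need at least one run per cell")


@dataclass
class SweepResult:
    """Per-run metric table and per-cell aggregates (mean and s.e.m.)."""

    runs: pd.DataFrame
    aggregates: pd.DataFrame


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-run seed from the base seed and cell/run indices."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def _evaluate_run(g: WeightedGraph, null: NullEnsembleConfig, seed: int) -> dict:
    q, _ = modularity_spectral(g)
    null_run = NullEnsembleConfig(
        n_nulls=null.n_nulls, swaps_per_edge=null.swaps_per_edge, seed=seed
    )
    return {
        "C": clustering_coefficient(g),
        "E": efficiency(g),
        "S": small_worldness(g, null_run),
        "Q": q,
        "outlier_proportion": outlier_proportion(g),
        "r": assortativity(g),
    }


def run_cell(
    spec: SweepSpec, regime: str, tau: float, p_random: float, cell_index: int
) -> pd.DataFrame:
    """All replicate runs of one (regime, τ, p_random) cell."""
    rows = []
    for run_idx in range(spec.runs_per_cell):
        seed = derive_seed(spec.base_seed, cell_index, run_idx)
        config = RewiringConfig(
            node_count=spec.node_count,
            edge_count=spec.edge_count,
            weight_regime=regime,
            tau=tau,
            p_random=p_random,
            total_rewirings=spec.total_rewirings,
            seed=seed,
        )
        g, _ = run_rewiring(config)
        row = {
            "regime": regime,
            "tau": tau,
            "p_random": p_random,
            "run": run_idx,
            "seed": seed,
            "degrees": g.degrees.tolist(),
        }
        try:
            row.update(_evaluate_run(g, spec.null, seed))
        except Exception as exc:  # metric failures recorded, not fatal
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_key(regime: str, tau: float, p_random: float) -> str:
    return f"{regime}_tau{tau:g}_p{p_random:g}"


def run_sweep(spec: SweepSpec, out_dir: str | Path | None = None) -> SweepResult:
    """Execute every cell of the sweep; optionally cache cells to disk.

    With ``out_dir`` set, each cell's per-run table is written to
    ``<out_dir>/<regime>_tau<τ>_p<p>.csv`` and existing cell files are loaded
    instead of recomputed, making sweeps resumable.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    frames = []
    cell_index = 0
    for regime in spec.weight_regimes:
        for p_random in spec.p_random_grid:
            for tau in spec.tau_grid:
                cache = out / f"{_cell_key(regime, tau, p_random)}.csv" if out else None
                if cache is not None and cache.exists():
                    frame = pd.read_csv(cache)
                else:
                    frame = run_cell(spec, regime, tau, p_random, cell_index)
                    if cache is not None:
                        frame.to_csv(cache, index=False)
                frames.append(frame)
                cell_index += 1
    runs = pd.concat(frames, ignore_index=True)
    present = [c for c in SCALAR_METRICS if c in runs.columns]
    grouped = runs.groupby(["regime", "p_random", "tau"])[present]
    agg = grouped.agg(["mean", "sem"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return SweepResult(runs=runs, aggregates=agg.reset_index())


@dataclass
class LogisticFit:
    """Four-parameter logistic fit of a sigmoidal curve."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    residual: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(x, dtype=float), self.floor, self.ceiling, self.midpoint, self.slope)


def _logistic(x, lo, hi, mid, slope):
    return lo + (hi - lo) / (1.0 + np.exp(-slope * (x - mid)))


def transition_tau(
    taus: Sequence[float], proportions: Sequence[float], full: bool = False
) -> float | LogisticFit:
    """Inflection point of the sigmoidal outlier-proportion-vs-τ curve.

    Fits proportion(τ) = lo + (hi−lo)/(1+exp(−slope(τ−mid))) by least squares
    and returns the midpoint, the τ marking the modular→centralized phase
    transition.
    """
    x = np.asarray(taus, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 τ points to locate the inflection")
    if np.ptp(y) < 1e-6:
        raise ValueError("flat curve: no transition to locate")
    order = np.argsort(x)
    x, y = x[order], y[order]
    mid0 = float(x[np.argmin(np.abs(y - (y.min() + np.ptp(y) / 2.0)))])
    span = max(np.ptp(x), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _logistic,
            x,
            y,
            p0=[y.min(), y.max(), mid0, 4.0 / span],
            bounds=([-0.5, -0.5, x.min(), 1e-6], [1.5, 1.5, x.max(), 1e3]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    residual = float(np.sqrt(np.mean((_logistic(x, *popt) - y) ** 2)))
    fit = LogisticFit(*popt, residual)
    return fit if full else float(fit.midpoint)


def metric_correlation(
    result: SweepResult,
    metric_a: str,
    metric_b: str,
    regime: str | None = None,
    p_random: float | None = None,
) -> float:
    """Pearson correlation between per-τ mean values of two metrics.

    Means are taken over replicate runs at each τ (at a fixed p_random),
    matching how the sweep's curves are drawn.
    """
    agg = result.aggregates
    if regime is not None:
        agg = agg[agg["regime"] == regime]
    if p_random is not None:
        agg = agg[np.isclose(agg["p_random"], p_random)]
    if len(agg) < 3:
        raise ValueError("need at least 3 τ points for a correlation")
    a = agg[f"{metric_a}_mean"].to_numpy()
    b = agg[f"{metric_b}_mean"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def snapshot_figure_data(trace: RewiringTrace) -> list[tuple[int, np.ndarray]]:
    """Adjacency snapshots permuted by their own Fiedler ordering for display.

    Sorting rows and columns by the Fiedler vector makes community block
    structure visible in the matrix plot.
    """
    out = []
    for it in sorted(trace.snapshots):
        A = trace.snapshots[it]
        decomp = spectral_decomposition(normalized_laplacian(WeightedGraph(A)))
        perm = fiedler_order(decomp)
        out.append((it, A[np.ix_(perm, perm)]))
    return out
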