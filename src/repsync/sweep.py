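"""Parameter sweeps over (K_m = K_p, γ) with replicate averaging.

Each grid cell runs ``n_reps`` independent simulations from fresh U(0, 1)
initial conditions, measures per-oscillator periods on the first mRNA
species, and aggregates Δp.  The display value is log10 of the cell-mean Δp
(mean first, then log), clamped below at ``log_floor`` because perfectly
synchronized cells have Δp exactly 0 (periods are integer multiples of Δt).

The map shows three regimes: a synchronized band at small γ, an island of
asynchronous behavior at intermediate saturation where the weakest
oscillator is outcompeted for enzyme, and a sharp transition near the γ at
which that oscillator can no longer sustain oscillations on its own.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import build_params
from .periodics import SyncResult, measure_sync
from .simulate import (
    SimConfig,
    SimulationError,
    discard_transient,
    integrate,
    integrate_single_network,
    sample_initial_state,
)

__all__ = [
    "SweepConfig",
    "CellResult",
    "SweepGrid",
    "run_cell",
    "run_grid",
    "classify_coupling",
    "find_gamma_transition",
    "find_asynchronous_island",
    "single_network_failure_gamma",
    "write_sweep",
    "read_sweep",
    "plot_heatmap",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid, replicate count and aggregation policy for a sweep.

    ``undetected_policy``: "exclude" drops replicates with any undetected
    period from the Δp mean (counting them in ``frac_undetected``);
    "penalize" instead assigns such replicates (max_lag·Δt)² per undetected
    pair, a worst-case period mismatch.
    """

    gamma_values: tuple[float, ...]
    kmkp_values: tuple[float, ...]
    n_reps: int = 100
    sim: SimConfig = field(default_factory=SimConfig)
    undetected_policy: str = "exclude"
    log_floor: float = -6.0
    threshold: float = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_values", tuple(float(g) for g in self.gamma_values))
        object.__setattr__(self, "kmkp_values", tuple(float(k) for k in self.kmkp_values))
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        for name, grid in (("gamma_values", self.gamma_values),
                           ("kmkp_values", self.kmkp_values)):
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.undetected_policy not in ("exclude", "penalize"):
            raise ValueError(f"unknown undetected_policy {self.undetected_policy!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_values"] = list(self.gamma_values)
        d["kmkp_values"] = list(self.kmkp_values)
        return d


@dataclass
class CellResult:
    """Aggregated synchronization statistics of one (γ, K_m=K_p) cell."""

    gamma: float
    kmkp: float
    mean_delta_p: float  # NaN if no replicate had a defined Δp
    log10_delta_p: float
    frac_undetected: float
    median_periods: tuple[float, float, float]  # NaN where never detected
    n_reps: int


@dataclass
class SweepGrid:
    """Matrix of :class:`CellResult` indexed by (γ row, K_m=K_p column)."""

    cells: list[list[CellResult]]
    config: SweepConfig
    seed: int

    @property
    def gamma_values(self) -> np.ndarray:
        return np.asarray(self.config.gamma_values)

    @property
    def kmkp_values(self) -> np.ndarray:
        return np.asarray(self.config.kmkp_values)

    def log10_matrix(self) -> np.ndarray:
        """log10 mean Δp, shape (n_gamma, n_kmkp); NaN where undefined."""
        return np.array([[c.log10_delta_p for c in row] for row in self.cells])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for row in self.cells:
            for c in row:
                rows.append({
                    "gamma": c.gamma,
                    "kmkp": c.kmkp,
                    "mean_delta_p": c.mean_delta_p,
                    "log10_delta_p": c.log10_delta_p,
                    "frac_undetected": c.frac_undetected,
                    "n_reps": c.n_reps,
                })
        return pd.DataFrame(rows)


def _replicate_seed(cell_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=cell_seed, spawn_key=(rep,))


def cell_seed_for(master_seed: int, i_gamma: int, i_kmkp: int) -> int:
    """Counter-based per-cell seed: cells are independent and individually
    reproducible regardless of evaluation order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i_gamma, i_kmkp))
    return int(ss.generate_state(1)[0] % 2**31)


def run_cell(gamma: float, kmkp: float, config: SweepConfig,
             cell_seed: int) -> CellResult:
    """Run ``n_reps`` replicates at one grid point and aggregate Δp.

    Each replicate: fresh U(0,1) initial conditions → integrate → discard
    transient → detect the three periods on m_{i,1} → Δp.  Integration
    failures are counted as undetected replicates, not fatal.
    """
    params = build_params(gamma, kmkp, kmkp)
    delta_ps: list[float] = []
    n_undet_reps = 0
    period_lists: list[list[float]] = [[], [], []]
    for rep in range(config.n_reps):
        rng = np.random.default_rng(_replicate_seed(cell_seed, rep))
        initial = sample_initial_state(rng)
        try:
            traj = integrate(params, config.sim, initial=initial)
        except SimulationError:
            n_undet_reps += 1
            continue
        traj = discard_transient(traj, config.sim.t_burn)
        res = measure_sync(traj, threshold=config.threshold)
        for i, est in enumerate(res.periods):
            if est.detected:
                period_lists[i].append(est.period)
        if res.delta_p is not None:
            delta_ps.append(res.delta_p)
        else:
            n_undet_reps += 1
            if config.undetected_policy == "penalize":
                max_lag_time = (len(traj.times) // 2) * traj.dt
                n_bad = res.n_undetected
                n_bad_pairs = 3 - (3 - n_bad) * (2 - n_bad) // 2 if n_bad < 3 else 3
                delta_ps.append(n_bad_pairs * max_lag_time**2)
    if delta_ps:
        mean_dp = float(np.mean(delta_ps))
        log_dp = np.log10(mean_dp) if mean_dp > 0 else config.log_floor
        log_dp = float(max(log_dp, config.log_floor))
    else:
        mean_dp = float("nan")
        log_dp = float("nan")
    med = tuple(float(np.median(pl)) if pl else float("nan") for pl in period_lists)
    return CellResult(
        gamma=float(gamma), kmkp=float(kmkp),
        mean_delta_p=mean_dp, log10_delta_p=log_dp,
        frac_undetected=n_undet_reps / config.n_reps,
        median_periods=med, n_reps=config.n_reps,
    )


def run_grid(config: SweepConfig, seed: int, progress: bool = False) -> SweepGrid:
    """Evaluate :func:`run_cell` at every grid point.

    Per-cell seeds are derived from ``seed`` and the cell's grid indices, so
    the result is identical regardless of evaluation order and each cell can
    be reproduced in isolation.
    """
    cells: list[list[CellResult]] = []
    for ig, gamma in enumerate(config.gamma_values):
        row = []
        for ik, kmkp in enumerate(config.kmkp_values):
            cell = run_cell(gamma, kmkp, config, cell_seed_for(seed, ig, ik))
            row.append(cell)
            if progress:
                print(f"  cell gamma={gamma:.3g} kmkp={kmkp:.3g}: "
                      f"log10(mean dp)={cell.log10_delta_p:.2f} "
                      f"undetected={cell.frac_undetected:.0%}", flush=True)
        cells.append(row)
    return SweepGrid(cells=cells, config=config, seed=seed)


def classify_coupling(result: SyncResult, rel_tol: float = 0.02) -> str:
    """Label period synchronization: fully / partially coupled or uncoupled.

    Two oscillators count as matched when their relative period difference
    |τ_i − τ_j| / mean(τ_i, τ_j) is within ``rel_tol``.  Fully coupled means
    all three pairs match; partially coupled exactly one pair; with fewer
    than two detected periods the label is "indeterminate".
    """
    detected = [e.period for e in result.periods if e.detected]
    if len(detected) < 2:
        return "indeterminate"
    n_match = 0
    n_pairs = 0
    for a in range(len(detected)):
        for b in range(a + 1, len(detected)):
            n_pairs += 1
            ta, tb = detected[a], detected[b]
            if abs(ta - tb) / (0.5 * (ta + tb)) <= rel_tol:
                n_match += 1
    if n_pairs == 3 and n_match == 3:
        return "fully_coupled"
    if n_match == 1:
        return "partially_coupled"
    return "uncoupled"


def find_gamma_transition(grid: SweepGrid, kmkp: float) -> float:
    """γ at the sharp synchronization transition along one K_m=K_p column.

    Returns the midpoint of the adjacent γ pair with the largest absolute
    jump in log10 mean Δp; cells with undefined Δp are skipped when forming
    adjacent pairs.
    """
    cols = grid.kmkp_values
    match = np.flatnonzero(np.isclose(cols, kmkp, rtol=1e-9, atol=0.0))
    if len(match) == 0:
        raise ValueError(f"kmkp={kmkp} is not a column of the grid ({cols})")
    ik = int(match[0])
    gammas = grid.gamma_values
    logs = grid.log10_matrix()[:, ik]
    finite = np.isfinite(logs)
    g = gammas[finite]
    v = logs[finite]
    if len(v) < 2:
        raise ValueError("not enough defined cells along the column")
    jumps = np.abs(np.diff(v))
    j = int(np.argmax(jumps))
    return float(0.5 * (g[j] + g[j + 1]))


def find_asynchronous_island(grid: SweepGrid, min_contrast: float = 1.0
                             ) -> list[tuple[float, float]]:
    """Locate the asynchronous island: a contiguous interior cell cluster
    whose log10 mean Δp exceeds every cell of its surrounding ring by at
    least ``min_contrast``.

    Candidate clusters are 4-connected components of super-threshold cells,
    scanned over all observed levels from high to low; clusters touching the
    grid boundary are excluded (their ring would be incomplete).  Returns
    the (γ, K_m=K_p) coordinates of the largest qualifying cluster, or an
    empty list if none exists.
    """
    L = grid.log10_matrix()
    n_g, n_k = L.shape
    work = np.where(np.isfinite(L), L, -np.inf)
    best: list[tuple[int, int]] = []
    for level in sorted(set(work[np.isfinite(work)].ravel()), reverse=True):
        mask = work >= level
        for comp in _components(mask):
            if any(i in (0, n_g - 1) or j in (0, n_k - 1) for i, j in comp):
                continue
            ring = _ring(comp, n_g, n_k)
            if not ring:
                continue
            inner_min = min(work[i, j] for i, j in comp)
            outer_max = max(work[i, j] for i, j in ring)
            if inner_min >= outer_max + min_contrast and len(comp) > len(best):
                best = comp
    return [(float(grid.gamma_values[i]), float(grid.kmkp_values[j]))
            for i, j in sorted(best)]


def _components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """4-connected components of a boolean grid (plain BFS)."""
    n_g, n_k = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(n_g):
        for j in range(n_k):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            comp = []
            while stack:
                a, b = stack.pop()
                comp.append((a, b))
                for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    na, nb = a + da, b + db
                    if 0 <= na < n_g and 0 <= nb < n_k and mask[na, nb] and not seen[na, nb]:
                        seen[na, nb] = True
                        stack.append((na, nb))
            comps.append(comp)
    return comps


def _ring(comp: list[tuple[int, int]], n_g: int, n_k: int) -> list[tuple[int, int]]:
    """All grid cells 8-adjacent to the component but not in it."""
    comp_set = set(comp)
    ring = set()
    for i, j in comp:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if (ni, nj) not in comp_set and 0 <= ni < n_g and 0 <= nj < n_k:
                    ring.add((ni, nj))
    return sorted(ring)


def single_network_failure_gamma(
    gammas: Sequence[float],
    kmkp: float,
    sim: SimConfig,
    n_reps: int = 3,
    seed: int = 0,
    threshold: float = 0.7,
    alpha2: float = 6.0,
    mode: str = "shared_load",
) -> Optional[float]:
    """Smallest γ at which the weakest repressilator (α = α₂−γ) fails period
    detection in every replicate, probing the mechanism behind the sharp
    synchronization transition: beyond it that oscillator cannot sustain
    oscillations on its own and is instead driven by the rest of the system.

    ``mode="shared_load"`` (default) replicates the weak oscillator three-fold
    (all activation rates set to α₂−γ in the coupled system), which preserves
    the total enzymatic load it experiences inside the full system — the
    per-capita degradation rate ``k/(K + Σ)`` is set by all nine species, so
    stripping the other networks away would triple it and kill oscillations
    far too early.  ``mode="isolated"`` does exactly that stripping (one
    network, saturation sums over its own species only) and is provided for
    comparison.

    Returns None if the oscillator survives the whole scan.
    """
    from .periodics import autocorrelation_of, detect_period

    if mode not in ("shared_load", "isolated"):
        raise ValueError(f"unknown mode {mode!r}")
    for ig, gamma in enumerate(sorted(gammas)):
        alpha = alpha2 - gamma
        if alpha <= 0:
            return float(gamma)
        any_detected = False
        for rep in range(n_reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ig, rep))
            rng = np.random.default_rng(ss)
            if mode == "shared_load":
                from .core_model import CoupledParams

                params = CoupledParams(alphas=(alpha,) * 3, km=kmkp, kp=kmkp)
                traj = integrate(params, sim, initial=rng.uniform(0, 1, size=18))
            else:
                traj = integrate_single_network(alpha, kmkp, kmkp, sim,
                                                initial=rng.uniform(0, 1, size=6))
            traj = discard_transient(traj, sim.t_burn)
            x = traj.states[:, 0]
            if np.ptp(x) < 1e-9:
                continue
            try:
                est = detect_period(autocorrelation_of(x, traj.dt),
                                    threshold=threshold)
            except ValueError:
                continue
            if est.detected:
                any_detected = True
                break
        if not any_detected:
            return float(gamma)
    return None


# ---------------------------------------------------------------------------
# persistence and plotting

def write_sweep(grid: SweepGrid, csv_path: Union[str, Path]) -> None:
    """Long-format CSV plus a JSON sidecar holding the config and seed."""
    csv_path = Path(csv_path)
    grid.to_dataframe().to_csv(csv_path, index=False)
    sidecar = {"config": grid.config.to_dict(), "seed": grid.seed}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sweep(csv_path: Union[str, Path]) -> SweepGrid:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    cfg_d = meta["config"]
    cfg = SweepConfig(
        gamma_values=tuple(cfg_d["gamma_values"]),
        kmkp_values=tuple(cfg_d["kmkp_values"]),
        n_reps=cfg_d["n_reps"],
        sim=SimConfig(**cfg_d["sim"]),
        undetected_policy=cfg_d["undetected_policy"],
        log_floor=cfg_d["log_floor"],
        threshold=cfg_d["threshold"],
    )
    df = pd.read_csv(csv_path)
    cells = []
    for gamma in cfg.gamma_values:
        row = []
        for kmkp in cfg.kmkp_values:
            r = df[(np.isclose(df.gamma, gamma)) & (np.isclose(df.kmkp, kmkp))].iloc[0]
            row.append(CellResult(
                gamma=float(gamma), kmkp=float(kmkp),
                mean_delta_p=float(r.mean_delta_p),
                log10_delta_p=float(r.log10_delta_p),
                frac_undetected=float(r.frac_undetected),
                median_periods=(float("nan"),) * 3,
                n_reps=int(r.n_reps),
            ))
        cells.append(row)
    return SweepGrid(cells=cells, config=cfg, seed=meta["seed"])


def plot_heatmap(grid: SweepGrid, path: Union[str, Path],
                 title: str = "Synchronization map") -> None:
    """Heatmap of log10 mean Δp: γ vertical, K_m=K_p horizontal (log scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = grid.log10_matrix()
    k = grid.kmkp_values
    g = grid.gamma_values
    fig, ax = plt.subplots(figsize=(7, 5))
    mesh = ax.pcolormesh(k, g, L, shading="nearest", cmap="viridis")
    ax.set_xscale("log")
    ax.set_xlabel(r"$K_m = K_p$")
    ax.set_ylabel(r"$\gamma$")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label=r"$\log_{10}\,\overline{\Delta p}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
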