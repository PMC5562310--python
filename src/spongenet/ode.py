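"""Predator-prey competition model of miRNA sponging.

Two miRNA species X, Y ("predators", concentrations x, y) compete for up to
two mRNA targets A, B ("preys", concentrations a, b).  All four species are
produced at a shared constant rate ``rho``; a predator-prey encounter removes
one molecule of each at a mass-action rate ``alpha``:

    dx/dt = rho - a11*x*a - a12*x*b
    dy/dt = rho - a21*y*a - a22*y*b
    da/dt = rho - a11*x*a - a21*y*a
    db/dt = rho - a12*x*b - a22*y*b

Three scenarios probe when the two predators' concentrations are linearly
correlated (hence connected in a 2-node correlation network at the usual 0.8
threshold): S1 — one shared prey, equal rates; S2 — one shared prey, unequal
rates; S3 — a second prey (the "sponge") with very different affinities for
the two predators.  The parameter values are illustrative only, not fitted
to any measurement.

Two correlation readouts are provided, because how a single deterministic
trajectory pair maps onto a patient-population correlation is genuinely
ambiguous: ``trajectory_correlation`` correlates x(t) with y(t) along one
solved trajectory, and ``ensemble_correlation`` correlates endpoint x with
endpoint y across replicate systems with jittered initial concentrations
(each replicate standing for one subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import new_network

__all__ = [
    "ScenarioSpec",
    "TrajectorySet",
    "simulate",
    "scenario_library",
    "trajectory_correlation",
    "scenario_network",
    "ensemble_correlation",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One parameterization of the competition model."""

    rho: float = 0.002
    alpha: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 0.0), (0.5, 0.0))
    x0: float = 0.25
    y0: float = 0.35
    a0: float = 0.3
    b0: float = 0.2
    t_end: float = 1000.0
    n_out: int = 1001
    label: str = ""

    def __post_init__(self) -> None:
        rates = [self.rho, *self.alpha[0], *self.alpha[1]]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if any(c < 0 for c in (self.x0, self.y0, self.a0, self.b0)):
            raise ValueError("initial concentrations must be non-negative")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if self.n_out < 2:
            raise ValueError("n_out must be >= 2")

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.a0, self.b0])


@dataclass
class TrajectorySet:
    """Solved concentration time courses on a uniform grid."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    a: np.ndarray
    b: np.ndarray
    spec: ScenarioSpec | None = field(default=None, repr=False)

    def series(self) -> dict[str, np.ndarray]:
        return {"x": self.x, "y": self.y, "a": self.a, "b": self.b}


def _rhs(t: float, state: np.ndarray, rho: float, alpha) -> list[float]:
    x, y, a, b = state
    (a11, a12), (a21, a22) = alpha
    return [
        rho - a11 * x * a - a12 * x * b,
        rho - a21 * y * a - a22 * y * b,
        rho - a11 * x * a - a21 * y * a,
        rho - a12 * x * b - a22 * y * b,
    ]


def simulate(
    spec: ScenarioSpec, rtol: float = 1e-8, atol: float = 1e-10
) -> TrajectorySet:
    """Integrate the model with an adaptive stiff-capable solver (LSODA).

    The model is positivity-preserving (every loss term vanishes at zero and
    production is non-negative), so concentrations undershooting below
    ``-100*atol`` indicate integrator failure and raise; smaller undershoots
    are clipped to zero.
    """
    grid = np.linspace(0.0, spec.t_end, spec.n_out)
    sol = solve_ivp(
        _rhs,
        (0.0, spec.t_end),
        spec.initial_state,
        args=(spec.rho, spec.alpha),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=grid,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed for {spec.label or spec}: {sol.message}")
    y = sol.y
    if y.min() < -100 * atol:
        raise RuntimeError(
            f"negative concentration {y.min():.3g} in {spec.label or 'scenario'}"
        )
    y = np.clip(y, 0.0, None)
    return TrajectorySet(time=grid, x=y[0], y=y[1], a=y[2], b=y[3], spec=spec)


def scenario_library() -> dict[str, ScenarioSpec]:
    """The three illustrative competition scenarios.

    S1: two predators, one prey, equal rates (0.5 / 0.5).
    S2: two predators, one prey, unequal rates (0.75 / 0.25).
    S3: two preys; shared high affinity for A (0.9), very different
        affinities for the sponge B (0.5 vs 0.1).
    One-prey scenarios keep the single 4-state integrator by setting ``b0=0``
    with zero B-column rates.
    """
    return {
        "S1": ScenarioSpec(alpha=((0.5, 0.0), (0.5, 0.0)), b0=0.0, label="S1"),
        "S2": ScenarioSpec(alpha=((0.75, 0.0), (0.25, 0.0)), b0=0.0, label="S2"),
        "S3": ScenarioSpec(alpha=((0.9, 0.5), (0.9, 0.1)), b0=0.2, label="S3"),
    }


def trajectory_correlation(
    traj: TrajectorySet, window: tuple[float, float] | None = None
) -> float:
    """Pearson r between the two predator series over the (optional) window."""
    mask = np.ones_like(traj.time, dtype=bool)
    if window is not None:
        lo, hi = window
        mask = (traj.time >= lo) & (traj.time <= hi)
        if mask.sum() < 3:
            raise ValueError("window contains fewer than 3 grid points")
    x, y = traj.x[mask], traj.y[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant predator series; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def ensemble_correlation(
    spec: ScenarioSpec,
    n_reps: int = 200,
    perturb_sd: float = 0.2,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Endpoint correlation across replicate systems.

    Each replicate multiplies every non-zero initial concentration by an
    independent log-normal factor ``exp(perturb_sd * N(0,1))`` and is
    integrated to ``t_end``; the returned value is the Pearson r between the
    replicate endpoint x and endpoint y values.
    """
    if perturb_sd <= 0:
        raise ValueError("perturb_sd must be positive (zero variance otherwise)")
    if n_reps < 3:
        raise ValueError("need at least 3 replicates")
    rng = np.random.default_rng(seed)
    base = spec.initial_state
    xs = np.empty(n_reps)
    ys = np.empty(n_reps)
    for i in range(n_reps):
        jitter = np.exp(perturb_sd * rng.standard_normal(4))
        state0 = base * jitter
        sol = solve_ivp(
            _rhs,
            (0.0, spec.t_end),
            state0,
            args=(spec.rho, spec.alpha),
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=[spec.t_end],
        )
        if not sol.success:
            raise RuntimeError(f"replicate {i} failed: {sol.message}")
        xs[i], ys[i] = sol.y[0, -1], sol.y[1, -1]
    return float(np.corrcoef(xs, ys)[0, 1])


def scenario_network(
    spec: ScenarioSpec,
    threshold: float = 0.8,
    mode: str = "timeseries",
    **mode_kwargs,
):
    """2-node network on {X, Y}: edge iff the chosen correlation readout
    meets the threshold (default 0.8, the correlation-method threshold)."""
    if mode == "timeseries":
        r = trajectory_correlation(simulate(spec), **mode_kwargs)
    elif mode == "ensemble":
        r = ensemble_correlation(spec, **mode_kwargs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    g = new_network(["X", "Y"], "correlation")
    g.graph["scenario"] = spec.label
    g.graph["r"] = r
    if r >= threshold:
        g.add_edge("X", "Y", r=r)
    return g
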