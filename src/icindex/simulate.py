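"""Stochastic GRN simulator of a cell-fate bifurcation.

The model is the canonical two-master circuit of binary lineage choice: two
mutually inhibiting, self-activating regulators (x, y) with Hill kinetics,
driven by a slowly decreasing bifurcation parameter μ that scales the
self-activation/decay balance.  At high μ a single symmetric (progenitor)
attractor exists; as μ falls the symmetric state destabilizes through a
pitchfork and two asymmetric lineage attractors appear.  A small additive
production bias on x tilts the pitchfork (the instructive signal), making one
branch "intended"; molecular noise can still push a minority of cells into the
other branch — the rebellious cells.  The remaining genes are linear noisy
readouts of (x, y), so snapshots have realistic dimensionality.

Cells are integrated independently by Euler–Maruyama with a reflecting
boundary at 0, each from its own counter-based noise stream, so ensembles are
reproducible from a seed and per-cell trajectories do not depend on how many
cells are simulated.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .io import ExpressionMatrix

LABELS = ("progenitor", "intended", "rebellious", "undecided")


@dataclass
class DownstreamGene:
    """Linear stochastic readout dz = decay·(basal + w_x·x + w_y·y − z)dt + σdW."""

    name: str
    basal: float
    w_x: float
    w_y: float
    decay: float = 2.0


@dataclass
class GrnModel:
    """Two-master mutual-inhibition/self-activation circuit plus readouts.

    dx/dt = μ·a·x^h/(S^h + x^h) + b·S^h/(S^h + y^h) + bias − k·x
    dy/dt = μ·a·y^h/(S^h + y^h) + b·S^h/(S^h + x^h)        − k·y

    ``a`` self-activation strength, ``b`` cross-inhibition strength, ``k``
    decay, ``S`` Hill threshold, ``h`` Hill exponent, ``bias ≥ 0`` the
    imperfection term on x (the instructed lineage), ``noise_sigma`` the
    additive noise scale shared by all genes.
    """

    a: float = 1.0
    b: float = 1.0
    k: float = 1.0
    S: float = 0.5
    h: float = 4.0
    bias: float = 0.0
    noise_sigma: float = 0.05
    downstream: list[DownstreamGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, val in (("a", self.a), ("b", self.b), ("k", self.k), ("S", self.S)):
            if val <= 0:
                raise ValueError(f"rate {name} must be > 0, got {val}")
        if self.h < 1:
            raise ValueError("Hill exponent h must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def gene_names(self) -> list[str]:
        return ["master_x", "master_y"] + [g.name for g in self.downstream]

    @property
    def n_genes(self) -> int:
        return 2 + len(self.downstream)

    # --- deterministic part -------------------------------------------------

    def _hill_act(self, u: np.ndarray) -> np.ndarray:
        uh = np.power(np.maximum(u, 0.0), self.h)
        return uh / (self.S ** self.h + uh)

    def _hill_inh(self, u: np.ndarray) -> np.ndarray:
        uh = np.power(np.maximum(u, 0.0), self.h)
        return self.S ** self.h / (self.S ** self.h + uh)

    def drift_masters(self, xy: np.ndarray, mu: float) -> np.ndarray:
        """Deterministic drift of the (x, y) master subsystem; xy is (..., 2)."""
        x, y = xy[..., 0], xy[..., 1]
        dx = mu * self.a * self._hill_act(x) + self.b * self._hill_inh(y) \
            + self.bias - self.k * x
        dy = mu * self.a * self._hill_act(y) + self.b * self._hill_inh(x) \
            - self.k * y
        return np.stack([dx, dy], axis=-1)

    def drift(self, state: np.ndarray, mu: float) -> np.ndarray:
        """Full m-dimensional drift; state is (..., m)."""
        out = np.empty_like(state)
        out[..., :2] = self.drift_masters(state[..., :2], mu)
        x, y = state[..., 0], state[..., 1]
        for j, g in enumerate(self.downstream):
            target = g.basal + g.w_x * x + g.w_y * y
            out[..., 2 + j] = g.decay * (target - state[..., 2 + j])
        return out

    def slaved_state(self, xy: np.ndarray) -> np.ndarray:
        """Full state with downstream genes at their conditional fixed points."""
        xy = np.asarray(xy, dtype=float)
        full = np.empty(xy.shape[:-1] + (self.n_genes,))
        full[..., :2] = xy
        for j, g in enumerate(self.downstream):
            full[..., 2 + j] = g.basal + g.w_x * xy[..., 0] + g.w_y * xy[..., 1]
        return full


# --- fixed points and stability ---------------------------------------------


def master_jacobian(model: GrnModel, xy, mu: float, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference 2×2 Jacobian of the master subsystem."""
    xy = np.asarray(xy, dtype=float)
    jac = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = eps
        jac[:, j] = (model.drift_masters(xy + step, mu)
                     - model.drift_masters(xy - step, mu)) / (2 * eps)
    return jac


def full_jacobian(model: GrnModel, state, mu: float, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference m×m Jacobian of the full system."""
    state = np.asarray(state, dtype=float)
    m = state.size
    jac = np.empty((m, m))
    for j in range(m):
        step = np.zeros(m)
        step[j] = eps
        jac[:, j] = (model.drift(state + step, mu)
                     - model.drift(state - step, mu)) / (2 * eps)
    return jac


class FixedPoint(NamedTuple):
    xy: np.ndarray
    stable: bool
    leading_eig: float  # largest real part of the master Jacobian spectrum


def find_fixed_points(model: GrnModel, mu: float,
                      tol: float = 1e-9) -> list[FixedPoint]:
    """All fixed points of the master subsystem, by multi-start root finding."""
    guesses = []
    grid = [0.02, 0.2, 0.5, 0.8, 1.2, 1.8, 2.5]
    for gx in grid:
        for gy in grid:
            guesses.append((gx, gy))
    found: list[FixedPoint] = []
    for guess in guesses:
        sol = optimize.root(lambda v: model.drift_masters(np.asarray(v), mu),
                            np.asarray(guess, dtype=float), tol=tol)
        if not sol.success:
            continue
        pt = np.maximum(sol.x, 0.0)
        if np.linalg.norm(model.drift_masters(pt, mu)) > 1e-6:
            continue
        if any(np.linalg.norm(pt - f.xy) < 1e-4 for f in found):
            continue
        eigs = np.linalg.eigvals(master_jacobian(model, pt, mu))
        lead = float(np.max(eigs.real))
        found.append(FixedPoint(xy=pt, stable=lead < 0, leading_eig=lead))
    return sorted(found, key=lambda f: (f.xy[0], f.xy[1]))


def stable_fixed_points(model: GrnModel, mu: float) -> list[FixedPoint]:
    pts = [f for f in find_fixed_points(model, mu) if f.stable]
    if not pts:
        raise RuntimeError(f"no stable fixed point at mu={mu}: invalid model/mu")
    return pts


def progenitor_fixed_point(model: GrnModel, mu: float) -> FixedPoint:
    """The most symmetric stable fixed point (minimal |x − y|).

    Roots that are symmetric up to root-finder tolerance are snapped onto the
    invariant line x = y exactly, so noise-free integration preserves the
    symmetry bitwise.
    """
    pts = stable_fixed_points(model, mu)
    best = min(pts, key=lambda f: abs(f.xy[0] - f.xy[1]))
    if model.bias == 0 and abs(best.xy[0] - best.xy[1]) < 1e-6:
        mid = 0.5 * (best.xy[0] + best.xy[1])
        best = FixedPoint(xy=np.array([mid, mid]), stable=best.stable,
                          leading_eig=best.leading_eig)
    return best


def classify_attractor(state, model: GrnModel, mu: float,
                       capture_fraction: float = 0.25,
                       fixed_points: list[FixedPoint] | None = None) -> str:
    """Label a cell state by the nearest stable attractor in the (x, y) plane.

    The capture radius is ``capture_fraction`` of the smallest inter-attractor
    distance (or of 1 + |fp| when only one attractor exists); states outside
    every radius are ``undecided``.  Post-bifurcation, the x-branch (x > y) is
    ``intended`` when bias ≥ 0 and the other branch is ``rebellious``; a
    symmetric attractor is the ``progenitor``.
    """
    state = np.asarray(state, dtype=float)
    xy = state[:2]
    fps = fixed_points if fixed_points is not None else stable_fixed_points(model, mu)
    if len(fps) > 1:
        dists = [np.linalg.norm(f.xy - g.xy) for i, f in enumerate(fps)
                 for g in fps[i + 1:]]
        radius = capture_fraction * min(dists)
    else:
        radius = capture_fraction * (1.0 + float(np.linalg.norm(fps[0].xy)))
    nearest = min(fps, key=lambda f: np.linalg.norm(xy - f.xy))
    if np.linalg.norm(xy - nearest.xy) > radius:
        return "undecided"
    dx = nearest.xy[0] - nearest.xy[1]
    sym_scale = 0.2 * (1.0 + abs(nearest.xy).sum())
    if abs(dx) < sym_scale:
        return "progenitor"
    # bias >= 0 instructs the x-branch; ties at bias == 0 default to x.
    intended_is_x = model.bias >= 0
    if (dx > 0) == intended_is_x:
        return "intended"
    return "rebellious"


# --- ensemble simulation -----------------------------------------------------


@dataclass
class Snapshot:
    """One sampling time: expression matrix plus attractor annotation."""

    time_label: str
    mu: float
    expression: ExpressionMatrix
    labels: pd.Series  # per-cell attractor label
    raw_state: np.ndarray  # n_cells x m concentrations (pre log transform)


@dataclass
class SimulationEnsemble:
    """Simulated snapshot ensemble with full provenance."""

    snapshots: list[Snapshot]
    seed: int
    dt: float
    t_segment: float
    model: GrnModel

    def to_expression_matrix(self) -> ExpressionMatrix:
        """Concatenate all snapshots into one ExpressionMatrix."""
        values = pd.concat([s.expression.values for s in self.snapshots])
        meta = pd.concat([s.expression.cell_meta for s in self.snapshots])
        roles = self.snapshots[0].expression.gene_roles
        return ExpressionMatrix(values=values, cell_meta=meta, gene_roles=roles)


def _cell_noise_streams(seed: int, n_cells: int) -> list[np.random.Generator]:
    return [np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            for i in range(n_cells)]


def simulate_ensemble(model: GrnModel, n_cells: int, mu_schedule, seed: int = 0,
                      *, dt: float = 0.01, t_segment: float = 15.0,
                      expression_scale: float = 20.0,
                      capture_fraction: float = 0.25) -> SimulationEnsemble:
    """Integrate an ensemble of cells through a piecewise-constant μ ramp.

    ``mu_schedule`` is a sequence of (time_label, mu), monotone in μ; each
    segment holds μ for ``t_segment`` time units and a snapshot is taken at
    its end.  All cells start at the first segment's progenitor fixed point.
    Expression is reported as log2(1 + expression_scale · concentration).
    """
    if n_cells < 10:
        raise ValueError(f"n_cells must be >= 10, got {n_cells}")
    schedule = [(str(t), float(m)) for t, m in mu_schedule]
    mus = [m for _, m in schedule]
    diffs = np.diff(mus)
    if not (np.all(diffs <= 0) or np.all(diffs >= 0)):
        raise ValueError("mu_schedule must be monotone in mu")

    m = model.n_genes
    start = progenitor_fixed_point(model, schedule[0][1])
    state = np.tile(model.slaved_state(start.xy), (n_cells, 1))
    rngs = _cell_noise_streams(seed, n_cells)
    n_steps = int(round(t_segment / dt))
    sqrt_dt = math.sqrt(dt)

    snapshots: list[Snapshot] = []
    for seg_idx, (label, mu) in enumerate(schedule):
        # per-cell noise for this whole segment, one stream per cell
        if model.noise_sigma > 0:
            noise = np.stack([rng.standard_normal((n_steps, m)) for rng in rngs],
                             axis=1)  # (steps, cells, m)
        else:
            noise = None
        for step in range(n_steps):
            state += model.drift(state, mu) * dt
            if noise is not None:
                state += model.noise_sigma * sqrt_dt * noise[step]
            np.abs(state, out=state)  # reflecting boundary at 0
            if not np.all(np.isfinite(state)):
                raise RuntimeError(
                    f"integration blow-up in segment '{label}'; dt={dt} too large?")
        fps = stable_fixed_points(model, mu)
        labels = pd.Series(
            [classify_attractor(state[i], model, mu, capture_fraction, fps)
             for i in range(n_cells)],
            index=[f"{label}_c{i:04d}" for i in range(n_cells)], name="attractor")
        expr = np.log2(1.0 + expression_scale * state)
        values = pd.DataFrame(expr, index=labels.index, columns=model.gene_names)
        meta = pd.DataFrame({"time_point": label, "treatment": "sim",
                             "fraction": labels.to_numpy()}, index=labels.index)
        roles = pd.Series("target", index=model.gene_names)
        snapshots.append(Snapshot(
            time_label=label, mu=mu,
            expression=ExpressionMatrix(values=values, cell_meta=meta,
                                        gene_roles=roles),
            labels=labels, raw_state=state.copy()))
    return SimulationEnsemble(snapshots=snapshots, seed=int(seed), dt=dt,
                              t_segment=t_segment, model=model)


# --- relaxation (critical slowing down) --------------------------------------


class RelaxationResult(NamedTuple):
    time: float
    censored: bool


def relaxation_time(model: GrnModel, mu: float, perturbation, threshold: float,
                    seed: int | None = None, *, n_cells: int = 1,
                    dt: float = 0.01, max_time: float = 500.0) -> RelaxationResult:
    """Time for a displaced cell cloud to relax back to the progenitor state.

    Cells start at the progenitor fixed point plus ``perturbation`` (an
    m-vector, the "sorted outlier" displacement) and are integrated (with
    noise if the model has any and a seed is given) until the ensemble median
    displacement falls below ``threshold`` × the initial displacement.
    Non-convergence within ``max_time`` is reported as right-censored.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    fp_full = model.slaved_state(progenitor_fixed_point(model, mu).xy)
    perturbation = np.asarray(perturbation, dtype=float)
    if perturbation.shape != fp_full.shape:
        raise ValueError(f"perturbation must be an m-vector of length {fp_full.size}")
    state = np.tile(fp_full + perturbation, (n_cells, 1))
    d0 = float(np.median(np.linalg.norm(state - fp_full, axis=1)))
    if threshold >= 1 or d0 == 0:
        return RelaxationResult(time=0.0, censored=False)
    use_noise = model.noise_sigma > 0 and seed is not None
    rngs = _cell_noise_streams(seed, n_cells) if use_noise else None
    sqrt_dt = math.sqrt(dt)
    t = 0.0
    while t < max_time:
        state += model.drift(state, mu) * dt
        if use_noise:
            state += model.noise_sigma * sqrt_dt * np.stack(
                [rng.standard_normal(fp_full.size) for rng in rngs])
        np.abs(state, out=state)
        t += dt
        d = float(np.median(np.linalg.norm(state - fp_full, axis=1)))
        if d <= threshold * d0:
            return RelaxationResult(time=t, censored=False)
    return RelaxationResult(time=max_time, censored=True)


def predicted_relaxation_time(model: GrnModel, mu: float, threshold: float) -> float:
    """Linearization prediction log(1/threshold)/|Re λ_max| at the progenitor."""
    fp_full = model.slaved_state(progenitor_fixed_point(model, mu).xy)
    eigs = np.linalg.eigvals(full_jacobian(model, fp_full, mu))
    lam = float(np.max(eigs.real))
    if lam >= 0:
        raise ValueError(f"progenitor state not attracting at mu={mu}")
    return math.log(1.0 / threshold) / abs(lam)


def slow_eigenvector(model: GrnModel, mu: float) -> np.ndarray:
    """Unit eigenvector of the slowest (least negative) mode at the progenitor."""
    fp_full = model.slaved_state(progenitor_fixed_point(model, mu).xy)
    eigvals, eigvecs = np.linalg.eig(full_jacobian(model, fp_full, mu))
    idx = int(np.argmax(eigvals.real))
    v = np.real(eigvecs[:, idx])
    return v / np.linalg.norm(v)


# --- pinned default scenario --------------------------------------------------


def load_scenario(path: str | Path) -> dict:
    """Load a scenario configuration (model + simulation keys) from YAML."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_from_config(cfg: dict) -> GrnModel:
    mc = dict(cfg["model"])
    downstream = [DownstreamGene(**d) for d in mc.pop("downstream", [])]
    return GrnModel(downstream=downstream, **mc)


def default_scenario_config() -> dict:
    """The pinned desk-scale study design shipped with the package."""
    ref = importlib.resources.files("icindex").joinpath("data/default_scenario.yaml")
    return yaml.safe_load(ref.read_text())


def simulate_from_config(cfg: dict, seed: int) -> SimulationEnsemble:
    model = model_from_config(cfg)
    sim = cfg["simulation"]
    return simulate_ensemble(
        model, n_cells=int(sim["n_cells"]),
        mu_schedule=[(s["time"], s["mu"]) for s in sim["schedule"]],
        seed=seed, dt=float(sim["dt"]), t_segment=float(sim["t_segment"]),
        expression_scale=float(sim["expression_scale"]),
        capture_fraction=float(sim["capture_fraction"]))


def default_scenario(seed: int = 1) -> SimulationEnsemble:
    """Simulate the pinned default scenario (500 cells × 12 genes, 4 snapshots).

    The design straddles the pitchfork: two pre-transition samplings, one just
    above the critical μ, one past it, with a mild instructive bias — the full
    early-warning phenomenology (falling cell–cell R, rising |gene–gene R|,
    peaking I_C, rebellious minority) at desk scale.
    """
    return simulate_from_config(default_scenario_config(), seed)
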