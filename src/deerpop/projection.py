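"""Monte-Carlo projection of the stage matrix under environmental
uncertainty in survival.

Each scenario fixes the fecundities and gives every stage a survival
interval — the 95% confidence limits of the field estimate.  For every
annual time step of a replicate the three survivals are redrawn
independently from uniform distributions on those intervals (all values
inside the CI treated as equally likely), the matrix is reassembled, and
the abundance vector is multiplied through.  Abundances stay continuous:
only parameter (environmental) stochasticity is modelled, not demographic
noise.

A replicate's growth rate is the realized geometric mean
``λ_rep = (N_T / N_0)^(1/T)`` of total abundance (the mean of the drawn
matrices' dominant eigenvalues is available as an alternative definition).
Scenario summaries average λ_rep over replicates, report its 25th–75th
percentile range and the fraction of replicates with λ_rep > 1, and average
the sensitivity and elasticity of every drawn annual matrix.

Seeding uses ``numpy.random.SeedSequence`` spawning: one master seed yields
an independent substream per replicate, so results do not depend on
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import STRUCTURAL_ENTRIES, assemble, dominant_eigen

Bounds = tuple[float, float]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named projection scenario: survival draw intervals, fixed
    fecundities, and the replication design."""

    name: str
    S_f_bounds: Bounds
    S_y_bounds: Bounds
    S_a_bounds: Bounds
    F_y: float
    F_a: float
    harvest_rate: float = 0.0  # metadata: already folded into bounds/fecundities
    years: int = 10
    replicates: int = 1000
    initial: tuple[float, float, float] = (192.0, 32.0, 276.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("S_f", self.S_f_bounds), ("S_y", self.S_y_bounds), ("S_a", self.S_a_bounds)
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{label} bounds {lo}–{hi} invalid")
        if self.F_y < 0 or self.F_a < 0:
            raise ValueError("fecundities must be non-negative")
        if self.years < 1 or self.replicates < 1:
            raise ValueError("years and replicates must be ≥ 1")
        if not 0.0 <= self.harvest_rate < 1.0:
            raise ValueError("harvest rate must be in [0, 1)")

    def reseeded(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


@dataclass
class ProjectionResult:
    """Replicate trajectories and scenario summaries.

    ``trajectories`` has shape (replicates, years+1, 3); ``lambdas`` the
    per-replicate realized growth rates; ``sensitivity``/``elasticity`` the
    per-parameter averages over every drawn annual matrix.
    """

    scenario: ScenarioSpec
    trajectories: np.ndarray
    lambdas: np.ndarray
    sensitivity: dict[str, float]
    elasticity: dict[str, float]
    summary: dict = field(default_factory=dict)

    def summarize(self) -> dict:
        lam = self.lambdas
        q25, q75 = np.percentile(lam, [25.0, 75.0])
        self.summary = {
            "scenario": self.scenario.name,
            "mean_lambda": float(lam.mean()),
            "iqr_low": float(q25),
            "iqr_high": float(q75),
            "fraction_positive": float(np.mean(lam > 1.0)),
            "replicates": int(lam.size),
            "years": int(self.scenario.years),
        }
        return self.summary


def draw_survivals(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    """One independent Uniform(lower, upper) draw per stage (upper bound
    inclusive for degenerate intervals)."""
    sf = rng.uniform(*spec.S_f_bounds) if spec.S_f_bounds[0] < spec.S_f_bounds[1] else spec.S_f_bounds[0]
    sy = rng.uniform(*spec.S_y_bounds) if spec.S_y_bounds[0] < spec.S_y_bounds[1] else spec.S_y_bounds[0]
    sa = rng.uniform(*spec.S_a_bounds) if spec.S_a_bounds[0] < spec.S_a_bounds[1] else spec.S_a_bounds[0]
    return sf, sy, sa


def project_replicate(
    spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """One stochastic trajectory: redraw survivals each year, reassemble the
    matrix with the scenario's fixed fecundities, project the vector.

    Returns the (years+1, 3) trajectory and the list of drawn annual
    matrices.
    """
    n = np.asarray(spec.initial, dtype=float)
    traj = np.empty((spec.years + 1, 3))
    traj[0] = n
    matrices: list[np.ndarray] = []
    for t in range(spec.years):
        sf, sy, sa = draw_survivals(spec, rng)
        A = assemble(sf, sy, sa, spec.F_y, spec.F_a)
        matrices.append(A)
        n = A @ n
        traj[t + 1] = n
    return traj, matrices


def replicate_growth_rate(trajectory: np.ndarray) -> float:
    """Realized geometric-mean annual growth (N_T / N_0)^(1/T) of total
    abundance; 0 if the population hit zero."""
    totals = np.asarray(trajectory).sum(axis=1)
    if totals[0] <= 0:
        raise ValueError("initial total abundance must be positive")
    if totals[-1] <= 0:
        return 0.0
    years = len(totals) - 1
    return float((totals[-1] / totals[0]) ** (1.0 / years))


def run_scenario(spec: ScenarioSpec, lambda_method: str = "realized") -> ProjectionResult:
    """Run all replicates of a scenario and summarize.

    ``lambda_method`` selects the per-replicate growth definition:
    ``"realized"`` (geometric mean of totals, default) or ``"eigen_mean"``
    (mean dominant eigenvalue of the replicate's drawn matrices).
    """
    if lambda_method not in ("realized", "eigen_mean"):
        raise ValueError(f"unknown lambda_method {lambda_method!r}")
    streams = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    trajectories = np.empty((spec.replicates, spec.years + 1, 3))
    lambdas = np.empty(spec.replicates)
    sens_sum = {k: 0.0 for k in STRUCTURAL_ENTRIES}
    elas_sum = {k: 0.0 for k in STRUCTURAL_ENTRIES}
    n_matrices = 0
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        traj, mats = project_replicate(spec, rng)
        trajectories[r] = traj
        if lambda_method == "realized":
            lambdas[r] = replicate_growth_rate(traj)
        else:
            lambdas[r] = float(np.mean([dominant_eigen(A).lam for A in mats]))
        for A in mats:
            eig = dominant_eigen(A)
            for k, s in eig.by_parameter("sensitivity").items():
                sens_sum[k] += s
            for k, e in eig.by_parameter("elasticity").items():
                elas_sum[k] += e
            n_matrices += 1
    result = ProjectionResult(
        scenario=spec,
        trajectories=trajectories,
        lambdas=lambdas,
        sensitivity={k: s / n_matrices for k, s in sens_sum.items()},
        elasticity={k: e / n_matrices for k, e in elas_sum.items()},
    )
    result.summarize()
    return result


def apply_harvest(
    S_y_bounds: Bounds,
    S_a_bounds: Bounds,
    F_y: float,
    F_a: float,
    h: float,
) -> tuple[Bounds, Bounds, float, float]:
    """Discount yearling and adult survival bounds and both fecundities by
    (1 − h) for an antlerless harvest rate h; fawn survival is untouched
    (no reported harvest of tagged fawns)."""
    if not 0.0 <= h < 1.0:
        raise ValueError("harvest rate must be in [0, 1)")
    k = 1.0 - h
    scale = lambda b: (b[0] * k, b[1] * k)
    return scale(S_y_bounds), scale(S_a_bounds), F_y * k, F_a * k
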