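"""Three-stage female-only Leslie matrix: assembly, eigen-analysis,
perturbation metrics, and derived demographic quantities.

The projection model is ``n(t+1) = A n(t)`` with stages fawn (0–1 yr),
yearling (1–2 yr) and adult (≥2 yr) and the fixed sparsity pattern::

        | 0    F_y  F_a |
    A = | S_f  0    0   |
        | 0    S_y  S_a |

Fecundity ``F_i = (B_i × S_i) / 2`` converts a birth rate (fawns per female
per year) into female fawns per female under a 1:1 birth sex ratio; fawns do
not reproduce.  The dominant eigenvalue λ of A is the asymptotic annual
growth multiplier; its right eigenvector w is the stable stage distribution
and its left eigenvector v the reproductive values.  Sensitivities
``s_ij = v_i w_j / ⟨v, w⟩`` and elasticities ``e_ij = (a_ij / λ) s_ij`` are
reported for the five structural entries only — the scenarios hold fecundity
constant, so survival inside a fecundity product is deliberately not chained
through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

STAGE_ORDER = ("fawn", "yearling", "adult")

#: (row, col) of the five structural entries, keyed by conventional name
STRUCTURAL_ENTRIES = {
    "F_y": (0, 1),
    "F_a": (0, 2),
    "S_f": (1, 0),
    "S_y": (2, 1),
    "S_a": (2, 2),
}


class DegenerateMatrixError(ValueError):
    """The projection matrix has no usable dominant eigen pair."""


def fecundity(birth_rate: float, survival: float) -> float:
    """Female fawns per female per year: (B × S) / 2 under a 1:1 birth sex
    ratio."""
    if birth_rate < 0:
        raise ValueError("birth rate must be non-negative")
    if not 0.0 <= survival <= 1.0:
        raise ValueError("survival must be a probability")
    return birth_rate * survival / 2.0


@dataclass(frozen=True)
class StageVitalRates:
    """Point estimates, 95% CI bounds and birth rates for the three stages.

    Fecundities derive from birth rates and point survivals unless
    explicitly overridden (scenarios that discount fecundity for harvest set
    ``F_y_override``/``F_a_override``).
    """

    S_f: float
    S_f_bounds: tuple[float, float]
    S_y: float
    S_y_bounds: tuple[float, float]
    S_a: float
    S_a_bounds: tuple[float, float]
    B_y: float = 1.09
    B_a: float = 1.43
    F_y_override: float | None = None
    F_a_override: float | None = None

    def __post_init__(self) -> None:
        for name in ("S_f", "S_y", "S_a"):
            point = getattr(self, name)
            lo, hi = getattr(self, name + "_bounds")
            if not (0.0 <= lo <= point <= hi <= 1.0):
                raise ValueError(f"{name}: need 0 ≤ {lo} ≤ {point} ≤ {hi} ≤ 1")

    @property
    def F_y(self) -> float:
        if self.F_y_override is not None:
            return self.F_y_override
        return fecundity(self.B_y, self.S_y)

    @property
    def F_a(self) -> float:
        if self.F_a_override is not None:
            return self.F_a_override
        return fecundity(self.B_a, self.S_a)


def build_matrix(vitals: StageVitalRates) -> np.ndarray:
    """Assemble the 3×3 projection matrix from vital rates."""
    return assemble(vitals.S_f, vitals.S_y, vitals.S_a, vitals.F_y, vitals.F_a)


def assemble(S_f: float, S_y: float, S_a: float, F_y: float, F_a: float) -> np.ndarray:
    """Place the five rates into the fixed sparsity pattern."""
    for name, s in (("S_f", S_f), ("S_y", S_y), ("S_a", S_a)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name}={s} outside [0, 1]")
    if F_y < 0 or F_a < 0:
        raise ValueError("fecundities must be non-negative")
    return np.array(
        [
            [0.0, F_y, F_a],
            [S_f, 0.0, 0.0],
            [0.0, S_y, S_a],
        ]
    )


def check_pattern(A: np.ndarray) -> None:
    """Validate the structural zero pattern of a candidate stage matrix."""
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError("stage matrix must be 3×3")
    if np.any(A < 0):
        raise ValueError("stage matrix entries must be non-negative")
    mask = np.zeros((3, 3), dtype=bool)
    for i, j in STRUCTURAL_ENTRIES.values():
        mask[i, j] = True
    if np.any(A[~mask] != 0):
        raise ValueError("nonzero entry outside the stage-matrix pattern")


def project_one_step(A: np.ndarray, n: np.ndarray) -> np.ndarray:
    """One annual projection step ``n(t+1) = A n(t)``."""
    return np.asarray(A) @ np.asarray(n)


@dataclass(frozen=True)
class EigenAnalysis:
    """Dominant eigen pair of a stage matrix with perturbation metrics.

    ``w`` sums to 1 (stable stage proportions); ``v`` is scaled so the fawn
    reproductive value is 1.  ``sensitivity``/``elasticity`` are full 3×3
    arrays that are zero off the structural pattern.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray
    sensitivity: np.ndarray
    elasticity: np.ndarray

    def by_parameter(self, which: str = "elasticity") -> dict[str, float]:
        """Metrics keyed by the conventional entry names F_y … S_a."""
        mat = getattr(self, which)
        return {name: float(mat[i, j]) for name, (i, j) in STRUCTURAL_ENTRIES.items()}


def dominant_eigen(A: np.ndarray) -> EigenAnalysis:
    """Dominant eigenvalue, stable stage structure, reproductive values,
    sensitivities and elasticities of a non-negative stage matrix."""
    A = np.asarray(A, dtype=float)
    check_pattern(A)
    eigvals, right = np.linalg.eig(A)
    k = int(np.argmax(eigvals.real))
    lam = float(eigvals[k].real)
    if lam <= 0 or abs(eigvals[k].imag) > 1e-12:
        raise DegenerateMatrixError(f"no positive dominant eigenvalue (λ={eigvals[k]})")
    w = right[:, k].real
    w = np.abs(w)
    if w.sum() == 0:
        raise DegenerateMatrixError("degenerate right eigenvector")
    w = w / w.sum()

    eigvals_l, left = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(eigvals_l - lam)))
    v = np.abs(left[:, kl].real)
    if v[0] > 0:
        v = v / v[0]

    denom = float(v @ w)
    sens = np.outer(v, w) / denom
    mask = np.zeros((3, 3), dtype=bool)
    for i, j in STRUCTURAL_ENTRIES.values():
        mask[i, j] = True
    sens = np.where(mask, sens, 0.0)
    elas = A * sens / lam
    return EigenAnalysis(lam=lam, w=w, v=v, sensitivity=sens, elasticity=elas)


def stable_stage_abundances(A: np.ndarray, total: int) -> np.ndarray:
    """Integer stage abundances: stable stage proportions × ``total``,
    rounded by largest remainder so the components sum exactly to total."""
    if total < 0:
        raise ValueError("total must be non-negative")
    if total == 0:
        return np.zeros(3, dtype=int)
    w = dominant_eigen(A).w
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))  # largest fractional remainders first
        base[order[:short]] += 1
    return base


def fawn_survival_threshold(vitals: StageVitalRates) -> float:
    """Fawn survival at which λ = 1, all other rates held at their points.

    Solved by bisection of the characteristic polynomial in ``S_f`` on
    [0, 1]; equals ``(1 − S_a) / (F_y + F_a S_y − F_y S_a)`` in closed form.
    Returns NaN when no break-even exists on [0, 1] (e.g. no reproduction).
    """
    def lam_minus_one(sf: float) -> float:
        return dominant_eigen(
            assemble(sf, vitals.S_y, vitals.S_a, vitals.F_y, vitals.F_a)
        ).lam - 1.0

    if vitals.S_a >= 1.0:
        return 0.0
    lo, hi = lam_minus_one(1e-12), lam_minus_one(1.0)
    if lo > 0:
        return 0.0
    if hi < 0:
        return float("nan")  # unattainable even at perfect fawn survival
    return float(optimize.brentq(lam_minus_one, 1e-12, 1.0, xtol=1e-6))


def recruitment_rate(B_adult: float, S_fawn: float) -> float:
    """Fawns recruited per female per year: birth rate × fawn survival."""
    if B_adult < 0 or not 0.0 <= S_fawn <= 1.0:
        raise ValueError("inputs out of range")
    return B_adult * S_fawn
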