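"""Stage-specific survival estimation from staggered-entry encounter
histories.

The estimator is the Kaplan–Meier product limit on a shared calendar-time
axis, generalized for staggered entry: an animal contributes to the risk set
at time ``t`` only if it had entered by ``t`` and had neither died nor been
censored before ``t``.  Variance follows Greenwood's formula and 95%
confidence intervals use the complementary log–log transform, which keeps
the interval inside [0, 1].

Hunter-harvest mortalities can be handled two ways before estimation:
removing harvested animals from the sample entirely (the convention that
drops a 45-deer sample to 43 when two are shot), or converting the harvest
death into right-censoring at the death time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import EncounterRecord

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class EstimationError(ValueError):
    """Raised when the product-limit estimator is undefined (e.g. a death
    time with an empty risk set)."""


@dataclass(frozen=True)
class SurvivalEstimate:
    """A survival probability over a fixed horizon with its 95% CI.

    ``n`` is the number of animals entering the estimate, ``n_events`` the
    number of deaths observed within the horizon.
    """

    point: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    horizon: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError(
                f"CI ordering violated: {self.ci_low} ≤ {self.point} ≤ {self.ci_high}"
            )
        if self.n_events > self.n:
            raise ValueError("more deaths than animals")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def km_curve(records: list[EncounterRecord], horizon: float) -> pd.DataFrame:
    """Staggered-entry Kaplan–Meier curve on the calendar-time axis.

    Returns a DataFrame with one row per distinct death time ≤ ``horizon``:
    ``time``, ``n_risk``, ``n_deaths``, ``survival`` (the product-limit
    estimate just after the deaths), and ``greenwood_var``.  Simultaneous
    deaths are handled by the usual multiple-decrement factor ``1 - d/n``;
    censoring at a death time is processed after the deaths, so such animals
    remain in that risk set.
    """
    if not records:
        raise EstimationError("no records to estimate from")

    entries = np.array([r.entry_time for r in records])
    exits = np.array([min(r.exit_time, horizon) for r in records])
    deaths = np.array([r.is_death and r.exit_time <= horizon for r in records])

    death_times = np.unique(exits[deaths])
    surv = 1.0
    cumvar = 0.0  # Greenwood sum d / (n (n - d))
    rows = []
    for t in death_times:
        at_risk = int(np.sum((entries <= t) & (exits >= t)))
        d = int(np.sum(deaths & (exits == t)))
        if at_risk == 0:
            raise EstimationError(f"empty risk set at death time {t}")
        if d >= at_risk:
            surv = 0.0
            cumvar = np.inf
        else:
            surv *= 1.0 - d / at_risk
            cumvar += d / (at_risk * (at_risk - d))
        rows.append(
            {
                "time": float(t),
                "n_risk": at_risk,
                "n_deaths": d,
                "survival": surv,
                "greenwood_var": surv**2 * cumvar if np.isfinite(cumvar) else 0.0,
                "_cumvar": cumvar,
            }
        )
    return pd.DataFrame(
        rows, columns=["time", "n_risk", "n_deaths", "survival", "greenwood_var", "_cumvar"]
    )


def _loglog_ci(surv: float, cumvar: float) -> tuple[float, float]:
    """95% CI from the complementary log–log transform of Greenwood's
    variance; degenerate at S=0 or S=1 where the transform is undefined."""
    if surv <= 0.0:
        return (0.0, 0.0)
    if surv >= 1.0 or cumvar == 0.0:
        return (surv, min(surv, 1.0)) if surv < 1.0 else (1.0, 1.0)
    se_theta = np.sqrt(cumvar) / abs(np.log(surv))
    lo = surv ** np.exp(Z95 * se_theta)
    hi = surv ** np.exp(-Z95 * se_theta)
    return (float(lo), float(min(hi, 1.0)))


def _estimate_at(records: list[EncounterRecord], horizon: float) -> SurvivalEstimate:
    curve = km_curve(records, horizon)
    if len(curve) == 0:
        surv, cumvar = 1.0, 0.0
    else:
        surv = float(curve["survival"].iloc[-1])
        cumvar = float(curve["_cumvar"].iloc[-1])
    lo, hi = _loglog_ci(surv, cumvar if np.isfinite(cumvar) else 0.0)
    return SurvivalEstimate(
        point=surv,
        ci_low=lo,
        ci_high=hi,
        n=len(records),
        n_events=int(curve["n_deaths"].sum()) if len(curve) else 0,
        horizon=horizon,
    )


def annual_survival(records: list[EncounterRecord]) -> SurvivalEstimate:
    """Annual (365-day) survival for a single yearling or adult stage.

    With no observed deaths the point estimate is 1.0 with a degenerate
    interval — the situation a small collared yearling sample can produce.
    """
    stages = {r.stage for r in records}
    if len(stages) > 1:
        raise EstimationError(f"records mix stages {sorted(stages)}")
    return _estimate_at(records, horizon=365.0)


def period_survival(records: list[EncounterRecord], horizon: float = 84.0) -> SurvivalEstimate:
    """Fawn-period (default 12-week) survival, used as the full fawn-stage
    annual parameter since older-fawn mortality is treated as negligible."""
    return _estimate_at(records, horizon=horizon)


def pool_study_years(
    records: list[EncounterRecord], year_length: float = 365.0
) -> list[EncounterRecord]:
    """Pool capture cohorts across study years onto one within-year axis.

    Each record's times are re-referenced to the origin of the study year
    it entered in, so a three-season staggered-entry design collapses into
    a single product-limit curve (the usual pooling when annual samples are
    small)."""
    out = []
    for r in records:
        shift = np.floor(r.entry_time / year_length) * year_length
        out.append(
            EncounterRecord(
                animal_id=r.animal_id,
                stage=r.stage,
                entry_time=r.entry_time - shift,
                exit_time=r.exit_time - shift,
                fate=r.fate,
                dam_id=r.dam_id,
            )
        )
    return out


def censor_harvest(
    records: list[EncounterRecord], mode: str = "remove_animal"
) -> list[EncounterRecord]:
    """Strip hunter-harvest mortality before estimating natural survival.

    ``remove_animal`` deletes harvested animals from the sample (n drops);
    ``censor_at_death`` keeps them, right-censored at the death time.
    """
    if mode == "remove_animal":
        return [r for r in records if r.fate != "harvest_death"]
    if mode == "censor_at_death":
        return [
            EncounterRecord(
                animal_id=r.animal_id,
                stage=r.stage,
                entry_time=r.entry_time,
                exit_time=r.exit_time,
                fate="censored_other" if r.fate == "harvest_death" else r.fate,
                dam_id=r.dam_id,
            )
            for r in records
        ]
    raise ValueError(f"unknown mode {mode!r}")
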