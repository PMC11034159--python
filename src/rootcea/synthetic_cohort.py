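"""Individual-level microsimulation and synthetic longitudinal exam data.

Two roles:

1. *Stochastic oracle for the cohort engine.* Each tooth's trajectory is
   sampled with exactly the same per-cycle event tree, cost accrual and
   discounting conventions as :func:`rootcea.cohort_engine.step`, so the
   sample means of discounted cost and effect are unbiased estimates of
   the deterministic cohort totals (per tooth).

2. *Synthetic dental-cohort generator.* Trajectories are down-sampled to
   exams every ``n`` years - recording only the observed state, as a real
   longitudinal oral-health cohort would - and the annual transition
   probabilities are re-estimated from the exam panel, exercising the
   interval-to-annual conversion. Defaults (1,000 subjects with 23 teeth,
   2-year exams) stand in for a community cohort of realistic size; they
   are synthetic choices, not a description of any particular study.

The generator assumes independent teeth, no dropout and no covariates,
mirroring the model's own assumptions; parameter-recovery results
therefore validate the estimation pipeline, not real-world epidemiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort_engine import CycleConventions, DEFAULT_CONVENTIONS, State
from .parameters import ModelConfig, annualize, effective_caries_prob

__all__ = [
    "ToothHistory",
    "SimulationResult",
    "ExamDataset",
    "Estimate",
    "EstimatedProbs",
    "simulate_teeth",
    "to_exam_dataset",
    "estimate_probs",
]

_EVENT_COLUMNS = ("caries_onset", "filling", "endo", "crown", "extraction", "refill")


@dataclass(frozen=True)
class ToothHistory:
    """One tooth's realized trajectory over the horizon.

    ``states`` has length ``horizon + 1`` (cycle 0 is baseline, all teeth
    intact); ``events`` is a list of ``(cycle, event_name)`` pairs; cost
    and effect are the tooth's realized discounted contributions.
    """

    subject_id: int
    tooth_id: int
    states: tuple[State, ...]
    events: tuple[tuple[int, str], ...]
    cost: float
    effect: float


@dataclass(frozen=True)
class SimulationResult:
    """Vectorized microsimulation output; indexable as ToothHistory records."""

    states: np.ndarray  # (n_teeth_total, horizon+1) int8
    events: dict[str, np.ndarray]  # name -> (n_teeth_total, horizon) bool
    cost: np.ndarray  # per-tooth discounted cost
    effect: np.ndarray  # per-tooth discounted effect
    strategy: str
    teeth_per_subject: int
    seed: int

    def __len__(self) -> int:
        return self.states.shape[0]

    def __getitem__(self, index: int) -> ToothHistory:
        if index < 0:
            index += len(self)
        if not (0 <= index < len(self)):
            raise IndexError(index)
        ev = tuple(
            (t + 1, name)
            for t in range(self.states.shape[1] - 1)
            for name in _EVENT_COLUMNS
            if self.events[name][index, t]
        )
        return ToothHistory(
            subject_id=index // self.teeth_per_subject,
            tooth_id=index % self.teeth_per_subject,
            states=tuple(State(s) for s in self.states[index]),
            events=ev,
            cost=float(self.cost[index]),
            effect=float(self.effect[index]),
        )

    def __iter__(self) -> Iterator[ToothHistory]:
        return (self[i] for i in range(len(self)))

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_effect(self) -> float:
        return float(self.effect.mean())


def simulate_teeth(
    config: ModelConfig,
    strategy: str,
    n_subjects: int,
    seed: int,
    conventions: CycleConventions = DEFAULT_CONVENTIONS,
) -> SimulationResult:
    """Simulate ``n_subjects * n_teeth`` independent tooth trajectories.

    A fixed number of uniform draws is consumed per cycle regardless of
    state occupancy, so two runs with the same seed but different risk
    ratios share their randomness draw-for-draw (at ``rr = 1`` the fluoride
    run reproduces the control trajectories exactly, apart from varnish
    charges).
    """
    settings = config.settings
    probs = config.probs
    costs = config.costs
    p_car_eff = effective_caries_prob(probs.p_car, strategy, config.modifier.rr_fluoride)
    varnish_on = strategy == "fluoride"
    r = settings.discount_rate
    T = settings.horizon
    n = n_subjects * settings.n_teeth

    rng = np.random.default_rng(seed)
    state = np.full(n, int(State.INTACT), dtype=np.int8)
    states = np.empty((n, T + 1), dtype=np.int8)
    states[:, 0] = state
    events = {name: np.zeros((n, T), dtype=bool) for name in _EVENT_COLUMNS}
    cost = np.zeros(n)
    effect = np.zeros(n)

    for t in range(1, T + 1):
        u_onset, u_treat, u_endo, u_crown, u_fail = rng.random((5, n))

        retained = state != State.EXTRACTED
        filled_at_start = state == State.FILLED

        onset = (state == State.INTACT) & (u_onset < p_car_eff)
        active = onset | (state == State.UNTREATED_CARIES)
        fill = active & (u_treat < probs.p_fill)
        extract = active & ~fill & (u_treat < probs.p_fill + probs.p_ext)
        endo = fill & (u_endo < probs.p_endo)
        crown = endo & (u_crown < probs.p_crown)

        new_state = state.copy()
        new_state[onset] = State.UNTREATED_CARIES
        new_state[fill] = State.FILLED
        new_state[crown] = State.CROWNED
        new_state[extract] = State.EXTRACTED

        at_risk = filled_at_start
        if conventions.refill_from == "same_cycle":
            at_risk = at_risk | (fill & ~crown)
        refill = at_risk & (u_fail < probs.p_fail)

        df_treat = (1.0 + r) ** -conventions.discount_exponent(t, "treatment")
        cycle_cost = np.zeros(n)
        cycle_cost[fill & ~endo] += costs.c_fill
        cycle_cost[endo] += costs.c_endo
        cycle_cost[crown] += costs.c_crown
        cycle_cost[extract] += costs.c_ext
        cycle_cost[refill] += costs.c_fill
        cost += cycle_cost * df_treat
        if varnish_on:
            df_varn = (1.0 + r) ** -conventions.discount_exponent(t, "varnish")
            base = retained if conventions.varnish_base == "retained_teeth" else np.ones(n, bool)
            cost[base] += costs.c_varnish * df_varn

        effect += (new_state == State.INTACT) * (1.0 + r) ** -t

        events["caries_onset"][:, t - 1] = onset
        events["filling"][:, t - 1] = fill
        events["endo"][:, t - 1] = endo
        events["crown"][:, t - 1] = crown
        events["extraction"][:, t - 1] = extract
        events["refill"][:, t - 1] = refill

        state = new_state
        states[:, t] = state

    return SimulationResult(
        states=states,
        events=events,
        cost=cost,
        effect=effect,
        strategy=strategy,
        teeth_per_subject=settings.n_teeth,
        seed=seed,
    )


@dataclass(frozen=True)
class ExamDataset:
    """Synthetic longitudinal exam panel: observed states every ``interval`` years.

    ``records`` columns: ``subject_id, tooth_id, exam_year, state`` (state
    names). ``ground_truth`` carries the generating annual probabilities,
    for parameter-recovery testing only - a real cohort would not have it.
    """

    interval: int
    horizon: int
    records: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def to_exam_dataset(sim: SimulationResult, exam_interval_n: int, ground_truth: dict | None = None) -> ExamDataset:
    """Down-sample annual trajectories to exams every ``exam_interval_n`` years.

    Only the observed state at each exam is kept - events between exams
    are lost, exactly the information loss of real cohort follow-up.
    """
    horizon = sim.states.shape[1] - 1
    if not (1 <= exam_interval_n <= horizon):
        raise ValueError(
            f"exam interval must lie in [1, horizon={horizon}]; got {exam_interval_n}"
        )
    exam_years = np.arange(0, horizon + 1, exam_interval_n)
    n = len(sim)
    sub = np.repeat(np.arange(n) // sim.teeth_per_subject, len(exam_years))
    tooth = np.repeat(np.arange(n) % sim.teeth_per_subject, len(exam_years))
    years = np.tile(exam_years, n)
    observed = sim.states[:, exam_years].ravel()
    records = pd.DataFrame(
        {
            "subject_id": sub,
            "tooth_id": tooth,
            "exam_year": years,
            "state": [State(s).name for s in observed],
        }
    )
    return ExamDataset(
        interval=exam_interval_n,
        horizon=horizon,
        records=records,
        ground_truth=ground_truth or {},
    )


@dataclass(frozen=True)
class Estimate:
    """Annualized transition-probability estimate with a 95% CI.

    The interval-scale proportion gets a Wilson score interval (stable for
    proportions near zero); point and bounds are then converted to the
    annual scale with the constant-hazard formula.
    """

    point: float
    ci_low: float
    ci_high: float
    interval_point: float
    n_at_risk: int
    n_events: int


@dataclass(frozen=True)
class EstimatedProbs:
    """Re-estimated cohort-derived probabilities (onset, filling, extraction)."""

    p_car: Estimate | None
    p_fill: Estimate | None
    p_ext: Estimate | None
    interval: int


def _estimate(n_events: int, n_at_risk: int, interval: int) -> Estimate | None:
    if n_at_risk == 0:
        return None
    p_int = n_events / n_at_risk
    lo, hi = proportion_confint(n_events, n_at_risk, alpha=0.05, method="wilson")
    return Estimate(
        point=annualize(p_int, interval),
        ci_low=annualize(float(lo), interval),
        ci_high=annualize(float(hi), interval),
        interval_point=p_int,
        n_at_risk=n_at_risk,
        n_events=n_events,
    )


def estimate_probs(dataset: ExamDataset) -> EstimatedProbs:
    """Estimate annual onset, filling and extraction probabilities from exams.

    For each consecutive exam pair the at-risk teeth are counted by their
    state at the earlier exam; the transition proportion over the interval
    is annualized. Onset (intact to any caries-derived state) has a single
    exit from the at-risk state, so annualization is exact at any exam
    interval; filling and extraction compete with each other within an
    interval, so their annualized estimates carry a small competing-risk
    bias for intervals longer than a year (see the methods note).
    """
    wide = (
        dataset.records.pivot_table(
            index=["subject_id", "tooth_id"],
            columns="exam_year",
            values="state",
            aggfunc="first",
        )
        .sort_index(axis=1)
        .to_numpy()
    )
    prev, curr = wide[:, :-1], wide[:, 1:]

    risk_car = prev == "INTACT"
    ev_car = risk_car & (curr != "INTACT")
    risk_act = prev == "UNTREATED_CARIES"
    ev_fill = risk_act & np.isin(curr, ("FILLED", "CROWNED"))
    ev_ext = risk_act & (curr == "EXTRACTED")

    return EstimatedProbs(
        p_car=_estimate(int(ev_car.sum()), int(risk_car.sum()), dataset.interval),
        p_fill=_estimate(int(ev_fill.sum()), int(risk_act.sum()), dataset.interval),
        p_ext=_estimate(int(ev_ext.sum()), int(risk_act.sum()), dataset.interval),
        interval=dataset.interval,
    )
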