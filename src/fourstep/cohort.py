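"""Seeded synthetic cohorts for the full analysis pipeline.

Generates three groups of subjects — a vmPFC lesion group, a lesion
control (LC) group, and healthy controls (HC) — with per-subject true
model parameters, simulated task data, and demographic/lesion-volume
covariates. The defaults emulate the qualitative study conditions: for
the board-game task the vmPFC group has an elevated feature-drop rate
and stopping probability (hence shallower search); for the Two-Step
task all groups share the same parameter distributions (no group
effect), while Step-2 responses slow after rare transitions in every
group. These defaults describe the synthetic world the pipeline is
tested in, not any real patient population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behav_stats import CovariateRecord
from .planner import PlannerParams
from .tournament import OpponentPool, build_opponent_pool, play_session
from .twostep_model import (
    PARAM_NAMES,
    RECOVERY_DISTRIBUTIONS,
    TwoStepParams,
    simulate_agent,
)
from .twostep_task import RARE, TaskConfig, generate_schedule, trials_to_frame

GROUP_NAMES = ("vmPFC", "LC", "HC")


@dataclass(frozen=True)
class PlannerGroupSpec:
    """Truncated-normal per-subject planner parameter distributions."""

    delta_mean: float = 0.15
    delta_sd: float = 0.1
    gamma_mean: float = 0.3
    gamma_sd: float = 0.1
    lapse_mean: float = 0.05
    lapse_sd: float = 0.03


@dataclass(frozen=True)
class CohortSpec:
    """Complete description of a synthetic cohort.

    ``group_sizes`` follow the study layouts (board game: 10/8/30;
    Two-Step: 30/19/20). Planner group shifts put the vmPFC group at a
    higher drop rate (0.4 vs 0.15) and higher stopping probability (0.5
    vs 0.3); Two-Step parameter distributions are identical across
    groups by default. Step-2 RTs are lognormal with an additive
    rare-transition slowing in milliseconds.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"vmPFC": 10, "LC": 8, "HC": 30}
    )
    planner_groups: dict = field(
        default_factory=lambda: {
            "vmPFC": PlannerGroupSpec(delta_mean=0.4, gamma_mean=0.5),
            "LC": PlannerGroupSpec(),
            "HC": PlannerGroupSpec(),
        }
    )
    twostep_groups: dict = field(
        default_factory=lambda: {g: dict(RECOVERY_DISTRIBUTIONS)
                                 for g in GROUP_NAMES}
    )
    games_per_subject: int = 40
    task_config: TaskConfig = field(default_factory=TaskConfig)
    rt_log_location: float = np.log(800.0)  # median Step-2 RT ~ 800 ms
    rt_log_scale: float = 0.3
    rt_rare_slowing_ms: float = 150.0
    # covariates: (mean, sd) per group
    age: dict = field(default_factory=lambda: {
        "vmPFC": (59.0, 10.0), "LC": (56.0, 9.0), "HC": (60.0, 8.0)})
    education: dict = field(default_factory=lambda: {
        "vmPFC": (3.0, 1.1), "LC": (3.1, 1.2), "HC": (4.1, 1.0)})
    # lesion volumes in voxels (lognormal parameters)
    vmpfc_volume_log: tuple = (8.0, 0.6)
    extra_volume_log: tuple = (7.5, 0.8)

    def base_planner_params(self) -> PlannerParams:
        return PlannerParams()


@dataclass
class Subject:
    subject_id: str
    group: str
    planner_params: PlannerParams | None = None
    twostep_params: TwoStepParams | None = None
    game_records: list = field(default_factory=list)
    trials: pd.DataFrame | None = None
    covariates: CovariateRecord | None = None


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subjects: list

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]

    def trial_table(self) -> pd.DataFrame:
        frames = [s.trials for s in self.subjects if s.trials is not None]
        if not frames:
            raise ValueError("cohort has no trial data")
        return pd.concat(frames, ignore_index=True)

    def all_game_records(self) -> list:
        out = []
        for s in self.subjects:
            out.extend(s.game_records)
        return out


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _subject_ids(spec: CohortSpec):
    for group in GROUP_NAMES:
        for i in range(spec.group_sizes.get(group, 0)):
            yield f"{group}_{i:02d}", group


def sample_planner_params(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> PlannerParams:
    g: PlannerGroupSpec = spec.planner_groups[group]
    base = spec.base_planner_params()
    return base.replace(
        delta=_truncnorm(rng, g.delta_mean, g.delta_sd, 0.0, 0.9),
        gamma=_truncnorm(rng, g.gamma_mean, g.gamma_sd, 0.02, 1.0),
        lapse=_truncnorm(rng, g.lapse_mean, g.lapse_sd, 0.0, 0.5),
    )


def sample_twostep_params(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> TwoStepParams:
    dists = spec.twostep_groups[group]
    kw = {}
    for name in PARAM_NAMES:
        mean, sd, lo, hi = dists[name]
        val = _truncnorm(rng, mean, sd, lo, hi)
        if name in ("alpha", "lam"):
            val = min(max(val, 1e-3), 1 - 1e-3)
        elif name.startswith("beta"):
            val = min(max(val, 1e-3), 10 - 1e-3)
        kw[name] = val
    return TwoStepParams(**kw)


def make_covariates(
    spec: CohortSpec, rng: np.random.Generator
) -> list[CovariateRecord]:
    """Demographics plus lesion volumes: vmPFC subjects have positive
    vmPFC and total volumes (vmPFC <= total), LC subjects lesion volume
    outside the mask only, HC subjects none."""
    records = []
    for sid, group in _subject_ids(spec):
        age_m, age_sd = spec.age[group]
        edu_m, edu_sd = spec.education[group]
        age = _truncnorm(rng, age_m, age_sd, 30.0, 85.0)
        edu = _truncnorm(rng, edu_m, edu_sd, 1.0, 6.0)
        if group == "vmPFC":
            v_vm = float(rng.lognormal(*spec.vmpfc_volume_log))
            v_total = v_vm + float(rng.lognormal(*spec.extra_volume_log)) \
                * float(rng.random() < 0.5)
        elif group == "LC":
            v_vm = 0.0
            v_total = float(rng.lognormal(*spec.extra_volume_log))
        else:
            v_vm = v_total = 0.0
        records.append(
            CovariateRecord(subject_id=sid, group=group, age=age,
                            education=edu, v_vmpfc=v_vm, v_total=v_total)
        )
    return records


def make_4iar_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    pool: OpponentPool | None = None,
    n_per_category: int = 10,
) -> SyntheticCohort:
    """Sample per-subject planner parameters from the group
    distributions and play each subject through a staircase session."""
    _validate(spec)
    if pool is None:
        pool = build_opponent_pool(rng, n_per_category=n_per_category)
    covs = {c.subject_id: c for c in make_covariates(spec, rng)}
    subjects = []
    for sid, group in _subject_ids(spec):
        params = sample_planner_params(spec, group, rng)
        records = play_session(
            params, pool, rng, n_games=spec.games_per_subject, subject_id=sid
        )
        subjects.append(
            Subject(subject_id=sid, group=group, planner_params=params,
                    game_records=records, covariates=covs[sid])
        )
    return SyntheticCohort(spec=spec, subjects=subjects)


def _rt_for_trials(spec: CohortSpec, transitions, rng) -> np.ndarray:
    base = rng.lognormal(spec.rt_log_location, spec.rt_log_scale,
                         size=len(transitions))
    return base + spec.rt_rare_slowing_ms * (np.asarray(transitions) == RARE)


def make_twostep_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> SyntheticCohort:
    """Sample per-subject learner parameters, simulate a full session on
    a fresh schedule per subject, and attach synthetic Step-2 RTs
    (lognormal, slowed after rare transitions)."""
    _validate(spec)
    covs = {c.subject_id: c for c in make_covariates(spec, rng)}
    subjects = []
    for sid, group in _subject_ids(spec):
        params = sample_twostep_params(spec, group, rng)
        schedule = generate_schedule(spec.task_config, rng)
        trials = simulate_agent(params, schedule, rng)
        frame = trials_to_frame(trials, subject_id=sid)
        frame["rt2_ms"] = _rt_for_trials(spec, frame["transition"], rng)
        subjects.append(
            Subject(subject_id=sid, group=group, twostep_params=params,
                    trials=frame, covariates=covs[sid])
        )
    return SyntheticCohort(spec=spec, subjects=subjects)


def _validate(spec: CohortSpec) -> None:
    for g, n in spec.group_sizes.items():
        if g not in GROUP_NAMES:
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError("group sizes must be >= 0")
    if spec.games_per_subject < 1:
        raise ValueError("games_per_subject must be >= 1")
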