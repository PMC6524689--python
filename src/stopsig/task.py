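"""Stop-signal task simulation under the independent horse-race model.

The task simulated here is a two-choice reaction task (left/right arrow,
left/right response) in which a random quarter of trials present a delayed
stop signal instructing the participant to withhold the prepared response.
Per session there is first a pure two-choice block and then a stop-signal
block; the stop-signal delay (SSD) follows a one-up/one-down staircase in
fixed steps so that inhibition succeeds on roughly half the stop trials.

Generative assumptions
----------------------
* Go finishing times are ex-Gaussian (Normal(mu, sigma) + Exponential(tau)),
  the standard parametric family for reaction-time data.
* The stop process has a Normal latency (truncated at zero), racing
  independently against the go process: a response is emitted on a stop trial
  iff the go process finishes before ``ssd + stop latency``.
* Participants strategically slow their go responses in the stop-signal
  block; this is modelled as a multiplicative factor on the ex-Gaussian
  location parameters (mu, tau), so mean RT scales by the same factor.
* Choice errors and omissions occur with small fixed probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError

__all__ = [
    "TaskDesign",
    "RaceModelParams",
    "BetweenSubjectVariation",
    "TrialRecord",
    "SessionResult",
    "staircase_update",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "study_cohort_spec",
    "write_trials_csv",
    "read_trials_csv",
]

BLOCKS = ("choice", "stopsignal")
TRIAL_TYPES = ("go", "stop")
SIDES = ("left", "right")
RESPONSES = ("left", "right", "none")


@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of one session.

    Defaults mirror the administered design: a 48-trial two-choice block
    followed by 288 stop-signal trials of which 25% carry a stop signal,
    with the SSD staircase starting at 100 ms and moving in 50 ms steps.
    """

    n_trials: int = 288
    stop_fraction: float = 0.25
    n_choice_trials: int = 48
    ssd_initial_ms: float = 100.0
    ssd_step_ms: float = 50.0
    ssd_min_ms: float = 0.0
    ssd_max_ms: float = 900.0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_choice_trials < 0:
            raise ConfigError("trial counts must be positive")
        if not (0.0 < self.stop_fraction < 1.0):
            raise ConfigError("stop_fraction must lie in (0, 1)")
        n_stop = self.n_trials * self.stop_fraction
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ConfigError(
                f"stop_fraction * n_trials = {n_stop} is not an integer"
            )
        if not (self.ssd_min_ms <= self.ssd_initial_ms <= self.ssd_max_ms):
            raise ConfigError("require ssd_min <= ssd_initial <= ssd_max")
        if self.ssd_step_ms <= 0:
            raise ConfigError("ssd_step_ms must be positive")

    @property
    def n_stop_trials(self) -> int:
        return int(round(self.n_trials * self.stop_fraction))

    @property
    def n_go_trials(self) -> int:
        return self.n_trials - self.n_stop_trials


@dataclass(frozen=True)
class RaceModelParams:
    """Generative parameters of the independent race for one participant.

    ``go_mu_ms``/``go_sigma_ms``/``go_tau_ms`` parameterize the ex-Gaussian
    go-RT distribution (mean = mu + tau). ``ssrt_mean_ms``/``ssrt_sd_ms`` give
    the Normal stop-latency distribution, truncated at zero.
    ``slowing_factor`` scales the go location (mu and tau) in the stop-signal
    block only, emulating strategic slowing relative to the pure choice block.
    """

    go_mu_ms: float
    go_sigma_ms: float
    go_tau_ms: float
    ssrt_mean_ms: float
    ssrt_sd_ms: float
    slowing_factor: float = 1.0
    choice_error_rate: float = 0.0
    omission_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.go_mu_ms, self.go_sigma_ms, self.go_tau_ms, self.ssrt_sd_ms) <= 0:
            raise ConfigError("ex-Gaussian and stop-latency scale parameters must be > 0")
        if self.ssrt_mean_ms < 0:
            raise ConfigError("ssrt_mean_ms must be >= 0")
        if self.slowing_factor < 1.0:
            raise ConfigError("slowing_factor must be >= 1")
        for name in ("choice_error_rate", "omission_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class BetweenSubjectVariation:
    """Between-participant spread applied when simulating a cohort.

    Per participant and effector, the go location (``go_mu_ms``) and the
    stop-latency mean (``ssrt_mean_ms``) receive Normal offsets; offsets are
    correlated across effectors with ``cross_effector_rho`` so that a cohort
    reproduces the hand-foot correlation observed in individual differences.
    """

    go_mu_sd_ms: float = 0.0
    ssrt_sd_ms: float = 0.0
    cross_effector_rho: float = 0.6

    def __post_init__(self) -> None:
        if self.go_mu_sd_ms < 0 or self.ssrt_sd_ms < 0:
            raise ConfigError("between-subject SDs must be >= 0")
        if not (-1.0 < self.cross_effector_rho < 1.0):
            raise ConfigError("cross_effector_rho must lie in (-1, 1)")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: stimulus, optional stop-signal delay, and the outcome."""

    trial_index: int
    block: str
    trial_type: str
    stimulus: str
    ssd_ms: float | None
    response: str
    rt_ms: float | None

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ConfigError(f"unknown block {self.block!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ConfigError(f"unknown trial_type {self.trial_type!r}")
        if self.stimulus not in SIDES:
            raise ConfigError(f"unknown stimulus {self.stimulus!r}")
        if self.response not in RESPONSES:
            raise ConfigError(f"unknown response {self.response!r}")
        if (self.ssd_ms is not None) != (self.trial_type == "stop"):
            raise ConfigError("ssd_ms must be present iff trial_type == 'stop'")
        if (self.rt_ms is not None) != (self.response != "none"):
            raise ConfigError("rt_ms must be present iff a response was given")
        if self.trial_type == "stop" and self.block != "stopsignal":
            raise ConfigError("stop trials occur only in the stopsignal block")

    @property
    def responded(self) -> bool:
        return self.response != "none"

    @property
    def correct(self) -> bool:
        return self.response == self.stimulus


@dataclass
class SessionResult:
    """One participant x effector: choice block plus stop-signal block."""

    participant_id: str
    group: str
    effector: str
    trials: list[TrialRecord]
    design: TaskDesign = field(default_factory=TaskDesign)

    def block_trials(self, block: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.block == block]

    @property
    def stop_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type == "stop"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def staircase_update(ssd_ms: float, responded: bool, design: TaskDesign) -> float:
    """One-up/one-down SSD tracking step.

    A response on a stop trial (failed inhibition) makes the next stop trial
    easier (SSD shorter by one step); successful inhibition makes it harder
    (SSD longer by one step). The result is clipped to the design bounds.
    """
    if ssd_ms < 0:
        raise ConfigError(f"ssd_ms must be nonnegative, got {ssd_ms}")
    new = ssd_ms - design.ssd_step_ms if responded else ssd_ms + design.ssd_step_ms
    return float(min(max(new, design.ssd_min_ms), design.ssd_max_ms))


def _draw_go_finish(params: RaceModelParams, rng: np.random.Generator, slowed: bool) -> float:
    f = params.slowing_factor if slowed else 1.0
    # location parameters scale with slowing; the Gaussian spread does not
    rt = rng.normal(params.go_mu_ms * f, params.go_sigma_ms) + rng.exponential(params.go_tau_ms * f)
    return float(max(rt, 1.0))


def _draw_stop_latency(params: RaceModelParams, rng: np.random.Generator) -> float:
    # Normal truncated at zero by rejection; at realistic parameter values
    # (mean >> sd) rejections are vanishingly rare.
    for _ in range(1000):
        x = rng.normal(params.ssrt_mean_ms, params.ssrt_sd_ms)
        if x >= 0:
            return float(x)
    return 0.0


def simulate_trial(
    trial_type: str,
    ssd_ms: float | None,
    params: RaceModelParams,
    rng,
    *,
    block: str = "stopsignal",
    trial_index: int = 0,
    stimulus: str | None = None,
) -> TrialRecord:
    """Simulate a single trial of the race.

    Draw order is fixed (stimulus, omission, choice error, go Normal, go
    exponential, then stop latency for stop trials) so that identical
    generator states yield identical trials.
    """
    if (ssd_ms is not None) != (trial_type == "stop"):
        raise ConfigError("ssd_ms must be supplied iff trial_type == 'stop'")
    rng = _as_rng(rng)
    if stimulus is None:
        stimulus = SIDES[rng.integers(2)]
    omitted = rng.random() < params.omission_rate
    flip = rng.random() < params.choice_error_rate
    go_finish = _draw_go_finish(params, rng, slowed=(block == "stopsignal"))
    side = stimulus if not flip else ("left" if stimulus == "right" else "right")

    if trial_type == "stop":
        stop_latency = _draw_stop_latency(params, rng)
        responds = (not omitted) and go_finish < ssd_ms + stop_latency
        if responds:
            return TrialRecord(trial_index, block, "stop", stimulus, float(ssd_ms), side, go_finish)
        return TrialRecord(trial_index, block, "stop", stimulus, float(ssd_ms), "none", None)

    if omitted:
        return TrialRecord(trial_index, block, "go", stimulus, None, "none", None)
    return TrialRecord(trial_index, block, "go", stimulus, None, side, go_finish)


def simulate_session(
    design: TaskDesign,
    params: RaceModelParams,
    seed,
    *,
    participant_id: str = "p000",
    group: str = "control",
    effector: str = "hands",
) -> SessionResult:
    """Simulate one session: choice block, then staircased stop-signal block.

    Stop trials occupy exactly ``round(stop_fraction * n_trials)`` uniformly
    shuffled positions; the SSD starts at ``ssd_initial_ms`` and is updated by
    :func:`staircase_update` after every stop trial. The choice block is
    generated without the slowing factor.
    """
    rng = _as_rng(seed)
    trials: list[TrialRecord] = []
    for i in range(design.n_choice_trials):
        trials.append(simulate_trial("go", None, params, rng, block="choice", trial_index=i))

    is_stop = np.zeros(design.n_trials, dtype=bool)
    is_stop[rng.permutation(design.n_trials)[: design.n_stop_trials]] = True
    ssd = float(design.ssd_initial_ms)
    for i in range(design.n_trials):
        if is_stop[i]:
            rec = simulate_trial("stop", ssd, params, rng, block="stopsignal", trial_index=i)
            ssd = staircase_update(ssd, rec.responded, design)
        else:
            rec = simulate_trial("go", None, params, rng, block="stopsignal", trial_index=i)
        trials.append(rec)
    return SessionResult(participant_id, group, effector, trials, design)


def simulate_cohort(
    group_specs: Mapping[str, Mapping[str, RaceModelParams]],
    n_per_group: int,
    design: TaskDesign | None = None,
    seed=0,
    subject_variation: BetweenSubjectVariation | None = None,
) -> list[SessionResult]:
    """Simulate a full cohort: every participant runs every effector.

    ``group_specs`` maps group label -> effector label -> generative
    parameters. Each participant receives an independently spawned child seed
    (derived from ``seed`` via :class:`numpy.random.SeedSequence`), so cohorts
    are reproducible and participants independent under reordering. With
    ``subject_variation``, each participant's go location and stop-latency
    mean are offset by Normal draws correlated across effectors.
    """
    if not group_specs:
        raise ConfigError("group_specs must name at least one group")
    if n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    design = design or TaskDesign()
    variation = subject_variation or BetweenSubjectVariation()

    sessions: list[SessionResult] = []
    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(len(group_specs))
    for g_idx, (group, effector_params) in enumerate(sorted(group_specs.items())):
        if not effector_params:
            raise ConfigError(f"group {group!r} specifies no effectors")
        effectors = sorted(effector_params)
        group_seq = group_seqs[g_idx]
        participant_seqs = group_seq.spawn(n_per_group)
        for p_idx, p_seq in enumerate(participant_seqs):
            pid = f"{group}_{p_idx:03d}"
            jitter_rng = np.random.default_rng(p_seq.spawn(1)[0])
            offsets = _participant_offsets(jitter_rng, effectors, variation)
            session_seqs = p_seq.spawn(len(effectors))
            for e_idx, effector in enumerate(effectors):
                params = effector_params[effector]
                d_go, d_stop = offsets[effector]
                jittered = replace(
                    params,
                    go_mu_ms=max(50.0, params.go_mu_ms + d_go),
                    ssrt_mean_ms=max(1.0, params.ssrt_mean_ms + d_stop),
                )
                sessions.append(
                    simulate_session(
                        design,
                        jittered,
                        np.random.default_rng(session_seqs[e_idx]),
                        participant_id=pid,
                        group=group,
                        effector=effector,
                    )
                )
    return sessions


def _participant_offsets(
    rng: np.random.Generator,
    effectors: Sequence[str],
    variation: BetweenSubjectVariation,
) -> dict[str, tuple[float, float]]:
    """Correlated per-effector offsets for (go_mu, ssrt_mean)."""
    k = len(effectors)
    rho = variation.cross_effector_rho
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    chol = np.linalg.cholesky(cov)
    z_go = chol @ rng.standard_normal(k)
    z_stop = chol @ rng.standard_normal(k)
    return {
        e: (variation.go_mu_sd_ms * z_go[i], variation.ssrt_sd_ms * z_stop[i])
        for i, e in enumerate(effectors)
    }


def study_cohort_spec() -> tuple[dict[str, dict[str, RaceModelParams]], BetweenSubjectVariation]:
    """Generative parameters emulating the reference study's conditions.

    Group-level stop-latency means follow the published group SSRT means
    (expert/control ~229/262 ms with hands, ~260/277 ms with feet); go-RT
    parameters are chosen so that mean two-choice RT matches the published
    ~408 ms (hands) and ~424 ms (feet) with no group difference; slowing
    factors match the published slowing indices (1.298 hands, 1.239 feet).
    Between-subject spreads are set so observed SDs (which also carry
    estimation noise) land near the published ones.
    """

    def params(effector: str, ssrt_mean: float) -> RaceModelParams:
        go = {"hands": (330.0, 28.0, 78.0, 1.298), "feet": (344.0, 30.0, 80.0, 1.239)}
        mu, sigma, tau, slow = go[effector]
        return RaceModelParams(
            go_mu_ms=mu,
            go_sigma_ms=sigma,
            go_tau_ms=tau,
            ssrt_mean_ms=ssrt_mean,
            ssrt_sd_ms=30.0,
            slowing_factor=slow,
            choice_error_rate=0.02,
            omission_rate=0.01,
        )

    specs = {
        "expert": {"hands": params("hands", 229.0), "feet": params("feet", 260.0)},
        "control": {"hands": params("hands", 262.0), "feet": params("feet", 277.0)},
    }
    variation = BetweenSubjectVariation(go_mu_sd_ms=30.0, ssrt_sd_ms=32.0, cross_effector_rho=0.6)
    return specs, variation


# ---------------------------------------------------------------------------
# trial-level CSV interchange

CSV_COLUMNS = [
    "participant_id",
    "group",
    "effector",
    "block",
    "trial_index",
    "trial_type",
    "stimulus",
    "ssd_ms",
    "response",
    "rt_ms",
]


def sessions_to_frame(sessions: Iterable[SessionResult]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (
                    s.participant_id,
                    s.group,
                    s.effector,
                    t.block,
                    t.trial_index,
                    t.trial_type,
                    t.stimulus,
                    t.ssd_ms,
                    t.response,
                    t.rt_ms,
                )
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trials_csv(sessions: Iterable[SessionResult], path) -> None:
    """Write sessions as a flat UTF-8 CSV; absent SSD/RT become empty fields."""
    sessions_to_frame(sessions).to_csv(path, index=False, na_rep="")


def _parse_optional_float(token: str, row: int, col: str) -> float | None:
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric {col} value {token!r}") from None


def read_trials_csv(path) -> list[SessionResult]:
    """Read a trial CSV back into sessions, validating every row.

    Sessions are grouped by (participant_id, effector) in file order; the
    per-session :class:`TaskDesign` is reconstructed from observed counts
    (SSD staircase settings are not serialized and take default values).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")

    buckets: dict[tuple[str, str], dict] = {}
    for row_pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        block, ttype, stim, resp = row.block, row.trial_type, row.stimulus, row.response
        if block not in BLOCKS:
            raise ParseError(f"row {row_pos}: unknown block {block!r}")
        if ttype not in TRIAL_TYPES:
            raise ParseError(f"row {row_pos}: unknown trial_type {ttype!r}")
        if stim not in SIDES:
            raise ParseError(f"row {row_pos}: unknown stimulus {stim!r}")
        if resp not in RESPONSES:
            raise ParseError(f"row {row_pos}: unknown response {resp!r}")
        ssd = _parse_optional_float(row.ssd_ms, row_pos, "ssd_ms")
        rt = _parse_optional_float(row.rt_ms, row_pos, "rt_ms")
        try:
            idx = int(row.trial_index)
        except ValueError:
            raise ParseError(f"row {row_pos}: non-integer trial_index {row.trial_index!r}") from None
        try:
            rec = TrialRecord(idx, block, ttype, stim, ssd, resp, rt)
        except ConfigError as exc:
            raise ParseError(f"row {row_pos}: {exc}") from None
        key = (row.participant_id, row.effector)
        bucket = buckets.setdefault(key, {"group": row.group, "trials": []})
        bucket["trials"].append(rec)

    sessions = []
    for (pid, effector), bucket in buckets.items():
        trials = bucket["trials"]
        n_stop = sum(1 for t in trials if t.trial_type == "stop")
        n_ss = sum(1 for t in trials if t.block == "stopsignal")
        n_choice = len(trials) - n_ss
        if n_ss == 0 or n_stop == 0:
            raise ParseError(f"session {pid}/{effector}: no stop-signal trials")
        design = TaskDesign(
            n_trials=n_ss, stop_fraction=n_stop / n_ss, n_choice_trials=n_choice
        )
        sessions.append(SessionResult(pid, bucket["group"], effector, trials, design))
    return sessions
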