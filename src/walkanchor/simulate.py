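"""Synthetic dual-site recordings with ground-truth ledgers.

The generator renders the behavioral phenomena that dissociate wrist- and
ankle-derived activity during free-living walking:

* ankle gait — a damped ~8 Hz impact transient per step, at cadence-
  defined times with 2% timing jitter, riding on gravity;
* wrist arm swing — a sinusoid at stride frequency (half the step
  frequency: arms swing once per stride) whose amplitude sets the
  wrist-derived intensity;
* arm-suppressed walking — amplitude zero (gait-aid use, hands occupied),
  with the forearm optionally reoriented horizontal palm-down
  (``adl_posture``, e.g. pushing a cart);
* parkinsonian tremor — a 4.5 Hz pronation–supination oscillation replacing
  arm swing;
* idle fidgeting, near-motionless sleep, and zero-noise constant-
  orientation nonwear blocks; white device noise elsewhere.

Each simulated participant comes with a :class:`GroundTruthLedger` holding
the exact step times, walking segments with expected LONG status and
expected intensity labels, and the sleep/nonwear intervals as generated —
the oracle every pipeline stage is tested against.

Scenario presets draw LONG-walk cadences from 90 spm up and keep walk
durations well clear of the 60 s bout criterion so that ledger expectations
are unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .config import IntensityCutPoints
from .errors import ConfigError, ProfileError
from .recording import TriaxialRecording

ARM_CONDITIONS = ("normal", "suppressed", "adl_posture", "tremor")

# ankle impact-burst shape
BURST_FREQ_HZ = 8.0
BURST_TAU_S = 0.05
BURST_AMP_G = 0.8
STEP_JITTER_FRAC = 0.02


@dataclass(frozen=True)
class WalkSegment:
    start_s: float
    duration_s: float
    cadence_spm: float
    arm_swing_amplitude_g: float = 0.45
    arm_condition: str = "normal"

    def __post_init__(self) -> None:
        if self.arm_condition not in ARM_CONDITIONS:
            raise ProfileError(f"unknown arm condition {self.arm_condition!r}")
        if not (40 <= self.cadence_spm <= 200):
            raise ProfileError(f"cadence {self.cadence_spm} outside [40, 200] spm")
        if self.arm_swing_amplitude_g < 0 or self.duration_s <= 0:
            raise ProfileError("amplitudes and durations must be non-negative/positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class ParticipantProfile:
    participant_id: str
    duration_h: float = 2.0
    sample_rate_hz: float = 50.0
    start_time: datetime = field(default_factory=lambda: datetime(2024, 3, 4, 0, 0, 0))
    walks: list[WalkSegment] = field(default_factory=list)
    tremor_frequency_hz: float = 4.5
    tremor_amplitude_g: float = 0.35
    sleep: tuple[float, float] | None = None
    nonwear: list[tuple[float, float]] = field(default_factory=list)
    noise_sd_g: float = 0.01
    fidget_amplitude_g: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted((w.start_s, w.end_s) for w in self.walks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ProfileError(f"walk segments overlap at {s2:.1f} s")
        total = self.duration_h * 3600
        for s, e in spans:
            if s < 0 or e > total:
                raise ProfileError("walk segment outside the recording")


@dataclass
class GroundTruthLedger:
    """What the generator actually produced, for checking the pipeline."""

    participant_id: str
    step_times: np.ndarray
    segments: list[dict]  # start/end/cadence/condition/steps/expected labels
    sleep: tuple[float, float] | None
    nonwear: list[tuple[float, float]]

    def expected_long_segments(self) -> list[dict]:
        return [s for s in self.segments if s["expected_long"]]

    def expected_sedentary_fraction(self) -> float:
        """Fraction of expected-LONG walking time whose expected wrist
        label is sedentary."""
        longs = self.expected_long_segments()
        total = sum(s["duration_s"] for s in longs)
        if total == 0:
            return float("nan")
        sed = sum(s["duration_s"] for s in longs if s["expected_label"] == "sedentary")
        return sed / total

    def total_steps(self) -> int:
        return len(self.step_times)


def expected_avm_mg(segment: WalkSegment, profile: ParticipantProfile) -> float:
    """Closed-form expected wrist AVM for a walk segment.

    The dominant ENMO contribution is the swing component along gravity:
    a half-wave-rectified sinusoid of amplitude A has mean A/pi.  For the
    tremor condition the tremor amplitude plays the same role; suppressed
    and ADL-posture segments leave only the noise floor (a few mg).
    """
    if segment.arm_condition == "normal":
        amp = segment.arm_swing_amplitude_g
    elif segment.arm_condition == "tremor":
        amp = profile.tremor_amplitude_g
    else:
        amp = 0.0
    return 1000.0 * amp / math.pi


def _expected_label(avm_mg: float, cuts: IntensityCutPoints) -> str:
    if avm_mg < cuts.light_threshold_mg:
        return "sedentary"
    if avm_mg < cuts.moderate_threshold_mg:
        return "light"
    return "MVPA"


# ---------------------------------------------------------------------------
# signal synthesis


def simulate_participant(
    profile: ParticipantProfile,
    cuts: IntensityCutPoints | None = None,
) -> tuple[TriaxialRecording, TriaxialRecording, GroundTruthLedger]:
    """Render one participant's wrist and ankle streams plus the ledger."""
    cuts = cuts or IntensityCutPoints()
    rng = np.random.default_rng(profile.seed)
    fs = profile.sample_rate_hz
    n = int(round(profile.duration_h * 3600 * fs))
    t_total = n / fs

    ankle = np.zeros((n, 3))
    wrist = np.zeros((n, 3))
    ankle[:, 2] = 1.0  # gravity along z
    wrist[:, 2] = 1.0

    # device noise everywhere (zeroed later inside nonwear)
    ankle += rng.normal(0.0, profile.noise_sd_g, size=(n, 3))
    wrist += rng.normal(0.0, profile.noise_sd_g, size=(n, 3))

    # idle wrist fidgeting: smoothed noise, removed again inside walks/sleep
    fidget = _smooth_noise(rng, n, fs, profile.fidget_amplitude_g)
    wrist[:, 0] += fidget

    burst = _burst_kernel(fs)
    all_steps: list[np.ndarray] = []
    segments: list[dict] = []
    for seg in sorted(profile.walks, key=lambda w: w.start_s):
        times = _step_times(rng, seg)
        amps = BURST_AMP_G * (1 + rng.normal(0, 0.1, size=len(times)))
        impulse = np.zeros(n)
        idx = np.round(times * fs).astype(int)
        ok = idx < n
        impulse[idx[ok]] = amps[ok]
        ankle[:, 0] += np.convolve(impulse, burst)[:n]

        i0, i1 = int(seg.start_s * fs), min(n, int(seg.end_s * fs))
        tt = np.arange(i0, i1) / fs
        wrist[i0:i1, 0] -= fidget[i0:i1]  # walking replaces fidgeting
        stride_hz = seg.cadence_spm / 60.0 / 2.0
        phase = rng.uniform(0, 2 * np.pi)
        if seg.arm_condition == "normal":
            a = seg.arm_swing_amplitude_g
            wrist[i0:i1, 2] += a * np.sin(2 * np.pi * stride_hz * tt + phase)
            wrist[i0:i1, 0] += 0.5 * a * np.cos(2 * np.pi * stride_hz * tt + phase)
        elif seg.arm_condition == "adl_posture":
            # horizontal forearm, palm down: gravity moves to the x axis
            wrist[i0:i1, 2] -= 1.0
            wrist[i0:i1, 0] += 1.0
        elif seg.arm_condition == "tremor":
            a = profile.tremor_amplitude_g
            wt = 2 * np.pi * profile.tremor_frequency_hz * tt + phase
            wrist[i0:i1, 2] += a * np.sin(wt)
            wrist[i0:i1, 0] += 0.5 * a * np.cos(wt)
        # suppressed: no swing term at all

        exp_avm = expected_avm_mg(seg, profile)
        med_cad = (
            float(np.median(60.0 / np.diff(times))) if len(times) >= 2 else float("nan")
        )
        bout_dur = float(times[-1] - times[0]) if len(times) >= 2 else 0.0
        segments.append(
            {
                "start_s": seg.start_s,
                "end_s": seg.end_s,
                "duration_s": seg.duration_s,
                "cadence_spm": seg.cadence_spm,
                "median_cadence_spm": med_cad,
                "arm_condition": seg.arm_condition,
                "arm_swing_amplitude_g": seg.arm_swing_amplitude_g,
                "n_steps": int(len(times)),
                "bout_duration_s": bout_dur,
                "expected_long": bool(bout_dur >= 60 and med_cad > 80),
                "expected_avm_mg": exp_avm,
                "expected_label": _expected_label(exp_avm, cuts),
            }
        )
        all_steps.append(times)

    if profile.sleep is not None:
        s, e = profile.sleep
        i0, i1 = int(s * fs), min(n, int(e * fs))
        wrist[i0:i1] = [0.3, 0.3, 0.9]  # oblique rest posture
        wrist[i0:i1] += rng.normal(0.0, 0.002, size=(i1 - i0, 3))
        ankle[i0:i1] = [0.0, 0.0, 1.0]
        ankle[i0:i1] += rng.normal(0.0, 0.002, size=(i1 - i0, 3))

    for s, e in profile.nonwear:
        i0, i1 = int(s * fs), min(n, int(e * fs))
        wrist[i0:i1] = [0.0, 1.0, 0.0]  # exactly constant: unambiguous nonwear
        ankle[i0:i1] = [0.0, 1.0, 0.0]

    step_times = (
        np.sort(np.concatenate(all_steps)) if all_steps else np.empty(0)
    )
    ledger = GroundTruthLedger(
        participant_id=profile.participant_id,
        step_times=step_times,
        segments=segments,
        sleep=profile.sleep,
        nonwear=list(profile.nonwear),
    )
    mk = lambda site, arr: TriaxialRecording(
        site=site,
        sample_rate_hz=fs,
        start_time=profile.start_time,
        samples=arr,
        device_id=f"SIM-{profile.participant_id}-{site}",
    )
    return mk("wrist", wrist), mk("ankle", ankle), ledger


def _burst_kernel(fs: float) -> np.ndarray:
    t = np.arange(0, 4 * BURST_TAU_S, 1 / fs)
    return np.exp(-t / BURST_TAU_S) * np.sin(2 * np.pi * BURST_FREQ_HZ * t)


def _step_times(rng: np.random.Generator, seg: WalkSegment) -> np.ndarray:
    """Step times with 2% Gaussian jitter on the inter-step intervals."""
    mean_dt = 60.0 / seg.cadence_spm
    n_max = int(seg.duration_s / mean_dt) + 2
    dts = mean_dt * (1 + STEP_JITTER_FRAC * rng.standard_normal(n_max))
    times = seg.start_s + mean_dt / 2 + np.cumsum(np.concatenate([[0.0], dts]))
    return times[times < seg.end_s - mean_dt / 4]


def _smooth_noise(rng, n: int, fs: float, amplitude: float) -> np.ndarray:
    """Low-frequency wandering signal used for idle fidgeting."""
    if amplitude == 0:
        return np.zeros(n)
    coarse_rate = 2.0  # Hz
    m = int(n * coarse_rate / fs) + 2
    coarse = rng.normal(0, amplitude, size=m)
    return np.interp(np.arange(n) / fs, np.arange(m) / coarse_rate, coarse)


# ---------------------------------------------------------------------------
# scenarios and cohorts

SCENARIOS = ("active_oa", "gait_aid", "tremor_pd", "mixed_adl")


def _scenario_segment(rng, scenario: str, start_s: float) -> WalkSegment:
    duration = float(rng.uniform(90, 240))
    if scenario == "active_oa":
        return WalkSegment(
            start_s, duration,
            cadence_spm=float(rng.uniform(95, 125)),
            arm_swing_amplitude_g=float(rng.uniform(0.38, 0.6)),
            arm_condition="normal",
        )
    if scenario == "gait_aid":
        # walker/cane use: most walks have no arm swing at the wrist
        cond = "suppressed" if rng.uniform() < 0.85 else "normal"
        return WalkSegment(
            start_s, duration,
            cadence_spm=float(rng.uniform(88, 108)),
            arm_swing_amplitude_g=float(rng.uniform(0.35, 0.5)),
            arm_condition=cond,
        )
    if scenario == "tremor_pd":
        cond = rng.choice(["suppressed", "tremor"], p=[0.5, 0.5])
        return WalkSegment(
            start_s, duration,
            cadence_spm=float(rng.uniform(105, 150)),
            arm_swing_amplitude_g=0.0,
            arm_condition=str(cond),
        )
    if scenario == "mixed_adl":
        cond = rng.choice(["normal", "adl_posture"], p=[0.5, 0.5])
        return WalkSegment(
            start_s, duration,
            cadence_spm=float(rng.uniform(92, 118)),
            arm_swing_amplitude_g=float(rng.uniform(0.38, 0.55)),
            arm_condition=str(cond),
        )
    raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def scenario_profile(
    scenario: str,
    participant_id: str,
    seed: int,
    *,
    duration_h: float = 2.0,
    sample_rate_hz: float = 50.0,
    n_walks: int | None = None,
    with_sleep: bool = False,
    with_nonwear: bool = False,
) -> ParticipantProfile:
    """Draw one participant profile from a named scenario preset."""
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    total = duration_h * 3600

    sleep = None
    day_start = 0.0
    if with_sleep:
        if duration_h < 24:
            raise ConfigError("with_sleep requires duration_h >= 24")
        sleep = (float(rng.uniform(0, 1800)), float(rng.uniform(6.5, 8.0)) * 3600)
        sleep = (sleep[0], sleep[0] + sleep[1])
        day_start = sleep[1] + 600

    if n_walks is None:
        n_walks = max(2, int((total - day_start) / 1800))
    walks: list[WalkSegment] = []
    cursor = day_start + float(rng.uniform(120, 600))
    for _ in range(n_walks):
        seg = _scenario_segment(rng, scenario, cursor)
        if seg.end_s > total - 60:
            break
        walks.append(seg)
        cursor = seg.end_s + float(rng.uniform(300, 1200))

    nonwear = []
    if with_nonwear and walks:
        nw_start = walks[-1].end_s + 300
        if nw_start + 4500 < total:
            nonwear = [(nw_start, nw_start + 4200)]

    return ParticipantProfile(
        participant_id=participant_id,
        duration_h=duration_h,
        sample_rate_hz=sample_rate_hz,
        walks=walks,
        sleep=sleep,
        nonwear=nonwear,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def graded_profile(
    participant_id: str,
    sedentary_fraction: float,
    seed: int,
    *,
    n_walks: int = 8,
    duration_h: float = 2.0,
    sample_rate_hz: float = 50.0,
) -> ParticipantProfile:
    """Profile whose expected LONG-walk sedentary fraction is controlled.

    A fraction of the walk segments (rounded to whole walks of equal
    duration) is arm-suppressed, the rest swing normally — useful for
    rank-order and quartile-recovery checks.
    """
    if not (0 <= sedentary_fraction <= 1):
        raise ConfigError("sedentary_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sed = int(round(sedentary_fraction * n_walks))
    conditions = ["suppressed"] * n_sed + ["normal"] * (n_walks - n_sed)
    rng.shuffle(conditions)
    total = duration_h * 3600
    duration = 120.0
    gap = (total - 600 - n_walks * duration) / max(1, n_walks)
    if gap < 30:
        raise ConfigError("duration too short for requested walk count")
    walks = []
    cursor = 300.0
    for cond in conditions:
        walks.append(
            WalkSegment(
                cursor,
                duration,
                cadence_spm=float(rng.uniform(100, 115)),
                arm_swing_amplitude_g=float(rng.uniform(0.4, 0.55)),
                arm_condition=cond,
            )
        )
        cursor += duration + gap
    return ParticipantProfile(
        participant_id=participant_id,
        duration_h=duration_h,
        sample_rate_hz=sample_rate_hz,
        walks=walks,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_cohort(
    n: int,
    scenario_mix: dict[str, int] | None = None,
    seed: int = 0,
    *,
    duration_h: float = 2.0,
    cuts: IntensityCutPoints | None = None,
):
    """Simulate ``n`` participants drawn from scenario presets.

    ``scenario_mix`` maps scenario name to participant count (must sum to
    ``n``); default is an even split across all four presets.  Returns a
    list of ``(wrist, ankle, ledger)`` triples plus a cohort ledger row per
    participant with the expected sedentary fraction during LONG walks.
    """
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    if scenario_mix is None:
        base, extra = divmod(n, len(SCENARIOS))
        scenario_mix = {
            s: base + (1 if i < extra else 0) for i, s in enumerate(SCENARIOS)
        }
    for s in scenario_mix:
        if s not in SCENARIOS:
            raise ConfigError(f"unknown scenario {s!r}; expected one of {SCENARIOS}")
    if sum(scenario_mix.values()) != n:
        raise ConfigError("scenario_mix counts must sum to n")

    rng = np.random.default_rng(seed)
    participants = []
    cohort_rows = []
    i = 0
    for scenario, count in scenario_mix.items():
        for _ in range(count):
            pid = f"S{i:03d}_{scenario}"
            profile = scenario_profile(
                scenario, pid, seed=int(rng.integers(0, 2**31 - 1)),
                duration_h=duration_h,
            )
            triple = simulate_participant(profile, cuts)
            participants.append(triple)
            cohort_rows.append(
                {
                    "participant_id": pid,
                    "scenario": scenario,
                    "n_walks": len(profile.walks),
                    "total_steps": triple[2].total_steps(),
                    "expected_sedentary_fraction": triple[2].expected_sedentary_fraction(),
                }
            )
            i += 1
    return participants, cohort_rows
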