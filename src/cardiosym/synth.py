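"""Synthetic RR-interval recordings and full crossover study cohorts.

The generator emulates the structure of a caffeine-supplementation
crossover in recreational cyclists: 14 subjects each measured under
three supplementation conditions (PP placebo–placebo, PC
placebo–caffeine, CC caffeine–caffeine), with 5-min supine recordings
(pre-supplementation, pre-exercise, post-exercise) and ≥1000-beat
recordings at three moments of a 16-km cycling time trial (beginning,
midway, final), plus time-trial outcome variables (completion time and
power output per third).

The beat-domain RR model is a two-oscillator + drift + noise process:

    RR_i = mean_rr + A_LF sin(2π f_LF t_i) + A_HF sin(2π f_HF t_i)
           + drift·i + ε_i,     ε_i ~ N(0, σ²),

with t_i the running beat time.  The low-frequency (~0.1 Hz) amplitude
is a sympathetic-modulation proxy and the high-frequency
(respiratory-band) amplitude a vagal proxy: raising A_HF raises the
fraction of two-variation (V2) symbolic patterns downstream, raising
A_LF or the drift raises zero-variation (V0) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .series import RRSeries, write_rr_file

__all__ = [
    "AutonomicProfile",
    "CohortSpec",
    "generate_rr_series",
    "generate_study",
    "default_cohort_spec",
    "CONDITIONS",
    "CONTEXTS",
    "SUPINE_CONTEXTS",
    "TT_CONTEXTS",
]

CONDITIONS = ("PP", "PC", "CC")
SUPINE_CONTEXTS = ("supine_pre_suppl", "supine_pre_exerc", "supine_post")
TT_CONTEXTS = ("tt_beginning", "tt_midway", "tt_final")
CONTEXTS = SUPINE_CONTEXTS + TT_CONTEXTS

# Physiological plausibility band for a single RR interval, ms.
RR_FLOOR_MS = 200.0
RR_CEIL_MS = 2500.0


@dataclass(frozen=True)
class AutonomicProfile:
    """Parameters of the beat-domain RR generative model for one recording.

    Attributes
    ----------
    mean_rr : float
        Mean RR interval, ms (>0).
    lf_amplitude : float
        Amplitude of the low-frequency oscillation, ms (sympathetic proxy).
    hf_amplitude : float
        Amplitude of the high-frequency oscillation, ms (vagal proxy).
    drift_slope : float
        Slow linear trend, ms per beat.
    noise_sd : float
        White beat-to-beat jitter SD, ms.
    lf_freq, hf_freq : float
        Oscillation frequencies, Hz; ``lf_freq < hf_freq``.
    """

    mean_rr: float
    lf_amplitude: float = 0.0
    hf_amplitude: float = 0.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.lf_amplitude < 0 or self.hf_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not self.lf_freq < self.hf_freq:
            raise ValueError("lf_freq must be below hf_freq")

    def validate_for(self, n_beats: int) -> None:
        """Reject parameter sets that can drive intervals implausibly low.

        The deterministic excursion (both amplitudes plus the accumulated
        drift) together with a 5-sigma noise allowance must keep every
        interval above the physiological floor.
        """
        excursion = (
            self.lf_amplitude
            + self.hf_amplitude
            + abs(self.drift_slope) * max(n_beats - 1, 0)
            + 5.0 * self.noise_sd
        )
        if excursion >= self.mean_rr - RR_FLOOR_MS:
            raise ValueError(
                "profile can produce non-positive / implausible intervals: "
                f"max excursion {excursion:.1f} ms >= mean_rr - {RR_FLOOR_MS:.0f} ms"
            )
        if self.mean_rr + excursion >= RR_CEIL_MS:
            raise ValueError(
                "profile can exceed the physiological ceiling "
                f"({RR_CEIL_MS:.0f} ms)"
            )


def generate_rr_series(
    profile: AutonomicProfile,
    n_beats: int,
    seed: int | np.random.SeedSequence,
    *,
    subject: str | None = None,
    condition: str | None = None,
    context: str | None = None,
) -> RRSeries:
    """Generate one synthetic RR recording from an autonomic profile.

    The oscillators are sampled at the running beat time, which is itself
    determined by the generated intervals, so the sequence is produced
    beat by beat.  Deterministic for a fixed seed.
    """
    if n_beats < 3:
        raise ValueError("n_beats must be at least 3")
    profile.validate_for(n_beats)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, profile.noise_sd, size=n_beats)
    rr = np.empty(n_beats, dtype=float)
    t = 0.0  # running beat time, s
    two_pi = 2.0 * np.pi
    for i in range(n_beats):
        rr[i] = (
            profile.mean_rr
            + profile.lf_amplitude * np.sin(two_pi * profile.lf_freq * t)
            + profile.hf_amplitude * np.sin(two_pi * profile.hf_freq * t)
            + profile.drift_slope * i
            + noise[i]
        )
        t += rr[i] / 1000.0
    return RRSeries(rr, subject=subject, condition=condition, context=context)


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic crossover cohort.

    ``profiles`` maps ``(condition, context)`` to an
    :class:`AutonomicProfile`; every condition×context pair must be
    present.  Time-trial completion times and per-third power outputs are
    drawn around the configured condition means with a shared
    subject-level random effect (the crossover induces within-subject
    correlation) plus residual noise.
    """

    n_subjects: int = 14
    conditions: tuple[str, ...] = CONDITIONS
    contexts: tuple[str, ...] = CONTEXTS
    profiles: dict = field(default_factory=dict)
    tt_time_means: dict = field(default_factory=dict)  # condition -> s
    tt_power_means: dict = field(default_factory=dict)  # (condition, moment) -> W
    tt_time_subject_sd: float = 60.0  # between-subject SD of TT time, s
    tt_time_resid_sd: float = 18.0  # residual SD of TT time, s
    tt_power_subject_sd: float = 15.0  # between-subject SD of power, W
    tt_power_resid_sd: float = 6.0  # residual SD of power, W
    hrv_subject_sd: float = 0.15  # SD of subject multiplier on amplitudes
    supine_beats: int = 420
    tt_beats: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2 (no variance otherwise)")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be distinct")
        for cond in self.conditions:
            for ctx in self.contexts:
                if (cond, ctx) not in self.profiles:
                    raise ValueError(f"missing profile for ({cond}, {ctx})")
            if cond not in self.tt_time_means:
                raise ValueError(f"missing tt_time mean for {cond}")
            for m in TT_CONTEXTS:
                if (cond, m) not in self.tt_power_means:
                    raise ValueError(f"missing tt_power mean for ({cond}, {m})")


def _recording_seed(
    master: int, subject_idx: int, condition: str, context: str
) -> np.random.SeedSequence:
    """Seed-splitting rule: one independent stream per recording.

    The child stream is keyed by (subject index, condition index, context
    index) through a ``SeedSequence`` spawn key, so enlarging the cohort
    or adding contexts never perturbs previously generated series.
    """
    return np.random.SeedSequence(
        master,
        spawn_key=(subject_idx, CONDITIONS.index(condition) if condition in CONDITIONS
                   else hash(condition) % 2**16,
                   CONTEXTS.index(context) if context in CONTEXTS
                   else hash(context) % 2**16),
    )


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study conditions: 14 cyclists, PP/PC/CC, six contexts.

    Supine recordings share one resting profile across conditions (the
    study found no supine differences).  During the time trial the heart
    rate is high (mean RR 380–450 ms) and respiratory-band vagal
    modulation rises from beginning to final; under caffeine (PC, CC)
    the final-moment vagal amplitude is larger and the slow
    sympathetic/drift component smaller than under placebo, and the
    completion time is shorter by ≈ 43.4 s (PC) and 39.3 s (CC) with
    power output higher by ≈ +6.17 / +5.55 W around 199.67 W.
    """
    supine = AutonomicProfile(
        mean_rr=900.0, lf_amplitude=25.0, hf_amplitude=30.0,
        drift_slope=0.02, noise_sd=10.0, lf_freq=0.1, hf_freq=0.25,
    )
    # Exercise: higher respiratory rate; hf band ~0.4 Hz.
    tt = {
        ("PP", "tt_beginning"): AutonomicProfile(450.0, 8.0, 6.0, 0.010, 4.0, 0.1, 0.4),
        ("PP", "tt_midway"): AutonomicProfile(400.0, 8.0, 7.0, 0.012, 4.0, 0.1, 0.4),
        ("PP", "tt_final"): AutonomicProfile(380.0, 10.0, 6.0, 0.020, 4.0, 0.1, 0.4),
        ("PC", "tt_beginning"): AutonomicProfile(450.0, 8.0, 6.0, 0.010, 4.0, 0.1, 0.4),
        ("PC", "tt_midway"): AutonomicProfile(400.0, 7.0, 10.0, 0.008, 4.0, 0.1, 0.4),
        ("PC", "tt_final"): AutonomicProfile(380.0, 5.0, 16.0, 0.005, 4.0, 0.1, 0.4),
        ("CC", "tt_beginning"): AutonomicProfile(450.0, 8.0, 6.0, 0.010, 4.0, 0.1, 0.4),
        ("CC", "tt_midway"): AutonomicProfile(400.0, 7.0, 10.0, 0.008, 4.0, 0.1, 0.4),
        ("CC", "tt_final"): AutonomicProfile(380.0, 5.0, 15.0, 0.006, 4.0, 0.1, 0.4),
    }
    profiles = {}
    for cond in CONDITIONS:
        for ctx in SUPINE_CONTEXTS:
            profiles[(cond, ctx)] = supine
        for ctx in TT_CONTEXTS:
            profiles[(cond, ctx)] = tt[(cond, ctx)]
    # Completion times: 16 km at ~40 km/h under placebo; caffeine deltas
    # from the study's reported contrasts (negative = faster).
    tt_time_means = {"PP": 1480.0, "PC": 1480.0 - 43.4, "CC": 1480.0 - 39.3}
    # Mean power ≈ 199.67 W; placebo ramps power across the trial while
    # the caffeine conditions hold it quasi-stable from the start.
    tt_power_means = {
        ("PP", "tt_beginning"): 188.0,
        ("PP", "tt_midway"): 198.0,
        ("PP", "tt_final"): 207.0,
        ("PC", "tt_beginning"): 202.5,
        ("PC", "tt_midway"): 204.0,
        ("PC", "tt_final"): 205.0,
        ("CC", "tt_beginning"): 201.5,
        ("CC", "tt_midway"): 203.5,
        ("CC", "tt_final"): 204.5,
    }
    kwargs = dict(
        profiles=profiles,
        tt_time_means=tt_time_means,
        tt_power_means=tt_power_means,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def generate_study(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a full cohort: per-recording RR series plus outcome table.

    Returns ``(cohort, recordings)`` where ``cohort`` is a DataFrame with
    one row per subject×condition (columns: subject_id, condition,
    tt_time_s, power per third, and per-context rr_file paths when
    ``out_dir`` is given) and ``recordings`` maps
    ``(subject_id, condition, context)`` to the :class:`RRSeries`.
    If ``out_dir`` is set, one RR text file per recording and a
    ``cohort.csv`` are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    n = spec.n_subjects
    # Subject-level effects come from per-subject keyed streams so that
    # enlarging the cohort never perturbs existing subjects' draws.
    subj_time_eff = np.empty(n)
    subj_power_eff = np.empty(n)
    subj_hrv_mult = np.empty(n)
    for si in range(n):
        r = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(2**20, si))
        )
        subj_time_eff[si] = r.normal(0.0, spec.tt_time_subject_sd)
        subj_power_eff[si] = r.normal(0.0, spec.tt_power_subject_sd)
        # multiplicative subject factor on oscillation amplitudes (>0)
        subj_hrv_mult[si] = np.exp(r.normal(0.0, spec.hrv_subject_sd))
    resid_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2**20 + 1,))
    )

    recordings: dict[tuple[str, str, str], RRSeries] = {}
    rows = []
    for si in range(n):
        sid = f"S{si + 1:02d}"
        for cond in spec.conditions:
            row = {"subject_id": sid, "condition": cond}
            row["tt_time_s"] = round(
                spec.tt_time_means[cond]
                + subj_time_eff[si]
                + resid_rng.normal(0.0, spec.tt_time_resid_sd),
                2,
            )
            for moment, col in zip(
                TT_CONTEXTS, ("power_beginning_w", "power_midway_w", "power_final_w")
            ):
                row[col] = round(
                    spec.tt_power_means[(cond, moment)]
                    + subj_power_eff[si]
                    + resid_rng.normal(0.0, spec.tt_power_resid_sd),
                    2,
                )
            for ctx in spec.contexts:
                base = spec.profiles[(cond, ctx)]
                prof = replace(
                    base,
                    lf_amplitude=base.lf_amplitude * subj_hrv_mult[si],
                    hf_amplitude=base.hf_amplitude * subj_hrv_mult[si],
                )
                n_beats = (
                    spec.supine_beats if ctx.startswith("supine") else spec.tt_beats
                )
                series = generate_rr_series(
                    prof,
                    n_beats,
                    _recording_seed(spec.seed, si, cond, ctx),
                    subject=sid,
                    condition=cond,
                    context=ctx,
                )
                recordings[(sid, cond, ctx)] = series
                if out is not None:
                    fname = f"{sid}_{cond}_{ctx}.rr"
                    write_rr_file(series, out / fname)
                    row[f"rr_file_{ctx}"] = fname
            rows.append(row)
    cohort = pd.DataFrame(rows)
    if out is not None:
        cohort.to_csv(out / "cohort.csv", index=False)
    return cohort, recordings
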