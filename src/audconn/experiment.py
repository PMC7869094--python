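"""Synthetic multi-subject experiments.

Emulates a sparse-sampling auditory fMRI study: 8 runs of 24 trials (6 per
condition, pseudorandomly interleaved), one 3.36-s volume at the end of
each 8-s trial, stimuli presented in the 4.64-s silent gap with onsets
jittered 0.4-2.4 s after the previous scan ends.  The four conditions
cross task (figure-ground vs speech-in-noise) with difficulty (TMRs
titrated to 60% vs 90% performance per subject).

Subject profiles combine psychophysical thresholds (drawn from a correlated
population), logistic observers consistent with those thresholds, and
ground-truth effective-connectivity parameters (group mean plus
between-subject variation on the modulations).  Ground-truth BOLD is
forward-simulated from the joint neural-hemodynamic model and corrupted
with white Gaussian noise at a stated SNR; behavioral yes/no responses come
from the same observers evaluated at each subject's fixed condition TMRs.

All randomness flows from one master seed through named ``SeedSequence``
substreams, so a dataset is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dcm.forward import integrate_and_sample
from .dcm.model import (
    CONDITIONS,
    REGIONS_8,
    DCMParameters,
    InputSet,
    ROITimeseries,
)
from .psychophysics import Observer

__all__ = [
    "ExperimentDesign", "SubjectProfile", "GroupDataset",
    "generate_design", "sample_population", "generate_group_dataset",
    "default_group_dcm",
]

TASKS = ("SFG", "SPIN")
#: population mean thresholds (dB TMR) for SFG-60, SFG-90, SPIN-60, SPIN-90
THRESHOLD_MEANS = (-8.0, -4.0, -6.0, -2.0)
THRESHOLD_SD = 2.0
STIM_DURATION = 3.1      # s; common neural boxcar for both tasks


@dataclass
class ExperimentDesign:
    """Trial and acquisition timing of one scanning session."""

    events: pd.DataFrame                 # onset, duration, trial_type, run
    n_runs: int = 8
    trials_per_run: int = 24
    conditions: tuple[str, ...] = CONDITIONS
    trial_period: float = 8.0            # s
    tr: float = 3.36                     # s (volume acquisition time)
    jitter: tuple[float, float] = (0.4, 2.4)

    @property
    def silent_gap(self) -> float:
        return self.trial_period - self.tr

    @property
    def run_duration(self) -> float:
        return self.trials_per_run * self.trial_period

    def acquisition_times(self) -> np.ndarray:
        """Run-relative acquisition (start) times, one per trial."""
        return self.trial_period * np.arange(1, self.trials_per_run + 1) - self.tr

    def validate(self) -> None:
        ev = self.events
        for run, grp in ev.groupby("run"):
            counts = grp["trial_type"].value_counts()
            per = self.trials_per_run // len(self.conditions)
            if not all(counts.get(c, 0) == per for c in self.conditions):
                raise ValueError(f"run {run}: unbalanced condition counts")
        trial_idx = np.floor(ev["onset"] / self.trial_period).astype(int)
        rel = ev["onset"] - self.trial_period * trial_idx
        lo, hi = self.jitter
        if np.any((rel < lo - 1e-9) | (rel > hi + 1e-9)):
            raise ValueError("onsets outside the jitter window")


def generate_design(seed: int | np.random.Generator, n_runs: int = 8,
                    trials_per_run: int = 24,
                    conditions: tuple[str, ...] = CONDITIONS,
                    trial_period: float = 8.0, tr: float = 3.36,
                    jitter: tuple[float, float] = (0.4, 2.4)
                    ) -> ExperimentDesign:
    """Pseudorandomly interleaved, jittered event table for one session.

    Each run holds ``trials_per_run / len(conditions)`` trials per
    condition in shuffled order; each trial's stimulus starts uniformly
    0.4-2.4 s after the previous scan ends (trial onset).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    per = trials_per_run // len(conditions)
    if per * len(conditions) != trials_per_run:
        raise ValueError("trials_per_run must divide evenly among conditions")
    rows = []
    for run in range(n_runs):
        order = rng.permutation(np.repeat(np.arange(len(conditions)), per))
        for k, ci in enumerate(order):
            onset = trial_period * k + rng.uniform(*jitter)
            rows.append({"onset": onset, "duration": STIM_DURATION,
                         "trial_type": conditions[int(ci)], "run": run})
    design = ExperimentDesign(events=pd.DataFrame(rows), n_runs=n_runs,
                              trials_per_run=trials_per_run,
                              conditions=conditions,
                              trial_period=trial_period, tr=tr,
                              jitter=jitter)
    design.validate()
    return design


@dataclass
class SubjectProfile:
    """Ground truth for one synthetic participant."""

    thresholds: dict[str, float]         # condition -> TMR (dB)
    observers: dict[str, Observer]       # task -> logistic observer
    dcm: DCMParameters                   # subject ground-truth parameters

    def __post_init__(self) -> None:
        for task in TASKS:
            t60 = self.thresholds[f"{task}-60"]
            t90 = self.thresholds[f"{task}-90"]
            if not np.isfinite([t60, t90]).all() or t60 > t90:
                raise ValueError(
                    f"{task}: 60%-threshold must not exceed 90%-threshold")

    def tmr_covariates(self) -> np.ndarray:
        """Absolute TMRs in condition order (the group-level regressors)."""
        return np.array([abs(self.thresholds[c]) for c in CONDITIONS])


def _observer_from_thresholds(t60: float, t90: float,
                              lapse: float = 0.02) -> Observer:
    """Logistic observer passing exactly through (t60, 0.6) and (t90, 0.9)."""
    top = 1.0 - lapse
    z60 = np.log((0.6 / top) / (1 - 0.6 / top))
    z90 = np.log((0.9 / top) / (1 - 0.9 / top))
    slope = (z90 - z60) / (t90 - t60)
    midpoint = t60 - z60 / slope
    return Observer(threshold_db=midpoint, slope=slope, guess=0.0,
                    lapse=lapse)


def default_group_dcm(regions: tuple[str, ...] = REGIONS_8) -> DCMParameters:
    """Group-mean ground-truth connectivity.

    Within each hemisphere, an auditory hierarchy (core Te1.0 -> belts
    Te1.1/Te1.2 -> Te3) with 0.2 Hz forward and 0.1 Hz backward coupling;
    homotopic interhemispheric coupling 0.05 Hz when both hemispheres are
    present.  Difficulty disinhibits left Te1.0 (-0.47) and left Te1.1
    (-0.51) intrinsically; all task-by-difficulty interaction modulations
    are zero.  All trials drive every region, strongest in core; the task
    input drives higher regions positively (speech engages belt and
    parabelt more than tone clouds do), which gives each region a distinct
    condition-amplitude fingerprint and keeps the modulation parameters
    identifiable.
    """
    p = DCMParameters.zeros(regions)
    names = list(regions)

    def link(a: str, b: str, w: float) -> None:
        if a in names and b in names:
            p.A[names.index(b), names.index(a)] = w

    for hemi in ("L", "R"):
        link(f"{hemi}_Te1.0", f"{hemi}_Te1.1", 0.2)
        link(f"{hemi}_Te1.0", f"{hemi}_Te1.2", 0.2)
        link(f"{hemi}_Te1.1", f"{hemi}_Te3", 0.2)
        link(f"{hemi}_Te1.2", f"{hemi}_Te3", 0.2)
        link(f"{hemi}_Te1.1", f"{hemi}_Te1.0", 0.1)
        link(f"{hemi}_Te1.2", f"{hemi}_Te1.0", 0.1)
        link(f"{hemi}_Te3", f"{hemi}_Te1.1", 0.1)
        link(f"{hemi}_Te3", f"{hemi}_Te1.2", 0.1)
    for area in ("Te1.0", "Te1.1", "Te1.2", "Te3"):
        link(f"L_{area}", f"R_{area}", 0.05)
        link(f"R_{area}", f"L_{area}", 0.05)
    for region, weight in (("L_Te1.0", -0.47), ("L_Te1.1", -0.51)):
        if region in names:
            i = names.index(region)
            p.B[0, i, i] = weight     # difficulty modulation (intrinsic)
    all_drive = {"Te1.0": 0.35, "Te1.1": 0.22, "Te1.2": 0.22, "Te3": 0.12}
    task_drive = {"Te1.0": -0.10, "Te1.1": 0.10, "Te1.2": 0.22, "Te3": 0.30}
    for i, r in enumerate(names):
        area = r.split("_", 1)[1]
        p.C[i, 0] = all_drive[area]
        p.C[i, 1] = task_drive[area]
    return p


def _rank_to_pearson(r_s: float) -> float:
    """Pearson correlation producing a target Spearman under Gaussianity."""
    return 2.0 * np.sin(np.pi * r_s / 6.0)


def sample_population(n_subjects: int,
                      correlation_spec: dict | float | None = None,
                      seed: int | np.random.Generator = 0, *,
                      regions: tuple[str, ...] = REGIONS_8,
                      between_subject_sd: float = 0.1,
                      threshold_means: tuple[float, ...] = THRESHOLD_MEANS,
                      threshold_sd: float = THRESHOLD_SD
                      ) -> list[SubjectProfile]:
    """Draw subject profiles from a correlated population.

    Thresholds for (SFG-60, SFG-90, SPIN-60, SPIN-90) follow a
    multivariate Gaussian whose correlations are set to reproduce target
    Spearman values: within-task 0.55 and between-task 0.35 by default
    (``correlation_spec`` may be a scalar for the between-task value or a
    dict with keys ``between`` and ``within``).  Draws violating the
    60-below-90 ordering are rejected and redrawn.  Ground-truth
    connectivity is the group mean with Gaussian between-subject variation
    (SD ``between_subject_sd``) on the modulations that are present in the
    group mean — subjects differ in how strongly difficulty disinhibits
    their auditory core and belt — while parameters whose group mean is
    zero, including every interaction modulation, stay exactly zero;
    average connectivity and drives are shared.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if correlation_spec is None:
        corr = {"between": 0.35, "within": 0.55}
    elif np.isscalar(correlation_spec):
        corr = {"between": float(correlation_spec),
                "within": float(correlation_spec)}
    else:
        corr = dict(correlation_spec)
    rw = _rank_to_pearson(corr["within"])
    rb = _rank_to_pearson(corr["between"])
    cmat = np.array([[1, rw, rb, rb],
                     [rw, 1, rb, rb],
                     [rb, rb, 1, rw],
                     [rb, rb, rw, 1]])
    chol = np.linalg.cholesky(cmat)
    mean = np.asarray(threshold_means, dtype=float)
    group = default_group_dcm(regions)
    mod_idx = np.nonzero(group.B)

    profiles: list[SubjectProfile] = []
    for _ in range(n_subjects):
        for _attempt in range(1000):
            t = mean + threshold_sd * (chol @ rng.standard_normal(4))
            if t[0] < t[1] and t[2] < t[3]:
                break
        else:
            raise RuntimeError("could not draw ordered thresholds")
        thresholds = dict(zip(CONDITIONS, map(float, t)))
        observers = {
            task: _observer_from_thresholds(thresholds[f"{task}-60"],
                                            thresholds[f"{task}-90"])
            for task in TASKS
        }
        dcm = DCMParameters(A=group.A.copy(), B=group.B.copy(),
                            C=group.C.copy(), hemo=group.hemo,
                            regions=regions)
        dcm.B[mod_idx] += between_subject_sd * rng.standard_normal(
            len(mod_idx[0]))
        profiles.append(SubjectProfile(thresholds=thresholds,
                                       observers=observers, dcm=dcm))
    return profiles


@dataclass
class GroupDataset:
    """A complete synthetic study: BOLD, events, behavior, covariates."""

    design: ExperimentDesign
    profiles: list[SubjectProfile]
    timeseries: list[ROITimeseries]
    behavior: list[pd.DataFrame]
    covariates: np.ndarray               # subjects x 4 (abs TMR per condition)
    snr: float
    dt: float
    master_seed: int
    regions: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.profiles)

    def inputs(self) -> InputSet:
        return InputSet.from_events(self.design.events, dt=self.dt,
                                    run_duration=self.design.run_duration,
                                    tr=self.design.tr,
                                    scan_period=self.design.trial_period)

    def covariate_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates,
                          columns=[f"abs_tmr_{c}" for c in CONDITIONS])
        df.insert(0, "subject", [f"sub-{i + 1:02d}"
                                 for i in range(self.n_subjects)])
        return df

    def truth_record(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "snr": self.snr,
            "dt": self.dt,
            "regions": list(self.regions),
            "group_mean_B": default_group_dcm(self.regions).B.tolist(),
            "subjects": [
                {"thresholds": p.thresholds, "A": p.dcm.A.tolist(),
                 "B": p.dcm.B.tolist(), "C": p.dcm.C.tolist()}
                for p in self.profiles
            ],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i in range(self.n_subjects):
            sub = path / f"sub-{i + 1:02d}"
            sub.mkdir(exist_ok=True)
            self.timeseries[i].to_csv(sub / "timeseries.csv")
            self.design.events.to_csv(sub / "events.tsv", sep="\t",
                                      index=False)
            self.behavior[i].to_csv(sub / "behavior.tsv", sep="\t",
                                    index=False)
        self.covariate_table().to_csv(path / "covariates.csv", index=False)
        (path / "truth.json").write_text(json.dumps(self.truth_record()))
        meta = {"master_seed": self.master_seed, "snr": self.snr,
                "dt": self.dt, "n_subjects": self.n_subjects,
                "regions": list(self.regions),
                "n_runs": self.design.n_runs,
                "trials_per_run": self.design.trials_per_run}
        (path / "dataset.json").write_text(json.dumps(meta, indent=1))
        return path


def _simulate_behavior(profile: SubjectProfile, design: ExperimentDesign,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Yes/no responses at the subject's fixed condition TMRs.

    The target (figure gap / matching sentence) is present on half the
    trials; the observer answers correctly with its psychometric
    probability at the condition TMR, so hits and correct rejections rise
    together with TMR (unbiased responding).
    """
    rows = []
    for row in design.events.itertuples(index=False):
        cond = row.trial_type
        task = cond.split("-")[0]
        tmr = profile.thresholds[cond]
        p = profile.observers[task].p_correct(tmr)
        present = bool(rng.random() < 0.5)
        correct = bool(rng.random() < p)
        response = present if correct else not present
        rows.append({"run": row.run, "onset": row.onset, "condition": cond,
                     "tmr_db": tmr, "target_present": int(present),
                     "response_yes": int(response), "correct": int(correct)})
    return pd.DataFrame(rows)


def generate_group_dataset(design: ExperimentDesign,
                           profiles: list[SubjectProfile], snr: float = 2.0,
                           seed: int = 0, dt: float = 0.05) -> GroupDataset:
    """Forward-simulate BOLD and behavior for every subject.

    Observation noise is white Gaussian, scaled per region so that
    std(signal)/std(noise) equals ``snr``.  Substream k of the master seed
    drives subject k's noise and behavior, so datasets are reproducible
    and subjects independent.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    streams = np.random.SeedSequence(seed).spawn(len(profiles))
    inputs = InputSet.from_events(design.events, dt=dt,
                                  run_duration=design.run_duration,
                                  tr=design.tr,
                                  scan_period=design.trial_period)
    series: list[ROITimeseries] = []
    behavior: list[pd.DataFrame] = []
    for profile, stream in zip(profiles, streams):
        rng = np.random.default_rng(stream)
        clean = integrate_and_sample(profile.dcm, inputs)
        sd = clean.data.std(axis=1) / snr
        noisy = clean.data + sd[:, None] * rng.standard_normal(
            clean.data.shape)
        series.append(ROITimeseries(regions=clean.regions, data=noisy,
                                    n_runs=clean.n_runs,
                                    scans_per_run=clean.scans_per_run,
                                    tr=clean.tr,
                                    scan_period=clean.scan_period))
        behavior.append(_simulate_behavior(profile, design, rng))
    covariates = np.array([p.tmr_covariates() for p in profiles])
    return GroupDataset(design=design, profiles=profiles, timeseries=series,
                        behavior=behavior, covariates=covariates, snr=snr,
                        dt=dt, master_seed=seed,
                        regions=profiles[0].dcm.regions)
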