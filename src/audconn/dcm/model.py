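"""Generative model definitions: bilinear neural dynamics, balloon
hemodynamics, experimental inputs, and the region-timeseries container.

Neural populations in R regions evolve as

    dz/dt = Abar(u) z + C u

where the effective coupling ``Abar(u)`` has off-diagonal entries
``A_ik + sum_j u_j B_j,ik`` (Hz) and diagonal (self) entries
``-0.5 * exp(a_ii + sum_j u_j b_j,ii)``.  The log-scaling convention for
self-connections guarantees self-inhibition for any input, and makes a
*negative* modulation b a *disinhibition* (slower decay, higher gain).

Each region's neural activity drives a balloon/windkessel hemodynamic
cascade (vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin
q) whose states determine the BOLD signal.  Experimental inputs are trial
boxcars: an all-trials drive plus effect-coded task, difficulty, and
task-by-difficulty regressors; difficulty and the interaction additionally
modulate connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS_8", "REGIONS_4", "INPUT_NAMES", "MOD_INPUTS", "CONDITIONS",
    "condition_codes", "HemodynamicParams", "DCMParameters", "InputSet",
    "ROITimeseries", "neural_derivative", "hemo_derivative",
    "bold_observation",
]

# Auditory-cortex parcels: core (Te1.0), posteromedial belt (Te1.1),
# anterolateral belt (Te1.2), higher auditory cortex (Te3), per hemisphere.
REGIONS_8 = ("L_Te1.0", "L_Te1.1", "L_Te1.2", "L_Te3",
             "R_Te1.0", "R_Te1.1", "R_Te1.2", "R_Te3")
REGIONS_4 = REGIONS_8[:4]

# Driving inputs.  "difficulty" and "interaction" also modulate connections.
INPUT_NAMES = ("all", "task", "difficulty", "interaction")
MOD_INPUTS = (2, 3)

CONDITIONS = ("SFG-60", "SFG-90", "SPIN-60", "SPIN-90")

#: echo time used by the BOLD observation equation (s)
TE = 0.03
_NU0 = 40.3    # frequency offset of fully deoxygenated blood (Hz)
_R0 = 25.0     # intravascular relaxation slope (Hz)

SELF_DECAY = -0.5   # baseline self-connection (Hz)


def condition_codes() -> np.ndarray:
    """Input vector u for each condition, shape (4 conditions, 4 inputs).

    Main effects are coded +/- 1/2 on trials (task: SPIN = +1/2,
    figure-ground = -1/2; difficulty: 60%-threshold = +1/2 i.e. harder,
    90%-threshold = -1/2); the interaction is their product (+/- 1/4).
    """
    u = np.zeros((4, 4))
    for k, cond in enumerate(CONDITIONS):
        task, level = cond.split("-")
        t = 0.5 if task == "SPIN" else -0.5
        d = 0.5 if level == "60" else -0.5
        u[k] = (1.0, t, d, t * d)
    return u


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model constants (canonical defaults).

    kappa   vasodilatory signal decay rate (1/s)
    gamma   flow-dependent feedback rate (1/s)
    tau     venous transit time (s)
    alpha   vessel stiffness exponent (Grubb)
    E0      resting oxygen extraction fraction
    V0      resting venous blood volume fraction
    epsilon intra/extravascular signal ratio
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 0.04
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.tau, self.V0, self.epsilon) <= 0:
            raise ValueError("hemodynamic constants must be positive")
        if not (0 < self.E0 < 1) or not (0 < self.alpha < 1):
            raise ValueError("require 0 < E0 < 1 and 0 < alpha < 1")

    def k_coefficients(self) -> tuple[float, float, float]:
        """BOLD observation coefficients (k1, k2, k3)."""
        k1 = 4.3 * _NU0 * self.E0 * TE
        k2 = self.epsilon * _R0 * self.E0 * TE
        k3 = 1.0 - self.epsilon
        return k1, k2, k3


@dataclass
class DCMParameters:
    """The generative model's connectivity and hemodynamic parameters.

    ``A`` (R x R): off-diagonal entries are extrinsic couplings in Hz;
    diagonal entries are unitless log-scalings of the -0.5 Hz baseline
    self-connection.  ``B`` (n_mod x R x R) uses the same convention, one
    matrix per modulatory input (difficulty, interaction).  ``C`` (R x m)
    holds driving-input weights.  Hemodynamic constants may be scalar
    (shared) or per-region; ``tau_scale``/``kappa_scale`` are per-region
    log-scalings of tau and kappa used by the inversion.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    regions: tuple[str, ...] = REGIONS_8
    tau_scale: np.ndarray | None = None      # per-region log-scaling of tau
    kappa_scale: np.ndarray | None = None    # per-region log-scaling of kappa

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        r = self.A.shape[0]
        if self.A.shape != (r, r):
            raise ValueError("A must be square")
        if self.B.ndim != 3 or self.B.shape[1:] != (r, r):
            raise ValueError("B must be (n_mod, R, R)")
        if self.C.shape[0] != r:
            raise ValueError("C must have one row per region")
        if len(self.regions) != r:
            raise ValueError("region labels must match A")
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()
                and np.isfinite(self.C).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @classmethod
    def zeros(cls, regions: tuple[str, ...] = REGIONS_8,
              n_mod: int = len(MOD_INPUTS),
              n_inputs: int = len(INPUT_NAMES), **kw) -> "DCMParameters":
        r = len(regions)
        return cls(A=np.zeros((r, r)), B=np.zeros((n_mod, r, r)),
                   C=np.zeros((r, n_inputs)), regions=regions, **kw)

    def tau_per_region(self) -> np.ndarray:
        t = np.full(self.n_regions, self.hemo.tau)
        if self.tau_scale is not None:
            t = t * np.exp(np.asarray(self.tau_scale, dtype=float))
        return t

    def kappa_per_region(self) -> np.ndarray:
        k = np.full(self.n_regions, self.hemo.kappa)
        if self.kappa_scale is not None:
            k = k * np.exp(np.asarray(self.kappa_scale, dtype=float))
        return k

    def to_json(self, path: str | Path) -> None:
        d = {
            "regions": list(self.regions),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "hemo": {k: getattr(self.hemo, k) for k in
                     ("kappa", "gamma", "tau", "alpha", "E0", "V0", "epsilon")},
            "layout": {"A": "[to][from]; diagonal = log-scaling of -0.5 Hz",
                       "B": "[mod_input][to][from]", "C": "[region][input]",
                       "inputs": list(INPUT_NAMES)},
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DCMParameters":
        d = json.loads(Path(path).read_text())
        return cls(A=np.array(d["A"]), B=np.array(d["B"]), C=np.array(d["C"]),
                   hemo=HemodynamicParams(**d["hemo"]),
                   regions=tuple(d["regions"]))


def effective_coupling(params: DCMParameters, u: np.ndarray) -> np.ndarray:
    """Input-dependent dynamics matrix Abar(u) in Hz."""
    u = np.asarray(u, dtype=float)
    mod = np.array([u[j] for j in MOD_INPUTS])
    M = params.A + np.tensordot(mod, params.B, axes=1)
    out = M.copy()
    np.fill_diagonal(out, SELF_DECAY * np.exp(np.diag(M)))
    return out


def neural_derivative(z: np.ndarray, u: np.ndarray,
                      params: DCMParameters) -> np.ndarray:
    """dz/dt of the bilinear neural model (Hz)."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (params.n_regions,) or u.shape != (params.C.shape[1],):
        raise ValueError("dimension mismatch")
    return effective_coupling(params, u) @ z + params.C @ u


def hemo_derivative(h: np.ndarray, z: np.ndarray | float,
                    hemo: HemodynamicParams,
                    tau: np.ndarray | float | None = None,
                    kappa: np.ndarray | float | None = None) -> np.ndarray:
    """Balloon-model derivative d(s, f, v, q)/dt for one or more regions.

    ``h`` is (..., 4) with states (s, f, v, q); f, v, q must be positive.
    ``tau``/``kappa`` override the shared constants per region.
    """
    h = np.asarray(h, dtype=float)
    s, f, v, q = np.moveaxis(h, -1, 0)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("f, v, q must be positive")
    tau = hemo.tau if tau is None else tau
    kappa = hemo.kappa if kappa is None else kappa
    ds = np.asarray(z, dtype=float) - kappa * s - hemo.gamma * (f - 1.0)
    df = s
    outflow = v ** (1.0 / hemo.alpha)
    dv = (f - outflow) / tau
    extraction = (1.0 - (1.0 - hemo.E0) ** (1.0 / f)) / hemo.E0
    dq = (f * extraction - outflow * q / v) / tau
    return np.stack(np.broadcast_arrays(ds, df, dv, dq), axis=-1)


def bold_observation(h: np.ndarray, hemo: HemodynamicParams) -> np.ndarray:
    """BOLD signal (percent) from hemodynamic states (..., 4)."""
    h = np.asarray(h, dtype=float)
    v, q = h[..., 2], h[..., 3]
    k1, k2, k3 = hemo.k_coefficients()
    return 100.0 * hemo.V0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))


@dataclass
class InputSet:
    """Trial inputs on a fine time grid, plus sparse acquisition times.

    Inputs are piecewise constant: at any instant either no trial is active
    (condition index 0) or exactly one of the four conditions is (index
    1..4).  This is exploited by the integrator, which pre-computes one
    dynamics matrix per distinct input vector.  Runs are integrated
    independently from rest.
    """

    dt: float                              # fine integration step (s)
    cond_idx: np.ndarray                   # (n_runs, n_steps) int8, 0 = baseline
    u_conditions: np.ndarray               # (K+1, m); row 0 = zeros
    acquisition_times: np.ndarray          # (n_scans,) run-relative, s
    run_duration: float                    # s
    tr: float = 3.36
    scan_period: float = 8.0

    def __post_init__(self) -> None:
        t = self.acquisition_times
        if not np.all(np.diff(t) > 0):
            raise ValueError("acquisition times must be strictly increasing")
        if t.size > 1 and not np.allclose(np.diff(t), self.scan_period):
            raise ValueError("acquisition times must be spaced scan_period apart")

    @property
    def n_runs(self) -> int:
        return self.cond_idx.shape[0]

    @property
    def n_steps(self) -> int:
        return self.cond_idx.shape[1]

    @property
    def sample_steps(self) -> np.ndarray:
        return np.round(self.acquisition_times / self.dt).astype(np.int64)

    def regressors(self) -> np.ndarray:
        """Materialize the m input regressors on the fine grid (all runs)."""
        return self.u_conditions[self.cond_idx.ravel()]

    @classmethod
    def from_events(cls, events: pd.DataFrame, dt: float = 0.05,
                    run_duration: float = 192.0, tr: float = 3.36,
                    scan_period: float = 8.0,
                    conditions: tuple[str, ...] = CONDITIONS,
                    onset_resolution: float = 0.1) -> "InputSet":
        """Build inputs from a BIDS-style event table.

        ``events`` needs columns ``onset`` (run-relative, s), ``duration``
        (s), ``trial_type``, and ``run`` (0-based).  Stimuli are modeled as
        neural boxcars of their acoustic duration.  Acquisition k begins
        ``scan_period*(k+1) - tr`` seconds into the run (a volume at the end
        of each trial).  Event edges are quantized to ``onset_resolution``
        so the realized inputs are identical for every fine step that
        divides it (making step-halving convergence checks meaningful).
        """
        if dt > 0.1:
            raise ValueError("fine step must be <= 0.1 s")
        n_runs = int(events["run"].max()) + 1
        n_steps = int(round(run_duration / dt))
        cond_idx = np.zeros((n_runs, n_steps), dtype=np.int8)
        cmap = {c: k + 1 for k, c in enumerate(conditions)}
        res = onset_resolution
        for row in events.itertuples(index=False):
            if row.onset < 0 or row.onset + row.duration > run_duration:
                raise ValueError("event outside the acquisition window")
            t0 = round(row.onset / res) * res
            t1 = round((row.onset + row.duration) / res) * res
            i0 = int(round(t0 / dt))
            i1 = int(round(t1 / dt))
            cond_idx[int(row.run), i0:i1] = cmap[row.trial_type]
        n_scans = int(round(run_duration / scan_period))
        acq = scan_period * np.arange(1, n_scans + 1) - tr
        u = np.vstack([np.zeros(4), condition_codes()])
        return cls(dt=dt, cond_idx=cond_idx, u_conditions=u,
                   acquisition_times=acq, run_duration=run_duration,
                   tr=tr, scan_period=scan_period)


@dataclass
class ROITimeseries:
    """Region-by-scan BOLD data from a sparse-sampling session."""

    regions: tuple[str, ...]
    data: np.ndarray                 # (R, n_scans_total)
    n_runs: int
    scans_per_run: int
    tr: float = 3.36
    scan_period: float = 8.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.regions),
                               self.n_runs * self.scans_per_run):
            raise ValueError("data must be (regions, n_runs * scans_per_run)")

    @property
    def run_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_runs), self.scans_per_run)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data.T, columns=list(self.regions))
        df.insert(0, "run", self.run_index)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, tr: float = 3.36,
                 scan_period: float = 8.0) -> "ROITimeseries":
        df = pd.read_csv(path)
        runs = df.pop("run").to_numpy()
        n_runs = int(runs.max()) + 1
        return cls(regions=tuple(df.columns), data=df.to_numpy().T,
                   n_runs=n_runs, scans_per_run=len(df) // n_runs,
                   tr=tr, scan_period=scan_period)
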