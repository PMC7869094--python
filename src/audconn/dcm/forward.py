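"""Forward integration of the joint neural-hemodynamic model.

The experimental inputs are piecewise constant (at most one trial active at
a time), so the input-dependent dynamics matrix takes only K+1 distinct
values per parameter set.  These are pre-computed once; the inner
fixed-step 4th-order Runge-Kutta loop then reduces to a matrix-vector
product plus element-wise balloon updates and is compiled with numba.  The
integrator is *batched* over parameter vectors, which makes the
finite-difference Jacobians used by the inversion a single call.

BOLD is predicted on the fine grid but returned only at the sparse
acquisition times (one volume at the end of each trial), mirroring a
sparse-sampling acquisition.  Runs are integrated independently from rest.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import (
    MOD_INPUTS,
    SELF_DECAY,
    DCMParameters,
    InputSet,
    ROITimeseries,
    bold_observation,
    hemo_derivative,
    neural_derivative,
)

__all__ = ["StabilityError", "integrate_and_sample", "integrate_batch",
           "integrate_reference", "batch_arrays"]


class StabilityError(RuntimeError):
    """Raised when the joint ODE diverges for the given parameters."""


@njit(cache=True)
def _deriv(Ad, cu, kappa, gamma, tau, ialpha, E0,
           z, s, f, v, q, dz, ds, df, dv, dq):          # pragma: no cover
    R = z.shape[0]
    for i in range(R):
        acc = cu[i]
        for k in range(R):
            acc += Ad[i, k] * z[k]
        dz[i] = acc
        ds[i] = z[i] - kappa[i] * s[i] - gamma[i] * (f[i] - 1.0)
        df[i] = s[i]
        outflow = v[i] ** ialpha[i]
        dv[i] = (f[i] - outflow) / tau[i]
        extraction = (1.0 - (1.0 - E0[i]) ** (1.0 / f[i])) / E0[i]
        dq[i] = (f[i] * extraction - outflow * q[i] / v[i]) / tau[i]


@njit(cache=True)
def _integrate_kernel(Ad, cu, kappa, gamma, tau, ialpha, E0,
                      c1, c2, c3, cond, sample_steps, dt,
                      out, ok):                          # pragma: no cover
    B = Ad.shape[0]
    R = Ad.shape[2]
    n_runs, n_steps = cond.shape
    S = sample_steps.shape[0]
    half = 0.5 * dt
    sixth = dt / 6.0
    z = np.empty(R); s = np.empty(R); f = np.empty(R); v = np.empty(R); q = np.empty(R)
    z1 = np.empty(R); s1 = np.empty(R); f1 = np.empty(R); v1 = np.empty(R); q1 = np.empty(R)
    k1z = np.empty(R); k1s = np.empty(R); k1f = np.empty(R); k1v = np.empty(R); k1q = np.empty(R)
    k2z = np.empty(R); k2s = np.empty(R); k2f = np.empty(R); k2v = np.empty(R); k2q = np.empty(R)
    k3z = np.empty(R); k3s = np.empty(R); k3f = np.empty(R); k3v = np.empty(R); k3q = np.empty(R)
    k4z = np.empty(R); k4s = np.empty(R); k4f = np.empty(R); k4v = np.empty(R); k4q = np.empty(R)
    for b in range(B):
        ok[b] = 1
        col = 0
        for run in range(n_runs):
            for i in range(R):
                z[i] = 0.0; s[i] = 0.0; f[i] = 1.0; v[i] = 1.0; q[i] = 1.0
            si = 0
            for t in range(n_steps):
                if si < S and t == sample_steps[si]:
                    for i in range(R):
                        out[b, i, col] = (c1[b, i] * (1.0 - q[i])
                                          + c2[b, i] * (1.0 - q[i] / v[i])
                                          + c3[b, i] * (1.0 - v[i]))
                    col += 1
                    si += 1
                c = cond[run, t]
                A = Ad[b, c]
                U = cu[b, c]
                _deriv(A, U, kappa[b], gamma[b], tau[b], ialpha[b], E0[b],
                       z, s, f, v, q, k1z, k1s, k1f, k1v, k1q)
                for i in range(R):
                    z1[i] = z[i] + half * k1z[i]; s1[i] = s[i] + half * k1s[i]
                    f1[i] = f[i] + half * k1f[i]; v1[i] = v[i] + half * k1v[i]
                    q1[i] = q[i] + half * k1q[i]
                _deriv(A, U, kappa[b], gamma[b], tau[b], ialpha[b], E0[b],
                       z1, s1, f1, v1, q1, k2z, k2s, k2f, k2v, k2q)
                for i in range(R):
                    z1[i] = z[i] + half * k2z[i]; s1[i] = s[i] + half * k2s[i]
                    f1[i] = f[i] + half * k2f[i]; v1[i] = v[i] + half * k2v[i]
                    q1[i] = q[i] + half * k2q[i]
                _deriv(A, U, kappa[b], gamma[b], tau[b], ialpha[b], E0[b],
                       z1, s1, f1, v1, q1, k3z, k3s, k3f, k3v, k3q)
                for i in range(R):
                    z1[i] = z[i] + dt * k3z[i]; s1[i] = s[i] + dt * k3s[i]
                    f1[i] = f[i] + dt * k3f[i]; v1[i] = v[i] + dt * k3v[i]
                    q1[i] = q[i] + dt * k3q[i]
                _deriv(A, U, kappa[b], gamma[b], tau[b], ialpha[b], E0[b],
                       z1, s1, f1, v1, q1, k4z, k4s, k4f, k4v, k4q)
                bad = False
                for i in range(R):
                    z[i] += sixth * (k1z[i] + 2 * k2z[i] + 2 * k3z[i] + k4z[i])
                    s[i] += sixth * (k1s[i] + 2 * k2s[i] + 2 * k3s[i] + k4s[i])
                    f[i] += sixth * (k1f[i] + 2 * k2f[i] + 2 * k3f[i] + k4f[i])
                    v[i] += sixth * (k1v[i] + 2 * k2v[i] + 2 * k3v[i] + k4v[i])
                    q[i] += sixth * (k1q[i] + 2 * k2q[i] + 2 * k3q[i] + k4q[i])
                    if (not np.isfinite(z[i])) or abs(z[i]) > 1e6 \
                            or f[i] <= 1e-6 or v[i] <= 1e-6 or q[i] <= 1e-6:
                        bad = True
                if bad:
                    ok[b] = 0
                    break
            if ok[b] == 0:
                break
        if ok[b] == 0:
            for i in range(R):
                for j in range(out.shape[2]):
                    out[b, i, j] = 1e6


def batch_arrays(A: np.ndarray, Bm: np.ndarray, C: np.ndarray,
                 u_conditions: np.ndarray, hemo_arrays: dict[str, np.ndarray]
                 ) -> tuple[np.ndarray, ...]:
    """Assemble kernel inputs from batched parameter arrays.

    A: (B,R,R) with diagonal log-scalings; Bm: (B,n_mod,R,R); C: (B,R,m);
    hemo_arrays: per-region (B,R) arrays kappa, gamma, tau, alpha, E0 and
    observation coefficients c1..c3 (already scaled to percent).
    Returns (Ad, cu, kappa, gamma, tau, ialpha, E0, c1, c2, c3).
    """
    u_mod = u_conditions[:, list(MOD_INPUTS)]                    # (K, n_mod)
    M = A[:, None] + np.einsum("kj,bjrs->bkrs", u_mod, Bm)       # (B,K,R,R)
    Ad = M.copy()
    r = A.shape[1]
    idx = np.arange(r)
    Ad[:, :, idx, idx] = SELF_DECAY * np.exp(M[:, :, idx, idx])
    cu = np.einsum("brm,km->bkr", C, u_conditions)
    h = hemo_arrays
    return (np.ascontiguousarray(Ad), np.ascontiguousarray(cu),
            h["kappa"], h["gamma"], h["tau"], 1.0 / h["alpha"], h["E0"],
            h["c1"], h["c2"], h["c3"])


def _hemo_arrays(params: DCMParameters, batch: int = 1) -> dict[str, np.ndarray]:
    r = params.n_regions
    h = params.hemo
    k1, k2, k3 = h.k_coefficients()
    scale = 100.0 * h.V0

    def tile(x):
        return np.tile(np.broadcast_to(np.asarray(x, float), (r,)), (batch, 1))

    return {
        "kappa": tile(params.kappa_per_region()),
        "gamma": tile(h.gamma),
        "tau": tile(params.tau_per_region()),
        "alpha": tile(h.alpha),
        "E0": tile(h.E0),
        "c1": tile(scale * k1),
        "c2": tile(scale * k2),
        "c3": tile(scale * k3),
    }


def integrate_batch(Ad, cu, kappa, gamma, tau, ialpha, E0, c1, c2, c3,
                    inputs: InputSet) -> tuple[np.ndarray, np.ndarray]:
    """Run the compiled integrator; returns (y, ok).

    y has shape (B, R, n_runs * n_scans); ok flags stable batch elements.
    """
    B, _, R = cu.shape
    sample_steps = inputs.sample_steps
    out = np.empty((B, R, inputs.n_runs * sample_steps.size))
    ok = np.empty(B, dtype=np.uint8)
    _integrate_kernel(Ad, cu, kappa, gamma, tau, ialpha, E0, c1, c2, c3,
                      inputs.cond_idx, sample_steps, inputs.dt, out, ok)
    return out, ok


def integrate_and_sample(params: DCMParameters, inputs: InputSet) -> ROITimeseries:
    """Integrate the joint model and sample BOLD at the acquisition times."""
    if inputs.dt > 0.1:
        raise ValueError("fine integration step must be <= 0.1 s")
    hemo = _hemo_arrays(params, batch=1)
    arrays = batch_arrays(params.A[None], params.B[None], params.C[None],
                          inputs.u_conditions, hemo)
    y, ok = integrate_batch(*arrays, inputs)
    if not ok[0]:
        worst = np.unravel_index(np.argmax(np.abs(params.A)), params.A.shape)
        raise StabilityError(
            "joint model diverged; largest |A| entry at "
            f"{params.regions[worst[0]]}<-{params.regions[worst[1]]} "
            f"= {params.A[worst]:.3f} Hz")
    return ROITimeseries(regions=params.regions, data=y[0],
                         n_runs=inputs.n_runs,
                         scans_per_run=inputs.sample_steps.size,
                         tr=inputs.tr, scan_period=inputs.scan_period)


def integrate_reference(params: DCMParameters, inputs: InputSet) -> np.ndarray:
    """Slow pure-numpy RK4 built from the public derivative functions.

    Independent of the compiled kernel; used to validate it.  Returns
    (R, n_runs * n_scans).
    """
    r = params.n_regions
    dt = inputs.dt
    tau = np.broadcast_to(params.tau_per_region(), (r,))
    kappa = np.broadcast_to(params.kappa_per_region(), (r,))
    sample_steps = set(inputs.sample_steps.tolist())
    cols = []
    for run in range(inputs.n_runs):
        z = np.zeros(r)
        h = np.tile([0.0, 1.0, 1.0, 1.0], (r, 1))
        for t in range(inputs.n_steps):
            if t in sample_steps:
                cols.append(bold_observation(h, params.hemo))
            u = inputs.u_conditions[inputs.cond_idx[run, t]]

            def deriv(zc, hc):
                dz = neural_derivative(zc, u, params)
                dh = hemo_derivative(hc, zc, params.hemo, tau=tau, kappa=kappa)
                return dz, dh

            dz1, dh1 = deriv(z, h)
            dz2, dh2 = deriv(z + 0.5 * dt * dz1, h + 0.5 * dt * dh1)
            dz3, dh3 = deriv(z + 0.5 * dt * dz2, h + 0.5 * dt * dh2)
            dz4, dh4 = deriv(z + dt * dz3, h + dt * dh3)
            z = z + dt / 6 * (dz1 + 2 * dz2 + 2 * dz3 + dz4)
            h = h + dt / 6 * (dh1 + 2 * dh2 + 2 * dh3 + dh4)
    return np.array(cols).T
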