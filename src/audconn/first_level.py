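"""First-level (within-subject) analysis of sparse-sampled BOLD.

Condition regressors are built by placing a delta function at each stimulus
onset, convolving with the canonical double-gamma hemodynamic response
function on a fine grid, and reading the result off at the sparse
acquisition times.  Ordinary least squares with run intercepts and motion
covariates of no interest gives per-region contrast t statistics.

Multivoxel summaries use the principal eigenvariate (first singular-vector
timeseries of a voxel-by-scan matrix) and canonical variate analysis (CVA)
of a design contrast against a multivoxel response, with Wilks'-lambda
chi-square significance and Fisher's method for combining subject p-values
at the group level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import null_space, orth

__all__ = [
    "DesignMatrix", "CVAResult", "canonical_hrf", "build_design",
    "glm_contrast", "principal_eigenvariate", "cva", "fisher_combine",
    "select_voxels",
]

# canonical double-gamma response: peak 6 s, undershoot 16 s, ratio 6
_HRF_PEAK_SHAPE = 6.0
_HRF_UNDER_SHAPE = 16.0
_HRF_RATIO = 6.0


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical hemodynamic response sampled at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, _HRF_PEAK_SHAPE) \
        - stats.gamma.pdf(t, _HRF_UNDER_SHAPE) / _HRF_RATIO
    return np.where(t >= 0, h, 0.0)


@dataclass
class DesignMatrix:
    """Scans-by-regressors design with labels and sampling times."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    times: np.ndarray          # session-relative acquisition times (s)

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.times.size, len(self.labels)):
            raise ValueError("matrix shape must be (n_scans, n_labels)")

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def build_design(events, acquisition_times: np.ndarray,
                 motion: np.ndarray | None = None,
                 run_index: np.ndarray | None = None,
                 conditions: tuple[str, ...] | None = None) -> DesignMatrix:
    """HRF-convolved condition regressors sampled at acquisition times.

    ``events`` is a table with session-relative ``onset`` (s) and
    ``trial_type`` columns; stimuli are modeled as delta functions.  Motion
    covariates (scans x k) and per-run intercepts are appended as
    regressors of no interest.
    """
    acquisition_times = np.asarray(acquisition_times, dtype=float)
    onsets = np.asarray(events["onset"], dtype=float)
    ttype = np.asarray(events["trial_type"])
    if conditions is None:
        conditions = tuple(dict.fromkeys(ttype))
    if onsets.size and (onsets.min() < 0
                        or onsets.max() > acquisition_times.max()):
        raise ValueError("event onsets outside the acquisition window")
    cols = []
    labels = []
    for cond in conditions:
        on = onsets[ttype == cond]
        # superposition of shifted HRFs evaluated exactly at scan times
        col = canonical_hrf(acquisition_times[:, None] - on[None, :]).sum(axis=1) \
            if on.size else np.zeros(acquisition_times.size)
        cols.append(col)
        labels.append(cond)
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != acquisition_times.size:
            motion = motion.T
        for k in range(motion.shape[1]):
            cols.append(motion[:, k])
            labels.append(f"motion{k}")
    if run_index is not None:
        run_index = np.asarray(run_index)
        for r in np.unique(run_index):
            cols.append((run_index == r).astype(float))
            labels.append(f"run{r}")
    else:
        cols.append(np.ones(acquisition_times.size))
        labels.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), labels=tuple(labels),
                        times=acquisition_times)


def glm_contrast(Y: np.ndarray, X: DesignMatrix | np.ndarray,
                 c: np.ndarray) -> np.ndarray:
    """OLS contrast t statistic, one per response column.

    ``Y`` is scans x responses (a single series may be 1-D); ``c`` is a
    contrast vector over the design columns.  Zero-residual fits return a
    large finite t with a warning rather than infinity.
    """
    x = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    c = np.asarray(c, dtype=float)
    n, q = x.shape
    if c.shape != (q,):
        raise ValueError("contrast length must match design columns")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    cvar = c @ xtx_inv @ c
    num = c @ beta
    if cvar == 0:
        return np.zeros(y.shape[1])
    se = np.sqrt(sigma2 * cvar)
    t = np.empty(y.shape[1])
    tiny = se < 1e-10 * (np.abs(num) + 1e-300)
    if tiny.any():
        warnings.warn(f"zero-residual fit; t capped (residual df={dof})",
                      RuntimeWarning, stacklevel=2)
    t[tiny] = np.sign(num[tiny]) * 1e8
    t[~tiny] = num[~tiny] / se[~tiny]
    return t


def principal_eigenvariate(Y: np.ndarray) -> np.ndarray:
    """Summary timeseries of a voxels-by-scans matrix.

    First right singular vector, scaled to unit variance, with its sign
    chosen so it correlates positively with the voxel-mean timeseries.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim != 2:
        raise ValueError("Y must be voxels x scans")
    _, _, vt = np.linalg.svd(y - y.mean(axis=1, keepdims=True),
                             full_matrices=False)
    v = vt[0]
    m = y.mean(axis=0)
    if np.dot(v, m - m.mean()) < 0:
        v = -v
    sd = v.std()
    return v / sd if sd > 0 else v


@dataclass(frozen=True)
class CVAResult:
    correlations: np.ndarray
    chi2: float
    df: int
    p_value: float


def cva(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> CVAResult:
    """Canonical variate analysis of a design contrast against ``Y``.

    The design is split into the contrast subspace X@C and its complement
    (nuisance); both the response and the contrast regressors are
    residualized against the nuisance before computing canonical
    correlations.  Significance of the full set of correlations uses the
    Wilks'-lambda chi-square (Bartlett) approximation.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(X, dtype=float)
    n, p = y.shape
    if p >= n:
        raise ValueError("more response dimensions than observations")
    cmat = np.atleast_2d(np.asarray(contrast, dtype=float))
    if cmat.shape[0] != x.shape[1]:
        cmat = cmat.T
    xc = x @ cmat
    c0 = null_space(cmat.T)
    x0 = x @ c0 if c0.size else np.zeros((n, 0))
    rank0 = 0
    if x0.shape[1]:
        q0 = orth(x0)
        rank0 = q0.shape[1]
        y = y - q0 @ (q0.T @ y)
        xc = xc - q0 @ (q0.T @ xc)
    y = y - y.mean(axis=0) if rank0 == 0 else y
    qy = orth(y - 0.0)
    qx = orth(xc)
    if qy.size == 0 or qx.size == 0:
        raise ValueError("degenerate response or contrast space")
    rho = np.linalg.svd(qy.T @ qx, compute_uv=False)
    rho = np.clip(rho, 0.0, 1.0 - 1e-12)
    k = qx.shape[1]
    wilks = np.prod(1.0 - rho ** 2)
    n_eff = n - rank0
    chi2 = -(n_eff - 1 - (p + k + 1) / 2.0) * np.log(wilks)
    df = p * k
    return CVAResult(correlations=rho, chi2=float(chi2), df=int(df),
                     p_value=float(stats.chi2.sf(chi2, df)))


def fisher_combine(p_values: np.ndarray) -> tuple[float, int, float]:
    """Fisher's method: chi-square = -2 sum(ln p), df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def select_voxels(group_p: np.ndarray, subject_p: np.ndarray,
                  group_alpha: float = 0.05, subject_alpha: float = 0.05,
                  step: float = 0.05) -> tuple[np.ndarray, float]:
    """Two-level voxel selection with threshold relaxation.

    Voxels must pass the (corrected) group threshold; among those, voxels
    passing the subject threshold are retained.  If none survive, the
    subject threshold is raised in ``step`` increments until at least one
    voxel does.  Returns (indices, final subject threshold).
    """
    group_p = np.asarray(group_p, dtype=float)
    subject_p = np.asarray(subject_p, dtype=float)
    mask = group_p <= group_alpha
    if not mask.any():
        raise ValueError("no voxels pass the group threshold")
    alpha = subject_alpha
    while alpha <= 1.0:
        idx = np.nonzero(mask & (subject_p <= alpha))[0]
        if idx.size:
            return idx, alpha
        alpha = round(alpha + step, 10)
    raise ValueError("no voxels survive any subject threshold")
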