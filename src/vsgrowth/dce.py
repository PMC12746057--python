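"""Spoiled-gradient-echo signal modelling and extended Tofts pharmacokinetics.

This module covers the quantitative DCE-MRI chain: the SPGR steady-state
signal equation, variable-flip-angle (VFA) T1 mapping, conversion of dynamic
signal to gadolinium concentration, and forward simulation / voxelwise
nonlinear fitting of the extended Tofts model (ETM)

    C_t(t) = v_p C_p(t) + K^trans \\int_0^t C_p(tau) exp(-k_ep (t - tau)) dtau

with k_ep = K^trans / v_e.  K^trans and k_ep are expressed in 1/min, time
grids are seconds at the module boundary and converted to minutes
internally, concentrations are mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AcquisitionParams",
    "BiexponentialAIF",
    "ParameterMaps",
    "spgr_signal",
    "fit_t1_vfa",
    "concentration_from_signal",
    "etm_forward",
    "fit_etm_voxel",
    "fit_etm_map",
    "DEFAULT_BOUNDS",
]

#: Bounded search region for (K^trans [1/min], v_e, v_p); encloses reported
#: tumour values with a wide margin.
DEFAULT_BOUNDS = ((0.0, 2.0), (1e-3, 1.0), (0.0, 0.5))

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class AcquisitionParams:
    """DCE acquisition description.

    Parameters
    ----------
    tr : repetition time in seconds.
    flip_angles : VFA flip angles in degrees (>= 2 for T1 mapping).
    dce_flip_angle : flip angle of the dynamic series, degrees.
    time_grid : frame times in seconds, strictly increasing.
    r1_relaxivity : contrast agent longitudinal relaxivity, 1/(s mM).
    baseline_frames : number of pre-contrast frames (>= 1).
    """

    tr: float
    flip_angles: tuple[float, ...]
    dce_flip_angle: float
    time_grid: np.ndarray
    r1_relaxivity: float = 4.5
    baseline_frames: int = 5

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        angles = tuple(float(a) for a in self.flip_angles)
        if any(a <= 0 or a > 90 for a in angles + (self.dce_flip_angle,)):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        t = np.asarray(self.time_grid, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        object.__setattr__(self, "flip_angles", angles)
        object.__setattr__(self, "time_grid", t)


@dataclass(frozen=True)
class BiexponentialAIF:
    """Population arterial input function C_p(t).

    A Weinmann-style biexponential decay scaled by injected dose, with a
    smooth exponential bolus rise so C_p is continuous at onset:
    ``C_p(t) = dose * (1 - exp(-r tau)) * sum_i a_i exp(-m_i tau)`` with
    ``tau = (t - onset)`` for t >= onset, zero before.  Amplitudes in
    kg/L, rates in 1/min, dose in mmol/kg, so C_p is in mM.
    """

    dose: float = 0.1
    amplitudes: tuple[float, float] = (3.99, 4.78)
    rates: tuple[float, float] = (0.144, 0.0111)
    rise_rate: float = 8.0  # 1/min; near-peak within ~30 s of onset
    onset_s: float = 60.0

    def plasma_concentration(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        tau_min = np.clip(t_s - self.onset_s, 0.0, None) / SECONDS_PER_MINUTE
        cp = self.dose * (1.0 - np.exp(-self.rise_rate * tau_min)) * sum(
            a * np.exp(-m * tau_min) for a, m in zip(self.amplitudes, self.rates)
        )
        return np.where(t_s >= self.onset_s, cp, 0.0)

    __call__ = plasma_concentration


@dataclass
class ParameterMaps:
    """Voxelwise ETM parameter maps on the ROI grid.

    Values are NaN outside ``mask``.  ``converged`` marks voxels whose fit
    terminated successfully; sentinel NaNs are never silent.
    """

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    mask: np.ndarray
    fit_rmse: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() == 0:
            raise ValueError("parameter maps require a nonempty mask")
        m = self.mask
        if np.any(self.ktrans[m] < 0):
            raise ValueError("ktrans must be nonnegative inside the mask")
        if np.any((self.ve[m] <= 0) | (self.ve[m] > 1)):
            raise ValueError("ve must lie in (0, 1] inside the mask")
        if np.any((self.vp[m] < 0) | (self.vp[m] > 1)):
            raise ValueError("vp must lie in [0, 1] inside the mask")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"ktrans": self.ktrans, "ve": self.ve, "vp": self.vp}


# ---------------------------------------------------------------------------
# SPGR signal model and T1 mapping
# ---------------------------------------------------------------------------

def spgr_signal(m0, t1, alpha_deg, tr):
    """Spoiled gradient-echo steady-state signal.

    ``S = M0 sin(a) (1 - E1) / (1 - cos(a) E1)`` with ``E1 = exp(-TR/T1)``.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if tr <= 0:
        raise ValueError("TR must be positive")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def fit_t1_vfa(signals, flip_angles_deg, tr):
    """Linearised VFA T1 fit.

    Regresses ``S/sin(a)`` on ``S/tan(a)`` across flip angles; the slope is
    ``E1`` and the intercept ``M0 (1 - E1)``.  Works voxelwise on arrays
    whose leading axis indexes flip angles.  Voxels with a slope outside
    (0, 1) or a degenerate design are returned as NaN.

    Returns
    -------
    (t10, m0) arrays of the trailing shape.
    """
    s = np.asarray(signals, dtype=float)
    angles = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    if angles.size < 2 or np.unique(angles).size < 2:
        raise ValueError("VFA fitting requires >= 2 distinct flip angles")
    if s.shape[0] != angles.size:
        raise ValueError("leading axis of signals must match flip angles")

    sin_a = np.sin(angles).reshape((-1,) + (1,) * (s.ndim - 1))
    tan_a = np.tan(angles).reshape((-1,) + (1,) * (s.ndim - 1))
    y = s / sin_a
    x = s / tan_a
    n = float(angles.size)
    sx, sy = x.sum(axis=0), y.sum(axis=0)
    sxx, sxy = (x * x).sum(axis=0), (x * y).sum(axis=0)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        bad = (~np.isfinite(slope)) | (slope <= 0) | (slope >= 1)
        bad |= np.isclose(denom, 0.0)
        # identical signal across angles cannot come from one (T1, M0)
        bad |= np.all(np.isclose(s, s[:1]), axis=0)
        t10 = -tr / np.log(slope)
        m0 = intercept / (1.0 - slope)
    t10 = np.where(bad, np.nan, t10)
    m0 = np.where(bad, np.nan, m0)
    if np.ndim(signals[0]) == 0:
        return float(t10), float(m0)
    return t10, m0


def concentration_from_signal(signal_t, s_pre, t10, acquisition: AcquisitionParams):
    """Convert a dynamic SPGR signal curve to concentration (mM).

    The pre-contrast signal ``s_pre`` and T10 fix the effective M0; the SPGR
    equation is inverted per frame for T1(t) and
    ``C(t) = (1/T1(t) - 1/T10) / r1``.  Frames whose signal falls outside
    the invertible SPGR range are clipped to the valid boundary and flagged.

    Returns
    -------
    (concentration, clipped) — arrays matching ``signal_t``.
    """
    s = np.asarray(signal_t, dtype=float)
    if s_pre <= 0:
        raise ValueError("baseline signal must be positive")
    if t10 <= 0:
        raise ValueError("T10 must be positive")
    a = np.deg2rad(acquisition.dce_flip_angle)
    tr = acquisition.tr
    e10 = np.exp(-tr / t10)
    # effective M0 sin(a) from the baseline signal
    m0sin = s_pre * (1.0 - np.cos(a) * e10) / (1.0 - e10)
    # invert S = m0sin (1-E1)/(1-cos a E1)  ->  E1 = (m0sin - S)/(m0sin - S cos a)
    denom = m0sin - s * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0sin - s) / denom
    clipped = (e1 <= 0.0) | (e1 >= 1.0) | ~np.isfinite(e1)
    e1 = np.clip(e1, 1e-12, 1.0 - 1e-12)
    r1_t = -np.log(e1) / tr  # 1/T1(t), 1/s
    conc = (r1_t - 1.0 / t10) / acquisition.r1_relaxivity
    return conc, clipped


# ---------------------------------------------------------------------------
# Extended Tofts model
# ---------------------------------------------------------------------------

def _cumulative_trapezoid_matrix(t: np.ndarray) -> np.ndarray:
    """W such that (W @ f)[i] = trapezoid integral of f from t[0] to t[i]."""
    n = t.size
    half = np.diff(t) / 2.0
    wfull = np.empty(n)
    wfull[0] = half[0] if n > 1 else 0.0
    if n > 1:
        wfull[1:-1] = half[:-1] + half[1:]
        wfull[-1] = half[-1]  # unused below the diagonal; overwritten there
    W = np.tril(np.broadcast_to(wfull, (n, n)).copy(), k=-1)
    if n > 1:
        W[np.arange(1, n), np.arange(1, n)] = half
    W[0, :] = 0.0
    return W


def etm_forward(ktrans, ve, vp, aif, t_s) -> np.ndarray:
    """Tissue concentration predicted by the extended Tofts model.

    The convolution integral is evaluated by trapezoidal quadrature on the
    acquisition time grid.  ``aif`` is any callable mapping seconds -> mM.
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    t_s = np.asarray(t_s, dtype=float)
    t_min = t_s / SECONDS_PER_MINUTE
    cp = np.asarray(aif(t_s), dtype=float)
    kep = ktrans / ve
    # lower-triangular kernel K[i, j] = exp(-kep (t_i - t_j)), j <= i
    dtm = t_min[:, None] - t_min[None, :]
    kernel = np.exp(-kep * np.clip(dtm, 0, None))
    integ = (_cumulative_trapezoid_matrix(t_min) * kernel) @ cp
    return vp * cp + ktrans * integ


def _etm_linear_init(ct, cp, t_min, bounds):
    """Murase-style linear least squares initialisation of the ETM.

    Uses the identity C_t = (Ktrans + kep vp) int Cp - kep int Ct + vp Cp.
    Falls back to midpoint-of-bounds on degenerate systems.
    """
    from scipy.integrate import cumulative_trapezoid

    int_cp = cumulative_trapezoid(cp, t_min, initial=0.0)
    int_ct = cumulative_trapezoid(ct, t_min, initial=0.0)
    A = np.column_stack([int_cp, -int_ct, cp])
    try:
        coef, *_ = np.linalg.lstsq(A, ct, rcond=None)
        kep = coef[1]
        vp = coef[2]
        ktrans = coef[0] - kep * vp
        if not np.all(np.isfinite([ktrans, kep, vp])) or kep <= 0:
            raise np.linalg.LinAlgError
        ve = ktrans / kep if ktrans > 0 else 0.5 * (bounds[1][0] + bounds[1][1])
    except np.linalg.LinAlgError:
        return tuple(0.5 * (lo + hi) for lo, hi in bounds)
    eps = 1e-6
    init = []
    for val, (lo, hi) in zip((ktrans, ve, vp), bounds):
        span = hi - lo
        init.append(float(np.clip(val, lo + eps * span, hi - eps * span)))
    return tuple(init)


def fit_etm_voxel(ct, aif, t_s, bounds=DEFAULT_BOUNDS):
    """Fit (K^trans, v_e, v_p) to one tissue concentration curve.

    Bounded trust-region nonlinear least squares, initialised from the
    linearised ETM solution.  Returns ``(ktrans, ve, vp, rmse, converged)``.
    An all-zero curve is reported as (0, nan, 0, 0, True) with v_e
    unidentifiable; non-convergence yields NaN sentinels with
    ``converged=False``.
    """
    ct = np.asarray(ct, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if ct.size < 4:
        raise ValueError("need at least 4 time points to fit the ETM")
    cp = np.asarray(aif(t_s), dtype=float)
    t_min = t_s / SECONDS_PER_MINUTE

    if np.allclose(ct, 0.0):
        return 0.0, np.nan, 0.0, 0.0, True

    x0 = _etm_linear_init(ct, cp, t_min, bounds)
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]

    def residuals(x):
        return etm_forward(x[0], max(x[1], 1e-12), x[2], aif, t_s) - ct

    try:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return np.nan, np.nan, np.nan, np.nan, False
    if not res.success:
        return np.nan, np.nan, np.nan, np.nan, False
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return float(res.x[0]), float(res.x[1]), float(res.x[2]), rmse, True


def fit_etm_map(dce_series, mask, acquisition: AcquisitionParams, aif,
                t10_map) -> ParameterMaps:
    """Voxelwise ETM fitting of a 4D dynamic series (time on the last axis).

    Each masked voxel's signal is converted to concentration using its T10
    and the mean of the pre-contrast frames, then fitted with
    :func:`fit_etm_voxel`.  Voxels outside the mask carry NaN sentinels.
    """
    series = np.asarray(dce_series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if series.shape[:-1] != mask.shape:
        raise ValueError("series spatial shape must match mask")
    t10_map = np.broadcast_to(np.asarray(t10_map, dtype=float), mask.shape)

    shape = mask.shape
    ktrans = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    rmse = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    nb = acquisition.baseline_frames
    t_s = acquisition.time_grid
    for idx in zip(*np.nonzero(mask)):
        sig = series[idx]
        s_pre = float(np.mean(sig[:nb]))
        conc, _ = concentration_from_signal(sig, s_pre, t10_map[idx], acquisition)
        conc = conc - float(np.mean(conc[:nb]))  # re-zero the baseline
        kt, v_e, v_p, r, ok = fit_etm_voxel(conc, aif, t_s)
        ktrans[idx], ve[idx], vp[idx], rmse[idx] = kt, v_e, v_p, r
        converged[idx] = ok

    # build the container with physically valid placeholders at failed voxels
    ve_safe = np.where(mask & ~(np.isfinite(ve) & (ve > 0) & (ve <= 1)), 1.0, ve)
    kt_safe = np.where(mask & ~(np.isfinite(ktrans) & (ktrans >= 0)), 0.0, ktrans)
    vp_safe = np.where(mask & ~(np.isfinite(vp) & (vp >= 0) & (vp <= 1)), 0.0, vp)
    maps = ParameterMaps(ktrans=kt_safe, ve=ve_safe, vp=vp_safe, mask=mask,
                         fit_rmse=rmse, converged=converged)
    return maps
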