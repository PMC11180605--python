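"""Rate-equation model of fluorescent-protein photobleaching under dual
visible / near-infrared (NIR) illumination.

The model tracks five molecular states: the singlet ground state ``S0``,
the emissive excited singlet ``S1``, the lowest triplet ``T1``, an upper
triplet ``Tn`` reached by absorption of a second photon from ``T1``, and
an absorbing pool ``B`` of irreversibly bleached molecules.

Visible light cycles ``S0 <-> S1`` and populates ``T1`` through
intersystem crossing; ``T1`` bleaches slowly on its own (rate ``k_b1``).
A second photon — NIR light resonant with the triplet-triplet absorption
band, or the visible beam itself through the small tail of that band —
promotes ``T1`` to ``Tn``, from which the molecule either returns to the
emissive manifold by reverse intersystem crossing (RISC, branching
``phi_risc``), bleaches (branching ``phi_bn``), or relaxes back to
``T1``.  Because ``T1`` is the gateway to photobleaching, the RISC
shortcut reduces the per-excitation-cycle bleaching probability and
stretches the total photon budget of the fluorophore.  The reduced-
photobleaching (RP) effect is the ratio of time-integrated emission with
NIR co-illumination to that without, at identical visible excitation.

All populations are occupation probabilities of a single molecule; the
dynamics are the linear master equation ``dp/dt = Q p`` with ``Q`` the
generator built by :func:`build_generator`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "HC_J_NM",
    "N_AVOGADRO",
    "STATES",
    "TripletSpectrum",
    "PhotophysicalParams",
    "Illumination",
    "BleachingTrace",
    "RPResult",
    "SolverError",
    "photon_flux",
    "cross_section_from_molar_absorptivity",
    "build_generator",
    "simulate_trace",
    "simulate_ensemble_mc",
    "integrated_emission",
    "rp_model",
    "scan_rp",
    "egfp_default_params",
]

# Planck constant times speed of light, expressed in J*nm so that the
# photon energy at wavelength lambda [nm] is HC_J_NM / lambda.
HC_J_NM = 6.62607015e-34 * 2.99792458e8 * 1e9  # 1.9864e-16 J nm
N_AVOGADRO = 6.02214076e23

#: State ordering used for every vector/matrix in this module.
STATES = ("S0", "S1", "T1", "Tn", "B")
_S0, _S1, _T1, _TN, _B = range(5)


class SolverError(RuntimeError):
    """Raised when population propagation fails to conserve probability."""


def photon_flux(intensity: float, wavelength: float) -> float:
    """Convert an irradiance to a photon flux.

    Parameters
    ----------
    intensity : float
        Irradiance in W/cm^2.
    wavelength : float
        Wavelength in nm.

    Returns
    -------
    float
        Photon flux in photons cm^-2 s^-1.
    """
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    return intensity * wavelength / HC_J_NM


def cross_section_from_molar_absorptivity(epsilon: float) -> float:
    """Molar absorption coefficient [M^-1 cm^-1] -> absorption cross-section [cm^2].

    sigma = ln(10) * 1000 * epsilon / N_A  (1000 cm^3 per litre).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return math.log(10.0) * 1000.0 * epsilon / N_AVOGADRO


@dataclass(frozen=True)
class TripletSpectrum:
    """Triplet-triplet absorption spectrum sigma_T(lambda).

    The tabulated spectrum is stored as a relative shape (normalized to 1
    at its maximum) times an absolute peak cross-section.  Evaluation is
    piecewise-linear; wavelengths outside the tabulated support raise
    rather than extrapolate.

    Attributes
    ----------
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid, nm.
    relative : ndarray
        Non-negative relative absorption on that grid (peak-normalized
        on construction).
    peak_cross_section_cm2 : float
        Absolute cross-section at the spectrum maximum, cm^2.
    """

    wavelengths_nm: np.ndarray
    relative: np.ndarray
    peak_cross_section_cm2: float

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.relative, dtype=float)
        if w.ndim != 1 or w.size < 2 or r.shape != w.shape:
            raise ValueError("spectrum needs matching 1-d wavelength/value arrays")
        if not np.all(np.diff(w) > 0):
            raise ValueError("spectrum wavelengths must be strictly increasing")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("spectrum values must be finite and >= 0")
        if self.peak_cross_section_cm2 < 0:
            raise ValueError("peak cross-section must be >= 0")
        rmax = r.max()
        if rmax <= 0:
            raise ValueError("spectrum must not be identically zero")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "relative", r / rmax)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def covers(self, wavelength: float) -> bool:
        lo, hi = self.support
        return lo <= wavelength <= hi

    def cross_section(self, wavelength: float) -> float:
        """sigma_T at ``wavelength`` [nm], in cm^2 (error outside support)."""
        lo, hi = self.support
        wl = np.asarray(wavelength, dtype=float)
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside spectrum support [{lo}, {hi}]"
            )
        val = np.interp(wl, self.wavelengths_nm, self.relative)
        return self.peak_cross_section_cm2 * val

    @classmethod
    def synthetic_egfp_like(
        cls,
        peak_cross_section_cm2: float,
        peak_nm: float = 900.0,
        fwhm_nm: float = 150.0,
        vis_tail: float = 0.02,
        vis_tail_nm: float = 470.0,
        tail_scale_nm: float = 150.0,
        grid: tuple[float, float, float] = (400.0, 1000.0, 2.0),
    ) -> "TripletSpectrum":
        """Synthetic single-peaked triplet spectrum.

        A Gaussian band centred at ``peak_nm`` (default 900 nm, where the
        published EGFP triplet absorption has its maximum) plus a small
        exponential tail anchored at the visible excitation band so that
        sigma_T(470 nm) is non-zero.  This is a synthetic stand-in for
        the published spectrum: only the peak position and the presence
        of a visible tail are anchored; width and tail size are
        documented defaults.
        """
        lo, hi, step = grid
        w = np.arange(lo, hi + 0.5 * step, step)
        gauss = np.exp(-4.0 * math.log(2.0) * ((w - peak_nm) / fwhm_nm) ** 2)
        tail = vis_tail * np.exp(-np.clip(w - vis_tail_nm, 0.0, None) / tail_scale_nm)
        return cls(w, gauss + tail, peak_cross_section_cm2)

    @classmethod
    def from_csv(cls, path: str | Path, peak_cross_section_cm2: float) -> "TripletSpectrum":
        """Read a 2-column CSV (wavelength_nm, cross_section) as a relative shape."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("spectrum CSV needs two columns")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), peak_cross_section_cm2)

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "relative": self.relative.tolist(),
            "peak_cross_section_cm2": self.peak_cross_section_cm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TripletSpectrum":
        return cls(
            np.asarray(d["wavelengths_nm"], float),
            np.asarray(d["relative"], float),
            float(d["peak_cross_section_cm2"]),
        )


@dataclass(frozen=True)
class PhotophysicalParams:
    """Molecular constants of the S0/S1/T1/Tn/B state graph.

    Attributes
    ----------
    sigma_S_vis : float
        Ground-state absorption cross-section at the visible excitation
        wavelength, cm^2.
    phi_f : float
        Fluorescence quantum yield of S1 (radiative fraction), in [0, 1].
    tau_S1 : float
        S1 lifetime, s.
    phi_isc : float
        Intersystem-crossing yield S1 -> T1, in [0, 1].
    tau_T1 : float
        T1 lifetime for decay back to S0, s.
    k_b1 : float
        Bleaching rate out of T1, s^-1.
    tau_Tn : float
        Tn lifetime, s (ns scale).
    phi_risc : float
        Branching fraction Tn -> S1 (reverse intersystem crossing).
    phi_bn : float
        Branching fraction Tn -> bleached.
    sigma_T : TripletSpectrum
        Triplet absorption spectrum; must cover the visible excitation
        wavelength and the NIR range in use.
    """

    sigma_S_vis: float
    phi_f: float
    tau_S1: float
    phi_isc: float
    tau_T1: float
    k_b1: float
    tau_Tn: float
    phi_risc: float
    phi_bn: float
    sigma_T: TripletSpectrum

    def __post_init__(self):
        if self.sigma_S_vis < 0 or self.k_b1 < 0:
            raise ValueError("cross-sections and rates must be >= 0")
        for name in ("tau_S1", "tau_T1", "tau_Tn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("phi_f", "phi_isc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.phi_risc < 0 or self.phi_bn < 0 or self.phi_risc + self.phi_bn > 1.0:
            raise ValueError("need phi_risc, phi_bn >= 0 and phi_risc + phi_bn <= 1")

    def evolve(self, **changes) -> "PhotophysicalParams":
        """Copy with the given scalar fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {
            name: getattr(self, name)
            for name in (
                "sigma_S_vis", "phi_f", "tau_S1", "phi_isc", "tau_T1",
                "k_b1", "tau_Tn", "phi_risc", "phi_bn",
            )
        }
        d["sigma_T"] = self.sigma_T.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhotophysicalParams":
        d = dict(d)
        d["sigma_T"] = TripletSpectrum.from_dict(d["sigma_T"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhotophysicalParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Illumination:
    """Wavelengths [nm] and irradiances [W/cm^2] of the two beams.

    ``I_nir = 0`` means the NIR beam is off.
    """

    lambda_vis: float = 470.0
    I_vis: float = 32.0
    lambda_nir: float = 900.0
    I_nir: float = 0.0

    def __post_init__(self):
        if self.I_vis < 0 or self.I_nir < 0:
            raise ValueError("intensities must be >= 0")
        if self.lambda_vis <= 0 or self.lambda_nir <= 0:
            raise ValueError("wavelengths must be > 0")

    def without_nir(self) -> "Illumination":
        return replace(self, I_nir=0.0)

    def with_nir(self, I_nir: float, lambda_nir: float | None = None) -> "Illumination":
        return replace(
            self, I_nir=I_nir,
            lambda_nir=self.lambda_nir if lambda_nir is None else lambda_nir,
        )


@dataclass
class BleachingTrace:
    """Time-stamped normalized fluorescence decay curve.

    ``signal[0]`` is 1 by construction (normalization to the first,
    singlet-equilibrated sample).
    """

    times: np.ndarray
    signal: np.ndarray
    roi_id: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and signal must be matching 1-d arrays")
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing with >= 2 samples")
        if np.any(s < -1e-12):
            raise ValueError("signal must be >= 0")
        self.times = t
        self.signal = np.clip(s, 0.0, None)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RPResult:
    """Reduced-photobleaching ratio and its two integrated emissions."""

    rp: float
    window: float
    auc_with: float
    auc_without: float


def _rates(params: PhotophysicalParams, illum: Illumination) -> dict[str, float]:
    """Elementary transition rates [s^-1] for the given illumination."""
    flux_vis = photon_flux(illum.I_vis, illum.lambda_vis)
    k_up = 0.0
    if illum.I_vis > 0:
        if not params.sigma_T.covers(illum.lambda_vis):
            raise ValueError(
                f"visible wavelength {illum.lambda_vis} nm outside triplet-spectrum support"
            )
        k_up += params.sigma_T.cross_section(illum.lambda_vis) * flux_vis
    if illum.I_nir > 0:
        if not params.sigma_T.covers(illum.lambda_nir):
            raise ValueError(
                f"NIR wavelength {illum.lambda_nir} nm outside triplet-spectrum support"
            )
        k_up += params.sigma_T.cross_section(illum.lambda_nir) * photon_flux(
            illum.I_nir, illum.lambda_nir
        )
    return {
        "k_exc": params.sigma_S_vis * flux_vis,
        "k_S": 1.0 / params.tau_S1,
        "k_T": 1.0 / params.tau_T1,
        "k_Tn": 1.0 / params.tau_Tn,
        "k_up": k_up,
    }


def build_generator(params: PhotophysicalParams, illum: Illumination) -> np.ndarray:
    """Generator matrix Q of the master equation dp/dt = Q p.

    Columns index the source state, rows the destination, in the order
    :data:`STATES`.  Off-diagonal entries are the elementary rates,
    diagonal entries minus the total outflow of the column; the bleached
    column B is zero (absorbing).
    """
    k = _rates(params, illum)
    Q = np.zeros((5, 5))
    Q[_S1, _S0] = k["k_exc"]
    Q[_S0, _S1] = (1.0 - params.phi_isc) * k["k_S"]
    Q[_T1, _S1] = params.phi_isc * k["k_S"]
    Q[_S0, _T1] = k["k_T"]
    Q[_B, _T1] = params.k_b1
    Q[_TN, _T1] = k["k_up"]
    Q[_S1, _TN] = params.phi_risc * k["k_Tn"]
    Q[_B, _TN] = params.phi_bn * k["k_Tn"]
    Q[_T1, _TN] = (1.0 - params.phi_risc - params.phi_bn) * k["k_Tn"]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(5)] = -Q.sum(axis=0)
    return Q


def _stiffness_ratio(Q: np.ndarray) -> float:
    d = np.abs(np.diag(Q))
    nz = d[d > 0]
    return float(nz.max() / nz.min()) if nz.size else 1.0


def _propagate(Q: np.ndarray, eval_times: np.ndarray) -> np.ndarray:
    """Populations at ``eval_times`` from p(0) = S0, via stepped expm."""
    p = np.zeros(5)
    p[_S0] = 1.0
    out = np.empty((eval_times.size, 5))
    cache: dict[bytes, np.ndarray] = {}
    t_prev = 0.0
    for i, t in enumerate(eval_times):
        dt = t - t_prev
        if dt > 0:
            key = np.float64(dt).tobytes()
            P = cache.get(key)
            if P is None:
                P = expm(Q * dt)
                colsum = P.sum(axis=0)
                if not np.all(np.isfinite(P)) or np.any(np.abs(colsum - 1.0) > 1e-6):
                    raise SolverError(
                        "propagator not column-stochastic (probability leak "
                        f"{np.abs(colsum - 1.0).max():.3e}); stiffness ratio "
                        f"{_stiffness_ratio(Q):.3e}"
                    )
                # the exact propagator of a generator is column-stochastic;
                # project out the ~1e-7 roundoff scipy's squaring phase leaves
                # on stiff generators (ns..s timescales in one matrix)
                P = np.clip(P, 0.0, None)
                P /= P.sum(axis=0, keepdims=True)
                cache[key] = P
            p = P @ p
        out[i] = p
        t_prev = t
    total = out.sum(axis=1)
    if not np.all(np.isfinite(out)) or np.any(np.abs(total - 1.0) > 1e-9):
        raise SolverError(
            "population propagation failed (probability not conserved); "
            f"stiffness ratio {_stiffness_ratio(Q):.3e}"
        )
    if np.any(out < -1e-12):
        raise SolverError(
            f"negative populations beyond tolerance; stiffness ratio {_stiffness_ratio(Q):.3e}"
        )
    return out


def simulate_trace(
    params: PhotophysicalParams,
    illum: Illumination,
    t_grid: Sequence[float],
    t_norm: float | None = None,
) -> tuple[BleachingTrace, np.ndarray]:
    """Solve the master equation and return the normalized fluorescence trace.

    The instantaneous fluorescence is proportional to
    ``phi_f * k_S * p_S1(t)``.  Because the molecule starts in S0, the
    t = 0 grid point is reported as the signal after singlet-manifold
    equilibration at ``t_norm`` (default: 100x the larger of tau_S1 and
    tau_Tn — far above the excited-state lifetimes, far below
    triplet-shelving and bleaching timescales) and the whole trace is
    normalized to that value — the model analogue of "normalized to 1
    at t = 0" for a first camera frame.

    Returns
    -------
    (BleachingTrace, ndarray)
        The normalized trace and the full (n_times, 5) state time course.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be 1-d with >= 2 points")
    if t[0] != 0 or not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if illum.I_vis <= 0:
        raise ValueError("no visible excitation: fluorescence trace undefined")
    if t_norm is None:
        t_norm = 100.0 * max(params.tau_S1, params.tau_Tn)
    t_norm = min(t_norm, float(t[1]))
    Q = build_generator(params, illum)
    eval_t = np.maximum(t, t_norm)
    states = _propagate(Q, eval_t)
    k_S = 1.0 / params.tau_S1
    raw = params.phi_f * k_S * states[:, _S1]
    ref = raw[0]
    if ref <= 0:
        raise SolverError("vanishing reference signal at t_norm")
    return BleachingTrace(times=t, signal=raw / ref), states


def integrated_emission(
    params: PhotophysicalParams,
    illum: Illumination,
    window: float = math.inf,
    n_points: int = 4001,
) -> float:
    """Total photons emitted (arbitrary proportional units).

    For an infinite window the integral of p_S1 is obtained exactly from
    the transient linear system ``M x = -p0`` on the non-bleached
    subspace (M = generator restricted to S0,S1,T1,Tn), giving
    ``phi_f * k_S * x_S1``.  For a finite window the simulated raw trace
    is integrated by the trapezoid rule on a uniform grid of
    ``n_points`` samples.
    """
    if illum.I_vis <= 0:
        return 0.0
    Q = build_generator(params, illum)
    k = _rates(params, illum)
    k_S = 1.0 / params.tau_S1
    if math.isinf(window):
        if not (params.k_b1 > 0 or (params.phi_bn > 0 and k["k_up"] > 0)):
            raise ValueError("emission integral diverges: no bleaching channel")
        M = Q[:4, :4]
        p0 = np.zeros(4)
        p0[_S0] = 1.0
        x = np.linalg.solve(M, -p0)
        return float(params.phi_f * k_S * x[_S1])
    if window <= 0:
        raise ValueError("window must be > 0 or infinite")
    # composite grid: log-spaced early part resolves the fast singlet/triplet
    # equilibration transient, linear part covers the slow bleaching decay
    t_eq = min(100.0 * max(params.tau_S1, params.tau_Tn), window * 1e-3)
    early = np.geomspace(t_eq, window / 50.0, 257)
    late = np.linspace(window / 50.0, window, n_points)
    t = np.unique(np.concatenate([[0.0], early, late]))
    eval_t = np.maximum(t, t_eq)
    states = _propagate(Q, eval_t)
    raw = params.phi_f * k_S * states[:, _S1]
    return float(np.trapezoid(raw, t))


def rp_model(
    params: PhotophysicalParams,
    illum_dual: Illumination,
    illum_vis_only: Illumination | None = None,
    window: float = math.inf,
    n_points: int = 4001,
) -> RPResult:
    """Reduced-photobleaching effect predicted by the model.

    RP = integrated emission with NIR / integrated emission without, at
    identical visible excitation.
    """
    if illum_vis_only is None:
        illum_vis_only = illum_dual.without_nir()
    if (
        illum_vis_only.lambda_vis != illum_dual.lambda_vis
        or illum_vis_only.I_vis != illum_dual.I_vis
    ):
        raise ValueError("visible illumination settings must match between conditions")
    if illum_vis_only.I_nir != 0:
        raise ValueError("reference condition must have I_nir = 0")
    auc_with = integrated_emission(params, illum_dual, window, n_points)
    auc_without = integrated_emission(params, illum_vis_only, window, n_points)
    if auc_without <= 0:
        raise ValueError("reference emission is zero; RP undefined")
    return RPResult(
        rp=auc_with / auc_without,
        window=window,
        auc_with=auc_with,
        auc_without=auc_without,
    )


def scan_rp(
    params: PhotophysicalParams,
    I_vis_values: Sequence[float] | None = None,
    I_nir_values: Sequence[float] | None = None,
    lambda_nir_values: Sequence[float] | None = None,
    base: Illumination | None = None,
    window: float = math.inf,
) -> pd.DataFrame:
    """RP over a cartesian grid of visible/NIR intensities and NIR wavelengths.

    Any axis left as None is pinned at the value in ``base``.  Returns a
    table with columns I_vis_W_cm2, I_nir_W_cm2, lambda_nir_nm, rp.
    """
    if base is None:
        base = Illumination()
    Iv = [base.I_vis] if I_vis_values is None else list(I_vis_values)
    In = [base.I_nir] if I_nir_values is None else list(I_nir_values)
    Ln = [base.lambda_nir] if lambda_nir_values is None else list(lambda_nir_values)
    if not Iv or not In or not Ln:
        raise ValueError("scan grids must be non-empty")
    rows = []
    for iv in Iv:
        for ln in Ln:
            for inir in In:
                illum = Illumination(base.lambda_vis, iv, ln, inir)
                rp = rp_model(params, illum, window=window).rp
                rows.append((iv, inir, ln, rp))
    return pd.DataFrame(rows, columns=["I_vis_W_cm2", "I_nir_W_cm2", "lambda_nir_nm", "rp"])


def simulate_ensemble_mc(
    params: PhotophysicalParams,
    illum: Illumination,
    t_grid: Sequence[float],
    n_molecules: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic jump-process (Gillespie) ensemble average of the model.

    Simulates ``n_molecules`` independent single-molecule trajectories of
    the same jump chain the generator encodes and returns the fraction of
    molecules in each state at every time in ``t_grid``, together with
    the binomial standard error of each fraction.  Used as an independent
    cross-check of the deterministic master-equation solution.
    """
    t_out = np.asarray(t_grid, dtype=float)
    if t_out.ndim != 1 or not np.all(np.diff(t_out) > 0):
        raise ValueError("t_grid must be 1-d strictly increasing")
    rng = np.random.default_rng(seed)
    Q = build_generator(params, illum)
    r_tot = -np.diag(Q).copy()
    # per-state cumulative destination probabilities
    P = Q.copy()
    np.fill_diagonal(P, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(r_tot[None, :] > 0, P / r_tot[None, :], 0.0)
    cumP = np.cumsum(P.T, axis=1)  # row = source state
    t_max = t_out[-1]
    n_t = t_out.size

    state = np.zeros(n_molecules, dtype=np.int64)
    t_cur = np.zeros(n_molecules)
    diff = np.zeros((5, n_t + 1))
    active = np.ones(n_molecules, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        s = state[idx]
        rt = r_tot[s]
        absorbing = rt <= 0
        if absorbing.any():
            a = idx[absorbing]
            i0 = np.searchsorted(t_out, t_cur[a], side="left")
            np.add.at(diff, (state[a], i0), 1.0)
            active[a] = False
            idx = idx[~absorbing]
            if idx.size == 0:
                continue
            s = state[idx]
            rt = r_tot[s]
        dwell = rng.exponential(1.0 / rt)
        t_next = t_cur[idx] + dwell
        i0 = np.searchsorted(t_out, t_cur[idx], side="left")
        i1 = np.searchsorted(t_out, t_next, side="left")
        np.add.at(diff, (s, i0), 1.0)
        np.add.at(diff, (s, i1), -1.0)
        u = rng.random(idx.size)
        dest = (u[:, None] > cumP[s]).sum(axis=1)
        state[idx] = dest
        t_cur[idx] = t_next
        done = t_next >= t_max
        if done.any():
            active[idx[done]] = False
    counts = np.cumsum(diff[:, :-1], axis=1).T  # (n_t, 5)
    occ = counts / n_molecules
    se = np.sqrt(np.clip(occ * (1.0 - occ), 0.0, None) / n_molecules)
    return occ, se


_DEFAULT_PARAMS_FILE = "egfp_default.json"


def egfp_default_params() -> PhotophysicalParams:
    """Calibrated EGFP-like default parameter set.

    These values are *reconstructed*, not transcribed: the fixed fields
    are textbook EGFP photophysics (fluorescence lifetime 2.6 ns, quantum
    yield 0.60, ground-state cross-section from the 488-nm molar
    absorption coefficient 55,900 M^-1 cm^-1) and the free fields
    (triplet-spectrum scale, phi_risc, phi_bn, k_b1, tau_T1) were fitted
    by :func:`riscbleach.calibration.calibrate_anchors` to the printed
    EGFP anchors (RP 3.5 at 32 W/cm^2 visible + 2 kW/cm^2 NIR, NIR
    plateau near 2 kW/cm^2, visible turnover near 100 W/cm^2).
    """
    ref = resources.files("riscbleach") / "data" / _DEFAULT_PARAMS_FILE
    return PhotophysicalParams.from_dict(json.loads(ref.read_text()))
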