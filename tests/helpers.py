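"""Independent oracles used by the test suite.

Everything here is deliberately computed by a different route than the
package implementation: closed-form branching probabilities instead of
linear solves, a quasi-steady-state reduced generator instead of the
full five-state one, and exhaustive assignment enumeration instead of
the Hungarian algorithm.
"""

from __future__ import annotations

import itertools

import numpy as np

from riscbleach.photophysics import Illumination, PhotophysicalParams, photon_flux


def _pump_rate(params: PhotophysicalParams, illum: Illumination) -> float:
    k_up = 0.0
    if illum.I_vis > 0:
        k_up += params.sigma_T.cross_section(illum.lambda_vis) * photon_flux(
            illum.I_vis, illum.lambda_vis
        )
    if illum.I_nir > 0:
        k_up += params.sigma_T.cross_section(illum.lambda_nir) * photon_flux(
            illum.I_nir, illum.lambda_nir
        )
    return k_up


def bleach_probability(params: PhotophysicalParams, illum: Illumination) -> float:
    """Closed-form probability that one T1 visit ends in bleaching.

    Collapsing the instantaneous Tn loop: from T1 the competing exits
    are k_T (to S0), k_b1 (to B) and k_up (to Tn); a Tn excursion ends
    in S1 with phi_risc, in B with phi_bn, or back in T1 (a retry).
    """
    k_T = 1.0 / params.tau_T1
    u = _pump_rate(params, illum)
    r, b = params.phi_risc, params.phi_bn
    denom = k_T + params.k_b1 + u * (r + b)
    return (params.k_b1 + u * b) / denom


def photon_budget_rp(params: PhotophysicalParams, illum_dual: Illumination) -> float:
    """RP from the photon-budget argument.

    Total photons before bleaching = phi_f / (phi_isc * P_B), because
    every S0 return is eventually re-excited; hence the infinite-window
    RP is exactly P_B(no NIR) / P_B(with NIR), independent of the
    excitation rate and the fluorescence yield.
    """
    return bleach_probability(params, illum_dual.without_nir()) / bleach_probability(
        params, illum_dual
    )


def qss_generator(params: PhotophysicalParams, illum: Illumination) -> np.ndarray:
    """4-state (S0, S1, T1, B) generator with Tn adiabatically eliminated.

    T1 outflows: k_T to S0, k_b1 to B, k_up*phi_risc to S1,
    k_up*phi_bn to B (the Tn fraction returning to T1 is a no-op).
    """
    k_exc = params.sigma_S_vis * photon_flux(illum.I_vis, illum.lambda_vis)
    k_S = 1.0 / params.tau_S1
    k_T = 1.0 / params.tau_T1
    u = _pump_rate(params, illum)
    Q = np.zeros((4, 4))
    Q[1, 0] = k_exc
    Q[0, 1] = (1 - params.phi_isc) * k_S
    Q[2, 1] = params.phi_isc * k_S
    Q[0, 2] = k_T
    Q[1, 2] = u * params.phi_risc
    Q[3, 2] = params.k_b1 + u * params.phi_bn
    Q[np.diag_indices(4)] = -Q.sum(axis=0)
    return Q


def brute_force_link_cost(xy_a: np.ndarray, xy_b: np.ndarray, d_max: float) -> float:
    """Minimum total assignment cost by exhaustive enumeration.

    Cost model: squared distance per link (links longer than d_max
    forbidden) plus d_max**2 per unlinked point in either frame.
    Feasible only for <= ~6 points per frame.
    """
    a = np.atleast_2d(xy_a)
    b = np.atleast_2d(xy_b)
    n, m = len(a), len(b)
    alt = d_max**2
    best = alt * (n + m)  # nothing linked
    idx_b = range(m)
    for k in range(1, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(idx_b, k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = float(((a[i] - b[j]) ** 2).sum())
                    if d2 > alt:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += alt * (n - k) + alt * (m - k)
                best = min(best, cost)
    return best


def lap_link_cost(xy_a, xy_b, links, d_max: float) -> float:
    """Total cost of a link set under the same cost model as above."""
    a = np.atleast_2d(xy_a)
    b = np.atleast_2d(xy_b)
    alt = d_max**2
    cost = sum(float(((a[i] - b[j]) ** 2).sum()) for i, j in links)
    cost += alt * (len(a) - len(links)) + alt * (len(b) - len(links))
    return cost


def fast_test_params(**overrides) -> PhotophysicalParams:
    """Moderately stiff parameter set for oracle-equivalence tests.

    All rates within a few decades of each other so that matrix
    exponentials are exact to machine precision and single-molecule jump
    counts stay small; same state graph as the calibrated set.
    """
    from riscbleach.photophysics import TripletSpectrum

    defaults = dict(
        sigma_S_vis=3e-18,      # with I_vis=32 W/cm2 @470nm: k_exc ~ 227 /s
        phi_f=0.6,
        tau_S1=2e-3,            # k_S = 500 /s
        phi_isc=0.3,
        tau_T1=5e-3,            # k_T = 200 /s
        k_b1=20.0,
        tau_Tn=1e-3,            # k_Tn = 1000 /s
        phi_risc=0.5,
        phi_bn=0.1,
        sigma_T=TripletSpectrum.synthetic_egfp_like(5e-20),
    )
    defaults.update(overrides)
    return PhotophysicalParams(**defaults)
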