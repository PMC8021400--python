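"""Numba-compiled ODE right-hand sides.

The scalar rate laws in :mod:`acekin.model` are the reference
implementation; these kernels evaluate the same algebra on packed parameter
arrays for speed inside the integrator (parameter estimation performs tens
of thousands of solves).  Inhibition terms are switched off by packing an
infinite Ki, so a single kernel serves all four model variants.

Labelled state layout (11 entries)::

    [GLC0, GLC1, ACE_env0, ACE_env1, X, ACCOA0, ACCOA1, ACP0, ACP1,
     ACE_cell0, ACE_cell1]

subscript 0 = unlabelled, 1 = 13C-labelled.  Unlabelled layout (6)::

    [GLC, ACE_env, X, ACCOA, ACP, ACE_cell]
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import ParameterSet
from .model import ModelVariant

__all__ = ["pack_params", "rhs_unlabelled", "rhs_labelled", "rates_from_packed"]


def pack_params(p: ParameterSet, variant: ModelVariant) -> np.ndarray:
    """Parameter array for the kernels, with inactive inhibitions disabled."""
    variant.check_parameters(p)
    q = p.to_array()
    if not variant.inhibit_glycolysis:
        q[2] = np.inf
    if not variant.inhibit_tca:
        q[5] = np.inf
    return q


@njit(cache=True)
def _uni_rates(GLC, AE, AC, AP, ACl, q):
    """Glycolysis, TCA and the six unidirectional Pta/AckA/exchange rates."""
    vgly = q[0] * GLC / (GLC + q[1]) / (1.0 + AE / q[2])
    vtca = q[3] * AC / (AC + q[4]) / (1.0 + AE / q[5])
    denom_p = (
        1.0 + AC / q[8] + q[27] / q[10] + AP / q[11] + q[26] / q[12]
        + AC * q[27] / (q[8] * q[9]) + AP * q[26] / (q[13] * q[12])
    )
    kp = q[6] / (q[8] * q[9]) / denom_p
    pta_f = kp * AC * q[27]
    pta_r = kp * AP * q[26] / q[7]
    denom_a = (1.0 + AP / q[16] + ACl / q[18]) * (1.0 + q[24] / q[17] + q[25] / q[19])
    ka = q[14] / (q[16] * q[17]) / denom_a
    acka_f = ka * AP * q[24]
    acka_r = ka * ACl * q[25] / q[15]
    denom_e = 1.0 + ACl / q[21] + AE / q[21]
    ke = q[20] / q[21] / denom_e
    ex_f = ke * ACl
    ex_r = ke * AE / q[22]
    return vgly, vtca, pta_f, pta_r, acka_f, acka_r, ex_f, ex_r


@njit(cache=True)
def rhs_unlabelled(t, y, q, D, vfeed):
    GLC = max(y[0], 0.0)
    AE = max(y[1], 0.0)
    X = max(y[2], 0.0)
    AC = max(y[3], 0.0)
    AP = max(y[4], 0.0)
    ACl = max(y[5], 0.0)
    vgly, vtca, ptf, ptr, akf, akr, exf, exr = _uni_rates(GLC, AE, AC, AP, ACl, q)
    vpta = ptf - ptr
    vacka = akf - akr
    vexch = exf - exr
    rho = X * q[28] / q[29]
    out = np.empty(6)
    out[0] = -vgly * rho + vfeed - D * GLC
    out[1] = vexch * rho - D * AE
    out[2] = X * vtca * q[23] - D * X
    out[3] = q[30] * vgly - vtca - vpta
    out[4] = vpta - vacka
    out[5] = vacka - vexch
    return out


@njit(cache=True)
def rhs_labelled(t, y, q, D, vfeed):
    GLC0 = max(y[0], 0.0)
    GLC1 = max(y[1], 0.0)
    AE0 = max(y[2], 0.0)
    AE1 = max(y[3], 0.0)
    X = max(y[4], 0.0)
    AC0 = max(y[5], 0.0)
    AC1 = max(y[6], 0.0)
    AP0 = max(y[7], 0.0)
    AP1 = max(y[8], 0.0)
    ACl0 = max(y[9], 0.0)
    ACl1 = max(y[10], 0.0)
    GLC = GLC0 + GLC1
    AE = AE0 + AE1
    AC = AC0 + AC1
    AP = AP0 + AP1
    ACl = ACl0 + ACl1
    vgly, vtca, ptf, ptr, akf, akr, exf, exr = _uni_rates(GLC, AE, AC, AP, ACl, q)
    rho = X * q[28] / q[29]
    # enrichment of each source pool; an empty pool carries no flux anyway
    eG1 = GLC1 / GLC if GLC > 0.0 else 0.0
    eA1 = AC1 / AC if AC > 0.0 else 0.0
    eP1 = AP1 / AP if AP > 0.0 else 0.0
    eC1 = ACl1 / ACl if ACl > 0.0 else 0.0
    eE1 = AE1 / AE if AE > 0.0 else 0.0
    eG0 = 1.0 - eG1
    eA0 = 1.0 - eA1
    eP0 = 1.0 - eP1
    eC0 = 1.0 - eC1
    eE0 = 1.0 - eE1
    n = q[30]
    out = np.empty(11)
    out[0] = -eG0 * vgly * rho + vfeed - D * GLC0
    out[1] = -eG1 * vgly * rho - D * GLC1
    out[2] = (eC0 * exf - eE0 * exr) * rho - D * AE0
    out[3] = (eC1 * exf - eE1 * exr) * rho - D * AE1
    out[4] = X * vtca * q[23] - D * X
    out[5] = eG0 * n * vgly + eP0 * ptr - eA0 * (vtca + ptf)
    out[6] = eG1 * n * vgly + eP1 * ptr - eA1 * (vtca + ptf)
    out[7] = eA0 * ptf + eC0 * akr - eP0 * (ptr + akf)
    out[8] = eA1 * ptf + eC1 * akr - eP1 * (ptr + akf)
    out[9] = eP0 * akf + eE0 * exr - eC0 * (akr + exf)
    out[10] = eP1 * akf + eE1 * exr - eC1 * (akr + exf)
    return out


def rates_from_packed(GLC, AE, AC, AP, ACl, q):
    """Unidirectional rates at one state (python-callable convenience)."""
    return _uni_rates(GLC, AE, AC, AP, ACl, q)
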