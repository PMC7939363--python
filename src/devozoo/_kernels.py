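"""Numba kernels for the force and diffusion inner loops.

These implement exactly the model described in :mod:`devozoo.simulator`
(piecewise-linear pair potential with anisotropic contact directions for
epithelial cylinders, apical-basal springs, gradient bending/torsion terms,
inverse-square-weighted diffusive exchange), written as explicit loops so the
per-pair branching compiles to machine code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COS45 = np.cos(np.pi / 4)


@njit(cache=True)
def pair_force_kernel(pos, kind, p_eqd, p_add, axes, pi, pj,
                      k_rep, k_adh, F):
    for n in range(len(pi)):
        i, j = pi[n], pj[n]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist < 1e-12:
            continue
        d_eqd = p_eqd[i] + p_eqd[j]
        d_add = p_add[i] + p_add[j]
        if dist < d_eqd:
            mag = k_rep * (d_eqd - dist)
        elif dist < d_add:
            span = d_add - d_eqd
            if span < 1e-12:
                span = 1e-12
            mag = -k_adh * (dist - d_eqd) * (d_add - dist) / span
        else:
            continue
        ux, uy, uz = dx / dist, dy / dist, dz / dist
        epi_i = kind[i] <= 1
        epi_j = kind[j] <= 1
        gx, gy, gz = ux, uy, uz
        if epi_i != epi_j:
            # sphere vs epithelial: along the axis for face contact,
            # perpendicular for lateral contact
            if epi_i:
                ax, ay, az = axes[i, 0], axes[i, 1], axes[i, 2]
            else:
                ax, ay, az = axes[j, 0], axes[j, 1], axes[j, 2]
            proj = ux * ax + uy * ay + uz * az
            if abs(proj) > _COS45:
                s = 1.0 if proj >= 0 else -1.0
                gx, gy, gz = s * ax, s * ay, s * az
            else:
                px = ux - proj * ax
                py = uy - proj * ay
                pz = uz - proj * az
                nrm = np.sqrt(px * px + py * py + pz * pz)
                if nrm > 0.3:
                    gx, gy, gz = px / nrm, py / nrm, pz / nrm
        elif epi_i and kind[i] == kind[j]:
            # same-side lateral epithelial contact: perpendicular to the
            # mean axis (center-to-center fallback when degenerate)
            ax = axes[i, 0] + axes[j, 0]
            ay = axes[i, 1] + axes[j, 1]
            az = axes[i, 2] + axes[j, 2]
            anrm = np.sqrt(ax * ax + ay * ay + az * az)
            if anrm > 1e-12:
                ax, ay, az = ax / anrm, ay / anrm, az / anrm
                proj = ux * ax + uy * ay + uz * az
                px = ux - proj * ax
                py = uy - proj * ay
                pz = uz - proj * az
                nrm = np.sqrt(px * px + py * py + pz * pz)
                if nrm > 0.3:
                    gx, gy, gz = px / nrm, py / nrm, pz / nrm
        F[j, 0] += mag * gx
        F[j, 1] += mag * gy
        F[j, 2] += mag * gz
        F[i, 0] -= mag * gx
        F[i, 1] -= mag * gy
        F[i, 2] -= mag * gz


@njit(cache=True)
def epithelial_force_kernel(pos, props, axes, ap, ba, apical_of, basal_of,
                            wlen, li, lj, k_spring, k_bending, k_torsion, F):
    I_EQS, I_ERP, I_EST = 2, 3, 4
    # apical-basal springs
    for c in range(len(ap)):
        a, b = ap[c], ba[c]
        wx = pos[b, 0] - pos[a, 0]
        wy = pos[b, 1] - pos[a, 1]
        wz = pos[b, 2] - pos[a, 2]
        d = np.sqrt(wx * wx + wy * wy + wz * wz)
        if d < 1e-12:
            continue
        rest = props[a, I_EQS] + props[b, I_EQS]
        fs = k_spring * (d - rest) / d
        F[a, 0] += fs * wx
        F[a, 1] += fs * wy
        F[a, 2] += fs * wz
        F[b, 0] -= fs * wx
        F[b, 1] -= fs * wy
        F[b, 2] -= fs * wz
    # bending + torsion over lateral same-side pairs, both orientations
    for n in range(len(li)):
        for orient in range(2):
            if orient == 0:
                i, j = li[n], lj[n]
            else:
                i, j = lj[n], li[n]
            ux = pos[j, 0] - pos[i, 0]
            uy = pos[j, 1] - pos[i, 1]
            uz = pos[j, 2] - pos[i, 2]
            ul = np.sqrt(ux * ux + uy * uy + uz * uz)
            if ul < 1e-12:
                continue
            ux, uy, uz = ux / ul, uy / ul, uz / ul
            aix, aiy, aiz = axes[i, 0], axes[i, 1], axes[i, 2]
            wl = wlen[i]
            if wl < 1e-12:
                wl = 1e-12
            # bending: E = 1/2 k p (axis_i . uhat)^2
            s = aix * ux + aiy * uy + aiz * uz
            kp = k_bending * props[i, I_ERP] * s
            gux = kp * (aix - s * ux) / ul
            guy = kp * (aiy - s * uy) / ul
            guz = kp * (aiz - s * uz) / ul
            F[j, 0] -= gux
            F[j, 1] -= guy
            F[j, 2] -= guz
            F[i, 0] += gux
            F[i, 1] += guy
            F[i, 2] += guz
            gwx = kp * (ux - s * aix) / wl
            gwy = kp * (uy - s * aiy) / wl
            gwz = kp * (uz - s * aiz) / wl
            bi, api_ = basal_of[i], apical_of[i]
            F[bi, 0] -= gwx
            F[bi, 1] -= gwy
            F[bi, 2] -= gwz
            F[api_, 0] += gwx
            F[api_, 1] += gwy
            F[api_, 2] += gwz
            # torsion: E = k p_bar (1 - axis_i . axis_j)
            ajx, ajy, ajz = axes[j, 0], axes[j, 1], axes[j, 2]
            s2 = aix * ajx + aiy * ajy + aiz * ajz
            kt = k_torsion * 0.5 * (props[i, I_EST] + props[j, I_EST])
            tx = kt * (ajx - s2 * aix) / wl
            ty = kt * (ajy - s2 * aiy) / wl
            tz = kt * (ajz - s2 * aiz) / wl
            F[bi, 0] += tx
            F[bi, 1] += ty
            F[bi, 2] += tz
            F[api_, 0] -= tx
            F[api_, 1] -= ty
            F[api_, 2] -= tz


@njit(cache=True)
def diffusion_kernel(pos, expr, pi, pj, genes, rates, out):
    for n in range(len(pi)):
        i, j = pi[n], pj[n]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < 1e-12:
            d2 = 1e-12
        w = 1.0 / d2
        for k in range(len(genes)):
            g = genes[k]
            flux = rates[k] * w * (expr[j, g] - expr[i, g])
            out[i, g] += flux
            out[j, g] -= flux
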