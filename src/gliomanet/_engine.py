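"""Fixed-step Euler-Maruyama kernel, jitted with numba.

All randomness is pregenerated outside the kernel with a seeded PCG64
generator and consumed strictly by step index, so trajectories are
bit-reproducible and the kernel can be stopped at a therapy trigger and
resumed mid-stream without disturbing the random sequence.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# slot codes shared with dynamics.compile_model
SLOT_PROLIF = 0
SLOT_CELL_DECAY = 1
SLOT_CONVERSION = 2
SLOT_SECRETION_CYT = 3
SLOT_SECRETION_PAIR = 4
SLOT_CYT_DECAY = 5
SLOT_RECRUIT = 6


@njit(cache=True)
def step_loop(y, theta,
              # model structure
              n_cells, cbar, angio_gated, crowding,
              conv_src, conv_dst, prod_cell, prod_cyt,
              e_src, e_n, e_a, e_up, e_slot_type, e_slot_idx,
              angio_driver, A_min, n_A,
              # effective parameters (therapy-rescaled copies)
              prolif, cell_decay, conv_rate, prod_rate, cyt_decay, e_K, K_A,
              # noise configuration
              sigma_prod, lo_prod, hi_prod,
              sigma_prolif, tau_prolif, sigma_conv, tau_conv,
              # jump configuration
              jump_kind, jump_cell, jump_src, jump_conv, jump_rate0,
              jump_ref, jump_sign,
              # pregenerated randoms, indexed [step, ...] (xi_prod by
              # refresh interval: white production noise has a fixed
              # refresh time so its strength is step-size independent)
              xi_prod, xi_stride, dw_prolif, dw_conv, u_jump, jump_mag,
              # loop control
              dt, step0, n_steps_total, save_stride, out,
              trigger_species, trigger_threshold, trigger_time):
    """Advance from step0 until the end or a trigger fires.

    Returns (next_step, fired) where fired is 1 if the trigger condition
    was met at the end of step ``next_step - 1``.
    """
    n_s = y.shape[0]
    n_cyt = n_s - n_cells
    n_conv = conv_src.shape[0]
    n_prod = prod_cell.shape[0]
    n_edges = e_src.shape[0]
    n_jump = jump_kind.shape[0]

    f_prolif = np.empty(n_cells)
    f_cdecay = np.empty(n_cells)
    f_conv = np.empty(n_conv)
    f_sec_cyt = np.empty(n_cyt)
    f_sec_pair = np.empty(n_prod)
    f_kdecay = np.empty(n_cyt)
    f_recruit = np.empty(n_cells)
    dy = np.empty(n_s)

    fired = 0
    step = step0
    while step < n_steps_total:
        t = step * dt
        # time trigger checked before the step so interventions start exactly
        # at the requested time
        if trigger_time >= 0.0 and t >= trigger_time:
            fired = 1
            break

        # --- modulation factors -----------------------------------------
        for i in range(n_cells):
            f_prolif[i] = 1.0
            f_cdecay[i] = 1.0
            f_recruit[i] = 1.0
        for i in range(n_conv):
            f_conv[i] = 1.0
        for i in range(n_cyt):
            f_sec_cyt[i] = 1.0
            f_kdecay[i] = 1.0
        for i in range(n_prod):
            f_sec_pair[i] = 1.0
        for k in range(n_edges):
            c = y[e_src[k]]
            if c < 0.0:
                c = 0.0
            r = (c / e_K[k]) ** e_n[k]
            h = r / (1.0 + r)
            if e_up[k] == 1:
                fac = 1.0 + (e_a[k] - 1.0) * h
            else:
                fac = 1.0 - (1.0 - e_a[k]) * h
            st = e_slot_type[k]
            si = e_slot_idx[k]
            if st == SLOT_PROLIF:
                f_prolif[si] *= fac
            elif st == SLOT_CELL_DECAY:
                f_cdecay[si] *= fac
            elif st == SLOT_CONVERSION:
                f_conv[si] *= fac
            elif st == SLOT_SECRETION_CYT:
                f_sec_cyt[si] *= fac
            elif st == SLOT_SECRETION_PAIR:
                f_sec_pair[si] *= fac
            elif st == SLOT_CYT_DECAY:
                f_kdecay[si] *= fac
            else:
                f_recruit[si] *= fac

        # --- angiogenesis and crowding ------------------------------------
        cv = y[angio_driver]
        if cv < 0.0:
            cv = 0.0
        r = (cv / K_A) ** n_A
        A = A_min + (1.0 - A_min) * (r / (1.0 + r))
        total = 0.0
        for i in range(n_cells):
            if crowding[i] == 1:
                total += y[i]

        # --- noisy rates ---------------------------------------------------
        for i in range(n_s):
            dy[i] = 0.0
        for i in range(n_cells):
            if sigma_prolif[i] > 0.0:
                theta[i] += math.sqrt(2.0 * dt / tau_prolif[i]) * dw_prolif[step, i]
                z = math.sin(theta[i])
                g = prolif[i] * (1.0 + sigma_prolif[i] * z)
            else:
                g = prolif[i]
            if g < 0.0:
                g = 0.0
            occ = total if crowding[i] == 1 else y[i]
            L = 1.0 - occ / cbar[i]
            if L < 0.0:
                L = 0.0
            grow = g * f_prolif[i] * L * y[i]
            if angio_gated[i] == 1:
                grow *= A
            dy[i] += grow - cell_decay[i] * f_cdecay[i] * y[i]
        for j in range(n_conv):
            if sigma_conv[j] > 0.0:
                theta[n_cells + j] += (math.sqrt(2.0 * dt / tau_conv[j])
                                       * dw_conv[step, j])
                z = math.sin(theta[n_cells + j])
                rate = conv_rate[j] * (1.0 + sigma_conv[j] * z)
            else:
                rate = conv_rate[j]
            if rate < 0.0:
                rate = 0.0
            flux = rate * f_conv[j] * y[conv_src[j]]
            dy[conv_src[j]] -= flux
            dy[conv_dst[j]] += flux
        for pidx in range(n_prod):
            j = prod_cyt[pidx]
            s = prod_rate[pidx]
            if sigma_prod[j] > 0.0:
                m = 1.0 + sigma_prod[j] * xi_prod[step // xi_stride, j]
                if m < lo_prod[j]:
                    m = lo_prod[j]
                elif m > hi_prod[j]:
                    m = hi_prod[j]
                s *= m
            dy[n_cells + j] += (s * f_sec_pair[pidx] * f_sec_cyt[j]
                                * y[prod_cell[pidx]])
        for j in range(n_cyt):
            dy[n_cells + j] -= cyt_decay[j] * f_kdecay[j] * y[n_cells + j]

        # --- Euler advance + jumps ------------------------------------------
        for i in range(n_s):
            y[i] += dt * dy[i]
        for q in range(n_jump):
            if jump_kind[q] == 0:
                lam = jump_rate0[q] * f_recruit[jump_cell[q]]
            else:
                src = jump_src[q]
                lam = jump_rate0[q] * (y[src] / jump_ref[q])
                cidx = jump_conv[q]
                if cidx >= 0:
                    lam *= f_conv[cidx]
            if lam < 0.0:
                lam = 0.0
            p = lam * dt
            # Poisson count by CDF inversion from one pregenerated uniform
            u = u_jump[step, q]
            acc = math.exp(-p)
            cdf = acc
            k = 0
            while u > cdf and k < 50:
                k += 1
                acc *= p / k
                cdf += acc
            if k > 0:
                y[jump_cell[q]] += jump_sign[q] * k * jump_mag[step, q]
        for i in range(n_s):
            if y[i] < 0.0:
                y[i] = 0.0

        step += 1
        if save_stride > 0 and step % save_stride == 0:
            row = step // save_stride
            for i in range(n_s):
                out[row, i] = y[i]
        if trigger_species >= 0 and y[trigger_species] >= trigger_threshold:
            fired = 1
            break
    return step, fired
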