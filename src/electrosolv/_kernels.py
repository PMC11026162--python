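"""Numba kernels for the 2D overdamped Brownian-dynamics integrator.

Forces derive from U(x) = A e^(-k1 x) + B e^(-k2 x) + U_vdW(x) + U_wall(x)
evaluated at the intersurface separation x = r_ij - R_i - R_j, with
force-shifted truncation at a centre-distance cutoff and the minimum-image
convention in a rectangular periodic box.
"""

import numpy as np
from numba import njit

X_FLOOR = 5e-10   # m; separations are clamped here when evaluating the wall


@njit(cache=True, fastmath=False)
def _pair_terms(x, A, B, k1, k2, AH, use_vdw, R1, R2):
    """Return (U(x), dU/dx) of the smooth potential for one pair."""
    u = A * np.exp(-k1 * x) + B * np.exp(-k2 * x)
    du = -A * k1 * np.exp(-k1 * x) - B * k2 * np.exp(-k2 * x)
    if use_vdw:
        d = x + R1 + R2
        d2 = d * d
        sp = d2 - (R1 + R2) ** 2
        sm = d2 - (R1 - R2) ** 2
        u += -(AH / 6.0) * (2 * R1 * R2 / sp + 2 * R1 * R2 / sm
                            + np.log(sp / sm))
        du += -(AH / 6.0) * 2.0 * d * (-2 * R1 * R2 / (sp * sp)
                                       - 2 * R1 * R2 / (sm * sm)
                                       + 1.0 / sp - 1.0 / sm)
    return u, du


@njit(cache=True, fastmath=False)
def _wall_terms(x, eps_w, x_w):
    """Steep inner power-law wall below x_w; (U, dU/dx), zero for x >= x_w."""
    if x >= x_w:
        return 0.0, 0.0
    xr = x if x > X_FLOOR else X_FLOOR
    ratio = x_w / xr
    u = eps_w * (ratio ** 6 - 1.0)
    du = -6.0 * eps_w * (x_w ** 6) / xr ** 7
    return u, du


@njit(cache=True, fastmath=False)
def forces_energy(pos, radii, Lx, Ly, A, B, k1, k2, AH, use_vdw,
                  eps_w, x_w, rc, forces, wall_forces):
    """Fill smooth `forces` and `wall_forces` (N,2); return total energy.

    The smooth part is force-shifted at the centre-distance cutoff rc; the
    wall (active only below x_w) is kept separate so the integrator can
    clamp it and the timestep-stability check can ignore it.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        wall_forces[i, 0] = 0.0
        wall_forces[i, 1] = 0.0
    rc2 = rc * rc
    utot = 0.0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
            r2 = dx * dx + dy * dy
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            contact = radii[i] + radii[j]
            x = r - contact
            if x < X_FLOOR:
                x = X_FLOOR
            xc = rc - contact
            u, du = _pair_terms(x, A, B, k1, k2, AH, use_vdw,
                                radii[i], radii[j])
            uc, duc = _pair_terms(xc, A, B, k1, k2, AH, use_vdw,
                                  radii[i], radii[j])
            # force-shifted truncation: F -> F - F(xc), U -> U - U(xc) + (x-xc) F'(xc)
            u_sh = u - uc - (x - xc) * duc
            f_mag = -(du - duc)          # along r-hat, positive = repulsive
            uw, duw = _wall_terms(x, eps_w, x_w)
            utot += u_sh + uw
            fx = f_mag * dx / r
            fy = f_mag * dy / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            fwx = -duw * dx / r
            fwy = -duw * dy / r
            wall_forces[i, 0] += fwx
            wall_forces[i, 1] += fwy
            wall_forces[j, 0] -= fwx
            wall_forces[j, 1] -= fwy
    return utot


@njit(cache=True, fastmath=False)
def run_bd(pos, radii, Lx, Ly, A, B, k1, k2, AH, use_vdw, eps_w, x_w, rc,
           mobility, noise_amp, dt, n_steps, sample_every, seed, max_disp,
           frames, energies):
    """Euler-Maruyama integration; fills `frames` and per-particle `energies`.

    Returns 0 on success, 1 when any single-step displacement exceeds
    `max_disp` (unstable timestep).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    wall_forces = np.zeros((n, 2))
    n_frames = frames.shape[0]
    # frame 0 is the initial configuration
    u0 = forces_energy(pos, radii, Lx, Ly, A, B, k1, k2, AH, use_vdw,
                       eps_w, x_w, rc, forces, wall_forces)
    for i in range(n):
        frames[0, i, 0] = pos[i, 0]
        frames[0, i, 1] = pos[i, 1]
    energies[0] = u0 / n
    isample = 1
    wall_clamp = 2.0 * x_w   # max wall pushback per step (overdamped contact)
    for step in range(1, n_steps + 1):
        forces_energy(pos, radii, Lx, Ly, A, B, k1, k2, AH, use_vdw,
                      eps_w, x_w, rc, forces, wall_forces)
        xi = np.random.standard_normal((n, 2))
        for i in range(n):
            drx = mobility[i] * forces[i, 0] * dt
            dry = mobility[i] * forces[i, 1] * dt
            # instability criterion on the smooth-potential drift: thermal
            # noise is bounded by the dt selection rule and the wall below
            if drx * drx + dry * dry > max_disp * max_disp:
                return 1
            dwx = mobility[i] * wall_forces[i, 0] * dt
            dwy = mobility[i] * wall_forces[i, 1] * dt
            wnorm = np.sqrt(dwx * dwx + dwy * dwy)
            if wnorm > wall_clamp:
                dwx *= wall_clamp / wnorm
                dwy *= wall_clamp / wnorm
            ddx = drx + dwx + noise_amp[i] * xi[i, 0]
            ddy = dry + dwy + noise_amp[i] * xi[i, 1]
            x_new = pos[i, 0] + ddx
            y_new = pos[i, 1] + ddy
            x_new -= Lx * np.floor(x_new / Lx)
            y_new -= Ly * np.floor(y_new / Ly)
            pos[i, 0] = x_new
            pos[i, 1] = y_new
        if step % sample_every == 0 and isample < n_frames:
            u = forces_energy(pos, radii, Lx, Ly, A, B, k1, k2, AH, use_vdw,
                              eps_w, x_w, rc, forces, wall_forces)
            for i in range(n):
                frames[isample, i, 0] = pos[i, 0]
                frames[isample, i, 1] = pos[i, 1]
            energies[isample] = u / n
            isample += 1
    return 0
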