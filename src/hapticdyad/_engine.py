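"""Compiled inner loop of the dyadic tracking simulation.

One 30 s trial is 3000 coupled steps of two agents; cohort sweeps run
thousands of trials, so the per-step arithmetic lives in a numba-jitted
kernel operating on flat scalars and preallocated arrays.  The kernel
mirrors, operation for operation, the public single-step functions in
:mod:`hapticdyad.agent_model` (a parity test enforces this), with the
perturbation plumbing and the three haptic strategies added:

* strategy 0 (no compensation): the haptic row is used as-is, referenced
  to the agent's own state at the delayed time.
* strategy 1 (as noise): same row, but the filter's haptic variance is
  inflated by a delay-attributed term (folded into ``rh`` upstream).
* strategy 2 (delay prediction): the delayed error row is advanced to
  the present by iterating the error dynamics under the nominal
  controller and the known target sequence, torque omitted.

Agent 0 is the (possibly perturbed) participant; agent 1 the partner,
which always receives the undelayed, noise-free band torque.
"""

import numba
import numpy as np

__all__ = ["advance_error", "run_pair", "STRAT_NONE", "STRAT_NOISE", "STRAT_PREDICT"]

STRAT_NONE = 0
STRAT_NOISE = 1
STRAT_PREDICT = 2


@numba.njit(cache=True)
def advance_error(ep, ev, j, i, pos, vel, dt, inertia, lp, lv):
    """Forward-integrate a tracking-error pair from step j to step i.

    Error dynamics under the plant, the feedback law and the known
    target sequence, with the interaction torque omitted:

        e_{k+1} = A e_k + B u_k + (A t*_k - t*_{k+1}),
        u_k     = -lp * e_p - lv * e_v.

    Exact (to round-off) for a torque-free agent whose controller acts
    on the true target, which is the oracle the tests use.
    """
    for k in range(j, i):
        u = -lp * ep - lv * ev
        ep_n = ep + dt * ev + (dt * vel[k] - (pos[k + 1] - pos[k]))
        ev_n = ev + dt * u / inertia + (vel[k] - vel[k + 1])
        ep = ep_n
        ev = ev_n
    return ep, ev


@numba.njit(cache=True)
def run_pair(pos, vel, dt, inertia,
             lp0, lv0, lp1, lv1,
             szv0, szv1, rh0, rh1,
             q00, q01, q11,
             stiffness, damping, nd, nd_vis, coupled, strategy0,
             mu0, mu1, eta,
             alpha, guard,
             q_out, qd_out, u_out, tau_out, band_out, qhat_out):
    """Simulate one trial of the coupled pair.

    Parameters are flat: per-agent gains ``lp*, lv*``; filter variances
    ``szv*`` (visual) and ``rh*`` (haptic row, strategy-adjusted);
    process noise entries ``q00, q01, q11``; band delay in steps ``nd``
    and visual-channel delay ``nd_vis`` (normally 0; used to calibrate
    delay-attributed noise); pre-scaled noise draws ``mu0, mu1`` (rad)
    and ``eta`` (Nm); ``alpha`` the EMA factor of the torque-trend
    velocity in the band inversion.

    Outputs are written in place; returns ``(steps_filled, diverged)``.
    ``q_out[a, i]`` doubles as the state history used by the delayed
    reconstruction.
    """
    n = mu0.shape[0]
    K = stiffness
    D = damping

    q0 = 0.0
    qd0 = 0.0
    q1 = 0.0
    qd1 = 0.0
    # estimator state per agent: mean (xp, xv), covariance (p00, p01, p11)
    xp0 = pos[0]
    xv0 = vel[0]
    p000 = 1e-4
    p001 = 0.0
    p011 = 1e-2
    xp1 = pos[0]
    xv1 = vel[0]
    p100 = 1e-4
    p101 = 0.0
    p111 = 1e-2

    t0_prev = 0.0
    t1_prev = 0.0
    have_t0 = False
    have_t1 = False
    qdr0_s = 0.0
    qdr1_s = 0.0

    for i in range(n):
        q_out[0, i] = q0
        qd_out[0, i] = qd0
        q_out[1, i] = q1
        qd_out[1, i] = qd1
        band_i = K * (q1 - q0) + D * (qd1 - qd0)
        band_out[i] = band_i

        if coupled:
            j = i - nd
            if j < 0:
                j = 0
            tau0 = band_out[j] + eta[i]
            tau1 = -band_i
        else:
            j = i
            tau0 = 0.0
            tau1 = 0.0

        # ---- agent 0 estimator -------------------------------------
        nxp = xp0 + dt * xv0
        nxv = xv0
        pp00 = p000 + dt * (p001 + p001) + dt * dt * p011 + q00
        pp01 = p001 + dt * p011 + q01
        pp11 = p011 + q11

        # visual row; nd_vis > 0 gives a stale visual channel (used to
        # calibrate the delay-attributed noise from solo-with-delay runs)
        jv = i - nd_vis
        if jv < 0:
            jv = 0
        z1 = q_out[0, jv] - pos[jv] + mu0[i]
        y = q0 - z1
        S = pp00 + szv0
        k0 = pp00 / S
        k1 = pp01 / S
        innov = y - nxp
        nxp = nxp + k0 * innov
        nxv = nxv + k1 * innov
        n00 = pp00 - k0 * pp00
        n01 = pp01 - k0 * pp01
        n10 = pp01 - k1 * pp00
        n11 = pp11 - k1 * pp01
        pp00 = n00
        pp01 = 0.5 * (n01 + n10)
        pp11 = n11

        if coupled:
            # invert the (delayed) band torque into a partner-target row:
            # spring-dominated inversion with a smoothed damping/lead term
            if have_t0:
                dtau = (tau0 - t0_prev) / dt
                qdr = qd_out[0, j] + dtau / K
                qdr0_s = alpha * qdr + (1.0 - alpha) * qdr0_s
            else:
                qdr0_s = qd_out[0, j]
            qr = q_out[0, j] + (tau0 - D * (qdr0_s - qd_out[0, j])) / K
            # quasi-static control inversion: partner reaction ~ -tau0,
            # inertial term negligible at these accelerations
            qtilde = qr + (tau0 + lv0 * (qdr0_s - vel[j])) / lp0
            e_h = q_out[0, j] - qtilde
            if strategy0 == STRAT_PREDICT and nd > 0:
                e_h, _ = advance_error(e_h, qd_out[0, j] - vel[j], j, i,
                                       pos, vel, dt, inertia, lp0, lv0)
            y2 = q0 - e_h
            S = pp00 + rh0
            k0 = pp00 / S
            k1 = pp01 / S
            innov = y2 - nxp
            nxp = nxp + k0 * innov
            nxv = nxv + k1 * innov
            n00 = pp00 - k0 * pp00
            n01 = pp01 - k0 * pp01
            n10 = pp01 - k1 * pp00
            n11 = pp11 - k1 * pp01
            pp00 = n00
            pp01 = 0.5 * (n01 + n10)
            pp11 = n11
            t0_prev = tau0
            have_t0 = True

        xp0 = nxp
        xv0 = nxv
        p000 = pp00
        p001 = pp01
        p011 = pp11

        # ---- agent 1 estimator (always undelayed, no compensation) --
        nxp = xp1 + dt * xv1
        nxv = xv1
        pp00 = p100 + dt * (p101 + p101) + dt * dt * p111 + q00
        pp01 = p101 + dt * p111 + q01
        pp11 = p111 + q11

        z1 = q1 - pos[i] + mu1[i]
        y = q1 - z1
        S = pp00 + szv1
        k0 = pp00 / S
        k1 = pp01 / S
        innov = y - nxp
        nxp = nxp + k0 * innov
        nxv = nxv + k1 * innov
        n00 = pp00 - k0 * pp00
        n01 = pp01 - k0 * pp01
        n10 = pp01 - k1 * pp00
        n11 = pp11 - k1 * pp01
        pp00 = n00
        pp01 = 0.5 * (n01 + n10)
        pp11 = n11

        if coupled:
            if have_t1:
                dtau = (tau1 - t1_prev) / dt
                qdr = qd1 + dtau / K
                qdr1_s = alpha * qdr + (1.0 - alpha) * qdr1_s
            else:
                qdr1_s = qd1
            qr = q1 + (tau1 - D * (qdr1_s - qd1)) / K
            qtilde = qr + (tau1 + lv1 * (qdr1_s - vel[i])) / lp1
            y2 = qtilde  # q1 - (q1 - qtilde)
            S = pp00 + rh1
            k0 = pp00 / S
            k1 = pp01 / S
            innov = y2 - nxp
            nxp = nxp + k0 * innov
            nxv = nxv + k1 * innov
            n00 = pp00 - k0 * pp00
            n01 = pp01 - k0 * pp01
            n10 = pp01 - k1 * pp00
            n11 = pp11 - k1 * pp01
            pp00 = n00
            pp01 = 0.5 * (n01 + n10)
            pp11 = n11
            t1_prev = tau1
            have_t1 = True

        xp1 = nxp
        xv1 = nxv
        p100 = pp00
        p101 = pp01
        p111 = pp11

        qhat_out[0, i] = xp0
        qhat_out[1, i] = xp1

        # ---- control and plant -------------------------------------
        u0 = -lp0 * (q0 - xp0) - lv0 * (qd0 - xv0)
        u1 = -lp1 * (q1 - xp1) - lv1 * (qd1 - xv1)
        u_out[0, i] = u0
        u_out[1, i] = u1
        tau_out[0, i] = tau0
        tau_out[1, i] = tau1

        q0_n = q0 + dt * qd0
        qd0_n = qd0 + dt * (u0 + tau0) / inertia
        q1_n = q1 + dt * qd1
        qd1_n = qd1 + dt * (u1 + tau1) / inertia
        q0 = q0_n
        qd0 = qd0_n
        q1 = q1_n
        qd1 = qd1_n

        if (not np.isfinite(q0)) or (not np.isfinite(q1)) \
                or abs(q0) > guard or abs(q1) > guard:
            return i + 1, True

    return n, False
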