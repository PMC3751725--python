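"""Compiled inner loop of the implicit-Euler solver.

Everything here operates on flat parameter arrays packed by
:mod:`cardioloop.engine`.  State vector layout::

    x = [volumes (ncomp) | branch flows (nb) | valve open fractions (nvalve)]

Chambers, when present, occupy compartment indices 0..3 in the order
la, lv, ra, rv, and the first four branches are the mitral, aortic,
tricuspid and pulmonary valves.  One implicit-Euler step solves
``F(x_new) = 0`` by modified Newton iteration with a finite-difference
Jacobian that is refreshed lazily (staleness or slow convergence).
"""

import numpy as np
from numba import njit

MMHG_TO_CGS = 1333.22

# chamber parameter columns
(IP_EMAX, IP_EMIN, IP_V0, IP_PHI, IP_A1, IP_A2, IP_N1, IP_N2, IP_ONSET,
 IP_RWALL, IP_ROUT, IP_STVTH, IP_STW, IP_V0D) = range(14)
NCHP = 14

# valve parameter columns
(IV_AMIN, IV_AMAX, IV_KOPEN, IV_KCLOSE) = range(4)

# global scalar slots
(G_DT, G_RHO, G_LAMBDA, G_PTHORAX, G_HR, G_TREF, G_KHB, G_FSHUNT, G_SATALV,
 G_VO2SYS, G_ESV0, G_ESA, G_VPC0, G_PSCALE, G_PHIPC, G_PMIN, G_MYOVOL,
 G_PVA_A, G_PVA_BL, G_PVA_CL, G_PVA_BR, G_PVA_CR,
 G_BARO_ON, G_SETP, G_GHR, G_GE, G_GR, G_BTAU, G_BLO, G_BHI, G_SENSE,
 G_O2_ON, G_ECG_DELAY) = range(33)
NGLOB = 33

# run-state slots ("misc")
(M_T, M_BSTART, M_TCUR, M_TPREV, M_BCOUNT, M_XMAP, M_VO2L, M_VO2R,
 M_SWL, M_SWR, M_MINVL, M_MINVR, M_PMVL, M_PMVR, M_MAXVL, M_MAXVR,
 M_STARVED, M_MHR, M_MEMAX, M_MRES, M_FAIL, M_FAILEQ, M_NEWTON_ITERS,
 M_JAC_AGE) = range(24)
MISC_LEN = 24

# beat log columns
(BL_T, BL_PERIOD, BL_SW_L, BL_PVA_L, BL_VO2_L, BL_SW_R, BL_PVA_R, BL_VO2_R,
 BL_EDV_L, BL_ESV_L) = range(10)
BEATLOG_COLS = 10

AREA_FLOOR = 1e-3
L_FLOOR = 1e-7
R_VALVE_LIN = 1e-4
EXP_CLIP = 60.0


@njit(cache=True)
def _dh_raw(t, tau1, tau2, n1, n2):
    if t <= 0.0:
        return 0.0
    x1 = (t / tau1) ** n1
    g1 = x1 / (1.0 + x1)
    g2 = 1.0 / (1.0 + (t / tau2) ** n2)
    return g1 * g2


@njit(cache=True)
def set_beat_timing(ch_par, nch, period, t_ref, ch_tau1, ch_tau2, ch_norm,
                    ch_onset):
    """Per-beat chamber timing: alpha scaling with sqrt of the rate factor.

    tau_i = alpha_i * sqrt(period * T_ref) equals alpha_i * T_ref at the
    reference rate and shortens with the square root of the rate increase.
    The normalization constant is rescanned because it depends on the
    taus and the period.
    """
    for c in range(nch):
        tau1 = ch_par[c, IP_A1] * np.sqrt(period * t_ref)
        tau2 = ch_par[c, IP_A2] * np.sqrt(period * t_ref)
        ch_tau1[c] = tau1
        ch_tau2[c] = tau2
        ch_onset[c] = ch_par[c, IP_ONSET] * np.sqrt(period / t_ref)
        m = 0.0
        npts = 800
        for k in range(1, npts):
            val = _dh_raw(period * k / npts, tau1, tau2,
                          ch_par[c, IP_N1], ch_par[c, IP_N2])
            if val > m:
                m = val
        ch_norm[c] = 1.0 / m


@njit(cache=True)
def _activations(act, ch_par, nch, t, bstart, t_cur, t_prev,
                 ch_tau1, ch_tau2, ch_norm, ch_onset):
    for c in range(nch):
        t_rel = t - bstart - ch_onset[c]
        if t_rel < 0.0:
            t_rel += t_prev
        if t_rel < 0.0:
            act[c] = 0.0
        else:
            act[c] = ch_norm[c] * _dh_raw(t_rel, ch_tau1[c], ch_tau2[c],
                                          ch_par[c, IP_N1], ch_par[c, IP_N2])


@njit(cache=True)
def _cexp(z):
    if z > EXP_CLIP:
        z = EXP_CLIP
    elif z < -EXP_CLIP:
        z = -EXP_CLIP
    return np.exp(z)


@njit(cache=True)
def advance_valve_fractions(zeta_tgt, x, p_prev, valve_par, nvalve,
                            ncomp, nb, b_up, b_dn, dt):
    """Exact one-step update of the pressure-driven opening dynamics.

    ``dz/dt = k_open dp (1-z)`` / ``k_close dp z`` is linear in z at frozen
    dp, so the step has a closed-form solution that never leaves [0, 1].
    The valve fractions are advanced with the previous step's pressure
    gradient and held fixed during the Newton solve of flows and volumes
    (first-order splitting, consistent at dt -> 0).
    """
    for vix in range(nvalve):
        z = x[ncomp + nb + vix]
        dp = p_prev[b_up[vix]] - p_prev[b_dn[vix]]
        if dp >= 0.0:
            z = 1.0 - (1.0 - z) * np.exp(-valve_par[vix, IV_KOPEN] * dp * dt)
        else:
            z = z * np.exp(valve_par[vix, IV_KCLOSE] * dp * dt)
        if z < 0.0:
            z = 0.0
        elif z > 1.0:
            z = 1.0
        zeta_tgt[vix] = z


@njit(cache=True)
def residual(F, p, xn, xo, qsh, act, zeta_tgt, nch, ncomp, nb, nvalve,
             b_up, b_dn, b_segu, b_segd, b_valve,
             sh_up, sh_dn,
             seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
             seg_comp_ch, seg_comp_coef, seg_resflag,
             ch_par, valve_par, glob, m_emax, m_res, dt):
    """Scaled implicit-Euler residual; also fills the pressure vector ``p``.

    Volume rows are in ml/s, branch rows in mmHg, valve-fraction rows in 1/s.
    Returns the pericardial pressure (for recording).
    """
    nseg = ncomp - nch
    # net inflow per compartment, from trial flows and (explicit) shunt flows
    nf = np.zeros(ncomp)
    for b in range(nb):
        q = xn[ncomp + b]
        nf[b_up[b]] -= q
        nf[b_dn[b]] += q
    for s in range(qsh.shape[0]):
        nf[sh_up[s]] -= qsh[s]
        nf[sh_dn[s]] += qsh[s]

    p_thorax = glob[G_PTHORAX]
    p_peri = 0.0
    if nch > 0:
        # pericardial pressure from total heart volume (chambers + blood in
        # pericardial vascular segments + myocardium)
        vheart = glob[G_MYOVOL]
        for c in range(nch):
            vheart += xn[c]
        for s in range(nseg):
            if seg_group[s] == 2:
                vheart += xn[nch + s]
        p_peri = glob[G_PMIN] + glob[G_PSCALE] * _cexp(
            (vheart - glob[G_VPC0]) / glob[G_PHIPC])

        # free-wall pressures and instantaneous elastances
        pfree = np.empty(4)
        einst = np.empty(4)
        for c in range(4):
            v = xn[c]
            emax = ch_par[c, IP_EMAX]
            if c == 1 or c == 3:
                emax *= m_emax
            vth = ch_par[c, IP_STVTH]
            if v > vth:
                ex = (v - vth) / ch_par[c, IP_STW]
                emax = emax / (1.0 + ex * ex)
            emin = ch_par[c, IP_EMIN]
            v0 = ch_par[c, IP_V0]
            phi = ch_par[c, IP_PHI]
            a = act[c]
            # passive curve anchored at its own zero-crossing volume; below
            # it the relaxed chamber generates suction
            ppas = emin * phi * (_cexp((v - ch_par[c, IP_V0D]) / phi) - 1.0)
            pfree[c] = a * emax * (v - v0) + (1.0 - a) * ppas
            einst[c] = a * emax + (1.0 - a) * emin

        # septal pressure transmission (ventricles: stiffness tracks elv;
        # atria: constant stiffness)
        esv = glob[G_ESV0] * einst[1]
        dlv = esv + einst[1]
        drv = esv + einst[3]
        plv = (esv * pfree[1] + einst[1] * pfree[3]) / dlv
        prv = (esv * pfree[3] + einst[3] * pfree[1]) / drv
        esa = glob[G_ESA]
        dla = esa + einst[0]
        dra = esa + einst[2]
        pla = (esa * pfree[0] + einst[0] * pfree[2]) / dla
        pra = (esa * pfree[2] + einst[2] * pfree[0]) / dra
        pext_ch = p_thorax + p_peri
        p[0] = pext_ch + pla + ch_par[0, IP_RWALL] * nf[0]
        p[1] = pext_ch + plv + ch_par[1, IP_RWALL] * nf[1]
        p[2] = pext_ch + pra + ch_par[2, IP_RWALL] * nf[2]
        p[3] = pext_ch + prv + ch_par[3, IP_RWALL] * nf[3]

    # vascular segments: volume-dependent properties and luminal pressure
    r_now = np.empty(nseg)
    i_now = np.empty(nseg)
    lam = glob[G_LAMBDA]
    for s in range(nseg):
        i = nch + s
        v = xn[i]
        if v < 1e-9:
            v = 1e-9
        w = v / seg_vref[s]
        rr = seg_r0a[s] / (w * w)
        if seg_resflag[s] == 1:
            rr *= m_res
        r_now[s] = rr
        ii = seg_i0a[s] / w
        i_now[s] = ii
        e_now = seg_e0a[s] * w ** -1.5
        omega = lam * np.sqrt(ii * e_now)
        ptm = seg_p0[s] * _cexp((seg_e0a[s] / seg_p0[s]) * (v - seg_vref[s]))
        if seg_group[s] == 0:
            pext = 0.0
        elif seg_group[s] == 1:
            pext = p_thorax
        else:
            pext = p_thorax + p_peri
        cc = seg_comp_ch[s]
        if cc >= 0:
            pext += seg_comp_coef[s] * p[cc]
        p[i] = pext + ptm + omega * nf[i]

    # volume equations
    for i in range(ncomp):
        F[i] = (xn[i] - xo[i]) / dt - nf[i]

    # branch momentum equations
    rho = glob[G_RHO]
    for b in range(nb):
        q = xn[ncomp + b]
        qo = xo[ncomp + b]
        dp = p[b_up[b]] - p[b_dn[b]]
        vix = b_valve[b]
        if vix >= 0:
            zeta = xn[ncomp + nb + vix]
            if zeta < 0.0:
                zeta = 0.0
            elif zeta > 1.0:
                zeta = 1.0
            a_eff = valve_par[vix, IV_AMIN] + (
                valve_par[vix, IV_AMAX] - valve_par[vix, IV_AMIN]) * zeta
            if a_eff < AREA_FLOOR:
                a_eff = AREA_FLOOR
            bern = rho / (2.0 * a_eff * a_eff) / MMHG_TO_CGS
            r_orif = np.sqrt(a_eff / np.pi)
            L = 2.0 * rho / (np.pi * r_orif) / MMHG_TO_CGS
            r_out = ch_par[b_up[b], IP_ROUT] + R_VALVE_LIN
            F[ncomp + b] = (L / dt) * (q - qo) - (
                dp - bern * q * abs(q) - r_out * q)
        else:
            R = 0.0
            L = 0.0
            if b_segu[b] >= 0:
                R += 0.5 * r_now[b_segu[b]]
                L += 0.5 * i_now[b_segu[b]]
            if b_segd[b] >= 0:
                R += 0.5 * r_now[b_segd[b]]
                L += 0.5 * i_now[b_segd[b]]
            if L < L_FLOOR:
                L = L_FLOOR
            F[ncomp + b] = (L / dt) * (q - qo) - (dp - R * q)

    # valve open fractions: pinned to their split-step exact update
    for vix in range(nvalve):
        F[ncomp + nb + vix] = (xn[ncomp + nb + vix] - zeta_tgt[vix]) / dt

    return p_peri


@njit(cache=True)
def fd_jacobian(J, xn, xo, qsh, act, zeta_tgt, scale, nch, ncomp, nb, nvalve,
                b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                seg_comp_ch, seg_comp_coef, seg_resflag,
                ch_par, valve_par, glob, m_emax, m_res, dt):
    n = xn.shape[0]
    F0 = np.empty(n)
    Fp = np.empty(n)
    ptmp = np.empty(ncomp)
    residual(F0, ptmp, xn, xo, qsh, act, zeta_tgt, nch, ncomp, nb, nvalve,
             b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
             seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
             seg_comp_ch, seg_comp_coef, seg_resflag,
             ch_par, valve_par, glob, m_emax, m_res, dt)
    xp = xn.copy()
    for j in range(n):
        eps = 1e-6 * scale[j]
        xp[j] = xn[j] + eps
        residual(Fp, ptmp, xp, xo, qsh, act, zeta_tgt, nch, ncomp, nb, nvalve,
                 b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                 seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                 seg_comp_ch, seg_comp_coef, seg_resflag,
                 ch_par, valve_par, glob, m_emax, m_res, dt)
        for i in range(n):
            J[i, j] = (Fp[i] - F0[i]) / eps
        xp[j] = xn[j]


@njit(cache=True)
def newton_solve(xn, xo, qsh, act, zeta_tgt, scale, Jinv, misc,
                 nch, ncomp, nb, nvalve,
                 b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                 seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                 seg_comp_ch, seg_comp_coef, seg_resflag,
                 ch_par, valve_par, glob, m_emax, m_res, dt,
                 p_out, jac_stride, tol):
    """Modified Newton for one implicit-Euler step.

    Returns 0 on success; on failure the index of the worst residual
    equation + 1.  ``Jinv`` is reused across steps and refreshed when stale
    or when convergence slows.
    """
    n = xn.shape[0]
    F = np.empty(n)
    J = np.empty((0, 0))
    if misc[M_JAC_AGE] < 0.0 or misc[M_JAC_AGE] >= jac_stride:
        J = np.empty((n, n))
        fd_jacobian(J, xn, xo, qsh, act, zeta_tgt, scale, nch, ncomp, nb,
                    nvalve, b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                    seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                    seg_comp_ch, seg_comp_coef, seg_resflag,
                    ch_par, valve_par, glob, m_emax, m_res, dt)
        Jinv[:, :] = np.linalg.inv(J)
        misc[M_JAC_AGE] = 0.0
    total_iters = 0.0
    refreshes = 0
    err_prev = 1e300
    for it in range(40):
        residual(F, p_out, xn, xo, qsh, act, zeta_tgt, nch, ncomp, nb,
                 nvalve, b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                 seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                 seg_comp_ch, seg_comp_coef, seg_resflag,
                 ch_par, valve_par, glob, m_emax, m_res, dt)
        dx = Jinv @ F
        # keep volumes positive: damp the update if it would cross zero
        shrink = 1.0
        for i in range(ncomp):
            if xn[i] - shrink * dx[i] <= 0.0:
                while shrink > 1e-4 and xn[i] - shrink * dx[i] <= 0.0:
                    shrink *= 0.5
        for i in range(n):
            xn[i] -= shrink * dx[i]
        total_iters += 1.0
        err = 0.0
        for i in range(n):
            e = abs(dx[i]) / scale[i]
            if e > err:
                err = e
        if err < tol:
            misc[M_NEWTON_ITERS] += total_iters
            return 0
        # refresh the Jacobian at the current iterate when contraction stalls
        if (err > 0.5 * err_prev or shrink < 1.0) and refreshes < 8:
            if J.shape[0] == 0:
                J = np.empty((n, n))
            fd_jacobian(J, xn, xo, qsh, act, zeta_tgt, scale, nch, ncomp,
                        nb, nvalve, b_up, b_dn, b_segu, b_segd, b_valve,
                        sh_up, sh_dn, seg_r0a, seg_i0a, seg_e0a, seg_vref,
                        seg_p0, seg_group, seg_comp_ch, seg_comp_coef,
                        seg_resflag, ch_par, valve_par, glob, m_emax, m_res,
                        dt)
            Jinv[:, :] = np.linalg.inv(J)
            misc[M_JAC_AGE] = 0.0
            refreshes += 1
            err_prev = 1e300
        else:
            err_prev = err
    # report the worst-residual equation for diagnostics
    residual(F, p_out, xn, xo, qsh, act, zeta_tgt, nch, ncomp, nb, nvalve,
             b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
             seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
             seg_comp_ch, seg_comp_coef, seg_resflag,
             ch_par, valve_par, glob, m_emax, m_res, dt)
    worst = 0
    wval = 0.0
    for i in range(n):
        if abs(F[i]) > wval:
            wval = abs(F[i])
            worst = i
    misc[M_NEWTON_ITERS] += total_iters
    return worst + 1


@njit(cache=True)
def _ecg_value(ch_par, nch, ecg_w, t, bstart, t_cur, t_prev,
               ch_tau1, ch_tau2, ch_norm, ch_onset, delay):
    out = 0.0
    for c in range(nch):
        if ecg_w[c] == 0.0:
            continue
        t_rel = t + delay - bstart - ch_onset[c]
        while t_rel >= t_cur:
            t_rel -= t_cur
        if t_rel < 0.0:
            t_rel += t_prev
        if t_rel > 0.0:
            out += ecg_w[c] * ch_norm[c] * _dh_raw(
                t_rel, ch_tau1[c], ch_tau2[c],
                ch_par[c, IP_N1], ch_par[c, IP_N2])
    return out


@njit(cache=True)
def run_chunk(x, sat, misc, p_prev,
              nch, ncomp, nb, nvalve,
              b_up, b_dn, b_segu, b_segd, b_valve,
              sh_up, sh_dn, sh_area, sh_coef,
              seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
              seg_comp_ch, seg_comp_coef, seg_resflag,
              ch_par, valve_par, glob, ecg_w,
              ch_tau1, ch_tau2, ch_norm, ch_onset,
              o2_sink_comp, o2_sink_branch, o2_cor_comp, o2_cor_vent,
              o2_pulm_branch,
              af_periods,
              n_steps, stride, rec, rec_start, beat_log, beat_start_count,
              Jinv, scale, jac_stride, tol):
    """Advance ``n_steps`` implicit-Euler steps, recording every ``stride``.

    Returns (number of recorded rows, number of completed beats, status);
    status 0 = ok, otherwise 1 + index of the worst residual equation at the
    failed step (time of failure is left in misc[M_FAIL]).
    """
    dt = glob[G_DT]
    t = misc[M_T]
    khb = glob[G_KHB]
    o2_on = glob[G_O2_ON] > 0.5
    baro_on = glob[G_BARO_ON] > 0.5
    sense = int(glob[G_SENSE])
    nsh = sh_up.shape[0]
    qsh = np.zeros(nsh)
    act = np.zeros(4)
    zeta_tgt = np.zeros(4)
    for vix in range(nvalve):
        zeta_tgt[vix] = x[ncomp + nb + vix]
    xn = np.empty(x.shape[0])
    nrec = 0
    nbeat = 0
    n_af = af_periods.shape[0]

    # populate p_prev from the current state if this is the first chunk
    if misc[M_JAC_AGE] < 0.0:
        Ftmp = np.empty(x.shape[0])
        _activations(act, ch_par, nch, t, misc[M_BSTART], misc[M_TCUR],
                     misc[M_TPREV], ch_tau1, ch_tau2, ch_norm, ch_onset)
        residual(Ftmp, p_prev, x, x, qsh, act, zeta_tgt, nch, ncomp, nb, nvalve,
                 b_up, b_dn, b_segu, b_segd, b_valve, sh_up, sh_dn,
                 seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0, seg_group,
                 seg_comp_ch, seg_comp_coef, seg_resflag,
                 ch_par, valve_par, glob, misc[M_MEMAX], misc[M_MRES], dt)

    for istep in range(n_steps):
        # ---- beat bookkeeping ------------------------------------------
        if nch > 0 and t - misc[M_BSTART] >= misc[M_TCUR] - 0.5 * dt:
            # finalize the ending beat: pressure-volume areas -> VO2
            v0l = ch_par[1, IP_V0]
            v0r = ch_par[3, IP_V0]
            pe_l = 0.5 * misc[M_PMVL] * (misc[M_MINVL] - v0l)
            if pe_l < 0.0:
                pe_l = 0.0
            pe_r = 0.5 * misc[M_PMVR] * (misc[M_MINVR] - v0r)
            if pe_r < 0.0:
                pe_r = 0.0
            pva_l = misc[M_SWL] + pe_l
            pva_r = misc[M_SWR] + pe_r
            if pva_l < 0.0:
                pva_l = 0.0
            if pva_r < 0.0:
                pva_r = 0.0
            ees_l = ch_par[1, IP_EMAX] * misc[M_MEMAX]
            ees_r = ch_par[3, IP_EMAX] * misc[M_MEMAX]
            vo2_l = glob[G_PVA_A] * pva_l + glob[G_PVA_BL] * ees_l + glob[G_PVA_CL]
            vo2_r = glob[G_PVA_A] * pva_r + glob[G_PVA_BR] * ees_r + glob[G_PVA_CR]
            ib = beat_start_count + nbeat
            if ib < beat_log.shape[0]:
                beat_log[ib, BL_T] = misc[M_BSTART]
                beat_log[ib, BL_PERIOD] = misc[M_TCUR]
                beat_log[ib, BL_SW_L] = misc[M_SWL]
                beat_log[ib, BL_PVA_L] = pva_l
                beat_log[ib, BL_VO2_L] = vo2_l * 60.0 / misc[M_TCUR]
                beat_log[ib, BL_SW_R] = misc[M_SWR]
                beat_log[ib, BL_PVA_R] = pva_r
                beat_log[ib, BL_VO2_R] = vo2_r * 60.0 / misc[M_TCUR]
                beat_log[ib, BL_EDV_L] = misc[M_MAXVL]
                beat_log[ib, BL_ESV_L] = misc[M_MINVL]
            nbeat += 1
            misc[M_BCOUNT] += 1.0
            misc[M_BSTART] += misc[M_TCUR]
            misc[M_TPREV] = misc[M_TCUR]
            # next period: AF sequence or (baroreflex-adjusted) heart rate
            if n_af > 0:
                k = int(misc[M_BCOUNT])
                if k >= n_af:
                    k = n_af - 1
                t_next = af_periods[k]
            else:
                t_next = 60.0 / (glob[G_HR] * misc[M_MHR])
            misc[M_TCUR] = t_next
            misc[M_VO2L] = vo2_l / t_next
            misc[M_VO2R] = vo2_r / t_next
            set_beat_timing(ch_par, nch, t_next, glob[G_TREF],
                            ch_tau1, ch_tau2, ch_norm, ch_onset)
            misc[M_SWL] = 0.0
            misc[M_SWR] = 0.0
            misc[M_MINVL] = x[1]
            misc[M_MINVR] = x[3]
            misc[M_PMVL] = p_prev[1]
            misc[M_PMVR] = p_prev[3]
            misc[M_MAXVL] = x[1]
            misc[M_MAXVR] = x[3]

        t_new = t + dt
        _activations(act, ch_par, nch, t_new, misc[M_BSTART], misc[M_TCUR],
                     misc[M_TPREV], ch_tau1, ch_tau2, ch_norm, ch_onset)

        # explicit Gorlin shunt flows from last step's pressures
        for s in range(nsh):
            dp = p_prev[sh_up[s]] - p_prev[sh_dn[s]]
            if dp >= 0.0:
                qsh[s] = sh_coef[s] * sh_area[s] * np.sqrt(dp)
            else:
                qsh[s] = -sh_coef[s] * sh_area[s] * np.sqrt(-dp)

        # ---- implicit Euler step ---------------------------------------
        advance_valve_fractions(zeta_tgt, x, p_prev, valve_par, nvalve,
                                ncomp, nb, b_up, b_dn, dt)
        xn[:] = x
        status = newton_solve(xn, x, qsh, act, zeta_tgt, scale, Jinv, misc,
                              nch, ncomp, nb, nvalve,
                              b_up, b_dn, b_segu, b_segd, b_valve,
                              sh_up, sh_dn,
                              seg_r0a, seg_i0a, seg_e0a, seg_vref, seg_p0,
                              seg_group, seg_comp_ch, seg_comp_coef,
                              seg_resflag, ch_par, valve_par, glob,
                              misc[M_MEMAX], misc[M_MRES], dt,
                              p_prev, jac_stride, tol)
        if status != 0:
            misc[M_FAIL] = t_new
            misc[M_FAILEQ] = float(status - 1)
            return nrec, nbeat, status
        misc[M_JAC_AGE] += 1.0
        for vix in range(nvalve):
            xn[ncomp + nb + vix] = zeta_tgt[vix]

        # ---- oxygen transport (explicit upwind, conservative) ----------
        if o2_on:
            content = np.empty(ncomp)
            for i in range(ncomp):
                content[i] = khb * sat[i] * x[i]
            for b in range(nb):
                q = xn[ncomp + b]
                donor = b_up[b] if q > 0.0 else b_dn[b]
                moved = q * dt * khb * sat[donor]
                content[b_up[b]] -= moved
                content[b_dn[b]] += moved
            for s in range(nsh):
                q = qsh[s]
                donor = sh_up[s] if q > 0.0 else sh_dn[s]
                moved = q * dt * khb * sat[donor]
                content[sh_up[s]] -= moved
                content[sh_dn[s]] += moved
            # pulmonary oxygenation: the non-shunted fraction of capillary
            # inflow equilibrates to the alveolar saturation
            qp = xn[ncomp + o2_pulm_branch]
            if qp > 0.0:
                donor = b_up[o2_pulm_branch]
                content[b_dn[o2_pulm_branch]] += (
                    qp * dt * khb * (1.0 - glob[G_FSHUNT])
                    * (glob[G_SATALV] - sat[donor]))
            # systemic consumption, distributed by bed outflow
            wsum = 0.0
            for k in range(o2_sink_comp.shape[0]):
                q = xn[ncomp + o2_sink_branch[k]]
                if q > 0.0:
                    wsum += q
            rate = glob[G_VO2SYS] * dt
            for k in range(o2_sink_comp.shape[0]):
                if wsum > 0.0:
                    q = xn[ncomp + o2_sink_branch[k]]
                    w = q / wsum if q > 0.0 else 0.0
                else:
                    w = 1.0 / o2_sink_comp.shape[0]
                ci = o2_sink_comp[k]
                content[ci] -= w * rate
                if content[ci] < 0.0:
                    content[ci] = 0.0
                    misc[M_STARVED] = 1.0
            # myocardial consumption from the PVA of the previous beat
            for k in range(o2_cor_comp.shape[0]):
                ci = o2_cor_comp[k]
                vo2 = misc[M_VO2L] if o2_cor_vent[k] == 1 else misc[M_VO2R]
                content[ci] -= vo2 * dt
                if content[ci] < 0.0:
                    content[ci] = 0.0
                    misc[M_STARVED] = 1.0
            for i in range(ncomp):
                s_new = content[i] / (khb * xn[i])
                if s_new < 0.0:
                    s_new = 0.0
                elif s_new > 100.0:
                    s_new = 100.0
                sat[i] = s_new

        # ---- per-beat accumulators and baroreflex ----------------------
        if nch > 0:
            misc[M_SWL] -= p_prev[1] * (xn[1] - x[1])
            misc[M_SWR] -= p_prev[3] * (xn[3] - x[3])
            if xn[1] < misc[M_MINVL]:
                misc[M_MINVL] = xn[1]
                misc[M_PMVL] = p_prev[1]
            if xn[3] < misc[M_MINVR]:
                misc[M_MINVR] = xn[3]
                misc[M_PMVR] = p_prev[3]
            if xn[1] > misc[M_MAXVL]:
                misc[M_MAXVL] = xn[1]
            if xn[3] > misc[M_MAXVR]:
                misc[M_MAXVR] = xn[3]

        if baro_on:
            misc[M_XMAP] += dt * (p_prev[sense] - misc[M_XMAP]) / glob[G_BTAU]
            err = glob[G_SETP] - misc[M_XMAP]
            lo = glob[G_BLO]
            hi = glob[G_BHI]
            mh = 1.0 + glob[G_GHR] * err
            me = 1.0 + glob[G_GE] * err
            mr = 1.0 + glob[G_GR] * err
            misc[M_MHR] = lo if mh < lo else (hi if mh > hi else mh)
            misc[M_MEMAX] = lo if me < lo else (hi if me > hi else me)
            misc[M_MRES] = lo if mr < lo else (hi if mr > hi else mr)
        else:
            misc[M_XMAP] += dt * (p_prev[sense] - misc[M_XMAP]) / glob[G_BTAU]

        x[:] = xn
        t = t_new
        misc[M_T] = t

        # ---- recording --------------------------------------------------
        if (istep + 1) % stride == 0:
            row = rec_start + nrec
            if row < rec.shape[0]:
                col = 0
                rec[row, col] = t
                col += 1
                for i in range(ncomp):
                    rec[row, col + i] = p_prev[i]
                col += ncomp
                for i in range(ncomp):
                    rec[row, col + i] = x[i]
                col += ncomp
                for i in range(ncomp):
                    rec[row, col + i] = sat[i]
                col += ncomp
                for b in range(nb):
                    rec[row, col + b] = x[ncomp + b]
                col += nb
                for vix in range(nvalve):
                    rec[row, col + vix] = x[ncomp + nb + vix]
                col += nvalve
                if nch > 0:
                    rec[row, col] = _ecg_value(
                        ch_par, nch, ecg_w, t, misc[M_BSTART], misc[M_TCUR],
                        misc[M_TPREV], ch_tau1, ch_tau2, ch_norm, ch_onset,
                        glob[G_ECG_DELAY])
                    # recompute pericardial pressure for the record
                    vheart = glob[G_MYOVOL]
                    for c in range(nch):
                        vheart += x[c]
                    for s in range(ncomp - nch):
                        if seg_group[s] == 2:
                            vheart += x[nch + s]
                    rec[row, col + 1] = glob[G_PMIN] + glob[G_PSCALE] * _cexp(
                        (vheart - glob[G_VPC0]) / glob[G_PHIPC])
                else:
                    rec[row, col] = 0.0
                    rec[row, col + 1] = 0.0
                rec[row, col + 2] = misc[M_XMAP]
                rec[row, col + 3] = misc[M_MHR]
                rec[row, col + 4] = misc[M_MEMAX]
                rec[row, col + 5] = misc[M_MRES]
                nrec += 1

    return nrec, nbeat, 0
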