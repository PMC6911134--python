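"""Numba inner loop of the lung-ventilator simulator.

Integrates the single-compartment equation of motion at a fine step with an
explicit first-order scheme, driving a small ventilator state machine:

    Paw + Pmus = Ers*V + Rphys*Qdot_term + PEEP_set + dP_ETT(Q)

with V referenced to the relaxed FRC at set PEEP.  Intrinsic PEEP is
realised by gas trapping: expiratory flow is clamped to zero once volume
reaches the trapped volume ``v_trap = PEEPi/Ers``, so end-expiratory
alveolar pressure sits at PEEP + PEEPi and inspiratory flow cannot start
until Pmus has overcome PEEPi.

Ventilator states: 0 = exhale (Paw relaxes to PEEP), 1 = trigger delay
(valve still closed, the patient draws from the circuit and Paw dips below
PEEP by r_trig*Q), 2 = insufflation (first-order pressurisation toward
PEEP + PS, or PEEP + atc_fraction*dP_ETT(Q) in tube-compensation mode),
3 = end-expiratory occlusion (flow clamped, Paw mirrors -Pmus).

Flow is solved each step from the monotone scalar equation
``R*Q + k1*Q + k2*Q|Q| + kb*|Q|^1.75*sign(Q) = x`` by safeguarded Newton.
"""

from numba import njit

STATE_EXHALE = 0
STATE_TRIG = 1
STATE_INSP = 2
STATE_OCCL = 3


@njit(cache=True)
def _solve_flow(x, r_lin, k1, k2, kb, q0):
    q = q0
    for _ in range(80):
        aq = abs(q)
        g = (r_lin + k1) * q + k2 * q * aq + kb * aq**0.75 * q - x
        if abs(g) < 1e-11:
            return q
        dg = r_lin + k1 + 2.0 * k2 * aq + 1.75 * kb * aq**0.75
        step = g / dg
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        q -= step
    return q


@njit(cache=True)
def run_engine(n, dt, pmus, ers, rphys, v_trap, peep, mode_atc, ps_level,
               atc_frac, k1, k2, kb, q_trig, valve_delay, rise_tau, rel_tau,
               cyc_frac, min_ti, max_ti, r_trig, refractory, neural_period,
               occ_start, occ_nsamp,
               flow, paw, vol, state_out,
               valve_open_idx, cycle_off_idx, breath_cycle, wob_cycle):
    """Fill flow/paw/vol/state arrays in place; return number of breaths."""
    v = v_trap
    q = 0.0
    paw_state = peep
    state = STATE_EXHALE
    t_trig_end = 0.0
    t_cycoff = -1e9
    insp_t = 0.0
    peakq = 0.0
    occ_ptr = 0
    n_occ = occ_start.shape[0]
    occ_end = -1
    paw_occ = 0.0
    pm_occ = 0.0
    n_breaths = 0
    max_breaths = valve_open_idx.shape[0]

    for i in range(n):
        t = i * dt
        pm = pmus[i]
        c = int(t / neural_period)

        if occ_ptr < n_occ and state != STATE_OCCL and i >= occ_start[occ_ptr]:
            if state == STATE_EXHALE:
                state = STATE_OCCL
                occ_end = i + occ_nsamp
                paw_occ = paw_state
                pm_occ = pm
            else:
                occ_ptr += 1  # breath still running; skip this occlusion

        if state == STATE_OCCL:
            q = 0.0
            paw_i = paw_occ - (pm - pm_occ)
            if i + 1 >= occ_end:
                state = STATE_EXHALE
                paw_state = paw_i
                occ_ptr += 1
                t_cycoff = -1e9  # allow immediate trigger on release
        elif state == STATE_EXHALE:
            paw_state += (peep - paw_state) * min(dt / rel_tau, 1.0)
            x = paw_state + pm - ers * v - peep
            q = _solve_flow(x, rphys, k1, k2, kb, q)
            if q < 0.0:
                if v <= v_trap + 1e-12:
                    q = 0.0
                    v = v_trap
                elif v + q * dt < v_trap:
                    q = (v_trap - v) / dt
            paw_i = paw_state
            if q >= q_trig and (t - t_cycoff) > refractory:
                state = STATE_TRIG
                t_trig_end = t + valve_delay
        elif state == STATE_TRIG:
            x = pm - ers * v
            q = _solve_flow(x, rphys + r_trig, k1, k2, kb, q)
            if q < 0.0 and v <= v_trap + 1e-12:
                q = 0.0
                v = v_trap
            paw_i = peep - r_trig * max(q, 0.0)
            if t >= t_trig_end:
                state = STATE_INSP
                insp_t = 0.0
                peakq = max(q, 0.0)
                paw_state = paw_i
                if n_breaths < max_breaths:
                    valve_open_idx[n_breaths] = i
                    breath_cycle[n_breaths] = c
        else:  # STATE_INSP
            if mode_atc:
                qp = max(q, 0.0)
                target = peep + atc_frac * (k1 * qp + k2 * qp * qp
                                            + kb * qp**1.75)
            else:
                target = peep + ps_level
            paw_state += (target - paw_state) * min(dt / rise_tau, 1.0)
            x = paw_state + pm - ers * v - peep
            q = _solve_flow(x, rphys, k1, k2, kb, q)
            if q > peakq:
                peakq = q
            insp_t += dt
            paw_i = paw_state
            if (insp_t >= min_ti and q <= cyc_frac * peakq) or insp_t >= max_ti:
                if n_breaths < max_breaths:
                    cycle_off_idx[n_breaths] = i
                n_breaths += 1
                state = STATE_EXHALE
                t_cycoff = t

        if q > 0.0 and (state == STATE_TRIG or state == STATE_INSP):
            wob_cycle[c] += pm * q * dt

        v += q * dt
        flow[i] = q
        paw[i] = paw_i
        vol[i] = v
        state_out[i] = state

    return n_breaths
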