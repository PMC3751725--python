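"""Model assembly and the implicit-Euler simulation driver.

``assemble`` packs a validated :class:`~cardioloop.parameters.ModelConfig`
into flat arrays for the compiled kernel and distributes the configured
blood volume over the compartments.  ``run`` advances the model, applying
timed events and staged parameter patches between kernel chunks, and
returns a :class:`SimTrace` with uniformly sampled signals plus per-beat
records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardioloop import _kernel as K
from cardioloop import vascular
from cardioloop.parameters import (ModelConfig, TimedEvent, get_path,
                                   set_path)
from cardioloop.units import O2_BINDING

__all__ = ["assemble", "step", "run", "SimState", "SimTrace", "SolverError"]

CHAMBER_ORDER = ("la", "lv", "ra", "rv")
VALVE_ORDER = ("mitral", "aortic", "tricuspid", "pulmonary")
GROUP_CODE = {"extrathoracic": 0, "intrathoracic": 1, "pericardial": 2}

NEWTON_TOL = 1e-9
JAC_STRIDE = 40.0


class SolverError(RuntimeError):
    pass


@dataclass
class _Packed:
    """Flat kernel arrays built from one configuration."""

    nch: int
    ncomp: int
    nb: int
    nvalve: int
    comp_names: list
    branch_names: list
    b_up: np.ndarray
    b_dn: np.ndarray
    b_segu: np.ndarray
    b_segd: np.ndarray
    b_valve: np.ndarray
    sh_up: np.ndarray
    sh_dn: np.ndarray
    sh_area: np.ndarray
    sh_coef: np.ndarray
    seg_r0a: np.ndarray
    seg_i0a: np.ndarray
    seg_e0a: np.ndarray
    seg_vref: np.ndarray
    seg_p0: np.ndarray
    seg_group: np.ndarray
    seg_comp_ch: np.ndarray
    seg_comp_coef: np.ndarray
    seg_resflag: np.ndarray
    ch_par: np.ndarray
    valve_par: np.ndarray
    glob: np.ndarray
    ecg_w: np.ndarray
    o2_sink_comp: np.ndarray
    o2_sink_branch: np.ndarray
    o2_cor_comp: np.ndarray
    o2_cor_vent: np.ndarray
    o2_pulm_branch: int
    init_volumes: np.ndarray
    init_sats: np.ndarray


def _pack(config: ModelConfig) -> _Packed:
    g = config.globals_
    if g.damping_lambda < 0.05:
        warnings.warn("vascular damping factor lambda < 0.05: viscoelastic "
                      "wall damping is nearly absent; pressure waveforms "
                      "develop undamped high-frequency oscillations and the "
                      "model is prone to numerical instability",
                      stacklevel=2)
    nch = 4 if config.chambers is not None else 0
    seg_names = [s.name for s in config.segments]
    comp_names = list(CHAMBER_ORDER[:nch]) + seg_names
    idx = {n: i for i, n in enumerate(comp_names)}
    nseg = len(seg_names)
    ncomp = nch + nseg

    # ---- segments ---------------------------------------------------------
    seg_r0a = np.empty(nseg)
    seg_i0a = np.empty(nseg)
    seg_e0a = np.empty(nseg)
    seg_vref = np.empty(nseg)
    seg_p0 = np.empty(nseg)
    seg_group = np.empty(nseg, dtype=np.int64)
    seg_comp_ch = np.full(nseg, -1, dtype=np.int64)
    seg_comp_coef = np.zeros(nseg)
    seg_resflag = np.zeros(nseg, dtype=np.int64)
    init_volumes = np.empty(ncomp)
    init_sats = np.empty(ncomp)
    for s, seg in enumerate(config.segments):
        seg_r0a[s] = vascular.base_resistance(g.blood_viscosity, seg.length,
                                              seg.r0, seg.n)
        seg_i0a[s] = vascular.base_inertance(g.blood_density, seg.length,
                                             seg.r0, seg.n)
        seg_e0a[s] = vascular.base_elastance(g.young_modulus, seg.h, seg.r0,
                                             seg.length, seg.n)
        seg_vref[s] = vascular.reference_volume(seg.r0, seg.length, seg.n)
        seg_p0[s] = seg.p0
        seg_group[s] = GROUP_CODE[seg.external_group]
        if seg.compression_chamber is not None:
            seg_comp_ch[s] = idx[seg.compression_chamber]
            seg_comp_coef[s] = seg.compression_coef
        seg_resflag[s] = 1 if seg.baroreflex_target else 0
        init_volumes[nch + s] = (seg.initial_volume if seg.initial_volume
                                 is not None else seg_vref[s])
        init_sats[nch + s] = (seg.init_sat if seg.init_sat is not None
                              else config.oxygen.init_arterial_sat)

    # ---- chambers ---------------------------------------------------------
    ch_par = np.zeros((4, K.NCHP))
    valve_par = np.zeros((4, 4))
    if nch:
        for c, name in enumerate(CHAMBER_ORDER):
            ch = config.chambers[name]
            v0d = ch.v0_passive if ch.v0_passive is not None else ch.v0
            ch_par[c] = [ch.e_max, ch.e_min, ch.v0, ch.phi_passive,
                         ch.alpha1, ch.alpha2, ch.n1, ch.n2, ch.onset_delay,
                         ch.r_wall, ch.r_outflow, ch.starling_v_threshold,
                         ch.starling_width, v0d]
            init_volumes[c] = ch.initial_volume
        for vix, name in enumerate(VALVE_ORDER):
            va = config.valves[name]
            valve_par[vix] = [va.a_min, va.a_max, va.k_open, va.k_close]
        init_sats[idx["la"]] = config.oxygen.init_arterial_sat
        init_sats[idx["lv"]] = config.oxygen.init_arterial_sat
        init_sats[idx["ra"]] = config.oxygen.init_venous_sat
        init_sats[idx["rv"]] = config.oxygen.init_venous_sat

    # ---- branches: valves first, in canonical order -----------------------
    valve_branches = {}
    vascular_branches = []
    for br in config.branches:
        if nch and br.source in CHAMBER_ORDER:
            if br.source == "la" and br.target == "lv":
                valve_branches["mitral"] = br
            elif br.source == "ra" and br.target == "rv":
                valve_branches["tricuspid"] = br
            elif br.source == "lv":
                valve_branches["aortic"] = br
            elif br.source == "rv":
                valve_branches["pulmonary"] = br
            else:
                raise ValueError(f"unsupported chamber outflow branch "
                                 f"{br.source}->{br.target}")
        else:
            vascular_branches.append(br)
    if nch:
        missing = set(VALVE_ORDER) - set(valve_branches)
        if missing:
            raise ValueError(f"missing valve branches: {sorted(missing)}")
        ordered = [valve_branches[n] for n in VALVE_ORDER] + vascular_branches
        nvalve = 4
    else:
        ordered = vascular_branches
        nvalve = 0
    nb = len(ordered)
    b_up = np.empty(nb, dtype=np.int64)
    b_dn = np.empty(nb, dtype=np.int64)
    b_segu = np.full(nb, -1, dtype=np.int64)
    b_segd = np.full(nb, -1, dtype=np.int64)
    b_valve = np.full(nb, -1, dtype=np.int64)
    branch_names = []
    for b, br in enumerate(ordered):
        b_up[b] = idx[br.source]
        b_dn[b] = idx[br.target]
        if b_up[b] >= nch:
            b_segu[b] = b_up[b] - nch
        if b_dn[b] >= nch:
            b_segd[b] = b_dn[b] - nch
        if nvalve and b < 4:
            b_valve[b] = b
            branch_names.append(VALVE_ORDER[b])
        else:
            branch_names.append(f"{br.source}__{br.target}")

    # ---- shunts -----------------------------------------------------------
    nsh = len(config.shunts)
    sh_up = np.empty(nsh, dtype=np.int64)
    sh_dn = np.empty(nsh, dtype=np.int64)
    sh_area = np.empty(nsh)
    sh_coef = np.empty(nsh)
    for s, sh in enumerate(config.shunts):
        sh_up[s] = idx[sh.source]
        sh_dn[s] = idx[sh.target]
        sh_area[s] = sh.area
        sh_coef[s] = sh.gorlin_c * math.sqrt(2.0 * sh.g)

    # ---- oxygen wiring ----------------------------------------------------
    o2 = config.oxygen
    sink_comp, sink_branch, cor_comp, cor_vent = [], [], [], []
    pulm_branch = -1
    outflow_of = {}
    for b in range(nb):
        outflow_of.setdefault(int(b_up[b]), b)
    for s, seg in enumerate(config.segments):
        ci = nch + s
        if seg.o2_systemic_sink:
            if ci not in outflow_of:
                raise ValueError(f"oxygen sink segment '{seg.name}' has no "
                                 "outflow branch")
            sink_comp.append(ci)
            sink_branch.append(outflow_of[ci])
        if seg.o2_myocardial is not None:
            cor_comp.append(ci)
            cor_vent.append(1 if seg.o2_myocardial == "lv" else 3)
        if seg.o2_pulmonary:
            for b in range(nb):
                if b_dn[b] == ci:
                    pulm_branch = b
                    break
    o2_on = o2.enabled
    if o2_on and pulm_branch < 0:
        warnings.warn("oxygen transport enabled but no segment is marked "
                      "o2_pulmonary; disabling oxygen exchange")
        o2_on = False

    # ---- globals ----------------------------------------------------------
    glob = np.zeros(K.NGLOB)
    glob[K.G_DT] = g.dt
    glob[K.G_RHO] = g.blood_density
    glob[K.G_LAMBDA] = g.damping_lambda
    glob[K.G_PTHORAX] = g.intrathoracic_pressure
    glob[K.G_HR] = g.heart_rate
    glob[K.G_TREF] = 60.0 / g.heart_rate
    glob[K.G_KHB] = O2_BINDING * g.hb
    glob[K.G_FSHUNT] = g.pulm_shunt_fraction
    glob[K.G_SATALV] = g.pulm_cap_sat
    glob[K.G_VO2SYS] = g.vo2_systemic / 60.0
    if config.septum is not None:
        glob[K.G_ESV0] = config.septum.esv0
        glob[K.G_ESA] = config.septum.esa
    if config.pericardium is not None:
        pc = config.pericardium
        glob[K.G_VPC0] = pc.v_pc0
        glob[K.G_PSCALE] = pc.p_scale
        glob[K.G_PHIPC] = pc.phi
        glob[K.G_PMIN] = pc.p_min
        glob[K.G_MYOVOL] = pc.myocardial_volume
    elif nch:
        raise ValueError("configurations with chambers require pericardium "
                         "and septum parameters")
    glob[K.G_PVA_A] = o2.pva_a
    glob[K.G_PVA_BL] = o2.pva_b * o2.lv_mass / 100.0
    glob[K.G_PVA_CL] = o2.pva_c * o2.lv_mass / 100.0
    glob[K.G_PVA_BR] = o2.pva_b * o2.rv_mass / 100.0
    glob[K.G_PVA_CR] = o2.pva_c * o2.rv_mass / 100.0
    br_cfg = config.baroreflex
    glob[K.G_BARO_ON] = 1.0 if br_cfg.enabled else 0.0
    glob[K.G_SETP] = br_cfg.setpoint
    glob[K.G_GHR] = br_cfg.gain_hr
    glob[K.G_GE] = br_cfg.gain_emax
    glob[K.G_GR] = br_cfg.gain_res
    glob[K.G_BTAU] = br_cfg.time_constant
    glob[K.G_BLO] = br_cfg.limit_lo
    glob[K.G_BHI] = br_cfg.limit_hi
    sense = br_cfg.sense_segment
    glob[K.G_SENSE] = float(idx.get(sense, nch if nseg else 0))
    glob[K.G_O2_ON] = 1.0 if o2_on else 0.0
    glob[K.G_ECG_DELAY] = config.ecg.delay
    ecg_w = np.zeros(4)
    for c, name in enumerate(CHAMBER_ORDER):
        ecg_w[c] = config.ecg.weights.get(name, 0.0)

    return _Packed(
        nch=nch, ncomp=ncomp, nb=nb, nvalve=nvalve,
        comp_names=comp_names, branch_names=branch_names,
        b_up=b_up, b_dn=b_dn, b_segu=b_segu, b_segd=b_segd, b_valve=b_valve,
        sh_up=sh_up, sh_dn=sh_dn, sh_area=sh_area, sh_coef=sh_coef,
        seg_r0a=seg_r0a, seg_i0a=seg_i0a, seg_e0a=seg_e0a,
        seg_vref=seg_vref, seg_p0=seg_p0, seg_group=seg_group,
        seg_comp_ch=seg_comp_ch, seg_comp_coef=seg_comp_coef,
        seg_resflag=seg_resflag, ch_par=ch_par, valve_par=valve_par,
        glob=glob, ecg_w=ecg_w,
        o2_sink_comp=np.array(sink_comp, dtype=np.int64),
        o2_sink_branch=np.array(sink_branch, dtype=np.int64),
        o2_cor_comp=np.array(cor_comp, dtype=np.int64),
        o2_cor_vent=np.array(cor_vent, dtype=np.int64),
        o2_pulm_branch=pulm_branch,
        init_volumes=init_volumes, init_sats=init_sats)


@dataclass
class SimState:
    """Full solver state: packed model plus the evolving state vector."""

    config: ModelConfig
    packed: _Packed
    x: np.ndarray
    sat: np.ndarray
    misc: np.ndarray
    p_prev: np.ndarray
    Jinv: np.ndarray
    scale: np.ndarray
    ch_tau1: np.ndarray
    ch_tau2: np.ndarray
    ch_norm: np.ndarray
    ch_onset: np.ndarray
    af_periods: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float64))

    @property
    def t(self) -> float:
        return float(self.misc[K.M_T])

    @property
    def n_states(self) -> int:
        return len(self.x)

    def total_volume(self) -> float:
        return float(self.x[:self.packed.ncomp].sum())

    def volumes(self) -> dict:
        return dict(zip(self.packed.comp_names, self.x[:self.packed.ncomp]))

    def pressures(self) -> dict:
        return dict(zip(self.packed.comp_names, self.p_prev))

    def external_pressure(self, group: str) -> float:
        """Current external pressure of a compartment group, mmHg."""
        p_thorax = float(self.packed.glob[K.G_PTHORAX])
        if group == "extrathoracic":
            return 0.0
        if group == "intrathoracic":
            return p_thorax
        if group == "pericardial":
            pk = self.packed
            vheart = float(pk.glob[K.G_MYOVOL]) + float(self.x[:pk.nch].sum())
            for s in range(pk.ncomp - pk.nch):
                if pk.seg_group[s] == 2:
                    vheart += self.x[pk.nch + s]
            return p_thorax + float(
                pk.glob[K.G_PMIN] + pk.glob[K.G_PSCALE]
                * np.exp((vheart - pk.glob[K.G_VPC0]) / pk.glob[K.G_PHIPC]))
        raise ValueError(f"unknown external-pressure group '{group}'")


def assemble(config: ModelConfig) -> SimState:
    """Build the initial solver state from a validated configuration.

    Initial volumes follow the per-compartment presets; any mismatch with the
    configured total blood volume (parameter patches can change reference
    volumes) is absorbed by the most compliant segment.  Flows start at zero
    and valves closed, so assembly is deterministic.
    """
    pk = _pack(config)
    x = np.zeros(pk.ncomp + pk.nb + pk.nvalve)
    x[:pk.ncomp] = pk.init_volumes
    total = x[:pk.ncomp].sum()
    diff = config.globals_.blood_volume - total
    if abs(diff) > 0.10 * config.globals_.blood_volume:
        raise ValueError(
            f"initial compartment volumes ({total:.0f} ml) are inconsistent "
            f"with the configured blood volume "
            f"({config.globals_.blood_volume:.0f} ml)")
    if pk.ncomp > pk.nch:
        reservoir = pk.nch + int(np.argmin(pk.seg_e0a))
        x[reservoir] += diff
    elif abs(diff) > 1e-9:
        raise ValueError("cannot absorb blood-volume mismatch without "
                         "vascular segments")

    misc = np.zeros(K.MISC_LEN)
    period = 60.0 / config.globals_.heart_rate
    misc[K.M_TCUR] = period
    misc[K.M_TPREV] = period
    misc[K.M_MHR] = 1.0
    misc[K.M_MEMAX] = 1.0
    misc[K.M_MRES] = 1.0
    misc[K.M_JAC_AGE] = -1.0
    sense = int(pk.glob[K.G_SENSE])
    misc[K.M_XMAP] = (pk.seg_p0[sense - pk.nch]
                      if sense >= pk.nch and pk.ncomp > pk.nch else 79.0)
    if pk.nch:
        misc[K.M_MINVL] = x[1]
        misc[K.M_MINVR] = x[3]
        misc[K.M_MAXVL] = x[1]
        misc[K.M_MAXVR] = x[3]

    n = len(x)
    scale = np.empty(n)
    scale[:pk.ncomp] = 50.0
    scale[pk.ncomp:pk.ncomp + pk.nb] = 50.0
    scale[pk.ncomp + pk.nb:] = 1.0

    ch_tau1 = np.zeros(4)
    ch_tau2 = np.zeros(4)
    ch_norm = np.ones(4)
    ch_onset = np.zeros(4)
    if pk.nch:
        K.set_beat_timing(pk.ch_par, pk.nch, period,
                          pk.glob[K.G_TREF], ch_tau1, ch_tau2, ch_norm,
                          ch_onset)

    return SimState(config=config, packed=pk, x=x, sat=pk.init_sats.copy(),
                    misc=misc, p_prev=np.zeros(pk.ncomp),
                    Jinv=np.zeros((n, n)), scale=scale,
                    ch_tau1=ch_tau1, ch_tau2=ch_tau2, ch_norm=ch_norm,
                    ch_onset=ch_onset)


def _chunk(state: SimState, n_steps: int, stride: int, rec: np.ndarray,
           rec_start: int, beat_log: np.ndarray, beat_count: int):
    pk = state.packed
    nrec, nbeat, status = K.run_chunk(
        state.x, state.sat, state.misc, state.p_prev,
        pk.nch, pk.ncomp, pk.nb, pk.nvalve,
        pk.b_up, pk.b_dn, pk.b_segu, pk.b_segd, pk.b_valve,
        pk.sh_up, pk.sh_dn, pk.sh_area, pk.sh_coef,
        pk.seg_r0a, pk.seg_i0a, pk.seg_e0a, pk.seg_vref, pk.seg_p0,
        pk.seg_group, pk.seg_comp_ch, pk.seg_comp_coef, pk.seg_resflag,
        pk.ch_par, pk.valve_par, pk.glob, pk.ecg_w,
        state.ch_tau1, state.ch_tau2, state.ch_norm, state.ch_onset,
        pk.o2_sink_comp, pk.o2_sink_branch, pk.o2_cor_comp, pk.o2_cor_vent,
        pk.o2_pulm_branch, state.af_periods,
        n_steps, stride, rec, rec_start, beat_log, beat_count,
        state.Jinv, state.scale, JAC_STRIDE, NEWTON_TOL)
    if status != 0:
        eq = int(state.misc[K.M_FAILEQ])
        raise SolverError(
            f"Newton iteration failed to converge at t="
            f"{state.misc[K.M_FAIL]:.4f} s; worst residual in equation "
            f"'{_equation_label(pk, eq)}'")
    return nrec, nbeat


def _equation_label(pk: _Packed, eq: int) -> str:
    if eq < pk.ncomp:
        return f"volume[{pk.comp_names[eq]}]"
    if eq < pk.ncomp + pk.nb:
        return f"flow[{pk.branch_names[eq - pk.ncomp]}]"
    return f"zeta[{VALVE_ORDER[eq - pk.ncomp - pk.nb]}]"


def step(state: SimState, n_steps: int = 1) -> SimState:
    """Advance the state in place by ``n_steps`` implicit-Euler steps."""
    rec = np.empty((0, 1))
    beat_log = np.empty((0, K.BEATLOG_COLS))
    _chunk(state, n_steps, n_steps + 1, rec, 0, beat_log, 0)
    return state


class SimTrace:
    """Uniformly sampled simulation output plus per-beat records.

    Columns: ``t`` (s); ``p_<name>`` luminal pressures (mmHg); ``v_<name>``
    volumes (ml); ``sat_<name>`` O2 saturations (%); ``q_<branch>`` flows
    (ml/s); ``zeta_<valve>`` open fractions; ``ecg`` (a.u.); ``p_peri``
    (mmHg); ``map_filt`` running-mean arterial pressure (mmHg); baroreflex
    multipliers ``m_hr``, ``m_emax``, ``m_res``.
    """

    def __init__(self, columns, data, beat_log, config,
                 comp_names, branch_names):
        self.columns = list(columns)
        self.data = data
        self.beat_log = beat_log
        self.config = config
        self.comp_names = list(comp_names)
        self.branch_names = list(branch_names)
        self._colmap = {c: i for i, c in enumerate(self.columns)}

    def __len__(self):
        return self.data.shape[0]

    @property
    def t(self):
        return self.data[:, 0]

    def __getitem__(self, name):
        return self.data[:, self._colmap[name]]

    def __contains__(self, name):
        return name in self._colmap

    @property
    def beats(self) -> pd.DataFrame:
        cols = ["t_start", "period", "sw_lv", "pva_lv", "vo2_lv",
                "sw_rv", "pva_rv", "vo2_rv", "edv_lv", "esv_lv"]
        return pd.DataFrame(self.beat_log, columns=cols)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.columns)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# units: t s; p_* mmHg; v_* ml; sat_* %; q_* ml/s; "
                     "zeta_* dimensionless; ecg a.u.\n")
            self.to_dataframe().to_csv(fh, index=False)

    def total_volume(self):
        cols = [self._colmap[f"v_{n}"] for n in self.comp_names]
        return self.data[:, cols].sum(axis=1)


def _trace_columns(pk: _Packed):
    cols = (["t"]
            + [f"p_{n}" for n in pk.comp_names]
            + [f"v_{n}" for n in pk.comp_names]
            + [f"sat_{n}" for n in pk.comp_names]
            + [f"q_{n}" for n in pk.branch_names]
            + [f"zeta_{VALVE_ORDER[v]}" for v in range(pk.nvalve)]
            + ["ecg", "p_peri", "map_filt", "m_hr", "m_emax", "m_res"])
    return cols


def _event_schedule(config: ModelConfig):
    """Expand timed events and staged patches into (time, [(path, value)])."""
    actions = {}
    for ev in config.timed_events:
        original = get_path(config, ev.path)
        actions.setdefault(ev.t_start, []).append((ev.path, ev.value))
        actions.setdefault(ev.t_end, []).append((ev.path, original))
    for stage in config.staged:
        t = float(stage["t"])
        for path, value in stage["patches"].items():
            actions.setdefault(t, []).append((path, value))
    return sorted(actions.items())


def run(config: ModelConfig, duration: float, record_interval: float = 0.001,
        rr_seed=None, rr_jitter: float = 0.2,
        state: SimState | None = None) -> SimTrace:
    """Simulate ``duration`` seconds and return the recorded trace.

    Timed events and staged patches attached to the configuration are applied
    at their scheduled times (parameters are re-packed between kernel
    chunks).  ``rr_seed`` activates randomized beat-to-beat cycle lengths
    (uniform jitter of ``rr_jitter`` around the mean RR interval) for the
    atrial-fibrillation mode; the seed makes the sequence reproducible.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if state is None:
        state = assemble(config)
    pk = state.packed
    dt = config.globals_.dt
    stride = max(1, round(record_interval / dt))
    n_total = round(duration / dt)
    n_rows = n_total // stride + 2
    rec = np.zeros((max(n_rows, 1), len(_trace_columns(pk))))
    max_beats = int(duration * config.globals_.heart_rate / 60.0 * 4) + 8
    beat_log = np.zeros((max_beats, K.BEATLOG_COLS))

    if rr_seed is not None:
        rng = np.random.default_rng(rr_seed)
        t0 = 60.0 / config.globals_.heart_rate
        nper = int(duration / t0 * 3) + 8
        state.af_periods = t0 * (1.0 + rr_jitter
                                 * rng.uniform(-1.0, 1.0, size=nper))
        state.misc[K.M_TCUR] = state.af_periods[0]

    schedule = [(t, acts) for t, acts in _event_schedule(config)
                if state.t < t <= state.t + duration]
    boundaries = [t for t, _ in schedule] + [state.t + duration]
    actions_at = dict(schedule)

    rec_count = 0
    beat_count = 0
    t_start = state.t
    t_prev = t_start
    cfg_live = config
    for t_next in boundaries:
        n_steps = round((t_next - t_prev) / dt)
        if n_steps > 0:
            nrec, nbeat = _chunk(state, n_steps, stride, rec, rec_count,
                                 beat_log, beat_count)
            rec_count += nrec
            beat_count += nbeat
        t_prev = t_next
        if t_next in actions_at:
            import copy as _copy
            cfg_live = _copy.deepcopy(cfg_live)
            for path, value in actions_at[t_next]:
                set_path(cfg_live, path, value)
            _repack(state, cfg_live)

    return SimTrace(_trace_columns(pk), rec[:rec_count],
                    beat_log[:beat_count], config,
                    pk.comp_names, pk.branch_names)


def _repack(state: SimState, config: ModelConfig) -> None:
    """Swap in new parameters mid-run, preserving the dynamic state."""
    pk_new = _pack(config)
    old = state.packed
    if (pk_new.ncomp != old.ncomp or pk_new.nb != old.nb
            or pk_new.nvalve != old.nvalve):
        raise ValueError("timed events may not change the model topology")
    state.packed = pk_new
    state.config = config
    state.misc[K.M_JAC_AGE] = -1.0  # force a Jacobian refresh
    if pk_new.nch:
        K.set_beat_timing(pk_new.ch_par, pk_new.nch,
                          state.misc[K.M_TCUR], pk_new.glob[K.G_TREF],
                          state.ch_tau1, state.ch_tau2, state.ch_norm,
                          state.ch_onset)
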