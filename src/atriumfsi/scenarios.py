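"""Scenario configuration and end-to-end case runs on the 2D testbed.

Six named cases mirror the physiological/pathological study conditions:

* ``original``   normal atrium: non-uniform wall thickness, active
                 contraction in late diastole, competent valve;
* ``af``         atrial fibrillation: active tension identically zero;
* ``mvr``        mitral regurgitation: chordae origins displaced toward
                 the atrium so the leaflets cannot coapt;
* ``rb_fibre``   rule-based fibre variant (the testbed's native
                 circumferential rule; flagged for config bookkeeping);
* ``uniform15``  uniform wall thickness at the non-uniform mean;
* ``uniform22``  uniform wall thickness ~50% thicker.

Each case runs a 0.1 s ramped initialization followed by >= 2 cardiac
cycles (0.8 s each) and reports metrics from the configured cycle, with a
cycle-to-cycle periodicity diagnostic.  Pressure drive: periodic-spline
pulmonary-vein and ventricular waveforms shaped by the four cycle phases
(systole, early/mid/late diastole), applied on the top and bottom box
faces; the ambient region vents through the top face and so tracks the
pulmonary-vein pressure as a pericardial-like reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import units
from .grid import StaggeredGrid, BoundarySpec, FluidProperties
from .materials import PassiveParams, ActiveParams, ActivationProfile
from .geometry import TestbedParams, build_2d_testbed
from .coupling import FSISystem, TetherSet, SpringSet
from .metrics import (
    MetricsBundle, polygon_area, chamber_mask, kinetic_energy,
    dissipation_rate, segment_patch, orifice_trace, volume_accounting,
    principal_strain, fibre_strain,
)
from .fe import kinematics

__all__ = ["PressureWaveform", "ScenarioConfig", "CASES", "run_case",
           "papillary_motion", "config_diff", "PHASES"]

CASES = ("original", "af", "mvr", "rb_fibre", "uniform15", "uniform22")

# cycle phases (s within a 0.8 s cycle whose origin is systole onset)
PHASES = {"sys": (0.0, 0.30), "edia": (0.30, 0.50),
          "mdia": (0.50, 0.68), "ldia": (0.68, 0.80)}


class PressureWaveform:
    """Periodic pressure trace through phase-anchored control points.

    points: ((t, p_mmHg), ...) within one cycle; interpolated with a
    periodic cubic spline.  Continuous, periodic with the cycle.
    """

    def __init__(self, points, cycle=0.8):
        pts = sorted(points)
        t = np.array([p[0] for p in pts] + [pts[0][0] + cycle])
        y = np.array([p[1] for p in pts] + [pts[0][1]])
        self.cycle = cycle
        self._spline = CubicSpline(t, y, bc_type="periodic")
        self._t0 = t[0]

    def mmhg(self, t):
        tau = np.mod(np.asarray(t, float) - self._t0, self.cycle) + self._t0
        return self._spline(tau)

    def __call__(self, t):
        """Pressure in dyn/cm^2."""
        return units.mmhg(self.mmhg(t))


class _RampedDrive:
    """Boundary pressure: ambient during startup, ramped to the waveform."""

    def __init__(self, wave: PressureWaveform, ambient_mmhg, t_init):
        self.wave = wave
        self.amb = units.mmhg(ambient_mmhg)
        self.t_init = t_init

    def __call__(self, t):
        if t >= self.t_init:
            return float(self.wave(t - self.t_init))
        r = max(t, 0.0) / self.t_init
        return float(self.amb + r * (self.wave(0.0) - self.amb))


class _GatedProfile:
    """Activation profile shifted past the initialization phase."""

    def __init__(self, inner: ActivationProfile, t_init):
        self.inner = inner
        self.t_init = t_init
        self.peak = inner.peak
        self.cycle = inner.cycle

    def __call__(self, t):
        t = np.asarray(t, float)
        out = np.where(t >= self.t_init, self.inner(t - self.t_init), 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one case run."""

    case: str = "original"
    cycle: float = 0.8
    n_cycles: int = 2
    report_cycle: int = 2
    init_duration: float = 0.1
    # waveform control points (t within cycle, p mmHg)
    lv_points: tuple = ((0.0, 12.0), (0.07, 30.0), (0.18, 26.0), (0.30, 8.0),
                       (0.36, 2.5), (0.50, 4.0), (0.68, 5.0), (0.75, 6.5))
    pv_points: tuple = ((0.0, 10.5), (0.15, 11.5), (0.31, 9.0),
                       (0.50, 9.5), (0.68, 10.5))
    ambient_mmhg: float = 8.0
    # materials
    passive: PassiveParams = field(default_factory=PassiveParams)
    # leaflets: tension-stiff along the fibre, bending-soft
    leaflet_passive: PassiveParams = field(default_factory=lambda: PassiveParams(
        a=1.5, b=2.0, a1=30.0, b1=2.0, beta=30.0))
    activation_peak: float = 56.2     # kPa
    activation_onset: float = 0.64
    activation_duration: float = 0.16
    gamma: float = 4.9
    # geometry / case structure
    testbed: TestbedParams = field(default_factory=TestbedParams)
    fibre_mode: str = "reference"     # 'reference' | 'rule'
    mvr_offset: float = 0.0
    # numerics
    dt_max: float = 1.1e-4
    cfl: float = 0.4
    kernel: str = "ib4"
    tether_kappa: float = 2.5e5       # dyn/cm per tethered node
    chordae_k: float = 3.0e4
    chordae_k2: float = 3.0e5
    scheme: str = "euler"   # desk-scale runs; 'midpoint' available
    sample_interval: float = 0.005
    papillary_amplitude: float = 0.22
    store_velocity: bool = False
    seed: int = 0

    @classmethod
    def from_case(cls, case: str, **over) -> "ScenarioConfig":
        if case not in CASES:
            raise ValueError(f"unknown case {case!r}; choose from {CASES}")
        kw = {}
        if case == "af":
            kw["activation_peak"] = 0.0
        elif case == "mvr":
            kw["mvr_offset"] = 1.15
        elif case == "rb_fibre":
            kw["fibre_mode"] = "rule"
        elif case == "uniform15":
            kw["testbed"] = TestbedParams(thickness_mode="uniform",
                                          thickness_factor=1.0)
        elif case == "uniform22":
            kw["testbed"] = TestbedParams(thickness_mode="uniform",
                                          thickness_factor=2.2 / 1.5)
        kw.update(over)
        cfg = cls(case=case, **kw)
        cfg.validate()
        return cfg

    def validate(self):
        if self.case == "af" and self.activation_peak != 0.0:
            raise ValueError("AF case requires zero activation peak")
        if self.case == "mvr" and self.mvr_offset <= 0.0:
            raise ValueError("MVR case requires a positive chordae offset")
        if self.case in ("uniform15", "uniform22") \
                and self.testbed.thickness_mode != "uniform":
            raise ValueError("uniform cases require uniform thickness mode")
        if self.report_cycle > self.n_cycles:
            raise ValueError("report_cycle exceeds n_cycles")
        return self


def config_diff(a: ScenarioConfig, b: ScenarioConfig) -> dict:
    """Fields (dotted for nested dataclasses) on which two configs differ."""
    out = {}

    def walk(x, y, prefix=""):
        if dataclasses.is_dataclass(x) and dataclasses.is_dataclass(y):
            for f in dataclasses.fields(x):
                walk(getattr(x, f.name), getattr(y, f.name),
                     prefix + f.name + ".")
        else:
            if x != y:
                out[prefix[:-1]] = (x, y)
    walk(a, b)
    return out


def papillary_motion(t, config: ScenarioConfig, base_origins: np.ndarray):
    """Chordae-origin target positions at time t (cycle clock).

    Smooth periodic blend between the diastolic rest positions and the
    systolic positions (shifted down the outflow channel); the MVR
    atrium-ward offset is already baked into base_origins.  C1-continuous
    across the cycle wrap (squared-sine window).
    """
    tau = np.mod(t, config.cycle)
    s0, s1 = PHASES["sys"]
    if s0 <= tau < s1:
        w = np.sin(np.pi * (tau - s0) / (s1 - s0)) ** 2
    else:
        w = 0.0
    out = np.array(base_origins, float)
    out[:, 1] -= config.papillary_amplitude * w
    return out


# ------------------------------------------------------------- case runner


def _build_system(config: ScenarioConfig):
    tb = replace(config.testbed, mvr_offset=config.mvr_offset)
    mesh = build_2d_testbed(tb)
    grid = StaggeredGrid.make(tb.domain, tb.n_cells)
    props = FluidProperties()
    t_init = config.init_duration
    lv = _RampedDrive(PressureWaveform(config.lv_points, config.cycle),
                      config.ambient_mmhg, t_init)
    pv = _RampedDrive(PressureWaveform(config.pv_points, config.cycle),
                      config.ambient_mmhg, t_init)
    # top face: PV drive (also vents the ambient region, which therefore
    # tracks PV pressure); bottom face: LV drive inside the baffled
    # plenum; side faces: rigid walls
    bc = (BoundarySpec(2)
          .set_pressure("y+", pv)
          .set_pressure("y-", lv))

    profile = _GatedProfile(
        ActivationProfile(peak=config.activation_peak,
                          onset=config.activation_onset,
                          duration=config.activation_duration,
                          cycle=config.cycle),
        t_init,
    )
    active = ActiveParams(gamma=config.gamma, profile=profile) \
        if config.activation_peak > 0 else None

    tether_nodes = mesh.node_sets["tether"]
    ref = mesh.nodes[tether_nodes].copy()
    tethers = [TetherSet(nodes=tether_nodes, target=lambda t: ref,
                         kappa=config.tether_kappa)]

    base_origins = mesh.meta["chordae_origins"]
    tips = mesh.node_sets["chordae_tips"]
    # chordae rest lengths belong to the normal anatomy: slack through the
    # opening/closing swing, taut when a tip everts past the annulus plane
    pmv_l, pmv_r = mesh.meta["mv_segment"]
    ann_centre = 0.5 * (pmv_l + pmv_r)
    rest = 0.95 * np.linalg.norm(mesh.meta["chordae_origins_normal"]
                                 - ann_centre, axis=1)

    def origins(t):
        return papillary_motion(max(t - t_init, 0.0), config, base_origins)

    springs = [SpringSet(nodes=tips, origins=origins, rest_length=rest,
                         k=config.chordae_k, k2=config.chordae_k2)]

    def ramp(t):
        return min(max(t, 0.0) / t_init, 1.0) if t_init > 0 else 1.0

    system = FSISystem(
        grid=grid, props=props, bc=bc, mesh=mesh,
        passive={"chamber": config.passive,
                 "leaflet": config.leaflet_passive},
        active=active, active_regions=("chamber",),
        kernel=config.kernel, tethers=tethers, springs=springs,
        limited=True, ramp=ramp,
    )
    return system, mesh, tb


def run_case(config: ScenarioConfig, out_dir=None, progress=False,
             log_every: float = 0.0) -> MetricsBundle:
    """Run one scenario end-to-end and return its MetricsBundle.

    The bundle's series frame holds the sampled time traces (chamber area,
    transmitral and PV fluxes, mean chamber pressure, KE, D, strain
    summaries); scalars hold the per-cycle volume accounting of the
    report cycle and the periodicity diagnostic.
    """
    config.validate()
    system, mesh, tb = _build_system(config)
    grid = system.grid
    t_init = config.init_duration
    T = config.cycle
    t_end = t_init + config.n_cycles * T

    mid_loop = mesh.meta["mid_loop"]
    chamber_elems = mesh.elem_sets["chamber"]
    pmv_l, pmv_r = mesh.meta["mv_segment"]
    mv_seg = segment_patch(pmv_l - [0, 0.06], pmv_r - [0, 0.06], 12)
    mv_pts, mv_w, mv_n = mv_seg
    if mv_n[1] > 0:
        mv_n = -mv_n                       # positive = LA -> LV (downward)
    pv_patches = []
    centre = np.asarray(tb.centre)
    for p0, p1 in mesh.meta["pv_segments"]:
        pts, w, n = segment_patch(p0, p1, 10)
        if n @ (centre - 0.5 * (p0 + p1)) < 0:
            n = -n                         # positive = into the LA
        pv_patches.append((pts, w, n))

    rows = []
    snaps = [] if config.store_velocity else None
    next_sample = 0.0
    next_log = 0.0

    while system.time < t_end - 1e-12:
        umax = grid.max_speed()
        dt = config.dt_max if umax < 1e-9 else min(
            config.dt_max, config.cfl * grid.h / umax)
        dt = min(dt, t_end - system.time)
        system.step(dt, scheme=config.scheme)

        if system.time + 1e-12 >= next_sample:
            next_sample += config.sample_interval
            chi = system.chi
            poly = chi[mid_loop]
            area = polygon_area(poly)
            mask = chamber_mask(grid, poly)
            state = kinematics(mesh, chi)
            _, fs_mean = fibre_strain(state, mesh, chamber_elems)
            _, e1_mean = principal_strain(state, mesh, chamber_elems)
            mv_mean, mv_flux = orifice_trace(grid, mv_pts, mv_w, mv_n,
                                             config.kernel)
            pv_flux = 0.0
            for pts, w, n in pv_patches:
                pv_flux += orifice_trace(grid, pts, w, n, config.kernel)[1]
            rows.append({
                "t": system.time,
                "t_cycle": system.time - t_init,
                "chamber_area": area,
                "p_mean_mmhg": units.to_mmhg(float(grid.p[mask].mean()))
                if mask.any() else np.nan,
                "ke": kinetic_energy(grid, mask) if mask.any() else np.nan,
                "dissipation": dissipation_rate(grid, mask, system.props.mu)
                if mask.any() else np.nan,
                "mv_flux": mv_flux,
                "mv_velocity": mv_mean,
                "pv_flux": pv_flux,
                "fibre_strain_mean": fs_mean,
                "eps1_mean": e1_mean,
                "max_u": umax,
            })
            if snaps is not None:
                snaps.append((system.time, [u.copy() for u in grid.u]))
        if progress and system.time >= next_log:
            next_log += max(log_every, 0.05)
            print(system.log_line(), flush=True)

    series = pd.DataFrame(rows)
    scalars = {"case": config.case}
    rc = config.report_cycle
    w0, w1 = t_init + (rc - 1) * T, t_init + rc * T
    rep = series[(series.t >= w0 - 1e-9) & (series.t <= w1 + 1e-9)]
    if len(rep) > 3:
        acct = volume_accounting(
            rep.t.to_numpy() - t_init, rep.chamber_area.to_numpy(),
            rep.mv_flux.to_numpy(),
            sys_start=PHASES["sys"][0], sys_end=PHASES["sys"][1], cycle=T)
        scalars.update(acct)
        tau = np.mod(rep.t_cycle.to_numpy(), T)
        in_sys = (tau >= PHASES["sys"][0]) & (tau < PHASES["sys"][1])
        if in_sys.any():
            scalars["p_sys_peak_mmhg"] = float(
                rep.p_mean_mmhg.to_numpy()[in_sys].max())
        scalars["fibre_strain_cycle_mean"] = float(rep.fibre_strain_mean.mean())
        scalars["fibre_strain_peak"] = float(rep.fibre_strain_mean.max())
        # deformation level over the cycle: mean magnitude and excursion
        # of the wall-averaged fibre strain trace
        scalars["fibre_strain_mag_mean"] = float(
            rep.fibre_strain_mean.abs().mean())
        scalars["fibre_strain_amplitude"] = float(
            rep.fibre_strain_mean.max() - rep.fibre_strain_mean.min())
        scalars["eps1_peak"] = float(rep.eps1_mean.max())
    # periodicity: relative L2 difference of the area traces, last 2 cycles
    if config.n_cycles >= 2:
        tgrid = np.linspace(0, T, 80, endpoint=False)
        v = []
        for k in (config.n_cycles - 1, config.n_cycles):
            wlo = t_init + (k - 1) * T
            seg = series[(series.t >= wlo - 1e-9) & (series.t <= wlo + T + 1e-9)]
            v.append(np.interp(tgrid, seg.t.to_numpy() - wlo,
                               seg.chamber_area.to_numpy()))
        num = np.linalg.norm(v[1] - v[0])
        den = np.linalg.norm(v[1])
        scalars["periodicity"] = float(num / den)

    bundle = MetricsBundle(series=series, scalars=scalars,
                           meta={"config": config, "snapshots": snaps,
                                 "mesh": mesh, "final_chi": system.chi})
    if out_dir is not None:
        from .io import write_run_outputs
        write_run_outputs(bundle, config, out_dir)
    return bundle
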