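"""Ventilator waveform generation for a single-compartment lung.

The lung is a linear resistance--compliance (RC) element.  Volume-control
(VC) breaths deliver a set tidal volume at constant inspiratory flow;
pressure-control (PC) breaths apply a set inspiratory pressure above PEEP
and let volume follow first-order RC charging.  Expiration is passive in
both modes: volume above the end-expiratory lung volume (EELV, maintained
by PEEP) decays exponentially with time constant ``tau = R * C``.

Volumes are in ml, pressures in cmH2O, flows in ml/s, times in s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ResolutionError

__all__ = [
    "Mode",
    "Phase",
    "VentilatorSettings",
    "RespiratoryMechanics",
    "VolumeTrace",
    "breath_timing",
    "vc_breath",
    "pc_breath",
    "pc_pressure_for_vt",
    "simulate_volume_trace",
]


class Mode(str, Enum):
    VC = "VC"
    PC = "PC"


class Phase(IntEnum):
    INSP = 0
    EXP = 1
    HOLD = 2


def breath_timing(rr: float, ie_ratio: float) -> tuple[float, float]:
    """Split the breath period into inspiratory and expiratory times.

    Parameters
    ----------
    rr : breaths per minute.
    ie_ratio : inspiratory:expiratory time ratio as a single number
        (0.25 means 1:4, 4.0 means 4:1).  Inverting an I:E ratio
        (``1/ie_ratio``) swaps Ti and Te exactly.

    Returns
    -------
    (Ti, Te) in seconds, with ``Ti + Te = 60 / rr``.
    """
    if rr <= 0 or ie_ratio <= 0:
        raise InvalidParameterError(
            f"rr and ie_ratio must be positive (got rr={rr}, ie_ratio={ie_ratio})"
        )
    period = 60.0 / rr
    ti = ie_ratio / (1.0 + ie_ratio) * period
    return ti, period - ti


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator configuration for one condition.

    Exactly one volume/pressure target is required by the active mode:
    ``vt`` (ml) for VC, ``p_insp`` (cmH2O above PEEP) for PC.
    """

    mode: Mode
    rr: float
    ie_ratio: float
    vt: float | None = None
    p_insp: float | None = None
    peep: float = 5.0
    fio2: float = 0.21
    rise_time: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.rr <= 0 or self.ie_ratio <= 0:
            raise InvalidParameterError("rr and ie_ratio must be positive")
        if self.peep < 0:
            raise InvalidParameterError("peep must be >= 0")
        if not 0 < self.fio2 <= 1:
            raise InvalidParameterError("fio2 must be in (0, 1]")
        if self.rise_time < 0:
            raise InvalidParameterError("rise_time must be >= 0")
        if self.mode is Mode.VC:
            if self.vt is None or self.vt <= 0:
                raise InvalidParameterError("VC mode requires vt > 0")
        else:
            if self.p_insp is None or self.p_insp <= 0:
                raise InvalidParameterError("PC mode requires p_insp > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.rr

    @property
    def ti(self) -> float:
        return breath_timing(self.rr, self.ie_ratio)[0]

    @property
    def te(self) -> float:
        return breath_timing(self.rr, self.ie_ratio)[1]

    def inverted(self) -> "VentilatorSettings":
        """Same condition with inspiration and expiration times swapped."""
        return VentilatorSettings(
            mode=self.mode, rr=self.rr, ie_ratio=1.0 / self.ie_ratio,
            vt=self.vt, p_insp=self.p_insp, peep=self.peep,
            fio2=self.fio2, rise_time=self.rise_time,
        )


@dataclass(frozen=True)
class RespiratoryMechanics:
    """Linear lung mechanics.  Defaults (tau = 0.54 s) keep peak airway
    pressure under the ~13.6 cmH2O observed with a 10 ml/kg breath at
    5 cmH2O PEEP in a ~29 kg pig."""

    compliance: float = 45.0    # ml / cmH2O
    resistance: float = 0.012   # cmH2O s / ml

    def __post_init__(self) -> None:
        if self.compliance <= 0 or self.resistance <= 0:
            raise InvalidParameterError("compliance and resistance must be > 0")

    @property
    def tau(self) -> float:
        """Expiratory time constant R*C in seconds."""
        return self.resistance * self.compliance


@dataclass
class VolumeTrace:
    """Uniformly sampled airway waveforms for one or more breaths.

    ``volume_above_eelv`` is gas volume above EELV (>= 0); ``flow`` is
    inspiratory-positive; ``phase`` holds :class:`Phase` codes per sample.
    """

    t: np.ndarray
    volume_above_eelv: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    phase: np.ndarray
    converged: bool = True
    end_expiratory_volumes: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "volume_ml": self.volume_above_eelv,
                "flow_ml_s": self.flow,
                "paw_cmh2o": self.paw,
                "phase": [Phase(p).name for p in self.phase],
            }
        )


def _check_resolution(dt: float, ti: float, te: float, tau: float) -> None:
    if dt <= 0:
        raise ResolutionError("dt must be positive")
    if dt >= ti or dt >= te or dt >= tau / 5.0:
        raise ResolutionError(
            f"dt={dt} too coarse for Ti={ti:.3g}, Te={te:.3g}, tau={tau:.3g}"
        )


def vc_breath(
    settings: VentilatorSettings,
    mech: RespiratoryMechanics,
    dt: float = 0.01,
    v0: float = 0.0,
) -> VolumeTrace:
    """One volume-control breath starting from residual volume ``v0``.

    Constant inspiratory flow ``vt/Ti`` for Ti, then passive exponential
    expiration toward EELV.  Airway pressure is
    ``peep + V/C + R*flow`` during inspiration and ``peep + V/C`` during
    expiration (the resistive term vanishes at the airway opening once the
    ventilator valve opens to PEEP).
    """
    if settings.mode is not Mode.VC:
        raise InvalidParameterError("vc_breath requires VC mode settings")
    ti, te = breath_timing(settings.rr, settings.ie_ratio)
    _check_resolution(dt, ti, te, mech.tau)
    n = int(round(settings.period / dt))
    ni = int(round(ti / dt))
    t = np.arange(n) * dt
    vol = np.empty(n)
    flow = np.empty(n)
    phase = np.empty(n, dtype=np.int8)

    insp_flow = settings.vt / ti
    vol[:ni] = v0 + insp_flow * t[:ni]
    flow[:ni] = insp_flow
    phase[:ni] = Phase.INSP

    v_ei = v0 + settings.vt
    texp = t[ni:] - ti
    vol[ni:] = v_ei * np.exp(-texp / mech.tau)
    flow[ni:] = -vol[ni:] / mech.tau
    phase[ni:] = Phase.EXP

    paw = settings.peep + vol / mech.compliance
    paw[:ni] += mech.resistance * flow[:ni]
    return VolumeTrace(t, vol, flow, paw, phase)


def pc_breath(
    settings: VentilatorSettings,
    mech: RespiratoryMechanics,
    dt: float = 0.01,
    v0: float = 0.0,
) -> VolumeTrace:
    """One pressure-control breath starting from residual volume ``v0``.

    Airway pressure ramps (over ``rise_time``) to ``peep + p_insp`` and
    volume follows exact first-order RC charging, stepped with the exact
    exponential propagator for piecewise-constant driving pressure.
    """
    if settings.mode is not Mode.PC:
        raise InvalidParameterError("pc_breath requires PC mode settings")
    ti, te = breath_timing(settings.rr, settings.ie_ratio)
    _check_resolution(dt, ti, te, mech.tau)
    n = int(round(settings.period / dt))
    ni = int(round(ti / dt))
    t = np.arange(n) * dt
    vol = np.empty(n)
    flow = np.empty(n)
    phase = np.empty(n, dtype=np.int8)
    tau, c = mech.tau, mech.compliance

    # inspiratory pressure target above PEEP at sample times
    if settings.rise_time > 0:
        ptgt = settings.p_insp * np.minimum(1.0, t[:ni] / settings.rise_time)
    else:
        ptgt = np.full(ni, settings.p_insp)
    decay = math.exp(-dt / tau)
    v = v0
    for k in range(ni):
        vol[k] = v
        flow[k] = (ptgt[k] - v / c) / mech.resistance
        # driving pressure held at its mid-step value across [t_k, t_k+dt)
        tm = t[k] + 0.5 * dt
        pbar = settings.p_insp * min(1.0, tm / settings.rise_time) \
            if settings.rise_time > 0 else settings.p_insp
        veq = c * pbar
        v = veq + (v - veq) * decay

    v_ei = v
    texp = t[ni:] - ti
    vol[ni:] = v_ei * np.exp(-texp / tau)
    flow[ni:] = -vol[ni:] / tau
    phase[:ni] = Phase.INSP
    phase[ni:] = Phase.EXP

    paw = settings.peep + vol / c
    paw[:ni] = settings.peep + ptgt
    return VolumeTrace(t, vol, flow, paw, phase)


def _pc_delivered(
    p_insp: float, mech: RespiratoryMechanics, ti: float, rise_time: float
) -> float:
    """Volume delivered at end-inspiration from V=0 under pressure p_insp."""
    if rise_time <= 0:
        return mech.compliance * p_insp * (1.0 - math.exp(-ti / mech.tau))
    # integrate the ramp analytically: dV/dt = (p(t) - V/C)/R
    tau, c = mech.tau, mech.compliance
    tr = min(rise_time, ti)
    slope = p_insp / rise_time  # cmH2O/s
    # during ramp: V(t) = C*slope*(t - tau*(1 - exp(-t/tau)))
    v_ramp = c * slope * (tr - tau * (1.0 - math.exp(-tr / tau)))
    if ti <= rise_time:
        return v_ramp
    rest = ti - rise_time
    return c * p_insp + (v_ramp - c * p_insp) * math.exp(-rest / tau)


def pc_pressure_for_vt(
    vt: float,
    mech: RespiratoryMechanics,
    ti: float,
    rise_time: float = 0.0,
    te: float | None = None,
) -> float:
    """Inspiratory pressure (above PEEP) that delivers ``vt`` in time Ti.

    With ``te=None``, the single-breath closed form
    ``vt / (C * (1 - exp(-Ti/tau)))`` (breath starting at EELV).  When the
    expiratory time ``te`` is given, the pressure is solved for the
    periodic steady state instead — at inverse I:E ratios expiration is
    incomplete and a single-breath pressure would under-deliver the tidal
    volume breath after breath.  Either way the delivered volume matches
    ``vt`` within 0.1% (the RC system is linear in p_insp, so one scaling
    refinement is exact up to integration error).
    """
    if vt <= 0:
        raise InvalidParameterError("vt must be > 0")
    if ti <= 0:
        raise InvalidParameterError("Ti must be > 0")
    a = math.exp(-ti / mech.tau)
    if te is None:
        p = vt / (mech.compliance * (1.0 - a))
        if rise_time > 0:
            p *= vt / _pc_delivered(p, mech, ti, rise_time)
        return p
    if te <= 0:
        raise InvalidParameterError("Te must be > 0")
    b = math.exp(-te / mech.tau)
    p = vt * (1.0 - a * b) / (mech.compliance * (1.0 - a) * (1.0 - b))
    if rise_time > 0:
        rr = 60.0 / (ti + te)
        settings = VentilatorSettings(
            mode=Mode.PC, rr=rr, ie_ratio=ti / te, p_insp=p,
            rise_time=rise_time,
        )
        tr = simulate_volume_trace(settings, mech, n_breaths=12)
        dt = tr.dt
        n_per = int(round((ti + te) / dt))
        last = tr.volume_above_eelv[-n_per:]
        p *= vt / float(last.max() - last.min())
    return p


def simulate_volume_trace(
    settings: VentilatorSettings,
    mech: RespiratoryMechanics,
    n_breaths: int,
    dt: float = 0.01,
    hold_s: float = 0.0,
    hold_phase: str = "expiration",
) -> VolumeTrace:
    """Concatenate ``n_breaths`` breaths, carrying residual volume across
    breaths until a periodic steady state is reached.

    ``hold_s`` > 0 appends a breath-hold (constant volume, zero flow) after
    the last breath, either at end-expiration or — after one extra
    inspiration — at end-inspiration (``hold_phase``).
    The trace is flagged non-converged (with a warning) if the end-expiratory
    volume still changes by more than 0.5% of the tidal volume between the
    last two breaths.
    """
    if n_breaths < 1:
        raise InvalidParameterError("n_breaths must be >= 1")
    breath_fn = vc_breath if settings.mode is Mode.VC else pc_breath
    pieces: list[VolumeTrace] = []
    v0 = 0.0
    end_exp = []
    t_offset = 0.0
    for _ in range(n_breaths):
        br = breath_fn(settings, mech, dt=dt, v0=v0)
        br.t = br.t + t_offset
        t_offset = br.t[-1] + dt
        v0 = br.volume_above_eelv[-1] * math.exp(-dt / mech.tau)
        end_exp.append(v0)
        pieces.append(br)

    vt_ref = settings.vt if settings.vt is not None \
        else mech.compliance * settings.p_insp
    converged = True
    if n_breaths >= 2 and abs(end_exp[-1] - end_exp[-2]) > 0.005 * vt_ref:
        converged = False
        warnings.warn(
            "periodic steady state not reached within "
            f"{n_breaths} breaths", RuntimeWarning, stacklevel=2,
        )

    if hold_s > 0:
        if hold_phase == "inspiration":
            br = breath_fn(settings, mech, dt=dt, v0=v0)
            ni = int(np.sum(br.phase == Phase.INSP))
            br.t = br.t[:ni] + t_offset
            br.volume_above_eelv = br.volume_above_eelv[:ni]
            br.flow = br.flow[:ni]
            br.paw = br.paw[:ni]
            br.phase = br.phase[:ni]
            t_offset = br.t[-1] + dt
            v_hold = br.volume_above_eelv[-1] + br.flow[-1] * dt
            pieces.append(br)
        elif hold_phase == "expiration":
            v_hold = v0
        else:
            raise InvalidParameterError(
                "hold_phase must be 'expiration' or 'inspiration'"
            )
        nh = int(round(hold_s / dt))
        th = np.arange(nh) * dt + t_offset
        hold = VolumeTrace(
            t=th,
            volume_above_eelv=np.full(nh, v_hold),
            flow=np.zeros(nh),
            paw=np.full(nh, settings.peep + v_hold / mech.compliance),
            phase=np.full(nh, Phase.HOLD, dtype=np.int8),
        )
        pieces.append(hold)

    return VolumeTrace(
        t=np.concatenate([p.t for p in pieces]),
        volume_above_eelv=np.concatenate([p.volume_above_eelv for p in pieces]),
        flow=np.concatenate([p.flow for p in pieces]),
        paw=np.concatenate([p.paw for p in pieces]),
        phase=np.concatenate([p.phase for p in pieces]),
        converged=converged,
        end_expiratory_volumes=np.asarray(end_exp),
    )
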