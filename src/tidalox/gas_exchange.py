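"""Single-alveolar-compartment oxygen mass balance.

The lung is one well-mixed alveolar gas compartment of volume
``V_A(t) = V_A,eelv + volume_above_eelv(t)`` with a constant oxygen uptake
``VO2`` (ml/s BTPS) by the pulmonary circulation.  The O2 partial volume
``n = F_A * V_A`` obeys

* inspiration:   dn/dt = F_insp(t) * Vdot(t) - VO2
* expiration:    dn/dt = -F_A * |Vdot(t)| - VO2
* breath hold:   dn/dt = -VO2            (V_A frozen)

where the first ``V_D`` ml of each inspiration re-enter at the
end-expiratory alveolar composition (series dead space) and the remainder
at FIO2.  Alveolar PO2 is ``F_A * (P_B - P_H2O)``.  During expiration or a
hold the dilution term cancels and alveolar PO2 falls at exactly
``VO2 * (P_B - P_H2O) / V_A`` — the inverse-lung-volume decline that the
breath-hold experiments probe.

The arterial channel is the alveolar signal after a pure transport delay,
first-order smoothing (sensor/circulatory dispersion), and — when a shunt
fraction is set — venous admixture mixed in O2-content units through an
empirical haemoglobin dissociation curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    CalibrationError,
    InvalidParameterError,
    ModelValidityError,
)
from .ventilation import (
    Mode,
    Phase,
    RespiratoryMechanics,
    VentilatorSettings,
    VolumeTrace,
    simulate_volume_trace,
)

__all__ = [
    "GasExchangeParams",
    "AlveolarState",
    "PO2Trace",
    "alveolar_volume_at_eelv",
    "predict_breath_hold_decline",
    "simulate_breath_hold",
    "simulate_tidal",
    "arterial_transmission",
    "o2_saturation",
    "o2_content",
    "calibrate_fio2",
    "vo2_stpd_to_btps",
    "CalibrationResult",
]

#: End-expiratory breath-hold PaO2 decline (mmHg/s) used to calibrate the
#: default oxygen uptake when none is given.
DEFAULT_EELV_DECLINE = 6.9


def vo2_stpd_to_btps(vo2_stpd: float, pb: float = 760.0, ph2o: float = 47.0) -> float:
    """Convert an oxygen uptake from STPD to BTPS ml/s."""
    return vo2_stpd * (760.0 / (pb - ph2o)) * (310.0 / 273.0)


@dataclass
class GasExchangeParams:
    """Physiology of the modelled animal.

    ``vo2`` (ml/s BTPS) defaults to the value that makes the closed-form
    end-expiratory breath-hold decline equal 6.9 mmHg/s — the calibration
    the model uses in place of a directly measured uptake.
    """

    mass: float = 29.0            # kg body weight
    eelv_per_kg: float = 22.3     # ml/kg, EELV at 5 cmH2O PEEP
    vd_per_kg: float = 3.0        # ml/kg series dead space
    vo2: float | None = None      # ml/s BTPS
    pb: float = 760.0             # mmHg barometric
    ph2o: float = 47.0            # mmHg water vapour at 37 C
    fio2: float = 0.25            # default inspired O2 fraction
    shunt: float = 0.0            # fraction of cardiac output
    hb: float = 10.0              # g/dl, used only when shunt > 0
    pv_o2: float = 40.0           # mmHg mixed venous PO2 for shunt mixing
    transit_delay: float = 2.0    # s, lung-to-sensor transport delay
    sensor_tau: float = 0.8       # s, first-order arterial smoothing

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidParameterError("mass must be > 0")
        if not self.eelv_per_kg > self.vd_per_kg >= 0:
            raise InvalidParameterError("require eelv_per_kg > vd_per_kg >= 0")
        if self.pb <= self.ph2o or self.ph2o <= 0:
            raise InvalidParameterError("require pb > ph2o > 0")
        if not 0 < self.fio2 <= 1:
            raise InvalidParameterError("fio2 must be in (0, 1]")
        if not 0 <= self.shunt < 1:
            raise InvalidParameterError("shunt must be in [0, 1)")
        if self.transit_delay < 0 or self.sensor_tau < 0:
            raise InvalidParameterError("delay/tau must be >= 0")
        if self.vo2 is None:
            self.vo2 = (
                DEFAULT_EELV_DECLINE
                * alveolar_volume_at_eelv(self)
                / (self.pb - self.ph2o)
            )
        if self.vo2 <= 0:
            raise InvalidParameterError("vo2 must be > 0")

    @property
    def vd(self) -> float:
        """Series dead space in ml."""
        return self.vd_per_kg * self.mass


@dataclass(frozen=True)
class AlveolarState:
    """Instantaneous alveolar gas state."""

    va: float          # ml BTPS
    fao2: float        # fraction
    pb: float = 760.0
    ph2o: float = 47.0

    def __post_init__(self) -> None:
        if self.va <= 0:
            raise InvalidParameterError("va must be > 0")
        if not 0 < self.fao2 < 1:
            raise InvalidParameterError("fao2 must be in (0, 1)")

    @property
    def pao2_alv(self) -> float:
        return self.fao2 * (self.pb - self.ph2o)


@dataclass
class PO2Trace:
    """Uniformly sampled alveolar and arterial PO2 with airway channels."""

    t: np.ndarray
    pao2_alv: np.ndarray
    pao2_art: np.ndarray
    volume_ml: np.ndarray          # absolute alveolar gas volume
    paw_cmh2o: np.ndarray
    phase: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def last(self, seconds: float) -> "PO2Trace":
        """Final ``seconds`` of the trace (steady-state analysis window)."""
        i0 = np.searchsorted(self.t, self.t[-1] - seconds + 0.5 * self.dt)
        return PO2Trace(
            t=self.t[i0:],
            pao2_alv=self.pao2_alv[i0:],
            pao2_art=self.pao2_art[i0:],
            volume_ml=self.volume_ml[i0:],
            paw_cmh2o=self.paw_cmh2o[i0:],
            phase=None if self.phase is None else self.phase[i0:],
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "pao2_alv_mmhg": self.pao2_alv,
                "pao2_art_mmhg": self.pao2_art,
                "volume_ml": self.volume_ml,
                "paw_cmh2o": self.paw_cmh2o,
            }
        )


def alveolar_volume_at_eelv(params: GasExchangeParams) -> float:
    """End-expiratory alveolar gas volume: EELV minus series dead space."""
    return (params.eelv_per_kg - params.vd_per_kg) * params.mass


def predict_breath_hold_decline(params: GasExchangeParams, va: float) -> float:
    """Closed-form alveolar PO2 decline rate (mmHg/s, magnitude) during a
    breath hold at fixed alveolar volume ``va``: VO2 * (PB - PH2O) / VA."""
    if va <= 0:
        raise InvalidParameterError("va must be > 0")
    return params.vo2 * (params.pb - params.ph2o) / va


def o2_saturation(po2):
    """Haemoglobin O2 saturation from PO2 (mmHg).

    Severinghaus' empirical fit S = 1 / (1 + 23400 / (PO2^3 + 150*PO2)),
    monotone in PO2 and -> 1 as PO2 -> infinity.
    """
    p = np.asarray(po2, dtype=float)
    s = 1.0 / (1.0 + 23400.0 / (p ** 3 + 150.0 * p))
    return float(s) if np.isscalar(po2) else s


def o2_content(po2, hb: float = 10.0):
    """Blood O2 content (ml O2 / dl): 1.34*Hb*S(PO2) + 0.003*PO2."""
    return 1.34 * hb * o2_saturation(po2) + 0.003 * np.asarray(po2, dtype=float)


def _po2_from_content(content: np.ndarray, hb: float) -> np.ndarray:
    grid_p = np.linspace(0.5, 800.0, 4000)
    grid_c = o2_content(grid_p, hb)
    return np.interp(content, grid_c, grid_p)


def arterial_transmission(trace: PO2Trace, params: GasExchangeParams) -> PO2Trace:
    """Fill the arterial channel from the alveolar one.

    Order of operations: constant-shunt venous admixture (in O2-content
    units, mixed venous PO2 fixed at ``params.pv_o2``), then a pure
    transport delay of ``transit_delay`` s, then first-order smoothing with
    time constant ``sensor_tau``.  With zero shunt, delay and tau the
    arterial channel is identical to the alveolar one.
    """
    dt = trace.dt
    x = np.asarray(trace.pao2_alv, dtype=float)
    if params.shunt > 0:
        cc = o2_content(x, params.hb)
        cv = o2_content(params.pv_o2, params.hb)
        ca = (1.0 - params.shunt) * cc + params.shunt * cv
        x = _po2_from_content(ca, params.hb)
    k = int(round(params.transit_delay / dt))
    if k >= len(x):
        raise InvalidParameterError("transit_delay longer than trace")
    if k > 0:
        x = np.concatenate([np.full(k, x[0]), x[:-k]])
    if params.sensor_tau > 0:
        a = math.exp(-dt / params.sensor_tau)
        x, _ = signal.lfilter([1.0 - a], [1.0, -a], x, zi=[a * x[0]])
    out = replace(trace)
    out.pao2_art = x
    return out


def simulate_breath_hold(
    params: GasExchangeParams,
    va: float,
    duration: float = 20.0,
    dt: float = 0.1,
    initial_pao2: float | None = None,
) -> PO2Trace:
    """Breath hold at fixed alveolar volume ``va`` (airway-open hold).

    Alveolar PO2 declines linearly at the closed-form rate; the arterial
    channel is the transmitted alveolar signal.  The trace is truncated
    (with a warning) if PO2 would reach the physical floor of zero O2
    fraction.
    """
    rate = predict_breath_hold_decline(params, va)
    p0 = (
        initial_pao2
        if initial_pao2 is not None
        else 0.9 * params.fio2 * (params.pb - params.ph2o)
    )
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    pao2 = p0 - rate * t
    if pao2[-1] <= 0:
        n_valid = int(np.searchsorted(-pao2, 0.0))
        warnings.warn(
            "breath hold truncated: alveolar PO2 reached the zero-fraction "
            "floor where the constant-uptake model is invalid",
            RuntimeWarning, stacklevel=2,
        )
        t, pao2 = t[:n_valid], pao2[:n_valid]
    trace = PO2Trace(
        t=t,
        pao2_alv=pao2,
        pao2_art=np.zeros_like(pao2),
        volume_ml=np.full_like(pao2, va),
        paw_cmh2o=np.zeros_like(pao2),
        meta={"va": va, "decline_rate": rate},
    )
    return arterial_transmission(trace, params)


def _integrate_o2(
    vol: VolumeTrace,
    params: GasExchangeParams,
    fio2: float,
    fao2_init: float | None = None,
) -> PO2Trace:
    """Euler integration of the O2 mass balance over a volume waveform.

    Uses exact volume increments (``dV = V[k+1]-V[k]``) so inspired and
    expired O2 volumes telescope consistently with the waveform, giving a
    discrete per-breath O2 budget that balances identically at periodic
    steady state.
    """
    va0 = alveolar_volume_at_eelv(params)
    vd = params.vd
    vo2 = params.vo2
    dt = vol.dt
    v = va0 + np.asarray(vol.volume_above_eelv, dtype=float)
    phase = np.asarray(vol.phase)
    nsteps = len(v)
    fa = np.empty(nsteps)
    n = (0.9 * fio2 if fao2_init is None else fao2_init) * v[0]

    # per-breath O2 budget, keyed by inspiration onsets
    budgets: list[dict] = []
    ins_o2 = exp_o2 = 0.0
    f_reinsp = n / v[0]
    cum_insp = 0.0
    prev = int(Phase.EXP)
    INSP, EXP = int(Phase.INSP), int(Phase.EXP)
    for k in range(nsteps - 1):
        fa_k = n / v[k]
        if not 0.0 < fa_k < 1.0:
            raise ModelValidityError(
                f"alveolar O2 fraction {fa_k:.4f} left (0, 1) at t={vol.t[k]:.2f}"
            )
        fa[k] = fa_k
        ph = int(phase[k])
        dv = v[k + 1] - v[k]
        if ph == INSP:
            if prev != INSP:
                if budgets or ins_o2 or exp_o2:
                    budgets.append({"inspired_ml": ins_o2, "expired_ml": exp_o2})
                ins_o2 = exp_o2 = 0.0
                cum_insp = 0.0
                f_reinsp = fa_k
            dvi = max(dv, 0.0)
            fin = f_reinsp if cum_insp < vd else fio2
            n += fin * dvi - vo2 * dt
            ins_o2 += fin * dvi
            cum_insp += dvi
        elif ph == EXP:
            # gas leaves at the start-of-step alveolar composition, which
            # makes the dilution term cancel exactly in P_A:
            # P[k+1] - P[k] = -(pb - ph2o) * vo2 * dt / V[k+1]
            dve = min(dv, 0.0)
            dn_out = (n / v[k]) * dve   # negative
            n += dn_out - vo2 * dt
            exp_o2 -= dn_out
        else:  # HOLD
            n += -vo2 * dt
        prev = ph
    fa[-1] = n / v[-1]
    budgets.append({"inspired_ml": ins_o2, "expired_ml": exp_o2})

    pao2_alv = fa * (params.pb - params.ph2o)
    trace = PO2Trace(
        t=np.asarray(vol.t),
        pao2_alv=pao2_alv,
        pao2_art=np.zeros(nsteps),
        volume_ml=v,
        paw_cmh2o=np.asarray(vol.paw),
        phase=phase,
        meta={
            "fio2": fio2,
            "o2_budget": pd.DataFrame(budgets),
            "converged": vol.converged,
        },
    )
    return arterial_transmission(trace, params)


def simulate_tidal(
    settings: VentilatorSettings,
    mech: RespiratoryMechanics,
    params: GasExchangeParams,
    duration: float,
    dt: float = 0.01,
    fio2: float | None = None,
    hold_s: float = 0.0,
    hold_phase: str = "expiration",
) -> PO2Trace:
    """Simulate tidal ventilation and return alveolar + arterial PO2.

    ``duration`` should span at least ~10 breath periods so a periodic
    steady state is reached before analysis; the transient is kept in the
    trace (slice with :meth:`PO2Trace.last`).  ``fio2`` overrides
    ``settings.fio2`` when given.  A trailing breath hold can be appended
    for hold protocols.
    """
    fio2 = settings.fio2 if fio2 is None else fio2
    if not 0 < fio2 <= 1:
        raise InvalidParameterError("fio2 must be in (0, 1]")
    n_breaths = max(1, math.ceil(duration / settings.period))
    vol = simulate_volume_trace(
        settings, mech, n_breaths, dt=dt, hold_s=hold_s, hold_phase=hold_phase
    )
    return _integrate_o2(vol, params, fio2)


@dataclass
class CalibrationResult:
    fio2: float
    mean_pao2: float
    trace: PO2Trace


def calibrate_fio2(
    settings: VentilatorSettings,
    mech: RespiratoryMechanics,
    params: GasExchangeParams,
    target_mean: float = 130.0,
    tol: float = 1.0,
    window: float = 120.0,
    dt: float = 0.01,
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisect FIO2 in (0.21, 1.0] until the steady-state mean arterial PO2
    over a 2-min window is within ``tol`` mmHg of ``target_mean``."""
    if target_mean <= 60:
        raise CalibrationError("target mean PaO2 must be physiologic (> 60 mmHg)")
    transient = max(10.0 * settings.period, 60.0)
    duration = transient + window

    def mean_at(fio2: float) -> tuple[float, PO2Trace]:
        tr = simulate_tidal(settings, mech, params, duration, dt=dt, fio2=fio2)
        return float(np.mean(tr.last(window).pao2_art)), tr

    lo, hi = 0.21, 1.0
    m_lo, tr_lo = mean_at(lo)
    if abs(m_lo - target_mean) <= tol:
        return CalibrationResult(lo, m_lo, tr_lo)
    if m_lo > target_mean:
        raise CalibrationError(
            f"target {target_mean} mmHg below reach: FIO2=0.21 already gives "
            f"{m_lo:.1f} mmHg"
        )
    m_hi, tr_hi = mean_at(hi)
    if m_hi < target_mean - tol:
        raise CalibrationError(
            f"target {target_mean} mmHg unreachable: FIO2=1.0 gives {m_hi:.1f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m, tr = mean_at(mid)
        if abs(m - target_mean) <= tol:
            return CalibrationResult(mid, m, tr)
        if m < target_mean:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("FIO2 bisection did not converge")
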