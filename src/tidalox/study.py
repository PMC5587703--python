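"""End-to-end study runs mirroring the experimental protocol.

``run_tidal_study`` simulates the 16 ventilation conditions.  Following
the protocol, each RR block holds two sets of four conditions; the FIO2 is
calibrated once on the set's anchor (volume control at I:E 1:2 or 1:4,
mean PaO2 ~130 mmHg) and then held fixed while mode and I:E change.
``run_breath_hold_study`` simulates the 18-hold sequence and applies the
steepest-5-s-decline statistic to the noisy traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .gas_exchange import (
    GasExchangeParams,
    calibrate_fio2,
    simulate_tidal,
)
from .synthetic import (
    ExperimentDesign,
    NoiseModel,
    TidalCondition,
    make_breath_hold_dataset,
)
from .trace_statistics import SampledTrace, oscillation_stats, steepest_decline
from .ventilation import (
    Mode,
    RespiratoryMechanics,
    VentilatorSettings,
    breath_timing,
    pc_pressure_for_vt,
)

__all__ = ["RunConfig", "run_tidal_study", "run_breath_hold_study"]


@dataclass
class RunConfig:
    """Configuration of a full simulated study."""

    params: GasExchangeParams = field(default_factory=GasExchangeParams)
    mechanics: RespiratoryMechanics = field(default_factory=RespiratoryMechanics)
    peep: float = 5.0
    target_mean_pao2: float = 130.0
    conditions: list[TidalCondition] = field(
        default_factory=ExperimentDesign.tidal_conditions
    )
    noise_sd: float = 1.0
    seed: int = 0
    dt: float = 0.01
    analysis_window: float = 120.0


def _settings_for(
    cond: TidalCondition, config: RunConfig, fio2: float
) -> VentilatorSettings:
    vt = cond.vt_per_kg * config.params.mass
    if cond.mode is Mode.VC:
        return VentilatorSettings(
            mode=Mode.VC, rr=cond.rr, ie_ratio=cond.ie_ratio, vt=vt,
            peep=config.peep, fio2=fio2,
        )
    ti, te = breath_timing(cond.rr, cond.ie_ratio)
    p = pc_pressure_for_vt(vt, config.mechanics, ti, rise_time=0.1, te=te)
    return VentilatorSettings(
        mode=Mode.PC, rr=cond.rr, ie_ratio=cond.ie_ratio, p_insp=p,
        peep=config.peep, fio2=fio2, rise_time=0.1,
    )


def run_tidal_study(config: RunConfig) -> pd.DataFrame:
    """Simulate every condition; one summary row each.

    Columns: condition label, mode, rr, ie_ratio, vt_ml, fio2, mean_pao2,
    amplitude_mean, amplitude_max, mean_paw_cmh2o, status.  A calibration
    failure marks its set's rows failed and the run continues.
    """
    anchors = {0.5: (0.5, 2.0), 2.0: (0.5, 2.0), 0.25: (0.25, 4.0),
               4.0: (0.25, 4.0)}
    rows = []
    # calibrate once per (rr, set) on the VC anchor condition
    fio2_by_set: dict[tuple[float, float], float | None] = {}
    rrs = sorted({c.rr for c in config.conditions})
    for rr in rrs:
        vt_per_kg = next(c.vt_per_kg for c in config.conditions if c.rr == rr)
        for anchor_ie in (0.5, 0.25):
            anchor = TidalCondition(Mode.VC, rr, anchor_ie, vt_per_kg)
            try:
                cal = calibrate_fio2(
                    _settings_for(anchor, config, fio2=0.25),
                    config.mechanics, config.params,
                    target_mean=config.target_mean_pao2,
                    window=config.analysis_window, dt=config.dt,
                )
                fio2_by_set[(rr, anchor_ie)] = cal.fio2
            except CalibrationError:
                fio2_by_set[(rr, anchor_ie)] = None

    for cond in config.conditions:
        set_key = (cond.rr, anchors[cond.ie_ratio][0])
        fio2 = fio2_by_set.get(set_key)
        row = {
            "condition": cond.label(),
            "mode": cond.mode.value,
            "rr": cond.rr,
            "ie_ratio": cond.ie_ratio,
            "vt_ml": cond.vt_per_kg * config.params.mass,
        }
        if fio2 is None:
            row.update(fio2=np.nan, mean_pao2=np.nan, amplitude_mean=np.nan,
                       amplitude_max=np.nan, mean_paw_cmh2o=np.nan,
                       status="calibration_failed")
            rows.append(row)
            continue
        settings = _settings_for(cond, config, fio2)
        transient = max(10.0 * settings.period, 60.0)
        trace = simulate_tidal(
            settings, config.mechanics, config.params,
            duration=transient + config.analysis_window, dt=config.dt,
        )
        stats = oscillation_stats(
            SampledTrace.from_po2trace(trace), rr_hint=cond.rr,
            window=config.analysis_window,
        )
        row.update(
            fio2=fio2,
            mean_pao2=stats.mean_pao2,
            amplitude_mean=stats.amplitude_mean,
            amplitude_max=stats.amplitude_max,
            mean_paw_cmh2o=stats.mean_paw,
            status="ok",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_breath_hold_study(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the 18-hold sequence and measure each steepest decline.

    Returns (per-hold table, per-volume summary with mean +/- SD of the
    measured rates against the closed-form prediction).
    """
    records, truth = make_breath_hold_dataset(
        config.params,
        noise=NoiseModel(sd=config.noise_sd, seed=config.seed),
    )
    rows = []
    for i, rec in enumerate(records):
        res = steepest_decline(rec.trace)
        rows.append(
            {
                "hold": i + 1,
                "volume_label": rec.label,
                "va_ml": rec.va,
                "measured_rate_mmhg_s": res.rate,
                "predicted_rate_mmhg_s": rec.true_rate,
                "valid": res.valid,
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("volume_label", sort=False)
        .agg(
            n=("measured_rate_mmhg_s", "size"),
            measured_mean=("measured_rate_mmhg_s", "mean"),
            measured_sd=("measured_rate_mmhg_s", "std"),
            predicted=("predicted_rate_mmhg_s", "first"),
            va_ml=("va_ml", "first"),
        )
        .reset_index()
    )
    return table, summary
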