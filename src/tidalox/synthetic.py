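"""Synthetic data generators: noisy PaO2 traces, breath-hold datasets with
known ground truth, CT phantoms with prescribed aeration composition, and
the experimental-design fixtures (16 tidal conditions, 18-hold sequence).

Every generator is deterministic given its seed and returns ground truth
alongside the data, so pipeline estimates can be checked for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ct_aeration import (
    CLASS_NAMES,
    AerationBands,
    CTVolume,
    DEFAULT_BANDS,
    voxel_gas_tissue,
)
from .errors import InvalidParameterError
from .gas_exchange import (
    GasExchangeParams,
    PO2Trace,
    alveolar_volume_at_eelv,
    predict_breath_hold_decline,
    simulate_breath_hold,
)
from .trace_statistics import SampledTrace
from .ventilation import Mode

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "TidalCondition",
    "Vo2Estimate",
    "BreathHoldRecord",
    "make_noisy_trace",
    "make_breath_hold_dataset",
    "estimate_vo2",
    "make_ct_phantom",
    "make_tidal_ct_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian sensor noise."""

    sd: float = 1.0   # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TidalCondition:
    mode: Mode
    rr: float
    ie_ratio: float
    vt_per_kg: float

    def label(self) -> str:
        num, den = (self.ie_ratio, 1) if self.ie_ratio >= 1 else (1, 1 / self.ie_ratio)
        return f"{self.mode.value} RR{self.rr:g} I:E {num:g}:{den:g}"


# volumes studied in the breath-hold protocol
HOLD_LABELS = ("Ve", "VT10", "VT20")


class ExperimentDesign:
    """The study design: 16 tidal conditions (2 modes x 4 I:E x 2 RR/VT
    pairings) and 18 breath holds (3 volumes x 6 repeats) sequenced so
    every ordered volume pair occurs."""

    IE_RATIOS = (0.5, 2.0, 0.25, 4.0)
    RR_VT = ((12.0, 10.0), (6.0, 20.0))

    @classmethod
    def tidal_conditions(cls) -> list[TidalCondition]:
        return [
            TidalCondition(mode=mode, rr=rr, ie_ratio=ie, vt_per_kg=vt)
            for rr, vt in cls.RR_VT
            for mode in (Mode.VC, Mode.PC)
            for ie in cls.IE_RATIOS
        ]

    @classmethod
    def breath_hold_sequence(cls) -> list[str]:
        """18-hold sequence covering all 9 ordered volume pairs.

        A de Bruijn cycle over {Ve, VT10, VT20} of length 9 visits every
        ordered pair once; traversing it twice gives 6 repeats per volume
        while keeping full sequential coverage (the authors' own sequence
        table is not public, so a balanced covering sequence is generated
        instead).
        """
        cycle = "AABACBBCC"
        key = dict(zip("ABC", HOLD_LABELS))
        return [key[ch] for ch in cycle * 2]


def make_noisy_trace(
    clean: PO2Trace, noise: NoiseModel, channel: str = "art"
) -> SampledTrace:
    """Sampled trace = chosen PO2 channel plus Gaussian sensor noise."""
    y = clean.pao2_art if channel == "art" else clean.pao2_alv
    y = np.asarray(y, dtype=float)
    if noise.sd > 0:
        y = y + noise.rng().normal(0.0, noise.sd, size=y.shape)
    return SampledTrace(
        t=np.asarray(clean.t, dtype=float),
        pao2=y,
        paw=np.asarray(clean.paw_cmh2o, dtype=float),
    )


@dataclass
class BreathHoldRecord:
    label: str
    va: float                 # ml
    trace: SampledTrace       # noisy decline segment (alveolar channel)
    true_rate: float          # mmHg/s ground truth


def make_breath_hold_dataset(
    params: GasExchangeParams,
    volumes: dict[str, float] | None = None,
    repeats: int = 6,
    noise: NoiseModel = NoiseModel(sd=1.0, seed=0),
    duration: float = 20.0,
    dt: float = 0.1,
    initial_pao2: float = 270.0,
) -> tuple[list[BreathHoldRecord], dict]:
    """Simulated breath-hold manoeuvres with sensor noise.

    Default volumes are the three studied levels: end-expiratory alveolar
    volume and the volumes after 10 and 20 ml/kg inflations.  With three
    volumes and six repeats the holds follow the pair-covering sequence;
    otherwise volumes are tiled.  Ground truth (VO2, per-volume rates) is
    returned alongside.
    """
    if volumes is None:
        va0 = alveolar_volume_at_eelv(params)
        volumes = {
            "Ve": va0,
            "VT10": va0 + 10.0 * params.mass,
            "VT20": va0 + 20.0 * params.mass,
        }
    if any(v <= 0 for v in volumes.values()):
        raise InvalidParameterError("hold volumes must be positive")
    if set(volumes) == set(HOLD_LABELS) and repeats == 6:
        sequence = ExperimentDesign.breath_hold_sequence()
    else:
        sequence = [lab for lab in volumes for _ in range(repeats)]
    rng = np.random.default_rng(noise.seed)
    records = []
    for label in sequence:
        va = volumes[label]
        clean = simulate_breath_hold(
            params, va, duration=duration, dt=dt, initial_pao2=initial_pao2
        )
        y = np.asarray(clean.pao2_alv, dtype=float)
        if noise.sd > 0:
            y = y + rng.normal(0.0, noise.sd, size=y.shape)
        records.append(
            BreathHoldRecord(
                label=label,
                va=va,
                trace=SampledTrace(t=np.asarray(clean.t), pao2=y),
                true_rate=predict_breath_hold_decline(params, va),
            )
        )
    truth = {
        "vo2": params.vo2,
        "volumes": dict(volumes),
        "rates": {
            lab: predict_breath_hold_decline(params, v)
            for lab, v in volumes.items()
        },
    }
    return records, truth


@dataclass
class Vo2Estimate:
    vo2: float
    se: float
    ci95: tuple[float, float]
    n: int


def estimate_vo2(
    declines, pb: float = 760.0, ph2o: float = 47.0
) -> Vo2Estimate:
    """Recover VO2 from measured decline rates at known alveolar volumes.

    The inverse-volume law says rate = VO2 * (PB - PH2O) / VA, so VO2 is
    the through-origin least-squares slope of rate against
    ``(PB - PH2O)/VA``.  Standard error and 95% t CI come from the fit
    residuals (undefined for a single observation).
    """
    arr = np.asarray(list(declines), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise InvalidParameterError("expected (rate, va) observations")
    rate, va = arr[:, 0], arr[:, 1]
    if np.any(va <= 0):
        raise InvalidParameterError("alveolar volumes must be positive")
    x = (pb - ph2o) / va
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise InvalidParameterError("degenerate regressor")
    slope = float(np.sum(x * rate) / sxx)
    n = len(arr)
    if n < 2:
        return Vo2Estimate(vo2=slope, se=float("nan"),
                           ci95=(float("nan"), float("nan")), n=n)
    resid = rate - slope * x
    se = float(np.sqrt(np.sum(resid ** 2) / (n - 1) / sxx))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    return Vo2Estimate(
        vo2=slope, se=se, ci95=(slope - tcrit * se, slope + tcrit * se), n=n
    )


def _band_mean_tissue_frac(band: tuple[float, float]) -> float:
    """Expected tissue fraction of a voxel with HU uniform on the band."""
    lo, hi = band
    mean_hu = 0.5 * (lo + hi)
    return float(np.clip(1.0 + mean_hu / 1000.0, 0.0, 1.0))


def make_ct_phantom(
    target_fractions,
    shape: tuple[int, ...] = (64, 64),
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 5.0),
    seed: int = 0,
    bands: AerationBands = DEFAULT_BANDS,
    mask_margin: int = 3,
) -> tuple[CTVolume, dict]:
    """CT phantom with prescribed per-class tissue-mass fractions.

    ``target_fractions`` orders as (overinflated, normal, poor,
    atelectatic) and must sum to 1.  Voxel counts per class are chosen so
    expected tissue-mass fractions match the targets; HU values are drawn
    uniformly within each band.  The lung mask is the array minus a border
    of ``mask_margin`` voxels (the border is air outside the lung, left
    free for inflation in :func:`make_tidal_ct_series`).  Ground truth
    (targets, achieved fractions, counts) is returned alongside.
    """
    f = np.asarray(target_fractions, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
        raise InvalidParameterError(
            "target_fractions must be 4 non-negative values summing to 1"
        )
    mask = np.zeros(shape, dtype=bool)
    inner = tuple(slice(mask_margin, s - mask_margin) for s in shape)
    mask[inner] = True
    n_lung = int(mask.sum())
    if n_lung < 4:
        raise InvalidParameterError("mask too small for a phantom")

    band_list = [bands.band(c) for c in CLASS_NAMES]
    mean_tissue = np.array([_band_mean_tissue_frac(b) for b in band_list])
    weights = np.where(f > 0, f / mean_tissue, 0.0)
    raw = weights / weights.sum() * n_lung
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding so counts sum to the mask size
    for i in np.argsort(raw - counts)[::-1][: n_lung - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    hu_lung = np.empty(n_lung)
    pos = 0
    for (lo, hi), c in zip(band_list, counts):
        hu_lung[pos:pos + c] = rng.uniform(lo, hi, size=c)
        pos += c
    rng.shuffle(hu_lung)

    hu = np.full(shape, -1000.0)
    hu[mask] = hu_lung
    ct = CTVolume(hu=hu, voxel_dims=voxel_dims, lung_mask=mask)

    vvol = ct.voxel_volume_ml
    _, tissue = voxel_gas_tissue(hu_lung, vvol)
    cls = bands.classify(hu_lung)
    tissue_by = np.bincount(cls, weights=tissue, minlength=4)
    achieved = tissue_by / tissue_by.sum()
    truth = {
        "target_fractions": dict(zip(CLASS_NAMES, f)),
        "achieved_fractions": dict(zip(CLASS_NAMES, achieved)),
        "counts": dict(zip(CLASS_NAMES, counts.tolist())),
        "total_tissue_mass_g": float(tissue_by.sum()),
        "seed": seed,
    }
    return ct, truth


def make_tidal_ct_series(
    base: CTVolume,
    inflation_profile,
    seed: int = 0,
    recruit_fraction: float = 0.15,
    hu_step: float = 80.0,
    tidal_gas_ml: float | None = None,
    cyclical_atelectasis_points: float = 0.0,
    bands: AerationBands = DEFAULT_BANDS,
) -> tuple[list[CTVolume], pd.DataFrame]:
    """Respiratory-cycle CT series built from a base phantom.

    ``inflation_profile`` gives per-frame inflation in [0, 1] (0 =
    end-expiration).  Inflation does two things:

    * recruits poorly aerated voxels into the normal band by lowering
      their HU by ``hu_step``, exactly compensated by raising the HU of an
      equal number of partner voxels that stay within the poor band — so
      total tissue mass and within-lung gas are conserved to float
      round-off (a stylized stand-in for tissue redistribution through the
      imaged slice);
    * adds inspired gas as pure-gas (-1000 HU, zero-mass) voxels appended
      to the mask at the lung border, up to ``tidal_gas_ml`` (default 20%
      of the base gas volume) at full inflation.

    Atelectatic voxels are untouched by default; a nonzero
    ``cyclical_atelectasis_points`` instead oscillates the atelectatic
    mass fraction by roughly that many percentage points (for contrast
    experiments).  Returns the frames and a per-frame ground-truth table.
    """
    u = np.asarray(inflation_profile, dtype=float)
    if u.ndim != 1 or len(u) < 2:
        raise InvalidParameterError("inflation profile needs >= 2 frames")
    if u.min() < 0 or u.max() > 1:
        raise InvalidParameterError("inflation values must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    hu0 = base.hu.copy()
    mask0 = base.lung_mask
    vvol = base.voxel_volume_ml
    flat_idx = np.flatnonzero(mask0.ravel())
    hu_lung = hu0.ravel()[flat_idx]

    p_lo, p_hi = bands.poor
    # recruitable: poor voxels whose HU - hu_step lands inside the normal band
    recr = np.flatnonzero((hu_lung >= p_lo) & (hu_lung <= p_hi)
                          & (hu_lung - hu_step <= bands.normal[1]))
    # partners: poor voxels whose HU + hu_step keeps them in the poor band
    part = np.flatnonzero((hu_lung >= p_lo) & (hu_lung <= p_hi)
                          & (hu_lung + hu_step <= p_hi))
    part = np.setdiff1d(part, recr)
    n_poor = int(np.sum((hu_lung >= p_lo) & (hu_lung <= p_hi)))
    k_max = int(min(len(recr), len(part), recruit_fraction * max(n_poor, 1)))
    recr = rng.permutation(recr)[:k_max]
    part = rng.permutation(part)[:k_max]

    a_lo, a_hi = bands.atelectatic
    at_recr = at_part = np.empty(0, dtype=int)
    ca_max = 0
    if cyclical_atelectasis_points > 0:
        at_step = 60.0
        at_recr_all = np.flatnonzero(
            (hu_lung >= a_lo) & (hu_lung <= a_hi)
            & (hu_lung - at_step <= p_hi) & (hu_lung - at_step >= p_lo)
        )
        at_part_all = np.flatnonzero(
            (hu_lung >= a_lo) & (hu_lung <= a_hi)
            & (hu_lung + at_step <= a_hi)
        )
        at_part_all = np.setdiff1d(at_part_all, at_recr_all)
        _, tis0 = voxel_gas_tissue(hu_lung, vvol)
        mean_at_mass = float(np.mean(tis0[at_recr_all])) if len(at_recr_all) else 0.0
        want = (cyclical_atelectasis_points / 100.0) * float(tis0.sum())
        ca_max = int(min(
            len(at_recr_all), len(at_part_all),
            round(want / mean_at_mass) if mean_at_mass > 0 else 0,
        ))
        at_recr = rng.permutation(at_recr_all)[:ca_max]
        at_part = rng.permutation(at_part_all)[:ca_max]

    # rim voxels just outside the lung used as pure inspired gas
    rim_mask = ~mask0
    rim_idx = rng.permutation(np.flatnonzero(rim_mask.ravel()))
    base_gas = float(np.sum(voxel_gas_tissue(hu_lung, vvol)[0]))
    if tidal_gas_ml is None:
        tidal_gas_ml = 0.2 * base_gas
    n_rim_max = min(len(rim_idx), int(round(tidal_gas_ml / vvol)))

    frames: list[CTVolume] = []
    rows = []
    for frame_i, uf in enumerate(u):
        hu_f = hu_lung.copy()
        k = int(round(uf * k_max))
        hu_f[recr[:k]] -= hu_step
        hu_f[part[:k]] += hu_step
        ka = int(round(uf * ca_max))
        if ka:
            hu_f[at_recr[:ka]] -= 60.0
            hu_f[at_part[:ka]] += 60.0
        n_rim = int(round(uf * n_rim_max))
        hu_full = np.full(base.hu.shape, -1000.0).ravel()
        hu_full[flat_idx] = hu_f
        mask_full = np.zeros(base.hu.size, dtype=bool)
        mask_full[flat_idx] = True
        mask_full[rim_idx[:n_rim]] = True
        frames.append(
            CTVolume(
                hu=hu_full.reshape(base.hu.shape),
                voxel_dims=base.voxel_dims,
                lung_mask=mask_full.reshape(base.hu.shape),
            )
        )
        gas_f, tis_f = voxel_gas_tissue(hu_f, vvol)
        cls = bands.classify(hu_f)
        tis_by = np.bincount(cls, weights=tis_f, minlength=4)
        row = {"frame": frame_i, "inflation": float(uf),
               "n_recruited": k, "n_rim_gas": n_rim}
        total = tis_by.sum()
        row.update({f"frac_{c}": float(m / total)
                    for c, m in zip(CLASS_NAMES, tis_by)})
        row["tissue_mass_g"] = float(total)
        row["gas_volume_ml"] = float(gas_f.sum() + n_rim * vvol)
        rows.append(row)
    return frames, pd.DataFrame(rows)
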