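"""Quantitative CT lung aeration analysis.

Each lung voxel is treated as a linear gas/tissue mixture on the
Hounsfield scale: gas fraction ``-HU/1000`` (clamped to [0, 1] over the
quantitation range [-1000, +100]), tissue density ``rho`` g/ml (water by
default).  Voxels are classified into the standard aeration bands
(overinflated / normally aerated / poorly aerated / atelectatic) and the
report gives per-class tissue mass, gas volume and tissue-mass fractions,
plus whole-lung gas and total volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidParameterError

__all__ = [
    "CLASS_NAMES",
    "AerationBands",
    "CTVolume",
    "AerationReport",
    "LungVolumeResult",
    "voxel_gas_tissue",
    "aeration_report",
    "lung_volume",
    "atelectasis_change",
    "cycle_mass_fractions",
    "load_ct_nifti",
    "save_ct_nifti",
]

CLASS_NAMES = ("overinflated", "normal", "poor", "atelectatic")

HU_MIN, HU_MAX = -1024.0, 3071.0
QUANT_LO, QUANT_HI = -1000.0, 100.0


@dataclass(frozen=True)
class AerationBands:
    """HU bands for the four aeration classes (inclusive integer limits).

    Defaults are the standard quantitative-CT convention:
    overinflated [-1000, -901], normal [-900, -501], poor [-500, -101],
    atelectatic [-100, +100].  Bands must be contiguous and ordered.
    """

    overinflated: tuple[float, float] = (-1000.0, -901.0)
    normal: tuple[float, float] = (-900.0, -501.0)
    poor: tuple[float, float] = (-500.0, -101.0)
    atelectatic: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        bands = [self.overinflated, self.normal, self.poor, self.atelectatic]
        for lo, hi in bands:
            if lo >= hi:
                raise InvalidParameterError("band limits must satisfy lo < hi")
        for (_, hi), (lo, _) in zip(bands[:-1], bands[1:]):
            if not 0 < lo - hi <= 1.0:
                raise InvalidParameterError("bands must be contiguous, ordered")

    @property
    def edges(self) -> np.ndarray:
        """Class decision thresholds (midpoints between adjacent bands)."""
        bands = [self.overinflated, self.normal, self.poor, self.atelectatic]
        return np.array(
            [0.5 * (hi + lo) for (_, hi), (lo, _) in zip(bands[:-1], bands[1:])]
        )

    def classify(self, hu: np.ndarray) -> np.ndarray:
        """Class index (0..3) per voxel.  Values below/above the
        quantitation range map to the nearest extreme band."""
        return np.searchsorted(self.edges, np.asarray(hu, dtype=float))

    def band(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


DEFAULT_BANDS = AerationBands()


@dataclass
class CTVolume:
    """A CT slice or volume in Hounsfield units with a lung mask."""

    hu: np.ndarray
    voxel_dims: tuple[float, float, float]   # mm
    lung_mask: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.hu.shape != self.lung_mask.shape:
            raise GeometryError("hu and lung_mask shapes differ")
        if not self.lung_mask.any():
            raise InvalidParameterError("lung mask is empty")
        if any(d <= 0 for d in self.voxel_dims):
            raise InvalidParameterError("voxel dimensions must be positive")
        if self.hu.min() < HU_MIN or self.hu.max() > HU_MAX:
            raise InvalidParameterError(
                f"HU values outside [{HU_MIN:.0f}, {HU_MAX:.0f}]"
            )

    @property
    def voxel_volume_ml(self) -> float:
        d = self.voxel_dims
        return float(d[0] * d[1] * d[2] / 1000.0)


@dataclass
class AerationReport:
    """Per-class tissue mass / gas volume and whole-lung totals."""

    tissue_mass_g: dict[str, float]
    gas_volume_ml: dict[str, float]
    mass_fraction: dict[str, float]
    total_lung_volume_ml: float
    total_gas_volume_ml: float
    total_tissue_mass_g: float
    n_voxels: int
    shape: tuple[int, ...]
    n_flagged: int = 0   # masked voxels outside the quantitation HU range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(CLASS_NAMES),
                "tissue_mass_g": [self.tissue_mass_g[c] for c in CLASS_NAMES],
                "gas_volume_ml": [self.gas_volume_ml[c] for c in CLASS_NAMES],
                "mass_fraction": [self.mass_fraction[c] for c in CLASS_NAMES],
            }
        )


@dataclass
class LungVolumeResult:
    total_ml: float    # gas + tissue of all masked voxels
    gas_ml: float
    tissue_ml: float


def voxel_gas_tissue(hu, voxel_volume: float, rho: float = 1.0):
    """Gas volume (ml) and tissue mass (g) of voxels from their HU.

    HU is clamped to the quantitation range [-1000, +100]; the gas
    fraction is ``-HU/1000`` clipped to [0, 1] and tissue occupies the
    remainder at density ``rho`` g/ml.
    """
    if voxel_volume <= 0:
        raise InvalidParameterError("voxel volume must be positive")
    hu_c = np.clip(np.asarray(hu, dtype=float), QUANT_LO, QUANT_HI)
    gas_frac = np.clip(-hu_c / 1000.0, 0.0, 1.0)
    gas = gas_frac * voxel_volume
    tissue = (1.0 - gas_frac) * voxel_volume * rho
    if np.isscalar(hu):
        return float(gas), float(tissue)
    return gas, tissue


def aeration_report(
    ct: CTVolume,
    bands: AerationBands = DEFAULT_BANDS,
    rho: float = 1.0,
) -> AerationReport:
    """Classify masked voxels and sum per-class gas volume and tissue mass.

    Masked voxels outside the quantitation range are counted in the
    nearest band (clamped HU) and reported in ``n_flagged``, never dropped.
    """
    hu = ct.hu[ct.lung_mask]
    vvol = ct.voxel_volume_ml
    gas, tissue = voxel_gas_tissue(hu, vvol, rho=rho)
    cls = bands.classify(hu)
    n_flagged = int(np.sum((hu < QUANT_LO) | (hu > QUANT_HI)))
    tissue_by = np.bincount(cls, weights=tissue, minlength=4)
    gas_by = np.bincount(cls, weights=gas, minlength=4)
    total_tissue = float(tissue_by.sum())
    if total_tissue <= 0:
        raise InvalidParameterError(
            "masked region holds no tissue mass; fractions undefined"
        )
    return AerationReport(
        tissue_mass_g={c: float(m) for c, m in zip(CLASS_NAMES, tissue_by)},
        gas_volume_ml={c: float(g) for c, g in zip(CLASS_NAMES, gas_by)},
        mass_fraction={
            c: float(m / total_tissue) for c, m in zip(CLASS_NAMES, tissue_by)
        },
        total_lung_volume_ml=float(len(hu) * vvol),
        total_gas_volume_ml=float(gas_by.sum()),
        total_tissue_mass_g=total_tissue,
        n_voxels=int(len(hu)),
        shape=tuple(ct.hu.shape),
        n_flagged=n_flagged,
    )


def lung_volume(ct: CTVolume, rho: float = 1.0) -> LungVolumeResult:
    """Whole-lung volumes: total (gas + tissue) and the gas part alone."""
    hu = ct.hu[ct.lung_mask]
    gas, tissue = voxel_gas_tissue(hu, ct.voxel_volume_ml, rho=rho)
    return LungVolumeResult(
        total_ml=float(hu.size * ct.voxel_volume_ml),
        gas_ml=float(np.sum(gas)),
        tissue_ml=float(np.sum(tissue) / rho),
    )


def atelectasis_change(a: AerationReport, b: AerationReport) -> float:
    """Change in atelectatic mass fraction, in percentage points of lung
    tissue mass (b minus a).  Reports must come from the same geometry."""
    if a.shape != b.shape or a.n_voxels != b.n_voxels:
        raise GeometryError("reports come from different geometries/masks")
    return (b.mass_fraction["atelectatic"] - a.mass_fraction["atelectatic"]) * 100.0


def cycle_mass_fractions(
    series: list[CTVolume],
    times,
    bands: AerationBands = DEFAULT_BANDS,
    rho: float = 1.0,
) -> pd.DataFrame:
    """Per-frame aeration reports across a respiratory cycle.

    Frames must share array shape and voxel size (masks may differ as the
    aerated lung expands).  Returns a tidy frame with one row per time
    point: per-class mass fractions, total tissue mass and gas volume.
    """
    times = np.asarray(times, dtype=float)
    if len(series) < 2:
        raise InvalidParameterError("need >= 2 frames spanning a cycle")
    if len(series) != len(times):
        raise InvalidParameterError("series and times lengths differ")
    ref = series[0]
    rows = []
    for ct, t in zip(series, times):
        if ct.hu.shape != ref.hu.shape or ct.voxel_dims != ref.voxel_dims:
            raise GeometryError("inconsistent frame geometry in series")
        rep = aeration_report(ct, bands=bands, rho=rho)
        row = {"time_s": t}
        row.update({f"frac_{c}": rep.mass_fraction[c] for c in CLASS_NAMES})
        row["tissue_mass_g"] = rep.total_tissue_mass_g
        row["gas_volume_ml"] = rep.total_gas_volume_ml
        rows.append(row)
    return pd.DataFrame(rows)


def load_ct_nifti(hu_path, mask_path) -> CTVolume:
    """Read a CT volume and lung mask from NIfTI files (voxel size from the
    image header)."""
    import nibabel as nib

    img = nib.load(str(hu_path))
    mask = nib.load(str(mask_path))
    zooms = img.header.get_zooms()[:3]
    dims = tuple(float(z) for z in zooms) if len(zooms) == 3 else (
        float(zooms[0]), float(zooms[1]), 1.0
    )
    return CTVolume(
        hu=np.asarray(img.dataobj, dtype=float),
        voxel_dims=dims,
        lung_mask=np.asarray(mask.dataobj) > 0,
    )


def save_ct_nifti(ct: CTVolume, hu_path, mask_path) -> None:
    import nibabel as nib

    affine = np.diag(list(ct.voxel_dims[: ct.hu.ndim]) + [1.0] * (4 - ct.hu.ndim))
    nib.save(nib.Nifti1Image(ct.hu.astype(np.float32), affine), str(hu_path))
    nib.save(
        nib.Nifti1Image(ct.lung_mask.astype(np.uint8), affine), str(mask_path)
    )
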