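"""Phantom calibration and the density--modulus chain.

Quantitative CT images carry Hounsfield units (HU). Calibration phantoms of
known equivalent mineral density (CaHA, here 0 / 0.075 / 0.150 g/cm^3) scanned
with the bone give a linear map ``rho_QCT = a + b * HU``. QCT density is
converted to ash density, then apparent density, and finally to an isotropic
Young's modulus through a power law::

    rho_ash = 0.0633 + 0.877 * rho_QCT      [g/cm^3]
    rho_app = rho_ash / 0.626               [g/cm^3]
    E       = 6850 * rho_app ** 1.49        [MPa]

A Poisson's ratio of 0.3 is used for all bone materials. For heterogeneous
models the per-element HU values are partitioned into a fixed number of
equal-width sets (default 100) and each set receives one modulus, which keeps
the number of distinct materials bounded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationFit",
    "MaterialField",
    "MaterialPartition",
    "fit_hu_density",
    "qct_to_ash",
    "ash_to_app",
    "modulus_from_app",
    "hu_to_modulus",
    "partition_materials",
    "assign_materials",
    "CORTICAL_MODULUS_MPA",
    "TRABECULAR_MODULUS_MPA",
    "POISSON_RATIO",
    "DENSITY_FLOOR",
]

#: Two-phase (composite femur) moduli, MPa.
CORTICAL_MODULUS_MPA = 16_700.0
TRABECULAR_MODULUS_MPA = 155.0

#: Poisson's ratio used for all bone materials.
POISSON_RATIO = 0.3

#: Floor applied to rho_QCT (g/cm^3) before the power law. The linear
#: calibration extrapolates below the phantom range and can return negative
#: densities for air/marrow voxels; those are clamped to a small positive
#: value so the modulus stays positive.
DENSITY_FLOOR = 1e-3

_ASH_INTERCEPT = 0.0633
_ASH_SLOPE = 0.877
_APP_DIVISOR = 0.626
_POWER_COEFF = 6850.0
_POWER_EXP = 1.49


@dataclass(frozen=True)
class CalibrationFit:
    """Linear HU -> QCT density map ``rho = a + b * HU``.

    Attributes
    ----------
    a : intercept, g/cm^3
    b : slope, g/cm^3 per HU (positive for physically ordered phantoms)
    r_squared : coefficient of determination of the fit
    """

    a: float
    b: float
    r_squared: float = 1.0

    def __post_init__(self):
        if self.b == 0:
            raise ValueError("calibration slope b must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def density(self, hu):
        """QCT density (g/cm^3) for HU value(s)."""
        return self.a + self.b * np.asarray(hu, dtype=float)

    def hu(self, rho_qct):
        """Inverse map: HU producing the given QCT density."""
        return (np.asarray(rho_qct, dtype=float) - self.a) / self.b

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"a": self.a, "b": self.b, "r_squared": self.r_squared}, fh, indent=1
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(a=d["a"], b=d["b"], r_squared=d.get("r_squared", 1.0))


def fit_hu_density(hu_means, densities) -> CalibrationFit:
    """Ordinary least-squares line ``density = a + b * HU``.

    Parameters
    ----------
    hu_means : mean HU of each phantom ROI
    densities : nominal phantom densities, g/cm^3

    Returns the fitted :class:`CalibrationFit` with R^2 evaluated on the
    same points.
    """
    hu = np.asarray(hu_means, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if hu.shape != rho.shape or hu.ndim != 1:
        raise ValueError("hu_means and densities must be 1-D and equal length")
    if hu.size < 2:
        raise ValueError("need at least two phantom points to fit a line")
    sxx = np.sum((hu - hu.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate phantom data: all HU values equal")
    b = np.sum((hu - hu.mean()) * (rho - rho.mean())) / sxx
    a = rho.mean() - b * hu.mean()
    resid = rho - (a + b * hu)
    ss_tot = np.sum((rho - rho.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return CalibrationFit(a=float(a), b=float(b), r_squared=float(min(max(r2, 0.0), 1.0)))


def qct_to_ash(rho_qct):
    """Ash density from QCT density: ``0.0633 + 0.877 * rho_QCT``."""
    return _ASH_INTERCEPT + _ASH_SLOPE * np.asarray(rho_qct, dtype=float)


def ash_to_app(rho_ash):
    """Apparent density from ash density: ``rho_ash / 0.626``."""
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash < 0):
        raise ValueError("ash density must be non-negative")
    return rho_ash / _APP_DIVISOR


def modulus_from_app(rho_app):
    """Young's modulus (MPa) from apparent density: ``6850 * rho_app^1.49``."""
    rho_app = np.asarray(rho_app, dtype=float)
    if np.any(rho_app <= 0):
        raise ValueError(
            "apparent density must be positive; clamp upstream (see DENSITY_FLOOR)"
        )
    return _POWER_COEFF * rho_app**_POWER_EXP


def hu_to_modulus(hu, fit: CalibrationFit, floor: float = DENSITY_FLOOR):
    """Full HU -> E chain with the QCT-density floor applied.

    ``rho_QCT`` values below ``floor`` (including negative extrapolations of
    the phantom line) are clamped before the ash/apparent conversions.
    """
    rho_qct = np.maximum(fit.density(hu), floor)
    return modulus_from_app(ash_to_app(qct_to_ash(rho_qct)))


@dataclass
class MaterialPartition:
    """Equal-width HU binning used for heterogeneous material assignment.

    ``bin_id`` maps each element to a *valid* bin (index into ``bin_hu``),
    or -1 where the element's bin was dropped (empty, or representative
    density not positive). ``bin_hu`` holds each valid bin's representative
    HU (the mean HU of its members).
    """

    bin_id: np.ndarray
    bin_hu: np.ndarray

    @property
    def n_bins_valid(self) -> int:
        return int(self.bin_hu.size)


def partition_materials(per_element_hu, n_sets: int = 100,
                        fit: CalibrationFit | None = None) -> MaterialPartition:
    """Partition per-element HU values into ``n_sets`` equal-width bins.

    Bins that are empty are dropped; when a calibration ``fit`` is supplied,
    bins whose representative (mean) HU maps to a non-positive QCT density are
    dropped as well, so skewed HU histograms typically yield fewer valid
    materials than ``n_sets``.
    """
    hu = np.asarray(per_element_hu, dtype=float)
    if hu.ndim != 1 or hu.size == 0:
        raise ValueError("per_element_hu must be a non-empty 1-D array")
    lo, hi = float(hu.min()), float(hu.max())
    if lo == hi:
        warnings.warn("all elements share one HU value; single material bin",
                      stacklevel=2)
        raw = np.zeros(hu.size, dtype=int)
        n_sets = 1
    else:
        width = (hi - lo) / n_sets
        raw = np.minimum(((hu - lo) / width).astype(int), n_sets - 1)
    means = np.full(n_sets, np.nan)
    counts = np.bincount(raw, minlength=n_sets)
    sums = np.bincount(raw, weights=hu, minlength=n_sets)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty]
    valid = nonempty.copy()
    if fit is not None:
        with np.errstate(invalid="ignore"):
            valid &= np.where(np.isnan(means), False, fit.density(np.nan_to_num(means)) > 0)
    if not valid.any():
        raise ValueError("no valid material bins (all HU map to non-positive density)")
    new_index = np.full(n_sets, -1, dtype=int)
    new_index[valid] = np.arange(int(valid.sum()))
    return MaterialPartition(bin_id=new_index[raw], bin_hu=means[valid])


@dataclass
class MaterialField:
    """Per-element elastic properties.

    Attributes
    ----------
    E : per-element Young's modulus, MPa (strictly positive)
    nu : Poisson's ratio, one value for all materials (default 0.3)
    bin_id : optional per-element material-bin index (heterogeneous mode)
    n_bins_valid : number of distinct valid materials, when binned
    """

    E: np.ndarray
    nu: float = POISSON_RATIO
    bin_id: np.ndarray | None = None
    n_bins_valid: int | None = None

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        if np.any(self.E <= 0):
            raise ValueError("all element moduli must be positive")

    @property
    def n_elements(self) -> int:
        return int(self.E.size)

    def copy(self) -> "MaterialField":
        return MaterialField(
            E=self.E.copy(),
            nu=self.nu,
            bin_id=None if self.bin_id is None else self.bin_id.copy(),
            n_bins_valid=self.n_bins_valid,
        )

    def to_csv(self, path, hu=None) -> None:
        """Export element_id, (HU,) bin, E as CSV."""
        import pandas as pd

        d = {"element_id": np.arange(self.n_elements)}
        if hu is not None:
            d["hu"] = np.asarray(hu)
        if self.bin_id is not None:
            d["bin"] = self.bin_id
        d["E_mpa"] = self.E
        pd.DataFrame(d).to_csv(path, index=False)


def assign_materials(mesh, image_or_hu, fit: CalibrationFit | None, mode: str,
                     n_sets: int = 100) -> MaterialField:
    """Build the per-element material field.

    ``mode='two_phase'`` uses the mesh's cortical/trabecular labels and the
    composite-femur constants (16.7 GPa / 155 MPa); ``image_or_hu`` and
    ``fit`` are ignored. ``mode='heterogeneous'`` samples HU at element
    centroids (trilinear, when a voxel image is given) or takes a per-element
    HU array, partitions it into ``n_sets`` equal-width bins and pushes each
    bin's representative HU through the calibration chain.
    """
    if mode == "two_phase":
        if mesh.region_label is None:
            raise ValueError("two_phase mode requires cortical/trabecular labels")
        from .mesh import CORTICAL

        E = np.where(mesh.region_label == CORTICAL,
                     CORTICAL_MODULUS_MPA, TRABECULAR_MODULUS_MPA)
        return MaterialField(E=E, nu=POISSON_RATIO)
    if mode != "heterogeneous":
        raise ValueError(f"unknown material mode {mode!r}")
    if fit is None:
        raise ValueError("heterogeneous mode requires a CalibrationFit")
    if hasattr(image_or_hu, "sample"):
        hu = image_or_hu.sample(mesh.centroids)
    else:
        hu = np.asarray(image_or_hu, dtype=float)
    if hu.shape[0] != mesh.n_elements:
        raise ValueError("per-element HU length does not match element count")
    part = partition_materials(hu, n_sets=n_sets, fit=fit)
    bin_E = hu_to_modulus(part.bin_hu, fit)
    floor_E = float(hu_to_modulus(fit.hu(DENSITY_FLOOR), fit))
    E = np.where(part.bin_id >= 0, bin_E[np.maximum(part.bin_id, 0)], floor_E)
    return MaterialField(E=E, nu=POISSON_RATIO, bin_id=part.bin_id,
                         n_bins_valid=part.n_bins_valid)
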