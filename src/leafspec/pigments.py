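"""Chlorophyll and carotenoid quantification from 80%-acetone extracts.

Implements the Lichtenthaler linear equations converting spectrophotometer
absorbances of the extract at 663, 646 and 470 nm into pigment
concentrations (mg L-1), and the leaf-area normalisation to mg m-2 /
g m-2.  The exact 2x2 inverse of the chlorophyll system (and the
rearranged carotenoid equation) is provided for forward simulation.

Concentration units
-------------------
* extract concentrations: mg per litre of 80% acetone (mg L-1)
* per-leaf-area concentrations: g m-2 (canonical) and mg m-2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Lichtenthaler coefficients for 80% (v/v) acetone extracts.
_CHL_A = (12.25, -2.79)    # x a663, x a646
_CHL_B = (-5.10, 21.50)
_CHL_AB = (7.15, 18.71)    # identically CHL_A + CHL_B
_CAR = (1000.0, -1.82, -85.02, 198.0)  # (x a470, x chl_a, x chl_b, divisor)


def _warn_range(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any((v < 0.0) | (v > 1.0)):
        warnings.warn(
            f"{name} outside the 0-1 absorbance range expected for a "
            "properly diluted extract",
            stacklevel=3,
        )


def chlorophyll_a_mg_per_l(a663, a646):
    """Chl a (mg L-1) from extract absorbances at 663 and 646 nm."""
    _warn_range("a663", a663)
    _warn_range("a646", a646)
    return _CHL_A[0] * np.asarray(a663, float) + _CHL_A[1] * np.asarray(a646, float)


def chlorophyll_b_mg_per_l(a663, a646):
    """Chl b (mg L-1) from extract absorbances at 663 and 646 nm."""
    _warn_range("a663", a663)
    _warn_range("a646", a646)
    return _CHL_B[0] * np.asarray(a663, float) + _CHL_B[1] * np.asarray(a646, float)


def chlorophyll_total_mg_per_l(a663, a646):
    """Chl a+b (mg L-1); coefficient-identical to Chl a + Chl b."""
    _warn_range("a663", a663)
    _warn_range("a646", a646)
    return _CHL_AB[0] * np.asarray(a663, float) + _CHL_AB[1] * np.asarray(a646, float)


def carotenoids_mg_per_l(a470, chl_a_mg_l, chl_b_mg_l):
    """Total carotenoids (mg L-1) from a470 and the chlorophylls in mg L-1.

    A negative result (pathological inputs) is returned unclamped with a
    warning so that assay or simulation errors stay visible.
    """
    _warn_range("a470", a470)
    c = (
        _CAR[0] * np.asarray(a470, float)
        + _CAR[1] * np.asarray(chl_a_mg_l, float)
        + _CAR[2] * np.asarray(chl_b_mg_l, float)
    ) / _CAR[3]
    if np.any(np.asarray(c) < 0):
        warnings.warn("negative carotenoid concentration (flagged, not clamped)",
                      stacklevel=2)
    return c


@dataclass(frozen=True)
class ExtractAssay:
    """One extract's spectrophotometer readings plus extraction geometry."""

    a663: float
    a646: float
    a470: float
    volume_ml: float = 10.0
    dilution_factor: float = 1.0
    leaf_area_m2: float = 2e-4  # the 2 cm2 standard punch

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")
        if self.leaf_area_m2 <= 0:
            raise ValueError("leaf_area_m2 must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        for name in ("a663", "a646", "a470"):
            _warn_range(name, getattr(self, name))

    @classmethod
    def from_cm2(cls, a663, a646, a470, *, volume_ml=10.0,
                 dilution_factor=1.0, leaf_area_cm2=2.0) -> "ExtractAssay":
        """Convenience constructor taking the punch area in cm2."""
        return cls(a663, a646, a470, volume_ml=volume_ml,
                   dilution_factor=dilution_factor,
                   leaf_area_m2=leaf_area_cm2 * 1e-4)


@dataclass(frozen=True)
class PigmentConcentrations:
    """Pigment contents per unit leaf area, in g m-2."""

    chl_a: float
    chl_b: float
    chl_ab: float
    car: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.chl_a, self.chl_b, self.chl_ab, self.car)


def to_area_basis(conc_mg_per_l, assay: ExtractAssay):
    """Extract concentration (mg L-1) -> leaf-area basis (mg m-2).

    mg m-2 = conc x volume(mL) x Fd / 1000 / area(m2).  Divide by a
    further 1000 for g m-2 (see :func:`to_area_basis_g`).
    """
    return (
        np.asarray(conc_mg_per_l, float)
        * assay.volume_ml
        * assay.dilution_factor
        / 1000.0
        / assay.leaf_area_m2
    )


def to_area_basis_g(conc_mg_per_l, assay: ExtractAssay):
    """Extract concentration (mg L-1) -> g m-2."""
    return to_area_basis(conc_mg_per_l, assay) / 1000.0


def assay_to_pigments(assay: ExtractAssay) -> PigmentConcentrations:
    """Full quantification chain: absorbances -> g m-2 for all pigments."""
    chl_a_l = chlorophyll_a_mg_per_l(assay.a663, assay.a646)
    chl_b_l = chlorophyll_b_mg_per_l(assay.a663, assay.a646)
    chl_ab_l = chlorophyll_total_mg_per_l(assay.a663, assay.a646)
    car_l = carotenoids_mg_per_l(assay.a470, chl_a_l, chl_b_l)
    return PigmentConcentrations(
        chl_a=float(to_area_basis_g(chl_a_l, assay)),
        chl_b=float(to_area_basis_g(chl_b_l, assay)),
        chl_ab=float(to_area_basis_g(chl_ab_l, assay)),
        car=float(to_area_basis_g(car_l, assay)),
    )


# --- inverse mapping (simulation support) ---------------------------------

_CHL_MATRIX = np.array([[_CHL_A[0], _CHL_A[1]],
                        [_CHL_B[0], _CHL_B[1]]])


def invert_chlorophyll_system(chl_a_mg_l, chl_b_mg_l):
    """Absorbances (a663, a646) that reproduce the target chlorophylls.

    Solves the 2x2 linear chlorophyll system exactly; raises if the
    solution leaves the 0-1 absorbance range (the extract would need a
    different dilution factor).
    """
    rhs = np.array([float(chl_a_mg_l), float(chl_b_mg_l)])
    a663, a646 = np.linalg.solve(_CHL_MATRIX, rhs)
    if not (0.0 <= a663 <= 1.0 and 0.0 <= a646 <= 1.0):
        raise ValueError(
            f"target chlorophylls need absorbances ({a663:.3f}, {a646:.3f}) "
            "outside [0, 1]; adjust the dilution factor"
        )
    return float(a663), float(a646)


def carotenoid_absorbance(car_mg_l, chl_a_mg_l, chl_b_mg_l) -> float:
    """a470 that reproduces the target carotenoid concentration."""
    a470 = (
        _CAR[3] * float(car_mg_l)
        - _CAR[1] * float(chl_a_mg_l)
        - _CAR[2] * float(chl_b_mg_l)
    ) / _CAR[0]
    if not 0.0 <= a470 <= 1.0:
        raise ValueError(
            f"target carotenoids need a470 = {a470:.3f} outside [0, 1]; "
            "adjust the dilution factor"
        )
    return a470


# --- pigment table I/O ----------------------------------------------------

PIGMENT_COLUMNS = ["sample_id", "chl_a_g_m2", "chl_b_g_m2",
                   "chl_ab_g_m2", "car_g_m2"]


def pigments_to_frame(sample_ids, pigments) -> pd.DataFrame:
    rows = [
        {"sample_id": sid, "chl_a_g_m2": p.chl_a, "chl_b_g_m2": p.chl_b,
         "chl_ab_g_m2": p.chl_ab, "car_g_m2": p.car}
        for sid, p in zip(sample_ids, pigments, strict=True)
    ]
    return pd.DataFrame(rows, columns=PIGMENT_COLUMNS)


def read_pigment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PIGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pigment CSV missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in pigment CSV")
    return df[PIGMENT_COLUMNS].assign(sample_id=df["sample_id"].astype(str))


def write_pigment_csv(df: pd.DataFrame, path) -> None:
    df[PIGMENT_COLUMNS].to_csv(path, index=False, float_format="%.12g")
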