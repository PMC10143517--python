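"""Wavelength grids, leaf spectral records and spectra CSV I/O.

Spectra are stored as *fractions* in [0, 1] (not percent).  The absorbed
fraction is always derived from the two measured channels as

    A = 1 - (R + T)

and never persisted, so the three channels can never drift apart on disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sensor-noise tolerance on R + T exceeding 1 before a record is flagged
#: as physically inconsistent.
ENERGY_TOL = 0.02

#: Any spectral value above this is taken to mean the file is percent-scaled.
PERCENT_SCALE_THRESHOLD = 1.5


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive integer wavelength grid in nm."""

    start_nm: int = 400
    stop_nm: int = 700
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.start_nm >= self.stop_nm:
            raise ValueError("start_nm must be < stop_nm")
        if self.step_nm < 1:
            raise ValueError("step_nm must be >= 1")
        if (self.stop_nm - self.start_nm) % self.step_nm != 0:
            raise ValueError("grid endpoints must be commensurate with step")

    @property
    def n_bands(self) -> int:
        return (self.stop_nm - self.start_nm) // self.step_nm + 1

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.stop_nm + 1, self.step_nm)

    def index_of(self, wavelength_nm: int) -> int:
        """Index of a wavelength on the grid (exact match required)."""
        off = wavelength_nm - self.start_nm
        if off < 0 or off % self.step_nm or wavelength_nm > self.stop_nm:
            raise ValueError(f"{wavelength_nm} nm is not on the grid")
        return off // self.step_nm


#: The visible / photosynthetically active grid used throughout: 400-700 nm
#: inclusive at 1 nm resolution, i.e. 301 bands.
DEFAULT_GRID = WavelengthGrid(400, 700, 1)


def to_absorbance(
    R: np.ndarray,
    T: np.ndarray,
    *,
    tol: float = ENERGY_TOL,
    return_info: bool = False,
):
    """Absorbed fraction ``A = 1 - (R + T)``, clipped into [0, 1].

    Parameters
    ----------
    R, T
        Reflectance and transmittance fractions, same shape.
    tol
        Allowed sensor-noise excess of ``R + T`` over 1 before the input is
        flagged physically inconsistent (a warning, not an error).
    return_info
        If true, also return ``(n_clipped, inconsistent)`` where
        ``inconsistent`` is True when any ``R + T > 1 + tol``.
    """
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if R.shape != T.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs T {T.shape}")
    A = 1.0 - (R + T)
    inconsistent = bool(np.any(R + T > 1.0 + tol))
    if inconsistent:
        warnings.warn(
            "R + T exceeds 1 beyond the sensor-noise tolerance; "
            "sample is physically inconsistent",
            stacklevel=2,
        )
    n_clipped = int(np.count_nonzero((A < 0.0) | (A > 1.0)))
    if n_clipped:
        logger.debug("to_absorbance clipped %d bands into [0, 1]", n_clipped)
    A = np.clip(A, 0.0, 1.0)
    if return_info:
        return A, n_clipped, inconsistent
    return A


@dataclass
class LeafSpectralRecord:
    """One leaf's reflectance/transmittance pair on a common grid."""

    sample_id: str
    group_label: str
    R: np.ndarray
    T: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.T is not None:
            self.T = np.asarray(self.T, dtype=float)

    @property
    def has_transmittance(self) -> bool:
        return self.T is not None

    def absorbance(self, *, tol: float = ENERGY_TOL) -> np.ndarray:
        """Derived absorbed fraction; unavailable for reflectance-only data."""
        if self.T is None:
            raise ValueError(
                f"record {self.sample_id!r} is reflectance-only; "
                "absorbance requires the transmittance channel"
            )
        return to_absorbance(self.R, self.T, tol=tol)


@dataclass
class ValidationReport:
    sample_id: str
    n_clipped: int = 0
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues and self.n_clipped == 0


def validate_record(
    record: LeafSpectralRecord, grid: WavelengthGrid
) -> ValidationReport:
    """Check shapes/ranges and apply the clipping policy in place.

    Values outside [0, 1] are clipped and counted; NaNs and shape
    mismatches are unrecoverable and raise.  Every mutation is logged in
    the returned report.
    """
    report = ValidationReport(sample_id=record.sample_id)
    channels = [("R", record.R)]
    if record.T is not None:
        channels.append(("T", record.T))
    for name, vec in channels:
        if vec.ndim != 1 or vec.size != grid.n_bands:
            raise ValueError(
                f"record {record.sample_id!r}: channel {name} has length "
                f"{vec.size}, expected {grid.n_bands}"
            )
        if np.any(np.isnan(vec)):
            raise ValueError(
                f"record {record.sample_id!r}: NaN values in channel {name}"
            )
        out = (vec < 0.0) | (vec > 1.0)
        n_out = int(np.count_nonzero(out))
        if n_out:
            report.n_clipped += n_out
            report.issues.append(f"{name}: {n_out} values clipped into [0, 1]")
            logger.info(
                "record %s: clipping %d out-of-range values in %s",
                record.sample_id, n_out, name,
            )
            np.clip(vec, 0.0, 1.0, out=vec)
    return report


@dataclass
class SpectralDataset:
    """A collection of leaf records sharing one wavelength grid."""

    grid: WavelengthGrid
    records: list[LeafSpectralRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def group_labels(self) -> list[str]:
        return [r.group_label for r in self.records]

    @property
    def reflectance_only(self) -> bool:
        return any(r.T is None for r in self.records)

    def reflectance_matrix(self) -> np.ndarray:
        return np.vstack([r.R for r in self.records])

    def transmittance_matrix(self) -> np.ndarray:
        if self.reflectance_only:
            raise ValueError("dataset is reflectance-only")
        return np.vstack([r.T for r in self.records])

    def absorbance_matrix(self) -> np.ndarray:
        if self.reflectance_only:
            raise ValueError(
                "dataset is reflectance-only; absorbance unavailable"
            )
        return np.vstack([r.absorbance() for r in self.records])

    def validate(self) -> list[ValidationReport]:
        return [validate_record(r, self.grid) for r in self.records]

    def subset(self, indices) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid,
            records=[self.records[i] for i in indices],
            provenance=self.provenance,
        )


def _wavelength_columns(columns, prefix: str) -> list[tuple[int, str]]:
    out = []
    for c in columns:
        if c.startswith(prefix + "_"):
            try:
                out.append((int(c.split("_", 1)[1]), c))
            except ValueError:
                raise ValueError(f"malformed wavelength column {c!r}")
    return out


def read_spectra_csv(path) -> SpectralDataset:
    """Read a wide-layout spectra CSV.

    Layout: ``sample_id, group, R_400 ... R_700[, T_400 ... T_700]`` with
    fractional values.  A file without T columns yields a reflectance-only
    dataset.  Percent-scaled files (any value > 1.5) are rejected.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("spectra CSV must have sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in spectra CSV")

    r_cols = _wavelength_columns(df.columns, "R")
    t_cols = _wavelength_columns(df.columns, "T")
    if not r_cols:
        raise ValueError("no R_<wavelength> columns found")

    wavelengths = [w for w, _ in r_cols]
    if wavelengths != sorted(wavelengths) or len(set(wavelengths)) != len(wavelengths):
        raise ValueError("R wavelength columns are not strictly increasing")
    steps = np.diff(wavelengths)
    if len(steps) and not np.all(steps == steps[0]):
        raise ValueError("R wavelengths are not evenly spaced")
    grid = WavelengthGrid(
        wavelengths[0], wavelengths[-1], int(steps[0]) if len(steps) else 1
    )

    has_t = bool(t_cols)
    if has_t and [w for w, _ in t_cols] != wavelengths:
        raise ValueError("T wavelength columns do not match R columns")

    r_mat = df[[c for _, c in r_cols]].to_numpy(dtype=float)
    t_mat = df[[c for _, c in t_cols]].to_numpy(dtype=float) if has_t else None
    if np.nanmax(r_mat) > PERCENT_SCALE_THRESHOLD or (
        has_t and np.nanmax(t_mat) > PERCENT_SCALE_THRESHOLD
    ):
        raise ValueError(
            "spectral values exceed 1.5; file looks percent-scaled -- "
            "divide by 100 to obtain fractional units before loading"
        )

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            LeafSpectralRecord(
                sample_id=str(row.sample_id),
                group_label=str(row.group),
                R=r_mat[i].copy(),
                T=t_mat[i].copy() if has_t else None,
            )
        )
    return SpectralDataset(grid=grid, records=records, provenance=str(path))


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    """Write the wide-layout spectra CSV (R and, if present, T channels)."""
    wl = dataset.grid.wavelengths()
    data = {
        "sample_id": dataset.sample_ids,
        "group": dataset.group_labels,
    }
    r_mat = dataset.reflectance_matrix()
    for j, w in enumerate(wl):
        data[f"R_{w}"] = r_mat[:, j]
    if not dataset.reflectance_only:
        t_mat = dataset.transmittance_matrix()
        for j, w in enumerate(wl):
            data[f"T_{w}"] = t_mat[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
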