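"""Readers, writers and normalizations for melting matrices and SAS curves.

A *melting matrix* arranges a temperature series of spectra as a single
real matrix: the spectral variable (wavelength in nm for circular
dichroism, Raman shift in cm^-1 for UV resonance Raman) runs down the
rows, temperature runs across the columns, so each column is one spectrum
at a fixed temperature and each row is a single-wavelength melting
profile.  Small-angle scattering curves are the usual 3-column
(Q, I, sigma) text files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Probe",
    "MeltingMatrix",
    "SASCurve",
    "read_melting_matrix",
    "write_melting_matrix",
    "normalize_cd",
    "normalize_uvrr",
    "read_sas_curve",
    "write_sas_curve",
]


class Probe(str, enum.Enum):
    """Spectroscopic probe that produced a melting matrix."""

    CD = "cd"
    UVRR = "uvrr"


class FormatError(ValueError):
    """Raised when a file does not parse as the documented dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


class StateError(RuntimeError):
    """Raised on an operation invalid for the object's current state."""


@dataclass(frozen=True)
class MeltingMatrix:
    """Spectra-by-temperature matrix with its two axes.

    Parameters
    ----------
    values : (n_axis, n_temp) array
        Signal; rows follow ``axis``, columns follow ``temperatures``.
    axis : (n_axis,) array
        Spectral positions (nm for CD, cm^-1 for UVRR).
    temperatures : (n_temp,) array
        Column temperatures in deg C, strictly increasing.
    probe : Probe
        Which spectroscopy produced the data.
    normalized : bool
        Whether a concentration/path-length (CD) or OH-band (UVRR)
        normalization has already been applied.
    unit : str
        Free-form signal unit label (carried as metadata, not enforced).
    """

    values: np.ndarray
    axis: np.ndarray
    temperatures: np.ndarray
    probe: Probe
    normalized: bool = False
    unit: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(
            self, "temperatures", np.asarray(self.temperatures, dtype=float)
        )
        object.__setattr__(self, "probe", Probe(self.probe))
        v, ax, t = self.values, self.axis, self.temperatures
        if v.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if v.shape != (ax.size, t.size):
            raise ValidationError(
                f"shape mismatch: values {v.shape} vs axis {ax.size} x temps {t.size}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("matrix contains non-finite entries")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(t))):
            raise ValidationError("axes must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def profile(self, position: float) -> tuple[float, np.ndarray]:
        """Melting profile at the axis point nearest ``position``.

        Returns the snapped axis value and the row of ``values``.
        """
        i = int(np.argmin(np.abs(self.axis - position)))
        return float(self.axis[i]), self.values[i]


@dataclass(frozen=True)
class SASCurve:
    """Small-angle scattering curve I(Q) with per-point uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    absolute_scale: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        q, i, s = self.q, self.intensity, self.sigma
        if not (q.shape == i.shape == s.shape) or q.ndim != 1:
            raise ValidationError("q, intensity, sigma must be equal-length vectors")
        if q.size and (np.any(q <= 0) or not np.all(np.diff(q) > 0)):
            raise ValidationError("q must be positive and strictly increasing")
        if np.any(s <= 0):
            raise ValidationError("sigma must be positive")
        if not np.all(np.isfinite(i)):
            raise ValidationError("intensity contains non-finite entries")

    def __len__(self) -> int:
        return self.q.size


# ---------------------------------------------------------------------------
# melting matrix file dialect: one header row of temperatures (first cell
# blank or a label), first column the spectral axis, whitespace/comma
# delimited, '#' comments ignored.
# ---------------------------------------------------------------------------


def _split(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.replace(",", " ").split()
    return [tok.strip() for tok in line.split(delimiter)]


def read_melting_matrix(
    path,
    probe: Probe | str,
    delimiter: str | None = None,
    normalized: bool = False,
    unit: str = "",
) -> MeltingMatrix:
    """Read a melting matrix from delimited text.

    The first non-comment row holds the temperatures (an optional leading
    label cell is tolerated); each following row is ``axis_value`` then one
    signal value per temperature.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")

    header = _split(rows[0], delimiter)
    # header may carry a leading axis-label cell; detect by float-parsability
    try:
        float(header[0])
        temps = [float(tok) for tok in header]
    except ValueError:
        temps = [float(tok) for tok in header[1:]]

    axis, data = [], []
    for ln in rows[1:]:
        toks = _split(ln, delimiter)
        if len(toks) != len(temps) + 1:
            raise FormatError(
                f"{path}: ragged row with {len(toks)} fields, expected {len(temps) + 1}"
            )
        try:
            vals = [float(tok) for tok in toks]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric field ({exc})") from exc
        axis.append(vals[0])
        data.append(vals[1:])

    return MeltingMatrix(
        values=np.array(data, dtype=float),
        axis=np.array(axis, dtype=float),
        temperatures=np.array(temps, dtype=float),
        probe=Probe(probe),
        normalized=normalized,
        unit=unit,
    )


def write_melting_matrix(m: MeltingMatrix, path, delimiter: str = "\t") -> None:
    """Write a melting matrix in the dialect :func:`read_melting_matrix` reads.

    Values are written with ``repr`` precision so a read/write cycle is
    bit-preserving.
    """
    with open(path, "w") as fh:
        fh.write(f"# probe={m.probe.value} normalized={m.normalized} unit={m.unit}\n")
        fh.write(
            "axis" + delimiter + delimiter.join(repr(float(t)) for t in m.temperatures)
        )
        fh.write("\n")
        for a, row in zip(m.axis, m.values):
            fh.write(
                repr(float(a))
                + delimiter
                + delimiter.join(repr(float(v)) for v in row)
            )
            fh.write("\n")


def normalize_cd(
    m: MeltingMatrix, strand_conc: float, path_length: float
) -> MeltingMatrix:
    """Normalize CD ellipticity to strand concentration and path length.

    Divides every entry by ``strand_conc * path_length`` (per-strand molar
    ellipticity convention for the full oligomer; no mean-residue scaling).

    Parameters
    ----------
    strand_conc : float
        Strand concentration in mol/L, > 0.
    path_length : float
        Cuvette path length in cm, > 0.
    """
    if m.probe is not Probe.CD:
        raise ValidationError("normalize_cd requires a CD matrix")
    if m.normalized:
        raise StateError("matrix already normalized; refusing to normalize twice")
    if strand_conc <= 0 or path_length <= 0:
        raise ValidationError("strand_conc and path_length must be > 0")
    scale = strand_conc * path_length
    return replace(
        m,
        values=m.values / scale,
        normalized=True,
        unit=(m.unit + "/(M cm)").lstrip("/") if m.unit else "per M cm",
    )


def oh_band_area(
    axis: np.ndarray, column: np.ndarray, window: tuple[float, float]
) -> float:
    """Trapezoidal integral of one spectrum over ``window`` on its axis."""
    lo, hi = min(window), max(window)
    sel = (axis >= lo) & (axis <= hi)
    if sel.sum() < 2:
        raise ValidationError(f"window {window} covers <2 axis points")
    return float(np.trapezoid(column[sel], axis[sel]))


def normalize_uvrr(
    m: MeltingMatrix,
    oh_band_window: tuple[float, float] = (3100.0, 3700.0),
    reference_area: float = 1.0,
    external_areas: np.ndarray | None = None,
) -> MeltingMatrix:
    """Normalize UVRR spectra column-wise to the water OH stretching band.

    Every temperature column is scaled so that its integrated area over the
    OH-band window (default 3100-3700 cm^-1, around the ~3400 cm^-1 water
    band) equals ``reference_area``.  When the stored axis does not reach
    the OH band — the usual case for matrices trimmed to the nucleobase
    fingerprint region — per-column areas measured externally may be
    supplied via ``external_areas``.
    """
    if m.probe is not Probe.UVRR:
        raise ValidationError("normalize_uvrr requires a UVRR matrix")
    if m.normalized:
        raise StateError("matrix already normalized; refusing to normalize twice")
    if reference_area <= 0:
        raise ValidationError("reference_area must be > 0")

    if external_areas is not None:
        areas = np.asarray(external_areas, dtype=float)
        if areas.shape != m.temperatures.shape:
            raise ValidationError("external_areas must have one value per column")
    else:
        lo, hi = min(oh_band_window), max(oh_band_window)
        if hi < m.axis.min() or lo > m.axis.max():
            raise ValidationError(
                "OH-band window outside the stored axis and no external areas given"
            )
        areas = np.array(
            [oh_band_area(m.axis, col, oh_band_window) for col in m.values.T]
        )
    if np.any(areas <= 0):
        raise ValidationError("non-positive OH-band area")
    return replace(
        m,
        values=m.values * (reference_area / areas)[np.newaxis, :],
        normalized=True,
    )


def read_sas_curve(
    path,
    absolute: bool = False,
    default_relative_sigma: float | None = None,
) -> SASCurve:
    """Read a 3-column (Q, I, sigma) scattering curve from text.

    Whitespace or comma delimited; lines starting with ``#`` are comments.
    A 2-column file is accepted only when ``default_relative_sigma`` gives
    an explicit relative-uncertainty policy for the missing column.
    """
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            rows.append([float(tok) for tok in _split(ln, None)])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError(f"{path}: ragged rows")
    arr = np.array(rows, dtype=float)
    if ncol >= 3:
        q, i, s = arr[:, 0], arr[:, 1], arr[:, 2]
    elif ncol == 2:
        if default_relative_sigma is None:
            raise FormatError(
                f"{path}: sigma column missing; pass default_relative_sigma "
                "to adopt a relative-uncertainty policy explicitly"
            )
        q, i = arr[:, 0], arr[:, 1]
        s = default_relative_sigma * np.abs(i)
    else:
        raise FormatError(f"{path}: expected 2 or 3 columns, found {ncol}")
    return SASCurve(q=q, intensity=i, sigma=s, absolute_scale=absolute)


def write_sas_curve(curve: SASCurve, path) -> None:
    """Write a curve as 3-column text, full precision, '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# absolute_scale={curve.absolute_scale}\n")
        fh.write("# q(1/A) I sigma\n")
        for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{float(q)!r} {float(i)!r} {float(s)!r}\n")
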