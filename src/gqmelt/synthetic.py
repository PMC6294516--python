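"""Synthetic melting matrices and scattering curves.

The generator builds data with exactly the statistical structure the
downstream analysis assumes: melting matrices are a species-spectra
basis weighted by sequential-model populations plus additive iid
Gaussian noise, and scattering curves are a monomer/dimer mixture
intensity with multiplicative Gaussian noise (the counting-dominated
regime of a SANS/SAXS measurement).  Everything is deterministic for a
fixed seed.

Default grids follow the study protocols this package models: CD-like
matrices span 220-325 nm over 30-82 C in 2 C steps; UVRR-like matrices
span 1000-1800 cm^-1 over 30-90 C in 4 C steps; scattering curves cover
Q = 0.02-1 1/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .melting import SequentialModelParams, sequential_populations
from .sas import MixtureModel, mixture_intensity
from .spectra_io import MeltingMatrix, Probe, SASCurve, ValidationError

__all__ = [
    "SpeciesSpectrum",
    "SyntheticSpec",
    "make_species_spectra",
    "generate_melting_matrix",
    "generate_sas_curve",
    "cd_axis",
    "uvrr_axis",
    "cd_temperatures",
    "uvrr_temperatures",
    "TEL22_CD_PARAMS",
    "TEL22_SEQUENCE",
]

#: human telomeric 22-mer AG3(TTAG3)3
TEL22_SEQUENCE = "AGGGTTAGGGTTAGGGTTAGGG"

#: sequential-model parameters for the free quadruplex melting seen by CD
#: (three steps N <-> I1 <-> I2 <-> U); enthalpies carry the reported
#: negative sign, midpoints in deg C.
TEL22_CD_PARAMS = SequentialModelParams(
    dH=(-27.3, -41.0, -63.2), Tm=(38.5, 60.3, 68.9)
)

#: two-step analog resolved by the UVRR probe (N <-> I1 <-> U).
TEL22_UVRR_PARAMS = SequentialModelParams(dH=(-34.5, -72.6), Tm=(44.5, 71.4))


def cd_axis(step: float = 1.0) -> np.ndarray:
    """Default CD wavelength axis, 220-325 nm."""
    return np.arange(220.0, 325.0 + step / 2, step)


def uvrr_axis(step: float = 2.0) -> np.ndarray:
    """Default UVRR Raman-shift axis, 1000-1800 cm^-1."""
    return np.arange(1000.0, 1800.0 + step / 2, step)


def cd_temperatures() -> np.ndarray:
    """CD melting protocol: 30-82 C in 2 C steps."""
    return np.arange(30.0, 82.0 + 1.0, 2.0)


def uvrr_temperatures() -> np.ndarray:
    """UVRR melting protocol: 30-90 C in 4 C steps."""
    return np.arange(30.0, 90.0 + 1.0, 4.0)


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Pure-species spectrum on a fixed axis."""

    axis: np.ndarray
    amplitude: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(self, "amplitude", np.asarray(self.amplitude, dtype=float))
        if self.axis.shape != self.amplitude.shape or self.axis.ndim != 1:
            raise ValidationError("axis and amplitude must be equal-length vectors")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValidationError("amplitude must be finite")


def _gauss_sum(axis: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    y = np.zeros_like(axis)
    for center, width, height in bands:
        y += height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return y


# CD presets (nm): band positions follow the canonical quadruplex CD
# signatures — hybrid folds show a positive ~290 nm band with a ~270 nm
# shoulder and a negative ~233 nm band; parallel folds a positive ~265 nm
# band with a ~245 nm minimum; the unfolded strand is nearly featureless.
_CD_PRESETS = {
    "hybrid": [(290.0, 9.0, 5.0), (270.0, 9.0, 2.6), (233.0, 7.0, -3.2)],
    "parallel": [(264.0, 9.0, 5.5), (245.0, 7.0, -3.0)],
    "unfolded": [(257.0, 14.0, 0.9), (238.0, 9.0, -0.35)],
}

# UVRR presets (cm^-1): guanine in-plane bands A/B/C at 1482/1578/1611
# plus the thymine band at 1370.  Stacked tetrads suppress resonance
# Raman intensity (hypochromism), so the folded spectrum is the weakest;
# unfolding raises A and B, downshifts B to ~1574 and C to ~1606.
_UVRR_PRESETS = {
    "hybrid": [  # folded quadruplex
        (1370.0, 11.0, 0.55),
        (1482.0, 10.0, 1.00),
        (1578.0, 11.0, 0.80),
        (1611.0, 9.0, 0.60),
    ],
    "parallel": [  # intermediate: partial unstacking plus its own markers —
        # suppressed thymine band, narrowed upshifted A band, and extra
        # adenine-region intensity near 1335/1530 — so the three-species
        # basis is genuinely three-dimensional, not an interpolation
        (1335.0, 10.0, 0.35),
        (1370.0, 11.0, 0.30),
        (1488.0, 9.0, 1.30),
        (1576.0, 11.0, 0.95),
        (1609.0, 9.0, 0.70),
        (1530.0, 9.0, 0.25),
    ],
    "unfolded": [
        (1370.0, 11.0, 0.60),
        (1482.0, 10.0, 1.60),
        (1574.0, 11.0, 1.20),
        (1606.0, 9.0, 0.75),
    ],
}


def make_species_spectra(
    probe: Probe | str,
    axis: np.ndarray,
    preset: str,
    bands: list[tuple[float, float, float]] | None = None,
    label: str = "",
) -> SpeciesSpectrum:
    """Build a pure-species spectrum as a sum of Gaussian bands.

    ``preset`` is one of ``hybrid``, ``parallel``, ``unfolded`` (band
    tables depend on the probe) or ``custom``, which requires an explicit
    ``bands`` list of (center, width, height) triples.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValidationError("axis must be increasing")
    probe = Probe(probe)
    if preset == "custom":
        if not bands:
            raise ValidationError("custom preset requires explicit bands")
        table = list(bands)
    else:
        presets = _CD_PRESETS if probe is Probe.CD else _UVRR_PRESETS
        if preset not in presets:
            raise ValidationError(
                f"unknown preset {preset!r}; choose from {sorted(presets)} or 'custom'"
            )
        table = presets[preset]
    return SpeciesSpectrum(
        axis=axis, amplitude=_gauss_sum(axis, table), label=label or preset
    )


def default_cd_species(axis: np.ndarray | None = None) -> list[SpeciesSpectrum]:
    """Four-species basis (N, I1, I2, U) for CD-like melting matrices.

    N is hybrid-like; the intermediates interpolate toward the unfolded
    signature with a growing ~264 nm shoulder and a deepening, red
    shifting low-wavelength minimum, keeping the four spectra linearly
    independent.
    """
    axis = cd_axis() if axis is None else np.asarray(axis, dtype=float)
    n = make_species_spectra(Probe.CD, axis, "hybrid", label="N")
    u = make_species_spectra(Probe.CD, axis, "unfolded", label="U")
    # each intermediate carries marker bands in regions where N and U are
    # weak, so the four spectra span a genuinely four-dimensional space and
    # the fourth melting component sits above a few-percent noise floor —
    # the detectability regime in which a four-species analysis operates
    i1 = SpeciesSpectrum(
        axis=axis,
        amplitude=_gauss_sum(
            axis,
            [
                (291.0, 8.0, 4.3),
                (268.0, 8.0, 3.2),
                (235.0, 7.0, -3.8),
                (249.0, 4.5, -2.0),
                (304.0, 5.0, 1.6),
            ],
        ),
        label="I1",
    )
    i2 = SpeciesSpectrum(
        axis=axis,
        amplitude=_gauss_sum(
            axis,
            [
                (287.0, 9.0, 2.5),
                (259.0, 8.0, 3.0),
                (243.0, 6.0, -2.8),
                (300.0, 4.5, -1.2),
                (225.0, 5.0, -2.0),
                (272.0, 4.0, 1.2),
            ],
        ),
        label="I2",
    )
    return [n, i1, i2, u]


def default_uvrr_species(axis: np.ndarray | None = None) -> list[SpeciesSpectrum]:
    """Three-species basis (N, I1, U) for UVRR-like melting matrices."""
    axis = uvrr_axis() if axis is None else np.asarray(axis, dtype=float)
    return [
        make_species_spectra(Probe.UVRR, axis, "hybrid", label="N"),
        make_species_spectra(Probe.UVRR, axis, "parallel", label="I1"),
        make_species_spectra(Probe.UVRR, axis, "unfolded", label="U"),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic melting matrix."""

    model: SequentialModelParams
    species_spectra: list[SpeciesSpectrum]
    temperatures: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    probe: Probe = Probe.CD

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "temperatures", np.asarray(self.temperatures, dtype=float)
        )
        object.__setattr__(self, "probe", Probe(self.probe))
        if len(self.species_spectra) != self.model.steps + 1:
            raise ValidationError(
                f"{self.model.steps}-step model needs {self.model.steps + 1} "
                f"species spectra, got {len(self.species_spectra)}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        ax0 = self.species_spectra[0].axis
        for sp in self.species_spectra[1:]:
            if not np.array_equal(sp.axis, ax0):
                raise ValidationError("all species spectra must share one axis")


def generate_melting_matrix(spec: SyntheticSpec) -> MeltingMatrix:
    """Melting matrix A = E F^T + noise from a synthetic recipe.

    E stacks the species spectra as columns, F holds the sequential-model
    populations at the requested temperatures, and the noise is iid
    Gaussian with standard deviation ``noise_sd`` (same units as the
    spectra).  Bitwise deterministic for a fixed spec and seed.
    """
    E = np.column_stack([sp.amplitude for sp in spec.species_spectra])
    F = sequential_populations(spec.model, spec.temperatures)  # (nT, n_species)
    clean = E @ F.T
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return MeltingMatrix(
        values=clean,
        axis=spec.species_spectra[0].axis,
        temperatures=spec.temperatures,
        probe=spec.probe,
    )


def default_q_grid(n: int = 120) -> np.ndarray:
    """Logarithmic Q grid over the study window 0.02-1 1/A."""
    return np.geomspace(0.02, 1.0, n)


def generate_sas_curve(
    model: MixtureModel,
    q: np.ndarray | None = None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> SASCurve:
    """Noisy scattering curve from a monomer/dimer mixture model.

    Intensities are the exact mixture intensity times (1 + eta) with eta
    iid Gaussian(0, noise_frac); the quoted sigma is noise_frac times the
    model intensity.  At ``noise_frac = 0`` the curve is exact and sigma
    falls back to a nominal 1% of the model intensity so the curve stays
    usable in weighted fits.
    """
    if noise_frac < 0:
        raise ValidationError("noise_frac must be >= 0")
    q = default_q_grid() if q is None else np.asarray(q, dtype=float)
    if np.any(q <= 0) or not np.all(np.diff(q) > 0):
        raise ValidationError("q must be positive increasing")
    ideal = mixture_intensity(q, model)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        intensity = ideal * (1.0 + rng.normal(0.0, noise_frac, size=q.shape))
        sigma = noise_frac * ideal
    else:
        intensity = ideal.copy()
        sigma = 0.01 * ideal
    return SASCurve(q=q, intensity=intensity, sigma=sigma)
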