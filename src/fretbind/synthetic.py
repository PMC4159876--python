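"""Seeded generators of synthetic spectra, quenching titrations and FRET
dilution series.

Every generator is a pure function of its spec (including the seed):
calling it twice yields bitwise-identical output. The generators emulate
the statistical structure the analysis assumes — smooth single-band
Gaussian spectra, saturating single-site quench titrations with
Beer-Lambert inner-filter absorbances and additive Gaussian detector
noise — so every pipeline stage can be exercised and round-tripped without
an experimental file. They do not emulate real fluorophore lineshapes
(vibronic shoulders, Stokes-shift asymmetry) or photophysics (bleaching,
triplet states), so agreement on synthetic data validates the estimators,
not any instrument-specific value of J.

Default parameters reproduce the study conditions of the donor/acceptor
pair the package was built around: a donor emission band at 520 nm, an
acceptor absorption band at 556 nm with peak extinction
41,955 M^-1 cm^-1, and titrations of a 5 µM receptor with ligand up to
20 µM, true Kd 1.0 µM, plateau quench fraction 0.47 and 3% additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import (
    DEFAULT_EPS_EXC,
    DEFAULT_EPS_EM,
    DEFAULT_PATH_EM_CM,
    DEFAULT_PATH_EXC_CM,
    TitrationPoint,
    TitrationSeries,
    binding_model,
)
from .spectra import Spectrum

#: Ligand concentrations (µM) of the default 12-point titration, 0-20 µM
#: against a 5 µM receptor: dense below Kd, sparse toward saturation.
DEFAULT_LIGAND_CONCS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of a synthetic Gaussian spectral band."""

    center: float  # nm
    width: float  # nm, Gaussian sigma
    peak_value: float  # intensity or M^-1 cm^-1
    grid: tuple[float, float, float]  # (start, stop, step) nm
    kind: str = "emission"
    label: str = ""

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not step > 0:
            raise ValueError("grid step must be positive")
        if not start < stop:
            raise ValueError("grid start must be below stop")
        if not self.peak_value > 0:
            raise ValueError("peak_value must be positive")


@dataclass(frozen=True)
class TitrationSpec:
    """Parameters of a synthetic quenching titration.

    ``true_Fmax`` is the plateau of the normalized quench signal
    S = (F0 - F_corr)/F0, i.e. the fraction of baseline fluorescence lost
    at saturation; it must lie in (0, 1]. ``noise_sd`` is the additive
    Gaussian noise standard deviation as a fraction of the plateau.
    ``f0`` is the corrected zero-ligand intensity in arbitrary units.
    """

    true_Kd: float = 1.0  # µM
    true_Fmax: float = 0.47
    n: float = 1.0
    receptor_total: float = 5.0  # µM
    ligand_concs: tuple[float, ...] = DEFAULT_LIGAND_CONCS
    noise_sd: float = 0.03
    noise_model: str = "additive"  # or "multiplicative"
    eps_exc: float = DEFAULT_EPS_EXC
    eps_em: float = DEFAULT_EPS_EM
    path_exc: float = DEFAULT_PATH_EXC_CM
    path_em: float = DEFAULT_PATH_EM_CM
    f0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(c < 0 for c in self.ligand_concs):
            raise ValueError("ligand concentrations must be >= 0")
        if not 0 < self.true_Fmax <= 1:
            raise ValueError("true_Fmax is a quench fraction and must lie in (0, 1]")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")
        if not (self.true_Kd > 0 and self.n > 0 and self.receptor_total > 0 and self.f0 > 0):
            raise ValueError("true_Kd, n, receptor_total and f0 must be positive")


def gen_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Gaussian band sampled on the requested grid.

    The band is rescaled so the value at the grid point nearest
    ``spec.center`` equals ``spec.peak_value`` exactly.
    """
    start, stop, step = spec.grid
    wl = np.arange(start, stop + step / 2, step)
    vals = np.exp(-((wl - spec.center) ** 2) / (2.0 * spec.width**2))
    nearest = int(np.argmin(np.abs(wl - spec.center)))
    vals = vals * (spec.peak_value / vals[nearest])
    return Spectrum(wl, vals, kind=spec.kind, label=spec.label or f"gaussian@{spec.center}nm")


def gen_titration(spec: TitrationSpec) -> TitrationSeries:
    """Synthetic quenching titration with inner-filter attenuation.

    The noiseless quench signal follows the depletion-corrected quadratic
    single-site model; corrected intensities ``F_corr = f0 * (1 - S)`` are
    de-corrected through the inverse inner-filter factor (with
    Beer-Lambert absorbances A = eps * c over 1 cm) to produce the
    "observed" intensities, then seeded Gaussian noise is added. The
    round trip through :func:`fretbind.binding.fit_binding` therefore
    recovers ``true_Kd`` exactly in the noiseless limit.
    """
    rng = np.random.default_rng(spec.seed)
    L = np.asarray(spec.ligand_concs, dtype=float)
    s_true = binding_model(
        L,
        Kd=spec.true_Kd,
        F_max=spec.true_Fmax,
        n=spec.n,
        receptor_total=spec.receptor_total,
        model="quadratic_depletion",
    )
    f_corr = spec.f0 * (1.0 - np.atleast_1d(s_true))
    a_exc = spec.eps_exc * L * 1e-6
    a_em = spec.eps_em * L * 1e-6
    factor = 10.0 ** ((a_exc * spec.path_exc + a_em * spec.path_em) / 2.0)
    f_obs = f_corr / factor
    noise = rng.normal(0.0, 1.0, size=L.size)
    if spec.noise_model == "additive":
        f_obs = f_obs + spec.noise_sd * spec.true_Fmax * spec.f0 * noise
    else:
        f_obs = f_obs * (1.0 + spec.noise_sd * noise)
    f_obs = np.clip(f_obs, 0.0, None)
    points = tuple(
        TitrationPoint(
            ligand_total=float(l),
            F_obs=float(f),
            A_exc=float(ax),
            A_em_1cm=float(ae),
        )
        for l, f, ax, ae in zip(L, f_obs, a_exc, a_em)
    )
    return TitrationSeries(
        points,
        receptor_total=spec.receptor_total,
        path_exc=spec.path_exc,
        path_em=spec.path_em,
        eps_exc=spec.eps_exc,
        eps_em=spec.eps_em,
    )


def gen_fret_series(
    E_true: float,
    spec: TitrationSpec,
    occupancy_model: str = "hyperbolic",
) -> pd.DataFrame:
    """Donor intensities without/with acceptor along an acceptor titration.

    The observed donor quench scales with the fraction of donor sites
    carrying a bound acceptor, ``F_AD / F_D = 1 - E_true * theta(L)``,
    with theta from the single-site binding model evaluated at the total
    acceptor concentrations of ``spec``. With hyperbolic occupancy
    (default), 1/theta is exactly affine in 1/L, so the double-reciprocal
    extrapolation of :mod:`fretbind.fret` recovers ``E_true`` exactly in
    the noiseless limit; depletion-quadratic occupancy is available for
    realism at the cost of slight curvature in the transformed plot.

    Returns a DataFrame with columns ``acceptor_conc_uM``, ``F_D``,
    ``F_AD``. Seeded Gaussian noise (``spec.noise_sd`` fractional) is
    applied to F_AD when nonzero.
    """
    if not 0 < E_true < 1:
        raise ValueError("E_true must lie strictly inside (0, 1)")
    rng = np.random.default_rng(spec.seed)
    L = np.asarray(spec.ligand_concs, dtype=float)
    theta = np.where(
        L > 0,
        binding_model(
            np.clip(L, 1e-30, None),
            Kd=spec.true_Kd,
            F_max=1.0,
            n=spec.n,
            receptor_total=spec.receptor_total,
            model="quadratic_depletion" if occupancy_model == "quadratic_depletion" else "hyperbolic",
        ),
        0.0,
    )
    f_d = np.full(L.size, spec.f0)
    f_ad = spec.f0 * (1.0 - E_true * theta)
    if spec.noise_sd > 0:
        f_ad = f_ad * (1.0 + spec.noise_sd * rng.normal(0.0, 1.0, size=L.size))
        f_ad = np.clip(f_ad, 0.0, None)
    return pd.DataFrame({"acceptor_conc_uM": L, "F_D": f_d, "F_AD": f_ad})
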