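"""Spectrum container, spectrum file I/O, and spectral integrals.

The quantities computed here feed the Förster-radius calculation in
:mod:`fretbind.fret`:

* the spectral overlap integral

  .. math::

     J = \\frac{\\int F_D(\\lambda)\\,\\varepsilon_A(\\lambda)\\,
     \\lambda^4\\,d\\lambda}{\\int F_D(\\lambda)\\,d\\lambda}

  between the donor emission spectrum ``F_D`` (arbitrary intensity units)
  and the acceptor molar extinction spectrum ``epsilon_A``
  (M^-1 cm^-1), carried internally in M^-1 cm^-1 nm^4 (the convention of
  the 0.211 Förster-radius prefactor) with explicit converters to the
  M^-1 cm^3 convention;

* the relative fluorescence quantum yield against a standard of known
  yield, corrected for absorbance and refractive index.

Spectrum files are plain delimited text (comma, tab or whitespace;
auto-detected) with wavelength in nm in the first column and the spectral
value in the second; a single header line is tolerated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid spectrum kinds. ``emission``/``excitation`` carry arbitrary
#: intensity units, ``extinction`` is in M^-1 cm^-1 and ``absorption`` is a
#: dimensionless absorbance.
SPECTRUM_KINDS = ("emission", "excitation", "absorption", "extinction")


class SpectrumFormatError(ValueError):
    """A spectrum file contains rows that cannot be parsed as two numbers."""


@dataclass(frozen=True)
class Spectrum:
    """An immutable sampled spectrum on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths : array-like of float
        Wavelength grid in nm, strictly increasing, at least two points.
    values : array-like of float
        Non-negative spectral values, one per wavelength. Interpretation
        depends on ``kind`` (intensity, absorbance, or extinction
        coefficient).
    kind : str
        One of :data:`SPECTRUM_KINDS`. Immutable after construction.
    label : str
        Free-text description used in reports.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays")
        if wl.size != vals.size:
            raise ValueError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("spectrum contains non-finite entries")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError(
                "spectral values must be non-negative; clamp baseline noise on load"
            )
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        wl = wl.copy()
        vals = vals.copy()
        wl.flags.writeable = False
        vals.flags.writeable = False
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def support(self) -> tuple[float, float]:
        """(min, max) wavelength of the sampled grid, in nm."""
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def area(self) -> float:
        """Trapezoidal integral of the spectrum over its grid."""
        return float(np.trapezoid(self.values, self.wavelengths))


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def read_spectrum(
    path: str | Path,
    kind: str,
    delimiter: str | None = None,
    label: str | None = None,
) -> Spectrum:
    """Read a two-column delimited spectrum file.

    Rows are sorted by wavelength; duplicate wavelengths are collapsed by
    averaging their values; negative values (baseline noise) are clamped to
    zero with a logged count. A single leading header line is tolerated.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SpectrumFormatError
        If a non-header row cannot be parsed as two numbers.
    ValueError
        If fewer than 2 usable points remain.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"spectrum file not found: {p}")
    lines = [
        ln for ln in p.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"spectrum file {p} is empty: fewer than 2 usable points")
    sep = delimiter or _sniff_delimiter(lines[0] if len(lines) == 1 else lines[1])
    rows: list[tuple[float, float]] = []
    for i, ln in enumerate(lines):
        parts = ln.split(sep) if sep else ln.split()
        parts = [s for s in (s.strip() for s in parts) if s]
        try:
            wl, val = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if i == 0:  # header line
                continue
            raise SpectrumFormatError(
                f"{p}, line {i + 1}: expected two numeric columns, got {ln!r}"
            ) from None
        rows.append((wl, val))
    if len(rows) < 2:
        raise ValueError(f"spectrum file {p} has fewer than 2 usable points")

    df = pd.DataFrame(rows, columns=["wl", "val"])
    df = df.groupby("wl", as_index=False, sort=True)["val"].mean()
    vals = df["val"].to_numpy()
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.warning("%s: clamped %d negative value(s) to 0", p, n_neg)
        vals = np.clip(vals, 0.0, None)
    return Spectrum(df["wl"].to_numpy(), vals, kind=kind, label=label or p.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with a header line."""
    p = Path(path)
    header = delimiter.join(["wavelength_nm", "value"])
    body = "\n".join(
        f"{wl:.6g}{delimiter}{val:.10g}"
        for wl, val in zip(spectrum.wavelengths, spectrum.values)
    )
    p.write_text(header + "\n" + body + "\n")


def normalize(spectrum: Spectrum, mode: str = "peak") -> Spectrum:
    """Rescale a spectrum so its peak is 1 (``mode='peak'``) or its
    trapezoidal area is 1 (``mode='area'``). Wavelengths are unchanged.
    """
    if mode not in ("peak", "area"):
        raise ValueError(f"mode must be 'peak' or 'area', got {mode!r}")
    scale = float(spectrum.values.max()) if mode == "peak" else spectrum.area()
    if scale <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(
        spectrum.wavelengths, spectrum.values / scale, kind=spectrum.kind, label=spectrum.label
    )


def resample(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (nm, strictly increasing).

    Values outside the spectrum's sampled support are zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resampling grid is empty")
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values, left=0.0, right=0.0)
    return Spectrum(grid, vals, kind=spectrum.kind, label=spectrum.label)


def overlap_integral(
    donor_emission: Spectrum, acceptor_extinction: Spectrum, step: float = 0.5
) -> float:
    """Spectral overlap integral J in M^-1 cm^-1 nm^4.

    Both spectra are linearly interpolated (zero outside their support) onto
    a common grid of spacing ``step`` nm spanning the union of their
    supports, and the ratio of trapezoidal integrals

    ``J = trapz(F_D * eps_A * lambda^4) / trapz(F_D)``

    is returned. The result is invariant under any positive rescaling of
    the donor emission spectrum.

    Use :func:`j_nm4_to_cm3` for the M^-1 cm^3 convention.
    """
    if donor_emission.kind != "emission":
        raise ValueError(f"donor spectrum must have kind='emission', got {donor_emission.kind!r}")
    if acceptor_extinction.kind != "extinction":
        raise ValueError(
            f"acceptor spectrum must have kind='extinction', got {acceptor_extinction.kind!r}"
        )
    if step <= 0:
        raise ValueError("step must be positive")
    d_lo, d_hi = donor_emission.support
    a_lo, a_hi = acceptor_extinction.support
    if min(d_hi, a_hi) <= max(d_lo, a_lo):
        raise ValueError(
            f"donor support [{d_lo}, {d_hi}] nm and acceptor support "
            f"[{a_lo}, {a_hi}] nm are disjoint"
        )
    lo, hi = min(d_lo, a_lo), max(d_hi, a_hi)
    grid = np.arange(lo, hi + step / 2, step)
    fd = np.interp(grid, donor_emission.wavelengths, donor_emission.values, left=0.0, right=0.0)
    ea = np.interp(
        grid, acceptor_extinction.wavelengths, acceptor_extinction.values, left=0.0, right=0.0
    )
    denom = np.trapezoid(fd, grid)
    if denom <= 0:
        raise ValueError("donor emission integrates to zero over the common grid")
    num = np.trapezoid(fd * ea * grid**4, grid)
    return float(num / denom)


def j_nm4_to_cm3(j_nm4: float) -> float:
    """Convert an overlap integral from M^-1 cm^-1 nm^4 to M^-1 cm^3."""
    return j_nm4 * 1e-28


def j_cm3_to_nm4(j_cm3: float) -> float:
    """Convert an overlap integral from M^-1 cm^3 to M^-1 cm^-1 nm^4."""
    return j_cm3 * 1e28


#: Quantum yield of the fluorescein disodium standard in 0.1 N NaOH.
FLUORESCEIN_QY_STANDARD = 0.92


@dataclass(frozen=True)
class QuantumYieldInputs:
    """Inputs of a relative quantum-yield determination.

    ``A`` is the absorbance at the excitation wavelength, ``Q`` the
    integrated area under the emission spectrum and ``eta`` the refractive
    index of the solvent; subscripts ``x`` and ``st`` refer to the unknown
    and the standard.
    """

    A_x: float
    A_st: float
    Q_x: float
    Q_st: float
    eta_x: float = 1.33
    eta_st: float = 1.33
    phi_st: float = FLUORESCEIN_QY_STANDARD

    def __post_init__(self) -> None:
        for name in ("A_x", "A_st", "Q_x", "Q_st", "eta_x", "eta_st"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.phi_st <= 1:
            raise ValueError("phi_st must lie in (0, 1]")


def quantum_yield(inputs: QuantumYieldInputs) -> float:
    """Relative fluorescence quantum yield of the unknown.

    ``phi_x = phi_st * (Q_x/Q_st) * (A_st/A_x) * (eta_x^2 / eta_st^2)``

    A result above 1 is physically impossible and is clipped to 1 with a
    warning (it indicates inconsistent absorbance/area measurements).
    """
    phi = (
        inputs.phi_st
        * (inputs.Q_x / inputs.Q_st)
        * (inputs.A_st / inputs.A_x)
        * (inputs.eta_x**2 / inputs.eta_st**2)
    )
    if phi > 1.0:
        warnings.warn(
            f"computed quantum yield {phi:.3f} exceeds 1; clipping to 1 "
            "(check absorbances and emission areas)",
            stacklevel=2,
        )
        phi = 1.0
    return float(phi)
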