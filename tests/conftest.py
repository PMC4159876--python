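import numpy as np
import pytest

from fretbind import SpectrumSpec, gen_spectrum


@pytest.fixture
def donor_emission():
    """Smooth Gaussian donor emission band peaked at 520 nm."""
    return gen_spectrum(
        SpectrumSpec(center=520.0, width=18.0, peak_value=1.0,
                     grid=(440.0, 660.0, 0.5), kind="emission")
    )


@pytest.fixture
def acceptor_extinction():
    """Gaussian acceptor extinction band: 41,955 M^-1 cm^-1 at 556 nm."""
    return gen_spectrum(
        SpectrumSpec(center=556.0, width=16.0, peak_value=41955.0,
                     grid=(440.0, 660.0, 0.5), kind="extinction")
    )


@pytest.fixture
def spectrum_file(tmp_path):
    """Write rows to a delimited spectrum file and return its path."""

    def _write(rows, delimiter=",", header=None, name="spec.csv"):
        p = tmp_path / name
        lines = [header] if header else []
        lines += [delimiter.join(str(x) for x in row) for row in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write


def fine_grid_overlap(donor, acceptor, step=0.001):
    """Independent brute-force oracle for the overlap integral.

    Direct trapezoidal quadrature of the defining ratio on a very fine
    common grid, sharing no code with the implementation under test.
    """
    lo = min(donor.wavelengths[0], acceptor.wavelengths[0])
    hi = max(donor.wavelengths[-1], acceptor.wavelengths[-1])
    lam = np.arange(lo, hi + step / 2, step)
    fd = np.interp(lam, donor.wavelengths, donor.values, left=0.0, right=0.0)
    ea = np.interp(lam, acceptor.wavelengths, acceptor.values, left=0.0, right=0.0)
    return np.trapezoid(fd * ea * lam**4, lam) / np.trapezoid(fd, lam)
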