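"""Förster radius, transfer efficiency and donor-acceptor distance.

The Förster radius is computed in the standard Å form

.. math::

   R_0 = 0.211\\,[\\kappa^2\\,\\eta^{-4}\\,\\Phi_D\\,J]^{1/6}

with the overlap integral J in M^-1 cm^-1 nm^4, kappa^2 the dipole
orientation factor (2/3 for freely rotating fluorophores), eta the
refractive index of the medium and Phi_D the donor quantum yield in the
absence of acceptor. Transfer efficiency and distance are related through
the sixth-power law E = R0^6 / (R0^6 + r^6).

The limiting efficiency at saturating acceptor is obtained from a
double-reciprocal plot of 1/E against 1/[acceptor]: the y-intercept of the
fitted line is 1/E at infinite acceptor concentration. That linear fit is
exposed as the scikit-learn style estimator
:class:`DoubleReciprocalExtrapolation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

#: Prefactor of the Å-scale Förster radius formula, J in M^-1 cm^-1 nm^4.
FORSTER_PREFACTOR = 0.211


@dataclass(frozen=True)
class ForsterParameters:
    """Photophysical parameters entering the Förster radius.

    Parameters
    ----------
    kappa2 : float
        Dipole orientation factor, in (0, 4]. 2/3 for isotropic rotation.
    eta : float
        Refractive index of the medium (1.4 for biomolecules in water).
    phi_d : float
        Donor quantum yield in the absence of acceptor, in (0, 1].
    J : float
        Spectral overlap integral in M^-1 cm^-1 nm^4
        (see :func:`fretbind.spectra.j_cm3_to_nm4`).
    """

    kappa2: float
    eta: float
    phi_d: float
    J: float

    def __post_init__(self) -> None:
        if not 0 < self.kappa2 <= 4:
            raise ValueError("kappa2 must lie in (0, 4]")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not 0 < self.phi_d <= 1:
            raise ValueError("phi_d must lie in (0, 1]")
        if not self.J > 0:
            raise ValueError("J must be positive")


def forster_radius(params: ForsterParameters) -> float:
    """Förster radius R0 in Å at which transfer efficiency is 50%."""
    return FORSTER_PREFACTOR * (
        params.kappa2 * params.eta**-4 * params.phi_d * params.J
    ) ** (1.0 / 6.0)


def efficiency_from_intensities(F_D: float, F_AD: float) -> float:
    """Transfer efficiency from donor intensity without (``F_D``) and with
    (``F_AD``) acceptor: ``E = 1 - F_AD / F_D``.

    Noisy intensities with ``F_AD`` outside ``[0, F_D]`` yield an E outside
    [0, 1]; these are clipped with a warning rather than rejected.
    """
    if not F_D > 0:
        raise ValueError("donor-only intensity F_D must be positive")
    E = 1.0 - F_AD / F_D
    if not 0.0 <= E <= 1.0:
        warnings.warn(
            f"efficiency {E:.4f} outside [0, 1] (F_AD={F_AD}, F_D={F_D}); clipping",
            stacklevel=2,
        )
        E = float(np.clip(E, 0.0, 1.0))
    return float(E)


def distance_from_efficiency(E: float, R0: float) -> float:
    """Donor-acceptor distance r = R0 (1/E - 1)^(1/6), in the units of R0."""
    if not 0 < E < 1:
        raise ValueError("E must lie strictly inside (0, 1)")
    if not R0 > 0:
        raise ValueError("R0 must be positive")
    return float(R0 * (1.0 / E - 1.0) ** (1.0 / 6.0))


def efficiency_from_distance(r: float, R0: float) -> float:
    """Transfer efficiency E = 1 / (1 + (r/R0)^6); strictly decreasing in r."""
    if not r > 0 or not R0 > 0:
        raise ValueError("r and R0 must be positive")
    return float(1.0 / (1.0 + (r / R0) ** 6))


def distance_uncertainty(E: float, se_E: float, R0: float, se_R0: float) -> float:
    """First-order (delta-method) standard error of the distance.

    Propagates independent uncertainties on E and R0 through
    r = R0 (1/E - 1)^(1/6).
    """
    r = distance_from_efficiency(E, R0)
    dr_dR0 = r / R0
    dr_dE = -R0 / 6.0 * (1.0 / E - 1.0) ** (-5.0 / 6.0) / E**2
    return float(np.hypot(dr_dR0 * se_R0, dr_dE * se_E))


@dataclass(frozen=True)
class EfficiencyFit:
    """Result of the double-reciprocal extrapolation to infinite acceptor.

    ``intercept`` is 1/E at infinite acceptor concentration, so the
    limiting efficiency is ``E_inf = 1 / intercept``; ``slope`` has units of
    µM (per reciprocal concentration). ``r2`` is the coefficient of
    determination of the line in the transformed coordinates.
    """

    slope: float
    intercept: float
    E_inf: float
    r2: float
    n_points: int
    se_intercept: float | None = None
    se_E_inf: float | None = None


class DoubleReciprocalExtrapolation(RegressorMixin, BaseEstimator):
    """Limiting FRET efficiency by linear extrapolation in 1/E vs 1/[A].

    Fits an ordinary least-squares line through the transformed points
    ``(1/[acceptor], 1/E_obs)``. The y-intercept estimates 1/E at infinite
    acceptor concentration, i.e. the efficiency with every donor site
    carrying an acceptor.

    Parameters
    ----------
    weighted : bool, default False
        If True, weight each transformed point by ``E_obs**4`` — the
        inverse delta-method variance of 1/E under homoscedastic noise on
        E — instead of the unweighted fit of the classical plotted
        procedure.

    Attributes
    ----------
    slope_, intercept_ : float
        Line coefficients in transformed coordinates.
    E_inf_ : float
        Limiting efficiency ``1 / intercept_``, in (0, 1).
    r2_ : float
        Coefficient of determination in transformed coordinates.
    se_intercept_, se_E_inf_ : float or None
        Asymptotic standard errors (None with fewer than 3 points).
    n_points_ : int
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        E = np.asarray(y, dtype=float).reshape(-1)
        if conc.size != E.size:
            raise ValueError("acceptor concentrations and efficiencies differ in length")
        if conc.size < 2:
            raise ValueError("need at least 2 points to extrapolate")
        if np.any(conc <= 0):
            raise ValueError("acceptor concentrations must be positive")
        if np.any((E <= 0) | (E >= 1)):
            raise ValueError("observed efficiencies must lie strictly inside (0, 1)")
        x = 1.0 / conc
        z = 1.0 / E
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: all acceptor concentrations equal")

        w = E**4 if self.weighted else np.ones_like(E)
        A = np.column_stack([x, np.ones_like(x)])
        Aw = A * np.sqrt(w)[:, None]
        zw = z * np.sqrt(w)
        beta, _, _, _ = np.linalg.lstsq(Aw, zw, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
        if intercept <= 1.0:
            raise ValueError(
                f"fitted intercept {intercept:.4g} <= 1 would imply a limiting "
                "efficiency >= 1; the data do not support the extrapolation"
            )
        resid = z - A @ beta
        ss_res = float(np.sum(w * resid**2))
        zbar = float(np.average(z, weights=w))
        ss_tot = float(np.sum(w * (z - zbar) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.slope_ = slope
        self.intercept_ = intercept
        self.E_inf_ = 1.0 / intercept
        self.n_points_ = int(conc.size)
        if conc.size > 2:
            dof = conc.size - 2
            s2 = ss_res / dof
            cov = s2 * np.linalg.inv(Aw.T @ Aw)
            self.se_intercept_ = float(np.sqrt(cov[1, 1]))
            # delta method: Var(1/b) ~ Var(b) / b^4
            self.se_E_inf_ = self.se_intercept_ / intercept**2
        else:
            self.se_intercept_ = None
            self.se_E_inf_ = None
        return self

    def predict(self, X):
        """Predicted efficiency at the given acceptor concentrations (µM)."""
        check_is_fitted(self, "intercept_")
        conc = np.asarray(X, dtype=float).reshape(-1)
        return 1.0 / (self.intercept_ + self.slope_ / conc)

    def result_(self) -> EfficiencyFit:
        check_is_fitted(self, "intercept_")
        return EfficiencyFit(
            slope=self.slope_,
            intercept=self.intercept_,
            E_inf=self.E_inf_,
            r2=self.r2_,
            n_points=self.n_points_,
            se_intercept=self.se_intercept_,
            se_E_inf=self.se_E_inf_,
        )


def extrapolate_efficiency(acceptor_conc, E_obs, weighted: bool = False) -> EfficiencyFit:
    """Fit the double-reciprocal line and return the limiting efficiency.

    Thin functional wrapper over :class:`DoubleReciprocalExtrapolation`.
    """
    est = DoubleReciprocalExtrapolation(weighted=weighted).fit(acceptor_conc, E_obs)
    return est.result_()
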