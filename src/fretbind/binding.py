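"""Inner-filter correction and single-site binding analysis of quenching
titrations.

A fluorescent receptor (here: microtubule-bound donor sites at fixed
concentration) is titrated with an absorbing, quenching ligand (labeled
tau). Three steps recover the apparent stoichiometric dissociation
constant:

1. observed donor intensities are corrected for the inner filter effect,
   ``F_corr = F_obs * 10^((A_exc * l_exc + A_em * l_em) / 2)`` with
   per-1-cm absorbances scaled by the actual excitation/emission cell
   pathlengths;
2. the corrected curve is inverted into a normalized quench signal
   ``S = (F0 - F_corr) / F0`` that rises from 0 and saturates at a plateau
   ``F_max``;
3. the quench signal is fitted by nonlinear least squares with a
   single-class-of-sites model. The default model accounts for ligand
   depletion exactly (the receptor concentration is comparable to Kd, so
   free ligand != total ligand): with ``R`` total receptor, ``L`` total
   ligand, ``n`` sites per receptor and ``b = nR + L + Kd``,

   ``S = F_max * (b - sqrt(b^2 - 4 n R L)) / (2 n R)``.

   A free≈total hyperbola ``S = F_max * L / (Kd + L)`` is kept for
   comparison.

The fit is exposed as the scikit-learn style estimator
:class:`BindingIsotherm`, with :func:`fit_binding` as the series-level
wrapper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

BINDING_MODELS = ("quadratic_depletion", "hyperbolic")

# Default cell geometry and ligand extinction coefficients: 1 cm excitation
# path, 0.2 cm emission path; rhodamine-labeled ligand absorbs with
# eps(494 nm) = 8624 and eps(520 nm) = 20,983 M^-1 cm^-1.
DEFAULT_PATH_EXC_CM = 1.0
DEFAULT_PATH_EM_CM = 0.2
DEFAULT_EPS_EXC = 8624.0
DEFAULT_EPS_EM = 20983.0


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point.

    ``A_exc``/``A_em_1cm`` are the ligand's absorbances at the excitation
    and emission wavelengths over a 1 cm path; when None they are computed
    from the series' extinction coefficients and the ligand concentration.
    """

    ligand_total: float  # µM
    F_obs: float  # intensity, a.u.
    A_exc: float | None = None
    A_em_1cm: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")
        if self.F_obs < 0:
            raise ValueError("F_obs must be >= 0")
        for name in ("A_exc", "A_em_1cm"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class TitrationSeries:
    """A quenching titration at fixed receptor concentration.

    Points are sorted by ligand concentration on construction, so the
    series is independent of input order. ``receptor_total`` is the fixed
    receptor (donor-site carrier) concentration in µM.
    """

    points: tuple[TitrationPoint, ...]
    receptor_total: float
    path_exc: float = DEFAULT_PATH_EXC_CM
    path_em: float = DEFAULT_PATH_EM_CM
    eps_exc: float = DEFAULT_EPS_EXC
    eps_em: float = DEFAULT_EPS_EM

    def __post_init__(self) -> None:
        if not self.receptor_total > 0:
            raise ValueError("receptor_total must be positive")
        if not (self.path_exc > 0 and self.path_em > 0):
            raise ValueError("pathlengths must be positive")
        pts = tuple(sorted(self.points, key=lambda pt: pt.ligand_total))
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ligand_total(self) -> np.ndarray:
        return np.array([pt.ligand_total for pt in self.points])

    @property
    def F_obs(self) -> np.ndarray:
        return np.array([pt.F_obs for pt in self.points])

    def absorbances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-1-cm absorbances (A_exc, A_em) for every point.

        Measured values take precedence; missing ones come from
        Beer-Lambert, ``A = eps * c``, with c converted from µM to M.
        """
        a_exc = np.array(
            [
                pt.A_exc if pt.A_exc is not None else self.eps_exc * pt.ligand_total * 1e-6
                for pt in self.points
            ]
        )
        a_em = np.array(
            [
                pt.A_em_1cm
                if pt.A_em_1cm is not None
                else self.eps_em * pt.ligand_total * 1e-6
                for pt in self.points
            ]
        )
        return a_exc, a_em

    def to_dataframe(self) -> pd.DataFrame:
        a_exc, a_em = self.absorbances()
        return pd.DataFrame(
            {
                "ligand_total_uM": self.ligand_total,
                "F_obs": self.F_obs,
                "A_exc": a_exc,
                "A_em_1cm": a_em,
            }
        )


def read_titration(
    path: str | Path,
    receptor_total: float,
    path_exc: float = DEFAULT_PATH_EXC_CM,
    path_em: float = DEFAULT_PATH_EM_CM,
    eps_exc: float = DEFAULT_EPS_EXC,
    eps_em: float = DEFAULT_EPS_EM,
) -> TitrationSeries:
    """Read a delimited titration table into a :class:`TitrationSeries`.

    Required columns: ``ligand_total_uM``, ``F_obs``; optional columns
    ``A_exc`` and ``A_em_1cm`` override Beer-Lambert absorbances.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"titration file not found: {p}")
    df = pd.read_csv(p, sep=None, engine="python")
    for col in ("ligand_total_uM", "F_obs"):
        if col not in df.columns:
            raise ValueError(f"titration file {p} lacks required column {col!r}")
    points = tuple(
        TitrationPoint(
            ligand_total=float(row["ligand_total_uM"]),
            F_obs=float(row["F_obs"]),
            A_exc=float(row["A_exc"]) if "A_exc" in df.columns else None,
            A_em_1cm=float(row["A_em_1cm"]) if "A_em_1cm" in df.columns else None,
        )
        for _, row in df.iterrows()
    )
    return TitrationSeries(
        points,
        receptor_total=receptor_total,
        path_exc=path_exc,
        path_em=path_em,
        eps_exc=eps_exc,
        eps_em=eps_em,
    )


def inner_filter_correct(
    F_obs,
    A_exc,
    A_em_1cm,
    path_exc: float = DEFAULT_PATH_EXC_CM,
    path_em: float = DEFAULT_PATH_EM_CM,
):
    """Inner-filter-corrected intensity.

    ``F_corr = F_obs * 10^((A_exc * path_exc + A_em_1cm * path_em) / 2)``

    with per-1-cm absorbances scaled by the cell pathlengths in cm (a
    0.2 cm emission path scales the emission absorbance by 0.2). Accepts
    scalars or arrays; ``F_corr >= F_obs`` always.
    """
    A_exc = np.asarray(A_exc, dtype=float)
    A_em_1cm = np.asarray(A_em_1cm, dtype=float)
    if np.any(A_exc < 0) or np.any(A_em_1cm < 0):
        raise ValueError("absorbances must be >= 0")
    if not (np.all(np.isfinite(A_exc)) and np.all(np.isfinite(A_em_1cm))):
        raise ValueError("absorbances must be finite")
    factor = 10.0 ** ((A_exc * path_exc + A_em_1cm * path_em) / 2.0)
    out = np.asarray(F_obs, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def correct_series(series: TitrationSeries) -> np.ndarray:
    """Inner-filter-corrected intensities for every point of a series."""
    a_exc, a_em = series.absorbances()
    return inner_filter_correct(
        series.F_obs, a_exc, a_em, path_exc=series.path_exc, path_em=series.path_em
    )


def quench_signal(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Inverted, normalized titration curve.

    Returns ``(ligand_total, S)`` with ``S_i = (F0 - F_corr_i) / F0``,
    where F0 is the corrected intensity of the zero-ligand reference point
    (which the series must contain). S rises from 0 toward the plateau
    F_max fitted by :class:`BindingIsotherm`.
    """
    if len(series) == 0 or series.points[0].ligand_total != 0.0:
        raise ValueError(
            "quench_signal needs a zero-ligand reference point to define F0"
        )
    f_corr = correct_series(series)
    f0 = f_corr[0]
    if not f0 > 0:
        raise ValueError("zero-ligand reference intensity must be positive")
    return series.ligand_total, (f0 - f_corr) / f0


def binding_model(
    ligand_total,
    Kd: float,
    F_max: float,
    n: float = 1.0,
    receptor_total: float = 5.0,
    model: str = "quadratic_depletion",
):
    """Predicted saturation signal of the single-class-of-sites model.

    ``model='quadratic_depletion'`` (default) solves the site-occupancy
    mass balance exactly; ``model='hyperbolic'`` uses the free≈total
    approximation, adequate only when Kd >> n * receptor_total. Both rise
    from 0 at zero ligand and saturate at ``F_max``.
    """
    if model not in BINDING_MODELS:
        raise ValueError(f"model must be one of {BINDING_MODELS}, got {model!r}")
    if not (Kd > 0 and F_max > 0 and n > 0 and receptor_total > 0):
        raise ValueError("Kd, F_max, n and receptor_total must be positive")
    L = np.asarray(ligand_total, dtype=float)
    if model == "hyperbolic":
        out = F_max * L / (Kd + L)
    else:
        nR = n * receptor_total
        b = nR + L + Kd
        disc = np.clip(b**2 - 4.0 * nR * L, 0.0, None)  # guard roundoff
        out = F_max * (b - np.sqrt(disc)) / (2.0 * nR)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BindingFit:
    """Converged single-site fit of a quench titration."""

    Kd: float  # µM
    F_max: float
    n: float
    se_Kd: float | None
    se_Fmax: float | None
    residuals: np.ndarray  # observed - predicted, per point
    converged: bool
    model: str
    n_points: int
    kd_at_bound: bool = False
    bootstrap_ci: tuple[float, float] | None = None  # 95% CI on Kd

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "Kd_uM": self.Kd,
            "F_max": self.F_max,
            "n": self.n,
            "se_Kd_uM": self.se_Kd,
            "se_F_max": self.se_Fmax,
            "n_points": self.n_points,
            "converged": self.converged,
            "kd_at_bound": self.kd_at_bound,
            "residuals": [float(r) for r in self.residuals],
        }
        if self.bootstrap_ci is not None:
            d["Kd_bootstrap_ci95_uM"] = list(self.bootstrap_ci)
        return d


class BindingIsotherm(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the single-site binding model.

    Minimizes ``sum((S_obs - model)^2)`` over (Kd, F_max) — and n when not
    fixed — by Levenberg-Marquardt, restarted from several initial Kd
    guesses spread around the half-saturation concentration to escape the
    shallow valleys typical of saturation fits; the best converged start is
    kept.

    Parameters
    ----------
    model : {'quadratic_depletion', 'hyperbolic'}
        Binding model, see :func:`binding_model`.
    receptor_total : float
        Fixed receptor concentration in µM.
    n : float or None, default 1.0
        Sites per receptor; a float fixes the stoichiometry, None fits it.
    kd_start_factors : tuple of float
        Multipliers of the half-saturation ligand concentration used as
        Kd starting guesses.
    kd_bounds : (float, float)
        Box constraints on Kd in µM; a fit ending on a bound is flagged.
    n_bootstrap : int, default 0
        Number of seeded residual-bootstrap resamples for a 95% CI on Kd
        (0 disables).
    random_state : int or None
        Seed for the bootstrap resampler.

    Attributes
    ----------
    Kd_, Fmax_, n_ : float
        Fitted parameters (n_ echoes the fixed value when not fitted).
    se_Kd_, se_Fmax_ : float or None
        Asymptotic standard errors from the local curvature.
    residuals_ : ndarray
        Observed minus predicted signal, per point.
    converged_ : bool
    kd_at_bound_ : bool
    bootstrap_ci_ : tuple or None
    """

    def __init__(
        self,
        model: str = "quadratic_depletion",
        receptor_total: float = 5.0,
        n: float | None = 1.0,
        kd_start_factors: tuple[float, ...] = (0.1, 1.0, 10.0),
        kd_bounds: tuple[float, float] = (1e-6, 1e6),
        n_bootstrap: int = 0,
        random_state: int | None = None,
    ):
        self.model = model
        self.receptor_total = receptor_total
        self.n = n
        self.kd_start_factors = kd_start_factors
        self.kd_bounds = kd_bounds
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------
    def _residual(self, params: lmfit.Parameters, L: np.ndarray, S: np.ndarray):
        pred = binding_model(
            L,
            Kd=params["Kd"].value,
            F_max=params["F_max"].value,
            n=params["n"].value,
            receptor_total=self.receptor_total,
            model=self.model,
        )
        return S - pred

    def _make_params(self, kd0: float, fmax0: float, n0: float) -> lmfit.Parameters:
        params = lmfit.Parameters()
        lo, hi = self.kd_bounds
        params.add("Kd", value=float(np.clip(kd0, lo, hi)), min=lo, max=hi)
        params.add("F_max", value=fmax0, min=1e-12)
        params.add("n", value=n0, min=1e-6, vary=self.n is None)
        return params

    def _fit_once(self, L, S, kd0, fmax0, n0):
        try:
            return lmfit.minimize(
                self._residual, self._make_params(kd0, fmax0, n0), args=(L, S), method="leastsq"
            )
        except Exception as exc:  # pragma: no cover - lmfit raise path
            logger.debug("start Kd0=%g failed: %s", kd0, exc)
            return None

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        L = np.asarray(X, dtype=float).reshape(-1)
        S = np.asarray(y, dtype=float).reshape(-1)
        if L.size != S.size:
            raise ValueError("ligand concentrations and signals differ in length")
        n_free = 2 + (1 if self.n is None else 0)
        if L.size <= n_free:
            raise ValueError(f"need more than {n_free} points to fit {n_free} parameters")
        if L.size < 4:
            warnings.warn("fewer than 4 titration points; fit will be poorly determined",
                          stacklevel=2)
        if np.any(L < 0):
            raise ValueError("ligand concentrations must be >= 0")

        fmax0 = float(S.max())
        if fmax0 <= 0:
            raise ValueError("signals are all <= 0; nothing to fit")
        # half-saturation ligand concentration as the anchor of Kd guesses
        above = L[(S >= fmax0 / 2.0) & (L > 0)]
        l_half = float(above.min()) if above.size else float(np.median(L[L > 0]))
        n0 = 1.0 if self.n is None else float(self.n)

        results = [
            res
            for f in self.kd_start_factors
            if (res := self._fit_once(L, S, f * l_half, fmax0, n0)) is not None
            and res.success
        ]
        if not results:
            raise RuntimeError(
                f"binding fit failed to converge from any of {len(self.kd_start_factors)} "
                f"starts (model={self.model}, {L.size} points, half-saturation ~{l_half:g} µM)"
            )
        best = min(results, key=lambda r: r.chisqr)
        kd_hat = float(best.params["Kd"].value)
        pos = L[L > 0]
        if pos.size and not (pos.min() < kd_hat < pos.max()):
            warnings.warn(
                "titration does not span sub- to supra-Kd ligand concentrations; "
                "Kd and F_max may be strongly correlated",
                stacklevel=2,
            )
        self.Kd_ = float(best.params["Kd"].value)
        self.Fmax_ = float(best.params["F_max"].value)
        self.n_ = float(best.params["n"].value)
        self.se_Kd_ = (
            float(best.params["Kd"].stderr) if best.params["Kd"].stderr is not None else None
        )
        self.se_Fmax_ = (
            float(best.params["F_max"].stderr)
            if best.params["F_max"].stderr is not None
            else None
        )
        self.residuals_ = np.asarray(best.residual)
        self.converged_ = True
        lo, hi = self.kd_bounds
        self.kd_at_bound_ = bool(self.Kd_ <= lo * 1.001 or self.Kd_ >= hi * 0.999)
        if self.kd_at_bound_:
            warnings.warn(f"fitted Kd={self.Kd_:g} µM sits on a bound", stacklevel=2)
        self.n_points_ = int(L.size)
        self.bootstrap_ci_ = (
            self._bootstrap(L, S) if self.n_bootstrap and self.n_bootstrap > 0 else None
        )
        return self

    def _bootstrap(self, L, S) -> tuple[float, float]:
        """Seeded residual bootstrap: refit on fitted curve + resampled residuals."""
        rng = np.random.default_rng(self.random_state)
        pred = self.predict(L)
        resid = S - pred
        kds = []
        for _ in range(self.n_bootstrap):
            s_b = pred + rng.choice(resid, size=resid.size, replace=True)
            res = self._fit_once(L, s_b, self.Kd_, self.Fmax_, self.n_)
            if res is not None and res.success:
                kds.append(float(res.params["Kd"].value))
        if len(kds) < max(10, self.n_bootstrap // 10):
            warnings.warn("too few successful bootstrap refits; CI unreliable", stacklevel=2)
        lo, hi = np.percentile(kds, [2.5, 97.5])
        return float(lo), float(hi)

    def predict(self, X):
        check_is_fitted(self, "Kd_")
        L = np.asarray(X, dtype=float).reshape(-1)
        return binding_model(
            L,
            Kd=self.Kd_,
            F_max=self.Fmax_,
            n=self.n_,
            receptor_total=self.receptor_total,
            model=self.model,
        )

    def result_(self) -> BindingFit:
        check_is_fitted(self, "Kd_")
        return BindingFit(
            Kd=self.Kd_,
            F_max=self.Fmax_,
            n=self.n_,
            se_Kd=self.se_Kd_,
            se_Fmax=self.se_Fmax_,
            residuals=self.residuals_,
            converged=self.converged_,
            model=self.model,
            n_points=self.n_points_,
            kd_at_bound=self.kd_at_bound_,
            bootstrap_ci=self.bootstrap_ci_,
        )


def fit_binding(
    series: TitrationSeries,
    model: str = "quadratic_depletion",
    n_fixed: float | None = 1.0,
    n_bootstrap: int = 0,
    random_state: int | None = None,
) -> BindingFit:
    """Correct, invert and fit a titration series; return the binding fit.

    Thin wrapper composing :func:`quench_signal` with
    :class:`BindingIsotherm` (n fixed to ``n_fixed``, or fitted when None).
    """
    L, S = quench_signal(series)
    est = BindingIsotherm(
        model=model,
        receptor_total=series.receptor_total,
        n=n_fixed,
        n_bootstrap=n_bootstrap,
        random_state=random_state,
    ).fit(L, S)
    return est.result_()
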