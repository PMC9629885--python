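"""Nonlinear least-squares fitting of the free-ADA binding models.

The entry point is :class:`FreeAdaBindingModel`, built from an
:class:`~ada_affinity.curves.AffinityCurve` with one or two phases; its
:meth:`~FreeAdaBindingModel.fit` returns a :class:`BindingFitResults`
carrying the estimates, their covariance (on the log-parameter scale),
confidence intervals and delta-method prediction bounds, with a
``summary()`` table.  ``fit_monophasic`` / ``fit_biphasic`` are thin
functional wrappers.

Estimation details
------------------
* Optimisation variables are the natural logs of (ab, kd[, ab2, kd2]):
  K_D spans femtomolar to micromolar in this assay, and the log transform
  both enforces positivity and conditions the problem.
* Deterministic multi-start: log10 K_D is initialised at every whole decade
  from two decades below the lowest observed dose to two above the highest;
  amplitudes start at the maximum observed signal (split 50/50 for the
  biphasic model).  The start with the smallest residual sum of squares
  wins; ties break toward the smaller high-affinity K_D.
* Loss is relative least squares by default (residuals scaled by the
  observed signal): immunoassay noise is close to constant-CV, so the
  relative loss is the statistically matched weighting and markedly
  reduces the K_D sampling error on curves whose plateau dominates the
  absolute residuals.  ``weights="unweighted"`` selects plain least
  squares on the raw signal instead.
* Parameter covariance is ``s^2 * (J'J)^{-1}`` with ``s^2 = rss/(n-k)``
  and J the Jacobian at the optimum in log space; confidence bounds on the
  mean response use first-order (delta-method) propagation with a
  Student-t quantile at ``n-k`` degrees of freedom.
* A fit whose K_D escapes far outside the observed dose window (beyond
  1000x either end) carries no affinity information and is flagged
  ``converged=False``; downstream QC then fails it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .curves import AffinityCurve
from .models import BindingParamsBi, BindingParamsMono

__all__ = [
    "FreeAdaBindingModel",
    "BindingFitResults",
    "fit_monophasic",
    "fit_biphasic",
    "predict_with_bounds",
]

# K_D estimates outside [min_dose/KD_WINDOW, max_dose*KD_WINDOW] are treated
# as unidentifiable from the observed dose range.
KD_WINDOW = 1e3
# phases closer than this K_D ratio are flagged indistinguishable
MIN_PHASE_SEPARATION = 3.0


def _mono_signal_and_grad(dose: np.ndarray, ab: float, kd: float):
    """Model value and gradient w.r.t. (log ab, log kd) for one phase.

    Uses the per-site occupancy t = x/(1+x), x = dose/kd, so extreme x
    reached during optimisation cannot overflow:
    f = ab*(1 - t^2) and df/dlog kd = 2*ab*t^2/(1+x).
    """
    x = dose / kd
    with np.errstate(divide="ignore"):
        t = np.where(x > 1.0, 1.0 / (1.0 + 1.0 / np.maximum(x, 1e-300)), x / (1.0 + x))
        inv_1px = np.where(x > 1.0, (1.0 / np.maximum(x, 1e-300)) * t, 1.0 / (1.0 + x))
    f = ab * (1.0 - t**2)
    d_log_ab = f
    d_log_kd = 2.0 * ab * t**2 * inv_1px
    return f, d_log_ab, d_log_kd


def _model(doses: np.ndarray, z: np.ndarray) -> np.ndarray:
    theta = np.exp(z)
    total = np.zeros_like(doses)
    for ab, kd in theta.reshape(-1, 2):
        total += _mono_signal_and_grad(doses, ab, kd)[0]
    return total


def _jacobian(doses: np.ndarray, z: np.ndarray) -> np.ndarray:
    theta = np.exp(z)
    cols = []
    for ab, kd in theta.reshape(-1, 2):
        _, d_ab, d_kd = _mono_signal_and_grad(doses, ab, kd)
        cols.extend([d_ab, d_kd])
    return np.column_stack(cols)


@dataclass
class BindingFitResults:
    """Results of a mono- or biphasic binding fit.

    Attributes
    ----------
    model : str
        ``"monophasic"`` or ``"biphasic"``.
    params : BindingParamsMono | BindingParamsBi
        Point estimates (biphasic phases ordered so ``kd1 <= kd2``).
    rss : float
        The minimised residual sum of squares (the weighted objective;
        equals the raw-signal RSS for an unweighted fit).
    rss_unweighted : float
        Residual sum of squares on the raw signal (signal units squared).
    n, k : int
        Number of points and of fitted parameters (2 or 4).
    cov_log : np.ndarray
        Covariance of the log-parameter estimates, ordered
        ``(log ab, log kd)`` per phase; ``inf`` entries mark a singular fit.
    converged : bool
        False when no start converged or the K_D estimate left the
        identifiable dose window.
    degenerate_phases : bool
        Biphasic only: ``kd2/kd1 <`` the minimum separation, i.e. the two
        phases are statistically indistinguishable.
    """

    model: str
    params: BindingParamsMono | BindingParamsBi
    rss: float
    n: int
    k: int
    cov_log: np.ndarray
    converged: bool
    curve: AffinityCurve
    degenerate_phases: bool = False
    rss_unweighted: float = float("nan")
    weights: str = "relative"

    # ---- inference ------------------------------------------------------

    @property
    def dof(self) -> int:
        return self.n - self.k

    @property
    def s2(self) -> float:
        """Residual variance estimate rss/(n-k)."""
        return self.rss / self.dof

    def _param_vector(self) -> np.ndarray:
        p = self.params
        if isinstance(p, BindingParamsMono):
            return np.array([p.ab, p.kd])
        return np.array([p.ab1, p.kd1, p.ab2, p.kd2])

    def kd_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Per-K_D confidence interval(s), molar, from the log-scale SE."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        tq = stats.t.ppf(0.5 + level / 2.0, self.dof)
        theta = self._param_vector()
        out: dict[str, tuple[float, float]] = {}
        names = ["kd"] if self.k == 2 else ["kd1", "kd2"]
        for j, name in zip(range(1, self.k, 2), names):
            var = self.cov_log[j, j]
            if not np.isfinite(var):
                out[name] = (0.0, np.inf)
                continue
            half = tq * np.sqrt(max(var, 0.0))
            out[name] = (theta[j] * np.exp(-half), theta[j] * np.exp(half))
        return out

    def predict(self, dose) -> np.ndarray:
        z = np.log(self._param_vector())
        return _model(np.atleast_1d(np.asarray(dose, dtype=float)), z)

    def predict_with_bounds(self, dose, level: float = 0.99):
        """Mean-response prediction with delta-method confidence bounds.

        Returns ``(prediction, lower, upper)`` arrays.  A singular
        covariance yields infinite bounds, which downstream QC treats as
        an automatic flatness failure.
        """
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        doses = np.atleast_1d(np.asarray(dose, dtype=float))
        z = np.log(self._param_vector())
        pred = _model(doses, z)
        if not np.all(np.isfinite(self.cov_log)):
            lower = np.full_like(pred, -np.inf)
            upper = np.full_like(pred, np.inf)
            return pred, lower, upper
        grad = _jacobian(doses, z)  # (m, k) d pred / d log-params
        var = np.einsum("ij,jk,ik->i", grad, self.cov_log, grad)
        var = np.maximum(var, 0.0)
        tq = stats.t.ppf(0.5 + level / 2.0, self.dof)
        half = tq * np.sqrt(var)
        return pred, pred - half, pred + half

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        p = self.params
        lines = [
            f"Free-ADA binding fit: {self.model}",
            f"  n = {self.n}, k = {self.k}, rss = {self.rss:.6g}, "
            f"converged = {self.converged}",
        ]
        ci = self.kd_ci(0.95)
        if isinstance(p, BindingParamsMono):
            lo, hi = ci["kd"]
            lines.append(f"  Ab  = {p.ab:.6g}")
            lines.append(f"  K_D = {p.kd:.4g} M  (95% CI {lo:.4g} .. {hi:.4g})")
        else:
            lines.append(f"  Ab1 = {p.ab1:.6g}  (high-affinity phase)")
            lo, hi = ci["kd1"]
            lines.append(f"  K_D1 = {p.kd1:.4g} M  (95% CI {lo:.4g} .. {hi:.4g})")
            lines.append(f"  Ab2 = {p.ab2:.6g}  (low-affinity phase)")
            lo, hi = ci["kd2"]
            lines.append(f"  K_D2 = {p.kd2:.4g} M  (95% CI {lo:.4g} .. {hi:.4g})")
            lines.append(
                f"  K_D(geo) = {p.kd_geo:.4g} M, proportion high = "
                f"{p.proportion_high:.3f}"
            )
            if self.degenerate_phases:
                lines.append("  [flag] phases indistinguishable (kd2/kd1 < 3)")
        return "\n".join(lines)


class FreeAdaBindingModel:
    """Mono- or biphasic free-ADA inhibition model for one affinity curve.

    Parameters
    ----------
    curve : AffinityCurve
        Dose-signal observations (doses molar).
    phases : int
        1 for the monophasic model (Ab, K_D), 2 for the biphasic model
        (Ab1, K_D1, Ab2, K_D2).
    weights : str
        ``"relative"`` (default) scales each residual by the observed
        signal, matching constant-CV assay noise; ``"unweighted"`` fits
        the raw signal.
    """

    #: convergence tolerances: relative cost change and max evaluations
    FTOL = 1e-10
    MAX_NFEV = 500

    def __init__(self, curve: AffinityCurve, phases: int = 1, weights: str = "relative"):
        if phases not in (1, 2):
            raise ValueError("phases must be 1 or 2")
        if weights not in ("relative", "unweighted"):
            raise ValueError("weights must be 'relative' or 'unweighted'")
        self.curve = curve
        self.phases = phases
        self.weights = weights
        self.k = 2 * phases
        if len(curve) <= self.k + 1:
            raise ValueError(
                f"need more than k+1 = {self.k + 1} points for the "
                f"{'biphasic' if phases == 2 else 'monophasic'} model"
            )

    @classmethod
    def from_dataframe(cls, df, sample_id: str, phases: int = 1) -> "FreeAdaBindingModel":
        from .curves import frame_to_curves

        curves = frame_to_curves(df[df["sample_id"] == sample_id])
        if not curves:
            raise KeyError(f"sample {sample_id!r} not found")
        return cls(curves[0], phases=phases)

    # ---- initialisation -------------------------------------------------

    def _kd_start_grid(self) -> np.ndarray:
        """One start per decade from min dose/100 to max dose*100."""
        doses = self.curve.doses[self.curve.doses > 0]
        lo = np.log10(doses.min()) - 2
        hi = np.log10(doses.max()) + 2
        return 10.0 ** np.arange(lo, hi + 1e-9)

    def _starts(self) -> list[np.ndarray]:
        """Deterministic multi-start grid over K_D decades.

        The model is linear in the amplitudes at fixed K_D, so each start's
        amplitudes come from a small (weighted) linear solve, clipped to a
        positive floor; this puts every start close to its local optimum.
        """
        smax = max(self.curve.signals.max(), 1e-12)
        kd_grid = self._kd_start_grid()
        w = self._weight_vector()
        y = self.curve.signals * w
        floor = smax * 1e-6
        starts = []
        if self.phases == 1:
            for kd in kd_grid:
                g = _mono_signal_and_grad(self.curve.doses, 1.0, kd)[0] * w
                denom = g @ g
                ab = (g @ y) / denom if denom > 0 else smax
                starts.append(np.log([max(ab, floor), kd]))
        else:
            for kd_a, kd_b in combinations(kd_grid, 2):
                g1 = _mono_signal_and_grad(self.curve.doses, 1.0, kd_a)[0] * w
                g2 = _mono_signal_and_grad(self.curve.doses, 1.0, kd_b)[0] * w
                G = np.column_stack([g1, g2])
                try:
                    amps, *_ = np.linalg.lstsq(G, y, rcond=None)
                except np.linalg.LinAlgError:
                    amps = np.array([smax / 2, smax / 2])
                ab1, ab2 = (max(a, floor) for a in amps)
                starts.append(np.log([ab1, kd_a, ab2, kd_b]))
        return starts

    # ---- fitting --------------------------------------------------------

    def _weight_vector(self) -> np.ndarray:
        if self.weights == "unweighted":
            return np.ones_like(self.curve.signals)
        # floor tiny observed signals so a zero well cannot dominate
        floor = max(self.curve.signals.max(), 1.0) * 1e-6
        return 1.0 / np.maximum(self.curve.signals, floor)

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Wide log-space box (±16 nats around the data scales): never
        binding for an identifiable fit, but keeps runaway starts finite."""
        smax = max(self.curve.signals.max(), 1e-12)
        doses = self.curve.doses[self.curve.doses > 0]
        ab_lo, ab_hi = np.log(smax) - 16, np.log(smax) + 16
        kd_lo, kd_hi = np.log(doses.min()) - 16, np.log(doses.max()) + 16
        lo = np.array([ab_lo, kd_lo] * self.phases)
        hi = np.array([ab_hi, kd_hi] * self.phases)
        return lo, hi

    def fit(self) -> BindingFitResults:
        doses = self.curve.doses
        signals = self.curve.signals
        w = self._weight_vector()
        lo, hi = self._bounds()

        def residuals(z):
            return (_model(doses, z) - signals) * w

        def jac(z):
            return _jacobian(doses, z) * w[:, None]

        best = None
        for z0 in self._starts():
            try:
                sol = least_squares(
                    residuals,
                    np.clip(z0, lo + 1e-6, hi - 1e-6),
                    jac=jac,
                    bounds=(lo, hi),
                    method="trf",
                    ftol=self.FTOL,
                    xtol=1e-12,
                    gtol=1e-12,
                    max_nfev=self.MAX_NFEV,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            rss = float(np.sum(sol.fun**2))
            key = (rss, self._tiebreak_kd(sol.x))
            if best is None or key < best[0]:
                best = (key, sol)
        if best is None:
            raise RuntimeError("all optimisation starts failed")
        sol = best[1]
        z = self._canonical_order(sol.x)
        resid_raw = _model(doses, z) - signals
        rss = float(np.sum((resid_raw * w) ** 2))
        rss_raw = float(np.sum(resid_raw**2))
        theta = np.exp(z)

        converged = bool(sol.success) or sol.status > 0
        # a K_D far outside the observed dose window is not identifiable
        dose_lo, dose_hi = doses[doses > 0].min(), doses.max()
        kds = theta[1::2]
        if np.any(kds < dose_lo / KD_WINDOW) or np.any(kds > dose_hi * KD_WINDOW):
            converged = False

        n, k = len(self.curve), self.k
        cov_log = self._covariance(z, rss, n, k, w)

        if self.phases == 1:
            params: BindingParamsMono | BindingParamsBi = BindingParamsMono(theta[0], theta[1])
            degenerate = False
        else:
            params = BindingParamsBi(theta[0], theta[1], theta[2], theta[3])
            degenerate = theta[3] / theta[1] < MIN_PHASE_SEPARATION
        return BindingFitResults(
            model="monophasic" if self.phases == 1 else "biphasic",
            params=params,
            rss=rss,
            n=n,
            k=k,
            cov_log=cov_log,
            converged=converged,
            curve=self.curve,
            degenerate_phases=degenerate,
            rss_unweighted=rss_raw,
            weights=self.weights,
        )

    def _tiebreak_kd(self, z: np.ndarray) -> float:
        return float(np.min(np.exp(z[1::2])))

    def _canonical_order(self, z: np.ndarray) -> np.ndarray:
        if self.phases == 1:
            return z
        if z[1] <= z[3]:
            return z
        return z[[2, 3, 0, 1]]

    def _covariance(
        self, z: np.ndarray, rss: float, n: int, k: int, w: np.ndarray
    ) -> np.ndarray:
        J = _jacobian(self.curve.doses, z) * w[:, None]
        JtJ = J.T @ J
        s2 = rss / (n - k)
        try:
            cond = np.linalg.cond(JtJ)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            return np.full((k, k), np.inf)
        return s2 * np.linalg.inv(JtJ)


def fit_monophasic(curve: AffinityCurve, weights: str = "relative") -> BindingFitResults:
    """Fit the two-parameter monophasic model to one curve."""
    return FreeAdaBindingModel(curve, phases=1, weights=weights).fit()


def fit_biphasic(curve: AffinityCurve, weights: str = "relative") -> BindingFitResults:
    """Fit the four-parameter biphasic model; phases returned high-affinity
    first (``kd1 <= kd2``)."""
    return FreeAdaBindingModel(curve, phases=2, weights=weights).fit()


def predict_with_bounds(fit: BindingFitResults, dose, level: float = 0.99):
    """Functional alias for :meth:`BindingFitResults.predict_with_bounds`."""
    return fit.predict_with_bounds(dose, level=level)
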