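"""Equilibrium sorption isotherms: evaluation, eligibility screening and
nonlinear least-squares fitting.

Four models relate the sorbed-phase concentration q (mg/kg) to the
equilibrium aqueous concentration Ce (mg/L):

=============  =====================================================
linear         q = K * Ce
freundlich     q = K_F * Ce**(1/n)
langmuir       q = q_max * b * Ce / (1 + b * Ce)
bet            q = q_m * K_B * Ce / ((C_s - Ce) * (1 + (K_B - 1) * Ce / C_s))
=============  =====================================================

The BET form is the aqueous-phase adaptation with the saturation
concentration C_s in place of vapour pressure; it diverges as Ce -> C_s
(multilayer sorption).  Fitting is done in natural (untransformed)
coordinates over a deterministic multiplicative start grid; linearised
regressions are used only to seed starting values.  Series are eligible
for fitting when at least five points with Ce > 0 are available spanning
at least a factor of five in Ce.  A Freundlich exponent 1/n > 1 (or a
well-fitting BET model) flags multilayer sorption.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitError, ValidationError

__all__ = [
    "MODEL_KINDS",
    "IsothermModel",
    "eval_isotherm",
    "check_eligibility",
    "Isotherm",
    "IsothermResults",
    "fit_isotherm",
    "fit_all_models",
]

MODEL_KINDS = ("linear", "freundlich", "langmuir", "bet")
PARAM_NAMES = {
    "linear": ("K",),
    "freundlich": ("K_F", "one_over_n"),
    "langmuir": ("q_max", "b"),
    "bet": ("q_m", "K_B", "c_s"),
}
#: r-squared above which a BET fit counts as "acceptable" for the
#: multilayer flag
BET_MULTILAYER_R2 = 0.9


def _eval(kind: str, values: np.ndarray, ce: np.ndarray) -> np.ndarray:
    if kind == "linear":
        (k,) = values
        return k * ce
    if kind == "freundlich":
        kf, n_inv = values
        return kf * np.power(ce, n_inv)
    if kind == "langmuir":
        qmax, b = values
        return qmax * b * ce / (1.0 + b * ce)
    if kind == "bet":
        qm, kb, cs = values
        return qm * kb * ce / ((cs - ce) * (1.0 + (kb - 1.0) * ce / cs))
    raise ValidationError(f"unknown isotherm kind {kind!r}")


@dataclass(frozen=True)
class IsothermModel:
    """A parameterised isotherm: ``kind`` plus its parameter dict."""

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValidationError(f"kind must be one of {MODEL_KINDS}")
        missing = [n for n in PARAM_NAMES[self.kind] if n not in self.params]
        if missing:
            raise ValidationError(f"{self.kind}: missing parameter(s) {missing}")
        if any(self.params[n] <= 0 for n in PARAM_NAMES[self.kind]):
            raise ValidationError(f"{self.kind}: all parameters must be positive")

    def predict(self, ce) -> np.ndarray:
        return eval_isotherm(self, ce)

    def _values(self) -> np.ndarray:
        return np.array([self.params[n] for n in PARAM_NAMES[self.kind]], dtype=float)


def eval_isotherm(model: IsothermModel, ce) -> np.ndarray:
    """Evaluate q(Ce) in mg/kg; BET requires Ce < C_s."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValidationError("Ce must be non-negative")
    if model.kind == "bet" and np.any(ce_arr >= model.params["c_s"]):
        raise ValidationError("BET isotherm is undefined for Ce >= C_s")
    out = _eval(model.kind, model._values(), ce_arr)
    return out if out.ndim else float(out)


def check_eligibility(points) -> tuple[bool, str]:
    """Fitting-eligibility rule: >= 5 points with Ce > 0 spanning >= 5x.

    ``points`` may be SorptionPoint objects or (ce, q) pairs/arrays; points
    with Ce = 0 (complete removal) are excluded before the check and noted
    in the reason string.
    """
    ce, _ = _extract_arrays(points)
    n_zero = int(np.sum(ce <= 0))
    ce = ce[ce > 0]
    notes = []
    if n_zero:
        notes.append(f"{n_zero} complete-removal point(s) excluded")
    if ce.size < 5:
        notes.insert(0, f"fewer than five data points (n={ce.size})")
        return False, "; ".join(notes)
    span = float(ce.max() / ce.min())
    if span < 5.0:
        notes.insert(0, f"concentration span {span:.3g}x < 5x")
        return False, "; ".join(notes)
    notes.insert(0, f"eligible (n={ce.size}, span {span:.3g}x)")
    return True, "; ".join(notes)


def _extract_arrays(points):
    if isinstance(points, (list, tuple)) and len(points) and hasattr(points[0], "ce"):
        ce = np.array([p.ce for p in points], dtype=float)
        q = np.array([p.q for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            ce, q = arr[:, 0], arr[:, 1]
        else:
            raise ValidationError("points must be SorptionPoints or (ce, q) pairs")
    return ce, q


class IsothermResults:
    """Fit results: parameters, standard errors, goodness of fit.

    ``multilayer_flag`` is True for a Freundlich fit with 1/n > 1 or an
    acceptable BET fit (r^2 >= 0.9), the signatures of multilayer sorption.
    """

    def __init__(self, model, bse, rss, nobs, eligible, reason, converged):
        self.model = model
        self.kind = model.kind
        self.params = dict(model.params)
        self.bse = bse
        self.rss = rss
        self.nobs = nobs
        self.eligible = eligible
        self.eligibility_reason = reason
        self.converged = converged

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.kind])

    @property
    def rsquared(self) -> float:
        return self._rsquared

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC from the Gaussian RSS likelihood."""
        n, p = self.nobs, self.n_params
        rss = max(self.rss, 1e-300)
        aic = n * np.log(rss / n) + 2 * p
        if n - p - 1 > 0:
            return aic + 2.0 * p * (p + 1) / (n - p - 1)
        return np.inf

    @property
    def multilayer_flag(self) -> bool:
        if self.kind == "freundlich":
            return self.params["one_over_n"] > 1.0
        if self.kind == "bet":
            return self.rsquared >= BET_MULTILAYER_R2
        return False

    def predict(self, ce):
        return self.model.predict(ce)

    def summary(self) -> str:
        lines = [
            f"{self.kind.capitalize()} isotherm fit",
            "=" * 44,
            f"n points: {self.nobs}   RSS: {self.rss:.5g}   R^2: {self.rsquared:.4f}",
            f"AICc: {self.aicc:.2f}   eligible: {self.eligible}   multilayer: {self.multilayer_flag}",
        ]
        for name in PARAM_NAMES[self.kind]:
            se = self.bse.get(name, np.nan)
            se_txt = f" +/- {se:.3g}" if np.isfinite(se) else ""
            lines.append(f"  {name:10s} = {self.params[name]:.5g}{se_txt}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<IsothermResults {self.kind} r2={self.rsquared:.3f}>"


class Isotherm:
    """statsmodels-style isotherm model built from (Ce, q) observations.

    Parameters
    ----------
    ce, q : array-like
        Equilibrium aqueous (mg/L) and sorbed (mg/kg) concentrations.
    kind : str
        One of ``linear``, ``freundlich``, ``langmuir``, ``bet``.
    c_s : float, optional
        Fix the BET saturation concentration (e.g. from solubility)
        instead of fitting it.
    """

    def __init__(self, ce, q, kind: str = "freundlich", c_s: float | None = None):
        if kind not in MODEL_KINDS:
            raise ValidationError(f"kind must be one of {MODEL_KINDS}")
        ce = np.asarray(ce, dtype=float)
        q = np.asarray(q, dtype=float)
        keep = ce > 0
        self.ce = ce[keep]
        self.q = q[keep]
        self.kind = kind
        self.c_s_fixed = c_s
        if c_s is not None and c_s <= float(self.ce.max()):
            raise ValidationError("fixed C_s must exceed every observed Ce")
        self.eligible, self.eligibility_reason = check_eligibility(
            np.column_stack([ce, q])
        )

    @classmethod
    def from_points(cls, points, kind: str = "freundlich", **kwargs) -> "Isotherm":
        ce, q = _extract_arrays(points)
        return cls(ce, q, kind=kind, **kwargs)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, kind: str = "freundlich",
        ce_col: str = "ce_mg_L", q_col: str = "q_mg_kg", **kwargs,
    ) -> "Isotherm":
        return cls(frame[ce_col].to_numpy(), frame[q_col].to_numpy(), kind=kind, **kwargs)

    # -- fitting ------------------------------------------------------------
    def fit(self, force: bool = False) -> IsothermResults:
        """Nonlinear least squares in natural space over a fixed start grid.

        Raises ValidationError for ineligible series unless ``force`` is
        set, in which case the result is returned marked ineligible.
        """
        if not self.eligible and not force:
            raise ValidationError(f"series not eligible for fitting: {self.eligibility_reason}")
        if self.ce.size < len(self._free_names()):
            raise FitError("fewer points than free parameters")
        if self.kind == "linear":
            return self._fit_linear()
        return self._fit_nonlinear()

    def _free_names(self):
        names = list(PARAM_NAMES[self.kind])
        if self.kind == "bet" and self.c_s_fixed is not None:
            names.remove("c_s")
        return names

    def _fit_linear(self) -> IsothermResults:
        # closed-form least squares through the origin
        k = float(np.sum(self.q * self.ce) / np.sum(self.ce ** 2))
        resid = self.q - k * self.ce
        rss = float(np.sum(resid ** 2))
        dof = max(self.ce.size - 1, 1)
        se = float(np.sqrt(rss / dof / np.sum(self.ce ** 2)))
        model = IsothermModel("linear", {"K": max(k, np.finfo(float).tiny)})
        return self._results(model, {"K": se}, rss, converged=True)

    def _fit_nonlinear(self) -> IsothermResults:
        free = self._free_names()
        base = self._initial_guess()
        lower = np.full(len(free), 1e-12)
        upper = np.full(len(free), np.inf)
        if self.kind == "bet" and "c_s" in free:
            lower[free.index("c_s")] = float(self.ce.max()) * (1.0 + 1e-6)
        factors = (0.3, 1.0, 3.0)
        best = None
        for combo in itertools.product(factors, repeat=len(free)):
            x0 = np.clip(base * np.array(combo), lower, upper)
            try:
                res = least_squares(
                    self._residuals, x0, bounds=(lower, upper),
                    x_scale=np.maximum(np.abs(x0), 1e-6),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except (ValueError, FloatingPointError):
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError(f"{self.kind} fit failed from every start")
        rss = float(2.0 * best.cost)
        dof = max(self.ce.size - len(free), 1)
        try:
            cov = np.linalg.pinv(best.jac.T @ best.jac) * rss / dof
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            ses = np.full(len(free), np.nan)
        params = dict(zip(free, (float(v) for v in best.x)))
        bse = dict(zip(free, (float(s) for s in ses)))
        if self.kind == "bet" and self.c_s_fixed is not None:
            params["c_s"] = float(self.c_s_fixed)
            bse["c_s"] = 0.0
        model = IsothermModel(self.kind, params)
        return self._results(model, bse, rss, converged=bool(best.success))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        free = self._free_names()
        params = dict(zip(free, theta))
        if self.kind == "bet" and self.c_s_fixed is not None:
            params["c_s"] = self.c_s_fixed
        values = np.array([params[n] for n in PARAM_NAMES[self.kind]])
        with np.errstate(all="ignore"):
            pred = _eval(self.kind, values, self.ce)
        pred = np.where(np.isfinite(pred), pred, 1e12)
        return pred - self.q

    def _initial_guess(self) -> np.ndarray:
        ce, q = self.ce, self.q
        if self.kind == "freundlich":
            # log-log regression seeds K_F and 1/n
            slope, intercept = np.polyfit(np.log(ce), np.log(np.maximum(q, 1e-12)), 1)
            return np.array([np.exp(intercept), max(slope, 0.05)])
        if self.kind == "langmuir":
            qmax0 = 1.2 * float(q.max())
            with np.errstate(divide="ignore", invalid="ignore"):
                b0 = np.nanmedian(q / (ce * np.maximum(qmax0 - q, 1e-9)))
            return np.array([qmax0, max(float(b0), 1e-3)])
        # bet
        guess = [float(q.max()) / 2.0, 50.0]
        if self.c_s_fixed is None:
            guess.append(2.0 * float(ce.max()))
        return np.array(guess)

    def _results(self, model, bse, rss, converged) -> IsothermResults:
        result = IsothermResults(
            model, bse, rss, self.ce.size, self.eligible, self.eligibility_reason, converged
        )
        tss = float(np.sum((self.q - self.q.mean()) ** 2))
        result._rsquared = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
        return result


def fit_isotherm(points, kind: str, force: bool = False, c_s: float | None = None) -> IsothermResults:
    """Fit one isotherm model to SorptionPoints or (ce, q) pairs."""
    return Isotherm.from_points(points, kind=kind, c_s=c_s).fit(force=force)


def fit_all_models(points, kinds=MODEL_KINDS, force: bool = False, c_s: float | None = None):
    """Fit several models; returns (table, best-set by small-sample AIC).

    Models within 2 AICc units of the minimum are reported as a tie set
    rather than a single winner.
    """
    results = {}
    for kind in kinds:
        try:
            results[kind] = fit_isotherm(points, kind, force=force, c_s=c_s)
        except FitError:
            continue
    if not results:
        raise FitError("every requested model failed to fit")
    table = pd.DataFrame(
        [
            {
                "model": kind,
                **res.params,
                "rss": res.rss,
                "r_squared": res.rsquared,
                "aicc": res.aicc,
                "eligible": res.eligible,
                "multilayer_flag": res.multilayer_flag,
            }
            for kind, res in results.items()
        ]
    ).set_index("model")
    best_aicc = table["aicc"].min()
    tie_set = sorted(table.index[table["aicc"] <= best_aicc + 2.0])
    return table, tie_set
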