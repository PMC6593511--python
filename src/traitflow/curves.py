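"""Pan-genome sampling curves and exponential model fits.

The exhausted-subsampling construction: for every subset size n = 1..N,
evaluate a statistic on (up to ``max_subsets``) genome subsets of size n —
the strict-intersection core size, the per-genome count of subset-unique
families, or the union (pan-genome) size.  The statistics are
order-invariant, so combinations stand in for permutations and the number
of distinct subsets evaluated is reported as ``subsets_used``.

Three models are fitted to the per-n means:

* core decay        ``Fc(n) = Kc * exp(-n / tau_c) + Omega``
* new-gene decay    ``Fs(n) = Ks * exp(-n / tau_s) + tg_theta``
* pan accumulation  ``P(n)  = D + tg_theta * (n - 1)
                             + Ks * exp(-2/tau_s) * (1 - r**(n-1)) / (1 - r)``
  with ``r = exp(-1/tau_s)`` and (Ks, tau_s, tg_theta) inherited from the
  Fs fit, so that the increment identity P(n) - P(n-1) = Fs(n) holds by
  construction.  Omega is the asymptotic core size; tg_theta the number of
  new strain-specific genes each additional genome keeps contributing.

Fitting is nonlinear least squares with the decay constant profiled out:
for fixed tau the model is linear in (K, asymptote), solved in closed form;
tau is then optimised from a log-spaced grid of starts, which makes the fit
deterministic and robust to poor initialisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

from .occurrence import OccurrenceMatrix

__all__ = [
    "SamplingCurve",
    "CurveFit",
    "CurveFitError",
    "core_curve",
    "specific_curve",
    "pan_curve",
    "fc",
    "fs",
    "pan_model",
    "fit_curve",
    "fit_pan",
    "SamplingCurveModel",
    "CurveFitResults",
]

CurveKind = Literal["core", "specific", "pan"]


class CurveFitError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


@dataclass
class SamplingCurve:
    """Subset statistics per subset size n, from exhausted subsampling."""

    kind: CurveKind
    points: dict[int, np.ndarray]
    subsets_used: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subsets_used:
            self.subsets_used = {n: len(v) for n, v in self.points.items()}

    @property
    def means(self) -> dict[int, float]:
        return {n: float(np.mean(v)) for n, v in sorted(self.points.items())}

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ns = np.array(sorted(self.points), dtype=float)
        ys = np.array([np.mean(self.points[int(n)]) for n in ns])
        return ns, ys


def _subsets(
    N: int, n: int, max_subsets: int, rng: np.random.Generator
) -> Iterable[tuple[int, ...]]:
    total = math.comb(N, n)
    if total <= max_subsets:
        yield from itertools.combinations(range(N), n)
        return
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_subsets:
        subset = tuple(sorted(rng.choice(N, size=n, replace=False).tolist()))
        if subset not in seen:
            seen.add(subset)
            yield subset


def _build_curve(
    m: OccurrenceMatrix,
    kind: CurveKind,
    value_fn: Callable[[np.ndarray, tuple[int, ...]], float],
    max_subsets: int,
    seed: int,
) -> SamplingCurve:
    if max_subsets < 1:
        raise ValueError(f"max_subsets must be >= 1, got {max_subsets}")
    mat = m.values().astype(bool)
    N = m.n_genomes
    rng = np.random.default_rng(seed)
    points: dict[int, np.ndarray] = {}
    for n in range(1, N + 1):
        vals = [value_fn(mat, s) for s in _subsets(N, n, max_subsets, rng)]
        points[n] = np.array(vals, dtype=float)
    return SamplingCurve(kind=kind, points=points)


def core_curve(
    m: OccurrenceMatrix, max_subsets: int = 1000, seed: int = 42
) -> SamplingCurve:
    """Strict-intersection core size per subset: families in ALL members."""

    def value(mat: np.ndarray, s: tuple[int, ...]) -> float:
        return float(mat[:, list(s)].all(axis=1).sum())

    return _build_curve(m, "core", value, max_subsets, seed)


def specific_curve(
    m: OccurrenceMatrix, max_subsets: int = 1000, seed: int = 42
) -> SamplingCurve:
    """Mean per-genome count of families unique to one genome of the subset."""

    def value(mat: np.ndarray, s: tuple[int, ...]) -> float:
        sub = mat[:, list(s)]
        return float((sub.sum(axis=1) == 1).sum()) / len(s)

    return _build_curve(m, "specific", value, max_subsets, seed)


def pan_curve(
    m: OccurrenceMatrix, max_subsets: int = 1000, seed: int = 42
) -> SamplingCurve:
    """Union (pan-genome) size per subset."""

    def value(mat: np.ndarray, s: tuple[int, ...]) -> float:
        return float(mat[:, list(s)].any(axis=1).sum())

    return _build_curve(m, "pan", value, max_subsets, seed)


def fc(n, K, tau, omega):
    """Core-genome decay model Fc."""
    n = np.asarray(n, dtype=float)
    return K * np.exp(-n / tau) + omega


def fs(n, K, tau, tg_theta):
    """Strain-specific (new gene) decay model Fs."""
    return fc(n, K, tau, tg_theta)


def pan_model(n, D, Ks, tau_s, tg_theta):
    """Pan-genome accumulation model P(n); P(1) = D."""
    n = np.asarray(n, dtype=float)
    r = np.exp(-1.0 / tau_s)
    geo = (1.0 - r ** (n - 1)) / (1.0 - r)
    return D + tg_theta * (n - 1) + Ks * np.exp(-2.0 / tau_s) * geo


@dataclass
class CurveFit:
    """Fitted exponential model: parameters, goodness of fit, residuals."""

    model: Literal["Fc", "Fs", "Pn"]
    params: dict[str, float]
    r2: float
    residuals: np.ndarray
    bse: dict[str, float] | None = None

    def predict(self, n) -> np.ndarray:
        p = self.params
        if self.model == "Fc":
            return fc(n, p["Kc"], p["tau_c"], p["Omega"])
        if self.model == "Fs":
            return fs(n, p["Ks"], p["tau_s"], p["tg_theta"])
        return pan_model(n, p["D"], p["Ks"], p["tau_s"], p["tg_theta"])


_PARAM_NAMES = {"Fc": ("Kc", "tau_c", "Omega"), "Fs": ("Ks", "tau_s", "tg_theta")}


def _profiled_sse(ns: np.ndarray, ys: np.ndarray, tau: float):
    """Closed-form (K, asymptote) for fixed tau; returns (sse, K, asym)."""
    basis = np.column_stack([np.exp(-ns / tau), np.ones_like(ns)])
    coef, *_ = np.linalg.lstsq(basis, ys, rcond=None)
    resid = ys - basis @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def fit_curve(
    curve: SamplingCurve | tuple[Sequence[float], Sequence[float]],
    model: Literal["Fc", "Fs"],
) -> CurveFit:
    """Least-squares fit of Fc or Fs to the per-n means of a sampling curve.

    The decay constant tau is profiled: for each candidate tau the linear
    pair (K, asymptote) is solved exactly, and tau is minimised from eight
    log-spaced starts in [0.3, 30], each polished by bounded scalar search.
    Deterministic; raises :class:`CurveFitError` if every start fails.
    """
    if model not in _PARAM_NAMES:
        raise ValueError(f"model must be 'Fc' or 'Fs', got {model!r}")
    if isinstance(curve, SamplingCurve):
        ns, ys = curve.arrays()
    else:
        ns = np.asarray(curve[0], dtype=float)
        ys = np.asarray(curve[1], dtype=float)
    if np.unique(ns).size < 4:
        raise ValueError("need means at >= 4 distinct n to fit a 3-parameter model")

    best: tuple[float, float] | None = None  # (sse, tau)
    for tau0 in np.geomspace(0.3, 30.0, 8):
        try:
            res = optimize.minimize_scalar(
                lambda t: _profiled_sse(ns, ys, t)[0],
                bounds=(max(tau0 / 4.0, 1e-3), tau0 * 4.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(res.x))
    if best is None:
        raise CurveFitError(f"{model} fit failed from all starts")

    _, tau = best
    _, K, asym = _profiled_sse(ns, ys, tau)
    names = _PARAM_NAMES[model]
    theta = np.array([K, tau, asym])
    fitted = fc(ns, *theta)
    resid = ys - fitted
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return CurveFit(
        model=model,
        params=dict(zip(names, theta.tolist())),
        r2=r2,
        residuals=resid,
        bse=_gauss_newton_bse(ns, resid, theta, names),
    )


def _gauss_newton_bse(ns, resid, theta, names) -> dict[str, float] | None:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    K, tau, _ = theta
    e = np.exp(-ns / tau)
    J = np.column_stack([e, K * e * ns / tau**2, np.ones_like(ns)])
    dof = ns.size - 3
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    return dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None)).tolist()))


def fit_pan(
    curve: SamplingCurve | tuple[Sequence[float], Sequence[float]],
    fs_fit: CurveFit,
) -> CurveFit:
    """Fit the pan accumulation model, inheriting (Ks, tau_s, tg_theta).

    Only the intercept D (= P(1), the mean single-genome size) is free; it
    is the least-squares solution given the inherited strain-specific decay.
    """
    needed = ("Ks", "tau_s", "tg_theta")
    if fs_fit.model != "Fs" or any(k not in fs_fit.params for k in needed):
        raise ValueError("fit_pan needs a fitted Fs model with Ks, tau_s, tg_theta")
    if isinstance(curve, SamplingCurve):
        ns, ys = curve.arrays()
    else:
        ns = np.asarray(curve[0], dtype=float)
        ys = np.asarray(curve[1], dtype=float)
    Ks = fs_fit.params["Ks"]
    tau_s = fs_fit.params["tau_s"]
    tg = fs_fit.params["tg_theta"]
    partial = pan_model(ns, 0.0, Ks, tau_s, tg)
    D = float(np.mean(ys - partial))
    resid = ys - (partial + D)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    bse_D = float(np.sqrt((resid @ resid) / max(ns.size - 1, 1) / ns.size))
    return CurveFit(
        model="Pn",
        params={"D": D, "Ks": Ks, "tau_s": tau_s, "tg_theta": tg},
        r2=r2,
        residuals=resid,
        bse={"D": bse_D},
    )


class SamplingCurveModel:
    """Exponential sampling-curve model in the Model/Results idiom.

    Wraps a :class:`SamplingCurve` (or one built from an occurrence matrix
    via :meth:`from_matrix`) and fits the model matching its kind.
    """

    _MODEL_FOR_KIND = {"core": "Fc", "specific": "Fs"}

    def __init__(self, curve: SamplingCurve, fs_fit: CurveFit | None = None):
        self.curve = curve
        self.fs_fit = fs_fit
        if curve.kind == "pan" and fs_fit is None:
            raise ValueError("pan curve model needs the fitted Fs results")

    @classmethod
    def from_matrix(
        cls,
        m: OccurrenceMatrix,
        kind: CurveKind,
        *,
        max_subsets: int = 1000,
        seed: int = 42,
        fs_fit: CurveFit | None = None,
    ) -> "SamplingCurveModel":
        builder = {"core": core_curve, "specific": specific_curve, "pan": pan_curve}
        return cls(builder[kind](m, max_subsets, seed), fs_fit=fs_fit)

    def fit(self) -> "CurveFitResults":
        if self.curve.kind == "pan":
            fit = fit_pan(self.curve, self.fs_fit)
        else:
            fit = fit_curve(self.curve, self._MODEL_FOR_KIND[self.curve.kind])
        return CurveFitResults(self, fit)


class CurveFitResults:
    """Fitted sampling-curve model with parameters and diagnostics."""

    def __init__(self, model: SamplingCurveModel, fit: CurveFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> dict[str, float]:
        return self.fit.params

    @property
    def bse(self) -> dict[str, float] | None:
        return self.fit.bse

    @property
    def rsquared(self) -> float:
        return self.fit.r2

    def predict(self, n) -> np.ndarray:
        return self.fit.predict(n)

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            f"Sampling-curve fit: {c.kind} ({self.fit.model})",
            "=" * 40,
            f"subset sizes n:     1..{max(c.points)}",
            f"subsets per n:      <= {max(c.subsets_used.values())}",
            f"r^2:                {self.fit.r2:.4f}",
            "",
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, val in self.fit.params.items():
            se = (self.fit.bse or {}).get(name)
            se_txt = f"{se:>12.3g}" if se is not None else f"{'-':>12}"
            lines.append(f"{name:<10}{val:>12.4g}{se_txt}")
        return "\n".join(lines)
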