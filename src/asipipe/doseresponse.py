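"""Sigmoidal dose-response analysis of per-cell ALK Signaling Index data.

Fits the four-parameter logistic (4PL) model

    r(d) = bottom + (top - bottom) * d^hill / (d^hill + ec50^hill)

to per-cell ASI observations against ligand concentration (pg/mL) or
shear-stress magnitude (dyn/cm^2).  In this parameterization a zero dose
evaluates exactly to ``bottom``, so untreated/static observations anchor the
lower asymptote without log-axis workarounds.  When the dose axis is shear
stress the midpoint parameter is conventionally called EF50; it is the same
parameter of the same model.

EC50s of two or more conditions are compared with the extra sum-of-squares
F test: the null model shares a single EC50 across conditions (bottom, top
and Hill slope stay condition-specific by default), the alternative fits
every condition independently, and

    F = ((SSE_null - SSE_alt) / (df_null - df_alt)) / (SSE_alt / df_alt)

is referred to the F distribution with those degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseDataset",
    "FourPLFit",
    "NestedFitComparison",
    "FoldSensitivity",
    "four_pl",
    "fit_4pl",
    "ec50",
    "fit_flow_response",
    "compare_ec50_f_test",
    "fold_sensitivity",
    "round_to_1_significant",
]

# Hill slopes are restricted to a generous positive range: the responses this
# package models (nuclear pSMAD accumulation) increase with dose.
_HILL_BOUNDS = (0.05, 10.0)


@dataclass
class DoseResponseDataset:
    """(dose, response) observations for one experimental condition.

    dose is in pg/mL for ligand titrations or dyn/cm^2 for shear-stress
    ramps; response is the dimensionless per-cell ASI in [0, 1].
    """

    dose: np.ndarray
    response: np.ndarray
    condition: str = ""
    replicate: str | int | None = None
    axis: str = "dose"  # "dose" (ligand) or "shear"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must have the same length")
        if self.dose.ndim != 1:
            raise ValueError("dose and response must be 1-D")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")

    @property
    def n_obs(self) -> int:
        return self.dose.size

    @property
    def n_distinct_doses(self) -> int:
        return np.unique(self.dose).size

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose_col: str = "dose",
        response_col: str = "asi",
        condition: str = "",
        axis: str = "dose",
    ) -> "DoseResponseDataset":
        return cls(
            dose=df[dose_col].to_numpy(dtype=float),
            response=df[response_col].to_numpy(dtype=float),
            condition=condition,
            axis=axis,
        )


def four_pl(
    dose: np.ndarray | float,
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
) -> np.ndarray | float:
    """Evaluate the 4PL curve; dose 0 maps exactly to ``bottom``."""
    d = np.asarray(dose, dtype=float)
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if hill <= 0:
        raise ValueError("hill must be positive")
    dh = np.power(np.clip(d, 0.0, None), hill)
    out = bottom + (top - bottom) * dh / (dh + ec50**hill)
    if np.isscalar(dose):
        return float(out)
    return out


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with residual bookkeeping.

    ``ec50`` is the half-maximal dose; on a shear-stress axis the same
    parameter is the EF50 (exposed via the :attr:`ef50` alias).
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    sse: float
    dof: int
    n_obs: int
    converged: bool
    axis: str = "dose"
    condition: str = ""

    @property
    def ef50(self) -> float:
        return self.ec50

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "axis": self.axis,
            "bottom": self.bottom,
            "top": self.top,
            "ec50" if self.axis == "dose" else "ef50": self.ec50,
            "hill": self.hill,
            "sse": self.sse,
            "dof": self.dof,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def _start_points(dose: np.ndarray, response: np.ndarray) -> list[tuple[float, float, float, float]]:
    """Multi-start initial guesses.

    bottom/top from the 5th/95th response quantiles; EC50 candidates from the
    dose bracketing the half-maximal per-dose mean response (geometric mean of
    the bracket) plus the geometric mid-range of positive doses as fallback;
    Hill slope in {0.5, 1, 2}.
    """
    b0 = float(np.quantile(response, 0.05))
    t0 = float(np.quantile(response, 0.95))
    pos = np.unique(dose[dose > 0])
    candidates: list[float] = []
    if pos.size:
        order = np.argsort(dose)
        d_s, r_s = dose[order], response[order]
        uniq = np.unique(d_s)
        means = np.array([r_s[d_s == u].mean() for u in uniq])
        half = 0.5 * (b0 + t0)
        above = np.nonzero(means >= half)[0]
        if above.size and above[0] > 0 and uniq[above[0] - 1] > 0:
            candidates.append(math.sqrt(uniq[above[0]] * uniq[above[0] - 1]))
        elif above.size and uniq[above[0]] > 0:
            candidates.append(float(uniq[above[0]]))
        candidates.append(math.sqrt(pos.min() * pos.max()))
        candidates.append(float(np.median(pos)))
    seen: set[float] = set()
    ec50s = []
    for c in candidates:
        key = round(math.log10(c), 3)
        if key not in seen:
            seen.add(key)
            ec50s.append(c)
    starts = []
    for e in ec50s:
        for h in (0.5, 1.0, 2.0):
            starts.append((b0, t0, e, h))
    return starts


def _residual_factory(dose, response, parameterization):
    if parameterization == "log":
        def resid(p):
            b, t, log_e, h = p
            return four_pl(dose, b, t, 10.0**log_e, h) - response
        def pack(b, t, e, h):
            return np.array([b, t, math.log10(e), h])
        def unpack(p):
            return p[0], p[1], 10.0 ** p[2], p[3]
    elif parameterization == "linear":
        def resid(p):
            b, t, e, h = p
            return four_pl(dose, b, t, e, h) - response
        def pack(b, t, e, h):
            return np.array([b, t, e, h])
        def unpack(p):
            return p[0], p[1], p[2], p[3]
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return resid, pack, unpack


def fit_4pl(
    data: DoseResponseDataset | pd.DataFrame,
    parameterization: str = "log",
    dose_col: str = "dose",
    response_col: str = "asi",
) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    ``parameterization`` selects the internal optimization variable for the
    midpoint: ``"log"`` optimizes log10(EC50) (the GraphPad log(agonist)
    convention) and ``"linear"`` optimizes EC50 directly; both describe the
    identical curve and agree on noise-free data.

    Requires >= 4 distinct doses.  Flat (unidentifiable) data yields a fit
    with ``converged=False`` rather than an exception.
    """
    if isinstance(data, pd.DataFrame):
        data = DoseResponseDataset.from_dataframe(data, dose_col, response_col)
    if data.n_distinct_doses < 4:
        raise ValueError(
            f"4PL fit needs >= 4 distinct doses, got {data.n_distinct_doses}"
        )
    dose, response = data.dose, data.response
    n = data.n_obs
    span = float(response.max() - response.min())
    if span == 0.0:
        # Constant responses: the midpoint and slope are unidentifiable.
        return FourPLFit(
            bottom=float(response[0]), top=float(response[0]),
            ec50=float(np.median(dose[dose > 0])) if np.any(dose > 0) else 1.0,
            hill=1.0, sse=0.0, dof=n - 4, n_obs=n, converged=False,
            axis=data.axis, condition=data.condition,
        )

    resid, pack, unpack = _residual_factory(dose, response, parameterization)
    pos = dose[dose > 0]
    e_lo, e_hi = pos.min() / 1e3, pos.max() * 1e3
    r_lo = float(response.min() - span)
    r_hi = float(response.max() + span)
    if parameterization == "log":
        lower = [r_lo, r_lo, math.log10(e_lo), _HILL_BOUNDS[0]]
        upper = [r_hi, r_hi, math.log10(e_hi), _HILL_BOUNDS[1]]
    else:
        lower = [r_lo, r_lo, e_lo, _HILL_BOUNDS[0]]
        upper = [r_hi, r_hi, e_hi, _HILL_BOUNDS[1]]

    best = None
    for b0, t0, e0, h0 in _start_points(dose, response):
        x0 = np.clip(pack(b0, t0, e0, h0), lower, upper)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] or (
            math.isclose(sse, best[0], rel_tol=1e-9)
            and abs(unpack(sol.x)[3]) < abs(unpack(best[1].x)[3])
        ):
            best = (sse, sol)
    if best is None:
        raise RuntimeError("4PL optimization failed from every start point")
    sse, sol = best
    b, t, e, h = unpack(sol.x)
    converged = bool(sol.success and (t - b) > 0.01 * span)
    return FourPLFit(
        bottom=float(b), top=float(t), ec50=float(e), hill=float(h),
        sse=sse, dof=n - 4, n_obs=n, converged=converged,
        axis=data.axis, condition=data.condition,
    )


def ec50(fit: FourPLFit, rtol: float = 1e-6) -> float:
    """Return the fitted half-maximal dose, verifying the midpoint identity
    r(ec50) = (top + bottom) / 2."""
    if not fit.converged:
        raise ValueError("EC50 undefined for an unconverged (unidentifiable) fit")
    mid = fit.predict(fit.ec50)
    expected = 0.5 * (fit.top + fit.bottom)
    scale = max(abs(fit.top - fit.bottom), 1e-12)
    if abs(mid - expected) > rtol * scale + 1e-12:
        raise AssertionError("midpoint identity violated; corrupted fit object")
    return fit.ec50


def fit_flow_response(
    data: DoseResponseDataset | pd.DataFrame, **kwargs
) -> FourPLFit:
    """Fit the ASI-vs-shear-stress sigmoid; the midpoint is the EF50.

    Static observations (0 dyn/cm^2) evaluate to ``bottom`` exactly and so
    anchor the lower asymptote.
    """
    if isinstance(data, pd.DataFrame):
        data = DoseResponseDataset.from_dataframe(
            data, kwargs.pop("dose_col", "dose"), kwargs.pop("response_col", "asi"),
            axis="shear",
        )
    else:
        data = DoseResponseDataset(
            data.dose, data.response, data.condition, data.replicate, axis="shear"
        )
    return fit_4pl(data, **kwargs)


@dataclass
class NestedFitComparison:
    """Extra sum-of-squares F test result for shared-vs-separate EC50s."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    shared_fit: dict
    separate_fits: list[FourPLFit] = field(default_factory=list)
    sse_null: float = math.nan
    sse_alt: float = math.nan

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "sse_null": self.sse_null,
            "sse_alt": self.sse_alt,
            "shared_fit": self.shared_fit,
            "separate_fits": [f.to_dict() for f in self.separate_fits],
        }


def _fit_shared_ec50(datasets: Sequence[DoseResponseDataset],
                     alt_fits: Sequence[FourPLFit]):
    """Null-model fit: one log10(EC50) shared, (bottom, top, hill) per dataset."""
    k = len(datasets)
    log_e0 = float(np.mean([math.log10(f.ec50) for f in alt_fits]))
    x0, lower, upper = [], [], []
    for f, ds in zip(alt_fits, datasets):
        span = max(float(ds.response.max() - ds.response.min()), 1e-6)
        x0 += [f.bottom, f.top, f.hill]
        lower += [ds.response.min() - span, ds.response.min() - span, _HILL_BOUNDS[0]]
        upper += [ds.response.max() + span, ds.response.max() + span, _HILL_BOUNDS[1]]
    pos = np.concatenate([ds.dose[ds.dose > 0] for ds in datasets])
    x0.append(log_e0)
    lower.append(math.log10(pos.min() / 1e3))
    upper.append(math.log10(pos.max() * 1e3))

    def resid(p):
        log_e = p[-1]
        parts = []
        for i, ds in enumerate(datasets):
            b, t, h = p[3 * i: 3 * i + 3]
            parts.append(four_pl(ds.dose, b, t, 10.0**log_e, h) - ds.response)
        return np.concatenate(parts)

    sol = optimize.least_squares(
        resid, np.clip(x0, lower, upper), bounds=(lower, upper), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=800,
    )
    sse = float(np.sum(sol.fun**2))
    params = {
        "ec50": 10.0 ** float(sol.x[-1]),
        "per_dataset": [
            {"bottom": float(sol.x[3 * i]), "top": float(sol.x[3 * i + 1]),
             "hill": float(sol.x[3 * i + 2])}
            for i in range(k)
        ],
    }
    return sse, params, sol


def compare_ec50_f_test(
    datasets: Sequence[DoseResponseDataset],
    parameterization: str = "log",
) -> NestedFitComparison:
    """Extra sum-of-squares F test: do the conditions share one EC50?

    The alternative model fits each dataset's four parameters freely; the
    null model constrains the EC50 to a single shared value while bottom,
    top and Hill slope remain per-dataset.  After the null fit each
    alternative fit is re-polished from the null solution so the nested-model
    inequality SSE_null >= SSE_alt holds by construction.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to compare EC50s")
    for i in range(len(datasets)):
        for j in range(i + 1, len(datasets)):
            a, b = datasets[i], datasets[j]
            if a.n_obs == b.n_obs and np.array_equal(a.dose, b.dose) and \
                    np.array_equal(a.response, b.response):
                warnings.warn(
                    "two identical datasets passed to compare_ec50_f_test; "
                    "expect F ~ 0 and p ~ 1", stacklevel=2,
                )
    alt_fits = [fit_4pl(ds, parameterization=parameterization) for ds in datasets]
    for f in alt_fits:
        if not f.converged:
            raise ValueError(
                f"dataset {f.condition!r} did not yield an identifiable 4PL fit"
            )
    sse_null, shared_params, sol = _fit_shared_ec50(datasets, alt_fits)

    # Re-polish each free fit starting from the null solution; keeps alt <= null.
    polished = []
    for i, (ds, f) in enumerate(zip(datasets, alt_fits)):
        p = shared_params["per_dataset"][i]
        resid, pack, unpack = _residual_factory(ds.dose, ds.response, "log")
        pos = ds.dose[ds.dose > 0]
        span = max(float(ds.response.max() - ds.response.min()), 1e-6)
        lower = [ds.response.min() - span, ds.response.min() - span,
                 math.log10(pos.min() / 1e3), _HILL_BOUNDS[0]]
        upper = [ds.response.max() + span, ds.response.max() + span,
                 math.log10(pos.max() * 1e3), _HILL_BOUNDS[1]]
        x0 = np.clip(pack(p["bottom"], p["top"], shared_params["ec50"], p["hill"]),
                     lower, upper)
        sol_i = optimize.least_squares(
            resid, x0, bounds=(lower, upper), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        sse_i = float(np.sum(sol_i.fun**2))
        if sse_i < f.sse:
            b_, t_, e_, h_ = unpack(sol_i.x)
            f = FourPLFit(
                bottom=float(b_), top=float(t_), ec50=float(e_), hill=float(h_),
                sse=sse_i, dof=f.dof, n_obs=f.n_obs, converged=True,
                axis=f.axis, condition=f.condition,
            )
        polished.append(f)
    alt_fits = polished

    n_total = sum(ds.n_obs for ds in datasets)
    k = len(datasets)
    sse_alt = float(sum(f.sse for f in alt_fits))
    df_alt = n_total - 4 * k
    df_null = n_total - (3 * k + 1)
    df_num = df_null - df_alt  # = k - 1
    extra = max(sse_null - sse_alt, 0.0)
    f_stat = (extra / df_num) / (sse_alt / df_alt)
    p_value = float(stats.f.sf(f_stat, df_num, df_alt))
    return NestedFitComparison(
        f_stat=float(f_stat), df_num=df_num, df_den=df_alt, p_value=p_value,
        shared_fit={"sse": sse_null, "dof": df_null, **shared_params},
        separate_fits=alt_fits, sse_null=sse_null, sse_alt=sse_alt,
    )


def round_to_1_significant(x: float) -> float:
    """Round to one significant figure (48.3 -> 50, 0.063 -> 0.06)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x))))))


@dataclass
class FoldSensitivity:
    """Flow-induced increase in ligand sensitivity from averaged EC50s."""

    static_ec50s: list[float]
    flow_ec50s: list[float]
    fold: float

    @property
    def fold_rounded(self) -> float:
        return round_to_1_significant(self.fold)


def fold_sensitivity(
    static_ec50s: Iterable[float], flow_ec50s: Iterable[float]
) -> FoldSensitivity:
    """mean(static EC50s) / mean(flow EC50s).

    Quantifies how much flow lowers the half-maximal ligand concentration;
    the averaged-EC50 convention matches how such tables are summarized.
    """
    s = [float(x) for x in static_ec50s]
    f = [float(x) for x in flow_ec50s]
    if not s or not f:
        raise ValueError("both EC50 lists must be non-empty")
    if any(x <= 0 for x in s + f):
        raise ValueError("EC50s must be positive")
    mean_f = float(np.mean(f))
    if mean_f == 0:
        raise ValueError("flow EC50 mean must be positive")
    return FoldSensitivity(s, f, float(np.mean(s)) / mean_f)
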