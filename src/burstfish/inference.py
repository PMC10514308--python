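"""Constrained fitting of the two-state model to per-cell count histograms.

The workflow mirrors the smFISH bursting analysis: per-cell transcript counts
are binned into a frequency histogram; the fraction of cells with a visible
nascent transcription site fixes the ratio k_on/k_off (active/inactive cells);
the remaining free parameters (k_on, k_prod) are fitted by unweighted least
squares between observed bin frequencies and the model bin probabilities.
Standard errors come from a parametric Monte-Carlo resampling of the fitted
law, and fits are compared between genotypes through burst-metric fold
changes (burst frequency k_on*k_off/(k_on+k_off), burst size k_prod/k_off).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.random import Generator
from scipy.optimize import least_squares

from .exceptions import (
    ArgumentError,
    BoundaryFitError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedRatioError,
)
from .telegraph import (
    KineticParams,
    _as_rng,
    bin_probabilities,
    sample_counts,
    telegraph_moments,
)

__all__ = [
    "NascentTally",
    "CountHistogram",
    "FitOptions",
    "FitResult",
    "MonteCarloErrors",
    "GoodnessOfFit",
    "BurstMetrics",
    "FoldChange",
    "FoldChanges",
    "AbsoluteRates",
    "active_inactive_ratio",
    "build_histogram",
    "fit_two_state",
    "monte_carlo_errors",
    "goodness_of_fit",
    "burst_metrics",
    "compare_fits",
    "to_absolute_rates",
]


# ---------------------------------------------------------------------------
# nascent tally and histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NascentTally:
    """Cells with/without a visible nascent transcription site."""

    n_nascent: int
    n_empty: int

    def __post_init__(self):
        if self.n_nascent < 0 or self.n_empty < 0:
            raise ArgumentError("tally counts must be non-negative")
        if self.n_nascent + self.n_empty < 1:
            raise ArgumentError("tally must contain at least one cell")

    @property
    def n_cells(self) -> int:
        return self.n_nascent + self.n_empty

    @property
    def nascent_fraction(self) -> float:
        return self.n_nascent / self.n_cells


def active_inactive_ratio(tally: NascentTally) -> float:
    """Active/inactive cell ratio = n_nascent/n_empty = k_on/k_off.

    Equating visibly transcribing (nascent-site) cells with the ON state
    turns the observed tally into a hard constraint between the two
    switching rates, which is what makes the histogram fit identifiable.
    """
    if tally.n_empty == 0:
        raise UndefinedRatioError(
            "all cells are active: active/inactive ratio is undefined"
        )
    return tally.n_nascent / tally.n_empty


@dataclass
class CountHistogram:
    """Binned per-cell transcript counts (left-closed, right-open bins)."""

    edges: np.ndarray
    frequencies: np.ndarray
    n_cells: int
    rule: str

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise ArgumentError("edges must be strictly increasing")
        if self.frequencies.size != self.edges.size - 1:
            raise ArgumentError("need one frequency per bin")
        if self.n_cells < 1:
            raise ArgumentError("n_cells must be >= 1")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ArgumentError("frequencies must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.frequencies.size

    def observed_counts(self) -> np.ndarray:
        return self.frequencies * self.n_cells


def build_histogram(
    counts, rule: str = "fd", width: float | None = None, max_bins: int = 256
) -> CountHistogram:
    """Bin per-cell counts with a deterministic, named rule.

    ``fd``    Freedman-Diaconis width 2*IQR/n^(1/3), rounded to an integer
              >= 1 (falls back to width 1 when the IQR collapses) and widened
              if needed so at most ``max_bins`` bins result.
    ``fixed`` explicit integer ``width``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1:
        raise ArgumentError("need at least one cell")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ArgumentError("counts must be finite and non-negative")
    lo = math.floor(counts.min())
    hi = counts.max()
    if rule == "fd":
        q75, q25 = np.percentile(counts, [75, 25])
        w = 2.0 * (q75 - q25) / counts.size ** (1.0 / 3.0)
        w = max(1.0, round(w))
        rule_id = "fd"
    elif rule == "fixed":
        if width is None or width <= 0:
            raise ArgumentError("rule='fixed' requires a positive width")
        w = float(width)
        rule_id = f"fixed:{width:g}"
    else:
        raise ArgumentError(f"unknown binning rule {rule!r}")
    w = max(w, math.ceil((hi - lo + 1.0) / max_bins))
    edges = np.arange(lo, hi + w + 1e-9, w, dtype=float)
    if edges[-1] <= hi:  # guard against float accumulation
        edges = np.append(edges, edges[-1] + w)
    freq, _ = np.histogram(counts, bins=edges)
    return CountHistogram(edges, freq / counts.size, counts.size, rule_id)


# ---------------------------------------------------------------------------
# constrained least-squares fit
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Bounds, starts and optimizer settings for the constrained fit."""

    k_on_bounds: tuple[float, float] = (1e-3, 50.0)
    k_prod_bounds: tuple[float, float] | None = None  # default (1, 10*max count)
    n_starts: int = 8
    initial: tuple[float, float] | None = None  # (k_on, k_prod) extra start
    quad_step: float | None = None  # tanh-sinh step override for bin probs
    xtol: float = 1e-10
    ftol: float = 1e-10


@dataclass
class GoodnessOfFit:
    chi2: float
    dof: int
    reduced: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "dof": self.dof, "reduced": self.reduced}


@dataclass
class MonteCarloErrors:
    se_k_on: float
    se_k_prod: float
    n_reps: int
    n_failed: int
    unreliable: bool

    def to_dict(self) -> dict:
        return {
            "se_k_on": self.se_k_on,
            "se_k_prod": self.se_k_prod,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "unreliable": self.unreliable,
        }


@dataclass
class FitResult:
    """Fitted constrained two-state model.

    Invariant: ``params.k_off == params.k_on / fixed_ratio`` by construction.
    """

    params: KineticParams
    fixed_ratio: float
    n_cells: int
    binning_rule: str
    converged: bool
    cost: float
    se_k_on: float | None = None
    se_k_prod: float | None = None
    gof: GoodnessOfFit | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "fixed_ratio": self.fixed_ratio,
            "n_cells": self.n_cells,
            "binning_rule": self.binning_rule,
            "converged": self.converged,
            "cost": self.cost,
            "se_k_on": self.se_k_on,
            "se_k_prod": self.se_k_prod,
            "gof": self.gof.to_dict() if self.gof else None,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if _json_safe(v)
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _constrained_params(k_on: float, ratio: float, k_prod: float) -> KineticParams:
    return KineticParams(k_on=k_on, k_off=k_on / ratio, k_prod=k_prod)


def _starts(options: FitOptions, bounds_on, bounds_prod, moment_start):
    """Log-spaced multi-starts across the (slightly shrunk) bounds box."""
    n = max(1, options.n_starts)
    starts = []
    if options.initial is not None:
        starts.append(options.initial)
    if moment_start is not None:
        starts.append(moment_start)
    lo_on, hi_on = bounds_on[0] * 3.0, bounds_on[1] / 3.0
    lo_p, hi_p = bounds_prod[0] * 3.0, bounds_prod[1] / 3.0
    n_grid = max(0, n - len(starts))
    if n_grid:
        n_on = max(1, int(round(math.sqrt(n_grid))))
        n_p = max(1, math.ceil(n_grid / n_on))
        for ko in np.geomspace(lo_on, hi_on, n_on):
            for kp in np.geomspace(lo_p, hi_p, n_p):
                starts.append((ko, kp))
    return starts[: max(n, len(starts[:2]))]


def _moment_start(hist: CountHistogram, ratio: float, bounds_on, bounds_prod):
    """Method-of-moments initial guess given the fixed k_on/k_off ratio."""
    mids = 0.5 * (hist.edges[:-1] + hist.edges[1:])
    mean = float(mids @ hist.frequencies)
    var = float(((mids - mean) ** 2) @ hist.frequencies)
    p_on = ratio / (1.0 + ratio)
    if mean <= 0:
        return None
    k_prod = mean / p_on
    # invert var = mean + k_prod^2*a*b/((a+b)^2*(a+b+1)) for a = k_on
    excess = max(var - mean, 1e-12)
    denom = k_prod**2 * p_on * (1.0 - p_on) / excess - 1.0
    k_on = ratio if denom <= 0 else max(ratio * denom / (1.0 + ratio), 1e-3)
    k_on = float(np.clip(k_on, bounds_on[0], bounds_on[1]))
    k_prod = float(np.clip(k_prod, bounds_prod[0], bounds_prod[1]))
    return (k_on, k_prod)


def fit_two_state(
    hist: CountHistogram,
    tally: NascentTally | float,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit (k_on, k_prod) by unweighted least squares on bin frequencies,
    with k_off = k_on/ratio eliminated through the nascent-cell constraint.

    ``tally`` may be a NascentTally or the pre-computed active/inactive
    ratio.  Bounded trust-region (trf) search from multiple log-spaced
    starts; the best objective wins, ties broken toward smaller k_prod.
    """
    options = options or FitOptions()
    if isinstance(tally, NascentTally):
        ratio = active_inactive_ratio(tally)
    else:
        ratio = float(tally)
    if ratio <= 0:
        warnings.warn(
            "active/inactive ratio is 0 (no nascent cells): k_on is forced to "
            "its lower boundary and the constrained fit is degenerate",
            stacklevel=2,
        )
        raise BoundaryFitError("cannot fix k_off = k_on/ratio with ratio 0")

    max_count = float(hist.edges[-1])
    if hist.n_bins < 2 or max_count <= 1.0:
        raise BoundaryFitError(
            "degenerate histogram (all counts in one bin); two-state fit "
            "requires spread in the data"
        )
    bounds_on = options.k_on_bounds
    bounds_prod = options.k_prod_bounds or (1.0, 10.0 * max_count)
    freqs = hist.frequencies
    edges = hist.edges

    def residuals(theta):
        k_on = math.exp(theta[0])
        k_prod = math.exp(theta[1])
        p = _constrained_params(k_on, ratio, k_prod)
        return bin_probabilities(p, edges, h=options.quad_step) - freqs

    lb = np.log([bounds_on[0], bounds_prod[0]])
    ub = np.log([bounds_on[1], bounds_prod[1]])
    moment0 = _moment_start(hist, ratio, bounds_on, bounds_prod)
    fits = []
    for k_on0, k_prod0 in _starts(options, bounds_on, bounds_prod, moment0):
        x0 = np.clip(np.log([k_on0, k_prod0]), lb, ub)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lb, ub),
                method="trf",
                xtol=options.xtol,
                ftol=options.ftol,
            )
        except Exception as exc:  # pragma: no cover - defensive
            fits.append({"success": False, "error": str(exc)})
            continue
        fits.append(
            {
                "success": bool(res.status > 0),
                "cost": float(res.cost),
                "x": res.x,
                "status": int(res.status),
            }
        )
    ok = [f for f in fits if f.get("success")]
    if not ok:
        raise FitFailureError(
            "no optimizer start converged", diagnostics={"starts": fits}
        )
    best_cost = min(f["cost"] for f in ok)
    candidates = [f for f in ok if f["cost"] <= best_cost * (1 + 1e-10) + 1e-300]
    best = min(candidates, key=lambda f: f["x"][1])  # tie -> smaller k_prod

    at_bound = bool(
        np.any(np.abs(best["x"] - lb) < 1e-6) or np.any(np.abs(best["x"] - ub) < 1e-6)
    )
    if at_bound:
        warnings.warn(
            "best fit sits on a parameter bound; treat the result as "
            "unconverged",
            stacklevel=2,
        )
    k_on, k_prod = map(math.exp, best["x"])
    return FitResult(
        params=_constrained_params(k_on, ratio, k_prod),
        fixed_ratio=ratio,
        n_cells=hist.n_cells,
        binning_rule=hist.rule,
        converged=not at_bound,
        cost=best["cost"],
        diagnostics={
            "n_starts": len(fits),
            "n_converged": len(ok),
            "status": best["status"],
            "at_bound": at_bound,
        },
    )


# ---------------------------------------------------------------------------
# Monte-Carlo errors
# ---------------------------------------------------------------------------


def _rebin_width(rule: str) -> dict:
    if rule.startswith("fixed:"):
        return {"rule": "fixed", "width": float(rule.split(":", 1)[1])}
    return {"rule": rule}


def monte_carlo_errors(
    fit: FitResult,
    n_cells: int | None = None,
    n_reps: int = 100,
    seed=0,
    options: FitOptions | None = None,
) -> MonteCarloErrors:
    """Parametric-bootstrap standard errors for the fitted parameters.

    Draws ``n_reps`` synthetic datasets of ``n_cells`` cells from the fitted
    PMF, resamples the nascent tally binomially at the fitted ON fraction,
    refits each dataset with the same binning rule, and reports the standard
    deviation of each refitted parameter.  Refits start from the parent
    optimum (plus spread starts) to keep the resampling cheap.  The result is
    also written onto ``fit.se_k_on`` / ``fit.se_k_prod``.
    """
    if n_reps < 2:
        raise ArgumentError("n_reps must be >= 2")
    if not fit.converged:
        raise ArgumentError("Monte-Carlo errors require a converged fit")
    n_cells = n_cells or fit.n_cells
    rng = _as_rng(seed)
    p_on = fit.params.on_fraction
    refit_opts = replace(
        options or FitOptions(),
        n_starts=3,
        initial=(fit.params.k_on, fit.params.k_prod),
    )
    k_ons, k_prods = [], []
    n_failed = 0
    for _ in range(n_reps):
        counts = sample_counts(fit.params, n_cells, rng)
        n_nascent = int(rng.binomial(n_cells, p_on))
        if n_nascent == 0 or n_nascent == n_cells:
            n_failed += 1
            continue
        hist = build_histogram(counts, **_rebin_width(fit.binning_rule))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_two_state(
                    hist, NascentTally(n_nascent, n_cells - n_nascent), refit_opts
                )
        except FitFailureError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        k_ons.append(refit.params.k_on)
        k_prods.append(refit.params.k_prod)
    if len(k_ons) < 2:
        raise FitFailureError(
            "fewer than two Monte-Carlo replicates could be refitted",
            diagnostics={"n_failed": n_failed},
        )
    unreliable = n_failed > 0.2 * n_reps
    if unreliable:
        warnings.warn(
            f"{n_failed}/{n_reps} Monte-Carlo replicate fits failed; the "
            "reported errors may be unreliable",
            stacklevel=2,
        )
    mc = MonteCarloErrors(
        se_k_on=float(np.std(k_ons, ddof=1)),
        se_k_prod=float(np.std(k_prods, ddof=1)),
        n_reps=n_reps,
        n_failed=n_failed,
        unreliable=unreliable,
    )
    fit.se_k_on = mc.se_k_on
    fit.se_k_prod = mc.se_k_prod
    return mc


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(
    fit: FitResult, hist: CountHistogram, min_expected: float = 5.0
) -> GoodnessOfFit:
    """Reduced Pearson chi-square of the fit against the observed histogram.

    Adjacent bins are pooled left-to-right until each pooled bin has an
    expected cell count of at least ``min_expected`` (a trailing short pool
    is merged into its neighbour); the statistic is divided by
    (pooled bins - 2 free parameters - 1).
    """
    observed = hist.observed_counts()
    expected = bin_probabilities(fit.params, hist.edges) * hist.n_cells
    pooled_o, pooled_e = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_e:
        pooled_o[-1] += acc_o
        pooled_e[-1] += acc_e
    n_pooled = len(pooled_e)
    dof = n_pooled - 2 - 1
    if dof < 1:
        raise InsufficientDataError(
            f"only {n_pooled} pooled bins; need at least 4 (2 free parameters "
            "+ 2) for a chi-square statistic"
        )
    o = np.asarray(pooled_o)
    e = np.asarray(pooled_e)
    chi2 = float(((o - e) ** 2 / e).sum())
    g = GoodnessOfFit(chi2=chi2, dof=dof, reduced=chi2 / dof)
    fit.gof = g
    return g


# ---------------------------------------------------------------------------
# burst metrics, fold changes, absolute rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstMetrics:
    """Derived burst statistics, all per mRNA degradation time.

    burst_frequency = k_on*k_off/(k_on+k_off): rate of productive ON periods;
    burst_size = k_prod/k_off: mean transcripts made per ON period;
    their product is the mean expression k_prod*k_on/(k_on+k_off).
    """

    burst_frequency: float
    burst_size: float
    mean_expression: float

    def to_dict(self) -> dict:
        return {
            "burst_frequency": self.burst_frequency,
            "burst_size": self.burst_size,
            "mean_expression": self.mean_expression,
        }


def burst_metrics(params: KineticParams) -> BurstMetrics:
    if not isinstance(params, KineticParams):
        raise InvalidParameterError("params must be a KineticParams")
    a, b, lam = params.k_on, params.k_off, params.k_prod
    freq = a * b / (a + b)
    size = lam / b
    return BurstMetrics(freq, size, freq * size)


@dataclass(frozen=True)
class FoldChange:
    """Reference/comparison ratio of one quantity with a direction label."""

    ratio: float  # reference / comparison

    @property
    def fold(self) -> float:
        return max(self.ratio, 1.0 / self.ratio)

    @property
    def direction(self) -> str:
        if math.isclose(self.ratio, 1.0, rel_tol=1e-12):
            return "unchanged"
        return "reduction" if self.ratio > 1.0 else "increase"

    def to_dict(self) -> dict:
        return {"ratio": self.ratio, "fold": self.fold, "direction": self.direction}


@dataclass(frozen=True)
class FoldChanges:
    k_on: FoldChange
    k_off: FoldChange
    k_prod: FoldChange
    burst_frequency: FoldChange
    burst_size: FoldChange
    reference: str = "reference"
    comparison: str = "comparison"

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "comparison": self.comparison,
            **{
                name: getattr(self, name).to_dict()
                for name in ("k_on", "k_off", "k_prod", "burst_frequency", "burst_size")
            },
        }


def _params_of(fit) -> KineticParams:
    if isinstance(fit, KineticParams):
        return fit
    if isinstance(fit, FitResult):
        if not fit.converged:
            raise ArgumentError("compare_fits requires converged fits")
        return fit.params
    raise ArgumentError("expected a FitResult or KineticParams")


def compare_fits(
    reference, comparison, labels: tuple[str, str] = ("reference", "comparison")
) -> FoldChanges:
    """Fold changes (reference vs comparison) of the rate constants and the
    derived burst metrics, with direction labels ('reduction' means the
    comparison is lower than the reference)."""
    ref = _params_of(reference)
    comp = _params_of(comparison)
    m_ref = burst_metrics(ref)
    m_comp = burst_metrics(comp)
    return FoldChanges(
        k_on=FoldChange(ref.k_on / comp.k_on),
        k_off=FoldChange(ref.k_off / comp.k_off),
        k_prod=FoldChange(ref.k_prod / comp.k_prod),
        burst_frequency=FoldChange(m_ref.burst_frequency / m_comp.burst_frequency),
        burst_size=FoldChange(m_ref.burst_size / m_comp.burst_size),
        reference=labels[0],
        comparison=labels[1],
    )


@dataclass(frozen=True)
class AbsoluteRates:
    """Rates per unit time obtained from an mRNA half-life."""

    k_on: float
    k_off: float
    k_prod: float
    degradation_rate: float

    def to_dict(self) -> dict:
        return {
            "k_on": self.k_on,
            "k_off": self.k_off,
            "k_prod": self.k_prod,
            "degradation_rate": self.degradation_rate,
        }


def to_absolute_rates(params: KineticParams, mrna_half_life: float) -> AbsoluteRates:
    """Convert dimensionless rates to absolute rates via delta = ln2/half-life."""
    if not (mrna_half_life > 0 and math.isfinite(mrna_half_life)):
        raise ArgumentError("mRNA half-life must be positive and finite")
    delta = math.log(2.0) / mrna_half_life
    return AbsoluteRates(
        k_on=params.k_on * delta,
        k_off=params.k_off * delta,
        k_prod=params.k_prod * delta,
        degradation_rate=delta,
    )


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------


def histogram_with_fit_frame(fit: FitResult, hist: CountHistogram) -> pd.DataFrame:
    """Observed bin frequencies next to fitted bin probabilities (for plotting)."""
    model = bin_probabilities(fit.params, hist.edges)
    return pd.DataFrame(
        {
            "bin_left": hist.edges[:-1],
            "bin_right": hist.edges[1:],
            "observed_frequency": hist.frequencies,
            "fitted_probability": model,
        }
    )
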