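"""Dose–response analytics.

Transcript side: a Williams-type trend prefilter (isotonic amalgamated
dose-group means against control, permutation p-value), exponential
(Exp5) benchmark-dose fitting ``m(d) = a * (c - (c - 1) * exp(-(b d)^g))``
and benchmark-dose retrieval, plus accumulation curves of per-gene BMDs.

Respirometry side: percent-of-control normalization of oxygen consumption
rates (subtract the positive-control mean, i.e. non-mitochondrial
respiration, and scale the vehicle basal mean to 100 %), and one-way
ANOVA + Dunnett many-to-one lowest-observed-effect levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from toxsig.errors import DesignError, ToxsigError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Williams trend test

def _pava(means, weights, increasing=True):
    """Weighted pool-adjacent-violators on a short 1-D sequence."""
    if not increasing:
        return [-m for m in _pava([-m for m in means], weights, True)]
    vals = list(means)
    wts = list(weights)
    idx = [[i] for i in range(len(vals))]
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            w = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / w
            wts[i] = w
            idx[i].extend(idx[i + 1])
            del vals[i + 1], wts[i + 1], idx[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = [0.0] * sum(len(b) for b in idx)
    for v, block in zip(vals, idx):
        for j in block:
            out[j] = v
    return out


@dataclass
class TrendTestResult:
    gene_id: str
    statistic: float
    pvalue: float
    max_fold_change: float
    direction: str
    passes_prefilter: bool = field(default=False)


def _williams_t(values_by_group, s2, n0):
    """Williams statistic for the increasing alternative.

    values_by_group: list of (mean, n) with control first. The treatment
    means are amalgamated to be nondecreasing; T compares the highest
    amalgamated mean with the control mean.
    """
    (m0, _), *treat = values_by_group
    means = [m for m, _ in treat]
    ns = [n for _, n in treat]
    iso = _pava(means, ns, increasing=True)
    mk, nk = iso[-1], ns[-1]
    se = math.sqrt(s2 * (1.0 / nk + 1.0 / n0))
    return (mk - m0) / se if se > 0 else 0.0


def williams_trend_test(
    responses: dict[float, np.ndarray],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    gene_id: str = "",
) -> TrendTestResult:
    """Williams-type monotone trend test of dose-group means vs control.

    ``responses`` maps dose (control = lowest, typically 0) to replicate
    values. The statistic uses isotonic (pool-adjacent-violators)
    amalgamation of the treated group means, scaled by the pooled
    within-group standard error; the direction (increasing or decreasing)
    with the larger |T| is reported. The p-value is a permutation p over
    random reassignment of replicates to dose groups (one-sided in the
    chosen direction, add-one corrected).

    ``max_fold_change`` is the largest |group mean / control mean| fold
    change across doses (as a ratio; for log2 data exponentiate first);
    the prefilter flag requires p < ``p_threshold`` and max FC >
    ``fc_threshold``.
    """
    doses = sorted(responses)
    if len(doses) < 2:
        raise DesignError("need a control and at least one dose group")
    groups = [np.asarray(responses[d], dtype=float) for d in doses]
    if any(g.size < 1 for g in groups):
        raise DesignError("every dose group needs at least one replicate")
    ns = [g.size for g in groups]
    df = sum(n - 1 for n in ns)
    if df <= 0:
        raise DesignError("no residual degrees of freedom; add replicates")
    s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / df

    def one_sided_t(gs, increasing):
        mg = [((g.mean() if increasing else -g.mean()), g.size) for g in gs]
        return _williams_t(mg, s2, mg[0][1])

    t_inc = one_sided_t(groups, True)
    t_dec = one_sided_t(groups, False)
    if t_inc >= t_dec:
        t_obs, direction = t_inc, "increasing"
    else:
        t_obs, direction = t_dec, "decreasing"

    # the permutation null mirrors the direction selection (max over the two
    # one-sided statistics), so the p-value is calibrated despite the
    # data-driven choice of direction
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    edges = np.cumsum(ns)[:-1]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        gs = np.split(perm, edges)
        if max(one_sided_t(gs, True), one_sided_t(gs, False)) >= t_obs:
            exceed += 1
    pvalue = (1 + exceed) / (1 + n_perm)

    m0 = groups[0].mean()
    if m0 == 0:
        max_fc = np.inf
    else:
        ratios = [g.mean() / m0 for g in groups[1:]]
        max_fc = max(max(abs(r) for r in ratios), max(abs(1 / r) if r != 0 else np.inf for r in ratios))
    passes = (pvalue < p_threshold) and (max_fc > fc_threshold)
    return TrendTestResult(
        gene_id=gene_id,
        statistic=float(t_obs),
        pvalue=float(pvalue),
        max_fold_change=float(max_fc),
        direction=direction,
        passes_prefilter=bool(passes),
    )


# ---------------------------------------------------------------------------
# Exp5 model

def exp5(d, a, b, c, g):
    """Exponential model 5: ``a * (c - (c - 1) * exp(-(b d)^g))``.

    ``a`` is the response at dose 0, ``c`` the fold asymptote at high dose
    (c > 1 increasing, c < 1 decreasing, c = 1 flat), ``b`` a rate in
    1/dose units and ``g`` a shape exponent.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        z = np.minimum(np.power(b * d, g), 700.0)
    return a * (c - (c - 1.0) * np.exp(-z))


@dataclass
class Exp5Fit:
    """Fitted Exp5 curve with benchmark-dose retrieval."""

    a: float
    b: float
    c: float
    g: float
    rss: float
    converged: bool
    n_obs: int
    bmr_type: str = "relative"
    bmr_value: float = 0.10
    bmd_: float | None = field(default=None, repr=False)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.g)

    def predict(self, d):
        return exp5(d, *self.params)

    @property
    def bmd(self) -> float:
        if self.bmd_ is None:
            self.bmd_ = compute_bmd(self, (self.bmr_type, self.bmr_value))
        return self.bmd_

    def summary(self) -> str:
        bmd = self.bmd
        return (
            f"Exp5 fit (n={self.n_obs}, converged={self.converged})\n"
            f"  a={self.a:.6g}  b={self.b:.6g}  c={self.c:.6g}  g={self.g:.6g}\n"
            f"  rss={self.rss:.6g}\n"
            f"  BMD ({self.bmr_type} {self.bmr_value:g}): "
            + (f"{bmd:.6g}" if np.isfinite(bmd) else "undefined")
        )


class Exp5Model:
    """Nonlinear least-squares Exp5 dose–response model.

    Parameters
    ----------
    doses, responses
        Matched arrays; doses >= 0, at least 4 distinct dose levels (the
        model has 4 free parameters).
    """

    def __init__(self, doses, responses):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if (self.doses < 0).any():
            raise ValueError("doses must be non-negative")
        if len(np.unique(self.doses)) < 4:
            raise DesignError(
                "Exp5 has 4 free parameters; need >= 4 distinct dose levels"
            )

    def _residuals(self, theta):
        a, logb, c, logg = theta
        b = np.exp(np.clip(logb, -50.0, 50.0))
        g = np.exp(np.clip(logg, -3.0, 3.0))
        return exp5(self.doses, a, b, c, g) - self.responses

    def _jacobian(self, theta):
        a, logb, c, logg = theta
        b = np.exp(np.clip(logb, -50.0, 50.0))
        g = np.exp(np.clip(logg, -3.0, 3.0))
        d = self.doses
        with np.errstate(over="ignore", divide="ignore"):
            bd = b * d
            z = np.minimum(np.power(bd, g), 700.0)
            E = np.exp(-z)
            ln_bd = np.where(bd > 0, np.log(np.where(bd > 0, bd, 1.0)), 0.0)
        core = a * (c - 1.0) * E * z  # z -> 0 at d = 0, killing both log-derivatives
        J = np.empty((d.size, 4))
        J[:, 0] = c - (c - 1.0) * E
        J[:, 1] = core * g
        J[:, 2] = a * (1.0 - E)
        J[:, 3] = core * ln_bd * g
        return J

    def fit(self, n_starts: int = 8, bmr=("relative", 0.10)) -> Exp5Fit:
        """Multi-start trust-region least squares over a log-spaced b grid."""
        d = self.doses
        y = self.responses
        ctrl = y[d == d.min()].mean() if (d == d.min()).any() else y.mean()
        a0 = ctrl if ctrl != 0 else max(abs(y).max(), 1e-6)
        top = y[d == d.max()].mean()
        c0 = np.clip(top / a0 if a0 != 0 else 1.0, 0.05, 20.0)
        pos = d[d > 0]
        # span rate constants from well below 1/d_max (shallow curves whose
        # benchmark response sits near the top dose) to beyond 1/d_min
        b_grid = np.geomspace(0.1 / pos.max(), 3.0 / pos.min(), n_starts)
        best = None
        best_ok = False
        for b0 in b_grid:
            theta0 = np.array([a0, np.log(b0), c0, 0.0])
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    theta0,
                    jac=self._jacobian,
                    method="trf",
                    xtol=1e-10,
                    ftol=1e-10,
                    gtol=1e-10,
                    max_nfev=1000,
                )
            except Exception:  # singular Jacobian at a bad start
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
                best_ok = bool(sol.success)
        if best is None:
            flat_rss = float(((y - y.mean()) ** 2).sum())
            return Exp5Fit(
                a=float(y.mean()), b=1.0, c=1.0, g=1.0, rss=flat_rss,
                converged=False, n_obs=len(y),
                bmr_type=bmr[0], bmr_value=bmr[1],
            )
        rss, sol = best
        a, logb, c, logg = sol.x
        # same clipping as the residual function, so stored parameters
        # reproduce the optimised curve
        b = float(np.exp(np.clip(logb, -50.0, 50.0)))
        g = float(np.exp(np.clip(logg, -3.0, 3.0)))
        return Exp5Fit(
            a=float(a), b=b, c=float(c), g=g,
            rss=rss, converged=best_ok, n_obs=len(y),
            bmr_type=bmr[0], bmr_value=bmr[1],
        )


def compute_bmd(fit: Exp5Fit, bmr=("relative", 0.10)) -> float:
    """Benchmark dose: the dose where the fitted curve reaches the BMR.

    For a relative BMR of magnitude ``p`` the target response is
    ``a*(1+p)`` for increasing curves (c > 1) and ``a*(1-p)`` for
    decreasing ones (c < 1); inversion is closed-form,
    ``BMD = (-ln((c - t/a) / (c - 1)))^(1/g) / b``. Targets outside the
    curve's range (a, a*c) yield NaN with a warning. ``("absolute", t)``
    uses the raw target ``t``.
    """
    a, b, c, g = fit.params
    kind, magnitude = bmr
    if c == 1.0 or a == 0.0:
        logger.warning("flat fitted curve; BMD undefined")
        return float("nan")
    if kind == "relative":
        target = a * (1.0 + magnitude) if c > 1.0 else a * (1.0 - magnitude)
    elif kind == "absolute":
        target = float(magnitude)
    elif kind == "sd":
        # magnitude = (k, control_sd): shift of k control SDs from baseline
        k, sd = magnitude
        target = a + (k * sd if c > 1.0 else -k * sd)
    else:
        raise ValueError(f"unknown BMR type {kind!r}")
    x = (c - target / a) / (c - 1.0)
    if not (0.0 < x < 1.0):
        logger.warning(
            "BMR target %.4g outside fitted range (%.4g, %.4g); BMD undefined",
            target, min(a, a * c), max(a, a * c),
        )
        return float("nan")
    return float((-math.log(x)) ** (1.0 / g) / b)


def accumulation_curve(bmds) -> pd.DataFrame:
    """Cumulative count of genes with BMD <= concentration.

    Returns a two-column frame ``(concentration, cumulative_count)`` with
    one row per distinct finite BMD, i.e. the breakpoints of the
    nondecreasing step function; evaluation at or beyond the largest BMD
    gives the total number of genes with a defined BMD.
    """
    vals = np.asarray(
        [v for v in (bmds.values() if isinstance(bmds, dict) else bmds) if np.isfinite(v)],
        dtype=float,
    )
    if vals.size == 0:
        return pd.DataFrame(columns=["concentration", "cumulative_count"])
    uniq, counts = np.unique(vals, return_counts=True)
    return pd.DataFrame(
        {"concentration": uniq, "cumulative_count": np.cumsum(counts)}
    )


# ---------------------------------------------------------------------------
# respirometry

def ocr_percent_of_control(
    raw,
    positive_control_values,
    vehicle_basal_values,
    noneffective_values=None,
):
    """Express OCR as percent of vehicle control.

    ``percent = 100 * (raw - mean(pos)) / (mean(vehicle basal) - mean(pos))``
    — the positive control (a full ETC inhibitor) defines non-mitochondrial
    respiration (0 %), the vehicle basal mean the 100 % asymptote. If
    ``noneffective_values`` (raw OCR at >= 2 non-effective concentrations)
    is given, the result is rescaled so their mean is 100 %.
    """
    pos = float(np.mean(np.asarray(positive_control_values, dtype=float)))
    veh = float(np.mean(np.asarray(vehicle_basal_values, dtype=float)))
    if veh == pos:
        raise ToxsigError("vehicle and positive-control means coincide")
    pct = 100.0 * (np.asarray(raw, dtype=float) - pos) / (veh - pos)
    if noneffective_values is not None:
        ne = np.asarray(noneffective_values, dtype=float)
        if ne.size < 2:
            raise ToxsigError("need >= 2 non-effective concentration values")
        ne_pct = 100.0 * (ne - pos) / (veh - pos)
        pct = 100.0 * pct / ne_pct.mean()
    return pct


def anova_dunnett_loel(
    responses: dict[float, np.ndarray],
    alpha: float = 0.05,
) -> tuple[float | None, pd.DataFrame]:
    """One-way ANOVA followed by Dunnett's many-to-one posttest.

    ``responses`` maps concentration to replicate values; the lowest
    concentration (typically 0) is the control. Returns the LOEL — the
    lowest concentration with Dunnett-adjusted p < ``alpha`` — or None,
    together with the per-concentration table (ANOVA F/p recorded in
    ``df.attrs``).
    """
    doses = sorted(responses)
    if len(doses) < 2:
        raise DesignError("need a control and at least one treated group")
    groups = [np.asarray(responses[d], dtype=float) for d in doses]
    if any(g.size < 2 for g in groups):
        raise DesignError("every group needs >= 2 replicates")
    control, treated = groups[0], groups[1:]
    f_stat, f_p = stats.f_oneway(*groups)
    res = stats.dunnett(*treated, control=control)
    table = pd.DataFrame(
        {
            "concentration": doses[1:],
            "mean_diff": [t.mean() - control.mean() for t in treated],
            "p_adjusted": res.pvalue,
        }
    )
    table.attrs["anova_F"] = float(f_stat)
    table.attrs["anova_p"] = float(f_p)
    sig = table[table["p_adjusted"] < alpha]
    loel = float(sig["concentration"].min()) if not sig.empty else None
    return loel, table
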