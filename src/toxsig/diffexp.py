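"""Negative-binomial Wald-test differential expression.

The model is the standard genewise NB GLM with log link used for targeted
count data: counts ``K_gj ~ NB(mean = s_j * q_gj, dispersion = alpha_g)``
with ``log q_gj = X_j . beta_g``. Size factors ``s_j`` come from the
median-of-ratios estimator; dispersions from a method-of-moments estimate
shrunk toward a fitted ``a0 + a1/mu`` mean–dispersion trend (a documented
simplification of empirical-Bayes shrinkage); coefficients from IRLS, with
Wald p-values for the condition coefficient against a standard normal.

Designs supported: pairwise (intercept + condition) and batch-aware
(intercept + experiment/batch dummies + condition), the latter giving the
marginal condition effect across batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from toxsig.containers import CountMatrix, SampleMeta
from toxsig.errors import DesignError, ToxsigError

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

DE_COLUMNS = [
    "ctr_read_counts",
    "treat_read_counts",
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "dispersion",
    "converged",
]


# ---------------------------------------------------------------------------
# normalization

def size_factors(cm: CountMatrix, method: str = "ratio") -> pd.Series:
    """Median-of-ratios size factors.

    Per sample, the median over genes of count / (geometric mean of that
    gene across samples), restricted to genes with an all-positive row
    (``method="ratio"``). ``method="poscounts"`` computes each gene's
    geometric mean over its positive entries only, as a fallback when no
    gene is positive everywhere. Factors are rescaled so their geometric
    mean is exactly 1.
    """
    K = cm.counts.to_numpy(dtype=float)
    if K.size == 0:
        raise ToxsigError("empty count matrix")
    with np.errstate(divide="ignore"):
        logK = np.log(K)
    if method == "ratio":
        ok = np.all(K > 0, axis=1)
        if not ok.any():
            raise ToxsigError(
                "no gene has positive counts in every sample; "
                "use method='poscounts' as a pseudo-reference fallback"
            )
        loggeo = logK[ok].mean(axis=1, keepdims=True)
        ratios = logK[ok] - loggeo
    elif method == "poscounts":
        pos = K > 0
        ok = pos.any(axis=1)
        loggeo = np.where(
            ok[:, None],
            np.nansum(np.where(pos, logK, np.nan), axis=1, keepdims=True)
            / np.maximum(pos.sum(axis=1, keepdims=True), 1),
            np.nan,
        )
        ratios = np.where(pos, logK - loggeo, np.nan)[ok]
    else:
        raise ValueError(f"unknown method {method!r}")
    logsf = np.nanmedian(ratios, axis=0)
    logsf = logsf - logsf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(logsf), index=cm.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion

def estimate_dispersion(
    cm: CountMatrix,
    sf: pd.Series,
    groups: pd.Series,
    shrinkage: float = 0.5,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion, method of moments with trend shrinkage.

    Within each replicate group the sample variance of normalized counts is
    pooled; the raw estimate is ``alpha_hat = max(0, (s2 - mu) / mu^2)``
    with ``mu`` the overall mean of normalized counts. A mean–dispersion
    trend ``alpha_tr(mu) = a0 + a1/mu`` is fit by least squares on genes
    with positive raw estimates and the final value is the convex blend
    ``(1 - shrinkage) * alpha_hat + shrinkage * alpha_tr(mu)``, floored.

    ``groups`` labels replicate groups (same compound, concentration and
    batch); every group must have >= 2 members.
    """
    groups = groups.reindex(cm.sample_ids)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise DesignError(f"groups with a single replicate: {bad}")
    norm = cm.counts.to_numpy(dtype=float) / sf.reindex(cm.sample_ids).to_numpy()
    mu = norm.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in sizes.index:
        cols = np.asarray(groups.values == g)
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.sum() - 1
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    alpha_hat = np.clip(alpha_hat, 0.0, None)

    use = (alpha_hat > 0) & (mu > 1e-8)
    if use.sum() >= 10:
        A = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(A, alpha_hat[use], rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
    else:  # too few informative genes to fit a trend
        a0, a1 = float(np.median(alpha_hat[use])) if use.any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    alpha = (1.0 - shrinkage) * alpha_hat + shrinkage * trend
    alpha = np.clip(alpha, floor, None)
    return pd.Series(alpha, index=cm.probe_ids, name="dispersion")


# ---------------------------------------------------------------------------
# genewise NB GLM via IRLS, vectorised across genes

def _nb_deviance(y, mu, alpha):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return 2.0 * (t1 - t2).sum(axis=1)


def _irls_nb(Y, X, offset, alpha, tol=1e-8, maxiter=100, ridge=1e-10):
    """Fit NB log-link GLMs for all genes at once.

    Y: (G, S) counts; X: (S, p) design; offset: (S,) log size factors;
    alpha: (G,) dispersions. Returns (beta (G,p), cov (G,p,p),
    converged (G,), n_iter).
    """
    G, S = Y.shape
    p = X.shape[1]
    eta0 = np.log(Y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, eta0.T, rcond=None)
    beta = beta.T  # (G, p)
    a = alpha[:, None]
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    it = 0
    for it in range(1, maxiter + 1):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X)
        XtWX += ridge * np.eye(p)
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        dev = _nb_deviance(Y, mu, a)
        done = np.abs(dev - dev_old) < tol * (np.abs(dev) + 0.1)
        newly = done & ~converged
        converged |= done
        # freeze converged genes to keep their estimates stable
        beta = np.where(converged[:, None] & ~newly[:, None], beta, beta_new)
        dev_old = dev
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + a * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + ridge * np.eye(p)
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged, it


# ---------------------------------------------------------------------------
# model / results objects

@dataclass
class DEResults:
    """Fitted differential-expression results.

    ``table`` holds, per gene: mean normalized counts of the control and
    treatment groups, baseMean (mean normalized counts over all compared
    samples), log2FoldChange (treatment over control), its standard error,
    the Wald statistic and p-value, the BH-adjusted p-value, the dispersion
    used, and a convergence flag.
    """

    table: pd.DataFrame
    size_factors: pd.Series
    design_columns: list[str]
    contrast: str

    def significant(
        self,
        padj_max: float = 0.05,
        lfc_min: float = 0.585,
        basemean_min: float = 10.0,
    ) -> pd.DataFrame:
        return significance_filter(self.table, padj_max, lfc_min, basemean_min)

    def summary(self) -> str:
        t = self.table
        n_sig = len(self.significant())
        lines = [
            f"NB Wald differential expression — contrast: {self.contrast}",
            f"design columns: {self.design_columns}",
            f"genes tested: {int(t['pvalue'].notna().sum())} of {len(t)}",
            f"significant (padj<0.05, |log2FC|>0.585, baseMean>10): {n_sig}",
            "",
            t.sort_values("padj").head(10).to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


class DEModel:
    """Negative-binomial Wald model for one contrast.

    Parameters
    ----------
    cm, meta
        Counts and annotation covering the compared samples (treatment and
        control groups; other samples may be present and are ignored).
    treatment, control
        Sample-id lists for the two groups.
    batch
        Optional per-sample batch labels (e.g. experiment id) to include
        as covariates; required for merged two-experiment class designs.
    size_factors_, dispersions
        Precomputed values; estimated from the compared samples otherwise.
    """

    def __init__(
        self,
        cm: CountMatrix,
        meta: SampleMeta | None,
        treatment: list[str],
        control: list[str],
        batch: pd.Series | None = None,
        size_factors_: pd.Series | None = None,
        dispersions: pd.Series | None = None,
        dispersion_shrinkage: float = 0.5,
    ):
        if not treatment or not control:
            raise DesignError("both contrast groups must be nonempty")
        overlap = set(treatment) & set(control)
        if overlap:
            raise DesignError(f"samples in both groups: {sorted(overlap)[:3]}")
        self.samples = list(control) + list(treatment)
        self.cm = cm.subset_samples(self.samples)
        self.meta = meta
        self.treatment = list(treatment)
        self.control = list(control)
        self.condition = np.array([0] * len(control) + [1] * len(treatment))
        self.dispersion_shrinkage = dispersion_shrinkage
        self._sf = size_factors_.reindex(self.samples) if size_factors_ is not None else None
        self._disp = dispersions
        self.design_columns = ["intercept"]
        self.batch = None
        if batch is not None:
            b = batch.reindex(self.samples)
            if b.isna().any():
                raise DesignError("batch labels missing for some compared samples")
            levels = sorted(b.unique())
            self.batch = b
            self.design_columns += [f"batch[{lv}]" for lv in levels[1:]]
        self.design_columns.append("condition")

    def _design(self) -> np.ndarray:
        n = len(self.samples)
        cols = [np.ones(n)]
        if self.batch is not None:
            levels = sorted(self.batch.unique())
            for lv in levels[1:]:
                cols.append((self.batch.values == lv).astype(float))
        cols.append(self.condition.astype(float))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # identify which columns are collinear with condition
            names = self.design_columns
            raise DesignError(
                f"confounded design: columns {names} are collinear "
                "(a condition level is nested within a batch)"
            )
        return X

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> DEResults:
        X = self._design()
        sf = self._sf if self._sf is not None else size_factors(self.cm)
        sf = sf.reindex(self.samples)
        K = self.cm.counts.to_numpy(dtype=float)
        genes = self.cm.probe_ids

        if self._disp is not None:
            disp = self._disp.reindex(genes).to_numpy()
        else:
            grp_labels = pd.Series(
                [
                    f"{c}|{self.batch[s] if self.batch is not None else 0}"
                    for s, c in zip(self.samples, self.condition)
                ],
                index=self.samples,
            )
            disp = estimate_dispersion(
                self.cm, sf, grp_labels, shrinkage=self.dispersion_shrinkage
            ).to_numpy()

        nonzero = K.sum(axis=1) > 0
        norm = K / sf.to_numpy()
        base_mean = norm.mean(axis=1)
        ctr_mean = norm[:, self.condition == 0].mean(axis=1)
        trt_mean = norm[:, self.condition == 1].mean(axis=1)

        G = len(genes)
        lfc = np.full(G, np.nan)
        lfc_se = np.full(G, np.nan)
        converged = np.zeros(G, dtype=bool)
        if nonzero.any():
            beta, cov, conv, n_iter = _irls_nb(
                K[nonzero], X, np.log(sf.to_numpy()), disp[nonzero],
                tol=tol, maxiter=maxiter,
            )
            ci = X.shape[1] - 1  # condition is the last column
            lfc[nonzero] = beta[:, ci] / LN2
            lfc_se[nonzero] = np.sqrt(cov[:, ci, ci]) / LN2
            converged[nonzero] = conv
            n_bad = int((~conv).sum())
            if n_bad:
                logger.warning("%d genes did not converge in %d IRLS iterations", n_bad, maxiter)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = lfc / lfc_se
        pvalue = np.where(np.isnan(stat), np.nan, 2.0 * stats.norm.sf(np.abs(stat)))
        padj = bh_adjust(pd.Series(pvalue, index=genes)).to_numpy()

        table = pd.DataFrame(
            {
                "ctr_read_counts": ctr_mean,
                "treat_read_counts": trt_mean,
                "baseMean": base_mean,
                "log2FoldChange": lfc,
                "lfcSE": lfc_se,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
                "dispersion": disp,
                "converged": converged,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        contrast = f"{len(self.treatment)} treated vs {len(self.control)} control"
        return DEResults(
            table=table,
            size_factors=sf,
            design_columns=self.design_columns,
            contrast=contrast,
        )


def pairwise_de(
    cm: CountMatrix,
    meta: SampleMeta,
    compound: str,
    concentration: float,
    **kwargs,
) -> DEResults:
    """Treatment-vs-vehicle contrast within the treatment's experiment."""
    treated = meta.samples_for(compound, concentration)
    treated = [s for s in treated if s in set(cm.sample_ids)]
    if not treated:
        raise DesignError(f"no samples for {compound} at {concentration}")
    exps = meta.table.set_index("sample_id").loc[treated, "experiment_id"].unique()
    control = [
        s
        for e in exps
        for s in meta.vehicles(e)
        if s in set(cm.sample_ids)
    ]
    return DEModel(cm, meta, treated, control, **kwargs).fit()


# ---------------------------------------------------------------------------
# multiplicity and filtering

def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini–Hochberg step-up adjustment; NaNs propagate."""
    p = pd.Series(pvalues, dtype=float)
    ok = p.notna()
    vals = p[ok].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if ok.any():
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def significance_filter(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 0.585,
    basemean_min: float = 10.0,
) -> pd.DataFrame:
    """Apply the standard significance cut-offs, all strict.

    Keeps genes with baseMean > ``basemean_min``, padj < ``padj_max`` and
    |log2FoldChange| > ``lfc_min`` (0.585 ≈ log2 1.5).
    """
    t = table
    mask = (
        (t["baseMean"] > basemean_min)
        & (t["padj"] < padj_max)
        & (t["log2FoldChange"].abs() > lfc_min)
    )
    return t[mask.fillna(False)]
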