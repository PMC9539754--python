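"""Moderated differential expression for multi-strain designs.

Per brain region, log2-CPM expression is modelled gene-wise by weighted
least squares on a design with cell-means strain coding (one coefficient
per strain) plus additive sex and batch adjustments.  Observation-level
precision weights are derived from a fitted mean–variance trend (the
voom idea: residual sqrt-sd regressed on average log-count, inverted to
weights).  Residual variances are shrunk toward a common prior by
empirical Bayes (moment matching on log variances), contrasts of strain
means give moderated t statistics, fold-change-threshold (TREAT-style)
tests give p-values against |log2FC| <= threshold, and the
Benjamini–Hochberg adjustment is applied once across an entire contrast
family ("global" FDR), so DEG counts are comparable across contrasts.

The cell-means strain coding makes every contrast an explicit weight
vector over strain means: pairwise contrasts are (+1, -1) pairs and the
Low_Average comparison weights one high-preference strain +1 against
the mean of the six low-preference strains (-1/6 each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

LOW_PREFERENCE = ("AJ", "CAST", "NOD", "NZO", "S129", "WSB")


# ---------------------------------------------------------------------------
# design and contrasts
# ---------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    factors: tuple[str, ...] = ("strain", "sex", "batch"),
) -> pd.DataFrame:
    """Design matrix: cell-means strain columns + treatment-coded covariates.

    The first factor (strain) gets one indicator column per level; each
    remaining factor contributes k-1 dummy columns (first level as
    reference).  Raises on rank deficiency, naming the offending columns.
    """
    main, *covars = factors
    blocks = [pd.get_dummies(samples[main], prefix=main, dtype=float)]
    for f in covars:
        if f not in samples.columns:
            continue
        d = pd.get_dummies(samples[f], prefix=f, dtype=float, drop_first=True)
        blocks.append(d)
    design = pd.concat(blocks, axis=1)
    design.index = samples.index

    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < design.shape[1]:
        # identify a dependent column via QR pivoting
        _, r = np.linalg.qr(x)
        bad = [design.columns[i] for i in range(r.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"suspect columns: {bad or 'confounded factors'}"
        )
    return design


@dataclass(frozen=True)
class Contrast:
    """A named weight vector over strain means (weights sum to zero)."""

    name: str
    weights: dict[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total) > 1e-10:
            raise ValueError(f"contrast {self.name!r} weights sum to {total}, not 0")
        vals = list(self.weights.values())
        # an all-zero vector is the degenerate self-contrast; otherwise
        # a valid contrast opposes at least one positive and one negative weight
        if any(v != 0 for v in vals) and not (
            any(v > 0 for v in vals) and any(v < 0 for v in vals)
        ):
            raise ValueError(f"contrast {self.name!r} needs positive and negative weights")

    def vector(self, design_columns: pd.Index, prefix: str = "strain") -> np.ndarray:
        vec = np.zeros(len(design_columns))
        for strain, w in self.weights.items():
            col = f"{prefix}_{strain}"
            if col not in design_columns:
                raise KeyError(f"contrast {self.name!r}: no design column {col!r}")
            vec[design_columns.get_loc(col)] = w
        return vec

    def reversed(self) -> "Contrast":
        a, b = self.name.split("_vs_") if "_vs_" in self.name else (self.name, "rev")
        return Contrast(f"{b}_vs_{a}", {s: -w for s, w in self.weights.items()})


def pairwise_contrasts(strains: list[str] | tuple[str, ...]) -> list[Contrast]:
    """All unordered pairwise contrasts, oriented first-minus-second in
    the given strain order (28 contrasts for 8 strains)."""
    out = []
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            out.append(Contrast(f"{a}_vs_{b}", {a: 1.0, b: -1.0}))
    return out


def low_average_contrasts(
    strains: list[str] | tuple[str, ...],
    high_preference: tuple[str, str] = ("B6", "PWK"),
) -> list[Contrast]:
    """Each high-preference strain vs the mean of the low-preference
    strains: weights +1 on the strain and -1/6 on each of the six lows."""
    lows = [s for s in strains if s not in high_preference]
    if not lows:
        raise ValueError("no low-preference strains available")
    out = []
    for hp in high_preference:
        if hp not in strains:
            raise KeyError(f"strain {hp!r} not in design")
        w = {hp: 1.0}
        w.update({s: -1.0 / len(lows) for s in lows})
        out.append(Contrast(f"{hp}_vs_LowAverage", w))
    return out


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)
# ---------------------------------------------------------------------------

def compute_precision_weights(
    counts: pd.DataFrame,
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    span: float = 0.5,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    An unweighted gene-wise fit of log2-CPM on the design yields residual
    standard deviations; their square roots are smoothed (lowess,
    ``frac=span``) against average log2 count, the trend is evaluated at
    each observation's fitted log2 count, and weights are the inverse
    fourth power of the predicted sqrt-sd.  Weights are strictly
    positive (floored at ``eps``).
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    y = norm.log2_cpm.to_numpy(dtype=float)
    eff_lib = norm.effective_lib_sizes.reindex(counts.columns).to_numpy(dtype=float)

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    fitted = beta @ x.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    # average log2 count; fitted values mapped from CPM to count scale
    mean_log_count = y.mean(axis=1) + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)

    ok = sigma > 0
    if ok.sum() < 10:
        trend_x = mean_log_count
        trend_y = np.full_like(trend_x, max(sqrt_sd[ok].mean(), eps) if ok.any() else 1.0)
    else:
        sm = lowess(sqrt_sd[ok], mean_log_count[ok], frac=span, return_sorted=True)
        trend_x, trend_y = sm[:, 0], sm[:, 1]

    fitted_log_count = fitted + np.log2(eff_lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_log_count, trend_x, trend_y)  # clamped at ends
    pred = np.maximum(pred, eps ** 0.25)
    w = 1.0 / pred**4
    return pd.DataFrame(np.maximum(w, eps), index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# gene-wise weighted least squares
# ---------------------------------------------------------------------------

@dataclass
class GeneFits:
    """Gene-wise weighted least-squares fits on one region's data."""

    coefficients: pd.DataFrame      # genes x design columns
    sigma2: pd.Series               # residual variances
    df_residual: float
    cov_unscaled: np.ndarray        # genes x p x p, (X'WX)^{-1}
    design_columns: pd.Index
    weights: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.coefficients.index


def fit_linear_models(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    weights: pd.DataFrame | None = None,
) -> GeneFits:
    """Weighted least squares per gene.

    Returns coefficients, residual variance ``s2`` (weighted RSS over
    n - p), residual df and the unscaled coefficient covariance
    (X'WX)^{-1} needed for contrast standard errors.
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    y = logcpm.to_numpy(dtype=float)
    g = y.shape[0]

    if weights is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ (xtx_inv @ x.T).T
        resid = y - beta @ x.T
        rss = (resid**2).sum(axis=1)
        cov = np.broadcast_to(xtx_inv, (g, p, p)).copy()
    else:
        w = weights.to_numpy(dtype=float)
        xw = x[None, :, :] * w[:, :, None]            # g x n x p
        xtwx = np.einsum("gni,nj->gij", xw, x)        # g x p x p
        xtwy = np.einsum("gn,ni->gi", y * w, x)       # g x p
        cov = np.linalg.inv(xtwx)
        beta = np.einsum("gij,gj->gi", cov, xtwy)
        resid = y - beta @ x.T
        rss = (w * resid**2).sum(axis=1)
    sigma2 = rss / (n - p)

    return GeneFits(
        coefficients=pd.DataFrame(beta, index=logcpm.index, columns=design.columns),
        sigma2=pd.Series(sigma2, index=logcpm.index, name="sigma2"),
        df_residual=float(n - p),
        cov_unscaled=cov,
        design_columns=design.columns,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


@dataclass
class ModeratedStats:
    """Empirical-Bayes variance moderation state."""

    d0: float                      # prior df (may be inf)
    s02: float                     # prior variance
    s2_post: pd.Series             # posterior (shrunken) variances
    df_total: float                # d0 + residual df (capped if d0 = inf)
    df_residual: float


def empirical_bayes_moderate(
    fits: GeneFits,
    d0: float | None = None,
    s02: float | None = None,
) -> ModeratedStats:
    """Shrink gene variances toward a common prior.

    The prior (d0, s0^2) is estimated by moment matching on log s^2
    (scaled-F theory: E[log s^2] and Var[log s^2] involve digamma and
    trigamma functions of the df), unless supplied.  Posterior variances
    are the df-weighted average (d0*s0^2 + d*s^2) / (d0 + d); d0 = inf
    collapses every variance to s0^2 (pooled limit), d0 = 0 leaves them
    untouched.
    """
    d = fits.df_residual
    s2 = fits.sigma2.to_numpy(dtype=float)
    if d0 is None or s02 is None:
        positive = s2[s2 > 0]
        if positive.size < 2:
            raise ValueError("too few positive residual variances to moderate")
        z = np.log(positive)
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        emean = e.mean()
        evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
        if d0 is None:
            if evar > 0:
                d0 = 2.0 * trigamma_inverse(evar)
            else:
                d0 = np.inf
        if s02 is None:
            if np.isfinite(d0):
                s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            else:
                s02 = float(np.exp(emean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = d
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    return ModeratedStats(
        d0=float(d0), s02=float(s02),
        s2_post=pd.Series(s2_post, index=fits.sigma2.index, name="s2_post"),
        df_total=df_total, df_residual=d,
    )


def _t_pvalue(t: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def apply_contrast(
    fits: GeneFits,
    mod: ModeratedStats,
    contrast: Contrast,
) -> pd.DataFrame:
    """Per-gene log2FC, moderated t and two-sided p for one contrast."""
    c = contrast.vector(fits.design_columns)
    logfc = fits.coefficients.to_numpy() @ c
    u = np.sqrt(np.einsum("i,gij,j->g", c, fits.cov_unscaled, c))
    se = u * np.sqrt(mod.s2_post.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = _t_pvalue(t, mod.df_total)
    p[se == 0] = 1.0
    return pd.DataFrame(
        {"gene": fits.genes, "log2FC": logfc, "t": t, "p": p, "se": se}
    ).set_index("gene", drop=False)


def treat_test(
    fits: GeneFits,
    mod: ModeratedStats,
    contrast: Contrast,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Test H0: |true log2FC| <= lfc_threshold (fold-change threshold test).

    The statistic is shifted toward the threshold boundary: with
    a = |log2FC|, p = P(T > (a - tau)/se) + P(T > (a + tau)/se) under a
    t distribution on the moderated df.  At tau = 0 this reduces to the
    ordinary two-sided moderated-t p-value; p is monotone increasing in
    tau for fixed data.
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    base = apply_contrast(fits, mod, contrast)
    a = np.abs(base["log2FC"].to_numpy())
    se = base["se"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_right = np.where(se > 0, (a - lfc_threshold) / se, -np.inf)
        t_left = np.where(se > 0, (a + lfc_threshold) / se, np.inf)
    if np.isinf(mod.df_total):
        p = stats.norm.sf(t_right) + stats.norm.sf(t_left)
    else:
        p = stats.t.sf(t_right, mod.df_total) + stats.t.sf(t_left, mod.df_total)
    out = base.copy()
    out["p_treat"] = np.clip(p, 0.0, 1.0)
    out["t_treat"] = np.maximum(t_right, 0.0) * np.sign(base["log2FC"].to_numpy())
    return out


def global_fdr(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up applied once to a pooled p-value vector."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    contrast_tables: dict[str, pd.DataFrame],
    region: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Assemble a DEG table with global FDR across the contrast family.

    ``contrast_tables`` maps contrast name -> the output of
    :func:`treat_test` (or :func:`apply_contrast`; then no TREAT flags).
    BH is applied once to all pooled (gene, contrast) p-values — the
    "global" multiple-testing family — and separately to the pooled
    TREAT p-values.  Flags:

    * ``is_deg``: global FDR < ``fdr_threshold``;
    * ``is_hdeg``: DEG and |log2FC| >= ``lfc_threshold`` and TREAT
      global FDR < ``fdr_threshold``;
    * ``is_hdeg_simple``: DEG and |log2FC| >= ``lfc_threshold`` (raw
      fold-change cutoff, no TREAT significance).
    """
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    frames = []
    for name, tab in contrast_tables.items():
        t = tab.copy()
        t["contrast"] = name
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    long["region"] = region
    long["fdr_global"] = global_fdr(long["p"])
    if "p_treat" in long.columns:
        long["fdr_treat_global"] = global_fdr(long["p_treat"])
    else:
        long["fdr_treat_global"] = np.nan
    long["direction"] = np.where(long["log2FC"] > 0, "up",
                                 np.where(long["log2FC"] < 0, "down", "none"))
    long["is_deg"] = long["fdr_global"] < fdr_threshold
    big = long["log2FC"].abs() >= lfc_threshold
    long["is_hdeg_simple"] = long["is_deg"] & big
    long["is_hdeg"] = (
        long["is_hdeg_simple"] & (long["fdr_treat_global"] < fdr_threshold)
    )
    cols = ["gene", "contrast", "region", "log2FC", "t", "p", "p_treat",
            "fdr_global", "fdr_treat_global", "direction", "is_deg",
            "is_hdeg", "is_hdeg_simple"]
    return long[[c for c in cols if c in long.columns]]


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ModeratedDE(BaseEstimator):
    """Precision-weighted moderated DE model for one region's samples.

    Parameters mirror the pipeline defaults: TMM normalization feeds in
    via ``norm`` at fit time, the design uses cell-means strain coding
    with additive sex/batch, voom-style weights with lowess span
    ``voom_span``, and DEG/hDEG calls at ``fdr_threshold`` /
    ``lfc_threshold`` with global BH across each contrast family.

    Fitted attributes: ``design_``, ``weights_``, ``fits_``
    (:class:`GeneFits`), ``moderated_`` (:class:`ModeratedStats`).
    """

    def __init__(self, factors: tuple[str, ...] = ("strain", "sex", "batch"),
                 voom_span: float = 0.5, fdr_threshold: float = 0.05,
                 lfc_threshold: float = 1.0, use_weights: bool = True):
        self.factors = factors
        self.voom_span = voom_span
        self.fdr_threshold = fdr_threshold
        self.lfc_threshold = lfc_threshold
        self.use_weights = use_weights

    def fit(self, counts: pd.DataFrame, samples: pd.DataFrame,
            norm: NormalizedMatrix | None = None):
        if norm is None:
            from .preprocess import tmm_normalize
            norm = tmm_normalize(counts)
        factors = tuple(
            f for f in self.factors
            if f == self.factors[0] or samples[f].nunique() > 1
        )
        self.design_ = build_design(samples.loc[counts.columns], factors)
        self.norm_ = norm
        if self.use_weights:
            self.weights_ = compute_precision_weights(
                counts, norm, self.design_, span=self.voom_span
            )
        else:
            self.weights_ = None
        self.fits_ = fit_linear_models(norm.log2_cpm, self.design_, self.weights_)
        self.moderated_ = empirical_bayes_moderate(self.fits_)
        return self

    @property
    def strains_(self) -> list[str]:
        prefix = f"{self.factors[0]}_"
        return [c.removeprefix(prefix) for c in self.fits_.design_columns
                if c.startswith(prefix)]

    def contrast_table(self, contrast: Contrast, treat: bool = True) -> pd.DataFrame:
        if treat:
            return treat_test(self.fits_, self.moderated_, contrast, self.lfc_threshold)
        return apply_contrast(self.fits_, self.moderated_, contrast)

    def deg_table(self, contrasts: list[Contrast], region: str = "all",
                  treat: bool = True) -> pd.DataFrame:
        tables = {c.name: self.contrast_table(c, treat=treat) for c in contrasts}
        return call_degs(tables, region=region,
                         fdr_threshold=self.fdr_threshold,
                         lfc_threshold=self.lfc_threshold)
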