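"""Gene/sample filtering and TMM normalization for bulk RNA-seq counts.

The filtering rules mirror a standard bulk pipeline on a founder-strain
brain dataset: drop genes whose mean CPM across all samples is below a
threshold, genes with a single extreme count, and features without a
chromosomal location; flag (never silently remove) samples whose mean
inter-sample correlation is an outlier.  Between-sample normalization is
the trimmed mean of M-values (TMM): per-sample scaling factors computed
against a reference sample from doubly trimmed, precision-weighted
log-ratios, rescaled to unit geometric mean.

Estimator classes follow scikit-learn conventions (``fit`` learns from a
genes x samples count DataFrame and stores trailing-underscore
attributes; ``transform`` applies the learned state); module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import NON_CHROMOSOMAL

_NON_CHROM_SENTINELS = {NON_CHROMOSOMAL, "", "na", "none", "non_chromosomal"}


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("gene and sample identifiers must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def _is_non_chromosomal(chrom: pd.Series) -> pd.Series:
    s = chrom.astype("string")
    return s.isna() | s.str.strip().str.lower().isin(_NON_CHROM_SENTINELS)


def compute_cpm(
    counts: pd.DataFrame,
    log_scale: bool = False,
    prior_count: float = 0.5,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million, optionally on the log2 scale.

    CPM is ``count / library_size * 1e6``.  The log variant is
    ``log2((count + prior_count) / (library_size + 2 * prior_count) * 1e6)``,
    which keeps zeros finite and shrinks log-ratios at low counts.
    ``lib_sizes`` defaults to column sums; pass effective library sizes
    to obtain normalized CPM.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    x = counts.to_numpy(dtype=float)
    if log_scale:
        vals = np.log2((x + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    else:
        vals = x / lib * 1e6
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


@dataclass
class FilterReport:
    """Per-rule removal bookkeeping; a gene is claimed by its first
    failing rule in the order low_cpm -> max_count -> non_chromosomal."""

    removed_low_cpm: list[str]
    removed_max_count: list[str]
    removed_non_chromosomal: list[str]
    n_input: int
    n_retained: int
    outlier_samples: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    @property
    def counts_by_rule(self) -> dict[str, int]:
        return {
            "low_cpm": len(self.removed_low_cpm),
            "max_count": len(self.removed_max_count),
            "non_chromosomal": len(self.removed_non_chromosomal),
        }

    @property
    def n_removed(self) -> int:
        return sum(self.counts_by_rule.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "counts_by_rule": self.counts_by_rule,
            "removed_low_cpm": self.removed_low_cpm,
            "removed_max_count": self.removed_max_count,
            "removed_non_chromosomal": self.removed_non_chromosomal,
            "params": self.params,
        }
        if self.outlier_samples is not None:
            payload["outlier_samples"] = self.outlier_samples.to_dict("records")
        Path(path).write_text(json.dumps(payload, indent=1))


class GeneFilter(BaseEstimator, TransformerMixin):
    """Remove low-expression, extreme-count and non-chromosomal genes.

    Parameters
    ----------
    cpm_threshold : float
        A gene is kept only if its mean CPM across all samples (raw
        library sizes) is >= this value.
    max_count : int
        A gene is removed if any single count is strictly above this.

    Attributes (after ``fit``)
    --------------------------
    kept_genes_ : pd.Index of retained gene ids
    report_ : FilterReport with per-rule removal lists
    """

    def __init__(self, cpm_threshold: float = 1.0, max_count: int = 50_000):
        self.cpm_threshold = cpm_threshold
        self.max_count = max_count

    def fit(self, counts: pd.DataFrame, genes: pd.DataFrame | None = None):
        _validate_counts(counts)
        if genes is not None and not counts.index.isin(genes.index).all():
            raise ValueError("gene table does not cover all genes in the count matrix")

        mean_cpm = compute_cpm(counts).mean(axis=1)
        fail_cpm = mean_cpm < self.cpm_threshold
        fail_max = counts.max(axis=1) > self.max_count
        if genes is not None and "chromosome" in genes.columns:
            fail_chrom = _is_non_chromosomal(
                genes["chromosome"].reindex(counts.index)
            ).to_numpy()
        else:
            fail_chrom = np.zeros(len(counts), dtype=bool)

        fail_cpm = fail_cpm.to_numpy()
        fail_max = fail_max.to_numpy()
        # first matching rule claims the gene
        claimed_cpm = fail_cpm
        claimed_max = fail_max & ~fail_cpm
        claimed_chrom = fail_chrom & ~fail_cpm & ~fail_max

        keep = ~(fail_cpm | fail_max | fail_chrom)
        self.kept_genes_ = counts.index[keep]
        self.report_ = FilterReport(
            removed_low_cpm=list(counts.index[claimed_cpm]),
            removed_max_count=list(counts.index[claimed_max]),
            removed_non_chromosomal=list(counts.index[claimed_chrom]),
            n_input=len(counts),
            n_retained=int(keep.sum()),
            params={"cpm_threshold": self.cpm_threshold, "max_count": self.max_count},
        )
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts.loc[counts.index.intersection(self.kept_genes_, sort=False)]

    def fit_transform(self, counts, genes=None, **kwargs):  # noqa: D102
        return self.fit(counts, genes).transform(counts)


def filter_genes(
    counts: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    cpm_threshold: float = 1.0,
    max_count: int = 50_000,
) -> tuple[pd.DataFrame, FilterReport]:
    """Functional wrapper over :class:`GeneFilter`."""
    f = GeneFilter(cpm_threshold=cpm_threshold, max_count=max_count).fit(counts, genes)
    return f.transform(counts), f.report_


class SampleOutlierDetector(BaseEstimator):
    """Flag samples with aberrant mean inter-sample correlation.

    Within each group (default: per brain region), each sample's mean
    Pearson correlation with all other group members is computed on
    log2-CPM; a sample is flagged when its mean correlation lies more
    than ``k_sd`` standard deviations *below* the mean of the remaining
    samples' mean correlations (leave-one-out z, so one gross outlier
    cannot inflate the spread it is judged against).  Nothing is removed
    automatically — the caller decides.
    """

    def __init__(self, k_sd: float = 3.0, group_by: str | None = "region",
                 on_logcpm: bool = True, prior_count: float = 0.5):
        self.k_sd = k_sd
        self.group_by = group_by
        self.on_logcpm = on_logcpm
        self.prior_count = prior_count

    def fit(self, counts: pd.DataFrame, samples: pd.DataFrame | None = None):
        if counts.shape[1] < 3:
            raise ValueError("need at least 3 samples for correlation outliers")
        x = (
            compute_cpm(counts, log_scale=True, prior_count=self.prior_count)
            if self.on_logcpm
            else counts.astype(float)
        )
        if self.group_by and samples is not None and self.group_by in samples.columns:
            groups = samples.loc[counts.columns, self.group_by]
        else:
            groups = pd.Series("all", index=counts.columns)

        rows = []
        for g, cols in groups.groupby(groups).groups.items():
            sub = x[list(cols)]
            if len(cols) < 3:
                continue
            if (sub.std(axis=0) == 0).any() or len(sub) < 2:
                # correlation undefined for constant columns: signal, no flags
                for s in cols:
                    rows.append({"sample_id": s, "group": g, "mean_corr": np.nan,
                                 "z": np.nan, "flagged": False})
                continue
            corr = np.corrcoef(sub.to_numpy().T)
            np.fill_diagonal(corr, np.nan)
            mean_corr = np.nanmean(corr, axis=1)
            # leave-one-out z: each sample scored against the spread of the
            # remaining samples, so a single gross outlier cannot mask itself
            z = np.empty_like(mean_corr)
            for i in range(len(mean_corr)):
                others = np.delete(mean_corr, i)
                mu, sd = others.mean(), others.std(ddof=1)
                if sd == 0:
                    z[i] = 0.0 if mean_corr[i] == mu else np.sign(mean_corr[i] - mu) * np.inf
                else:
                    z[i] = (mean_corr[i] - mu) / sd
            for s, mc, zi in zip(cols, mean_corr, z):
                rows.append({
                    "sample_id": s, "group": g, "mean_corr": float(mc),
                    "z": float(zi), "flagged": bool(zi < -self.k_sd),
                })
        self.scores_ = pd.DataFrame(rows).set_index("sample_id", drop=False)
        self.flagged_samples_ = list(self.scores_.loc[self.scores_["flagged"], "sample_id"])
        return self

    def fit_predict(self, counts, samples=None) -> list[str]:
        return self.fit(counts, samples).flagged_samples_


def detect_outlier_samples(
    counts: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    k_sd: float = 3.0,
    group_by: str | None = "region",
) -> pd.DataFrame:
    """Per-sample mean inter-sample correlation z-scores and flags."""
    det = SampleOutlierDetector(k_sd=k_sd, group_by=group_by).fit(counts, samples)
    return det.scores_


@dataclass
class NormalizedMatrix:
    """TMM-normalized expression: log2-CPM plus the per-sample factors."""

    log2_cpm: pd.DataFrame
    norm_factors: pd.Series
    lib_sizes: pd.Series
    prior_count: float = 0.5

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.log2_cpm.to_csv(out / "log2_cpm.tsv", sep="\t", index_label="gene_id")
        meta = {
            "prior_count": self.prior_count,
            "norm_factors": self.norm_factors.to_dict(),
            "lib_sizes": self.lib_sizes.to_dict(),
        }
        (out / "norm_factors.json").write_text(json.dumps(meta, indent=1))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference.

    M-values (log2 ratio of CPM) and A-values (mean log2 CPM) are
    computed over genes positive in both samples; the upper and lower
    ``trim_m`` fraction of M and ``trim_a`` fraction of A are discarded;
    the factor is 2**(inverse-variance weighted mean of the remaining M),
    with delta-method binomial weights.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a = m[fin], a[fin]
    o, r = o[fin], r[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    # rank-based double trim (ties broken by order, matching an
    # ordinal-rank spreadsheet computation)
    rank_m = np.argsort(np.argsort(m, kind="mergesort"), kind="mergesort") + 1
    rank_a = np.argsort(np.argsort(a, kind="mergesort"), kind="mergesort") + 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0

    obs_k = o[keep2] * lib_obs
    ref_k = r[keep2] * lib_ref
    w = (lib_obs - obs_k) / (lib_obs * obs_k) + (lib_ref - ref_k) / (lib_ref * ref_k)
    f = np.sum(m[keep2] / w) / np.sum(1.0 / w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed-mean-of-M-values between-sample normalization.

    ``fit`` chooses the reference sample (the one whose 75th-percentile
    count fraction is closest to the mean of those fractions), computes
    one factor per sample and rescales factors to unit geometric mean.
    ``transform`` returns log2-CPM computed with effective library
    sizes (library size x factor).
    """

    def __init__(self, trim_m: float = 0.3, trim_a: float = 0.05,
                 prior_count: float = 0.5):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior_count = prior_count

    def fit(self, counts: pd.DataFrame, y=None):
        _validate_counts(counts)
        if counts.shape[1] < 2:
            raise ValueError("TMM needs at least 2 samples")
        x = counts.to_numpy(dtype=float)
        lib = x.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero library size")

        # upper-quartile count fraction per sample, zero rows excluded
        nonzero = x[x.sum(axis=1) > 0]
        f75 = np.quantile(nonzero / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

        factors = np.array([
            1.0 if j == ref_idx else _tmm_pair_factor(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                self.trim_m, self.trim_a,
            )
            for j in range(x.shape[1])
        ])
        factors /= np.exp(np.mean(np.log(factors)))

        self.reference_sample_ = counts.columns[ref_idx]
        self.norm_factors_ = pd.Series(factors, index=counts.columns, name="norm_factor")
        self.lib_sizes_ = pd.Series(lib, index=counts.columns, name="lib_size")
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        eff = self.lib_sizes_ * self.norm_factors_
        return compute_cpm(
            counts, log_scale=True, prior_count=self.prior_count, lib_sizes=eff
        )

    def fit_normalize(self, counts: pd.DataFrame) -> NormalizedMatrix:
        self.fit(counts)
        return NormalizedMatrix(
            log2_cpm=self.transform(counts),
            norm_factors=self.norm_factors_,
            lib_sizes=self.lib_sizes_,
            prior_count=self.prior_count,
        )


def tmm_normalize(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """Functional wrapper over :class:`TMMNormalizer`."""
    return TMMNormalizer(trim_m=trim_m, trim_a=trim_a, prior_count=prior_count).fit_normalize(counts)
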