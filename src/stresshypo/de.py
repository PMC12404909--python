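"""Weighted per-gene linear models, empirical-Bayes moderation, and
permutation-based empirical FDR.

The model is the standard small-n RNA-seq workhorse: per gene, weighted
least squares of log2-CPM on an intercept plus a two-group indicator, with
voom precision weights. Per-gene residual variances ``s_g^2`` (df ``d_g``)
are shrunk toward a common prior ``s_0^2`` with prior df ``d_0`` estimated
by moment matching on ``log s_g^2`` (trigamma inversion), giving moderated
t-statistics referred to a t distribution with ``d_0 + d_g`` df.

Because only 20 samples support each test, significance is assessed against
an empirical null: group labels are permuted (uniform relabelings, sampled
with replacement), the full fit+moderation pipeline re-run, and each gene's
p-value converted to an empirical FDR

    eFDR(p) = mean_perm #{null p <= p} / max(1, #{observed p <= p}),

capped at 1 and made monotone by a running minimum from the largest observed
p downward (q-value convention). A gene is called differentially expressed
when eFDR < 0.05 and |log2FC| >= 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import CountMatrix, NormalizedMatrix, filter_min_count, voom_transform

__all__ = [
    "GeneFit",
    "ModeratedStats",
    "PermutationNull",
    "TagSeqDE",
    "DEResults",
    "fit_gene_models",
    "ebayes_moderate",
    "permutation_null",
    "compute_efdr",
    "call_degs",
    "cross_region_tables",
]


@dataclass
class GeneFit:
    """Per-gene weighted least-squares fit of a two-group design."""

    log2fc: np.ndarray  # group coefficient, Stressed - Control
    stdev_unscaled: np.ndarray  # coefficient sd per unit residual sd
    sigma2: np.ndarray  # residual variance s_g^2
    df_residual: float  # d_g, n - 2
    gene_ids: list[str]


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics."""

    d0: float  # prior df (may be inf)
    s0_2: float  # prior variance
    post_var: np.ndarray  # shrunken variances
    t: np.ndarray
    p: np.ndarray
    df_total: float


@dataclass
class PermutationNull:
    """Null p-values from permuted group labels."""

    n_perm: int
    seed: int | None
    null_p: np.ndarray  # (n_perm, n_genes)

    @property
    def pooled_sorted(self) -> np.ndarray:
        return np.sort(self.null_p, axis=None)


# ---------------------------------------------------------------------------
# Fitting


def _wls_stats(
    y: np.ndarray, w: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row WLS of y on [1, x]. Returns (beta1, stdev_unscaled, sigma2).

    Exploits x in {0,1}: with weights w the normal equations collapse to
    weighted group sums, so each permutation costs two matrix–vector
    products.
    """
    sw = w.sum(axis=1)
    swx = w @ x  # = sum of weights in group 1 (x^2 = x)
    swy = (w * y).sum(axis=1)
    swxy = (w * y) @ x
    swyy = (w * y * y).sum(axis=1)

    dxx = swx - swx * swx / sw
    dxy = swxy - swx * swy / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        beta1 = dxy / dxx
        rss = swyy - swy * swy / sw - beta1 * beta1 * dxx
        stdev_unscaled = 1.0 / np.sqrt(dxx)
    sigma2 = np.maximum(rss, 0.0) / (y.shape[1] - 2)
    return beta1, stdev_unscaled, sigma2


def fit_gene_models(norm: NormalizedMatrix, design: Sequence[int] | np.ndarray) -> GeneFit:
    """Weighted least squares of log2-CPM on intercept + group, per gene."""
    x = np.asarray(design, dtype=float)
    levels = np.unique(x)
    if len(levels) != 2:
        raise ValueError("design must contain exactly two groups")
    x = (x == levels[1]).astype(float)
    if min(x.sum(), (1 - x).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    if not np.all(norm.weights > 0):
        raise ValueError("weights must be strictly positive")
    beta1, su, s2 = _wls_stats(norm.logcpm, norm.weights, x)
    return GeneFit(beta1, su, s2, float(norm.n_samples - 2), list(norm.gene_ids))


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F model for residual variances.

    Under ``s_g^2 ~ s0^2 * F(d_g, d0)``, ``log s_g^2`` has variance
    ``trigamma(d/2) + trigamma(d0/2)`` and a closed-form mean; excess
    variance of the observed log variances beyond the pure-sampling term
    determines d0 via trigamma inversion. When there is no excess the prior
    is degenerate (d0 = inf) and every gene shares s0^2.
    """
    s2 = sigma2[sigma2 > 0]
    if s2.size < 2:
        raise ValueError("need at least 2 positive residual variances")
    z = np.log(s2)
    zbar, zvar = float(z.mean()), float(z.var(ddof=1))
    sampling = float(special.polygamma(1, df / 2.0))
    excess = zvar - sampling
    if excess <= 0:
        d0 = np.inf
        log_s0 = zbar - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            zbar
            - float(special.digamma(df / 2.0))
            + np.log(df / 2.0)
            + float(special.digamma(d0 / 2.0))
            - np.log(d0 / 2.0)
        )
    return d0, float(np.exp(log_s0))


def ebayes_moderate(fit: GeneFit, d0: float | None = None) -> ModeratedStats:
    """Moderated t-statistics with variance shrinkage.

    ``d0`` may be forced: 0 disables moderation (ordinary t), ``inf``
    replaces every variance by the common prior.
    """
    if (fit.sigma2 > 0).sum() < 10 and d0 is None:
        raise ValueError("need at least 10 genes with positive residual variance")
    if d0 is None:
        d0, s0_2 = estimate_prior(fit.sigma2, fit.df_residual)
    elif d0 == 0:
        s0_2 = 0.0
    else:
        _, s0_2 = estimate_prior(fit.sigma2, fit.df_residual)

    d = fit.df_residual
    if np.isinf(d0):
        post = np.full_like(fit.sigma2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        post = fit.sigma2.copy()
        df_total = d
    else:
        post = (d0 * s0_2 + d * fit.sigma2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(invalid="ignore", divide="ignore"):
        t = fit.log2fc / (fit.stdev_unscaled * np.sqrt(post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedStats(d0, s0_2, post, t, p, df_total)


# ---------------------------------------------------------------------------
# Permutation null and eFDR


def permutation_null(
    norm: NormalizedMatrix,
    design: Sequence[int] | np.ndarray,
    n_perm: int = 5000,
    seed: int | None = 0,
    d0: float | None = None,
    permutations: np.ndarray | None = None,
) -> PermutationNull:
    """Null p-value distribution from permuted group labels.

    Each permutation shuffles the label vector uniformly at random over
    samples (with replacement across permutations, identity not excluded),
    re-fits every gene and re-estimates the moderation prior. Explicit label
    matrices can be supplied via ``permutations`` (n_perm x n_samples).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(design, dtype=float)
    levels = np.unique(x)
    x = (x == levels[-1]).astype(float)
    rng = np.random.default_rng(seed)
    y, w = norm.logcpm, norm.weights
    df = float(norm.n_samples - 2)
    out = np.empty((n_perm, norm.n_genes))
    for k in range(n_perm):
        xp = (
            np.asarray(permutations[k], dtype=float)
            if permutations is not None
            else rng.permutation(x)
        )
        beta1, su, s2 = _wls_stats(y, w, xp)
        mod = ebayes_moderate(GeneFit(beta1, su, s2, df, norm.gene_ids), d0=d0)
        out[k] = mod.p
    return PermutationNull(n_perm, seed, out)


def compute_efdr(observed_p: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Per-gene empirical FDR against the permutation null.

    eFDR(p_g) = [mean over permutations of #{null p <= p_g}] divided by
    #{observed p <= p_g}, capped at 1, then made monotone non-decreasing in
    p by a running minimum taken from the largest observed p downward.
    """
    p = np.asarray(observed_p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("observed p-values must lie in [0, 1]")
    pooled = null.pooled_sorted
    null_le = np.searchsorted(pooled, p, side="right") / null.n_perm
    order = np.argsort(p, kind="stable")
    obs_le = np.empty_like(p)
    sorted_p = p[order]
    # observed exceedance counts, tie-aware
    obs_le[order] = np.searchsorted(sorted_p, sorted_p, side="right")
    ratio = np.minimum(null_le / np.maximum(obs_le, 1.0), 1.0)
    # monotone enforcement: running min from largest p down
    efdr = np.empty_like(p)
    efdr[order] = np.minimum.accumulate(ratio[order][::-1])[::-1]
    return efdr


def call_degs(
    log2fc: np.ndarray,
    efdr: np.ndarray,
    lfc_threshold: float = 0.2,
    efdr_threshold: float = 0.05,
) -> np.ndarray:
    """Classify genes as 'up', 'down', or 'ns'."""
    if lfc_threshold <= 0 or efdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    call = np.full(len(log2fc), "ns", dtype=object)
    sig = efdr < efdr_threshold
    call[sig & (log2fc >= lfc_threshold)] = "up"
    call[sig & (log2fc <= -lfc_threshold)] = "down"
    return call


# ---------------------------------------------------------------------------
# Model / Results surface


class TagSeqDE:
    """Two-group differential expression model for a Tag-seq count matrix.

    Parameters
    ----------
    norm : NormalizedMatrix
        voom-transformed expression (log2-CPM + precision weights).
    design : array-like of group indicators (0 = Control, 1 = Stressed).

    Use :meth:`from_counts` to start from raw counts and a sample sheet.
    """

    def __init__(self, norm: NormalizedMatrix, design: Sequence[int] | np.ndarray):
        self.norm = norm
        self.design = np.asarray(design, dtype=float)

    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        sample_sheet: pd.DataFrame,
        min_count: int = 10,
        filter_mode: str = "any",
    ) -> "TagSeqDE":
        """Filter low-count genes, voom-transform, and build the model.

        ``sample_sheet`` must carry a 'group' column over ``counts.sample_ids``
        with levels Control/Stressed.
        """
        group = (
            sample_sheet.loc[counts.sample_ids, "group"]
            .map({"Control": 0, "Stressed": 1})
            .to_numpy()
        )
        if np.any(pd.isna(group)):
            raise ValueError("sample sheet group must be Control or Stressed")
        filtered = filter_min_count(counts, min_count, mode=filter_mode)
        return cls(voom_transform(filtered, group), group)

    def fit(
        self,
        n_perm: int = 5000,
        seed: int | None = 0,
        d0: float | None = None,
        lfc_threshold: float = 0.2,
        efdr_threshold: float = 0.05,
    ) -> "DEResults":
        """Fit, moderate, build the permutation null, and call DEGs."""
        genefit = fit_gene_models(self.norm, self.design)
        mod = ebayes_moderate(genefit, d0=d0)
        null = permutation_null(self.norm, self.design, n_perm=n_perm, seed=seed, d0=d0)
        efdr = compute_efdr(mod.p, null)
        call = call_degs(genefit.log2fc, efdr, lfc_threshold, efdr_threshold)
        return DEResults(self, genefit, mod, null, efdr, call, lfc_threshold, efdr_threshold)


class DEResults:
    """Results of a :class:`TagSeqDE` fit.

    Attributes
    ----------
    table : DataFrame with columns (log2FC, t, p, eFDR, call), gene-indexed.
    """

    def __init__(
        self,
        model: TagSeqDE,
        genefit: GeneFit,
        moderated: ModeratedStats,
        null: PermutationNull,
        efdr: np.ndarray,
        call: np.ndarray,
        lfc_threshold: float,
        efdr_threshold: float,
    ):
        self.model = model
        self.genefit = genefit
        self.moderated = moderated
        self.null = null
        self.lfc_threshold = lfc_threshold
        self.efdr_threshold = efdr_threshold
        self.table = pd.DataFrame(
            {
                "log2FC": genefit.log2fc,
                "t": moderated.t,
                "p": moderated.p,
                "eFDR": efdr,
                "call": call,
            },
            index=pd.Index(genefit.gene_ids, name="gene"),
        )

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def n_tested(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        d0 = self.moderated.d0
        lines = [
            "Two-group moderated DE with permutation eFDR",
            "=" * 46,
            f"genes tested:        {self.n_tested}",
            f"samples:             {self.model.norm.n_samples}",
            f"permutations:        {self.null.n_perm}",
            f"prior df d0:         {'inf' if np.isinf(d0) else f'{d0:.2f}'}",
            f"prior variance s0^2: {self.moderated.s0_2:.4g}",
            f"thresholds:          |log2FC| >= {self.lfc_threshold}, eFDR < {self.efdr_threshold}",
            f"up / down / ns:      {self.n_up} / {self.n_down} / "
            f"{self.n_tested - self.n_up - self.n_down}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cross-region tables


def cross_region_tables(
    results: Mapping[str, DEResults | pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap and incongruence tables across regions.

    Overlap: genes with the same non-ns call in >= 2 regions, with direction
    and the region list. Incongruence: genes up in >= 1 region and down in
    >= 1 other, with the regions per direction.
    """
    if len(results) < 2:
        raise ValueError("need at least two regions")
    calls: dict[str, pd.Series] = {}
    for region, res in results.items():
        table = res.table if isinstance(res, DEResults) else res
        calls[region] = table["call"]
    regions = list(calls)
    genes = sorted(set().union(*(c.index for c in calls.values())))

    overlap_rows, incong_rows = [], []
    for g in genes:
        ups = [r for r in regions if g in calls[r].index and calls[r][g] == "up"]
        downs = [r for r in regions if g in calls[r].index and calls[r][g] == "down"]
        if len(ups) >= 2:
            overlap_rows.append({"gene": g, "direction": "Up", "regions": ", ".join(ups)})
        if len(downs) >= 2:
            overlap_rows.append({"gene": g, "direction": "Down", "regions": ", ".join(downs)})
        if ups and downs:
            incong_rows.append(
                {"gene": g, "region_up": ", ".join(ups), "region_down": ", ".join(downs)}
            )
    overlap = pd.DataFrame(overlap_rows, columns=["gene", "direction", "regions"])
    incong = pd.DataFrame(incong_rows, columns=["gene", "region_up", "region_down"])
    return overlap, incong
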