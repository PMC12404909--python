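"""Count-matrix container, expression filters, normalization, and sample QC.

Two normalization paths coexist because the differential-expression and
network stages make different variance assumptions:

* a voom-style transform — log2 counts-per-million plus per-observation
  inverse-variance precision weights read off a fitted mean–variance trend —
  feeds the weighted linear models of the DE stage;
* median-of-ratios size factors with a ``log2(normalized count + 1)``
  transform feed the correlation network stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy import sparse
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_counts",
    "write_counts",
    "filter_min_count",
    "filter_prevalence",
    "size_factors",
    "normalize_median_of_ratios",
    "voom_transform",
    "pca_samples",
    "validate_markers",
]


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its contract."""


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer counts.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Raw counts; must be integral and non-negative.
    gene_ids, sample_ids : sequences of unique str
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise CountMatrixError("counts must be a 2-D gene x sample array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountMatrixError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountMatrixError("duplicate sample ids")
        bad = np.argwhere(self.values < 0)
        if bad.size:
            i, j = bad[0]
            raise CountMatrixError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            bad = np.argwhere(rounded != self.values)
            if bad.size:
                i, j = bad[0]
                raise CountMatrixError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
                )
            self.values = rounded.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix with genes selected by boolean mask or index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[keep],
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
        )


@dataclass
class NormalizedMatrix:
    """log2-CPM expression with voom-style precision weights.

    Attributes
    ----------
    logcpm : ndarray (genes x samples)
        ``log2((count + 0.5) / (libsize + 1) * 1e6)``.
    weights : ndarray (genes x samples)
        Inverse-variance precision weights (fitted sqrt-sd to the -4).
    size_factors : ndarray (samples,)
        Effective library scaling used (here: library size / mean library size).
    trend : list of (mean_log_count, sqrt_sd) knots
        The fitted mean–variance curve.
    """

    logcpm: np.ndarray
    weights: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    size_factors: np.ndarray
    trend: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.logcpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.logcpm.shape[1]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.logcpm, index=self.gene_ids, columns=self.sample_ids).to_csv(
            outdir / "logcpm.tsv", sep="\t"
        )
        pd.DataFrame(self.weights, index=self.gene_ids, columns=self.sample_ids).to_csv(
            outdir / "weights.tsv", sep="\t"
        )
        meta = {
            "size_factors": dict(zip(self.sample_ids, map(float, self.size_factors))),
            "trend": [[float(a), float(b)] for a, b in self.trend],
        }
        (outdir / "trend.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "NormalizedMatrix":
        outdir = Path(outdir)
        logcpm = pd.read_csv(outdir / "logcpm.tsv", sep="\t", index_col=0)
        weights = pd.read_csv(outdir / "weights.tsv", sep="\t", index_col=0)
        meta = json.loads((outdir / "trend.json").read_text())
        return cls(
            logcpm.to_numpy(float),
            weights.to_numpy(float),
            list(logcpm.index),
            list(logcpm.columns),
            np.array([meta["size_factors"][s] for s in logcpm.columns]),
            [tuple(k) for k in meta["trend"]],
        )


# ---------------------------------------------------------------------------
# I/O


def write_counts(counts: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write counts as TSV (genes in rows) or MatrixMarket with id sidecars."""
    path = Path(path)
    if format == "tsv":
        counts.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        mmwrite(str(path), sparse.coo_matrix(counts.values))
        path.with_suffix(".rownames.txt").write_text("\n".join(counts.gene_ids) + "\n")
        path.with_suffix(".colnames.txt").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene × sample count matrix.

    TSV: first column gene ids, header sample ids. MatrixMarket: ``.mtx``
    triplets plus ``.rownames.txt``/``.colnames.txt`` sidecars.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix.from_frame(df)
    if format == "mtx":
        raw = mmread(str(path))
        mat = np.asarray(raw.todense()) if sparse.issparse(raw) else np.asarray(raw)
        genes = path.with_suffix(".rownames.txt").read_text().split()
        samples = path.with_suffix(".colnames.txt").read_text().split()
        return CountMatrix(mat, genes, samples)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Filtering


def filter_min_count(counts: CountMatrix, min_count: int = 10, *, mode: str = "any") -> CountMatrix:
    """Drop weakly expressed genes by a per-sample minimum count.

    mode="any" (default): keep a gene if it reaches ``min_count`` in at least
    one sample, i.e. drop only genes below the floor everywhere. mode="all":
    the stricter reading — keep only genes at or above the floor in every
    sample.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if mode == "any":
        keep = (counts.values >= min_count).any(axis=1)
    elif mode == "all":
        keep = (counts.values >= min_count).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        warnings.warn("filter removed every gene", stacklevel=2)
    return counts.subset_genes(keep)


def filter_prevalence(
    counts: CountMatrix, min_count: int = 15, max_low_fraction: float = 0.75
) -> CountMatrix:
    """Drop genes with count < ``min_count`` in more than ``max_low_fraction`` of samples."""
    if not 0.0 <= max_low_fraction <= 1.0:
        raise ValueError("max_low_fraction must be in [0, 1]")
    low_frac = (counts.values < min_count).mean(axis=1)
    keep = low_frac <= max_low_fraction
    if not keep.any():
        warnings.warn("filter removed every gene", stacklevel=2)
    return counts.subset_genes(keep)


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median ratio of its counts to the per-gene
    geometric mean across samples.
    """
    vals = counts.values.astype(float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise CountMatrixError(
            "no gene has positive counts in every sample; filter low-count genes first"
        )
    ref = vals[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_median_of_ratios(counts: CountMatrix) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression used by the network stage."""
    sf = size_factors(counts)
    norm = np.log2(counts.values / sf[None, :] + 1.0)
    return pd.DataFrame(norm, index=counts.gene_ids, columns=counts.sample_ids)


def _logcpm(values: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    return np.log2((values + 0.5) / (lib_sizes[None, :] + 1.0) * 1e6)


def voom_transform(
    counts: CountMatrix,
    design: Sequence[int] | np.ndarray,
    span: float = 0.5,
) -> NormalizedMatrix:
    """Counts → log2-CPM with precision weights from a mean–variance trend.

    Per gene, an unweighted group-means fit gives residual standard
    deviations; their square roots are lowess-smoothed against average
    log2-count, and each observation's weight is the interpolated sqrt-sd at
    its fitted log-count, raised to the −4. The trend is flat beyond its
    fitted range so extreme genes get bounded weights.
    """
    group = np.asarray(design, dtype=float)
    if group.ndim != 1 or len(group) != counts.n_samples:
        raise ValueError("design must be one group indicator per sample")
    levels = np.unique(group)
    if len(levels) != 2 or min((group == lv).sum() for lv in levels) < 2:
        raise ValueError("need two design groups with at least 2 samples each")

    lib = counts.library_sizes.astype(float)
    y = _logcpm(counts.values.astype(float), lib)

    # unweighted two-group-means fit
    g1 = group == levels[1]
    fitted = np.empty_like(y)
    fitted[:, ~g1] = y[:, ~g1].mean(axis=1, keepdims=True)
    fitted[:, g1] = y[:, g1].mean(axis=1, keepdims=True)
    df_resid = counts.n_samples - 2
    sigma = np.sqrt(((y - fitted) ** 2).sum(axis=1) / df_resid)

    # mean–variance trend: sqrt residual sd vs average log2 count
    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)
    smooth = lowess(sqrt_sd, mean_log_count, frac=span, it=3, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    ys = np.maximum(ys, 1e-6)  # guard exactly-zero residual genes

    # per-observation fitted log-count, interpolated on the trend
    fitted_count = fitted + np.log2((lib[None, :] + 1.0) / 1e6)
    fitted_count = np.clip(fitted_count, xs[0], xs[-1])  # flat extrapolation
    w = np.interp(fitted_count, xs, ys) ** -4.0

    return NormalizedMatrix(
        logcpm=y,
        weights=w,
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        size_factors=lib / lib.mean(),
        trend=list(zip(map(float, xs), map(float, ys))),
    )


# ---------------------------------------------------------------------------
# QC


def pca_samples(
    norm: NormalizedMatrix | pd.DataFrame,
    n_components: int = 2,
    outlier_k: float = 3.0,
) -> pd.DataFrame:
    """Sample scores on the top principal axes of gene-standardized expression.

    A sample is flagged as an outlier when its distance from the score-space
    centroid exceeds ``outlier_k`` times the median distance.
    """
    if isinstance(norm, NormalizedMatrix):
        mat = norm.logcpm
        samples = norm.sample_ids
    else:
        mat = norm.to_numpy(float)
        samples = list(norm.columns)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = mat.std(axis=1, ddof=1)
    if not (sd > 0).any():
        raise ValueError("expression matrix is constant")
    z = (mat[sd > 0] - mat[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0, None]
    n_components = min(n_components, mat.shape[1] - 1, z.shape[0])
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(z.T)
    dist = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    med = np.median(dist)
    flags = dist > outlier_k * med if med > 0 else np.zeros(len(dist), bool)
    out = pd.DataFrame(
        scores, index=samples, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    out["outlier"] = flags
    return out


def validate_markers(counts: CountMatrix, markers: Sequence[str]) -> pd.DataFrame:
    """Report presence and mean CPM of region marker genes (e.g. hcrt, npvf, npy)."""
    lib = counts.library_sizes.astype(float)
    cpm = (counts.values + 0.5) / (lib[None, :] + 1.0) * 1e6
    index = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = []
    for m in markers:
        i = index.get(m)
        if i is None:
            rows.append({"marker": m, "found": False, "mean_cpm": np.nan})
        else:
            rows.append({"marker": m, "found": True, "mean_cpm": float(cpm[i].mean())})
    return pd.DataFrame(rows).set_index("marker")
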