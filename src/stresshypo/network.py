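"""Signed-hybrid weighted co-expression networks.

Pipeline: Pearson correlation across samples → signed-hybrid adjacency
(``cor**beta`` for positive correlations, 0 otherwise) → topological overlap
matrix (TOM) → average-linkage clustering of ``1 - TOM`` → modules →
module eigengenes (first principal component of each module's standardized
expression) → module membership (kME), hub genes, and an OLS test of each
eigengene on the group indicator.

The soft power can be fixed (default 6) or chosen by a scale-free-topology
scan with two selection rules: the literal "fit above 0.8 with minimal mean
connectivity" rule, and the conventional smallest qualifying power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PowerScan",
    "CoexpressionNetwork",
    "ModuleResults",
    "scale_free_fit",
    "pick_power",
    "adjacency_signed_hybrid",
    "tom_similarity",
    "detect_modules",
    "eigengenes",
    "module_membership",
    "me_group_regression",
    "hub_genes",
]


@dataclass
class PowerScan:
    """Scale-free-topology scan over candidate soft powers."""

    powers: list[int]
    r2_signed: list[float]
    mean_k: list[float]
    selected: int
    flagged: bool  # True when no candidate exceeded the fit threshold


def _pearson(expr: np.ndarray) -> np.ndarray:
    """Gene × gene Pearson correlation; constant genes yield NaN rows."""
    sd = expr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    c = (z @ z.T) / expr.shape[1]
    np.clip(c, -1.0, 1.0, out=c)
    return c


def adjacency_signed_hybrid(
    expr: np.ndarray | pd.DataFrame, power: float
) -> np.ndarray:
    """a_ij = cor(x_i, x_j)^power when cor > 0, else 0; a_ii = 1."""
    if power < 1:
        raise ValueError("power must be >= 1")
    mat = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    c = _pearson(mat)
    if np.isnan(c).any():
        bad = np.flatnonzero(np.isnan(np.diag(c)))
        raise ValueError(f"constant gene(s) at rows {bad[:5].tolist()}; drop them first")
    a = np.where(c > 0, c, 0.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def _connectivity(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(
    expr: np.ndarray | pd.DataFrame, power: float, n_bins: int = 10
) -> tuple[float, float]:
    """Signed scale-free fit index and mean connectivity at one soft power.

    Connectivities are binned, log10 frequency is regressed on log10 mean
    connectivity per occupied bin, and R^2 is signed by the negated slope
    sign (scale-free topology has a falling log-log frequency curve).
    Returns (r2_signed, mean_k); r2 is NaN when fewer than 2 occupied bins.
    """
    adj = adjacency_signed_hybrid(expr, power)
    k = _connectivity(adj)
    mean_k = float(k.mean())
    if np.allclose(k, 0):
        raise ValueError("empty network: all off-diagonal adjacencies are zero")
    if np.allclose(k, k[0]):
        return float("nan"), mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = idx == b
        if members.sum() and k[members].mean() > 0:
            xs.append(np.log10(k[members].mean()))
            ys.append(np.log10(members.mean()))
    if len(xs) < 2:
        return float("nan"), mean_k
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r * r * -np.sign(slope)), mean_k


def pick_power(
    expr: np.ndarray | pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    fit_threshold: float = 0.8,
    rule: str = "paper",
    n_bins: int = 10,
) -> PowerScan:
    """Scan candidate soft powers and select one.

    rule="paper": among candidates with signed fit > threshold, take the one
    with minimal mean connectivity (since connectivity falls with power,
    this is the largest qualifying power). rule="smallest": the smallest
    qualifying power. If none qualifies, the candidate with maximal fit is
    taken and the scan flagged.
    """
    r2s, ks = [], []
    for b in powers:
        r2, mk = scale_free_fit(expr, b, n_bins=n_bins)
        r2s.append(r2)
        ks.append(mk)
    defined = [i for i, r2 in enumerate(r2s) if np.isfinite(r2)]
    if not defined:
        raise ValueError("scale-free fit undefined at every candidate power")
    qualifying = [i for i in defined if r2s[i] > fit_threshold]
    if qualifying:
        if rule == "paper":
            sel = min(qualifying, key=lambda i: ks[i])
        elif rule == "smallest":
            sel = min(qualifying)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        flagged = False
    else:
        sel = max(defined, key=lambda i: r2s[i])
        flagged = True
    return PowerScan(list(powers), r2s, ks, int(powers[sel]), flagged)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor-weighted similarity in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with the
    sum over u != i, j and k the connectivity; TOM_ii = 1.
    """
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Clusters below min size become 0; survivors renumbered 1.. by size."""
    out = np.zeros_like(labels)
    sizes = pd.Series(labels).value_counts()
    keep = [
        (int(c), int(lab))
        for lab, c in sizes.items()
        if c >= min_module_size
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, old) in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    method: str = "static",
) -> np.ndarray:
    """Modules by average-linkage clustering on 1 - TOM.

    method="static": cut the dendrogram at ``cut_height``. method=
    "dynamic_tree": adaptive variant — scan cut heights over the merge-height
    range and keep the cut yielding the most clusters of at least
    ``min_module_size`` (ties to the higher cut). Clusters below the minimum
    size get label 0; surviving modules are numbered by decreasing size.
    """
    n = tom.shape[0]
    if min_module_size > n:
        return np.zeros(n, dtype=int)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    if method == "static":
        raw = fcluster(z, t=cut_height, criterion="distance")
    elif method == "dynamic_tree":
        heights = z[:, 2]
        candidates = np.unique(
            np.quantile(heights, np.linspace(0.5, 1.0, 40), method="nearest")
        )
        best_raw, best_score = None, (-1, -np.inf)
        for h in candidates:
            cand = fcluster(z, t=h, criterion="distance")
            sizes = np.bincount(cand)[1:]  # fcluster labels start at 1
            score = (int((sizes >= min_module_size).sum()), h)
            if score > best_score:
                best_score, best_raw = score, cand
        raw = best_raw
    else:
        raise ValueError(f"unknown method {method!r}")
    return _relabel_by_size(np.asarray(raw), min_module_size)


def eigengenes(
    expr: np.ndarray | pd.DataFrame, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Module eigengenes and per-module variance explained.

    The eigengene is the first principal-component score of the module's
    gene-standardized expression, scaled to unit variance and oriented so
    its mean correlation with member genes is positive.
    """
    mat = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    samples = (
        list(expr.columns) if isinstance(expr, pd.DataFrame) else list(range(mat.shape[1]))
    )
    mes, varexp = {}, {}
    for m in sorted(set(labels) - {0}):
        sub = mat[labels == m]
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        corrs = np.array([np.corrcoef(row, me)[0, 1] for row in z])
        if corrs.mean() < 0:
            me = -me
        mes[m] = me
        varexp[m] = float(s[0] ** 2 / (s ** 2).sum())
    me_df = pd.DataFrame(mes, index=samples)
    me_df.columns = [f"ME{m}" for m in me_df.columns]
    return me_df, varexp


def module_membership(
    expr: np.ndarray | pd.DataFrame, mes: pd.DataFrame
) -> pd.DataFrame:
    """kME: Pearson correlation of each gene with each module eigengene."""
    mat = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    genes = (
        list(expr.index) if isinstance(expr, pd.DataFrame) else list(range(mat.shape[0]))
    )
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zg = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    mevals = mes.to_numpy(float)
    zm = (mevals - mevals.mean(axis=0)) / mevals.std(axis=0)
    kme = (zg @ zm) / mat.shape[1]
    kme[sd == 0] = np.nan  # constant genes: membership undefined
    return pd.DataFrame(np.clip(kme, -1, 1), index=genes, columns=mes.columns)


def me_group_regression(
    mes: pd.DataFrame, group: Sequence[int] | np.ndarray
) -> pd.DataFrame:
    """OLS of each module eigengene on intercept + group indicator.

    Returns per module (b, SE, p): the group coefficient, its standard
    error, and the two-sided t-test p-value on n - 2 df. For a binary
    indicator b equals the difference of group means and the t statistic
    the pooled-variance two-sample t.
    """
    x = np.asarray(group, dtype=float)
    levels = np.unique(x)
    if len(levels) != 2 or min((x == lv).sum() for lv in levels) < 2:
        raise ValueError("need two groups with at least 2 samples each")
    x = (x == levels[1]).astype(float)
    n = len(x)
    rows = []
    for col in mes.columns:
        y = mes[col].to_numpy(float)
        xc = x - x.mean()
        b = float((xc @ y) / (xc @ xc))
        a = y.mean() - b * x.mean()
        resid = y - a - b * x
        s2 = float(resid @ resid) / (n - 2)
        se = np.sqrt(s2 / (xc @ xc))
        t = b / se if se > 0 else np.inf * np.sign(b)
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append({"module": col, "b": b, "SE": se, "p": p})
    return pd.DataFrame(rows).set_index("module")


def hub_genes(
    kme: pd.DataFrame, labels: np.ndarray, top_n: int = 5
) -> dict[int, list[str]]:
    """Per module, the top-|kME| member genes (ties broken by gene id)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    genes = np.asarray(kme.index, dtype=object)
    out: dict[int, list[str]] = {}
    for m in sorted(set(labels) - {0}):
        members = genes[labels == m]
        scores = kme.loc[members, f"ME{m}"].abs()
        ranked = sorted(members, key=lambda g: (-scores[g], g))
        out[m] = [str(g) for g in ranked[:top_n]]
    return out


# ---------------------------------------------------------------------------
# Model / Results surface


class CoexpressionNetwork:
    """Signed-hybrid WGCNA-style model over a normalized expression matrix.

    Parameters
    ----------
    expr : DataFrame (genes x samples)
        Expression on a log scale (median-of-ratios normalized log2 counts).
    group : array-like group indicator per sample, optional
        Enables the eigengene-vs-group regression.
    power : int or "scan"
        Soft-thresholding power; "scan" selects by scale-free fit.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        group: Sequence[int] | np.ndarray | None = None,
        power: int | str = 6,
        power_rule: str = "paper",
        powers: Sequence[int] = tuple(range(1, 21)),
    ):
        sd = expr.to_numpy(float).std(axis=1)
        if (sd == 0).any():
            expr = expr.loc[sd > 0]  # constant genes carry no correlation signal
        self.expr = expr
        self.group = None if group is None else np.asarray(group, dtype=float)
        self.power = power
        self.power_rule = power_rule
        self.powers = powers

    def fit(
        self,
        min_module_size: int = 30,
        cut_height: float = 0.995,
        method: str = "static",
        top_hubs: int = 5,
    ) -> "ModuleResults":
        if self.power == "scan":
            scan = pick_power(self.expr, self.powers, rule=self.power_rule)
            power, power_scan = scan.selected, scan
        else:
            power, power_scan = int(self.power), None
        adj = adjacency_signed_hybrid(self.expr, power)
        tom = tom_similarity(adj)
        del adj
        labels = detect_modules(tom, min_module_size, cut_height, method)
        del tom
        mes, varexp = eigengenes(self.expr, labels)
        kme = module_membership(self.expr, mes) if len(mes.columns) else pd.DataFrame(index=self.expr.index)
        regression = (
            me_group_regression(mes, self.group)
            if self.group is not None and len(mes.columns)
            else None
        )
        hubs = hub_genes(kme, labels, top_hubs) if len(mes.columns) else {}
        return ModuleResults(self, power, power_scan, labels, mes, varexp, kme, regression, hubs)


class ModuleResults:
    """Results of a :class:`CoexpressionNetwork` fit."""

    def __init__(self, model, power, power_scan, labels, mes, varexp, kme, regression, hubs):
        self.model = model
        self.power = power
        self.power_scan = power_scan
        self.labels = pd.Series(labels, index=model.expr.index, name="module")
        self.eigengenes = mes
        self.variance_explained = varexp
        self.kme = kme
        self.group_regression = regression
        self.hubs = hubs

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() != 0).sum())

    def summary(self) -> str:
        lines = [
            "Signed-hybrid co-expression network",
            "=" * 40,
            f"genes:               {len(self.labels)}",
            f"soft power:          {self.power}",
            f"modules (size >= min): {self.n_modules}",
            f"assigned genes:      {int((self.labels != 0).sum())}",
        ]
        if self.group_regression is not None:
            sig = self.group_regression[self.group_regression["p"] < 0.05]
            lines.append(f"group-associated MEs (p<.05): {len(sig)}")
            for mod, row in sig.iterrows():
                lines.append(
                    f"  {mod}: b = {row['b']:+.3f} +/- {row['SE']:.3f}, p = {row['p']:.3g}"
                )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.labels.to_csv(outdir / "modules.tsv", sep="\t")
        self.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        self.kme.to_csv(outdir / "kme.tsv", sep="\t")
        if self.group_regression is not None:
            self.group_regression.to_csv(outdir / "me_group_regression.tsv", sep="\t")
        pd.DataFrame(
            [(m, i + 1, g) for m, gs in self.hubs.items() for i, g in enumerate(gs)],
            columns=["module", "rank", "gene"],
        ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
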