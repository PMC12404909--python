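"""Synthetic Tag-seq experiments with planted structure.

The generator emulates a two-group (Control vs Stressed) bulk 3'-tag
sequencing design with 10 animals per group: negative-binomial counts with a
log2-scale baseline, per-sample library-size factors, an exact planted
log2 fold change for a chosen set of genes, and co-expression modules driven
by latent per-sample factors, some of which differ between groups. A matching
phenotype simulator draws metabolic and behavioral measures from per-group
normal summaries (mean, SD), truncating masses and counts at zero.

Everything downstream (filters, voom, moderated tests, permutation eFDR,
network modules, phenotype tests) can be exercised against the returned
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_phenotypes",
    "PHENOTYPE_SUMMARIES",
    "BEHAVIOR_SUMMARIES",
]


class ParameterError(ValueError):
    """Raised when a simulation parameter violates its contract."""


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment.

    Defaults mirror the emulated study design: 10 animals per group, planted
    differential expression split half up / half down at a modest effect
    size, and a dozen latent co-expression modules of which two shift
    between groups.
    """

    n_genes: int = 5000
    n_per_group: int = 10
    n_de: int = 500
    lfc_de: float = 0.5
    nb_dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (2.0, 10.0)
    n_modules: int = 12
    module_size_range: tuple[int, int] = (30, 300)
    module_cor_strength: float = 0.7
    n_group_shifted_modules: int = 2
    group_shift: float = 2.0  # latent eigengene offset between groups, in latent-SD units
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        def _positive(name: str, value: float) -> None:
            if not value > 0:
                raise ParameterError(f"{name} must be positive, got {value}")

        _positive("n_genes", self.n_genes)
        _positive("n_per_group", self.n_per_group)
        _positive("lfc_de", self.lfc_de)
        _positive("nb_dispersion", self.nb_dispersion)
        if self.n_de < 0:
            raise ParameterError(f"n_de must be >= 0, got {self.n_de}")
        if self.n_de > self.n_genes:
            raise ParameterError("n_de exceeds n_genes")
        if self.n_modules < 0:
            raise ParameterError(f"n_modules must be >= 0, got {self.n_modules}")
        if self.n_group_shifted_modules < 0 or self.n_group_shifted_modules > self.n_modules:
            raise ParameterError("n_group_shifted_modules must be in [0, n_modules]")
        if not 0 < self.module_cor_strength < 1:
            raise ParameterError("module_cor_strength must be in (0, 1)")
        for name in ("baseline_logmean_range", "module_size_range", "lib_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        if self.module_size_range[0] < 1:
            raise ParameterError("module_size_range entries must be positive")
        if self.lib_size_range[0] <= 0:
            raise ParameterError("lib_size_range entries must be positive")
        if self.n_modules * self.module_size_range[1] > 0 and (
            self.n_modules * self.module_size_range[0] > self.n_genes
        ):
            raise ParameterError("sum of minimal module sizes exceeds n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    de_genes: dict[str, float]  # gene id -> signed planted log2FC
    module_assignment: dict[str, int]  # gene id -> module label, 0 = background
    group_shifted_modules: list[int]
    lib_factors: dict[str, float]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_genes={k: float(v) for k, v in d["de_genes"].items()},
            module_assignment={k: int(v) for k, v in d["module_assignment"].items()},
            group_shifted_modules=[int(m) for m in d["group_shifted_modules"]],
            lib_factors={k: float(v) for k, v in d["lib_factors"].items()},
        )


_LN2 = np.log(2.0)


def simulate_experiment(
    params: SimulationParams,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic experiment.

    Returns the count matrix, a sample sheet (sample id, group), and the
    planted truth. Counts are negative binomial with variance
    ``mu + dispersion * mu**2``; planted DE genes differ between groups by
    exactly ``lfc_de`` on the log2 mean; module genes share a latent
    per-sample factor whose loading is calibrated so the gene–eigengene
    correlation approaches ``module_cor_strength``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_struct, rng_latent, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n = 2 * params.n_per_group
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    samples = [f"C{i + 1:02d}" for i in range(params.n_per_group)] + [
        f"S{i + 1:02d}" for i in range(params.n_per_group)
    ]
    group = np.r_[np.zeros(params.n_per_group), np.ones(params.n_per_group)]

    lo, hi = params.baseline_logmean_range
    base_log2 = rng_struct.uniform(lo, hi, size=params.n_genes)

    # module sizes and assignment; planted DE genes live outside modules so
    # the two kinds of planted signal stay separable
    sizes = (
        rng_struct.integers(
            params.module_size_range[0], params.module_size_range[1] + 1, params.n_modules
        )
        if params.n_modules
        else np.array([], dtype=int)
    )
    while sizes.sum() + params.n_de > params.n_genes and sizes.size:
        sizes = np.maximum(params.module_size_range[0], sizes - 10)
        if sizes.sum() + params.n_de > params.n_genes and (
            sizes == params.module_size_range[0]
        ).all():
            raise ParameterError("n_genes too small for requested modules plus DE genes")

    perm = rng_struct.permutation(params.n_genes)
    labels = np.zeros(params.n_genes, dtype=int)
    pos = 0
    for m, sz in enumerate(sizes, start=1):
        labels[perm[pos : pos + sz]] = m
        pos += sz
    de_idx = perm[pos : pos + params.n_de]
    n_up = (params.n_de + 1) // 2  # ties toward up
    de_sign = np.r_[np.ones(n_up), -np.ones(params.n_de - n_up)]

    # latent per-sample factors; group-shifted modules get a mean offset
    shifted = list(range(1, params.n_group_shifted_modules + 1))
    latent = rng_latent.standard_normal((params.n_modules, n)) if params.n_modules else np.empty((0, n))
    for j, m in enumerate(shifted):
        # alternate direction so stress raises some modules and lowers others
        latent[m - 1] += params.group_shift * group * (1.0 if j % 2 == 0 else -1.0)

    # log2-scale mean matrix
    log2_mu = np.tile(base_log2[:, None], (1, n))
    log2_mu[de_idx] += (de_sign[:, None] * params.lfc_de / 2.0) * (2 * group[None, :] - 1)

    # loading chosen so gene-vs-latent correlation ~ module_cor_strength given
    # the NB noise scale (delta method on log2 counts)
    mu0 = 2.0 ** base_log2
    sigma_g = np.sqrt(params.nb_dispersion + 1.0 / mu0) / _LN2
    c = params.module_cor_strength
    lam = c / np.sqrt(1.0 - c * c) * sigma_g
    for m in range(1, params.n_modules + 1):
        members = labels == m
        log2_mu[members] += lam[members, None] * latent[m - 1][None, :]

    lib = rng_struct.uniform(*params.lib_size_range, size=n)
    mu = 2.0 ** log2_mu * lib[None, :]

    r = 1.0 / params.nb_dispersion
    counts = rng_counts.negative_binomial(r, r / (r + mu))

    sheet = pd.DataFrame(
        {"sample": samples, "group": np.where(group == 1, "Stressed", "Control")}
    ).set_index("sample")

    truth = SyntheticTruth(
        de_genes={genes[i]: float(s * params.lfc_de) for i, s in zip(de_idx, de_sign)},
        module_assignment={genes[i]: int(labels[i]) for i in range(params.n_genes)},
        group_shifted_modules=shifted,
        lib_factors=dict(zip(samples, map(float, lib))),
    )
    return CountMatrix(counts, genes, samples), sheet, truth


# ---------------------------------------------------------------------------
# Phenotypes

#: Reported per-group metabolic summaries (mean, SD) of the emulated study:
#: body weight at P42 (g), weight gained P28→P42 (%), total white adipose
#: tissue (g), and food efficiency (g gained / g eaten).
PHENOTYPE_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "body_weight_p42": {"Control": (83.8, 7.66), "Stressed": (91.8, 11.9)},
    "weight_gain_pct": {"Control": (48.89, 7.08), "Stressed": (59.38, 7.01)},
    "fat_mass": {"Control": (5.21, 1.13), "Stressed": (6.83, 2.25)},
    "food_efficiency": {"Control": (0.162, 0.025), "Stressed": (0.191, 0.028)},
}

#: Daily subjugation behaviors of Stressed animals (drawn only for that
#: group): attacks received 0–2/day, tail-ups 1–3/day, resident scent marks
#: 0–1/day — encoded as normal (mean, SD) at the range midpoints.
BEHAVIOR_SUMMARIES: dict[str, tuple[float, float]] = {
    "attacks_received": (1.0, 0.5),
    "tail_ups": (2.0, 0.5),
    "scent_marks": (0.5, 0.25),
}

#: Measures that cannot be negative (floored at 0 when drawn).
NONNEGATIVE_MEASURES = {
    "body_weight_p42",
    "fat_mass",
    "food_efficiency",
    "attacks_received",
    "tail_ups",
    "scent_marks",
}


def simulate_phenotypes(
    group_summaries: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_per_group: int = 10,
    seed: int = 0,
    behavior_summaries: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Draw a per-animal phenotype sheet from per-group normal summaries.

    ``group_summaries`` maps measure -> {group label: (mean, sd)}. Measures in
    ``NONNEGATIVE_MEASURES`` are truncated at zero. Behaviors are drawn for
    the Stressed group only (Control animals were never attacked) and left
    missing for Controls.
    """
    if group_summaries is None:
        group_summaries = PHENOTYPE_SUMMARIES
    if behavior_summaries is None:
        behavior_summaries = BEHAVIOR_SUMMARIES
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    for measure, groups in group_summaries.items():
        for label, (_, sd) in groups.items():
            if sd <= 0:
                raise ParameterError(f"sd must be positive for {measure}/{label}, got {sd}")
    for measure, (_, sd) in behavior_summaries.items():
        if sd <= 0:
            raise ParameterError(f"sd must be positive for behavior {measure}, got {sd}")

    rng = np.random.default_rng(seed)
    labels = sorted({lb for gs in group_summaries.values() for lb in gs})
    rows: dict[str, list] = {"sample": [], "group": []}
    for li, label in enumerate(labels):
        prefix = label[0].upper()
        for i in range(n_per_group):
            rows["sample"].append(f"{prefix}{i + 1:02d}")
            rows["group"].append(label)
    df = pd.DataFrame(rows).set_index("sample")

    for measure, groups in group_summaries.items():
        col = np.empty(len(df))
        for label, (mean, sd) in groups.items():
            mask = (df["group"] == label).to_numpy()
            col[mask] = rng.normal(mean, sd, size=mask.sum())
        if measure in NONNEGATIVE_MEASURES:
            col = np.maximum(col, 0.0)
        df[measure] = col

    stressed = (df["group"] == "Stressed").to_numpy()
    for behavior, (mean, sd) in behavior_summaries.items():
        col = np.full(len(df), np.nan)
        if stressed.any():
            col[stressed] = np.maximum(rng.normal(mean, sd, size=stressed.sum()), 0.0)
        df[behavior] = col
    return df
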