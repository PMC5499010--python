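"""Correlation statistics quantifying the deconvolution artifact.

Provides Pearson, Spearman (midranks for ties) and rank-based partial
correlation conditioning on a covariate such as tumor purity; cohort-level
artifact reports comparing truth-truth, estimate-estimate and
estimate-truth correlations; and the gene-by-gene purity-correlation
ranking that flags signature genes expressed by malignant cells.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import scipy.stats

from .deconv import FractionEstimate
from .simulate import MixtureSet, TumorCohort

__all__ = [
    "UndefinedCorrelationError",
    "ArtifactReport",
    "PurityRanking",
    "pearson",
    "spearman",
    "partial_spearman",
    "artifact_report",
    "purity_correlation_ranking",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input, degenerate
    conditioning)."""


def _validate_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x, y = _validate_pair(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Rank correlation: Pearson on midrank-transformed data."""
    x, y = _validate_pair(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(scipy.stats.spearmanr(x, y).statistic)


def partial_spearman(x, y, z) -> float:
    """Spearman correlation of x and y after removing the rank-linear
    contribution of the conditioning variable z.

    Computed by the partial-correlation-of-ranks formula
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) on
    midrank-transformed data; equivalent to correlating the residuals of
    ranked x and ranked y regressed on ranked z.
    """
    x, y = _validate_pair(x, y, 4)
    z = np.asarray(z, dtype=float).ravel()
    if z.shape != x.shape:
        raise ValueError("conditioning vector length mismatch")
    for v, name in ((x, "x"), (y, "y"), (z, "z")):
        if np.std(v) == 0:
            raise UndefinedCorrelationError(f"{name} is constant")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rz = scipy.stats.rankdata(z)
    r_xy = pearson(rx, ry)
    r_xz = pearson(rx, rz)
    r_yz = pearson(ry, rz)
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:  # |r| = 1 up to floating point
        raise UndefinedCorrelationError(
            "x or y is rank-degenerate in the conditioning variable")
    return float((r_xy - r_xz * r_yz) / math.sqrt(denom))


@dataclasses.dataclass(frozen=True)
class ArtifactReport:
    """Correlation summary for one cohort and one focal cell-type pair.

    ``r_truth`` is the Pearson correlation between the two true fractions
    (None when the truth is constant, e.g. fixed-fraction designs — reported
    as undefined, not 0); ``r_est``/``rho_est`` correlate the two components'
    *normalized* estimates; ``r_est_vs_truth`` is the per-component
    estimate-truth Pearson correlation.  Degenerate (all-zero) estimates are
    excluded pairwise and counted in ``n_excluded``.
    """

    pair: tuple[str, str]
    r_truth: float | None
    r_est: float | None
    rho_est: float | None
    r_est_vs_truth: tuple[float | None, float | None]
    n_used: int
    n_excluded: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _constant(v: np.ndarray) -> bool:
    # exact or numerically degenerate constancy (e.g. tiled fixed fractions)
    return np.ptp(v) <= 1e-12 * max(1.0, float(np.abs(v).max()))


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.size < 3 or _constant(x) or _constant(y):
        return None
    return pearson(x, y)


def artifact_report(truth: MixtureSet, estimates: list[FractionEstimate],
                    pair: tuple[int, int] | None = None) -> ArtifactReport:
    """Correlations among true and estimated fractions for the focal pair.

    ``pair`` defaults to the cohort's mixed components.  Requires at least
    3 non-degenerate samples.
    """
    if len(estimates) != truth.n_samples:
        raise ValueError("estimates are not aligned with the cohort")
    if pair is None:
        pair = truth.component_indices
    c1, c2 = pair
    usable = np.array([not e.degenerate for e in estimates], dtype=bool)
    n_used = int(usable.sum())
    n_excluded = truth.n_samples - n_used
    if n_used < 3:
        raise ValueError(f"only {n_used} usable samples; need at least 3")
    est = np.array([estimates[i].normalized
                    for i in np.nonzero(usable)[0]])
    f1 = truth.true_fractions[usable, c1]
    f2 = truth.true_fractions[usable, c2]
    g1, g2 = est[:, c1], est[:, c2]
    rho_est = None
    if not (_constant(g1) or _constant(g2)):
        rho_est = spearman(g1, g2)
    return ArtifactReport(
        pair=(truth.cell_types[c1], truth.cell_types[c2]),
        r_truth=_safe_pearson(f1, f2),
        r_est=_safe_pearson(g1, g2),
        rho_est=rho_est,
        r_est_vs_truth=(_safe_pearson(g1, f1), _safe_pearson(g2, f2)),
        n_used=n_used,
        n_excluded=n_excluded,
    )


@dataclasses.dataclass(frozen=True)
class PurityRanking:
    """Genes ranked (descending) by their correlation with tumor purity.

    A positive correlation means higher expression in purer (more
    malignant) samples, i.e. the gene is expressed by malignant cells and
    is not immune-specific.  ``planted_recovery`` is the fraction of truly
    planted genes found in the top len(planted) ranks (None when the cohort
    has no planted genes); constant genes get missing r and rank last.
    """

    gene_ids: list[str]
    r: np.ndarray
    n_positive: int
    planted_recovery: float | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"gene": self.gene_ids, "r": self.r})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def purity_correlation_ranking(cohort: TumorCohort,
                               method: str = "pearson") -> PurityRanking:
    """Correlate each gene's expression with purity and rank descending."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if cohort.n_samples < 10:
        raise ValueError("need at least 10 samples")
    corr = pearson if method == "pearson" else spearman
    purity = cohort.purity
    r = np.full(len(cohort.gene_ids), np.nan)
    for g in range(len(cohort.gene_ids)):
        expr = cohort.expression[:, g]
        if np.std(expr) == 0:
            continue  # constant gene: missing r, ranked last
        r[g] = corr(expr, purity)
    order = np.argsort(np.where(np.isnan(r), -np.inf, r))[::-1]
    ranked_genes = [cohort.gene_ids[i] for i in order]
    ranked_r = r[order]
    n_positive = int(np.nansum(ranked_r > 0))
    planted_recovery = None
    if cohort.planted_genes:
        k = len(cohort.planted_genes)
        top = set(ranked_genes[:k])
        planted_recovery = len(top & set(cohort.planted_genes)) / k
    return PurityRanking(ranked_genes, ranked_r, n_positive, planted_recovery)
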