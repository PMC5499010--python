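"""Synthetic signatures, mixture cohorts and purity-confounded tumor cohorts.

Three generators drive every experiment in this package:

* :func:`make_profile_pair` / :func:`make_synthetic_signature` build
  reference profiles with a *controlled* Pearson correlation between chosen
  column pairs, standing in for real signature-matrix contrasts such as the
  near-orthogonal CD8 T-cell / neutrophil pair (r ~ 0) and the highly
  similar naive / memory B-cell pair (r ~ 0.9).
* :func:`simulate_mixtures` builds two-component in-silico bulk cohorts
  Y_i = f1_i * X1 + f2_i * X2 + eps_i, with fractions drawn Uniform(0, 0.5)
  (or held fixed) and Gaussian noise whose SD equals the SD of the first
  component's profile.
* :func:`simulate_tumor_cohort` builds cohorts in which a per-sample tumor
  purity scales a malignant profile that expresses a planted subset of the
  signature genes, confounding gene-purity correlations.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .signature import SignatureMatrix

__all__ = [
    "FractionSampler",
    "MixtureSet",
    "TumorCohort",
    "ProfileConstructionError",
    "make_profile_pair",
    "make_synthetic_signature",
    "simulate_mixtures",
    "simulate_tumor_cohort",
]

#: Default marginal moments for synthetic linear-scale expression profiles.
#: Coefficient of variation 1 gives the right-skewed, strictly positive
#: shape typical of linear-scale microarray/RNA-seq signature values.
DEFAULT_MARGINAL_MEAN = 10.0
DEFAULT_MARGINAL_SD = 10.0


class ProfileConstructionError(RuntimeError):
    """Raised when a target profile correlation cannot be achieved."""


@dataclasses.dataclass(frozen=True)
class FractionSampler:
    """Sampler for the true mixing fractions of the mixed components.

    ``uniform`` mode draws each component independently from
    Uniform(low, high); the default bounds (0, 0.5) keep the two-component
    sum below 1.  ``fixed`` mode repeats the same constants for every
    sample (default 0.25 each, the Uniform(0, 0.5) midpoint).
    """

    mode: str = "uniform"
    low: float = 0.0
    high: float = 0.5
    fixed_values: tuple[float, ...] = (0.25, 0.25)

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "fixed"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.mode == "uniform":
            if not 0 <= self.low < self.high:
                raise ValueError("require 0 <= low < high")
        else:
            vals = np.asarray(self.fixed_values, dtype=float)
            if np.any(vals < 0) or vals.sum() > 1 + 1e-12:
                raise ValueError("fixed fractions must be >= 0 and sum to <= 1")

    def sample(self, n_samples: int, n_components: int,
               rng: np.random.Generator) -> np.ndarray:
        """Draw an (n_samples, n_components) fraction matrix."""
        if self.mode == "uniform":
            return rng.uniform(self.low, self.high, size=(n_samples, n_components))
        vals = np.asarray(self.fixed_values, dtype=float)
        if len(vals) != n_components:
            raise ValueError(
                f"{len(vals)} fixed values for {n_components} components"
            )
        return np.tile(vals, (n_samples, 1))


@dataclasses.dataclass(frozen=True)
class MixtureSet:
    """A simulated bulk cohort with known ground-truth fractions.

    ``expression`` is samples x genes; ``true_fractions`` is samples x
    cell-types with zeros in every non-component column (the generator mixes
    two cell types only, but downstream solvers see all columns and may
    mis-assign mass to the others).
    """

    gene_ids: list[str]
    cell_types: list[str]
    expression: np.ndarray
    true_fractions: np.ndarray
    noise_sd: float
    component_indices: tuple[int, int]
    seed: int

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    def to_tsv(self, directory: str | Path, prefix: str = "mixture") -> None:
        """Write expression (genes x samples), truth, and a JSON sidecar."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        samples = [f"S{i + 1}" for i in range(self.n_samples)]
        pd.DataFrame(self.expression.T, index=self.gene_ids, columns=samples) \
            .rename_axis("Gene symbol") \
            .to_csv(directory / f"{prefix}_expression.tsv", sep="\t")
        pd.DataFrame(self.true_fractions, index=samples, columns=self.cell_types) \
            .rename_axis("sample") \
            .to_csv(directory / f"{prefix}_true_fractions.tsv", sep="\t")
        meta = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "component_indices": list(self.component_indices),
            "n_samples": self.n_samples,
        }
        (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


@dataclasses.dataclass(frozen=True)
class TumorCohort:
    """A simulated tumor cohort with known purity and planted malignant genes.

    Expression is purity * malignant_profile + (1 - purity) * immune mixture
    + non-negative noise; ``planted_genes`` are the signature genes given
    nonzero malignant expression, violating the immune-specificity
    assumption of the signature.
    """

    gene_ids: list[str]
    expression: np.ndarray
    purity: np.ndarray
    malignant_profile: np.ndarray
    planted_genes: list[str]
    seed: int

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    def to_tsv(self, directory: str | Path, prefix: str = "tumor") -> None:
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        samples = [f"S{i + 1}" for i in range(self.n_samples)]
        pd.DataFrame(self.expression.T, index=self.gene_ids, columns=samples) \
            .rename_axis("Gene symbol") \
            .to_csv(directory / f"{prefix}_expression.tsv", sep="\t")
        pd.DataFrame({"purity": self.purity}, index=samples) \
            .rename_axis("sample") \
            .to_csv(directory / f"{prefix}_purity.tsv", sep="\t")
        meta = {"seed": self.seed, "planted_genes": self.planted_genes}
        (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def _to_marginal(z: np.ndarray, mean: float, sd: float, shape: str) -> np.ndarray:
    """Map standard-normal draws onto a non-negative expression marginal."""
    if shape == "lognormal":
        # moment-matched lognormal: strictly positive, right-skewed
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(mu + math.sqrt(sigma2) * z)
    if shape == "normal":
        return np.clip(mean + sd * z, 0.0, None)
    raise ValueError(f"unknown marginal shape {shape!r}")


def _sample_pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def make_profile_pair(n_genes: int, target_rho: float,
                      marginal_mean: float = DEFAULT_MARGINAL_MEAN,
                      marginal_sd: float = DEFAULT_MARGINAL_SD,
                      seed: int = 0, shape: str = "lognormal",
                      tol: float = 0.02, max_iter: int = 80,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two non-negative expression profiles with a controlled correlation.

    A shared standard-normal base vector and an independent one are combined
    with a latent mixing coefficient, mapped to the requested marginal, and
    the achieved sample Pearson correlation is driven to ``target_rho``
    (within ``tol``) by bisection on the latent coefficient.  The latent
    draws are fixed by ``seed``, so the output is deterministic.

    Raises :class:`ProfileConstructionError` (reporting the achieved
    correlation) if the tolerance cannot be met.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if not -0.99 <= target_rho <= 0.99:
        raise ValueError("target_rho must lie in [-0.99, 0.99]")
    if marginal_mean <= 0 or marginal_sd <= 0:
        raise ValueError("marginal mean and SD must be positive")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_genes)
    z2 = rng.standard_normal(n_genes)
    x1 = _to_marginal(z1, marginal_mean, marginal_sd, shape)

    def achieved(latent_rho: float) -> float:
        w = latent_rho * z1 + math.sqrt(max(0.0, 1.0 - latent_rho ** 2)) * z2
        return _sample_pearson(x1, _to_marginal(w, marginal_mean, marginal_sd, shape))

    lo, hi = -0.9999, 0.9999
    r_lo, r_hi = achieved(lo), achieved(hi)
    if not r_lo <= target_rho <= r_hi:
        raise ProfileConstructionError(
            f"target rho {target_rho} outside achievable range "
            f"[{r_lo:.3f}, {r_hi:.3f}]"
        )
    latent = 0.0
    for _ in range(max_iter):
        latent = 0.5 * (lo + hi)
        r = achieved(latent)
        if abs(r - target_rho) <= tol / 4.0:
            break
        if r < target_rho:
            lo = latent
        else:
            hi = latent
    w = latent * z1 + math.sqrt(max(0.0, 1.0 - latent ** 2)) * z2
    x2 = _to_marginal(w, marginal_mean, marginal_sd, shape)
    final = _sample_pearson(x1, x2)
    if abs(final - target_rho) > tol:
        raise ProfileConstructionError(
            f"achieved rho {final:.4f}, target {target_rho} +/- {tol}"
        )
    return x1, x2


def make_synthetic_signature(n_genes: int, n_cell_types: int,
                             rho_spec: list[tuple[tuple[int, int], float]] | None = None,
                             marginal_mean: float = DEFAULT_MARGINAL_MEAN,
                             marginal_sd: float = DEFAULT_MARGINAL_SD,
                             seed: int = 0, shape: str = "lognormal",
                             ) -> SignatureMatrix:
    """Synthetic signature matrix with planted inter-profile correlations.

    ``rho_spec`` lists disjoint column-index pairs with a target Pearson
    correlation each; all other columns are drawn independently and redrawn
    if they exceed a sampling-noise correlation bound (2.2/sqrt(n_genes),
    i.e. |r| < 0.1 at n_genes >= 500) against any already-placed column, so
    near-independence is guaranteed rather than merely expected.  Column
    pairs are built with :func:`make_profile_pair`; the whole matrix is
    deterministic in ``seed``.
    """
    rho_spec = list(rho_spec or [])
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    used: set[int] = set()
    for (a, b), rho in rho_spec:
        if a == b or not (0 <= a < n_cell_types and 0 <= b < n_cell_types):
            raise ValueError(f"invalid column pair ({a}, {b})")
        if a in used or b in used:
            raise ValueError("rho_spec pairs must be disjoint")
        used.update((a, b))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cell_types + len(rho_spec))
    child_seeds = (child_seeds % (2 ** 31)).tolist()
    values = np.empty((n_genes, n_cell_types))
    for k, ((a, b), rho) in enumerate(rho_spec):
        x1, x2 = make_profile_pair(n_genes, rho, marginal_mean, marginal_sd,
                                   seed=child_seeds[n_cell_types + k], shape=shape)
        values[:, a], values[:, b] = x1, x2
    max_bg_r = 2.2 / math.sqrt(n_genes)
    placed = sorted(used)
    for j in range(n_cell_types):
        if j in used:
            continue
        rng = np.random.default_rng(child_seeds[j])
        for _ in range(200):
            col = _to_marginal(rng.standard_normal(n_genes),
                               marginal_mean, marginal_sd, shape)
            if all(abs(_sample_pearson(col, values[:, k])) <= max_bg_r
                   for k in placed):
                break
        else:
            raise ProfileConstructionError(
                f"could not draw a near-independent column {j}")
        values[:, j] = col
        placed.append(j)
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    cell_types = [f"CT{j + 1:02d}" for j in range(n_cell_types)]
    return SignatureMatrix(gene_ids, cell_types, values)


def simulate_mixtures(sig: SignatureMatrix, components: tuple[int, int],
                      sampler: FractionSampler, n_samples: int, seed: int,
                      noise_sd: float | None = None,
                      per_gene_noise: bool = False,
                      clip: bool = False) -> MixtureSet:
    """Simulate a two-component bulk cohort Y_i = f1_i*X1 + f2_i*X2 + eps_i.

    The noise eps_i is i.i.d. Gaussian per gene with one global SD equal to
    the sample SD of the first component's profile across genes (override
    with ``noise_sd``; set 0 for noiseless mixtures).  With
    ``per_gene_noise`` each gene instead gets SD proportional to its own
    X1 value, a sensitivity variant.  Expression is not clipped at zero by
    default, preserving the stated noise model; pass ``clip=True`` for
    solvers that require non-negative input.
    """
    c1, c2 = components
    if c1 == c2:
        raise ValueError("components must be distinct")
    if not (0 <= c1 < sig.n_cell_types and 0 <= c2 < sig.n_cell_types):
        raise ValueError("component index out of range")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    x1 = sig.values[:, c1]
    x2 = sig.values[:, c2]
    base_sd = float(np.std(x1, ddof=1))
    if base_sd == 0:
        raise ValueError("first component profile has zero variance")
    if noise_sd is None:
        noise_sd = base_sd
    rng = np.random.default_rng(seed)
    fractions = sampler.sample(n_samples, 2, rng)
    signal = fractions[:, [0]] * x1[None, :] + fractions[:, [1]] * x2[None, :]
    if per_gene_noise:
        scale = noise_sd / base_sd * np.abs(x1)[None, :]
        noise = rng.standard_normal((n_samples, sig.n_genes)) * scale
    else:
        noise = rng.normal(0.0, noise_sd, size=(n_samples, sig.n_genes)) \
            if noise_sd > 0 else np.zeros((n_samples, sig.n_genes))
    expression = signal + noise
    if clip:
        expression = np.clip(expression, 0.0, None)
    true_fractions = np.zeros((n_samples, sig.n_cell_types))
    true_fractions[:, c1] = fractions[:, 0]
    true_fractions[:, c2] = fractions[:, 1]
    return MixtureSet(list(sig.gene_ids), list(sig.cell_types), expression,
                      true_fractions, float(noise_sd), (c1, c2), seed)


def simulate_tumor_cohort(sig: SignatureMatrix, n_samples: int,
                          purity_low: float = 0.2, purity_high: float = 0.95,
                          planted_fraction: float = 0.25,
                          malignant_magnitude: float = 2.0,
                          immune_sampler: FractionSampler | None = None,
                          noise_sd: float | None = None,
                          seed: int = 0) -> TumorCohort:
    """Simulate tumor samples whose purity confounds gene-purity correlations.

    A malignant profile is zero except on a random ceil(q * n_genes) subset
    of signature genes (q = ``planted_fraction``), where it equals
    ``malignant_magnitude`` times that gene's mean signature expression.
    Per sample: purity ~ Uniform(purity_low, purity_high), immune mixing
    weights are drawn by ``immune_sampler`` and renormalized to sum to 1,
    and expression = purity * malignant + (1 - purity) * immune mixture +
    half-normal noise (default SD: 10% of the mean signature expression;
    0 disables it).  Genes planted in the malignant profile correlate
    positively with purity; purely immune genes correlate negatively.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not 0.0 <= purity_low < purity_high <= 1.0:
        raise ValueError("purity bounds must satisfy 0 <= low < high <= 1")
    if immune_sampler is None:
        immune_sampler = FractionSampler(mode="uniform", low=0.0, high=1.0)
    rng = np.random.default_rng(seed)
    n_genes = sig.n_genes
    mean_expr = sig.values.mean(axis=1)
    if noise_sd is None:
        noise_sd = 0.1 * float(sig.values.mean())

    n_planted = math.ceil(planted_fraction * n_genes)
    planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False)) \
        if n_planted else np.array([], dtype=int)
    malignant = np.zeros(n_genes)
    malignant[planted_idx] = malignant_magnitude * mean_expr[planted_idx]

    purity = rng.uniform(purity_low, purity_high, size=n_samples)
    weights = immune_sampler.sample(n_samples, sig.n_cell_types, rng)
    row_sums = weights.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    weights = weights / row_sums
    immune = weights @ sig.values.T
    expression = purity[:, None] * malignant[None, :] \
        + (1.0 - purity)[:, None] * immune
    if noise_sd > 0:
        expression = expression + np.abs(
            rng.normal(0.0, noise_sd, size=expression.shape))
    planted_genes = [sig.gene_ids[i] for i in planted_idx]
    return TumorCohort(list(sig.gene_ids), expression, purity, malignant,
                       planted_genes, seed)
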