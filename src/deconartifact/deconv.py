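"""Cell-type fraction estimation under three regression regimes.

The three solvers isolate the two sources of artifactual negative
correlation between estimated fractions:

* :func:`svr_deconvolve` — linear nu-support-vector regression on z-scored
  data with negative coefficients clipped and the rest renormalized to the
  simplex (the CIBERSORT-style pipeline: both collinearity-sensitive
  regression *and* sum-to-one closure).
* :func:`nnls_deconvolve` — plain non-negative least squares on the raw
  scale, no sum constraint (regression artifact only; the raw coefficients
  are free of the closure effect).
* :func:`cls_deconvolve` — least squares constrained to the probability
  simplex at fit time (closure imposed directly, no clipping heuristic).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize
from sklearn.svm import NuSVR

from .signature import SignatureMatrix
from .simulate import MixtureSet

__all__ = [
    "FractionEstimate",
    "svr_deconvolve",
    "nnls_deconvolve",
    "cls_deconvolve",
    "deconvolve_cohort",
    "estimates_to_frame",
]

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclasses.dataclass(frozen=True)
class FractionEstimate:
    """Estimated cell-type fractions for one sample.

    ``raw`` holds the non-negative coefficients before any sum-to-one step;
    ``normalized`` is the simplex-normalized view (None when the estimate is
    degenerate, i.e. all coefficients were zero — flagged, never NaN).
    """

    cell_types: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None
    solver: str
    solver_params: dict = dataclasses.field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return self.normalized is None

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "raw", raw)
        if raw.shape != (len(self.cell_types),):
            raise ValueError("coefficient length does not match cell types")
        if np.any(raw < 0):
            raise ValueError("raw coefficients must be non-negative")
        if self.normalized is not None:
            norm = np.asarray(self.normalized, dtype=float)
            object.__setattr__(self, "normalized", norm)
            if abs(norm.sum() - 1.0) > 1e-9 or np.any(norm < 0):
                raise ValueError("normalized fractions must be a simplex point")


def _check_alignment(sig: SignatureMatrix, y: np.ndarray,
                     min_extra_genes: int = 0) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != sig.n_genes:
        raise ValueError(
            f"mixture has {y.shape[0]} genes, signature has {sig.n_genes}")
    if sig.n_genes < sig.n_cell_types + min_extra_genes:
        raise ValueError(
            f"need at least {min_extra_genes} more genes than cell types")
    return y


def _finalize(cell_types: list[str], raw: np.ndarray, solver: str,
              params: dict) -> FractionEstimate:
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total > 0:
        normalized = raw / total
    else:
        normalized = None
        params = {**params, "degenerate": True}
    return FractionEstimate(list(cell_types), raw, normalized, solver, params)


def svr_deconvolve(sig: SignatureMatrix, mixture_profile: np.ndarray,
                   nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
                   C: float = 1.0) -> FractionEstimate:
    """nu-SVR deconvolution with simplex renormalization.

    The mixture vector is z-scored across genes and the signature matrix is
    standardized by its grand mean and SD (one scalar each, so the relative
    magnitudes of the columns — and hence the meaning of the coefficients as
    fractions — are preserved; per-column z-scoring would rescale each
    coefficient by that column's SD and distort the recovered proportions).
    A linear-kernel NuSVR is fitted for each nu in ``nu_grid`` and the fit
    with the lowest RMSE between fitted and observed standardized mixture
    wins (ties go to the smallest nu).  Negative coefficients are clipped to
    zero *then* the vector is renormalized to sum to 1 — the closure step
    that couples the estimates.
    """
    y = _check_alignment(sig, mixture_profile, min_extra_genes=2)
    x = sig.values
    xz = (x - x.mean()) / x.std(ddof=1)
    y_sd = y.std(ddof=1)
    if y_sd == 0:
        return _finalize(sig.cell_types, np.zeros(sig.n_cell_types), "svr",
                         {"selected_nu": None, "nu_grid": list(nu_grid)})
    yz = (y - y.mean()) / y_sd
    best: tuple[float, float, np.ndarray] | None = None  # (rmse, nu, coef)
    for nu in sorted(nu_grid):
        model = NuSVR(kernel="linear", nu=nu, C=C)
        model.fit(xz, yz)
        fitted = xz @ model.coef_.ravel() + model.intercept_.item()
        rmse = float(np.sqrt(np.mean((fitted - yz) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, nu, model.coef_.ravel().copy())
    assert best is not None
    rmse, nu, coef = best
    return _finalize(sig.cell_types, coef, "svr",
                     {"selected_nu": nu, "rmse": rmse, "C": C,
                      "nu_grid": list(nu_grid)})


def nnls_deconvolve(sig: SignatureMatrix,
                    mixture_profile: np.ndarray) -> FractionEstimate:
    """Non-negative least squares on unstandardized values, no sum constraint.

    raw = argmin ||X f - Y||_2 subject to f >= 0.  The raw coefficients are
    the quantity of interest here: they carry no closure artifact.
    """
    y = _check_alignment(sig, mixture_profile)
    coef, _ = scipy.optimize.nnls(sig.values, y)
    return _finalize(sig.cell_types, coef, "nnls", {})


def cls_deconvolve(sig: SignatureMatrix,
                   mixture_profile: np.ndarray) -> FractionEstimate:
    """Least squares constrained to the probability simplex at fit time.

    Solves argmin ||X f - Y||_2 subject to f >= 0 and sum(f) = 1.  The
    equality constraint is imposed by augmenting the system with a heavily
    weighted sum-to-one row (a standard weighted-NNLS reduction of the
    equality-constrained problem), then the solution is renormalized so the
    returned vector sums to 1 exactly.  raw and normalized coincide.
    """
    y = _check_alignment(sig, mixture_profile)
    x = sig.values
    scale = max(1.0, float(np.abs(x).max()), float(np.abs(y).max()))
    w = 1e6 * scale
    x_aug = np.vstack([x, w * np.ones((1, sig.n_cell_types))])
    y_aug = np.concatenate([y, [w]])
    coef, _ = scipy.optimize.nnls(x_aug, y_aug, maxiter=50 * sig.n_cell_types)
    total = coef.sum()
    if total <= 0 or abs(total - 1.0) > 1e-3:
        raise RuntimeError(
            f"simplex-constrained solver failed to converge (sum={total:.6g})")
    coef = coef / total
    return FractionEstimate(list(sig.cell_types), coef, coef, "cls", {})


_SOLVERS = {
    "svr": svr_deconvolve,
    "nnls": nnls_deconvolve,
    "cls": cls_deconvolve,
}


def deconvolve_cohort(sig: SignatureMatrix, mixtures: MixtureSet,
                      solver: str = "svr", **solver_kwargs,
                      ) -> list[FractionEstimate]:
    """Deconvolve every sample of a cohort, order preserved.

    Per-sample degenerate flags are propagated, never aborting the cohort.
    """
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; expected one of "
                         f"{sorted(_SOLVERS)}")
    if list(mixtures.gene_ids) != list(sig.gene_ids):
        raise ValueError("mixture genes are not aligned with the signature")
    fn = _SOLVERS[solver]
    return [fn(sig, mixtures.expression[i], **solver_kwargs)
            for i in range(mixtures.n_samples)]


def estimates_to_frame(estimates: list[FractionEstimate]):
    """Tabulate cohort estimates: rows = samples, columns = cell types,
    plus solver metadata columns (selected nu, degenerate flag).

    The layout is structurally compatible with the fraction tables emitted
    by deconvolution web servers, so external output can be analyzed
    side by side.
    """
    import pandas as pd

    if not estimates:
        return pd.DataFrame()
    cell_types = estimates[0].cell_types
    rows = []
    for est in estimates:
        vec = est.normalized if est.normalized is not None else est.raw
        row = dict(zip(cell_types, vec))
        row["solver"] = est.solver
        row["selected_nu"] = est.solver_params.get("selected_nu")
        row["degenerate"] = est.degenerate
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.index = [f"S{i + 1}" for i in range(len(rows))]
    return frame
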