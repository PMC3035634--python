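"""Per-gene-set mixed model testing and FDR screening.

For each gene set the outcome is the long vector of log2 expression values of
the member genes; disease group is the fixed effect of interest; batch and
subject enter as random intercepts; and random coefficients on eigenvectors of
the within-set gene-gene correlation matrix absorb heterogeneous co-expression
among the member genes. Screening a collection produces one raw p-value per
set and Benjamini-Hochberg adjusted p-values across all screened sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._fit import fit_marginal
from .errors import (
    DegenerateDataError,
    SetLookupError,
    ValidationError,
)
from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata, restrict_to_measured

__all__ = [
    "ModelSpec",
    "EigenBasis",
    "GeneSetResult",
    "ScreenTable",
    "center_by_group",
    "gene_correlation_eigen",
    "fit_gene_set_model",
    "bh_fdr_adjust",
    "screen_gene_sets",
]

_TESTS = ("t", "wald", "lrt")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the per-set mixed model.

    Parameters
    ----------
    K_max : maximum number of correlation eigenvectors retained as random
        coefficient terms; the actual K also honours ``explain_frac``.
    variance_floor : lower bound for variance ratios during optimization.
    test : group-effect test. ``"t"`` (default) is a Wald t statistic with
        between-subject denominator degrees of freedom (n_subjects - 2) at
        the REML fit; ``"wald"`` refers the same statistic squared to
        chi2(1); ``"lrt"`` refits both nested models by full ML and refers
        the deviance to chi2(1).
    include_batch : drop the batch random intercept when False (it is also
        dropped automatically when only one batch level is present).
    explain_frac : retain the smallest K whose eigenvalues cumulatively
        explain at least this fraction of the correlation-matrix trace.
    """

    K_max: int = 5
    variance_floor: float = 1e-8
    test: str = "t"
    include_batch: bool = True
    explain_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.K_max < 0:
            raise ValidationError(f"K_max must be >= 0, got {self.K_max}")
        if self.variance_floor < 0:
            raise ValidationError("variance_floor must be >= 0")
        if self.test not in _TESTS:
            raise ValidationError(f"test must be one of {_TESTS}, got {self.test!r}")
        if not 0.0 < self.explain_frac <= 1.0:
            raise ValidationError("explain_frac must be in (0, 1]")


@dataclass(frozen=True)
class EigenBasis:
    """Top eigenpairs of a gene-gene correlation matrix.

    ``loadings`` is G x K with orthonormal columns; ``eigenvalues`` are
    non-negative and non-increasing, summing to at most G (the trace of a
    correlation matrix).
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float))
        if self.loadings.shape[1] != len(self.eigenvalues):
            raise ValidationError("loadings/eigenvalues length mismatch")
        if np.any(self.eigenvalues < -1e-8):
            raise ValidationError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValidationError("eigenvalues must be non-increasing")

    @property
    def K(self) -> int:
        return self.loadings.shape[1]


@dataclass
class GeneSetResult:
    set_name: str
    size: int
    raw_p: float
    fdr_p: float
    beta_hat: float
    var_components: dict
    converged: bool
    n_eigen: int = 0
    message: str = ""


@dataclass
class ScreenTable:
    """Ordered screen results, ascending raw p, ties broken by set name."""

    results: list[GeneSetResult]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_name": [r.set_name for r in self.results],
                "size": [r.size for r in self.results],
                "raw_p": [r.raw_p for r in self.results],
                "fdr_p": [r.fdr_p for r in self.results],
                "beta_hat": [r.beta_hat for r in self.results],
                "converged": [r.converged for r in self.results],
            }
        )

    def write(self, path, full_precision: bool = False) -> None:
        df = self.to_dataframe()
        if not full_precision:
            for col in ("raw_p", "fdr_p", "beta_hat"):
                df[col] = df[col].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "NA")
        df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.results)


# ---------------------------------------------------------------------------


def center_by_group(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Subtract each gene's group-specific mean (preprocessing for the
    correlation estimate, so true group separation does not inflate apparent
    gene-gene correlation)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    group = np.asarray(group)
    out = values.copy()
    for lvl in np.unique(group):
        mask = group == lvl
        if mask.sum() < 2:
            raise ValidationError(f"group {lvl!r} has fewer than 2 samples")
        out[:, mask] -= out[:, mask].mean(axis=1, keepdims=True)
    return out


def gene_correlation_eigen(residuals: np.ndarray, K_max: int) -> EigenBasis:
    """Eigendecomposition of the Pearson correlation matrix of gene rows,
    returning the top ``min(K_max, rank)`` eigenpairs."""
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    G, n = R.shape
    if G < 2:
        raise ValidationError("need >= 2 genes for a correlation matrix")
    sd = R.std(axis=1)
    zero = np.nonzero(sd <= 0)[0]
    if zero.size:
        raise DegenerateDataError(
            f"zero-variance gene rows at indices {zero.tolist()}; filter before eigen"
        )
    C = np.corrcoef(R)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > 1e-10 * max(evals[0], 1.0)))
    K = min(int(K_max), rank)
    return EigenBasis(evecs[:, :K], evals[:K])


def _select_n_eigen(eigenvalues: np.ndarray, K_max: int, explain_frac: float) -> int:
    """Smallest K whose eigenvalues cumulatively explain ``explain_frac`` of
    the trace, capped at K_max."""
    if K_max == 0 or eigenvalues.size == 0:
        return 0
    total = float(np.sum(eigenvalues))
    if total <= 0:
        return 0
    cum = np.cumsum(eigenvalues) / total
    k80 = int(np.searchsorted(cum, explain_frac - 1e-12) + 1)
    return min(int(K_max), k80, len(eigenvalues))


def bh_fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    adjusted_i = min over {j : p_(j) >= p_i} of min(1, m * p_(j) / j) over
    the sorted order; monotone in raw-p rank and always >= raw.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------


def _mean_orthogonal_loadings(E: np.ndarray, min_norm: float = 1e-2):
    """Project the constant gene direction 1/sqrt(G) out of estimated
    eigenvector loadings and renormalize.

    The group contrast acts on the set-average (all-ones) direction in gene
    space; eigenvectors are estimated from the same data the model is fitted
    to, and their overlap with that direction lets overfitted factor terms
    absorb exactly the between-sample variation the group test relies on,
    inflating the type-I error. Restricting the factor random effects to the
    mean-orthogonal subspace removes the double use: the subject component
    then carries all set-average variance and the group test keeps its
    nominal level. Columns nearly parallel to the constant direction (these
    duplicate the subject random intercept) are dropped.
    """
    G = E.shape[0]
    q1 = np.full(G, 1.0 / np.sqrt(G))
    Ep = E - np.outer(q1, q1 @ E)
    norms = np.linalg.norm(Ep, axis=0)
    keep = norms > min_norm
    if not np.any(keep):
        return None
    return Ep[:, keep] / norms[keep]


def _prepare_set_matrix(
    set_genes, matrix: ExpressionMatrix, meta: SampleMetadata, min_size: int
):
    wanted = set(set_genes)
    genes = [g for g in matrix.gene_ids if g in wanted]
    size = len(genes)
    if size < max(min_size, 1):
        raise ValidationError(
            f"gene set has {size} measured genes, below min_size={max(min_size, 1)}"
        )
    if meta.samples != matrix.sample_ids:
        meta = meta.reorder(matrix.sample_ids)
    Y = matrix.subset_genes(genes).values
    return genes, Y, meta


def fit_gene_set_model(
    set_genes,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    spec: ModelSpec = ModelSpec(),
    *,
    min_size: int = 1,
    set_name: str = "",
) -> GeneSetResult:
    """Fit the mixed model for one gene set and test the group effect.

    Returns a :class:`GeneSetResult` with ``raw_p`` set and ``fdr_p`` NaN
    (the FDR adjustment is defined across a screened family, not per set).
    ``beta_hat`` is the group (case - control) effect on the log2 scale.
    """
    genes, Y, meta = _prepare_set_matrix(set_genes, matrix, meta, min_size)
    size = len(genes)
    if np.ptp(Y) == 0.0:
        raise DegenerateDataError(f"set {set_name or '<set>'}: all values identical")

    case = meta.case_mask.astype(float)
    resid = center_by_group(Y, meta.group)

    # genes flat within both groups carry no residual variation: drop from
    # the correlation estimate and the fit (callers normally filter upstream)
    sd = resid.std(axis=1)
    flat = sd <= 1e-12 * max(float(np.abs(Y).max()), 1.0)
    if np.any(flat):
        dropped = [g for g, f in zip(genes, flat) if f]
        warnings.warn(
            f"set {set_name or '<set>'}: dropping zero-variance genes {dropped}",
            stacklevel=2,
        )
        keep = ~flat
        genes = [g for g, k in zip(genes, keep) if k]
        Y, resid = Y[keep], resid[keep]
        if len(genes) == 0:
            raise DegenerateDataError(
                f"set {set_name or '<set>'}: no genes with residual variance"
            )

    E = None
    n_eigen = 0
    if spec.K_max > 0 and len(genes) >= 2:
        basis = gene_correlation_eigen(resid, K_max=len(genes))
        n_eigen = _select_n_eigen(basis.eigenvalues, spec.K_max, spec.explain_frac)
        if n_eigen:
            E = _mean_orthogonal_loadings(basis.loadings[:, :n_eigen])
            n_eigen = E.shape[1] if E is not None else 0

    kwargs = dict(
        include_batch=spec.include_batch,
        variance_floor=spec.variance_floor,
    )
    fit = fit_marginal(
        Y, case, meta.batch, meta.subject, E, reml=True, include_group=True, **kwargs
    )
    beta_hat = float(fit.beta[1])
    converged = fit.converged

    if spec.test == "t":
        df = fit.n_subjects - 2
        if df <= 0:
            raise ValidationError("not enough subjects for a t test (need >= 3)")
        tstat = beta_hat / fit.se[1] if fit.se[1] > 0 else np.inf * np.sign(beta_hat)
        raw_p = float(2.0 * sps.t.sf(abs(tstat), df))
    elif spec.test == "wald":
        w = (beta_hat / fit.se[1]) ** 2 if fit.se[1] > 0 else np.inf
        raw_p = float(sps.chi2.sf(w, 1))
    else:  # lrt: both nested models refit by full ML
        full = fit_marginal(
            Y, case, meta.batch, meta.subject, E, reml=False, include_group=True, **kwargs
        )
        null = fit_marginal(
            Y, case, meta.batch, meta.subject, E, reml=False, include_group=False, **kwargs
        )
        stat = max(0.0, 2.0 * (full.loglik - null.loglik))
        raw_p = float(sps.chi2.sf(stat, 1))
        beta_hat = float(full.beta[1])
        converged = converged and full.converged and null.converged

    return GeneSetResult(
        set_name=set_name,
        size=size,
        raw_p=raw_p,
        fdr_p=float("nan"),
        beta_hat=beta_hat,
        var_components=fit.components,
        converged=converged,
        n_eigen=n_eigen,
    )


def screen_gene_sets(
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    spec: ModelSpec = ModelSpec(),
    min_size: int = 5,
) -> ScreenTable:
    """Screen a gene set collection: restrict to measured genes, fit every
    surviving set, BH-adjust across all screened sets, sort ascending raw p.

    Per-set failures are reported (``converged=False``, NaN p) rather than
    aborting the screen; failed sets are excluded from the BH family.
    """
    restricted = restrict_to_measured(collection, matrix.gene_ids, min_size=min_size)
    if len(restricted) == 0:
        raise ValidationError("no gene sets survive restriction to the measured genes")
    if meta.samples != matrix.sample_ids:
        meta = meta.reorder(matrix.sample_ids)

    results: list[GeneSetResult] = []
    for gs in restricted.sets():
        try:
            res = fit_gene_set_model(
                gs.genes, matrix, meta, spec, min_size=min_size, set_name=gs.name
            )
        except (DegenerateDataError, ValidationError) as exc:
            warnings.warn(f"set {gs.name}: fit failed ({exc}); reported unconverged")
            res = GeneSetResult(
                set_name=gs.name,
                size=gs.size,
                raw_p=float("nan"),
                fdr_p=float("nan"),
                beta_hat=float("nan"),
                var_components={},
                converged=False,
                message=str(exc),
            )
        results.append(res)

    ok = [r for r in results if np.isfinite(r.raw_p)]
    if ok:
        adj = bh_fdr_adjust([r.raw_p for r in ok])
        for r, a in zip(ok, adj):
            r.fdr_p = float(a)

    results.sort(key=lambda r: (not np.isfinite(r.raw_p), r.raw_p if np.isfinite(r.raw_p) else 0.0, r.set_name))
    return ScreenTable(results)
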