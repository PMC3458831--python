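"""Multiple regression on distance matrices (MRM) with permutation tests.

The response and predictor distance matrices are vectorized on their lower
triangles and fit by ordinary least squares with an intercept.  Explanatory
power is decomposed into sequential (type-I) sums of squares in the
user-supplied predictor order, so that SST = sum(SS_k) + SSE holds exactly.
Significance is assessed by matrix permutation: the taxa of the response
matrix are permuted simultaneously on rows and columns (predictors held
fixed), the model is refit, and p-values use the add-one convention
p = (b + 1) / (R + 1) — two-sided via |beta| for coefficients, upper-tail
for the (nonnegative) sequential SS.  With R = 10,000 randomizations the
minimum reportable p is about 0.0001.

Sampled permutations are drawn uniformly from the non-identity permutations;
the exhaustive mode (``permutations="exhaustive"``) enumerates all n! taxon
permutations and counts exceedances including the identity, so the two
estimators coincide when sampling covers every non-identity permutation.

Implementation notes: the design matrix is orthogonalized once by a QR
factorization; sequential SS are the squared projections of the response on
the successively orthogonalized predictor directions, which makes the
permutation loop a single matrix product over batches of permuted response
vectors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .phylo_distance import DistanceMatrix

__all__ = [
    "MRMError",
    "CollinearityError",
    "PredictorStats",
    "MRMResult",
    "vectorize_lower",
    "mrm_fit",
    "mrm_permutation_test",
    "variance_decomposition",
    "format_mrm_table",
]

_RANK_TOL = 1e-8
_EXHAUSTIVE_MAX_N = 8


class MRMError(ValueError):
    """Invalid MRM input."""


class CollinearityError(MRMError):
    """Predictor design is rank-deficient."""


@dataclass(frozen=True)
class PredictorStats:
    """Observed-data statistics for one predictor (one row of the table)."""

    name: str
    coefficient: float
    partial_correlation: float
    seq_ss: float
    p_beta: Optional[float] = None
    p_ss: Optional[float] = None


@dataclass(frozen=True)
class MRMResult:
    """Full MRM output: fit statistics plus permutation p-values."""

    predictors: tuple[PredictorStats, ...]
    intercept: float
    sst: float
    sse: float
    percent_variance: float
    n_taxa: int
    n_pairs: int
    randomizations: int = 0
    seed: Optional[int] = None
    permute: str = "response"
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "predictors": [
                {
                    "name": p.name,
                    "coefficient": p.coefficient,
                    "partial_correlation": p.partial_correlation,
                    "seq_ss": p.seq_ss,
                    "p_beta": p.p_beta,
                    "p_ss": p.p_ss,
                }
                for p in self.predictors
            ],
            "intercept": self.intercept,
            "sst": self.sst,
            "sse": self.sse,
            "percent_variance": self.percent_variance,
            "n_taxa": self.n_taxa,
            "n_pairs": self.n_pairs,
            "randomizations": self.randomizations,
            "seed": self.seed,
            "permute": self.permute,
            "exhaustive": self.exhaustive,
        }


def vectorize_lower(matrix: DistanceMatrix) -> np.ndarray:
    """Strict lower triangle of a symmetric matrix as a vector.

    Entries (i, j) with i > j in canonical label order, row-major; length
    n(n-1)/2.
    """
    values = matrix.values
    if matrix.n < 3:
        raise MRMError("need at least 3 taxa to vectorize a distance matrix")
    if not np.allclose(values, values.T, rtol=0.0, atol=1e-9):
        raise MRMError("matrix is asymmetric beyond tolerance 1e-9")
    i, j = np.tril_indices(matrix.n, k=-1)
    return values[i, j].astype(float)


def _aligned_vectors(
    Y: DistanceMatrix, Xs: Sequence[DistanceMatrix], names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    order = Y.labels
    y = vectorize_lower(Y)
    cols = []
    for name, X in zip(names, Xs):
        if set(X.labels) != set(order):
            raise MRMError(f"predictor {name!r} taxon set differs from response")
        cols.append(vectorize_lower(X.reorder(order)))
    return y, np.column_stack(cols)


def _design_qr(Xmat: np.ndarray, names: Sequence[str]):
    m = Xmat.shape[0]
    design = np.column_stack([np.ones(m), Xmat])
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    scale = np.max(diag) if np.max(diag) > 0 else 1.0
    bad = [names[k - 1] for k in range(1, design.shape[1]) if diag[k] < _RANK_TOL * scale]
    if bad:
        raise CollinearityError(
            f"rank-deficient design; collinear/degenerate predictor(s): {bad}"
        )
    return design, Q, R


@dataclass(frozen=True)
class _Fit:
    beta: np.ndarray  # intercept + p coefficients
    seq_ss: np.ndarray
    sse: float
    sst: float
    partial_corr: np.ndarray


def _fit_from_qr(Q: np.ndarray, R: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    c = Q.T @ y  # projections on successive orthogonal directions
    beta = np.linalg.solve(R, c)
    proj_sq = c**2
    yty = float(y @ y)
    sst = yty - proj_sq[0]  # first design column is the constant
    sse = yty - float(np.sum(proj_sq))
    seq_ss = proj_sq[1:]
    return beta, seq_ss, max(sse, 0.0), max(sst, 0.0)


def _partial_correlations(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual-residual correlations: y and x_k each residualized on the
    intercept and the other predictors."""
    p = design.shape[1] - 1
    out = np.zeros(p)
    for k in range(1, p + 1):
        others = np.delete(design, k, axis=1)
        coef_y, *_ = np.linalg.lstsq(others, y, rcond=None)
        coef_x, *_ = np.linalg.lstsq(others, design[:, k], rcond=None)
        ry = y - others @ coef_y
        rx = design[:, k] - others @ coef_x
        sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
        out[k - 1] = float(ry @ rx / (sy * sx)) if sy > 0 and sx > 0 else 0.0
    return out


def _fit(y: np.ndarray, Xmat: np.ndarray, names: Sequence[str]) -> _Fit:
    if np.std(y) == 0:
        raise MRMError("response matrix has zero variance")
    design, Q, R = _design_qr(Xmat, names)
    beta, seq_ss, sse, sst = _fit_from_qr(Q, R, y)
    partial = _partial_correlations(design, y)
    return _Fit(beta=beta, seq_ss=seq_ss, sse=sse, sst=sst, partial_corr=partial)


def _resolve_names(Xs: Sequence[DistanceMatrix], names: Optional[Sequence[str]]) -> list[str]:
    if names is None:
        return [f"X{k + 1}" for k in range(len(Xs))]
    if len(names) != len(Xs):
        raise MRMError("names and predictors differ in length")
    return list(names)


def mrm_fit(
    Y: DistanceMatrix,
    Xs: Sequence[DistanceMatrix],
    names: Optional[Sequence[str]] = None,
) -> MRMResult:
    """OLS fit of a response distance matrix on predictor matrices.

    Returns observed-data statistics only (no permutation p-values):
    coefficients, partial correlations, sequential SS in the given predictor
    order, SSE, SST and percent variance explained.
    """
    names = _resolve_names(Xs, names)
    if not Xs:
        raise MRMError("need at least one predictor matrix")
    y, Xmat = _aligned_vectors(Y, Xs, names)
    fit = _fit(y, Xmat, names)
    return _result_from_fit(fit, names, Y.n, len(y))


def _result_from_fit(
    fit: _Fit,
    names: Sequence[str],
    n_taxa: int,
    n_pairs: int,
    p_beta: Optional[np.ndarray] = None,
    p_ss: Optional[np.ndarray] = None,
    randomizations: int = 0,
    seed: Optional[int] = None,
    permute: str = "response",
    exhaustive: bool = False,
) -> MRMResult:
    predictors = tuple(
        PredictorStats(
            name=names[k],
            coefficient=float(fit.beta[k + 1]),
            partial_correlation=float(fit.partial_corr[k]),
            seq_ss=float(fit.seq_ss[k]),
            p_beta=None if p_beta is None else float(p_beta[k]),
            p_ss=None if p_ss is None else float(p_ss[k]),
        )
        for k in range(len(names))
    )
    pct = 100.0 * (fit.sst - fit.sse) / fit.sst if fit.sst > 0 else 0.0
    return MRMResult(
        predictors=predictors,
        intercept=float(fit.beta[0]),
        sst=fit.sst,
        sse=fit.sse,
        percent_variance=pct,
        n_taxa=n_taxa,
        n_pairs=n_pairs,
        randomizations=randomizations,
        seed=seed,
        permute=permute,
        exhaustive=exhaustive,
    )


def _permuted_response_vectors(
    Ymat: np.ndarray, perms: np.ndarray, tril: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    i, j = tril
    out = np.empty((perms.shape[0], i.size))
    for r in range(perms.shape[0]):
        p = perms[r]
        out[r] = Ymat[p[i], p[j]]
    return out


def mrm_permutation_test(
    Y: DistanceMatrix,
    Xs: Sequence[DistanceMatrix],
    permutations: Union[int, str] = 9999,
    seed: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
    permute: str = "response",
    batch_size: int = 2000,
) -> MRMResult:
    """MRM with matrix-permutation p-values.

    For each randomization a uniform non-identity permutation of the taxa
    is applied simultaneously to the rows and columns of the response
    matrix (predictors fixed) and the model refit.  p_beta is two-sided on
    |beta|; p_SS is upper-tailed on the sequential SS; both use the
    add-one convention (b + 1) / (R + 1).  ``permutations="exhaustive"``
    enumerates all n! permutations (n <= 8) for exact p-values.

    ``permute="predictors"`` is a sensitivity variant that permutes the
    taxa of every predictor jointly instead; by relabelling equivalence it
    is computed by permuting the response with the inverse permutation, and
    the choice is recorded in the result metadata.
    """
    names = _resolve_names(Xs, names)
    if not Xs:
        raise MRMError("need at least one predictor matrix")
    if permute not in ("response", "predictors"):
        raise MRMError("permute must be 'response' or 'predictors'")
    y, Xmat = _aligned_vectors(Y, Xs, names)
    if np.std(y) == 0:
        raise MRMError("response matrix has zero variance")
    design, Q, R = _design_qr(Xmat, names)
    beta, seq_ss, sse, sst = _fit_from_qr(Q, R, y)
    partial = _partial_correlations(design, y)
    fit = _Fit(beta=beta, seq_ss=seq_ss, sse=sse, sst=sst, partial_corr=partial)

    n = Y.n
    Ymat = Y.reorder(Y.labels).values
    tril = np.tril_indices(n, k=-1)
    abs_beta_obs = np.abs(beta[1:])
    ss_obs = seq_ss

    exhaustive = permutations == "exhaustive"
    if exhaustive:
        if n > _EXHAUSTIVE_MAX_N:
            raise MRMError(
                f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_MAX_N} taxa"
            )
        perms_iter = (
            np.array(batch)
            for batch in _chunks(itertools.permutations(range(n)), batch_size)
        )
        total = math.factorial(n)
        count_beta = np.zeros(len(names))
        count_ss = np.zeros(len(names))
        for perms in perms_iter:
            cb, cs = _count_exceedances(Ymat, perms, tril, Q, R, abs_beta_obs, ss_obs)
            count_beta += cb
            count_ss += cs
        # identity is included in the enumeration and always exceeds itself
        p_beta = count_beta / total
        p_ss = count_ss / total
        randomizations = total
    else:
        Rn = int(permutations)
        if Rn < 1:
            raise MRMError("permutations must be >= 1")
        rng = np.random.default_rng(seed)
        identity = np.arange(n)
        count_beta = np.zeros(len(names))
        count_ss = np.zeros(len(names))
        remaining = Rn
        while remaining > 0:
            k = min(remaining, batch_size)
            perms = np.empty((k, n), dtype=np.intp)
            for r in range(k):
                p = rng.permutation(n)
                while np.array_equal(p, identity):
                    p = rng.permutation(n)
                if permute == "predictors":
                    p = np.argsort(p)  # inverse permutation (relabelling equivalence)
                perms[r] = p
            cb, cs = _count_exceedances(Ymat, perms, tril, Q, R, abs_beta_obs, ss_obs)
            count_beta += cb
            count_ss += cs
            remaining -= k
        p_beta = (count_beta + 1.0) / (Rn + 1.0)
        p_ss = (count_ss + 1.0) / (Rn + 1.0)
        randomizations = Rn

    return _result_from_fit(
        fit,
        names,
        n,
        len(y),
        p_beta=p_beta,
        p_ss=p_ss,
        randomizations=randomizations,
        seed=seed,
        permute=permute,
        exhaustive=exhaustive,
    )


def _count_exceedances(Ymat, perms, tril, Q, R, abs_beta_obs, ss_obs):
    Yp = _permuted_response_vectors(Ymat, perms, tril)  # (k, m)
    C = Q.T @ Yp.T  # (p+1, k)
    betas = np.linalg.solve(R, C)[1:, :]  # (p, k)
    seq_ss = C[1:, :] ** 2
    # tiny relative slack so exact ties (identity/automorphic permutations)
    # count as exceedances despite float-level differences between the
    # batched and the observed computation
    tol_b = 1e-9 * (1.0 + abs_beta_obs[:, None])
    tol_s = 1e-9 * (1.0 + ss_obs[:, None])
    cb = np.sum(np.abs(betas) >= abs_beta_obs[:, None] - tol_b, axis=1)
    cs = np.sum(seq_ss >= ss_obs[:, None] - tol_s, axis=1)
    return cb.astype(float), cs.astype(float)


def _chunks(iterable, size):
    it = iter(iterable)
    while True:
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield chunk


def variance_decomposition(sst: float, seq_ss: Sequence[float]) -> tuple[float, float]:
    """Error SS and percent variance explained from SST and sequential SS.

    SSE = SST - sum(SS_k); percent = 100 * (SST - SSE) / SST.  These are the
    additivity identities every fit satisfies; exposed so a printed
    decomposition can be completed/checked.
    """
    model_ss = float(np.sum(seq_ss))
    if sst <= 0:
        raise MRMError("SST must be positive")
    if model_ss > sst * (1 + 1e-12):
        raise MRMError("model SS exceeds SST")
    sse = sst - model_ss
    percent = 100.0 * model_ss / sst
    return sse, percent


def format_mrm_table(result: MRMResult) -> str:
    """Plain-text summary table (observed stats and permutation p-values)."""
    lines = [
        f"The total sum of squares for the response: {result.sst:.4f}",
        "Variable\tPartial Corr.\tBeta\tSS\tP(Beta)\tP(SS)",
    ]
    for p in result.predictors:
        pb = "-" if p.p_beta is None else f"{p.p_beta:.4f}"
        ps = "-" if p.p_ss is None else f"{p.p_ss:.4f}"
        lines.append(
            f"{p.name}\t{p.partial_correlation:.6f}\t{p.coefficient:.6f}"
            f"\t{p.seq_ss:.4f}\t{pb}\t{ps}"
        )
    lines.append(f"Error sum of squares: {result.sse:.4f}")
    lines.append(
        f"Percent of the variance explained by the model: {result.percent_variance:.2f}"
    )
    return "\n".join(lines)
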