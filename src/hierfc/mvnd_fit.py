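"""Matrix-variate normal fitting of a connectivity-network sequence.

Each windowed connectivity matrix W_k (N×N, symmetric) is modelled as a
draw from a matrix-variate normal with mean M and row/column covariance
both equal to one symmetric factor C, i.e. vec(W) ~ N(vec(M), C ⊗ C).
M is the low-order connectivity estimate (the elementwise mean of the
windows); C is the high-order estimate, a covariance *between whole
connectivity patterns* across windows.

The maximum-likelihood factor solves the fixed-point equation

    C = (1/(K·N)) Σ_k (W_k − M) C⁻¹ (W_k − M)ᵀ.

Iterating that equation literally is unstable: scaling C by a maps the
update to C/a, a period-2 oscillation that never settles.  ``fit_factor``
therefore runs the flip-flop algorithm — alternating exact conditional
maximization over the two Kronecker factors, each half-step provably
non-decreasing in likelihood — and collapses the (proportional) factors
into one symmetric C by scale balancing.  The balanced C satisfies the
fixed-point equation above at convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateCovarianceError, NumericalError, ValidationError

_COND_LIMIT = 1e12  # condition number beyond which the ridge kicks in


@dataclass
class FitConfig:
    """Convergence settings for the flip-flop iteration."""

    tol: float = 1e-6
    max_iter: int = 100
    ridge: float = 1e-6


@dataclass
class MvndFit:
    """Result of a matrix-variate normal fit.

    ``mean`` is the low-order estimate M̂, ``factor`` the high-order
    Kronecker factor Ĉ (symmetric, PSD, trace ≥ 0).  ``loglik_trace``
    records the model log-likelihood after every full flip-flop iterate
    and is non-decreasing.  ``ridge_used`` is the largest ridge actually
    added to stabilize an inversion (0 if none was needed).
    """

    mean: np.ndarray
    factor: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    ridge_used: float = 0.0


def _as_stack(seq) -> np.ndarray:
    """Accept an FcnSequence, a list of matrices, or a (K, n, n) array."""
    mats = getattr(seq, "matrices", seq)
    arr = np.asarray(mats, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValidationError(f"expected a (K, n, n) stack, got shape {arr.shape}")
    if arr.shape[0] < 1:
        raise ValidationError("empty matrix sequence")
    return arr


def fit_mean(seq) -> np.ndarray:
    """Maximum-likelihood mean: the elementwise average of the K matrices."""
    return _as_stack(seq).mean(axis=0)


def _stable_inv(c: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """Inverse of a symmetric PSD matrix, ridged only when ill-conditioned.

    Returns (inverse, ridge actually added).  The ridge scales with the
    mean eigenvalue (trace/N) so it is unit-free; for an exactly zero
    matrix it falls back to the absolute ridge value.
    """
    n = c.shape[0]
    eigvals = np.linalg.eigvalsh(c)
    lo, hi = eigvals[0], eigvals[-1]
    if hi <= 0:
        if ridge <= 0:
            raise DegenerateCovarianceError("singular factor and no ridge configured")
        eps = ridge
    elif lo <= hi / _COND_LIMIT:
        if ridge <= 0:
            raise DegenerateCovarianceError(
                f"factor condition number exceeds {_COND_LIMIT:g} and no ridge configured"
            )
        eps = ridge * np.trace(c) / n
    else:
        return np.linalg.inv(c), 0.0
    return np.linalg.inv(c + eps * np.eye(n)), eps


def matnorm_loglik(seq, m_hat: np.ndarray, c: np.ndarray, ridge: float = 0.0) -> float:
    """Log-likelihood of the sequence under mean M and symmetric factor C.

    Equals the multivariate-normal log-density of the vectorized matrices
    with covariance C ⊗ C, summed over the K samples.
    """
    stack = _as_stack(seq)
    n = stack.shape[1]
    ci, eps = _stable_inv(np.asarray(c, dtype=float), ridge)
    c_eff = np.asarray(c, dtype=float) + eps * np.eye(n)
    sign, logdet = np.linalg.slogdet(c_eff)
    if sign <= 0:
        raise NumericalError("factor has non-positive determinant")
    total = 0.0
    for w in stack:
        r = w - m_hat
        total += (
            -0.5 * n * n * np.log(2 * np.pi)
            - n * logdet
            - 0.5 * float(np.trace(ci @ r @ ci @ r.T))
        )
    if not np.isfinite(total):
        raise NumericalError("non-finite log-likelihood")
    return float(total)


def _loglik_two_factor(resids: np.ndarray, u: np.ndarray, v: np.ndarray,
                       ui: np.ndarray, vi: np.ndarray) -> float:
    n = u.shape[0]
    k = resids.shape[0]
    _, ldu = np.linalg.slogdet(u)
    _, ldv = np.linalg.slogdet(v)
    quad = float(np.einsum("ij,kjl,lm,kim->", ui, resids, vi, resids))
    return -0.5 * k * n * n * np.log(2 * np.pi) - 0.5 * k * n * (ldu + ldv) - 0.5 * quad


def _balance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Collapse proportional factors U ∝ V into one C with C ⊗ C = U ⊗ V."""
    tu, tv = np.trace(u), np.trace(v)
    if tu <= 0 or tv <= 0:
        return 0.5 * (u + v)
    return u * np.sqrt(tv / tu)


def fit_factor(
    seq,
    m_hat: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    ridge: float = 1e-6,
) -> MvndFit:
    """Flip-flop MLE of the symmetric Kronecker factor C.

    Starts both factors at the identity; each full iterate updates the row
    factor given the column factor and vice versa (both exact conditional
    maximizations), symmetrizes to suppress floating-point drift, and
    records the log-likelihood.  Stops when the relative Frobenius change
    of the balanced factor drops below ``tol``.

    With K = 1 (or any all-zero residuals) the MLE degenerates to C = 0;
    this is returned as an exact zero factor when a ridge is configured
    and raised as :class:`DegenerateCovarianceError` otherwise.
    """
    stack = _as_stack(seq)
    k, n, _ = stack.shape
    m = fit_mean(stack) if m_hat is None else np.asarray(m_hat, dtype=float)
    if m.shape != (n, n):
        raise ValidationError(f"mean shape {m.shape} incompatible with samples {n}×{n}")
    resids = stack - m[None, :, :]

    if np.max(np.abs(resids)) == 0.0:
        if ridge <= 0:
            raise DegenerateCovarianceError(
                f"all {k} residual matrices are zero (K={k}); the covariance MLE "
                "is degenerate — supply more windows or a positive ridge"
            )
        return MvndFit(
            mean=m, factor=np.zeros((n, n)), loglik_trace=[], n_iter=0,
            converged=True, ridge_used=ridge,
        )

    u = np.eye(n)
    v = np.eye(n)
    c_prev = np.eye(n)
    trace: list[float] = []
    ridge_used = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vi, eps_v = _stable_inv(v, ridge)
        u = np.einsum("kij,jl,kml->im", resids, vi, resids) / (k * n)
        u = (u + u.T) / 2.0
        ui, eps_u = _stable_inv(u, ridge)
        v = np.einsum("kji,jl,klm->im", resids, ui, resids) / (k * n)
        v = (v + v.T) / 2.0
        ridge_used = max(ridge_used, eps_u, eps_v)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise NumericalError(f"non-finite factor iterate at iteration {it}")
        ui2, _ = _stable_inv(u, ridge)
        vi2, _ = _stable_inv(v, ridge)
        trace.append(_loglik_two_factor(resids, u, v, ui2, vi2))
        c = _balance(u, v)
        rel = np.linalg.norm(c - c_prev) / max(np.linalg.norm(c_prev), 1e-300)
        c_prev = c
        if rel < tol:
            converged = True
            break

    c = _balance(u, v)
    c = (c + c.T) / 2.0
    if np.trace(c) < 0:  # sign convention; PSD by construction, defensive only
        c = -c
    return MvndFit(
        mean=m, factor=c, loglik_trace=trace, n_iter=it,
        converged=converged, ridge_used=ridge_used,
    )


# ---------------------------------------------------------------------------
# serialization: JSON header + TSV matrices


def save_fit(fit: MvndFit, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "ridge_used": fit.ridge_used,
        "loglik_trace": list(map(float, fit.loglik_trace)),
    }
    (out / "fit.json").write_text(json.dumps(header, indent=1))
    np.savetxt(out / "mean.tsv", fit.mean, delimiter="\t", fmt="%.17g")
    np.savetxt(out / "factor.tsv", fit.factor, delimiter="\t", fmt="%.17g")


def load_fit(in_dir: str | Path) -> MvndFit:
    src = Path(in_dir)
    header = json.loads((src / "fit.json").read_text())
    return MvndFit(
        mean=np.atleast_2d(np.loadtxt(src / "mean.tsv", delimiter="\t")),
        factor=np.atleast_2d(np.loadtxt(src / "factor.tsv", delimiter="\t")),
        loglik_trace=header["loglik_trace"],
        n_iter=header["n_iter"],
        converged=header["converged"],
        ridge_used=header["ridge_used"],
    )
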