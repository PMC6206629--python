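"""Finite mixture model over candidate genomes, EM fit, posterior assignment.

A read with length ``L_j`` and matched length ``M_ji`` against genome ``i``
contributes the component probability

    R_i * p_i**(L_j - M_ji) * (1 - p_i)**M_ji

where ``R_i`` is the genome's mixture proportion and ``p_i`` its per-base
mismatch probability.  The marginal probability of a read is the sum of this
term over the read's candidate genomes (the genomes BLAST reported for it);
genomes without a reported hit contribute zero.  Two fitting modes exist:

* ``"common_p"`` — one shared mismatch probability for every genome (the
  TAMER model);
* ``"per_genome_p"`` — a separate mismatch probability per genome (the
  TADIP extension).

All likelihood arithmetic is carried out in log space with a per-read
log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .alignment_io import AlignmentTable

__all__ = [
    "ModelParams",
    "FitResult",
    "log_likelihood",
    "e_step",
    "m_step",
    "expected_complete_loglik",
    "fit_em",
    "posterior_assignment",
    "assign_reads",
    "default_init",
]

Mode = Literal["common_p", "per_genome_p"]

#: Mismatch probabilities are clipped into [EPS_P, 1 - EPS_P]; a genome with
#: only perfect matches would otherwise hit p = 0 and an infinite log term.
EPS_P = 1e-6

#: Posterior mass below which a genome is treated as empty in the M-step.
EMPTY_MASS = 1e-12


@dataclass
class ModelParams:
    """Mixture parameters: proportions ``R`` and mismatch probabilities ``p``."""

    R: np.ndarray
    p: np.ndarray
    mode: Mode = "per_genome_p"

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.R.ndim != 1 or self.p.shape != self.R.shape:
            raise ValueError("R and p must be 1-D arrays of equal length")
        if (self.R < 0).any() or abs(self.R.sum() - 1.0) > 1e-12:
            raise ValueError("R must be non-negative and sum to 1")
        if (self.p <= 0).any() or (self.p >= 1).any():
            raise ValueError("p must lie strictly inside (0, 1)")
        if self.mode == "common_p" and not np.allclose(self.p, self.p[0]):
            raise ValueError("common_p mode requires a constant p vector")

    @property
    def n_genomes(self) -> int:
        return len(self.R)


@dataclass
class FitResult:
    """EM fit outcome: parameters, log-likelihood trace, convergence flag."""

    params: ModelParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    posterior: np.ndarray = field(repr=False, default=None)  # per-hit T_ji

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _check_dims(params: ModelParams, data: AlignmentTable) -> None:
    if params.n_genomes != data.n_genomes:
        raise ValueError(
            f"params have {params.n_genomes} genomes, data has {data.n_genomes}"
        )


def _hit_log_terms(params: ModelParams, data: AlignmentTable) -> np.ndarray:
    """Per-hit log of R_i p_i^(L_j-M_ji) (1-p_i)^M_ji."""
    g = data.hit_genome
    M = data.hit_matched
    L = data.read_length[data.hit_read]
    with np.errstate(divide="ignore"):  # R_i = 0 -> -inf is meaningful
        logR = np.log(params.R)
    return logR[g] + (L - M) * np.log(params.p[g]) + M * np.log1p(-params.p[g])


def _segment_logsumexp(
    values: np.ndarray, indptr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-sum-exp over CSR segments; returns (lse, values - lse[segment])."""
    starts = indptr[:-1]
    seg_max = np.maximum.reduceat(values, starts)
    # empty segments cannot occur (every read has >= 1 hit)
    counts = np.diff(indptr)
    with np.errstate(invalid="ignore"):  # -inf - -inf when a read underflows
        centered = values - np.repeat(seg_max, counts)
        sums = np.add.reduceat(np.exp(centered), starts)
    lse = seg_max + np.log(sums)
    return lse, centered


def log_likelihood(params: ModelParams, data: AlignmentTable) -> float:
    """Observed-data log-likelihood, summed over reads in log space."""
    _check_dims(params, data)
    lse, _ = _segment_logsumexp(_hit_log_terms(params, data), data.indptr)
    if not np.all(np.isfinite(lse)):
        j = int(np.argmax(~np.isfinite(lse)))
        raise FloatingPointError(
            f"read {data.read_ids[j]!r}: every candidate term underflows "
            "to zero likelihood"
        )
    return float(lse.sum())


def e_step(params: ModelParams, data: AlignmentTable) -> np.ndarray:
    """Posterior responsibilities ``T_ji``, one value per stored hit.

    Returned in the table's CSR hit order; each read's responsibilities
    sum to 1 over its candidate genomes.
    """
    _check_dims(params, data)
    lse, centered = _segment_logsumexp(_hit_log_terms(params, data), data.indptr)
    if not np.all(np.isfinite(lse)):
        j = int(np.argmax(~np.isfinite(lse)))
        raise FloatingPointError(
            f"read {data.read_ids[j]!r}: posterior undefined (all candidate "
            "terms underflow)"
        )
    T = np.exp(centered)
    # normalize: centered is relative to the segment max, not the lse
    norm = np.add.reduceat(T, data.indptr[:-1])
    return T / np.repeat(norm, np.diff(data.indptr))


def m_step(
    T: np.ndarray,
    data: AlignmentTable,
    mode: Mode = "per_genome_p",
    p_fallback: np.ndarray | None = None,
) -> ModelParams:
    """Closed-form maximizers of the expected complete-data log-likelihood.

    ``R_i`` is the mean responsibility; ``p_i`` is one minus the
    responsibility-weighted match rate.  In ``common_p`` mode the match
    rate is pooled over all genomes.  A genome with (numerically) zero
    posterior mass keeps ``p_fallback`` (its rate is 0/0 there).
    """
    k = data.n_genomes
    g = data.hit_genome
    L = data.read_length[data.hit_read]
    mass = np.bincount(g, weights=T, minlength=k)
    R = mass / data.n_reads
    R = R / R.sum()
    wM = np.bincount(g, weights=T * data.hit_matched, minlength=k)
    wL = np.bincount(g, weights=T * L, minlength=k)
    if mode == "common_p":
        p = np.full(k, 1.0 - wM.sum() / wL.sum())
    else:
        empty = mass < EMPTY_MASS
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 1.0 - wM / wL
        if empty.any():
            if p_fallback is None:
                raise ValueError(
                    "genome(s) with zero posterior mass and no fallback p: "
                    f"{list(np.asarray(data.genome_ids)[empty])}"
                )
            p[empty] = p_fallback[empty]
    p = np.clip(p, EPS_P, 1.0 - EPS_P)
    return ModelParams(R=R, p=p, mode=mode)


def expected_complete_loglik(
    params: ModelParams, T: np.ndarray, data: AlignmentTable
) -> float:
    """The EM surrogate objective Q(params | T): expectation of the
    complete-data log-likelihood under responsibilities ``T``."""
    terms = _hit_log_terms(params, data)
    finite = T > 0  # 0 * log 0 = 0 convention
    return float(np.sum(T[finite] * terms[finite]))


def default_init(data: AlignmentTable, mode: Mode = "per_genome_p") -> ModelParams:
    """Deterministic data-driven start: uniform ``R``; naive per-genome
    mismatch rates over reported hits (pooled in ``common_p`` mode)."""
    k = data.n_genomes
    g = data.hit_genome
    L = data.read_length[data.hit_read]
    sumM = np.bincount(g, weights=data.hit_matched.astype(float), minlength=k)
    sumL = np.bincount(g, weights=L.astype(float), minlength=k)
    if mode == "common_p":
        p = np.full(k, 1.0 - sumM.sum() / sumL.sum())
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sumL > 0, 1.0 - sumM / sumL, 0.5)
    p = np.clip(p, EPS_P, 1.0 - EPS_P)
    return ModelParams(R=np.full(k, 1.0 / k), p=p, mode=mode)


def fit_em(
    data: AlignmentTable,
    mode: Mode = "per_genome_p",
    init: ModelParams | Literal["default"] = "default",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit the mixture by EM.

    Alternates the posterior (E) and closed-form maximization (M) steps
    until the relative log-likelihood change ``|Δl| / (|l| + 1)`` drops
    below ``tol`` or ``max_iter`` is reached.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    params = default_init(data, mode) if init == "default" else init
    if params.mode != mode:
        raise ValueError(f"init mode {params.mode!r} != requested mode {mode!r}")
    trace = [log_likelihood(params, data)]
    converged = False
    T = None
    for it in range(1, max_iter + 1):
        T = e_step(params, data)
        params = m_step(T, data, mode=mode, p_fallback=params.p)
        ll = log_likelihood(params, data)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        trace.append(ll)
        if abs(ll - trace[-2]) / (abs(ll) + 1.0) < tol:
            converged = True
            break
    T = e_step(params, data)
    return FitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=len(trace) - 1,
        converged=converged,
        posterior=T,
    )


def posterior_assignment(params: ModelParams, data: AlignmentTable) -> np.ndarray:
    """Per-read origin probabilities ``P_ji`` at the given (fitted) parameters.

    Structurally identical to the E-step posterior; returned per hit in
    CSR order, rows summing to 1.
    """
    return e_step(params, data)


def assign_reads(
    P: np.ndarray,
    data: AlignmentTable,
    tie_tol: float = 1e-9,
) -> dict[str, dict[str, float]]:
    """Assign each read to its maximum-posterior genome.

    Every candidate whose posterior is within ``tie_tol`` of the read's
    maximum is included, so near-exact ties yield multiple assignment.
    Returns ``{read_id: {genome_id: posterior}}``.
    """
    if len(P) != data.n_hits:
        raise ValueError("P must have one entry per stored hit")
    out: dict[str, dict[str, float]] = {}
    starts = data.indptr[:-1]
    seg_max = np.maximum.reduceat(P, starts)
    counts = np.diff(data.indptr)
    keep = P >= np.repeat(seg_max, counts) - tie_tol
    jj = data.hit_read
    for idx in np.flatnonzero(keep):
        read = data.read_ids[jj[idx]]
        out.setdefault(read, {})[data.genome_ids[data.hit_genome[idx]]] = float(
            P[idx]
        )
    # preserve read order, include every read
    return {r: out[r] for r in data.read_ids}
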