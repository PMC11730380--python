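"""Self-representation of the known DDI network (drug relation regularization).

Every row of the interaction matrix J is a vector describing one drug in the
interaction space. The relation structure M reconstructs each such row as a
non-negative combination of the *other* rows:

    minimize_{M >= 0}  1/2 ||(N o M) J - J||_F^2
                       + 1/2 ||N J - J||^2
                       + theta_drr/2 ||(N o M) e||_2^2
    subject to         (N o M) e = e

where N is the off-diagonal mask (N_ij = 0 iff i = j), ``o`` the Hadamard
product and e the all-ones vector, so (N o M) e is the vector of row sums.
The middle term is constant in M and kept only for reporting. The learned M
then regularizes predicted scores through the self-representation residual
penalty ||(I - M) S||_F^2: score rows that M can rebuild from their known
neighbours' rows are preferred, which propagates interaction evidence along
the learned structure.

Optimization uses a constrained multiplicative update (non-negativity
preserved by construction) followed by row rescaling that enforces the
row-sum constraint exactly, with a damping safeguard that guarantees a
non-increasing objective history. Drugs with no known interactions have no
neighbourhood to reconstruct from; their rows are frozen at zero and
excluded from the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import InteractionMatrix

__all__ = [
    "RelationStructure",
    "drr_objective",
    "update_M",
    "learn_relation_structure",
    "drr_penalty",
]


@dataclass
class RelationStructure:
    """Fitted self-representation of a DDI network."""

    M: np.ndarray
    theta_drr: float
    multiplier: float
    iterations_run: int = 0
    residual_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if (M < 0).any():
            raise ValueError("M must be non-negative")
        np.fill_diagonal(M, 0.0)
        self.M = M

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def mask(self) -> np.ndarray:
        """The boolean off-diagonal mask N (0 on the diagonal, 1 elsewhere)."""
        N = np.ones_like(self.M)
        np.fill_diagonal(N, 0.0)
        return N


def _masked(struct: RelationStructure) -> np.ndarray:
    # N o M; M keeps a zero diagonal so this is M itself, but go through the
    # mask so the algebra reads like the model.
    return struct.mask() * struct.M


def drr_objective(struct: RelationStructure, J: InteractionMatrix | np.ndarray) -> float:
    """Objective of the self-representation fit (includes its constant term)."""
    Jv = J.values if isinstance(J, InteractionMatrix) else np.asarray(J, dtype=float)
    if Jv.shape != struct.M.shape:
        raise ValueError("shape mismatch between M and J")
    NM = _masked(struct)
    N = struct.mask()
    recon = 0.5 * np.linalg.norm(NM @ Jv - Jv, "fro") ** 2
    const = 0.5 * np.linalg.norm(N @ Jv - Jv, "fro") ** 2
    rowsum = 0.5 * struct.theta_drr * float(np.sum(NM.sum(axis=1) ** 2))
    return float(recon + const + rowsum)


def update_M(struct: RelationStructure, J: InteractionMatrix | np.ndarray) -> RelationStructure:
    """One constrained multiplicative step on M.

    M_ij <- M_ij * (mult*ee^T(I + JJ^T) + JJ^T)_ij
                 / ((N o M)(theta*ee^T + theta*ee^T JJ^T + JJ^T))_ij

    for i != j, with the diagonal pinned at zero. Entries whose denominator
    vanishes (isolated drugs) are left unchanged, so non-negativity is
    preserved by construction.
    """
    Jv = J.values if isinstance(J, InteractionMatrix) else np.asarray(J, dtype=float)
    n = struct.n
    if Jv.shape != (n, n):
        raise ValueError("shape mismatch between M and J")
    JJt = Jv @ Jv.T
    ones = np.ones((n, n))
    theta = struct.theta_drr
    mult = struct.multiplier
    numer = mult * ones @ (np.eye(n) + JJt) + JJt
    denom = _masked(struct) @ (theta * ones + theta * ones @ JJt + JJt)
    ratio = np.ones_like(numer)
    ok = denom > 0
    ratio[ok] = numer[ok] / denom[ok]
    M_new = struct.M * ratio
    np.fill_diagonal(M_new, 0.0)
    return RelationStructure(
        M_new, theta, mult, struct.iterations_run, list(struct.residual_history)
    )


def _rescale_rows(M: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Rescale the active rows of M to unit sum; zero-sum rows untouched."""
    out = M.copy()
    sums = out.sum(axis=1)
    scale = np.where((sums > 0) & active, sums, 1.0)
    out /= scale[:, None]
    return out


def learn_relation_structure(
    J: InteractionMatrix | np.ndarray,
    theta_drr: float = 1e-2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> RelationStructure:
    """Fit the relation structure M to a known-DDI network.

    Starts from a strictly positive random off-diagonal matrix (multiplicative
    updates cannot escape exact zeros), alternates the multiplicative step
    with exact row rescaling, and stops when the relative objective change
    drops below ``tol`` or after ``max_iter`` sweeps. A candidate sweep that
    would increase the objective is damped toward the previous iterate
    (halving) so the recorded history is non-increasing.
    """
    Jv = J.values if isinstance(J, InteractionMatrix) else np.asarray(J, dtype=float)
    n = Jv.shape[0]
    if Jv.sum() == 0:
        raise ValueError("cannot learn a relation structure from an edgeless network")
    active = Jv.sum(axis=1) > 0  # drugs with >= 1 known interaction

    rng = np.random.default_rng(seed)
    M0 = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(M0, 0.0)
    M0[~active] = 0.0
    M0 = _rescale_rows(M0, active)

    struct = RelationStructure(M0, theta_drr, multiplier=theta_drr)
    history = [drr_objective(struct, Jv)]
    # The ||NJ - J||^2 term is constant in M: keep it in the reported
    # objective but leave it out of the convergence ratio.
    N = struct.mask()
    const = 0.5 * np.linalg.norm(N @ Jv - Jv, "fro") ** 2

    for it in range(1, max_iter + 1):
        stepped = update_M(struct, Jv)
        M_cand = _rescale_rows(stepped.M, active)
        M_cand[~active] = 0.0
        target = M_cand
        new_obj = drr_objective(
            RelationStructure(M_cand, theta_drr, theta_drr), Jv
        )
        # Damping safeguard: the rescale step has no monotonicity guarantee,
        # so back off toward the previous iterate until the objective does
        # not increase (rows of both endpoints sum to one, so the convex
        # combination stays feasible).
        eta = 1.0
        while new_obj > history[-1] and eta > 1e-9:
            eta /= 2.0
            M_cand = (1 - eta) * struct.M + eta * target
            new_obj = drr_objective(
                RelationStructure(M_cand, theta_drr, theta_drr), Jv
            )
        if new_obj > history[-1]:
            break  # no descent available; stop at the previous iterate
        prev = history[-1]
        struct = RelationStructure(M_cand, theta_drr, theta_drr, it, history)
        history.append(new_obj)
        prev_var, new_var = prev - const, new_obj - const
        if prev_var <= 0.0 or abs(prev_var - new_var) / max(abs(prev_var), 1e-30) < tol:
            break

    struct.residual_history = history
    return struct


def drr_penalty(struct: RelationStructure | np.ndarray, S: np.ndarray) -> float:
    """The drug-relation regularization penalty ||(I - M) S||_F^2.

    The relation structure demands that each drug's score row be
    reconstructible from the other rows, S_i. ~ sum_l M_il S_l., so the
    penalty is the squared Frobenius norm of the self-representation
    residual (I - M) S. It is zero exactly when S obeys the learned
    structure, and its minimization pulls each score row toward the
    M-weighted combination of its known neighbours' rows.
    """
    M = struct.M if isinstance(struct, RelationStructure) else np.asarray(struct, dtype=float)
    S = np.asarray(S, dtype=float)
    if M.shape != S.shape:
        raise ValueError("shape mismatch between M and S")
    n = M.shape[0]
    return float(np.linalg.norm((np.eye(n) - M) @ S, "fro") ** 2)
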