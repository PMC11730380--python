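"""Multi-view feature projection into the interaction space (the model core).

Each of the m binary feature matrices H^i (drugs x descriptors) is mapped
into the interaction space by a non-negative projection Z^i (descriptors x
drugs), so that H^i Z^i approximates both the score matrix S and the known
network J. The joint objective couples all views:

    f(Z, S) = theta * sum_i (||S - H^i Z^i||_F^2 + ||J - H^i Z^i||_F^2)
            + lambda * sum_i (tr(Z^i^T O Z^i) + tr(H^i^T O H^i))
            + ||S - J||_F^2
            + sigma * ||(I - M) S||_F^2

with Z^i >= 0, O the all-ones matrix (so tr(Z^T O Z) is the sum of squared
column sums — a group-sparsity pressure on the projections), and M the
relation structure learned from J. The H terms are data constants kept for
reporting only.

Optimization alternates an exact linear solve for S (the stationarity
condition of f in S) with one multiplicative sweep over the Z^i, whose
coefficient matrices are derived from the gradient of the substituted
objective g(Z) = f(Z, S*(Z)); because S*(Z) is a stationary point of f in S,
that gradient is simply the partial gradient of f evaluated at S*(Z).

Prediction modes: scores for pairs of networked drugs are read off S
(symmetrized), and a cold-start drug with feature vectors {h^i} is scored
against the catalog by (sum_i h^i Z^i) / (m + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .datamodel import DrugCatalog, FeatureMatrix, InteractionMatrix, check_aligned
from .relation import RelationStructure, drr_penalty, learn_relation_structure

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "ProjectionModel",
    "full_objective",
    "solve_S",
    "reduced_objective",
    "update_Z",
    "fit",
    "predict_within",
    "predict_new_drug",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Tunable weights and solver settings.

    lambda_sparsity controls the sparsity pressure on the projections,
    theta the weight of the projection-error terms, and sigma the weight of
    the drug-relation regularization. ``goal2_denominator`` selects the
    normalization of the cold-start score (``"m+1"`` as printed, or ``"m"``).
    """

    lambda_sparsity: float = 1e-1
    theta: float = 1e-5
    sigma: float = 1e-3
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0
    goal2_denominator: str = "m+1"

    def __post_init__(self) -> None:
        for name in ("lambda_sparsity", "theta", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.goal2_denominator not in ("m", "m+1"):
            raise ValueError("goal2_denominator must be 'm' or 'm+1'")

    @classmethod
    def goal1(cls, **overrides) -> "Hyperparameters":
        """Best within-network grid point: (lambda, theta, sigma) = (1e-1, 1e-5, 1e-3)."""
        base = dict(lambda_sparsity=1e-1, theta=1e-5, sigma=1e-3)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def goal2(cls, **overrides) -> "Hyperparameters":
        """Best cold-start grid point: (lambda, theta, sigma) = (1e-3, 1e-2, 0).

        sigma is zero because a drug outside the network has no known
        interactions for the relation structure to reconstruct.
        """
        base = dict(lambda_sparsity=1e-3, theta=1e-2, sigma=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class ProjectionModel:
    """A fitted predictor: projections, scores, and everything to reuse them."""

    Zs: list[np.ndarray]
    S: np.ndarray
    Y: np.ndarray
    hp: Hyperparameters
    relation: RelationStructure
    catalog: DrugCatalog
    feature_names: list[str]
    descriptor_counts: list[int]
    J: np.ndarray
    objective_history: list = field(default_factory=list)
    converged_at: int = 0

    @property
    def m(self) -> int:
        return len(self.Zs)


def _as_arrays(
    Hs: Sequence[FeatureMatrix | np.ndarray],
) -> list[np.ndarray]:
    return [H.values if isinstance(H, FeatureMatrix) else np.asarray(H, float) for H in Hs]


def _as_J(J: InteractionMatrix | np.ndarray) -> np.ndarray:
    return J.values if isinstance(J, InteractionMatrix) else np.asarray(J, float)


def _as_M(M: RelationStructure | np.ndarray | None, n: int) -> np.ndarray:
    if M is None:
        return np.zeros((n, n))
    return M.M if isinstance(M, RelationStructure) else np.asarray(M, float)


def _ones_quad(X: np.ndarray) -> float:
    """tr(X^T O X) with O all-ones: the sum of squared column sums."""
    return float(np.sum(X.sum(axis=0) ** 2))


def full_objective(
    Hs: Sequence[FeatureMatrix | np.ndarray],
    Zs: Sequence[np.ndarray],
    S: np.ndarray,
    J: InteractionMatrix | np.ndarray,
    M: RelationStructure | np.ndarray | None,
    hp: Hyperparameters,
) -> float:
    """Evaluate the joint objective f(Z, S), constants included."""
    Hv, Jv = _as_arrays(Hs), _as_J(J)
    S = np.asarray(S, float)
    Mv = _as_M(M, Jv.shape[0])
    theta, lam, sigma = hp.theta, hp.lambda_sparsity, hp.sigma
    total = float(np.linalg.norm(S - Jv, "fro") ** 2)
    for H, Z in zip(Hv, Zs, strict=True):
        HZ = H @ Z
        total += theta * (
            np.linalg.norm(S - HZ, "fro") ** 2 + np.linalg.norm(Jv - HZ, "fro") ** 2
        )
        total += lam * (_ones_quad(np.asarray(Z, float)) + _ones_quad(H))
    if sigma != 0.0:
        total += sigma * drr_penalty(Mv, S)
    return float(total)


def _system_matrix(Mv: np.ndarray, m: int, hp: Hyperparameters) -> np.ndarray:
    """(1 + m*theta) I + sigma (I - M)^T (I - M): the S-stationarity system.

    The relation term contributes the PSD Gram matrix of the residual
    operator, so the system is always symmetric positive definite and its
    solution is the unique minimizer of the objective in S.
    """
    n = Mv.shape[0]
    A = (1.0 + m * hp.theta) * np.eye(n)
    if hp.sigma != 0.0:
        ImM = np.eye(n) - Mv
        A += hp.sigma * (ImM.T @ ImM)
    return A


def solve_S(
    Hs: Sequence[FeatureMatrix | np.ndarray],
    Zs: Sequence[np.ndarray],
    J: InteractionMatrix | np.ndarray,
    M: RelationStructure | np.ndarray | None,
    hp: Hyperparameters,
) -> np.ndarray:
    """Closed-form score matrix: the stationary point of f in S.

    Solves ((1 + m*theta) I + sigma (I-M)^T (I-M)) S = theta*sum_i H^i Z^i + J
    as a linear system (never an explicit inverse).
    """
    Hv, Jv = _as_arrays(Hs), _as_J(J)
    Mv = _as_M(M, Jv.shape[0])
    m = len(Hv)
    rhs = Jv + hp.theta * sum(H @ Z for H, Z in zip(Hv, Zs, strict=True))
    A = _system_matrix(Mv, m, hp)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"score system is singular or near-singular (cond ~ {cond:.3e}); "
            "reduce sigma or refit the relation structure"
        )
    S = scipy.linalg.solve(A, rhs, assume_a="sym")
    return S


def reduced_objective(
    Hs: Sequence[FeatureMatrix | np.ndarray],
    Zs: Sequence[np.ndarray],
    J: InteractionMatrix | np.ndarray,
    M: RelationStructure | np.ndarray | None,
    hp: Hyperparameters,
) -> float:
    """The objective as a function of the projections only.

    Obtained by substituting the closed-form S into the joint objective and
    dropping the Z-independent feature-norm constant, so differences of this
    quantity equal differences of the full objective at the corresponding
    closed-form scores.
    """
    Hv = _as_arrays(Hs)
    S = solve_S(Hv, Zs, J, M, hp)
    const = hp.lambda_sparsity * sum(_ones_quad(H) for H in Hv)
    return full_objective(Hv, Zs, S, J, M, hp) - const


def _sign_split(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(|X| + X)/2 and (|X| - X)/2."""
    ax = np.abs(X)
    return (ax + X) / 2.0, (ax - X) / 2.0


def update_Z(
    Hs: Sequence[FeatureMatrix | np.ndarray],
    Zs: Sequence[np.ndarray],
    J: InteractionMatrix | np.ndarray,
    M: RelationStructure | np.ndarray | None,
    hp: Hyperparameters,
) -> list[np.ndarray]:
    """One multiplicative sweep over the projections, Z^i for i = 1..m.

    For each view the gradient of the substituted objective is the linear
    form C Z^i - B with

        C = 4 theta H^T H + 2 lambda O - 2 theta^2 H^T Y H
        B = 2 theta H^T ((I + Y) J + theta Y sum_{j != i} H^j Z^j)

    (Y is the resolvent of the S system; the last C term is Z^i's own
    contribution to S*). The update multiplies elementwise by
    (C^- Z + B^+) / (C^+ Z + B^-); entries with a vanishing denominator are
    left unchanged, so non-negativity is closed under the sweep.
    """
    Hv, Jv = _as_arrays(Hs), _as_J(J)
    Mv = _as_M(M, Jv.shape[0])
    m = len(Hv)
    theta, lam = hp.theta, hp.lambda_sparsity
    A = _system_matrix(Mv, m, hp)
    lu = scipy.linalg.lu_factor(A)
    YJ = scipy.linalg.lu_solve(lu, Jv)

    Zs_new = [np.asarray(Z, float).copy() for Z in Zs]
    for i, H in enumerate(Hv):
        YH = scipy.linalg.lu_solve(lu, H)  # Y H^i
        HtH = H.T @ H
        ni = H.shape[1]
        C = 4.0 * theta * HtH + 2.0 * lam * np.ones((ni, ni)) - 2.0 * theta**2 * (H.T @ YH)
        cross = sum(Hv[j] @ Zs_new[j] for j in range(m) if j != i)
        if isinstance(cross, int):  # m == 1: empty sum
            cross = np.zeros_like(Jv)
        B = 2.0 * theta * H.T @ (Jv + YJ + theta * scipy.linalg.lu_solve(lu, cross))
        Cp, Cm = _sign_split(C)
        Bp, Bm = _sign_split(B)
        Z = Zs_new[i]
        numer = Cm @ Z + Bp
        denom = Cp @ Z + Bm
        ratio = np.ones_like(Z)
        ok = denom > 0
        ratio[ok] = numer[ok] / denom[ok]
        Zs_new[i] = Z * ratio
    return Zs_new


def fit(
    Hs: Sequence[FeatureMatrix],
    J: InteractionMatrix,
    hp: Hyperparameters | None = None,
    theta_drr: float = 1e-2,
) -> ProjectionModel:
    """Fit the full predictor on catalog-aligned inputs.

    When sigma > 0 the relation structure M is first learned from J;
    otherwise M is the zero matrix and the relation penalty is inactive.
    The projections start from seeded uniform noise scaled by 1/sqrt(n_i)
    and the solver alternates Z sweeps with exact S solves until the
    relative change of the (constant-free) objective drops below ``tol``.
    """
    hp = hp or Hyperparameters.goal1()
    if not Hs:
        raise ValueError("at least one feature matrix is required")
    check_aligned(J, Hs)
    Hv, Jv = _as_arrays(Hs), _as_J(J)
    n, m = Jv.shape[0], len(Hv)

    if hp.sigma > 0:
        relation = learn_relation_structure(J, theta_drr=theta_drr, seed=hp.seed)
    else:
        relation = RelationStructure(np.zeros((n, n)), theta_drr, theta_drr)

    rng = np.random.default_rng(hp.seed)
    Zs = [rng.uniform(0.0, 1.0, size=(H.shape[1], n)) / np.sqrt(H.shape[1]) for H in Hv]

    const = hp.lambda_sparsity * sum(_ones_quad(H) for H in Hv)
    S = solve_S(Hv, Zs, Jv, relation, hp)
    history = [full_objective(Hv, Zs, S, Jv, relation, hp) - const]
    converged_at = hp.max_iter
    for it in range(1, hp.max_iter + 1):
        Zs = update_Z(Hv, Zs, Jv, relation, hp)
        S = solve_S(Hv, Zs, Jv, relation, hp)
        obj = full_objective(Hv, Zs, S, Jv, relation, hp) - const
        prev = history[-1]
        history.append(obj)
        if abs(prev - obj) / max(abs(prev), 1e-30) < hp.tol:
            converged_at = it
            break

    A = _system_matrix(relation.M, m, hp)
    Y = np.linalg.inv(A)  # small dense resolvent, kept for cold-start scoring
    return ProjectionModel(
        Zs=Zs,
        S=S,
        Y=Y,
        hp=hp,
        relation=relation,
        catalog=J.catalog,
        feature_names=[H.feature_name for H in Hs],
        descriptor_counts=[H.n_descriptors for H in Hs],
        J=Jv,
        objective_history=history,
        converged_at=converged_at,
    )


def predict_within(
    model: ProjectionModel, pairs: Sequence[tuple[str, str]]
) -> list[tuple[str, str, float, bool]]:
    """Score pairs of networked drugs.

    Returns (drug_a, drug_b, score, known) rows with score = (S_ij + S_ji)/2
    and ``known`` flagging pairs already in the training network. Self-pairs
    are rejected: self-interaction is undefined.
    """
    out = []
    S, Jv = model.S, model.J
    for a, b in pairs:
        i, j = model.catalog.position(a), model.catalog.position(b)
        if i == j:
            raise ValueError(f"self-interaction ({a}, {b}) is undefined")
        score = 0.5 * (S[i, j] + S[j, i])
        out.append((a, b, float(score), bool(Jv[i, j])))
    return out


def predict_new_drug(
    model: ProjectionModel,
    features: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Score a cold-start drug against every catalog drug.

    ``features`` maps feature-space name to the new drug's binary descriptor
    vector; a missing feature space contributes a zero vector (logged). The
    score vector is (sum_i h^i Z^i) / (m + 1), elementwise non-negative for
    binary inputs.
    """
    m = model.m
    n = len(model.catalog)
    acc = np.zeros(n)
    for name, Z, ni in zip(model.feature_names, model.Zs, model.descriptor_counts):
        if name not in features or features[name] is None:
            logger.warning("cold-start drug has no %r features; using zeros", name)
            continue
        h = np.asarray(features[name], float).ravel()
        if h.shape[0] != ni:
            raise ValueError(
                f"feature space {name!r}: vector length {h.shape[0]} != {ni} descriptors"
            )
        acc += h @ Z
    denom = m + 1 if model.hp.goal2_denominator == "m+1" else m
    return acc / denom
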