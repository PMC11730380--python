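"""Synthetic drug datasets with plantable shared structure.

Real inputs for this tool are DrugBank-style exports: a DDI edge list plus
one binary descriptor table per feature space. The generator emulates their
shapes at desk scale with a planted low-rank mechanism so that the network
is partially predictable from the features:

* each drug gets a sparse non-negative latent profile (a row of U, n x r);
* each feature space binarizes U W^i for a sparse non-negative mixing W^i,
  then flips bits at the requested noise rate;
* the interaction network takes the top-``density`` quantile of the drug-drug
  latent affinity U U^T (symmetric, zero diagonal).

Defaults are the packaged study conditions: n = 200 drugs, m = 4 feature
spaces (pathway / enzyme / target / chemical substructure) with descriptor
counts (120, 100, 150, 300) — the real datasets' magnitudes scaled down so a
fit takes seconds — rank 10, edge density 0.05 and a 5% feature noise rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DrugCatalog, FeatureMatrix, InteractionMatrix

__all__ = ["SyntheticDataset", "generate", "generate_holdout_drugs", "generate_toy_molecules"]

DEFAULT_FEATURE_NAMES = ("pathway", "enzyme", "target", "substructure")

#: Fraction of ones in each binary feature matrix before noise.
_FEATURE_DENSITY = 0.15


@dataclass
class SyntheticDataset:
    catalog: DrugCatalog
    Hs: list[FeatureMatrix]
    J: InteractionMatrix
    latent: np.ndarray
    params: dict

    @property
    def n(self) -> int:
        return len(self.catalog)

    @property
    def m(self) -> int:
        return len(self.Hs)


def _feature_names(m: int) -> list[str]:
    if m <= len(DEFAULT_FEATURE_NAMES):
        return list(DEFAULT_FEATURE_NAMES[:m])
    return list(DEFAULT_FEATURE_NAMES) + [
        f"feature_{i}" for i in range(len(DEFAULT_FEATURE_NAMES) + 1, m + 1)
    ]


def generate(
    n: int = 200,
    m: int = 4,
    dims: tuple[int, ...] = (120, 100, 150, 300),
    rank: int = 10,
    density: float = 0.05,
    noise: float = 0.05,
    seed: int = 42,
) -> SyntheticDataset:
    """Generate a catalog, m binary feature matrices and a DDI network."""
    if n < 10:
        raise ValueError("need n >= 10 drugs")
    if len(dims) != m:
        raise ValueError(f"need one descriptor count per feature space ({m}), got {len(dims)}")
    if rank >= min(dims):
        raise ValueError("rank must be smaller than every descriptor count")
    if not 0 < density < 0.5:
        raise ValueError("density must be in (0, 0.5)")
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    catalog = DrugCatalog(tuple(f"SYN{i:04d}" for i in range(n)))

    # Sparse non-negative latent profiles: each drug loads on few factors.
    U = rng.dirichlet(np.full(rank, 0.3), size=n)

    Hs = []
    for name, ni in zip(_feature_names(m), dims):
        W = rng.uniform(0.0, 1.0, size=(rank, ni))
        W *= rng.random(size=(rank, ni)) < 0.3  # each descriptor tied to few factors
        X = U @ W
        thresh = np.quantile(X, 1.0 - _FEATURE_DENSITY)
        H = (X > thresh).astype(float)
        if noise > 0:
            flips = rng.random(size=H.shape) < noise
            H = np.where(flips, 1.0 - H, H)
        Hs.append(FeatureMatrix(name, tuple(f"{name}_{d}" for d in range(ni)), H, catalog))

    # Network: top-density quantile of the latent affinity, symmetrized.
    A = U @ U.T
    iu, ju = np.triu_indices(n, k=1)
    n_edges = int(round(density * iu.size))
    order = np.argsort(A[iu, ju])[::-1][:n_edges]
    J = np.zeros((n, n))
    J[iu[order], ju[order]] = 1.0
    J += J.T
    Jm = InteractionMatrix(J, catalog)

    params = dict(n=n, m=m, dims=tuple(dims), rank=rank, density=density, noise=noise, seed=seed)
    return SyntheticDataset(catalog, Hs, Jm, U, params)


def generate_holdout_drugs(
    ds: SyntheticDataset, fraction: float = 0.2, seed: int | None = None
) -> tuple[SyntheticDataset, list[dict]]:
    """Split off a cold-start drug subset.

    Returns the induced training dataset and, per held-out drug, a record
    with its id, its feature vectors per feature space, and its true
    interaction labels against the training drugs (in training-catalog order).
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = ds.n
    n_hold = int(round(fraction * n))
    if n - n_hold < 10:
        raise ValueError("holdout would leave fewer than 10 training drugs")
    rng = np.random.default_rng(ds.params["seed"] + 1 if seed is None else seed)
    hold_idx = np.sort(rng.choice(n, size=n_hold, replace=False))
    keep = np.setdiff1d(np.arange(n), hold_idx)

    train_cat = DrugCatalog(tuple(np.asarray(ds.catalog.ids)[keep]))
    train_Hs = [
        FeatureMatrix(H.feature_name, H.descriptors, H.values[keep], train_cat)
        for H in ds.Hs
    ]
    train_J = InteractionMatrix(ds.J.values[np.ix_(keep, keep)], train_cat)
    train = SyntheticDataset(
        train_cat, train_Hs, train_J, ds.latent[keep],
        {**ds.params, "n": len(keep), "holdout_fraction": fraction},
    )

    holdouts = []
    for i in hold_idx:
        holdouts.append(
            {
                "drug": ds.catalog.ids[i],
                "features": {H.feature_name: H.values[i].copy() for H in ds.Hs},
                "labels": ds.J.values[i, keep].astype(int),
            }
        )
    return train, holdouts


# Small drug-like scaffolds; decorations are appended at a substitution point.
_SCAFFOLDS = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
    "C1CCCCC1",          # cyclohexane
    "C1CCNCC1",          # piperidine
    "C1CCOC1",           # tetrahydrofuran
    "c1cnc2[nH]ccc2c1",  # azaindole
    "c1ccc2[nH]ccc2c1",  # indole
)

_DECORATIONS = ("", "C", "CC", "CCO", "C(=O)O", "C(=O)N", "N", "O", "Cl", "F", "C(C)C", "OC")


def generate_toy_molecules(count: int, seed: int = 0) -> list[str]:
    """Deterministic list of parsable drug-like SMILES strings."""
    if count < 1:
        raise ValueError("count must be >= 1")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < count:
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        deco = _DECORATIONS[rng.integers(len(_DECORATIONS))]
        smiles = scaffold + deco if deco else scaffold
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - all combinations are valid
            continue
        out.append(Chem.MolToSmiles(mol))
    return out
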