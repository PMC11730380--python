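"""Core containers: drug catalog, interaction network, binary feature tables.

All matrices in the package are aligned against a :class:`DrugCatalog`, which
fixes a stable 0-based ordering of drug identifiers. Files always refer to
drugs by identifier, never by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DrugCatalog",
    "InteractionMatrix",
    "FeatureMatrix",
    "substructure_descriptor_labels",
    "N_SUBSTRUCTURE_DESCRIPTORS",
]

#: Dimensionality of the PubChem chemical-substructure descriptor set.
N_SUBSTRUCTURE_DESCRIPTORS = 881


def substructure_descriptor_labels() -> list[str]:
    """Return the packaged chemical-substructure descriptor label list.

    The labels are stable synthetic names (``PCFP_0001`` .. ``PCFP_0881``)
    standing in for the 881 PubChem substructure keys; the length of the
    list is what downstream feature tables are checked against.
    """
    return [f"PCFP_{i:04d}" for i in range(1, N_SUBSTRUCTURE_DESCRIPTORS + 1)]


@dataclass(frozen=True)
class DrugCatalog:
    """Ordered collection of unique drug identifiers."""

    ids: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("catalog must contain at least one drug")
        idx: dict[str, int] = {}
        for pos, drug in enumerate(self.ids):
            if not drug:
                raise ValueError("empty drug identifier")
            if drug in idx:
                raise ValueError(f"duplicate drug identifier: {drug!r}")
            idx[drug] = pos
        object.__setattr__(self, "index", idx)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "DrugCatalog":
        """Build a catalog keeping first-appearance order, dropping repeats."""
        seen: dict[str, None] = {}
        for d in ids:
            seen.setdefault(d, None)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, drug: str) -> bool:
        return drug in self.index

    def position(self, drug: str) -> int:
        try:
            return self.index[drug]
        except KeyError:
            raise KeyError(f"drug {drug!r} not in catalog") from None


@dataclass
class InteractionMatrix:
    """Symmetric binary known-DDI network J over a catalog.

    J[i, j] = 1 when drugs i and j are known to interact. The diagonal is
    zero: self-interaction is undefined.
    """

    values: np.ndarray
    catalog: DrugCatalog

    def __post_init__(self) -> None:
        J = np.asarray(self.values, dtype=float)
        n = len(self.catalog)
        if J.shape != (n, n):
            raise ValueError(f"interaction matrix shape {J.shape} != ({n}, {n})")
        if not np.isin(J, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0/1")
        if not np.array_equal(J, J.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.trace(J) != 0:
            raise ValueError("interaction matrix diagonal must be zero")
        self.values = J

    @property
    def n_drugs(self) -> int:
        return len(self.catalog)

    @property
    def n_interactions(self) -> int:
        """Number of unordered known interacting pairs."""
        return int(self.values.sum()) // 2

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered interacting pairs as (id_a, id_b), a before b in catalog order."""
        ii, jj = np.nonzero(np.triu(self.values, k=1))
        ids = self.catalog.ids
        return [(ids[i], ids[j]) for i, j in zip(ii, jj)]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], catalog: DrugCatalog
    ) -> "InteractionMatrix":
        """Build a symmetrized network from unordered id pairs (self-pairs ignored)."""
        n = len(catalog)
        J = np.zeros((n, n))
        for a, b in pairs:
            i, j = catalog.position(a), catalog.position(b)
            if i == j:
                continue
            J[i, j] = J[j, i] = 1.0
        return cls(J, catalog)


@dataclass
class FeatureMatrix:
    """Binary drug x descriptor incidence table for one feature space.

    Rows follow the catalog order; columns follow ``descriptors``. Entry
    (i, d) is 1 when descriptor d applies to drug i.
    """

    feature_name: str
    descriptors: tuple[str, ...]
    values: np.ndarray
    catalog: DrugCatalog

    def __post_init__(self) -> None:
        H = np.asarray(self.values, dtype=float)
        n = len(self.catalog)
        if H.shape != (n, len(self.descriptors)):
            raise ValueError(
                f"feature matrix {self.feature_name!r}: shape {H.shape} != "
                f"({n}, {len(self.descriptors)})"
            )
        if not np.isin(H, (0.0, 1.0)).all():
            raise ValueError(f"feature matrix {self.feature_name!r} entries must be 0/1")
        self.values = H

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptors)

    def row(self, drug: str) -> np.ndarray:
        return self.values[self.catalog.position(drug)]


def check_aligned(J: InteractionMatrix, Hs: Sequence[FeatureMatrix]) -> None:
    """Raise if the feature matrices are not built against J's catalog."""
    for H in Hs:
        if H.catalog is not J.catalog and H.catalog.ids != J.catalog.ids:
            raise ValueError(
                f"feature matrix {H.feature_name!r} is not aligned with the "
                "interaction matrix catalog"
            )
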