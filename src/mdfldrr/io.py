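"""Readers and writers for the plain-text file shapes the tool touches.

Supported formats:

* DDI edge list — TSV/CSV with >= 2 identifier columns per row, no header.
* Feature table — long form (``drug<TAB>descriptor`` incidence pairs) or wide
  form (header of descriptor labels, 0/1 cells); detected by sniffing.
* SMILES — standard SMI (``SMILES id`` per line) or a flagged two-column
  ``id,SMILES`` table.
* Predictions — CSV with header ``drug_a,drug_b,score[,severity_score,severity_level]``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .datamodel import DrugCatalog, FeatureMatrix, InteractionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_feature_table",
    "read_smiles",
    "write_predictions",
]


def _sniff_delimiter(line: str) -> str:
    """Tab wins over comma when both appear; defaults to comma."""
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace split


def _split(line: str, delim: str | None) -> list[str]:
    fields = line.split(delim) if delim else line.split()
    return [f.strip() for f in fields]


def read_interactions(
    path: str | Path, catalog: DrugCatalog | None = None
) -> InteractionMatrix:
    """Read a DDI edge list into a symmetric :class:`InteractionMatrix`.

    An edge listed in either direction sets both J[i, j] and J[j, i].
    Self-pairs are dropped with a warning. When no catalog is supplied one is
    built from the union of identifiers in first-appearance order.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty interaction file: {path}")
    delim = _sniff_delimiter(lines[0])

    pairs: list[tuple[str, str]] = []
    order: dict[str, None] = {}
    for lineno, line in enumerate(lines, 1):
        fields = _split(line, delim)
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        order.setdefault(a, None)
        order.setdefault(b, None)
        if a == b:
            logger.warning("%s:%d: self-pair (%s, %s) dropped", path, lineno, a, b)
            continue
        pairs.append((a, b))

    if catalog is None:
        catalog = DrugCatalog.from_ids(order)
    else:
        for drug in order:
            if drug not in catalog:
                raise KeyError(f"{path}: drug {drug!r} absent from supplied catalog")
    return InteractionMatrix.from_pairs(pairs, catalog)


def write_interactions(J: InteractionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write the unordered interacting pairs of J as an edge list."""
    with open(path, "w", newline="") as fh:
        for a, b in J.pairs():
            fh.write(f"{a}{delimiter}{b}\n")


def _looks_wide(lines: list[str], delim: str | None) -> bool:
    # Wide form: header row of descriptor labels, then one 0/1 cell per
    # descriptor. Long form always has exactly two label columns, so three
    # or more header fields means wide; with exactly two, a binary data
    # cell disambiguates.
    if len(_split(lines[0], delim)) >= 3:
        return True
    if len(lines) < 2:
        return False
    first_data = _split(lines[1], delim)
    if len(first_data) < 2:
        return False
    return all(cell in ("0", "1") for cell in first_data[1:])


def read_feature_table(
    path: str | Path,
    catalog: DrugCatalog,
    feature_name: str,
    strict: bool = False,
) -> FeatureMatrix:
    """Read a binary drug-descriptor incidence table.

    Long form lists ``drug, descriptor`` pairs (descriptor order = first
    appearance); wide form has a descriptor-label header and 0/1 cells
    (descriptor order = header order). Drugs in the catalog but absent from
    the file get all-zero rows. Unknown drug ids are skipped with a warning,
    or raise under ``strict``.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty feature file: {path}")
    delim = _sniff_delimiter(lines[0])
    n = len(catalog)

    if _looks_wide(lines, delim):
        descriptors = tuple(_split(lines[0], delim)[1:])
        H = np.zeros((n, len(descriptors)))
        seen: set[str] = set()
        for lineno, line in enumerate(lines[1:], 2):
            fields = _split(line, delim)
            drug, cells = fields[0], fields[1:]
            if len(cells) != len(descriptors):
                raise ValueError(
                    f"{path}:{lineno}: {len(cells)} cells for {len(descriptors)} descriptors"
                )
            if drug not in catalog:
                if strict:
                    raise KeyError(f"{path}:{lineno}: unknown drug {drug!r}")
                logger.warning("%s:%d: unknown drug %r skipped", path, lineno, drug)
                continue
            for cell in cells:
                if cell not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: non-binary cell {cell!r}")
            H[catalog.position(drug)] = [float(c) for c in cells]
            seen.add(drug)
    else:
        descriptors_order: dict[str, int] = {}
        incidences: list[tuple[str, str]] = []
        seen = set()
        for lineno, line in enumerate(lines, 1):
            fields = _split(line, delim)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected drug, descriptor pair")
            drug, desc = fields[0], fields[1]
            if drug not in catalog:
                if strict:
                    raise KeyError(f"{path}:{lineno}: unknown drug {drug!r}")
                logger.warning("%s:%d: unknown drug %r skipped", path, lineno, drug)
                continue
            descriptors_order.setdefault(desc, len(descriptors_order))
            incidences.append((drug, desc))
            seen.add(drug)
        descriptors = tuple(descriptors_order)
        H = np.zeros((n, len(descriptors)))
        for drug, desc in incidences:
            H[catalog.position(drug), descriptors_order[desc]] = 1.0

    missing = [d for d in catalog.ids if d not in seen]
    if missing:
        logger.warning(
            "%s: %d catalog drugs absent from feature file (all-zero rows): %s%s",
            path, len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
        )
    return FeatureMatrix(feature_name, descriptors, H, catalog)


def scan_feature_drugs(path: str | Path) -> list[str]:
    """Drug identifiers appearing in a feature table, in file order.

    Works for both long and wide layouts (for wide, the header row is
    skipped). Used to assemble a catalog covering drugs that have features
    but no known interactions.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return []
    delim = _sniff_delimiter(lines[0])
    start = 1 if _looks_wide(lines, delim) else 0
    seen: dict[str, None] = {}
    for line in lines[start:]:
        seen.setdefault(_split(line, delim)[0], None)
    return list(seen)


def read_smiles(path: str | Path, id_first: bool = False) -> dict[str, str]:
    """Read a SMI file into an id -> SMILES map.

    Standard SMI convention is ``SMILES<whitespace>identifier`` per line;
    ``id_first`` flags the two-column ``identifier<delimiter>SMILES`` layout.
    Later duplicates override earlier ones with a warning.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        delim = _sniff_delimiter(line) if id_first else None
        fields = _split(line, delim)
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected SMILES and identifier")
        if id_first:
            drug, smiles = fields[0], fields[1]
        else:
            smiles, drug = fields[0], fields[1]
        if not smiles:
            raise ValueError(f"{path}:{lineno}: empty SMILES field")
        if drug in out:
            logger.warning("%s:%d: duplicate id %r, last entry wins", path, lineno, drug)
        out[drug] = smiles
    return out


def write_predictions(
    rows: Iterable[Sequence],
    path: str | Path,
    severity: bool = False,
) -> None:
    """Write scored drug pairs as CSV, sorted by descending score.

    Each row is ``(drug_a, drug_b, score)`` or, with ``severity``,
    ``(drug_a, drug_b, score, severity_score, severity_level)``. Ties are
    broken by (drug_a, drug_b) lexicographic order. Scores are written with
    at least six significant digits.
    """
    rows = list(rows)
    for r in rows:
        if not np.isfinite(r[2]):
            raise ValueError(f"non-finite score for pair ({r[0]}, {r[1]})")
    rows.sort(key=lambda r: (-float(r[2]), r[0], r[1]))
    header = ["drug_a", "drug_b", "score"]
    if severity:
        header += ["severity_score", "severity_level"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in rows:
            out = [r[0], r[1], f"{float(r[2]):.6g}"]
            if severity:
                sev_score = r[3] if len(r) > 3 else ""
                sev_level = r[4] if len(r) > 4 else ""
                out += ["" if sev_score in ("", None) else f"{float(sev_score):g}",
                        "" if sev_level is None else str(sev_level)]
            writer.writerow(out)
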