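"""Mapping co-evolving residue pairs onto multi-chain structures.

Loads Cα-only models from PDB/mmCIF, measures minimal cross-chain Cα–Cα
distances over all chain-copy combinations (the relevant contact in a
symmetric oligomer), classifies scored pairs as intra-protein,
homo-oligomeric, or hetero-oligomeric, applies the paper-style selection
rules (70%-of-top threshold, top-N, minimum score), and reports the
fraction of selected pairs that fall within the interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import DataError, EmptyInputError, MappingError

logger = logging.getLogger(__name__)


@dataclass
class StructureModel:
    """Cα coordinates per chain, with a chain → protein-family mapping.

    ``chains`` maps chain id to ``(residue_numbers, coords)`` where
    ``coords`` is an (n, 3) array in Å.  ``offsets`` optionally maps a
    family id to the integer offset from 1-based profile column to author
    residue number (``residue_number = profile_column + offset``).
    """

    chains: dict[str, tuple[np.ndarray, np.ndarray]]
    chain_to_protein: dict[str, str]
    offsets: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for cid in self.chain_to_protein:
            if cid not in self.chains:
                raise MappingError(f"chain {cid!r} not present in structure")
        for cid, (resnum, xyz) in self.chains.items():
            if not np.all(np.isfinite(xyz)):
                raise DataError(f"chain {cid!r} has non-finite coordinates")

    def family_chains(self, family_id: str) -> list[str]:
        out = [
            c for c, fam in self.chain_to_protein.items() if fam == family_id
        ]
        if not out:
            raise MappingError(f"no chain mapped to family {family_id!r}")
        return out

    def residue_coord(self, chain_id: str, residue_number: int) -> np.ndarray | None:
        resnum, xyz = self.chains[chain_id]
        hits = np.nonzero(resnum == residue_number)[0]
        if hits.size == 0:
            return None
        return xyz[hits[0]]

    def _resnum(self, family_id: str, profile_index: int) -> int:
        offset = (self.offsets or {}).get(family_id, 0)
        return profile_index + offset


def load_structure(
    path: str | Path,
    chain_map: dict[str, str],
    offsets: dict[str, int] | None = None,
) -> StructureModel:
    """Load a Cα-only model from a PDB or mmCIF file.

    ``chain_map`` maps chain ids to protein family ids; chains absent from
    the map are ignored, a mapped chain absent from the file is an error.
    Residues lacking a Cα atom are skipped with a logged warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"{path}: cannot parse structure: {exc}") from None
    if len(st) == 0:
        raise DataError(f"{path}: structure has no models")
    model = st[0]

    chains: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chain in model:
        if chain.name not in chain_map:
            continue
        resnums: list[int] = []
        coords: list[list[float]] = []
        skipped = 0
        for residue in chain:
            # name "CA" + element C excludes calcium ions (element Ca)
            ca = next(
                (
                    a
                    for a in residue
                    if a.name == "CA" and a.element.name == "C"
                ),
                None,
            )
            if ca is None:
                skipped += 1
                continue
            resnums.append(residue.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if skipped:
            logger.warning(
                "%s chain %s: skipped %d residues without a CA atom",
                path.name,
                chain.name,
                skipped,
            )
        chains[chain.name] = (
            np.array(resnums, dtype=int),
            np.array(coords, dtype=float).reshape(-1, 3),
        )
    missing = set(chain_map) - set(chains)
    if missing:
        raise MappingError(
            f"{path}: chains {sorted(missing)} named in chain_map are absent"
        )
    return StructureModel(chains, dict(chain_map), offsets)


def min_cross_distance(
    m: StructureModel,
    fam_a: str,
    i: int,
    fam_b: str,
    j: int,
) -> float | None:
    """Minimal Cα–Cα distance over all chain-copy combinations.

    ``i`` and ``j`` are 1-based profile columns of families ``fam_a`` and
    ``fam_b``.  For ``fam_a == fam_b`` only distinct-chain combinations are
    considered (the cross-copy contact in an oligomer).  Returns ``None``
    when either residue is unresolved in every copy.
    """
    chains_a = m.family_chains(fam_a)
    chains_b = m.family_chains(fam_b)
    ri = m._resnum(fam_a, i)
    rj = m._resnum(fam_b, j)
    best: float | None = None
    for ca in chains_a:
        pi = m.residue_coord(ca, ri)
        if pi is None:
            continue
        for cb in chains_b:
            if fam_a == fam_b and ca == cb:
                continue
            pj = m.residue_coord(cb, rj)
            if pj is None:
                continue
            dist = float(np.linalg.norm(pi - pj))
            if best is None or dist < best:
                best = dist
    return best


def _min_within_distance(
    m: StructureModel, fam: str, i: int, j: int
) -> float | None:
    """Minimal Cα–Cα distance between residues i and j within one chain,
    minimized over the family's chain copies."""
    ri = m._resnum(fam, i)
    rj = m._resnum(fam, j)
    best: float | None = None
    for c in m.family_chains(fam):
        pi = m.residue_coord(c, ri)
        pj = m.residue_coord(c, rj)
        if pi is None or pj is None:
            continue
        dist = float(np.linalg.norm(pi - pj))
        if best is None or dist < best:
            best = dist
    return best


def classify_pair(
    m: StructureModel,
    fam_a: str,
    i: int,
    fam_b: str,
    j: int,
    contact_cutoff: float = 12.0,
) -> str:
    """Classify a co-evolving pair by how it is realized in the structure.

    Pairs between different families are ``hetero_oligomeric``.  Within one
    family, the pair is ``homo_oligomeric`` when the minimal cross-chain
    distance is smaller than the minimal within-chain distance (the
    covariation is realized between oligomer copies), else ``intra``.
    """
    if fam_a != fam_b:
        return "hetero_oligomeric"
    cross = min_cross_distance(m, fam_a, i, fam_b, j)
    within = _min_within_distance(m, fam_a, i, j)
    if cross is None and within is None:
        raise MappingError(
            f"residues {i}/{j} of {fam_a!r} unresolved in every chain copy"
        )
    if within is None:
        return "homo_oligomeric"
    if cross is None:
        return "intra"
    return "homo_oligomeric" if cross < within else "intra"


@dataclass
class SelectedPair:
    """A scored residue pair selected for structural mapping."""

    i: int
    j: int
    score: float
    category: str | None = None
    min_distance: float | None = None
    within_interface: bool | None = None


def select_pairs(
    ranked: list[tuple[int, int, float]], mode: str = "threshold70"
) -> list[SelectedPair]:
    """Select pairs from a ranked list by one of three rules.

    ``"threshold70"`` keeps every pair scoring at least 70% of the top
    pair's score (the illustration threshold used for interface mapping);
    ``"top:N"`` keeps the first N pairs (all, when fewer are available);
    ``"min_score:X"`` keeps pairs with score >= X.
    """
    if mode == "threshold70":
        if not ranked:
            raise EmptyInputError("threshold70 selection needs a non-empty list")
        cut = 0.7 * ranked[0][2]
        chosen = [p for p in ranked if p[2] >= cut]
    elif mode.startswith("top:"):
        n = int(mode.split(":", 1)[1])
        if n < 1:
            raise DataError(f"top:N requires N >= 1, got {n}")
        chosen = ranked[:n]
    elif mode.startswith("min_score:"):
        x = float(mode.split(":", 1)[1])
        chosen = [p for p in ranked if p[2] >= x]
    else:
        raise DataError(f"unknown selection mode {mode!r}")
    return [SelectedPair(i, j, s) for i, j, s in chosen]


def annotate_pairs(
    selected: list[SelectedPair],
    m: StructureModel,
    fam_a: str,
    fam_b: str,
    contact_cutoff: float = 12.0,
) -> list[SelectedPair]:
    """Fill category, minimal cross-chain distance and interface membership
    for each selected pair.  Pairs unresolved in the structure keep
    ``min_distance=None`` and are reported, never dropped."""
    for p in selected:
        p.category = classify_pair(m, fam_a, p.i, fam_b, p.j, contact_cutoff)
        p.min_distance = min_cross_distance(m, fam_a, p.i, fam_b, p.j)
        p.within_interface = (
            None if p.min_distance is None else p.min_distance <= contact_cutoff
        )
    return selected


def interface_precision(
    selected: list[SelectedPair], contact_cutoff: float = 12.0
) -> float:
    """Fraction of selected pairs whose minimal cross-chain distance is at
    most ``contact_cutoff``; pairs without a computable distance are
    excluded from the denominator."""
    if not selected:
        raise EmptyInputError("interface_precision needs a non-empty selection")
    measured = [p for p in selected if p.min_distance is not None]
    if not measured:
        raise EmptyInputError("no selected pair has a computable distance")
    within = sum(p.min_distance <= contact_cutoff for p in measured)
    return within / len(measured)


def residue_hotspot_mode(
    ranked: list[tuple[int, int, float]],
    side: str = "B",
    top_k: int = 50,
) -> list[tuple[int, int]]:
    """Collect one side's residues from the top-scoring pairs.

    Used when the partner protein is absent from the structure: the
    residues of the present protein appearing among the ``top_k``
    top-scoring pairs are returned with occurrence counts (descending
    count, then ascending residue index), ready for mapping onto that
    protein alone.
    """
    if top_k < 1:
        raise DataError(f"top_k must be >= 1, got {top_k}")
    if not ranked:
        raise EmptyInputError("residue_hotspot_mode needs a non-empty list")
    if side not in ("A", "B"):
        raise DataError(f"side must be 'A' or 'B', got {side!r}")
    col = 0 if side == "A" else 1
    counts: dict[int, int] = {}
    for pair in ranked[:top_k]:
        res = pair[col]
        counts[res] = counts.get(res, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def write_selected_pairs(
    selected: list[SelectedPair], path: str | Path
) -> None:
    """Write selected pairs as TSV
    (``i  j  score  category  min_distance_A  within_interface``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("i\tj\tscore\tcategory\tmin_distance_A\twithin_interface\n")
        for p in selected:
            dist = "NA" if p.min_distance is None else repr(p.min_distance)
            within = "NA" if p.within_interface is None else str(p.within_interface)
            fh.write(
                f"{p.i}\t{p.j}\t{p.score!r}\t{p.category}\t{dist}\t{within}\n"
            )


def summarize_selection(
    selected: list[SelectedPair], contact_cutoff: float = 12.0
) -> dict:
    """JSON-ready summary: counts per category, unresolved count, precision."""
    categories: dict[str, int] = {}
    for p in selected:
        categories[p.category or "unannotated"] = (
            categories.get(p.category or "unannotated", 0) + 1
        )
    unresolved = sum(p.min_distance is None for p in selected)
    summary = {
        "n_selected": len(selected),
        "categories": categories,
        "n_unresolved": unresolved,
        "contact_cutoff_A": contact_cutoff,
    }
    if len(selected) > unresolved:
        summary["interface_precision"] = interface_precision(
            selected, contact_cutoff
        )
    return summary


def write_residue_attributes(
    values: list[tuple[int, int]], path: str | Path
) -> None:
    """Write a generic residue → value table for molecular viewers."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("residue\tvalue\n")
        for res, val in values:
            fh.write(f"{res}\t{val}\n")


def write_selection_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
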