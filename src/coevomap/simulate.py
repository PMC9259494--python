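"""Synthetic genomes, coupled MSAs and toy structures with known truth.

Every pipeline stage is exercised against data whose ground truth is known
by construction:

* :func:`gen_genome_records` — hit tables for two families where a fraction
  of nucleotide records carry both genes within an operon-scale gene
  separation, plus decoy hits that fail the coverage/e-value filters.
* :func:`gen_coupled_msa` — a paired alignment whose background columns are
  independent draws from per-column profiles and whose planted column pairs
  are coupled through a fixed one-to-one state mapping with mixing weight
  ``epsilon`` (``epsilon=1`` makes the coupling deterministic, so the
  pair's mutual information equals the marginal column entropy — a closed
  form the tests use).
* :func:`gen_structure` — a toy symmetric multi-chain model in which every
  planted pair is in Cα–Cα contact (≤ ``contact_distance``) and every other
  inter-family pair is far (≥ ``far_distance``).
* :func:`gen_bundle` — a consistent triple of the above in which the
  planted couplings are recoverable end-to-end.

The coupling model is deliberately not a Potts model: a one-to-one mapping
mixed with independence gives closed-form expectations for testing while
still exercising the ranking and selection logic.  The default generator
has no phylogenetic correlation between rows; an optional
duplication-with-mutation mode provides correlated rows for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np

from .errors import DataError, FeasibilityError
from .hits import AA_ALPHABET, HomologHit, write_hit_table
from .msa import PairedMSA, write_msa
from .structure import StructureModel

_Q = len(AA_ALPHABET)


# ---------------------------------------------------------------------------
# Genomes / hit tables
# ---------------------------------------------------------------------------


def gen_genome_records(
    n_records: int,
    colocate_prob: float = 0.6,
    max_separation: int = 20,
    seed: int = 0,
    len_a: int = 30,
    len_b: int = 30,
    family_a: str = "famA",
    family_b: str = "famB",
    decoy_fraction: float = 0.15,
) -> tuple[list[HomologHit], list[HomologHit], list[str]]:
    """Generate hit tables for two families over synthetic genome records.

    With probability ``colocate_prob`` a record carries both families with
    gene separation drawn uniformly in ``[1, max_separation - 1]`` (these
    are the *planted* co-located pairs, returned as truth); otherwise the
    record carries both families too far apart, or only one of them.
    Planted hits always pass the default coverage/e-value filters; an
    additional ``decoy_fraction`` of records carries hits that fail them,
    so the filters are exercised.

    Returns ``(hits_a, hits_b, colocated_record_ids)``.
    """
    if not 0.0 <= colocate_prob <= 1.0:
        raise DataError(f"colocate_prob must be in [0, 1], got {colocate_prob}")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise DataError(f"decoy_fraction must be in [0,1], got {decoy_fraction}")
    if n_records < 0:
        raise DataError(f"n_records must be >= 0, got {n_records}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ALPHABET))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(letters, size=length))

    def passing_hit(fam: str, rec: str, gi: int, length: int) -> HomologHit:
        return HomologHit(
            fam,
            rec,
            gi,
            evalue=float(10.0 ** rng.uniform(-30, -12)),
            query_coverage=float(rng.uniform(0.65, 1.0)),
            aligned_seq=random_seq(length),
        )

    def failing_hit(fam: str, rec: str, gi: int, length: int) -> HomologHit:
        if rng.random() < 0.5:  # fail on coverage
            cov = float(rng.uniform(0.05, 0.60))
            ev = float(10.0 ** rng.uniform(-30, -12))
        else:  # fail on e-value
            cov = float(rng.uniform(0.65, 1.0))
            ev = float(10.0 ** rng.uniform(-2, 1))
        return HomologHit(fam, rec, gi, ev, cov, random_seq(length))

    # The per-record co-location decisions are the generator's first draw:
    # one uniform per record, co-located iff u < colocate_prob.  Tests
    # re-execute this documented draw stream to check the planted count.
    u_all = rng.random(n_records)

    hits_a: list[HomologHit] = []
    hits_b: list[HomologHit] = []
    colocated: list[str] = []
    for r in range(n_records):
        rec = f"REC{r:06d}"
        u = u_all[r]
        if u < colocate_prob:
            gi_a = int(rng.integers(0, 50))
            sep = int(rng.integers(1, max_separation))
            hits_a.append(passing_hit(family_a, rec, gi_a, len_a))
            hits_b.append(passing_hit(family_b, rec, gi_a + sep, len_b))
            colocated.append(rec)
        elif u < colocate_prob + (1 - colocate_prob) / 2:
            # Both present but beyond the separation limit.
            gi_a = int(rng.integers(0, 50))
            sep = int(rng.integers(max_separation, 3 * max_separation))
            hits_a.append(passing_hit(family_a, rec, gi_a, len_a))
            hits_b.append(passing_hit(family_b, rec, gi_a + sep, len_b))
        else:
            # Only one family present.
            gi = int(rng.integers(0, 50))
            if rng.random() < 0.5:
                hits_a.append(passing_hit(family_a, rec, gi, len_a))
            else:
                hits_b.append(passing_hit(family_b, rec, gi, len_b))
        if rng.random() < decoy_fraction:
            gi = int(rng.integers(0, 50))
            if rng.random() < 0.5:
                hits_a.append(failing_hit(family_a, rec, gi, len_a))
            else:
                hits_b.append(failing_hit(family_b, rec, gi, len_b))
    return hits_a, hits_b, colocated


# ---------------------------------------------------------------------------
# Coupled MSA
# ---------------------------------------------------------------------------


def gen_coupled_msa(
    len_a: int,
    len_b: int,
    n_seqs: int,
    planted: list[tuple[int, int]],
    epsilon: float = 0.9,
    seed: int = 0,
    gap_rate: float = 0.0,
    profile_concentration: float = 1.0,
    row_ids: list[str] | None = None,
    duplication_rate: float = 0.0,
    mutation_rate: float = 0.05,
) -> tuple[PairedMSA, list[tuple[int, int]]]:
    """Generate a paired MSA with planted inter-block coupled column pairs.

    Planted pairs are 1-based ``(i, j)`` with ``i`` in block A and ``j`` in
    block B.  Background columns draw i.i.d. from a per-column Dirichlet
    profile (concentration ``profile_concentration``).  For a planted pair,
    with probability ``epsilon`` the pair is drawn jointly: the A-state is
    drawn from column i's profile and the B-state is its image under a
    fixed random one-to-one alphabet mapping; with probability
    ``1 - epsilon`` the two states are drawn independently from their
    marginals (column j's profile is the pushforward of column i's, so the
    marginal distribution of column j does not depend on ``epsilon``).
    Gaps are injected i.i.d. at ``gap_rate`` after the draw.

    With ``duplication_rate > 0`` each row is, with that probability, a
    copy of the previous row with per-column mutation probability
    ``mutation_rate`` — a crude stand-in for phylogenetic redundancy used
    to stress the identity filter.

    Returns the MSA and the planted truth (echoed back).
    """
    if n_seqs < 2:
        raise DataError(f"n_seqs must be >= 2, got {n_seqs}")
    if not 0.0 <= epsilon <= 1.0:
        raise DataError(f"epsilon must be in [0, 1], got {epsilon}")
    if not 0.0 <= gap_rate < 1.0:
        raise DataError(f"gap_rate must be in [0, 1), got {gap_rate}")
    if len(set(planted)) != len(planted):
        raise DataError("duplicate planted pairs")
    for i, j in planted:
        if not (1 <= i <= len_a and 1 <= j <= len_b):
            raise DataError(f"planted pair ({i}, {j}) out of bounds")

    rng = np.random.default_rng(seed)
    L = len_a + len_b
    profiles = rng.dirichlet(np.full(_Q, profile_concentration), size=L)

    # Fixed one-to-one alphabet mapping per planted pair.
    mappings = {pair: rng.permutation(_Q) for pair in planted}
    planted_b_cols = {len_a + j - 1: (i - 1, pair) for pair in planted for i, j in [pair]}

    states = np.empty((n_seqs, L), dtype=int)
    for c in range(L):
        if c in planted_b_cols:
            continue
        states[:, c] = rng.choice(_Q, size=n_seqs, p=profiles[c])
    for c, (a_col, pair) in planted_b_cols.items():
        sigma = mappings[pair]
        coupled = rng.random(n_seqs) < epsilon
        # Independent draw from the pushforward marginal.
        push = np.zeros(_Q)
        np.add.at(push, sigma, profiles[a_col])
        indep = rng.choice(_Q, size=n_seqs, p=push)
        states[:, c] = np.where(coupled, sigma[states[:, a_col]], indep)

    if duplication_rate > 0:
        for r in range(1, n_seqs):
            if rng.random() < duplication_rate:
                mutate = rng.random(L) < mutation_rate
                row = states[r - 1].copy()
                row[mutate] = rng.integers(0, _Q, size=int(mutate.sum()))
                states[r] = row

    letters = np.array(list(AA_ALPHABET))
    chars = letters[states]
    if gap_rate > 0:
        gaps = rng.random((n_seqs, L)) < gap_rate
        chars = np.where(gaps, "-", chars)

    if row_ids is None:
        row_ids = [f"seq{r:05d}" for r in range(n_seqs)]
    if len(row_ids) != n_seqs:
        raise DataError("row_ids length must equal n_seqs")
    rows = [(rid, "".join(row)) for rid, row in zip(row_ids, chars)]
    return PairedMSA(rows, len_a, len_b), list(planted)


# ---------------------------------------------------------------------------
# Toy structure
# ---------------------------------------------------------------------------


def _component_paths(
    planted: list[tuple[int, int]]
) -> list[list[tuple[str, int]]]:
    """Decompose the planted bipartite contact graph into simple paths.

    Nodes are ``("A", i)`` / ``("B", j)``.  Each residue may appear in at
    most two planted pairs; components must be open paths (closed cycles
    are geometrically infeasible for the line layout and raise).
    """
    adj: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for i, j in planted:
        a, b = ("A", i), ("B", j)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for node, nbrs in adj.items():
        if len(nbrs) > 2:
            raise FeasibilityError(
                f"residue {node} appears in {len(nbrs)} planted pairs (max 2)"
            )
    paths: list[list[tuple[str, int]]] = []
    seen: set[tuple[str, int]] = set()
    # Start walks from endpoints (degree 1) so each open path is traced once.
    for start in sorted(adj):
        if start in seen or len(adj[start]) != 1:
            continue
        path = [start]
        seen.add(start)
        current = start
        while True:
            nxt = [n for n in adj[current] if n not in seen]
            if not nxt:
                break
            current = nxt[0]
            path.append(current)
            seen.add(current)
        paths.append(path)
    if len(seen) != len(adj):
        raise FeasibilityError(
            "planted contact graph contains a closed cycle; infeasible for "
            "the line layout"
        )
    return paths


def gen_structure(
    len_a: int,
    len_b: int,
    planted: list[tuple[int, int]],
    n_copies_a: int = 1,
    n_copies_b: int = 1,
    contact_distance: float = 8.0,
    far_distance: float = 20.0,
    seed: int = 0,
    family_a: str = "famA",
    family_b: str = "famB",
) -> StructureModel:
    """Build a toy multi-chain Cα model realizing the planted contacts.

    Planted pairs are placed ≤ ``contact_distance`` apart between the
    first (designated) copies of A and B; all non-planted inter-family
    pairs end up ≥ ``far_distance`` apart across *all* copy combinations.
    Symmetric copies are generated by rotation about the z axis; every base
    coordinate lies on the half-plane y=0, x ≥ R_min, with R_min chosen
    from the smallest nonzero relative rotation angle so rotated copies
    cannot come closer than ``far_distance``.

    Feasibility requires ``far_distance <= 3 * contact_distance`` (the
    line layout places path neighbours one step apart and needs three
    steps to exceed ``far_distance``) and a planted graph that is a union
    of open paths with residue degree ≤ 2.
    """
    if n_copies_a < 1 or n_copies_b < 1:
        raise DataError("copy counts must be >= 1")
    if far_distance > 3 * contact_distance:
        raise FeasibilityError(
            f"far_distance {far_distance} > 3 * contact_distance "
            f"{3 * contact_distance}: line layout infeasible"
        )
    paths = _component_paths(planted)

    # Step between path neighbours: within the contact range but large
    # enough that third neighbours (the nearest non-planted inter pairs on
    # a path) exceed far_distance.
    step = max(far_distance / 3.0, contact_distance * 0.9)
    step = min(step, contact_distance)

    # Minimum radius so any two distinct rotation angles keep copies apart.
    angles_a = [2 * np.pi * k / n_copies_a for k in range(n_copies_a)]
    angles_b = [2 * np.pi * k / n_copies_b for k in range(n_copies_b)]
    min_delta = None
    for aa in angles_a + angles_b:
        for bb in angles_a + angles_b:
            d = abs((aa - bb + np.pi) % (2 * np.pi) - np.pi)
            if d > 1e-9 and (min_delta is None or d < min_delta):
                min_delta = d
    if min_delta is None:
        r_min = far_distance  # single copy of each: radius unconstrained
    else:
        r_min = far_distance / (2 * np.sin(min_delta / 2)) + far_distance

    base_a = np.zeros((len_a, 3))
    base_b = np.zeros((len_b, 3))
    placed_a = np.zeros(len_a, dtype=bool)
    placed_b = np.zeros(len_b, dtype=bool)

    z = 0.0
    for path in paths:
        for node in path:
            side, res = node
            pos = np.array([r_min, 0.0, z])
            if side == "A":
                base_a[res - 1] = pos
                placed_a[res - 1] = True
            else:
                base_b[res - 1] = pos
                placed_b[res - 1] = True
            z += step
        z += far_distance + step  # gap between components

    # Unplanted residues in two family-specific far lanes.
    z_a = 0.0
    for r in range(len_a):
        if not placed_a[r]:
            base_a[r] = np.array([r_min + 3 * far_distance, 0.0, z_a])
            z_a += far_distance
    z_b = 0.0
    for r in range(len_b):
        if not placed_b[r]:
            base_b[r] = np.array([r_min + 6 * far_distance, 0.0, z_b])
            z_b += far_distance

    def rotate(coords: np.ndarray, angle: float) -> np.ndarray:
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return coords @ rot.T

    chains: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chain_to_protein: dict[str, str] = {}
    ids_a = "ACEGIKMOQS"
    ids_b = "BDFHJLNPRT"
    if n_copies_a > len(ids_a) or n_copies_b > len(ids_b):
        raise DataError("at most 10 copies per family supported")
    resnums_a = np.arange(1, len_a + 1)
    resnums_b = np.arange(1, len_b + 1)
    for k, angle in enumerate(angles_a):
        cid = ids_a[k]
        chains[cid] = (resnums_a.copy(), rotate(base_a, angle))
        chain_to_protein[cid] = family_a
    for k, angle in enumerate(angles_b):
        cid = ids_b[k]
        chains[cid] = (resnums_b.copy(), rotate(base_b, angle))
        chain_to_protein[cid] = family_b

    model = StructureModel(chains, chain_to_protein)
    _verify_constraints(
        model, len_a, len_b, planted, contact_distance, far_distance,
        family_a, family_b,
    )
    return model


def _verify_constraints(
    model: StructureModel,
    len_a: int,
    len_b: int,
    planted: list[tuple[int, int]],
    contact_distance: float,
    far_distance: float,
    family_a: str,
    family_b: str,
) -> None:
    """Exhaustively check the constructive distance guarantees."""
    from .structure import min_cross_distance

    tol = 1e-6  # absorbs rounding at exact-equality configurations
    planted_set = set(planted)
    for i, j in planted:
        d = min_cross_distance(model, family_a, i, family_b, j)
        if d is None or d > contact_distance + tol:
            raise FeasibilityError(
                f"planted pair ({i}, {j}) not in contact: {d}"
            )
    for i in range(1, len_a + 1):
        for j in range(1, len_b + 1):
            if (i, j) in planted_set:
                continue
            d = min_cross_distance(model, family_a, i, family_b, j)
            if d is not None and d < far_distance - tol:
                raise FeasibilityError(
                    f"non-planted pair ({i}, {j}) too close: {d:.2f} Å"
                )


def write_structure_pdb(
    model: StructureModel, path: str | Path, bfactor: float = 0.0
) -> None:
    """Write the Cα-only model as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    for cid, (resnums, coords) in model.chains.items():
        chain = gemmi.Chain(cid)
        for num, xyz in zip(resnums, coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = bfactor
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


@dataclass
class BundleConfig:
    """Generator configuration for a full synthetic study.

    Defaults define the reference synthetic conditions: alignment blocks of
    30 columns each, ten planted coupled pairs at coupling 0.9 (strong but
    not deterministic), ~60% of 1200 genome records co-located so the
    curated MSA retains several hundred rows, 5% gaps, and trimeric copies
    of each protein in the toy structure.
    """

    n_records: int = 1200
    colocate_prob: float = 0.6
    max_separation: int = 20
    len_a: int = 30
    len_b: int = 30
    n_planted: int = 10
    epsilon: float = 0.9
    gap_rate: float = 0.05
    n_copies_a: int = 3
    n_copies_b: int = 3
    contact_distance: float = 8.0
    far_distance: float = 20.0
    family_a: str = "famA"
    family_b: str = "famB"
    decoy_fraction: float = 0.15
    duplication_rate: float = 0.0


@dataclass
class SyntheticBundle:
    """A consistent genomes/MSA/structure triple with planted truth."""

    hits_a: list[HomologHit]
    hits_b: list[HomologHit]
    truth_pairs: list[tuple[int, int]]
    msa: PairedMSA
    structure: StructureModel
    params: dict = field(default_factory=dict)


def _draw_planted_pairs(
    rng: np.random.Generator, len_a: int, len_b: int, n_planted: int
) -> list[tuple[int, int]]:
    """Distinct planted pairs using each residue at most once (degree 1),
    keeping the structure layout trivially feasible."""
    if n_planted > min(len_a, len_b):
        raise DataError(
            f"cannot plant {n_planted} degree-1 pairs with blocks of "
            f"{len_a} and {len_b} columns"
        )
    cols_a = rng.choice(len_a, size=n_planted, replace=False) + 1
    cols_b = rng.choice(len_b, size=n_planted, replace=False) + 1
    return sorted(zip(map(int, cols_a), map(int, cols_b)))


def gen_bundle(config: BundleConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a consistent synthetic study.

    The coupled MSA rows are assigned to the co-located genome records, so
    running the full pipeline (filter → pair → concatenate → curate →
    score → select → map) on the bundle's hit tables recovers the planted
    pairs, which by construction are the only inter-family contacts in the
    bundle's structure.
    """
    config = config or BundleConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)

    hits_a, hits_b, colocated = gen_genome_records(
        config.n_records,
        config.colocate_prob,
        config.max_separation,
        seed=int(sub[0]),
        len_a=config.len_a,
        len_b=config.len_b,
        family_a=config.family_a,
        family_b=config.family_b,
        decoy_fraction=config.decoy_fraction,
    )
    planted = _draw_planted_pairs(
        rng, config.len_a, config.len_b, config.n_planted
    )
    n_rows = max(len(colocated), 2)
    msa, _ = gen_coupled_msa(
        config.len_a,
        config.len_b,
        n_rows,
        planted,
        epsilon=config.epsilon,
        seed=int(sub[1]),
        gap_rate=config.gap_rate,
        row_ids=(
            colocated
            if len(colocated) >= 2
            else [f"pad{k}" for k in range(n_rows)]
        ),
        duplication_rate=config.duplication_rate,
    )
    # Overwrite the co-located hits' aligned sequences with the coupled rows
    # so the planted signal survives the real pairing path.
    seq_by_record = {rid: seq for rid, seq in msa.rows}
    colocated_set = set(colocated)

    def reseq(hits: list[HomologHit], start: int, stop: int) -> list[HomologHit]:
        out = []
        for h in hits:
            if h.record_id in colocated_set and h.evalue <= 1e-3:
                seq = seq_by_record[h.record_id][start:stop]
                h = HomologHit(
                    h.family_id, h.record_id, h.gene_index, h.evalue,
                    h.query_coverage, seq,
                )
            out.append(h)
        return out

    hits_a = reseq(hits_a, 0, config.len_a)
    hits_b = reseq(hits_b, config.len_a, config.len_a + config.len_b)

    structure = gen_structure(
        config.len_a,
        config.len_b,
        planted,
        n_copies_a=config.n_copies_a,
        n_copies_b=config.n_copies_b,
        contact_distance=config.contact_distance,
        far_distance=config.far_distance,
        seed=int(sub[2]),
        family_a=config.family_a,
        family_b=config.family_b,
    )
    params = asdict(config)
    params["seed"] = seed
    return SyntheticBundle(hits_a, hits_b, planted, msa, structure, params)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle in the formats the pipeline reads.

    Writes hit tables (TSV), the coupled MSA (FASTA + sidecar), the toy
    structure (PDB), the chain map (JSON) and the truth/params (JSON).
    Returns the path of each artifact.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fam_a = bundle.params.get("family_a", "famA")
    fam_b = bundle.params.get("family_b", "famB")
    paths = {
        "hits_a": out_dir / "hits_a.tsv",
        "hits_b": out_dir / "hits_b.tsv",
        "msa": out_dir / "msa.fasta",
        "structure": out_dir / "structure.pdb",
        "chain_map": out_dir / "chain_map.json",
        "truth": out_dir / "truth.json",
    }
    write_hit_table(bundle.hits_a, paths["hits_a"])
    write_hit_table(bundle.hits_b, paths["hits_b"])
    write_msa(bundle.msa, paths["msa"])
    write_structure_pdb(bundle.structure, paths["structure"])
    paths["chain_map"].write_text(
        json.dumps(bundle.structure.chain_to_protein, sort_keys=True) + "\n"
    )
    paths["truth"].write_text(
        json.dumps(
            {
                "truth_pairs": [list(p) for p in bundle.truth_pairs],
                "params": bundle.params,
                "family_a": fam_a,
                "family_b": fam_b,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths
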