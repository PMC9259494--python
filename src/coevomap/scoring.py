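"""Inter-protein contact-probability scoring.

Two backends produce an ``L_A x L_B`` score matrix over the paired MSA's
two blocks:

* **distogram** — consume an externally predicted distance-bin probability
  tensor (one probability vector over distance bins per residue pair, as a
  structure-prediction network emits) and sum the mass of bins at or below a
  distance cutoff (12 Å by default) to obtain a contact probability.
* **mi_apc** — a self-contained mutual-information scorer with the
  average-product correction (APC), computed directly from the paired MSA.
  It is a controlled, verifiable stand-in for network-based co-evolution
  scores, suitable for desk-scale analysis and for testing the downstream
  ranking/selection/mapping stages against planted ground truth.

Scores from either backend feed :func:`rank_inter_pairs` and then the
selection and structure-mapping stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError, ParseError
from .hits import AA_ALPHABET
from .msa import PairedMSA

logger = logging.getLogger(__name__)

_PROB_SUM_TOL = 1e-4


@dataclass
class Distogram:
    """Per residue pair, probability mass over ascending distance bins.

    ``prob`` has shape ``(len_a, len_b, n_bins)`` where ``n_bins`` equals
    ``len(bin_edges) - 1`` plus one trailing "no contact" bin when
    ``has_nocontact_bin`` is set.  Bin ``k`` covers distances
    ``[bin_edges[k], bin_edges[k+1])``.
    """

    len_a: int
    len_b: int
    bin_edges: np.ndarray
    has_nocontact_bin: bool
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise DataError("bin_edges must hold at least two distances")
        if self.bin_edges[0] < 0:
            raise DataError("bin edges must be non-negative")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise DataError("bin_edges must be strictly increasing")
        n_bins = self.bin_edges.size - 1 + int(self.has_nocontact_bin)
        if self.prob.shape != (self.len_a, self.len_b, n_bins):
            raise DataError(
                f"prob tensor shape {self.prob.shape} != expected "
                f"({self.len_a}, {self.len_b}, {n_bins})"
            )
        if np.any(self.prob < 0):
            raise DataError("probabilities must be non-negative")
        sums = self.prob.sum(axis=2)
        dev = np.abs(sums - 1.0)
        if np.any(dev > _PROB_SUM_TOL):
            i, j = np.unravel_index(int(dev.argmax()), dev.shape)
            raise DataError(
                f"probability vector for pair ({i + 1}, {j + 1}) sums to "
                f"{sums[i, j]:.6f} (deviation > {_PROB_SUM_TOL})"
            )
        # Exact renormalization after the tolerance check.
        self.prob = self.prob / sums[:, :, None]


@dataclass
class ScoreMatrix:
    """``len_a x len_b`` co-evolution scores between two protein blocks."""

    len_a: int
    len_b: int
    scores: np.ndarray
    backend: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.len_a, self.len_b):
            raise DataError(
                f"score matrix shape {self.scores.shape} != "
                f"({self.len_a}, {self.len_b})"
            )
        if not np.all(np.isfinite(self.scores)):
            raise DataError("scores must be finite")
        if self.backend == "distogram" and (
            self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12
        ):
            raise DataError("distogram-backend scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Distogram I/O
# ---------------------------------------------------------------------------

#: Long-format TSV columns; ``i``/``j`` are 1-based residue indices and the
#: no-contact bin (if present) is the single row per pair with ``bin_upper``
#: equal to ``inf``.
DISTOGRAM_TSV_COLUMNS = ("i", "j", "bin_lower", "bin_upper", "prob")


def read_distogram(path: str | Path) -> Distogram:
    """Read a distogram from long-format TSV (``.tsv``) or HDF5 (``.h5``).

    Probability vectors are renormalized only when their deviation from 1
    is at most 1e-4; larger deviations are rejected.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_distogram_h5(path)
    return _read_distogram_tsv(path)


def _read_distogram_tsv(path: Path) -> Distogram:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from None
    if tuple(df.columns) != DISTOGRAM_TSV_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {list(DISTOGRAM_TSV_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise EmptyInputError(f"{path}: distogram has no residue pairs")

    finite = df[np.isfinite(df["bin_upper"])]
    nocontact = df[~np.isfinite(df["bin_upper"])]
    has_nocontact = not nocontact.empty

    edge_pairs = sorted(
        set(zip(finite["bin_lower"], finite["bin_upper"]))
    )
    edges = [edge_pairs[0][0]]
    for lo, hi in edge_pairs:
        if lo != edges[-1]:
            raise ParseError(
                f"{path}: bins are not contiguous/ascending at [{lo}, {hi})"
            )
        edges.append(hi)
    bin_edges = np.array(edges, dtype=float)
    n_finite = len(edge_pairs)

    len_a = int(df["i"].max())
    len_b = int(df["j"].max())
    if df["i"].min() < 1 or df["j"].min() < 1:
        raise ParseError(f"{path}: residue indices must be 1-based")

    n_bins = n_finite + int(has_nocontact)
    prob = np.zeros((len_a, len_b, n_bins))
    bin_index = {pair: k for k, pair in enumerate(edge_pairs)}
    fi = finite["i"].to_numpy(int) - 1
    fj = finite["j"].to_numpy(int) - 1
    fk = np.array(
        [bin_index[p] for p in zip(finite["bin_lower"], finite["bin_upper"])]
    )
    prob[fi, fj, fk] = finite["prob"].to_numpy(float)
    if has_nocontact:
        if not np.all(nocontact["bin_lower"].to_numpy() == bin_edges[-1]):
            raise ParseError(
                f"{path}: no-contact bin must start at the last edge "
                f"{bin_edges[-1]}"
            )
        prob[
            nocontact["i"].to_numpy(int) - 1,
            nocontact["j"].to_numpy(int) - 1,
            n_bins - 1,
        ] = nocontact["prob"].to_numpy(float)
    try:
        return Distogram(len_a, len_b, bin_edges, has_nocontact, prob)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


def _read_distogram_h5(path: Path) -> Distogram:
    with h5py.File(path, "r") as fh:
        if "prob" not in fh:
            raise ParseError(f"{path}: missing 'prob' dataset")
        prob = fh["prob"][()]
        meta = json.loads(fh["prob"].attrs["meta"])
    if prob.size == 0:
        raise EmptyInputError(f"{path}: distogram has no residue pairs")
    try:
        return Distogram(
            prob.shape[0],
            prob.shape[1],
            np.array(meta["bin_edges"], dtype=float),
            bool(meta["has_nocontact_bin"]),
            prob,
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


def write_distogram(d: Distogram, path: str | Path) -> None:
    """Write a distogram in the TSV or HDF5 layout (chosen by extension)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("prob", data=d.prob)
            ds.attrs["meta"] = json.dumps(
                {
                    "bin_edges": d.bin_edges.tolist(),
                    "has_nocontact_bin": d.has_nocontact_bin,
                },
                sort_keys=True,
            )
        return
    rows = []
    uppers = list(d.bin_edges[1:])
    lowers = list(d.bin_edges[:-1])
    if d.has_nocontact_bin:
        lowers.append(d.bin_edges[-1])
        uppers.append(np.inf)
    for i in range(d.len_a):
        for j in range(d.len_b):
            for k, (lo, hi) in enumerate(zip(lowers, uppers)):
                rows.append((i + 1, j + 1, lo, hi, d.prob[i, j, k]))
    pd.DataFrame(rows, columns=list(DISTOGRAM_TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Distogram aggregation
# ---------------------------------------------------------------------------


def aggregate_contact_probability(
    d: Distogram, distance_cutoff: float = 12.0
) -> ScoreMatrix:
    """Sum bin probabilities for distances at or below ``distance_cutoff``.

    A bin qualifies iff its *upper* edge is <= the cutoff, so the score is
    exactly the probability that the pair's distance is <= cutoff whenever
    the cutoff coincides with a bin edge (as 12 Å does on standard grids).
    The no-contact bin never qualifies.
    """
    if not d.bin_edges[0] <= distance_cutoff <= d.bin_edges[-1]:
        raise DataError(
            f"distance_cutoff {distance_cutoff} outside binned range "
            f"[{d.bin_edges[0]}, {d.bin_edges[-1]}]"
        )
    qualifying = d.bin_edges[1:] <= distance_cutoff
    scores = d.prob[:, :, : qualifying.size][:, :, qualifying].sum(axis=2)
    return ScoreMatrix(d.len_a, d.len_b, scores, backend="distogram")


# ---------------------------------------------------------------------------
# Mutual information with average-product correction
# ---------------------------------------------------------------------------


def _mi_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """MI in bits for a stack of q x q contingency tables.

    ``counts`` has shape (..., q, q).  With pseudocount ``lam``, the joint
    distribution is ``(n_ab + lam/q**2) / (n + lam)`` and marginals are its
    row/column sums, so the joint remains a proper distribution.
    """
    q = counts.shape[-1]
    n = counts.sum(axis=(-2, -1), keepdims=True)
    joint = (counts + pseudocount / q**2) / (n + pseudocount)
    pa = joint.sum(axis=-1, keepdims=True)
    pb = joint.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log2(joint) - np.log2(pa) - np.log2(pb)
        terms = np.where(joint > 0, joint * log_term, 0.0)
    mi = terms.sum(axis=(-2, -1))
    # Clamp tiny negative round-off; true MI is non-negative.
    return np.maximum(mi, 0.0)


def _apc(mi: np.ndarray, *, symmetric_block: bool) -> np.ndarray:
    """Average-product correction: subtract mean_i * mean_j / mean_all.

    For a symmetric intra-block matrix the means exclude the diagonal
    (self-MI is column entropy, not a coupling).
    """
    if symmetric_block:
        L = mi.shape[0]
        if L < 2:
            return np.zeros_like(mi)
        off = ~np.eye(L, dtype=bool)
        row_mean = (mi * off).sum(axis=1) / (L - 1)
        overall = (mi * off).sum() / (L * (L - 1))
        if overall == 0:
            out = mi.copy()
            np.fill_diagonal(out, 0.0)  # self-MI is entropy, not coupling
            return out
        corrected = mi - np.outer(row_mean, row_mean) / overall
        np.fill_diagonal(corrected, 0.0)
        return corrected
    row_mean = mi.mean(axis=1)
    col_mean = mi.mean(axis=0)
    overall = mi.mean()
    if overall == 0:
        return mi.copy()
    return mi - np.outer(row_mean, col_mean) / overall


def mi_apc_scores(
    msa: PairedMSA, pseudocount: float = 1.0
) -> tuple[ScoreMatrix, ScoreMatrix, ScoreMatrix]:
    """Mutual information (bits) with APC for all column pairs.

    For each pair of columns, rows carrying a gap in either column are
    excluded from that pair's counts; MI is computed from add-pseudocount
    joint/marginal frequencies over the 20-letter amino-acid alphabet, then
    the average-product correction is applied separately to the
    inter-block, intra-A and intra-B matrices.

    Column pairs with fewer than two mutually ungapped rows score 0 (a
    warning is logged).  Sequence weighting is deliberately not applied on
    the default path: the scorer's job is to be a transparent, verifiable
    coupling detector, not a phylogeny-corrected estimator.

    Returns ``(inter, intra_a, intra_b)`` score matrices.
    """
    if msa.n_rows < 2:
        raise DataError("MI requires an MSA with at least 2 rows")
    if pseudocount < 0:
        raise DataError(f"pseudocount must be >= 0, got {pseudocount}")

    arr = msa.to_array()
    L = msa.width
    q = len(AA_ALPHABET)
    # One-hot with gap rows all-zero: the contraction then counts exactly
    # the rows where both columns are ungapped.
    lookup = {aa: k for k, aa in enumerate(AA_ALPHABET)}
    idx = np.array(
        [[lookup.get(c, -1) for c in row] for row in arr], dtype=int
    )
    onehot = np.zeros((L, arr.shape[0], q))
    cols, rows = np.meshgrid(np.arange(L), np.arange(arr.shape[0]))
    valid = idx >= 0
    onehot[cols[valid], rows[valid], idx[valid]] = 1.0

    counts = np.einsum("ina,jnb->ijab", onehot, onehot)
    n_pairs = counts.sum(axis=(2, 3))
    mi = _mi_from_counts(counts, pseudocount)

    sparse = n_pairs < 2
    np.fill_diagonal(sparse, False)
    if sparse.any():
        logger.warning(
            "%d column pairs had fewer than 2 ungapped rows; MI set to 0",
            int(sparse.sum()),
        )
        mi[sparse] = 0.0

    La, Lb = msa.len_a, msa.len_b
    inter = _apc(mi[:La, La:], symmetric_block=False)
    intra_a = _apc(mi[:La, :La], symmetric_block=True)
    intra_b = _apc(mi[La:, La:], symmetric_block=True)
    return (
        ScoreMatrix(La, Lb, inter, backend="mi_apc"),
        ScoreMatrix(La, La, intra_a, backend="mi_apc"),
        ScoreMatrix(Lb, Lb, intra_b, backend="mi_apc"),
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def rank_inter_pairs(
    sm: ScoreMatrix, min_score: float = 0.05
) -> list[tuple[int, int, float]]:
    """Rank inter-protein residue pairs by descending score.

    Pairs scoring below ``min_score`` are dropped; ties are broken by
    ascending ``(i, j)``.  Residue indices are reported 1-based.
    """
    if not np.isfinite(min_score):
        raise DataError("min_score must be finite")
    ii, jj = np.nonzero(sm.scores >= min_score)
    pairs = [
        (int(i) + 1, int(j) + 1, float(sm.scores[i, j])) for i, j in zip(ii, jj)
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def write_score_matrix(sm: ScoreMatrix, path: str | Path) -> None:
    """Write scores as TSV (``i  j  score``, 1-based) preceded by a JSON
    header line (``#``-prefixed) carrying the backend."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "#"
            + json.dumps(
                {"backend": sm.backend, "len_a": sm.len_a, "len_b": sm.len_b},
                sort_keys=True,
            )
            + "\n"
        )
        fh.write("i\tj\tscore\n")
        for i in range(sm.len_a):
            for j in range(sm.len_b):
                fh.write(f"{i + 1}\t{j + 1}\t{float(sm.scores[i, j])!r}\n")


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    """Read a score matrix written by :func:`write_score_matrix`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing JSON header line")
        meta = json.loads(header[1:])
        df = pd.read_csv(fh, sep="\t")
    scores = np.zeros((meta["len_a"], meta["len_b"]))
    scores[df["i"] - 1, df["j"] - 1] = df["score"]
    return ScoreMatrix(meta["len_a"], meta["len_b"], scores, meta["backend"])
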