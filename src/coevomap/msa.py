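"""Paired (concatenated two-block) multiple sequence alignments.

Each row of a :class:`PairedMSA` concatenates one homologue of protein A
(columns ``0 .. len_a-1``) with its genome-neighbour homologue of protein B
(columns ``len_a .. len_a+len_b-1``), both already aligned to their family
profiles.  Before co-evolution analysis the alignment is curated by a
per-row gap filter (gap fraction <= 25% by default) and a greedy redundancy
filter (pairwise identity <= 90% among retained rows by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .hits import PairedRecord


@dataclass
class PairedMSA:
    """Concatenated two-block alignment: one (record_id, sequence) per row."""

    rows: list[tuple[str, str]]
    len_a: int
    len_b: int

    def __post_init__(self) -> None:
        width = self.len_a + self.len_b
        for rid, seq in self.rows:
            if len(seq) != width:
                raise DataError(
                    f"row {rid!r} has length {len(seq)}, expected {width}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return self.len_a + self.len_b

    def to_array(self) -> np.ndarray:
        """Rows as a (n_rows, width) array of single characters."""
        if not self.rows:
            return np.empty((0, self.width), dtype="U1")
        return np.array([list(seq) for _, seq in self.rows], dtype="U1")


def build_paired_msa(
    pairs: list[PairedRecord], len_a: int, len_b: int
) -> PairedMSA:
    """Concatenate each pair's aligned sequences into one MSA row.

    Row order follows the input order.  A hit whose aligned sequence length
    does not match the declared block length raises a :class:`DataError`
    naming the record.
    """
    rows: list[tuple[str, str]] = []
    for p in pairs:
        if len(p.hit_a.aligned_seq) != len_a:
            raise DataError(
                f"record {p.record_id!r}: block-A sequence length "
                f"{len(p.hit_a.aligned_seq)} != {len_a}"
            )
        if len(p.hit_b.aligned_seq) != len_b:
            raise DataError(
                f"record {p.record_id!r}: block-B sequence length "
                f"{len(p.hit_b.aligned_seq)} != {len_b}"
            )
        rows.append((p.record_id, p.hit_a.aligned_seq + p.hit_b.aligned_seq))
    return PairedMSA(rows, len_a, len_b)


def gap_filter(msa: PairedMSA, max_gap_ratio: float = 0.25) -> PairedMSA:
    """Keep rows whose gap fraction (``'-'`` count / width) is at most
    ``max_gap_ratio``.  Order preserved; the boundary row (exactly 25% gaps
    at the default) is kept."""
    if not 0.0 <= max_gap_ratio <= 1.0:
        raise DataError(f"max_gap_ratio must be in [0, 1], got {max_gap_ratio}")
    width = msa.width
    kept = [
        (rid, seq)
        for rid, seq in msa.rows
        if seq.count("-") / width <= max_gap_ratio
    ]
    return PairedMSA(kept, msa.len_a, msa.len_b)


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Fraction of matching positions over columns where both sequences are
    non-gap; 0 when no such column exists."""
    both = [(a, b) for a, b in zip(seq1, seq2) if a != "-" and b != "-"]
    if not both:
        return 0.0
    return sum(a == b for a, b in both) / len(both)


def redundancy_filter(msa: PairedMSA, max_identity: float = 0.90) -> PairedMSA:
    """Greedy keep-first redundancy removal.

    Scanning rows in order, a row is dropped when its identity to any
    previously *retained* row exceeds ``max_identity``.  Identity counts
    matches over mutually non-gap columns only.  Deterministic given row
    order; after the scan no retained pair exceeds the threshold.
    """
    if not 0.0 < max_identity <= 1.0:
        raise DataError(f"max_identity must be in (0, 1], got {max_identity}")
    if msa.n_rows <= 1:
        return PairedMSA(list(msa.rows), msa.len_a, msa.len_b)

    arr = msa.to_array()
    nongap = arr != "-"
    kept_idx: list[int] = []
    for r in range(arr.shape[0]):
        redundant = False
        for k in kept_idx:
            shared = nongap[r] & nongap[k]
            n_shared = int(shared.sum())
            if n_shared == 0:
                continue
            matches = int((arr[r][shared] == arr[k][shared]).sum())
            if matches / n_shared > max_identity:
                redundant = True
                break
        if not redundant:
            kept_idx.append(r)
    kept = [msa.rows[i] for i in kept_idx]
    return PairedMSA(kept, msa.len_a, msa.len_b)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_msa(msa: PairedMSA, path: str | Path, fmt: str = "fasta") -> None:
    """Write the alignment as FASTA or Stockholm plus a JSON sidecar
    recording the block partition ``(len_a, len_b)``."""
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.rows
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "stockholm":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")
    else:
        raise DataError(f"unsupported MSA format {fmt!r}")
    _sidecar_path(path).write_text(
        json.dumps({"len_a": msa.len_a, "len_b": msa.len_b}, sort_keys=True)
        + "\n"
    )


def read_msa(path: str | Path, fmt: str = "fasta") -> PairedMSA:
    """Read an alignment written by :func:`write_msa` (sidecar required)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise DataError(f"missing sidecar {sidecar} with block partition")
    meta = json.loads(sidecar.read_text())
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif fmt == "stockholm":
        records = list(AlignIO.read(str(path), "stockholm"))
    else:
        raise DataError(f"unsupported MSA format {fmt!r}")
    rows = [(rec.id, str(rec.seq)) for rec in records]
    return PairedMSA(rows, int(meta["len_a"]), int(meta["len_b"]))
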