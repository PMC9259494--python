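"""Homologue hit tables and genomic co-location pairing.

A *hit* is one match of a protein-family profile on a nucleotide record
(a genome or plasmid sequence), carrying the ordinal position of the coding
gene on that record, the search e-value, the coverage of the query profile,
and the hit sequence aligned to the query profile (so all hits of one family
share one length).

Two families are paired by genomic proximity: homologues of A and B found on
the same nucleotide record and separated by fewer than ``max_separation``
coding genes are taken as operon neighbours, hence as interacting partners
whose sequences may co-evolve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from pathlib import Path

from .errors import DataError, ParseError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AA_ALPHABET + "-")

#: Column order of the hit-table TSV format (header row required).
HIT_TABLE_COLUMNS = (
    "family_id",
    "record_id",
    "gene_index",
    "evalue",
    "coverage",
    "aligned_seq",
)

#: E-value schedule of the upstream six-round iterative profile search.
#: Carried as configuration metadata only (written to the run log); the
#: search itself is upstream of this package.
ITERATIVE_SEARCH_EVALUES = (1e-12, 1e-12, 1e-12, 1e-12, 1e-6, 1e-3)


@dataclass(frozen=True)
class HomologHit:
    """One profile-search hit of a protein family on a nucleotide record."""

    family_id: str
    record_id: str
    gene_index: int
    evalue: float
    query_coverage: float
    aligned_seq: str

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise DataError(
                f"gene_index must be >= 0, got {self.gene_index} "
                f"({self.family_id} on {self.record_id})"
            )
        if self.evalue < 0:
            raise DataError(f"evalue must be >= 0, got {self.evalue}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise DataError(
                f"coverage must be in [0, 1], got {self.query_coverage}"
            )
        bad = set(self.aligned_seq) - _VALID_CHARS
        if bad:
            raise DataError(
                f"aligned_seq contains invalid characters {sorted(bad)} "
                f"({self.family_id} on {self.record_id})"
            )


@dataclass(frozen=True)
class PairedRecord:
    """A co-located (A, B) homologue pair on one nucleotide record."""

    record_id: str
    hit_a: HomologHit
    hit_b: HomologHit

    def __post_init__(self) -> None:
        if not (self.hit_a.record_id == self.hit_b.record_id == self.record_id):
            raise DataError(
                f"paired hits must share record_id {self.record_id!r}, got "
                f"{self.hit_a.record_id!r} / {self.hit_b.record_id!r}"
            )

    @property
    def separation(self) -> int:
        """Absolute difference in coding-gene index between the two hits."""
        return abs(self.hit_a.gene_index - self.hit_b.gene_index)


def read_hit_table(
    path: str | Path, family_id: str, profile_length: int
) -> list[HomologHit]:
    """Read a TSV hit table, keeping only rows of ``family_id``.

    The file must be tab-separated with the header
    ``family_id  record_id  gene_index  evalue  coverage  aligned_seq``
    (``gene_index`` 0-based).  Every retained row's ``aligned_seq`` must
    have length ``profile_length``.

    Raises
    ------
    ParseError
        Malformed header or row (names the line number).
    DataError
        A row violating a type invariant, or an aligned_seq of the wrong
        length (names the line number).
    """
    path = Path(path)
    hits: list[HomologHit] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if tuple(header) != HIT_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {list(HIT_TABLE_COLUMNS)}, "
                f"got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(HIT_TABLE_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected "
                    f"{len(HIT_TABLE_COLUMNS)} fields, got {len(row)}"
                )
            fam, rec, gi_s, ev_s, cov_s, seq = row
            if fam != family_id:
                continue
            try:
                gene_index = int(gi_s)
                evalue = float(ev_s)
                coverage = float(cov_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if len(seq) != profile_length:
                raise DataError(
                    f"{path}: line {lineno}: aligned_seq length {len(seq)} "
                    f"!= profile length {profile_length} for {family_id}"
                )
            try:
                hit = HomologHit(fam, rec, gene_index, evalue, coverage, seq)
            except DataError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_hit_table(hits: list[HomologHit], path: str | Path) -> None:
    """Write hits in the TSV format :func:`read_hit_table` reads."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HIT_TABLE_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.family_id,
                    h.record_id,
                    h.gene_index,
                    repr(h.evalue),
                    repr(h.query_coverage),
                    h.aligned_seq,
                ]
            )


def filter_hits(
    hits: list[HomologHit],
    min_coverage: float = 0.60,
    max_evalue: float = 1e-3,
) -> list[HomologHit]:
    """Keep hits with coverage strictly above ``min_coverage`` and e-value
    at most ``max_evalue``.  Order is preserved.

    Coverage uses strict ``>`` (a hit covering exactly 60% of the query is
    removed at the default threshold); the e-value cutoff is inclusive, the
    usual semantics of search-tool cutoffs.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise DataError(f"min_coverage must be in [0, 1], got {min_coverage}")
    if not max_evalue >= 0:
        raise DataError(f"max_evalue must be >= 0, got {max_evalue}")
    return [
        h
        for h in hits
        if h.query_coverage > min_coverage and h.evalue <= max_evalue
    ]


def pair_by_locus(
    hits_a: list[HomologHit],
    hits_b: list[HomologHit],
    max_separation: int = 20,
    pairing: str = "closest",
) -> list[PairedRecord]:
    """Pair hits of two families that co-locate on a nucleotide record.

    For each record carrying hits of both families, candidate pairs are
    those with ``|gene_index_a - gene_index_b| < max_separation`` (strict:
    "fewer than" ``max_separation`` coding genes apart).

    With ``pairing="closest"`` (default) exactly one pair per record is
    emitted: the candidate with the smallest separation, ties broken by
    smallest combined e-value, then by ascending ``(gene_index_a,
    gene_index_b)``.  With ``pairing="all"`` every candidate pair is kept.
    Output is sorted by ``record_id`` (and gene indices within a record for
    ``"all"``).
    """
    if max_separation < 1:
        raise DataError(f"max_separation must be >= 1, got {max_separation}")
    if pairing not in ("closest", "all"):
        raise DataError(f"pairing must be 'closest' or 'all', got {pairing!r}")

    by_record_a: dict[str, list[HomologHit]] = {}
    for h in hits_a:
        by_record_a.setdefault(h.record_id, []).append(h)
    by_record_b: dict[str, list[HomologHit]] = {}
    for h in hits_b:
        by_record_b.setdefault(h.record_id, []).append(h)

    out: list[PairedRecord] = []
    for record_id in sorted(set(by_record_a) & set(by_record_b)):
        candidates = [
            (a, b)
            for a, b in product(by_record_a[record_id], by_record_b[record_id])
            if abs(a.gene_index - b.gene_index) < max_separation
        ]
        if not candidates:
            continue
        if pairing == "closest":
            a, b = min(
                candidates,
                key=lambda ab: (
                    abs(ab[0].gene_index - ab[1].gene_index),
                    ab[0].evalue + ab[1].evalue,
                    ab[0].gene_index,
                    ab[1].gene_index,
                ),
            )
            out.append(PairedRecord(record_id, a, b))
        else:
            candidates.sort(key=lambda ab: (ab[0].gene_index, ab[1].gene_index))
            out.extend(PairedRecord(record_id, a, b) for a, b in candidates)
    return out


def write_paired_records(pairs: list[PairedRecord], path: str | Path) -> None:
    """Write paired records as TSV (one row per pair)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "record_id",
                "gene_index_a",
                "gene_index_b",
                "separation",
                "evalue_a",
                "evalue_b",
                "aligned_seq_a",
                "aligned_seq_b",
            ]
        )
        for p in pairs:
            writer.writerow(
                [
                    p.record_id,
                    p.hit_a.gene_index,
                    p.hit_b.gene_index,
                    p.separation,
                    repr(p.hit_a.evalue),
                    repr(p.hit_b.evalue),
                    p.hit_a.aligned_seq,
                    p.hit_b.aligned_seq,
                ]
            )
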