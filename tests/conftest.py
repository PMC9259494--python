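import numpy as np
import pytest

from coevomap.hits import HomologHit
from coevomap.msa import PairedMSA
from coevomap.simulate import BundleConfig, gen_bundle


def make_hit(
    family="famA",
    record="REC1",
    gene_index=0,
    evalue=1e-20,
    coverage=0.8,
    seq="MKLV",
):
    return HomologHit(family, record, gene_index, evalue, coverage, seq)


@pytest.fixture
def toy_msa():
    """6-row paired MSA (L_A=L_B=2) for MI oracle checks."""
    rows = [
        ("s1", "AKAY"),
        ("s2", "AKAY"),
        ("s3", "CRCW"),
        ("s4", "CRAY"),
        ("s5", "AKCW"),
        ("s6", "CRCW"),
    ]
    return PairedMSA(rows, 2, 2)


@pytest.fixture(scope="session")
def bundle():
    """Default-conditions synthetic bundle, shared across tests."""
    return gen_bundle(BundleConfig(), seed=1)


def brute_force_mi(columns_a, columns_b, pseudocount):
    """Independent contingency-table MI oracle (bits).

    Counts pairs directly with Python dicts over the 20-letter alphabet,
    excluding rows gapped in either column; pseudocount lambda adds
    lambda/q^2 to every joint cell so the joint stays a distribution.
    Returns 0.0 when fewer than two mutually ungapped rows remain (the
    scorer's documented sparse-pair behaviour).
    """
    import math

    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    q = len(alphabet)
    pairs = [
        (a, b)
        for a, b in zip(columns_a, columns_b)
        if a != "-" and b != "-"
    ]
    n = len(pairs)
    if n < 2:
        return 0.0
    counts = {}
    for a, b in pairs:
        counts[(a, b)] = counts.get((a, b), 0) + 1
    mi = 0.0
    lam = pseudocount
    for a in alphabet:
        pa = (sum(counts.get((a, b2), 0) for b2 in alphabet) + lam / q) / (
            n + lam
        )
        for b in alphabet:
            pab = (counts.get((a, b), 0) + lam / q**2) / (n + lam)
            pb = (
                sum(counts.get((a2, b), 0) for a2 in alphabet) + lam / q
            ) / (n + lam)
            if pab > 0:
                mi += pab * math.log2(pab / (pa * pb))
    return max(mi, 0.0)


def brute_force_mi_matrices(msa, pseudocount=1.0):
    """Full (inter, intra_a, intra_b) APC-corrected matrices by brute force."""
    cols = ["".join(seq[c] for _, seq in msa.rows) for c in range(msa.width)]
    L = msa.width
    mi = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            mi[i, j] = brute_force_mi(cols[i], cols[j], pseudocount)

    def apc_rect(m):
        overall = m.mean()
        if overall == 0:
            return m.copy()
        return m - np.outer(m.mean(axis=1), m.mean(axis=0)) / overall

    def apc_sym(m):
        L = m.shape[0]
        if L < 2:
            return np.zeros_like(m)
        off = ~np.eye(L, dtype=bool)
        row = (m * off).sum(axis=1) / (L - 1)
        overall = (m * off).sum() / (L * (L - 1))
        if overall == 0:
            out = m.copy()
            np.fill_diagonal(out, 0.0)
            return out
        out = m - np.outer(row, row) / overall
        np.fill_diagonal(out, 0.0)
        return out

    La = msa.len_a
    return (
        apc_rect(mi[:La, La:]),
        apc_sym(mi[:La, :La]),
        apc_sym(mi[La:, La:]),
    )
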