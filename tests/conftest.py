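"""Shared fixtures and independent exact-arithmetic oracles.

The oracles here recompute the enrichment statistics from their definitions
using ``fractions.Fraction`` (no floating point, no shared code with the
implementation) and are the reference the implementation is checked against.
"""

from fractions import Fraction
from math import comb

import pytest

import ptmenrich as pe


@pytest.fixture(scope="session")
def vocab():
    return pe.parse_ptm_vocabulary(pe.packaged_data_path("ptmlist_fixture.txt"))


@pytest.fixture(scope="session")
def keyword_universe(vocab):
    extra = pe.read_keyword_list(pe.packaged_data_path("ptm_keywords.txt"))
    return vocab.keywords | set(extra)


@pytest.fixture(scope="session")
def toy_db(vocab, keyword_universe):
    records = pe.parse_flatfile_records(pe.packaged_data_path("swissprot_fixture.dat"))
    return pe.build_database(records, vocab, keyword_universe,
                             source_name="swissprot_fixture.dat",
                             vocabulary_version="ptmlist_fixture.txt")


def hypergeom_tail_oracle(N: int, K: int, n: int, m: int) -> Fraction:
    """Exact upper-tail hypergeometric probability by rational enumeration."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(m, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def running_sum_oracle(scores, hits, p: int):
    """Exact weighted KS running sum by direct rational summation.

    ``scores`` are integers (descending along the list), ``hits`` a boolean
    sequence, ``p`` an integer weight exponent.  Returns (profile, peak index,
    ES) as Fractions, taking the first position of maximal |value|.
    """
    n = len(scores)
    n_hits = sum(hits)
    assert 0 < n_hits < n
    n_r = sum(Fraction(abs(s)) ** p for s, h in zip(scores, hits) if h)
    profile = []
    value = Fraction(0)
    for s, h in zip(scores, hits):
        if h:
            value += Fraction(abs(s)) ** p / n_r
        else:
            value -= Fraction(1, n - n_hits)
        profile.append(value)
    peak = max(range(n), key=lambda i: (abs(profile[i]), -i))
    return profile, peak, profile[peak]


def signed_ks_oracle(scores, hits):
    """Classical two-sample signed KS statistic over the ranked list (p=0)."""
    n = len(scores)
    n_hits = sum(hits)
    value = Fraction(0)
    best = Fraction(0)
    for h in hits:
        value += Fraction(1, n_hits) if h else -Fraction(1, n - n_hits)
        if abs(value) > abs(best):
            best = value
    return best
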