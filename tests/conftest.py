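"""Shared fixtures and small independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clonarch.bulk_burden import VariantTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_table(rows, sample_class=None, calling_mode="matched") -> VariantTable:
    """Build a VariantTable from terse row dicts (defaults filled in)."""
    defaults = {
        "chrom": "1",
        "ref": "A",
        "alt": "T",
        "sample": "s1",
        "depth": 30,
        "alt_fwd": 0,
        "alt_rev": 0,
        "median_alignment_score": 150,
        "clipped_fraction": 0.1,
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["pos"] = 1000 + i
        r.update(row)
        full.append(r)
    columns = [
        "chrom", "pos", "ref", "alt", "sample", "depth", "alt_fwd", "alt_rev",
        "median_alignment_score", "clipped_fraction",
    ]
    df = pd.DataFrame(full, columns=columns + [c for c in (full[0] if full else {}) if c not in columns])
    if not full:
        df = pd.DataFrame(columns=columns)
    classes = sample_class or {}
    for s in df["sample"].unique() if len(df) else []:
        classes.setdefault(s, "tissue")
    return VariantTable(df=df, sample_class=classes, calling_mode=calling_mode)


@pytest.fixture
def variant_table_factory():
    return make_table


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def enumerate_two_sided_pvalue(k: int, n: int) -> Fraction:
    """Exact two-sided binomial p-value at p=1/2 by full outcome enumeration:
    the summed probability of every outcome no more probable than ``k``."""
    if n == 0:
        return Fraction(1)
    pk = Fraction(comb(n, k))
    total = sum(Fraction(comb(n, x)) for x in range(n + 1) if comb(n, x) <= pk)
    return total / Fraction(2) ** n


def enumerate_lower_tail_pvalue(k: int, n: int, p: Fraction) -> Fraction:
    """P(X <= k) for X ~ Binomial(n, p) by enumeration with exact rationals."""
    if n == 0:
        return Fraction(1)
    return sum(
        Fraction(comb(n, x)) * p**x * (1 - p) ** (n - x) for x in range(int(k) + 1)
    )


def brute_force_parsimony(mat: np.ndarray) -> int:
    """Minimum parsimony score over all unrooted topologies by exhaustive
    enumeration of internal state assignments (independent of Fitch).

    ``mat`` is taxa x characters (binary), already including any outgroup row.
    Practical for <= 6 taxa.
    """
    n_leaves, n_chars = mat.shape
    n_int = n_leaves - 2
    assigns = np.array(list(itertools.product([0, 1], repeat=n_int)))

    def trees(edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield edges
            return
        for i, (a, b) in enumerate(edges):
            new = edges[:i] + edges[i + 1:] + [
                (a, next_internal), (b, next_internal), (next_leaf, next_internal)
            ]
            yield from trees(new, next_leaf + 1, next_internal + 1)

    best = None
    for edges in trees([(0, n_leaves), (1, n_leaves), (2, n_leaves)], 3, n_leaves + 1):
        E = np.array(edges)
        total = 0
        for c in range(n_chars):
            states = np.empty((assigns.shape[0], 2 * n_leaves - 2), dtype=int)
            states[:, :n_leaves] = mat[:, c]
            states[:, n_leaves:] = assigns
            diff = states[:, E[:, 0]] != states[:, E[:, 1]]
            total += int(diff.sum(axis=1).min())
        if best is None or total < best:
            best = total
    return best
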