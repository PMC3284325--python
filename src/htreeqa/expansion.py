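"""Tristate binary expansion of genotype columns and the four-gamete test.

Each unphased genotype column S' over {0, 1, H} expands into three binary
columns: S'(0) replaces H by 1, S'(1) replaces H by 0, and S'(H) marks the
heterozygous rows. Row-wise this codes the calls 0, 1, H as the triplets
(0,0,0), (1,1,0) and (1,0,1). Any two of the three expanded columns of one
SNP are always four-gamete compatible with each other, which is why a
two-of-three column selection (see :mod:`htreeqa.compatibility`) can certify
a tristate semi-perfect phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import HET, MAJOR, MINOR, MISSING

#: expanded-column kinds, in the fixed order (S'(0), S'(1), S'(H))
KINDS = ("s0", "s1", "sH")


@dataclass(frozen=True)
class ExpandedTriple:
    """The three binary columns S'(0), S'(1), S'(H) of one genotype column."""

    s0: np.ndarray
    s1: np.ndarray
    sH: np.ndarray

    def by_kind(self, kind: str) -> np.ndarray:
        return {"s0": self.s0, "s1": self.s1, "sH": self.sH}[kind]

    def masks(self) -> tuple[int, int, int]:
        """The three columns as row bitmasks (bit i set = row i carries 1)."""
        return (_mask(self.s0), _mask(self.s1), _mask(self.sH))


def _mask(column: np.ndarray) -> int:
    out = 0
    for i in np.flatnonzero(column):
        out |= 1 << int(i)
    return out


def expand_column(column: np.ndarray) -> ExpandedTriple:
    """Expand one genotype column (codes over {0, 1, H}) into its triple.

    Raises if a missing call is present: filter markers first.
    """
    column = np.asarray(column)
    if (column == MISSING).any():
        raise ValueError("cannot expand a column with missing calls; filter first")
    bad = ~np.isin(column, (MAJOR, MINOR, HET))
    if bad.any():
        raise ValueError(f"invalid call code {column[bad][0]}")
    s0 = ((column == MINOR) | (column == HET)).astype(np.uint8)
    s1 = (column == MINOR).astype(np.uint8)
    sH = (column == HET).astype(np.uint8)
    return ExpandedTriple(s0=s0, s1=s1, sH=sH)


def four_gamete_pass(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff the two binary columns show at most three of the four
    row-wise allele pairs {00, 01, 10, 11}.

    Only observed rows count (no phantom gametes), so columns of length one
    and constant columns always pass.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("four_gamete_pass needs two equal-length 1-D columns")
    seen = np.zeros(4, dtype=bool)
    seen[2 * a + b] = True
    return int(seen.sum()) <= 3


def four_gamete_pass_masks(ma: int, mb: int, full: int) -> bool:
    """Bitmask form of the four-gamete test.

    ``full`` has one bit set per row; ``ma``/``mb`` mark the rows carrying 1.
    """
    n_pairs = (
        ((ma & mb) != 0)
        + ((ma & ~mb & full) != 0)
        + ((~ma & mb & full) != 0)
        + ((~ma & ~mb & full) != 0)
    )
    return n_pairs <= 3
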