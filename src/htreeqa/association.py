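"""Tree-partition association testing.

Removing x distinct edges from an interval's phylogeny partitions the
samples into x + 1 groups. Each partition G is scored with the ratio of
between-group to within-group sums of squares,

    F(G) = sum_j t_j (Xbar_j - Xbar)^2  /  sum_j sum_i (X_ij - Xbar_j)^2,

with no degrees-of-freedom scaling. For a nominal p-value
the statistic is rescaled to the classical one-way ANOVA F with
(p - 1, t - p) degrees of freedom, or a label-permutation p-value is used.
Partitions with different group counts are compared by nominal p-value, not
by the raw ratio, which lacks df normalization. A partition that separates
the phenotype perfectly (zero within-group sum of squares with non-zero
between) has no finite F; its parametric p is a flagged sentinel that sorts
below every achievable parametric p-value, leaving genome-wide permutation
as the authoritative significance source for such hits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy import stats

from .compatibility import CompatibleInterval
from .genodata import GenotypeMatrix, PhenotypeVector
from .phylogeny import SemiPerfectTree, build_tristate_tree

#: sentinel nominal p for degenerate perfect separation; sorts below any
#: achievable parametric p-value (those are clipped at PARAMETRIC_MIN_P)
DEGENERATE_P = 5e-324
PARAMETRIC_MIN_P = 1e-300

#: relative tolerance deciding that a within-group sum of squares is zero
_SS_RTOL = 1e-12


@dataclass(frozen=True)
class ScanConfig:
    """Parameters shared by interval scoring and the genome-wide scan."""

    n_perm: int = 1000          # genome-wide FWER permutations
    alpha: float = 0.05         # FWER level for the significance threshold
    max_cut: int = 2            # max edges removed per partition
    min_group: int = 1          # min samples per partition group
    p_mode: Literal["parametric", "permutation"] = "parametric"
    n_perm_nominal: int = 200   # shuffles for per-partition permutation p
    seed: int = 0
    add_one: bool = False       # (n+1)/(nPerm+1) correction for permutation p
    max_interval_width: int | None = None

    def __post_init__(self) -> None:
        if self.max_cut < 1 or self.min_group < 1:
            raise ValueError("max_cut and min_group must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class Partition:
    """Disjoint sample groups induced by removing a set of tree edges."""

    groups: tuple[tuple[int, ...], ...]
    removed_edges: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def assignment(self, n_samples: int) -> np.ndarray:
        """Group index per sample (-1 for samples in no group)."""
        out = np.full(n_samples, -1, dtype=np.int32)
        for g, members in enumerate(self.groups):
            out[list(members)] = g
        return out


@dataclass
class AssociationResult:
    interval: CompatibleInterval
    best_partition: Partition | None
    f_value: float
    nominal_p: float
    method: str
    degenerate: bool = False
    n_partitions: int = 0
    #: per removed edge, the (marker index, expanded-column kind) label set
    removed_edge_labels: tuple[tuple[tuple[object, str], ...], ...] = ()


def enumerate_partitions(
    tree: SemiPerfectTree, max_cut: int = 2, min_group: int = 1
) -> Iterator[Partition]:
    """All partitions from removing 1..max_cut distinct edges, keeping only
    those whose every group holds at least ``min_group`` samples.

    Deterministic order: number of removed edges ascending, then edge-index
    combinations lexicographically.
    """
    if max_cut < 1 or min_group < 1:
        raise ValueError("max_cut and min_group must be >= 1")
    n_edges = tree.n_edges
    for x in range(1, max_cut + 1):
        for combo in itertools.combinations(range(n_edges), x):
            groups = tree.partition_groups(combo)
            if all(len(g) >= min_group for g in groups):
                yield Partition(groups=groups, removed_edges=combo)


# ---------------------------------------------------------------------------
# partition sums of squares
# ---------------------------------------------------------------------------

def _group_sums(values: np.ndarray, labels: np.ndarray, p: int):
    """Between/within sums of squares for one phenotype vector."""
    counts = np.bincount(labels, minlength=p).astype(float)
    if (counts == 0).any():
        raise ValueError("empty group in partition")
    sums = np.bincount(labels, weights=values, minlength=p)
    total = values.sum()
    t = values.size
    sst = float(((values - total / t) ** 2).sum())
    between = float((sums**2 / counts).sum() - total**2 / t)
    between = max(between, 0.0)
    within = max(sst - between, 0.0)
    return between, within, sst, counts


def f_statistic(
    partition: Partition, phenotype: PhenotypeVector
) -> tuple[float, bool]:
    """The raw between/within sum-of-squares ratio plus degeneracy flag.

    Returns (inf, True) for perfect separation (zero within-group variance
    with non-zero between), and (0.0, False) when both sums are zero
    (constant phenotype).
    """
    if partition.n_groups < 2:
        raise ValueError("need at least two groups")
    values, labels = _scored_arrays(partition, phenotype)
    between, within, sst, _ = _group_sums(values, labels, partition.n_groups)
    if within <= _SS_RTOL * max(sst, 1.0):
        if between <= _SS_RTOL * max(sst, 1.0):
            return 0.0, False
        return float("inf"), True
    return between / within, False


def _scored_arrays(partition: Partition, phenotype: PhenotypeVector):
    """Phenotype values and group labels over the scored (non-missing)
    samples; raises if a group loses all its samples."""
    n = len(phenotype)
    assign = partition.assignment(n)
    scored = (assign >= 0) & np.isfinite(phenotype.values)
    values = phenotype.values[scored]
    labels = assign[scored]
    if values.size == 0:
        raise ValueError("no phenotyped samples in partition")
    present = np.bincount(labels, minlength=partition.n_groups)
    if (present == 0).any():
        raise ValueError("empty group in partition")
    return values, labels


def parametric_p_from_ss(
    between: float, within: float, sst: float, p: int, t: int
) -> tuple[float, bool]:
    """(nominal p, degenerate flag) from the classical df-scaled F-test."""
    if t <= p:
        raise ValueError(
            f"parametric F-test needs more samples ({t}) than groups ({p}); "
            "use permutation mode"
        )
    scale = max(sst, 1.0)
    if within <= _SS_RTOL * scale:
        if between <= _SS_RTOL * scale:
            return 1.0, False
        return DEGENERATE_P, True
    f_scaled = (between / (p - 1)) / (within / (t - p))
    return max(float(stats.f.sf(f_scaled, p - 1, t - p)), PARAMETRIC_MIN_P), False


def nominal_p(
    partition: Partition,
    phenotype: PhenotypeVector,
    mode: Literal["parametric", "permutation"] = "parametric",
    n_perm: int = 1000,
    rng_seed: int = 0,
    *,
    add_one: bool = False,
) -> float:
    """Nominal p-value of one partition.

    Parametric mode applies the df-scaled one-way ANOVA F-test; it requires
    more samples than groups and returns the flagged sentinel
    :data:`DEGENERATE_P` under perfect separation. Permutation mode reports
    the fraction of ``n_perm`` label shuffles whose ratio statistic reaches
    the observed one (optionally with the (n+1)/(nPerm+1) correction).
    """
    values, labels = _scored_arrays(partition, phenotype)
    p = partition.n_groups
    t = values.size
    between, within, sst, _ = _group_sums(values, labels, p)
    if mode == "parametric":
        return parametric_p_from_ss(between, within, sst, p, t)[0]
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")

    def ratio(b: float, w: float) -> float:
        scale = max(sst, 1.0)
        if w <= _SS_RTOL * scale:
            return 0.0 if b <= _SS_RTOL * scale else float("inf")
        return b / w

    observed = ratio(between, within)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(values)
        b, w, _, _ = _group_sums(shuffled, labels, p)
        if ratio(b, w) >= observed:
            count += 1
    if add_one:
        return (count + 1) / (n_perm + 1)
    return count / n_perm


def scan_interval(
    matrix: GenotypeMatrix,
    interval: CompatibleInterval,
    phenotype: PhenotypeVector,
    config: ScanConfig | None = None,
    *,
    tree: SemiPerfectTree | None = None,
) -> AssociationResult:
    """Best partition of one compatible interval.

    Builds the tristate tree, enumerates partitions under the config caps,
    scores each, and returns the minimum nominal p-value. Ties break toward
    fewer removed edges, then lexicographically smaller edge-index sets
    (which is the enumeration order). Partitions whose every group cannot be
    scored (a group containing only phenotype-missing samples) are skipped.
    """
    config = config or ScanConfig()
    tree = tree or build_tristate_tree(matrix, interval)
    best: AssociationResult | None = None
    n_scored = 0
    for part in enumerate_partitions(tree, config.max_cut, config.min_group):
        try:
            values, labels = _scored_arrays(part, phenotype)
        except ValueError:
            continue
        p = part.n_groups
        t = values.size
        if config.p_mode == "parametric" and t <= p:
            continue
        between, within, sst, _ = _group_sums(values, labels, p)
        if config.p_mode == "parametric":
            pval, degen = parametric_p_from_ss(between, within, sst, p, t)
        else:
            pval = nominal_p(
                part,
                phenotype,
                mode="permutation",
                n_perm=config.n_perm_nominal,
                rng_seed=config.seed,
                add_one=config.add_one,
            )
            degen = within <= _SS_RTOL * max(sst, 1.0) and between > _SS_RTOL * max(
                sst, 1.0
            )
        fval = (
            float("inf")
            if degen
            else (between / within if within > 0 else 0.0)
        )
        n_scored += 1
        if best is None or pval < best.nominal_p:
            best = AssociationResult(
                interval=interval,
                best_partition=part,
                f_value=fval,
                nominal_p=pval,
                method=config.p_mode,
                degenerate=degen,
                removed_edge_labels=tuple(
                    tree.edges[e].labels for e in part.removed_edges
                ),
            )
    if best is None:
        # no scorable partition (e.g. a single-node tree): null result
        best = AssociationResult(
            interval=interval,
            best_partition=None,
            f_value=0.0,
            nominal_p=1.0,
            method=config.p_mode,
        )
    best.n_partitions = n_scored
    return best
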