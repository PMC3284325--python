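"""Genome-wide scan with permutation control of the family-wise error rate.

The scan computes all maximal compatible intervals and their tristate trees
once; permutations only shuffle the phenotype values across individuals and
re-score the same partitions. For each permutation the genome-wide minimum
nominal p-value is recorded; the corrected p-value of the observed scan is
the proportion of permutations whose minimum is at least as significant
(ties count toward significance, which is conservative), and the empirical
alpha-quantile of the permutation minima is the nominal-p threshold at
family-wise level alpha.

Each permutation draws its shuffle from a stream spawned deterministically
from the master seed, so results are bit-reproducible and independent of
evaluation order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .association import (
    DEGENERATE_P,
    PARAMETRIC_MIN_P,
    _SS_RTOL,
    AssociationResult,
    Partition,
    ScanConfig,
    enumerate_partitions,
)
from .compatibility import CompatContext, CompatibleInterval, enumerate_maximal_intervals
from .genodata import GenotypeMatrix, PhenotypeVector
from .phylogeny import SemiPerfectTree, build_tristate_tree


@dataclass
class ScanPrep:
    """Phenotype-independent scan state: intervals, trees and partitions.

    Computed once per genotype matrix and reused across permutations (and
    across phenotypes drawn on the same genotypes); ``counters`` instruments
    how much structural work was done.
    """

    intervals: list[CompatibleInterval]
    trees: list[SemiPerfectTree]
    partitions: list[list[Partition]]
    counters: dict[str, int] = field(default_factory=dict)


@dataclass
class ScanResult:
    """Genome scan output: per-interval results plus FWER quantities."""

    results: list[AssociationResult]
    observed_min_p: float
    perm_min_ps: np.ndarray
    corrected_p: float
    threshold_at_alpha: float
    config: ScanConfig
    counters: dict[str, int] = field(default_factory=dict)


def prepare_scan(matrix: GenotypeMatrix, config: ScanConfig | None = None) -> ScanPrep:
    """Enumerate maximal compatible intervals, build every tristate tree,
    and pre-enumerate the candidate partitions."""
    config = config or ScanConfig()
    context = CompatContext(matrix)
    intervals = enumerate_maximal_intervals(
        matrix, max_width=config.max_interval_width, context=context
    )
    trees = [build_tristate_tree(matrix, iv) for iv in intervals]
    partitions = [
        list(enumerate_partitions(tree, config.max_cut, config.min_group))
        for tree in trees
    ]
    return ScanPrep(
        intervals=intervals,
        trees=trees,
        partitions=partitions,
        counters={
            "intervals": len(intervals),
            "trees_built": len(trees),
            "partitions_enumerated": sum(len(p) for p in partitions),
        },
    )


def _pvalues_for_labels(
    Y: np.ndarray, sst: float, labels: np.ndarray, p: int, config: ScanConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nominal p per phenotype row for one partition (vectorized).

    ``Y`` is (rows x scored samples); every row is a permutation of row 0 so
    the total sum of squares ``sst`` is shared. Returns (pvals, f_eq1,
    degenerate) arrays over rows; ``f_eq1`` is the unscaled between/within
    ratio.
    """
    t = Y.shape[1]
    counts = np.bincount(labels, minlength=p).astype(float)
    onehot = np.zeros((t, p))
    onehot[np.arange(t), labels] = 1.0
    sums = Y @ onehot
    total = Y[0].sum()
    between = (sums**2 / counts).sum(axis=1) - total**2 / t
    np.clip(between, 0.0, None, out=between)
    within = np.clip(sst - between, 0.0, None)

    scale = max(sst, 1.0)
    zero_within = within <= _SS_RTOL * scale
    zero_between = between <= _SS_RTOL * scale
    degenerate = zero_within & ~zero_between

    f_eq1 = np.where(zero_within, np.where(zero_between, 0.0, np.inf), 0.0)
    ok = ~zero_within
    ratio = np.zeros_like(between)
    np.divide(between, within, where=ok, out=ratio)
    f_eq1 = np.where(ok, ratio, f_eq1)

    if config.p_mode == "parametric":
        if t <= p:
            raise ValueError(
                f"parametric F-test needs more samples ({t}) than groups ({p})"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            f_scaled = (between / (p - 1)) / np.where(zero_within, np.nan, within / (t - p))
        pvals = np.empty(Y.shape[0])
        ok = ~zero_within
        pvals[ok] = np.maximum(
            stats.f.sf(f_scaled[ok], p - 1, t - p), PARAMETRIC_MIN_P
        )
        pvals[zero_within & zero_between] = 1.0
        pvals[degenerate] = DEGENERATE_P
    else:
        n_perm = Y.shape[0] - 1
        perm_sorted = np.sort(f_eq1[1:])
        count_ge = n_perm - np.searchsorted(perm_sorted, f_eq1, side="left")
        if config.add_one:
            pvals = (count_ge + 1) / (n_perm + 1)
        else:
            pvals = count_ge / n_perm
    return pvals, f_eq1, degenerate


def genome_scan(
    matrix: GenotypeMatrix,
    phenotype: PhenotypeVector,
    config: ScanConfig | None = None,
    *,
    precomputed: ScanPrep | None = None,
) -> ScanResult:
    """Full genome scan with permutation FWER control.

    Scores the observed phenotype and ``config.n_perm`` shuffles against the
    same trees and partitions; intervals and trees are never rebuilt for a
    permutation. Fully reproducible for a fixed ``config.seed``.
    """
    config = config or ScanConfig()
    if config.n_perm < 20:
        warnings.warn(
            f"n_perm={config.n_perm} gives coarse p-value granularity",
            stacklevel=2,
        )
    prep = precomputed if precomputed is not None else prepare_scan(matrix, config)
    if not prep.intervals:
        raise ValueError("no compatible intervals found (empty matrix?)")

    values = np.asarray(phenotype.values, dtype=float)
    if len(values) != matrix.n_samples:
        raise ValueError("phenotype length does not match genotype samples")
    scored = np.isfinite(values)
    t = int(scored.sum())
    if t < 3:
        raise ValueError("need at least three phenotyped samples")

    base = values[scored]
    n_perm = config.n_perm
    Y = np.empty((n_perm + 1, t))
    Y[0] = base
    streams = np.random.SeedSequence(config.seed).spawn(n_perm)
    for r, child in enumerate(streams, start=1):
        Y[r] = np.random.default_rng(child).permutation(base)
    sst = float(((base - base.mean()) ** 2).sum())

    running_min = np.ones(n_perm + 1)
    results: list[AssociationResult] = []
    cache: dict[tuple[int, bytes], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    n_scored = 0

    for iv, tree, parts in zip(prep.intervals, prep.trees, prep.partitions):
        best: AssociationResult | None = None
        for part in parts:
            labels = part.assignment(matrix.n_samples)[scored]
            if (labels < 0).any():
                continue  # partition does not cover all scored samples
            if (np.bincount(labels, minlength=part.n_groups) == 0).any():
                continue  # a group lost every phenotyped sample
            p = part.n_groups
            if config.p_mode == "parametric" and t <= p:
                continue
            key = (p, labels.tobytes())
            got = cache.get(key)
            if got is None:
                got = _pvalues_for_labels(Y, sst, labels, p, config)
                cache[key] = got
                running_min = np.minimum(running_min, got[0])
            pvals, f_eq1, degen = got
            n_scored += 1
            if best is None or pvals[0] < best.nominal_p:
                fval = float(f_eq1[0])
                best = AssociationResult(
                    interval=iv,
                    best_partition=part,
                    f_value=fval,
                    nominal_p=float(pvals[0]),
                    method=config.p_mode,
                    degenerate=bool(degen[0]),
                    removed_edge_labels=tuple(
                        tree.edges[e].labels for e in part.removed_edges
                    ),
                )
        if best is None:
            best = AssociationResult(
                interval=iv,
                best_partition=None,
                f_value=0.0,
                nominal_p=1.0,
                method=config.p_mode,
            )
        best.n_partitions = sum(1 for _ in parts)
        results.append(best)

    observed_min_p = min(r.nominal_p for r in results)
    perm_min_ps = running_min[1:]
    corrected_p = float((perm_min_ps <= observed_min_p).sum() / n_perm)
    threshold_at_alpha = _lower_quantile(perm_min_ps, config.alpha)

    counters = dict(prep.counters)
    counters["partitions_scored"] = n_scored
    counters["distinct_partitions"] = len(cache)
    return ScanResult(
        results=results,
        observed_min_p=float(observed_min_p),
        perm_min_ps=perm_min_ps,
        corrected_p=corrected_p,
        threshold_at_alpha=float(threshold_at_alpha),
        config=config,
        counters=counters,
    )


def _lower_quantile(xs: np.ndarray, alpha: float) -> float:
    """Type-1 (lower) empirical alpha-quantile."""
    xs = np.sort(np.asarray(xs))
    h = max(1, math.ceil(alpha * xs.size))
    return float(xs[h - 1])
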