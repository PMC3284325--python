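"""Synthetic genotypes, phenotypes, and QTL-detection scoring.

Genotypes are drawn from a founder-mosaic model emulating a multiparental
(Collaborative-Cross-like) population: a small set of random binary founder
haplotypes, and per individual two gametes that each copy founder segments
with rare switch points. Low per-marker recombination rates yield long
shared founder blocks, which is what makes multi-SNP compatible intervals
exist; residual heterozygosity is tuned by partially coupling the two
gametes of an individual, mimicking incomplete inbreeding.

Phenotypes follow the standard variance-partition formulas. For the
additive model

    y_i = sqrt(1 - pi) * N(0, 1) + Q_i * sqrt(pi / (2 p (1 - p))),

with Q_i in {-1, 0, +1} for homozygous wild-type / heterozygous / homozygous
mutant and p the (empirical) minor allele frequency of the causative SNP,
so pi is the fraction of phenotypic variance attributable to the locus. The
recessive and overdominant models use Q'_i in {0, 1} (homozygous mutant,
respectively heterozygous carriers) with coefficient
sqrt(pi / (2 p' (1 - p'))) where p' is the fraction of homozygous mutants;
``variance_exact=True`` substitutes sqrt(pi / (c (1 - c))) with c the
carrier fraction of Q', which makes the explained-variance fraction exactly
pi for the binary codings as well.

The causative SNP is drawn among markers with minor allele frequency above
``maf_floor`` and is removed from the analysis matrix; a detected interval
counts as a true positive when it contains a marker within ``window_snps``
pre-masking marker indices of the causative SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .genodata import HET, MAJOR, MINOR, GenotypeMatrix, PhenotypeVector
from .fwer import ScanResult

Model = Literal["additive", "recessive", "overdominant"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated case.

    Defaults mirror the simulation design the method was evaluated under:
    170 individuals, 10,000 SNPs, causative SNP drawn above a 0.15 minor
    allele frequency floor, an eight-founder mosaic with about one founder
    switch per thousand markers, and 16% residual heterozygosity.
    """

    model: Model = "additive"
    pi: float = 0.25
    n_samples: int = 170
    n_snps: int = 10_000
    maf_floor: float = 0.15
    n_founders: int = 8
    recomb_rate: float = 0.001
    founder_block_rate: float = 0.02
    het_target: float = 0.16
    seed: int = 0
    variance_exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.n_founders < 2:
            raise ValueError("need at least two founders")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated case (pre-masking coordinates)."""

    causative_index: int
    marker_id: str
    model: Model
    pi: float
    q: tuple[float, ...]  # per-sample causative coding


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _tree_consistent_founders(
    rng: np.random.Generator, nf: int, m: int, block_rate: float
) -> np.ndarray:
    """Founder haplotypes (nf x m) whose columns are tree splits.

    Markers are grouped into geometric blocks; each block draws a random
    rooted founder genealogy (node i attaches below a uniform earlier node)
    and each marker carries the clade indicator of a uniform non-root node,
    so any two columns of a block are nested or disjoint and hence
    four-gamete compatible.
    """
    founders = np.zeros((nf, m), dtype=np.int8)
    j = 0
    while j < m:
        # clade membership per node of a fresh random genealogy
        clades = np.zeros((nf, nf), dtype=bool)
        for node in range(nf):
            clades[node, node] = True
        for node in range(nf - 1, 0, -1):
            parent = int(rng.integers(0, node))
            clades[parent] |= clades[node]
        block_len = int(rng.geometric(min(block_rate, 1.0))) if block_rate > 0 else m
        end = min(m, j + max(block_len, 1))
        for jj in range(j, end):
            v = int(rng.integers(1, nf)) if nf > 1 else 0
            founders[:, jj] = clades[v].astype(np.int8)
        j = end
    return founders


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Founder-mosaic diploid genotypes on one chromosome.

    Founder haplotypes are locally tree-consistent: markers fall into
    founder-LD blocks (geometric lengths, ``founder_block_rate`` per
    marker); within a block every marker is a random clade split of one
    random founder genealogy, so founder columns of a block are mutually
    four-gamete compatible. Sample-level incompatibilities therefore come
    from mosaic recombination and block boundaries, exactly the two ways a
    recombination-limited population breaks local phylogenies, which is
    what makes multi-SNP compatible intervals exist.

    The two gametes of an individual share their switch points (segments are
    co-inherited under partial inbreeding); at each new segment the second
    gamete copies the first gamete's founder except with the decoupling
    probability that calibrates the expected matrix heterozygosity to
    ``het_target``, in which case it draws an independent founder. The
    genotype is H where the two gamete alleles disagree. The returned matrix
    is allele-normalized.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, m, nf = config.n_samples, config.n_snps, config.n_founders
    founders = _tree_consistent_founders(rng, nf, m, config.founder_block_rate)

    # heterozygosity = P(gametes carry different founders) x mean allele
    # disagreement between two distinct founders; the first factor is
    # decouple * (nf-1)/nf, the second is measured on the realized founders
    diff = 0.0
    for a in range(nf):
        for b in range(a + 1, nf):
            diff += float((founders[a] != founders[b]).mean())
    diff /= nf * (nf - 1) / 2
    expected_het = (1.0 - 1.0 / nf) * diff
    decouple = min(config.het_target / expected_het, 1.0) if expected_het > 0 else 0.0
    hap = np.empty((2, n, m), dtype=np.int8)
    f1 = np.zeros(n, dtype=np.int64)
    f2 = np.zeros(n, dtype=np.int64)
    for j in range(m):
        if j == 0:
            switch = np.ones(n, dtype=bool)
        else:
            switch = rng.random(n) < config.recomb_rate
        new1 = rng.integers(0, nf, size=n)
        new2 = rng.integers(0, nf, size=n)
        indep = rng.random(n) < decouple
        f1 = np.where(switch, new1, f1)
        f2 = np.where(switch, np.where(indep, new2, new1), f2)
        hap[0, :, j] = founders[f1, j]
        hap[1, :, j] = founders[f2, j]

    calls = np.where(
        hap[0] == hap[1], np.where(hap[0] == 1, MINOR, MAJOR), HET
    ).astype(np.int8)
    markers = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1, dtype=np.int64) * 1000,
        }
    )
    samples = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(samples, markers, calls, normalize=True)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def causative_coding(calls: np.ndarray, model: Model) -> np.ndarray:
    """Per-sample Q coding of one genotype column under a genetic model."""
    if model == "additive":
        q = np.where(calls == MINOR, 1.0, np.where(calls == HET, 0.0, -1.0))
    elif model == "recessive":
        q = (calls == MINOR).astype(float)
    elif model == "overdominant":
        q = (calls == HET).astype(float)
    else:
        raise ValueError(f"unknown model {model!r}")
    return q


def pick_causative(
    matrix: GenotypeMatrix, config: SimConfig, *, seed: int | None = None
) -> TruthRecord:
    """Draw the causative SNP uniformly among markers with MAF above the
    floor and record its per-sample coding."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 1])
    )
    maf = matrix.minor_allele_frequency()
    eligible = np.flatnonzero(maf > config.maf_floor)
    if eligible.size == 0:
        raise ValueError(f"no marker with MAF > {config.maf_floor}")
    j = int(rng.choice(eligible))
    q = causative_coding(matrix.column(j), config.model)
    return TruthRecord(
        causative_index=int(matrix.markers["orig_index"].iloc[j]),
        marker_id=str(matrix.markers["id"].iloc[j]),
        model=config.model,
        pi=config.pi,
        q=tuple(float(x) for x in q),
    )


def genetic_coefficient(
    calls: np.ndarray, model: Model, pi: float, *, variance_exact: bool = False
) -> float:
    """The scale multiplying Q in the phenotype formula."""
    m = calls.size
    if model == "additive":
        p = float((2 * (calls == MINOR).sum() + (calls == HET).sum()) / (2 * m))
        if p <= 0.0 or p >= 1.0:
            raise ValueError("causative marker is monomorphic (p in {0, 1})")
        return float(np.sqrt(pi / (2.0 * p * (1.0 - p))))
    p_hom = float((calls == MINOR).mean())
    if variance_exact:
        carrier = float(causative_coding(calls, model).mean())
        if carrier <= 0.0 or carrier >= 1.0:
            raise ValueError("causative coding is constant")
        return float(np.sqrt(pi / (carrier * (1.0 - carrier))))
    if p_hom <= 0.0 or p_hom >= 1.0:
        raise ValueError("homozygous-mutant fraction p' in {0, 1}")
    return float(np.sqrt(pi / (2.0 * p_hom * (1.0 - p_hom))))


def simulate_phenotype(
    matrix: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    *,
    seed: int | None = None,
) -> PhenotypeVector:
    """Phenotype from the configured genetic model at the causative SNP.

    A pure function of (matrix, truth, seed): the environmental noise is
    sqrt(1 - pi) * N(0, 1) and the genetic term is Q times the model
    coefficient. The matrix must still contain the causative marker.
    """
    where = np.flatnonzero(
        matrix.markers["orig_index"].to_numpy() == truth.causative_index
    )
    if where.size != 1:
        raise ValueError(
            f"causative marker (orig index {truth.causative_index}) not in matrix"
        )
    calls = matrix.column(int(where[0]))
    q = causative_coding(calls, truth.model)
    coef = genetic_coefficient(
        calls, truth.model, truth.pi, variance_exact=config.variance_exact
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 2])
    )
    noise = rng.standard_normal(matrix.n_samples)
    values = np.sqrt(1.0 - truth.pi) * noise + q * coef
    return PhenotypeVector(values, matrix.samples, name=f"sim_{truth.model}")


def mask_causative(matrix: GenotypeMatrix, truth: TruthRecord) -> GenotypeMatrix:
    """Remove the causative column; pre-masking indices survive in the
    ``orig_index`` marker metadata."""
    where = np.flatnonzero(
        matrix.markers["orig_index"].to_numpy() == truth.causative_index
    )
    if where.size == 0:
        raise ValueError(
            f"causative marker (orig index {truth.causative_index}) already masked"
        )
    keep = [j for j in range(matrix.n_markers) if j != int(where[0])]
    return matrix.subset_markers(keep)


def simulate_case(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord]:
    """Genotypes, phenotype and truth for one replicate; the returned matrix
    has the causative SNP masked."""
    full = simulate_genotypes(config)
    truth = pick_causative(full, config)
    pheno = simulate_phenotype(full, truth, config)
    masked = mask_causative(full, truth)
    return masked, pheno, truth


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionOutcome:
    """Per-replicate detection bookkeeping."""

    n_reported: int
    n_true_positive: int
    truth_detected: bool


def score_detection(
    scan: ScanResult,
    truth: TruthRecord,
    matrix: GenotypeMatrix,
    *,
    window_snps: int = 50,
) -> DetectionOutcome:
    """Score one replicate's scan against the simulated truth.

    Reported QTL are intervals whose nominal p-value is at or below the
    scan's FWER threshold. A reported interval is a true positive when it
    contains a marker within ``window_snps`` pre-masking marker indices of
    the causative SNP.
    """
    orig = matrix.markers["orig_index"].to_numpy()
    n_reported = 0
    n_tp = 0
    for res in scan.results:
        if res.nominal_p > scan.threshold_at_alpha:
            continue
        n_reported += 1
        span = orig[res.interval.ref.u : res.interval.ref.v + 1]
        if np.abs(span - truth.causative_index).min() <= window_snps:
            n_tp += 1
    return DetectionOutcome(
        n_reported=n_reported,
        n_true_positive=n_tp,
        truth_detected=n_tp > 0,
    )


def aggregate(outcomes: Iterable[DetectionOutcome]) -> dict[str, float]:
    """Precision, recall and F1 over replicates (0/0 conventions -> 0).

    Precision counts every reported interval; recall counts replicates whose
    simulated causative SNP was covered by at least one true positive; F1 is
    the harmonic mean of the two.
    """
    outcomes = list(outcomes)
    total_reported = sum(o.n_reported for o in outcomes)
    total_tp = sum(o.n_true_positive for o in outcomes)
    n_truth = len(outcomes)
    precision = total_tp / total_reported if total_reported else 0.0
    recall = (
        sum(o.truth_detected for o in outcomes) / n_truth if n_truth else 0.0
    )
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}
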