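"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from htreeqa import GenotypeMatrix, PhenotypeVector, read_genotypes_tsv

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")
from htreeqa.expansion import expand_column, four_gamete_pass
from htreeqa.genodata import HET, MAJOR, MINOR

DATA = Path(__file__).parent / "data"

SAMPLES5 = ("A", "B", "C", "D", "E")


@pytest.fixture(scope="session")
def worked_matrix() -> GenotypeMatrix:
    """The five-sample, five-marker worked example (recessive trait on the
    second marker; C and E carry the low phenotype)."""
    return read_genotypes_tsv(DATA / "worked_example_genotypes.tsv")


@pytest.fixture(scope="session")
def worked_phenotype(worked_matrix) -> PhenotypeVector:
    return PhenotypeVector(
        np.array([10.0, 10.0, 2.0, 10.0, 2.0]), worked_matrix.samples
    )


def make_matrix(
    rows: list[str], *, chrom: str | list[str] = "1", normalize: bool = False
) -> GenotypeMatrix:
    """Genotype matrix from per-sample call strings like '0H1'."""
    code = {"0": MAJOR, "1": MINOR, "H": HET, "N": -1}
    calls = np.array([[code[c] for c in r] for r in rows], dtype=np.int8)
    n_markers = calls.shape[1]
    chroms = [chrom] * n_markers if isinstance(chrom, str) else list(chrom)
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(n_markers)],
            "chrom": chroms,
            "pos": np.arange(1, n_markers + 1) * 10,
        }
    )
    samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(samples, markers, calls, normalize=normalize)


def random_genotype_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_markers: int,
    p_het: float = 0.3,
) -> GenotypeMatrix:
    calls = rng.choice(
        np.array([MAJOR, MINOR, HET], dtype=np.int8),
        size=(n_samples, n_markers),
        p=[(1 - p_het) * 0.55, (1 - p_het) * 0.45, p_het],
    )
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(n_markers)],
            "chrom": ["1"] * n_markers,
            "pos": np.arange(1, n_markers + 1) * 10,
        }
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)], markers, calls, normalize=False
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

KEPT = ((0, 1), (0, 2), (1, 2))


def brute_force_compatible(matrix: GenotypeMatrix, u: int, v: int) -> bool:
    """Exhaustive 3^n check over all two-of-three column selections."""
    triples = [expand_column(matrix.column(j)) for j in range(u, v + 1)]
    cols = [(t.s0, t.s1, t.sH) for t in triples]
    n = len(cols)
    for choice in itertools.product(range(3), repeat=n):
        kept = []
        for k, c in enumerate(choice):
            a, b = KEPT[c]
            kept.append(cols[k][a])
            kept.append(cols[k][b])
        ok = True
        for x in range(len(kept)):
            for y in range(x + 1, len(kept)):
                if not four_gamete_pass(kept[x], kept[y]):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return True
    return False


def quadratic_maximal_intervals(matrix: GenotypeMatrix) -> set[tuple[int, int]]:
    """All maximal compatible intervals by testing every interval."""
    from htreeqa import decide_compatibility

    n = matrix.n_markers
    compat = {}
    for u in range(n):
        for v in range(u, n):
            try:
                ref = matrix.interval(u, v)
            except ValueError:
                compat[(u, v)] = False
                continue
            compat[(u, v)] = decide_compatibility(matrix, ref) is not None
    out = set()
    for (u, v), ok in compat.items():
        if not ok:
            continue
        wider = (u > 0 and compat.get((u - 1, v), False)) or (
            v < n - 1 and compat.get((u, v + 1), False)
        )
        if not wider:
            out.add((u, v))
    return out


def anova_sums(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Naive between/within sums of squares (loop-based oracle)."""
    grand = values.mean()
    between = within = 0.0
    for g in np.unique(labels):
        grp = values[labels == g]
        between += len(grp) * (grp.mean() - grand) ** 2
        within += ((grp - grp.mean()) ** 2).sum()
    return between, within
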