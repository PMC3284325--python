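"""Genotype and phenotype containers with I/O and allele-coding normalization.

Unphased genotype calls are coded over the alphabet {0, 1, H, N}: homozygous
major, homozygous minor, heterozygous, and missing. Internally calls live in
an int8 matrix of shape (n_samples, n_markers) using the codes in
:data:`CALL_CODES`. After normalization the "1" allele is guaranteed to be the
minor allele at every marker (counting each homozygous-minor call twice and
each heterozygote once over twice the non-missing sample count); markers whose
input labels had to be swapped are counted in ``GenotypeMatrix.n_swapped``.

Supported on-disk formats:

* a simple marker-major TSV dialect with header
  ``marker  chrom  pos  <sample1>  <sample2> ...`` and one marker per row,
  calls in {0, 1, H, N};
* VCF v4.x (diploid GT fields only; multi-allelic records are skipped).

Phenotypes are plain two-column TSV files (``sample  value``, header
optional) and are re-ordered to the genotype sample order on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("htreeqa")

MAJOR = 0
MINOR = 1
HET = 2
MISSING = -1

CALL_CODES = {"0": MAJOR, "1": MINOR, "H": HET, "N": MISSING}
CALL_SYMBOLS = {v: k for k, v in CALL_CODES.items()}

MARKER_COLUMNS = ["id", "chrom", "pos"]


class GenotypeParseError(ValueError):
    """Raised when a genotype or phenotype file cannot be parsed."""


@dataclass(frozen=True)
class IntervalRef:
    """A run of consecutive markers on one chromosome.

    ``u`` and ``v`` are 0-based inclusive marker indices into the owning
    :class:`GenotypeMatrix`.
    """

    chrom: str
    u: int
    v: int

    def __post_init__(self) -> None:
        if not (0 <= self.u <= self.v):
            raise ValueError(f"invalid interval bounds u={self.u}, v={self.v}")

    @property
    def width(self) -> int:
        return self.v - self.u + 1

    def marker_range(self) -> range:
        return range(self.u, self.v + 1)


class GenotypeMatrix:
    """Samples x markers genotype matrix over {0, 1, H, missing}.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers (rows).
    markers
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based bp),
        one row per marker (columns of ``calls``). An ``orig_index`` column
        is preserved if present (used to track pre-filtering coordinates)
        and created otherwise.
    calls
        int8 array of shape (n_samples, n_markers) using the codes in
        :data:`CALL_CODES`.
    normalize
        If true (default), relabel alleles marker-wise so that "1" is the
        minor allele; a tie at frequency exactly 0.5 keeps the input labels.
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: pd.DataFrame,
        calls: np.ndarray,
        *,
        normalize: bool = True,
    ) -> None:
        self.samples: tuple[str, ...] = tuple(str(s) for s in samples)
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeParseError("duplicate sample id in genotype input")
        markers = markers.reset_index(drop=True).copy()
        for col in MARKER_COLUMNS:
            if col not in markers.columns:
                raise ValueError(f"marker table missing column {col!r}")
        if "orig_index" not in markers.columns:
            markers["orig_index"] = np.arange(len(markers))
        markers["pos"] = markers["pos"].astype(np.int64)
        self.markers: pd.DataFrame = markers

        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if calls.shape != (len(self.samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(markers)} markers"
            )
        if calls.shape[0] < 1 or calls.shape[1] < 1:
            raise ValueError("need at least one sample and one marker")
        bad = ~np.isin(calls, (MAJOR, MINOR, HET, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"invalid call code {calls[i, j]} at sample "
                f"{self.samples[i]!r}, marker {markers['id'].iloc[j]!r}"
            )
        self.calls: np.ndarray = calls
        self._check_positions_sorted()
        self.n_swapped: int = 0
        if normalize:
            self.n_swapped = self._normalize_inplace()
        self.calls.setflags(write=False)

    # -- construction / validation helpers --------------------------------

    def _check_positions_sorted(self) -> None:
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"marker positions decrease within chromosome {chrom!r}"
                )

    def _normalize_inplace(self) -> int:
        freq = self.minor_allele_frequency()
        swap = freq > 0.5
        n_swap = int(swap.sum())
        if n_swap:
            cols = self.calls[:, swap]
            swapped = cols.copy()
            swapped[cols == MAJOR] = MINOR
            swapped[cols == MINOR] = MAJOR
            self.calls[:, swap] = swapped
        return n_swap

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.calls[:, j]

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of allele "1" over non-missing calls.

        Each homozygous-1 call counts twice, each heterozygote once, over
        two chromosomes per non-missing sample. Markers with no non-missing
        call get frequency 0.
        """
        n1 = (self.calls == MINOR).sum(axis=0)
        nh = (self.calls == HET).sum(axis=0)
        nobs = (self.calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(nobs > 0, (2.0 * n1 + nh) / (2.0 * nobs), 0.0)
        return freq

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def heterozygosity(self) -> float:
        """Fraction of non-missing calls that are heterozygous."""
        obs = self.calls != MISSING
        n_obs = int(obs.sum())
        return float((self.calls == HET).sum() / n_obs) if n_obs else 0.0

    def is_monomorphic(self) -> np.ndarray:
        """Markers whose non-missing calls are all identical (or all missing)."""
        out = np.ones(self.n_markers, dtype=bool)
        for code in (MAJOR, MINOR, HET):
            present = (self.calls == code).any(axis=0)
            others = ((self.calls != code) & (self.calls != MISSING)).any(axis=0)
            out &= ~(present & others)
        return out

    def chromosome_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chrom, first_index, last_index) runs of markers."""
        blocks: list[tuple[str, int, int]] = []
        chroms = self.markers["chrom"].tolist()
        start = 0
        for j in range(1, self.n_markers + 1):
            if j == self.n_markers or chroms[j] != chroms[start]:
                blocks.append((chroms[start], start, j - 1))
                start = j
        return blocks

    def interval(self, u: int, v: int) -> IntervalRef:
        """Build a validated :class:`IntervalRef` over markers [u, v]."""
        if not (0 <= u <= v < self.n_markers):
            raise ValueError(f"interval [{u}, {v}] out of range")
        chroms = set(self.markers["chrom"].iloc[u : v + 1])
        if len(chroms) != 1:
            raise ValueError(f"interval [{u}, {v}] crosses chromosomes {chroms}")
        return IntervalRef(chrom=chroms.pop(), u=u, v=v)

    # -- subsetting ---------------------------------------------------------

    def subset_markers(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(
            self.samples,
            self.markers.iloc[idx],
            self.calls[:, idx].copy(),
            normalize=False,
        )

    def subset_samples(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.markers,
            self.calls[idx, :].copy(),
            normalize=False,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers, "
            f"het={self.heterozygosity():.3f})"
        )


@dataclass
class PhenotypeVector:
    """Quantitative trait values aligned to a genotype matrix's sample order.

    NaN marks a missing phenotype (such samples are kept for tree building
    but dropped from association scoring); infinities are rejected.
    """

    values: np.ndarray
    samples: tuple[str, ...]
    name: str = "phenotype"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.samples = tuple(self.samples)
        if self.values.ndim != 1 or len(self.values) != len(self.samples):
            raise ValueError("phenotype length must equal sample count")
        if np.isinf(self.values).any():
            raise ValueError("phenotype contains non-finite (infinite) values")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# TSV genotype dialect
# ---------------------------------------------------------------------------

def read_genotypes_tsv(path: str | Path, *, normalize: bool = True) -> GenotypeMatrix:
    """Read the marker-major TSV genotype dialect.

    Header row: ``marker  chrom  pos  <sample1> <sample2> ...``; one marker
    per row, calls in {0, 1, H, N}. The returned matrix is allele-normalized
    unless ``normalize=False``; the number of markers whose alleles were
    swapped is recorded in ``n_swapped``.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[0] != "marker":
            raise GenotypeParseError(
                f"{path}: expected header 'marker\\tchrom\\tpos\\t<samples...>'"
            )
        samples = header[3:]
        ids, chroms, poss = [], [], []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            chroms.append(parts[1])
            try:
                poss.append(int(parts[2]))
            except ValueError as exc:
                raise GenotypeParseError(f"{path}:{lineno}: bad position {parts[2]!r}") from exc
            row = []
            for k, sym in enumerate(parts[3:]):
                try:
                    row.append(CALL_CODES[sym])
                except KeyError as exc:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: invalid call symbol {sym!r} for sample "
                        f"{samples[k]!r} at marker {parts[0]!r}"
                    ) from exc
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no marker rows")
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    calls = np.asarray(rows, dtype=np.int8).T  # markers-major file -> samples x markers
    return GenotypeMatrix(samples, markers, calls, normalize=normalize)


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV genotype dialect (inverse of the reader)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("marker\tchrom\tpos\t" + "\t".join(matrix.samples) + "\n")
        for j in range(matrix.n_markers):
            row = matrix.markers.iloc[j]
            syms = [CALL_SYMBOLS[int(c)] for c in matrix.calls[:, j]]
            fh.write(f"{row['id']}\t{row['chrom']}\t{row['pos']}\t" + "\t".join(syms) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | Path, *, normalize: bool = True) -> GenotypeMatrix:
    """Read diploid GT fields from a VCF into a GenotypeMatrix.

    0/0 -> 0, 1/1 -> 1, 0/1 or 1/0 -> H, ./. (or half-missing) -> missing.
    Multi-allelic records are skipped with a warning; haploid or polyploid
    GT fields raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss = [], [], []
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d (%s)",
                variant.CHROM, variant.POS, ",".join(variant.ALT) or ".",
            )
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2:
                raise GenotypeParseError(
                    f"non-diploid GT ({len(alleles)} alleles) at record "
                    f"{variant.CHROM}:{variant.POS}, sample {samples[i]!r}"
                )
            a, b = alleles
            if a < 0 or b < 0:
                row[i] = MISSING
            elif a == 0 and b == 0:
                row[i] = MAJOR
            elif a == 1 and b == 1:
                row[i] = MINOR
            else:
                row[i] = HET
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no usable bi-allelic records")
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(samples, markers, np.vstack(rows).T, normalize=normalize)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype(
    path: str | Path,
    matrix: GenotypeMatrix,
    *,
    drop_missing: bool = False,
    name: str | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a two-column ``sample  value`` TSV and align it to ``matrix``.

    Samples present in the matrix but absent from the file raise unless
    ``drop_missing`` is set, in which case both the matrix and the phenotype
    are reduced consistently to the intersection. Returns the (possibly
    reduced) matrix together with the aligned phenotype.
    """
    path = Path(path)
    table: dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise GenotypeParseError(f"{path}:{lineno}: expected two columns")
            sid, raw = parts
            if lineno == 1 and sid.lower() in {"sample", "id", "sample_id"}:
                continue  # optional header
            try:
                value = float(raw)
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{path}:{lineno}: non-numeric phenotype {raw!r} for sample {sid!r}"
                ) from exc
            if sid in table:
                raise GenotypeParseError(f"{path}:{lineno}: duplicate sample {sid!r}")
            table[sid] = value

    missing = [s for s in matrix.samples if s not in table]
    if missing and not drop_missing:
        raise ValueError(
            f"samples without phenotype: {missing[:5]}{'...' if len(missing) > 5 else ''} "
            "(pass drop_missing=True to drop them)"
        )
    if missing:
        keep = [i for i, s in enumerate(matrix.samples) if s in table]
        matrix = matrix.subset_samples(keep)
    values = np.array([table[s] for s in matrix.samples], dtype=float)
    pheno = PhenotypeVector(values, matrix.samples, name=name or path.stem)
    return matrix, pheno


def write_phenotype(pheno: PhenotypeVector, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s, v in zip(pheno.samples, pheno.values):
            fh.write(f"{s}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def filter_markers(
    matrix: GenotypeMatrix,
    *,
    max_missing: float = 0.0,
    drop_monomorphic: bool = False,
) -> GenotypeMatrix:
    """Drop markers whose missing rate exceeds ``max_missing`` and, optionally,
    monomorphic markers.

    Missing calls are never imputed: downstream compatibility logic is
    defined only on {0, 1, H}, so the default ``max_missing=0`` excludes any
    marker with a missing call. Original marker indices survive in the
    ``orig_index`` metadata column.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    keep = matrix.missing_rate() <= max_missing
    if drop_monomorphic:
        keep &= ~matrix.is_monomorphic()
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_markers: dropped %d of %d markers", n_drop, matrix.n_markers)
    return matrix.subset_markers(np.flatnonzero(keep))
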