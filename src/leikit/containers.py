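"""In-memory containers for genotype, allele-frequency and ranking data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call.  0 is a valid genotype (zero copies
#: of the reference allele), so missingness needs its own code.
MISSING = -1


class LeikitError(Exception):
    """Base class for all leikit errors."""


class ContractError(LeikitError):
    """An input violates a documented container invariant."""


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype codes counting REFERENCE alleles.

    ``codes[i, j]`` is the number of reference alleles (0, 1 or 2) carried by
    sample ``i`` at marker ``j``, or :data:`MISSING`.  Coordinates are
    1-based inclusive, VCF style.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    codes: np.ndarray
    population_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n, L = self.codes.shape
        if n != len(self.sample_ids) or L != len(self.marker_ids):
            raise ContractError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(self.bp) != L or len(self.chrom) != L:
            raise ContractError("marker map length does not match marker_ids")
        valid = (self.codes >= 0) & (self.codes <= 2)
        if not np.all(valid | (self.codes == MISSING)):
            raise ContractError("genotype codes must be in {0,1,2} or MISSING")
        if np.any(self.bp <= 0):
            raise ContractError("bp positions must be positive (1-based)")
        if self.population_labels is not None and len(self.population_labels) != n:
            raise ContractError("population_labels length does not match samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def populations(self) -> list[str]:
        """Sorted unique population names; raises if unlabeled."""
        if self.population_labels is None:
            raise ContractError("genotype matrix has no population labels")
        return sorted(set(self.population_labels))

    def subset_markers(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Return a new matrix restricted to the marker columns in ``index``."""
        idx = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            chrom=self.chrom[idx],
            bp=self.bp[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            codes=self.codes[:, idx],
            population_labels=(
                list(self.population_labels)
                if self.population_labels is not None
                else None
            ),
        )


@dataclass
class PopAlleleFreqTable:
    """Per-marker, per-population reference-allele frequencies.

    ``f[j, p]`` is the reference-allele frequency of marker ``j`` in
    population ``p``; ``c[p]`` the number of diploid individuals sampled
    from population ``p``.
    """

    marker_ids: list[str]
    population_names: list[str]
    f: np.ndarray
    c: np.ndarray
    chrom: np.ndarray | None = None
    bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.c = np.asarray(self.c, dtype=np.int64)
        if len(set(self.population_names)) != len(self.population_names):
            raise ContractError("population names must be unique")
        if self.f.shape != (len(self.marker_ids), len(self.population_names)):
            raise ContractError(
                f"frequency array shape {self.f.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.population_names)} populations"
            )
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ContractError("allele frequencies must lie in [0, 1]")
        if self.c.shape != (len(self.population_names),) or np.any(self.c < 1):
            raise ContractError("every population count c_j must be >= 1")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_populations(self) -> int:
        return len(self.population_names)

    def subset_markers(self, index: np.ndarray | list[int]) -> "PopAlleleFreqTable":
        idx = np.asarray(index, dtype=np.intp)
        return PopAlleleFreqTable(
            marker_ids=[self.marker_ids[i] for i in idx],
            population_names=list(self.population_names),
            f=self.f[idx],
            c=self.c.copy(),
            chrom=self.chrom[idx] if self.chrom is not None else None,
            bp=self.bp[idx] if self.bp is not None else None,
        )


@dataclass
class MarkerScoreVector:
    """Per-marker informativeness scores with a deterministic ranking.

    ``rank`` is a permutation of 1..L with 1 = most informative; ties are
    broken by genomic position (chrom, bp) then marker id so repeated runs
    produce identical output.
    """

    method_name: str
    marker_ids: list[str]
    scores: np.ndarray
    rank: np.ndarray | None = None
    chrom: np.ndarray | None = None
    bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.marker_ids),):
            raise ContractError("scores length does not match marker_ids")
        if self.rank is not None:
            self.rank = np.asarray(self.rank, dtype=np.int64)
            L = len(self.marker_ids)
            if sorted(self.rank.tolist()) != list(range(1, L + 1)):
                raise ContractError("rank must be a permutation of 1..L")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def top(self, n: int) -> list[str]:
        """Marker ids of the ``n`` best-ranked markers, best first."""
        if self.rank is None:
            raise ContractError("ranking not attached; call rank_markers first")
        order = np.argsort(self.rank)
        return [self.marker_ids[i] for i in order[:n]]

    def top_indices(self, n: int) -> np.ndarray:
        if self.rank is None:
            raise ContractError("ranking not attached; call rank_markers first")
        return np.argsort(self.rank)[:n]
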