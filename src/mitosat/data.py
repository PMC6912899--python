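"""Core in-memory containers for paired microsatellite / mtDNA population data.

Microsatellite genotypes are stored on the repeat scale: an allele is a
positive integer repeat count and every statistic downstream depends only on
differences between counts, so no fragment-length conversion is ever applied.
Missing calls use the sentinel 0; a call is either fully observed (two
positive alleles, stored sorted ascending) or fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 0

SEQ_ALPHABET = set("ACGTN-")
#: sites treated as unobserved in pairwise sequence comparisons
SEQ_MISSING = set("N-")


class DataError(ValueError):
    """Structural problem in a genotype table or alignment."""


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls for a set of individuals.

    Parameters
    ----------
    individual_ids : list of str
    locations : list of str
        One sampling-location label per individual.
    loci : list of str
        Ordered locus names, identical for every individual.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Unordered allele pairs in repeat units, sorted ascending within the
        pair. Missing calls are ``(0, 0)``.
    """

    individual_ids: list[str]
    locations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, nl = len(self.individual_ids), len(self.loci)
        if len(self.locations) != n:
            raise DataError("one location label required per individual")
        if self.calls.shape != (n, nl, 2):
            raise DataError(
                f"calls shape {self.calls.shape} != ({n}, {nl}, 2)"
            )
        if (self.calls < 0).any():
            raise DataError("allele sizes must be positive (0 = missing)")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise DataError("calls must have two alleles or be fully missing")
        # canonical order inside the unordered pair
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def location_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.locations:
            seen.setdefault(loc)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing loci."""
        return self.missing_mask().mean(axis=1)

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            [self.individual_ids[i] for i in keep],
            [self.locations[i] for i in keep],
            list(self.loci),
            self.calls[keep],
        )

    def population(self, location: str) -> "GenotypeTable":
        mask = np.array([loc == location for loc in self.locations])
        if not mask.any():
            raise DataError(f"no individuals from location {location!r}")
        return self.subset(mask)

    def allele_array(self, locus_index: int) -> np.ndarray:
        """All non-missing gene copies at one locus (flat array)."""
        col = self.calls[:, locus_index, :]
        return col[col > MISSING]

    def relabel(self, mapping: dict[str, str]) -> "GenotypeTable":
        return GenotypeTable(
            list(self.individual_ids),
            [mapping.get(loc, loc) for loc in self.locations],
            list(self.loci),
            self.calls.copy(),
        )


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid DNA sequences with sampling locations."""

    individual_ids: list[str]
    locations: list[str]
    sequences: list[str]
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        if len(self.locations) != n or len(self.sequences) != n:
            raise DataError("ids, locations and sequences must align")
        if n == 0:
            raise DataError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DataError(f"unequal sequence lengths: {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise DataError("zero-length sequences")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - SEQ_ALPHABET
        if bad:
            raise DataError(f"invalid sequence characters: {sorted(bad)}")
        self._matrix = (
            np.frombuffer("".join(self.sequences).encode(), dtype="S1")
            .reshape(n, -1)
            .copy()
        )

    @property
    def n_sequences(self) -> int:
        return len(self.individual_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def location_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.locations:
            seen.setdefault(loc)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """Byte matrix view (n_sequences, length), dtype S1."""
        return self._matrix

    def observed_mask(self) -> np.ndarray:
        """True where the site is an observed base (not N or gap)."""
        m = self._matrix
        return (m != b"N") & (m != b"-")

    def subset(self, keep: np.ndarray) -> "HaplotypeAlignment":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypeAlignment(
            [self.individual_ids[i] for i in keep],
            [self.locations[i] for i in keep],
            [self.sequences[i] for i in keep],
        )

    def population(self, location: str) -> "HaplotypeAlignment":
        mask = np.array([loc == location for loc in self.locations])
        if not mask.any():
            raise DataError(f"no sequences from location {location!r}")
        return self.subset(mask)

    def relabel(self, mapping: dict[str, str]) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            list(self.individual_ids),
            [mapping.get(loc, loc) for loc in self.locations],
            list(self.sequences),
        )


@dataclass
class PopulationMap:
    """individual -> location map, with optional location -> group levels."""

    individual_to_location: dict[str, str]
    location_to_group: dict[str, str] | None = None

    def location_of(self, individual: str) -> str:
        try:
            return self.individual_to_location[individual]
        except KeyError:
            raise DataError(f"individual {individual!r} absent from map") from None

    def group_of(self, location: str) -> str:
        if self.location_to_group is None:
            raise DataError("map carries no group level")
        try:
            return self.location_to_group[location]
        except KeyError:
            raise DataError(f"location {location!r} has no group") from None

    @property
    def locations(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.individual_to_location.values():
            seen.setdefault(loc)
        return list(seen)


def gene_copies_to_individuals(n_gene_copies: float, ploidy: int = 2) -> float:
    """Convert an effective size in gene copies to individuals.

    Autosomal diploid loci carry two gene copies per individual, so the
    conversion halves the estimate; mtDNA is haploid (ploidy 1).
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return n_gene_copies / ploidy
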