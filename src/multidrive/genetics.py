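"""Haplotype and genotype bookkeeping for multiplexed drive target sites.

A drive locus carries ``m`` gRNA target sites on one chromosome. Each site is
wild type (W), functional resistant (R) or nonfunctional resistant (N), unless
the whole chromosome has been converted to the drive construct (D), which is
copied as a unit and never forms a mosaic with the other alleles. With no
positional effects and no recombination, a non-drive haplotype is fully
described by the unordered multiset of its site alleles, i.e. by the counts
(n_W, n_R, n_N) with n_W + n_R + n_N = m. The number of haplotypes is therefore
C(m+2, 2) + 1: e.g. 4, 7 and 11 for m = 1, 2 and 3.

Ordering convention (stable across runs and used for all I/O columns):
non-drive haplotypes sorted lexicographically on their canonical allele string
with W < R < N (WW, WR, WN, RR, RN, NN for m = 2), and the drive haplotype D
last. Diploid genotypes are unordered pairs of haplotype indices stored in
row-major upper-triangle order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

ALLELES = ("W", "R", "N")
DRIVE_LABEL = "D"

#: canonical within-haplotype allele order (W first, then R, then N)
_ALLELE_RANK = {"W": 0, "R": 1, "N": 2}


@dataclass(frozen=True)
class Haplotype:
    """One chromosome state: the drive construct, or a multiset of site alleles.

    Parameters
    ----------
    m : number of target sites (gRNAs).
    counts : (n_W, n_R, n_N) for non-drive haplotypes; ``None`` for drive.
    is_drive : True for the indivisible drive construct.
    """

    m: int
    counts: tuple[int, int, int] | None
    is_drive: bool = False

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.is_drive:
            if self.counts is not None:
                raise ValueError("drive haplotype carries no site alleles")
        else:
            if self.counts is None:
                raise ValueError("non-drive haplotype requires site-allele counts")
            if len(self.counts) != 3 or any(c < 0 for c in self.counts):
                raise ValueError(f"invalid allele counts {self.counts}")
            if sum(self.counts) != self.m:
                raise ValueError(
                    f"allele counts {self.counts} do not sum to m={self.m}"
                )

    @classmethod
    def drive(cls, m: int) -> "Haplotype":
        return cls(m=m, counts=None, is_drive=True)

    @classmethod
    def from_string(cls, label: str, m: int | None = None) -> "Haplotype":
        """Parse a label such as ``"WRN"`` or ``"D"`` (order irrelevant)."""
        label = label.strip().upper()
        if label == DRIVE_LABEL:
            if m is None:
                raise ValueError("m is required to build the drive haplotype")
            return cls.drive(m)
        if not label or any(a not in _ALLELE_RANK for a in label):
            raise ValueError(f"unknown allele symbol in {label!r}")
        if m is not None and len(label) != m:
            raise ValueError(f"label {label!r} has {len(label)} sites, expected m={m}")
        counts = (label.count("W"), label.count("R"), label.count("N"))
        return cls(m=len(label), counts=counts)

    @property
    def label(self) -> str:
        if self.is_drive:
            return DRIVE_LABEL
        n_w, n_r, n_n = self.counts
        return "W" * n_w + "R" * n_r + "N" * n_n

    @property
    def n_wild(self) -> int:
        """Number of cleavable (W) sites; 0 for the drive haplotype."""
        return 0 if self.is_drive else self.counts[0]

    def resistant_site_count(self) -> int:
        """Number of sites carrying R or N. Undefined for the drive haplotype."""
        if self.is_drive:
            raise ValueError("resistant site count is undefined for the drive haplotype")
        return self.counts[1] + self.counts[2]

    def is_fully_resistant(self) -> bool:
        """True iff every one of the m sites carries R or N (drive excluded)."""
        return (not self.is_drive) and self.counts[0] == 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def resistant_site_count(h: Haplotype) -> int:
    """Module-level alias for :meth:`Haplotype.resistant_site_count`."""
    return h.resistant_site_count()


def is_fully_resistant(h: Haplotype) -> bool:
    return h.is_fully_resistant()


@lru_cache(maxsize=None)
def enumerate_haplotypes(m: int) -> tuple[Haplotype, ...]:
    """All haplotypes for ``m`` target sites, in the canonical order.

    Non-drive haplotypes are ordered lexicographically on their canonical
    allele string under W < R < N; the drive haplotype is last. The count is
    C(m+2, 2) + 1.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    haps = []
    for n_w in range(m, -1, -1):
        for n_r in range(m - n_w, -1, -1):
            n_n = m - n_w - n_r
            haps.append(Haplotype(m=m, counts=(n_w, n_r, n_n)))
    haps.append(Haplotype.drive(m))
    return tuple(haps)


@lru_cache(maxsize=None)
def haplotype_index(m: int) -> dict[str, int]:
    """Map from haplotype label to its canonical index."""
    return {h.label: i for i, h in enumerate(enumerate_haplotypes(m))}


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of haplotype indices, stored with ``i <= j``."""

    i: int
    j: int

    def __post_init__(self):
        if self.i > self.j:
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)

    def label(self, haplotypes) -> str:
        return f"{haplotypes[self.i].label}/{haplotypes[self.j].label}"


@lru_cache(maxsize=None)
def enumerate_genotypes(m: int) -> tuple[Genotype, ...]:
    """All unordered haplotype pairs, row-major upper triangle; H(H+1)/2 total."""
    n_hap = len(enumerate_haplotypes(m))
    return tuple(
        Genotype(i, j) for i, j in itertools.combinations_with_replacement(range(n_hap), 2)
    )


def genotype_index(i: int, j: int, n_hap: int) -> int:
    """Flattened upper-triangle index of the unordered pair (i, j)."""
    if i > j:
        i, j = j, i
    if not (0 <= i <= j < n_hap):
        raise ValueError(f"haplotype indices ({i}, {j}) out of range for H={n_hap}")
    return i * n_hap - (i * (i - 1)) // 2 + (j - i)
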