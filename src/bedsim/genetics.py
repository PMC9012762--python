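"""Alleles, genotypes, and inheritance under homing drive conversion.

Each locus carries three possible alleles: wild-type (W), drive (D), and a
cleavage-resistant resistance allele (R).  Drive conversion (homing) acts in
the germline of drive/wild-type heterozygotes only: before segregation the
wild-type target is converted to a drive copy with probability ``h`` (homing
efficiency), to a resistance allele with probability ``r`` (resistance allele
formation), and left intact otherwise.  Resistance alleles are
cleavage-resistant by construction and are never re-cut, so D/R and W/R
genotypes segregate Mendelianly.

Binary-expression designs (ffBED, sBED) use two unlinked autosomal loci —
locus A carries the transactivator drive, locus B the effector drive — while
single-drive designs (ffSD) use one locus.  Loci segregate independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache


class Allele(str, Enum):
    """One of the three allele states at a target locus."""

    W = "W"  # wild-type
    D = "D"  # drive
    R = "R"  # cleavage-resistant (resistance) allele

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical allele ordering used for all vectorised tables.
ALLELES: tuple[Allele, ...] = (Allele.W, Allele.D, Allele.R)
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered diploid allele pair at one locus.

    Equality and hashing are order-insensitive: ``LocusGenotype(W, D)`` and
    ``LocusGenotype(D, W)`` are the same canonical object state.
    """

    a: Allele
    b: Allele

    def __post_init__(self) -> None:
        # canonicalise: sort by the ALLELES order so (D, W) == (W, D)
        i, j = _ALLELE_INDEX[self.a], _ALLELE_INDEX[self.b]
        if i > j:
            object.__setattr__(self, "a", ALLELES[j])
            object.__setattr__(self, "b", ALLELES[i])

    @classmethod
    def from_string(cls, s: str) -> "LocusGenotype":
        if len(s) != 2:
            raise ValueError(f"locus genotype string must have length 2: {s!r}")
        return cls(Allele(s[0]), Allele(s[1]))

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.a, self.b)

    def count(self, allele: Allele) -> int:
        return (self.a == allele) + (self.b == allele)

    @property
    def has_drive(self) -> bool:
        return self.count(Allele.D) > 0

    @property
    def drive_dosage(self) -> int:
        """Number of drive alleles at this locus (0, 1, or 2)."""
        return self.count(Allele.D)

    def __str__(self) -> str:
        return f"{self.a.value}{self.b.value}"


#: The six canonical locus genotypes, in the fixed table order.
LOCUS_GENOTYPES: tuple[LocusGenotype, ...] = tuple(
    LocusGenotype(ALLELES[i], ALLELES[j])
    for i in range(3)
    for j in range(i, 3)
)
LOCUS_GENOTYPE_INDEX = {g: k for k, g in enumerate(LOCUS_GENOTYPES)}

WW = LocusGenotype.from_string("WW")
WD = LocusGenotype.from_string("WD")
WR = LocusGenotype.from_string("WR")
DD = LocusGenotype.from_string("DD")
DR = LocusGenotype.from_string("DR")
RR = LocusGenotype.from_string("RR")


@dataclass(frozen=True)
class Genotype:
    """Full diploid genotype: one :class:`LocusGenotype` per (unlinked) locus.

    Two loci for BED designs (A = transactivator, B = effector), one locus
    for single-drive designs.
    """

    loci: tuple[LocusGenotype, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("genotype needs at least one locus")

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse e.g. ``'DW'`` (one locus) or ``'DD/WW'`` (two loci)."""
        return cls(tuple(LocusGenotype.from_string(p) for p in s.split("/")))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def count_drive_types(self) -> int:
        """Number of loci carrying at least one drive allele.

        Dominant unintended drive costs act once per drive *type* carried
        (copy-number independent), so this is the exponent of per-drive
        multiplicative costs, e.g. ``(1 - u) ** count_drive_types``.
        """
        return sum(1 for lg in self.loci if lg.has_drive)

    def __str__(self) -> str:
        return "/".join(str(lg) for lg in self.loci)


def count_drive_types(g: Genotype) -> int:
    """Module-level alias of :meth:`Genotype.count_drive_types`."""
    return g.count_drive_types()


def all_genotypes(n_loci: int) -> tuple[Genotype, ...]:
    """All genotypes for a design with ``n_loci`` loci, in row-major table
    order (locus A index varies slowest)."""
    return tuple(
        Genotype(combo)
        for combo in itertools.product(LOCUS_GENOTYPES, repeat=n_loci)
    )


def genotype_index(g: Genotype) -> int:
    """Row-major index of ``g`` within :func:`all_genotypes(g.n_loci)`."""
    idx = 0
    for lg in g.loci:
        idx = idx * 6 + LOCUS_GENOTYPE_INDEX[lg]
    return idx


@dataclass(frozen=True)
class GameteDistribution:
    """Marginal allele probabilities in a gamete at one locus."""

    pW: float
    pD: float
    pR: float

    def __post_init__(self) -> None:
        total = self.pW + self.pD + self.pR
        if min(self.pW, self.pD, self.pR) < -1e-12 or abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"invalid gamete distribution ({self.pW}, {self.pD}, {self.pR})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pW, self.pD, self.pR)

    def prob(self, allele: Allele) -> float:
        return self.as_tuple()[_ALLELE_INDEX[allele]]


def _check_conversion_params(h: float, r: float) -> None:
    if not (0.0 <= h <= 1.0 and 0.0 <= r <= 1.0 and h + r <= 1.0 + 1e-12):
        raise ValueError(
            f"homing efficiency h={h} and resistance formation r={r} must be "
            "probabilities with h + r <= 1"
        )


def gamete_distribution(
    locus_genotype: LocusGenotype, h: float, r: float
) -> GameteDistribution:
    """Gamete allele distribution at one locus under homing conversion.

    Conversion happens only in D/W heterozygotes: the wild-type target is cut
    and repaired into a drive copy with probability ``h``, into a resistance
    allele with probability ``r``, and stays wild-type otherwise; one of the
    two (post-conversion) alleles is then drawn fairly.  All other genotypes
    segregate Mendelianly — in particular resistance alleles are never re-cut.

    For D/W the marginals are ``pD = (1 + h)/2``, ``pR = r/2``,
    ``pW = (1 - h - r)/2``.
    """
    _check_conversion_params(h, r)
    if locus_genotype == WD:
        return GameteDistribution(pW=(1.0 - h - r) / 2.0, pD=(1.0 + h) / 2.0, pR=r / 2.0)
    counts = [locus_genotype.count(a) for a in ALLELES]
    return GameteDistribution(*(c / 2.0 for c in counts))


@lru_cache(maxsize=None)
def _locus_offspring_table(
    mother: LocusGenotype, father: LocusGenotype, h: float, r: float
) -> tuple[float, ...]:
    """Offspring locus-genotype distribution (length 6, table order)."""
    gm = gamete_distribution(mother, h, r).as_tuple()
    gf = gamete_distribution(father, h, r).as_tuple()
    out = [0.0] * 6
    for i, pm in enumerate(gm):
        if pm == 0.0:
            continue
        for j, pf in enumerate(gf):
            if pf == 0.0:
                continue
            child = LocusGenotype(ALLELES[i], ALLELES[j])
            out[LOCUS_GENOTYPE_INDEX[child]] += pm * pf
    return tuple(out)


def offspring_distribution(
    mother: Genotype, father: Genotype, h: float, r: float
) -> dict[Genotype, float]:
    """Exact offspring genotype distribution for one cross.

    The product over unlinked loci of the outer product of the parental
    gamete distributions, with unordered-pair collapsing.  Serves both as the
    exact oracle for inheritance and as the kernel behind the aggregated
    multinomial egg sampling in the lifecycle engine.
    """
    if mother.n_loci != father.n_loci:
        raise ValueError(
            f"parents have different locus counts: "
            f"{mother.n_loci} vs {father.n_loci}"
        )
    per_locus = [
        _locus_offspring_table(ml, fl, h, r)
        for ml, fl in zip(mother.loci, father.loci)
    ]
    result: dict[Genotype, float] = {}
    for combo in itertools.product(range(6), repeat=mother.n_loci):
        p = 1.0
        for locus, k in enumerate(combo):
            p *= per_locus[locus][k]
        if p > 0.0:
            result[Genotype(tuple(LOCUS_GENOTYPES[k] for k in combo))] = p
    return result
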