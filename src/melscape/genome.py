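"""Genome and gene models shared across the pipeline.

Coordinates are 0-based half-open internally (BED convention). SEG input,
which is 1-based inclusive, is converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genome model.

    ``centromere`` splits the p arm ([0, centromere)) from the q arm
    ([centromere, length)).
    """

    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )

    def arm(self, pos: int) -> str:
        """Arm label ('1p', '1q', ...) of a position on this chromosome."""
        num = self.name.removeprefix("chr")
        return f"{num}p" if pos < self.centromere else f"{num}q"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic footprint and cancer-gene annotation.

    ``role`` follows the tumor-suppressor / oncogene dichotomy used when
    grouping pathogenic alterations: TSGs are inactivated (damaging mutation
    or homozygous deletion), oncogenes are activated (hotspot mutation or
    amplification); ``both`` is eligible for either grouping.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    arm: str
    role: str = "unknown"  # oncogene | tsg | both | unknown
    in_cancer_gene_list: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start >= end")
        if self.role not in {"oncogene", "tsg", "both", "unknown"}:
            raise ValueError(f"{self.symbol}: unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes plus helpers for arm lookup."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def __iter__(self):
        return iter(self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def total_mb(self) -> float:
        return self.total_length / 1e6

    def arm(self, chrom: str, pos: int) -> str:
        return self.get(chrom).arm(pos)

    def contains(self, gene: GeneModel) -> bool:
        try:
            c = self.get(gene.chrom)
        except KeyError:
            return False
        return 0 <= gene.start and gene.end <= c.length


def default_genome() -> GenomeModel:
    """Compact genome model used by the synthetic cohort.

    Eight chromosomes with realistic arm structure and melanoma-relevant
    names, scaled so a 240-sample whole-genome cohort simulates quickly.
    Mutation burden is always computed against this model's own mappable
    size, so per-megabase rates are independent of the scaling.
    """
    return GenomeModel(
        (
            Chromosome("chr2", 200_000_000, 93_000_000),
            Chromosome("chr3", 180_000_000, 91_000_000),
            Chromosome("chr5", 160_000_000, 48_000_000),
            Chromosome("chr6", 150_000_000, 61_000_000),
            Chromosome("chr7", 140_000_000, 60_000_000),
            Chromosome("chr11", 135_000_000, 53_000_000),
            Chromosome("chr12", 133_000_000, 35_000_000),
            Chromosome("chr17", 81_000_000, 24_000_000),
        )
    )


def default_gene_catalog() -> tuple[GeneModel, ...]:
    """Cancer-gene catalog placed on :func:`default_genome`.

    Symbols and roles follow well-known melanoma drivers; coordinates are
    synthetic positions on the scaled genome, arms consistent with the
    chromosome models.
    """
    g = [
        # symbol, chrom, start, end, role
        ("SF3B1", "chr2", 150_000_000, 150_050_000, "oncogene"),
        ("MITF", "chr3", 60_000_000, 60_030_000, "oncogene"),
        ("CTNNB1", "chr3", 41_000_000, 41_040_000, "oncogene"),
        ("TERT", "chr5", 1_250_000, 1_300_000, "oncogene"),
        ("SKP2", "chr5", 36_000_000, 36_030_000, "oncogene"),
        ("FER", "chr5", 108_000_000, 108_040_000, "oncogene"),
        ("PTP4A1", "chr6", 64_000_000, 64_030_000, "oncogene"),
        ("ARID1B", "chr6", 140_000_000, 140_060_000, "tsg"),
        ("BRAF", "chr7", 120_000_000, 120_060_000, "oncogene"),
        ("EGFR", "chr7", 55_000_000, 55_060_000, "oncogene"),
        ("PTPRJ", "chr11", 48_000_000, 48_050_000, "tsg"),
        ("CCND1", "chr11", 69_000_000, 69_020_000, "oncogene"),
        ("PAK1", "chr11", 77_000_000, 77_030_000, "oncogene"),
        ("GAB2", "chr11", 78_000_000, 78_030_000, "oncogene"),
        ("YAP1", "chr11", 102_000_000, 102_030_000, "oncogene"),
        ("ATM", "chr11", 108_000_000, 108_060_000, "tsg"),
        ("KRAS", "chr12", 25_000_000, 25_030_000, "oncogene"),
        ("CDK4", "chr12", 58_000_000, 58_020_000, "oncogene"),
        ("MDM2", "chr12", 69_000_000, 69_030_000, "oncogene"),
        ("ATRX", "chr17", 10_000_000, 10_060_000, "tsg"),
        ("TP53", "chr17", 7_500_000, 7_530_000, "tsg"),
        ("NF1", "chr17", 29_000_000, 29_080_000, "tsg"),
        ("SPRED1", "chr2", 30_000_000, 30_040_000, "tsg"),
        ("KIT", "chr12", 100_000_000, 100_040_000, "oncogene"),
        ("PTEN", "chr3", 130_000_000, 130_040_000, "tsg"),
        ("CDKN2A", "chr6", 21_000_000, 21_030_000, "tsg"),
    ]
    genome = default_genome()
    return tuple(
        GeneModel(sym, chrom, s, e, genome.arm(chrom, (s + e) // 2), role)
        for sym, chrom, s, e, role in g
    )
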