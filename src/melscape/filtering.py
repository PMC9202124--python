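"""Consensus somatic variant filtering and germline variant filtering.

Somatic candidates come from two caller channels (a Mutect2-like and a
Strelka2-like tool). Calls are merged by variant key and then pass a
deterministic rule chain:

* population SNPs (max allele fraction > 1% in any database/population) are
  removed;
* orientation-bias artifacts (flag consumed from upstream) are removed;
* noncoding variants must be PASS in both channels;
* coding/splice variants PASS in both channels need >= 4 alt reads;
* coding/splice variants PASS in a single channel need 10x coverage in both
  tumor and normal, >= 6 tumor alt reads, and at most one normal alt read or
  <= 3% normal allele fraction;
* indels carrying the first caller's clustered-events filter labels are
  removed.

Germline variants need >= 4 alt reads, allele fraction >= 25%, and must not
be common SNPs; candidate pathogenic germline variants additionally must not
be benign per ClinVar, neutral/inconclusive per OncoKB, or truncations very
close to the protein C-terminus. Variants at high allele fraction in blood
but absent from a tumor that retained both alleles are flagged as likely
clonal hematopoiesis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import drivers
from .genome import GeneModel

POPULATION_AF_THRESHOLD = 0.01
CLUSTERED_EVENT_LABELS = frozenset({"clustered_events", "clustered_events;haplotype"})
QC_MIN_COVERAGE = 25.0
QC_MIN_PURITY = 0.20

# enumerated drop-reason codes
POP_AF = "POP_AF"
LOW_SUPPORT_BOTH_PASS = "LOW_SUPPORT_BOTH_PASS"
SINGLE_TOOL_COVERAGE = "SINGLE_TOOL_COVERAGE"
SINGLE_TOOL_TUMOR_ALT = "SINGLE_TOOL_TUMOR_ALT"
SINGLE_TOOL_NORMAL_CONTAM = "SINGLE_TOOL_NORMAL_CONTAM"
CLUSTERED_EVENTS = "CLUSTERED_EVENTS"
NONCODING_NOT_BOTH_PASS = "NONCODING_NOT_BOTH_PASS"
ORIENTATION_ARTIFACT = "ORIENTATION_ARTIFACT"
NOT_PASSED_ANY = "NOT_PASSED_ANY"
GERMLINE_LOW_READS = "GERMLINE_LOW_READS"
GERMLINE_LOW_AF = "GERMLINE_LOW_AF"

_PURINES = {"A", "G"}


@dataclass(frozen=True)
class CallerStatus:
    called: bool = False
    passed: bool = False
    filter_labels: tuple[str, ...] = ()


@dataclass
class SomaticCallRecord:
    """One candidate somatic variant with two-channel caller evidence."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str  # SNV | INS | DEL
    region_class: str  # coding | splice | noncoding
    caller1: CallerStatus = field(default_factory=CallerStatus)
    caller2: CallerStatus = field(default_factory=CallerStatus)
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    population_af: Mapping[str, float] = field(default_factory=dict)
    orientation_artifact: bool = False
    trinucleotide_context: Optional[str] = None
    # optional annotation carried through to driver classification
    gene: Optional[str] = None
    protein_change: Optional[str] = None
    oncokb_label: str = "unknown"
    damaging_class: str = "other"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.tumor_alt > self.tumor_depth:
            raise ValueError("tumor_alt > tumor_depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError("normal_alt > normal_depth")
        if (
            self.variant_class == "SNV"
            and self.trinucleotide_context is not None
            and len(self.trinucleotide_context) == 3
            and self.trinucleotide_context[1] != self.ref
        ):
            raise ValueError("context middle base does not match ref")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_maf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_maf(self) -> Optional[float]:
        return self.normal_alt / self.normal_depth if self.normal_depth else None

    @property
    def max_population_af(self) -> float:
        return max(self.population_af.values(), default=0.0)


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be True exactly when reasons is empty")


@dataclass
class GermlineCallRecord:
    """One germline variant in the blood/normal DNA, with annotations."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    population_af: Mapping[str, float] = field(default_factory=dict)
    clinvar_label: str = "unknown"
    oncokb_label: str = "unknown"
    damaging_class: str = "other"
    near_c_terminus: bool = False
    gene: Optional[str] = None
    tumor_depth_at_locus: Optional[int] = None
    tumor_alt_at_locus: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads > depth")

    @property
    def allele_fraction(self) -> float:
        if self.depth == 0:
            raise ValueError("depth is zero")
        return self.alt_reads / self.depth

    @property
    def max_population_af(self) -> float:
        return max(self.population_af.values(), default=0.0)


def merge_caller_calls(
    channel1: Iterable[SomaticCallRecord], channel2: Iterable[SomaticCallRecord]
) -> list[SomaticCallRecord]:
    """Union of the two caller channels, one record per variant key.

    When both channels report a variant, read counts come from channel 1
    (deterministic, no averaging); each channel's called/PASS status is
    preserved on the merged record. A position reported with conflicting
    reference alleles is a data error.
    """
    merged: dict[tuple, SomaticCallRecord] = {}
    ref_at: dict[tuple, str] = {}

    def check_ref(rec: SomaticCallRecord) -> None:
        locus = (rec.sample_id, rec.chrom, rec.pos, rec.alt)
        prev = ref_at.setdefault(locus, rec.ref)
        if prev != rec.ref:
            raise ValueError(
                f"conflicting ref alleles at {rec.chrom}:{rec.pos} ({prev} vs {rec.ref})"
            )

    for rec in channel1:
        check_ref(rec)
        merged[rec.key] = rec
    for rec in channel2:
        check_ref(rec)
        if rec.key in merged:
            merged[rec.key].caller2 = rec.caller2
        else:
            merged[rec.key] = rec
    return list(merged.values())


def filter_population_snps(
    records: Iterable[SomaticCallRecord], threshold: float = POPULATION_AF_THRESHOLD
) -> list[SomaticCallRecord]:
    """Drop variants exceeding the SNP threshold in ANY database/population.

    The rule is a strict ">": a variant at exactly the threshold is kept.
    Missing databases count as frequency 0.
    """
    return [r for r in records if r.max_population_af <= threshold]


def apply_somatic_evidence_filters(record: SomaticCallRecord) -> FilterDecision:
    """Read-evidence rule chain for one merged somatic candidate."""
    if record.region_class not in {"coding", "splice", "noncoding"}:
        raise ValueError(f"missing/unknown region_class {record.region_class!r}")
    reasons: list[str] = []

    if record.variant_class == "SNV" and record.orientation_artifact:
        reasons.append(ORIENTATION_ARTIFACT)

    if record.variant_class in {"INS", "DEL"} and any(
        lbl in CLUSTERED_EVENT_LABELS for lbl in record.caller1.filter_labels
    ):
        reasons.append(CLUSTERED_EVENTS)

    n_pass = int(record.caller1.passed) + int(record.caller2.passed)
    if record.region_class == "noncoding":
        if n_pass < 2:
            reasons.append(NONCODING_NOT_BOTH_PASS)
    elif n_pass == 2:
        if record.tumor_alt < 4:
            reasons.append(LOW_SUPPORT_BOTH_PASS)
    elif n_pass == 1:
        if record.tumor_depth < 10 or record.normal_depth < 10:
            reasons.append(SINGLE_TOOL_COVERAGE)
        if record.tumor_alt < 6:
            reasons.append(SINGLE_TOOL_TUMOR_ALT)
        nm = record.normal_maf
        # normal_depth == 0 gives no evidence against contamination: fail
        if not (record.normal_alt <= 1 or (nm is not None and nm <= 0.03)):
            reasons.append(SINGLE_TOOL_NORMAL_CONTAM)
    else:
        reasons.append(NOT_PASSED_ANY)

    return FilterDecision(keep=not reasons, reasons=tuple(dict.fromkeys(reasons)))


def run_somatic_filter(
    channel1: Iterable[SomaticCallRecord],
    channel2: Iterable[SomaticCallRecord],
    snp_threshold: float = POPULATION_AF_THRESHOLD,
) -> tuple[list[SomaticCallRecord], list[tuple[SomaticCallRecord, FilterDecision]]]:
    """Full consensus filter: merge, SNP removal, evidence rules.

    Returns (kept records, dropped records with their decisions).
    """
    merged = merge_caller_calls(channel1, channel2)
    kept: list[SomaticCallRecord] = []
    dropped: list[tuple[SomaticCallRecord, FilterDecision]] = []
    for rec in merged:
        if rec.max_population_af > snp_threshold:
            dropped.append((rec, FilterDecision(False, (POP_AF,))))
            continue
        decision = apply_somatic_evidence_filters(rec)
        if decision.keep:
            kept.append(rec)
        else:
            dropped.append((rec, decision))
    return kept, dropped


def filter_germline_variant(
    record: GermlineCallRecord, snp_threshold: float = POPULATION_AF_THRESHOLD
) -> FilterDecision:
    """Read-support, allele-fraction, and SNP filter for germline calls.

    Boundaries are inclusive on the keep side: exactly 4 alt reads and
    exactly 25% allele fraction are kept.
    """
    if record.depth == 0:
        raise ValueError("germline record with zero depth")
    reasons = []
    if record.alt_reads < 4:
        reasons.append(GERMLINE_LOW_READS)
    if record.allele_fraction < 0.25:
        reasons.append(GERMLINE_LOW_AF)
    if record.max_population_af > snp_threshold:
        reasons.append(POP_AF)
    return FilterDecision(keep=not reasons, reasons=tuple(reasons))


def is_candidate_pathogenic_germline(
    record: GermlineCallRecord, gene: GeneModel, snp_threshold: float = POPULATION_AF_THRESHOLD
) -> bool:
    """Whether a germline variant qualifies as a possible driver event."""
    if not filter_germline_variant(record, snp_threshold).keep:
        return False
    if record.clinvar_label == "benign_likely_benign":
        return False
    if record.oncokb_label in {"neutral", "inconclusive"}:
        return False
    if record.near_c_terminus:
        return False
    return drivers.is_pathogenic(
        gene, oncokb_label=record.oncokb_label, damaging_class=record.damaging_class
    )


def flag_clonal_hematopoiesis(
    record: GermlineCallRecord, tumor_minor_cn: Optional[int], min_tumor_depth: int = 20
) -> bool:
    """Flag blood-only variants that the tumor (retaining both alleles) lacks.

    Absence from the tumor is only informative when the tumor kept both
    alleles at the locus (minor copy >= 1): under LOH the missing allele may
    simply have been lost.
    """
    if record.tumor_depth_at_locus is None or record.tumor_alt_at_locus is None:
        return False
    if tumor_minor_cn is None or tumor_minor_cn < 1:
        return False
    return (
        record.tumor_alt_at_locus == 0
        and record.tumor_depth_at_locus >= min_tumor_depth
    )


def sample_qc_filter(
    sheet: pd.DataFrame,
    min_coverage: float = QC_MIN_COVERAGE,
    min_purity: float = QC_MIN_PURITY,
) -> list[str]:
    """Cohort-level sample QC on the sample sheet.

    Excludes samples with mean coverage under ``min_coverage`` or purity
    under ``min_purity`` (both strict "under", so exact boundary values are
    kept). For a patient with several remaining samples, only one is kept:
    the metastasis with the highest purity (or, if no metastasis remains,
    the highest-purity sample), ties broken by sample_id.
    """
    df = sheet.copy()
    df = df[(df["mean_coverage"] >= min_coverage) & (df["purity"] >= min_purity)]
    kept: list[str] = []
    for _, grp in df.groupby("patient_id", sort=False):
        if len(grp) == 1:
            kept.append(grp.iloc[0]["sample_id"])
            continue
        mets = grp[grp["specimen"] == "metastasis"]
        pool = mets if len(mets) else grp
        pool = pool.sort_values(["purity", "sample_id"], ascending=[False, True])
        kept.append(pool.iloc[0]["sample_id"])
    order = {s: i for i, s in enumerate(sheet["sample_id"])}
    return sorted(kept, key=order.get)
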