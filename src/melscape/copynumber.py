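"""Purity/ploidy-aware absolute copy number.

The observed log2 ratio of a tumor segment with integer copy number ``n`` in
a specimen of tumor purity rho and tumor ploidy phi, against a diploid
normal, is

    log2 Ratio = log2( ((1 - rho) * 2 + rho * n) / ((1 - rho) * 2 + rho * phi) )

The denominator is the average copy number of the admixed specimen, so a
segment at the tumor's own ploidy has ratio 0. Inverting the formula
recovers the absolute copy number of each segment from the observed ratio
once purity and ploidy are known; purity itself can be re-estimated from
the median mutant allele fraction of clonal somatic mutations in diploid
regions (MAF = rho/2) or from the folded allele fraction of germline
heterozygous variants in hemizygous regions (retained-allele fraction =
1/(2 - rho)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import GeneModel

AMPLIFICATION_MAX_LENGTH = 10_000_000  # focal: <= 10 Mb


@dataclass(frozen=True)
class PurityPloidy:
    """Tumor purity rho in (0, 1] and ploidy phi > 0 for one sample."""

    purity: float
    ploidy: float
    source: str = "external"  # external | somatic_maf | germline_hemizygous

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy {self.ploidy} must be positive")


@dataclass
class CNSegment:
    """A copy-number segment (0-based half-open coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    total_cn: Optional[float] = None  # real-valued n
    total_cn_int: Optional[int] = None
    minor_cn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.minor_cn is not None and self.total_cn_int is not None:
            if self.minor_cn > self.total_cn_int / 2 + 1e-9:
                raise ValueError("minor_cn exceeds total/2")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneCNState:
    """Gene-level copy-number call rolled up from segments."""

    gene: str
    state: str  # amplified | homozygous_deletion | loh | gain | loss | neutral
    total_cn: Optional[float]
    total_cn_int: Optional[int]
    minor_cn: Optional[int]
    segment_index: Optional[int]
    covered: bool = True


def expected_log2_ratio(n: float, pp: PurityPloidy) -> float:
    """Forward model: log2 ratio of a segment with tumor copy number ``n``."""
    if n < 0:
        raise ValueError("copy number must be nonnegative")
    rho, phi = pp.purity, pp.ploidy
    num = (1.0 - rho) * 2.0 + rho * n
    den = (1.0 - rho) * 2.0 + rho * phi
    if num == 0:
        # pure tumor, homozygous deletion: the ratio's true limit
        return -math.inf
    return math.log2(num / den)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def absolute_copy_number(log2_ratio: float, pp: PurityPloidy) -> tuple[float, int]:
    """Invert the forward model: (real n, integer n) from an observed ratio.

    Negative real solutions (noise below homozygous deletion) are clamped to
    0; the integer call rounds half away from zero.
    """
    rho, phi = pp.purity, pp.ploidy
    n_real = (2.0 ** log2_ratio * ((1.0 - rho) * 2.0 + rho * phi) - (1.0 - rho) * 2.0) / rho
    n_real = max(n_real, 0.0)
    return n_real, _round_half_away(n_real)


def purity_from_somatic_maf(mafs: Sequence[float], min_count: int = 20) -> float:
    """Purity from the median MAF of clonal het mutations in diploid regions.

    A clonal mutation on one of two tumor copies in a diploid region has
    MAF = rho/2, so rho = 2 * median(MAF), clamped to (0, 1].
    """
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size < min_count:
        raise ValueError(
            f"need >= {min_count} clonal diploid-region MAFs, got {mafs.size}"
        )
    return float(np.clip(2.0 * np.median(mafs), 0.0, 1.0))


def purity_from_hemizygous_vaf(vafs: Sequence[float], min_count: int = 20) -> float:
    """Purity from germline het allele fractions in hemizygous (n=1) regions.

    In a region where the tumor retains a single copy, the retained allele's
    read fraction in the admixed specimen is 1/(2 - rho) (one tumor copy plus
    one normal copy over one tumor copy plus two normal copies). Allele
    fractions are folded to the major allele before taking the median, so
    either allele of the het site can be supplied. A folded median <= 0.5 is
    non-informative and yields 0.0.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    if vafs.size < min_count:
        raise ValueError(
            f"need >= {min_count} hemizygous-region VAFs, got {vafs.size}"
        )
    folded = np.maximum(vafs, 1.0 - vafs)
    med = float(np.median(folded))
    if med <= 0.5:
        return 0.0
    return float(np.clip(2.0 - 1.0 / med, 0.0, 1.0))


def call_amplification(seg: CNSegment, pp: PurityPloidy) -> bool:
    """Focal amplification: integer n more than twice ploidy, span <= 10 Mb."""
    if seg.total_cn_int is None:
        raise ValueError("segment copy number not computed")
    return seg.total_cn_int > 2.0 * pp.ploidy and seg.length <= AMPLIFICATION_MAX_LENGTH


def call_homozygous_deletion(seg: CNSegment) -> bool:
    """Both copies lost: integer total copy number 0."""
    if seg.total_cn_int is None:
        raise ValueError("segment copy number not computed")
    return seg.total_cn_int == 0


def call_loh(seg: CNSegment) -> Optional[bool]:
    """Loss of heterozygosity: minor copy 0 with >= 1 copy retained.

    Returns None (not evaluable) when the minor copy number is missing.
    """
    if seg.total_cn_int is None:
        raise ValueError("segment copy number not computed")
    if seg.minor_cn is None:
        return None
    return seg.minor_cn == 0 and seg.total_cn_int >= 1


def compute_segment_cn(segments: Iterable[CNSegment], pp: PurityPloidy) -> list[CNSegment]:
    """Fill total_cn / total_cn_int on each segment from its log2 ratio."""
    out = []
    for seg in segments:
        n_real, n_int = absolute_copy_number(seg.log2_ratio, pp)
        minor = seg.minor_cn
        if minor is not None and minor > n_int / 2:
            minor = n_int // 2
        out.append(replace(seg, total_cn=n_real, total_cn_int=n_int, minor_cn=minor))
    return out


def median_center(segments: Sequence[CNSegment]) -> list[CNSegment]:
    """Subtract the length-weighted median log2 ratio from every segment.

    With the weights accumulated in ratio order, if the half-weight point
    falls exactly between two values their mean is used (so two equal-length
    segments center to +/- half their gap).
    """
    if not segments:
        raise ValueError("no segments")
    ratios = np.array([s.log2_ratio for s in segments], dtype=float)
    weights = np.array([s.length for s in segments], dtype=float)
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if math.isclose(cum[idx], half) and idx + 1 < len(r):
        med = 0.5 * (r[idx] + r[idx + 1])
    else:
        med = r[idx]
    return [replace(s, log2_ratio=s.log2_ratio - med) for s in segments]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_gene_cn(
    gene: GeneModel, segments: Sequence[CNSegment], pp: PurityPloidy
) -> GeneCNState:
    """Roll segment calls up to one gene-level state.

    The gene follows the segment covering the larger share of its span; ties
    break toward the segment whose copy number departs further from ploidy.
    States, in precedence order on the chosen segment: amplified (> 2x ploidy
    and <= 10 Mb), homozygous_deletion (n=0), LOH (minor 0, n >= 1), gain
    (ploidy < n <= 2x ploidy), loss (0 < n < floor(ploidy)), else neutral.
    """
    best = None
    best_key = None
    for i, seg in enumerate(segments):
        if seg.chrom != gene.chrom:
            continue
        ov = _overlap(gene.start, gene.end, seg.start, seg.end)
        if ov <= 0:
            continue
        if seg.total_cn_int is None:
            raise ValueError("segment copy number not computed")
        key = (ov, abs((seg.total_cn or seg.total_cn_int) - pp.ploidy))
        if best_key is None or key > best_key:
            best, best_key = (i, seg), key
    if best is None:
        return GeneCNState(gene.symbol, "neutral", None, None, None, None, covered=False)
    i, seg = best
    n = seg.total_cn_int
    if call_amplification(seg, pp):
        state = "amplified"
    elif n == 0:
        state = "homozygous_deletion"
    elif call_loh(seg):
        state = "loh"
    elif n > pp.ploidy:
        # includes broad (> 10 Mb) high-CN segments that fail the focal rule
        state = "gain"
    elif 0 < n < math.floor(pp.ploidy):
        state = "loss"
    else:
        state = "neutral"
    return GeneCNState(gene.symbol, state, seg.total_cn, n, seg.minor_cn, i)
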