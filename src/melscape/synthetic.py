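"""Synthetic two-subtype melanoma cohort generator with full ground truth.

Emulates the structure of a harmonized acral + mucosal cohort (147 + 93
samples by default): per-sample purity and ploidy, integer copy-number
profiles observed through purity/ploidy-attenuated log2 ratios with
Gaussian noise, clonal somatic mutations whose allele fractions follow
purity and local copy number, two noisy caller channels per mutation,
germline variants (including hemizygous-region allele-fraction shifts,
planted pathogenic variants with optional second hits, and occasional
clonal-hematopoiesis lookalikes), planted alteration co-occurrence or
exclusivity structure, trinucleotide-context catalogs mixed from reference
signatures, and structural-variant junction lists.

All randomness flows from a single integer seed through spawned
``numpy.random.SeedSequence`` streams, one per sample and purpose, so the
same seed reproduces the cohort bit-for-bit and per-sample output does not
depend on generation order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .copynumber import expected_log2_ratio, PurityPloidy
from .genome import GeneModel, GenomeModel, default_gene_catalog, default_genome
from .signatures import (
    CONTEXT_LABELS,
    revcomp,
    synthetic_reference_signatures,
)

ASSOCIATIONS = ("co_occurring", "exclusive", "independent")


@dataclass(frozen=True)
class CallerNoise:
    """Per-channel caller error model.

    ``fn1``/``fn2``: probability a true mutation is missed (absent or not
    PASS) in each channel. ``fp1``/``fp2``: expected false-positive calls per
    true mutation, emitted with low read support in one channel only.
    ``artifact_rate``: fraction of extra both-channel-PASS SNVs carrying the
    orientation-artifact flag. ``clustered_indel_rate``: fraction of extra
    indels carrying the first caller's clustered-events label.
    """

    fn1: float = 0.02
    fn2: float = 0.02
    fp1: float = 0.02
    fp2: float = 0.02
    artifact_rate: float = 0.01
    clustered_indel_rate: float = 0.005

    def __post_init__(self) -> None:
        for name in ("fn1", "fn2", "fp1", "fp2", "artifact_rate", "clustered_indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PlantedPair:
    group_a: str
    group_b: str
    association: str  # co_occurring | exclusive | independent
    strength: float = 1.0  # multiplier on P(b | a) relative to P(b)

    def __post_init__(self) -> None:
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"unknown association {self.association!r}")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")


def _default_group_frequencies() -> dict[str, tuple[float, float]]:
    """Per-group carrier probability for (acral, mucosal) samples.

    Loosely shaped like the recurrent alteration groups of an acral/mucosal
    cohort: a subtype-exclusive splicing-factor hotspot, acral-enriched
    11q13-14 amplifications, and a set of shared drivers.
    """
    return {
        "BRAF_class1": (0.20, 0.065),
        "BRAF_other": (0.07, 0.07),
        "SF3B1_mutation": (0.0, 0.129),
        "KIT_mutation": (0.08, 0.10),
        "NF1_inactivation": (0.10, 0.10),
        "TP53_inactivation": (0.03, 0.10),
        "ATRX_inactivation": (0.02, 0.10),
        "PTEN_inactivation": (0.08, 0.08),
        "CDKN2A_inactivation": (0.30, 0.25),
        "PTPRJ_inactivation": (0.05, 0.05),
        "SPRED1_inactivation": (0.08, 0.05),
        "CDK4_amplification": (0.15, 0.15),
        "MDM2_amplification": (0.12, 0.10),
        "CCND1_amplification": (0.25, 0.15),
        "PAK1_amplification": (0.286, 0.118),
        "GAB2_amplification": (0.306, 0.161),
        "TERT_amplification": (0.238, 0.129),
        "SKP2_amplification": (0.117, 0.117),
        "FER_amplification": (0.04, 0.04),
        "PTP4A1_amplification": (0.12, 0.08),
        "YAP1_amplification": (0.10, 0.09),
        "MITF_amplification": (0.025, 0.06),
    }


def _default_planted_pairs() -> tuple[PlantedPair, ...]:
    return (
        PlantedPair("CDK4_amplification", "CDKN2A_inactivation", "exclusive", 0.1),
        PlantedPair("ATRX_inactivation", "TP53_inactivation", "co_occurring", 4.0),
        PlantedPair("PTP4A1_amplification", "CCND1_amplification", "co_occurring", 3.0),
    )


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subtype_a: int = 147  # acral
    n_subtype_b: int = 93  # mucosal
    purity_range: tuple[float, float] = (0.3, 0.9)
    ploidy_choices: tuple[float, ...] = (2.0, 3.1, 4.0)
    ploidy_weights: tuple[float, ...] = (0.7, 0.2, 0.1)
    genome: GenomeModel = field(default_factory=default_genome)
    gene_catalog: tuple[GeneModel, ...] = field(default_factory=default_gene_catalog)
    group_frequencies: dict[str, tuple[float, float]] = field(
        default_factory=_default_group_frequencies
    )
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=_default_planted_pairs)
    mutations_per_mb_range: tuple[float, float] = (1.0, 3.0)
    signature_weights: Optional[Mapping[str, float]] = None  # default below
    reference_signatures: Optional[pd.DataFrame] = None
    caller_noise: CallerNoise = field(default_factory=CallerNoise)
    segment_log2_noise_sd: float = 0.05
    depth_mean: float = 80.0
    depth_size: float = 10.0  # negative-binomial dispersion (larger = tighter)
    mutation_multiplicity: int = 1  # mutated copies per clonal mutation
    arm_event_prob: float = 0.25
    homdel_fraction: float = 0.4  # TSG inactivation via homdel vs mutation
    tsg_loh_prob: float = 0.6  # second hit for mutational TSG inactivation
    snp_leak_rate: float = 0.01  # common-SNP contaminant calls per true mutation
    germline_background_per_sample: int = 120
    germline_common_fraction: float = 0.7
    germline_driver_rate: float = 0.18
    germline_second_hit_rate: float = 0.2
    clonal_hematopoiesis_rate: float = 0.02
    sv_background_mean: float = 234.0
    sv_background_mean_braf1: float = 136.0
    sv_cross_region_mean: float = 3.0
    survival_median_months: float = 40.0
    survival_hazard: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must sit inside (0, 1]")
        if any(p <= 0 for p in self.ploidy_choices):
            raise ValueError("ploidy choices must be positive")
        for grp, (fa, fb) in self.group_frequencies.items():
            if not (0 <= fa <= 1 and 0 <= fb <= 1):
                raise ValueError(f"{grp}: frequencies outside [0, 1]")
        for gene in self.gene_catalog:
            if not self.genome.contains(gene):
                raise ValueError(f"gene {gene.symbol} outside genome model")
        if self.segment_log2_noise_sd < 0:
            raise ValueError("segment_log2_noise_sd must be nonnegative")
        if self.reference_signatures is None:
            self.reference_signatures = synthetic_reference_signatures(n_flat=4, seed=7)
        if self.signature_weights is None:
            names = list(self.reference_signatures.columns)
            w = {n: 0.0 for n in names}
            # mostly-flat background with a modest UV component
            w["SBS7"] = 0.15
            rest = [n for n in names if n != "SBS7"]
            for n in rest:
                w[n] = 0.85 / len(rest)
            self.signature_weights = w
        total = sum(self.signature_weights.values())
        if abs(total - 1.0) > 1e-9 or min(self.signature_weights.values()) < 0:
            raise ValueError("signature weights must be nonnegative and sum to 1")

    @property
    def n_samples(self) -> int:
        return self.n_subtype_a + self.n_subtype_b

    @property
    def genes_by_symbol(self) -> dict[str, GeneModel]:
        return {g.symbol: g for g in self.gene_catalog}


@dataclass
class CohortGroundTruth:
    """Everything the generator knows: the recovery targets for all tests."""

    purity_ploidy: pd.DataFrame  # sample_id, purity, ploidy
    true_segments: pd.DataFrame  # sample_id, chrom, start, end, total_cn, minor_cn
    true_mutations: pd.DataFrame  # per-mutation truth incl. true_maf, local CN
    alteration_matrix: pd.DataFrame  # samples x groups binary truth
    exposures: pd.DataFrame  # samples x signatures, fractions
    germline_truth: pd.DataFrame  # planted germline drivers + second-hit flag
    cross_region_junctions: pd.DataFrame  # sample_id, n_planted


@dataclass
class CohortBundle:
    """The observable datasets the pipeline consumes."""

    mutations: pd.DataFrame  # two-channel somatic candidate table
    germline: pd.DataFrame
    segments: pd.DataFrame  # SEG-dialect observed segments
    junctions: pd.DataFrame  # BEDPE-style
    sample_sheet: pd.DataFrame
    reference_signatures: pd.DataFrame


# ---------------------------------------------------------------------------
# alteration truth

def simulate_alteration_truth(
    n_a: int,
    n_b: int,
    group_frequencies: Mapping[str, tuple[float, float]],
    planted_pairs: Sequence[PlantedPair],
    rng: np.random.Generator,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binary truth matrix with planted pairwise structure.

    Groups not named in a planted pair are independent Bernoulli draws at
    the subtype frequency. For a planted pair (A, B) the B margin is
    preserved while P(B | A) is scaled by ``strength`` (strength 0 under
    ``exclusive`` forbids co-occurrence entirely).
    """
    n = n_a + n_b
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    subtype_b = np.arange(n) >= n_a
    groups = list(group_frequencies)
    freq = np.array(
        [
            np.where(subtype_b, group_frequencies[g][1], group_frequencies[g][0])
            for g in groups
        ]
    ).T  # n x k
    occ = (rng.random((n, len(groups))) < freq).astype(int)
    col = {g: i for i, g in enumerate(groups)}
    for pair in planted_pairs:
        if pair.association == "independent":
            continue
        ia, ib = col[pair.group_a], col[pair.group_b]
        fb = freq[:, ib]
        fa = freq[:, ia]
        # strength < 1 depletes (exclusive), > 1 enriches (co_occurring)
        p_given_a = np.clip(pair.strength * fb, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_given_not_a = np.clip(
                (fb - fa * p_given_a) / np.maximum(1.0 - fa, 1e-12), 0.0, 1.0
            )
        a = occ[:, ia].astype(bool)
        u = rng.random(n)
        occ[:, ib] = np.where(a, u < p_given_a, u < p_given_not_a).astype(int)
    return pd.DataFrame(occ, index=pd.Index(sample_ids, name="sample_id"), columns=groups)


# ---------------------------------------------------------------------------
# copy-number profile

def _split_segment(segments: list[list], chrom: str, start: int, end: int, n: int, minor: int):
    """Carve a focal [start, end) segment with copy state (n, minor) into a profile."""
    out = []
    for seg in segments:
        c, s, e, cn, mn = seg
        if c != chrom or e <= start or s >= end:
            out.append(seg)
            continue
        if s < start:
            out.append([c, s, start, cn, mn])
        if e > end:
            out.append([c, end, e, cn, mn])
    out.append([chrom, start, end, n, minor])
    out.sort(key=lambda x: (x[0], x[1]))
    return out


def simulate_cn_profile(
    config: CohortConfig,
    ploidy: float,
    truth_groups: Mapping[str, int],
    rng: np.random.Generator,
    force_loh_genes: Sequence[str] = (),
) -> tuple[list[list], dict[str, str]]:
    """True integer copy-number profile for one sample.

    Starts at round(ploidy) everywhere, applies random arm-level gains and
    losses, focal amplifications (> 2x ploidy, <= ~6 Mb) over the genes of
    carried amplification groups, homozygous deletions or LOH for carried
    TSG-inactivation groups, and forced LOH over ``force_loh_genes``
    (germline second hits). Returns the segment list [chrom, start, end,
    total, minor] and, per TSG group carried, its inactivation mechanism
    ('homdel' or 'mutation'/'mutation_loh').
    """
    base = int(round(ploidy))
    base_minor = base // 2
    segments: list[list] = []
    genes = config.genes_by_symbol
    for chrom in config.genome:
        for (s, e) in ((0, chrom.centromere), (chrom.centromere, chrom.length)):
            n, minor = base, base_minor
            r = rng.random()
            if r < config.arm_event_prob / 2:
                n, minor = base + 1, base_minor
            elif r < config.arm_event_prob:
                n = max(base - 1, 0)
                minor = min(base_minor, n // 2)
            elif r < config.arm_event_prob + 0.05:
                minor = 0  # copy-neutral LOH
            segments.append([chrom.name, s, e, n, minor])

    mechanisms: dict[str, str] = {}
    for grp, carried in truth_groups.items():
        if not carried:
            continue
        gene_sym = grp.split("_")[0] if not grp.startswith("BRAF") else "BRAF"
        gene = genes.get(gene_sym)
        if gene is None:
            continue
        chrom = config.genome.get(gene.chrom)
        if grp.endswith("_amplification"):
            length = int(rng.uniform(1e6, 6e6))
            mid = (gene.start + gene.end) // 2
            start = max(0, min(mid - length // 2, chrom.length - length))
            amp_n = int(round(2 * ploidy)) + 1 + int(rng.poisson(2))
            segments = _split_segment(segments, gene.chrom, start, start + length, amp_n, 1)
        elif grp.endswith("_inactivation"):
            if rng.random() < config.homdel_fraction:
                length = int(rng.uniform(5e5, 3e6))
                mid = (gene.start + gene.end) // 2
                start = max(0, min(mid - length // 2, chrom.length - length))
                segments = _split_segment(segments, gene.chrom, start, start + length, 0, 0)
                mechanisms[grp] = "homdel"
            elif rng.random() < config.tsg_loh_prob:
                length = int(rng.uniform(3e6, 1e7))
                mid = (gene.start + gene.end) // 2
                start = max(0, min(mid - length // 2, chrom.length - length))
                seg_n = max(base - 1, 1)
                segments = _split_segment(
                    segments, gene.chrom, start, start + length, seg_n, 0
                )
                mechanisms[grp] = "mutation_loh"
            else:
                mechanisms[grp] = "mutation"
    for sym in force_loh_genes:
        gene = genes[sym]
        chrom = config.genome.get(gene.chrom)
        length = int(rng.uniform(3e6, 1e7))
        mid = (gene.start + gene.end) // 2
        start = max(0, min(mid - length // 2, chrom.length - length))
        segments = _split_segment(segments, gene.chrom, start, start + length, max(base - 1, 1), 0)
    return segments, mechanisms


def simulate_segments(
    true_profile: Sequence[Sequence],
    purity: float,
    ploidy: float,
    noise_sd: float,
    rng: np.random.Generator,
    sample_id: str = "",
) -> pd.DataFrame:
    """Observe a true profile through the purity/ploidy log2-ratio model.

    Each segment's observed ratio is the exact forward-model value plus
    N(0, noise_sd) noise. Output is SEG-dialect (1-based inclusive
    coordinates, Segment_Mean = observed log2 ratio).
    """
    pp = PurityPloidy(purity, ploidy)
    rows = []
    for chrom, start, end, n, _minor in true_profile:
        ratio = expected_log2_ratio(n, pp)
        if noise_sd > 0:
            ratio += rng.normal(0.0, noise_sd)
        rows.append(
            {
                "Sample": sample_id,
                "Chromosome": chrom,
                "Start": start + 1,
                "End": end,
                "Num_Probes": max(int((end - start) / 1e4), 2),
                "Segment_Mean": ratio,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# somatic mutations and caller channels

_SUB_PARSE = [(lbl, lbl[2], lbl[4], lbl[0] + lbl[2] + lbl[6]) for lbl in CONTEXT_LABELS]


def _draw_contexts(k: int, probs: np.ndarray, rng: np.random.Generator):
    """Draw k substitution classes; return ref, alt, context arrays.

    Half the draws are flipped to the purine strand so that strand folding
    downstream is exercised.
    """
    idx = rng.choice(96, size=k, p=probs)
    refs, alts, ctxs = [], [], []
    flip = rng.random(k) < 0.5
    for i, f in zip(idx, flip):
        _, ref, alt, ctx = _SUB_PARSE[i]
        if f:
            ctxs.append(revcomp(ctx))
            refs.append(revcomp(ref))
            alts.append(revcomp(alt))
        else:
            ctxs.append(ctx)
            refs.append(ref)
            alts.append(alt)
    return np.array(refs), np.array(alts), np.array(ctxs)


def _nb_depth(k: int, mean: float, size: float, rng: np.random.Generator) -> np.ndarray:
    p = size / (size + mean)
    return np.maximum(rng.negative_binomial(size, p, size=k), 1)


def true_maf(purity: float, total_cn: float, multiplicity: int = 1) -> float:
    """Clonal mutant allele fraction given purity and local total copy number."""
    return purity * multiplicity / (2.0 * (1.0 - purity) + purity * total_cn)


def simulate_caller_channels(
    candidates: pd.DataFrame,
    caller_noise: CallerNoise,
    rng: np.random.Generator,
    genome: Optional[GenomeModel] = None,
    depth_mean: float = 80.0,
    depth_size: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two noisy caller channels from a candidate mutation table.

    Each candidate is independently present-and-PASS in each channel with
    probability 1 - FN (candidates flagged ``force_both_pass`` skip the FN
    draw). Per-channel false positives are appended at the configured rate
    with low alt-read support. Returns the two channel tables, each with
    called/pass/filters columns.
    """
    n = len(candidates)
    out = []
    for ch, fn, fp in ((1, caller_noise.fn1, caller_noise.fp1), (2, caller_noise.fn2, caller_noise.fp2)):
        present = rng.random(n) >= fn
        if "force_both_pass" in candidates.columns:
            present |= candidates["force_both_pass"].to_numpy(dtype=bool)
        df = candidates.loc[present].copy()
        df["called"] = True
        df["pass"] = True
        if "filters" not in df.columns:
            df["filters"] = ""
        if ch == 2:
            df["filters"] = ""  # clustered-events labels belong to caller 1
        n_fp = rng.poisson(fp * max(n, 1))
        if n_fp and genome is not None:
            chroms = [c.name for c in genome]
            lengths = np.array([c.length for c in genome], dtype=float)
            ci = rng.choice(len(chroms), size=n_fp, p=lengths / lengths.sum())
            depth = _nb_depth(n_fp, depth_mean, depth_size, rng)
            alt = np.minimum(rng.integers(1, 4, size=n_fp), depth)
            bases = np.array(list("ACGT"))
            ref = bases[rng.integers(0, 4, size=n_fp)]
            alt_base = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=n_fp)) % 4]
            fps = pd.DataFrame(
                {
                    "sample": candidates["sample"].iloc[0] if n else "",
                    "chrom": [chroms[i] for i in ci],
                    "pos": rng.integers(1, lengths[ci].astype(np.int64)),
                    "ref": ref,
                    "alt": alt_base,
                    "class": "SNV",
                    "region": "noncoding",
                    "t_depth": depth,
                    "t_alt": alt,
                    "n_depth": _nb_depth(n_fp, depth_mean, depth_size, rng),
                    "n_alt": 0,
                    "pop_af_max": 0.0,
                    "orientation_artifact": False,
                    "context": "",
                    "is_true": False,
                    "called": True,
                    "pass": True,
                    "filters": "",
                }
            )
            df = pd.concat([df, fps], ignore_index=True)
        out.append(df)
    return out[0], out[1]


def merge_channel_tables(ch1: pd.DataFrame, ch2: pd.DataFrame) -> pd.DataFrame:
    """Outer-join the two channel tables into one two-channel candidate table."""
    key = ["sample", "chrom", "pos", "ref", "alt"]
    status1 = ch1[key + ["called", "pass", "filters"]].rename(
        columns={"called": "caller1_called", "pass": "caller1_pass", "filters": "caller1_filters"}
    )
    status2 = ch2[key + ["called", "pass", "filters"]].rename(
        columns={"called": "caller2_called", "pass": "caller2_pass", "filters": "caller2_filters"}
    )
    payload_cols = [c for c in ch1.columns if c not in {"called", "pass", "filters"}]
    payload = pd.concat(
        [ch1[payload_cols], ch2[payload_cols]], ignore_index=True
    ).drop_duplicates(subset=key, keep="first")
    merged = payload.merge(status1, on=key, how="left").merge(status2, on=key, how="left")
    for ch in (1, 2):
        for col, fill in ((f"caller{ch}_called", False), (f"caller{ch}_pass", False)):
            merged[col] = merged[col].astype(object).where(merged[col].notna(), fill).astype(bool)
        col = f"caller{ch}_filters"
        merged[col] = merged[col].astype(object).where(merged[col].notna(), "")
    return merged.sort_values(["sample", "chrom", "pos", "ref", "alt"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# whole-cohort generation

def _segment_lookup(profile: Sequence[Sequence]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {seg[0] for seg in profile}:
        segs = sorted((s for s in profile if s[0] == chrom), key=lambda x: x[1])
        starts = np.array([s[1] for s in segs])
        ends = np.array([s[2] for s in segs])
        ns = np.array([s[3] for s in segs])
        minors = np.array([s[4] for s in segs])
        by_chrom[chrom] = (starts, ends, ns, minors)
    return by_chrom


def _lookup_cn(by_chrom, chrom: str, pos: int) -> tuple[int, int]:
    starts, ends, ns, minors = by_chrom[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    i = max(min(i, len(starts) - 1), 0)
    return int(ns[i]), int(minors[i])


_DRIVER_CHANGES = {
    "SF3B1": ("R625H", "missense", "hotspot"),
    "KIT": ("L576P", "missense", "oncogenic"),
    "CTNNB1": ("S45F", "missense", "oncogenic"),
    "MITF": ("E318K", "missense", "likely_oncogenic"),
    "KRAS": ("G12D", "missense", "oncogenic"),
    "EGFR": ("L858R", "missense", "oncogenic"),
}


def generate_cohort(config: CohortConfig) -> tuple[CohortBundle, CohortGroundTruth]:
    """Generate the full observable bundle plus ground truth for one cohort."""
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_samples = root.spawn(2)
    rng_cohort = np.random.default_rng(ss_cohort)
    n = config.n_samples
    sample_ids = [
        (f"A_SYN_{i:04d}" if i < config.n_subtype_a else f"M_SYN_{i:04d}")
        for i in range(n)
    ]
    subtypes = ["acral"] * config.n_subtype_a + ["mucosal"] * config.n_subtype_b

    truth_matrix = simulate_alteration_truth(
        config.n_subtype_a,
        config.n_subtype_b,
        config.group_frequencies,
        config.planted_pairs,
        rng_cohort,
        sample_ids=sample_ids,
    )

    sig_names = list(config.reference_signatures.columns)
    weights = np.array([config.signature_weights[s] for s in sig_names])
    class_probs = config.reference_signatures.to_numpy() @ weights
    class_probs = class_probs / class_probs.sum()

    genes = config.genes_by_symbol
    tsg_genes = [g.symbol for g in config.gene_catalog if g.role in {"tsg", "both"}]

    pp_rows, seg_true_rows, seg_obs, mut_true, chan1_all, chan2_all = [], [], [], [], [], []
    germ_rows, germ_truth_rows, junc_rows, sheet_rows, xregion_rows = [], [], [], [], []

    sample_seeds = ss_samples.spawn(n)
    for i, (sid, subtype) in enumerate(zip(sample_ids, subtypes)):
        rng = np.random.default_rng(sample_seeds[i])
        purity = float(rng.uniform(*config.purity_range))
        ploidy = float(
            rng.choice(config.ploidy_choices, p=np.asarray(config.ploidy_weights))
        )
        truth_groups = truth_matrix.loc[sid].to_dict()

        # germline driver planting (decides forced LOH before CN profile)
        has_germ = rng.random() < config.germline_driver_rate
        germ_gene = rng.choice(tsg_genes) if has_germ else None
        second_hit = bool(has_germ and rng.random() < config.germline_second_hit_rate)

        profile, mechanisms = simulate_cn_profile(
            config, ploidy, truth_groups, rng,
            force_loh_genes=[germ_gene] if second_hit else (),
        )
        by_chrom = _segment_lookup(profile)
        pp_rows.append({"sample_id": sid, "purity": purity, "ploidy": ploidy})
        for chrom, s, e, cn, minor in profile:
            seg_true_rows.append(
                {"sample_id": sid, "chrom": chrom, "start": s, "end": e,
                 "total_cn": cn, "minor_cn": minor}
            )
        seg_obs.append(
            simulate_segments(profile, purity, ploidy, config.segment_log2_noise_sd, rng, sid)
        )

        # background somatic mutations
        rate = rng.uniform(*config.mutations_per_mb_range)
        n_mut = rng.poisson(rate * config.genome.total_mb)
        chrom_lengths = np.array([c.length for c in config.genome], dtype=float)
        chrom_names = [c.name for c in config.genome]
        ci = rng.choice(len(chrom_names), size=n_mut, p=chrom_lengths / chrom_lengths.sum())
        pos = (rng.random(n_mut) * chrom_lengths[ci]).astype(np.int64) + 1
        refs, alts, ctxs = _draw_contexts(n_mut, class_probs, rng)
        cn_arr = np.zeros(n_mut, dtype=int)
        gene_arr = np.full(n_mut, "", dtype=object)
        for k, chrom in enumerate(chrom_names):
            sel = ci == k
            if not sel.any():
                continue
            starts, ends, ns, _minors = by_chrom[chrom]
            seg_i = np.clip(np.searchsorted(starts, pos[sel], side="right") - 1, 0, len(starts) - 1)
            cn_arr[sel] = ns[seg_i]
            for g in config.gene_catalog:
                if g.chrom != chrom:
                    continue
                hit = sel & (pos > g.start) & (pos <= g.end)
                gene_arr[hit] = g.symbol
        keep = cn_arr > 0  # homozygous deletions leave no template to mutate
        maf_arr = true_maf(purity, cn_arr[keep].astype(float), config.mutation_multiplicity)
        rows = [
            (chrom_names[ci[j]], int(pos[j]), refs[j], alts[j], "SNV",
             "coding" if gene_arr[j] else "noncoding", gene_arr[j],
             "", "unknown", "other", float(m), int(cn_arr[j]), False, ctxs[j])
            for j, m in zip(np.flatnonzero(keep), maf_arr)
        ]

        # planted driver mutations (always clonal, coding)
        for grp, carried in truth_groups.items():
            if not carried or grp.endswith("_amplification"):
                continue
            if grp.endswith("_inactivation") and mechanisms.get(grp) == "homdel":
                continue
            gene_sym = "BRAF" if grp.startswith("BRAF") else grp.split("_")[0]
            gene = genes.get(gene_sym)
            if gene is None:
                continue
            gpos = int(rng.integers(gene.start + 1, gene.end))
            cn, _minor = _lookup_cn(by_chrom, gene.chrom, gpos)
            cn = max(cn, 1)
            maf = true_maf(purity, cn, config.mutation_multiplicity)
            if grp == "BRAF_class1":
                change = "V600E" if rng.random() < 0.9 else "V600K"
                dmg, okb = "missense", "oncogenic"
            elif grp == "BRAF_other":
                change, dmg, okb = "G469A", "missense", "likely_oncogenic"
            elif grp.endswith("_mutation"):
                change, dmg, okb = _DRIVER_CHANGES.get(gene_sym, ("E100K", "missense", "oncogenic"))[0:3]
            else:  # TSG point inactivation
                change = f"Q{int(rng.integers(50, 500))}*"
                dmg, okb = rng.choice(["nonsense", "frameshift", "splice_site"]), "unknown"
            rows.append(
                (gene.chrom, gpos, "C", "T", "SNV", "coding", gene_sym,
                 f"p.{change}", okb, dmg, maf, cn, True, "ACA")
            )

        mut_df = pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "class", "region", "gene",
                     "protein_change", "oncokb", "damaging_class", "true_maf",
                     "local_cn", "is_driver", "context"],
        )
        mut_df.insert(0, "sample", sid)

        depth = _nb_depth(len(mut_df), config.depth_mean, config.depth_size, rng)
        alt_reads = rng.binomial(depth, np.clip(mut_df["true_maf"].to_numpy(), 0, 1))
        mut_df["t_depth"] = depth
        mut_df["t_alt"] = alt_reads
        mut_df["n_depth"] = _nb_depth(len(mut_df), config.depth_mean, config.depth_size, rng)
        mut_df["n_alt"] = 0
        mut_df["pop_af_max"] = 0.0
        mut_df["orientation_artifact"] = False
        mut_df["is_true"] = True
        mut_df["force_both_pass"] = mut_df["is_driver"]

        mut_true.append(mut_df)

        # contaminant candidates: common-SNP leaks, orientation artifacts,
        # clustered-events indels (none are in the truth set)
        contam = []
        noise = config.caller_noise
        n_leak = rng.poisson(config.snp_leak_rate * max(len(mut_df), 1))
        n_art = rng.poisson(noise.artifact_rate * max(len(mut_df), 1))
        n_clust = rng.poisson(noise.clustered_indel_rate * max(len(mut_df), 1))
        for kind, count in (("leak", n_leak), ("artifact", n_art), ("clustered", n_clust)):
            for _ in range(count):
                cidx = int(rng.integers(0, len(chrom_names)))
                cpos = int(rng.integers(1, chrom_lengths[cidx]))
                d = int(_nb_depth(1, config.depth_mean, config.depth_size, rng)[0])
                contam.append(
                    {
                        "sample": sid, "chrom": chrom_names[cidx], "pos": cpos,
                        "ref": "C", "alt": "T" if kind != "clustered" else "TA",
                        "class": "SNV" if kind != "clustered" else "INS",
                        "region": "coding", "gene": "", "protein_change": "",
                        "oncokb": "unknown", "damaging_class": "other",
                        "true_maf": np.nan, "local_cn": np.nan, "is_driver": False,
                        "context": "ACA" if kind != "clustered" else "",
                        "t_depth": d, "t_alt": max(int(d * 0.3), 4),
                        "n_depth": d, "n_alt": 0,
                        "pop_af_max": float(rng.uniform(0.011, 0.2)) if kind == "leak" else 0.0,
                        "orientation_artifact": kind == "artifact",
                        "is_true": False,
                        "force_both_pass": True,
                        "filters": "clustered_events" if kind == "clustered" else "",
                    }
                )
        candidates = pd.concat([mut_df, pd.DataFrame(contam)], ignore_index=True) if contam else mut_df
        if "filters" not in candidates.columns:
            candidates["filters"] = ""
        candidates["filters"] = candidates["filters"].fillna("")

        ch1, ch2 = simulate_caller_channels(
            candidates, noise, rng, genome=config.genome,
            depth_mean=config.depth_mean, depth_size=config.depth_size,
        )
        chan1_all.append(ch1)
        chan2_all.append(ch2)

        # germline variants
        n_back = config.germline_background_per_sample
        gci = rng.choice(len(chrom_names), size=n_back, p=chrom_lengths / chrom_lengths.sum())
        gpos = (rng.random(n_back) * chrom_lengths[gci]).astype(np.int64) + 1
        gdepth = _nb_depth(n_back, config.depth_mean, config.depth_size, rng)
        galt = rng.binomial(gdepth, 0.5)
        common = rng.random(n_back) < config.germline_common_fraction
        for j in range(n_back):
            chrom = chrom_names[gci[j]]
            cn, minor = _lookup_cn(by_chrom, chrom, int(gpos[j]))
            alt_copies = minor if rng.random() < 0.5 else cn - minor
            frac = (purity * alt_copies + (1 - purity)) / max(
                purity * cn + (1 - purity) * 2, 1e-9
            )
            tdepth = int(_nb_depth(1, config.depth_mean, config.depth_size, rng)[0])
            germ_rows.append(
                {
                    "patient_id": sid, "chrom": chrom, "pos": int(gpos[j]),
                    "ref": "A", "alt": "G",
                    "depth": int(gdepth[j]), "alt_reads": int(galt[j]),
                    "pop_af_max": float(rng.uniform(0.02, 0.5)) if common[j] else 0.0,
                    "clinvar": "unknown", "oncokb": "unknown",
                    "damaging_class": "other", "near_c_terminus": False, "gene": "",
                    "tumor_depth": tdepth,
                    "tumor_alt": int(rng.binomial(tdepth, min(max(frac, 0.0), 1.0))),
                    "local_total_cn": cn, "local_minor_cn": minor,
                }
            )
        if has_germ:
            gene = genes[germ_gene]
            pos_g = int(rng.integers(gene.start + 1, gene.end))
            d = max(int(_nb_depth(1, config.depth_mean, config.depth_size, rng)[0]), 20)
            cn, minor = _lookup_cn(by_chrom, gene.chrom, pos_g)
            # germline variant sits on the retained allele when LOH planted
            alt_copies = cn - minor if second_hit else 1
            frac = (purity * alt_copies + (1 - purity)) / max(purity * cn + (1 - purity) * 2, 1e-9)
            tdepth = int(_nb_depth(1, config.depth_mean, config.depth_size, rng)[0])
            germ_rows.append(
                {
                    "patient_id": sid, "chrom": gene.chrom, "pos": pos_g,
                    "ref": "C", "alt": "T",
                    "depth": d, "alt_reads": int(rng.binomial(d, 0.5)),
                    "pop_af_max": 0.0, "clinvar": "pathogenic", "oncokb": "unknown",
                    "damaging_class": "nonsense", "near_c_terminus": False,
                    "gene": germ_gene,
                    "tumor_depth": tdepth,
                    "tumor_alt": int(rng.binomial(tdepth, min(max(frac, 0.0), 1.0))),
                    "local_total_cn": cn, "local_minor_cn": minor,
                }
            )
            germ_truth_rows.append(
                {"patient_id": sid, "gene": germ_gene, "second_hit": second_hit}
            )
        if rng.random() < config.clonal_hematopoiesis_rate:
            d = int(rng.integers(40, 90))
            germ_rows.append(
                {
                    "patient_id": sid, "chrom": "chr12", "pos": 4_500_000,
                    "ref": "G", "alt": "T",
                    "depth": d, "alt_reads": int(rng.binomial(d, 0.45)),
                    "pop_af_max": 0.0, "clinvar": "pathogenic", "oncokb": "oncogenic",
                    "damaging_class": "missense", "near_c_terminus": False,
                    "gene": "JAK2",
                    "tumor_depth": int(rng.integers(40, 90)), "tumor_alt": 0,
                    "local_total_cn": int(round(ploidy)), "local_minor_cn": int(round(ploidy)) // 2,
                }
            )

        # structural-variant junctions
        braf1 = bool(truth_groups.get("BRAF_class1", 0))
        sv_mean = config.sv_background_mean_braf1 if braf1 else config.sv_background_mean
        n_j = rng.poisson(sv_mean)
        for _ in range(n_j):
            c1 = int(rng.integers(0, len(chrom_names)))
            c2 = int(rng.integers(0, len(chrom_names)))
            p1 = int(rng.integers(0, chrom_lengths[c1] - 1))
            p2 = int(rng.integers(0, chrom_lengths[c2] - 1))
            junc_rows.append(
                {"chrom1": chrom_names[c1], "start1": p1, "end1": p1 + 1,
                 "chrom2": chrom_names[c2], "start2": p2, "end2": p2 + 1,
                 "name": "background", "score": 0, "strand1": "+", "strand2": "-",
                 "sample_id": sid}
            )
        n_x = 0
        if truth_groups.get("PTP4A1_amplification", 0) and truth_groups.get(
            "CCND1_amplification", 0
        ):
            n_x = 1 + int(rng.poisson(config.sv_cross_region_mean))
            for _ in range(n_x):
                p1 = int(rng.integers(63_000_000, 65_000_000))
                p2 = int(rng.integers(68_000_000, 79_000_000))
                junc_rows.append(
                    {"chrom1": "chr6", "start1": p1, "end1": p1 + 1,
                     "chrom2": "chr11", "start2": p2, "end2": p2 + 1,
                     "name": "cross_region", "score": 0, "strand1": "+", "strand2": "-",
                     "sample_id": sid}
                )
        xregion_rows.append({"sample_id": sid, "n_planted": n_x})

        # clinical covariates and survival
        if subtype == "acral":
            site = rng.choice(["sole", "subungual"], p=[0.66, 0.34])
        else:
            site = rng.choice(
                ["sinonasal", "genitourinary", "gastrointestinal"], p=[0.5, 0.28, 0.22]
            )
        hazard = 1.0
        for grp, hr in config.survival_hazard.items():
            if truth_groups.get(grp, 0):
                hazard *= hr
        scale = config.survival_median_months / math.log(2) / hazard
        t_event = rng.exponential(scale)
        t_censor = rng.uniform(6, 120)
        sheet_rows.append(
            {
                "sample_id": sid, "patient_id": f"P_{sid}", "subtype": subtype,
                "site": site,
                "specimen": rng.choice(["primary", "metastasis"], p=[0.45, 0.55]),
                "assay": rng.choice(["WGS", "WXS"], p=[0.7, 0.3]),
                "mean_coverage": float(np.clip(rng.normal(80, 10), 30, None)),
                "purity": float(np.clip(purity + rng.normal(0, 0.02), 0.05, 1.0)),
                "survival_months": float(min(t_event, t_censor)),
                "survival_event": bool(t_event <= t_censor),
                "ancestry": rng.choice(["EUR", "EAS"], p=[0.6, 0.4]),
            }
        )

    mutations = merge_channel_tables(
        pd.concat(chan1_all, ignore_index=True), pd.concat(chan2_all, ignore_index=True)
    )
    truth_mut = pd.concat(mut_true, ignore_index=True)
    exposures = pd.DataFrame(
        np.tile(weights, (n, 1)), index=pd.Index(sample_ids, name="sample_id"),
        columns=sig_names,
    )
    bundle = CohortBundle(
        mutations=mutations.drop(
            columns=["force_both_pass", "is_driver", "is_true", "true_maf", "local_cn"],
            errors="ignore",
        ),
        germline=pd.DataFrame(germ_rows),
        segments=pd.concat(seg_obs, ignore_index=True),
        junctions=pd.DataFrame(junc_rows),
        sample_sheet=pd.DataFrame(sheet_rows),
        reference_signatures=config.reference_signatures,
    )
    truth = CohortGroundTruth(
        purity_ploidy=pd.DataFrame(pp_rows),
        true_segments=pd.DataFrame(seg_true_rows),
        true_mutations=truth_mut,
        alteration_matrix=truth_matrix,
        exposures=exposures,
        germline_truth=pd.DataFrame(germ_truth_rows, columns=["patient_id", "gene", "second_hit"]),
        cross_region_junctions=pd.DataFrame(xregion_rows),
    )
    return bundle, truth
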