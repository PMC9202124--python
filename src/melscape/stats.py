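"""Cohort-level statistics: burden, frequency comparisons, co-occurrence,
rank-sum and survival tests, and structural-variant junction summaries.

Frequency differences between subtypes (or clinical strata) use two-sided
Fisher's exact tests with Benjamini-Hochberg correction across the tested
alteration groups. Pairwise interdependence between alteration groups is
scored on the 2x2 carrier table, with the effect reported as the log2 ratio
of observed to expected co-occurrence (expected = n_a * n_b / N under
independence, with a 0.5 pseudo-count so exclusive pairs stay finite);
amplification pairs on the same chromosomal arm are excluded because their
co-occurrence is explained by shared arm-level gains rather than selection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .drivers import AlterationMatrix

LOG2_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class PairwiseTestResult:
    """One tested pair (group x group, or group x cohort label)."""

    group_a: str
    group_b: str
    a: int  # both / carrier-in-class-1
    b: int
    c: int
    d: int
    effect_log2: Optional[float]
    p_value: Optional[float]
    fdr: Optional[float] = None
    excluded: bool = False
    excluded_reason: str = ""

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("negative survival time")


def mutation_burden(n_mutations: int, covered_mb: float) -> float:
    """Somatic mutations per megabase of covered genome."""
    if covered_mb <= 0:
        raise ValueError("covered_mb must be positive")
    return n_mutations / covered_mb


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Two-sided by probability-mass ordering: the p-value sums hypergeometric
    probabilities of all same-margin tables no more likely than the observed
    one (up to a small relative slack for ties). Degenerate margins give 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (step-up, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _attach_fdr(results: list[PairwiseTestResult]) -> list[PairwiseTestResult]:
    tested = [i for i, r in enumerate(results) if not r.excluded]
    if tested:
        fdrs = bh_adjust([results[i].p_value for i in tested])
        for i, f in zip(tested, fdrs):
            r = results[i]
            results[i] = PairwiseTestResult(
                r.group_a, r.group_b, r.a, r.b, r.c, r.d,
                r.effect_log2, r.p_value, fdr=float(f),
            )
    return results


def compare_group_frequencies(
    matrix: AlterationMatrix, labels: Mapping[str, str] | pd.Series
) -> list[PairwiseTestResult]:
    """Per-group carrier-frequency comparison between two sample classes.

    ``labels`` maps every sample to one of exactly two class labels. For
    each alteration group a 2x2 (carrier x class) two-sided Fisher test is
    run and BH-adjusted across groups. The effect is the log2 ratio of
    carrier frequencies (pseudo-counted).
    """
    labels = pd.Series(labels)
    missing = [s for s in matrix.samples if s not in labels.index]
    if missing:
        raise ValueError(f"unlabeled samples: {missing[:3]}...")
    lab = labels.loc[matrix.samples]
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    in1 = (lab == classes[0]).to_numpy()
    n1, n2 = int(in1.sum()), int((~in1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate partition: one class is empty")
    results = []
    for grp in matrix.group_names:
        carrier = matrix.occupancy[grp].to_numpy().astype(bool)
        a = int((carrier & in1).sum())
        c = int((carrier & ~in1).sum())
        b, d = n1 - a, n2 - c
        f1 = (a + LOG2_PSEUDOCOUNT) / (n1 + LOG2_PSEUDOCOUNT)
        f2 = (c + LOG2_PSEUDOCOUNT) / (n2 + LOG2_PSEUDOCOUNT)
        results.append(
            PairwiseTestResult(
                grp, f"{classes[0]}_vs_{classes[1]}", a, b, c, d,
                effect_log2=math.log2(f1 / f2),
                p_value=fisher_exact_2x2(a, b, c, d),
            )
        )
    return _attach_fdr(results)


def cooccurrence_scan(
    matrix: AlterationMatrix, exclude_same_arm_amplifications: bool = True
) -> list[PairwiseTestResult]:
    """All-pairs co-occurrence / mutual-exclusivity scan over the matrix.

    For each unordered pair of groups: observed co-carriers o, expected
    e = n_a * n_b / N under independence, effect = log2((o+0.5)/(e+0.5)),
    two-sided Fisher on the carrier 2x2, BH over the tested pairs. Pairs of
    amplification groups sharing a chromosomal arm are marked excluded and
    not tested.
    """
    occ = matrix.occupancy.to_numpy().astype(bool)
    names = matrix.group_names
    N = matrix.n_samples
    meta = matrix.groups
    results: list[PairwiseTestResult] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            if exclude_same_arm_amplifications and len(meta):
                ci, cj = meta.loc[gi], meta.loc[gj]
                if (
                    ci["category"] == "oncogene_amplification"
                    and cj["category"] == "oncogene_amplification"
                    and ci["arm"] != ""
                    and ci["arm"] == cj["arm"]
                ):
                    o = int((occ[:, i] & occ[:, j]).sum())
                    na, nb = int(occ[:, i].sum()), int(occ[:, j].sum())
                    results.append(
                        PairwiseTestResult(
                            gi, gj, o, na - o, nb - o, N - na - nb + o,
                            effect_log2=None, p_value=None,
                            excluded=True, excluded_reason="same_arm",
                        )
                    )
                    continue
            na, nb = int(occ[:, i].sum()), int(occ[:, j].sum())
            o = int((occ[:, i] & occ[:, j]).sum())
            e = na * nb / N
            results.append(
                PairwiseTestResult(
                    gi, gj, o, na - o, nb - o, N - na - nb + o,
                    effect_log2=math.log2((o + LOG2_PSEUDOCOUNT) / (e + LOG2_PSEUDOCOUNT)),
                    p_value=fisher_exact_2x2(o, na - o, nb - o, N - na - nb + o),
                )
            )
    return _attach_fdr(results)


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def logrank_test(records: Iterable[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value).

    chi^2 = (sum_t (O1 - E1))^2 / sum_t V1 over distinct event times, with
    the usual hypergeometric expectation and variance at each time.
    """
    from lifelines.statistics import logrank_test as _ll_logrank

    records = list(records)
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1 = [r for r in records if r.group == groups[0]]
    g2 = [r for r in records if r.group == groups[1]]
    if not g1 or not g2:
        raise ValueError("a group has no subjects")
    if not any(r.event for r in records):
        raise ValueError("no events observed")
    res = _ll_logrank(
        [r.time for r in g1], [r.time for r in g2],
        event_observed_A=[int(r.event) for r in g1],
        event_observed_B=[int(r.event) for r in g2],
    )
    return float(res.test_statistic), float(res.p_value)


def kaplan_meier(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier survival curve S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    from lifelines import KaplanMeierFitter

    records = list(records)
    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [int(r.event) for r in records])
    df = kmf.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


def count_interregion_junctions(
    junctions: pd.DataFrame,
    region_a: tuple[str, int, int],
    region_b: tuple[str, int, int],
    per_sample: bool = True,
) -> pd.Series:
    """Count SV junctions with one endpoint in each region (either order).

    ``junctions`` is a BEDPE-style frame with columns chrom1/start1/end1,
    chrom2/start2/end2 and a ``sample_id`` column (0-based half-open
    endpoints). Junctions entirely inside one region do not count.
    """
    def in_region(chrom, start, end, region):
        rc, rs, re = region
        return (chrom == rc) & (start < re) & (end > rs)

    a1 = in_region(junctions["chrom1"], junctions["start1"], junctions["end1"], region_a)
    b1 = in_region(junctions["chrom1"], junctions["start1"], junctions["end1"], region_b)
    a2 = in_region(junctions["chrom2"], junctions["start2"], junctions["end2"], region_a)
    b2 = in_region(junctions["chrom2"], junctions["start2"], junctions["end2"], region_b)
    cross = (a1 & b2) | (b1 & a2)
    if not per_sample:
        return pd.Series({"all": int(cross.sum())})
    return junctions.loc[cross].groupby("sample_id").size()


def linked_samples(
    junctions: pd.DataFrame,
    region_a: tuple[str, int, int],
    region_b: tuple[str, int, int],
    threshold: int = 1,
) -> list[str]:
    """Samples with at least ``threshold`` junctions linking the two regions."""
    counts = count_interregion_junctions(junctions, region_a, region_b)
    return sorted(counts[counts >= threshold].index)


def results_to_frame(results: Sequence[PairwiseTestResult]) -> pd.DataFrame:
    """Tabulate PairwiseTestResults in the results-TSV column layout."""
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a, "group_b": r.group_b,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "effect_log2": r.effect_log2, "p": r.p_value, "fdr": r.fdr,
                "excluded_reason": r.excluded_reason,
            }
            for r in results
        ]
    )
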