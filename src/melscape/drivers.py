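"""Pathogenic-alteration classification and alteration-group construction.

A mutation in a catalogued cancer gene counts as pathogenic if (1) it is
annotated oncogenic / likely oncogenic / hotspot, or (2) it is a damaging
class (nonsense, stoploss, frameshift, splice site) in a tumor suppressor
gene. Alterations are grouped per gene: TSG inactivation merges damaging
mutations with homozygous deletions; oncogene mutation and amplification are
kept as separate groups; BRAF splits into class 1 (V600E/V600K) versus other
pathogenic BRAF mutations. Groups observed in fewer than ``min_count``
samples are dropped.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .copynumber import GeneCNState
from .genome import GeneModel

ONCOGENIC_LABELS = frozenset({"oncogenic", "likely_oncogenic", "hotspot"})
DAMAGING_CLASSES = frozenset({"nonsense", "stoploss", "frameshift", "splice_site"})
BRAF_CLASS1_CHANGES = frozenset({"V600E", "V600K"})

CATEGORIES = (
    "tsg_inactivation",
    "oncogene_mutation",
    "oncogene_amplification",
    "braf_class1",
    "braf_other",
)

_PROTEIN_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*]|fs\*?\d*|del|ins[A-Z]*)$")


def is_pathogenic(gene: GeneModel, oncokb_label: str, damaging_class: str) -> bool:
    """Core pathogenicity rule shared by somatic and germline classification."""
    if not gene.in_cancer_gene_list:
        return False
    if oncokb_label in ONCOGENIC_LABELS:
        return True
    return damaging_class in DAMAGING_CLASSES and gene.role in {"tsg", "both"}


def classify_pathogenic_mutation(variant, gene: GeneModel) -> bool:
    """Whether a (somatic) variant is a pathogenic mutation of ``gene``.

    ``variant`` needs ``oncokb_label`` and ``damaging_class`` attributes
    (e.g. a SomaticCallRecord). In-frame indels are pathogenic only through
    their annotation, since the damaging-class rule names specific classes.
    """
    return is_pathogenic(gene, variant.oncokb_label, variant.damaging_class)


def classify_braf(variant, gene: Optional[GeneModel] = None) -> str:
    """BRAF mutation class: 'class1' (V600E/V600K), 'other', or 'none'."""
    symbol = gene.symbol if gene is not None else getattr(variant, "gene", None)
    if symbol != "BRAF":
        return "none"
    change = getattr(variant, "protein_change", None)
    if not change:
        return "none"
    m = _PROTEIN_RE.match(change)
    if m is None:
        warnings.warn(f"unparseable protein change {change!r}", stacklevel=2)
        return "none"
    short = f"{m.group(1)}{m.group(2)}{m.group(3)}"
    if short in BRAF_CLASS1_CHANGES:
        return "class1"
    if gene is not None and not is_pathogenic(
        gene, variant.oncokb_label, variant.damaging_class
    ):
        return "none"
    return "other"


@dataclass(frozen=True)
class AlterationEvent:
    """One pathogenic alteration of one gene in one sample."""

    sample_id: str
    gene: str
    category: str  # one of CATEGORIES
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def group(self) -> str:
        if self.category == "tsg_inactivation":
            return f"{self.gene}_inactivation"
        if self.category == "oncogene_mutation":
            return f"{self.gene}_mutation"
        if self.category == "oncogene_amplification":
            return f"{self.gene}_amplification"
        return "BRAF_class1" if self.category == "braf_class1" else "BRAF_other"


@dataclass
class AlterationMatrix:
    """Samples x alteration-group binary occupancy with group metadata.

    ``occupancy`` is a 0/1 DataFrame (rows = samples, columns = groups);
    ``groups`` carries per-group metadata (gene, category, chromosomal arm,
    carrier count). Column order is deterministic: count descending, then
    group name.
    """

    occupancy: pd.DataFrame
    groups: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.occupancy.sum(axis=0)
        if not (counts.values == self.groups["count"].values).all():
            raise ValueError("group counts inconsistent with occupancy column sums")

    @property
    def samples(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def group_names(self) -> list[str]:
        return list(self.occupancy.columns)

    @property
    def n_samples(self) -> int:
        return len(self.occupancy)


def build_alteration_matrix(
    events: Iterable[AlterationEvent],
    samples: Optional[Sequence[str]] = None,
    gene_arms: Optional[Mapping[str, str]] = None,
    min_count: int = 10,
) -> AlterationMatrix:
    """Assemble the binary samples x groups matrix from alteration events.

    Duplicate (sample, group) events collapse to a single carrier. Groups
    carried by fewer than ``min_count`` samples are dropped. ``samples``
    fixes the row universe (samples with no retained alteration still get a
    row); by default it is the set of samples seen in the events, sorted.
    """
    events = list(events)
    if samples is None:
        samples = sorted({e.sample_id for e in events})
    samples = list(samples)
    sample_set = set(samples)
    for e in events:
        if e.sample_id not in sample_set:
            raise ValueError(f"event for unknown sample {e.sample_id!r}")

    meta: dict[str, dict] = {}
    carriers: dict[str, set[str]] = {}
    for e in events:
        grp = e.group
        carriers.setdefault(grp, set()).add(e.sample_id)
        meta.setdefault(
            grp,
            {
                "gene": e.gene,
                "category": e.category,
                "arm": (gene_arms or {}).get(e.gene, ""),
            },
        )

    retained = [g for g, s in carriers.items() if len(s) >= min_count]
    retained.sort(key=lambda g: (-len(carriers[g]), g))

    occ = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=retained, dtype=int)
    for g in retained:
        occ.loc[list(carriers[g] & sample_set), g] = 1
    groups = pd.DataFrame(
        [
            {
                "group": g,
                "gene": meta[g]["gene"],
                "category": meta[g]["category"],
                "arm": meta[g]["arm"],
                "count": len(carriers[g]),
            }
            for g in retained
        ]
    ).set_index("group") if retained else pd.DataFrame(
        columns=["gene", "category", "arm", "count"]
    )
    return AlterationMatrix(occupancy=occ, groups=groups)


def germline_biallelic_check(gene_cn_state: Optional[GeneCNState]) -> Optional[bool]:
    """Second-hit assessment for a pathogenic germline variant carrier.

    True when the carrier's tumor lost the wild-type allele at the gene (LOH
    or homozygous deletion); False when the tumor retained both alleles;
    None when the copy-number state is unavailable.
    """
    if gene_cn_state is None or not gene_cn_state.covered:
        return None
    if gene_cn_state.state in {"loh", "homozygous_deletion"}:
        return True
    if gene_cn_state.minor_cn is None:
        return None
    return gene_cn_state.minor_cn == 0


def events_from_calls(
    mutations,
    gene_states: Mapping[tuple[str, str], GeneCNState],
    genes: Mapping[str, GeneModel],
) -> list[AlterationEvent]:
    """Derive alteration events from filtered mutations and gene CN states.

    ``mutations`` is an iterable of records with sample_id/gene/annotation
    attributes; ``gene_states`` maps (sample_id, gene symbol) to the rolled
    up copy-number state. BRAF class-1 carriers are not double-counted in
    the generic BRAF-other or oncogene-mutation groups.
    """
    events: list[AlterationEvent] = []
    for rec in mutations:
        sym = getattr(rec, "gene", None)
        if not sym or sym not in genes:
            continue
        gene = genes[sym]
        if not classify_pathogenic_mutation(rec, gene):
            continue
        mut_id = f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}"
        if sym == "BRAF":
            cls = classify_braf(rec, gene)
            if cls == "class1":
                events.append(AlterationEvent(rec.sample_id, sym, "braf_class1", mut_id))
            elif cls == "other":
                events.append(AlterationEvent(rec.sample_id, sym, "braf_other", mut_id))
            continue
        if gene.role in {"tsg", "both"} and rec.damaging_class in DAMAGING_CLASSES:
            events.append(AlterationEvent(rec.sample_id, sym, "tsg_inactivation", mut_id))
        elif gene.role in {"oncogene", "both"}:
            events.append(AlterationEvent(rec.sample_id, sym, "oncogene_mutation", mut_id))
        elif gene.role == "tsg":
            # annotated-oncogenic but non-truncating TSG mutation still inactivates
            events.append(AlterationEvent(rec.sample_id, sym, "tsg_inactivation", mut_id))
    for (sample_id, sym), state in gene_states.items():
        if sym not in genes:
            continue
        gene = genes[sym]
        if state.state == "amplified" and gene.role in {"oncogene", "both"}:
            events.append(
                AlterationEvent(sample_id, sym, "oncogene_amplification", f"seg:{state.segment_index}")
            )
        elif state.state == "homozygous_deletion" and gene.role in {"tsg", "both"}:
            events.append(
                AlterationEvent(sample_id, sym, "tsg_inactivation", f"seg:{state.segment_index}")
            )
    return events
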