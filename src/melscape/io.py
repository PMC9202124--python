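"""Readers and writers for the pipeline's tab-separated dialects.

Conventions: SEG files are 1-based inclusive and converted to the internal
0-based half-open convention on read (and back on write); BED/BEDPE are
0-based half-open and pass through unchanged; variant positions are 1-based
(VCF/MAF convention). Unknown columns are preserved on round-trip.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .copynumber import CNSegment
from .filtering import CallerStatus, GermlineCallRecord, SomaticCallRecord
from .signatures import CONTEXT_LABELS

PathLike = Union[str, Path]

MUTATION_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "class", "region",
    "caller1_called", "caller1_pass", "caller1_filters",
    "caller2_called", "caller2_pass", "caller2_filters",
    "t_depth", "t_alt", "n_depth", "n_alt",
    "pop_af_max", "orientation_artifact", "context",
]
SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]
SAMPLE_SHEET_COLUMNS = [
    "sample_id", "patient_id", "subtype", "site", "specimen", "assay",
    "mean_coverage", "purity", "survival_months", "survival_event", "ancestry",
]


def _read_tsv(path: PathLike, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: {label} file missing columns {missing}")
    return df


def write_mutations_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "chrom", "pos", "ref", "alt"], "mutations")
    for col in ("caller1_called", "caller1_pass", "caller2_called", "caller2_pass",
                "orientation_artifact"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col in ("caller1_filters", "caller2_filters", "context"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def somatic_records_from_frame(df: pd.DataFrame) -> list[SomaticCallRecord]:
    """Materialize SomaticCallRecords from a two-channel mutations frame."""
    records = []
    for r in df.to_dict("records"):
        records.append(
            SomaticCallRecord(
                sample_id=r["sample"], chrom=r["chrom"], pos=int(r["pos"]),
                ref=r["ref"], alt=r["alt"],
                variant_class=r.get("class", "SNV"),
                region_class=r.get("region", "noncoding"),
                caller1=CallerStatus(
                    bool(r.get("caller1_called", False)),
                    bool(r.get("caller1_pass", False)),
                    tuple(str(r.get("caller1_filters", "") or "").split("|")) if r.get("caller1_filters") else (),
                ),
                caller2=CallerStatus(
                    bool(r.get("caller2_called", False)),
                    bool(r.get("caller2_pass", False)),
                    tuple(str(r.get("caller2_filters", "") or "").split("|")) if r.get("caller2_filters") else (),
                ),
                tumor_depth=int(r.get("t_depth", 0)),
                tumor_alt=int(r.get("t_alt", 0)),
                normal_depth=int(r.get("n_depth", 0)),
                normal_alt=int(r.get("n_alt", 0)),
                population_af={"max": float(r.get("pop_af_max", 0.0) or 0.0)},
                orientation_artifact=bool(r.get("orientation_artifact", False)),
                trinucleotide_context=(str(r.get("context")) or None)
                if r.get("context") not in (None, "", float("nan")) and str(r.get("context")) != "nan"
                else None,
                gene=(r.get("gene") or None) if str(r.get("gene", "")) != "nan" else None,
                protein_change=(r.get("protein_change") or None)
                if str(r.get("protein_change", "")) != "nan" else None,
                oncokb_label=str(r.get("oncokb", "unknown")) if str(r.get("oncokb", "")) != "nan" else "unknown",
                damaging_class=str(r.get("damaging_class", "other")) if str(r.get("damaging_class", "")) != "nan" else "other",
            )
        )
    return records


def germline_records_from_frame(df: pd.DataFrame) -> list[GermlineCallRecord]:
    records = []
    for r in df.to_dict("records"):
        records.append(
            GermlineCallRecord(
                patient_id=r["patient_id"], chrom=r["chrom"], pos=int(r["pos"]),
                ref=r["ref"], alt=r["alt"],
                depth=int(r["depth"]), alt_reads=int(r["alt_reads"]),
                population_af={"max": float(r.get("pop_af_max", 0.0) or 0.0)},
                clinvar_label=str(r.get("clinvar", "unknown")),
                oncokb_label=str(r.get("oncokb", "unknown")),
                damaging_class=str(r.get("damaging_class", "other")),
                near_c_terminus=bool(r.get("near_c_terminus", False)),
                gene=r.get("gene") or None,
                tumor_depth_at_locus=int(r["tumor_depth"]) if not pd.isna(r.get("tumor_depth", np.nan)) else None,
                tumor_alt_at_locus=int(r["tumor_alt"]) if not pd.isna(r.get("tumor_alt", np.nan)) else None,
            )
        )
    return records


def write_seg(df_or_segments, path: PathLike) -> None:
    """Write SEG (1-based inclusive). Accepts a SEG-dialect frame or CNSegments."""
    if isinstance(df_or_segments, pd.DataFrame):
        df = df_or_segments
    else:
        df = pd.DataFrame(
            [
                {
                    "Sample": s.sample_id, "Chromosome": s.chrom,
                    "Start": s.start + 1, "End": s.end,
                    "Num_Probes": max(int(s.length / 1e4), 2),
                    "Segment_Mean": s.log2_ratio,
                }
                for s in df_or_segments
            ]
        )
    df.to_csv(path, sep="\t", index=False)


def read_seg(path: PathLike) -> pd.DataFrame:
    """Read SEG as written (1-based inclusive coordinates preserved)."""
    return _read_tsv(path, SEG_COLUMNS, "SEG")


def seg_frame_to_segments(df: pd.DataFrame) -> list[CNSegment]:
    """SEG-dialect frame (1-based inclusive) to internal CNSegments (0-based)."""
    return [
        CNSegment(
            sample_id=r["Sample"], chrom=r["Chromosome"],
            start=int(r["Start"]) - 1, end=int(r["End"]),
            log2_ratio=float(r["Segment_Mean"]),
        )
        for r in df.to_dict("records")
    ]


def read_bed(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + [f"extra_{i}" for i in range(df.shape[1] - len(cols))]
    return df


def write_bedpe(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bedpe(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BEDPE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: BEDPE missing columns {missing}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id", "patient_id"], "sample sheet")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    if "survival_event" in df.columns:
        df["survival_event"] = df["survival_event"].astype(bool)
    return df


def write_signature_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="context")


def read_signature_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="context")
    if set(CONTEXT_LABELS) - set(df.index):
        raise ValueError(f"{path}: signature matrix missing context rows")
    return df.reindex(list(CONTEXT_LABELS))


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        return super().default(o)


def write_ground_truth_json(truth, path: PathLike) -> None:
    payload = {
        "purity_ploidy": truth.purity_ploidy.to_dict("records"),
        "true_segments": truth.true_segments.to_dict("records"),
        "true_mutations": truth.true_mutations.to_dict("records"),
        "alteration_matrix": {
            "samples": list(truth.alteration_matrix.index),
            "groups": list(truth.alteration_matrix.columns),
            "occupancy": truth.alteration_matrix.to_numpy().tolist(),
        },
        "exposures": truth.exposures.reset_index().to_dict("records"),
        "germline_truth": truth.germline_truth.to_dict("records"),
        "cross_region_junctions": truth.cross_region_junctions.to_dict("records"),
    }
    Path(path).write_text(json.dumps(payload, cls=_JSONEncoder))


def read_ground_truth_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
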