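"""End-to-end orchestration: simulate -> QC -> filter -> CN -> drivers -> stats.

Each stage consumes the previous stage's tables, writes its outputs under
the configured output directory, and reports record counts into a
machine-readable JSON manifest. Given the same configuration and seed the
run is deterministic, including the manifest bytes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as msio
from . import stats as msstats
from .config import PipelineConfig
from .copynumber import PurityPloidy, assign_gene_cn, compute_segment_cn
from .drivers import build_alteration_matrix, events_from_calls
from .filtering import (
    FilterDecision,
    apply_somatic_evidence_filters,
    sample_qc_filter,
)
from .genome import default_gene_catalog
from .signatures import build_96_catalog, refit_signatures
from .synthetic import CohortBundle, CohortConfig, generate_cohort

logger = logging.getLogger("melscape")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    bundle: Optional[CohortBundle] = None
    truth: Optional[object] = None
    kept_mutations: Optional[pd.DataFrame] = None
    gene_states: Optional[pd.DataFrame] = None
    matrix: Optional[object] = None
    stats_tables: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_inputs(config: PipelineConfig) -> CohortBundle:
    def need(path, stage, what):
        if path is None:
            raise PipelineError(stage, f"missing required input: {what}")
        p = Path(path)
        if not p.exists():
            raise PipelineError(stage, f"input file not found: {p}")
        return p

    mutations = msio.read_mutations_tsv(need(config.mutations_path, "filter", "mutations TSV"))
    segments = msio.read_seg(need(config.segments_path, "cn", "SEG file"))
    sheet = msio.read_sample_sheet(need(config.sample_sheet_path, "qc", "sample sheet"))
    germline = (
        pd.read_csv(config.germline_path, sep="\t") if config.germline_path else pd.DataFrame()
    )
    junctions = (
        msio.read_bedpe(config.junctions_path) if config.junctions_path else pd.DataFrame()
    )
    signatures = (
        msio.read_signature_matrix(config.signatures_path) if config.signatures_path else None
    )
    if signatures is None:
        from .signatures import synthetic_reference_signatures

        signatures = synthetic_reference_signatures(n_flat=4, seed=7)
    return CohortBundle(mutations, germline, segments, junctions, sheet, signatures)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}}
    truth = None

    # ------------------------------------------------------------------ simulate
    if config.run_simulate:
        logger.info("stage simulate: generating synthetic cohort")
        cohort_cfg = CohortConfig(seed=config.seed, **config.cohort)
        bundle, truth = generate_cohort(cohort_cfg)
        msio.write_mutations_tsv(bundle.mutations, outdir / "mutations.tsv")
        bundle.germline.to_csv(outdir / "germline.tsv", sep="\t", index=False)
        msio.write_seg(bundle.segments, outdir / "segments.seg")
        msio.write_bedpe(bundle.junctions, outdir / "junctions.bedpe")
        msio.write_sample_sheet(bundle.sample_sheet, outdir / "samples.tsv")
        msio.write_signature_matrix(bundle.reference_signatures, outdir / "signatures.tsv")
        msio.write_ground_truth_json(truth, outdir / "ground_truth.json")
        genome = cohort_cfg.genome
        gene_catalog = cohort_cfg.gene_catalog
        manifest["stages"]["simulate"] = {
            "n_samples": len(bundle.sample_sheet),
            "n_candidate_mutations": len(bundle.mutations),
            "n_segments": len(bundle.segments),
            "n_germline": len(bundle.germline),
            "n_junctions": len(bundle.junctions),
        }
    else:
        bundle = _load_inputs(config)
        from .genome import default_genome

        genome = default_genome()
        gene_catalog = default_gene_catalog()

    sheet = bundle.sample_sheet

    # ------------------------------------------------------------------ qc
    included = sample_qc_filter(
        sheet, min_coverage=config.qc_min_coverage, min_purity=config.qc_min_purity
    )
    manifest["stages"]["qc"] = {"n_included": len(included), "n_total": len(sheet)}
    logger.info("stage qc: %d/%d samples retained", len(included), len(sheet))
    sheet = sheet[sheet["sample_id"].isin(included)].reset_index(drop=True)

    kept_df = gene_states_df = None
    matrix = None
    stats_tables: dict = {}

    # ------------------------------------------------------------------ filter
    if config.run_filter:
        muts = bundle.mutations[bundle.mutations["sample"].isin(included)]
        records = msio.somatic_records_from_frame(muts)
        kept_rows, dropped_rows = [], []
        for rec, row in zip(records, muts.to_dict("records")):
            if rec.max_population_af > config.pop_af_threshold:
                dropped_rows.append({**row, "drop_reasons": "POP_AF"})
                continue
            decision = apply_somatic_evidence_filters(rec)
            if decision.keep:
                kept_rows.append(row)
            else:
                dropped_rows.append({**row, "drop_reasons": "|".join(decision.reasons)})
        kept_df = pd.DataFrame(kept_rows, columns=muts.columns)
        dropped_df = pd.DataFrame(dropped_rows, columns=list(muts.columns) + ["drop_reasons"])
        msio.write_mutations_tsv(kept_df, outdir / "mutations_kept.tsv")
        msio.write_mutations_tsv(dropped_df, outdir / "mutations_dropped.tsv")
        manifest["stages"]["filter"] = {
            "n_input": len(muts), "n_kept": len(kept_df), "n_dropped": len(dropped_df),
        }
        logger.info("stage filter: kept %d / %d", len(kept_df), len(muts))

    # ------------------------------------------------------------------ cn
    if config.run_cn:
        if "ploidy" not in sheet.columns and truth is not None:
            pp_map = truth.purity_ploidy.set_index("sample_id")
            sheet = sheet.merge(
                pp_map[["ploidy"]], left_on="sample_id", right_index=True, how="left"
            )
        if "ploidy" not in sheet.columns:
            raise PipelineError("cn", "sample sheet lacks a ploidy column")
        seg_df = bundle.segments[bundle.segments["Sample"].isin(included)]
        gene_state_rows = []
        genes = {g.symbol: g for g in gene_catalog}
        for sid, sub in seg_df.groupby("Sample", sort=False):
            row = sheet[sheet["sample_id"] == sid].iloc[0]
            pp = PurityPloidy(float(row["purity"]), float(row["ploidy"]))
            segs = compute_segment_cn(msio.seg_frame_to_segments(sub), pp)
            for gene in gene_catalog:
                st = assign_gene_cn(gene, segs, pp)
                gene_state_rows.append(
                    {
                        "sample_id": sid, "gene": st.gene, "state": st.state,
                        "total_cn": st.total_cn, "total_cn_int": st.total_cn_int,
                        "minor_cn": st.minor_cn, "covered": st.covered,
                    }
                )
        gene_states_df = pd.DataFrame(gene_state_rows)
        gene_states_df.to_csv(outdir / "gene_states.tsv", sep="\t", index=False)
        manifest["stages"]["cn"] = {
            "n_segments": len(seg_df),
            "n_gene_states": len(gene_states_df),
            "n_amplified": int((gene_states_df["state"] == "amplified").sum()),
            "n_homdel": int((gene_states_df["state"] == "homozygous_deletion").sum()),
        }

    # ------------------------------------------------------------------ drivers
    if config.run_drivers:
        if kept_df is None or gene_states_df is None:
            raise PipelineError("drivers", "drivers stage needs filter and cn outputs")
        genes = {g.symbol: g for g in gene_catalog}
        kept_records = msio.somatic_records_from_frame(kept_df)
        state_map = {}
        from .copynumber import GeneCNState

        for r in gene_states_df.to_dict("records"):
            state_map[(r["sample_id"], r["gene"])] = GeneCNState(
                r["gene"], r["state"],
                r["total_cn"], r["total_cn_int"],
                None if pd.isna(r["minor_cn"]) else int(r["minor_cn"]),
                None, covered=bool(r["covered"]),
            )
        events = events_from_calls(kept_records, state_map, genes)
        gene_arms = {g.symbol: g.arm for g in gene_catalog}
        matrix = build_alteration_matrix(
            events, samples=included, gene_arms=gene_arms,
            min_count=config.min_group_count,
        )
        matrix.occupancy.to_csv(outdir / "alteration_matrix.tsv", sep="\t")
        matrix.groups.to_csv(outdir / "alteration_groups.tsv", sep="\t")
        manifest["stages"]["drivers"] = {
            "n_events": len(events),
            "n_groups_retained": len(matrix.group_names),
        }
        logger.info("stage drivers: %d groups retained", len(matrix.group_names))

    # ------------------------------------------------------------------ stats
    if config.run_stats:
        if matrix is None:
            raise PipelineError("stats", "stats stage needs the alteration matrix")
        if "subtype" not in sheet.columns:
            raise PipelineError("stats", "sample sheet lacks a subtype column")
        labels = sheet.set_index("sample_id")["subtype"]
        subtype_res = msstats.compare_group_frequencies(matrix, labels)
        cooc_res = msstats.cooccurrence_scan(matrix)
        msstats.results_to_frame(subtype_res).to_csv(
            outdir / "subtype_comparison.tsv", sep="\t", index=False
        )
        msstats.results_to_frame(cooc_res).to_csv(
            outdir / "cooccurrence.tsv", sep="\t", index=False
        )

        # per-sample burden and UV-signature fraction
        burden_rows = []
        if kept_df is not None:
            snv_kept = kept_df[kept_df["class"] == "SNV"]
            records_by_sample = {
                sid: msio.somatic_records_from_frame(sub)
                for sid, sub in snv_kept.groupby("sample", sort=False)
            }
            for sid in included:
                recs = records_by_sample.get(sid, [])
                burden = msstats.mutation_burden(
                    int((kept_df["sample"] == sid).sum()), genome.total_mb
                )
                sbs7 = np.nan
                if recs:
                    catalog = build_96_catalog(recs, sample_id=sid)
                    expo = refit_signatures(catalog, bundle.reference_signatures)
                    if expo.total > 0 and "SBS7" in expo.signature_names:
                        sbs7 = expo.fraction_of("SBS7")
                burden_rows.append(
                    {"sample_id": sid, "mutations_per_mb": burden, "sbs7_fraction": sbs7}
                )
            burden_df = pd.DataFrame(burden_rows)
            burden_df.to_csv(outdir / "burden.tsv", sep="\t", index=False)
            merged = burden_df.merge(sheet, on="sample_id")
            a = merged.loc[merged["subtype"] == "acral", "mutations_per_mb"]
            b = merged.loc[merged["subtype"] == "mucosal", "mutations_per_mb"]
            stats_tables["burden"] = burden_df
            burden_p = (
                msstats.rank_sum_test(a, b) if len(a) and len(b) else float("nan")
            )
            manifest["stages"]["stats"] = {
                "n_subtype_tests": len(subtype_res),
                "n_cooccurrence_pairs": len(cooc_res),
                "burden_rank_sum_p": burden_p,
                "median_burden_acral": float(a.median()) if len(a) else None,
                "median_burden_mucosal": float(b.median()) if len(b) else None,
            }
        stats_tables["subtype"] = msstats.results_to_frame(subtype_res)
        stats_tables["cooccurrence"] = msstats.results_to_frame(cooc_res)

    manifest["n_samples_final"] = len(sheet)
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return PipelineResult(
        outdir=outdir, manifest=manifest, bundle=bundle, truth=truth,
        kept_mutations=kept_df, gene_states=gene_states_df, matrix=matrix,
        stats_tables=stats_tables,
    )
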