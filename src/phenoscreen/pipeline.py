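"""End-to-end pipeline: normalize → hitcall → cytotox → signatures →
similarity → cluster → qc, with every stage output written to a results
directory.  Outputs are deterministic for a given config and seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .cytotox import cytotox_counts, cytotox_summary_table
from .hitcalls import concordance_table, hitcall_table
from .io import ProfileMatrix, write_level5_table
from .normalize import (HistoricalEnvelope, build_envelope,
                        compute_log10_ratios, invert_down_endpoints)
from .qc import plate_cv_table
from .signatures import evaluate_all, signature_table, summarize_all
from .similarity import ReferenceDB, search_all
from .som import TwoPassClustering, two_pass_clustering
from .vocab import Vocabulary, default_vocabulary

log = logging.getLogger("phenoscreen")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    profiles: ProfileMatrix               # un-inverted Log10Ratios
    profiles_inverted: ProfileMatrix      # direction-corrected (hit calling)
    envelope: HistoricalEnvelope
    hits: pd.DataFrame
    concordance: pd.DataFrame
    cytotox_summary: pd.DataFrame
    n_cytotox: pd.Series
    signature_calls: pd.DataFrame
    signature_summaries: pd.DataFrame
    signature_table: pd.DataFrame
    similarity_matches: pd.DataFrame | None = None
    clustering: TwoPassClustering | None = None
    plate_cvs: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 wells: pd.DataFrame,
                 historical_controls: pd.DataFrame,
                 reference_db: ReferenceDB | None = None,
                 vocabulary: Vocabulary | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage over a validated well table.

    ``historical_controls`` is the long table of historical vehicle
    Log10Ratios used for the significance envelope; ``reference_db`` enables
    the similarity stage.  When ``outdir`` is given, each stage's table is
    written there as CSV/TSV.
    """
    vocabulary = vocabulary or default_vocabulary()
    log.info("pipeline start: seed=%d, %d wells", config.seed, len(wells))

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    if historical_controls is None or len(historical_controls) == 0:
        raise StageError("envelope", ValueError("historical controls are required"))

    profiles = stage("normalize", compute_log10_ratios, wells, vocabulary)
    inverted = stage("normalize", invert_down_endpoints, profiles, vocabulary)
    envelope = stage("envelope", build_envelope, historical_controls,
                     config.envelope_coverage, config.envelope_method)

    hits = stage("hitcall", hitcall_table, inverted, config)
    concordance = stage("hitcall", concordance_table, hits)

    counts = stage("cytotox", cytotox_counts, hits, vocabulary,
                   profiles.values.index)
    cytotox_summary = stage(
        "cytotox", cytotox_summary_table, hits, vocabulary, profiles,
        config.cytotox_log10ratio, config.overt_strict,
        config.nonspecific_cytotox_min)

    calls = stage("signatures", evaluate_all, profiles, envelope, vocabulary,
                  config)
    summaries = stage("signatures", summarize_all, calls, profiles.replicate_of)
    table = stage("signatures", signature_table, summaries)

    matches = None
    if reference_db is not None:
        matches = stage("similarity", search_all, profiles, reference_db,
                        config.similarity_r_min, config.similarity_top_k,
                        True, config.max_cytotox_endpoints_for_profiling)

    clustering = stage("cluster", two_pass_clustering, profiles, counts, config)
    cvs = stage("qc", plate_cv_table, wells)

    result = PipelineResult(
        profiles=profiles, profiles_inverted=inverted, envelope=envelope,
        hits=hits, concordance=concordance, cytotox_summary=cytotox_summary,
        n_cytotox=counts, signature_calls=calls,
        signature_summaries=summaries, signature_table=table,
        similarity_matches=matches, clustering=clustering, plate_cvs=cvs,
    )
    if outdir is not None:
        write_results(result, outdir, config)
    return result


def write_results(result: PipelineResult, outdir: str | Path,
                  config: PipelineConfig | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config is not None:
        config.to_yaml(out / "config.yaml")
    result.profiles.to_tsv(out / "profiles.tsv")
    result.profiles_inverted.to_tsv(out / "profiles_inverted.tsv")
    result.envelope.to_tsv(out / "envelope.tsv")
    write_level5_table(result.hits, out / "hitcalls.csv")
    result.concordance.to_csv(out / "concordance.csv", index=False)
    result.cytotox_summary.to_csv(out / "cytotox_summary.csv", index=False)
    result.signature_calls.to_csv(out / "signature_calls.csv", index=False)
    result.signature_table.to_csv(out / "signature_table.csv")
    if result.similarity_matches is not None:
        result.similarity_matches.to_csv(out / "similarity_matches.csv",
                                         index=False)
    if result.clustering is not None:
        result.clustering.assignments_full.to_csv(out / "clusters_full.csv")
        result.clustering.assignments_filtered.to_csv(
            out / "clusters_filtered.csv")
        result.clustering.cluster_summary.to_csv(
            out / "cluster_summary.csv", index=False)
        result.clustering.som_filtered.codebook_frame().to_csv(
            out / "codebook_filtered.tsv", sep="\t")
    if result.plate_cvs is not None:
        result.plate_cvs.rename("cv_percent").to_csv(out / "plate_cv.csv")
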