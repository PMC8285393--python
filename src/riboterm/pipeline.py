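"""Stage orchestration: simulate → score → metagene → compare.

Each run function takes a :class:`~riboterm.config.RunConfig`, writes
TSV/JSON outputs with ``#``-prefixed provenance headers (config hash,
package version, thresholds), and logs one line per stage with the counts
that matter (records read, deduplicated, dropped, transcripts eligible).
Identical config + inputs + seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import pandas as pd

from . import __version__
from .annotation import TranscriptModel, load_transcript_models
from .config import RunConfig
from .footprints import DensityTrack, build_density, load_footprint_table
from .metrics import MetageneProfile, ScoreTable, metagene, score_table
from .stats import ComparisonResult, mann_whitney_u, wilcoxon_signed_rank

log = logging.getLogger("riboterm")


def _provenance(config: RunConfig, **extra) -> dict:
    prov = {
        "config_hash": config.config_hash(),
        "riboterm_version": __version__,
        "min_cds_reads": config.min_cds_reads,
    }
    prov.update(extra)
    return prov


def _load_models(config: RunConfig) -> list[TranscriptModel]:
    if config.annotation is None:
        raise ValueError("config.annotation is required")
    models, report = load_transcript_models(
        config.annotation, config.fasta, config.fasta_is_genome
    )
    log.info(
        "annotation: %d transcripts loaded, %d dropped %s",
        report.n_loaded,
        report.n_dropped,
        report.dropped_by_reason,
    )
    return models


def _condition_tracks(
    config: RunConfig, models: list[TranscriptModel], condition: str
) -> dict[str, DensityTrack]:
    records = load_footprint_table(config.footprints[condition])
    tracks, rep = build_density(records, models, config.offsets)
    log.info(
        "footprints[%s]: %d read, %d duplicates removed, %d length-filtered, "
        "%d unknown transcript, %d unassignable P-site, %d retained",
        condition,
        rep.n_input,
        rep.n_deduped,
        rep.n_length_filtered,
        rep.n_unknown_transcript,
        rep.n_unassigned_psite,
        rep.n_retained,
    )
    return tracks


@dataclass
class ScoreRunResult:
    score_tables: dict[str, ScoreTable]
    score_paths: dict[str, str]
    comparisons: pd.DataFrame
    comparison_path: str


def compare_tables(
    config: RunConfig, tables: dict[str, ScoreTable]
) -> pd.DataFrame:
    """Run the configured pairwise tests on score tables.

    Pause scores: signed-rank over transcripts eligible in both conditions
    (paired by transcript_id).  RRTS: Mann–Whitney U over each condition's
    eligible transcripts, treatment as the first sample.
    """
    rows = []
    for comp in config.comparisons:
        for name in (comp.reference, comp.treatment):
            if name not in tables:
                raise ValueError(f"comparison names unknown condition {name!r}")
        ref, trt = tables[comp.reference], tables[comp.treatment]
        ref_pause = {r.transcript_id: r.pause_score for r in ref.rows if r.eligible_pause}
        trt_pause = {r.transcript_id: r.pause_score for r in trt.rows if r.eligible_pause}
        shared = sorted(set(ref_pause) & set(trt_pause))
        if not shared:
            raise ValueError(
                f"no transcripts eligible for pause score in both "
                f"{comp.reference!r} and {comp.treatment!r}"
            )
        res_pause = wilcoxon_signed_rank(
            [trt_pause[t] for t in shared],
            [ref_pause[t] for t in shared],
            alternative=comp.pause_alternative,
        )
        ref_rrts = [r.rrts for r in ref.rows if r.eligible_rrts]
        trt_rrts = [r.rrts for r in trt.rows if r.eligible_rrts]
        if not ref_rrts or not trt_rrts:
            empty = comp.reference if not ref_rrts else comp.treatment
            raise ValueError(f"no transcripts eligible for RRTS in {empty!r}")
        res_rrts = mann_whitney_u(trt_rrts, ref_rrts, alternative=comp.rrts_alternative)
        for metric, res in (("pause_score", res_pause), ("rrts", res_rrts)):
            rows.append(_comparison_row(comp.reference, comp.treatment, metric, res))
    return pd.DataFrame(rows)


def _comparison_row(reference: str, treatment: str, metric: str, res: ComparisonResult) -> dict:
    return {
        "reference": reference,
        "treatment": treatment,
        "metric": metric,
        "test": res.test_name,
        "alternative": res.alternative,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n": res.n,
        "n2": res.n2 if res.n2 is not None else "",
        "direction": res.direction,
        "mode": res.mode,
        "n_zero_dropped": res.n_zero_dropped,
    }


def _write_with_header(df: pd.DataFrame, path: str, provenance: dict) -> None:
    with open(path, "w") as fh:
        for key, val in sorted(provenance.items()):
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_score(config: RunConfig) -> ScoreRunResult:
    """Score every condition and run the configured comparisons."""
    os.makedirs(config.output_dir, exist_ok=True)
    models = _load_models(config)
    tables: dict[str, ScoreTable] = {}
    paths: dict[str, str] = {}
    for condition in sorted(config.footprints):
        tracks = _condition_tracks(config, models, condition)
        table = score_table(
            tracks,
            models,
            config.min_cds_reads,
            provenance=_provenance(
                config, condition=condition, offsets=config.offsets.to_dict()
            ),
        )
        n_pause = sum(r.eligible_pause for r in table.rows)
        n_rrts = sum(r.eligible_rrts for r in table.rows)
        if n_pause == 0 and n_rrts == 0:
            raise ValueError(f"condition {condition!r}: zero eligible transcripts")
        log.info(
            "scores[%s]: %d rows, %d pause-eligible, %d RRTS-eligible, "
            "ineligible by reason %s",
            condition, len(table.rows), n_pause, n_rrts, table.ineligible_counts(),
        )
        path = os.path.join(config.output_dir, f"{condition}.scores.tsv")
        table.write_tsv(path)
        tables[condition] = table
        paths[condition] = path

    comparisons = compare_tables(config, tables)
    comp_path = os.path.join(config.output_dir, "comparisons.tsv")
    _write_with_header(comparisons, comp_path, _provenance(config))
    return ScoreRunResult(tables, paths, comparisons, comp_path)


def run_metagene(config: RunConfig) -> dict[str, str]:
    """Write one stop-aligned metagene profile per condition."""
    os.makedirs(config.output_dir, exist_ok=True)
    models = _load_models(config)
    out: dict[str, str] = {}
    for condition in sorted(config.footprints):
        tracks = _condition_tracks(config, models, condition)
        profile: MetageneProfile = metagene(
            tracks,
            models,
            window_up=config.metagene_window_up,
            window_down=config.metagene_window_down,
            min_cds_reads=config.min_cds_reads,
        )
        path = os.path.join(config.output_dir, f"{condition}.metagene.tsv")
        profile.write_tsv(path, _provenance(config, condition=condition))
        out[condition] = path
    return out


def run_simulate(config: RunConfig) -> RunConfig:
    """Simulate a multi-arm experiment into the output directory.

    Returns a config pointing at the generated transcript table and
    footprint files, ready for :func:`run_score` / :func:`run_metagene`
    without edits.
    """
    from .simulate import simulate_experiment

    out = simulate_experiment(
        config.simulate_params,
        config.simulate_conditions,
        config.seed,
        config.output_dir,
    )
    log.info(
        "simulate: %d transcripts, %d conditions -> %s",
        config.simulate_params.n_transcripts,
        len(config.simulate_conditions),
        config.output_dir,
    )
    names = list(out.footprint_tables)
    comparisons = config.comparisons
    if not comparisons and len(names) >= 2:
        from .config import ComparisonSpec

        comparisons = [
            ComparisonSpec(reference=names[0], treatment=other) for other in names[1:]
        ]
    return replace(
        config,
        annotation=out.transcript_table,
        fasta=None,
        footprints=dict(out.footprint_tables),
        comparisons=comparisons,
    )
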