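"""End-to-end evaluation runs: simulate/load -> stats -> distances -> divergence
-> identification -> report bundle.

Every stage is a pure function of (inputs, config, seed); a run writes a
deterministic bundle of TSV/JSON reports plus a manifest with SHA-256 hashes
of every file, so re-running the same config byte-identically reproduces the
bundle. For a three-locus dataset the divergence and identification tables
carry seven analysis columns: the three single loci, the three pairs and the
triple.

Multi-locus handling is dual, matching how combinations are used in barcode
studies: distance-based analyses (divergence metrics, gap histograms,
rank-sum tests) run on the concatenated supermatrix restricted to samples
present in all member loci, while identification combines the per-locus
calls with the traffic-light rule (a sample is identified if any member
locus identifies it).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .alnstats import compute_alignment_stats, write_stats_table
from .distances import distance_matrix
from .divergence import (
    divergence_summary,
    gap_histogram,
    paired_inter_distances,
    partition_pairs,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .errors import BarcodegapError, ValidationError
from .identify import (
    DEFAULT_DISTANCE_THRESHOLD,
    DEFAULT_EVALUE_CUTOFF,
    efficiency_report,
    identify_all_best_hit,
    identify_all_nearest,
    traffic_light_combine,
)
from .io import (
    LocusAlignment,
    MultiLocusDataset,
    concatenate_loci,
    read_locus_alignment,
)
from .synthetic import SynthConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "PipelineStageError", "run_evaluation"]

logger = logging.getLogger(__name__)


class PipelineStageError(BarcodegapError):
    """A named pipeline stage failed; partial outputs may exist on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one full evaluation run.

    Exactly one of ``synth`` (generate the dataset) or ``fasta_paths`` +
    ``meta_path`` (load pre-aligned input) must be given. ``combinations``
    defaults to every pair plus the full locus set.
    """

    outdir: str | Path
    synth: SynthConfig | None = None
    fasta_paths: dict[str, str | Path] | None = None  # locus name -> aligned FASTA
    meta_path: str | Path | None = None
    model: str = "k2p"
    bin_width: float = 0.001
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    methods: Sequence[str] = ("nearest_distance", "best_hit")
    combinations: Sequence[Sequence[str]] | None = None
    overwrite: bool = False

    def validate_inputs(self) -> None:
        if (self.synth is None) == (self.fasta_paths is None):
            raise ValidationError("give exactly one of synth config or input paths")
        if self.fasta_paths is not None and self.meta_path is None:
            raise ValidationError("file input requires a metadata table")
        for m in self.methods:
            if m not in ("nearest_distance", "best_hit"):
                raise ValidationError(f"unknown identification method {m!r}")


def _default_combinations(locus_names: list[str]) -> list[list[str]]:
    combos: list[list[str]] = []
    for r in range(2, len(locus_names) + 1):
        combos.extend(list(c) for c in iter_combinations(locus_names, r))
    return combos


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_evaluation(config: RunConfig) -> dict:
    """Run the full evaluation and write the report bundle to ``config.outdir``.

    Returns a dict with in-memory results (``stats``, ``divergence``,
    ``wilcoxon``, ``histograms``, ``identification``) and the written
    ``files`` mapping.
    """
    config.validate_inputs()
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise ValidationError(
            f"{outdir} is non-empty; pass overwrite=True to replace its contents"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # --- stage: input -----------------------------------------------------
    stage = "input"
    try:
        logger.info("[stage:%s] assembling dataset", stage)
        if config.synth is not None:
            dataset, truth = generate_dataset(config.synth)
            ds_paths = write_dataset(dataset, truth, outdir / "dataset")
            files.update({f"dataset/{k}": v for k, v in ds_paths.items()})
        else:
            loci = [
                read_locus_alignment(path, config.meta_path, name)
                for name, path in config.fasta_paths.items()
            ]
            dataset = MultiLocusDataset(loci)
        locus_names = dataset.locus_names
        combos = (
            [list(c) for c in config.combinations]
            if config.combinations is not None
            else _default_combinations(locus_names)
        )
        for combo in combos:
            unknown = [n for n in combo if n not in locus_names]
            if unknown:
                raise ValidationError(f"combination {combo} names unknown loci {unknown}")
            if len(combo) < 2:
                raise ValidationError(f"combination {combo} needs >= 2 loci")
        all_meta = dataset.all_samples()
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise PipelineStageError(stage, exc) from exc

    # analysis units: single loci, then concatenations
    stage = "concatenate"
    try:
        units: list[LocusAlignment] = [dataset.get_locus(n) for n in locus_names]
        units += [concatenate_loci(dataset, combo) for combo in combos]
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: alignment stats ------------------------------------------
    stage = "alnstats"
    try:
        logger.info("[stage:%s]", stage)
        stats = [compute_alignment_stats(u) for u in units]
        path = outdir / "alignment_stats.tsv"
        write_stats_table(stats, path)
        files["alignment_stats"] = path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: distances -------------------------------------------------
    stage = "distances"
    try:
        logger.info("[stage:%s] model=%s", stage, config.model)
        dms = {u.locus: distance_matrix(u, config.model) for u in units}
        for name, dm in dms.items():
            path = outdir / f"distances_{name.replace('+', '_')}.tsv"
            dm.write_tsv(path)
            files[f"distances/{name}"] = path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: divergence ------------------------------------------------
    stage = "divergence"
    try:
        logger.info("[stage:%s]", stage)
        parts = {name: partition_pairs(dm) for name, dm in dms.items()}
        summaries = {name: divergence_summary(p, name) for name, p in parts.items()}
        rows = [row for name in dms for row in summaries[name].to_rows()]
        path = outdir / "divergence_summary.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        files["divergence_summary"] = path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: rank tests --------------------------------------------------
    stage = "wilcoxon"
    try:
        logger.info("[stage:%s]", stage)
        signed_rows = []
        for name_a, name_b in iter_combinations(locus_names, 2):
            a, b, keys = paired_inter_distances(parts[name_a], parts[name_b])
            if not keys:
                continue
            res = wilcoxon_signed_rank(a, b)
            signed_rows.append(
                {
                    "locus_a": name_a, "locus_b": name_b,
                    "w_plus": res.w_plus, "w_minus": res.w_minus,
                    "n": res.n_used, "p_value": res.p_value,
                    "direction": {
                        "a>b": f"{name_a}>{name_b}", "b>a": f"{name_b}>{name_a}"
                    }.get(res.direction, "none"),
                }
            )
        ranksum_rows = []
        for name, part in parts.items():
            if not part.intra_pairs or not part.inter_pairs:
                continue
            res = wilcoxon_rank_sum(part.intra_distances, part.inter_distances)
            ranksum_rows.append(
                {
                    "locus": name,
                    "rank_sum_intra": res.rank_sum_a, "u_intra": res.u_a,
                    "n_intra": res.n_a, "n_inter": res.n_b,
                    "p_value": res.p_value,
                    "direction": {"a>b": "intra>inter", "b>a": "inter>intra"}.get(
                        res.direction, "none"
                    ),
                }
            )
        p1 = outdir / "wilcoxon_signed_rank.tsv"
        _write_tsv(pd.DataFrame(signed_rows), p1)
        files["wilcoxon_signed_rank"] = p1
        p2 = outdir / "wilcoxon_rank_sum.tsv"
        _write_tsv(pd.DataFrame(ranksum_rows), p2)
        files["wilcoxon_rank_sum"] = p2
        wilcoxon = {"signed_rank": signed_rows, "rank_sum": ranksum_rows}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: barcoding gap ----------------------------------------------
    stage = "gap"
    try:
        logger.info("[stage:%s] bin_width=%g", stage, config.bin_width)
        histograms = {name: gap_histogram(p, config.bin_width) for name, p in parts.items()}
        gap_summary = {}
        for name, h in histograms.items():
            path = outdir / f"gap_histogram_{name.replace('+', '_')}.tsv"
            _write_tsv(pd.DataFrame(h.to_rows()), path)
            files[f"gap_histogram/{name}"] = path
            gap_summary[name] = {
                "zero_fraction_inter_pairs": h.zero_fraction_inter_pairs,
                "zero_involved_sample_fraction": h.zero_involved_sample_fraction,
                "sections": h.sections,
            }
        path = outdir / "gap_summary.json"
        path.write_text(json.dumps(gap_summary, indent=2, sort_keys=True))
        files["gap_summary"] = path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: identification ----------------------------------------------
    stage = "identify"
    try:
        logger.info("[stage:%s] methods=%s", stage, ",".join(config.methods))
        call_rows = []
        reports = []
        for method in config.methods:
            per_locus_calls = {}
            for name in locus_names:
                if method == "nearest_distance":
                    calls = identify_all_nearest(dms[name], config.distance_threshold)
                else:
                    calls = identify_all_best_hit(
                        dataset.get_locus(name), config.evalue_cutoff
                    )
                per_locus_calls[name] = calls
            unit_calls = dict(per_locus_calls)
            for combo in combos:
                combined = traffic_light_combine(per_locus_calls, combo)
                unit_calls["+".join(combo)] = combined
            for unit_name, calls in unit_calls.items():
                reports.append(efficiency_report(calls, all_meta, unit_name, method))
                call_rows.extend(
                    {
                        "sample_id": c.sample_id, "species": c.true_species,
                        "locus": c.locus, "method": c.method, "outcome": c.outcome,
                        "best_match_species": c.best_match_species,
                        "score_or_distance": c.score_or_distance,
                        "threshold_used": c.threshold_used,
                    }
                    for c in calls
                )
        p1 = outdir / "identification_calls.tsv"
        _write_tsv(pd.DataFrame(call_rows), p1)
        files["identification_calls"] = p1
        summary_rows = [
            {
                "locus": r.locus, "method": r.method,
                "species_efficiency_pct": 100.0 * r.species_efficiency,
                "sample_efficiency_pct": 100.0 * r.sample_efficiency,
                "n_correct_samples": r.n_correct_samples, "n_samples": r.n_samples,
                "n_correct_species": r.n_correct_species, "n_species": r.n_species,
                "n_singleton_species": r.n_singleton_species,
            }
            for r in reports
        ]
        p2 = outdir / "identification_summary.tsv"
        _write_tsv(pd.DataFrame(summary_rows), p2)
        files["identification_summary"] = p2
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # --- stage: manifest ----------------------------------------------------
    stage = "manifest"
    try:
        manifest = {
            "package_version": __version__,
            "model": config.model,
            "bin_width": config.bin_width,
            "distance_threshold": config.distance_threshold,
            "evalue_cutoff": config.evalue_cutoff,
            "methods": list(config.methods),
            "combinations": [list(c) for c in combos],
            "seed": config.synth.seed if config.synth is not None else None,
            "synth_config": config.synth.to_dict() if config.synth is not None else None,
            "files": {k: _sha256(p) for k, p in sorted(files.items())},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        files["manifest"] = path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    return {
        "dataset": dataset,
        "stats": stats,
        "distance_matrices": dms,
        "partitions": parts,
        "divergence": summaries,
        "wilcoxon": wilcoxon,
        "histograms": histograms,
        "identification": reports,
        "files": files,
    }
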