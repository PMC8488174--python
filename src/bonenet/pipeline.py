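"""End-to-end driver: simulate/ingest -> (segment) -> quantify -> network -> stats.

Every run writes its stage outputs plus a manifest recording the config
hash, seed, executed stages and a SHA-256 checksum per output file;
re-running with an identical config and seed reproduces identical
checksums, including for the stochastic simulation stage (all randomness
flows from the config seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import mouse_60min_schedule
from .io import (
    read_hu_table,
    read_metadata,
    read_schedule,
    read_tac_tables,
    write_graph,
    write_hu_table,
    write_metadata,
    write_schedule,
    write_tac_tables,
)
from .network import assemble_profiles, graph_summary, knn_threshold_graph, pearson_matrix
from .quantify import (
    AnimalMeta,
    decay_correct_table,
    density_metabolism_quotient,
    suv_records,
)
from .segmentation import HUWindow, extract_hu, extract_tacs, restrict_labels, threshold_mask
from .stats import normality_test, one_way_anova_with_comparisons, per_bone_regressions
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger("bonenet")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_config(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=config.seed)

    def record(stage: str, *paths: Path) -> None:
        manifest.stages.append(stage)
        for p in paths:
            manifest.outputs[p.name] = _sha256(p)

    # ---------------- acquire: simulate or ingest -------------------------
    inputs = config.inputs
    volumetric = inputs.ct_nii and inputs.pet_nii and inputs.labels_nii
    try:
        if volumetric:
            schedule = (
                read_schedule(inputs.schedule_csv) if inputs.schedule_csv else mouse_60min_schedule()
            )
            logger.info("segmenting volumetric inputs (HU window [%g, %g])",
                        config.segmentation.hu_lower, config.segmentation.hu_upper)
            ct = nib.load(inputs.ct_nii)
            pet = nib.load(inputs.pet_nii)
            labels = nib.load(inputs.labels_nii)
            window = HUWindow(config.segmentation.hu_lower, config.segmentation.hu_upper)
            mask = threshold_mask(ct, window)
            vois = restrict_labels(labels, mask, inputs.bone_labels)
            tacs = [extract_tacs(pet, schedule, vois)]
            meta = read_metadata(inputs.metadata_csv)
            hu_series = extract_hu(ct, vois)
            hu = pd.DataFrame(
                {
                    "animal_id": meta["animal_id"].iloc[0],
                    "bone": hu_series.index,
                    "hu": hu_series.to_numpy(),
                }
            )
            tacs[0].animal_id = str(meta["animal_id"].iloc[0])
            stage = "segment"
        elif inputs.tac_csv:
            if not inputs.schedule_csv or not inputs.metadata_csv:
                raise PipelineError("ingest", "tac_csv requires schedule_csv and metadata_csv")
            schedule = read_schedule(inputs.schedule_csv)
            tacs = read_tac_tables(inputs.tac_csv, schedule)
            meta = read_metadata(inputs.metadata_csv)
            hu = read_hu_table(inputs.hu_csv) if inputs.hu_csv else None
            stage = "ingest"
        else:
            schedule = mouse_60min_schedule()
            spec = CohortSpec(
                n_animals=config.cohort.n_animals,
                shared_driver_strength=config.cohort.shared_driver_strength,
                noise_scale=config.cohort.noise_scale,
                dose_mean_MBq=config.cohort.dose_mean_MBq,
                dose_sd_MBq=config.cohort.dose_sd_MBq,
                weight_mean_g=config.cohort.weight_mean_g,
                weight_sd_g=config.cohort.weight_sd_g,
                seed=config.seed,
            )
            logger.info("simulating cohort: %d animals, %d bones, seed %d",
                        spec.n_animals, len(spec.bone_names), spec.seed)
            cohort = generate_cohort(spec, schedule)
            tacs, meta, hu = cohort.tacs, cohort.metadata, cohort.hu
            stage = "simulate"

        tac_path = out_dir / "tacs.csv"
        sched_path = out_dir / "schedule.csv"
        meta_path = out_dir / "metadata.csv"
        write_tac_tables(tacs, tac_path)
        write_schedule(schedule, sched_path)
        write_metadata(meta, meta_path)
        paths = [tac_path, sched_path, meta_path]
        if hu is not None:
            hu_path = out_dir / "hu.csv"
            write_hu_table(hu, hu_path)
            paths.append(hu_path)
        record(stage, *paths)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("acquire", str(e)) from e

    # ---------------- quantify -------------------------------------------
    try:
        metas = {
            str(r.animal_id): AnimalMeta(
                animal_id=str(r.animal_id),
                dose_MBq=float(r.dose_MBq),
                weight_g=float(r.weight_g),
                delay_s=float(r.delay_s),
            )
            for r in meta.itertuples()
        }
        suv_rows, eq_rows = [], []
        for t in tacs:
            m = metas[str(t.animal_id)]
            source = decay_correct_table(t) if config.quantify.decay_correct else t
            for rec in suv_records(source, m, config.quantify.window_min):
                eq_rows.append(
                    {"animal_id": rec.animal_id, "bone": rec.bone, "suv": rec.equilibrium_suv}
                )
                row = {"animal_id": rec.animal_id, "bone": rec.bone}
                row.update(
                    {c: v for c, v in zip(source.values.columns, rec.suv_tac)}
                )
                suv_rows.append(row)
        suv_tac_df = pd.DataFrame(suv_rows)
        eq_df = pd.DataFrame(eq_rows)
        suv_tac_path = out_dir / "suv_tacs.csv"
        eq_path = out_dir / "equilibrium_suv.csv"
        suv_tac_df.to_csv(suv_tac_path, index=False)
        eq_df.to_csv(eq_path, index=False)
        paths = [suv_tac_path, eq_path]

        if hu is not None:
            mean_suv = eq_df.groupby("bone", sort=False)["suv"].mean()
            mean_hu = hu.groupby("bone", sort=False)["hu"].mean()
            quotient = density_metabolism_quotient(mean_suv, mean_hu)
            q_path = out_dir / "quotient.csv"
            quotient.to_csv(q_path)
            paths.append(q_path)
        record("quantify", *paths)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("quantify", str(e)) from e

    # ---------------- network --------------------------------------------
    try:
        profiles = assemble_profiles(tacs, mode=config.network.mode)
        r = pearson_matrix(profiles)
        g = knn_threshold_graph(
            r, r_min=config.network.r_min, k=config.network.knn, rule=config.network.rule
        )
        summary = graph_summary(g)
        logger.info("network: %d nodes, %d edges", g.number_of_nodes(), summary.n_edges)
        graphml_path = out_dir / "network.graphml"
        edges_path = out_dir / "edges.tsv"
        corr_path = out_dir / "correlations.csv"
        write_graph(g, graphml_path, edges_path)
        r.to_csv(corr_path)
        summary_path = out_dir / "network_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "degrees": summary.degrees,
                    "components": [sorted(c) for c in summary.components],
                    "mean_edge_weight": None
                    if np.isnan(summary.mean_edge_weight)
                    else summary.mean_edge_weight,
                    "n_edges": summary.n_edges,
                },
                indent=2,
                sort_keys=True,
            )
        )
        record("network", graphml_path, edges_path, corr_path, summary_path)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("network", str(e)) from e

    # ---------------- stats ----------------------------------------------
    try:
        stats_paths = []
        groups = {
            bone: grp["suv"].to_numpy()
            for bone, grp in eq_df.groupby("bone", sort=False)
        }
        norm_rows = []
        for bone, vals in groups.items():
            try:
                res = normality_test(vals)
                norm_rows.append(
                    {"bone": bone, "shapiro_w": res.statistic, "p": res.p_value}
                )
            except ValueError as e:
                norm_rows.append({"bone": bone, "shapiro_w": np.nan, "p": np.nan})
                logger.warning("normality test skipped for %s: %s", bone, e)
        norm_path = out_dir / "normality.csv"
        pd.DataFrame(norm_rows).to_csv(norm_path, index=False)
        stats_paths.append(norm_path)

        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            comp = one_way_anova_with_comparisons(groups)
            comp_rows = [
                {
                    "bone_a": c.pair[0],
                    "bone_b": c.pair[1],
                    "mean_diff": c.mean_diff,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in comp.comparisons
            ]
            comp_path = out_dir / "comparisons.csv"
            pd.DataFrame(comp_rows).to_csv(comp_path, index=False)
            anova_path = out_dir / "anova.json"
            anova_path.write_text(
                json.dumps({"F": comp.f_statistic, "p": comp.p_value}, indent=2)
            )
            stats_paths += [comp_path, anova_path]

        if hu is not None and eq_df.groupby("bone")["animal_id"].nunique().min() >= 2:
            regressions = per_bone_regressions(eq_df, hu)
            reg_path = out_dir / "regressions.csv"
            regressions.to_csv(reg_path)
            stats_paths.append(reg_path)
        record("stats", *stats_paths)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("stats", str(e)) from e

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    logger.info("run complete: %s", manifest_path)
    return manifest
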