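"""End-to-end orchestration: segment -> align -> classify -> evaluate.

Stages chain: the segmentation's labelled crowns become the alignment's
crown records; the alignment transfers species labels from field stems to
crowns, providing the classifier's training set; evaluation scores each
stage against supplied ground truth.  Any stage can also be run on its own
through the module functions or the CLI, with external inputs replacing
the upstream stage, mirroring workflows where each task's input data is
provided a priori.

The run report is a plain JSON-serialisable dict of per-stage counts and
scores.  Timings go to the log only, so two runs with the same config and
seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import classification as cl
from . import evaluation as ev
from .io_core import (
    CanopyHeightModel,
    CrownRecord,
    PixelObservation,
    SpectralCube,
    load_yaml_config,
    read_chm,
    read_crowns,
    read_cube,
    read_label_raster,
    read_stems,
    write_crown_polygons,
    write_label_raster,
)
from .segmentation import CrownLabelGrid, SegmentationConfig, segment_scene

logger = logging.getLogger("crownpipe")

__all__ = ["RunConfig", "run_pipeline", "extract_crown_pixels", "map_crowns_by_overlap"]

ALL_STAGES = ("segment", "align", "classify", "evaluate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Input paths: ``chm`` and ``cube`` feed segmentation; ``stems`` feeds
    alignment; ``train_pairs`` (stem_id, crown_id rows) together with
    ``train_crowns`` supply the known correspondences on which the
    allometric regression and the RMS normalizers are fitted.  Truth paths
    (``truth_labels``, ``truth_pairs``, ``truth_species``) are only needed
    when the evaluate stage is enabled.
    """

    out_dir: str
    chm: str
    cube: str
    stems: str = ""
    train_pairs: str = ""
    train_crowns: str = ""
    truth_labels: str = ""
    truth_pairs: str = ""
    truth_species: str = ""
    stages: tuple[str, ...] = ALL_STAGES
    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    position_only: bool = False
    n_structural: int = 3
    n_spectral: int = 10
    standardize: bool = False
    plot_id: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = load_yaml_config(path)
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        stages = tuple(data.pop("stages", ALL_STAGES))
        return cls(segmentation=seg, stages=stages, **data)


def extract_crown_pixels(
    grid: CrownLabelGrid,
    chm: CanopyHeightModel,
    cube: SpectralCube,
    id_format: str = "C{k:04d}",
) -> list[PixelObservation]:
    """Per-pixel observations (height + spectrum) for every labelled crown.

    Pixels with a NaN height are skipped.  Crown ids follow ``id_format``
    on the 1-based label, matching the ids given by the polygonizer.
    """
    cube.check_coregistered(chm)
    pixels: list[PixelObservation] = []
    for k in range(1, grid.n_crowns + 1):
        rows, cols = np.nonzero(grid.labels == k)
        crown_id = id_format.format(k=k)
        for r, c in zip(rows, cols):
            h = chm.heights[r, c]
            if not np.isfinite(h):
                continue
            pixels.append(
                PixelObservation(
                    crown_id=crown_id,
                    height_m=float(h),
                    reflectances=cube.reflectance[:, r, c],
                )
            )
    return pixels


def map_crowns_by_overlap(
    predicted: CrownLabelGrid,
    reference: CrownLabelGrid,
    pred_format: str = "C{k:04d}",
    ref_format: str = "C{k:04d}",
) -> dict[str, str]:
    """Map each predicted crown id to the reference crown it overlaps most.

    Predicted crowns with no overlap with any reference crown are omitted.
    Ties go to the smaller reference label.
    """
    if predicted.labels.shape != reference.labels.shape:
        raise ValueError("grid geometry mismatch between predicted and reference")
    mapping: dict[str, str] = {}
    ref = reference.labels
    for k in range(1, predicted.n_crowns + 1):
        sel = ref[predicted.labels == k]
        sel = sel[sel > 0]
        if sel.size == 0:
            continue
        counts = np.bincount(sel)
        best = int(np.argmax(counts))  # argmax keeps the smaller label on ties
        mapping[pred_format.format(k=k)] = ref_format.format(k=best)
    return mapping


def _crown_records_from_grid(
    grid: CrownLabelGrid, chm: CanopyHeightModel, plot_id: str
) -> list[CrownRecord]:
    s = chm.pixel_size
    ox, oy = chm.origin
    crowns = []
    for k in range(1, grid.n_crowns + 1):
        rows, cols = np.nonzero(grid.labels == k)
        if rows.size == 0:
            continue
        crowns.append(
            CrownRecord(
                crown_id=f"C{k:04d}",
                x_pos=float(np.mean(ox + (cols + 0.5) * s)),
                y_pos=float(np.mean(oy - (rows + 0.5) * s)),
                area_m2=float(rows.size) * s * s,
                plot_id=plot_id,
            )
        )
    return crowns


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in order and return the run report.

    The report is also written to ``<out_dir>/report.json``.  A stage
    failure aborts the run with the stage named; outputs of completed
    stages are retained on disk.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": cfg.seed, "stages": list(cfg.stages)}}

    chm = read_chm(cfg.chm)
    cube = read_cube(cfg.cube)

    grid: CrownLabelGrid | None = None
    pred_crowns: list[CrownRecord] = []
    align_result: al.AlignmentResult | None = None
    predictions: list[cl.Prediction] = []

    # ---- segment ---------------------------------------------------------
    if "segment" in cfg.stages:
        t0 = time.perf_counter()
        try:
            grid, polygons = segment_scene(chm, cube, cfg.segmentation)
        except Exception as exc:
            raise RuntimeError(f"stage 'segment' failed: {exc}") from exc
        write_crown_polygons(polygons, out_dir / "crowns.geojson")
        write_label_raster(
            grid.labels, chm.origin, chm.pixel_size, out_dir / "labels.tif",
            crs_label=chm.crs_label,
        )
        pred_crowns = _crown_records_from_grid(grid, chm, cfg.plot_id)
        report["segmentation"] = {
            "n_treetops": len(grid.treetops or []),
            "n_crowns": len(polygons),
        }
        logger.info(
            "segment: %d treetops, %d crowns (%.2f s)",
            len(grid.treetops or []), len(polygons), time.perf_counter() - t0,
        )

    # ---- align -----------------------------------------------------------
    if "align" in cfg.stages:
        t0 = time.perf_counter()
        try:
            stems = read_stems(cfg.stems)
            train_crowns = read_crowns(cfg.train_crowns)
            train_pairs = [
                (str(r.stem_id), str(r.crown_id))
                for r in pd.read_csv(cfg.train_pairs).itertuples()
            ]
            stems = al.cluster_stems_to_plots(stems, train_crowns)
            stem_by_id = {s.stem_id: s for s in stems}
            crown_by_id = {c.crown_id: c for c in train_crowns}
            corrected_train = al.correct_offset(stems, train_crowns)
            corrected_by_id = {s.stem_id: s for s in corrected_train}
            pairs_records = [
                (corrected_by_id[sid], crown_by_id[cid]) for sid, cid in train_pairs
            ]
            model = al.fit_allometry(
                [
                    (stem.stem_diameter_cm, al.diameter_from_area(crown.area_m2))
                    for stem, crown in pairs_records
                ]
            )
            norm = al.compute_normalization(pairs_records, model)
            target_crowns = pred_crowns if pred_crowns else train_crowns
            matched_stems = al.correct_offset(stems, target_crowns)
            align_result = al.optimal_pairing(
                matched_stems, target_crowns, model, norm, cfg.position_only
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'align' failed: {exc}") from exc
        pd.DataFrame(
            [
                (sid, cid, align_result.per_pair_cost[(sid, cid)])
                for sid, cid in align_result.pairs
            ],
            columns=["stem_id", "crown_id", "pair_cost"],
        ).to_csv(out_dir / "alignment.csv", index=False)
        (out_dir / "alignment_model.json").write_text(
            json.dumps(
                {
                    "slope": model.slope,
                    "intercept": model.intercept,
                    "r_squared": model.r_squared,
                    "d_rms": norm.d_rms,
                    "x_rms": norm.x_rms,
                    "y_rms": norm.y_rms,
                    "total_cost": align_result.total_cost,
                },
                indent=1,
                sort_keys=True,
            )
        )
        report["alignment"] = {
            "n_pairs": len(align_result.pairs),
            "n_unmatched_stems": len(align_result.unmatched_stems),
            "n_unmatched_crowns": len(align_result.unmatched_crowns),
            "total_cost": align_result.total_cost,
            "allometry_slope": model.slope,
            "allometry_intercept": model.intercept,
            "allometry_r_squared": model.r_squared,
        }
        logger.info(
            "align: %d pairs, total cost %.3f (%.2f s)",
            len(align_result.pairs), align_result.total_cost, time.perf_counter() - t0,
        )
        stems_for_labels = stem_by_id

    # ---- classify --------------------------------------------------------
    if "classify" in cfg.stages:
        t0 = time.perf_counter()
        try:
            if grid is None:
                raise ValueError("classify requires the segment stage")
            if align_result is None:
                raise ValueError("classify requires the align stage")
            pixels = extract_crown_pixels(grid, chm, cube)
            features = cl.aggregate_features(pixels)
            species_by_crown: dict[str, str] = {}
            for sid, cid in align_result.pairs:
                sp = stems_for_labels[sid].species
                if sp is not None:
                    species_by_crown[cid] = sp
            train = [f for f in features if f.crown_id in species_by_crown]
            reducer = cl.fit_reducer(
                train, cfg.n_structural, cfg.n_spectral, cfg.standardize
            )
            train_reduced = [cl.reduce(f, reducer) for f in train]
            templates = cl.fit_templates(
                train_reduced, [species_by_crown[f.crown_id] for f in train]
            )
            predictions = cl.classify(
                [(f.crown_id, cl.reduce(f, reducer)) for f in features], templates
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
        species = sorted({t.species for t in templates})
        pd.DataFrame(
            [
                {
                    "crown_id": p.crown_id,
                    "label": p.label,
                    **{f"posterior_{k}": p.posterior[k] for k in species},
                }
                for p in predictions
            ]
        ).to_csv(out_dir / "predictions.csv", index=False)
        report["classification"] = {
            "n_classified": len(predictions),
            "n_training": len(train),
            "n_species": len(species),
        }
        logger.info(
            "classify: %d trees over %d species (%.2f s)",
            len(predictions), len(species), time.perf_counter() - t0,
        )

    # ---- evaluate --------------------------------------------------------
    if "evaluate" in cfg.stages:
        t0 = time.perf_counter()
        try:
            scores: dict = {}
            truth_grid: CrownLabelGrid | None = None
            if cfg.truth_labels and grid is not None:
                truth_arr, _, _, _ = read_label_raster(cfg.truth_labels)
                truth_grid = CrownLabelGrid(labels=truth_arr, treetops=None)
                seg_score = ev.score_segmentation(grid, truth_grid)
                scores["segmentation"] = {
                    "mean_jaccard": seg_score.mean_jaccard,
                    "unmatched_reference": seg_score.unmatched_reference,
                    "unmatched_predicted": seg_score.unmatched_predicted,
                }
            if cfg.truth_pairs and align_result is not None and truth_grid is not None:
                truth_pairs = [
                    (str(r.stem_id), str(r.crown_id))
                    for r in pd.read_csv(cfg.truth_pairs).itertuples()
                ]
                crown_map = map_crowns_by_overlap(grid, truth_grid)
                mapped = [
                    (sid, crown_map[cid])
                    for sid, cid in align_result.pairs
                    if cid in crown_map
                ]
                produced = set(mapped)
                accuracy = sum(
                    1 for t in truth_pairs if tuple(t) in produced
                ) / len(truth_pairs)
                scores["alignment"] = {"accuracy": accuracy}
            if cfg.truth_species and predictions and truth_grid is not None:
                truth_species = {
                    str(r.crown_id): str(r.species)
                    for r in pd.read_csv(cfg.truth_species).itertuples()
                }
                crown_map = map_crowns_by_overlap(grid, truth_grid)
                scorable = [
                    p for p in predictions
                    if p.crown_id in crown_map and crown_map[p.crown_id] in truth_species
                ]
                truth_for_pred = {
                    p.crown_id: truth_species[crown_map[p.crown_id]] for p in scorable
                }
                cls_score = ev.score_classification(scorable, truth_for_pred)
                scores["classification"] = {
                    "rank1": cls_score.rank1,
                    "cross_entropy": cls_score.cross_entropy,
                    "per_class": {
                        k: {"precision": v[0], "recall": v[1], "f1": v[2]}
                        for k, v in cls_score.per_class.items()
                    },
                }
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
        report["scores"] = scores
        logger.info("evaluate: done (%.2f s)", time.perf_counter() - t0)

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
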