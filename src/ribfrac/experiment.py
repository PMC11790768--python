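"""In-memory end-to-end study on separable synthetic data.

This is the package's parameter-recovery experiment: generate annotated
unfolded-rib images in the separable regime (large motif magnitude, low
noise), mine ~2,000 patches, split group-wise, train the CPU backbone with
the two-phase schedule, and score all six (level x assessment) reports. The
whole run is seeded and returns every intermediate count, so callers can
report problem sizes alongside the metrics.

The defaults here ARE the study conditions; they are deliberately not
exposed as pipeline knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import SimulationParams, generate_image
from .preprocessing import CropSpec, to_large_coords, upscale_image
from .synthetic import FractureAnnotation
from .mining import (
    PatchSample,
    ShiftScheme,
    box_overlap_curation,
    extract_patch,
    mine_fracture_samples,
    negative_window_corners,
)
from .partition import GroupedDataset, check_no_leakage, group_split
from .classifier import (
    ModelConfig,
    PhaseSpec,
    TrainSchedule,
    build_model,
    predict_logits,
    train_two_phase,
)
from .aggregation import aggregate_group, groups_from_records
from .evaluation import ALL_LEVELS, assess_aggregated, assess_standard

#: Conditions of the desk-scale study: clearly separable motifs, mild noise.
STUDY_PARAMS = SimulationParams(
    motif_magnitude=14,
    noise_sigma=2.0,
    fractures_per_image=4,
    n_rib_bands=8,
)

STUDY_N_POSITIVE = 15
STUDY_N_NEGATIVE = 6

#: Two-phase schedule at desk scale: the standard patience values with a
#: 30-epoch cap per phase, which the small backbone saturates well within.
STUDY_SCHEDULE = TrainSchedule(
    phase1=PhaseSpec(True, 1e-4, 30),
    phase2=PhaseSpec(False, 8e-5, 30),
    early_stop_patience=15,
    plateau_patience=2,
    plateau_factor=0.1,
)


@dataclass
class StudyResult:
    reports: dict  # "<level>_<assessment>" -> MetricsReport
    history: list[dict]
    n_patches: int
    n_positive_samples: int
    n_negative_samples: int
    n_test_groups: int
    n_test_fracture_groups: int
    aggregated_missed_fractures: int
    records: list = field(default_factory=list)  # per-patch test LogitRecords
    groups: list = field(default_factory=list)  # test AggregatedPredictions
    extras: dict = field(default_factory=dict)


def mine_study_samples(
    params: SimulationParams = STUDY_PARAMS,
    n_positive: int = STUDY_N_POSITIVE,
    n_negative: int = STUDY_N_NEGATIVE,
    seed: int = 0,
    factor: int = 3,
) -> tuple[list[PatchSample], list[PatchSample]]:
    """Generate images, upscale, and mine balanced positives/negatives."""
    params = SimulationParams(**{**params.__dict__, "class_mix": dict(params.class_mix), "seed": seed})
    neg_params = SimulationParams(
        **{**params.__dict__, "class_mix": dict(params.class_mix), "fractures_per_image": 0}
    )
    spec = CropSpec(0, 0, params.image_height, params.image_width)
    curation = box_overlap_curation(0.5)
    positives: list[PatchSample] = []
    for i in range(n_positive):
        img, anns = generate_image(params, f"pos_{i:04d}")
        large = upscale_image(img, factor)
        anns_large = [
            FractureAnnotation(
                image_id=a.image_id,
                x=to_large_coords(a.x, a.y, spec, factor)[0],
                y=to_large_coords(a.x, a.y, spec, factor)[1],
                label=a.label,
                extent_box=(
                    *to_large_coords(a.extent_box[0], a.extent_box[1], spec, factor),
                    *to_large_coords(a.extent_box[2], a.extent_box[3], spec, factor),
                ),
            )
            for a in anns
        ]
        positives.extend(mine_fracture_samples(large, anns_large, curation=curation))

    sources = []
    neg_images = {}
    for i in range(n_negative):
        img, _ = generate_image(neg_params, f"neg_{i:04d}")
        large = upscale_image(img, factor)
        neg_images[large.image_id] = large
        sources.extend((large.image_id, rc) for rc in negative_window_corners(large.shape))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xBA1]))
    n_target = min(len(positives), len(sources))
    chosen = np.sort(rng.choice(len(sources), size=n_target, replace=False))
    negatives = []
    for i in chosen:
        image_id, (r, c) = sources[i]
        img = neg_images[image_id]
        half = 49
        negatives.append(
            PatchSample(
                patch=extract_patch(img, (c + half, r + half)),
                label="no_fracture",
                image_id=image_id,
                group_id=f"{image_id}_neg_r{r}_c{c}",
                center=(c + half, r + half),
            )
        )
    return positives, negatives


def run_study(
    seed: int = 0,
    params: SimulationParams = STUDY_PARAMS,
    n_positive: int = STUDY_N_POSITIVE,
    n_negative: int = STUDY_N_NEGATIVE,
    schedule: TrainSchedule = STUDY_SCHEDULE,
    backbone: str = "small_convnet",
) -> StudyResult:
    """Full simulate -> mine -> split -> train -> predict -> aggregate ->
    evaluate run; returns all six reports plus run sizes."""
    positives, negatives = mine_study_samples(params, n_positive, n_negative, seed=seed)
    ds = GroupedDataset.from_samples(positives + negatives)
    train_all, test = group_split(ds, test_fraction=0.30, seed=seed, tolerance=0.03)
    fit, val = group_split(train_all, test_fraction=0.15, seed=seed + 1, tolerance=None)
    check_no_leakage(fit, val, test)

    model = build_model(ModelConfig(backbone=backbone), seed=seed)
    model, history = train_two_phase(model, fit, val, schedule, seed=seed)

    records = predict_logits(model, test)
    groups = [aggregate_group(g) for g in groups_from_records(records)]

    reports = {}
    for level in ALL_LEVELS:
        reports[f"{level.name}_standard"] = assess_standard(records, level)
        reports[f"{level.name}_aggregated"] = assess_aggregated(groups, level)

    frac_groups = [g for g in groups if g.true_label != 0]
    missed = sum(1 for g in frac_groups if g.final_label == 0)
    return StudyResult(
        reports=reports,
        history=history,
        n_patches=len(ds),
        n_positive_samples=len(positives),
        n_negative_samples=len(negatives),
        n_test_groups=len(groups),
        n_test_fracture_groups=len(frac_groups),
        aggregated_missed_fractures=missed,
        records=records,
        groups=groups,
    )
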