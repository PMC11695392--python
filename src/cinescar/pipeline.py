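"""End-to-end assembly: phantom/loaded slices -> channels -> samples -> CNN.

This is the glue that the examples, the CLI and the acceptance script share:
it turns a cine loop plus contours into the five preprocessed channels
(C, FA, FP, MA, MP), stacks them per evaluation protocol, and runs the whole
simulate / split / train / evaluate experiment on a synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import Kind, ParametricImage, fourier_images
from .io import CineLoop, ContourSet, SliceRecord, load_loop, myocardium_mask, \
    rasterize_mask, select_ed_frame, select_es_frame
from .model import ModelConfig, build_model
from .monogenic import build_filters, monogenic_diff
from .phantom import PhantomConfig, PhantomPatient, generate_cohort
from .preprocess import compute_bbox, crop, make_c_channel, normalize, resize
from .protocols import ProtocolSample, build_sample, get_protocol
from .train import (
    EvalReport,
    TrainConfig,
    evaluate_patients,
    evaluate_slices,
    split_patients,
    train,
)

SCAR = "SCAR"


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing and filter parameters shared across a dataset."""

    out_side: int = 224
    margin_px: int = 4
    wavelength: float = 16.0
    sigma_on_f: float = 0.5
    mask_all_channels: bool = False


def slice_channels(
    loop: CineLoop,
    contours: ContourSet,
    config: PipelineConfig = PipelineConfig(),
) -> dict[Kind, ParametricImage]:
    """Compute all five preprocessed channels for one slice.

    Parametric maps are computed on full frames, then every channel is
    cropped with the LV bounding box derived from the ED epicardial contour,
    normalized per channel and resized to ``out_side``.  Only C is
    myocardium-masked unless ``mask_all_channels`` is set.
    """
    ed = select_ed_frame(loop, contours)
    es = select_es_frame(loop, contours)
    shape = loop.shape
    epi_mask = rasterize_mask(contours.epi[ed], shape)
    myo = myocardium_mask(contours, ed, shape)
    bbox = compute_bbox(epi_mask, config.margin_px)

    fa, fp = fourier_images(loop)
    filters = build_filters(shape, config.wavelength, config.sigma_on_f)
    diff = monogenic_diff(
        loop.frames[ed], loop.frames[es], filters,
        patient_id=loop.patient_id, slice_index=loop.slice_index,
    )

    channels: dict[Kind, ParametricImage] = {}
    c_img = make_c_channel(loop.frames[ed], myo, bbox)
    channels["C"] = c_img
    for kind, img in (("FA", fa), ("FP", fp), ("MA", diff.ma), ("MP", diff.mp)):
        data = img.data
        if config.mask_all_channels:
            data = np.where(myo, data, 0.0)
        channels[kind] = ParametricImage(
            crop(data, bbox), kind,
            patient_id=loop.patient_id, slice_index=loop.slice_index,
        )
    for kind, img in channels.items():
        img.data = resize(normalize(img.data), config.out_side)
        img.patient_id = loop.patient_id
        img.slice_index = loop.slice_index
    return channels


def samples_from_patients(
    patients: list[PhantomPatient],
    protocol_name: str,
    config: PipelineConfig = PipelineConfig(),
) -> list[ProtocolSample]:
    """Build protocol samples for every slice of an in-memory cohort."""
    protocol = get_protocol(protocol_name)
    samples = []
    for patient in patients:
        for loop, contours, label in patient.slices:
            channels = slice_channels(loop, contours, config)
            samples.append(
                build_sample(
                    protocol,
                    channels,
                    label=1 if label == SCAR else 0,
                    patient_id=patient.patient_id,
                    slice_index=loop.slice_index,
                )
            )
    return samples


def samples_from_records(
    records: list[SliceRecord],
    protocol_name: str,
    config: PipelineConfig = PipelineConfig(),
) -> list[ProtocolSample]:
    """Build protocol samples from manifest records on disk."""
    protocol = get_protocol(protocol_name)
    samples = []
    for record in records:
        loop, contours = load_loop(record)
        channels = slice_channels(loop, contours, config)
        samples.append(
            build_sample(
                protocol,
                channels,
                label=1 if record.gt_label == SCAR else 0,
                patient_id=record.patient_id,
                slice_index=record.slice_index,
            )
        )
    return samples


@dataclass
class ExperimentResult:
    protocol: str
    slice_report: EvalReport
    patient_report: EvalReport
    history: dict[str, list[float]]
    n_train: int
    n_val: int
    n_test: int
    extras: dict = field(default_factory=dict)


def run_experiment(
    patients: list[PhantomPatient],
    protocol_name: str,
    pipeline_config: PipelineConfig,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_seed: int = 0,
) -> ExperimentResult:
    """Split a cohort patient-wise, train one model, evaluate both levels."""
    roster = [(p.patient_id, p.patient_label) for p in patients]
    plan = split_patients(roster, seed=split_seed)
    plan.assert_disjoint()
    by_id = {p.patient_id: p for p in patients}
    groups = {
        "train": [by_id[i] for i in plan.train_ids],
        "val": [by_id[i] for i in plan.val_ids],
        "test": [by_id[i] for i in plan.test_ids],
    }
    sample_sets = {
        name: samples_from_patients(group, protocol_name, pipeline_config)
        for name, group in groups.items()
    }
    protocol = get_protocol(protocol_name)
    model_config = ModelConfig(
        **{
            **model_config.__dict__,
            "in_channels": protocol.n_channels,
            "input_side": pipeline_config.out_side,
        }
    )
    model = build_model(model_config)
    model, history = train(model, sample_sets["train"], sample_sets["val"], train_config)
    slice_report, probs = evaluate_slices(
        model, sample_sets["test"], train_config.threshold
    )
    patient_labels = {pid: by_id[pid].patient_label for pid in plan.test_ids}
    patient_report = evaluate_patients(
        probs, sample_sets["test"], patient_labels, train_config.threshold
    )
    return ExperimentResult(
        protocol=protocol_name,
        slice_report=slice_report,
        patient_report=patient_report,
        history=history,
        n_train=len(sample_sets["train"]),
        n_val=len(sample_sets["val"]),
        n_test=len(sample_sets["test"]),
    )


def small_study_conditions(seed: int = 0) -> tuple[list[PhantomPatient], PipelineConfig, ModelConfig, TrainConfig]:
    """The package's reference synthetic study at desk scale.

    32 scar + 20 control patients, 3 slices each, 64-pixel grids, 30 frames,
    kappa = 0.1 (severely hypokinetic scar sector), moderate Gaussian noise
    (sigma 6 against a blood-myocardium contrast of 120), crop/resize side
    32, reduced-width model.  The training recipe keeps the clinical
    protocol's loss, batch size, patience and on-the-fly augmentation but
    uses a larger learning rate and a 100-epoch cap, matched to the much
    smaller model and dataset.
    """
    base = PhantomConfig(
        grid_size=64,
        n_frames=30,
        center=(32.0, 32.0),
        r_endo_ed=12.0,
        wall_thickness_ed=6.0,
        contraction_fraction=0.25,
        scar_sector=(0.0, np.pi / 2),
        scar_motion_ratio=0.1,
        noise_sigma=6.0,
    )
    patients = generate_cohort(
        n_scar_patients=32,
        n_control_patients=20,
        slices_per_patient=3,
        base_config=base,
        seed=seed,
    )
    pipeline_config = PipelineConfig(out_side=32, margin_px=4, wavelength=8.0)
    model_config = ModelConfig(
        in_channels=1,
        input_side=32,
        base_filters=8,
        residual_filters=(16, 32, 64),
        fc_units=(64, 32),
        seed=seed,
    )
    train_config = TrainConfig(
        learning_rate=0.05,
        max_epochs=100,
        patience=16,
        batch_size=32,
        # augmentation magnitudes scale with resolution: at side 32 the
        # full-size shift fraction would push the ventricle out of frame
        shift_frac=0.05,
        rot_deg=10.0,
        seed=seed,
    )
    return patients, pipeline_config, model_config, train_config
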