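"""End-to-end conveniences: micrograph -> measurement table.

Also hosts the synthetic recovery experiment used for validation: render
scenes of rods of known true length, run the full pipeline on each, and
return the pooled measurement table alongside the ground truth.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_PIXEL_SIZE_NM, Micrograph
from .measure import MeasurementParams, measure_all, measurements_to_frame
from .segmentation import SegmentationParams, segment
from .synthetic import NoiseModel, render_scene


def measure_micrograph(
    img: Micrograph,
    seg_params: SegmentationParams | None = None,
    meas_params: MeasurementParams | None = None,
) -> pd.DataFrame:
    """Segment one micrograph and measure every retained object."""
    label_map = segment(img, seg_params)
    return measurements_to_frame(measure_all(label_map, meas_params))


def _scene_capacity(max_length_nm: float, width_nm: float, image_px: int,
                    min_gap_nm: float, pixel_size_nm: float) -> int:
    diag = math.hypot(max_length_nm, width_nm) / pixel_size_nm
    cell = diag + min_gap_nm / pixel_size_nm
    return int(image_px // cell) ** 2


def run_recovery_experiment(
    lengths_nm: Sequence[float],
    seed: int,
    image_px: int = 2048,
    width_nm: float = 18.0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    min_gap_nm: float = 54.0,
    noise: NoiseModel | None = None,
    seg_params: SegmentationParams | None = None,
    meas_params: MeasurementParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render isolated rods of the given true lengths and measure them.

    Rods are packed into as many ``image_px``-square scenes as needed
    (capacity per scene follows from the largest rod plus the minimum
    gap). Returns ``(measured, truth)`` data frames; ``measured`` is the
    pooled pipeline output over all scenes.

    Scene seeds are derived deterministically from ``seed``.
    """
    lengths = [float(l) for l in lengths_nm]
    if not lengths:
        raise ValueError("no rod lengths given")
    per_scene = _scene_capacity(max(lengths), width_nm, image_px,
                                min_gap_nm, pixel_size_nm)
    if per_scene < 1:
        raise ValueError(
            f"image of {image_px} px cannot hold a {max(lengths)} nm rod "
            f"with {min_gap_nm} nm clearance"
        )
    n_scenes = math.ceil(len(lengths) / per_scene)
    scene_seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2**31)

    measured_frames, truth_rows = [], []
    for s in range(n_scenes):
        batch = lengths[s * per_scene:(s + 1) * per_scene]
        scene = render_scene(
            batch, width_nm=width_nm, image_shape=(image_px, image_px),
            pixel_size_nm=pixel_size_nm, noise=noise, min_gap_nm=min_gap_nm,
            seed=int(scene_seeds[s]), source_id=f"synthetic:scene={s}",
        )
        measured_frames.append(
            measure_micrograph(scene.image, seg_params, meas_params)
        )
        for rod in scene.rods:
            truth_rows.append({
                "source_id": scene.image.source_id,
                "true_length_nm": rod.true_length_nm,
                "true_width_nm": rod.true_width_nm,
                "orientation_deg": rod.orientation_deg,
                "multimer_k": rod.multimer_k,
            })
    measured = pd.concat(measured_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return measured, truth
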