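"""Ratiometric quantification of two-channel metabolic sensor/dye images.

Each image pair (numerator and denominator excitation channels of a
sensor such as PercevalHR, or dye states such as the JC-1
J-aggregate/monomer) is reduced to a single ROI ratio, then normalized
to the averaged control measurements taken under the same condition
(culture medium), so the control group has mean exactly 1 within every
condition.

The ratio is the ratio of ROI means, not the mean of pixelwise ratios:
it is robust to zero-valued pixels and matches whole-image intensity
measurement practice. A pixelwise mode exists behind a flag. No
background subtraction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RatioMeasurement",
    "SENSOR_CHANNELS",
    "roi_mean_intensity",
    "compute_ratio",
    "normalize_to_control",
]

#: Numerator / denominator channel conventions per sensor. For the
#: excitation-ratiometric sensors the numerator is the state-reporting
#: wavelength (PercevalHR 488 nm = high ATP:ADP over 405 nm = low;
#: pHRed 561 nm over 458 nm; iGlucoSnFR green over its mRuby
#: normalizer); JC-1 is J-aggregate over monomer; RH421 and mitoRFP are
#: single dyes normalized to the H2BGFP infection tracer.
SENSOR_CHANNELS: dict[str, tuple[str, str]] = {
    "PercevalHR": ("ex488", "ex405"),
    "JC1": ("J_aggregate", "monomer"),
    "pHRed": ("ex561", "ex458"),
    "iGlucoSnFR": ("ex488", "ex561"),
    "RH421": ("RH421", "H2BGFP"),
    "mitoRFP": ("mitoRFP", "H2BGFP"),
}


@dataclass(frozen=True)
class RatioMeasurement:
    """One image's sensor readout: raw and control-normalized ratio."""

    sensor: str
    numerator_mean: float
    denominator_mean: float
    raw_ratio: float
    normalized_ratio: float | None = None
    retina_id: str = ""
    image_id: str = ""
    condition: str = ""
    group: str = ""


def roi_mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the masked pixels."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(image[mask].mean())


def compute_ratio(
    channel_num: np.ndarray,
    channel_den: np.ndarray,
    mask: np.ndarray | None,
    sensor: str,
    *,
    retina_id: str = "",
    image_id: str = "",
    condition: str = "",
    group: str = "",
    pixelwise: bool = False,
) -> RatioMeasurement:
    """ROI ratio of two co-registered channels.

    ``mask=None`` measures the whole field. Default is the ratio of ROI
    means; ``pixelwise=True`` averages per-pixel ratios instead (pixels
    with zero denominator are excluded there).
    """
    if sensor not in SENSOR_CHANNELS:
        raise ValueError(f"unknown sensor {sensor!r}; known: {sorted(SENSOR_CHANNELS)}")
    num = np.asarray(channel_num, dtype=np.float64)
    den = np.asarray(channel_den, dtype=np.float64)
    if num.shape != den.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        mask = np.ones(num.shape, dtype=bool)
    num_mean = roi_mean_intensity(num, mask)
    den_mean = roi_mean_intensity(den, mask)
    if den_mean <= 0:
        raise ValueError("denominator ROI mean must be > 0")
    if pixelwise:
        m = np.asarray(mask, dtype=bool) & (den != 0)
        if not m.any():
            raise ValueError("no valid pixels for pixelwise ratio")
        raw = float((num[m] / den[m]).mean())
    else:
        raw = num_mean / den_mean
    return RatioMeasurement(
        sensor=sensor,
        numerator_mean=num_mean,
        denominator_mean=den_mean,
        raw_ratio=raw,
        retina_id=retina_id,
        image_id=image_id,
        condition=condition,
        group=group,
    )


def normalize_to_control(
    measurements: Sequence[RatioMeasurement], control_group: str
) -> list[RatioMeasurement]:
    """Divide every raw ratio by its condition's control-group mean.

    Conditions (media) are normalized independently, so the control
    group's normalized mean is exactly 1 within each condition.

    Raises
    ------
    ValueError
        If some condition has no control-group measurement (the message
        names the condition).
    """
    measurements = list(measurements)
    conditions = {m.condition for m in measurements}
    ctrl_mean: dict[str, float] = {}
    for cond in conditions:
        ctrl = [m.raw_ratio for m in measurements if m.condition == cond and m.group == control_group]
        if not ctrl:
            raise ValueError(f"no control ({control_group!r}) measurements for condition {cond!r}")
        ctrl_mean[cond] = float(np.mean(ctrl))
    return [replace(m, normalized_ratio=m.raw_ratio / ctrl_mean[m.condition]) for m in measurements]
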