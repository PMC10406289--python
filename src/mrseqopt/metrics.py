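"""The 12 acquisition metrics scored on reconstructed phantom images.

From the square phantom: three tissue contrasts (CGC, GWC, CWC — ratios of
mean signal between CSF/GM/WM evaluation squares), three tissue SNRs
(single-image background method with the Rayleigh correction factor 0.655),
the ghost level (mean ghost-region / mean object-region signal; small is
good), sharpness and homogeneity (Pearson correlation against the simulated
target structure).  From the circular phantom: motion sensitivity
(1 - max PCC over integer circular PE shifts — a pure shift of the object is
deliberately not penalized) and distortion sensitivity (the argmax shift
divided by the PE matrix size).  Acquisition time completes the vector.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Optional

import numpy as np

from . import sequence_engine
from .dsl import METRIC_NAMES, SequenceSpec
from .phantom import DigitalPhantom
from .simulator import ReconImage

__all__ = [
    "AcquisitionMetrics",
    "contrast",
    "snr",
    "ghost_level",
    "sharpness",
    "homogeneity",
    "motion_sensitivity",
    "distortion_sensitivity",
    "compute_all",
    "RAYLEIGH_FACTOR",
    "SNR_CAP",
]

RAYLEIGH_FACTOR = 0.655  # background magnitude-noise std = 0.655 * sigma
SNR_CAP = 1e6  # returned for noiseless/degenerate backgrounds

#: canonical metric name -> AcquisitionMetrics field
METRIC_FIELDS = {
    "CGC": "cgc",
    "GWC": "gwc",
    "CWC": "cwc",
    "SNR_CSF": "snr_csf",
    "SNR_GM": "snr_gm",
    "SNR_WM": "snr_wm",
    "GHOST": "ghost_level",
    "SHARPNESS": "sharpness",
    "HOMOGENEITY": "homogeneity",
    "MOTION_SENS": "motion_sens",
    "DISTORTION_SENS": "distortion_sens",
    "ACQ_TIME": "acq_time",
}


@dataclass
class AcquisitionMetrics:
    cgc: float
    gwc: float
    cwc: float
    snr_csf: float
    snr_gm: float
    snr_wm: float
    ghost_level: float
    sharpness: float
    homogeneity: float
    motion_sens: float
    distortion_sens: float
    acq_time: float  # ms

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        """Values in canonical METRIC_NAMES order."""
        return np.array([getattr(self, METRIC_FIELDS[name]) for name in METRIC_NAMES])

    def __getitem__(self, metric: str) -> float:
        return getattr(self, METRIC_FIELDS[metric])


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ReconImage) else np.asarray(img)


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels for a correlation")
    if np.ptp(b) == 0:
        raise ValueError("reference is constant over the mask")
    if np.ptp(a) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# square-phantom metrics
# --------------------------------------------------------------------------


def contrast(img, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Ratio of mean signal in ``mask_a`` over mean signal in ``mask_b``."""
    pix = _pixels(img)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("contrast masks must be non-empty")
    denom = pix[mask_b].mean()
    if denom <= 0:
        raise ValueError("undefined contrast: zero mean in denominator region")
    return float(pix[mask_a].mean() / denom)


def snr(img, tissue_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Single-image SNR: mean(tissue) / (std(background) / 0.655), capped."""
    pix = _pixels(img)
    if not background_mask.any():
        raise ValueError("empty background mask")
    noise = pix[background_mask].std() / RAYLEIGH_FACTOR
    if noise <= 0:
        return SNR_CAP
    return float(min(pix[tissue_mask].mean() / noise, SNR_CAP))


def ghost_level(img, object_mask: np.ndarray, ghost_mask: np.ndarray) -> float:
    """Mean ghost-region signal over mean object signal (0 = no ghost)."""
    pix = _pixels(img)
    if not object_mask.any() or not ghost_mask.any():
        raise ValueError("empty ghost/object mask")
    if (object_mask & ghost_mask).any():
        raise ValueError("ghost and object masks must be disjoint")
    return float(pix[ghost_mask].mean() / pix[object_mask].mean())


def sharpness(img, structure_mask: np.ndarray, reference) -> float:
    """PCC between image and target structure, restricted to the mask."""
    pix = _pixels(img)
    ref = _pixels(reference)
    return _pcc(pix[structure_mask], ref[structure_mask])


def homogeneity(img, csf_window: np.ndarray, reference) -> float:
    """PCC over a window covering the filled CSF area including its boundary."""
    return sharpness(img, csf_window, reference)


# --------------------------------------------------------------------------
# circular-phantom metrics
# --------------------------------------------------------------------------


def _shift_pcc_scan(moving, reference, area_mask: np.ndarray, n_pe: int) -> np.ndarray:
    mov = _pixels(moving)
    ref = _pixels(reference)
    if not area_mask.any():
        raise ValueError("empty evaluation mask")
    return np.array(
        [_pcc(np.roll(mov, d, axis=0)[area_mask], ref[area_mask]) for d in range(n_pe)]
    )


def motion_sensitivity(motion_img, reference_img, area_mask: np.ndarray, n_pe: int) -> float:
    """1 - max PCC over integer circular PE shifts of the motion image."""
    return float(1.0 - _shift_pcc_scan(motion_img, reference_img, area_mask, n_pe).max())


def distortion_sensitivity(offres_img, reference_img, area_mask: np.ndarray, n_pe: int) -> float:
    """Circular distance of the best-matching PE shift over the matrix size.

    Ties are broken toward the smaller circular distance, so a perfectly
    undistorted image scores exactly 0.
    """
    pcc = _shift_pcc_scan(offres_img, reference_img, area_mask, n_pe)
    best = pcc.max()
    candidates = np.where(pcc >= best - 1e-12)[0]
    circ = np.minimum(candidates, n_pe - candidates)
    return float(circ.min() / n_pe)


# --------------------------------------------------------------------------
# the full 12-metric vector
# --------------------------------------------------------------------------


def compute_all(
    spec: SequenceSpec,
    square: DigitalPhantom,
    circular: DigitalPhantom,
    images: Dict[str, ReconImage],
    acq_time_ms: Optional[float] = None,
) -> AcquisitionMetrics:
    """Score the four simulations of one sequence.

    ``images`` must hold the reconstructions keyed ``square`` (noisy),
    ``circular`` (plain), ``circular_offres`` and ``circular_motion``.
    """
    for key in ("square", "circular", "circular_offres", "circular_motion"):
        if key not in images:
            raise ValueError(f"missing simulation {key!r}")
    sq = images["square"]
    masks = square.masks
    ref_sq = square.reference_image
    circ_ref = images["circular"]
    n_pe = circ_ref.pixels.shape[0] if hasattr(circ_ref, "pixels") else circ_ref.shape[0]
    eval_mask = circular.masks["evaluation"]
    if acq_time_ms is None:
        acq_time_ms = sequence_engine.acquisition_time(spec)

    return AcquisitionMetrics(
        cgc=contrast(sq, masks["csf"], masks["gm"]),
        gwc=contrast(sq, masks["gm"], masks["wm"]),
        cwc=contrast(sq, masks["csf"], masks["wm"]),
        snr_csf=snr(sq, masks["csf"], masks["background"]),
        snr_gm=snr(sq, masks["gm"], masks["background"]),
        snr_wm=snr(sq, masks["wm"], masks["background"]),
        ghost_level=ghost_level(sq, masks["object"], masks["ghost"]),
        sharpness=sharpness(sq, masks["structure"], ref_sq),
        homogeneity=homogeneity(sq, masks["homogeneity"], ref_sq),
        motion_sens=motion_sensitivity(images["circular_motion"], circ_ref, eval_mask, n_pe),
        distortion_sens=distortion_sensitivity(
            images["circular_offres"], circ_ref, eval_mask, n_pe
        ),
        acq_time=float(acq_time_ms),
    )
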