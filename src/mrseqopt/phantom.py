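"""Digital brain-tissue phantoms for simulated MRI acquisitions.

Two 2D phantoms are provided, both on a 100 x 100 mm field of view:

* a *square* phantom with CSF, gray-matter and white-matter panels plus a
  striped CSF structure section, used to score contrast, SNR, ghosting,
  sharpness and homogeneity; and
* a *circular* phantom — a small disk, optionally with uniform off-resonance
  or a repeating translational motion pattern along the phase-encoding
  direction — used to score motion and distortion sensitivity.

Spins (isochromats) sit on a regular sub-grid so phantom construction is
deterministic; the number of spins is exactly ``fov_x * fov_y * density``.
Tissue relaxation values default to 3 T brain-tissue literature values.
Image-grid convention: row index = phase-encoding (PE) axis, column index =
readout (RO) axis; pixel (r, c) is centered at y = r - fov/2, x = c - fov/2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "TissueParams",
    "MotionTrajectory",
    "DigitalPhantom",
    "make_square_phantom",
    "make_circular_phantom",
    "displacement",
    "DEFAULT_TISSUES",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue class."""

    t1: float  # ms
    t2: float  # ms
    proton_density: float  # (0, 1]
    delta_f: float = 0.0  # off-resonance, Hz

    def __post_init__(self):
        if not (self.t1 > self.t2 > 0):
            raise ValueError("tissue requires t1 > t2 > 0")
        if self.proton_density <= 0:
            raise ValueError("proton density must be positive")


#: 3 T literature defaults for brain tissue.
DEFAULT_TISSUES: Dict[str, TissueParams] = {
    "CSF": TissueParams(t1=4000.0, t2=2000.0, proton_density=1.0),
    "GM": TissueParams(t1=1350.0, t2=110.0, proton_density=0.8),
    "WM": TissueParams(t1=850.0, t2=80.0, proton_density=0.65),
}

LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3}


@dataclass(frozen=True)
class MotionTrajectory:
    """Repeating rigid translation along the phase-encoding axis.

    ``linear_repeating`` is a sawtooth ramp: displacement grows linearly from
    0 to ``amplitude`` over one period, then wraps back to 0.  ``period`` may
    be None, meaning "one measurement duration" (resolved at simulation time).
    """

    pattern: str = "none"  # none | linear_repeating
    amplitude: float = 5.0  # mm
    period: Optional[float] = None  # ms

    def displacement(self, t: float, period: Optional[float] = None) -> float:
        return displacement(self, t, period)


def displacement(traj: MotionTrajectory, t, period: Optional[float] = None):
    """Displacement (mm) along PE at time ``t`` (ms); vectorized over t."""
    t = np.asarray(t, dtype=float)
    if traj.pattern == "none":
        return np.zeros_like(t) if t.ndim else 0.0
    if traj.pattern != "linear_repeating":
        raise ValueError(f"unknown motion pattern {traj.pattern!r}")
    per = traj.period if traj.period is not None else period
    if per is None or per <= 0:
        raise ValueError("motion period is unset")
    out = traj.amplitude * np.mod(t / per, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class DigitalPhantom:
    """Labeled 2D tissue grid with spins, masks and a motion trajectory."""

    name: str
    fov: Tuple[float, float]  # (PE, RO) extent in mm
    spin_density: float  # spins per mm^2
    label_grid: np.ndarray  # (fov_pe, fov_ro) int labels on the 1-mm grid
    tissues: Dict[str, TissueParams]
    masks: Dict[str, np.ndarray]
    spin_positions: np.ndarray  # (N, 2) [y_pe, x_ro] mm, FOV-centered
    spin_labels: np.ndarray  # (N,) int labels
    motion: MotionTrajectory = field(default_factory=MotionTrajectory)

    @property
    def n_spins(self) -> int:
        return len(self.spin_positions)

    def spin_arrays(self):
        """Per-spin (pd, t1, t2, delta_f) arrays in label order."""
        n = self.n_spins
        pd = np.zeros(n)
        t1 = np.full(n, np.inf)
        t2 = np.full(n, np.inf)
        df = np.zeros(n)
        for tissue, lab in LABELS.items():
            if tissue == "background":
                continue
            sel = self.spin_labels == lab
            params = self.tissues[tissue]
            pd[sel] = params.proton_density
            t1[sel] = params.t1
            t2[sel] = params.t2
            df[sel] = params.delta_f
        return pd, t1, t2, df

    @property
    def reference_image(self) -> np.ndarray:
        """Ground-truth proton-density map on the 1-mm pixel grid."""
        pd_of_label = np.zeros(max(LABELS.values()) + 1)
        for tissue, lab in LABELS.items():
            if tissue != "background":
                pd_of_label[lab] = self.tissues[tissue].proton_density
        return pd_of_label[self.label_grid]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            name=self.name,
            fov=np.asarray(self.fov),
            spin_density=self.spin_density,
            label_grid=self.label_grid,
            spin_positions=self.spin_positions,
            spin_labels=self.spin_labels,
            **{f"mask_{k}": v for k, v in self.masks.items()},
        )


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


def _pixel_grid(fov: Tuple[float, float]):
    """Pixel-center coordinates of the 1-mm image grid."""
    ny, nx = int(round(fov[0])), int(round(fov[1]))
    y = np.arange(ny) - ny / 2.0
    x = np.arange(nx) - nx / 2.0
    return np.meshgrid(y, x, indexing="ij")


def _spin_grid(fov: Tuple[float, float], density: float):
    """Regular sub-grid holding exactly fov_pe * fov_ro * density spins.

    The per-axis subdivision factors are chosen as the most isotropic integer
    factorization of ``density`` (e.g. 4/mm^2 -> 2 x 2, 2/mm^2 -> 2 x 1).
    """
    total = fov[0] * fov[1] * density
    if density <= 0 or abs(total - round(total)) > 1e-9:
        raise ValueError("fov * density must give an integer spin count")
    dens_int = density
    # factor density into ky * kx subdivisions per mm
    best = None
    for ky in range(1, int(np.ceil(np.sqrt(dens_int))) + 1):
        if abs(dens_int / ky - round(dens_int / ky)) < 1e-9:
            kx = int(round(dens_int / ky))
            best = (ky, kx)
    if best is None:
        raise ValueError(f"cannot factor spin density {density} into a regular grid")
    ky, kx = best
    ny = int(round(fov[0] * ky))
    nx = int(round(fov[1] * kx))
    y = (np.arange(ny) + 0.5) / ky - fov[0] / 2.0
    x = (np.arange(nx) + 0.5) / kx - fov[1] / 2.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return np.column_stack([yy.ravel(), xx.ravel()])


def _rect(yy, xx, y0, y1, x0, x1):
    return (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)


# --------------------------------------------------------------------------
# square phantom
# --------------------------------------------------------------------------

#: Geometry of the square phantom (mm, FOV-centered); config-overridable.
SQUARE_GEOMETRY = {
    "object_half_pe": 23.0,  # object spans |y| < 23 so its N/2 ghost clears it
    "object_half_ro": 42.0,
    "panel_edges": (-42.0, -21.0, 0.0, 21.0, 42.0),  # CSF | GM | WM | structure
    "stripe_width": 3.0,  # CSF stripes in the structure section
    "tissue_mask_half": 6.0,  # evaluation squares inside each tissue panel
    # noise region: image corners, clear of the object, its ghost replica and
    # the strongest truncation-ringing tails of both
    "background_margin": 45.0,  # |x| >= margin ...
    "background_corner_pe": 40.0,  # ... and |y| >= this
}


def _square_labels(yy, xx, geom):
    labels = np.zeros(yy.shape, dtype=np.int8)
    hp, hr = geom["object_half_pe"], geom["object_half_ro"]
    e = geom["panel_edges"]
    inside = _rect(yy, xx, -hp, hp, -hr, hr)
    labels[inside & (xx < e[1])] = LABELS["CSF"]
    labels[inside & (xx >= e[1]) & (xx < e[2])] = LABELS["GM"]
    labels[inside & (xx >= e[2]) & (xx < e[3])] = LABELS["WM"]
    # structure section: vertical CSF stripes on background
    stripes = inside & (xx >= e[3])
    stripe_idx = np.floor((xx - e[3]) / geom["stripe_width"]).astype(int)
    labels[stripes & (stripe_idx % 2 == 0)] = LABELS["CSF"]
    return labels


def make_square_phantom(
    fov: Tuple[float, float] = (100.0, 100.0),
    spin_density: float = 4.0,
    tissues: Optional[Dict[str, TissueParams]] = None,
    geometry: Optional[dict] = None,
) -> DigitalPhantom:
    """Square contrast/SNR/ghost/sharpness phantom (default 40,000 spins)."""
    if fov[0] <= 0 or fov[1] <= 0:
        raise ValueError("FOV must be positive")
    geom = dict(SQUARE_GEOMETRY)
    if geometry:
        geom.update(geometry)
    scale = min(fov) / 100.0
    if scale != 1.0:  # shrink geometry proportionally for reduced-FOV phantoms
        geom = {
            k: tuple(v * scale for v in val) if isinstance(val, tuple) else val * scale
            for k, val in geom.items()
        }
    tissues = dict(tissues or DEFAULT_TISSUES)

    yy, xx = _pixel_grid(fov)
    label_grid = _square_labels(yy, xx, geom)
    spins = _spin_grid(fov, spin_density)
    spin_labels = _square_labels(spins[:, 0], spins[:, 1], geom)

    hp, hr = geom["object_half_pe"], geom["object_half_ro"]
    e = geom["panel_edges"]
    half = geom["tissue_mask_half"]
    support = label_grid > 0
    n_pe = label_grid.shape[0]

    def tissue_square(center_x):
        return _rect(yy, xx, -half, half, center_x - half, center_x + half)

    masks = {
        "object": _rect(yy, xx, -hp, hp, -hr, hr),
        "support": support,
        "csf": tissue_square((e[0] + e[1]) / 2.0),
        "gm": tissue_square((e[1] + e[2]) / 2.0),
        "wm": tissue_square((e[2] + e[3]) / 2.0),
        "structure": _rect(yy, xx, -hp, hp, e[3], e[4]),
        "homogeneity": _rect(yy, xx, -hp - 2, hp + 2, e[0] - 2, e[1] + 2),
        "background": (np.abs(xx) >= geom["background_margin"])
        & (np.abs(yy) >= geom["background_corner_pe"]),
    }
    masks["ghost"] = np.roll(masks["object"], n_pe // 2, axis=0) & ~masks["object"]
    masks["background"] &= ~masks["object"] & ~masks["ghost"]
    return DigitalPhantom(
        name="square",
        fov=fov,
        spin_density=spin_density,
        label_grid=label_grid,
        tissues=tissues,
        masks=masks,
        spin_positions=spins,
        spin_labels=spin_labels,
    )


# --------------------------------------------------------------------------
# circular phantom
# --------------------------------------------------------------------------


def make_circular_phantom(
    fov: Tuple[float, float] = (100.0, 100.0),
    spin_density: float = 2.0,
    radius: float = 15.0,
    tissue: str = "GM",
    tissues: Optional[Dict[str, TissueParams]] = None,
    off_resonance: bool = False,
    off_resonance_hz: float = 50.0,
    motion: bool = False,
    motion_amplitude: float = 5.0,
    motion_period: Optional[float] = None,
) -> DigitalPhantom:
    """Small disk phantom for motion/distortion scoring (default 20,000 spins).

    With ``off_resonance`` set, every tissue precesses at a uniform
    ``off_resonance_hz``; with ``motion`` set, a sawtooth translation of
    ``motion_amplitude`` mm along PE repeats every ``motion_period`` ms
    (None = one measurement duration).
    """
    if fov[0] <= 0 or fov[1] <= 0:
        raise ValueError("FOV must be positive")
    base = dict(tissues or DEFAULT_TISSUES)
    df = off_resonance_hz if off_resonance else 0.0
    base = {
        key: TissueParams(p.t1, p.t2, p.proton_density, df) for key, p in base.items()
    }

    yy, xx = _pixel_grid(fov)
    rr2 = yy**2 + xx**2
    lab = LABELS[tissue]
    label_grid = np.where(rr2 <= radius**2, lab, 0).astype(np.int8)
    spins = _spin_grid(fov, spin_density)
    spin_r2 = spins[:, 0] ** 2 + spins[:, 1] ** 2
    spin_labels = np.where(spin_r2 <= radius**2, lab, 0).astype(np.int8)

    window = 2.0 * radius
    masks = {
        "support": label_grid > 0,
        "evaluation": _rect(yy, xx, -window, window, -window, window),
    }
    traj = MotionTrajectory(
        pattern="linear_repeating" if motion else "none",
        amplitude=motion_amplitude,
        period=motion_period,
    )
    return DigitalPhantom(
        name="circular",
        fov=fov,
        spin_density=spin_density,
        label_grid=label_grid,
        tissues=base,
        masks=masks,
        spin_positions=spins,
        spin_labels=spin_labels,
        motion=traj,
    )
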