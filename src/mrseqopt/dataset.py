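"""Training-data generation: parameter grid, simulation campaign, holdout split.

The default grid is the Cartesian product of the per-family parameter lists
used for training-data generation (four families: EPI, SE-EPI, bSSFP, RARE),
filtered by the physical validity checks of :mod:`.sequence_engine`.  Each
surviving sequence is simulated four times — square phantom; circular plain;
circular with off-resonance; circular with motion — and scored into one row
of 12 inputs and 12 metrics.  Rows are split 60/20/20 into train/test/
validation partitions (three-way holdout).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import sequence_engine, simulator
from .dsl import METRIC_NAMES, PrescanSpec, PulseSpec, SequenceSpec, expand_defaults
from .phantom import DigitalPhantom, make_circular_phantom, make_square_phantom

__all__ = [
    "TRAINING_GRID",
    "INPUT_COLUMNS",
    "NUMERIC_COLUMNS",
    "METRIC_COLUMNS",
    "spec_to_vector",
    "vector_to_spec",
    "build_grid",
    "default_phantoms",
    "simulate_sequence",
    "run_campaign",
    "split",
    "small_grid_config",
]

logger = logging.getLogger(__name__)

#: Per-family parameter value lists of the shipped training grid.
TRAINING_GRID: Dict[str, dict] = {
    "EPI": {
        "matrix": [32, 64],
        "te": [10.0, 60.0, 110.0],
        "tr": [100.0, 1500.0, 6000.0],
        "etl": [1],
        "epi_factor": [16, 32, 64],
        "readout_duration": [0.4, 0.5],
        "excitation_angle": [90.0],
        "refocussing_angle": [0.0],
        "measurements": [1, 10],
        "prescans": [0],
    },
    "SE-EPI": {
        "matrix": [32, 64],
        "te": [10.0, 60.0, 110.0],
        "tr": [100.0, 1500.0, 6000.0],
        "etl": [1],
        "epi_factor": [16, 32, 64],
        "readout_duration": [0.4, 0.5],
        "excitation_angle": [90.0],
        "refocussing_angle": [180.0],
        "measurements": [1, 10],
        "prescans": [0],
    },
    "bSSFP": {
        "matrix": [32, 64],
        "te": [2.0, 5.0, 8.0, 11.0, 14.0, 17.0],
        "tr": [4.0, 12.0, 20.0, 28.0, 36.0],
        "etl": [1],
        "epi_factor": [1],
        "readout_duration": [2.0],
        "excitation_angle": [90.0],
        "refocussing_angle": [0.0],
        "measurements": [1, 2],
        "prescans": [8],
    },
    "RARE": {
        "matrix": [32, 64],
        "te": [10.0, 60.0, 110.0, 160.0],
        "tr": [100.0, 1500.0, 6000.0],
        "etl": [16, 32, 64],
        "epi_factor": [1],
        "readout_duration": [1.0, 1.1],
        "excitation_angle": [90.0],
        "refocussing_angle": [180.0],
        "measurements": [1, 10],
        "prescans": [0],
    },
}

INPUT_COLUMNS = [
    "echo_type",
    "readout_type",
    "matrix",
    "te",
    "tr",
    "etl",
    "epi_factor",
    "readout_duration",
    "excitation_angle",
    "refocussing_angle",
    "measurements",
    "prescans",
]

#: The categorical-free view used by surrogates; echo/readout type are
#: recoverable from refocussing_angle (0 = gradient echo) and epi_factor
#: (1 = line readout).
NUMERIC_COLUMNS = [c for c in INPUT_COLUMNS if c not in ("echo_type", "readout_type")]

METRIC_COLUMNS = [metrics_mod.METRIC_FIELDS[name] for name in METRIC_NAMES]


# --------------------------------------------------------------------------
# sequence vector <-> spec
# --------------------------------------------------------------------------


def spec_to_vector(spec: SequenceSpec) -> dict:
    """The 12 named training inputs of one sequence."""
    return {
        "echo_type": spec.echo_type,
        "readout_type": spec.readout_type,
        "matrix": spec.n_rows,
        "te": spec.te,
        "tr": spec.tr,
        "etl": spec.etl,
        "epi_factor": spec.epi_factor,
        "readout_duration": spec.readout_duration,
        "excitation_angle": spec.excitation.angle,
        "refocussing_angle": spec.refocussing_angle,
        "measurements": spec.measurements,
        "prescans": spec.prescan_count,
    }


def vector_to_spec(vec: dict, name: Optional[str] = None) -> SequenceSpec:
    """Decode a sequence vector back into a complete SequenceSpec.

    Echo/readout type are taken from the categorical entries when present,
    otherwise recovered from refocussing_angle and epi_factor.
    """
    echo = vec.get("echo_type") or ("SpinEcho" if vec["refocussing_angle"] > 0 else "GradientEcho")
    readout = vec.get("readout_type") or (
        "LineReadout" if int(round(vec["epi_factor"])) <= 1 else "EPIReadout"
    )
    base = expand_defaults(
        SequenceSpec(name=name or "decoded", echo_type=echo, readout_type=readout)
    )
    spec = replace(
        base,
        excitation=PulseSpec("sincpulse", float(vec["excitation_angle"])),
        refocussing=(
            PulseSpec("sincpulse", float(vec["refocussing_angle"]))
            if echo == "SpinEcho"
            else None
        ),
        readout_duration=float(vec["readout_duration"]),
        n_columns=int(vec["matrix"]),
        n_rows=int(vec["matrix"]),
        te=float(vec["te"]),
        tr=float(vec["tr"]),
        epi_factor=int(vec["epi_factor"]),
        etl=int(vec["etl"]),
        measurements=int(vec["measurements"]),
        prescans=PrescanSpec(int(vec["prescans"]), "linear") if vec["prescans"] > 0 else None,
    )
    if name is None:
        spec.name = _auto_name(spec)
    return spec


def _auto_name(spec: SequenceSpec) -> str:
    return (
        f"{spec.family}-m{spec.n_rows}-te{spec.te:g}-tr{spec.tr:g}"
        f"-etl{spec.etl}-epi{spec.epi_factor}-ro{spec.readout_duration:g}"
        f"-n{spec.measurements}"
    )


# --------------------------------------------------------------------------
# grid construction
# --------------------------------------------------------------------------


def build_grid(
    grid_cfg: Optional[Dict[str, dict]] = None, filter_valid: bool = True
) -> List[SequenceSpec]:
    """Cartesian product of the per-family value lists, validity-filtered."""
    grid_cfg = grid_cfg or TRAINING_GRID
    specs: List[SequenceSpec] = []
    for family, params in grid_cfg.items():
        keys = list(params)
        for combo in itertools.product(*(params[k] for k in keys)):
            vec = dict(zip(keys, combo))
            spec = vector_to_spec(vec)
            if spec.family != family:
                raise ValueError(f"grid row for {family} decodes to {spec.family}")
            if not filter_valid or sequence_engine.validate(spec).valid:
                specs.append(spec)
    if filter_valid and not specs:
        raise ValueError("validity filtering removed every grid combination")
    return specs


def small_grid_config(matrix: int = 16) -> Dict[str, dict]:
    """A reduced grid (single small matrix, single measurement) for fast runs."""
    cfg = {}
    for family, params in TRAINING_GRID.items():
        small = {k: list(v) for k, v in params.items()}
        small["matrix"] = [matrix]
        small["measurements"] = [1]
        small["readout_duration"] = [params["readout_duration"][-1]]
        small["etl"] = sorted({min(v, matrix) for v in params["etl"]})
        small["epi_factor"] = sorted({min(v, matrix) for v in params["epi_factor"]})
        cfg[family] = small
    return cfg


# --------------------------------------------------------------------------
# simulation campaign
# --------------------------------------------------------------------------


def default_phantoms(fov: float = 100.0) -> Dict[str, DigitalPhantom]:
    """The four phantom configurations of one campaign."""
    size = (fov, fov)
    return {
        "square": make_square_phantom(fov=size),
        "circular": make_circular_phantom(fov=size),
        "circular_offres": make_circular_phantom(fov=size, off_resonance=True),
        "circular_motion": make_circular_phantom(fov=size, motion=True),
    }


def simulate_sequence(
    spec: SequenceSpec,
    phantoms: Dict[str, DigitalPhantom],
    noise_level: float = simulator.DEFAULT_NOISE_LEVEL,
    noise_seed: int = simulator.DEFAULT_NOISE_SEED,
) -> metrics_mod.AcquisitionMetrics:
    """Run the four simulations of one sequence and score the 12 metrics."""
    plan = sequence_engine.compile(spec)
    images = {}
    for key, phantom in phantoms.items():
        k = simulator.simulate(
            plan,
            phantom,
            off_resonance=key.endswith("offres"),
            motion=key.endswith("motion"),
        )
        if key == "square" and noise_level > 0:
            sigma = simulator.noise_sigma_for(k, noise_level)
            k = simulator.add_noise(k, sigma, seed=noise_seed)
        images[key] = simulator.reconstruct(k)
    return metrics_mod.compute_all(spec, phantoms["square"], phantoms["circular"], images)


def run_campaign(
    specs: List[SequenceSpec],
    phantoms: Optional[Dict[str, DigitalPhantom]] = None,
    noise_level: float = simulator.DEFAULT_NOISE_LEVEL,
    seed: int = 0,
    resume: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Simulate and score every sequence; returns the training table.

    Per-row noise seeds derive deterministically from ``seed`` and the row
    index, so identical configs reproduce bitwise-identical tables.  Rows
    whose simulation fails are logged and excluded.  Passing a previously
    written table as ``resume`` skips sequences already present.
    """
    phantoms = phantoms or default_phantoms()
    done = set(resume["name"]) if resume is not None and "name" in resume else set()
    rows = [] if resume is None else resume.to_dict("records")
    for index, spec in enumerate(specs):
        if spec.name in done:
            continue
        noise_seed = int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
        start = time.perf_counter()
        try:
            acq = simulate_sequence(spec, phantoms, noise_level, noise_seed)
        except Exception:  # pragma: no cover - defensive logging path
            logger.exception("simulation failed for %s; row excluded", spec.name)
            continue
        row = {"name": spec.name, "family": spec.family}
        row.update(spec_to_vector(spec))
        row.update(acq.to_dict())
        rows.append(row)
        logger.info(
            "simulated %s (%d/%d) in %.2f s", spec.name, index + 1, len(specs),
            time.perf_counter() - start,
        )
    columns = ["name", "family"] + INPUT_COLUMNS + METRIC_COLUMNS
    return pd.DataFrame(rows, columns=columns)


# --------------------------------------------------------------------------
# three-way holdout split
# --------------------------------------------------------------------------


def split(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Label rows train/test/validation in 60/20/20 proportions."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows for a 60/20/20 split")
    n_test = int(round(0.2 * n))
    n_val = int(round(0.2 * n))
    order = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[: n - n_test - n_val]] = "train"
    labels[order[n - n_test - n_val : n - n_val]] = "test"
    labels[order[n - n_val :]] = "validation"
    out = table.copy()
    out["split"] = labels
    return out
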