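"""Compile sequence specifications into executable encoding plans.

A :class:`SequenceSpec` describes *what* to acquire; the encoding plan says
*when*: the RF schedule (hard pulses at their center times), the k-space line
ordering of every shot, and the ADC sample times of every line.  Four
Cartesian families are supported, derived from echo type x readout type:

==============  =========================================================
family          timing layout (per shot, times relative to excitation)
==============  =========================================================
RARE            CPMG echo train; refocussing pulse m at (m - 1/2) * esp,
                echo m at m * esp; esp chosen so the echo that acquires the
                k-space center falls exactly at TE.
SE-EPI / EPI    echo-planar train with alternating readout polarity and
                echo spacing = readout duration + ramp allowance; the
                center line is sampled at TE (refocussing at TE/2 for the
                spin-echo variant).
bSSFP           one line per TR with alternating 0/180 degree excitation
                phase; a linear flip-angle ramp of dummy prescans
                (no ADC) precedes the first measurement.
==============  =========================================================

All RF pulses are instantaneous rotations; a nominal 1 ms pulse duration is
reserved in the timing checks.  PE lines are ordered linear-ascending and
interleaved over shots (line j of shot s has index j * n_shots + s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .dsl import SequenceSpec

__all__ = [
    "RFEvent",
    "Line",
    "Shot",
    "EncodingPlan",
    "ValidityReport",
    "compile",
    "validate",
    "acquisition_time",
    "PULSE_DURATION",
    "EPI_RAMP",
]

PULSE_DURATION = 1.0  # ms reserved per hard pulse
EPI_RAMP = 0.1  # ms gradient ramp allowance between EPI lines


@dataclass(frozen=True)
class RFEvent:
    time: float  # ms, relative to shot excitation (prescans: absolute slot)
    flip: float  # degrees
    phase: float  # degrees
    kind: str  # excitation | refocussing | prescan


@dataclass
class Line:
    pe_index: int
    polarity: int  # +1 / -1; EPI alternates, line readouts are constant
    center_time: float  # ms relative to shot excitation
    sample_times: np.ndarray  # ms, strictly increasing (acquisition order)

    def to_dict(self):
        return {
            "pe_index": self.pe_index,
            "polarity": self.polarity,
            "center_time": self.center_time,
            "sample_times": self.sample_times.tolist(),
        }


@dataclass
class Shot:
    rf: List[RFEvent]
    lines: List[Line]


@dataclass
class EncodingPlan:
    spec: SequenceSpec
    shots: List[Shot]  # one measurement
    tr: float
    n_measurements: int
    prescans: List[RFEvent]  # executed at TR spacing before the first shot
    dwell: float  # ms
    echo_spacing: float  # ms
    spoil_end_of_shot: bool
    n_rows: int
    n_columns: int

    @property
    def shots_per_measurement(self) -> int:
        return len(self.shots)

    def to_dict(self):
        return {
            "family": self.spec.family,
            "tr": self.tr,
            "n_measurements": self.n_measurements,
            "dwell": self.dwell,
            "echo_spacing": self.echo_spacing,
            "spoil_end_of_shot": self.spoil_end_of_shot,
            "prescans": [vars(rf) for rf in self.prescans],
            "shots": [
                {
                    "rf": [vars(rf) for rf in shot.rf],
                    "lines": [line.to_dict() for line in shot.lines],
                }
                for shot in self.shots
            ],
        }


@dataclass
class ValidityReport:
    violations: List[tuple] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str) -> None:
        self.violations.append((code, message))


# --------------------------------------------------------------------------
# timing helpers
# --------------------------------------------------------------------------


def _sample_times(center: float, n_columns: int, dwell: float) -> np.ndarray:
    """ADC sample times in acquisition order; sample n/2 sits at the center."""
    return center + (np.arange(n_columns) - n_columns // 2) * dwell


def _center_echo_index(n_rows: int, n_shots: int) -> int:
    """0-based train index at which the k-space center line is acquired."""
    return (n_rows // 2) // n_shots


def _rare_timing(spec: SequenceSpec):
    n_shots = spec.n_rows // spec.etl
    m_center = _center_echo_index(spec.n_rows, n_shots) + 1  # 1-indexed echo
    esp = spec.te / m_center
    return n_shots, m_center, esp


def _epi_timing(spec: SequenceSpec):
    n_shots = spec.n_rows // spec.epi_factor
    j_center = _center_echo_index(spec.n_rows, n_shots)
    esp = spec.readout_duration + EPI_RAMP
    return n_shots, j_center, esp


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


def validate(spec: SequenceSpec) -> ValidityReport:
    """Check physical plausibility; always returns a report object."""
    report = ValidityReport()
    if not spec.is_complete():
        report.add("INCOMPLETE_SPEC", "sequence has unset fields")
        return report

    for name in ("n_columns", "n_rows", "epi_factor", "etl", "measurements"):
        if getattr(spec, name) < 1:
            report.add("NONPOSITIVE_COUNT", f"{name} must be >= 1")
    if spec.prescans is not None and spec.prescans.count < 0:
        report.add("NONPOSITIVE_COUNT", "prescan count must be >= 0")
    if spec.echo_type == "SpinEcho" and spec.refocussing is None:
        report.add("REFOCUSSING_MISSING", "spin echo requires a refocussing pulse")
    if spec.echo_type == "GradientEcho" and spec.refocussing is not None:
        report.add("REFOCUSSING_PRESENT", "gradient echo must not refocus")
    if not (0 <= spec.excitation.angle < 360):
        report.add("ANGLE_RANGE", "excitation angle outside [0, 360)")
    if spec.te >= spec.tr:
        report.add("TE_GE_TR", f"TE {spec.te} must be smaller than TR {spec.tr}")
    if spec.n_rows % 2:
        report.add("MATRIX_ODD", "number of rows must be even")
    if report.violations:
        return report

    ro = spec.readout_duration
    family = spec.family
    if family == "RARE":
        if spec.n_rows % spec.etl:
            report.add("MATRIX_NOT_DIVISIBLE", "n_rows must be a multiple of ETL")
            return report
        n_shots, m_center, esp = _rare_timing(spec)
        if esp < ro + PULSE_DURATION:
            report.add(
                "TE_TOO_SHORT",
                f"echo spacing {esp:.2f} ms below readout + pulse ({ro + PULSE_DURATION:.2f} ms)",
            )
        if spec.etl * esp + ro / 2 > spec.tr:
            report.add("READOUT_EXCEEDS_TR", "echo train does not fit into TR")
    elif family in ("EPI", "SE-EPI"):
        if spec.n_rows % spec.epi_factor:
            report.add("MATRIX_NOT_DIVISIBLE", "n_rows must be a multiple of the EPI factor")
            return report
        n_shots, j_center, esp = _epi_timing(spec)
        train_start = spec.te - j_center * esp - ro / 2
        min_start = PULSE_DURATION / 2
        if family == "SE-EPI":
            min_start = spec.te / 2 + PULSE_DURATION / 2
            if spec.te / 2 < PULSE_DURATION:
                report.add("TE_TOO_SHORT", "refocussing pulse does not fit before TE/2")
        if train_start < min_start:
            report.add("TE_TOO_SHORT", "echo train start precedes the RF pulses")
        if spec.te + (spec.epi_factor - 1 - j_center) * esp + ro / 2 > spec.tr:
            report.add("READOUT_EXCEEDS_TR", "echo train does not fit into TR")
    else:  # bSSFP
        if spec.te < PULSE_DURATION / 2 + ro / 2:
            report.add("TE_TOO_SHORT", "readout does not fit between pulse and TE")
        if spec.te + ro / 2 > spec.tr:
            report.add("READOUT_EXCEEDS_TR", "readout does not fit into TR")
    return report


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------


def compile(spec: SequenceSpec) -> EncodingPlan:  # noqa: A001 - domain verb
    """Compile a complete, valid SequenceSpec into an EncodingPlan."""
    report = validate(spec)
    if not report.valid:
        codes = ", ".join(code for code, _ in report.violations)
        raise ValueError(f"invalid sequence: {codes}")

    family = spec.family
    dwell = spec.readout_duration / spec.n_columns
    exc = spec.excitation

    if family == "RARE":
        n_shots, m_center, esp = _rare_timing(spec)
        shots = []
        for s in range(n_shots):
            rf = [RFEvent(0.0, exc.angle, 0.0, "excitation")]
            lines = []
            for e in range(spec.etl):
                m = e + 1
                rf.append(RFEvent((m - 0.5) * esp, spec.refocussing.angle, 90.0, "refocussing"))
                center = m * esp
                lines.append(
                    Line(e * n_shots + s, +1, center, _sample_times(center, spec.n_columns, dwell))
                )
            shots.append(Shot(rf, lines))
        spoil = any(sp.location in ("after_echotrain", "after_segment") for sp in spec.spoiling)
        prescans: List[RFEvent] = []
        echo_spacing = esp
    elif family in ("EPI", "SE-EPI"):
        n_shots, j_center, esp = _epi_timing(spec)
        shots = []
        for s in range(n_shots):
            rf = [RFEvent(0.0, exc.angle, 0.0, "excitation")]
            if family == "SE-EPI":
                rf.append(RFEvent(spec.te / 2, spec.refocussing.angle, 90.0, "refocussing"))
            lines = []
            for j in range(spec.epi_factor):
                center = spec.te + (j - j_center) * esp
                lines.append(
                    Line(
                        j * n_shots + s,
                        +1 if j % 2 == 0 else -1,
                        center,
                        _sample_times(center, spec.n_columns, dwell),
                    )
                )
            shots.append(Shot(rf, lines))
        spoil = any(sp.location in ("after_echotrain", "after_segment") for sp in spec.spoiling)
        prescans = []
        echo_spacing = esp
    else:  # bSSFP
        count = spec.prescan_count
        prescans = []
        if count:
            flips = np.linspace(exc.angle / (count + 1), exc.angle, count)
            prescans = [
                RFEvent(0.0, float(flip), 180.0 * (i % 2), "prescan")
                for i, flip in enumerate(flips)
            ]
        shots = []
        for k in range(spec.n_rows):
            phase = 180.0 * ((count + k) % 2)
            rf = [RFEvent(0.0, exc.angle, phase, "excitation")]
            lines = [Line(k, +1, spec.te, _sample_times(spec.te, spec.n_columns, dwell))]
            shots.append(Shot(rf, lines))
        spoil = False  # balanced: transverse magnetization is recycled
        echo_spacing = spec.tr

    return EncodingPlan(
        spec=spec,
        shots=shots,
        tr=spec.tr,
        n_measurements=spec.measurements,
        prescans=prescans,
        dwell=dwell,
        echo_spacing=echo_spacing,
        spoil_end_of_shot=spoil,
        n_rows=spec.n_rows,
        n_columns=spec.n_columns,
    )


def acquisition_time(spec: SequenceSpec) -> float:
    """Total acquisition time in ms: TR * shots * measurements + TR * prescans."""
    report = validate(spec)
    if not report.valid:
        codes = ", ".join(code for code, _ in report.violations)
        raise ValueError(f"invalid sequence: {codes}")
    family = spec.family
    if family == "RARE":
        shots = spec.n_rows // spec.etl
    elif family in ("EPI", "SE-EPI"):
        shots = spec.n_rows // spec.epi_factor
    else:
        shots = spec.n_rows
    return spec.tr * shots * spec.measurements + spec.tr * spec.prescan_count
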