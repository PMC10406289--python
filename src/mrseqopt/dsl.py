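"""Domain-specific languages for MRI sequence optimization.

Two small languages are defined here:

* a *requirements* DSL in which a clinician states the optimization goal
  ("maximize GWC"), hard constraints ("SNR_GM is greater than 30") and soft
  preferences ("avoid ghosting", "have high CGC"); and
* a *sequence* DSL that describes one Cartesian MRI sequence through its echo
  type, readout type and protocol parameters (TE, TR, matrix, echo train, ...).

Statements end with a period, keywords are case-insensitive, quoted names are
case-sensitive, and whitespace/newlines carry no meaning.  Sequence texts that
give only the first sentence (echo + readout) are completed by
:func:`expand_defaults` with the family defaults of the four shipped sequences
(RARE, SE-EPI, EPI, bSSFP).  :func:`translate_requirement` turns a parsed
requirement into a numeric :class:`OptimizationProblem` using an ordinal
dictionary that maps vague wording ("avoid", "high") onto numeric bounds.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

# --------------------------------------------------------------------------
# metric registry
# --------------------------------------------------------------------------

#: Canonical names of the 12 acquisition metrics, in fixed column order.
METRIC_NAMES = (
    "CGC",
    "GWC",
    "CWC",
    "SNR_CSF",
    "SNR_GM",
    "SNR_WM",
    "GHOST",
    "SHARPNESS",
    "HOMOGENEITY",
    "MOTION_SENS",
    "DISTORTION_SENS",
    "ACQ_TIME",
)

#: Metrics penalized exponentially when an avoid-constraint is violated.
ARTIFACT_METRICS = frozenset({"GHOST", "MOTION_SENS", "DISTORTION_SENS"})

_METRIC_ALIASES = {
    "ghosting": "GHOST",
    "ghost": "GHOST",
    "motion": "MOTION_SENS",
    "motion.sens": "MOTION_SENS",
    "motion_sens": "MOTION_SENS",
    "distortion": "DISTORTION_SENS",
    "distortion.sens": "DISTORTION_SENS",
    "distortion_sens": "DISTORTION_SENS",
    "sharpness": "SHARPNESS",
    "homogeneity": "HOMOGENEITY",
    "acquisition time": "ACQ_TIME",
    "acquisition_time": "ACQ_TIME",
    "time": "ACQ_TIME",
    "snr-csf": "SNR_CSF",
    "snr-gm": "SNR_GM",
    "snr-wm": "SNR_WM",
}

#: Sequence parameters allowed on either side of a strict constraint.
SEQUENCE_PARAM_NAMES = (
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
)


def canonical_metric(name: str) -> Optional[str]:
    """Map a DSL metric spelling onto its canonical name, or None."""
    key = name.strip()
    if key.upper() in METRIC_NAMES:
        return key.upper()
    return _METRIC_ALIASES.get(key.lower())


def canonical_operand(name: str) -> str:
    """Canonicalize a quoted constraint operand (metric or sequence param)."""
    metric = canonical_metric(name)
    if metric is not None:
        return metric
    low = name.strip().lower().replace("-", "_")
    if low in SEQUENCE_PARAM_NAMES:
        return low
    raise DSLError(f"unknown metric or sequence parameter name {name!r}")


# --------------------------------------------------------------------------
# AST dataclasses
# --------------------------------------------------------------------------


class DSLError(ValueError):
    """Raised on any syntax or semantic error in a DSL text."""


@dataclass(frozen=True)
class PulseSpec:
    pulse_type: str
    angle: float  # degrees


@dataclass(frozen=True)
class PrescanSpec:
    count: int
    pulse_type: Optional[str] = None  # e.g. "linear" ramp


@dataclass(frozen=True)
class SpoilingSpec:
    #: one of around_refocussing, after_echotrain, after_segment, around_readout
    location: str
    spoil_type: Optional[str] = None


SPOIL_LOCATIONS = (
    "around_refocussing",
    "after_echotrain",
    "after_segment",
    "around_readout",
)


@dataclass
class SequenceSpec:
    """Parametric description of one Cartesian MRI sequence.

    Unset (None) fields mean "not specified in the text"; call
    :func:`expand_defaults` to fill them from the family defaults.
    ``readout_duration`` is stored in ms (DSL text uses microseconds).
    """

    name: str
    echo_type: str  # GradientEcho | SpinEcho
    readout_type: str  # LineReadout | EPIReadout
    excitation: Optional[PulseSpec] = None
    refocussing: Optional[PulseSpec] = None
    readout_duration: Optional[float] = None  # ms
    n_columns: Optional[int] = None
    te: Optional[float] = None  # ms
    tr: Optional[float] = None  # ms
    epi_factor: Optional[int] = None
    etl: Optional[int] = None
    n_rows: Optional[int] = None
    measurements: Optional[int] = None
    prescans: Optional[PrescanSpec] = None
    spoiling: tuple = ()

    @property
    def family(self) -> str:
        """Sequence family implied by echo and readout type."""
        return {
            ("SpinEcho", "LineReadout"): "RARE",
            ("SpinEcho", "EPIReadout"): "SE-EPI",
            ("GradientEcho", "EPIReadout"): "EPI",
            ("GradientEcho", "LineReadout"): "bSSFP",
        }[(self.echo_type, self.readout_type)]

    @property
    def refocussing_angle(self) -> float:
        """Refocussing flip angle; 0 encodes a gradient echo (no refocussing)."""
        return 0.0 if self.refocussing is None else self.refocussing.angle

    @property
    def prescan_count(self) -> int:
        return 0 if self.prescans is None else self.prescans.count

    def is_complete(self) -> bool:
        required = (
            self.excitation,
            self.readout_duration,
            self.n_columns,
            self.te,
            self.tr,
            self.epi_factor,
            self.etl,
            self.n_rows,
            self.measurements,
        )
        # refocussing consistency with the echo type is a semantic rule
        # checked by sequence_engine.validate, not a completeness question
        return all(v is not None for v in required)


Relation = str  # 'lt' | 'eq' | 'gt'

_REL_WORDS = {
    ("is", "smaller", "than"): "lt",
    ("is", "lower", "than"): "lt",
    ("equals",): "eq",
    ("is", "greater", "than"): "gt",
    ("is", "higher", "than"): "gt",
}

QUANTIFIERS = ("very_low", "low", "decent", "high", "very_high")


@dataclass(frozen=True)
class StrictConstraint:
    lhs: str  # canonical metric or sequence-parameter name
    relation: Relation
    rhs: Union[str, float]  # canonical name or number


@dataclass(frozen=True)
class VagueConstraint:
    kind: str  # allow | avoid | aim
    metric: str
    quantifier: Optional[str] = None  # only for kind == 'aim'


@dataclass
class RequirementSpec:
    goal_direction: str  # minimize | maximize
    goal_metric: str
    strict_constraints: list = field(default_factory=list)
    vague_constraints: list = field(default_factory=list)
    starting_sequence: Optional[SequenceSpec] = None


@dataclass(frozen=True)
class NumericConstraint:
    """A fully numeric constraint of the translated optimization problem."""

    lhs: str
    relation: Relation
    rhs: Union[str, float]
    soft: bool = False
    artifact: bool = False  # exponential penalty when violated


@dataclass
class OptimizationProblem:
    goal_metric: str
    direction: str
    strict: list = field(default_factory=list)
    vague: list = field(default_factory=list)
    artifact_flags: set = field(default_factory=set)


# --------------------------------------------------------------------------
# ordinal dictionary
# --------------------------------------------------------------------------

DEFAULT_ORDINAL_DICTIONARY = {
    # aim bands: quantifier -> (relation, bound); lower bounds for quality
    # metrics, upper bounds (looser with higher quantifier) for artifacts.
    "aim": {
        "contrast": {"very_low": 1.0, "low": 2.0, "decent": 5.0, "high": 10.0, "very_high": 20.0},
        "snr": {"very_low": 5.0, "low": 10.0, "decent": 20.0, "high": 30.0, "very_high": 50.0},
        "quality": {"very_low": 0.5, "low": 0.65, "decent": 0.75, "high": 0.85, "very_high": 0.95},
        "artifact": {"very_low": 0.01, "low": 0.05, "decent": 0.10, "high": 0.20, "very_high": 0.50},
    },
    "avoid": 0.05,
    "allow": 0.20,
}

_METRIC_FAMILY = {
    "CGC": "contrast",
    "GWC": "contrast",
    "CWC": "contrast",
    "SNR_CSF": "snr",
    "SNR_GM": "snr",
    "SNR_WM": "snr",
    "SHARPNESS": "quality",
    "HOMOGENEITY": "quality",
    "GHOST": "artifact",
    "MOTION_SENS": "artifact",
    "DISTORTION_SENS": "artifact",
}


class OrdinalDictionary:
    """Maps vague constraint wording onto numeric bounds.

    ``avoid``/``allow`` apply to artifact metrics and give upper bounds;
    ``aim`` quantifiers give lower bounds for contrast/SNR/quality metrics and
    upper bounds for artifact metrics, monotone in the quantifier order.
    """

    def __init__(self, table: Optional[dict] = None):
        self.table = copy.deepcopy(DEFAULT_ORDINAL_DICTIONARY)
        if table:
            for key, val in table.items():
                if isinstance(val, dict) and key in self.table:
                    for fam, bands in val.items():
                        self.table[key].setdefault(fam, {})
                        self.table[key][fam].update(bands)
                else:
                    self.table[key] = val

    def resolve(self, constraint: VagueConstraint) -> NumericConstraint:
        metric = constraint.metric
        family = _METRIC_FAMILY.get(metric)
        if family is None:
            raise DSLError(f"metric {metric!r} has no ordinal dictionary entry")
        if constraint.kind in ("avoid", "allow"):
            if family != "artifact":
                raise DSLError(
                    f"'{constraint.kind}' applies to artifact metrics, not {metric!r}"
                )
            bound = float(self.table[constraint.kind])
            return NumericConstraint(metric, "lt", bound, soft=True, artifact=True)
        if constraint.quantifier is None:
            raise DSLError(f"aim-constraint on {metric!r} is missing a quantifier")
        bound = float(self.table["aim"][family][constraint.quantifier])
        relation = "lt" if family == "artifact" else "gt"
        return NumericConstraint(
            metric, relation, bound, soft=True, artifact=(family == "artifact")
        )


# --------------------------------------------------------------------------
# tokenizer
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<string>"[^"]*")
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<word>[A-Za-z][A-Za-z0-9_-]*)
  | (?P<punct>[.,:])
  | (?P<ws>\s+)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str  # string | number | word | punct
    value: str
    line: int
    column: int


def tokenize(text: str) -> list:
    tokens = []
    line, col = 1, 1
    for match in _TOKEN_RE.finditer(text):
        kind = match.lastgroup
        value = match.group()
        if kind == "bad":
            raise DSLError(f"unexpected character {value!r} at line {line}, column {col}")
        if kind != "ws":
            tokens.append(Token(kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
    return tokens


class _TokenStream:
    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0

    def peek(self, offset: int = 0) -> Optional[Token]:
        idx = self.pos + offset
        return self.tokens[idx] if idx < len(self.tokens) else None

    def next(self) -> Token:
        tok = self.peek()
        if tok is None:
            raise DSLError("unexpected end of input")
        self.pos += 1
        return tok

    def at_keyword(self, *words: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "word" and tok.value.lower() in words

    def expect_keyword(self, word: str) -> Token:
        tok = self.peek()
        if tok is None or tok.kind != "word" or tok.value.lower() != word.lower():
            where = "end of input" if tok is None else f"line {tok.line}, column {tok.column}"
            got = "nothing" if tok is None else repr(tok.value)
            raise DSLError(f"expected keyword {word!r}, got {got} at {where}")
        return self.next()

    def expect_punct(self, char: str) -> Token:
        tok = self.peek()
        if tok is None or tok.kind != "punct" or tok.value != char:
            where = "end of input" if tok is None else f"line {tok.line}, column {tok.column}"
            got = "nothing" if tok is None else repr(tok.value)
            raise DSLError(f"expected {char!r}, got {got} at {where}")
        return self.next()

    def expect_string(self) -> str:
        tok = self.peek()
        if tok is None or tok.kind != "string":
            where = "end of input" if tok is None else f"line {tok.line}, column {tok.column}"
            raise DSLError(f"expected a quoted name at {where}")
        return self.next().value[1:-1]

    def expect_number(self) -> float:
        tok = self.peek()
        if tok is None or tok.kind != "number":
            where = "end of input" if tok is None else f"line {tok.line}, column {tok.column}"
            raise DSLError(f"expected a number at {where}")
        return float(self.next().value)

    def expect_word(self) -> str:
        tok = self.peek()
        if tok is None or tok.kind != "word":
            where = "end of input" if tok is None else f"line {tok.line}, column {tok.column}"
            raise DSLError(f"expected a word at {where}")
        return self.next().value

    def end_statement(self, lenient_keywords=("specify", "add", "define")) -> None:
        """Consume the statement period; tolerate a missing period (optionally
        after a dangling comma) when the next statement keyword follows."""
        tok = self.peek()
        if tok is not None and tok.kind == "punct" and tok.value == ",":
            nxt = self.peek(1)
            if nxt is not None and nxt.kind == "word" and nxt.value.lower() in lenient_keywords:
                self.next()
                return
        if tok is not None and tok.kind == "punct" and tok.value == ".":
            self.next()
            return
        if tok is None or (tok.kind == "word" and tok.value.lower() in lenient_keywords):
            return
        where = f"line {tok.line}, column {tok.column}"
        raise DSLError(f"expected '.' to end statement, got {tok.value!r} at {where}")


# --------------------------------------------------------------------------
# sequence DSL parser
# --------------------------------------------------------------------------

_ECHO_TYPES = {"spinecho": "SpinEcho", "gradientecho": "GradientEcho"}
_READOUT_TYPES = {"linereadout": "LineReadout", "epireadout": "EPIReadout"}


def parse_sequence(text: str) -> SequenceSpec:
    """Parse a sequence-DSL text into a (possibly incomplete) SequenceSpec."""
    stream = _TokenStream(tokenize(text))
    spec = _parse_sequence_stream(stream)
    tok = stream.peek()
    if tok is not None:
        raise DSLError(
            f"unexpected trailing input {tok.value!r} at line {tok.line}, column {tok.column}"
        )
    return spec


def _parse_sequence_stream(stream: _TokenStream) -> SequenceSpec:
    stream.expect_keyword("define")
    stream.expect_keyword("MRI")
    stream.expect_keyword("sequence")
    name = stream.expect_string()
    stream.expect_keyword("using")
    stream.expect_keyword("a")
    echo_raw = stream.expect_string()
    echo = _ECHO_TYPES.get(echo_raw.lower())
    if echo is None:
        raise DSLError(f"unknown echo type {echo_raw!r}")
    stream.expect_keyword("with")
    readout_raw = stream.expect_string()
    readout = _READOUT_TYPES.get(readout_raw.lower())
    if readout is None:
        raise DSLError(f"unknown readout type {readout_raw!r}")
    stream.end_statement()

    spec = SequenceSpec(name=name, echo_type=echo, readout_type=readout)
    seen = set()
    spoiling = []
    while True:
        tok = stream.peek()
        if tok is None:
            break
        if stream.at_keyword("add"):
            stream.next()
            _parse_addition(stream, spec, spoiling)
        elif stream.at_keyword("specify"):
            stream.next()
            _parse_specification(stream, spec, seen)
        else:
            break
    spec.spoiling = tuple(spoiling)
    return spec


def _parse_addition(stream: _TokenStream, spec: SequenceSpec, spoiling: list) -> None:
    if stream.at_keyword("gradient"):
        stream.next()
        stream.expect_keyword("spoiling")
        where = stream.expect_word().lower()
        if where not in ("around", "after"):
            raise DSLError(f"expected 'around' or 'after' in spoiling addition, got {where!r}")
        target = stream.expect_word().lower()
        location = f"{where}_{target}"
        if location not in SPOIL_LOCATIONS:
            raise DSLError(f"unknown spoiling location {location!r}")
        spoil_type = None
        if stream.at_keyword("of"):
            stream.next()
            stream.expect_keyword("type")
            spoil_type = stream.expect_word().lower()
        stream.end_statement()
        spoiling.append(SpoilingSpec(location, spoil_type))
    elif stream.at_keyword("prescans"):
        stream.next()
        if spec.prescans is not None:
            raise DSLError("duplicate 'Add prescans' block")
        stream.expect_keyword("with")
        stream.expect_keyword("count")
        count = int(stream.expect_number())
        ptype = None
        if stream.at_keyword("and"):
            stream.next()
            stream.expect_keyword("type")
            ptype = stream.expect_word().lower()
        stream.end_statement()
        spec.prescans = PrescanSpec(count, ptype)
    else:
        tok = stream.peek()
        raise DSLError(f"unknown addition {tok.value!r} at line {tok.line}")


def _set_once(spec: SequenceSpec, seen: set, block: str, **fields) -> None:
    if block in seen:
        raise DSLError(f"duplicate 'Specify {block}' block")
    seen.add(block)
    for key, value in fields.items():
        setattr(spec, key, value)


def _parse_specification(stream: _TokenStream, spec: SequenceSpec, seen: set) -> None:
    if stream.at_keyword("echo"):
        stream.next()
        stream.expect_keyword("as")
        stream.expect_keyword("excitation")
        stream.expect_keyword("with")
        stream.expect_keyword("type")
        exc_type = stream.expect_word()
        stream.expect_keyword("and")
        stream.expect_keyword("angle")
        exc_angle = stream.expect_number()
        refocussing = None
        tok = stream.peek()
        if tok is not None and tok.kind == "punct" and tok.value == ",":
            nxt = stream.peek(1)
            if nxt is not None and nxt.kind == "word" and nxt.value.lower() == "and":
                stream.next()  # ','
                stream.next()  # 'and'
                stream.expect_keyword("refocussing")
                stream.expect_keyword("with")
                stream.expect_keyword("type")
                ref_type = stream.expect_word()
                stream.expect_keyword("and")
                stream.expect_keyword("angle")
                ref_angle = stream.expect_number()
                refocussing = PulseSpec(ref_type, ref_angle)
        stream.end_statement()
        _set_once(
            spec,
            seen,
            "echo",
            excitation=PulseSpec(exc_type, exc_angle),
            refocussing=refocussing,
        )
    elif stream.at_keyword("readout"):
        stream.next()
        stream.expect_keyword("with")
        stream.expect_keyword("duration")
        duration_us = stream.expect_number()
        stream.expect_keyword("and")
        stream.expect_keyword("number-of-columns")
        columns = int(stream.expect_number())
        stream.end_statement()
        _set_once(spec, seen, "readout", readout_duration=duration_us / 1000.0, n_columns=columns)
    elif stream.at_keyword("timing"):
        stream.next()
        stream.expect_keyword("parameters")
        stream.expect_keyword("with")
        stream.expect_keyword("TE")
        te = stream.expect_number()
        stream.expect_keyword("and")
        stream.expect_keyword("TR")
        tr = stream.expect_number()
        stream.end_statement()
        _set_once(spec, seen, "timing", te=te, tr=tr)
    elif stream.at_keyword("trajectory"):
        stream.next()
        stream.expect_keyword("with")
        stream.expect_keyword("Epi-Factor")
        epi = int(stream.expect_number())
        stream.expect_keyword("and")
        stream.expect_keyword("ETL")
        etl = int(stream.expect_number())
        stream.expect_keyword("and")
        stream.expect_keyword("number-of-rows")
        rows = int(stream.expect_number())
        stream.end_statement()
        _set_once(spec, seen, "trajectory", epi_factor=epi, etl=etl, n_rows=rows)
    elif stream.at_keyword("measurements"):
        stream.next()
        stream.expect_keyword("with")
        stream.expect_keyword("count")
        count = int(stream.expect_number())
        stream.end_statement()
        _set_once(spec, seen, "measurements", measurements=count)
    else:
        tok = stream.peek()
        raise DSLError(f"unknown specification {tok.value!r} at line {tok.line}")


# --------------------------------------------------------------------------
# default expansion
# --------------------------------------------------------------------------

_FAMILY_DEFAULTS = {
    "RARE": dict(
        excitation=PulseSpec("sincpulse", 90.0),
        refocussing=PulseSpec("sincpulse", 180.0),
        readout_duration=2.0,
        n_columns=64,
        te=44.0,
        tr=500.0,
        epi_factor=1,
        etl=8,
        n_rows=64,
        measurements=1,
        prescans=None,
        spoiling=(
            SpoilingSpec("around_refocussing", "balanced"),
            SpoilingSpec("after_echotrain", None),
        ),
    ),
    "SE-EPI": dict(
        excitation=PulseSpec("sincpulse", 90.0),
        refocussing=PulseSpec("sincpulse", 180.0),
        readout_duration=0.5,
        n_columns=64,
        te=50.0,
        tr=1000.0,
        epi_factor=64,
        etl=1,
        n_rows=64,
        measurements=10,
        prescans=None,
        spoiling=(
            SpoilingSpec("around_refocussing", "balanced"),
            SpoilingSpec("after_segment", None),
        ),
    ),
    "EPI": dict(
        excitation=PulseSpec("sincpulse", 90.0),
        refocussing=None,
        readout_duration=0.5,
        n_columns=64,
        te=35.0,
        tr=1000.0,
        epi_factor=64,
        etl=1,
        n_rows=64,
        measurements=10,
        prescans=None,
        spoiling=(SpoilingSpec("after_segment", None),),
    ),
    "bSSFP": dict(
        excitation=PulseSpec("sincpulse", 90.0),
        refocussing=None,
        readout_duration=2.0,
        n_columns=64,
        te=4.0,
        tr=8.0,
        epi_factor=1,
        etl=1,
        n_rows=64,
        measurements=1,
        prescans=PrescanSpec(8, "linear"),
        spoiling=(SpoilingSpec("around_readout", "balanced"),),
    ),
}


def expand_defaults(spec: SequenceSpec) -> SequenceSpec:
    """Fill every unset field with the family default (idempotent)."""
    defaults = _FAMILY_DEFAULTS[spec.family]
    out = replace(spec)
    for key, value in defaults.items():
        if key == "spoiling":
            if not out.spoiling:
                out.spoiling = value
        elif getattr(out, key) is None:
            setattr(out, key, value)
    if out.echo_type == "GradientEcho":
        out.refocussing = None
    return out


# --------------------------------------------------------------------------
# rendering (inverse of parse_sequence)
# --------------------------------------------------------------------------


def render_sequence(spec: SequenceSpec) -> str:
    """Emit DSL text; ``parse_sequence(render_sequence(s)) == s`` for complete s."""
    if not spec.is_complete():
        raise DSLError("cannot render an incomplete sequence specification")
    lines = [
        f'define MRI sequence "{spec.name}"',
        f'  using a "{spec.echo_type}" with "{spec.readout_type}".',
    ]
    if spec.prescans is not None:
        clause = f"  with count {spec.prescans.count}"
        if spec.prescans.pulse_type is not None:
            clause += f" and type {spec.prescans.pulse_type}"
        lines += ["Add prescans", clause + "."]
    for spoil in spec.spoiling:
        where, target = spoil.location.split("_", 1)
        head = f"Add gradient spoiling {where} {target}"
        if spoil.spoil_type is not None:
            lines += [head, f"  of type {spoil.spoil_type}."]
        else:
            lines += [head + "."]
    lines += [
        "Specify echo",
        "  as excitation",
        f"    with type {spec.excitation.pulse_type} and angle {_fmt(spec.excitation.angle)}"
        + ("," if spec.refocussing is not None else "."),
    ]
    if spec.refocussing is not None:
        lines += [
            "  and refocussing",
            f"    with type {spec.refocussing.pulse_type} and angle {_fmt(spec.refocussing.angle)}.",
        ]
    lines += [
        "Specify readout",
        f"  with duration {_fmt(round(spec.readout_duration * 1000.0, 6))}",
        f"  and number-of-columns {spec.n_columns}.",
        "Specify timing parameters",
        f"  with TE {_fmt(spec.te)}",
        f"  and TR {_fmt(spec.tr)}.",
        "Specify trajectory",
        f"  with Epi-Factor {spec.epi_factor}",
        f"  and ETL {spec.etl}",
        f"  and number-of-rows {spec.n_rows}.",
        "Specify measurements",
        f"  with count {spec.measurements}.",
    ]
    return "\n".join(lines) + "\n"


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


# --------------------------------------------------------------------------
# requirements DSL parser
# --------------------------------------------------------------------------


def parse_requirement(text: str) -> RequirementSpec:
    """Parse a requirements-DSL text into a RequirementSpec."""
    if not text.strip():
        raise DSLError("empty requirement text")
    stream = _TokenStream(tokenize(text))
    stream.expect_keyword("define")
    stream.expect_keyword("optimization")
    stream.expect_keyword("requirement")
    stream.expect_punct(":")

    direction_tok = stream.expect_word().lower()
    if direction_tok not in ("minimize", "maximize"):
        raise DSLError(f"expected 'minimize' or 'maximize', got {direction_tok!r}")
    goal_name = stream.expect_string()
    goal_metric = canonical_metric(goal_name)
    if goal_metric is None:
        raise DSLError(f"unknown goal metric {goal_name!r}")
    stream.expect_punct(".")

    req = RequirementSpec(goal_direction=direction_tok, goal_metric=goal_metric)

    if stream.at_keyword("obey"):
        stream.next()
        stream.expect_keyword("the")
        stream.expect_keyword("following")
        stream.expect_keyword("constraints")
        stream.expect_punct(":")
        while stream.peek() is not None and stream.peek().kind == "string":
            req.strict_constraints.append(_parse_strict(stream))

    if stream.at_keyword("aim"):
        stream.next()
        stream.expect_keyword("for")
        stream.expect_keyword("the")
        stream.expect_keyword("following")
        stream.expect_punct(":")
        while stream.at_keyword("avoid", "allow", "have"):
            req.vague_constraints.append(_parse_vague(stream))

    if stream.at_keyword("define"):
        req.starting_sequence = _parse_sequence_stream(stream)

    tok = stream.peek()
    if tok is not None:
        raise DSLError(
            f"unexpected trailing input {tok.value!r} at line {tok.line}, column {tok.column}"
        )
    return req


def _parse_strict(stream: _TokenStream) -> StrictConstraint:
    lhs = canonical_operand(stream.expect_string())
    words = [stream.expect_word().lower()]
    if words[0] == "is":
        words.append(stream.expect_word().lower())
        words.append(stream.expect_word().lower())
    relation = _REL_WORDS.get(tuple(words))
    if relation is None:
        raise DSLError(f"malformed relation keyword {' '.join(words)!r}")
    tok = stream.peek()
    if tok is not None and tok.kind == "number":
        rhs: Union[str, float] = stream.expect_number()
    else:
        rhs = canonical_operand(stream.expect_string())
    stream.expect_punct(".")
    return StrictConstraint(lhs, relation, rhs)


def _parse_vague(stream: _TokenStream) -> VagueConstraint:
    kind = stream.expect_word().lower()
    quantifier = None
    if kind == "have":
        kind = "aim"
        word = stream.expect_word().lower()
        if word == "very":
            word = f"very_{stream.expect_word().lower()}"
        if word not in QUANTIFIERS:
            raise DSLError(f"unknown quantifier {word!r}")
        quantifier = word
    metric_name = stream.expect_string()
    metric = canonical_metric(metric_name)
    if metric is None:
        raise DSLError(f"unknown metric name {metric_name!r}")
    stream.expect_punct(".")
    return VagueConstraint(kind, metric, quantifier)


def render_requirement(req: RequirementSpec) -> str:
    """Emit requirements-DSL text (round-trips through parse_requirement)."""
    lines = ["define optimization requirement :", f'  {req.goal_direction} "{req.goal_metric}".']
    if req.strict_constraints:
        lines.append("  obey the following constraints:")
        rel_words = {"lt": "is smaller than", "eq": "equals", "gt": "is greater than"}
        for sc in req.strict_constraints:
            rhs = _fmt(sc.rhs) if isinstance(sc.rhs, float) else f'"{sc.rhs}"'
            lines.append(f'    "{sc.lhs}" {rel_words[sc.relation]} {rhs}.')
    if req.vague_constraints:
        lines.append("  aim for the following :")
        for vc in req.vague_constraints:
            if vc.kind == "aim":
                lines.append(f'    have {vc.quantifier.replace("_", " ")} "{vc.metric}".')
            else:
                lines.append(f'    {vc.kind} "{vc.metric}".')
    text = "\n".join(lines) + "\n"
    if req.starting_sequence is not None:
        text += render_sequence(req.starting_sequence)
    return text


# --------------------------------------------------------------------------
# translation to an optimization problem
# --------------------------------------------------------------------------


def translate_requirement(
    req: RequirementSpec, dictionary: Optional[OrdinalDictionary] = None
) -> OptimizationProblem:
    """Translate a parsed requirement into a numeric optimization problem.

    Strict constraints are copied verbatim (order preserved); vague
    constraints are mapped through the ordinal dictionary; avoid/allow and
    aim-constraints on ghost/motion/distortion are flagged for the
    exponential artifact penalty.
    """
    dictionary = dictionary or OrdinalDictionary()
    problem = OptimizationProblem(goal_metric=req.goal_metric, direction=req.goal_direction)
    for sc in req.strict_constraints:
        problem.strict.append(NumericConstraint(sc.lhs, sc.relation, sc.rhs, soft=False))
    for vc in req.vague_constraints:
        numeric = dictionary.resolve(vc)
        problem.vague.append(numeric)
        if numeric.artifact:
            problem.artifact_flags.add(numeric.lhs)
    return problem
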