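"""Session configuration and response-file handling.

A sensory session is defined by a JSON configuration document (title, sample
codes, scale definitions, randomization and ranking options) and produces a
tab-delimited ``.txt`` response file, one line per answered question plus an
optional ranking line.  This module owns both formats: a validated
:class:`SessionConfig` model that round-trips through JSON, and a
parser/writer pair for the response dialect.

The response dialect
--------------------
Each assessment line has eight tab-separated fields::

    Assessment<TAB>Image<TAB>Sample<TAB>Baby<TAB>Face scale<TAB>Progress<TAB>85<TAB>Time: 10:23:03

i.e. assessment kind, the literal token ``Sample``, the sample label, the
scale kind, the literal token ``Progress``, the numeric answer, and a
time-of-day stamp carrying the literal prefix ``Time:``.  A ranking line
alternates ``Sample <label>`` and ``Position <n>`` fields::

    Rank<TAB>Sample Baby<TAB>Position 1<TAB>Sample Dog<TAB>Position 2

Scale ranges are fixed per scale kind: the face scale spans 0-100, the
15-point nonstructured continuous scale spans 0-15, and categorical answers
are indices into the declared level list.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "SessionConfig",
    "QuestionSpec",
    "RankingSpec",
    "ConditionalRule",
    "MediaRef",
    "ResponseRecord",
    "RankRecord",
    "ResponseParseError",
    "build_config",
    "parse_config",
    "randomize_presentation",
    "parse_response_file",
    "write_response_file",
    "example_response_text",
]

#: Numeric range of each continuous scale kind (categorical handled separately).
SCALE_RANGES = {
    "face": (0.0, 100.0),
    "continuous15": (0.0, 15.0),
}

#: Scale-kind labels as they appear in response files, mapped to config kinds.
SCALE_LABELS = {
    "Face scale": "face",
    "Continuous scale": "continuous15",
    "Categorical scale": "categorical",
}
_KIND_TO_LABEL = {v: k for k, v in SCALE_LABELS.items()}


class MediaRef(BaseModel):
    """Reference to an image/video/sound attachment shown with a question."""

    kind: str = Field(pattern="^(image|video|sound)$")
    path: str


class ConditionalRule(BaseModel):
    """Branch rule: if the answer equals ``when_answer``, jump to ``then_question``."""

    when_answer: float | str
    then_question: str


class QuestionSpec(BaseModel):
    id: str
    descriptor: str
    scale_kind: str = Field(pattern="^(categorical|continuous15|face)$")
    levels: list[str] = Field(default_factory=list)
    conditional: Optional[ConditionalRule] = None
    media: Optional[MediaRef] = None
    display_time: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_levels(self) -> "QuestionSpec":
        if self.scale_kind == "categorical" and len(self.levels) < 2:
            raise ValueError(
                f"categorical question {self.id!r} needs >= 2 levels, got {len(self.levels)}"
            )
        if self.scale_kind != "categorical" and self.levels:
            raise ValueError(f"levels only apply to categorical questions ({self.id!r})")
        return self

    def value_range(self) -> tuple[float, float]:
        """Inclusive numeric range of valid answers for this question."""
        if self.scale_kind == "categorical":
            return (0.0, float(len(self.levels) - 1))
        return SCALE_RANGES[self.scale_kind]


class RankingSpec(BaseModel):
    """Preference-ranking task inserted at ``position`` in the question flow."""

    position: int = Field(ge=0)
    n_samples: int = Field(ge=1)


class SessionConfig(BaseModel):
    """A full session definition, serialisable to the app's JSON config document."""

    title: str
    sample_codes: list[str]
    randomize: bool = True
    repeat_questions: bool = True
    ranking: Optional[RankingSpec] = None
    questions: list[QuestionSpec]
    seed: int = 0

    @field_validator("sample_codes")
    @classmethod
    def _codes_valid(cls, v: list[str]) -> list[str]:
        for code in v:
            if not (len(code) == 3 and code.isdigit()):
                raise ValueError(f"sample code {code!r} is not a 3-digit code")
        seen = set()
        for code in v:
            if code in seen:
                raise ValueError(f"duplicate sample code {code!r}")
            seen.add(code)
        return v

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        if not self.questions:
            raise ValueError("a session needs at least one question")
        ids = [q.id for q in self.questions]
        if len(set(ids)) != len(ids):
            raise ValueError("question ids must be unique")
        id_set = set(ids)
        for q in self.questions:
            if q.conditional and q.conditional.then_question not in id_set:
                raise ValueError(
                    f"conditional on {q.id!r} targets unknown question "
                    f"{q.conditional.then_question!r}"
                )
        self._reject_conditional_cycles()
        if self.ranking and self.ranking.n_samples > len(self.sample_codes):
            raise ValueError(
                f"ranking asks for {self.ranking.n_samples} samples but only "
                f"{len(self.sample_codes)} are defined"
            )
        return self

    def _reject_conditional_cycles(self) -> None:
        nxt = {
            q.id: q.conditional.then_question for q in self.questions if q.conditional
        }
        for start in nxt:
            seen = {start}
            cur = start
            while cur in nxt:
                cur = nxt[cur]
                if cur in seen:
                    raise ValueError(f"conditional questions form a cycle through {cur!r}")
                seen.add(cur)


def build_config(spec: SessionConfig) -> str:
    """Serialise a validated :class:`SessionConfig` to a JSON document.

    The document round-trips: ``parse_config(build_config(s)) == s``.
    """
    return json.dumps(spec.model_dump(mode="json"), indent=2)


def parse_config(document: str | dict) -> SessionConfig:
    """Parse and validate a JSON config document."""
    if isinstance(document, str):
        document = json.loads(document)
    return SessionConfig.model_validate(document)


def randomize_presentation(codes: list[str], participant_id: str, seed: int) -> list[str]:
    """Deterministic per-participant permutation of the sample presentation order.

    The permutation is keyed by a SHA-256 hash of ``(seed, participant_id)`` so
    it is stable across platforms and sessions, and distinct participants get
    independent uniform orders.
    """
    if not codes:
        raise ValueError("cannot randomize an empty sample list")
    digest = hashlib.sha256(f"{seed}:{participant_id}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big") % (2**63))
    return [codes[i] for i in rng.permutation(len(codes))]


class ResponseRecord(BaseModel):
    """One parsed assessment line of a response file."""

    assessment_kind: str
    sample_label: str
    question_kind: str
    value: float
    timestamp: _dt.time

    @model_validator(mode="after")
    def _check_range(self) -> "ResponseRecord":
        kind = SCALE_LABELS.get(self.question_kind)
        if kind in SCALE_RANGES:
            lo, hi = SCALE_RANGES[kind]
            if not (lo <= self.value <= hi):
                raise ValueError(
                    f"value {self.value} for sample {self.sample_label!r} outside "
                    f"{self.question_kind} range [{lo}, {hi}]"
                )
        return self


class RankRecord(BaseModel):
    """A parsed ranking line: ordered (sample label, 1-based position) pairs."""

    entries: list[tuple[str, int]]

    @model_validator(mode="after")
    def _check(self) -> "RankRecord":
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("ranked sample labels must be unique")
        positions = sorted(e[1] for e in self.entries)
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(f"positions must be 1..k without gaps, got {positions}")
        return self


class ResponseParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _format_value(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def _parse_assessment(fields: list[str], lineno: int) -> ResponseRecord:
    if len(fields) != 8 or fields[2] != "Sample" or fields[5] != "Progress":
        raise ResponseParseError(
            "malformed assessment line (expected 8 tab-separated fields "
            "'Assessment, kind, Sample, label, scale, Progress, value, Time: hh:mm:ss')",
            lineno,
        )
    _, kind, _, label, qkind, _, raw_value, raw_time = fields
    try:
        value = float(raw_value)
    except ValueError:
        raise ResponseParseError(
            f"non-numeric value {raw_value!r} for sample {label!r}", lineno
        ) from None
    if not raw_time.startswith("Time: "):
        raise ResponseParseError(f"timestamp field {raw_time!r} lacks 'Time: ' prefix", lineno)
    try:
        ts = _dt.time.fromisoformat(raw_time[len("Time: "):])
    except ValueError:
        raise ResponseParseError(f"invalid timestamp {raw_time!r}", lineno) from None
    try:
        return ResponseRecord(
            assessment_kind=kind, sample_label=label, question_kind=qkind,
            value=value, timestamp=ts,
        )
    except ValueError as exc:
        raise ResponseParseError(str(exc), lineno) from None


def _parse_rank(fields: list[str], lineno: int) -> RankRecord:
    body = [f for f in fields[1:] if f]  # tolerate a trailing tab
    if not body or len(body) % 2:
        raise ResponseParseError("rank line must alternate 'Sample x' / 'Position n'", lineno)
    entries = []
    for sample_field, pos_field in zip(body[::2], body[1::2]):
        if not sample_field.startswith("Sample "):
            raise ResponseParseError(f"expected 'Sample <label>', got {sample_field!r}", lineno)
        if not pos_field.startswith("Position "):
            raise ResponseParseError(f"expected 'Position <n>', got {pos_field!r}", lineno)
        try:
            pos = int(pos_field[len("Position "):])
        except ValueError:
            raise ResponseParseError(f"non-integer position {pos_field!r}", lineno) from None
        entries.append((sample_field[len("Sample "):], pos))
    try:
        return RankRecord(entries=entries)
    except ValueError as exc:
        raise ResponseParseError(str(exc), lineno) from None


def parse_response_file(text: str) -> tuple[list[ResponseRecord], Optional[RankRecord]]:
    """Parse a response ``.txt`` file into records.

    Returns one :class:`ResponseRecord` per ``Assessment`` line (in file
    order) and the :class:`RankRecord` if a ``Rank`` line is present.
    Malformed lines raise :class:`ResponseParseError` with the line number.
    """
    records: list[ResponseRecord] = []
    rank: Optional[RankRecord] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        tag = fields[0]
        if tag == "Assessment":
            records.append(_parse_assessment(fields, lineno))
        elif tag == "Rank":
            if rank is not None:
                raise ResponseParseError("multiple rank lines", lineno)
            rank = _parse_rank(fields, lineno)
        else:
            raise ResponseParseError(f"unknown line tag {tag!r}", lineno)
    return records, rank


def write_response_file(
    records: list[ResponseRecord], rank: Optional[RankRecord] = None
) -> str:
    """Serialise records back to the tab-delimited dialect (inverse of parse)."""
    lines = []
    for rec in records:
        kind = SCALE_LABELS.get(rec.question_kind)
        if kind in SCALE_RANGES:
            lo, hi = SCALE_RANGES[kind]
            if not (lo <= rec.value <= hi):
                raise ValueError(
                    f"value {rec.value} for sample {rec.sample_label!r} outside "
                    f"{rec.question_kind} range [{lo}, {hi}]"
                )
        lines.append(
            "\t".join(
                [
                    "Assessment",
                    rec.assessment_kind,
                    "Sample",
                    rec.sample_label,
                    rec.question_kind,
                    "Progress",
                    _format_value(rec.value),
                    f"Time: {rec.timestamp.strftime('%H:%M:%S')}",
                ]
            )
        )
    if rank is not None:
        fields = ["Rank"]
        for label, pos in rank.entries:
            fields += [f"Sample {label}", f"Position {pos}"]
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def example_response_text() -> str:
    """The bundled example response file (nine face-scale image assessments)."""
    from importlib import resources

    return (
        resources.files("biosense").joinpath("data/example_session.txt").read_text()
    )
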