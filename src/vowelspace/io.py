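"""Formant-table data model, validation, and readers/writers.

The package consumes long-format tables of vowel tokens, one row per
production: speaker, session (baseline/post), vowel, repetition, F1 (Hz),
F2 (Hz). Audio and formant tracking are upstream of this package; tables
typically originate from Praat script exports, whose column headings vary
across versions, so the reader resolves a set of header aliases
case-insensitively.

Mis-tracked formants (F2 at or below F1, values outside a plausible Hz
range) are surfaced as validation warnings rather than dropped or
imputed: in child speech such tokens are common and the analyst must see
them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    EmptyInputError,
    PackagingError,
    ParseError,
    SchemaError,
)
from .vowels import ALL_VOWELS, VowelLabel

SESSIONS = ("baseline", "post")

#: Plausible formant range for child speech, Hz. Values outside are
#: flagged, never rejected.
PLAUSIBLE_HZ = (100.0, 4000.0)


@dataclass(frozen=True)
class FormantToken:
    """One measured vowel production."""

    speaker: str
    session: str
    vowel: VowelLabel
    repetition: int
    f1: float
    f2: float


@dataclass(frozen=True)
class VowelMeans:
    """Per speaker/session/vowel averaged formant coordinates."""

    speaker: str
    session: str
    vowel: VowelLabel
    f1_mean: float
    f2_mean: float
    n_tokens: int


@dataclass(frozen=True)
class ChangeRecord:
    """Per-speaker metric changes (post − baseline) plus gain score."""

    speaker: str
    d_aavs: float
    d_qvsa: float
    d_vsahull: float
    wcab_ae_gain: float


@dataclass
class ValidationWarning:
    row: int
    code: str
    message: str


@dataclass
class ValidationReport:
    warnings: list[ValidationWarning] = field(default_factory=list)

    def add(self, row: int, code: str, message: str) -> None:
        self.warnings.append(ValidationWarning(row, code, message))

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)


# Header aliases, matched after lowercasing and stripping spaces,
# underscores, parentheses and units.
_COLUMN_ALIASES = {
    "speaker": {"speaker", "speakerid", "participant", "participantid", "subject", "id"},
    "session": {"session", "time", "timepoint", "phase"},
    "vowel": {"vowel", "phoneme", "vowelcode", "target"},
    "repetition": {"repetition", "rep", "token", "tokennumber", "trial"},
    "f1_hz": {"f1hz", "f1", "firstformant"},
    "f2_hz": {"f2hz", "f2", "secondformant"},
}


def _normalise_header(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col in columns:
            if _normalise_header(col) in aliases:
                resolved[canonical] = col
                break
    missing = sorted(set(_COLUMN_ALIASES) - set(resolved))
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)}; found {list(columns)}"
        )
    return resolved


def read_formant_table(
    path: str | Path, *, dialect: str = "csv"
) -> tuple[list[FormantToken], ValidationReport]:
    """Read a long-format formant token table.

    Parameters
    ----------
    path
        CSV (or TSV with ``dialect='tsv'``) file with a header row naming
        the six required columns (aliases accepted, case-insensitive).

    Returns
    -------
    tokens, report
        All rows as :class:`FormantToken`, in file order, and a
        :class:`ValidationReport` of soft data-quality flags
        (``f2_le_f1``, ``out_of_range``).

    Raises
    ------
    SchemaError, ParseError, DuplicateKeyError
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)

    tokens: list[FormantToken] = []
    report = ValidationReport()
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        raw = dict(zip(df.columns, row))
        speaker = str(raw[cols["speaker"]]).strip()
        session = str(raw[cols["session"]]).strip().lower()
        if session not in SESSIONS:
            raise ParseError(
                f"row {i}: session {raw[cols['session']]!r} is not one of {SESSIONS}"
            )
        try:
            vowel = VowelLabel.from_string(str(raw[cols["vowel"]]))
        except ValueError as exc:
            raise ParseError(f"row {i}, column {cols['vowel']}: {exc}") from None
        rep = _parse_number(raw, cols["repetition"], i, integer=True)
        f1 = _parse_number(raw, cols["f1_hz"], i)
        f2 = _parse_number(raw, cols["f2_hz"], i)
        if f1 <= 0 or f2 <= 0:
            raise ParseError(f"row {i}: formant values must be positive (f1={f1}, f2={f2})")

        key = (speaker, session, vowel, rep)
        if key in seen:
            raise DuplicateKeyError(
                f"row {i} duplicates (speaker={speaker}, session={session}, "
                f"vowel={vowel.value}, repetition={rep}) first seen at row {seen[key]}"
            )
        seen[key] = i

        if f2 <= f1:
            report.add(i, "f2_le_f1", f"row {i}: f2 ({f2}) <= f1 ({f1}); likely mis-tracked formant")
        for name, val in (("f1", f1), ("f2", f2)):
            if not (PLAUSIBLE_HZ[0] <= val <= PLAUSIBLE_HZ[1]):
                report.add(i, "out_of_range", f"row {i}: {name} = {val} Hz outside plausible range")
        tokens.append(FormantToken(speaker, session, vowel, int(rep), f1, f2))
    return tokens, report


def _parse_number(raw: dict, col: str, row: int, *, integer: bool = False) -> float:
    text = str(raw[col]).strip()
    try:
        value = float(text)
        if integer:
            if value != int(value):
                raise ValueError
            return int(value)
        return value
    except ValueError:
        kind = "integer" if integer else "number"
        raise ParseError(f"row {row}, column {col}: {text!r} is not a valid {kind}") from None


def write_formant_table(tokens: Iterable[FormantToken], path: str | Path) -> None:
    """Write tokens as the canonical CSV layout (round-trips exactly)."""
    tokens_to_frame(tokens).to_csv(path, index=False)


def tokens_to_frame(tokens: Iterable[FormantToken]) -> pd.DataFrame:
    """Long-format DataFrame view with canonical column names."""
    return pd.DataFrame(
        [
            {
                "speaker": t.speaker,
                "session": t.session,
                "vowel": t.vowel.value,
                "repetition": t.repetition,
                "f1_hz": t.f1,
                "f2_hz": t.f2,
            }
            for t in tokens
        ],
        columns=["speaker", "session", "vowel", "repetition", "f1_hz", "f2_hz"],
    )


def frame_to_tokens(df: pd.DataFrame) -> list[FormantToken]:
    return [
        FormantToken(
            str(r.speaker),
            str(r.session),
            VowelLabel.from_string(str(r.vowel)),
            int(r.repetition),
            float(r.f1_hz),
            float(r.f2_hz),
        )
        for r in df.itertuples(index=False)
    ]


def compute_vowel_means(tokens: Sequence[FormantToken]) -> list[VowelMeans]:
    """Arithmetic mean F1/F2 per (speaker, session, vowel) cell.

    No pooling across speakers or sessions; ``n_tokens`` counts
    contributing repetitions.
    """
    if not tokens:
        raise EmptyInputError("no tokens to average")
    df = tokens_to_frame(tokens)
    grouped = df.groupby(["speaker", "session", "vowel"], sort=True).agg(
        f1_mean=("f1_hz", "mean"), f2_mean=("f2_hz", "mean"), n_tokens=("f1_hz", "size")
    )
    return [
        VowelMeans(sp, sess, VowelLabel(v), float(g.f1_mean), float(g.f2_mean), int(g.n_tokens))
        for (sp, sess, v), g in grouped.iterrows()
    ]


def means_to_frame(means: Iterable[VowelMeans]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "speaker": m.speaker,
                "session": m.session,
                "vowel": m.vowel.value,
                "f1_mean": m.f1_mean,
                "f2_mean": m.f2_mean,
                "n_tokens": m.n_tokens,
            }
            for m in means
        ],
        columns=["speaker", "session", "vowel", "f1_mean", "f2_mean", "n_tokens"],
    )


def _fixture_path(name: str) -> Path:
    ref = importlib.resources.files("vowelspace").joinpath("data", name)
    path = Path(str(ref))
    if not path.exists():
        raise PackagingError(f"packaged fixture {name} not found")
    return path


def load_group_means_fixture(group: str = "DS") -> list[VowelMeans]:
    """Published group-average formant means for the 10-vowel inventory.

    ``group='DS'`` returns the study cohort's baseline means (session
    label ``baseline``); ``group='TD'`` returns typically-developing
    reference norms (session label ``reference``). One record per vowel.
    """
    if group not in ("DS", "TD"):
        raise ValueError(f"group must be 'DS' or 'TD', got {group!r}")
    df = pd.read_csv(_fixture_path("group_formant_means.csv"))
    sub = df[df["group"] == group]
    if len(sub) != len(ALL_VOWELS):
        raise PackagingError(
            f"group means fixture corrupt: expected {len(ALL_VOWELS)} rows for {group}, got {len(sub)}"
        )
    session = "baseline" if group == "DS" else "reference"
    return [
        VowelMeans(group, session, VowelLabel(r.vowel), float(r.f1_hz), float(r.f2_hz), 1)
        for r in sub.itertuples(index=False)
    ]


def load_change_scores_fixture() -> list[ChangeRecord]:
    """Per-speaker metric changes and intelligibility gains (13 speakers).

    Transcription of the study cohort's published change table: ΔAAVS,
    ΔqVSA, ΔVSAhull in Hz² and the WCAB growth-scale-value gain.
    """
    df = pd.read_csv(_fixture_path("cohort_change_scores.csv"))
    if len(df) != 13 or df["speaker"].duplicated().any():
        raise PackagingError("change-score fixture corrupt: expected 13 unique speakers")
    records = [
        ChangeRecord(
            str(r.speaker),
            float(r.d_aavs),
            float(r.d_qvsa),
            float(r.d_vsahull),
            float(r.wcab_ae_gain),
        )
        for r in df.itertuples(index=False)
    ]
    if not all(np.isfinite([v for r in records for v in (r.d_aavs, r.d_qvsa, r.d_vsahull, r.wcab_ae_gain)])):
        raise PackagingError("change-score fixture corrupt: non-finite value")
    return records


def read_gain_table(path: str | Path) -> dict[str, float]:
    """Read a per-speaker gain-score table (columns: speaker, gain)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    speaker_col = cols.get("speaker")
    gain_col = next((cols[k] for k in ("gain", "wcab_ae_gain", "wcabaegain") if k in cols), None)
    if speaker_col is None or gain_col is None:
        raise SchemaError("gain table needs columns 'speaker' and 'gain' (or 'wcab_ae_gain')")
    if df[speaker_col].duplicated().any():
        raise DuplicateKeyError("gain table has duplicate speakers")
    return {str(r[speaker_col]): float(r[gain_col]) for _, r in df.iterrows()}


def changes_to_frame(records: Iterable[ChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "speaker": r.speaker,
                "d_aavs": r.d_aavs,
                "d_qvsa": r.d_qvsa,
                "d_vsahull": r.d_vsahull,
                "wcab_ae_gain": r.wcab_ae_gain,
            }
            for r in records
        ],
        columns=["speaker", "d_aavs", "d_qvsa", "d_vsahull", "wcab_ae_gain"],
    )
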