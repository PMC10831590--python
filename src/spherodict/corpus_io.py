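"""Reading and validating visit tables, tokenization, and vocabulary building.

A *visit table* is a :class:`pandas.DataFrame` with one row per emergency
department visit.  Canonical columns (after schema mapping):

``visit_id``, ``text`` (the free-text suspected-diagnosis note),
``chief_complaint`` (optional structured code), the binary outcomes
``y_inpatient`` and ``y_low_esi``, any covariate columns, and ``timestamp``.
Rows whose note is empty are retained but flagged ``text_missing`` so the
caller can reproduce the usual exclusion step explicitly.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default frequency floor for vocabulary construction: words occurring fewer
#: than this many times in the corpus are dropped.
DEFAULT_MIN_COUNT = 10

# Runs of Unicode letters; digits and punctuation act as separators.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

#: Canonical column names a visit table may carry.
CANONICAL_COLUMNS = (
    "visit_id",
    "text",
    "chief_complaint",
    "y_inpatient",
    "y_low_esi",
    "timestamp",
)

_BINARY_COLUMNS = ("y_inpatient", "y_low_esi")


class SchemaError(ValueError):
    """A mandatory column is missing or the schema is malformed."""


class RowValidationError(ValueError):
    """A row carries an unparseable value; the message lists the row ids."""


def tokenize(text: str | None) -> list[str]:
    """Split free text into lowercase word tokens.

    Splits on any non-letter character, so punctuation and standalone digits
    vanish; Unicode letters (umlauts etc.) are preserved.  Deterministic and
    idempotent over join/retokenize.

    >>> tokenize("Druck auf Thorax.")
    ['druck', 'auf', 'thorax']
    """
    if text is None:
        return []
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(str(text))]


def tokenize_corpus(texts: Iterable[str | None]) -> list[list[str]]:
    """Tokenize each note, preserving order; one token list per visit."""
    return [tokenize(t) for t in texts]


def build_vocabulary(
    corpus: Sequence[Sequence[str]], min_count: int = DEFAULT_MIN_COUNT
) -> dict[str, int]:
    """Count token frequencies across the corpus and apply the frequency floor.

    Parameters
    ----------
    corpus
        Per-visit token sequences.
    min_count
        Words occurring fewer than ``min_count`` times are excluded.
        Default 10: rare words make unreliable dictionary keywords and
        unreliable embedding neighbours.

    Returns
    -------
    dict mapping word -> exact corpus frequency (all ``>= min_count``).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if not corpus:
        raise ValueError("empty corpus: no visits to count")
    counts = Counter()
    for tokens in corpus:
        counts.update(tokens)
    return {w: c for w, c in counts.items() if c >= min_count}


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_visits(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited visit file into a canonical visit table.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.  The delimiter is sniffed from the
        header (comma, tab or semicolon) unless ``delimiter`` overrides it.
    schema
        Map from canonical names (``visit_id``, ``text``, outcome and
        covariate names) to the file's column names.  Unmapped columns are
        carried through unchanged.  If omitted, the file is assumed to use
        canonical names already.  The ``text`` column is mandatory.

    Returns
    -------
    DataFrame with one row per input row (row count preserved), canonical
    column names, and a boolean ``text_missing`` flag for rows whose note
    is empty or blank.

    Raises
    ------
    SchemaError
        If the text column (or any explicitly mapped column) is absent.
    RowValidationError
        If an outcome column contains values other than 0/1 (or NA).
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str} if schema is None else None)

    rename: dict[str, str] = {}
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(
                f"columns named in schema are absent from {path.name}: {missing}"
            )
        rename = {src: canon for canon, src in schema.items()}
        df = df.rename(columns=rename)

    if "text" not in df.columns:
        raise SchemaError(
            "visit table must contain a 'text' column (map it via the schema)"
        )
    if "visit_id" in df.columns:
        df["visit_id"] = df["visit_id"].astype(str)
    else:
        df.insert(0, "visit_id", [str(i) for i in range(len(df))])

    for col in _BINARY_COLUMNS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[~(vals.isin([0, 1]) | vals.isna())].tolist()
            if bad or (vals.isna() & df[col].notna()).any():
                bad_ids = df.loc[
                    sorted(set(bad) | set(df.index[vals.isna() & df[col].notna()])),
                    "visit_id",
                ].tolist()
                raise RowValidationError(
                    f"column {col!r} must be binary 0/1; offending rows: {bad_ids}"
                )
            df[col] = vals

    text = df["text"].fillna("")
    df["text"] = text.astype(str)
    df["text_missing"] = text.astype(str).str.strip() == ""

    n_flag = int(df["text_missing"].sum())
    logger.info(
        "loaded %d visits from %s (%d with empty note text)", len(df), path, n_flag
    )
    return df


def save_visits(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a visit table back to delimited text (lossless round-trip)."""
    df.to_csv(path, sep=delimiter, index=False)
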