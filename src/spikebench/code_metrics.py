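"""Code-complexity metric: lines of code (LOC) and number of characters
(NOC) after stripping comments, blank lines and unnecessary spaces.

The normalizer understands three comment dialects spanning the languages of
simulator modules (Python scripts, C/C++ sources, NMODL mechanism files):

- ``hash``:  ``#`` line comments; Python string literals (including triple
  quotes) are protected so a ``#`` inside a string survives;
- ``c``:     ``//`` line comments and ``/* ... */`` block comments; double-
  and single-quoted literals protected;
- ``colon``: ``:`` line comments (NMODL convention).

"Unnecessary spaces" means runs of horizontal whitespace collapsed to a
single space and per-line leading/trailing whitespace removed (``collapse``
mode); ``remove`` mode deletes them entirely.  NOC never counts line
terminators, so the metric is invariant to LF/CRLF convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["CodeMetrics", "normalize_source", "count_loc_noc", "measure"]

DIALECTS = ("hash", "c", "colon")


@dataclass(frozen=True)
class CodeMetrics:
    loc: int
    noc: int
    dialect: str = "hash"


def _strip_hash(text: str) -> str:
    """Remove # comments, protecting Python-style string literals."""
    out = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        if ch in "\"'":
            for quote in (ch * 3, ch):
                if text.startswith(quote, i):
                    end = _scan_string(text, i, quote)
                    out.append(text[i:end])
                    i = end
                    break
            continue
        out.append(ch)
        i += 1
    return "".join(out)


def _scan_string(text: str, start: int, quote: str) -> int:
    """Index one past the end of the string literal opening at ``start``."""
    i = start + len(quote)
    n = len(text)
    while i < n:
        if text[i] == "\\":
            i += 2
            continue
        if text.startswith(quote, i):
            return i + len(quote)
        if len(quote) == 1 and text[i] == "\n":
            return i  # unterminated single-line literal: stop at EOL
        i += 1
    return n


def _strip_c(text: str) -> str:
    """Remove // and /* */ comments, protecting string/char literals."""
    out = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in "\"'":
            end = _scan_string(text, i, ch)
            out.append(text[i:end])
            i = end
            continue
        if text.startswith("//", i):
            while i < n and text[i] != "\n":
                i += 1
            continue
        if text.startswith("/*", i):
            close = text.find("*/", i + 2)
            if close == -1:
                line = text.count("\n", 0, i) + 1
                raise ValueError(f"unterminated block comment at line {line}")
            # keep interior newlines so later line numbers stay meaningful
            out.append("\n" * text.count("\n", i, close + 2))
            i = close + 2
            continue
        out.append(ch)
        i += 1
    return "".join(out)


def _strip_colon(text: str) -> str:
    """Remove ':'-to-end-of-line comments (NMODL style)."""
    return "\n".join(line.split(":", 1)[0] for line in text.split("\n"))


_STRIPPERS = {"hash": _strip_hash, "c": _strip_c, "colon": _strip_colon}
_WS_RUN = re.compile(r"[ \t]+")


def normalize_source(text: str, dialect: str = "hash", spaces: str = "collapse") -> str:
    """Strip comments, blank lines and unnecessary spaces; idempotent.

    ``spaces="collapse"`` (default) shrinks internal whitespace runs to one
    space; ``"remove"`` deletes them outright (the alternative reading of
    the metric, which also merges tokens).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if spaces not in ("collapse", "remove"):
        raise ValueError(f"unknown spaces mode {spaces!r}")
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    text = _STRIPPERS[dialect](text)
    repl = " " if spaces == "collapse" else ""
    lines = []
    for line in text.split("\n"):
        line = _WS_RUN.sub(repl, line).strip()
        if line:
            lines.append(line)
    return "\n".join(lines)


def count_loc_noc(text: str, dialect: str = "hash") -> CodeMetrics:
    """LOC/NOC of already-normalized text.

    loc = number of non-empty lines; noc = characters excluding line
    terminators.
    """
    lines = [ln for ln in text.replace("\r\n", "\n").split("\n") if ln]
    return CodeMetrics(
        loc=len(lines), noc=sum(len(ln) for ln in lines), dialect=dialect
    )


def measure(text: str, dialect: str = "hash", spaces: str = "collapse") -> CodeMetrics:
    """Normalize raw source text and count LOC/NOC in one call."""
    return count_loc_noc(normalize_source(text, dialect, spaces), dialect)
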