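"""Tokenization with character spans.

Whitespace/punctuation splitting that keeps exact character offsets, so
token-level agreement and BIO export can be mapped back onto the text.
Dotted date patterns (13.05.2019) and clock times (14:30) are kept as
single tokens, since they are annotated as single temporal mentions.
"""

from __future__ import annotations

import re
from typing import NamedTuple

_TOKEN_RE = re.compile(
    r"\d{1,2}\.\d{1,2}\.\d{2,4}"  # day.month.year dates
    r"|\d{1,2}\.\d{4}"            # month.year dates
    r"|\d{1,2}:\d{2}"             # clock times
    r"|\w+"
    r"|[^\w\s]",
    re.UNICODE,
)


class Token(NamedTuple):
    start: int
    end: int
    text: str


def tokenize_text(text: str) -> list[Token]:
    """Tokens with 0-based half-open character spans."""
    return [Token(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]
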