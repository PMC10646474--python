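"""Reading and writing Portable Game Notation (PGN).

The reader is deliberately tolerant: it splits a stream into games on tag
sections, tokenizes movetext (stripping comments, variations and numeric
annotation glyphs), and skips — but counts — games whose movetext cannot
be tokenized as SAN.  Legality of the move sequence is *not* checked here;
that is a filtering decision made downstream.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

_TAG_RE = re.compile(r'^\[(\w+)\s+"(.*)"\]\s*$')
_SAN_TOKEN_RE = re.compile(
    r"^(O-O(-O)?|0-0(-0)?|[KQRBN]?[a-h]?[1-8]?x?[a-h][1-8](=[QRBN])?)[+#]?[!?]*$"
)
_RESULT_TOKENS = {"1-0", "0-1", "1/2-1/2", "*"}


class PgnError(ValueError):
    pass


class EmptyInputError(PgnError):
    """The stream contained no parseable games."""


@dataclass
class RawGame:
    """One syntactically valid game: tag pairs plus SAN tokens."""

    tags: dict[str, str]
    moves: list[str]
    result_token: str | None = None


@dataclass
class ParseReport:
    parsed: int = 0
    skipped: int = 0
    skip_reasons: list[str] = field(default_factory=list)


def _strip_movetext(text: str) -> str:
    """Remove comments {...}, variations (...) (nested) and ; line comments."""
    out, depth, brace = [], 0, False
    i = 0
    while i < len(text):
        ch = text[i]
        if brace:
            if ch == "}":
                brace = False
        elif ch == "{":
            brace = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif ch == ";":
            while i < len(text) and text[i] != "\n":
                i += 1
            out.append("\n")
        elif depth == 0:
            out.append(ch)
        i += 1
    return "".join(out)


def _tokenize(movetext: str):
    moves, result = [], None
    for tok in _strip_movetext(movetext).split():
        if tok in _RESULT_TOKENS:
            result = tok
            break
        tok = re.sub(r"^\d+\.(\.\.)?", "", tok).lstrip(".")  # move numbers
        if not tok or tok.startswith("$"):
            continue
        if not _SAN_TOKEN_RE.match(tok):
            raise PgnError(f"bad movetext token {tok!r}")
        moves.append(tok)
    return moves, result


def read_pgn(stream) -> tuple[list[RawGame], ParseReport]:
    """Parse a PGN text stream into games; malformed games are skipped.

    Raises :class:`EmptyInputError` if no game parses at all.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        text = stream.read()
    except OSError as exc:  # pragma: no cover - passthrough contract
        raise PgnError(f"unreadable stream: {exc}") from exc

    # split into (tags, movetext) chunks: a tag section starts each game
    games: list[tuple[dict, str]] = []
    tags: dict[str, str] = {}
    body: list[str] = []
    in_body = False
    for line in text.splitlines():
        m = _TAG_RE.match(line)
        if m:
            if in_body:
                games.append((tags, "\n".join(body)))
                tags, body, in_body = {}, [], False
            tags[m.group(1)] = m.group(2)
        elif line.strip():
            body.append(line)
            in_body = True
    if tags or body:
        games.append((tags, "\n".join(body)))

    report = ParseReport()
    out = []
    for tags, movetext in games:
        try:
            moves, result = _tokenize(movetext)
            if not moves and not tags:
                raise PgnError("empty game")
            out.append(RawGame(tags=tags, moves=moves, result_token=result or tags.get("Result")))
            report.parsed += 1
        except PgnError as exc:
            report.skipped += 1
            report.skip_reasons.append(str(exc))
            log.warning("skipping malformed game: %s", exc)
    if not out:
        raise EmptyInputError("no parseable games in input")
    return out, report


def write_pgn(games, path=None) -> str:
    """Serialize RawGame objects (or (tags, moves, result) tuples) to PGN text."""
    chunks = []
    for g in games:
        if not isinstance(g, RawGame):
            tags, moves, result = g
            g = RawGame(tags=dict(tags), moves=list(moves), result_token=result)
        tag_order = ["Event", "Site", "Date", "Round", "White", "Black", "Result"]
        keys = [k for k in tag_order if k in g.tags] + [
            k for k in g.tags if k not in tag_order
        ]
        lines = [f'[{k} "{g.tags[k]}"]' for k in keys]
        body = []
        for i, mv in enumerate(g.moves):
            if i % 2 == 0:
                body.append(f"{i // 2 + 1}.")
            body.append(mv)
        body.append(g.result_token or g.tags.get("Result", "*"))
        chunks.append("\n".join(lines) + "\n\n" + " ".join(body) + "\n")
    text = "\n".join(chunks)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
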