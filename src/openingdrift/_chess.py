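"""Compact chess move-legality engine.

Implements exactly what the ingest pipeline needs: applying games recorded
in standard algebraic notation (SAN) from the normal starting position,
generating legal moves (for SAN disambiguation and check/mate suffixes),
and hashing positions so that transpositions — identical board states
reached through different move orders — can be detected.

Board representation: a length-64 list of piece characters, square 0 = a1,
square 7 = h1, square 63 = h8 (file = sq % 8, rank = sq // 8).  White
pieces are upper-case "PNBRQK", black lower-case, empty squares "".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

WHITE = "w"
BLACK = "b"

_KNIGHT_STEPS = ((1, 2), (2, 1), (2, -1), (1, -2), (-1, -2), (-2, -1), (-2, 1), (-1, 2))
_KING_STEPS = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))
_BISHOP_DIRS = ((1, 1), (-1, 1), (-1, -1), (1, -1))
_ROOK_DIRS = ((1, 0), (0, 1), (-1, 0), (0, -1))

_SAN_RE = re.compile(
    r"^([KQRBN]?)([a-h]?)([1-8]?)(x?)([a-h][1-8])(?:=([QRBN]))?[+#]?$"
)


class IllegalMoveError(ValueError):
    """Raised when a SAN token does not denote a legal move in the position."""


def _sq(file: int, rank: int) -> int:
    return rank * 8 + file


def square_name(sq: int) -> str:
    return "abcdefgh"[sq % 8] + "12345678"[sq // 8]


@dataclass(frozen=True)
class Move:
    from_sq: int
    to_sq: int
    promotion: str | None = None  # "Q", "R", "B" or "N"
    is_castle: bool = False
    is_ep: bool = False


class Board:
    """Mutable chess position supporting push/SAN round-trips."""

    __slots__ = ("squares", "turn", "castling", "ep")

    def __init__(self) -> None:
        self.squares: list[str] = [""] * 64
        back = "RNBQKBNR"
        for f in range(8):
            self.squares[_sq(f, 0)] = back[f]
            self.squares[_sq(f, 1)] = "P"
            self.squares[_sq(f, 6)] = "p"
            self.squares[_sq(f, 7)] = back[f].lower()
        self.turn = WHITE
        self.castling = {"K", "Q", "k", "q"}
        self.ep: int | None = None  # en-passant target square, if any

    def copy(self) -> "Board":
        b = Board.__new__(Board)
        b.squares = self.squares.copy()
        b.turn = self.turn
        b.castling = self.castling.copy()
        b.ep = self.ep
        return b

    # -- piece helpers -------------------------------------------------

    def _is_own(self, sq: int) -> bool:
        p = self.squares[sq]
        return bool(p) and (p.isupper() == (self.turn == WHITE))

    def _is_enemy(self, sq: int, color: str | None = None) -> bool:
        color = color or self.turn
        p = self.squares[sq]
        return bool(p) and (p.isupper() != (color == WHITE))

    def _king_sq(self, color: str) -> int:
        k = "K" if color == WHITE else "k"
        return self.squares.index(k)

    # -- attack detection ---------------------------------------------

    def attacked(self, sq: int, by: str) -> bool:
        """True if `sq` is attacked by any piece of colour `by`."""
        f0, r0 = sq % 8, sq // 8
        up = by == WHITE  # attacker pawn moves up the board
        pawn = "P" if up else "p"
        dr = -1 if up else 1  # attacker sits one rank behind its target
        for df in (-1, 1):
            f, r = f0 + df, r0 + dr
            if 0 <= f < 8 and 0 <= r < 8 and self.squares[_sq(f, r)] == pawn:
                return True
        knight = "N" if up else "n"
        for df, dr in _KNIGHT_STEPS:
            f, r = f0 + df, r0 + dr
            if 0 <= f < 8 and 0 <= r < 8 and self.squares[_sq(f, r)] == knight:
                return True
        king = "K" if up else "k"
        for df, dr in _KING_STEPS:
            f, r = f0 + df, r0 + dr
            if 0 <= f < 8 and 0 <= r < 8 and self.squares[_sq(f, r)] == king:
                return True
        for dirs, sliders in ((_BISHOP_DIRS, "BQ"), (_ROOK_DIRS, "RQ")):
            want = sliders if up else sliders.lower()
            for df, dr in dirs:
                f, r = f0 + df, r0 + dr
                while 0 <= f < 8 and 0 <= r < 8:
                    p = self.squares[_sq(f, r)]
                    if p:
                        if p in want:
                            return True
                        break
                    f, r = f + df, r + dr
        return False

    def in_check(self, color: str | None = None) -> bool:
        color = color or self.turn
        other = BLACK if color == WHITE else WHITE
        return self.attacked(self._king_sq(color), other)

    # -- move generation ----------------------------------------------

    def _pseudo_moves(self):
        white = self.turn == WHITE
        fwd = 1 if white else -1
        start_rank = 1 if white else 6
        promo_rank = 7 if white else 0
        for sq in range(64):
            if not self._is_own(sq):
                continue
            p = self.squares[sq].upper()
            f0, r0 = sq % 8, sq // 8
            if p == "P":
                r1 = r0 + fwd
                if 0 <= r1 < 8 and not self.squares[_sq(f0, r1)]:
                    yield from self._pawn_moves(sq, _sq(f0, r1), promo_rank)
                    r2 = r0 + 2 * fwd
                    if r0 == start_rank and not self.squares[_sq(f0, r2)]:
                        yield Move(sq, _sq(f0, r2))
                for df in (-1, 1):
                    f1 = f0 + df
                    if not (0 <= f1 < 8 and 0 <= r1 < 8):
                        continue
                    to = _sq(f1, r1)
                    if self._is_enemy(to):
                        yield from self._pawn_moves(sq, to, promo_rank)
                    elif to == self.ep:
                        yield Move(sq, to, is_ep=True)
            elif p == "N":
                yield from self._step_moves(sq, _KNIGHT_STEPS)
            elif p == "K":
                yield from self._step_moves(sq, _KING_STEPS)
                yield from self._castle_moves(sq)
            else:
                dirs = {"B": _BISHOP_DIRS, "R": _ROOK_DIRS}.get(p, _BISHOP_DIRS + _ROOK_DIRS)
                for df, dr in dirs:
                    f, r = f0 + df, r0 + dr
                    while 0 <= f < 8 and 0 <= r < 8:
                        to = _sq(f, r)
                        if self._is_own(to):
                            break
                        yield Move(sq, to)
                        if self.squares[to]:
                            break
                        f, r = f + df, r + dr

    @staticmethod
    def _pawn_moves(frm: int, to: int, promo_rank: int):
        if to // 8 == promo_rank:
            for promo in "QRBN":
                yield Move(frm, to, promotion=promo)
        else:
            yield Move(frm, to)

    def _step_moves(self, sq: int, steps):
        f0, r0 = sq % 8, sq // 8
        for df, dr in steps:
            f, r = f0 + df, r0 + dr
            if 0 <= f < 8 and 0 <= r < 8 and not self._is_own(_sq(f, r)):
                yield Move(sq, _sq(f, r))

    def _castle_moves(self, king_sq: int):
        white = self.turn == WHITE
        rank = 0 if white else 7
        if king_sq != _sq(4, rank) or self.in_check():
            return
        other = BLACK if white else WHITE
        rights = ("K", "Q") if white else ("k", "q")
        # (right, rook file, empty files, king path files)
        for right, empties, path, to_file in (
            (rights[0], (5, 6), (5, 6), 6),
            (rights[1], (1, 2, 3), (2, 3), 2),
        ):
            if right not in self.castling:
                continue
            if any(self.squares[_sq(f, rank)] for f in empties):
                continue
            if any(self.attacked(_sq(f, rank), other) for f in path):
                continue
            yield Move(king_sq, _sq(to_file, rank), is_castle=True)

    def legal_moves(self) -> list[Move]:
        out = []
        for mv in self._pseudo_moves():
            b = self.copy()
            b._apply(mv)
            if not b.in_check(self.turn):
                out.append(mv)
        return out

    # -- state updates -------------------------------------------------

    def _apply(self, mv: Move) -> None:
        piece = self.squares[mv.from_sq]
        white = self.turn == WHITE
        self.ep = None
        if piece.upper() == "P" and abs(mv.to_sq - mv.from_sq) == 16:
            self.ep = (mv.from_sq + mv.to_sq) // 2
        if mv.is_ep:
            self.squares[mv.to_sq + (-8 if white else 8)] = ""
        if mv.is_castle:
            rank = mv.from_sq // 8
            if mv.to_sq % 8 == 6:
                rook_from, rook_to = _sq(7, rank), _sq(5, rank)
            else:
                rook_from, rook_to = _sq(0, rank), _sq(3, rank)
            self.squares[rook_to] = self.squares[rook_from]
            self.squares[rook_from] = ""
        self.squares[mv.from_sq] = ""
        if mv.promotion:
            self.squares[mv.to_sq] = mv.promotion if white else mv.promotion.lower()
        else:
            self.squares[mv.to_sq] = piece
        # castling-right bookkeeping: king/rook moved or rook captured
        for sq, right in ((4, "KQ"), (0, "Q"), (7, "K"), (60, "kq"), (56, "q"), (63, "k")):
            if mv.from_sq == sq or mv.to_sq == sq:
                self.castling -= set(right)
        self.turn = BLACK if white else WHITE

    def push(self, mv: Move) -> None:
        self._apply(mv)

    # -- SAN -----------------------------------------------------------

    def parse_san(self, san: str) -> Move:
        token = san.strip().rstrip("!?").replace("0", "O")
        legal = self.legal_moves()
        if token.rstrip("+#") in ("O-O", "O-O-O"):
            to_file = 6 if token.rstrip("+#") == "O-O" else 2
            for mv in legal:
                if mv.is_castle and mv.to_sq % 8 == to_file:
                    return mv
            raise IllegalMoveError(f"illegal castle {san!r}")
        m = _SAN_RE.match(token)
        if not m:
            raise IllegalMoveError(f"unparseable SAN {san!r}")
        piece, dis_file, dis_rank, _x, target, promo = m.groups()
        piece = piece or "P"
        to = _sq("abcdefgh".index(target[0]), int(target[1]) - 1)
        cands = []
        for mv in legal:
            if mv.is_castle or mv.to_sq != to:
                continue
            if self.squares[mv.from_sq].upper() != piece:
                continue
            if dis_file and mv.from_sq % 8 != "abcdefgh".index(dis_file):
                continue
            if dis_rank and mv.from_sq // 8 != int(dis_rank) - 1:
                continue
            if (mv.promotion or None) != (promo or None):
                continue
            cands.append(mv)
        if len(cands) != 1:
            raise IllegalMoveError(f"SAN {san!r} matches {len(cands)} moves")
        return cands[0]

    def san(self, mv: Move) -> str:
        """Canonical SAN for a legal move, including +/# suffix."""
        piece = self.squares[mv.from_sq].upper()
        capture = bool(self.squares[mv.to_sq]) or mv.is_ep
        if mv.is_castle:
            core = "O-O" if mv.to_sq % 8 == 6 else "O-O-O"
        elif piece == "P":
            core = ""
            if capture:
                core += "abcdefgh"[mv.from_sq % 8] + "x"
            core += square_name(mv.to_sq)
            if mv.promotion:
                core += "=" + mv.promotion
        else:
            rivals = [
                m
                for m in self.legal_moves()
                if m.to_sq == mv.to_sq
                and m.from_sq != mv.from_sq
                and self.squares[m.from_sq].upper() == piece
            ]
            dis = ""
            if rivals:
                same_file = any(m.from_sq % 8 == mv.from_sq % 8 for m in rivals)
                same_rank = any(m.from_sq // 8 == mv.from_sq // 8 for m in rivals)
                if not same_file:
                    dis = "abcdefgh"[mv.from_sq % 8]
                elif not same_rank:
                    dis = "12345678"[mv.from_sq // 8]
                else:
                    dis = square_name(mv.from_sq)
            core = piece + dis + ("x" if capture else "") + square_name(mv.to_sq)
        after = self.copy()
        after._apply(mv)
        if after.in_check(after.turn):
            core += "#" if not after.legal_moves() else "+"
        return core

    def push_san(self, san: str) -> str:
        """Apply a SAN token; returns the canonical SAN actually played."""
        mv = self.parse_san(san)
        canonical = self.san(mv)
        self._apply(mv)
        return canonical

    # -- position identity ---------------------------------------------

    def position_key(self) -> str:
        """FEN-style key: placement, side to move, castling, en-passant.

        The en-passant field is recorded only when a pawn of the side to
        move could actually capture onto the target square (pins ignored),
        so that positions differing only by an unusable double-push flag
        still compare equal.
        """
        rows = []
        for rank in range(7, -1, -1):
            row, run = "", 0
            for f in range(8):
                p = self.squares[_sq(f, rank)]
                if p:
                    row += (str(run) if run else "") + p
                    run = 0
                else:
                    run += 1
            rows.append(row + (str(run) if run else ""))
        castl = "".join(c for c in "KQkq" if c in self.castling) or "-"
        ep = "-"
        if self.ep is not None:
            pawn = "P" if self.turn == WHITE else "p"
            rank = self.ep // 8 + (-1 if self.turn == WHITE else 1)
            for df in (-1, 1):
                f = self.ep % 8 + df
                if 0 <= f < 8 and self.squares[_sq(f, rank)] == pawn:
                    ep = square_name(self.ep)
                    break
        return "/".join(rows) + f" {self.turn} {castl} {ep}"


def replay(sans: list[str]) -> Board:
    """Apply a list of SAN moves from the starting position."""
    b = Board()
    for s in sans:
        b.push_san(s)
    return b


def canonicalize(sans: list[str]) -> list[str]:
    """Normalize a SAN sequence (annotations stripped, suffixes canonical)."""
    b = Board()
    return [b.push_san(s) for s in sans]
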