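"""Phone-level feature tables and fixed-shape word encodings.

Words enter the transfer models as sequences of subsegmental articulatory
feature vectors (one vector per phone, entries in {-1, 0, +1} following the
ternary convention of articulatory feature systems: +1 the feature is
present, -1 absent, 0 not applicable).  Sequences are zero-padded to a fixed
length of 15 positions and truncated beyond it; the all-zero row is reserved
for padding and masked out downstream, which is why a feature table may never
assign the all-zero vector to a real phone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

#: Fixed sequence length: words longer than this are truncated (prefix kept).
MAX_PHONES = 15

__all__ = [
    "MAX_PHONES",
    "PhoneticFeatureTable",
    "EncodedWord",
    "FeatureTableError",
    "SegmentationError",
    "load_feature_table",
    "save_feature_table",
    "segment_ipa",
    "encode_word",
    "decode_word",
]


class FeatureTableError(ValueError):
    """Malformed feature table (duplicate phone, ragged row, bad value...)."""


class SegmentationError(ValueError):
    """A phone string could not be segmented against a feature table."""

    def __init__(self, message: str, offset: int):
        super().__init__(message)
        self.offset = offset


@dataclass
class PhoneticFeatureTable:
    """Ordered map from phone symbol to a ternary feature vector.

    Parameters
    ----------
    symbols
        Phone symbols, in table order.  Must be unique.
    matrix
        ``(P, F)`` array with entries in ``{-1, 0, +1}``; row ``i`` is the
        feature vector of ``symbols[i]``.  No row may be all zero (the zero
        vector is the padding symbol).
    """

    symbols: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.symbols):
            raise FeatureTableError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.symbols)} symbols"
            )
        if len(set(self.symbols)) != len(self.symbols):
            dupes = sorted({s for s in self.symbols if self.symbols.count(s) > 1})
            raise FeatureTableError(f"duplicate phone symbol(s): {dupes}")
        bad = ~np.isin(self.matrix, (-1.0, 0.0, 1.0))
        if bad.any():
            r = int(np.argwhere(bad)[0, 0])
            raise FeatureTableError(
                f"feature values outside {{-1,0,1}} in row for {self.symbols[r]!r}"
            )
        zero = ~self.matrix.any(axis=1)
        if zero.any():
            r = int(np.argmax(zero))
            raise FeatureTableError(
                f"all-zero feature vector for phone {self.symbols[r]!r} "
                "(the zero vector is reserved for padding)"
            )
        self._index = {s: i for i, s in enumerate(self.symbols)}

    @property
    def feature_dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def vector(self, symbol: str) -> np.ndarray:
        try:
            return self.matrix[self._index[symbol]]
        except KeyError:
            raise KeyError(f"unknown phone symbol {symbol!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhoneticFeatureTable):
            return NotImplemented
        return self.symbols == other.symbols and np.array_equal(
            self.matrix, other.matrix
        )


@dataclass
class EncodedWord:
    """A word as a fixed-shape ``(15, F)`` feature matrix with prefix mask."""

    matrix: np.ndarray  # (MAX_PHONES, F)
    mask: np.ndarray  # (MAX_PHONES,) bool, True on the first `length` rows
    length: int


def load_feature_table(path) -> PhoneticFeatureTable:
    """Read a feature table from CSV with header ``phone,f1,...,fF``."""
    symbols: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "phone":
            raise FeatureTableError(f"{path}: expected header starting with 'phone'")
        width = len(header) - 1
        if width < 1:
            raise FeatureTableError(f"{path}: no feature columns")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width + 1:
                raise FeatureTableError(
                    f"{path}:{lineno}: ragged row for phone {row[0]!r} "
                    f"({len(row) - 1} values, expected {width})"
                )
            symbol = row[0]
            if symbol in symbols:
                raise FeatureTableError(
                    f"{path}:{lineno}: duplicate phone {symbol!r}"
                )
            try:
                values = [float(v) for v in row[1:]]
            except ValueError as exc:
                raise FeatureTableError(
                    f"{path}:{lineno}: non-numeric value for phone {symbol!r}"
                ) from exc
            symbols.append(symbol)
            rows.append(values)
    if not symbols:
        raise FeatureTableError(f"{path}: empty feature table")
    return PhoneticFeatureTable(symbols, np.array(rows, dtype=float))


def save_feature_table(table: PhoneticFeatureTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phone"] + [f"f{i + 1}" for i in range(table.feature_dim)])
        for symbol, row in zip(table.symbols, table.matrix):
            writer.writerow([symbol] + [f"{v:g}" for v in row])


def segment_ipa(s: str, table: PhoneticFeatureTable) -> list[str]:
    """Greedy longest-match segmentation of ``s`` into the table's symbols.

    Whitespace separates tokens and is never part of a symbol.  Multi-character
    symbols (affricates, diacritic-bearing segments) are matched greedily from
    the left, longest symbol first.
    """
    if not s:
        raise SegmentationError("empty phone string", 0)
    max_len = max(len(sym) for sym in table.symbols)
    phones: list[str] = []
    i = 0
    while i < len(s):
        if s[i].isspace():
            i += 1
            continue
        for k in range(min(max_len, len(s) - i), 0, -1):
            candidate = s[i : i + k]
            if candidate in table:
                phones.append(candidate)
                i += k
                break
        else:
            raise SegmentationError(
                f"no phone symbol matches input at offset {i} ({s[i:]!r})", i
            )
    if not phones:
        raise SegmentationError("phone string contains only whitespace", 0)
    return phones


def encode_word(phones, table: PhoneticFeatureTable) -> EncodedWord:
    """Stack the phones' feature vectors into a padded ``(15, F)`` matrix.

    The first ``min(len(phones), 15)`` rows carry the feature vectors in
    order; later phones are discarded (prefix truncation) and remaining rows
    are zero with ``mask=False``.
    """
    phones = list(phones)
    if not phones:
        raise ValueError("cannot encode an empty phone sequence")
    length = min(len(phones), MAX_PHONES)
    matrix = np.zeros((MAX_PHONES, table.feature_dim), dtype=float)
    for i, symbol in enumerate(phones[:MAX_PHONES]):
        matrix[i] = table.vector(symbol)
    mask = np.zeros(MAX_PHONES, dtype=bool)
    mask[:length] = True
    return EncodedWord(matrix=matrix, mask=mask, length=length)


def decode_word(encoded: EncodedWord, table: PhoneticFeatureTable) -> list[str]:
    """Recover the phone symbols of the masked rows (inverse of encode_word)."""
    phones = []
    for row in encoded.matrix[: encoded.length]:
        matches = np.flatnonzero((table.matrix == row).all(axis=1))
        if matches.size == 0:
            raise ValueError("row does not match any phone in the table")
        phones.append(table.symbols[int(matches[0])])
    return phones
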