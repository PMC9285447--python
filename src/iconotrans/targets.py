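"""Output spaces: dense visual/semantic vectors and one-hot word classes.

Dense targets travel in the standard word-embedding text format (header line
``N dim``, then ``id v1 ... vdim`` per row).  Word classes go through a
collapse scheme (raw tag -> coarse supertag) with optional dropped supertags:
a word whose supertag is dropped is silently excluded (SKIP) rather than
raising, mirroring the removal of a class dimension that has no surviving
members.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SKIP",
    "DenseTargetStore",
    "WordClassScheme",
    "TargetFormatError",
    "load_dense_vectors",
    "save_dense_vectors",
    "load_class_scheme",
    "filter_unambiguous",
    "encode_class",
]


class TargetFormatError(ValueError):
    """Malformed dense-vector file or class scheme."""


class _Skip:
    """Sentinel for words whose word class is excluded from the encoding."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SKIP"


SKIP = _Skip()


@dataclass
class DenseTargetStore:
    """Map from concept id to a dense target vector of fixed dimension."""

    vectors: dict[str, np.ndarray]
    dim: int
    kind: str  # "visual" (elementwise >= 0) or "semantic" (signed)

    def __post_init__(self) -> None:
        if self.kind not in ("visual", "semantic"):
            raise ValueError(f"kind must be 'visual' or 'semantic', got {self.kind!r}")
        for cid, vec in self.vectors.items():
            if len(vec) != self.dim:
                raise TargetFormatError(
                    f"vector for {cid!r} has length {len(vec)}, expected {self.dim}"
                )
            if self.kind == "visual" and np.any(np.asarray(vec) < 0):
                raise TargetFormatError(
                    f"visual vector for {cid!r} has a negative entry"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, cid: str) -> np.ndarray:
        return self.vectors[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.vectors


def load_dense_vectors(path, kind: str) -> DenseTargetStore:
    """Parse a word-embedding text file (``N dim`` header, one id per row)."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise TargetFormatError(f"{path}: expected header 'N dim'")
        try:
            n, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise TargetFormatError(f"{path}: non-integer header {header!r}") from exc
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            cid = parts[0]
            if cid in vectors:
                raise TargetFormatError(f"{path}:{lineno}: duplicate id {cid!r}")
            if len(parts) - 1 != dim:
                raise TargetFormatError(
                    f"{path}:{lineno}: row for {cid!r} has {len(parts) - 1} "
                    f"values, header says {dim}"
                )
            vectors[cid] = np.array([float(v) for v in parts[1:]], dtype=float)
    if len(vectors) != n:
        raise TargetFormatError(
            f"{path}: header announces {n} rows, found {len(vectors)}"
        )
    return DenseTargetStore(vectors=vectors, dim=dim, kind=kind)


def save_dense_vectors(store: DenseTargetStore, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(store.vectors)} {store.dim}\n")
        for cid, vec in store.vectors.items():
            fh.write(f"{cid} " + " ".join(f"{v:.8g}" for v in vec) + "\n")


@dataclass
class WordClassScheme:
    """Tag-collapse scheme: raw tag -> supertag, with dropped supertags.

    The one-hot encoding dimension is ``len(supertags) - len(dropped)``; the
    active supertags keep their order in ``supertags``.
    """

    collapse_map: dict[str, str]
    supertags: list[str]
    dropped: frozenset[str] = frozenset()
    _active: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dropped = frozenset(self.dropped)
        unknown = self.dropped - set(self.supertags)
        if unknown:
            raise ValueError(f"dropped supertags not in scheme: {sorted(unknown)}")
        missing = set(self.collapse_map.values()) - set(self.supertags)
        if missing:
            raise ValueError(f"collapse targets not in supertags: {sorted(missing)}")
        self._active = [t for t in self.supertags if t not in self.dropped]
        if not self._active:
            raise ValueError("all supertags dropped; empty encoding")

    @property
    def active_supertags(self) -> list[str]:
        return list(self._active)

    @property
    def encoding_dim(self) -> int:
        return len(self._active)

    @classmethod
    def identity(cls, classes: list[str]) -> "WordClassScheme":
        """Trivial scheme where every raw tag is its own supertag."""
        return cls({c: c for c in classes}, list(classes))


def load_class_scheme(path, dropped=()) -> WordClassScheme:
    """Read a collapse map CSV (``raw_tag,supertag``; supertags in first-seen order)."""
    collapse: dict[str, str] = {}
    supertags: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["raw_tag", "supertag"]:
            raise TargetFormatError(f"{path}: expected header 'raw_tag,supertag'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise TargetFormatError(f"{path}:{lineno}: expected two columns")
            raw, supertag = row
            if raw in collapse:
                raise TargetFormatError(f"{path}:{lineno}: duplicate raw tag {raw!r}")
            collapse[raw] = supertag
            if supertag not in supertags:
                supertags.append(supertag)
    return WordClassScheme(collapse, supertags, frozenset(dropped))


def filter_unambiguous(entries):
    """Keep only words associated with exactly one raw tag.

    ``entries`` is an iterable of ``(word, set_of_raw_tags)``; the result is a
    list of ``(word, raw_tag)`` for the unambiguous words, input order kept.
    Idempotent: applying it to its own output (with singleton tag sets)
    changes nothing.
    """
    out = []
    for word, tags in entries:
        tags = set(tags) if not isinstance(tags, (set, frozenset)) else tags
        if len(tags) == 1:
            out.append((word, next(iter(tags))))
    return out


def encode_class(raw_tag: str, scheme: WordClassScheme):
    """One-hot encode a raw tag over the scheme's active supertags.

    Returns the one-hot vector, or the :data:`SKIP` sentinel when the tag
    collapses to a dropped supertag.
    """
    try:
        supertag = scheme.collapse_map[raw_tag]
    except KeyError:
        raise KeyError(f"unknown raw tag {raw_tag!r}") from None
    if supertag in scheme.dropped:
        return SKIP
    vec = np.zeros(scheme.encoding_dim, dtype=float)
    vec[scheme._active.index(supertag)] = 1.0
    return vec
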