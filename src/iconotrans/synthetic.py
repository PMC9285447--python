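"""Synthetic multilingual lexicons with a planted, tunable non-arbitrary signal.

The generator emulates the statistical structure that the cross-lingual
transfer design assumes: a set of concepts shared (aligned) across six
languages from six distinct families, variable-length phone strings over a
synthetic inventory, dense nonnegative "visual" and dense "semantic" target
vectors per concept, and a skewed word-class distribution.

Generative model
----------------
Each concept ``i`` has a latent meaning ``m_i ~ N(0, I_M)`` and a word class
``c_i ~ Categorical(class_probs)``.  Targets are noisy linear(+rectified)
readouts of the meaning:

* visual:    ``v_i = max(0, A m_i + sigma * eps)``   (nonnegative, like
  rectified convolutional feature maps)
* semantic:  ``s_i = B m_i + sigma * eps``           (signed, like word
  embeddings)

Word forms are sampled phone by phone.  The score of phone ``p`` for concept
``i`` in language ``l`` is::

    beta  * cos(feat(p), u_i)        u_i = tanh(G m_i)      iconicity
  + gamma * cos(feat(p), w_{c_i})    w_c = tanh(H onehot(c)) systematicity
  + lambda_lang * b_{l,p}            language-specific phonotactic bias

and phones are drawn from a softmax of these scores at a given temperature.
``G`` and ``H`` are fixed random readouts shared across *all* languages, so a
nonzero ``beta`` (``gamma``) plants a cross-lingually consistent
form-to-meaning (form-to-class) association; ``beta = gamma = 0`` yields an
arbitrary lexicon in which forms carry language bias only (the null).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .features import PhoneticFeatureTable

__all__ = [
    "SyntheticConfig",
    "Concept",
    "LexiconEntry",
    "MultilingualLexicon",
    "make_feature_table",
    "make_concepts",
    "make_forms",
    "generate",
    "write_lexicon",
    "read_lexicon",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one role of the pipeline, from one base seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic lexicon generator.

    ``beta`` and ``gamma`` are the planted iconicity (form-to-meaning) and
    systematicity (form-to-class) strengths in [0, 1]; both zero gives an
    arbitrary (null) lexicon.  ``lambda_lang`` weighs language-specific phone
    biases (phonotactic idiosyncrasy), ``sigma`` the target noise, and
    ``temperature`` the entropy of phone sampling.
    """

    n_concepts: int = 600
    n_languages: int = 6
    inventory_size: int = 40
    feature_dim: int = 24
    meaning_dim: int = 16
    visual_dim: int = 64
    semantic_dim: int = 32
    n_classes: int = 5
    class_probs: tuple[float, ...] | None = None  # default: 1/rank, normalized
    word_len_range: tuple[int, int] = (3, 9)
    class_distinctiveness: tuple[float, ...] | None = None  # default: log-spaced
    beta: float = 1.0
    gamma: float = 1.0
    lambda_lang: float = 1.0
    sigma: float = 0.1
    temperature: float = 0.5
    seed: int = 0

    def resolved_class_distinctiveness(self) -> np.ndarray:
        """Per-class markedness profile, rms-normalized so gamma keeps its
        meaning as the overall systematicity strength."""
        if self.class_distinctiveness is None:
            d = np.geomspace(6.0, 0.1, self.n_classes)
        else:
            d = np.asarray(self.class_distinctiveness, dtype=float)
        return d / np.sqrt(np.mean(d**2))

    def resolved_class_probs(self) -> np.ndarray:
        if self.class_probs is None:
            p = 1.0 / np.arange(1, self.n_classes + 1)
            return p / p.sum()
        return np.asarray(self.class_probs, dtype=float)

    def validate(self) -> None:
        if self.n_concepts < 1 or self.n_languages < 1:
            raise ValueError("n_concepts and n_languages must be positive")
        if not (0.0 <= self.beta <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if self.lambda_lang < 0 or self.sigma < 0:
            raise ValueError("lambda_lang and sigma must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        lo, hi = self.word_len_range
        if not (1 <= lo <= hi <= 15):
            raise ValueError("word_len_range must lie within [1, 15]")
        p = self.resolved_class_probs()
        if len(p) != self.n_classes:
            raise ValueError("class_probs length must equal n_classes")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("class_probs must be a probability vector")
        if 3**self.feature_dim <= self.inventory_size:
            raise ValueError("3^feature_dim must exceed inventory_size")


@dataclass
class Concept:
    concept_id: str
    meaning: np.ndarray  # (M,)
    word_class: int


@dataclass
class LexiconEntry:
    concept_id: str
    language_id: str
    family_id: str
    phones: list[str]


@dataclass
class MultilingualLexicon:
    """Concept-aligned entries across languages, with per-concept targets."""

    feature_table: PhoneticFeatureTable
    concepts: list[Concept]
    entries: list[LexiconEntry]
    visual_targets: dict[str, np.ndarray]
    semantic_targets: dict[str, np.ndarray]
    config: SyntheticConfig | None = None

    @property
    def languages(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.language_id)
        return list(seen)

    @property
    def families(self) -> dict[str, str]:
        return {e.language_id: e.family_id for e in self.entries}

    def concept_classes(self) -> dict[str, int]:
        return {c.concept_id: c.word_class for c in self.concepts}

    def entries_by_language(self) -> dict[str, list[LexiconEntry]]:
        out: dict[str, list[LexiconEntry]] = {}
        for e in self.entries:
            out.setdefault(e.language_id, []).append(e)
        return out


def make_feature_table(P: int, F: int, seed: int) -> PhoneticFeatureTable:
    """Draw ``P`` distinct nonzero ternary feature vectors in ``{-1,0,1}^F``.

    Symbols are ``p00, p01, ...``.  The all-zero vector is excluded (reserved
    for padding) and rows are pairwise distinct.
    """
    if P < 2 or F < 1:
        raise ValueError("need P >= 2 phones and F >= 1 features")
    if 3**F - 1 < P:
        raise ValueError(
            f"cannot draw {P} distinct nonzero vectors from {{-1,0,1}}^{F}"
        )
    rng = _rng(seed, 0)
    rows: list[tuple[float, ...]] = []
    seen: set[tuple[float, ...]] = set()
    attempts = 0
    limit = 1000 * P + 1000
    while len(rows) < P:
        attempts += 1
        if attempts > limit:
            raise RuntimeError("feature-table sampling failed to find distinct rows")
        vec = tuple(float(v) for v in rng.integers(-1, 2, size=F))
        if not any(vec) or vec in seen:
            continue
        seen.add(vec)
        rows.append(vec)
    width = max(2, len(str(P - 1)))
    symbols = [f"p{i:0{width}d}" for i in range(P)]
    return PhoneticFeatureTable(symbols, np.array(rows, dtype=float))


def _targets_from_meanings(
    meanings: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy linear readouts of meanings: rectified visual, signed semantic."""
    n, M = meanings.shape
    A = rng.standard_normal((cfg.visual_dim, M)) / np.sqrt(M)
    B = rng.standard_normal((cfg.semantic_dim, M)) / np.sqrt(M)
    visual = meanings @ A.T + cfg.sigma * rng.standard_normal((n, cfg.visual_dim))
    semantic = meanings @ B.T + cfg.sigma * rng.standard_normal((n, cfg.semantic_dim))
    return np.maximum(visual, 0.0), semantic


def make_concepts(
    cfg: SyntheticConfig,
) -> tuple[list[Concept], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Sample concepts (meaning + class) and their visual/semantic targets."""
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    width = max(4, len(str(cfg.n_concepts - 1)))
    ids = [f"c{i:0{width}d}" for i in range(cfg.n_concepts)]
    meanings = rng.standard_normal((cfg.n_concepts, cfg.meaning_dim))
    classes = rng.choice(cfg.n_classes, size=cfg.n_concepts, p=cfg.resolved_class_probs())
    visual, semantic = _targets_from_meanings(meanings, cfg, rng)
    concepts = [
        Concept(cid, meanings[i], int(classes[i])) for i, cid in enumerate(ids)
    ]
    return (
        concepts,
        {cid: visual[i] for i, cid in enumerate(ids)},
        {cid: semantic[i] for i, cid in enumerate(ids)},
    )


def _cosine_rows(matrix: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Cosine of each matrix row with ``vec`` (0 where either norm vanishes)."""
    norms = np.linalg.norm(matrix, axis=1) * np.linalg.norm(vec)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (matrix @ vec) / norms
    return np.where(norms > 1e-12, out, 0.0)


def make_forms(
    concepts: list[Concept],
    languages: list[tuple[str, str]],
    table: PhoneticFeatureTable,
    cfg: SyntheticConfig,
) -> list[LexiconEntry]:
    """Sample a word form for every (concept, language) pair.

    ``languages`` is a list of ``(language_id, family_id)`` pairs.  Phone
    scores combine the shared iconic and systematic readouts with
    language-specific biases (see module docstring); each phone position is
    drawn i.i.d. from the softmax of the scores at ``cfg.temperature``.
    """
    if len(table) == 0:
        raise ValueError("empty phone inventory")
    rng = _rng(cfg.seed, 2)
    M, C, F, P = cfg.meaning_dim, cfg.n_classes, table.feature_dim, len(table)

    G = rng.standard_normal((F, M)) / np.sqrt(M)
    H = rng.standard_normal((F, C))
    biases = rng.standard_normal((len(languages), P))  # b_{l,p}

    def _standardize(rows: np.ndarray) -> np.ndarray:
        # Center each row (softmax ignores constant shifts) and scale every
        # component by ONE pooled sd so beta, gamma and lambda_lang weigh
        # commensurable quantities (raw cosines have spread ~1/sqrt(F), far
        # below the unit-variance language biases).  The pooled scale
        # preserves relative spread BETWEEN rows: distinctive classes and
        # expressible concepts stay stronger than diffuse ones.
        centered = rows - rows.mean(axis=-1, keepdims=True)
        pooled = np.sqrt(np.mean(centered**2))
        return centered / (pooled if pooled > 1e-12 else 1.0)

    biases = _standardize(biases)

    # Per-concept shared scores (language independent).
    iconic = np.zeros((len(concepts), P))
    systematic = np.zeros((len(concepts), P))
    class_dirs = np.tanh(H)  # (F, C); column c is w_c
    class_scores = _standardize(
        np.stack([_cosine_rows(table.matrix, class_dirs[:, c]) for c in range(C)])
    )  # (C, P)
    # Word classes differ sharply in phonological markedness (closed
    # function-word classes and depictive classes like interjections carry
    # far more distinctive phone preferences than large open classes).  The
    # distinctiveness profile scales each class's standardized score row;
    # without it every class would be equally transparent by construction and
    # the cross-language profile of per-class difficulty would be degenerate.
    class_scores = class_scores * cfg.resolved_class_distinctiveness()[:, None]
    for i, concept in enumerate(concepts):
        u = np.tanh(G @ concept.meaning)
        iconic[i] = _cosine_rows(table.matrix, u)
        systematic[i] = class_scores[concept.word_class]
    iconic = _standardize(iconic)

    lo, hi = cfg.word_len_range
    entries: list[LexiconEntry] = []
    for li, (language_id, family_id) in enumerate(languages):
        scores = (
            cfg.beta * iconic
            + cfg.gamma * systematic
            + cfg.lambda_lang * biases[li][None, :]
        ) / cfg.temperature
        scores -= scores.max(axis=1, keepdims=True)
        probs = np.exp(scores)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        lengths = rng.integers(lo, hi + 1, size=len(concepts))
        draws = rng.random((len(concepts), hi))
        # Rowwise inverse-CDF sampling of phone indices.
        idx = (draws[:, :, None] > cum[:, None, :]).sum(axis=2)
        for i, concept in enumerate(concepts):
            phones = [table.symbols[j] for j in idx[i, : lengths[i]]]
            entries.append(
                LexiconEntry(concept.concept_id, language_id, family_id, phones)
            )
    return entries


def generate(cfg: SyntheticConfig) -> MultilingualLexicon:
    """Generate a full multilingual lexicon (table, concepts, forms, targets)."""
    cfg.validate()
    table = make_feature_table(cfg.inventory_size, cfg.feature_dim, cfg.seed)
    concepts, visual, semantic = make_concepts(cfg)
    languages = [(f"lang{i}", f"fam{i}") for i in range(cfg.n_languages)]
    entries = make_forms(concepts, languages, table, cfg)
    return MultilingualLexicon(
        feature_table=table,
        concepts=concepts,
        entries=entries,
        visual_targets=visual,
        semantic_targets=semantic,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Serialization: TSV lexicon, CSV feature table, word-embedding text targets.
# ---------------------------------------------------------------------------


def _write_vectors(path, store: dict[str, np.ndarray]) -> None:
    ids = list(store)
    dim = len(store[ids[0]]) if ids else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(ids)} {dim}\n")
        for cid in ids:
            values = " ".join(f"{v:.8g}" for v in store[cid])
            fh.write(f"{cid} {values}\n")


def write_lexicon(lexicon: MultilingualLexicon, outdir) -> None:
    """Write the lexicon as plain-text interchange files under ``outdir``.

    Produces ``lexicon.tsv`` (concept_id, language_id, family_id,
    space-separated phones, word_class), ``feature_table.csv``, and
    ``visual.vec`` / ``semantic.vec`` in the word-embedding text format.
    """
    import os

    from .features import save_feature_table

    os.makedirs(outdir, exist_ok=True)
    classes = lexicon.concept_classes()
    with open(os.path.join(outdir, "lexicon.tsv"), "w", encoding="utf-8") as fh:
        fh.write("concept_id\tlanguage_id\tfamily_id\tphones\tword_class\n")
        for e in lexicon.entries:
            fh.write(
                f"{e.concept_id}\t{e.language_id}\t{e.family_id}\t"
                f"{' '.join(e.phones)}\t{classes[e.concept_id]}\n"
            )
    save_feature_table(lexicon.feature_table, os.path.join(outdir, "feature_table.csv"))
    _write_vectors(os.path.join(outdir, "visual.vec"), lexicon.visual_targets)
    _write_vectors(os.path.join(outdir, "semantic.vec"), lexicon.semantic_targets)


def read_lexicon(indir) -> MultilingualLexicon:
    """Load a lexicon previously written by :func:`write_lexicon`.

    Latent meanings are not serialized; reloaded concepts carry empty meaning
    vectors (they are not needed downstream of generation).
    """
    import os

    from .features import load_feature_table
    from .targets import load_dense_vectors

    table = load_feature_table(os.path.join(indir, "feature_table.csv"))
    visual = load_dense_vectors(os.path.join(indir, "visual.vec"), kind="visual")
    semantic = load_dense_vectors(os.path.join(indir, "semantic.vec"), kind="semantic")
    entries: list[LexiconEntry] = []
    classes: dict[str, int] = {}
    with open(os.path.join(indir, "lexicon.tsv"), encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append(
                LexiconEntry(
                    row["concept_id"],
                    row["language_id"],
                    row["family_id"],
                    row["phones"].split(),
                )
            )
            classes[row["concept_id"]] = int(row["word_class"])
    concepts = [
        Concept(cid, np.zeros(0), word_class) for cid, word_class in classes.items()
    ]
    return MultilingualLexicon(
        feature_table=table,
        concepts=concepts,
        entries=entries,
        visual_targets=dict(visual.vectors),
        semantic_targets=dict(semantic.vectors),
    )
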