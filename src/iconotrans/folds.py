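"""Zero-shot transfer conditions: concept splits, held-out-family folds,
shuffled-output baselines, and class-balancing oversampling.

A condition holds one language (and with it, its whole family) out: the model
trains on the *training* concepts of every other family and is tested on the
*test* concepts of the held-out language only, so train and test are disjoint
in both concepts and languages.  The randomized baseline reuses the exact
same training inputs with the targets permuted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import EncodedWord, encode_word
from .synthetic import MultilingualLexicon
from .targets import SKIP

__all__ = [
    "ConceptSplit",
    "TransferCondition",
    "BaselinePairing",
    "DisjointReport",
    "split_concepts",
    "build_condition",
    "shuffle_targets",
    "oversample_classes",
    "verify_disjoint",
    "concat_train_count",
]


@dataclass
class ConceptSplit:
    train_ids: set[str]
    test_ids: set[str]
    ratio: float
    seed: int


@dataclass
class TransferCondition:
    heldout_language: str
    heldout_family: str
    train_pairs: list[tuple[EncodedWord, np.ndarray]]
    test_pairs: list[tuple[EncodedWord, np.ndarray]]
    train_provenance: list[tuple[str, str, str]]  # (concept, language, family)
    test_provenance: list[tuple[str, str, str]]


@dataclass
class BaselinePairing:
    """Training pairs with targets permuted; inputs and multiset of targets
    are identical to the originals."""

    pairs: list[tuple[EncodedWord, np.ndarray]]
    permutation: np.ndarray
    seed: int | None


@dataclass
class DisjointReport:
    passed: bool
    concept_overlap: list[str] = field(default_factory=list)
    family_leaks: list[tuple[str, str, str]] = field(default_factory=list)
    foreign_test_entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def split_concepts(concept_ids, ratio: float, seed: int) -> ConceptSplit:
    """Uniform random concept partition with ``|train| = round_half_up(ratio*n)``.

    Round-half-up is used so that e.g. 1161 concepts at ratio 0.8 give
    929/232 and 24612 give 19690/4922 (floor would give 928 and 19689).
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    ids = sorted(concept_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two concepts to split")
    n_train = int(math.floor(ratio * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = {ids[i] for i in perm[:n_train]}
    test = {ids[i] for i in perm[n_train:]}
    return ConceptSplit(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


def concat_train_count(per_language_train: int, n_languages: int = 6) -> int:
    """Size of the concatenated training set when one language is held out.

    With ``n_languages`` languages (one family each) and ``per_language_train``
    training items in each, every condition trains on the remaining
    ``n_languages - 1`` languages, i.e. ``per_language_train * (n_languages - 1)``
    items (e.g. 13397 -> 66985, 19690 -> 98450 for six languages).
    """
    if per_language_train < 0 or n_languages < 2:
        raise ValueError("need nonnegative size and at least two languages")
    return per_language_train * (n_languages - 1)


def build_condition(
    lexicon: MultilingualLexicon,
    targets,
    split: ConceptSplit,
    heldout: str,
) -> TransferCondition:
    """Assemble one held-out-family condition from a lexicon and a target map.

    ``targets`` maps concept_id to a target vector or :data:`SKIP`; SKIP
    concepts are excluded from both sets.  Training pairs come from the train
    concepts of every language whose family differs from the held-out
    language's family, in (language order, then concept order); test pairs are
    the test concepts of the held-out language only.
    """
    families = lexicon.families
    if heldout not in families:
        raise ValueError(f"unknown held-out language {heldout!r}")
    heldout_family = families[heldout]
    table = lexicon.feature_table

    def usable(cid: str) -> bool:
        t = targets.get(cid, SKIP)
        return t is not SKIP

    train_pairs, train_prov = [], []
    test_pairs, test_prov = [], []
    by_language = lexicon.entries_by_language()
    for language in lexicon.languages:
        entries = sorted(by_language[language], key=lambda e: e.concept_id)
        family = families[language]
        if family != heldout_family:
            for e in entries:
                if e.concept_id in split.train_ids and usable(e.concept_id):
                    train_pairs.append(
                        (encode_word(e.phones, table), np.asarray(targets[e.concept_id]))
                    )
                    train_prov.append((e.concept_id, language, family))
        if language == heldout:
            for e in entries:
                if e.concept_id in split.test_ids and usable(e.concept_id):
                    test_pairs.append(
                        (encode_word(e.phones, table), np.asarray(targets[e.concept_id]))
                    )
                    test_prov.append((e.concept_id, language, family))
    if not train_pairs or not test_pairs:
        raise ValueError(
            f"empty {'train' if not train_pairs else 'test'} set for held-out "
            f"{heldout!r} after filtering"
        )
    return TransferCondition(
        heldout_language=heldout,
        heldout_family=heldout_family,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        train_provenance=train_prov,
        test_provenance=test_prov,
    )


def shuffle_targets(
    train_pairs,
    seed: int | None = None,
    permutation=None,
    groups=None,
) -> BaselinePairing:
    """Permute the target side of the training pairs (randomized baseline).

    One uniform permutation is drawn over the whole concatenated training set.
    ``permutation`` overrides the random draw (e.g. an explicit identity);
    ``groups`` (a parallel list of group keys, e.g. language ids) restricts
    shuffling to within-group, for the per-language baseline variant.
    """
    n = len(train_pairs)
    if n < 2:
        raise ValueError("need at least two pairs to shuffle")
    if permutation is not None:
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(n)):
            raise ValueError("permutation must be a permutation of range(n)")
    elif groups is not None:
        if len(groups) != n:
            raise ValueError("groups must parallel train_pairs")
        rng = np.random.default_rng(seed)
        perm = np.arange(n)
        for g in dict.fromkeys(groups):
            idx = np.array([i for i, gi in enumerate(groups) if gi == g])
            perm[idx] = idx[rng.permutation(len(idx))]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
    pairs = [(train_pairs[i][0], train_pairs[int(perm[i])][1]) for i in range(n)]
    return BaselinePairing(pairs=pairs, permutation=perm, seed=seed)


def oversample_classes(train_pairs, labels, seed: int):
    """Raise every minority class to the majority count by resampling.

    ``labels`` parallels ``train_pairs``.  Each non-majority class is topped
    up by sampling with replacement from its own pairs; the majority class
    (and any already-balanced input) is untouched.  Returns the augmented
    ``(pairs, labels)``; originals always come first, in input order.
    """
    if len(labels) != len(train_pairs):
        raise ValueError("labels must parallel train_pairs")
    if not train_pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    counts: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        counts.setdefault(lab, []).append(i)
    majority = max(len(v) for v in counts.values())
    pairs_out = list(train_pairs)
    labels_out = list(labels)
    for lab in sorted(counts, key=str):
        idx = counts[lab]
        deficit = majority - len(idx)
        if deficit > 0:
            extra = rng.choice(idx, size=deficit, replace=True)
            for i in extra:
                pairs_out.append(train_pairs[int(i)])
                labels_out.append(lab)
    return pairs_out, labels_out


def verify_disjoint(condition: TransferCondition) -> DisjointReport:
    """Check the three disjointness invariants of a transfer condition.

    1. no concept appears in both train and test provenance;
    2. the held-out language's family is absent from train provenance;
    3. test provenance contains only the held-out language.
    """
    train_concepts = {p[0] for p in condition.train_provenance}
    test_concepts = {p[0] for p in condition.test_provenance}
    overlap = sorted(train_concepts & test_concepts)
    leaks = [
        p for p in condition.train_provenance if p[2] == condition.heldout_family
    ]
    foreign = [
        p for p in condition.test_provenance if p[1] != condition.heldout_language
    ]
    return DisjointReport(
        passed=not (overlap or leaks or foreign),
        concept_overlap=overlap,
        family_leaks=leaks,
        foreign_test_entries=foreign,
    )
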