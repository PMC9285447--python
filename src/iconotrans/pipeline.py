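"""End-to-end orchestration of the three transfer experiments.

One run: generate (or load) a multilingual lexicon, pick the target space
(visual, semantic, or word class), split concepts once, then for every
language build the held-out-family condition, train the experimental model
and its shuffled-output baseline twin (identical architecture and seed; only
the input-output pairing differs), predict on the held-out language's test
set, and evaluate the contrast.  Results are rendered as TSV tables in the
layout of the experiment reports, plus a per-class accuracy table and mean
pairwise correlation for word-class runs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from . import folds as F
from . import mapper as M
from . import stats as S
from .synthetic import MultilingualLexicon, SyntheticConfig, generate, read_lexicon
from .targets import SKIP, WordClassScheme, encode_class

__all__ = [
    "RunConfig",
    "FoldOutcome",
    "RunResult",
    "run_experiment",
    "report",
    "default_mapper_config",
    "load_run_config",
]

EXPERIMENTS = ("visual", "semantic", "wordclass")

_DEFAULT_HIDDEN = {"visual": 500, "semantic": 50, "wordclass": 25}
_DEFAULT_RATIO = {"visual": 0.8, "semantic": 0.8, "wordclass": 0.5}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full sixfold experiment."""

    experiment: str = "visual"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    data_dir: str | None = None  # load a written lexicon instead of generating
    split_ratio: float | None = None  # default 0.8 (0.5 for wordclass)
    mapper_overrides: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=lambda: {})
    out_dir: str | None = None

    def resolved_ratio(self) -> float:
        return self.split_ratio if self.split_ratio is not None else _DEFAULT_RATIO[self.experiment]

    def resolved_seeds(self) -> dict:
        base = {"split": 11, "shuffle": 13, "model": 17, "oversample": 19}
        base.update(self.seeds)
        return base

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")


@dataclass
class FoldOutcome:
    heldout_language: str
    result: object  # ContrastResult or ClassContrastResult
    n_train: int
    n_test: int
    train_manifest: list[tuple[str, str, str]]
    test_manifest: list[tuple[str, str, str]]


@dataclass
class RunResult:
    experiment: str
    folds: dict  # language -> FoldOutcome
    per_language_class_accuracy: dict | None = None
    per_class_mean: dict | None = None
    mean_pairwise_r: float | None = None
    config: RunConfig | None = None


def default_mapper_config(experiment: str, output_dim: int, **overrides) -> M.MapperConfig:
    """Per-experiment mapper defaults (hidden size, activation, loss)."""
    if experiment == "wordclass":
        base = dict(output_activation="softmax", loss="categorical_cross_entropy")
    elif experiment == "visual":
        base = dict(output_activation="relu", loss="negative_cosine")
    else:
        base = dict(output_activation="linear", loss="negative_cosine")
    base.update(hidden_units=_DEFAULT_HIDDEN[experiment], output_dim=output_dim)
    base.update(overrides)
    return M.MapperConfig(**base)


def _experiment_targets(cfg: RunConfig, lexicon: MultilingualLexicon):
    """Map concept -> target vector (or SKIP) for the configured experiment."""
    if cfg.experiment == "visual":
        return dict(lexicon.visual_targets)
    if cfg.experiment == "semantic":
        return dict(lexicon.semantic_targets)
    classes = lexicon.concept_classes()
    names = sorted({f"class{c}" for c in classes.values()})
    scheme = WordClassScheme.identity(names)
    return {
        cid: encode_class(f"class{c}", scheme) for cid, c in classes.items()
    }


def _oversample_per_language(condition, seed: int):
    """Balance classes within each training language, then re-concatenate."""
    pairs, prov = condition.train_pairs, condition.train_provenance
    out_pairs = []
    for language in dict.fromkeys(p[1] for p in prov):
        idx = [i for i, p in enumerate(prov) if p[1] == language]
        lang_pairs = [pairs[i] for i in idx]
        labels = [int(np.argmax(pairs[i][1])) for i in idx]
        balanced, _ = F.oversample_classes(lang_pairs, labels, seed)
        out_pairs.extend(balanced)
    return out_pairs


def run_experiment(cfg: RunConfig) -> RunResult:
    """Run the full sixfold zero-shot transfer experiment."""
    cfg.validate()
    seeds = cfg.resolved_seeds()
    lexicon = read_lexicon(cfg.data_dir) if cfg.data_dir else generate(cfg.synthetic)
    targets = _experiment_targets(cfg, lexicon)
    eligible = [cid for cid, t in targets.items() if t is not SKIP]
    split = F.split_concepts(eligible, cfg.resolved_ratio(), seeds["split"])

    output_dim = len(next(t for t in targets.values() if t is not SKIP))
    mcfg = default_mapper_config(
        cfg.experiment, output_dim, seed=seeds["model"], **cfg.mapper_overrides
    )

    folds_out: dict[str, FoldOutcome] = {}
    per_language_acc: dict[str, dict] = {}
    for fold_idx, language in enumerate(lexicon.languages):
        condition = F.build_condition(lexicon, targets, split, language)
        report_obj = F.verify_disjoint(condition)
        if not report_obj:
            raise RuntimeError(
                f"disjointness violated in fold {language!r}: {report_obj}"
            )
        train_pairs = condition.train_pairs
        if cfg.experiment == "wordclass":
            train_pairs = _oversample_per_language(
                condition, seeds["oversample"] + fold_idx
            )
        baseline_pairing = F.shuffle_targets(
            train_pairs, seed=seeds["shuffle"] + fold_idx
        )

        if cfg.experiment == "wordclass":
            model = M.train_classifier(train_pairs, mcfg)
            baseline = M.train_classifier(baseline_pairing.pairs, mcfg)
        else:
            model = M.train_regressor(train_pairs, mcfg)
            baseline = M.train_regressor(baseline_pairing.pairs, mcfg)

        test_words = [w for w, _ in condition.test_pairs]
        test_targets = [t for _, t in condition.test_pairs]
        preds_model = M.predict(model, test_words)
        preds_base = M.predict(baseline, test_words)

        if cfg.experiment == "wordclass":
            classes = list(range(output_dim))
            true = [int(np.argmax(t)) for t in test_targets]
            pm = [int(np.argmax(p)) for p in preds_model]
            pb = [int(np.argmax(p)) for p in preds_base]
            metrics_model = S.classification_metrics(true, pm, classes)
            metrics_base = S.classification_metrics(true, pb, classes)
            mc = S.mcnemar(
                [t == p for t, p in zip(true, pm)],
                [t == p for t, p in zip(true, pb)],
            )
            result = S.ClassContrastResult(
                model=metrics_model, baseline=metrics_base, chi2=mc.chi2, p=mc.p
            )
            per_language_acc[language] = metrics_model["per_class_accuracy"]
        else:
            cos_model = [S.cosine(p, t) for p, t in zip(preds_model, test_targets)]
            cos_base = [S.cosine(p, t) for p, t in zip(preds_base, test_targets)]
            result = S.paired_contrast(cos_model, cos_base)

        folds_out[language] = FoldOutcome(
            heldout_language=language,
            result=result,
            n_train=len(train_pairs),
            n_test=len(condition.test_pairs),
            train_manifest=condition.train_provenance,
            test_manifest=condition.test_provenance,
        )

    run = RunResult(experiment=cfg.experiment, folds=folds_out, config=cfg)
    if cfg.experiment == "wordclass":
        # Classes with no test support in some language are dropped from the
        # consistency profiles so every language shares the same class set.
        common = set.intersection(
            *(
                {c for c, a in acc.items() if not np.isnan(a)}
                for acc in per_language_acc.values()
            )
        )
        trimmed = {
            lang: {c: acc[c] for c in common}
            for lang, acc in per_language_acc.items()
        }
        per_class_mean, mean_r, _ = S.cross_language_consistency(trimmed)
        run.per_language_class_accuracy = per_language_acc
        run.per_class_mean = per_class_mean
        run.mean_pairwise_r = mean_r
    if cfg.out_dir:
        write_result_tables(run, cfg.out_dir)
    return run


def run_single_fold(cfg: RunConfig, heldout: str):
    """Run one held-out-family fold only and return its contrast result.

    Used for calibration studies where many independent single-fold runs are
    cheaper than full sixfold sweeps.
    """
    cfg.validate()
    seeds = cfg.resolved_seeds()
    lexicon = read_lexicon(cfg.data_dir) if cfg.data_dir else generate(cfg.synthetic)
    targets = _experiment_targets(cfg, lexicon)
    eligible = [cid for cid, t in targets.items() if t is not SKIP]
    split = F.split_concepts(eligible, cfg.resolved_ratio(), seeds["split"])
    output_dim = len(next(t for t in targets.values() if t is not SKIP))
    mcfg = default_mapper_config(
        cfg.experiment, output_dim, seed=seeds["model"], **cfg.mapper_overrides
    )
    condition = F.build_condition(lexicon, targets, split, heldout)
    train_pairs = condition.train_pairs
    if cfg.experiment == "wordclass":
        train_pairs = _oversample_per_language(condition, seeds["oversample"])
    baseline_pairing = F.shuffle_targets(train_pairs, seed=seeds["shuffle"])
    if cfg.experiment == "wordclass":
        model = M.train_classifier(train_pairs, mcfg)
        baseline = M.train_classifier(baseline_pairing.pairs, mcfg)
    else:
        model = M.train_regressor(train_pairs, mcfg)
        baseline = M.train_regressor(baseline_pairing.pairs, mcfg)
    test_words = [w for w, _ in condition.test_pairs]
    test_targets = [t for _, t in condition.test_pairs]
    preds_model = M.predict(model, test_words)
    preds_base = M.predict(baseline, test_words)
    if cfg.experiment == "wordclass":
        true = [int(np.argmax(t)) for t in test_targets]
        pm = [int(np.argmax(p)) for p in preds_model]
        pb = [int(np.argmax(p)) for p in preds_base]
        mc = S.mcnemar(
            [t == p for t, p in zip(true, pm)],
            [t == p for t, p in zip(true, pb)],
        )
        return S.ClassContrastResult(
            model=S.classification_metrics(true, pm, list(range(output_dim))),
            baseline=S.classification_metrics(true, pb, list(range(output_dim))),
            chi2=mc.chi2,
            p=mc.p,
        )
    cos_model = [S.cosine(p, t) for p, t in zip(preds_model, test_targets)]
    cos_base = [S.cosine(p, t) for p, t in zip(preds_base, test_targets)]
    return S.paired_contrast(cos_model, cos_base)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _regression_rows(run: RunResult):
    for language, fold in run.folds.items():
        r = fold.result
        yield (
            language,
            r.model_summary,
            r.baseline_summary,
            r.t,
            r.p,
            r.d,
        )


def report(run: RunResult) -> str:
    """Render the per-fold results as a human-readable table."""
    if not run.folds:
        raise ValueError("empty run result")
    lines = []
    if run.experiment == "wordclass":
        header = (
            "Language",
            "Accuracy",
            "Precision",
            "F1",
            "BaseAcc",
            "BasePrec",
            "BaseF1",
            "chi2",
            "p",
        )
        lines.append("\t".join(header))
        for language, fold in run.folds.items():
            r = fold.result
            lines.append(
                "\t".join(
                    [language]
                    + [
                        f"{v:.4f}"
                        for v in (
                            r.model["accuracy"],
                            r.model["weighted_precision"],
                            r.model["weighted_f1"],
                            r.baseline["accuracy"],
                            r.baseline["weighted_precision"],
                            r.baseline["weighted_f1"],
                            r.chi2,
                        )
                    ]
                    + [f"{r.p:.4g}"]
                )
            )
        if run.mean_pairwise_r is not None:
            lines.append(f"# mean pairwise Pearson r = {run.mean_pairwise_r:.4f}")
    else:
        header = (
            "Language",
            "Cosine",
            "SD",
            "CI_low",
            "CI_high",
            "BaseCosine",
            "BaseSD",
            "BaseCI_low",
            "BaseCI_high",
            "t",
            "p",
            "d",
        )
        lines.append("\t".join(header))
        for language, ms, bs, t, p, d in _regression_rows(run):
            lines.append(
                "\t".join(
                    [language]
                    + [
                        f"{v:.4f}"
                        for v in (
                            ms.mean,
                            ms.sd,
                            ms.ci_low,
                            ms.ci_high,
                            bs.mean,
                            bs.sd,
                            bs.ci_low,
                            bs.ci_high,
                            t,
                        )
                    ]
                    + [f"{p:.4g}", f"{d:.4f}"]
                )
            )
    return "\n".join(lines) + "\n"


def write_result_tables(run: RunResult, outdir) -> None:
    """Write the results table, fold manifests, and (for word-class runs)
    the per-class accuracy table under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "results.tsv"), "w", encoding="utf-8") as fh:
        fh.write(report(run))
    with open(os.path.join(outdir, "manifest.tsv"), "w", encoding="utf-8") as fh:
        fh.write("fold\tconcept_id\tlanguage_id\tfamily_id\trole\n")
        for language, fold in run.folds.items():
            for cid, lang, fam in fold.train_manifest:
                fh.write(f"{language}\t{cid}\t{lang}\t{fam}\ttrain\n")
            for cid, lang, fam in fold.test_manifest:
                fh.write(f"{language}\t{cid}\t{lang}\t{fam}\ttest\n")
    if run.per_language_class_accuracy is not None:
        classes = sorted(
            {c for acc in run.per_language_class_accuracy.values() for c in acc}
        )
        with open(
            os.path.join(outdir, "per_class_accuracy.tsv"), "w", encoding="utf-8"
        ) as fh:
            fh.write("language\t" + "\t".join(str(c) for c in classes) + "\n")
            for lang, acc in run.per_language_class_accuracy.items():
                fh.write(
                    lang
                    + "\t"
                    + "\t".join(f"{acc.get(c, float('nan')):.6f}" for c in classes)
                    + "\n"
                )


def load_run_config(data: dict) -> RunConfig:
    """Build a RunConfig from a plain dict (parsed YAML/JSON)."""
    data = dict(data)
    synth = data.pop("synthetic", None)
    if synth is not None:
        if "word_len_range" in synth:
            synth["word_len_range"] = tuple(synth["word_len_range"])
        if synth.get("class_probs") is not None:
            synth["class_probs"] = tuple(synth["class_probs"])
        data["synthetic"] = SyntheticConfig(**synth)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
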