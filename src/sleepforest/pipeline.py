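"""End-to-end staging experiment: simulate/load -> preprocess -> features
-> normalize -> ontology -> per-gender selection -> weights -> weighted
forest -> evaluation.

The protocol mirrors a leakage-guarded two-half design: one half of the
epochs (stratified by stage and gender) is used only for the correlation
analysis that picks each gender's optimal feature subset; the disjoint
other half is split 2/3 train / 1/3 test for weight computation and
classification.  Five experiment cases are preset: five-state staging
with plain information gain (case 1), five-state with the
standard-deviation-weighted criterion (case 2), and the weighted
criterion under the four-, three- and two-state merge schemes
(cases 3-5).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, feature_select, forest, ontology
from .epoch_io import StageScheme, feature_columns
from .errors import SleepForestError
from .features import FeatureConfig, extract_feature_matrix, minmax_apply, minmax_fit
from .preprocess import FilterSpec, preprocess_epoch
from .synthetic import SimulationConfig, generate_dataset

CASES = {
    1: {"scheme": "five", "weighted": False},
    2: {"scheme": "five", "weighted": True},
    3: {"scheme": "four", "weighted": True},
    4: {"scheme": "three", "weighted": True},
    5: {"scheme": "two", "weighted": True},
}


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    feature_table: str | None = None  # CSV path or in-memory table bypasses simulation
    scheme: str = "five"
    selection_scheme: str = "five"  # correlation analysis is run once,
    # against the five-state codes, whatever scheme classification uses
    weighted: bool = True
    selection_fraction: float = 0.5   # correlation half
    train_fraction: float = 2.0 / 3.0  # of the classification half
    p_threshold: float | None = feature_select.DEFAULT_THRESHOLD
    threshold_candidates: tuple = feature_select.DEFAULT_CANDIDATES
    adaptive: bool = False            # search candidates instead of fixed p
    n_trees: int = 30
    seed: int = 0
    filter_enabled: bool = True
    ica_enabled: bool = True
    output_dir: str | None = None


def _stratified_split(matrix: pd.DataFrame, fraction: float, seed: int):
    """Disjoint (a, b) index split, stratified by (stage, gender)."""
    rng = np.random.default_rng(seed)
    a_idx = []
    for _, group in matrix.groupby(["stage", "gender"], sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        n_a = int(round(fraction * len(idx)))
        a_idx.extend(idx[:n_a])
    a_mask = matrix.index.isin(a_idx)
    return matrix[a_mask], matrix[~a_mask]


def build_feature_table(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate epochs, preprocess and extract the 60-feature table."""
    epochs, meta = generate_dataset(config.simulation)
    if config.filter_enabled:
        epochs = [
            preprocess_epoch(
                ep, FilterSpec(), ica_enabled=config.ica_enabled,
                ica_seed=config.seed,
            )
            for ep in epochs
        ]
    return extract_feature_matrix(epochs, meta, FeatureConfig())


def run_experiment(config: ExperimentConfig, feature_table: pd.DataFrame | None = None):
    """Execute the full protocol; returns a manifest dict with the
    evaluation report under ``"report"``.

    ``feature_table`` (or ``config.feature_table``) short-circuits
    simulation and feature extraction, so several schemes can be compared
    on identical data.
    """
    if feature_table is None:
        if config.feature_table is not None:
            from .epoch_io import read_feature_table

            feature_table = read_feature_table(config.feature_table)
        else:
            feature_table = build_feature_table(config)
    matrix = feature_table.reset_index(drop=True)
    scheme = StageScheme.by_name(config.scheme)
    feats = feature_columns(matrix)

    # --- leakage guard: correlation half vs classification half -----------
    corr_half, clf_half = _stratified_split(
        matrix, config.selection_fraction, config.seed
    )
    overlap = set(corr_half["epoch_id"]) & set(clf_half["epoch_id"])
    if overlap:
        raise SleepForestError(f"correlation/classification halves overlap: {overlap}")

    # --- normalization fitted on the correlation half for selection -------
    norm_corr = minmax_apply(corr_half, minmax_fit(corr_half, feats))

    # --- ontology ingest: the correlation half is stored and queried back -
    store = ontology.bootstrap_schema()
    meta_stub = _subject_meta_from_table(matrix)
    ontology.ingest_feature_matrix(store, norm_corr, meta_stub)
    norm_corr = ontology.export_feature_matrix(store, feats)

    # --- per-gender selection on the correlation half ----------------------
    subsets, thresholds = {}, {}
    sel_scheme = StageScheme.by_name(config.selection_scheme)
    genders = sorted(g for g in matrix["gender"].unique() if g)
    for gender in genders:
        results = feature_select.correlate_features(norm_corr, gender, sel_scheme)
        if config.adaptive:
            evaluator = _make_cv_evaluator(norm_corr, gender, sel_scheme, config)
            p_star = feature_select.adaptive_threshold(
                results, config.threshold_candidates, evaluator, gender
            )
        else:
            p_star = config.p_threshold
        subsets[gender] = feature_select.select_subset(results, p_star, gender)
        thresholds[gender] = p_star

    # --- classification half: train 2/3 / test 1/3 per gender -------------
    y_true_all, y_pred_all, votes_all = [], [], []
    per_gender = {}
    for gender in genders:
        rows = clf_half[clf_half["gender"] == gender]
        train, test = _stratified_split(rows, config.train_fraction, config.seed + 1)
        params = minmax_fit(train, feats)
        train_n = minmax_apply(train, params)
        test_n = minmax_apply(test, params)
        subset = subsets[gender]
        w = forest.feature_weights(train_n, subset) if config.weighted else None
        y_train = feature_select.stage_codes(train_n, scheme)
        model = forest.train_forest_frame(
            train_n, y_train, subset.features, w=w,
            n_trees=config.n_trees, seed=config.seed,
        )
        y_test = feature_select.stage_codes(test_n, scheme)
        y_pred = model.predict_frame(test_n)
        votes = model.predict_votes(
            test_n[list(subset.features)].to_numpy(dtype=float)
        )
        y_true_all.extend(scheme.labels[i] for i in y_test)
        y_pred_all.extend(scheme.labels[i] for i in y_pred)
        votes_all.append(votes / config.n_trees)
        per_gender[gender] = {
            "n_train": len(train), "n_test": len(test),
            "subset": list(subset.features),
            "threshold": thresholds[gender],
            "weights": None if w is None else dict(zip(w.features, w.weights.tolist())),
        }

    report = evaluation.evaluate(
        y_true_all, y_pred_all, scheme.labels, scores=np.vstack(votes_all)
    )
    manifest = {
        "scheme": config.scheme,
        "weighted": config.weighted,
        "seed": config.seed,
        "n_trees": config.n_trees,
        "n_epochs": len(matrix),
        "n_correlation_half": len(corr_half),
        "n_classification_half": len(clf_half),
        "per_gender": per_gender,
        "y_true": y_true_all,
        "y_pred": y_pred_all,
        "accuracy": report.accuracy,
        "kappa": report.kappa_cohen,
        "report": report,
        "ontology_instances": len(store.instances),
    }
    if config.output_dir:
        _write_outputs(Path(config.output_dir), config, manifest, report)
    return manifest


def _subject_meta_from_table(matrix: pd.DataFrame):
    """Minimal SubjectMeta stubs for tables without a sidecar (age unknown
    in a bare CSV; recorded as the placeholder 1)."""
    from .epoch_io import SubjectMeta

    out = []
    for sid, group in matrix.groupby("subject_id", sort=True):
        gender = group["gender"].iloc[0]
        if gender not in ("female", "male"):
            gender = "female"
        out.append(SubjectMeta(subject_id=str(sid), gender=gender, age=1))
    return out


def _make_cv_evaluator(norm_matrix, gender, scheme, config):
    """5-fold CV accuracy of a small (10-tree) forest on the induced
    subset — the scorer behind the self-adaptive threshold."""

    rows = norm_matrix[norm_matrix["gender"] == gender].reset_index(drop=True)
    y = feature_select.stage_codes(rows, scheme)

    def evaluator(subset) -> float:
        X = rows[list(subset.features)].to_numpy(dtype=float)
        rng = np.random.default_rng(config.seed)
        idx = rng.permutation(len(y))
        folds = np.array_split(idx, 5)
        correct = 0
        for k in range(5):
            test_idx = folds[k]
            train_idx = np.concatenate([folds[j] for j in range(5) if j != k])
            model = forest.build_forest(
                X[train_idx], y[train_idx], n_trees=10, seed=config.seed,
                features=tuple(subset.features),
                n_classes=len(scheme.labels),
            )
            correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
        return correct / len(y)

    return evaluator


def _write_outputs(outdir: Path, config, manifest, report):
    outdir.mkdir(parents=True, exist_ok=True)
    slim = {k: v for k, v in manifest.items() if k != "report"}
    slim["simulation"] = asdict(config.simulation)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(slim, fh, indent=1)
    report.cm.to_frame().to_csv(outdir / "confusion_matrix.csv")
    report.to_frame().to_csv(outdir / "per_class_metrics.csv", index=False)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report.summary() + "\n")


def run_cases(
    config: ExperimentConfig,
    cases=(1, 2, 3, 4, 5),
    feature_table: pd.DataFrame | None = None,
) -> dict:
    """Run the preset experiment cases on one shared feature table."""
    if feature_table is None:
        feature_table = build_feature_table(config)
    out = {}
    for case in cases:
        preset = CASES[case]
        cfg = ExperimentConfig(**{
            **asdict_shallow(config),
            "scheme": preset["scheme"],
            "weighted": preset["weighted"],
        })
        out[case] = run_experiment(cfg, feature_table=feature_table)
    return out


def asdict_shallow(config: ExperimentConfig) -> dict:
    return {k: getattr(config, k) for k in config.__dataclass_fields__}
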