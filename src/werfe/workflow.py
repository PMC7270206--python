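"""Side-by-side comparison of WERFE with single-RFE and filter baselines.

All methods in one comparison run on the same dataset with the same master
seed, so selection folds and evaluation folds are identical across
methods; the fold-assignment hash is logged to make that checkable.  The
report has one row per method: gene number of the selected subset and its
cross-validated accuracy / sensitivity / specificity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import classifier_names
from .dataset import ExpressionDataset
from .ensemble import WERFE, Selector, default_selectors
from .errors import ConfigError
from .evaluation import cross_val_predictions, stratified_folds
from .ism import ism_select
from .metrics import roc_curve_auc
from .rankers import make_ranker, ranker_names

__all__ = ["RunConfig", "run_comparison", "KNOWN_METHODS", "fold_hash"]

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("werfe", "svmrfe", "rfrfe", "fisher_ism", "relieff_ism")


@dataclass
class RunConfig:
    """Everything one comparison run needs; the seed is mandatory."""

    seed: int
    methods: tuple[str, ...] = KNOWN_METHODS
    k: int = 10
    k_eval: int = 10
    s: int | None = None
    eval_classifier: str = "svm"
    eval_params: dict = field(default_factory=dict)
    selector_params: dict = field(default_factory=dict)  # n_trees, C overrides
    theta: int = 10
    step: int = 10
    relieff_k: int = 10
    max_genes: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required; silent nondeterminism is not allowed")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ConfigError(f"unknown methods {unknown}; known: {list(KNOWN_METHODS)}")
        if self.eval_classifier not in classifier_names():
            raise ConfigError(
                f"unknown eval classifier {self.eval_classifier!r}; "
                f"registered: {classifier_names()}"
            )


def fold_hash(data: ExpressionDataset, k: int, seed: int) -> str:
    """Digest of the stratified fold assignment (identical across methods)."""
    assignment = np.empty(data.n_samples, dtype=int)
    for fold, (_, te) in enumerate(stratified_folds(data, k, seed)):
        assignment[te] = fold
    return hashlib.sha256(assignment.tobytes()).hexdigest()[:16]


def _single_selector(name: str, config: RunConfig) -> Selector:
    sp = config.selector_params
    if name == "svmrfe":
        C = sp.get("C", 1.0)
        return Selector("svm", "svm", s=config.s, ranker_params={"C": C},
                        classifier_params={"C": C})
    n_trees = sp.get("n_trees", 500)
    return Selector("rf", "rf", s=config.s, ranker_params={"n_trees": n_trees},
                    classifier_params={"n_trees": n_trees})


def run_comparison(data: ExpressionDataset, config: RunConfig) -> pd.DataFrame:
    """Run every requested method on `data`; one report row per method.

    When ``config.out_dir`` is set, writes the combined table
    (``comparison.tsv``), per-method gene lists and ROC overlay points.
    """
    logger.info(
        "comparison on %dx%d data; selection-fold hash %s, eval-fold hash %s",
        data.n_samples,
        data.n_genes,
        fold_hash(data, config.k, config.seed),
        fold_hash(data, config.k_eval, config.seed),
    )
    sp = config.selector_params
    rows = []
    roc_frames = []
    gene_lists: dict[str, tuple[str, ...]] = {}
    for method in config.methods:
        if method == "werfe":
            selectors = default_selectors(
                s=config.s, n_trees=sp.get("n_trees", 500), C=sp.get("C", 1.0)
            )
            subset = _fit_ensemble(data, selectors, config)
        elif method in ("svmrfe", "rfrfe"):
            subset = _fit_ensemble(data, [_single_selector(method, config)], config)
        else:  # fisher_ism / relieff_ism
            ranker_name = "fisher" if method == "fisher_ism" else "relieff"
            params = {"k_neighbors": config.relieff_k} if ranker_name == "relieff" else {}
            scores = make_ranker(ranker_name, **params)(data, config.seed)
            result = ism_select(
                data,
                scores,
                theta=min(config.theta, data.n_genes),
                step=config.step,
                eval_classifier=config.eval_classifier,
                k_eval=config.k_eval,
                seed=config.seed,
                eval_params=config.eval_params,
            )
            subset = result.best.gene_ids

        y_true, y_pred, y_score = cross_val_predictions(
            data, subset, config.eval_classifier, config.k_eval, config.seed,
            config.eval_params,
        )
        from .metrics import confusion_metrics

        rep = confusion_metrics(y_true, y_pred)
        roc = roc_curve_auc(y_true, y_score)
        gene_lists[method] = subset
        rows.append(
            {
                "method": method,
                "gene_number": len(subset),
                "accuracy_pct": rep.accuracy,
                "sensitivity_pct": rep.sensitivity,
                "specificity_pct": rep.specificity,
                "auc": roc.auc,
            }
        )
        roc_frames.append(
            pd.DataFrame(
                {
                    "method": method,
                    "fpr": roc.roc_points[:, 0],
                    "tpr": roc.roc_points[:, 1],
                }
            )
        )

    report = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "comparison.tsv", sep="\t", index=False)
        pd.concat(roc_frames).to_csv(out / "roc_overlay.tsv", sep="\t", index=False)
        for method, subset in gene_lists.items():
            (out / f"genes_{method}.txt").write_text("\n".join(subset) + "\n")
    return report


def _fit_ensemble(data: ExpressionDataset, selectors, config: RunConfig) -> tuple[str, ...]:
    model = WERFE(
        data,
        selectors=selectors,
        k=config.k,
        eval_classifier=config.eval_classifier,
        eval_params=config.eval_params,
        k_eval=config.k_eval,
        max_genes=config.max_genes,
    )
    return model.fit(seed=config.seed).final_subset
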