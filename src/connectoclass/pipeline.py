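"""End-to-end analysis: cohort -> graphs -> features -> SVM -> inference.

``run_pipeline`` executes the full study design from one :class:`RunConfig`:
preprocess every subject's connectivity matrix to a fixed-density binary
graph, compute the nine-metric feature table, run univariate permutation
tests, leave-one-out cross-validate the full nine-feature SVM, evaluate all
511 feature subsets, aggregate accuracies per metric, and compare regional
degree centrality between groups with FDR control.  Every stochastic step is
seeded from a single master seed, so a run is a pure function of its config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import aggregate_by_metric, run_exhaustive, sign_test_threshold
from .inference import regional_degree_tests, univariate_metric_tests
from .metrics import FEATURE_NAMES, compute_feature_table
from .preprocess import preprocess_cohort
from .simulate import Cohort, CohortConfig, generate_cohort, read_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one full analysis run.

    Defaults are the canonical analysis parameters: 25% sparsity, 10
    modularity iterations, 10 small-worldness null graphs, 100,000 label
    shuffles, alpha = 0.05 and FDR q = 0.05, standardized features.
    """

    input_dir: str | None = None  # None -> synthetic mode
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    sparsity: float = 0.25
    threshold_basis: str = "possible"
    n_modularity_iter: int = 10
    n_null: int = 10
    n_perm: int = 100_000
    alpha: float = 0.05
    q: float = 0.05
    scale_features: bool = True
    seed: int = 0
    output_dir: str | None = None


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_dir is not None:
        return read_cohort(config.input_dir)
    return generate_cohort(
        dataclasses.replace(config.cohort, seed=config.cohort.seed)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) a summary.

    When ``config.output_dir`` is set, writes features.csv, univariate.csv,
    cv_full_model.csv, subsets.csv, metric_aggregates.csv, regional.csv and
    summary.json there.
    """
    from .svm import loocv  # local import to keep module load cheap

    cohort = _load_cohort(config)
    ss = np.random.SeedSequence(config.seed)
    seed_features, seed_univ, seed_regional = ss.spawn(3)

    graphs = preprocess_cohort(
        cohort.matrices, s=config.sparsity, basis=config.threshold_basis
    )
    features = compute_feature_table(
        graphs,
        n_modularity_iter=config.n_modularity_iter,
        n_null=config.n_null,
        seed=seed_features,
        subject_ids=cohort.subject_ids,
    )

    univariate = univariate_metric_tests(
        features, cohort.y, n_perm=config.n_perm, seed=np.random.default_rng(seed_univ),
        q=config.q,
    )

    X = features.to_numpy()
    full_cv = loocv(X, cohort.y, scale=config.scale_features)
    exhaustive = run_exhaustive(
        X, cohort.y, alpha=config.alpha, scale=config.scale_features
    )
    aggregates = aggregate_by_metric(
        exhaustive, FEATURE_NAMES, mean_ranks=full_cv.mean_ranks
    )

    regional = regional_degree_tests(
        graphs,
        cohort.y,
        region_labels=cohort.region_labels,
        n_perm=config.n_perm,
        seed=np.random.default_rng(seed_regional),
        q=config.q,
    )

    best_metric = aggregates["mean_accuracy"].idxmax()
    summary = {
        "n_subjects": cohort.n_subjects,
        "n_control": int((cohort.y == 1).sum()),
        "n_mdd": int((cohort.y == -1).sum()),
        "n_nodes": int(graphs.shape[-1]),
        "n_edges_per_graph": int(graphs[0].sum() // 2),
        "sign_test_threshold": sign_test_threshold(cohort.n_subjects, config.alpha),
        "full_model": {
            "accuracy": full_cv.accuracy,
            "sensitivity": full_cv.sensitivity,
            "specificity": full_cv.specificity,
            "n_correct": full_cv.n_correct,
            "mean_weight_ranks": dict(
                zip(FEATURE_NAMES, map(float, full_cv.mean_ranks))
            ),
        },
        "exhaustive": {
            "n_subsets": len(exhaustive.evaluations),
            "n_significant": exhaustive.n_significant,
            "binomial_p": exhaustive.binomial_p,
        },
        "best_metric_by_mean_accuracy": best_metric,
        "univariate_fdr_significant": univariate.index[
            univariate["fdr_significant"]
        ].tolist(),
        "regional_fdr_significant": regional.loc[
            regional["fdr_significant"], "region"
        ].tolist(),
        "seed": config.seed,
        "config": _config_dict(config),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index_label="subject_id")
        univariate.to_csv(out / "univariate.csv", index_label="metric")
        exhaustive.to_frame().to_csv(out / "subsets.csv", index=False)
        aggregates.to_csv(out / "metric_aggregates.csv")
        regional.to_csv(out / "regional.csv", index=False)
        import pandas as pd

        pd.DataFrame(
            {
                "subject_id": cohort.subject_ids,
                "y_true": full_cv.y_true,
                "y_pred": full_cv.y_pred,
            }
        ).to_csv(out / "cv_full_model.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _config_dict(config: RunConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["cohort"]["nodal_effect"] = [list(e) for e in raw["cohort"]["nodal_effect"]]
    return raw
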