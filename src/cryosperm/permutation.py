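"""Label-permutation significance testing of the classification pipeline.

The observed nested cross-validated accuracy is located within a null
distribution built by shuffling the class labels and rerunning the whole
fixed-PC pipeline (fold assignment, z-scoring, PCA and the classifier are
all refit per permutation). The p-value is the proportion of permutations
whose accuracy is greater than or equal to the observed value (ties count).

By default each permutation reruns the fixed-5-PC pipeline, not the nested
PC search (running the grid search inside every one of ~1000 permutations
is disproportionate and the search selects no label-dependent quantity
beyond the PC count); ``nested=True`` enables the full search. The
uncorrected p = m/B is the default; ``corrected=True`` switches to the
(m+1)/(B+1) bias-corrected estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .feature_table import FeatureTable, METADATA_COLUMNS, SchemaError
from .nested_cv import CVConfig, _run_cv


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    b: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "null_accuracies": self.null_accuracies.tolist(),
            "p_value": self.p_value,
            "b": self.b,
            "seed": self.seed,
        }


def permute_labels(labels, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the label multiset (counts preserved)."""
    y = np.asarray(labels, dtype=object)
    if y.size == 0:
        raise ValueError("empty label sequence")
    return rng.permutation(y)


def permutation_pvalue(observed: float, null_accuracies, corrected: bool = False) -> float:
    """Proportion of null accuracies ≥ observed (ties counted as ≥)."""
    null = np.asarray(null_accuracies, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    m = int(np.count_nonzero(null >= observed))
    if corrected:
        return (m + 1) / (null.size + 1)
    return m / null.size


def run_permutation_test(
    table: FeatureTable,
    label_column: str,
    config: CVConfig = CVConfig(),
    b: int = 1000,
    seed: int = 0,
    nested: bool = False,
    corrected: bool = False,
) -> PermutationResult:
    """Null distribution of pipeline accuracies under shuffled labels.

    Accuracy means the mean of outer-fold accuracies throughout. Folds are
    re-drawn per permutation from a derived seed so no single arbitrary
    partition is frozen into the null.
    """
    if b < 1:
        raise ValueError("need at least one permutation")
    if label_column not in METADATA_COLUMNS:
        raise SchemaError(f"label column must be one of {METADATA_COLUMNS}")
    if not nested and config.fixed_pcs is None:
        config = replace(config, fixed_pcs=5)
    X = table.feature_matrix(include_age=config.include_age)
    y = table.labels(label_column)

    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=b + 1)
    shuffle_seeds = master.integers(0, 2**31 - 1, size=b)

    observed = _run_cv(X, y, replace(config, seed=int(run_seeds[0])), label_column).mean_accuracy
    null = np.empty(b)
    for i in range(b):
        y_perm = permute_labels(y, np.random.default_rng(int(shuffle_seeds[i])))
        try:
            null[i] = _run_cv(
                X, y_perm, replace(config, seed=int(run_seeds[i + 1])), label_column
            ).mean_accuracy
        except Exception as exc:  # surface the offending permutation
            raise RuntimeError(f"pipeline failed at permutation {i}: {exc}") from exc
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=permutation_pvalue(observed, null, corrected=corrected),
        b=b,
        seed=seed,
    )
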