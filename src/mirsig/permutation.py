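"""Random-signature permutation null.

How good is a selected k-probe signature compared with *any* k probes off the
same card?  This module draws many random same-size signatures from the assay
probe pool, fits the DLDA predictor with each on the training data, evaluates
the chosen metric on an evaluation cohort, and reports the empirical adjusted
p-value

    empirical_p = (n_random - n_outperformed) / n_random,

where ``n_outperformed`` counts random signatures whose metric falls
*strictly below* the candidate's — ties count against the candidate, the
conservative convention (no pseudo-count; a candidate beating 9510 of 10,000
random signatures reports exactly p = 0.049).  The (b+1)/(n+1) estimator is
available behind ``plus_one`` for users who prefer it.

Because DLDA statistics are per-probe (diagonal covariance), a signature's
margin is the sum of per-probe score contributions; the implementation
precomputes those contributions once and sums them per random signature,
which is mathematically identical to refitting DLDA per signature and is
verified against an explicit refit loop in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct import DeltaCtMatrix
from .dlda import _class_stats
from .exceptions import ValidationError
from .signature import SignatureSet

VALID_METRICS = ("validation_accuracy", "loocv_accuracy")


@dataclass
class PermutationResult:
    """Summary of one permutation run.

    ``empirical_p`` always equals ``(n_random - n_outperformed) / n_random``
    (or the plus-one variant when requested); it is a deterministic function
    of the stored counts.
    """

    n_random: int
    k: int
    candidate_metric: float
    n_outperformed: int
    empirical_p: float
    seed: int | None
    metric_name: str
    plus_one: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_outperformed <= self.n_random:
            raise ValidationError("n_outperformed must lie in [0, n_random]")
        expected = _empirical_p(self.n_random, self.n_outperformed, self.plus_one)
        if abs(self.empirical_p - expected) > 1e-12:
            raise ValidationError(
                f"empirical_p {self.empirical_p} inconsistent with counts (expected {expected})"
            )

    @classmethod
    def from_counts(
        cls,
        n_random: int,
        n_outperformed: int,
        *,
        k: int = 13,
        candidate_metric: float = float("nan"),
        seed: int | None = None,
        metric_name: str = "validation_accuracy",
        plus_one: bool = False,
    ) -> "PermutationResult":
        """Build a result from stored counts alone (e.g. to recompute the
        adjusted p-value from a published summary)."""
        return cls(
            n_random=n_random,
            k=k,
            candidate_metric=candidate_metric,
            n_outperformed=n_outperformed,
            empirical_p=_empirical_p(n_random, n_outperformed, plus_one),
            seed=seed,
            metric_name=metric_name,
            plus_one=plus_one,
        )


def _empirical_p(n_random: int, n_outperformed: int, plus_one: bool) -> float:
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    b = n_random - n_outperformed  # random signatures at least as good
    if plus_one:
        return (b + 1) / (n_random + 1)
    return b / n_random


def draw_random_signatures(
    probe_pool, k: int, n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> list[tuple[str, ...]]:
    """Draw ``n`` independent signatures of ``k`` distinct probes, uniformly
    without replacement from ``probe_pool`` (duplicates across signatures are
    allowed)."""
    pool = list(probe_pool)
    idx = _draw_index_matrix(len(pool), k, n, rng or np.random.default_rng(seed))
    arr = np.asarray(pool, dtype=object)
    return [tuple(arr[row]) for row in idx]


def _draw_index_matrix(pool_size: int, k: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if k > pool_size:
        raise ValidationError(f"k={k} exceeds probe pool size {pool_size}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    # uniform k-subsets: the k smallest of n iid uniforms per row
    keys = rng.random((n, pool_size))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _prepare_xy(matrix: DeltaCtMatrix, probes: list[str], labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    lab = pd.Series(labels)
    lab = lab[lab.isin(["sensitive", "resistant"])]
    use = [s for s in matrix.sample_ids if s in lab.index]
    X = matrix.restrict(probes)[use].T.to_numpy(float)
    y = lab.loc[use].to_numpy()
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    y01 = (y == "sensitive").astype(int)  # 0 = resistant, 1 = sensitive
    return X, y01, use


def _margin_contributions(
    X_train: np.ndarray, y01: np.ndarray, X_eval: np.ndarray, variance_floor: float
) -> np.ndarray:
    """Per-probe contribution to the sensitive-minus-resistant margin for
    every evaluation sample: D[j, s] sums over a signature's probes to give
    that signature's margin on sample s."""
    means, variances, _, _ = _class_stats(X_train, y01, variance_floor, pooled=True)
    mu_r, mu_s = means[0], means[1]
    var = variances[0]
    d_r = (X_eval - mu_r[None, :]) ** 2
    d_s = (X_eval - mu_s[None, :]) ** 2
    return (0.5 * (d_r - d_s) / var[None, :]).T  # probes × eval samples


def permutation_test(
    candidate,
    pool,
    train: DeltaCtMatrix,
    labels,
    evaluation: DeltaCtMatrix | None = None,
    evaluation_labels=None,
    *,
    n: int = 10_000,
    seed: int | None = 0,
    metric: str = "validation_accuracy",
    variance_floor: float = 1e-8,
    plus_one: bool = False,
    return_metrics: bool = False,
):
    """Compare a candidate signature against ``n`` random same-size
    signatures drawn from ``pool``.

    ``metric='validation_accuracy'`` (default) fits each signature's DLDA on
    the training samples and scores accuracy on the labelled evaluation
    cohort; ``metric='loocv_accuracy'`` uses leave-one-out accuracy on the
    training samples instead, for designs without external data.
    """
    if metric not in VALID_METRICS:
        raise ValidationError(f"metric must be one of {VALID_METRICS}")
    cand_probes = list(candidate.probe_ids) if isinstance(candidate, SignatureSet) else list(candidate)
    pool = list(pool)
    k = len(cand_probes)
    known = set(pool) | set(train.probe_ids)
    unknown = [p for p in cand_probes if p not in known]
    if unknown:
        raise ValidationError(f"candidate probe(s) outside pool and training matrix: {', '.join(unknown)}")

    if metric == "validation_accuracy":
        if evaluation is None or evaluation_labels is None:
            raise ValidationError("validation_accuracy metric requires a labelled evaluation set")
        eval_lab = pd.Series(evaluation_labels)
        eval_lab = eval_lab[eval_lab.isin(["sensitive", "resistant"])]
        eval_ids = [s for s in evaluation.sample_ids if s in eval_lab.index]
        if not eval_ids:
            raise ValidationError("evaluation set has no labelled samples")
        all_probes = sorted(set(pool) | set(cand_probes))
        Xtr, y01, _ = _prepare_xy(train, all_probes, labels)
        Xev = evaluation.restrict(all_probes)[eval_ids].T.to_numpy(float)
        y_eval = (eval_lab.loc[eval_ids].to_numpy() == "sensitive").astype(int)
        D = _margin_contributions(Xtr, y01, Xev, variance_floor)
        pos = {p: i for i, p in enumerate(all_probes)}

        rng = np.random.default_rng(seed)
        idx_pool = np.asarray([pos[p] for p in pool])
        idx = idx_pool[_draw_index_matrix(len(pool), k, n, rng)]
        margins = D[idx].sum(axis=1)  # n × eval samples
        rand_metrics = ((margins > 0).astype(int) == y_eval[None, :]).mean(axis=1)
        cand_idx = np.asarray([pos[p] for p in cand_probes])
        cand_margin = D[cand_idx].sum(axis=0)
        cand_metric = float(((cand_margin > 0).astype(int) == y_eval).mean())
    else:
        all_probes = sorted(set(pool) | set(cand_probes))
        Xtr, y01, use = _prepare_xy(train, all_probes, labels)
        if np.bincount(y01, minlength=2).min() < 3:
            raise ValidationError("loocv_accuracy metric needs >=3 training samples per class")
        pos = {p: i for i, p in enumerate(all_probes)}
        n_train = Xtr.shape[0]
        # per-fold margin contributions for the held-out sample
        D = np.empty((len(all_probes), n_train))
        for i in range(n_train):
            keep = np.ones(n_train, dtype=bool)
            keep[i] = False
            D[:, i] = _margin_contributions(
                Xtr[keep], y01[keep], Xtr[i][None, :], variance_floor
            )[:, 0]
        rng = np.random.default_rng(seed)
        idx_pool = np.asarray([pos[p] for p in pool])
        idx = idx_pool[_draw_index_matrix(len(pool), k, n, rng)]
        margins = D[idx].sum(axis=1)
        rand_metrics = ((margins > 0).astype(int) == y01[None, :]).mean(axis=1)
        cand_idx = np.asarray([pos[p] for p in cand_probes])
        cand_margin = D[cand_idx].sum(axis=0)
        cand_metric = float(((cand_margin > 0).astype(int) == y01).mean())

    n_outperformed = int((rand_metrics < cand_metric).sum())
    result = PermutationResult(
        n_random=n,
        k=k,
        candidate_metric=cand_metric,
        n_outperformed=n_outperformed,
        empirical_p=_empirical_p(n, n_outperformed, plus_one),
        seed=seed,
        metric_name=metric,
        plus_one=plus_one,
    )
    if return_metrics:
        return result, rand_metrics
    return result
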