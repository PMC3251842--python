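"""Per-probe differential-expression screen.

Classical two-sample Student's t-test (pooled variance) on ΔCt values between
sensitive and resistant training samples, with a significance filter that
produces the ordered candidate probe list consumed by the signature search.
No multiple-testing correction is applied at this stage; family-wise control
arrives downstream through the random-signature permutation null.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .ct import DeltaCtMatrix
from .exceptions import ValidationError

#: Pooled-SD floor (cycles) protecting constant probes (e.g. all-imputed rows).
SD_FLOOR = 1e-8


def _two_sample_t(
    x_sens: np.ndarray, x_res: np.ndarray, welch: bool, sd_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t over probe rows.  Returns (t, p, df, floored)
    with t oriented as sensitive − resistant."""
    n1, n2 = x_sens.shape[1], x_res.shape[1]
    m1, m2 = x_sens.mean(axis=1), x_res.mean(axis=1)
    v1 = x_sens.var(axis=1, ddof=1)
    v2 = x_res.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        floored = se2 < sd_floor**2
        se = np.sqrt(np.maximum(se2, sd_floor**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        sd = np.sqrt(pooled)
        floored = sd < sd_floor
        sd = np.maximum(sd, sd_floor)
        se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
        df = np.full(m1.shape, float(n1 + n2 - 2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0), df, floored


def probe_t_test(
    matrix: DeltaCtMatrix,
    labels,
    *,
    exclude_controls: bool = True,
    welch: bool = False,
    sd_floor: float = SD_FLOOR,
) -> pd.DataFrame:
    """Two-sample Student's t-test per probe between the sensitive and
    resistant samples named by ``labels``.

    Returns a DataFrame indexed by probe id with columns
    ``mean_delta_ct_sensitive``, ``mean_delta_ct_resistant``, ``difference``
    (sensitive − resistant, cycles), ``t_statistic``, ``p_value``,
    ``direction`` and ``variance_floored``.  Because lower ΔCt means more
    transcript, a negative difference marks a probe *up*-regulated in
    sensitive samples.
    """
    lab = pd.Series(labels)
    lab = lab[lab.isin(["sensitive", "resistant"])]
    sens = [s for s in matrix.sample_ids if lab.get(s) == "sensitive"]
    res = [s for s in matrix.sample_ids if lab.get(s) == "resistant"]
    if len(sens) < 2 or len(res) < 2:
        raise ValidationError(
            f"need >=2 samples per class, got {len(sens)} sensitive / {len(res)} resistant"
        )
    values = matrix.assay_values() if exclude_controls else matrix.values
    t, p, _, floored = _two_sample_t(
        values[sens].to_numpy(float), values[res].to_numpy(float), welch, sd_floor
    )
    m_s = values[sens].mean(axis=1)
    m_r = values[res].mean(axis=1)
    diff = m_s - m_r
    out = pd.DataFrame(
        {
            "mean_delta_ct_sensitive": m_s,
            "mean_delta_ct_resistant": m_r,
            "difference": diff,
            "t_statistic": t,
            "p_value": p,
            "direction": np.where(diff < 0, "up_in_sensitive", "down_in_sensitive"),
            "variance_floored": floored,
        },
        index=values.index,
    )
    out.index.name = "probe_id"
    return out


def filter_significant(stats_table: pd.DataFrame, alpha: float = 0.1) -> list[str]:
    """Probes with p < alpha (strict), ordered by ascending p; ties broken by
    descending |t| and then lexicographic probe id.  The ordering is the
    candidate ranking the nested-prefix signature search consumes."""
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    hits = stats_table[stats_table["p_value"] < alpha].copy()
    hits["_abs_t"] = hits["t_statistic"].abs()
    hits = (
        hits.reset_index()
        .sort_values(
            by=["p_value", "_abs_t", "probe_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .set_index("probe_id")
    )
    return list(hits.index)


class TTestScreen(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping the per-probe t screen.

    ``fit(X, y)`` takes a samples × probes frame and class labels; the fitted
    screen exposes ``stats_`` and the ordered ``selected_probes_`` and its
    ``transform`` restricts X to the selected probes.
    """

    def __init__(self, alpha: float = 0.1, welch: bool = False, sd_floor: float = SD_FLOOR):
        self.alpha = alpha
        self.welch = welch
        self.sd_floor = sd_floor

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = pd.Series(np.asarray(y), index=X.index)
        matrix = DeltaCtMatrix(values=X.T, normalization_mode="per_sample")
        self.stats_ = probe_t_test(
            matrix, y, exclude_controls=False, welch=self.welch, sd_floor=self.sd_floor
        )
        self.selected_probes_ = filter_significant(self.stats_, alpha=self.alpha)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_probes_"):
            raise ValidationError("TTestScreen is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        missing = [p for p in self.selected_probes_ if p not in X.columns]
        if missing:
            raise ValidationError(f"probe(s) absent from X: {', '.join(map(str, missing))}")
        return X[self.selected_probes_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.selected_probes_, dtype=object)
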