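"""RReliefF: Relief-family feature weighting for a continuous target.

Relief-style estimators score a feature by how much its value differences
co-occur with target differences among nearest neighbours, which makes them
sensitive to conditional dependencies and robust to collinearity — the
reason they are a standard choice for selecting predictive brain regions.

For ``m`` sampled instances and each instance's ``k`` nearest neighbours
(Manhattan distance on min-max-normalized features), three accumulators are
kept, each neighbour contributing with influence 1/k:

    N_dC       += diff_y(i, j) / k
    N_dA[A]    += diff_A(i, j) / k
    N_dC&dA[A] += diff_y(i, j) * diff_A(i, j) / k

with diff(A, I1, I2) = |A(I1) − A(I2)| / (max A − min A) for numeric
attributes (indicator of inequality for nominal; zero-range features have
diff 0), and the target diff normalized the same way.  The final weight is

    W[A] = N_dC&dA[A] / N_dC  −  (N_dA[A] − N_dC&dA[A]) / (m − N_dC)

which always lies in [−1, 1].  ``m=None`` runs the deterministic exhaustive
mode (one pass over every instance, in order).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclasses.dataclass(frozen=True)
class AttributeWeights:
    """Per-feature Relief weights plus the run's sampling metadata."""

    weights: pd.Series  # index = feature names, values in [-1, 1]
    m: int
    k: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return self.weights.rename("weight").rename_axis("feature").reset_index()


def _normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale each column; zero-range columns are defined to diff 0."""
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    Z = (X - lo) / safe
    Z[:, rng == 0] = 0.0
    return Z, rng


def rrelieff(
    X,
    y,
    m: int | None = 10,
    k: int = 5,
    seed: int | None = 0,
    nominal: list[str] | None = None,
) -> AttributeWeights:
    """Relief weights for regression.

    Parameters
    ----------
    X : DataFrame or 2D array, instances × features (finite values).
    y : continuous target, one value per instance (must not be constant).
    m : number of randomly sampled instances (without replacement);
        ``None`` = exhaustive deterministic pass over all instances.
    k : neighbours per sampled instance; ties in distance are broken by
        the lower instance index.
    nominal : feature names treated as nominal (indicator diff).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    n, d = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y disagree on the number of instances")
    if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(ya)):
        raise ValueError("features and target must be finite")
    y_range = ya.max() - ya.min()
    if y_range == 0:
        raise ValueError("constant target: target diff undefined")
    if k < 1 or k >= n:
        raise ValueError("need 1 <= k < n")

    Z, col_range = _normalize(Xa)
    nominal_idx = np.zeros(d, dtype=bool)
    if nominal:
        for nm in nominal:
            nominal_idx[names.index(nm)] = True
    # per-pair diff matrix columns: numeric -> normalized abs difference,
    # nominal -> inequality indicator
    yz = (ya - ya.min()) / y_range

    if m is None:
        sample = np.arange(n)
    else:
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(seed)
        m_eff = min(m, n)
        sample = np.sort(rng.choice(n, size=m_eff, replace=False))

    # distances from sampled instances to all instances (Manhattan on Z,
    # with nominal columns as 0/1 indicators — identical here since nominal
    # inputs are expected to be 0/1 coded already after normalization)
    D = cdist(Z[sample], Z, metric="cityblock")
    if nominal_idx.any():
        # replace nominal contribution by the inequality indicator
        for j in np.nonzero(nominal_idx)[0]:
            num_part = np.abs(Z[sample][:, [j]] - Z[:, [j]])
            ind_part = (Xa[sample][:, [j]] != Xa[:, [j]]).astype(float)
            D += ind_part - num_part

    N_dC = 0.0
    N_dA = np.zeros(d)
    N_dCdA = np.zeros(d)
    influence = 1.0 / k

    for s_pos, i in enumerate(sample):
        dist = D[s_pos].copy()
        dist[i] = np.inf  # exclude self
        order = np.lexsort((np.arange(n), dist))
        neighbours = order[:k]
        for j in neighbours:
            dy = abs(yz[i] - yz[j])
            da = np.abs(Z[i] - Z[j])
            if nominal_idx.any():
                da[nominal_idx] = (Xa[i, nominal_idx] != Xa[j, nominal_idx]).astype(float)
            N_dC += influence * dy
            N_dA += influence * da
            N_dCdA += influence * dy * da

    m_used = len(sample)
    weights = np.zeros(d)
    if N_dC > 0:
        weights = N_dCdA / N_dC
    denom = m_used - N_dC
    if denom > 0:
        weights = weights - (N_dA - N_dCdA) / denom
    series = pd.Series(weights, index=names)
    return AttributeWeights(weights=series, m=m_used, k=k, seed=seed)


def select_features(
    weights: AttributeWeights | pd.Series,
    rule: str | tuple = "positive",
) -> list[str]:
    """Feature subset from Relief weights.

    Rules: ``"positive"`` (default) keeps strictly positive weights, ordered
    by descending weight; ``("top", j)`` keeps the j best; ``("threshold",
    tau)`` keeps weights >= tau.  Ties are broken by feature order.
    """
    w = weights.weights if isinstance(weights, AttributeWeights) else weights
    order = w.sort_values(ascending=False, kind="stable")
    if rule == "positive":
        return list(order[order > 0].index)
    if isinstance(rule, tuple) and len(rule) == 2:
        kind, arg = rule
        if kind == "top":
            return list(order.index[: int(arg)])
        if kind == "threshold":
            return list(order[order >= float(arg)].index)
    raise ValueError(f"unknown selection rule {rule!r}")


def regions_from_selected(selected: list[str], manifest: pd.DataFrame) -> list[int]:
    """Region ids with at least one selected feature column."""
    cols = set(selected)
    hit = manifest.loc[manifest["column"].isin(cols), "region_id"].dropna()
    return sorted(int(r) for r in hit.unique())
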