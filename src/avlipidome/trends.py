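"""Lipid Trend Analysis: impute, stage-average, z-score, GMM-cluster.

Each lipid's trajectory over the three disease stages (mildly diseased
-> fibrotic -> calcific) is reduced to its three stage means, z-scored
across the stages, and clustered with a Gaussian mixture model (k = 5
in the study). Cluster ids are relabeled in descending cluster size so
that a fixed seed yields a canonical, reproducible labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .containers import ConcentrationMatrix
from .errors import AllMissingLipid, MissingStage
from .nomenclature import STAGES

logger = logging.getLogger(__name__)

__all__ = [
    "impute_min_fifth",
    "stage_average",
    "zscore_rows",
    "TrendClusterer",
    "gmm_trend_cluster",
    "trend_summary",
    "TrendClustering",
]


def impute_min_fifth(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Fill missing cells with 1/5 of the lipid's observed minimum.

    Observed values are never touched; rows with no observation at all
    are dropped with a warning (:class:`AllMissingLipid` is only raised
    if *every* row is empty).
    """
    values = matrix.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.all():
        raise AllMissingLipid("every lipid row is entirely missing")
    if all_missing.any():
        logger.warning(
            "dropping %d all-missing lipid rows", int(all_missing.sum())
        )
        values = values[~all_missing]
    fill = values.min(axis=1, skipna=True) / 5.0
    values = values.T.fillna(fill).T
    return ConcentrationMatrix(values, matrix.samples)


def stage_average(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Arithmetic mean per lipid per stage: a lipids x 3 matrix."""
    present = set(matrix.samples["stage"])
    missing = [s for s in STAGES if s not in present]
    if missing:
        raise MissingStage(f"stages absent from metadata: {missing}")
    stage = matrix.samples["stage"]
    out = matrix.values.T.groupby(stage).mean().T
    return out[list(STAGES)]


def zscore_rows(stage_matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row across the stage means (population SD).

    Rows with zero variance (flat trajectories) become all-zero rows so
    they remain clusterable rather than NaN.
    """
    arr = stage_matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(
        (arr - mean) / sd, index=stage_matrix.index, columns=stage_matrix.columns
    )


class TrendClusterer(ClusterMixin, BaseEstimator):
    """Gaussian-mixture clustering of z-scored stage trajectories.

    scikit-learn-compatible estimator: ``fit(X)`` takes a lipids x
    n_stages matrix of stage means (rows are the objects clustered),
    z-scores each row, fits a full-covariance Gaussian mixture with a
    fixed seed, hard-assigns by maximum posterior and relabels clusters
    in descending size (ties broken by first occurrence), yielding ids
    1..k.

    Parameters
    ----------
    n_clusters : number of mixture components (study value 5).
    covariance_type : passed to :class:`sklearn.mixture.GaussianMixture`.
    n_init : restarts of the EM fit; more restarts stabilize the seed.
    random_state : seed making the fit deterministic.
    reg_covar : covariance regularization; raised automatically on a
        singular fit (the retry is logged).

    Attributes
    ----------
    labels_ : ndarray of cluster ids in 1..n_clusters, size-canonical.
    zscores_ : the z-scored matrix actually clustered.
    cluster_sizes_ : pandas Series, id -> member count.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        covariance_type: str = "full",
        n_init: int = 10,
        random_state: int = 42,
        reg_covar: float = 1e-6,
    ):
        self.n_clusters = n_clusters
        self.covariance_type = covariance_type
        self.n_init = n_init
        self.random_state = random_state
        self.reg_covar = reg_covar

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < self.n_clusters:
            raise ValueError(
                f"need >= {self.n_clusters} lipids, got {len(X)}"
            )
        if not np.all(np.isfinite(X.to_numpy(dtype=float))):
            raise ValueError("stage matrix contains non-finite values")
        z = zscore_rows(X)

        reg = self.reg_covar
        for attempt in range(3):
            try:
                gmm = GaussianMixture(
                    n_components=self.n_clusters,
                    covariance_type=self.covariance_type,
                    n_init=self.n_init,
                    random_state=self.random_state,
                    reg_covar=reg,
                ).fit(z.to_numpy())
                break
            except ValueError:
                reg *= 100.0
                logger.warning(
                    "singular mixture fit; retrying with reg_covar=%g", reg
                )
        else:  # pragma: no cover - extremely degenerate input
            raise
        raw = gmm.predict(z.to_numpy())

        # Size-descending canonical relabeling to 1..k.
        order = pd.Series(raw).value_counts(sort=True).index.to_list()
        # value_counts ties: keep deterministic order by (count desc, first seen)
        first_seen = {lab: int(np.argmax(raw == lab)) for lab in set(raw)}
        order = sorted(
            set(raw), key=lambda lab: (-(raw == lab).sum(), first_seen[lab])
        )
        remap = {old: new + 1 for new, old in enumerate(order)}
        # Components that received no members keep an arbitrary tail id.
        tail = len(order)
        for comp in range(self.n_clusters):
            if comp not in remap:
                tail += 1
                remap[comp] = tail

        self.labels_ = np.array([remap[r] for r in raw])
        self.zscores_ = z
        self.index_ = X.index
        self.gmm_ = gmm
        self.cluster_sizes_ = (
            pd.Series(self.labels_).value_counts().sort_index()
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class TrendClustering:
    """Cluster memberships plus per-cluster stage-mean +/- SD trajectories."""

    membership: pd.Series          # lipid -> cluster id (1..k)
    zscores: pd.DataFrame          # lipids x stages, the clustered values
    k: int
    random_state: int
    scaling: str = "zscore"

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.membership.value_counts().sort_index()


def gmm_trend_cluster(
    stage_matrix: pd.DataFrame,
    k: int = 5,
    seed: int = 42,
    covariance_type: str = "full",
    n_init: int = 10,
) -> TrendClustering:
    """Cluster a lipids x 3 stage-mean matrix; see :class:`TrendClusterer`."""
    est = TrendClusterer(
        n_clusters=k,
        covariance_type=covariance_type,
        n_init=n_init,
        random_state=seed,
    ).fit(stage_matrix)
    return TrendClustering(
        membership=pd.Series(est.labels_, index=stage_matrix.index,
                             name="cluster"),
        zscores=est.zscores_,
        k=k,
        random_state=seed,
    )


def trend_summary(tc: TrendClustering) -> pd.DataFrame:
    """Plot-ready table: per cluster per stage, mean and SD of member z-scores."""
    rows = []
    for cluster in sorted(tc.membership.unique()):
        members = tc.membership.index[tc.membership == cluster]
        z = tc.zscores.loc[members]
        for stage in tc.zscores.columns:
            rows.append(
                {
                    "cluster": int(cluster),
                    "stage": stage,
                    "mean": float(z[stage].mean()),
                    "sd": float(z[stage].std(ddof=0)),
                    "n_lipids": len(members),
                }
            )
    return pd.DataFrame(rows)
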