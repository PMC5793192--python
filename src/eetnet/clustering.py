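"""Soft clustering of six-sample proteomic trajectories and active-protein calls.

The experiment behind this module samples *Shewanella oneidensis* MR-1 at six
successive steady states: S1-S3 under high O2 (extracellular electron
transfer, EET, inactive) and S4-S6 under low O2 (EET active).  Proteins whose
abundance steps sharply between S3 and S4 mark the activation transition.
The workflow is

1. drop proteins never detected (all six abundances exactly zero),
2. standardise each remaining trajectory to mean 0 / sd 1,
3. fuzzy c-means with ``c=4`` clusters and fuzzifier ``m=1.5``,
4. call the clusters whose centroid steps sharply downward / upward across
   the S3->S4 boundary; their members are the "active" proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

#: Ordered sample columns of every expression matrix.
SAMPLES = ["S1", "S2", "S3", "S4", "S5", "S6"]

#: Oxygen phase of each sample: the EET process is inactive while O2 is high.
PHASES = {"S1": "high-O2", "S2": "high-O2", "S3": "high-O2",
          "S4": "low-O2", "S5": "low-O2", "S6": "low-O2"}

#: Index of the S3 -> S4 consecutive step among the five steps of a profile.
TRANSITION_STEP = 2


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique protein index, the six sample columns.

    Returns the matrix with columns in canonical S1..S6 order.
    """
    missing = [s for s in SAMPLES if s not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix lacks sample columns: {missing}")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids: {dupes[:5]}")
    return matrix[SAMPLES]


def filter_unexpressed(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove proteins with zero copies in all six samples; keep row order."""
    matrix = validate_expression(matrix)
    keep = (matrix != 0).any(axis=1)
    return matrix.loc[keep]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise trajectories to mean 0, sd 1.

    Constant rows cannot be standardised; they are dropped with a warning
    (all-zero rows should already be gone via :func:`filter_unexpressed`).
    """
    matrix = validate_expression(matrix)
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant-abundance rows that "
            "cannot be standardised",
            stacklevel=2,
        )
        matrix = matrix.loc[~constant]
        values = values[~constant]
        sd = sd[~constant]
    centered = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered / sd[:, None], index=matrix.index,
                        columns=SAMPLES)


@dataclass
class ClusteringConfig:
    """Parameters of the fuzzy c-means run.

    ``c=4`` and ``m=1.5`` are the published settings for this proteome;
    ``m`` close to 1 approaches hard k-means, larger ``m`` softens
    memberships.
    """

    c: int = 4
    m: float = 1.5
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("cluster count c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class MembershipMatrix:
    """Result of a fuzzy c-means fit."""

    protein_ids: list[str]
    memberships: np.ndarray          # (n, c), rows sum to 1
    centroids: np.ndarray            # (c, 6) standardized profiles
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax cluster per protein; ties go to the lowest cluster index."""
        return self.memberships.argmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k}" for k in range(self.memberships.shape[1])]
        df = pd.DataFrame(self.memberships, index=self.protein_ids, columns=cols)
        df["hard_label"] = self.hard_labels
        return df


def _fcm_memberships(dist_sq: np.ndarray, m: float) -> np.ndarray:
    """u_ij proportional to (1/d_ij^2)^(1/(m-1)), normalised per row.

    A zero distance pins the full membership on the coincident centroid(s).
    """
    with np.errstate(divide="ignore"):
        inv = dist_sq ** (-1.0 / (m - 1.0))
    zero_rows = np.isinf(inv).any(axis=1)
    if zero_rows.any():
        pinned = np.isinf(inv[zero_rows])
        inv[zero_rows] = pinned / pinned.sum(axis=1, keepdims=True)
    u = inv / inv.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(matrix: pd.DataFrame,
                 config: ClusteringConfig | None = None) -> MembershipMatrix:
    """Fuzzy c-means (Bezdek) on row-standardised trajectories.

    Alternates the closed-form membership update
    ``u_ij = (1/d_ij^2)^(1/(m-1)) / sum_k (1/d_ik^2)^(1/(m-1))`` with the
    weighted-centroid update ``v_j = sum_i u_ij^m x_i / sum_i u_ij^m`` until
    the objective ``J = sum_ij u_ij^m d_ij^2`` changes by less than ``tol``.
    Each of the ``n_init`` restarts is seeded k-means++-style; the restart
    with the lowest final objective wins, which guards against the local
    optima a single start can fall into.
    """
    config = config or ClusteringConfig()
    matrix = validate_expression(matrix)
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if config.c > n:
        raise ValueError(f"c={config.c} exceeds the {n} available rows")
    best: MembershipMatrix | None = None
    for restart in range(config.n_init):
        fit = _fcm_single(X, matrix, config, config.seed + restart)
        if best is None or fit.objective < best.objective:
            best = fit
    return best


def _fcm_single(X: np.ndarray, matrix: pd.DataFrame,
                config: ClusteringConfig, seed: int) -> MembershipMatrix:
    centroids, _ = kmeans_plusplus(
        X, n_clusters=config.c, random_state=seed)
    trace: list[float] = []
    u = None
    converged = False
    for _ in range(config.max_iter):
        dist_sq = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(dist_sq, config.m)
        objective = float((u ** config.m * dist_sq).sum())
        um = u ** config.m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        if trace and abs(trace[-1] - objective) < config.tol:
            trace.append(objective)
            converged = True
            break
        trace.append(objective)
    if not converged:
        warnings.warn("fuzzy c-means did not converge within max_iter",
                      stacklevel=2)
    # final memberships consistent with the returned centroids
    dist_sq = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _fcm_memberships(dist_sq, config.m)
    return MembershipMatrix(
        protein_ids=list(matrix.index),
        memberships=u,
        centroids=centroids,
        objective=float((u ** config.m * dist_sq).sum()),
        objective_trace=trace,
        converged=converged,
    )


@dataclass
class ActiveProteinSet:
    """Proteins in the sharp S3->S4 decrease / increase clusters."""

    down_set: set[str]
    up_set: set[str]

    def __post_init__(self) -> None:
        overlap = self.down_set & self.up_set
        if overlap:
            raise ValueError(f"down/up sets overlap: {sorted(overlap)[:5]}")

    @property
    def union(self) -> set[str]:
        return self.down_set | self.up_set


def identify_active_clusters(result: MembershipMatrix,
                             sharp_ratio: float = 2.0) -> ActiveProteinSet:
    """Pick the sharp-decrease and sharp-increase clusters from the centroids.

    For each centroid the five consecutive steps ``v[t+1]-v[t]`` are examined.
    A cluster is *sharp* iff the absolute S3->S4 step is the largest of the
    five AND exceeds ``sharp_ratio`` times the largest other absolute step.
    Exactly the sharp cluster with a negative transition feeds ``down_set``
    and the one with a positive transition feeds ``up_set``; members are
    assigned by hard label.
    """
    steps = np.diff(result.centroids, axis=1)           # (c, 5)
    trans = steps[:, TRANSITION_STEP]
    others = np.abs(np.delete(steps, TRANSITION_STEP, axis=1)).max(axis=1)
    sharp = (np.abs(trans) >= others) & (np.abs(trans) > sharp_ratio * others)
    down = [k for k in range(len(trans)) if sharp[k] and trans[k] < 0]
    up = [k for k in range(len(trans)) if sharp[k] and trans[k] > 0]
    if len(down) != 1 or len(up) != 1:
        detail = "; ".join(
            f"cluster {k}: S3->S4 step {trans[k]:+.3f}, "
            f"max other step {others[k]:.3f}" for k in range(len(trans)))
        raise ValueError(
            "expected exactly one sharp-decrease and one sharp-increase "
            f"cluster (found {len(down)} down, {len(up)} up); consider "
            f"adjusting sharp_ratio. Centroid steps: {detail}")
    labels = result.hard_labels
    ids = np.asarray(result.protein_ids)
    return ActiveProteinSet(
        down_set=set(ids[labels == down[0]]),
        up_set=set(ids[labels == up[0]]),
    )
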