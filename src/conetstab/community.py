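"""Community-level structure: Bray-Curtis distances, PCoA, PERMANOVA and the
control-vs-drought similarity used as a resistance/resilience metric.

PERMANOVA follows the classic pseudo-F construction on a distance matrix with
a label-permutation null and the +1 Monte-Carlo correction (the p-value can
never be 0). PCoA is classical metric scaling of the double-centred squared
distance matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.base import BaseEstimator

from .otu import OtuTable, TableError, SAMPLINGS

logger = logging.getLogger("conetstab")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with sample ids; Bray-Curtis lies in [0,1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    if table.shape[1] < 2:
        raise TableError("need at least 2 samples for a distance matrix")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise TableError(f"sample {bad!r} has zero total reads")
    x = table.matrix().T.astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are empty")
    return float(np.abs(x - y).sum() / denom)


# -- PCoA ------------------------------------------------------------------

class PCoA(BaseEstimator):
    """Principal coordinates analysis (classical metric scaling).

    ``fit`` eigendecomposes -1/2 J D^2 J; coordinates are eigenvectors scaled
    by sqrt(eigenvalue) for positive eigenvalues, sorted descending. Negative
    eigenvalues (possible for non-Euclidean distances such as Bray-Curtis)
    are reported in ``eigenvalues_`` but contribute no axis.

    Attributes
    ----------
    coordinates_ : ndarray (n_samples, k)
    eigenvalues_ : ndarray, all eigenvalues sorted descending
    proportion_explained_ : ndarray, positive eigenvalues / their sum
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, d: DistanceMatrix | np.ndarray, y=None) -> "PCoA":
        values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
        self.sample_ids_ = d.sample_ids if isinstance(d, DistanceMatrix) else [
            str(i) for i in range(values.shape[0])
        ]
        n = values.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (values ** 2) @ j
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        tol = max(1e-10, 1e-10 * abs(eigval[0])) if n else 0.0
        pos = eigval > tol
        n_pos = int(pos.sum())
        k = self.n_components if self.n_components is not None else n_pos
        if k > n_pos:
            logger.warning(
                "pcoa: requested %d axes but only %d positive eigenvalues", k, n_pos
            )
            k = n_pos
        coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
        self.eigenvalues_ = eigval
        self.n_positive_ = n_pos
        self.proportion_explained_ = (
            eigval[:n_pos] / eigval[:n_pos].sum() if n_pos else np.array([])
        )
        self.coordinates_ = coords
        return self

    def fit_transform(self, d, y=None) -> np.ndarray:
        return self.fit(d).coordinates_


def pcoa(d: DistanceMatrix, k: int | None = None) -> PCoA:
    return PCoA(n_components=k).fit(d)


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    R2: float
    p: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    """(SS_between, SS_within) from squared distances for one labelling."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in levels:
        mask = (groups == g).astype(float)
        n_g = mask.sum()
        ss_within += mask @ d2 @ mask / (2 * n_g)
    return ss_total - ss_within, ss_within


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under random relabelling;
    with ``exact=True`` all distinct label arrangements are enumerated
    instead and p is the exact fraction (the identity arrangement included).
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(d.sample_ids):
        raise ValueError("labels must align with distance matrix samples")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError(f"group {levels[np.argmin(counts)]!r} has < 2 members")
    d2 = d.values ** 2
    n, a = len(labels), len(levels)
    ss_b, ss_w = _permanova_ss(d2, labels, levels)
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
    r2 = ss_b / (ss_b + ss_w)

    if exact:
        hits = 0
        total = 0
        for perm in _distinct_arrangements(labels):
            ss_b_p, ss_w_p = _permanova_ss(d2, perm, levels)
            f_p = (ss_b_p / (a - 1)) / (ss_w_p / (n - a))
            hits += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(f_obs, a - 1, n - a, r2, hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ss_b_p, ss_w_p = _permanova_ss(d2, perm, levels)
        f_p = (ss_b_p / (a - 1)) / (ss_w_p / (n - a))
        hits += f_p >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, a - 1, n - a, r2, p, n_perm)


def _distinct_arrangements(labels: np.ndarray):
    """All distinct assignments of the label multiset to positions."""
    n = len(labels)
    seen = set()
    for perm in itertools.permutations(range(n)):
        arr = tuple(labels[list(perm)])
        if arr not in seen:
            seen.add(arr)
            yield np.asarray(arr)


# -- resistance / resilience ----------------------------------------------

def resilience_similarity(
    table: OtuTable,
    meta: pd.DataFrame,
    pairing: str = "matched",
) -> tuple[pd.DataFrame, dict]:
    """Control-drought Bray-Curtis similarity per sampling.

    similarity = 1 - Bray-Curtis for each (control, drought) pair at the same
    sampling. ``matched`` pairing joins mesocosms sharing (block,
    plant_treatment); ``all_pairs`` crosses every control with every drought
    sample. Returns the pair table and a one-way ANOVA of similarity across
    samplings.
    """
    if pairing not in ("matched", "all_pairs"):
        raise ValueError("pairing must be 'matched' or 'all_pairs'")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    records = []
    counts = table.counts
    for sampling in [s for s in SAMPLINGS if (meta["sampling"] == s).any()]:
        sub = meta[meta["sampling"] == sampling]
        ctrl = sub[sub["treatment"] == "control"]
        drou = sub[sub["treatment"] == "drought"]
        if len(ctrl) == 0 or len(drou) == 0:
            logger.warning("resilience: sampling %s lacks one treatment", sampling)
            continue
        if pairing == "matched":
            key_cols = ["block"] + (
                ["plant_treatment"] if "plant_treatment" in meta.columns else []
            )
            ctrl_keys = ctrl.set_index(key_cols if len(key_cols) > 1 else key_cols[0])
            pairs = []
            for sid_d, row in drou.iterrows():
                key = tuple(row[k] for k in key_cols) if len(key_cols) > 1 else row[key_cols[0]]
                try:
                    match = ctrl_keys.loc[[key]]
                except KeyError:
                    logger.info("resilience: no control match for %s", sid_d)
                    continue
                for sid_c in match["sample_id"]:
                    pairs.append((sid_c, sid_d))
        else:
            pairs = list(itertools.product(ctrl["sample_id"], drou["sample_id"]))
        for sid_c, sid_d in pairs:
            d = bray_curtis_pair(counts[sid_c].to_numpy(), counts[sid_d].to_numpy())
            records.append(
                {
                    "sampling": sampling,
                    "control_sample": sid_c,
                    "drought_sample": sid_d,
                    "similarity": 1.0 - d,
                }
            )
    result = pd.DataFrame(records, columns=["sampling", "control_sample", "drought_sample", "similarity"])
    anova: dict = {"F": math.nan, "p": math.nan}
    groups = [g["similarity"].to_numpy() for _, g in result.groupby("sampling", observed=True)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) >= 2:
        f, p = stats.f_oneway(*groups)
        anova = {"F": float(f), "p": float(p)}
    return result, anova
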