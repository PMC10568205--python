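"""Fitness scores, dropout detection, trajectory clustering and TS calling.

A strain's fitness score at a timepoint is its relative barcode abundance
(reads over total sample reads) normalized to its relative abundance at the
first timepoint, so a neutrally growing strain sits at 1, an outcompeted
strain decays toward 0. Temperature sensitivity is called from the contrast
between the 30 degC and 42 degC trajectory clusters: a strain whose 42 degC
category is strictly worse than its 30 degC one is a putative TS mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .barcode_counting import CountMatrix

__all__ = [
    "FitnessSeries",
    "ClusterAssignment",
    "fitness_scores",
    "detect_dropouts",
    "cluster_trajectories",
    "call_ts",
    "CATEGORY_ORDER",
]

#: Fitness categories from best to worst.
CATEGORY_ORDER = ("high", "reduced", "low")
_CAT_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass
class FitnessSeries:
    """Long-format fitness scores with mean/smoothed per-strain summaries.

    ``scores`` columns: strain_id, temperature, replicate, time_h, fitness.
    Strains with zero reads at t=0 in a (temperature, replicate) track have
    NaN fitness there (undefined, excluded downstream rather than imputed).
    """

    scores: pd.DataFrame
    smoothing_window: int = 3

    def mean_series(self, temperature: float) -> pd.DataFrame:
        """Per-strain mean over replicates, strains x timepoints."""
        sub = self.scores[self.scores["temperature"] == temperature]
        return (
            sub.pivot_table(
                index="strain_id", columns="time_h", values="fitness", aggfunc="mean"
            )
            .sort_index(axis=1)
        )

    def smoothed(self, temperature: float) -> pd.DataFrame:
        """Centered moving average (window 3) of the replicate-mean series."""
        m = self.mean_series(temperature)
        return m.T.rolling(self.smoothing_window, center=True, min_periods=1).mean().T


@dataclass(frozen=True)
class ClusterAssignment:
    strain_id: str
    temperature: float
    cluster_id: int
    category: str


def fitness_scores(counts: CountMatrix) -> FitnessSeries:
    """Compute fitness scores n = (c_it/sum_j c_jt) / (c_i0/sum_j c_j0).

    Each (temperature, replicate) track is normalized to its own t=0
    sample. Samples with zero total reads are rejected.
    """
    rows = []
    meta = counts.samples
    for (temp, rep), group in meta.groupby(["temperature", "replicate"]):
        group = group.sort_values("time_h")
        times = group["time_h"].to_numpy()
        if times[0] != 0:
            raise ValueError(f"no t=0 sample for temperature {temp}, replicate {rep}")
        cols = counts.counts[list(group.index)]
        totals = cols.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total reads rejected: {bad}")
        freq = cols / totals
        f0 = freq.iloc[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = freq.div(f0, axis=0)
        fit[f0 == 0] = np.nan
        for j, (sample_id, t) in enumerate(zip(group.index, times)):
            rows.append(
                pd.DataFrame(
                    {
                        "strain_id": fit.index,
                        "temperature": temp,
                        "replicate": rep,
                        "time_h": t,
                        "fitness": fit.iloc[:, j].to_numpy(),
                    }
                )
            )
    return FitnessSeries(pd.concat(rows, ignore_index=True))


def detect_dropouts(counts: CountMatrix, min_mean_reads: float = 15.0) -> set[str]:
    """Strains whose mean read count over the t=0 samples is below threshold.

    These strains vanished during the preculture and are excluded from
    clustering and TS scoring.
    """
    t0_cols = counts.sample_ids(time_h=0)
    if not t0_cols:
        raise ValueError("no t=0 samples present")
    mean_t0 = counts.counts[t0_cols].mean(axis=1)
    return set(mean_t0.index[mean_t0 < min_mean_reads])


def _categorize(centers_final: np.ndarray, k: int) -> dict[int, str]:
    """Map cluster ids to high/reduced/low from the cluster-mean endpoint.

    At the default k=6 the 4/1/1 split of the screen is used (clusters
    ranked by endpoint mean: top four high, next reduced, last low); for
    other k, endpoint thresholds of 0.7 and 0.3 apply.
    """
    order = np.argsort(-centers_final)  # best first
    cats: dict[int, str] = {}
    if k == 6:
        for rank, cid in enumerate(order):
            cats[int(cid)] = "high" if rank < 4 else ("reduced" if rank == 4 else "low")
    else:
        for cid in range(k):
            v = centers_final[cid]
            cats[int(cid)] = "high" if v >= 0.7 else ("reduced" if v >= 0.3 else "low")
    return cats


def cluster_trajectories(
    series: FitnessSeries,
    temperature: float,
    k: int = 6,
    seed: int = 1,
    n_restarts: int = 50,
    exclude: set[str] | None = None,
) -> list[ClusterAssignment]:
    """K-means clustering of replicate-mean fitness trajectories.

    Features are the raw (unscaled) mean-fitness vectors over the ordered
    timepoints; Euclidean distance, ``n_restarts`` initializations, fixed
    seed. Strains with any undefined timepoint and dropouts (``exclude``)
    are left out.
    """
    m = series.mean_series(temperature)
    if exclude:
        m = m.drop(index=[s for s in exclude if s in m.index])
    m = m.dropna(axis=0)
    if len(m) < k:
        raise ValueError(f"need at least k={k} strains, have {len(m)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(m.to_numpy())
    cats = _categorize(km.cluster_centers_[:, -1], k)
    return [
        ClusterAssignment(strain, temperature, int(lab), cats[int(lab)])
        for strain, lab in zip(m.index, labels)
    ]


def call_ts(
    assign30: list[ClusterAssignment], assign42: list[ClusterAssignment]
) -> set[str]:
    """Putative TS mutants: 42 degC category strictly worse than at 30 degC.

    Categories order high > reduced > low. Strains clustered at only one
    temperature are excluded with a warning.
    """
    cat30 = {a.strain_id: a.category for a in assign30}
    cat42 = {a.strain_id: a.category for a in assign42}
    only_one = set(cat30) ^ set(cat42)
    if only_one:
        warnings.warn(
            f"{len(only_one)} strains present at one temperature only; excluded",
            stacklevel=2,
        )
    return {
        s
        for s in set(cat30) & set(cat42)
        if _CAT_RANK[cat42[s]] > _CAT_RANK[cat30[s]]
    }
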