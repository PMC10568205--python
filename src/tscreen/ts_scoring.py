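"""Per-gene ranking of putative TS alleles.

Candidate alleles must clear six criteria (read depth at t=0, high final
fitness at 30 degC, low final fitness at 42 degC, bounded replicate error,
sufficient 30 degC area under the curve, and a nonlinear separation between
the two final fitness scores). Passing alleles are then ranked library-wide
on four quantities and combined into a rank-weighted composite score; the
lowest-scoring allele per gene is selected for reconstruction.

The nonlinear criterion n30 > 1/(1 + 0.25 * n42**3) + 0.3 demands near-full
fitness at 30 degC when the strain still grows at 42 degC, relaxing toward
the plain n30 > 0.3 floor as the 42 degC fitness collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_counting import CountMatrix
from .screen_fitness import FitnessSeries

__all__ = [
    "TSRecord",
    "auc",
    "replicate_error",
    "nonlinear_threshold",
    "passes_criteria",
    "composite_score",
    "build_records",
]

#: Composite-score weights for the four rankings.
RANK_WEIGHTS = {"r_t0": 1.25, "diff_auc": 2.0, "diff_t12": 1.5, "e": 0.75}


@dataclass
class TSRecord:
    """Per-strain summary quantities entering the TS composite score."""

    strain_id: str
    gene_id: str
    r_t0: float  # mean reads at t=0
    n30_final: float  # mean fitness, last timepoint, 30 degC
    n42_final: float
    e: float  # replicate error
    auc30: float
    auc42: float

    @property
    def diff_auc(self) -> float:
        """Relative AUC difference; +inf when AUC42 = 0 (ranked best)."""
        if self.auc42 == 0:
            return np.inf
        return (self.auc30 - self.auc42) / self.auc42

    @property
    def diff_t12(self) -> float:
        return self.n30_final - self.n42_final


def auc(time_h, fitness) -> float:
    """Trapezoidal area under a fitness-vs-time curve (fitness x hours)."""
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(fitness, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two timepoints for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    return float(np.trapezoid(y, t))


def replicate_error(
    rep_a_30, rep_b_30, rep_a_42, rep_b_42
) -> float:
    """Replicate error e: summed |A - B| / mean(A, B) over time, both temps.

    Dimensionless and scale-invariant; a timepoint where both replicates
    are zero contributes nothing.
    """
    total = 0.0
    for a_series, b_series in ((rep_a_30, rep_b_30), (rep_a_42, rep_b_42)):
        a = np.asarray(a_series, dtype=float)
        b = np.asarray(b_series, dtype=float)
        if a.shape != b.shape:
            raise ValueError("replicates must share timepoints")
        mean = (a + b) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.abs(a - b) / mean
        term[mean == 0] = 0.0
        total += float(np.nansum(term))
    return total


def nonlinear_threshold(n42_final: float) -> float:
    """30 degC fitness floor as a function of the 42 degC final fitness."""
    return 1.0 / (1.0 + 0.25 * n42_final**3) + 0.3


def passes_criteria(
    rec: TSRecord,
    min_t0_reads: float = 15.0,
    min_n30: float = 0.3,
    max_n42: float = 0.4,
    max_e: float = 15.0,
    min_auc30: float = 5.0,
) -> dict[str, bool]:
    """Evaluate the six TS criteria; all must hold for score eligibility."""
    return {
        "t0_reads": rec.r_t0 >= min_t0_reads,
        "n30_final": rec.n30_final > min_n30,
        "n42_final": rec.n42_final < max_n42,
        "error": rec.e < max_e,
        "auc30": rec.auc30 > min_auc30,
        "nonlinear": rec.n30_final > nonlinear_threshold(rec.n42_final),
    }


def composite_score(
    records: list[TSRecord], per_gene_ranks: bool = False
) -> pd.DataFrame:
    """Rank-weighted composite score and per-gene selection.

    Criteria-passing records are ranked (dense ranks, ties share the rank)
    on: most t=0 reads, largest relative AUC difference, largest final
    fitness difference, smallest replicate error. The composite is
    1.25*rank_t0 + 2*rank_diffAUC + 1.5*rank_diff12 + 0.75*rank_e; per
    gene, the record with the lowest composite is selected (ties: higher
    t=0 reads, then strain id). Ranks are library-wide by default;
    ``per_gene_ranks`` restricts each ranking to the gene's own records.
    """
    passing = [r for r in records if all(passes_criteria(r).values())]
    if not passing:
        return pd.DataFrame(
            columns=["strain_id", "gene_id", "score", "selected"]
        ).set_index("strain_id")
    df = pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in passing],
            "gene_id": [r.gene_id for r in passing],
            "r_t0": [r.r_t0 for r in passing],
            "diff_auc": [r.diff_auc for r in passing],
            "diff_t12": [r.diff_t12 for r in passing],
            "e": [r.e for r in passing],
        }
    ).set_index("strain_id")

    def _ranks(sub: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=sub.index)
        out["rank_r_t0"] = sub["r_t0"].rank(method="dense", ascending=False)
        out["rank_diff_auc"] = sub["diff_auc"].rank(method="dense", ascending=False)
        out["rank_diff_t12"] = sub["diff_t12"].rank(method="dense", ascending=False)
        out["rank_e"] = sub["e"].rank(method="dense", ascending=True)
        return out

    if per_gene_ranks:
        ranks = pd.concat([_ranks(g) for _, g in df.groupby("gene_id")])
        ranks = ranks.loc[df.index]
    else:
        ranks = _ranks(df)
    df = df.join(ranks)
    df["score"] = (
        RANK_WEIGHTS["r_t0"] * df["rank_r_t0"]
        + RANK_WEIGHTS["diff_auc"] * df["rank_diff_auc"]
        + RANK_WEIGHTS["diff_t12"] * df["rank_diff_t12"]
        + RANK_WEIGHTS["e"] * df["rank_e"]
    )
    df["selected"] = False
    for gene, sub in df.groupby("gene_id"):
        ordered = sub.sort_values(
            ["score", "r_t0", "strain_id"], ascending=[True, False, True],
            kind="stable",
        )
        df.loc[ordered.index[0], "selected"] = True
    return df


def build_records(
    counts: CountMatrix,
    series: FitnessSeries,
    strain_genes: dict[str, str],
    strains: set[str] | None = None,
) -> list[TSRecord]:
    """Assemble TSRecords from counts and fitness scores.

    AUCs use the replicate-mean series; the replicate error pairs the two
    replicate tracks per temperature. ``strains`` restricts the output
    (e.g. to the TS calls); strains with undefined fitness anywhere are
    skipped.
    """
    t0_cols = counts.sample_ids(time_h=0)
    r_t0 = counts.counts[t0_cols].mean(axis=1)

    mean30 = series.mean_series(30.0)
    mean42 = series.mean_series(42.0)
    reps = sorted(series.scores["replicate"].unique())
    if len(reps) != 2:
        raise ValueError(f"expected 2 replicates, found {len(reps)}")

    def _rep_series(temp, rep):
        sub = series.scores[
            (series.scores["temperature"] == temp)
            & (series.scores["replicate"] == rep)
        ]
        return sub.pivot(index="strain_id", columns="time_h", values="fitness")

    a30, b30 = _rep_series(30.0, reps[0]), _rep_series(30.0, reps[1])
    a42, b42 = _rep_series(42.0, reps[0]), _rep_series(42.0, reps[1])

    records = []
    pool = strains if strains is not None else set(mean30.index) & set(mean42.index)
    for strain in sorted(pool):
        if strain not in mean30.index or strain not in mean42.index:
            continue
        m30 = mean30.loc[strain]
        m42 = mean42.loc[strain]
        if m30.isna().any() or m42.isna().any():
            continue
        records.append(
            TSRecord(
                strain_id=strain,
                gene_id=strain_genes.get(strain, strain),
                r_t0=float(r_t0.get(strain, 0.0)),
                n30_final=float(m30.iloc[-1]),
                n42_final=float(m42.iloc[-1]),
                e=replicate_error(
                    a30.loc[strain], b30.loc[strain],
                    a42.loc[strain], b42.loc[strain],
                ),
                auc30=auc(m30.index, m30.to_numpy()),
                auc42=auc(m42.index, m42.to_numpy()),
            )
        )
    return records
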