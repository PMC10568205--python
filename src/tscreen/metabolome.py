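"""Flow-injection MS metabolomics: spectra to modified z-scores to pathways.

Per sample, the ten highest-TIC spectra are summed, peaks above height and
prominence floors are picked, and peaks are annotated against monoisotopic
metabolite masses as [M-H]- / [M+H]+ ions within a 3-mDa tolerance. Per
metabolite the maximum annotated peak height is kept; replicate means are
normalized to a control strain in log2 space and robustly standardized per
metabolite as modified z-scores, 0.6745 * (x - median) / MAD, with
replicate standard deviations propagated through the log-ratio. Increases
with a modified z-score above 3 feed the pathway bottleneck analysis
(substrate accumulation, target-pathway responses), strain-strain Pearson
correlations, and one-tailed Fisher enrichment tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "Spectrum",
    "MetaboliteMatrix",
    "ModZMatrix",
    "PathwayMap",
    "PROTON_MASS",
    "sum_top_spectra",
    "pick_peaks",
    "annotate_peaks",
    "resolve_annotations",
    "mod_z",
    "pathway_response",
    "correlation_matrix",
    "compare_pcc_groups",
    "enrichment_test",
    "read_spectrum_tsv",
    "read_spectrum_mzxml",
]

PROTON_MASS = 1.007276  # Da
MODZ_CONST = 0.6745


@dataclass
class Spectrum:
    """One profile-mode FI-MS spectrum."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class MetaboliteMatrix:
    """Replicate-mean peak heights (metabolite x strain) and their sds."""

    x: pd.DataFrame
    sigma_x: pd.DataFrame
    control_id: str


@dataclass
class ModZMatrix:
    """Modified z-scores per (metabolite, strain) with propagated sds."""

    modz: pd.DataFrame
    sigma_modz: pd.DataFrame
    x_norm: pd.DataFrame
    undefined_metabolites: list[str] = field(default_factory=list)


@dataclass
class PathwayMap:
    """Metabolite/pathway membership and enzyme-gene links."""

    metabolite_pathways: dict[str, set[str]]
    gene_target_pathway: dict[str, str] = field(default_factory=dict)
    gene_substrate: dict[str, str] = field(default_factory=dict)

    @property
    def pathways(self) -> set[str]:
        out = set()
        for ps in self.metabolite_pathways.values():
            out |= ps
        return out


def sum_top_spectra(spectra: list[Spectrum], n: int = 10) -> Spectrum:
    """Sum the ``n`` highest-TIC spectra on the union m/z grid.

    Spectra are resampled to the union of their m/z axes by nearest bin
    before the element-wise sum; fewer than ``n`` spectra sums all of them
    with a warning.
    """
    if not spectra:
        raise ValueError("no spectra")
    if len(spectra) < n:
        warnings.warn(
            f"only {len(spectra)} spectra available, summing all", stacklevel=2
        )
    chosen = sorted(spectra, key=lambda s: -s.tic)[: min(n, len(spectra))]
    grid = np.unique(np.concatenate([s.mz for s in chosen]))
    total = np.zeros_like(grid)
    for s in chosen:
        idx = np.searchsorted(grid, s.mz)
        idx = np.clip(idx, 0, grid.size - 1)
        left = np.clip(idx - 1, 0, grid.size - 1)
        use_left = np.abs(grid[left] - s.mz) < np.abs(grid[idx] - s.mz)
        nearest = np.where(use_left, left, idx)
        np.add.at(total, nearest, s.intensity)
    return Spectrum(grid, total, chosen[0].polarity)


def pick_peaks(
    spectrum: Spectrum, min_height: float = 1000.0, min_prominence: float = 500.0
) -> pd.DataFrame:
    """Local maxima with height and topographic prominence above the floors.

    Returns a DataFrame with ``mz`` (apex) and ``height`` columns.
    """
    if spectrum.mz.size == 0:
        return pd.DataFrame(columns=["mz", "height"])
    idx, props = signal.find_peaks(
        spectrum.intensity, height=min_height, prominence=min_prominence
    )
    return pd.DataFrame({"mz": spectrum.mz[idx], "height": props["peak_heights"]})


def annotate_peaks(
    peaks: pd.DataFrame,
    metabolite_masses: list[tuple[str, float]] | dict[str, float],
    polarity: str,
    tol_mda: float = 3.0,
) -> pd.DataFrame:
    """Match picked peaks to metabolites as [M-H]- or [M+H]+ ions.

    A peak annotates a metabolite when |peak m/z - (M -+ 1.007276)| is
    within ``tol_mda`` mDa; per metabolite the maximum annotated peak
    height is kept. Returns columns metabolite, mz, height, delta_mda,
    polarity, ambiguous — the last flags peaks claimed by more than one
    metabolite (isobars within tolerance).
    """
    if isinstance(metabolite_masses, dict):
        items = list(metabolite_masses.items())
    else:
        items = list(metabolite_masses)
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate metabolite names")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    sign = +1.0 if polarity == "positive" else -1.0
    tol = tol_mda / 1000.0
    rows = []
    mz = peaks["mz"].to_numpy() if len(peaks) else np.array([])
    h = peaks["height"].to_numpy() if len(peaks) else np.array([])
    for name, mass in items:
        target = mass + sign * PROTON_MASS
        if mz.size == 0:
            continue
        d = np.abs(mz - target)
        hit = d <= tol
        if not hit.any():
            continue
        j = np.flatnonzero(hit)[np.argmax(h[hit])]
        rows.append(
            {
                "metabolite": name,
                "mz": mz[j],
                "height": h[j],
                "delta_mda": d[j] * 1000.0,
                "polarity": polarity,
            }
        )
    out = pd.DataFrame(
        rows, columns=["metabolite", "mz", "height", "delta_mda", "polarity"]
    )
    out["ambiguous"] = out["mz"].duplicated(keep=False) if len(out) else False
    return out


def resolve_annotations(
    neg: pd.DataFrame | None, pos: pd.DataFrame | None
) -> pd.DataFrame:
    """Resolve metabolites annotated in both polarities to the higher peak.

    Automated stand-in for manual curation by peak shape and height: only
    the height is used.
    """
    frames = [f for f in (neg, pos) if f is not None and len(f)]
    if not frames:
        return pd.DataFrame(columns=["metabolite", "mz", "height", "delta_mda", "polarity"])
    allf = pd.concat(frames, ignore_index=True)
    keep = allf.sort_values(["height", "polarity"], ascending=[False, True])
    return (
        keep.drop_duplicates("metabolite", keep="first")
        .sort_values("metabolite")
        .reset_index(drop=True)
    )


def mod_z(matrix: MetaboliteMatrix) -> ModZMatrix:
    """Modified z-scores across strains per metabolite, with error propagation.

    x_norm = log2(x / x_control); modz = 0.6745 * (x_norm - median) / MAD,
    median and MAD across strains within each metabolite. The propagated sd
    is 0.6745 * sigma_xnorm / MAD with
    sigma_xnorm = sqrt((sigma_i/x_i)^2 + (sigma_c/x_c)^2) / ln 2.
    Metabolites with MAD = 0 are undefined (NaN, flagged).
    """
    x = matrix.x
    if matrix.control_id not in x.columns:
        raise ValueError(f"control strain {matrix.control_id!r} missing")
    xc = x[matrix.control_id]
    if (xc <= 0).any():
        bad = list(xc.index[xc <= 0])
        raise ValueError(f"control intensities must be > 0; offending: {bad[:5]}")
    x_norm = np.log2(x.div(xc, axis=0))
    med = x_norm.median(axis=1)
    dev = x_norm.sub(med, axis=0)
    mad = dev.abs().median(axis=1)
    undefined = list(mad.index[mad == 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        modz = MODZ_CONST * dev.div(mad, axis=0)
    modz.loc[undefined] = np.nan

    sc = matrix.sigma_x[matrix.control_id]
    rel = (matrix.sigma_x.div(x)) ** 2
    rel_c = (sc / xc) ** 2
    sigma_xnorm = np.sqrt(rel.add(rel_c, axis=0)) / math.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_modz = MODZ_CONST * sigma_xnorm.div(mad, axis=0)
    sigma_modz.loc[undefined] = np.nan
    return ModZMatrix(modz, sigma_modz, x_norm, undefined)


def pathway_response(
    modz: ModZMatrix | pd.DataFrame,
    pmap: PathwayMap,
    threshold: float = 3.0,
    strain_genes: dict[str, str] | None = None,
) -> dict:
    """Count metabolite increases (modz > threshold) per pathway and strain.

    Returns a dict with:

    - ``counts``: DataFrame (strain, pathway) -> number of increased
      metabolites (a metabolite in several pathways contributes to each;
      unmapped metabolites go to the 'unmapped' bucket with a warning);
    - ``pathways_per_strain``: responding-pathway count per strain;
    - ``strains_per_pathway``: responding-strain count per pathway;
    - ``target_response`` / ``substrate_increase``: per-strain flags, when
      ``strain_genes`` links strains to enzyme genes in the map.
    """
    z = modz.modz if isinstance(modz, ModZMatrix) else modz
    unmapped = [m for m in z.index if m not in pmap.metabolite_pathways]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} metabolites missing from the pathway map; "
            "counted under 'unmapped'",
            stacklevel=2,
        )
    pathways = sorted(pmap.pathways) + (["unmapped"] if unmapped else [])
    counts = pd.DataFrame(0, index=z.columns, columns=pathways)
    counts.index.name = "strain_id"
    inc = z > threshold
    for met in z.index:
        ps = pmap.metabolite_pathways.get(met, {"unmapped"})
        hit = inc.loc[met]
        for p in ps:
            counts[p] += hit.astype(int)

    real = [p for p in pathways if p != "unmapped"]
    pathways_per_strain = (counts[real] > 0).sum(axis=1)
    strains_per_pathway = (counts[real] > 0).sum(axis=0)

    target_response = {}
    substrate_increase = {}
    if strain_genes:
        for strain, gene in strain_genes.items():
            if strain not in z.columns:
                continue
            tp = pmap.gene_target_pathway.get(gene)
            target_response[strain] = bool(tp and counts.loc[strain].get(tp, 0) > 0)
            sub = pmap.gene_substrate.get(gene)
            substrate_increase[strain] = bool(
                sub in z.index and inc.loc[sub, strain]
            )
    return {
        "counts": counts,
        "pathways_per_strain": pathways_per_strain,
        "strains_per_pathway": strains_per_pathway,
        "target_response": pd.Series(target_response, dtype=bool),
        "substrate_increase": pd.Series(substrate_increase, dtype=bool),
    }


def correlation_matrix(
    modz: ModZMatrix | pd.DataFrame, min_metabolites: int = 3
) -> pd.DataFrame:
    """Strain x strain Pearson correlations over defined metabolites.

    Pairs with fewer than ``min_metabolites`` shared defined entries, or a
    constant profile, are NaN.
    """
    z = modz.modz if isinstance(modz, ModZMatrix) else modz
    strains = list(z.columns)
    pcc = pd.DataFrame(np.nan, index=strains, columns=strains)
    for i, a in enumerate(strains):
        col = z[a].dropna()
        if len(col) >= min_metabolites and col.std(ddof=0) > 0:
            pcc.loc[a, a] = 1.0
        for b in strains[i + 1 :]:
            pair = pd.concat([z[a], z[b]], axis=1, keys=["x", "y"]).dropna()
            if len(pair) < min_metabolites:
                continue
            va, vb = pair["x"].to_numpy(), pair["y"].to_numpy()
            if np.std(va) == 0 or np.std(vb) == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            pcc.loc[a, b] = pcc.loc[b, a] = r
    return pcc


def compare_pcc_groups(
    pcc: pd.DataFrame,
    pathway_pairs: set[frozenset] | None = None,
    complex_pairs: set[frozenset] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparisons of PCC groups.

    Compares all off-diagonal pairs vs pathway-internal vs complex-internal
    groups (normal approximation with tie correction).
    """
    strains = list(pcc.index)
    all_vals, path_vals, cplx_vals = [], [], []
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            v = pcc.loc[a, b]
            if np.isnan(v):
                continue
            all_vals.append(v)
            key = frozenset((a, b))
            if pathway_pairs and key in pathway_pairs:
                path_vals.append(v)
            if complex_pairs and key in complex_pairs:
                cplx_vals.append(v)
    groups = {"all": all_vals, "pathway": path_vals, "complex": cplx_vals}
    rows = []
    names = list(groups)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            v1, v2 = groups[g1], groups[g2]
            if len(v1) < 1 or len(v2) < 1:
                continue
            stat, p = stats.mannwhitneyu(
                v1, v2, alternative="two-sided", method="asymptotic"
            )
            rows.append(
                {"group1": g1, "group2": g2, "n1": len(v1), "n2": len(v2),
                 "median1": float(np.median(v1)), "median2": float(np.median(v2)),
                 "statistic": float(stat), "p_value": float(p)}
            )
    return pd.DataFrame(rows)


def enrichment_test(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher exact test P(X >= a) for the 2x2 table [[a,b],[c,d]].

    ``a`` counts mutants that are in the group AND have the feature. An
    empty margin yields p = 1 by convention (with a warning).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    N = a + b + c + d
    K = a + b  # feature-positive total (row 1)
    n = a + c  # group size (column 1)
    if a + b == 0 or a + c == 0 or b + d == 0 or c + d == 0:
        warnings.warn("empty margin in 2x2 table; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    return float(stats.hypergeom.sf(a - 1, N, K, n))


def read_spectrum_tsv(path, polarity: str = "negative") -> Spectrum:
    """Read a two-column (m/z, intensity) TSV into a Spectrum."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["mz", "intensity"])
    order = np.argsort(df["mz"].to_numpy())
    return Spectrum(df["mz"].to_numpy()[order], df["intensity"].to_numpy()[order], polarity)


def read_spectrum_mzxml(path, polarity: str = "negative") -> list[Spectrum]:
    """Read all scans of an mzXML file into Spectrum objects (needs pyteomics)."""
    from pyteomics import mzxml

    out = []
    with mzxml.read(str(path)) as reader:
        for scan in reader:
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            order = np.argsort(mz)
            out.append(Spectrum(mz[order], inten[order], polarity))
    return out
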