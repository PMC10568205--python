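"""Seeded generators for every input the screen pipeline consumes.

The generators emulate the study design — a 7-timepoint, 2-temperature,
2-replicate serial-dilution competition read out by multinomial barcode
sampling, plate-reader OD curves at 10 temperatures, and FI-MS metabolite
intensity matrices with planted substrate increases — and serialize the
ground truth next to every dataset so each analysis stage can be scored
against what was planted. Every generator is a pure function of its
config: equal seeds give byte-identical outputs.

Competition dynamics are modelled in continuous exponential phase: the
3-hourly back-dilutions keep cultures exponential and preserve
composition, so relative abundance follows p_i(t) ~ p_i(0) * exp(mu_i(T) t)
and death is a negative rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._sequences import SGRNA_HANDLE, SPACER5, revcomp
from .barcode_counting import CountMatrix
from .growth_model import GrowthCurve, arrhenius_mu, R_GAS
from .metabolome import MetaboliteMatrix, PathwayMap, Spectrum

__all__ = [
    "SimConfig",
    "GroundTruth",
    "METABOLITE_MASSES",
    "simulate_screen",
    "simulate_fastq_pairs",
    "simulate_growth_curves",
    "simulate_spectra",
    "simulate_metabolome",
]

#: Bundled synthetic annotation panel: common E. coli metabolites with
#: monoisotopic masses (Da). Includes the threonine/homoserine isobar pair
#: to exercise annotation ambiguity.
METABOLITE_MASSES: dict[str, float] = {
    "glucose": 180.06339,
    "fructose-6-phosphate": 260.02972,
    "pyruvate": 88.01604,
    "phosphoenolpyruvate": 167.98237,
    "glyceraldehyde-3-phosphate": 169.99802,
    "citrate": 192.02700,
    "succinate": 118.02661,
    "fumarate": 116.01096,
    "malate": 134.02152,
    "alpha-ketoglutarate": 146.02152,
    "glutamate": 147.05316,
    "glutamine": 146.06914,
    "aspartate": 133.03751,
    "asparagine": 132.05349,
    "alanine": 89.04768,
    "serine": 105.04259,
    "threonine": 119.05824,
    "homoserine": 119.05824,
    "methionine": 149.05105,
    "lysine": 146.10553,
    "arginine": 174.11168,
    "histidine": 155.06948,
    "citrulline": 175.09569,
    "shikimate": 174.05282,
    "shikimate-3-phosphate": 254.01915,
    "3-methyl-2-oxobutanoate": 116.04734,
    "AMP": 347.06308,
    "tryptophan": 204.08988,
    "phenylalanine": 165.07898,
    "tyrosine": 181.07389,
}

_C0 = 273.15


@dataclass
class SimConfig:
    """Study-condition parameters for all generators."""

    seed: int
    # competition screen
    n_strains: int = 500
    n_genes: int = 100
    frac_ts: float = 0.1
    frac_dropout: float = 0.05
    # non-TS strains fall into three temperature-independent fitness classes
    # (healthy / mildly reduced / strongly defective), as in a library where
    # many designed mutations destabilize their protein at both temperatures
    frac_defect: float = 0.2  # strong fitness defect at BOTH temperatures
    frac_mild: float = 0.2  # mild fitness defect at BOTH temperatures
    mu_defect_range: tuple = (0.02, 0.15)  # h^-1 at 30 degC, strong defects
    mild_deficit_range: tuple = (0.03, 0.12)  # h^-1 below control, mild class
    mu30_mean: float = 0.35  # h^-1, control-like growth at 30 degC
    mu30_sd: float = 0.01  # neutral strain-to-strain variation
    mu30_ts_sd: float = 0.01  # TS strains grow control-like at 30 degC
    mu42_shift: float = 0.3  # non-TS strains: mu42 = mu30 + shift
    mu42_ts_min: float = -0.3  # TS strains: mu42 ~ U(min, 0]; death allowed
    read_depth: int = 1_000_000
    timepoints_h: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    dilution_interval_h: float = 3.0
    replicates: int = 2
    replicate_rate_cv: float = 0.02  # lognormal jitter of rates per replicate
    barcode_len: int = 60
    # growth curves
    n_growth_strains: int = 50
    growth_temps: tuple = tuple(np.round(np.linspace(30.0, 44.0, 10), 2))
    growth_replicates: int = 3
    od0: float = 0.05
    od_cap: float = 1.0
    od_noise_cv: float = 0.02
    od_sampling_min: float = 10.0
    od_duration_h: float = 8.0
    # spectra
    mz_min: float = 50.0
    mz_max: float = 400.0
    mz_step: float = 0.001
    peak_sigma_mda: float = 5.0
    # metabolome matrix
    n_met_strains: int = 20
    n_pathways: int = 8
    met_replicates: int = 3
    met_cv: float = 0.10
    substrate_fold: float = 8.0


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    strains: pd.DataFrame | None = None
    metabolites: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"extra": self.extra}
        for name in ("strains", "metabolites", "peaks"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.reset_index().to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_screen(
    config: SimConfig,
    mu30_override=None,
    mu42_override=None,
    p0_override=None,
):
    """Simulate the pooled competition assay.

    Returns (CountMatrix, designs, GroundTruth). ``designs`` maps strain id
    to its variable cassette region (the barcode). Relative abundance
    follows exponential competition; reads per sample are one multinomial
    draw of the configured depth. Per-replicate growth rates get a small
    lognormal jitter so replicate error is realistically nonzero. The
    ``*_override`` arrays pin growth rates / start composition to exact
    values (for closed-form checks), bypassing the population sampling.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    if n < 2 or config.read_depth <= 0:
        raise ValueError("degenerate config: need >= 2 strains and depth > 0")
    strain_ids = [f"s{i:04d}" for i in range(n)]
    genes = [f"g{i % config.n_genes:03d}" for i in range(n)]

    mu30 = np.clip(rng.normal(config.mu30_mean, config.mu30_sd, n), 0.05, None)
    is_ts = rng.random(n) < config.frac_ts
    # TS mutants grow control-like at the permissive temperature; their
    # defect only unfolds at 42 degC (a rate <= 0, death allowed).
    mu30[is_ts] = np.clip(
        rng.normal(config.mu30_mean, config.mu30_ts_sd, is_ts.sum()), 0.05, None
    )
    # non-TS strains with temperature-independent defects (destabilized at
    # both temperatures): a strongly defective and a mildly reduced class
    u = rng.random(n)
    is_defect = (~is_ts) & (u < config.frac_defect)
    is_mild = (~is_ts) & (u >= config.frac_defect) & (
        u < config.frac_defect + config.frac_mild
    )
    mu30[is_defect] = rng.uniform(*config.mu_defect_range, is_defect.sum())
    mu30[is_mild] = config.mu30_mean - rng.uniform(
        *config.mild_deficit_range, is_mild.sum()
    )
    mu42 = mu30 + config.mu42_shift
    mu42[is_ts] = rng.uniform(config.mu42_ts_min, 0.0, is_ts.sum())

    p0 = rng.dirichlet(np.full(n, 5.0))
    dropout = rng.random(n) < config.frac_dropout
    p0[dropout] *= 1e-4
    p0 /= p0.sum()

    if mu30_override is not None:
        mu30 = np.asarray(mu30_override, dtype=float)
        is_ts = np.zeros(n, dtype=bool)
        is_defect = np.zeros(n, dtype=bool)
        is_mild = np.zeros(n, dtype=bool)
    if mu42_override is not None:
        mu42 = np.asarray(mu42_override, dtype=float)
    if p0_override is not None:
        p0 = np.asarray(p0_override, dtype=float)
        p0 = p0 / p0.sum()
        dropout = np.zeros(n, dtype=bool)

    counts = {}
    meta_rows = []
    for temp, mu in ((30.0, mu30), (42.0, mu42)):
        for r in range(config.replicates):
            rep = "AB"[r] if r < 2 else f"R{r}"
            jitter = rng.lognormal(0.0, config.replicate_rate_cv, n)
            mu_rep = mu * jitter
            for t in config.timepoints_h:
                w = p0 * np.exp(mu_rep * t)
                p = w / w.sum()
                sample_id = f"T{int(temp)}_{rep}_t{int(t):02d}"
                counts[sample_id] = rng.multinomial(config.read_depth, p)
                meta_rows.append(
                    {"sample_id": sample_id, "temperature": temp,
                     "time_h": float(t), "replicate": rep}
                )
    count_df = pd.DataFrame(counts, index=pd.Index(strain_ids, name="strain_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    designs = dict(zip(strain_ids, _random_barcodes(rng, n, config.barcode_len)))
    truth = GroundTruth(
        strains=pd.DataFrame(
            {"strain_id": strain_ids, "gene_id": genes, "is_ts": is_ts,
             "is_defect": is_defect, "is_mild": is_mild, "mu30": mu30,
             "mu42": mu42, "p0": p0, "dropout_planted": dropout}
        ).set_index("strain_id"),
        extra={"kind": "screen", "seed": config.seed},
    )
    return CountMatrix(count_df, samples), designs, truth


def simulate_fastq_pairs(
    designs: dict[str, str],
    counts: pd.Series,
    seed: int,
    error_rate: float = 0.0,
    read_len: int = 80,
    qual: int = 35,
):
    """Yield (read1, qual1, read2, qual2) pairs for one sample's counts.

    Each strain's template is SPACER5 + barcode + handle; both mates carry
    independent per-base errors at ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def _corrupt(seq: str) -> str:
        if error_rate == 0:
            return seq
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < error_rate:
                out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4]
        return "".join(out)

    quals = [qual] * read_len
    for strain, c in counts.items():
        template = SPACER5 + designs[strain] + SGRNA_HANDLE
        for _ in range(int(c)):
            r1 = _corrupt(template[:read_len])
            r2 = _corrupt(revcomp(template)[:read_len])
            yield r1, quals[: len(r1)], r2, quals[: len(r2)]


def _sample_arrhenius_truth(rng: np.random.Generator, mu30_target: float,
                            collapse_T: float) -> dict[str, float]:
    """Truth parameters with mu(30) ~ target and collapse near ``collapse_T``."""
    E1 = rng.uniform(5e4, 7e4)
    E2 = E1 * rng.uniform(5.0, 10.0)
    TK30 = 30.0 + _C0
    a1 = np.log(mu30_target) + E1 / (R_GAS * TK30)
    # activating and inactivating terms cross at the collapse temperature
    a2 = a1 + (E2 - E1) / (R_GAS * (collapse_T + _C0))
    return {"a_act": a1, "E_act": E1, "a_inact": a2, "E_inact": E2}


def simulate_growth_curves(config: SimConfig):
    """Plate-reader OD curves for a panel of TS strains plus a control.

    OD grows exponentially at the strain's Arrhenius-truth rate, capped at
    the carrying capacity, with multiplicative lognormal noise. Returns
    (curves, GroundTruth); the control strain ('control') has negligible
    inactivation below 44 degC.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.od_duration_h + 1e-9, config.od_sampling_min / 60.0)
    rows = []
    curves: list[GrowthCurve] = []
    strain_ids = ["control"] + [f"ts{i:03d}" for i in range(config.n_growth_strains)]
    for sid in strain_ids:
        mu30_t = float(np.clip(rng.normal(config.mu30_mean, 0.03), 0.2, None))
        collapse = 50.0 if sid == "control" else float(rng.uniform(38.0, 44.0))
        p = _sample_arrhenius_truth(rng, mu30_t, collapse)
        rows.append({"strain_id": sid, "collapse_T": collapse, **p})
        for T in config.growth_temps:
            mu = float(arrhenius_mu(T, **p))
            for r in range(config.growth_replicates):
                noise = rng.lognormal(0.0, config.od_noise_cv, t.size)
                od = np.minimum(config.od0 * np.exp(mu * t), config.od_cap) * noise
                curves.append(
                    GrowthCurve(t, od, temperature=float(T), strain_id=sid,
                                replicate=f"r{r}")
                )
    truth = GroundTruth(
        strains=pd.DataFrame(rows).set_index("strain_id"),
        extra={"kind": "growth", "seed": config.seed},
    )
    return curves, truth


def simulate_spectra(
    config: SimConfig,
    metabolites: dict[str, float] | None = None,
    polarity: str = "negative",
    n_spectra: int = 12,
    height_range: tuple[float, float] = (2e3, 5e4),
    baseline: float = 50.0,
):
    """Profile-mode FI-MS spectra with Gaussian peaks at [M-+H] ion masses.

    Returns (spectra, GroundTruth). Every metabolite of the panel gets one
    peak; per-spectrum heights scale with a spectrum-level intensity factor
    so the top-TIC selection is exercised (the last two spectra are scaled
    to tiny TIC).
    """
    rng = np.random.default_rng(config.seed)
    panel = metabolites if metabolites is not None else METABOLITE_MASSES
    sign = +1.0 if polarity == "positive" else -1.0
    from .metabolome import PROTON_MASS

    grid = np.arange(config.mz_min, config.mz_max, config.mz_step)
    sigma = config.peak_sigma_mda / 1000.0
    apexes = []
    heights = {}
    for name, mass in panel.items():
        ion = mass + sign * PROTON_MASS
        if not (config.mz_min + 0.1 < ion < config.mz_max - 0.1):
            continue
        h = float(rng.uniform(*height_range))
        heights[name] = h
        apexes.append({"metabolite": name, "ion_mz": ion, "height": h})

    spectra = []
    for k in range(n_spectra):
        scale = 0.01 if k >= n_spectra - 2 else float(rng.uniform(0.8, 1.2))
        inten = rng.uniform(0.0, baseline, grid.size) * scale
        for row in apexes:
            ion, h = row["ion_mz"], row["height"]
            lo = np.searchsorted(grid, ion - 5 * sigma)
            hi = np.searchsorted(grid, ion + 5 * sigma)
            inten[lo:hi] += (
                h * scale * np.exp(-0.5 * ((grid[lo:hi] - ion) / sigma) ** 2)
            )
        spectra.append(Spectrum(grid.copy(), inten, polarity))
    truth = GroundTruth(
        peaks=pd.DataFrame(apexes),
        extra={"kind": "spectra", "seed": config.seed, "polarity": polarity},
    )
    return spectra, truth


def simulate_metabolome(config: SimConfig):
    """Metabolite x strain intensity matrix with planted substrate increases.

    Half of the non-control strains are enzyme mutants whose substrate
    metabolite is increased ``substrate_fold``-fold; replicate noise is
    lognormal at the configured CV. Returns
    (MetaboliteMatrix, PathwayMap, GroundTruth).
    """
    rng = np.random.default_rng(config.seed)
    mets = list(METABOLITE_MASSES)
    n_strains = config.n_met_strains
    strains = ["control"] + [f"m{i:03d}" for i in range(n_strains - 1)]

    pathway_names = [f"pw{i:02d}" for i in range(config.n_pathways)]
    met_pw: dict[str, set[str]] = {}
    for j, m in enumerate(mets):
        ps = {pathway_names[j % config.n_pathways]}
        if rng.random() < 0.25:  # some metabolites sit in two pathways
            ps.add(pathway_names[int(rng.integers(config.n_pathways))])
        met_pw[m] = ps

    enzyme_strains = strains[1 : 1 + (n_strains - 1) // 2]
    gene_sub = {}
    gene_pw = {}
    sub_choices = rng.choice(len(mets), size=len(enzyme_strains), replace=False)
    for s, mi in zip(enzyme_strains, sub_choices):
        met = mets[int(mi)]
        gene_sub[f"gene_{s}"] = met
        gene_pw[f"gene_{s}"] = sorted(met_pw[met])[0]

    base = rng.lognormal(np.log(1e4), 0.5, len(mets))
    true_fold = pd.DataFrame(1.0, index=mets, columns=strains)
    for s in enzyme_strains:
        true_fold.loc[gene_sub[f"gene_{s}"], s] = config.substrate_fold

    x = pd.DataFrame(index=pd.Index(mets, name="metabolite"), columns=strains,
                     dtype=float)
    sx = x.copy()
    for s in strains:
        mean_level = base * true_fold[s].to_numpy()
        reps = mean_level[:, None] * rng.lognormal(
            0.0, config.met_cv, (len(mets), config.met_replicates)
        )
        x[s] = reps.mean(axis=1)
        sx[s] = reps.std(axis=1, ddof=1)

    pmap = PathwayMap(met_pw, gene_pw, gene_sub)
    truth = GroundTruth(
        metabolites=true_fold,
        strains=pd.DataFrame(
            {"strain_id": strains,
             "gene_id": [f"gene_{s}" if s in enzyme_strains else "" for s in strains],
             "substrate": [gene_sub.get(f"gene_{s}", "") for s in strains]}
        ).set_index("strain_id"),
        extra={"kind": "metabolome", "seed": config.seed,
               "substrate_fold": config.substrate_fold},
    )
    return MetaboliteMatrix(x, sx, "control"), pmap, truth
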