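"""Synthetic breeding-panel generator.

Emulates a cabbage hybrid-breeding study design: 14 doubled-haploid parent
lines, 11 derived F1 hybrids (including one reciprocal pair), 2 commercial
check hybrids, 3-4 replicate heads per genotype, and 13 glucosinolates in
four structural classes. The stochastic model is:

* line means per compound are drawn uniformly from compound-specific
  ranges calibrated to published cabbage concentrations (µmol g⁻¹ dw);
* a planted dichotomy splits lines into a 3C-aliphatic-high and a
  4C-aliphatic-high group (the dominant axis of real cabbage panels);
* hybrid true means are multiplicative around the mid-parent value,
  H = (1 + δ)·MPV, so a planted per-compound δ maps exactly to MPH = 100δ;
* gluconasturtiin (GNS) follows a two-locus null-allele model: a fully
  homozygous line lacking a functional allele at either pathway locus
  accumulates no GNS; a hybrid lacks GNS iff both parents are null at the
  same locus, while parents null at *different* loci complement each other
  and the hybrid regains GNS;
* replicates are the true mean times lognormal noise with a configurable
  CV (multiplicative, mean-one), so concentrations stay positive;
* agronomic traits use the same machinery with uniformly positive planted
  heterosis, largest for head weight;
* peak areas are the exact inverse of the internal-standard quantification
  model (50 mg dry mass, 25 nmol IS), optionally with area-level noise.

All randomness flows from a single seed; each operation derives its own
namespaced stream so panels are reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panels import TRAIT_CODES
from .pedigree import Genotype, Pedigree, Role
from .quantification import DEFAULT_DRY_MASS_G, DEFAULT_IS_AMOUNT_NMOL, MrmSample
from .registry import GSLClass, analytes, build_registry

# Compound-specific line-mean ranges (µmol g⁻¹ dw), loosely calibrated to
# published cabbage panels: sinigrin and glucobrassicin dominate, the
# aromatic gluconasturtiin is a trace compound (~0.1% of the total).
DEFAULT_LINE_RANGES: dict[str, tuple[float, float]] = {
    "SIN": (2.68, 27.28),
    "GIB": (2.01, 16.66),
    "GBN": (0.8, 6.5),
    "PRO": (0.30, 18.36),
    "EPRO": (0.05, 0.60),
    "GNP": (0.50, 8.00),
    "GRA": (0.30, 4.00),
    "GER": (0.05, 0.80),
    "GBS": (2.70, 14.06),
    "MGBS": (0.50, 3.00),
    "HGBS": (0.10, 1.00),
    "NGBS": (0.20, 1.50),
    "GNS": (0.02, 0.12),
}

# Planted per-compound hybrid effects (MPH/100): gluconapin consistently
# positive, glucobrassicin and neoglucobrassicin consistently negative,
# the rest mildly heterotic either way.
DEFAULT_HYBRID_DELTA: dict[str, float] = {
    "SIN": 0.05,
    "GIB": 0.05,
    "GBN": 0.40,
    "PRO": 0.20,
    "EPRO": 0.10,
    "GNP": 1.00,
    "GRA": 0.10,
    "GER": 0.50,
    "GBS": -0.30,
    "MGBS": 0.00,
    "HGBS": 0.00,
    "NGBS": -0.35,
    "GNS": 0.50,
}

DEFAULT_TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "HW": (200.0, 800.0),  # g
    "HD": (8.0, 15.0),  # cm
    "HH": (8.0, 14.0),  # cm
    "ICL": (3.0, 7.0),  # cm
    "HC": (0.30, 0.70),  # g cm⁻³
}

# Uniformly positive agronomic heterosis, head weight by far the largest.
DEFAULT_TRAIT_DELTA: dict[str, float] = {
    "HW": 4.738,
    "HD": 0.80,
    "HH": 0.70,
    "ICL": 0.60,
    "HC": 0.406,
}

DEFAULT_CALIBRATION_SLOPES: dict[str, float] = {
    "SIN": 1800.0, "GIB": 2400.0, "GBN": 1500.0, "PRO": 2100.0, "EPRO": 2050.0,
    "GNP": 1700.0, "GRA": 2600.0, "GER": 1400.0, "GBS": 3200.0, "MGBS": 2900.0,
    "HGBS": 3100.0, "NGBS": 2700.0, "GNS": 2000.0, "GTP": 2200.0,
}


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults mirror the emulated design."""

    seed: int = 0
    n_lines: int = 14
    n_hybrids: int = 11
    n_checks: int = 2
    p_four_replicates: float = 0.75  # 4 heads unless pest/disease loss → 3
    replicate_cv: float = 0.15
    line_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LINE_RANGES)
    )
    hybrid_delta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HYBRID_DELTA))
    cluster_fraction: float = 0.4  # fraction of lines in the 4C-high group
    cluster_separation: float = 0.6  # 0 = no dichotomy, →1 = disjoint sub-ranges
    gns_null_p: float = 0.25  # per-locus nonfunctional-allele probability
    gns_null_alleles: dict[str, tuple[bool, bool]] | None = None  # explicit per-line loci
    trait_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_RANGES)
    )
    trait_delta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_DELTA))
    calibration_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_SLOPES)
    )
    area_cv: float = 0.0  # noise on simulated peak areas; 0 → exactly invertible
    dry_mass_g: float = DEFAULT_DRY_MASS_G
    is_amount_nmol: float = DEFAULT_IS_AMOUNT_NMOL

    def __post_init__(self):
        for comp, d in self.hybrid_delta.items():
            if d <= -1:
                raise ValueError(f"hybrid effect for {comp} must exceed -1")
        for t, d in self.trait_delta.items():
            if d <= -1:
                raise ValueError(f"trait effect for {t} must exceed -1")
        for comp, (lo, hi) in self.line_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"line range for {comp} must be positive and ordered")
        for t, (lo, hi) in self.trait_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"trait range for {t} must be positive and ordered")


@dataclass
class SimulationTruth:
    """Ground truth paired with an emitted panel, for recovery tests."""

    genotype_means: pd.DataFrame  # genotype × compound true means
    median_mph: pd.Series  # per-compound true median MPH (%) across hybrids
    cluster_labels: pd.Series  # planted 3C-high vs 4C-high label per genotype
    gns_loci: dict[str, tuple[bool, bool]]  # per-line (locus1_null, locus2_null)
    trait_means: pd.DataFrame | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # namespaced child stream: reproducible independently of call order
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def simulate_pedigree(config: SimulationConfig | None = None) -> Pedigree:
    """Lines L1..Ln, hybrids Hib1..Hibm on distinct ordered line pairs
    (Hib1/Hib2 are reciprocals when possible), plus unrelated checks."""
    config = config or SimulationConfig()
    rng = _rng(config, 1)
    n = config.n_lines
    if config.n_hybrids > n * (n - 1):
        raise ValueError("more hybrids requested than distinct ordered line pairs")
    lines = [f"L{i + 1}" for i in range(n)]
    pairs: list[tuple[str, str]] = []
    if config.n_hybrids >= 2 and n >= 2:
        a, b = rng.choice(n, size=2, replace=False)
        pairs += [(lines[a], lines[b]), (lines[b], lines[a])]  # reciprocal pair
    all_pairs = [(lines[i], lines[j]) for i in range(n) for j in range(n) if i != j]
    rng.shuffle(all_pairs)
    for p in all_pairs:
        if len(pairs) >= config.n_hybrids:
            break
        if p not in pairs:
            pairs.append(p)
    pairs = pairs[: config.n_hybrids]
    genotypes = [Genotype(gid, Role.LINE) for gid in lines]
    genotypes += [
        Genotype(f"Hib{k + 1}", Role.HYBRID, mother_id=m, father_id=f)
        for k, (m, f) in enumerate(pairs)
    ]
    genotypes += [Genotype(f"Check{k + 1}", Role.COMMERCIAL_HYBRID) for k in range(config.n_checks)]
    return Pedigree(genotypes)


def _sub_range(lo: float, hi: float, s: float, high: bool) -> tuple[float, float]:
    """Upper (high=True) or lower sub-range covering a (1 − s/2) slice."""
    cut = lo + s * (hi - lo)
    return (cut, hi) if high else (lo, lo + (1 - s) * (hi - lo))


def _gns_loci(config: SimulationConfig, line_ids: list[str], rng) -> dict[str, tuple[bool, bool]]:
    if config.gns_null_alleles is not None:
        missing = set(line_ids) - set(config.gns_null_alleles)
        if missing:
            raise ValueError(f"gns_null_alleles missing lines: {sorted(missing)}")
        return {g: tuple(config.gns_null_alleles[g]) for g in line_ids}
    return {g: (rng.random() < config.gns_null_p, rng.random() < config.gns_null_p) for g in line_ids}


def _replicate_counts(pedigree: Pedigree, config: SimulationConfig, rng) -> dict[str, int]:
    return {
        gid: (4 if rng.random() < config.p_four_replicates else 3)
        for gid in pedigree.genotypes
    }


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Multiplicative, mean-one, strictly positive replicate noise."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_concentrations(
    config: SimulationConfig | None = None, pedigree: Pedigree | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Replicate-level concentration panel plus its ground truth."""
    config = config or SimulationConfig()
    pedigree = pedigree or simulate_pedigree(config)
    rng = _rng(config, 2)
    comps = analytes()
    names = [c.abbreviation for c in comps]
    missing = set(names) - set(config.line_ranges)
    if missing:
        raise ValueError(f"line_ranges missing compounds: {sorted(missing)}")

    line_ids = [g.genotype_id for g in pedigree.lines]
    n4high = int(round(config.cluster_fraction * len(line_ids)))
    order = rng.permutation(len(line_ids))
    group_4c_high = {line_ids[i] for i in order[:n4high]}
    loci = _gns_loci(config, line_ids, rng)

    # true line means
    means = pd.DataFrame(0.0, index=list(pedigree.genotypes), columns=names)
    for gid in line_ids:
        high4 = gid in group_4c_high
        for c in comps:
            lo, hi = config.line_ranges[c.abbreviation]
            if c.gsl_class is GSLClass.ALIPHATIC_4C:
                lo, hi = _sub_range(lo, hi, config.cluster_separation, high=high4)
            elif c.gsl_class is GSLClass.ALIPHATIC_3C:
                lo, hi = _sub_range(lo, hi, config.cluster_separation, high=not high4)
            means.loc[gid, c.abbreviation] = rng.uniform(lo, hi)
        if loci[gid][0] or loci[gid][1]:
            means.loc[gid, "GNS"] = 0.0  # homozygous null at a pathway locus

    # true hybrid means: multiplicative heterosis around the MPV
    for hyb in pedigree.hybrids:
        mother, father = pedigree.parents_of(hyb.genotype_id)
        mpv = (means.loc[mother] + means.loc[father]) / 2.0
        for name in names:
            delta = config.hybrid_delta.get(name, 0.0)
            means.loc[hyb.genotype_id, name] = (1.0 + delta) * mpv[name]
        # two-locus complementation for GNS
        null_same_locus = any(loci[mother][k] and loci[father][k] for k in (0, 1))
        if null_same_locus:
            means.loc[hyb.genotype_id, "GNS"] = 0.0
        elif means.loc[hyb.genotype_id, "GNS"] == 0.0:
            # parents null at different loci: complementation restores GNS
            lo, hi = config.line_ranges["GNS"]
            means.loc[hyb.genotype_id, "GNS"] = rng.uniform(lo, hi)

    # commercial checks: line-like profiles, no pedigree
    for chk in pedigree.commercial_hybrids:
        for c in comps:
            lo, hi = config.line_ranges[c.abbreviation]
            means.loc[chk.genotype_id, c.abbreviation] = rng.uniform(lo, hi)

    # replicate-level panel with lognormal noise
    counts = _replicate_counts(pedigree, config, rng)
    rows = []
    for gid in means.index:
        n_rep = counts[gid]
        noise = _lognormal_noise(rng, config.replicate_cv, (n_rep, len(names)))
        for r in range(n_rep):
            for j, name in enumerate(names):
                rows.append(
                    {
                        "genotype_id": gid,
                        "replicate": r + 1,
                        "compound": name,
                        "umol_per_g_dw": float(means.loc[gid, name] * noise[r, j]),
                    }
                )
    panel = pd.DataFrame(rows)

    # true per-compound median MPH across hybrids
    mph_rows = {}
    for name in names:
        vals = []
        for hyb in pedigree.hybrids:
            mother, father = pedigree.parents_of(hyb.genotype_id)
            mpv = (means.loc[mother, name] + means.loc[father, name]) / 2.0
            if mpv > 0:
                vals.append(100.0 * (means.loc[hyb.genotype_id, name] - mpv) / mpv)
        mph_rows[name] = float(np.median(vals)) if vals else float("nan")

    labels = pd.Series(
        {
            gid: (2 if means.loc[gid, [c.abbreviation for c in comps if c.gsl_class is GSLClass.ALIPHATIC_4C]].sum()
                  > means.loc[gid, [c.abbreviation for c in comps if c.gsl_class is GSLClass.ALIPHATIC_3C]].sum()
                  else 1)
            for gid in means.index
        },
        name="planted_cluster",
    )
    truth = SimulationTruth(
        genotype_means=means,
        median_mph=pd.Series(mph_rows, name="median_mph"),
        cluster_labels=labels,
        gns_loci=loci,
    )
    return panel, truth


def simulate_agronomic(
    config: SimulationConfig | None = None, pedigree: Pedigree | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait panel with uniformly positive planted heterosis.

    Returns (panel, true genotype × trait means). Checks behave like strong
    hybrids: line-range baseline scaled by (1 + δ_trait).
    """
    config = config or SimulationConfig()
    pedigree = pedigree or simulate_pedigree(config)
    rng = _rng(config, 4)
    traits = list(TRAIT_CODES)
    means = pd.DataFrame(0.0, index=list(pedigree.genotypes), columns=traits)
    for gid in [g.genotype_id for g in pedigree.lines]:
        for t in traits:
            lo, hi = config.trait_ranges[t]
            means.loc[gid, t] = rng.uniform(lo, hi)
    for hyb in pedigree.hybrids:
        mother, father = pedigree.parents_of(hyb.genotype_id)
        mpv = (means.loc[mother] + means.loc[father]) / 2.0
        for t in traits:
            means.loc[hyb.genotype_id, t] = (1.0 + config.trait_delta[t]) * mpv[t]
    for chk in pedigree.commercial_hybrids:
        for t in traits:
            lo, hi = config.trait_ranges[t]
            means.loc[chk.genotype_id, t] = (1.0 + config.trait_delta[t]) * rng.uniform(lo, hi)

    counts = _replicate_counts(pedigree, config, rng)
    rows = []
    for gid in means.index:
        n_rep = counts[gid]
        noise = _lognormal_noise(rng, config.replicate_cv, (n_rep, len(traits)))
        for r in range(n_rep):
            for j, t in enumerate(traits):
                rows.append(
                    {
                        "genotype_id": gid,
                        "replicate": r + 1,
                        "trait": t,
                        "value": float(means.loc[gid, t] * noise[r, j]),
                    }
                )
    return pd.DataFrame(rows), means


def calibration_table(config: SimulationConfig | None = None) -> pd.DataFrame:
    config = config or SimulationConfig()
    return pd.DataFrame(
        {
            "compound": list(config.calibration_slopes),
            "slope": list(config.calibration_slopes.values()),
            "intercept": 0.0,
            "n_points": 6,
            "r2": 1.0,
        }
    )


def simulate_peak_areas(
    panel: pd.DataFrame, config: SimulationConfig | None = None
) -> tuple[list[MrmSample], pd.DataFrame]:
    """Forward MRM model: exact inverse of the quantification equations.

    area_analyte = slope_analyte × nmol_in_sample × (1 + noise) with
    nmol = concentration[µmol g⁻¹] × 1000 × dry_mass[g]; the IS area comes
    from its own slope and the spiked 25 nmol. With ``area_cv = 0`` the
    quantifier reproduces the input panel to floating-point accuracy.
    """
    config = config or SimulationConfig()
    rng = _rng(config, 3)
    slopes = config.calibration_slopes
    is_abbr = build_registry()[-1].abbreviation  # GTP
    samples = []
    for (gid, rep), sub in panel.groupby(["genotype_id", "replicate"], sort=False):
        areas = {}
        for _, row in sub.iterrows():
            comp = row["compound"]
            nmol = row["umol_per_g_dw"] * 1000.0 * config.dry_mass_g
            noise = 1.0 + (rng.normal(0.0, config.area_cv) if config.area_cv > 0 else 0.0)
            areas[comp] = slopes[comp] * nmol * max(noise, 0.0)
        is_noise = 1.0 + (rng.normal(0.0, config.area_cv) if config.area_cv > 0 else 0.0)
        areas[is_abbr] = slopes[is_abbr] * config.is_amount_nmol * max(is_noise, 1e-6)
        samples.append(
            MrmSample(
                sample_id=f"{gid}_r{rep}",
                genotype_id=str(gid),
                replicate_index=int(rep),
                areas=areas,
                dry_mass_g=config.dry_mass_g,
                is_amount_nmol=config.is_amount_nmol,
            )
        )
    return samples, calibration_table(config)


def simulate_calibration_standards(
    slopes: dict[str, float],
    n_points: int = 6,
    max_nmol: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear standard series (compound, nmol, area) for curve-fitting tests."""
    rng = np.random.default_rng(seed)
    levels = np.linspace(max_nmol / n_points, max_nmol, n_points)
    rows = []
    for comp, slope in slopes.items():
        areas = slope * levels + rng.normal(0.0, noise_sd, size=n_points)
        rows += [{"compound": comp, "nmol": float(x), "area": float(a)} for x, a in zip(levels, areas)]
    return pd.DataFrame(rows)


def noise_free(config: SimulationConfig | None = None) -> SimulationConfig:
    """Copy of a config with all stochastic noise switched off."""
    config = config or SimulationConfig()
    return replace(config, replicate_cv=0.0, area_cv=0.0)
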