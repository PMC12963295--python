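"""End-to-end orchestration: simulate → quantify → profile → heterosis →
predict → compare, with a JSON manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import agronomic_summary, compare_concentrations
from .composition import (
    hierarchical_cluster,
    pca,
    replace_zeros,
    spearman_matrix,
    standardize,
)
from .heterosis import bootstrap_table, heterosis_table, mph_summary, standardized_mph_matrix
from .panels import genotype_means, total_gsl, validate_concentration_panel
from .pedigree import Pedigree
from .prediction import parent_hybrid_regressions, regressions_frame
from .quantification import quantify_batch
from .registry import registry_frame
from .simulate import (
    SimulationConfig,
    simulate_agronomic,
    simulate_concentrations,
    simulate_peak_areas,
    simulate_pedigree,
)

log = logging.getLogger("glshet")


@dataclass
class RunConfig:
    """Knobs for one reproducible pipeline run."""

    seed: int = 0
    B: int = 1000
    alpha: float = 0.05
    delta_fraction: float = 0.65
    linkage_method: str = "ward"
    k: int = 2
    include_checks_in_tests: bool = True
    prediction_interval: bool = False
    pca_scale_mode: str = "zscore"
    out_dir: str = "results"
    concentrations_path: str | None = None  # skip simulation/quantification if given
    genotypes_path: str | None = None
    traits_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.B < 100:
            raise ValueError("B must be at least 100")
        if self.concentrations_path and not self.genotypes_path:
            raise ValueError("a concentrations file requires a genotypes file")


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")
    manifest["outputs"][path.name] = int(len(df))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write CSV outputs plus manifest.json.

    Identical config + seed yields byte-identical outputs. Returns a dict
    with the key tables and the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "outputs": {},
        "notes": {},
    }

    if config.concentrations_path:
        log.info("stage simulate/quantify: skipped, reading concentrations from disk")
        panel = pd.read_csv(config.concentrations_path)
        pedigree = Pedigree.from_frame(pd.read_csv(config.genotypes_path))
        traits = pd.read_csv(config.traits_path) if config.traits_path else None
    else:
        sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
        # dataclass asdict loses nothing here: SimulationConfig is flat
        pedigree = simulate_pedigree(sim)
        true_panel, truth = simulate_concentrations(sim, pedigree)
        samples, calibration = simulate_peak_areas(true_panel, sim)
        panel, failures = quantify_batch(samples, calibration)
        traits, _ = simulate_agronomic(sim, pedigree)
        manifest["notes"]["n_quantification_failures"] = int(len(failures))
        _write(registry_frame(), out / "compounds.csv", manifest)
        _write(pedigree.to_frame(), out / "genotypes.csv", manifest)
        _write(calibration, out / "calibration.csv", manifest)
        _write(true_panel, out / "concentrations_true.csv", manifest)
        truth.genotype_means.to_csv(out / "truth_means.csv", float_format="%.10g")
        manifest["outputs"]["truth_means.csv"] = int(len(truth.genotype_means))

    validate_concentration_panel(panel)
    _write(panel, out / "concentrations.csv", manifest)
    if traits is not None:
        _write(traits, out / "traits.csv", manifest)

    log.info("stage composition")
    means = genotype_means(panel).mean
    comp = replace_zeros(means, config.delta_fraction)
    clust = hierarchical_cluster(comp, linkage_method=config.linkage_method, k=config.k)
    dist = clust.distances.copy()
    dist.index.name, dist.columns.name = "genotype_a", "genotype_b"
    dist_long = dist.stack().rename("aitchison").reset_index()
    _write(dist_long, out / "distances.csv", manifest)
    _write(clust.labels.rename_axis("genotype_id").reset_index(), out / "clusters.csv", manifest)
    _write(standardize(means).rename_axis("genotype_id").reset_index(), out / "zscores.csv", manifest)
    spear = spearman_matrix(means)
    _write(spear.rename_axis("compound").reset_index(), out / "spearman.csv", manifest)
    p = pca(means, scale_mode=config.pca_scale_mode)
    _write(p.scores.rename_axis("genotype_id").reset_index(), out / "pca_scores.csv", manifest)
    _write(p.loadings.rename_axis("compound").reset_index(), out / "pca_loadings.csv", manifest)
    _write(
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(p.variance_fractions))],
             "variance_fraction": p.variance_fractions}
        ),
        out / "pca_variance.csv",
        manifest,
    )

    log.info("stage heterosis")
    table = heterosis_table(panel, pedigree)
    n_undefined = int((~table["defined"]).sum())
    manifest["notes"]["n_undefined_mph_cells"] = n_undefined
    _write(table, out / "mph.csv", manifest)
    _write(mph_summary(table), out / "mph_summary.csv", manifest)
    _write(bootstrap_table(table, B=config.B, alpha=config.alpha, seed=config.seed),
           out / "bootstrap_ci.csv", manifest)
    zmph = standardized_mph_matrix(table)
    _write(zmph.rename_axis("hybrid_id").reset_index(), out / "mph_zscores.csv", manifest)

    log.info("stage prediction")
    regs = parent_hybrid_regressions(
        panel, pedigree, alpha=config.alpha, prediction_interval=config.prediction_interval
    )
    _write(regressions_frame(regs), out / "regression.csv", manifest)
    bands = pd.concat(
        [r.band.assign(trait=t) for t, r in regs.items() if r.fittable], ignore_index=True
    )
    _write(bands, out / "bands.csv", manifest)

    log.info("stage compare")
    tests = compare_concentrations(
        panel, pedigree, alpha=config.alpha, include_checks=config.include_checks_in_tests
    )
    _write(tests, out / "group_tests.csv", manifest)
    agro = None
    if traits is not None:
        agro = agronomic_summary(
            traits, pedigree, alpha=config.alpha, include_checks=config.include_checks_in_tests
        )
        _write(agro["tests"], out / "agronomic_tests.csv", manifest)
        _write(agro["zscores"].rename_axis("genotype_id").reset_index(),
               out / "agronomic_zscores.csv", manifest)

    digest = hashlib.sha256()
    for name in sorted(manifest["outputs"]):
        digest.update((out / name).read_bytes())
    manifest["content_sha256"] = digest.hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d outputs to %s", len(manifest["outputs"]), out)

    return {
        "pedigree": pedigree,
        "panel": panel,
        "means": means,
        "clustering": clust,
        "pca": p,
        "spearman": spear,
        "mph": table,
        "regressions": regs,
        "group_tests": tests,
        "agronomic": agro,
        "manifest": manifest,
    }
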