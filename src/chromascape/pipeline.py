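"""End-to-end orchestration: simulate -> metrics -> models -> report.

Stages communicate only through documented file formats (CSV, GeoJSON,
Newick, JSON) so real data can replace any synthetic stage.  A run is a
pure function of its configuration and seed: identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colours, landscape, models, phylo, simulate
from .errors import ChromascapeError, InvalidParameterError

logger = logging.getLogger("chromascape.pipeline")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "chromascape_run"
    seed: int = 0
    n_species: int = 80
    n_sites: int = 500
    alpha: float = 0.05
    unbiased_gini: bool = True
    habitat_reference: str | None = None
    mantel_permutations: int = 999
    mantel_responses: tuple = ("gini", "black", "grey", "white")
    affinity_strength: float = 1.5
    richness_target: float = 17.7
    tree_set: tuple = ((11, 7), (23, 3))  # (topology-seed, count) pairs
    # when set, these input files replace the corresponding synthetic stage
    colour_table_path: str | None = None
    community_path: str | None = None
    patches_path: str | None = None
    trees_path: str | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.mantel_permutations < 1:
            raise InvalidParameterError("mantel_permutations must be >= 1")
        for name in ("colour_table_path", "community_path", "patches_path", "trees_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InvalidParameterError(f"{name} does not exist: {p}")

    def scenario(self) -> simulate.SyntheticScenario:
        return simulate.SyntheticScenario(
            seed=self.seed,
            n_species=self.n_species,
            n_sites=self.n_sites,
            affinity_strength=self.affinity_strength,
            richness_target=self.richness_target,
        )


def _stage(name: str):
    logger.info("[%s] starting", name)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the JSON-serializable run summary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario()

    # --- stage: simulate / load inputs -------------------------------------
    _stage("simulate")
    if config.colour_table_path:
        colour_table = colours.load_colour_table(config.colour_table_path)
    else:
        colour_table = simulate.gen_colour_table(config.n_species, seed=config.seed)
        _write_csv(colour_table, out / "colour_table.csv")

    if config.trees_path:
        trees = phylo.read_trees(config.trees_path)
    else:
        trees = simulate.gen_tree_set(
            config.n_species, list(config.tree_set), seed=config.seed
        )
        phylo.write_trees(trees, out / "trees.nwk")

    if config.patches_path:
        patches_by_site = landscape.patches_from_geojson(config.patches_path)
        coord_table = None
        truth = None
    else:
        patches_by_site, coord_table, truth = simulate.gen_landscape(scenario)
        all_patches = [p for ps in patches_by_site.values() for p in ps]
        landscape.patches_to_geojson(all_patches, out / "patches.geojson")

    # --- stage: landscape metrics ------------------------------------------
    _stage("landscape")
    comps = [
        landscape.buffer_composition(patches)
        for patches in patches_by_site.values()
    ]
    site_metrics = landscape.site_metrics_table(comps)
    if coord_table is not None:
        site_metrics = site_metrics.join(coord_table)

    # --- stage: communities -------------------------------------------------
    if config.community_path:
        community = pd.read_csv(config.community_path, index_col="site_id")
        coord_cols = [c for c in ("lon", "lat") if c in community.columns]
        if coord_cols and "lon" not in site_metrics.columns:
            site_metrics = site_metrics.join(community[coord_cols])
        community = community.drop(columns=coord_cols)
    else:
        mcc_for_sim = trees[0]
        community, truth = simulate.gen_communities(
            colour_table,
            mcc_for_sim,
            site_metrics["habitat"],
            scenario,
        )
        with_coords = community.copy()
        with_coords.insert(0, "lat", site_metrics["lat"])
        with_coords.insert(0, "lon", site_metrics["lon"])
        _write_csv(with_coords, out / "community.csv")
        truth.to_json(out / "ground_truth.json")
    site_metrics["richness"] = community.sum(axis=1)

    # --- stage: colour composition -----------------------------------------
    _stage("colours")
    composition = colours.community_composition_table(
        community, colour_table, unbiased_gini=config.unbiased_gini
    )
    _write_csv(composition, out / "composition.csv")

    # --- stage: phylogenetic metrics ---------------------------------------
    _stage("phylo")
    mcc = phylo.max_clade_credibility(trees)
    phylo.write_trees([mcc], out / "mcc.nwk")
    site_metrics["psv"] = phylo.psv_table(community, mcc)
    _write_csv(site_metrics, out / "site_metrics.csv")

    merged = site_metrics.join(composition)

    # --- stage: association models -----------------------------------------
    _stage("fit")
    mantel = models.mantel_screen(
        merged,
        list(config.mantel_responses),
        n_perm=config.mantel_permutations,
        seed=config.seed,
    )
    _write_csv(mantel, out / "mantel.csv")

    results = []
    for colour in colours.COLOURS:
        spec = models.ModelSpec(
            response=colour,
            predictors=models.COLOUR_PREDICTORS,
            reference=config.habitat_reference,
        )
        results.append(models.fit_colour_glm(merged, spec))
    gini_spec = models.ModelSpec(
        response="gini",
        predictors=models.INEQUALITY_PREDICTORS,
        reference=config.habitat_reference,
    )
    gini_glm = models.fit_colour_glm(merged, gini_spec)
    results.append(gini_glm)
    mixed_spec = models.ModelSpec(
        response="gini",
        predictors=models.INEQUALITY_PREDICTORS,
        random_intercept=True,
    )
    gini_glmm = models.fit_inequality_mixed(merged, mixed_spec)

    for res in results:
        _write_csv(res.terms, out / f"model_{res.response}.csv")
    _write_csv(gini_glmm.terms, out / "model_gini_glmm.csv")

    table = models.sign_table(results, alpha=config.alpha)
    _write_csv(table, out / "sign_table.csv")

    # --- stage: report ------------------------------------------------------
    _stage("report")
    summary = {
        "config": dataclasses.asdict(config),
        "software": {
            "python": sys.version.split()[0],
            "chromascape": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_sites": int(community.shape[0]),
        "n_species": int(community.shape[1]),
        "mean_richness": float(site_metrics["richness"].mean()),
        "mean_gini": float(composition["gini"].mean()),
        "mean_psv": float(site_metrics["psv"].mean()),
        "habitat_counts": site_metrics["habitat"].value_counts().to_dict(),
        "glmm_r_squared": gini_glmm.r_squared,
        "glmm_variance_components": gini_glmm.variance_components,
        "alpha": config.alpha,
        "habitat_reference": gini_glm.reference,
        "family": gini_glm.family,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _version() -> str:
    try:
        return importlib.metadata.version("chromascape")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def validate_inputs(
    colour_table_path=None,
    community_path=None,
    trees_path=None,
    patches_path=None,
) -> list[str]:
    """Schema checks across input files; returns a list of violations."""
    violations: list[str] = []
    colour_table = None
    community = None
    if colour_table_path:
        try:
            colour_table = pd.read_csv(colour_table_path, index_col="species_id")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            violations.append(f"colour_table: unreadable ({exc})")
        else:
            missing = [c for c in colours.COLOURS if c not in colour_table.columns]
            if missing:
                violations.append(f"colour_table: missing colour columns {missing}")
            else:
                sums = colour_table[list(colours.COLOURS)].sum(axis=1)
                bad = colour_table.index[(sums - 100).abs() > 0.5].tolist()
                if bad:
                    violations.append(
                        f"colour_table: profiles not summing to ~100: {bad[:5]}"
                    )
    if community_path:
        try:
            community = pd.read_csv(community_path, index_col="site_id")
        except Exception as exc:  # noqa: BLE001
            violations.append(f"community: unreadable ({exc})")
        else:
            species_cols = [c for c in community.columns if c not in ("lon", "lat")]
            values = community[species_cols].to_numpy()
            if not np.isin(values, (0, 1)).all():
                violations.append("community: non-binary presence values")
            if colour_table is not None:
                unknown = [
                    s for s in species_cols if s not in colour_table.index
                ]
                if unknown:
                    violations.append(
                        f"community: species absent from colour table: {unknown[:5]}"
                    )
    if trees_path:
        try:
            trees = phylo.read_trees(trees_path)
        except Exception as exc:  # noqa: BLE001
            violations.append(f"trees: unreadable ({exc})")
        else:
            if community is not None and trees:
                tips = {t.taxon.label for t in trees[0].leaf_node_iter()}
                species_cols = [
                    c for c in community.columns if c not in ("lon", "lat")
                ]
                uncovered = [s for s in species_cols if s not in tips]
                if uncovered:
                    violations.append(
                        f"trees: tips do not cover species: {uncovered[:5]}"
                    )
    if patches_path:
        try:
            landscape.patches_from_geojson(patches_path)
        except (ChromascapeError, OSError, KeyError, ValueError) as exc:
            violations.append(f"patches: invalid ({exc})")
    return violations
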