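"""Configuration-driven orchestration of the full analysis.

One YAML config describes either a synthetic world (the default) or
paths to real inputs, plus the analysis options; ``run_pipeline``
executes world construction, grid assembly, imputation and signal
tests, diversity layers (TD, SES-MPD/NRI, decoupled FDis), the
random-forest stability layer, VIF screening and CAR/OLS models per
biome and metric, and the ecotone permutation tests, writing a bundle
of CSV/JSON results with full provenance (config hash and per-stage
seeds derived from the master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, ecotone, functional, io, phylo, spatial, stability, synthetic
from .grid import DiversityLayer, GridSpec

log = logging.getLogger("griddiv")

__all__ = ["PipelineConfig", "ResultBundle", "validate_config", "run_pipeline",
           "load_config", "derive_seed"]

STAGES = ("simulate", "assemble", "diversity", "stability", "model", "ecotone")

DEFAULT_SYNTHETIC = {
    "grid": {"n_rows": 20, "n_cols": 24, "cell_size": 0.5, "origin": [-70.0, 0.0]},
    "n_species": 60,
    "n_biomes": 3,
    "outside_cols": 4,
    "n_slices": 31,
    "spatial_range": 3.0,
    "temporal_drift": 0.05,
    "temporal_noise": 0.0,
    "niche_breadth": 1.2,
    "missing_fraction": 0.165,
    "layers": ["bio01", "bio12", "bio17", "pet", "elevation"],
    "n_quant": 3,
    "quant_names": ["svl", "head_width", "tibia_length"],
    "categorical": {
        "development": [["direct", "indirect"], 0.3],
        "tadpole": [["endotrophic-nonhatched", "endotrophic-free", "exotrophic"], 0.3],
    },
}

DEFAULT_ANALYSIS = {
    "n_null": 199,           # SES-MPD null draws
    "n_signal_reps": 199,    # signal-test randomisations
    "n_perm": 999,           # ecotone permutations
    "n_boot": 999,           # bootstrap CI resamples
    "adjacency": "queen",
    "vif_threshold": 3.0,
    "buffer": 3,
    "stability_threshold": 0.5,
    "n_trees": 200,
    "n_pseudo_absences": None,  # default: all eligible outside cells
    "pd_metric": "nri",         # which PD variant feeds the models
    "predictors": None,         # default: climate + terrain + stability
    "phylo_axes_mass": 0.95,    # eigenvalue mass kept when decoupling FD
}


@dataclass
class PipelineConfig:
    seed: int = 42
    output_dir: str = "griddiv_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    analysis: dict = field(default_factory=dict)

    def resolved_analysis(self) -> dict:
        out = dict(DEFAULT_ANALYSIS)
        out.update(self.analysis or {})
        return out

    def resolved_synthetic(self) -> dict:
        out = json.loads(json.dumps(DEFAULT_SYNTHETIC))
        out.update(self.synthetic or {})
        return out

    def content_hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "synthetic": self.synthetic, "inputs": self.inputs,
             "analysis": self.analysis},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(
        seed=int(raw.get("seed", 42)),
        output_dir=raw.get("output_dir", "griddiv_out"),
        synthetic=raw.get("synthetic"),
        inputs=raw.get("inputs"),
        analysis=raw.get("analysis", {}),
    )


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed into the master."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns error strings, never raises."""
    errors: list[str] = []
    if config.synthetic is not None and config.inputs is not None:
        errors.append("config sets both 'synthetic' and 'inputs'; exactly one allowed")
    if config.synthetic is None and config.inputs is None:
        return errors  # defaults to the synthetic world
    if config.inputs is not None:
        required = {"tree", "traits", "presence_or_ranges", "climate", "biomes", "grid"}
        missing = required - set(config.inputs)
        if missing:
            errors.append(f"inputs block missing keys: {sorted(missing)}")
        else:
            try:
                world = _load_world(config)
            except Exception as exc:  # content errors reported, not raised
                errors.append(f"failed to load inputs: {exc}")
                return errors
            tree_tips = set(phylo._leaf_labels(world["tree"]))
            for sp in world["traits"].species:
                if sp not in tree_tips:
                    errors.append(f"species {sp!r} in traits but not in tree")
            for sp in world["presence"].species_ids:
                if sp not in tree_tips:
                    errors.append(f"species {sp!r} in presence matrix but not in tree")
    an = config.resolved_analysis()
    if an["adjacency"] not in ("queen", "rook"):
        errors.append("analysis.adjacency must be 'queen' or 'rook'")
    if an["pd_metric"] not in ("nri", "ses"):
        errors.append("analysis.pd_metric must be 'nri' or 'ses'")
    return errors


@dataclass
class ResultBundle:
    """Everything the pipeline produced, plus provenance."""

    config_hash: str
    seeds: dict[str, int]
    layers: dict[str, DiversityLayer]
    missingness: dict
    signal_tests: pd.DataFrame
    importance: dict[str, pd.DataFrame]
    car_tables: pd.DataFrame
    car_meta: list[dict]
    ecotone_results: pd.DataFrame
    vif_log: dict[str, list]
    skipped: list[str]

    def bundle_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.layers):
            h.update(name.encode())
            h.update(np.nan_to_num(self.layers[name].values).tobytes())
        h.update(self.car_tables.to_csv().encode())
        h.update(self.ecotone_results.to_csv().encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# world construction / loading
# ---------------------------------------------------------------------------

def _build_synthetic_world(config: PipelineConfig) -> dict:
    syn = config.resolved_synthetic()
    g = syn["grid"]
    grid = GridSpec(g["n_rows"], g["n_cols"], g.get("cell_size", 0.5),
                    tuple(g.get("origin", (0.0, 0.0))))
    seeds = {s: derive_seed(config.seed, s) for s in
             ("tree", "traits", "mask", "climate", "biomes", "ranges")}
    tree = synthetic.generate_phylogeny(syn["n_species"], seeds["tree"])
    cat_spec = {
        name: (list(states), float(rate))
        for name, (states, rate) in syn["categorical"].items()
    }
    traits = synthetic.simulate_traits(
        tree, syn["n_quant"], sigma2=1.0, categorical_spec=cat_spec,
        seed=seeds["traits"], quant_names=syn["quant_names"],
    )
    traits_masked = synthetic.mask_trait_values(
        traits, syn["missing_fraction"], seeds["mask"]
    )
    stack = synthetic.generate_climate_stack(
        grid, syn["layers"], syn["n_slices"],
        spatial_range=syn["spatial_range"],
        temporal_drift=syn["temporal_drift"],
        temporal_noise=syn.get("temporal_noise", 0.0),
        seed=seeds["climate"],
        gradient={"bio01": 2.0},  # west-east gradient aligns biome bands with climate
    )
    if "elevation" in stack.layer_names:
        terr = synthetic.derive_terrain(
            grid.to_array(stack.layer("elevation")), cell_size=grid.cell_size
        )
        for name in ("slope", "aspect", "roughness"):
            stack = stack.with_layer(name, terr[name].ravel())
    biomes = synthetic.generate_biome_map(
        grid, syn["n_biomes"], seed=seeds["biomes"],
        outside_cols=syn["outside_cols"],
    )
    ranges = synthetic.generate_ranges(
        grid, tree, stack.layer("bio01"), niche_breadth=syn["niche_breadth"],
        seed=seeds["ranges"],
    )
    return {"grid": grid, "tree": tree, "traits": traits_masked, "stack": stack,
            "biomes": biomes, "ranges": ranges, "seeds": seeds}


def _load_world(config: PipelineConfig) -> dict:
    paths = config.inputs
    g = paths["grid"]
    grid = GridSpec(g["n_rows"], g["n_cols"], g.get("cell_size", 0.5),
                    tuple(g.get("origin", (0.0, 0.0))))
    tree = io.read_tree(paths["tree"])
    from .traits import TraitTable

    traits = TraitTable.from_csv(
        paths["traits"],
        quantitative=paths.get("quantitative_traits", []),
        categorical=paths.get("categorical_traits", []),
    )
    stack = io.climate_from_csv(paths["climate"], grid)
    biomes = io.biomes_from_csv(paths["biomes"], grid)
    por = paths["presence_or_ranges"]
    if paths.get("kind", "ranges") == "presence":
        presence = assembly.PresenceMatrix.from_csv(por, grid)
    else:
        presence = assembly.rasterize_ranges(io.ranges_from_csv(por, grid), grid)
    return {"grid": grid, "tree": tree, "traits": traits, "stack": stack,
            "biomes": biomes, "presence": presence, "seeds": {}}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, write: bool = True) -> ResultBundle:
    """Execute all stages and (optionally) write the results bundle."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    an = config.resolved_analysis()
    t0 = time.time()
    skipped: list[str] = []

    # -- stage: simulate / ingest ------------------------------------------
    if config.inputs is not None:
        world = _load_world(config)
        presence = world["presence"]
    else:
        world = _build_synthetic_world(config)
        presence = assembly.rasterize_ranges(world["ranges"], world["grid"])
    grid, tree, stack, biomes = (world["grid"], world["tree"], world["stack"],
                                 world["biomes"])
    seeds = dict(world["seeds"])
    log.info("world ready (%.1fs): %d cells, %d species, %d slices",
             time.time() - t0, grid.n_cells, presence.n_species, stack.n_slices)

    # analysis mask: cells inside any modelled biome
    biome_mask = np.isin(biomes.labels, biomes.biomes)

    # -- stage: assemble ----------------------------------------------------
    missingness = assembly.missingness_summary(world["traits"])
    td = assembly.taxonomic_diversity(presence, mask=biome_mask)

    # -- stage: imputation + signal ----------------------------------------
    seeds["signal"] = derive_seed(config.seed, "signal")
    traits_full = phylo.impute_traits(tree, world["traits"])
    signal_rows = []
    _, C = phylo.phylo_covariance(tree, phylo._leaf_labels(tree))
    for tr in traits_full.quantitative:
        res = phylo.blomberg_k(
            tree, traits_full.data[tr], n_reps=an["n_signal_reps"],
            seed=seeds["signal"], _cov=C,
        )
        signal_rows.append({"trait": tr, "statistic": res.statistic,
                            "method": res.method, "p_value": res.p_value})
    for tr in traits_full.categorical:
        res = phylo.categorical_signal(
            tree, traits_full.data[tr], n_reps=an["n_signal_reps"],
            seed=seeds["signal"],
        )
        signal_rows.append({"trait": tr, "statistic": res.statistic,
                            "method": res.method, "p_value": res.p_value})
    signal_tests = pd.DataFrame(signal_rows)

    # -- stage: diversity ---------------------------------------------------
    seeds["ses"] = derive_seed(config.seed, "ses")
    labels, D = phylo.cophenetic_matrix(tree)
    # regional pool: species occurring inside the modelled biomes; species
    # confined to the outside band carry no within-biome occurrences, so
    # dropping their columns leaves every analysed community unchanged
    pool = [sp for sp in presence.species_ids
            if presence.column(sp)[biome_mask].any()]
    pool_cols = [presence.species_ids.index(sp) for sp in pool]
    pool_matrix = assembly.PresenceMatrix(
        grid, pool, presence.values[:, pool_cols]
    )
    ses = phylo.ses_mpd(pool_matrix, (labels, D), pool=pool,
                        n_null=an["n_null"], seed=seeds["ses"])
    pd_layer = ses.layer(an["pd_metric"])
    pd_layer.values[~biome_mask] = np.nan

    gow_species, G = functional.gower(traits_full)
    Dsub = D[np.ix_(
        [labels.index(sp) for sp in gow_species],
        [labels.index(sp) for sp in gow_species],
    )]
    phylo_ord = functional.pcoa(Dsub, correction="none", species=gow_species)
    n_sp = len(gow_species)
    # retain the leading phylogenetic axes covering a set fraction of the
    # positive eigenvalue mass; using all n-1 axes would saturate the
    # regression and force the residual space (hence FDis) to zero
    pos = phylo_ord.eigenvalues[phylo_ord.eigenvalues > 0]
    mass = np.cumsum(pos) / pos.sum()
    n_axes = int(np.searchsorted(mass, an["phylo_axes_mass"]) + 1)
    n_axes = min(n_axes, phylo_ord.coordinates.shape[1], max(n_sp - 2, 1))
    resid_space = functional.decouple(
        G, phylo_ord, species=gow_species, max_predictors=n_axes,
    )
    fd = functional.functional_dispersion(presence, resid_space)
    fd.values[~biome_mask] = np.nan
    log.info("diversity layers done (%.1fs)", time.time() - t0)

    # -- stage: stability ---------------------------------------------------
    seeds["stability"] = derive_seed(config.seed, "stability")
    region = np.ones(grid.n_cells, dtype=bool)
    n_outside = int(np.sum(biomes.labels == synthetic.OUTSIDE))
    stab_layers: dict[str, stability.StabilityLayer] = {}
    importance: dict[str, pd.DataFrame] = {}
    clim_predictors = [l for l in stack.layer_names if l not in
                       ("slope", "aspect", "roughness")]
    if n_outside == 0:
        skipped.append("stability: no cells outside the modelled biomes "
                       "for pseudo-absence sampling")
    else:
        n_pa = an["n_pseudo_absences"] or n_outside
        pa = stability.sample_pseudo_absences(region, biomes, min(n_pa, n_outside),
                                              seed=seeds["stability"])
        for biome in biomes.biomes:
            pts = stability.make_training_points(biomes, stack, biome, pa,
                                                 predictors=clim_predictors)
            clf = stability.fit_biome_classifier(pts, n_trees=an["n_trees"],
                                                 seed=seeds["stability"])
            binary, _ = stability.project_slices(clf, stack,
                                                 threshold=an["stability_threshold"])
            stab_layers[biome] = stability.stability(binary, grid)
            importance[biome] = clf.importance
        log.info("stability layers done (%.1fs)", time.time() - t0)

    # -- stage: models ------------------------------------------------------
    car_rows, car_meta = [], []
    vif_log: dict[str, list] = {}
    metric_layers = {"TD": td, "PD": pd_layer, "FD": fd}
    candidate = an["predictors"] or [l for l in stack.layer_names
                                     if l != "elevation"]
    for biome in biomes.biomes:
        cells = biomes.cells_of(biome)
        Xall = pd.DataFrame(
            {name: stack.layer(name)[cells] for name in candidate},
            index=cells,
        )
        if biome in stab_layers:
            Xall["stability"] = stab_layers[biome].values[cells]
        Xall = Xall.loc[:, Xall.std(ddof=0) > 0]
        try:
            Xkeep, removed = spatial.vif_filter(Xall, threshold=an["vif_threshold"])
        except ValueError as exc:
            skipped.append(f"model[{biome}]: {exc}")
            continue
        vif_log[biome] = removed
        Xz = spatial.standardize(Xkeep)
        for metric, layer in metric_layers.items():
            y = layer.values[cells]
            ok = ~np.isnan(y)
            if ok.sum() <= Xz.shape[1] + 2 or np.nanstd(y[ok]) == 0:
                skipped.append(f"model[{biome}/{metric}]: too few defined cells")
                continue
            use_cells = cells[ok]
            W = spatial.build_adjacency(grid, use_cells, scheme=an["adjacency"])
            Xm = spatial.standardize(Xkeep.loc[use_cells])
            try:
                car = spatial.fit_car(y[ok], Xm, W)
                ols_tab, ols_r2 = spatial.fit_ols_standardized(y[ok], Xm)
            except ValueError as exc:
                skipped.append(f"model[{biome}/{metric}]: {exc}")
                continue
            for var in Xm.columns:
                car_rows.append({
                    "biome": biome, "metric": metric, "variable": var,
                    "beta": car.params.loc[var, "beta"],
                    "p": car.params.loc[var, "p"],
                    "beta_ols": ols_tab.loc[var, "beta"],
                    "p_ols": ols_tab.loc[var, "p"],
                })
            car_meta.append({"biome": biome, "metric": metric,
                             **car.to_json_dict(), "r2_ols": ols_r2})
    car_tables = pd.DataFrame(car_rows)
    log.info("models done (%.1fs)", time.time() - t0)

    # -- stage: ecotone -----------------------------------------------------
    seeds["ecotone"] = derive_seed(config.seed, "ecotone")
    eco_rows = []
    biome_list = biomes.biomes
    if len(biome_list) < 2:
        skipped.append("ecotone: fewer than two biomes, stage skipped")
    else:
        for focal in biome_list:
            for neighbor in biome_list:
                if focal == neighbor:
                    continue
                eco = ecotone.ecotone_cells(biomes, focal, neighbor)
                if len(eco) == 0:
                    continue
                core = ecotone.core_cells(biomes, focal, buffer=an["buffer"])
                # restrict to cells where FD is defined (occupied cells)
                eco.cells = eco.cells[~np.isnan(fd.values[eco.cells])]
                core.cells = core.cells[~np.isnan(fd.values[core.cells])]
                if len(eco) == 0 or len(core) == 0:
                    skipped.append(
                        f"ecotone[{focal}-{neighbor}]: empty ecotone or core "
                        f"after masking undefined FD"
                    )
                    continue
                res = ecotone.fd_permutation_test(
                    fd, eco, core, n_perm=an["n_perm"], seed=seeds["ecotone"],
                    n_boot=an["n_boot"],
                )
                eco_rows.append({"pair": f"{focal}-{neighbor}",
                                 "effect": res.difference,
                                 "ci_low": res.ci_low, "ci_high": res.ci_high,
                                 "p": res.p_upper, "p_two_sided": res.p_two_sided,
                                 "n_ecotone": res.n_ecotone, "n_core": res.n_core,
                                 "with_replacement": res.with_replacement})
    ecotone_results = pd.DataFrame(eco_rows)
    log.info("pipeline complete (%.1fs)", time.time() - t0)

    layers: dict[str, DiversityLayer] = {"TD": td, "PD": pd_layer, "FD": fd}
    for biome, sl in stab_layers.items():
        layers[f"stability_{biome}"] = sl.as_layer()

    bundle = ResultBundle(
        config_hash=config.content_hash(),
        seeds=seeds,
        layers=layers,
        missingness=missingness,
        signal_tests=signal_tests,
        importance=importance,
        car_tables=car_tables,
        car_meta=car_meta,
        ecotone_results=ecotone_results,
        vif_log=vif_log,
        skipped=skipped,
    )
    if write:
        _write_bundle(bundle, config, world, presence)
    return bundle


def _write_bundle(bundle: ResultBundle, config: PipelineConfig, world: dict,
                  presence) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, layer in bundle.layers.items():
        io.layer_to_csv(layer, out / f"layer_{name}.csv")
    presence.to_csv(out / "presence.csv")
    io.write_tree(world["tree"], out / "tree.nwk")
    world["traits"].to_csv(out / "traits.csv")
    io.biomes_to_csv(world["biomes"], out / "biomes.csv")
    bundle.signal_tests.to_csv(out / "signal_tests.csv", index=False)
    bundle.car_tables.to_csv(out / "car_models.csv", index=False)
    bundle.ecotone_results.to_csv(out / "ecotone_tests.csv", index=False)
    for biome, imp in bundle.importance.items():
        imp.to_csv(out / f"importance_{biome}.csv", index=False)
    manifest = {
        "config_hash": bundle.config_hash,
        "bundle_hash": bundle.bundle_hash(),
        "seeds": bundle.seeds,
        "missingness": bundle.missingness,
        "car_meta": bundle.car_meta,
        "vif_removed": bundle.vif_log,
        "skipped": bundle.skipped,
    }
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
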