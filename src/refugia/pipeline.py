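"""End-to-end orchestration: simulate a study system, run the genetic
landscape workflow, and run the distribution-modelling workflow.

Every run is a pure function of (config, seed) and writes plain-text
artifacts (FASTA, CSV, newick, GeoJSON, ESRI ASCII rasters, JSON manifests)
into a target directory, so reruns with the same config are reproducible
byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape as gl
from . import njtree, sdm, sequences, significance, synthetic
from .grid import (
    GridSpec,
    RasterStack,
    mask_to_polygon,
    read_ascii_grid,
    read_geojson,
    write_ascii_grid,
    write_geojson,
)

logger = logging.getLogger(__name__)

OUTGROUP_LABEL = "OUTGROUP"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Full parameterization of a synthetic study and both analysis arms.

    Defaults are the package's reference study conditions: a 60x60 grid of
    0.05-degree cells, five climate layers with a north-south gradient on
    the first, a glacial cooling shift on that same layer, two parapatric
    species, 18 populations of 5 individuals each per species, and planted
    contact-zone introgression at probability 0.5.
    """

    seed: int = 1
    grid: dict = field(
        default_factory=lambda: dict(
            n_rows=60, n_cols=60, origin_lon=0.0, origin_lat=40.0, cell_size=0.05
        )
    )
    climate: dict = field(
        default_factory=lambda: dict(
            n_layers=5,
            autocorr_length=8.0,
            inter_layer_corr=0.0,
            glacial_shift=[-1.0, 0.0, 0.0, 0.0, 0.0],
            gradient_weight=[1.5, 0.0, 0.0, 0.0, 0.0],
        )
    )
    species: dict = field(default_factory=lambda: dict(n_species=2, range_threshold=0.45))
    sequences: dict = field(
        default_factory=lambda: dict(
            n_pops_per_species=18,
            n_per_pop=5,
            seq_length=658,
            mut_rate=3.0,
            introgression_prob=0.5,
            species_divergence=40,
            outgroup_divergence=120,
        )
    )
    occurrences: dict = field(default_factory=lambda: dict(n_per_species=100))
    tree: dict = field(default_factory=lambda: dict(bootstrap_replicates=200))
    landscape: dict = field(
        default_factory=lambda: dict(idw_power=2.0, idw_k=12, exclusion="population")
    )
    sdm: dict = field(
        default_factory=lambda: dict(
            corr_threshold=0.7, buffer_km=50.0, n_background=400, beta=1.0, n_knots=4
        )
    )
    nulltest: dict = field(default_factory=lambda: dict(n_null=99))
    scenarios: list = field(default_factory=lambda: ["current", "lgm"])

    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            base = getattr(cfg, key)
            if isinstance(base, dict) and isinstance(val, dict):
                base.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stage 0: simulate


def simulate(config: RunConfig, outdir: str | Path, seed: int | None = None) -> synthetic.TruthRecord:
    """Generate a full synthetic input bundle into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    spec = config.grid_spec()
    logger.info("simulate: grid %dx%d, seed %d", spec.n_rows, spec.n_cols, seed)

    current, glacial = synthetic.generate_climate_stack(spec, seed=seed, **config.climate)
    truth = synthetic.generate_species_system((current, glacial), seed=seed + 1, **config.species)
    aln_df, pops_df = synthetic.simulate_sequences(truth, seed=seed + 2, **config.sequences)

    # sequence + population tables
    aln = sequences.Alignment.from_frame(aln_df)
    sequences.write_fasta(aln, out / "alignment.fasta")
    pops_with_meta = pops_df.copy()
    ind_meta = aln_df[["individual", "population", "species"]].merge(
        pops_df[["population", "lon", "lat"]], on="population"
    )
    ind_meta.to_csv(out / "populations.csv", index=False)
    pops_with_meta.to_csv(out / "population_coords.csv", index=False)
    with open(out / "outgroup.fasta", "w") as fh:
        fh.write(f">{OUTGROUP_LABEL}\n{truth.outgroup_sequence}\n")

    # occurrence localities biased by current suitability
    occ_frames = []
    for k, sp in enumerate(truth.species):
        occ = synthetic.sample_occurrences(
            truth.suitability_current[sp], spec, config.occurrences["n_per_species"], seed=seed + 10 + k
        )
        occ.insert(0, "species", sp)
        occ_frames.append(occ)
    localities = pd.concat(occ_frames, ignore_index=True)
    localities.to_csv(out / "localities.csv", index=False)

    # rasters and range polygons
    for name, arr in current.layers.items():
        write_ascii_grid(out / f"climate_current_{name}.asc", arr, spec)
    for name, arr in glacial.layers.items():
        write_ascii_grid(out / f"climate_lgm_{name}.asc", arr, spec)
    for sp in truth.species:
        write_ascii_grid(out / f"suitability_current_{sp}.asc", truth.suitability_current[sp], spec)
        write_ascii_grid(out / f"suitability_lgm_{sp}.asc", truth.suitability_glacial[sp], spec)
    write_geojson(
        out / "ranges.geojson",
        {sp: mask_to_polygon(truth.range_masks[sp], spec) for sp in truth.species},
    )

    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh)
    config.to_yaml(out / "config.yaml")
    return truth


def truth_to_dict(truth: synthetic.TruthRecord) -> dict:
    def cells(mask: np.ndarray) -> list[list[int]]:
        return [[int(r), int(c)] for r, c in np.argwhere(mask)]

    return {
        "grid": asdict(truth.grid) if not isinstance(truth.grid, dict) else truth.grid,
        "species": truth.species,
        "range_cells": {sp: cells(truth.range_masks[sp]) for sp in truth.species},
        "refugium_cells": {sp: cells(truth.refugium_masks[sp]) for sp in truth.species},
        "contact_cells": {sp: cells(truth.contact_masks[sp]) for sp in truth.species},
        "founders": truth.founders,
        "introgressions": [list(t) for t in truth.introgressions],
        "outgroup_sequence": truth.outgroup_sequence,
    }


def truth_from_dict(data: dict) -> synthetic.TruthRecord:
    grid = GridSpec(**data["grid"])

    def mask(cells: list[list[int]]) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        for r, c in cells:
            m[r, c] = True
        return m

    species = data["species"]
    return synthetic.TruthRecord(
        grid=grid,
        species=species,
        suitability_current={},
        suitability_glacial={},
        range_masks={sp: mask(data["range_cells"][sp]) for sp in species},
        refugium_masks={sp: mask(data["refugium_cells"][sp]) for sp in species},
        contact_masks={sp: mask(data["contact_cells"][sp]) for sp in species},
        founders=data["founders"],
        introgressions=[tuple(t) for t in data["introgressions"]],
        outgroup_sequence=data["outgroup_sequence"],
    )


def load_stack(bundle: Path, scenario: str) -> RasterStack:
    layers = {}
    grid = None
    for path in sorted(bundle.glob(f"climate_{scenario}_*.asc")):
        name = path.stem.replace(f"climate_{scenario}_", "")
        arr, grid = read_ascii_grid(path)
        layers[name] = arr
    if not layers:
        raise FileNotFoundError(f"no climate rasters for scenario {scenario!r} in {bundle}")
    return RasterStack(grid=grid, layers=layers, scenario=scenario)


# ---------------------------------------------------------------------------
# stage 1: genetic landscape workflow


def run_phylogeography(
    bundle_dir: str | Path, outdir: str | Path, config: RunConfig | None = None
) -> dict:
    """Alignment -> haplotypes -> NJ tree -> introgression flags -> exclusion
    -> per-species pi and Z_i value points -> IDW surfaces -> cropped
    composites under both scaling modes.  Returns the run manifest."""
    bundle, out = Path(bundle_dir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or _bundle_config(bundle)
    manifest: dict = {"stage": "phylogeography", "config": asdict(config)}

    aln = sequences.read_alignment(bundle / "alignment.fasta", bundle / "populations.csv")
    logger.info("read %d sequences of length %d", len(aln), aln.length)
    hap_set = sequences.collapse_haplotypes(aln)
    manifest["n_sequences"] = len(aln)
    manifest["n_haplotypes"] = len(hap_set.haplotype_ids)

    # tree over haplotypes plus outgroup
    outgroup_seq = None
    og_path = bundle / "outgroup.fasta"
    if og_path.exists():
        from Bio import SeqIO

        outgroup_seq = str(next(SeqIO.parse(str(og_path), "fasta")).seq).upper()
    labels = list(hap_set.haplotype_ids)
    seqs = list(hap_set.sequences)
    if outgroup_seq is not None:
        labels.append(OUTGROUP_LABEL)
        seqs.append(outgroup_seq)
    dmat, labels = sequences.distance_matrix(seqs, labels, kind="proportion")
    tree = njtree.nj_tree(dmat, labels)
    b_reps = int(config.tree.get("bootstrap_replicates", 0))
    support = {}
    if b_reps > 0:
        support = njtree.bootstrap_support(seqs, labels, tree, n_replicates=b_reps, seed=config.seed)
    rooted = njtree.root_with_outgroup(tree, OUTGROUP_LABEL) if outgroup_seq else tree

    ind_species = dict(zip(aln.individuals, aln.species))
    ind_pop = dict(zip(aln.individuals, aln.populations))
    lineages, report = njtree.assign_lineages(
        rooted,
        hap_set,
        ind_species,
        outgroup=OUTGROUP_LABEL if outgroup_seq else None,
        distances=(dmat, labels),
    )
    hap_set.lineages = lineages
    flags, pop_classes = njtree.flag_introgression(hap_set, lineages, ind_species, ind_pop)
    n_flagged = int((flags["status"] == "introgressed").sum())
    logger.info("flagged %d introgressed individuals", n_flagged)
    manifest["monophyly"] = report
    manifest["n_introgressed_individuals"] = n_flagged
    manifest["population_classes"] = pop_classes

    # exclusion of introgressed mitochondria before spatial statistics
    mode = config.landscape.get("exclusion", "population")
    introgressed_inds = set(flags.loc[flags["status"] == "introgressed", "individual"])
    if mode == "population":
        bad_pops = {pop for pop, cls in pop_classes.items() if cls != "original"}
        keep = {i for i in aln.individuals if ind_pop[i] not in bad_pops}
    elif mode == "individual":
        keep = {i for i in aln.individuals if i not in introgressed_inds}
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    retained = aln.subset(keep)

    pops = pd.read_csv(bundle / "population_coords.csv")
    ranges = read_geojson(bundle / "ranges.geojson")
    grid = load_stack(bundle, "current").grid

    power = float(config.landscape.get("idw_power", 2.0))
    k = int(config.landscape.get("idw_k", 12))
    species_list = sorted(set(aln.species))
    retention = {}
    points_rows = []
    rasters_pi: dict[str, np.ndarray] = {}
    rasters_zi: dict[str, np.ndarray] = {}
    by_pop: dict[str, list[str]] = {}
    for ind, pop, seq in zip(retained.individuals, retained.populations, retained.sequences):
        by_pop.setdefault(pop, []).append(seq)

    for sp in species_list:
        sp_pops = pops[pops["species"] == sp]
        total = len(sp_pops)
        live = sp_pops[sp_pops["population"].isin(by_pop)]
        pi_points, zi_ready = [], []
        for _, row in live.iterrows():
            seqs_p = by_pop[row["population"]]
            if len(seqs_p) >= 2:
                pi_points.append(
                    {
                        "species": sp,
                        "kind": "pi",
                        "lon": row["lon"],
                        "lat": row["lat"],
                        "value": gl.population_pi(seqs_p),
                        "population": row["population"],
                    }
                )
            else:
                logger.info("population %s has a single retained sequence; skipped for pi", row["population"])
            zi_ready.append(row)
        retention[sp] = {
            "total_populations": total,
            "kept_for_zi": len(zi_ready),
            "kept_for_pi": len(pi_points),
        }
        points_rows.extend(pi_points)

        zi_points = []
        if len(zi_ready) >= 2:
            coords = np.array([[r["lon"], r["lat"]] for r in zi_ready])
            edges = gl.delaunay_network(coords)
            for i, j in edges:
                a, b = zi_ready[i], zi_ready[j]
                vp = gl.edge_genetic_distance(
                    by_pop[a["population"]],
                    by_pop[b["population"]],
                    (a["lon"], a["lat"]),
                    (b["lon"], b["lat"]),
                )
                vp.update({"species": sp, "population": f"{a['population']}-{b['population']}"})
                zi_points.append(vp)
        points_rows.extend(zi_points)

        poly = ranges.get(sp)
        for kind, pts, store in (("pi", pi_points, rasters_pi), ("zi", zi_points, rasters_zi)):
            if not pts:
                continue
            surf = gl.idw_interpolate(pd.DataFrame(pts), grid, power=power, k=k)
            if poly is not None:
                surf = gl.crop_to_range(surf, grid, poly)
            store[sp] = surf
            write_ascii_grid(out / f"{kind}_{sp}.asc", surf, grid)

    pd.DataFrame(points_rows).to_csv(out / "value_points.csv", index=False)
    for kind, store in (("pi", rasters_pi), ("zi", rasters_zi)):
        for mode_name in ("global", "per_species"):
            scaled = gl.composite_scale(store, mode=mode_name) if store else {}
            for sp, arr in scaled.items():
                write_ascii_grid(out / f"{kind}_{sp}_composite_{mode_name}.asc", arr, grid)

    manifest["retention"] = retention
    tree.write(path=str(out / "haplotype_tree.nwk"), schema="newick")
    if support:
        manifest["bootstrap"] = {
            "replicates": b_reps,
            "n_supported_80": sum(1 for v in support.values() if v >= 80.0),
            "n_internal_edges": len(support),
        }
    flags.to_csv(out / "introgression_flags.csv", index=False)
    with open(out / "lineages.json", "w") as fh:
        json.dump(lineages, fh, indent=1, sort_keys=True)
    with open(out / "manifest_phylogeo.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stage 2: distribution modelling workflow


def run_sdm(bundle_dir: str | Path, outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Screen variables, build background, fit + null-test a hinge maxent
    model per species, project onto every scenario, crop and composite."""
    bundle, out = Path(bundle_dir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or _bundle_config(bundle)
    manifest: dict = {"stage": "sdm", "config": asdict(config)}
    pcfg = config.sdm

    stacks = {"current": load_stack(bundle, "current")}
    for scen in config.scenarios:
        if scen != "current":
            stacks[scen] = load_stack(bundle, scen)
    current = stacks["current"]
    localities = pd.read_csv(bundle / "localities.csv")
    ranges = read_geojson(bundle / "ranges.geojson")

    background = sdm.build_background(
        localities,
        current,
        buffer_km=float(pcfg.get("buffer_km", 200.0)),
        n_background=int(pcfg.get("n_background", 400)),
        seed=config.seed,
    )
    retained = sdm.screen_variables(
        current, background.cells, threshold=float(pcfg.get("corr_threshold", 0.7))
    )
    logger.info("retained layers after screening: %s", retained)
    manifest["retained_layers"] = retained
    cols = [background.layer_names.index(n) for n in retained]
    background = sdm.BackgroundSet(
        cells=background.cells,
        coords=background.coords,
        X=background.X[:, cols],
        layer_names=retained,
        buffer_km=background.buffer_km,
        buffer_mask=background.buffer_mask,
    )
    candidate_cells = np.argwhere(background.buffer_mask & current.finite_mask())
    candidate_X = current.values_at_cells(candidate_cells, retained)

    beta = float(pcfg.get("beta", 1.0))
    n_knots = int(pcfg.get("n_knots", 8))
    n_null = int(config.nulltest.get("n_null", 99))
    species_results = {}
    composites: dict[str, dict[str, np.ndarray]] = {s: {} for s in stacks}
    for si, sp in enumerate(sorted(localities["species"].unique())):
        occ = localities[localities["species"] == sp]
        cells = np.unique(occ[["row", "col"]].to_numpy(), axis=0)
        presence_X = current.values_at_cells(cells, retained)
        model = sdm.fit_entropy_model(presence_X, background, beta=beta, n_knots=n_knots)
        obs_auc = significance.training_auc(model, presence_X, background)
        result = significance.null_model_test(
            obs_auc,
            n_localities=len(presence_X),
            candidate_X=candidate_X,
            background=background,
            n_null=n_null,
            beta=beta,
            n_knots=n_knots,
            seed=config.seed + 100 + si,
        )
        species_results[sp] = {
            "n_presence_cells": int(len(presence_X)),
            "auc": obs_auc,
            "rank": result.rank,
            "significant": result.significant,
        }
        logger.info("%s: AUC %.3f rank %d significant=%s", sp, obs_auc, result.rank, result.significant)
        with open(out / f"model_{sp}.json", "w") as fh:
            json.dump(model.to_dict(), fh)
        pd.DataFrame({"replicate": range(1, n_null + 1), "auc": result.null_aucs}).to_csv(
            out / f"null_aucs_{sp}.csv", index=False
        )
        with open(out / f"nulltest_{sp}.json", "w") as fh:
            json.dump(result.to_dict(), fh)

        poly = ranges.get(sp)
        for scen, stack in stacks.items():
            raw, logistic = sdm.project_model(model, stack)
            write_ascii_grid(out / f"suitability_{scen}_{sp}_raw.asc", raw, stack.grid)
            cropped = gl.crop_to_range(logistic, stack.grid, poly) if poly is not None else logistic
            write_ascii_grid(out / f"suitability_{scen}_{sp}.asc", cropped, stack.grid)
            composites[scen][sp] = cropped

    for scen, store in composites.items():
        for mode_name in ("global", "per_species"):
            scaled = gl.composite_scale(store, mode=mode_name) if store else {}
            for sp, arr in scaled.items():
                write_ascii_grid(
                    out / f"suitability_{scen}_{sp}_composite_{mode_name}.asc", arr, current.grid
                )

    manifest["species"] = species_results
    manifest["n_background"] = int(len(background.X))
    with open(out / "manifest_sdm.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _bundle_config(bundle: Path) -> RunConfig:
    cfg_path = bundle / "config.yaml"
    if cfg_path.exists():
        return RunConfig.from_yaml(cfg_path)
    return RunConfig()


def run_all(config: RunConfig, workdir: str | Path) -> dict:
    """simulate -> phylogeography -> sdm in one self-contained directory."""
    work = Path(workdir)
    simulate(config, work / "bundle")
    m1 = run_phylogeography(work / "bundle", work / "phylogeo", config)
    m2 = run_sdm(work / "bundle", work / "sdm", config)
    return {"phylogeography": m1, "sdm": m2}
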