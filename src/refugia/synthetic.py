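"""Synthetic study systems with known ground truth.

Generates the inputs a glacial-refugium analysis consumes — spatially
autocorrelated climate layers for a "current" and a "glacial" snapshot,
species ranges carved out of climate space by Gaussian niches, mitochondrial
sequence samples whose diversity is structured by refugial persistence
versus postglacial expansion, planted mitochondrial introgression at
parapatric contact zones, and suitability-biased occurrence records — while
recording every planted signal in a :class:`TruthRecord` so downstream
estimators can be scored against truth.

The demographic model is deliberately minimal: refugial populations carry a
small local radiation of haplotypes derived from a per-refugium founder,
expansion populations carry the nearest founder haplotype nearly unchanged
(the classic star-phylogeny footprint of rapid range expansion), and contact
-zone individuals swap their whole mitochondrial sequence with a neighbouring
species' local haplotype with fixed probability (maternal inheritance, no
recombination).  Substitutions are Jukes–Cantor single-site replacements
with no indels, which is all a mismatch-count pipeline can see.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, RasterStack

BASES = np.array(list("ACGT"))

__all__ = [
    "TruthRecord",
    "generate_climate_stack",
    "generate_species_system",
    "simulate_sequences",
    "sample_occurrences",
]


@dataclass
class TruthRecord:
    """Ground truth of a simulated species system."""

    grid: GridSpec
    species: list[str]
    suitability_current: dict[str, np.ndarray]
    suitability_glacial: dict[str, np.ndarray]
    range_masks: dict[str, np.ndarray]
    refugium_masks: dict[str, np.ndarray]
    contact_masks: dict[str, np.ndarray]
    founders: dict[str, list[str]] = field(default_factory=dict)
    # (individual id, donor species) for every planted foreign mitochondrion
    introgressions: list[tuple[str, str]] = field(default_factory=list)
    outgroup_sequence: str | None = None

    def contact_cells(self, species: str) -> set[tuple[int, int]]:
        return {tuple(rc) for rc in np.argwhere(self.contact_masks[species])}


def generate_climate_stack(
    spec: GridSpec,
    n_layers: int = 5,
    autocorr_length: float = 8.0,
    inter_layer_corr: float = 0.0,
    glacial_shift: np.ndarray | list[float] | None = None,
    gradient_weight: np.ndarray | list[float] | None = None,
    seed: int = 0,
) -> tuple[RasterStack, RasterStack]:
    """Simulate co-registered current and glacial climate stacks.

    Each layer is Gaussian-kernel-smoothed white noise (correlation length
    ``autocorr_length`` cells), optionally blended with a north→south linear
    gradient (``gradient_weight`` per layer; positive = southern cells high),
    standardized to mean 0 / sd 1 over cells.  Layers share pairwise
    correlation ``inter_layer_corr`` (induced before smoothing, which
    preserves it).  The glacial stack is the current stack plus a constant
    per-layer offset ``glacial_shift``.
    """
    if spec.n_rows < 8 or spec.n_cols < 8:
        raise ValueError("climate grids need at least 8x8 cells")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if autocorr_length < 1:
        raise ValueError("autocorr_length must be >= 1 cell")
    rho = float(inter_layer_corr)
    if abs(rho) > 1:
        raise ValueError("inter_layer_corr must lie in [-1, 1]")
    if abs(rho) == 1 and n_layers > 2:
        raise ValueError("|inter_layer_corr| = 1 is over-constrained for more than 2 layers")
    if rho <= -1.0 / (n_layers - 1):
        raise ValueError(
            f"equicorrelation {rho} is not positive semi-definite for {n_layers} layers"
        )
    shift = np.zeros(n_layers) if glacial_shift is None else np.asarray(glacial_shift, dtype=float)
    if shift.shape != (n_layers,):
        raise ValueError("glacial_shift must provide one offset per layer")
    gradw = np.zeros(n_layers) if gradient_weight is None else np.asarray(gradient_weight, dtype=float)
    if gradw.shape != (n_layers,):
        raise ValueError("gradient_weight must provide one weight per layer")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_layers, spec.n_rows, spec.n_cols))
    # induce the requested equicorrelation across layers at every cell
    corr = np.full((n_layers, n_layers), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    mixed = np.einsum("ij,jrc->irc", chol, white)

    # north→south ramp, row 0 = north; standardized so gradient_weight is in sd units
    ramp = np.linspace(-1.0, 1.0, spec.n_rows)[:, None] * np.ones((1, spec.n_cols))
    ramp = (ramp - ramp.mean()) / ramp.std()

    layers: dict[str, np.ndarray] = {}
    for i in range(n_layers):
        f = ndimage.gaussian_filter(mixed[i], sigma=autocorr_length, mode="reflect")
        f = (f - f.mean()) / f.std()
        f = f + gradw[i] * ramp
        f = (f - f.mean()) / f.std()
        layers[f"bio{i + 1}"] = f
    current = RasterStack(grid=spec, layers=layers, scenario="current")
    glacial = RasterStack(
        grid=spec,
        layers={n: layers[n] + shift[i] for i, n in enumerate(layers)},
        scenario="lgm",
    )
    return current, glacial


def generate_species_system(
    stacks: tuple[RasterStack, RasterStack],
    n_species: int = 2,
    niche_centers: dict[str, dict[str, float]] | None = None,
    niche_breadths: dict[str, dict[str, float]] | None = None,
    range_threshold: float = 0.5,
    seed: int = 0,
) -> TruthRecord:
    """Carve species ranges, refugia and contact zones out of climate space.

    Suitability of a cell for a species is the product of Gaussian responses
    to the layers named in its niche (each response peaks at 1, so the
    product lies in (0, 1]).  Range mask = current suitability >= ``range_threshold``;
    refugium mask = cells above threshold under *both* scenarios; contact
    zone = range cells 8-adjacent to (or shared with) another species' range.

    When niches are not supplied, ``n_species`` species are spread along the
    first layer's gradient (centers evenly spaced in [-1, 1.2] sd units on
    bio1, all centered at 0 on bio2).
    """
    current, glacial = stacks
    if n_species < 2 and niche_centers is None:
        raise ValueError("need at least 2 species")
    if niche_centers is None:
        centers = np.linspace(1.2, -1.0, n_species)
        niche_centers = {f"sp{i + 1}": {"bio1": c, "bio2": 0.0} for i, c in enumerate(centers)}
    if niche_breadths is None:
        niche_breadths = {
            sp: {layer: 1.0 for layer in layers} for sp, layers in niche_centers.items()
        }
    species = list(niche_centers)
    if any(len(layers) < 2 for layers in niche_centers.values()):
        raise ValueError("each niche must be defined on at least 2 layers")

    def suitability(stack: RasterStack, sp: str) -> np.ndarray:
        s = np.ones(stack.grid.shape)
        for layer, c in niche_centers[sp].items():
            b = niche_breadths[sp][layer]
            s = s * np.exp(-((stack.layers[layer] - c) ** 2) / (2.0 * b * b))
        return s

    suit_cur, suit_gla = {}, {}
    range_masks, refug_masks = {}, {}
    for sp in species:
        sc = suitability(current, sp)
        sg = suitability(glacial, sp)
        suit_cur[sp], suit_gla[sp] = sc, sg
        mask = sc >= range_threshold
        if not mask.any():
            raise ValueError(
                f"species {sp!r} has an empty range; lower range_threshold (= {range_threshold})"
            )
        range_masks[sp] = mask
        refug_masks[sp] = mask & (sg >= range_threshold)

    struct = np.ones((3, 3), dtype=bool)  # 8-neighborhood
    contact_masks = {}
    for sp in species:
        others = np.zeros(current.grid.shape, dtype=bool)
        for other in species:
            if other != sp:
                others |= range_masks[other]
        contact_masks[sp] = range_masks[sp] & ndimage.binary_dilation(others, structure=struct)

    return TruthRecord(
        grid=current.grid,
        species=species,
        suitability_current=suit_cur,
        suitability_glacial=suit_gla,
        range_masks=range_masks,
        refugium_masks=refug_masks,
        contact_masks=contact_masks,
    )


def _mutate(seq: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Apply k Jukes-Cantor single-site substitutions (sites chosen uniformly)."""
    out = seq.copy()
    for _ in range(k):
        site = rng.integers(len(out))
        out[site] = (out[site] + rng.integers(1, 4)) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


def simulate_sequences(
    truth: TruthRecord,
    n_pops_per_species: int = 18,
    n_per_pop: int = 5,
    seq_length: int = 658,
    mut_rate: float = 3.0,
    introgression_prob: float = 0.5,
    species_divergence: int = 40,
    outgroup_divergence: int = 120,
    refugial_fraction: float = 0.35,
    n_contact_pops: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one-locus mitochondrial samples over the species system.

    Returns ``(alignment_df, populations_df)``: per-individual rows
    (``individual, population, species, sequence``) and per-population rows
    (``population, species, lon, lat, refugial``).  Founder haplotypes,
    planted introgressions and the outgroup sequence are recorded on
    ``truth`` in place.

    Population placement is stratified: up to ``n_contact_pops`` populations
    are forced onto contact-zone cells, about ``refugial_fraction`` onto
    refugium cells, the remainder onto expansion (range-only) cells.
    Refugial populations receive a local radiation of founder-derived
    haplotypes (Poisson(``mut_rate``) substitutions per local lineage);
    expansion populations receive the nearest refugium founder with 0-2
    private substitutions shared by the whole population.
    """
    if seq_length < 100:
        raise ValueError("seq_length must be >= 100")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=seq_length)

    pops_rows: list[dict] = []
    aln_rows: list[dict] = []
    truth.founders = {}
    truth.introgressions = []

    # first pass: place populations and draw within-species haplotypes
    pop_sequences: dict[str, list[np.ndarray]] = {}  # population -> per-individual seq
    pop_meta: dict[str, dict] = {}
    struct = np.ones((3, 3), dtype=bool)
    for sp in truth.species:
        ancestor = _mutate(root, rng.poisson(species_divergence), rng)
        refug = truth.refugium_masks[sp]
        rng_mask = truth.range_masks[sp]
        patches, n_patches = ndimage.label(refug, structure=struct)
        founders: list[np.ndarray] = []
        patch_centroids: list[np.ndarray] = []
        if n_patches == 0:
            founders.append(_mutate(ancestor, rng.poisson(mut_rate), rng))
            patch_centroids.append(np.argwhere(rng_mask).mean(axis=0))
        for p in range(1, n_patches + 1):
            founders.append(_mutate(ancestor, rng.poisson(mut_rate), rng))
            patch_centroids.append(np.argwhere(patches == p).mean(axis=0))
        truth.founders[sp] = [_decode(f) for f in founders]
        centroids = np.array(patch_centroids)

        # stratified cell sampling: contact, refugial, expansion
        contact_cells = np.argwhere(truth.contact_masks[sp])
        refug_cells = np.argwhere(refug & ~truth.contact_masks[sp])
        expand_cells = np.argwhere(rng_mask & ~refug & ~truth.contact_masks[sp])
        n_total = n_pops_per_species
        avail = len(contact_cells) + len(refug_cells) + len(expand_cells)
        if n_total > avail:
            raise ValueError(
                f"requested {n_total} populations for {sp!r} but only {avail} range cells"
            )

        def take(cells: np.ndarray, k: int) -> list[np.ndarray]:
            k = min(k, len(cells))
            if k == 0:
                return []
            idx = rng.choice(len(cells), size=k, replace=False)
            return [cells[i] for i in idx]

        chosen = take(contact_cells, min(n_contact_pops, n_total))
        n_ref = max(1, int(round(refugial_fraction * n_total))) if len(refug_cells) else 0
        chosen += take(refug_cells, min(n_ref, n_total - len(chosen)))
        chosen += take(expand_cells, n_total - len(chosen))
        # top up from any remaining stratum if one ran short
        if len(chosen) < n_total:
            used = {tuple(c) for c in chosen}
            rest = [c for c in np.argwhere(rng_mask) if tuple(c) not in used]
            chosen += take(np.array(rest), n_total - len(chosen))

        for k, cell in enumerate(chosen):
            pop_id = f"{sp}_p{k + 1:02d}"
            r, c = int(cell[0]), int(cell[1])
            lon, lat = truth.grid.cell_center(r, c)
            is_refugial = bool(refug[r, c])
            nearest = int(np.argmin(((centroids - cell) ** 2).sum(axis=1)))
            if is_refugial:
                # local radiation around the patch founder
                founder = founders[nearest]
                n_local = 1 + min(n_per_pop - 1, int(rng.poisson(1.2)))
                local = [_mutate(founder, rng.poisson(mut_rate), rng) for _ in range(n_local)]
                seqs = [local[rng.integers(n_local)] for _ in range(n_per_pop)]
            else:
                extra = 0 if mut_rate == 0 else int(rng.integers(0, 3))
                hap = _mutate(founders[nearest], extra, rng)
                seqs = [hap for _ in range(n_per_pop)]
            pop_sequences[pop_id] = seqs
            pop_meta[pop_id] = {
                "population": pop_id,
                "species": sp,
                "cell": (r, c),
                "lon": lon,
                "lat": lat,
                "refugial": is_refugial,
                "contact": bool(truth.contact_masks[sp][r, c]),
            }

    # second pass: plant introgression at contact populations
    for pop_id, meta in pop_meta.items():
        if not meta["contact"] or introgression_prob <= 0:
            continue
        sp = meta["species"]
        cell = np.array(meta["cell"])
        # donor = the other species whose range touches this cell, nearest population wins
        donors = []
        for other in truth.species:
            if other == sp:
                continue
            dil = ndimage.binary_dilation(truth.range_masks[other], structure=struct)
            if dil[meta["cell"]]:
                donors.append(other)
        if not donors:
            continue
        # prefer donor populations outside the contact zone so the copied
        # haplotype is guaranteed to stay present in the donor species
        best: tuple[float, str] | None = None
        for other in donors:
            cands = [
                (m, np.hypot(*(np.array(m["cell"]) - cell)))
                for m in pop_meta.values()
                if m["species"] == other
            ]
            if not cands:
                continue
            noncontact = [cd for cd in cands if not cd[0]["contact"]]
            pool = noncontact if noncontact else cands
            m, d = min(pool, key=lambda cd: cd[1])
            if best is None or d < best[0]:
                best = (d, m["population"])
        if best is None:
            continue
        donor_pop = best[1]
        donor_sp = pop_meta[donor_pop]["species"]
        donor_seqs = pop_sequences[donor_pop]
        for j in range(n_per_pop):
            if rng.random() < introgression_prob:
                pop_sequences[pop_id][j] = donor_seqs[rng.integers(len(donor_seqs))]
                truth.introgressions.append((f"{pop_id}_i{j + 1}", donor_sp))

    for pop_id, meta in pop_meta.items():
        pops_rows.append(
            {k: meta[k] for k in ("population", "species", "lon", "lat", "refugial")}
        )
        for j, s in enumerate(pop_sequences[pop_id]):
            aln_rows.append(
                {
                    "individual": f"{pop_id}_i{j + 1}",
                    "population": pop_id,
                    "species": meta["species"],
                    "sequence": _decode(s),
                }
            )

    truth.outgroup_sequence = _decode(_mutate(root, rng.poisson(outgroup_divergence), rng))
    return pd.DataFrame(aln_rows), pd.DataFrame(pops_rows)


def sample_occurrences(
    suitability: np.ndarray,
    grid: GridSpec,
    n_points: int,
    seed: int = 0,
    jitter: bool = False,
) -> pd.DataFrame:
    """Draw occurrence localities with probability proportional to suitability.

    Cells are sampled without replacement; each locality sits at its cell
    center unless ``jitter`` spreads it uniformly within the cell.
    """
    suit = np.where(np.isfinite(suitability), suitability, 0.0)
    flat = suit.ravel()
    positive = np.flatnonzero(flat > 0)
    if positive.size == 0:
        raise ValueError("suitability has no positive cells")
    if n_points > positive.size:
        raise ValueError(
            f"requested {n_points} localities but only {positive.size} cells have positive suitability"
        )
    rng = np.random.default_rng(seed)
    p = flat[positive] / flat[positive].sum()
    picks = rng.choice(positive, size=n_points, replace=False, p=p)
    rows = []
    for flat_idx in picks:
        r, c = divmod(int(flat_idx), grid.n_cols)
        lon, lat = grid.cell_center(r, c)
        if jitter:
            lon += (rng.random() - 0.5) * grid.cell_size
            lat += (rng.random() - 0.5) * grid.cell_size
        rows.append({"lon": lon, "lat": lat, "row": r, "col": c})
    return pd.DataFrame(rows)
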