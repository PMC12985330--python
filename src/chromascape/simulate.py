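"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the four data streams the analysis consumes:

* a species colour table — Dirichlet colour profiles whose mean matches
  the colour shares typical of European breeding-bird communities
  (grey ~39%, white ~20%, black ~17%, brown ~14%, ...);
* species-level phylogenies — ultrametric Yule (pure-birth) trees, and
  tree sets mixing a few topologies to exercise MCC selection;
* land-use mosaics — square-grid cell mosaics clipped to the 200 m buffer
  disc, with class quotas chosen so each site's true habitat label is
  recoverable by the classification ruleset;
* communities — logistic habitat-affinity occupancy calibrated to a
  target mean species richness;

plus a direct linear-model scenario in which site-level colour inequality
is generated from planted coefficients, for coefficient/sign recovery
checks of the association stage.

Every generator is a pure function of its seed; all randomness flows from
one scenario seed through independent named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .colours import COLOURS
from .errors import InvalidParameterError
from .landscape import (
    DEFAULT_BUFFER_RADIUS,
    FOREST_CLASSES,
    HABITAT_LABELS,
    LAND_USE_CLASSES,
    LandUsePatch,
    MIXED,
)

#: Default mean colour shares (percent) used as the Dirichlet mean:
#: community-level averages typical of a national breeding-bird survey.
DEFAULT_COLOUR_MEAN_PCT = np.array(
    [17.207, 1.188, 13.542, 0.541, 39.151, 0.121, 0.372, 1.959, 20.194, 5.724]
)

#: Dirichlet concentration scale: alpha = scale * mean/100.  Low values give
#: strongly specialised species palettes, high values near-identical ones.
DEFAULT_CONCENTRATION_SCALE = 5.0

DEFAULT_PLANTED_COEFFICIENTS = {
    "intercept": 0.55,
    "lur": -0.010,
    "wedge": 2.0e-5,
    "richness": -0.005,
    "psv": 0.20,
    "lon": 0.0,
    "lat": 0.0,
}


def default_concentration(scale: float = DEFAULT_CONCENTRATION_SCALE) -> np.ndarray:
    return scale * DEFAULT_COLOUR_MEAN_PCT / 100.0


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study."""

    seed: int = 0
    n_species: int = 80
    n_sites: int = 500
    colour_concentration: np.ndarray = field(default_factory=default_concentration)
    habitat_mix: dict[str, float] = field(
        default_factory=lambda: {
            "croplands": 0.25,
            "deciduous_forest": 0.15,
            "coniferous_forest": 0.10,
            "urban": 0.15,
            "wetlands_water": 0.10,
            MIXED: 0.25,
        }
    )
    affinity_strength: float = 1.5
    richness_target: float = 17.7
    planted_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_COEFFICIENTS)
    )
    noise_sd: float = 0.05
    group_sd: float = 0.0  # habitat random-intercept SD in the direct scenario

    def __post_init__(self):
        self.colour_concentration = np.asarray(self.colour_concentration, dtype=float)
        if self.n_species < 2:
            raise InvalidParameterError("n_species must be >= 2")
        if self.n_sites < 1:
            raise InvalidParameterError("n_sites must be >= 1")
        if self.colour_concentration.shape != (10,) or (
            self.colour_concentration <= 0
        ).any():
            raise InvalidParameterError(
                "colour_concentration must be 10 strictly positive values"
            )
        if abs(sum(self.habitat_mix.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("habitat_mix proportions must sum to 1")
        unknown = set(self.habitat_mix) - set(HABITAT_LABELS)
        if unknown:
            raise InvalidParameterError(f"unknown habitat labels: {sorted(unknown)}")
        if self.affinity_strength < 0:
            raise InvalidParameterError("affinity_strength must be >= 0")
        if self.richness_target >= self.n_species:
            raise InvalidParameterError(
                "richness_target must be below n_species"
            )
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """What the generators actually planted."""

    species_affinity: dict[str, str] = field(default_factory=dict)
    site_habitat: dict[str, str] = field(default_factory=dict)
    planted_coefficients: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


_STREAMS = ("colour", "phylogeny", "treeset", "landscape", "community", "direct")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named substream of the scenario seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS.index(stream),))
    )


def species_ids(n_species: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(1, n_species + 1)]


def site_ids(n_sites: int) -> list[str]:
    return [f"site{i:05d}" for i in range(1, n_sites + 1)]


# ---------------------------------------------------------------------------
# colour table
# ---------------------------------------------------------------------------

def gen_colour_table(
    n_species: int,
    concentration: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet colour profiles (percent, rows sum to 100) per species."""
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    alpha = (
        default_concentration()
        if concentration is None
        else np.asarray(concentration, dtype=float)
    )
    if alpha.shape != (10,) or (alpha <= 0).any():
        raise InvalidParameterError("concentration must be 10 positive values")
    rng = _rng(seed, "colour")
    profiles = rng.dirichlet(alpha, size=n_species) * 100.0
    table = pd.DataFrame(profiles, index=species_ids(n_species), columns=list(COLOURS))
    table.index.name = "species_id"
    return table


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def gen_phylogeny(
    n_species: int,
    seed: int = 0,
    birth_rate: float = 1.0,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with ``n_species`` labelled tips.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); all tips extend to the present, so the tree is ultrametric
    with strictly positive branch lengths.
    """
    if n_species < 2:
        raise InvalidParameterError("a phylogeny needs >= 2 species")
    rng = _rng(seed, "phylogeny")
    ns = taxon_namespace or dendropy.TaxonNamespace(species_ids(n_species))
    tree = dendropy.Tree(taxon_namespace=ns)
    # simulate speciation times forward from the root split
    birth_times = [0.0, 0.0]  # per active lineage: time its branch started
    parents: list[int] = [-1, -1]  # index into node records
    t = 0.0
    # node records: (parent_index, start_time); tips filled at the end
    records: list[tuple[int, float]] = [(-1, 0.0), (-1, 0.0)]
    active = [0, 1]
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        split = active[rng.integers(len(active))]
        records.append((split, t))
        records.append((split, t))
        active.remove(split)
        active.extend([len(records) - 2, len(records) - 1])
    t_final = t + rng.exponential(1.0 / (birth_rate * len(active)))
    # build dendropy nodes
    nodes = []
    root = tree.seed_node
    for idx, (parent, start) in enumerate(records):
        if parent == -1:
            node = dendropy.Node()
            root.add_child(node)
        else:
            node = dendropy.Node()
            nodes[parent].add_child(node)
        node._start = start
        nodes.append(node)
    labels = list(species_ids(n_species))
    rng.shuffle(labels)
    label_iter = iter(labels)
    for idx in active:
        nodes[idx].taxon = ns.get_taxon(next(label_iter))
    # edge lengths: child start minus parent start; tips end at t_final
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        end = (
            min(c._start for c in node.child_nodes())
            if node.child_nodes()
            else t_final
        )
        node.edge.length = end - node._start
    # drop unary internal passthrough nodes created by the record layout
    tree.suppress_unifurcations()
    return tree


def gen_tree_set(
    n_species: int,
    topology_weights: list[tuple[int, int]],
    seed: int = 0,
) -> list[dendropy.Tree]:
    """A tree sample mixing a few topologies with branch-length jitter.

    ``topology_weights`` is a list of (topology-seed, count) pairs; all
    trees generated from one topology-seed share that topology (branch
    lengths are rescaled by a random positive factor per replicate).
    """
    if not topology_weights:
        raise InvalidParameterError("topology_weights must be non-empty")
    if any(count < 1 for _, count in topology_weights):
        raise InvalidParameterError("topology counts must be >= 1")
    rng = _rng(seed, "treeset")
    ns = dendropy.TaxonNamespace(species_ids(n_species))
    trees = []
    for topo_seed, count in topology_weights:
        base = gen_phylogeny(n_species, seed=topo_seed, taxon_namespace=ns)
        base_str = base.as_string(schema="newick")
        for _ in range(count):
            tree = dendropy.Tree.get(
                data=base_str,
                schema="newick",
                taxon_namespace=ns,
                rooting="default-rooted",
            )
            scale = rng.lognormal(0.0, 0.1)
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= scale
            trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

# Per-site class quotas for a target habitat label.  Dominant-class shares
# sit well away from the rule thresholds so grid discretization cannot flip
# the recoverable label; filler classes vary in number and share so that
# land-use richness is not a deterministic function of the habitat label.
def _split_remainder(
    remainder: float, fillers, rng: np.random.Generator, cap: float
) -> dict[str, float]:
    while True:  # redraw until no filler share crosses its cap
        shares = rng.dirichlet(np.full(len(fillers), 2.0)) * remainder
        if shares.max() <= cap:
            return dict(zip(fillers, shares))


def _class_quota(label: str, rng: np.random.Generator) -> dict[str, float]:
    others = [c for c in LAND_USE_CLASSES if c != label]
    non_urban = [c for c in others if c != "urban"]
    if label == MIXED:
        k = int(rng.integers(4, 6))
        chosen = list(
            rng.choice([c for c in LAND_USE_CLASSES if c != "urban"], k, replace=False)
        )
        while True:
            shares = rng.dirichlet(np.full(k, 8.0))
            quota = dict(zip(chosen, shares))
            forest = sum(quota.get(c, 0.0) for c in FOREST_CLASSES)
            if shares.max() <= 0.50 and forest <= 0.50:
                return quota
    if label in FOREST_CLASSES:
        other_forest = (
            "coniferous_forest" if label == "deciduous_forest" else "deciduous_forest"
        )
        main = rng.uniform(0.65, 0.75)
        other_share = rng.uniform(0.0, 0.08)
        n_fill = int(rng.integers(2, 5))
        fillers = rng.choice(
            [c for c in non_urban if c != other_forest], n_fill, replace=False
        )
        quota = {label: main, other_forest: other_share}
        quota.update(
            _split_remainder(1.0 - main - other_share, fillers, rng, cap=0.30)
        )
        return quota
    if label == "urban":
        main = rng.uniform(0.38, 0.50)
        n_fill = int(rng.integers(2, 5))
        while True:
            fillers = rng.choice(others, n_fill, replace=False)
            quota = {"urban": main}
            quota.update(_split_remainder(1.0 - main, fillers, rng, cap=0.40))
            if sum(quota.get(c, 0.0) for c in FOREST_CLASSES) <= 0.50:
                return quota
    main = rng.uniform(0.65, 0.78)
    n_fill = int(rng.integers(2, 5))
    fillers = rng.choice(non_urban, n_fill, replace=False)
    quota = {label: main}
    quota.update(_split_remainder(1.0 - main, fillers, rng, cap=0.30))
    return quota


def gen_landscape(
    scenario: SyntheticScenario,
    cell_size: float = 25.0,
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    site_spacing: float = 1000.0,
) -> tuple[dict[str, list[LandUsePatch]], pd.DataFrame, GroundTruth]:
    """Grid-mosaic land-use patches per site buffer.

    Each buffer disc is tiled with square cells clipped to the disc, cells
    are assigned classes by area quotas drawn for the site's true habitat
    label, and contiguous same-class cells are merged into patches.
    Returns (patches by site, site coordinate table, ground truth).
    """
    if cell_size <= 0:
        raise InvalidParameterError("cell_size must be > 0")
    rng = _rng(scenario.seed, "landscape")
    labels = list(scenario.habitat_mix)
    probs = np.array([scenario.habitat_mix[h] for h in labels])
    sites = site_ids(scenario.n_sites)
    true_labels = rng.choice(labels, size=len(sites), p=probs)

    n_side = int(np.ceil(2 * buffer_radius / cell_size))
    grid_cols = int(np.ceil(np.sqrt(len(sites))))
    truth = GroundTruth(planted_coefficients=dict(scenario.planted_coefficients))
    patches_by_site: dict[str, list[LandUsePatch]] = {}
    coords = []
    for s_idx, (site, label) in enumerate(zip(sites, true_labels)):
        cx = (s_idx % grid_cols) * site_spacing
        cy = (s_idx // grid_cols) * site_spacing
        disc = Point(cx, cy).buffer(buffer_radius, quad_segs=64)
        cells = []
        for i in range(n_side):
            for j in range(n_side):
                cell = box(
                    cx - buffer_radius + i * cell_size,
                    cy - buffer_radius + j * cell_size,
                    cx - buffer_radius + (i + 1) * cell_size,
                    cy - buffer_radius + (j + 1) * cell_size,
                )
                clipped = cell.intersection(disc)
                if clipped.area > 0:
                    cells.append(clipped)
        order = rng.permutation(len(cells))
        quota = _class_quota(label, rng)
        total_area = sum(c.area for c in cells)
        # fill class quotas by cumulative area over a random cell order
        assignment = {}
        classes = list(quota)
        bounds = np.cumsum([quota[c] for c in classes]) * total_area
        acc = 0.0
        k = 0
        for idx in order:
            while k < len(classes) - 1 and acc >= bounds[k]:
                k += 1
            assignment[idx] = classes[k]
            acc += cells[idx].area
        site_patches = []
        for cls in classes:
            cls_cells = [cells[i] for i, c in assignment.items() if c == cls]
            if not cls_cells:
                continue
            merged = unary_union(cls_cells)
            polys = getattr(merged, "geoms", [merged])
            for poly in polys:
                site_patches.append(
                    LandUsePatch(site_id=site, landuse=cls, geometry=poly)
                )
        patches_by_site[site] = site_patches
        truth.site_habitat[site] = str(label)
        coords.append({"site_id": site, "lon": cx, "lat": cy})
    coord_table = pd.DataFrame(coords).set_index("site_id")
    return patches_by_site, coord_table, truth


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _calibrate_intercept(
    richness_target: float,
    n_species: int,
    affinity_strength: float,
    p_match: float,
) -> float:
    """Solve the occupancy intercept so mean richness hits the target."""
    target_rate = richness_target / n_species

    def gap(b):
        return (
            p_match * expit(b + affinity_strength)
            + (1 - p_match) * expit(b)
            - target_rate
        )

    return brentq(gap, -30.0, 30.0)


def gen_communities(
    colour_table: pd.DataFrame,
    phylogeny: dendropy.Tree,
    site_labels: dict[str, str] | pd.Series,
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Binary site x species matrix from logistic habitat-affinity occupancy.

    Each species is assigned one affinity habitat (drawn from the habitat
    mix); presence probability is expit(b + a * match) where ``a`` is the
    affinity strength and ``b`` is calibrated so mean richness is close to
    the richness target.  Sites are resampled until they hold >= 2 species.
    """
    if scenario.richness_target < 2:
        raise InvalidParameterError("richness_target must be >= 2")
    species = list(colour_table.index)
    tree_tips = {leaf.taxon.label for leaf in phylogeny.leaf_node_iter()}
    if set(species) != tree_tips:
        raise InvalidParameterError("colour table and tree species sets differ")
    rng = _rng(scenario.seed, "community")
    labels = list(scenario.habitat_mix)
    probs = np.array([scenario.habitat_mix[h] for h in labels])
    affinity = rng.choice(labels, size=len(species), p=probs)
    p_match = float((probs**2).sum())
    b = _calibrate_intercept(
        scenario.richness_target, len(species), scenario.affinity_strength, p_match
    )
    if isinstance(site_labels, pd.Series):
        site_labels = site_labels.to_dict()
    sites = list(site_labels)
    matrix = np.zeros((len(sites), len(species)), dtype=int)
    for si, site in enumerate(sites):
        habitat = site_labels[site]
        logits = b + scenario.affinity_strength * (affinity == habitat)
        p = expit(logits)
        row = rng.random(len(species)) < p
        while row.sum() < 2:  # guarantee a community PSV/Gini can use
            row = rng.random(len(species)) < p
        matrix[si] = row
    community = pd.DataFrame(matrix, index=sites, columns=species)
    community.index.name = "site_id"
    truth = GroundTruth(
        species_affinity=dict(zip(species, map(str, affinity))),
        site_habitat={s: str(l) for s, l in site_labels.items()},
        planted_coefficients=dict(scenario.planted_coefficients),
    )
    return community, truth


# ---------------------------------------------------------------------------
# direct linear-model scenario
# ---------------------------------------------------------------------------

#: Distributions of the direct-scenario predictors (documented defaults):
#: LUR ~ 1 + Binomial(9, 0.4); WEDGE ~ Gamma(k=3, theta=1500) metres;
#: richness ~ 2 + Poisson(15); PSV ~ Beta(10, 5); lon ~ U(6.6, 18.5);
#: lat ~ U(36.6, 47.1) (degrees, roughly the Italian peninsula's extent).
DIRECT_PREDICTORS = ("lur", "wedge", "richness", "psv", "lon", "lat")


def gen_inequality_scenario(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Site table with colour inequality generated from planted coefficients.

    response = intercept + sum(coef * predictor) + habitat random offset
    (SD ``group_sd``) + Gaussian noise (SD ``noise_sd``); the ground truth
    echoes the planted coefficients.
    """
    coefs = scenario.planted_coefficients
    missing = [p for p in DIRECT_PREDICTORS if p not in coefs]
    if missing:
        raise InvalidParameterError(f"missing planted coefficients: {missing}")
    rng = _rng(scenario.seed, "direct")
    n = scenario.n_sites
    labels = list(scenario.habitat_mix)
    probs = np.array([scenario.habitat_mix[h] for h in labels])
    data = pd.DataFrame(
        {
            "habitat": rng.choice(labels, size=n, p=probs),
            "lur": 1 + rng.binomial(9, 0.4, size=n),
            "wedge": rng.gamma(3.0, 1500.0, size=n),
            "richness": 2 + rng.poisson(15.0, size=n),
            "psv": rng.beta(10.0, 5.0, size=n),
            "lon": rng.uniform(6.6, 18.5, size=n),
            "lat": rng.uniform(36.6, 47.1, size=n),
        },
        index=site_ids(n),
    )
    data.index.name = "site_id"
    eta = np.full(n, float(coefs.get("intercept", 0.0)))
    for pred in DIRECT_PREDICTORS:
        eta += coefs[pred] * data[pred].to_numpy(dtype=float)
    group_offsets = {h: rng.normal(0.0, scenario.group_sd) for h in labels}
    eta += np.array([group_offsets[h] for h in data["habitat"]])
    data["gini"] = eta + rng.normal(0.0, scenario.noise_sd, size=n)
    truth = GroundTruth(
        site_habitat=dict(zip(data.index, data["habitat"].astype(str))),
        planted_coefficients=dict(coefs),
    )
    return data, truth
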