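"""Synthetic destructive-sampling data with realistic vertical WD structure.

The generator emulates a multi-site tropical destructive-sampling campaign:
a pool of species spanning the full tropical wood-density range
(~0.22-1.02 g.cm^-3), trees assigned to species and sites, six vertical
compartments per tree (stump to small branches), and two wedge samples plus
field log measurements per compartment.

The central statistical feature is the coupling between a tree's vertical
WD gradient and its basal wood density: dense-wood (shade-tolerant) trees
tend to decrease in WD from stump to branch tips, light-wood (pioneer)
trees stay flat or increase. The per-tree stump-to-small-branch WD change is

    G = gradient_slope * (wd_pivot - WD_basal) + eps,   eps ~ N(0, slope_sd)

and compartment k (rank 0..5) has expected WD
``WD_basal + G*k/5 + quad_coeff*(k/5)^2``. With the default preset this
yields a population in which roughly 83% of trees have decreasing profiles
and the mean small-branch-to-stump difference is about -13% of the stump
WD, while the gradient direction correlates negatively with basal WD --
the regime in which naive volume-to-mass conversion with a basal or
database WD systematically overestimates biomass.

All randomness flows through a single ``numpy`` Generator seeded from
``SimulationConfig.seed``; identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .compartments import COMPARTMENTS, STEM, STEM_BASE, STUMP
from .fieldcalc import truncated_cone_volume

__all__ = [
    "SpeciesInfo",
    "SimulationConfig",
    "TrueTree",
    "generate_species_pool",
    "generate_trees",
    "generate_samples",
    "generate_logs",
    "generate_phylogeny",
    "generate_dataset",
    "write_dataset",
]

GUILDS = ("P", "NPLD", "ST")

#: Expected compartment volume fractions (Stu, Ste_b, Ste, LB, MB, SB):
#: dominant-trunk trees with a modest crown.
DEFAULT_VOLUME_FRACTIONS = (0.05, 0.05, 0.55, 0.20, 0.10, 0.05)


@dataclass(frozen=True)
class SpeciesInfo:
    species_id: str
    family: str
    WD_GWD: float  # database species-average wood density, g.cm^-3
    guild: str  # P | NPLD | ST


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic campaign. Defaults are the study preset."""

    n_species: int = 51
    n_trees: int = 822
    n_sites: int = 6
    #: coupling of the vertical gradient to basal WD (dimensionless)
    gradient_slope: float = 0.45
    #: basal WD at which profiles flip from decreasing to increasing, g.cm^-3
    wd_pivot: float = 0.36
    #: optional curvature of the profile in relative rank, g.cm^-3
    quad_coeff: float = 0.0
    #: per-tree gradient scatter around the coupling line, g.cm^-3
    slope_sd: float = 0.035
    #: per-compartment measurement-scale WD noise, g.cm^-3
    noise_sd_wd: float = 0.02
    #: relative (lognormal-scale) noise on sample masses and volumes
    noise_sd_mass: float = 0.02
    #: per-tree basal WD scatter around the species mean, g.cm^-3
    basal_sd: float = 0.05
    #: SD of the additive site intercept on basal WD (0 = no site effect)
    site_sd: float = 0.0
    #: probability that a tree lacks a distinct stem base (no Ste_b samples)
    drop_stem_base_prob: float = 0.1
    #: expected compartment volume fractions, Dirichlet-centred
    volume_fractions: tuple[float, ...] = DEFAULT_VOLUME_FRACTIONS
    #: Dirichlet concentration (higher = less tree-to-tree variation)
    dirichlet_conc: float = 120.0
    #: "mixed" (trunk coned, branches weighed) | "coned" | "weighed"
    log_mode: str = "mixed"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_species, self.n_trees, self.n_sites) < 1:
            raise ValueError("counts n_species, n_trees, n_sites must be >= 1")
        if self.noise_sd_wd < 0 or self.noise_sd_mass < 0 or self.slope_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.drop_stem_base_prob <= 1.0:
            raise ValueError("drop_stem_base_prob must be in [0, 1]")
        if len(self.volume_fractions) != 6 or abs(sum(self.volume_fractions) - 1) > 1e-9:
            raise ValueError("volume_fractions must be 6 values summing to 1")
        if self.log_mode not in ("mixed", "coned", "weighed"):
            raise ValueError(f"unknown log_mode {self.log_mode!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for one generation stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[stream]]))


_STREAMS = {
    "species": 0,
    "trees": 1,
    "samples": 2,
    "logs": 3,
    "phylogeny": 4,
}


@dataclass(frozen=True)
class TrueTree:
    """Ground-truth state of one simulated tree."""

    tree_id: str
    species_id: str
    site: str
    DBH: float  # cm
    H: float  # m
    Ht: float  # m
    Cr: float  # m
    wd_true: dict[str, float] = field(default_factory=dict)  # per compartment
    mc_true: dict[str, float] = field(default_factory=dict)
    volume_true: dict[str, float] = field(default_factory=dict)  # cm^3
    has_stem_base: bool = True


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

def generate_species_pool(config: SimulationConfig) -> list[SpeciesInfo]:
    """Draw the species pool spanning the tropical WD range.

    WD_GWD is uniform on [0.22, 1.02]; the regeneration guild is drawn with
    probabilities that shift from pioneer (P) at low WD to shade-tolerant
    (ST) at high WD, via Bernstein weights on the normalized WD.
    """
    config.validate()
    rng = config.rng("species")
    n = config.n_species
    wd = np.sort(rng.uniform(0.22, 1.02, size=n))
    # ~16 families, contiguous in an arbitrary (non-WD) order
    n_fam = max(1, round(n * 16 / 51))
    fam_of = rng.integers(0, n_fam, size=n)
    pool = []
    for i in range(n):
        z = (wd[i] - 0.22) / 0.80
        probs = np.array([(1 - z) ** 2, 2 * z * (1 - z), z**2])
        guild = rng.choice(GUILDS, p=probs / probs.sum())
        pool.append(
            SpeciesInfo(
                species_id=f"sp{i + 1:03d}",
                family=f"fam{fam_of[i] + 1:02d}",
                WD_GWD=float(wd[i]),
                guild=str(guild),
            )
        )
    return pool


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def generate_trees(
    pool: list[SpeciesInfo], config: SimulationConfig
) -> list[TrueTree]:
    """Simulate tree structure, true compartment WD profiles and volumes."""
    if not pool:
        raise ValueError("species pool is empty")
    config.validate()
    rng = config.rng("trees")
    n = config.n_trees
    sites = [f"site{j + 1}" for j in range(config.n_sites)]
    site_effect = (
        rng.normal(0.0, config.site_sd, size=config.n_sites)
        if config.site_sd > 0
        else np.zeros(config.n_sites)
    )

    # species abundances are uneven but no species dominates the campaign
    # (most-sampled species around 5-6% of trees, a tail of rare ones)
    weights = rng.dirichlet(np.full(len(pool), 4.0))
    sp_idx = rng.choice(len(pool), size=n, p=weights)

    # each species occurs at a random subset of sites (many at only 1-2)
    sites_of_species = []
    for _ in pool:
        k = 1 + rng.binomial(config.n_sites - 1, 0.35)
        sites_of_species.append(rng.choice(config.n_sites, size=k, replace=False))

    base = np.asarray(config.volume_fractions)
    trees: list[TrueTree] = []
    for i in range(n):
        sp = pool[sp_idx[i]]
        site_i = int(rng.choice(sites_of_species[sp_idx[i]]))

        dbh = float(np.clip(rng.lognormal(math.log(40.0), 0.45), 10.0, 180.0))
        h = float(np.clip(math.exp(0.95 + 0.55 * math.log(dbh)) * rng.lognormal(0, 0.08), 5.0, 60.0))
        sm = float(rng.beta(11, 9))
        ht = sm * h
        cr = float(0.12 * dbh * rng.lognormal(0, 0.2))

        wd_basal = float(
            np.clip(sp.WD_GWD + site_effect[site_i] + rng.normal(0, config.basal_sd), 0.15, 1.15)
        )
        grad = config.gradient_slope * (config.wd_pivot - wd_basal) + rng.normal(
            0, config.slope_sd
        )
        rel_rank = np.arange(6) / 5.0
        mu = wd_basal + grad * rel_rank + config.quad_coeff * rel_rank**2
        wd_c = np.clip(mu + rng.normal(0, config.noise_sd_wd, size=6), 0.08, 1.40)
        mc_c = rng.uniform(-0.55, -0.25, size=6)

        # total fresh volume: form factor x basal area x height
        v_total = 0.35 * math.pi / 4.0 * dbh**2 * (h * 100.0)
        fracs = rng.dirichlet(base * config.dirichlet_conc)
        volumes = v_total * fracs

        trees.append(
            TrueTree(
                tree_id=f"t{i + 1:04d}",
                species_id=sp.species_id,
                site=sites[site_i],
                DBH=dbh,
                H=h,
                Ht=ht,
                Cr=cr,
                wd_true=dict(zip(COMPARTMENTS, wd_c.tolist())),
                mc_true=dict(zip(COMPARTMENTS, mc_c.tolist())),
                volume_true=dict(zip(COMPARTMENTS, volumes.tolist())),
                has_stem_base=bool(rng.random() >= config.drop_stem_base_prob),
            )
        )
    return trees


# ---------------------------------------------------------------------------
# Wedge samples and field logs
# ---------------------------------------------------------------------------

def _sampled_compartments(tree: TrueTree) -> list[str]:
    return [c for c in COMPARTMENTS if c != STEM_BASE or tree.has_stem_base]


def generate_samples(
    tree: TrueTree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Two wedge samples per sampled compartment (Ste_b possibly absent).

    Each sample's fresh volume is drawn uniformly, its dry mass set by the
    compartment's true WD and its fresh mass by the compartment's true
    moisture content; ``noise_sd_mass`` then perturbs all three on the log
    scale, so at zero noise ``m_d/v_f`` equals the true WD exactly.
    """
    config.validate()
    if rng is None:
        rng = config.rng("samples")
    rows = []
    for comp in _sampled_compartments(tree):
        wd = tree.wd_true[comp]
        mc = tree.mc_true[comp]
        for k in range(2):
            v_f = rng.uniform(25.0, 60.0)
            mc_i = float(np.clip(mc + 0.5 * config.noise_sd_mass * rng.normal(), -0.65, -0.10))
            m_d = wd * v_f
            m_f = m_d / (1.0 + mc_i)
            noise = np.exp(rng.normal(0.0, config.noise_sd_mass, size=3))
            rows.append(
                {
                    "tree_id": tree.tree_id,
                    "compartment": comp,
                    "sample_no": k + 1,
                    "m_f": m_f * noise[0],
                    "v_f": v_f * noise[1],
                    "m_d": min(m_d * noise[2], m_f * noise[0] * 0.95),
                }
            )
    return pd.DataFrame(rows)


def generate_logs(
    tree: TrueTree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Field measurements reproducing each compartment's true volume.

    Trunk compartments (and all compartments in ``log_mode="coned"``) are
    emitted as truncated-cone logs whose geometry integrates exactly to the
    true volume; branch compartments are weighed fresh, with the fresh mass
    consistent with the compartment's true WD and moisture content.
    """
    config.validate()
    if rng is None:
        rng = config.rng("logs")
    rows = []
    for comp in COMPARTMENTS:
        v_comp = tree.volume_true[comp]
        if config.log_mode == "coned":
            coned = True
        elif config.log_mode == "weighed":
            coned = False
        else:
            coned = comp in (STUMP, STEM_BASE, STEM)
        n_logs = int(np.clip(1 + v_comp // 3.0e5, 1, 4))
        splits = rng.dirichlet(np.full(n_logs, 8.0)) * v_comp
        for v_log in splits:
            if coned:
                h = float(rng.uniform(100.0, 200.0))
                taper = float(rng.uniform(0.7, 0.95))
                # V = pi*h/3 * r1^2 (1 + taper + taper^2)  ->  solve for r1
                r1 = math.sqrt(3.0 * v_log / (math.pi * h * (1 + taper + taper**2)))
                rows.append(
                    {
                        "tree_id": tree.tree_id,
                        "compartment": comp,
                        "kind": "coned",
                        "fresh_mass": np.nan,
                        "r1": r1,
                        "r2": r1 * taper,
                        "h": h,
                        "volume": np.nan,
                    }
                )
            else:
                m_f = v_log * tree.wd_true[comp] / (1.0 + tree.mc_true[comp])
                rows.append(
                    {
                        "tree_id": tree.tree_id,
                        "compartment": comp,
                        "kind": "weighed",
                        "fresh_mass": m_f,
                        "r1": np.nan,
                        "r2": np.nan,
                        "h": np.nan,
                        "volume": np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def generate_phylogeny(pool: list[SpeciesInfo], config: SimulationConfig) -> str:
    """Random ultrametric (pure-birth) phylogeny over the species labels.

    Returned as a newick string with branch lengths; total root-to-tip
    depth is scaled to 1. Deterministic given the config seed.
    """
    if len(pool) < 2:
        raise ValueError("a phylogeny requires at least 2 species")
    rng = config.rng("phylogeny")
    labels = [sp.species_id for sp in pool]

    # Yule process grown forward: start with one lineage, split a random
    # lineage at exponential waiting times until all tips exist.
    n = len(labels)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    order = rng.permutation(n)
    for node, k in zip(active, order):
        node.taxon = taxa.get_taxon(labels[k])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = 0.0
        else:
            end = node.birth_time if not node.is_leaf() else t_end
            node.edge.length = end - node.parent_node.birth_time
    # normalise depth to 1
    for node in tree.preorder_node_iter():
        node.edge.length = (node.edge.length or 0.0) / t_end
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame | str]:
    """Generate all tables of one synthetic campaign.

    Returns a dict with ``species``, ``trees``, ``samples``, ``logs``
    DataFrames, the ``phylogeny`` newick string, and ``truth`` (per-tree,
    per-compartment true WD and volume, for validation only).
    """
    config.validate()
    pool = generate_species_pool(config)
    trees = generate_trees(pool, config)
    s_rng = config.rng("samples")
    l_rng = config.rng("logs")
    samples = pd.concat(
        [generate_samples(t, config, s_rng) for t in trees], ignore_index=True
    )
    logs = pd.concat([generate_logs(t, config, l_rng) for t in trees], ignore_index=True)

    species_df = pd.DataFrame(
        {
            "species_id": [sp.species_id for sp in pool],
            "family": [sp.family for sp in pool],
            "WD_GWD": [sp.WD_GWD for sp in pool],
            "guild": [sp.guild for sp in pool],
        }
    )
    trees_df = pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in trees],
            "species_id": [t.species_id for t in trees],
            "site": [t.site for t in trees],
            "DBH": [t.DBH for t in trees],
            "H": [t.H for t in trees],
            "Ht": [t.Ht for t in trees],
            "Cr": [t.Cr for t in trees],
        }
    )
    truth = pd.DataFrame(
        [
            {
                "tree_id": t.tree_id,
                "compartment": c,
                "wd_true": t.wd_true[c],
                "volume_true": t.volume_true[c],
            }
            for t in trees
            for c in COMPARTMENTS
        ]
    )
    phylo = generate_phylogeny(pool, config) if len(pool) >= 2 else ""
    return {
        "species": species_df,
        "trees": trees_df,
        "samples": samples,
        "logs": logs,
        "phylogeny": phylo,
        "truth": truth,
    }


def write_dataset(dataset: dict, out_dir) -> list[str]:
    """Write the generated tables as CSV (+ phylogeny.nwk); returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("species", "trees", "samples", "logs", "truth"):
        path = out / f"{name}.csv"
        dataset[name].to_csv(path, index=False)
        written.append(str(path))
    if dataset.get("phylogeny"):
        path = out / "phylogeny.nwk"
        path.write_text(dataset["phylogeny"] + "\n")
        written.append(str(path))
    return written
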