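"""Synthetic metacommunities under controlled assembly regimes.

Generates a birth-death phylogeny, Brownian niche optima on it, a
coastline-like landscape with an estuarine gradient in the driving
environmental variable, and OTU count tables assembled under one of four
regimes (selection, dispersal_limitation, homogenizing_dispersal, drift).
Every artifact round-trips through the standard input formats, so the whole
pipeline is testable without external data.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import OTUTable, SampleMetadata
from .spatial import haversine_km

REGIMES = ("selection", "dispersal_limitation", "homogenizing_dispersal", "drift")


@dataclass
class ScenarioConfig:
    """Knobs of the generator; defaults give 17 two-layer estuarine sites."""

    n_sites: int = 17
    n_taxa: int = 300
    birth_rate: float = 1.0
    death_rate: float = 0.5
    niche_signal: float = 10.0  # Brownian variance per unit branch length
    env_gradient: tuple[float, float] = (1.82, 32.17)  # driving variable range
    selection_sigma: float = 2.5  # niche breadth, same units as the gradient
    dispersal_scale_km: float = 25.0  # exponential kernel length
    migration: float = 0.01  # weight of the shared pool mixed into every sample
    depth: int = 10_000  # individuals per sample
    drift_depth: int = 500
    drift_sigma: float = 0.5  # per-sample lognormal abundance drift
    pool_sigma: float = 2.0  # lognormal sd of regional abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.depth < 1 or self.drift_depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("birth_rate", "death_rate", "niche_signal", "selection_sigma",
                     "dispersal_scale_km", "migration", "pool_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.env_gradient
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("env_gradient must be a finite increasing range")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one scenario seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Tree and niches
# ---------------------------------------------------------------------------


def simulate_tree(config: ScenarioConfig) -> dendropy.Tree:
    """Birth-death tree conditioned on ``n_taxa`` extant tips.

    Tips are relabelled OTU_1..OTU_n in leaf order.  The sampler can stop a
    run at a synchronous speciation event, leaving zero-length terminal
    edges; those are nudged to a small positive length so that every branch
    length is strictly positive.
    """
    rng = random.Random(zlib.crc32(f"{config.seed}:tree".encode()))
    last_err = None
    for _ in range(20):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_taxa,
                rng=rng,
            )
            break
        except Exception as err:  # extinct clade; retry with advanced rng state
            last_err = err
    else:
        raise RuntimeError(f"birth-death simulation failed after retries: {last_err}")
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
    eps = max(max(lengths), 1.0) * 1e-6
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"OTU_{i}"
    return tree


def evolve_niches(tree: dendropy.Tree, rate: float, seed: int,
                  root_value: float = 0.0) -> dict[str, float]:
    """Brownian-motion niche optima along the tree from ``root_value``.

    Each branch adds a Normal(0, rate * branch_length) increment, so sibling
    tips separated by short branches get similar optima (phylogenetic niche
    conservatism).  Returns tip label -> optimum.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    value = {tree.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            length = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(rate * length))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return out


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

_BASE_LAT = 21.8
_BASE_LON = 112.6
_LON_SPAN = 2.5  # ~ 240 km east-west at this latitude
_LAT_SPAN = 0.8  # ~ 90 km arc amplitude


def simulate_landscape(config: ScenarioConfig) -> SampleMetadata:
    """Sites along a coastline-like arc with an estuarine gradient.

    Each site yields a surface and a bottom sample.  The driving variable
    ("salinity") increases monotonically along the axis and spans exactly
    the configured range; depth, DO and turbidity get layer-specific means.
    """
    rng = substream(config.seed, "landscape")
    n = config.n_sites
    t = np.linspace(0.0, 1.0, n)
    lat = _BASE_LAT + _LAT_SPAN * np.sin(np.pi * t)
    lon = _BASE_LON + _LON_SPAN * t
    lo, hi = config.env_gradient
    sal = lo + (hi - lo) * t
    if n > 2:  # jitter interior values, keep endpoints exact and order monotone
        jitter = rng.normal(0.0, 0.01 * (hi - lo), size=n - 2)
        sal[1:-1] = np.clip(sal[1:-1] + jitter, lo, hi)
        sal[1:-1] = np.sort(sal[1:-1])
    site_depth = rng.uniform(6.0, 30.0, size=n)
    offshore = 5.0 + 55.0 * np.abs(np.sin(2.0 * np.pi * t)) + rng.uniform(0, 5, size=n)

    rows = []
    for i in range(n):
        site = f"site{i + 1:02d}"
        for layer in ("surface", "bottom"):
            do_mean = 6.5 if layer == "surface" else 3.5
            turb_mean = 5.0 if layer == "surface" else 12.0
            rows.append(
                {
                    "sample_id": f"{site}_{'S' if layer == 'surface' else 'B'}",
                    "site_id": site,
                    "layer": layer,
                    "latitude": float(lat[i]),
                    "longitude": float(lon[i]),
                    "salinity": float(sal[i]),
                    "DO": float(max(rng.normal(do_mean, 1.5), 0.1)),
                    "turbidity": float(rng.lognormal(np.log(turb_mean), 0.4)),
                    "TALK": float(rng.normal(120.0, 12.0)),
                    "depth": 0.5 if layer == "surface" else float(site_depth[i]),
                    "offshore_distance": float(offshore[i]),
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def assemble_communities(
    regime: str,
    tree: dendropy.Tree,
    niches: dict[str, float] | None,
    landscape: SampleMetadata,
    config: ScenarioConfig,
) -> OTUTable:
    """Multinomial count table under one assembly regime.

    selection
        expected abundance of taxon t at sample s is a Gaussian niche match
        exp(-(E_s - mu_t)^2 / (2 sigma^2)) with Brownian niche optima.
    dispersal_limitation
        each taxon gets a random spatial centre; expected abundance is its
        regional log-normal weight times exp(-d_km / dispersal_scale_km).
    homogenizing_dispersal
        every sample is a multinomial draw from one shared regional pool at
        full depth.
    drift
        independent shallow multinomial draws from the shared pool, with each
        sample's expected abundances first perturbed by i.i.d. lognormal
        noise (demographic stochasticity).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    rng = substream(config.seed, f"assembly:{regime}")
    taxa = _tip_labels(tree)
    n_taxa = len(taxa)
    samples = landscape.sample_ids
    pool = rng.lognormal(0.0, config.pool_sigma, size=n_taxa)
    pool /= pool.sum()

    counts = np.zeros((n_taxa, len(samples)))
    if regime == "selection":
        if niches is None:
            raise ValueError("selection regime needs niche optima")
        mu = np.array([niches[t] for t in taxa])
        # linearly standardise the Brownian optima onto the gradient: the
        # root value wanders seed to seed, and an affine map preserves the
        # phylogenetic correlation structure that the niche signal encodes
        lo, hi = config.env_gradient
        sd = mu.std()
        if sd > 0:
            mu = (lo + hi) / 2.0 + (mu - mu.mean()) * ((hi - lo) / 4.0) / sd
        env = landscape.get("salinity").to_numpy(dtype=float)
        sigma = config.selection_sigma
        for j in range(len(samples)):
            lam = np.exp(-((env[j] - mu) ** 2) / (2.0 * sigma**2))
            lam = (1.0 - config.migration) * lam / lam.sum() + config.migration * pool
            counts[:, j] = rng.multinomial(config.depth, lam / lam.sum())
    elif regime == "dispersal_limitation":
        lat = rng.uniform(_BASE_LAT, _BASE_LAT + _LAT_SPAN, size=n_taxa)
        lon = rng.uniform(_BASE_LON, _BASE_LON + _LON_SPAN, size=n_taxa)
        coords = landscape.coordinates()
        for j in range(len(samples)):
            d = np.array(
                [haversine_km(coords[j, 0], coords[j, 1], lat[i], lon[i]) for i in range(n_taxa)]
            )
            lam = pool * np.exp(-d / config.dispersal_scale_km)
            lam = (1.0 - config.migration) * lam / lam.sum() + config.migration * pool
            counts[:, j] = rng.multinomial(config.depth, lam / lam.sum())
    elif regime == "homogenizing_dispersal":
        for j in range(len(samples)):
            counts[:, j] = rng.multinomial(config.depth, pool)
    else:  # drift: demographic stochasticity perturbs each sample's
        # abundances around the shared pool, then a shallow multinomial draw
        for j in range(len(samples)):
            lam = pool * np.exp(rng.normal(0.0, config.drift_sigma, size=n_taxa))
            counts[:, j] = rng.multinomial(config.drift_depth, lam / lam.sum())

    table = OTUTable(list(taxa), list(samples), counts)
    # guard against an (improbable) empty sample at tiny depths
    zero = np.flatnonzero(table.counts.sum(axis=0) == 0)
    for j in zero:
        k = int(rng.integers(n_taxa))
        table.counts[k, j] = 1.0
    return table


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    regime: str
    config: ScenarioConfig
    tree: dendropy.Tree
    niches: dict[str, float]
    metadata: SampleMetadata
    table: OTUTable


def generate_scenario(regime: str, config: ScenarioConfig | None = None, **overrides) -> Scenario:
    """Full scenario from one seed via named substreams (tree, niches,
    landscape, assembly)."""
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        config = ScenarioConfig(**{**asdict(config), **overrides})
    tree = simulate_tree(config)
    lo, hi = config.env_gradient
    niches = evolve_niches(
        tree,
        config.niche_signal,
        seed=zlib.crc32(f"{config.seed}:niches".encode()),
        root_value=(lo + hi) / 2.0,
    )
    landscape = simulate_landscape(config)
    table = assemble_communities(regime, tree, niches, landscape, config)
    return Scenario(regime, config, tree, niches, landscape, table)


def write_scenario(directory, scenario: Scenario) -> dict[str, str]:
    """Emit table.tsv, tree.nwk, meta.csv and truth.json in pipeline formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": directory / "table.tsv",
        "tree": directory / "tree.nwk",
        "meta": directory / "meta.csv",
        "truth": directory / "truth.json",
    }
    scenario.table.write_tsv(paths["table"])
    scenario.tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=False)
    scenario.metadata.write_csv(paths["meta"])
    truth = {
        "regime": scenario.regime,
        "config": {
            **asdict(scenario.config),
            "env_gradient": list(scenario.config.env_gradient),
        },
        "niches": {k: float(v) for k, v in sorted(scenario.niches.items())},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
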