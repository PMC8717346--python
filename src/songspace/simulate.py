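"""Synthetic data generator for the full analysis pipeline.

Emulates the hierarchical structure of a multi-population, multi-species
sexed song dataset: species mean acoustic phenotypes evolve by Brownian
motion on a simulated ultrametric tree; populations, individuals, songs and
elements add nested Gaussian perturbations; males receive a configurable
shift on designated "elaboration" features, optionally modulated by
population-level life-history covariates so that a sex-by-covariate
interaction of known magnitude is planted. Element timing is driven by the
same latent structure, so derived song duration and element rate carry the
planted effects. The default preset mirrors a 9-species / 15-population
study layout (one species with five sampled populations, two with two,
the rest with one).

All randomness flows from one master seed through counter-derived child
seeds, so any stage regenerates independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io import ELEMENT_FEATURES
from .phylo import phylo_vcv

__all__ = ["SimConfig", "simulate_tree", "simulate_dataset",
           "simulate_null_dataset"]

#: Features whose male shift carries the planted elaboration signal.
DEFAULT_ELABORATION_FEATURES = ("duration_90", "entropy", "modulation_index")

_COVARIATE_RANGES = {
    "epp": (0.05, 0.70),
    "brood_size": (2.0, 4.0),
    "breeding_synchrony": (0.1, 0.9),
    "group_size": (2.0, 6.0),
    "breeding_male_density": (0.2, 2.0),
    "male_provisioning": (0.2, 0.6),
    "male_survival": (0.4, 0.9),
    "latitude": (-38.0, -7.0),
}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study-shaped preset."""

    n_species: int = 9
    populations_per_species: tuple[int, ...] = (5, 2, 2, 1, 1, 1, 1, 1, 1)
    individuals_per_population: int = 4
    songs_per_individual: int = 3
    elements_per_song: tuple[int, int] = (4, 9)
    n_features: int = len(ELEMENT_FEATURES)
    sex_effect: dict = field(default_factory=lambda: {
        "duration_90": 1.0, "entropy": 1.0, "modulation_index": 1.0})
    elaboration_features: tuple[str, ...] = DEFAULT_ELABORATION_FEATURES
    lifehistory_slopes: dict = field(default_factory=dict)
    bm_sigma2: float = 1.0
    population_sd: float = 0.5
    individual_sd: float = 0.5
    song_sd: float = 0.3
    element_sd: float = 1.0
    sex_ratio: float = 0.5
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.populations_per_species) != self.n_species:
            raise ValueError("populations_per_species must have n_species entries")
        if self.elements_per_song[0] > self.elements_per_song[1]:
            raise ValueError("elements_per_song range is empty")
        if not 8 <= self.n_features <= len(ELEMENT_FEATURES):
            raise ValueError(f"n_features must be in [8, {len(ELEMENT_FEATURES)}]")
        if min(self.population_sd, self.individual_sd, self.song_sd,
               self.element_sd) < 0:
            raise ValueError("hierarchical SDs must be >= 0")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return ELEMENT_FEATURES[: self.n_features]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth tree with depth normalized to 1.

    Lineages split at exponential waiting times (rate proportional to the
    number of live lineages) until ``n_species`` tips exist, then all tips
    extend to the present. Tips are labeled ``sp01 ...`` in traversal order.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = _rng(seed, 0)
    # node: [children, birth_time]; leaves carry end time at close
    root = {"t0": 0.0, "children": []}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        kids = [{"t0": t, "children": []}, {"t0": t, "children": []}]
        node["children"] = kids
        active.extend(kids)
    T = t + rng.exponential(1.0 / len(active))

    labels = iter(f"sp{i + 1:02d}" for i in range(n_species))

    def newick(node, parent_t0):
        length = ((node["t0"] if node["children"] else T) - parent_t0) / T
        if node["children"]:
            inner = ",".join(newick(c, node["t0"]) for c in node["children"])
            return f"({inner}):{length:.10f}"
        return f"{next(labels)}:{length:.10f}"

    inner = ",".join(newick(c, 0.0) for c in root["children"])
    s = f"({inner});"
    return dendropy.Tree.get(data=s, schema="newick")


def simulate_dataset(config: SimConfig, tree: dendropy.Tree | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dendropy.Tree]:
    """Generate (element table, life-history table, tree) under ``config``.

    Each element's feature vector is species BM mean + population +
    individual + song + element noise, plus the male sex shift; frequency
    columns are mapped onto a positive Hz-like scale with the element-level
    95% frequency constructed above the 5% one so song-level frequency
    ranges stay non-negative.
    """
    if tree is None:
        tree = simulate_tree(config.n_species, config.seed)
    vcv = phylo_vcv(tree)
    species = vcv.species
    if len(species) != config.n_species:
        raise ValueError("tree tip count does not match n_species")
    feats = list(config.feature_names)
    p = len(feats)
    elab_idx = [feats.index(f) for f in config.elaboration_features if f in feats]

    rng_sp = _rng(config.seed, 1)
    L = np.linalg.cholesky(vcv.C + 1e-12 * np.eye(len(species)))
    species_means = np.sqrt(config.bm_sigma2) * (L @ rng_sp.standard_normal(
        (len(species), p)))

    # populations and their life-history covariates
    rng_lh = _rng(config.seed, 2)
    pop_rows = []
    for s_i, (sp, n_pops) in enumerate(zip(species, config.populations_per_species)):
        for p_i in range(n_pops):
            row = {"population": f"{sp}_pop{p_i + 1}", "species": sp}
            for cov, (lo, hi) in _COVARIATE_RANGES.items():
                row[cov] = rng_lh.uniform(lo, hi)
            pop_rows.append(row)
    lh = pd.DataFrame(pop_rows)
    covs_z = {}
    for cov in _COVARIATE_RANGES:
        col = lh[cov]
        covs_z[cov] = ((col - col.mean()) / (col.std(ddof=1) or 1.0)).to_numpy()

    # male shift per population on each feature; elaboration features add the
    # covariate-modulated component (the planted sex-by-covariate interaction)
    base_shift = np.zeros(p)
    for f, v in config.sex_effect.items():
        if f in feats:
            base_shift[feats.index(f)] = v
    pop_shift = np.tile(base_shift, (len(lh), 1))
    for cov, slope in config.lifehistory_slopes.items():
        pop_shift[:, elab_idx] += slope * covs_z[cov][:, None]

    rng_pop = _rng(config.seed, 3)
    pop_eff = rng_pop.normal(0, config.population_sd, (len(lh), p))
    pop_tempo = rng_pop.normal(0, config.population_sd, len(lh))

    lo_e, hi_e = config.elements_per_song
    rows = []
    for pop_i, pop in lh.iterrows():
        sp_i = species.index(pop["species"])
        rng_p = _rng(config.seed, 4, pop_i)
        shift_scalar = (pop_shift[pop_i, elab_idx].mean() if elab_idx else 0.0)
        n_male = round(config.sex_ratio * config.individuals_per_population)
        for ind_i in range(config.individuals_per_population):
            sex = "male" if ind_i < n_male else "female"
            ind_eff = rng_p.normal(0, config.individual_sd, p)
            ind_tempo = rng_p.normal(0, config.individual_sd)
            for song_i in range(config.songs_per_individual):
                song_eff = rng_p.normal(0, config.song_sd, p)
                song_tempo = rng_p.normal(0, config.song_sd)
                # the elaboration latent drives element count and stretch, so
                # song duration and element rate inherit the planted male
                # shift and its covariate modulation
                latent = (pop_tempo[pop_i] + ind_tempo + song_tempo
                          + (shift_scalar if sex == "male" else 0.0))
                n_e = int(np.clip(round(rng_p.uniform(lo_e, hi_e) + latent),
                                  1, hi_e + 3))
                stretch = float(np.exp(0.5 * np.clip(latent, -4, 4)))
                t = 0.0
                sid = f"{pop['population']}_i{ind_i + 1}_s{song_i + 1}"
                for e_i in range(n_e):
                    dur = 0.12 * stretch * rng_p.uniform(0.7, 1.3)
                    gap = 0.08 * stretch * rng_p.uniform(0.7, 1.3)
                    x = (species_means[sp_i] + pop_eff[pop_i] + ind_eff
                         + song_eff + rng_p.normal(0, config.element_sd, p))
                    if sex == "male":
                        x = x + pop_shift[pop_i]
                    rows.append({
                        "song_id": sid,
                        "individual_id": f"{pop['population']}_i{ind_i + 1}",
                        "population": pop["population"],
                        "species": pop["species"],
                        "sex": sex,
                        "start_time": t,
                        "end_time": t + dur,
                        **dict(zip(feats, x)),
                    })
                    t += dur + gap
    elements = pd.DataFrame(rows)

    # map frequency-like columns onto a positive Hz-ish scale
    for f in ("freq_5", "freq_25", "freq_75", "peak_freq", "mean_freq",
              "median_freq", "max_peak_freq_contour"):
        if f in elements:
            elements[f] = 3500.0 + 500.0 * elements[f]
    if "freq_95" in elements:
        elements["freq_95"] = (elements["freq_5"] + 400.0
                               + 250.0 * np.abs(elements["freq_95"]))

    # blank covariate cells (latitude stays complete: it is always known)
    rng_miss = _rng(config.seed, 5)
    for cov in _COVARIATE_RANGES:
        if cov == "latitude" or config.missing_rate <= 0:
            continue
        mask = rng_miss.random(len(lh)) < config.missing_rate
        lh.loc[mask, cov] = np.nan
    return elements, lh, tree


def simulate_null_dataset(config: SimConfig, tree: dendropy.Tree | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dendropy.Tree]:
    """As :func:`simulate_dataset` with every sex effect and slope forced to 0."""
    null = replace(config, sex_effect={}, lifehistory_slopes={})
    return simulate_dataset(null, tree)
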