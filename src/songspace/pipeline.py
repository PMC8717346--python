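"""End-to-end orchestration of the three comparative analyses.

Given an element table, a per-population life-history table, and a
calibrated ultrametric species tree, the pipeline produces:

- ``run_sex_differences``: per-species out-of-bag sex-classification tables
  (from species-specific acoustic spaces) and per-variable mixed models of
  sex differences;
- ``run_elaboration``: elaboration PC scores (from a global element
  embedding) modeled against each life-history covariate with a
  sex-by-covariate interaction;
- ``run_dimorphism``: per-population acoustic-area dimorphism metrics (from
  a song-level unsupervised-forest NMDS space) modeled against each
  covariate;
- ``run_phylosig``: Blomberg's K per song-level variable from species means.

Element diversity uses the species-specific embedding for the
sex-classification analysis and the global embedding for the elaboration
and dimorphism analyses. Every stage is deterministic given the manifest's
master seed.
"""

from __future__ import annotations

import logging
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .acoustic_space import (RFParams, fit_supervised_rf,
                             fit_unsupervised_rf_proximity, classical_mds,
                             kruskal_nmds, proximity_to_distance)
from .elaboration import ElaborationPCA
from .geometry import balanced_subsample_dimorphism, element_diversity_scores
from .mixedmodel import (CHAIN_PRESETS, ChainSpec, GibbsMixedModel, PriorSpec,
                         RandomEffect, design_matrix, scale_covariates)
from .phylo import blomberg_k, phylo_vcv

__all__ = ["RunManifest", "prepare_song_table", "run_sex_differences",
           "run_elaboration", "run_dimorphism", "run_phylosig", "run_all"]

log = logging.getLogger("songspace")

#: Song-level variables used for the sex-difference and dimorphism spaces.
SONG_SPACE_VARIABLES = ("song_duration", "element_number", "element_rate",
                        "freq_5", "freq_95", "freq_range", "element_diversity")


@dataclass
class RunManifest:
    """Everything that determines a run's outputs, besides code version."""

    seed: int = 1
    n_trees: int = 2000
    min_node_size: int = 1
    mtry_song: int = 3
    mtry_element: int = 5
    mds_vectors: int = 5
    retain: float = 0.95
    dimorphism_iterations: int = 100
    chain_preset: str = "test"
    prune_threshold: float = 0.95
    phylo_random: bool = True
    out_dir: str | None = None

    def chain(self, seed_offset: int = 0) -> ChainSpec:
        base = CHAIN_PRESETS[self.chain_preset]
        return ChainSpec(base.n_iter, base.burn_in, base.thin,
                         (self.seed + seed_offset) % (2**31 - 1))

    def rf(self, mtry: int, seed_offset: int = 0) -> RFParams:
        return RFParams(self.n_trees, self.min_node_size, mtry,
                        (self.seed + seed_offset) % (2**31 - 1))


def _element_embedding(elements: pd.DataFrame, manifest: RunManifest,
                       seed_offset: int = 0) -> np.ndarray:
    """Element acoustic space: prune correlated features, unsupervised-forest
    proximity, classical MDS; returns the first two axes per element row."""
    feats = [f for f in sio.ELEMENT_FEATURES if f in elements.columns]
    X, _, kept = sio.prune_correlated_features(elements[feats],
                                               manifest.prune_threshold)
    P = fit_unsupervised_rf_proximity(
        X.to_numpy(), manifest.rf(min(manifest.mtry_element, len(kept)),
                                  seed_offset))
    emb = classical_mds(P.to_distance(), k=manifest.mds_vectors)
    return emb.coords[:, :2]


def prepare_song_table(elements: pd.DataFrame, manifest: RunManifest,
                       seed_offset: int = 0) -> pd.DataFrame:
    """Song table with the element-diversity column filled from an element
    embedding over the given element rows."""
    t0 = time.perf_counter()
    songs = sio.derive_song_table(elements)
    coords = _element_embedding(elements, manifest, seed_offset)
    scores = element_diversity_scores(coords, elements["song_id"].to_numpy(),
                                      manifest.retain)
    songs["element_diversity"] = songs["song_id"].map(scores)
    log.info("song table (%d songs) in %.1fs", len(songs),
             time.perf_counter() - t0)
    return songs


def _phylo_random_effects(df: pd.DataFrame, tree, include_individual=True,
                          phylo_random=True) -> list[RandomEffect]:
    effects = []
    if include_individual:
        effects.append(RandomEffect("individual", df["individual_id"].to_numpy()))
    if phylo_random and tree is not None:
        vcv = phylo_vcv(tree)
        present = [s for s in vcv.species if s in set(df["species"])]
        sub = vcv.reorder(present)
        effects.append(RandomEffect("species_phylo", df["species"].to_numpy(),
                                    cov=sub.C, cov_levels=sub.species))
    effects.append(RandomEffect(
        "population", (df["species"].astype(str) + ":" +
                       df["population"].astype(str)).to_numpy()))
    return effects


def run_sex_differences(elements: pd.DataFrame, tree, manifest: RunManifest
                        ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Species-by-species sex classification and per-variable sex models.

    Returns ``(classification_table, model_tables)``: the first has one row
    per species (total/female/male OOB % correct); the second maps each
    song-level variable to its mixed-model summary (sex, species and their
    interaction as fixed effects; individual, phylogenetic species effect,
    and population-in-species as random intercepts).
    """
    reports = []
    song_tables = []
    for i, (sp, sub) in enumerate(elements.groupby("species", sort=True)):
        songs = prepare_song_table(sub, manifest, seed_offset=100 + i)
        song_tables.append(songs)
        if songs["sex"].nunique() < 2 or songs["sex"].value_counts().min() < 2:
            log.warning("species %s lacks both sexes; excluded from "
                        "classification", sp)
            continue
        rep = fit_supervised_rf(
            songs[list(SONG_SPACE_VARIABLES)].to_numpy(),
            songs["sex"].to_numpy(),
            manifest.rf(manifest.mtry_song, 200 + i),
            species=sp, feature_names=SONG_SPACE_VARIABLES)
        reports.append({
            "species": sp,
            "total_pct_correct": 100 * (1 - rep.oob_total_error),
            "female_pct_correct": 100 * rep.per_sex_correct.get("female", np.nan),
            "male_pct_correct": 100 * rep.per_sex_correct.get("male", np.nan),
            **{f"importance_{k}": v for k, v in sorted(
                rep.importance.items(), key=lambda kv: -kv[1])},
        })
    classification = pd.DataFrame(reports)

    all_songs = pd.concat(song_tables, ignore_index=True)
    models = {}
    for j, var in enumerate(SONG_SPACE_VARIABLES):
        X = design_matrix(all_songs, ["sex", "species", "sex:species"])
        fit = GibbsMixedModel(PriorSpec(), manifest.chain(300 + j)).fit(
            X, all_songs[var].to_numpy(),
            _phylo_random_effects(all_songs, tree,
                                  phylo_random=manifest.phylo_random))
        models[var] = fit.summary_
    return classification, models


def run_elaboration(elements: pd.DataFrame, lifehistory: pd.DataFrame, tree,
                    manifest: RunManifest,
                    covariates: tuple[str, ...] = sio.LIFE_HISTORY_COVARIATES,
                    n_components: int = 3) -> tuple[pd.DataFrame, "ElaborationPCA"]:
    """Elaboration PCs modeled against each life-history covariate.

    One univariate model per (PC, covariate): covariate, sex and their
    interaction as fixed effects; individual, phylogenetic species effect and
    population-in-species as random intercepts. Populations missing a
    covariate drop out of that covariate's model. Latitude enters as absolute
    degrees. Returns a long table of posterior summaries and the PCA model.
    """
    songs = prepare_song_table(elements, manifest, seed_offset=0)
    pca = ElaborationPCA(n_components_kept=n_components).fit(songs)
    scores = pca.transform(songs)
    data = pd.concat([songs, scores], axis=1)
    lh = lifehistory.copy()
    if "latitude" in lh:
        lh["latitude"] = lh["latitude"].abs()
    data = data.merge(lh, on=["population", "species"], how="left")

    rows = []
    for ci, cov in enumerate(covariates):
        sub = data[data[cov].notna()].reset_index(drop=True)
        if sub.empty or sub[cov].nunique() < 2:
            log.warning("covariate %s unusable; skipped", cov)
            continue
        X = design_matrix(sub, [cov, "sex", f"{cov}:sex"])
        effects = _phylo_random_effects(sub, tree,
                                        phylo_random=manifest.phylo_random)
        for pc_i in range(n_components):
            pc = f"PC{pc_i + 1}"
            fit = GibbsMixedModel(PriorSpec(),
                                  manifest.chain(400 + 10 * ci + pc_i)).fit(
                X, sub[pc].to_numpy(), effects)
            summ = fit.summary_
            for term in summ.index:
                if term == "(Intercept)":
                    continue
                rows.append({"response": pc, "covariate": cov, "term": term,
                             **summ.loc[term].to_dict()})
    return pd.DataFrame(rows), pca


def compute_dimorphism_table(songs: pd.DataFrame, manifest: RunManifest
                             ) -> pd.DataFrame:
    """Song-level NMDS acoustic space and per-population dimorphism metrics."""
    X, _, _ = sio.prune_correlated_features(
        songs[list(SONG_SPACE_VARIABLES)], manifest.prune_threshold)
    P = fit_unsupervised_rf_proximity(
        X.to_numpy(), manifest.rf(min(manifest.mtry_song, X.shape[1]), 500))
    emb = kruskal_nmds(proximity_to_distance(P), k=2,
                       seed=manifest.seed % (2**31 - 1))
    coords = emb.coords
    rows = []
    for pop, sub in songs.groupby("population", sort=True):
        idx = sub.index.to_numpy()
        sexes = sub["sex"].to_numpy()
        male, female = coords[idx][sexes == "male"], coords[idx][sexes == "female"]
        if len(male) == 0 or len(female) == 0:
            log.warning("population %s lacks a sex; skipped", pop)
            continue
        if min(len(male), len(female)) < 3:
            log.warning("population %s has <3 songs for a sex; metrics "
                        "low-confidence", pop)
        res = balanced_subsample_dimorphism(
            male, female, coords[idx],
            n_iter=manifest.dimorphism_iterations,
            seed=(manifest.seed + zlib.crc32(str(pop).encode()) % 10000)
                 % (2**31 - 1),
            retain=manifest.retain, population=pop)
        rows.append({"population": pop, "species": sub["species"].iloc[0],
                     "overlap_prop": res.overlap_prop,
                     "centroid_distance": res.centroid_distance,
                     "area_size_difference": res.area_size_difference,
                     "n_male": res.n_male, "n_female": res.n_female,
                     "seed": res.seed})
    return pd.DataFrame(rows)


def run_dimorphism(elements: pd.DataFrame, lifehistory: pd.DataFrame, tree,
                   manifest: RunManifest,
                   covariates: tuple[str, ...] = sio.LIFE_HISTORY_COVARIATES
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population dimorphism metrics modeled against each covariate.

    One univariate model per (metric, covariate) with the covariate as the
    sole fixed effect and phylogenetic species plus population-in-species
    random intercepts (no individual term: one value per population).
    Returns ``(model_table, dimorphism_table)``.
    """
    songs = prepare_song_table(elements, manifest, seed_offset=0)
    dimorph = compute_dimorphism_table(songs, manifest)
    lh = lifehistory.copy()
    if "latitude" in lh:
        lh["latitude"] = lh["latitude"].abs()
    data = dimorph.merge(lh, on=["population", "species"], how="left")

    rows = []
    metrics = ("overlap_prop", "centroid_distance", "area_size_difference")
    for ci, cov in enumerate(covariates):
        sub = data[data[cov].notna()].reset_index(drop=True)
        if sub.empty or sub[cov].nunique() < 2:
            log.warning("covariate %s unusable; skipped", cov)
            continue
        X = design_matrix(sub, [cov])
        effects = _phylo_random_effects(sub, tree, include_individual=False,
                                        phylo_random=manifest.phylo_random)
        for mi, metric in enumerate(metrics):
            fit = GibbsMixedModel(PriorSpec(),
                                  manifest.chain(600 + 10 * ci + mi)).fit(
                X, sub[metric].to_numpy(), effects)
            summ = fit.summary_
            rows.append({"response": metric, "covariate": cov,
                         **summ.loc[cov].to_dict()})
    return pd.DataFrame(rows), dimorph


def run_phylosig(elements: pd.DataFrame, tree, manifest: RunManifest
                 ) -> pd.DataFrame:
    """Blomberg's K for each song-level variable, from species means."""
    songs = prepare_song_table(elements, manifest, seed_offset=0)
    species = sorted(songs["species"].unique())
    if len(species) < 4:
        raise ValueError("need >= 4 species for phylogenetic signal")
    rows = []
    for var in SONG_SPACE_VARIABLES:
        tips = songs.groupby("species")[var].mean().to_dict()
        rows.append({"variable": var, "K": blomberg_k(tree, tips),
                     "n_species": len(species)})
    return pd.DataFrame(rows)


def _write_manifest_sidecar(manifest: RunManifest, path: Path) -> None:
    import songspace
    lines = ["songspace_version: " + songspace.__version__]
    for k, v in asdict(manifest).items():
        if k != "out_dir":
            lines.append(f"{k}: {v}")
    path.write_text("\n".join(lines) + "\n")


def run_all(elements: pd.DataFrame, lifehistory: pd.DataFrame, tree,
            manifest: RunManifest) -> dict[str, pd.DataFrame]:
    """Run all four analyses; write TSVs (+ metadata sidecar) if
    ``manifest.out_dir`` is set; return the result tables."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    t0 = time.perf_counter()
    classification, sex_models = run_sex_differences(elements, tree, manifest)
    elab, pca = run_elaboration(elements, lifehistory, tree, manifest)
    dim_models, dimorph = run_dimorphism(elements, lifehistory, tree, manifest)
    ktab = run_phylosig(elements, tree, manifest)
    log.info("full pipeline in %.1fs", time.perf_counter() - t0)

    sex_long = pd.concat(
        [df.assign(response=var).rename_axis("term").reset_index()
         for var, df in sex_models.items()], ignore_index=True)
    results = {
        "classification": classification,
        "sex_difference_models": sex_long,
        "elaboration_models": elab,
        "pca_loadings": pca.loadings_table().rename_axis("variable").reset_index(),
        "dimorphism_metrics": dimorph,
        "dimorphism_models": dim_models,
        "phylogenetic_signal": ktab,
    }
    if manifest.out_dir:
        out = Path(manifest.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        _write_manifest_sidecar(manifest, out / "run_metadata.txt")
    return results
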