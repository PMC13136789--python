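"""Orchestration, file I/O, alpha diversity and the end-to-end run.

Counts are stored as TSV with taxa as rows and sample IDs as columns;
metadata as TSV with one row per sample (sample_id, source, dilution,
replicate, day).  ``run_all`` chains synthesis -> founding CV -> OTU-level
modality -> community divergence -> energy landscape -> dynamic regimes,
echoing the configuration and seeds so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence, founding, landscape, modality, regimes, synth
from ._containers import CommunityTable

__all__ = [
    "RunConfig",
    "read_counts",
    "read_metadata",
    "load_table",
    "write_counts",
    "write_metadata",
    "alpha_diversity",
    "temporal_dissimilarity",
    "run_all",
]

log = logging.getLogger("stochassembly")


@dataclass
class RunConfig:
    """Thresholds and seeds for an end-to-end run (one master seed)."""

    seed: int = 0
    n_replicates: int = 24
    sample_days: tuple = (2, 4, 6, 8)
    read_depth: int = 5000
    bootstrap: int = 200
    n_sim: int = 96
    alpha: float = 0.05
    fdr_level: float = 0.05
    pseudocount: float = 0.5
    # presence at "appreciable abundance": the generator's coexisting tail
    # sits near 1-3% relative abundance, so membership patterns only become
    # informative above it
    detection_threshold: float = 0.05
    prevalence_threshold: float = 0.5
    metric: str = "bray_curtis"
    criterion: str = "average_depth"
    ising_mode: str = "pseudolikelihood"
    stages: tuple = ("synth", "founding", "modality", "divergence",
                     "landscape", "regimes")
    counts_path: str | None = None
    metadata_path: str | None = None
    extra: dict = field(default_factory=dict)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must contain a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID {dup!r} in metadata")
    return meta.set_index("sample_id")


def load_table(counts_path, metadata_path) -> CommunityTable:
    """Read counts + metadata, auto-detecting taxa-x-samples orientation."""
    counts = read_counts(counts_path)
    meta = read_metadata(metadata_path)
    cols_hit = sum(c in meta.index for c in counts.columns)
    rows_hit = sum(r in meta.index for r in counts.index)
    if rows_hit > cols_hit:
        counts = counts.T
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise ValueError(f"counts column {missing[0]!r} not found in metadata")
    return CommunityTable(counts.astype(int), meta)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="taxon")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def alpha_diversity(counts) -> pd.DataFrame:
    """Shannon H (natural log), evenness H/ln S, effective number exp(H),
    richness — one row per sample (columns of a taxa x samples table)."""
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    x = df.to_numpy(dtype=float)
    tot = x.sum(axis=0)
    if np.any(tot == 0):
        bad = df.columns[np.where(tot == 0)[0][0]]
        raise ValueError(f"all-zero sample {bad!r}")
    p = x / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=0)
    S = (x > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(S > 1, H / np.log(np.maximum(S, 2)), 1.0)
    return pd.DataFrame({"shannon": H, "evenness": evenness,
                         "effective_number": np.exp(H), "richness": S},
                        index=df.columns)


def temporal_dissimilarity(table: CommunityTable,
                           metrics=("bray_curtis", "jaccard")) -> pd.DataFrame:
    """Mean dissimilarity between consecutive time points per replicate,
    summarized per inoculum setting."""
    rows = []
    for key, sub in table.meta.groupby(["source", "dilution", "replicate"],
                                       sort=True):
        sub = sub.sort_values("day")
        if len(sub) < 2:
            continue
        mat = table.counts[sub.index].T
        for metric in metrics:
            dd = divergence.pairwise_dissimilarity(mat, metric).matrix
            steps = np.diagonal(dd, offset=1)
            for (d_from, d_to), v in zip(
                    zip(sub["day"][:-1], sub["day"][1:], strict=True), steps,
                    strict=True):
                rows.append({"source": key[0], "dilution": key[1],
                             "replicate": key[2], "day_from": d_from,
                             "day_to": d_to, "metric": metric, "value": v})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (df.groupby(["source", "dilution", "metric", "day_from", "day_to"])
            ["value"].mean().rename("mean_dissimilarity").reset_index())


def _common_taxa(table, threshold):
    """Taxa nonzero in at least ``threshold`` of the replicates of a setting."""
    frac = (table.counts > 0).mean(axis=1)
    return list(frac.index[frac >= threshold])


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages in order, writing per-stage TSV/JSON.

    Returns a dict of in-memory results keyed by stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh)
        log.info("run_all seed=%s stages=%s", config.seed, config.stages)

        pools = synth.default_pools()
        if config.counts_path:
            table = load_table(config.counts_path, config.metadata_path)
        else:
            design = synth.default_design(n_replicates=config.n_replicates,
                                          seed=config.seed)
            design.sample_days = tuple(config.sample_days)
            params = [synth.default_dynamics(p, read_depth=config.read_depth)
                      for p in pools]
            table = synth.generate_dataset(pools, design, params)
        if "synth" in config.stages and not config.counts_path:
            write_counts(table.counts, out / "counts.tsv")
            write_metadata(table.meta, out / "metadata.tsv")
            for pool in pools:
                pd.DataFrame({"taxon": pool.taxon_ids,
                              "rel_abundance": pool.rel_abundance}).to_csv(
                    out / f"pool_{pool.name}.tsv", sep="\t", index=False)
        results["table"] = table

        pool_by_source = {p.name: p for p in pools}
        dilutions = sorted(table.meta["dilution"].unique(), reverse=True)

        if "founding" in config.stages:
            results["founding"] = _stage_founding(
                pool_by_source, dilutions, config, out)
        if "modality" in config.stages:
            results["modality"] = _stage_modality(
                table, pool_by_source, config, out,
                results.get("founding"))
        if "divergence" in config.stages:
            results["divergence"] = _stage_divergence(table, config, out)
        if "landscape" in config.stages:
            results["landscape"] = _stage_landscape(table, config, out)
        if "regimes" in config.stages:
            results["regimes"] = _stage_regimes(
                table, config, out, results.get("landscape"))

        results["alpha"] = alpha_diversity(table.counts)
        results["alpha"].to_csv(out / "alpha_diversity.tsv", sep="\t")
        results["temporal"] = temporal_dissimilarity(table)
        results["temporal"].to_csv(out / "temporal_dissimilarity.tsv", sep="\t",
                                   index=False)
        return results
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        log.error("run failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage_founding(pool_by_source, dilutions, config, out):
    rows = []
    for sname, pool in pool_by_source.items():
        for dil in dilutions:
            cv = founding.founding_cv(pool, dil, n_sim=config.n_sim,
                                      seed=np.random.SeedSequence(
                                          [config.seed, 1]),
                                      method="simulate")
            df = cv.to_frame()
            df["source"], df["dilution"] = sname, dil
            loss = founding.simulate_otu_loss(pool, dil, n_sim=config.n_sim,
                                              seed=np.random.SeedSequence(
                                                  [config.seed, 2]))
            df["expected_otu_loss"] = loss.expected_loss
            rows.append(df.reset_index())
    res = pd.concat(rows, ignore_index=True)
    res.to_csv(out / "founding_cv.tsv", sep="\t", index=False)
    return res


def _stage_modality(table, pool_by_source, config, out, founding_df):
    rows = []
    for (src, dil, day), sub in table.meta.groupby(["source", "dilution", "day"],
                                                   sort=True):
        setting = table.subset(sub.index)
        taxa = _common_taxa(setting, config.prevalence_threshold)
        clr = modality.clr_transform(setting.counts.loc[taxa].T,
                                     config.pseudocount)
        depths = setting.counts.sum(axis=0).to_numpy()
        for t_i, taxon in enumerate(taxa):
            res = modality.multimodality_test(
                clr.iloc[:, t_i].to_numpy(), B=config.bootstrap,
                seed=np.random.SeedSequence([config.seed, 3, t_i]),
                alpha=config.alpha)
            wm = modality.within_mode_variation(
                setting.counts.loc[taxon].to_numpy(), depths, res)
            rows.append({"source": src, "dilution": dil, "day": day,
                         "taxon": taxon, "statistic": res.statistic,
                         "p_value": res.p_value, "n_modes": res.n_modes,
                         "sigma_hat": wm.value})
    res = pd.DataFrame(rows)
    if not res.empty and founding_df is not None:
        cv_map = founding_df.set_index(["source", "dilution", "taxon"])["cv"]
        res["cv"] = [cv_map.get((s, d, t), np.nan)
                     for s, d, t in zip(res["source"], res["dilution"],
                                        res["taxon"], strict=True)]
        res["scaled_statistic"] = np.concatenate([
            modality.scale_statistics(g["statistic"].to_numpy())
            for _, g in res.groupby(["source", "day"], sort=True)])
        reg = modality.regress_vs_cv(
            res["statistic"], res["cv"],
            groups=[f"{s}_day{d}" for s, d in zip(res["source"], res["day"],
                                                  strict=True)],
            fdr_alpha=config.fdr_level)
        reg.to_csv(out / "modality_regressions.tsv", sep="\t")
    res.to_csv(out / "modality.tsv", sep="\t", index=False)
    return res


def _stage_divergence(table, config, out):
    rows = []
    for (src, dil, day), sub in table.meta.groupby(["source", "dilution", "day"],
                                                   sort=True):
        counts = table.counts[sub.index].T
        dist = divergence.pairwise_dissimilarity(counts, config.metric)
        res = divergence.community_multimodality(
            dist, B=config.bootstrap,
            seed=np.random.SeedSequence([config.seed, 4]),
            alpha=config.alpha, counts=counts)
        wm = divergence.community_within_mode_variation(
            counts, res.mode_assignments, n_sim=config.n_sim,
            seed=np.random.SeedSequence([config.seed, 5]), metric=config.metric)
        rows.append({"source": src, "dilution": dil, "day": day,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n_modes": res.n_modes, "sigma_hat": wm.mean_sigma})
    res = pd.DataFrame(rows)
    res["scaled_statistic"] = np.concatenate([
        modality.scale_statistics(g["statistic"].to_numpy())
        for _, g in res.groupby("source", sort=True)])
    res.to_csv(out / "divergence.tsv", sep="\t", index=False)
    return res


def _stage_landscape(table, config, out):
    # binarize within each source: presence patterns are only comparable
    # among samples sharing a species pool
    binaries = {}
    payload = {"retained_taxa": {}, "frameworks": {}}
    for src, sub in table.meta.groupby("source", sort=True):
        try:
            binary, retained, _ = landscape.binarize(
                table.counts[sub.index], config.detection_threshold,
                prevalence_bounds=(0.02, 0.98))
        except ValueError as exc:
            log.warning("landscape: source %s skipped (%s)", src, exc)
            continue
        binaries[src] = binary
        payload["retained_taxa"][src] = retained
    models = {}
    for fw in (1, 2):
        for key, ids in landscape.framework_split(table, fw).items():
            src = key[0]
            if src not in binaries:
                continue
            sub = binaries[src].loc[ids]
            model = landscape.fit_ising(sub, mode=config.ising_mode,
                                        l2_penalty=0.01, seed=config.seed)
            summary = landscape.summarize_landscape(model, sub.to_numpy())
            name = "|".join(map(str, key))
            payload["frameworks"][f"fw{fw}:{name}"] = {
                "h": model.h.tolist(),
                "J": model.J.tolist(),
                "n_minima": len(summary.local_minima),
                "minima_energies": [e for _, e in summary.local_minima],
                "n_occupied_basins": int(np.unique(
                    summary.basin_assignment).size),
            }
            models[(fw, key)] = (model, summary)
    with open(out / "landscape.json", "w") as fh:
        json.dump(payload, fh, indent=1)

    # shared mMDS embedding per source for the regime stage
    coords = {}
    for src, sub in table.meta.groupby("source", sort=True):
        mat = table.counts[sub.index].T
        dist = divergence.pairwise_dissimilarity(mat, config.metric)
        xy, stress = landscape.mmds_embed(dist.matrix, seed=config.seed)
        coords[src] = pd.DataFrame(xy, index=sub.index,
                                   columns=["mds1", "mds2"])
        coords[src]["stress"] = stress
    embedding = pd.concat(coords.values())
    embedding.to_csv(out / "embedding.tsv", sep="\t", index_label="sample_id")
    return {"models": models, "embedding": embedding}


def _stage_regimes(table, config, out, landscape_results):
    if landscape_results is not None:
        embedding = landscape_results["embedding"][["mds1", "mds2"]]
    else:
        coords = {}
        for src, sub in table.meta.groupby("source", sort=True):
            mat = table.counts[sub.index].T
            dist = divergence.pairwise_dissimilarity(mat, config.metric)
            xy, _ = landscape.mmds_embed(dist.matrix, seed=config.seed)
            coords[src] = pd.DataFrame(xy, index=sub.index,
                                       columns=["mds1", "mds2"])
        embedding = pd.concat(coords.values())
    frames = []
    for src, sub in table.meta.groupby("source", sort=True):
        rep = regimes.regime_report(table.subset(sub.index),
                                    embedding.loc[sub.index],
                                    per_dilution=True,
                                    criterion=config.criterion)
        frames.append(rep)
    res = pd.concat(frames)
    res.to_csv(out / "regimes.tsv", sep="\t")
    return res
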