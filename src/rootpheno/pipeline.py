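"""End-to-end orchestration: derive → summarize → stats → group → cluster →
integrate → allometry, with a manifest recording parameters and input hashes.

Every stage is also callable on its own through the library API or the CLI;
this module only sequences them and owns the on-disk layout of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import allometry as allom
from . import cluster as clus
from . import groups as grp
from . import integrate as integ
from . import stats as st
from . import traits as tr
from .derived import ConductanceParams, augment_table

__all__ = ["PipelineConfig", "run_pipeline", "CLUSTERING_TRAIT_POOL"]

logger = logging.getLogger("rootpheno")

#: root traits eligible for clustering when present in an experiment:
#: anatomy, nodal root number, and whichever depth measure was recorded
CLUSTERING_TRAIT_POOL = [
    "RXSA", "LTA", "TSA", "TCA", "AA", "percAA", "MXA", "MXV",
    "nodal_root_number", "root_depth", "root_angle", "deep_root_prop",
]

#: traits ranked per cluster for the integration heatmap (clustering pool
#: plus shoot traits, so biomass rank orders the integrated groups)
RANKING_TRAIT_POOL = CLUSTERING_TRAIT_POOL + ["biomass", "tillers"]


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run; round-tripped into the output directory."""

    input_table: str | None = None
    trait_dictionary: str | None = None
    output_dir: str = "results"
    seed: int = 0
    sd_multiplier: float = 1.0
    two_sided_filter: bool = True
    split_threshold: float = 50.0
    k_min: int = 2
    k_max: int = 8
    G: int = 6
    central_stat: str = "mean"
    cluster_traits: list[str] | None = None
    p_threshold: float = 0.05
    viscosity: float = 8.9e-4
    lta_total_metaxylem: bool = False
    correlation_alpha: float = 0.1
    log_level: str = "INFO"
    skip_stages: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _experiment_traits(table: pd.DataFrame, experiment: str, pool: list[str]) -> list[str]:
    sub = table[table["experiment"] == experiment]
    return [t for t in pool if t in sub.columns and sub[t].notna().any()]


def run_pipeline(config: PipelineConfig, table: pd.DataFrame | None = None) -> Path:
    """Run every stage on a validated plant table and write CSV outputs.

    ``table`` may be passed directly (e.g. fresh from the generator);
    otherwise it is read from ``config.input_table``.  Returns the output
    directory.  The manifest lists each executed stage with its parameters
    and the SHA-256 of each written file, so identical config + inputs give
    identical hashes.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = (tr.TraitDictionary.from_yaml(config.trait_dictionary)
                  if config.trait_dictionary else tr.DEFAULT_TRAITS)
    if table is None:
        if config.input_table is None:
            raise ValueError("no input table: set input_table or pass one directly")
        table = tr.read_table(config.input_table, dictionary)
    else:
        table = tr.validate_table(table, dictionary)

    manifest: dict = {"stages": [], "outputs": {}}
    skip = set(config.skip_stages)

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append({"stage": stage, "params": params})
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        logger.info("stage %s: wrote %s", stage, [f.name for f in files])

    # 1. derive ------------------------------------------------------------
    if "derive" not in skip:
        params = ConductanceParams(viscosity=config.viscosity)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = augment_table(table, params=params,
                                  lta_total_metaxylem=config.lta_total_metaxylem)
        for w in caught:
            logger.warning("derive: %s", w.message)
        f = out / "plants_derived.csv"
        tr.write_results(table, f)
        record("derive", {"viscosity": config.viscosity,
                          "lta_total_metaxylem": config.lta_total_metaxylem}, [f])

    # 2. summarize ---------------------------------------------------------
    means = tr.genotype_means(table)
    f = out / "genotype_means.csv"
    tr.write_results(means, f)
    record("summarize", {}, [f])
    experiments = sorted(table["experiment"].unique())
    all_traits = tr.trait_columns(table)

    # 3. response statistics -------------------------------------------------
    if "stats" not in skip:
        plast = pd.concat([st.plasticity(means, t) for t in all_traits], ignore_index=True)
        gcv_among = pd.concat([st.gcv(means, t, scope="among_genotypes") for t in all_traits],
                              ignore_index=True)
        gcv_within = pd.concat([st.gcv(table, t, scope="within_genotype") for t in all_traits],
                               ignore_index=True)
        anova_rows, corr_rows = [], []
        for exp in experiments:
            sub = table[table["experiment"] == exp]
            for t in _experiment_traits(table, exp, all_traits):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        a = st.anova_effect_sizes(sub.dropna(subset=[t]), t)
                    a.insert(0, "experiment", exp)
                    anova_rows.append(a)
                except ValueError as exc:
                    logger.warning("anova skipped for %s in %s: %s", t, exp, exc)
            ctraits = _experiment_traits(table, exp, all_traits)
            c = st.correlation_matrix(means, ctraits, treatment="D", experiment=exp,
                                      alpha=config.correlation_alpha)
            c.insert(0, "experiment", exp)
            corr_rows.append(c)
        files = []
        for name, df in [("plasticity", plast), ("gcv_among", gcv_among),
                         ("gcv_within", gcv_within),
                         ("anova", pd.concat(anova_rows, ignore_index=True)),
                         ("correlations", pd.concat(corr_rows, ignore_index=True))]:
            f = out / f"{name}.csv"
            tr.write_results(df, f)
            files.append(f)
        record("stats", {"correlation_alpha": config.correlation_alpha}, files)

    # 4. performance groups ----------------------------------------------------
    groupings: dict[str, grp.PerformanceGrouping] = {}
    if "group" not in skip:
        frames, comps = [], []
        for exp in experiments:
            g = grp.filter_by_ww_biomass(means, exp, sd_multiplier=config.sd_multiplier,
                                         two_sided=config.two_sided_filter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = grp.split_best_worst(means, g, threshold=config.split_threshold)
            groupings[exp] = g
            frames.append(g.to_frame())
            for t in _experiment_traits(table, exp, all_traits):
                try:
                    comps.append(grp.compare_groups(means, g, t))
                except ValueError as exc:
                    logger.warning("group comparison skipped for %s in %s: %s", t, exp, exc)
        f1 = out / "performance_groups.csv"
        tr.write_results(pd.concat(frames, ignore_index=True), f1)
        f2 = out / "group_comparisons.csv"
        tr.write_results(pd.concat(comps, ignore_index=True), f2)
        record("group", {"sd_multiplier": config.sd_multiplier,
                         "two_sided": config.two_sided_filter,
                         "split_threshold": config.split_threshold}, [f1, f2])

    # 5. clustering ------------------------------------------------------------
    models: dict[str, clus.ClusterModel] = {}
    cluster_traits_used: dict[str, list[str]] = {}
    if "cluster" not in skip:
        diag_rows, files = [], []
        for exp in experiments:
            traits_here = (config.cluster_traits
                           or _experiment_traits(table, exp, CLUSTERING_TRAIT_POOL))
            cluster_traits_used[exp] = traits_here
            units = groupings[exp].retained if exp in groupings else None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fm = clus.standardize(means, traits_here, exp, treatment="D", units=units)
            k_range = range(config.k_min, config.k_max + 1)
            model = clus.choose_k(fm, k_range=k_range)
            clus.silhouette(fm, model)
            bm = means[(means["experiment"] == exp) & (means["treatment"] == "D")
                       & (means["trait"] == "biomass")].set_index("genotype")["mean"]
            clus.canonicalize_labels(model, biomass=bm if len(bm) else None)
            models[exp] = model
            f = out / f"clusters_{exp}.csv"
            tr.write_results(model, f)
            files += [f, f.with_name(f.stem + "_medoids.csv")]
            for k in sorted(model.avg_sil_by_k):
                diag_rows.append(dict(experiment=exp, k=k,
                                      avg_silhouette=model.avg_sil_by_k[k],
                                      wss=model.wss_by_k[k],
                                      selected=(k == model.k)))
        f = out / "cluster_diagnostics.csv"
        tr.write_results(pd.DataFrame(diag_rows), f)
        files.append(f)
        record("cluster", {"k_range": [config.k_min, config.k_max],
                           "traits": cluster_traits_used}, files)

    # 6. integration -------------------------------------------------------------
    grouping_df = None
    if "integrate" not in skip and models:
        rank_matrix = None
        for exp, model in models.items():
            traits_here = _experiment_traits(table, exp, RANKING_TRAIT_POOL)
            central = integ.cluster_central_values(
                means, model.assignments(), traits_here, exp,
                central_stat=config.central_stat)
            rm = integ.rank_clusters(central, exp, central_stat=config.central_stat)
            rank_matrix = rm if rank_matrix is None else rank_matrix.append(rm)
        G = config.G
        total_clusters = len(rank_matrix.ranks)
        if G > total_clusters:
            logger.warning("G=%d exceeds the %d clusters; using G=%d", G, total_clusters,
                           total_clusters)
            G = total_clusters
        grouping = integ.group_integrated(rank_matrix, G=G)
        f1 = out / "rank_matrix.csv"
        rank_matrix.ranks.to_csv(f1, float_format="%.12g")
        f2 = out / "integrated_groups.csv"
        tr.write_results(grouping.to_frame(), f2)
        f3 = out / "rank_heatmap.csv"
        integ.rank_heatmap(rank_matrix, grouping, csv_path=f3,
                           plot_path=out / "rank_heatmap.png")
        record("integrate", {"G": G, "central_stat": config.central_stat}, [f1, f2, f3])

        # cluster → integrated group, mapped down to member genotypes
        frames = []
        for exp, model in models.items():
            a = model.assignments()
            a["experiment"] = exp
            a["group"] = [grouping.assignment[(exp, c)] for c in a["cluster"]]
            frames.append(a.rename(columns={"unit": "genotype"})[
                ["experiment", "genotype", "cluster", "group"]])
        grouping_df = pd.concat(frames, ignore_index=True)
        f = out / "genotype_integrated_groups.csv"
        tr.write_results(grouping_df, f)
        record("map_groups", {}, [f])

    # 7. allometry ----------------------------------------------------------------
    if "allometry" not in skip and grouping_df is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = allom.allometry_table(means, grouping_df, dictionary,
                                         p_threshold=config.p_threshold)
        f = out / "allometry.csv"
        tr.write_results(fits, f)
        record("allometry", {"p_threshold": config.p_threshold}, [f])

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
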