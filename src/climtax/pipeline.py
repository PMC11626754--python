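"""End-to-end pipeline: integrate -> describe -> select -> cluster -> profile.

A single :func:`run_pipeline` call executes the full two-level taxonomy on
either a pair of CSV inputs or a synthetic configuration, writes every
intermediate artifact as CSV into the run directory, and records a
machine-readable manifest.  Identical configuration + seed reproduces
byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import climate as clim
from . import io as cio
from . import subclusters as sub
from .descriptives import summary_table
from .exceptions import ConfigurationError, ValidationError
from .feature_selection import pca_select
from .heom import DistanceMatrix, HeomSchema, distance_matrix
from .synthetic import (
    CATEGORY_LEVELS,
    CLIMATE_ITEMS,
    SyntheticConfig,
    generate_climate,
    generate_injuries,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_scatter"]

_NUMERIC_DESCRIPTIVES = [
    "hour",
    "age_group",
    "n_regular_classes",
    "n_special_classes",
    "avg_students_regular",
    "avg_students_special",
]


@dataclass
class PipelineConfig:
    """Settings of one pipeline run (defaults follow the reference study:
    five level-1 clusters scanned over 2-8, two sub-clusters, PCA loading
    threshold 0.5)."""

    climate_csv: str | None = None
    injury_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str | None = None
    k1: int = 5
    k_scan: tuple = (2, 8)
    k2: int = 2
    pca_threshold: float = 0.5
    heom_mode: str = "representative"
    gamma: float = 3.0
    seed: int = 0
    n_init: int = 25
    allow_later_years: bool = False
    pair_sample_limit: int = 200_000
    make_plots: bool = True

    def validate(self):
        have_files = self.climate_csv is not None and self.injury_csv is not None
        if have_files == (self.synthetic is not None):
            raise ConfigurationError(
                "provide exactly one of (climate_csv + injury_csv) or a synthetic config"
            )


@dataclass
class PipelineResult:
    config: PipelineConfig
    climate: pd.DataFrame
    injuries: pd.DataFrame
    integrated: pd.DataFrame
    integration_report: cio.IntegrationReport
    selection: object
    kcurve: clim.KSelectionCurve
    model: clim.KMeansModel
    school_year_labels: pd.Series        # (school_id, year) -> cluster 1..k1
    case_clusters: pd.Series             # case_id -> cluster 1..k1
    profile: clim.ClusterProfile
    submodels: dict                      # cluster -> SubClusterModel
    subprofiles: dict                    # cluster -> SubClusterProfile
    leaf_cases: dict                     # "c.s" -> member case DataFrame
    distances: DistanceMatrix
    ground_truth: object = None
    manifest: dict = field(default_factory=dict)

    @property
    def leaf_labels(self):
        return list(self.leaf_cases)


def _relabel_by_gpf(model: clim.KMeansModel, native_centroids: pd.DataFrame):
    """Deterministic cluster numbering: 1 = highest general-positive-feeling
    centroid, descending.  Returns old-label -> new-label (1-based) map."""
    order = native_centroids["gpf"].sort_values(ascending=False).index
    return {old: i + 1 for i, old in enumerate(order)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full two-level taxonomy.  See module docstring."""
    config.validate()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs -------------------------------------------------
    ground_truth = None
    if config.synthetic is not None:
        climate_df, ground_truth = generate_climate(config.synthetic)
        injuries_df, ground_truth = generate_injuries(config.synthetic, ground_truth)
        injuries_df = injuries_df.copy()
        injuries_df["date"] = pd.to_datetime(injuries_df["date"])
    else:
        climate_df, climate_rep = cio.read_climate(config.climate_csv)
        injuries_df, injury_rep = cio.read_injuries(config.injury_csv)
        log.info(
            "validated inputs: %d/%d climate rows, %d/%d injury rows",
            climate_rep.n_valid, climate_rep.n_input, injury_rep.n_valid, injury_rep.n_input,
        )
    log.info("inputs: %d school-year climate rows, %d injury cases", len(climate_df), len(injuries_df))

    # ---- stage: integration -------------------------------------------
    integrated, integration_report = cio.integrate(
        climate_df, injuries_df, allow_later_years=config.allow_later_years
    )
    log.info(
        "integration: %d same-year, %d fallback, %d unmatched",
        integration_report.n_same_year,
        integration_report.n_fallback,
        integration_report.n_unmatched,
    )

    # ---- stage: descriptives ------------------------------------------
    descriptives = summary_table(
        integrated,
        numeric=_NUMERIC_DESCRIPTIVES + CLIMATE_ITEMS,
        categorical=list(CATEGORY_LEVELS),
    )

    # ---- stage: feature selection -------------------------------------
    selection = pca_select(climate_df[CLIMATE_ITEMS], threshold=config.pca_threshold)
    retained = selection.retained
    log.info(
        "PCA retention: %d/%d items retained (%s); first two components explain %.1f%%",
        len(retained), len(CLIMATE_ITEMS), ", ".join(retained),
        100 * selection.variance_explained_first2,
    )
    if len(retained) < 2:
        raise ValidationError("fewer than 2 climate items retained; cannot cluster")

    # ---- stage: level-1 clustering ------------------------------------
    X = climate_df[retained]
    Z, st = clim.standardize(X)
    lo, hi = config.k_scan
    kcurve = clim.scan_k(
        Z, range(int(lo), int(hi) + 1), seed=config.seed, chosen_k=config.k1,
        n_init=config.n_init,
    )
    model = kcurve.models[config.k1]
    sy_profile = clim.profile_clusters(climate_df[CLIMATE_ITEMS], model.labels)
    relabel = _relabel_by_gpf(model, sy_profile.centroids_native)
    sy_labels = pd.Series(
        [relabel[l] for l in model.labels],
        index=pd.MultiIndex.from_frame(climate_df[["school_id", "year"]]),
        name="cluster",
    )
    case_clusters = clim.assign_cases(sy_labels, integrated)
    # case-weighted profile: Table-2-style counts are cases, not school-years
    matched = integrated[integrated["match_status"] != "unmatched"]
    profile = clim.profile_clusters(
        matched[CLIMATE_ITEMS].set_axis(matched["case_id"]),
        case_clusters.loc[matched["case_id"]].to_numpy(),
    )
    log.info("level-1 case counts per cluster: %s", profile.counts.to_dict())

    # ---- stage: level-2 sub-clustering --------------------------------
    cases_by_id = matched.set_index("case_id")
    submodels, subprofiles, leaf_cases = {}, {}, {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for c in sorted(case_clusters.unique()):
        ids = case_clusters.index[case_clusters == c]
        parent = cases_by_id.loc[ids].reset_index()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sm = sub.fit_subclusters(
            parent, parent_cluster=int(c), k=config.k2, gamma=config.gamma,
            seed=sub_seed, n_init=config.n_init,
        )
        submodels[int(c)] = sm
        subprofiles[int(c)] = sub.crosstab_profile(sm, parent)
        for s in range(config.k2):
            leaf = f"{int(c)}.{s + 1}"
            member_ids = sm.labels.index[sm.labels == s]
            leaf_cases[leaf] = cases_by_id.loc[member_ids].reset_index()

    # ---- stage: HEOM distance matrix ----------------------------------
    schema = HeomSchema.from_dataframe(
        cases_by_id,
        numeric=list(sub.DEFAULT_NUMERIC_VARS),
        nominal=list(sub.DEFAULT_CATEGORICAL_VARS),
    )
    distances = distance_matrix(
        leaf_cases, schema, mode=config.heom_mode,
        pair_sample_limit=config.pair_sample_limit, seed=config.seed,
    )

    manifest = _build_manifest(
        config, integration_report, selection, kcurve, model, profile,
        submodels, distances, climate_df, injuries_df, ground_truth,
        case_clusters, leaf_cases,
    )

    result = PipelineResult(
        config=config,
        climate=climate_df,
        injuries=injuries_df,
        integrated=integrated,
        integration_report=integration_report,
        selection=selection,
        kcurve=kcurve,
        model=model,
        school_year_labels=sy_labels,
        case_clusters=case_clusters,
        profile=profile,
        submodels=submodels,
        subprofiles=subprofiles,
        leaf_cases=leaf_cases,
        distances=distances,
        ground_truth=ground_truth,
        manifest=manifest,
    )
    if out:
        _write_artifacts(result, out, descriptives)
    return result


def recovery_scores(result: PipelineResult) -> dict:
    """Adjusted Rand indices of the recovered taxonomy against planted labels
    (synthetic runs only).

    level-1: matched cases' recovered cluster vs planted climate class.
    level-2: within each planted class, planted sub-class vs recovered leaf,
    case-weighted mean over classes.
    """
    from sklearn.metrics import adjusted_rand_score

    gt = result.ground_truth
    if gt is None or not gt.case_to_subclass:
        raise ValidationError("recovery scores require a synthetic run with ground truth")
    ids = result.case_clusters.index
    true_class = np.array([gt.case_to_subclass[i][0] for i in ids])
    pred = result.case_clusters.to_numpy()
    ari1 = float(adjusted_rand_score(true_class, pred))
    leaf_of = {}
    for leaf, df in result.leaf_cases.items():
        for cid in df["case_id"]:
            leaf_of[cid] = leaf
    aris, weights = [], []
    for c in np.unique(true_class):
        sel = ids[true_class == c]
        t = [gt.case_to_subclass[i][1] for i in sel]
        p = [leaf_of[i] for i in sel]
        aris.append(float(adjusted_rand_score(t, p)))
        weights.append(len(sel))
    ari2 = float(np.average(aris, weights=weights))
    return {"level1_ari": ari1, "level2_ari": ari2, "level2_ari_per_class": aris}


def export_scatter(
    matched_climate: pd.DataFrame, labels: pd.Series, variable: str
) -> pd.DataFrame:
    """Plot-ready table: one row per school-year with ``variable``, the
    general-positive-feeling score and the cluster label."""
    if variable not in matched_climate.columns:
        raise ValidationError(f"unknown variable {variable!r}")
    out = pd.DataFrame(
        {
            "school_id": matched_climate["school_id"].to_numpy(),
            "year": matched_climate["year"].to_numpy(),
            variable: matched_climate[variable].to_numpy(),
            "gpf": matched_climate["gpf"].to_numpy(),
            "cluster": np.asarray(labels),
        }
    )
    return out


def _build_manifest(
    config, integration_report, selection, kcurve, model, profile,
    submodels, distances, climate_df, injuries_df, ground_truth,
    case_clusters, leaf_cases,
) -> dict:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "k1": config.k1,
        "k2": config.k2,
        "k_scan": list(config.k_scan),
        "pca_threshold": config.pca_threshold,
        "gamma": config.gamma,
        "heom_mode": config.heom_mode,
        "n_init": config.n_init,
        "n_climate_rows": int(len(climate_df)),
        "n_injury_cases": int(len(injuries_df)),
        "match_counts": {
            "same_year": integration_report.n_same_year,
            "fallback": integration_report.n_fallback,
            "unmatched": integration_report.n_unmatched,
        },
        "retained_items": list(selection.retained),
        "variance_explained_first2": selection.variance_explained_first2,
        "k_scan_table": kcurve.table.to_dict(orient="records"),
        "bic_argmin": kcurve.bic_argmin,
        "level1_sse": model.sse,
        "level1_case_counts": {str(k): int(v) for k, v in profile.counts.items()},
        "level2_costs": {str(c): m.cost for c, m in submodels.items()},
        "leaf_labels": list(leaf_cases),
        "synthetic": config.synthetic is not None,
    }
    return manifest


def _write_artifacts(result: PipelineResult, out: Path, descriptives: pd.DataFrame) -> None:
    cfg = result.config
    descriptives.to_csv(out / "descriptives.csv", index=False)
    result.selection.to_frame().to_csv(out / "pca_loadings.csv")
    result.kcurve.table.to_csv(out / "k_scan.csv", index=False)
    result.profile.to_frame().to_csv(out / "climate_profile.csv")
    result.profile.zscores.to_csv(out / "climate_zscores.csv")
    result.integration_report.to_frame().to_csv(out / "integration_report.csv", index=False)
    pd.DataFrame(
        {
            "case_id": result.case_clusters.index,
            "cluster": result.case_clusters.to_numpy(),
        }
    ).to_csv(out / "case_clusters.csv", index=False)
    for c, prof in result.subprofiles.items():
        prof.to_frame().to_csv(out / f"subcluster_profile_cluster{c}.csv", index=False)
    result.distances.to_dataframe().to_csv(out / "heom_distance_matrix.csv")
    matched_sy = result.climate
    sy_label_values = result.school_year_labels.to_numpy()
    for variable in [v for v in CLIMATE_ITEMS if v != "gpf"]:
        export_scatter(matched_sy, sy_label_values, variable).to_csv(
            out / f"scatter_{variable}_vs_gpf.csv", index=False
        )
    if result.ground_truth is not None:
        result.ground_truth.school_frame().to_csv(out / "ground_truth_schools.csv", index=False)
        result.ground_truth.case_frame().to_csv(out / "ground_truth_cases.csv", index=False)
        result.manifest["recovery"] = recovery_scores(result)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if cfg.make_plots:
        _plot_heatmap(result.distances, out / "heom_heatmap.png")
        _plot_scatters(matched_sy, sy_label_values, out)


def _plot_heatmap(distances: DistanceMatrix, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    df = distances.to_dataframe()
    im = ax.imshow(df.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(df)), df.columns, rotation=45)
    ax.set_yticks(range(len(df)), df.index)
    for i in range(len(df)):
        for j in range(len(df)):
            ax.text(j, i, f"{df.iat[i, j]:.2f}", ha="center", va="center", fontsize=7, color="w")
    ax.set_title(f"HEOM distances between leaf sub-clusters ({distances.mode})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_scatters(climate_sy: pd.DataFrame, labels, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for variable in [v for v in CLIMATE_ITEMS if v != "gpf"]:
        fig, ax = plt.subplots(figsize=(6, 5))
        tab = export_scatter(climate_sy, labels, variable)
        for c, g in tab.groupby("cluster"):
            ax.scatter(g[variable], g["gpf"], s=8, label=f"cluster {c}", alpha=0.6)
        ax.set_xlabel(variable)
        ax.set_ylabel("general positive feeling")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"scatter_{variable}_vs_gpf.png", dpi=150)
        plt.close(fig)
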