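"""End-to-end pipeline: score -> extract -> threshold -> metrics -> inference.

Every stage writes its tabular outputs plus a JSON manifest carrying the
parameters, the master seed and input hashes; reruns with the same config and
seed are bit-reproducible.  Stochastic stages consume named substreams of the
master seed and never touch global RNG state.
"""

from __future__ import annotations

import importlib.metadata
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import stress
from .construction import fisher_z, sparsity_grid, threshold_sparsity
from .cubes import resize_to_atlas, tile_cubes
from .inference import bh_fdr, detect_hubs, group_effect_lm, hub_ttests, partial_correlation
from .metrics import compute_metrics
from .nbs import EdgeDataset, run_nbs

logger = logging.getLogger("morphnet")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

GLOBAL_MEASURES = ["mean_CP", "mean_DC", "LP", "E_glob", "SW"]

# seed substream tags
_SUB_SMALL_WORLD = 10
_SUB_NBS = 20


class PipelineError(RuntimeError):
    """Stage failure, annotated with stage name and subject id."""


@dataclass
class RunConfig:
    cohort_csv: Path
    atlas: Path
    lookup: Path
    volumes_dir: Path
    out_dir: Path
    sparsity_levels: tuple = field(default_factory=sparsity_grid)
    n_null: int = 20
    covariates: tuple = ("age", "sex", "site", "PDS")
    include_ses_variant: bool = True
    nbs_n_perm: int = 1000
    nbs_alpha: float = 0.05
    nbs_mode: str = "edge_fdr"
    nbs_primary_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cohort_csv", "atlas", "lookup", "volumes_dir", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        self.sparsity_levels = tuple(float(s) for s in self.sparsity_levels)

    def validate(self) -> None:
        for name in ("cohort_csv", "atlas", "lookup"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"config path {name}={p} does not exist")
        if not self.volumes_dir.is_dir():
            raise FileNotFoundError(f"volumes_dir {self.volumes_dir} is not a directory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paths = raw.get("paths", {})
        base = Path(path).parent
        def _p(key):
            return (base / paths[key]).resolve() if not Path(paths[key]).is_absolute() else Path(paths[key])
        kwargs = dict(
            cohort_csv=_p("cohort_csv"),
            atlas=_p("atlas"),
            lookup=_p("lookup"),
            volumes_dir=_p("volumes_dir"),
            out_dir=_p("out_dir"),
            seed=int(raw.get("seed", 0)),
        )
        if "sparsity_levels" in raw:
            kwargs["sparsity_levels"] = tuple(raw["sparsity_levels"])
        sw = raw.get("small_world", {})
        if "n_null" in sw:
            kwargs["n_null"] = int(sw["n_null"])
        cov = raw.get("covariates", {})
        if "base" in cov:
            kwargs["covariates"] = tuple(cov["base"])
        if "with_ses" in cov:
            kwargs["include_ses_variant"] = bool(cov["with_ses"])
        nbs_cfg = raw.get("nbs", {})
        for src, dst in [
            ("n_perm", "nbs_n_perm"),
            ("alpha", "nbs_alpha"),
            ("mode", "nbs_mode"),
            ("primary_threshold", "nbs_primary_threshold"),
        ]:
            if src in nbs_cfg:
                kwargs[dst] = nbs_cfg[src]
        return cls(**kwargs)


def _version() -> str:
    try:
        return importlib.metadata.version("morphnet")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def _base_manifest(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "package_version": _version(),
        "inputs": {
            "cohort_csv": mio.file_sha256(config.cohort_csv),
            "atlas": mio.file_sha256(config.atlas),
            "lookup": mio.file_sha256(config.lookup),
        },
    }


def stage_score(config: RunConfig) -> pd.DataFrame:
    cohort = pd.read_csv(config.cohort_csv)
    scored = stress.score_cohort(cohort)
    out = config.out_dir / "cohort_scored.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    scored.to_csv(out, index=False, float_format="%.6f")
    mio.write_manifest(config.out_dir / "manifest_score.json", _base_manifest(config, "score"))
    return scored


def stage_extract(config: RunConfig, scored: pd.DataFrame) -> dict:
    """Per-subject r- and z-scale ROI matrices from GM volumes."""
    atlas = mio.read_volume(config.atlas, kind="atlas")
    zmats: dict[str, object] = {}
    mat_dir = config.out_dir / "matrices"
    cube_counts = {}
    for _, row in scored.iterrows():
        sid = str(row["subject_id"])
        try:
            gm = mio.read_volume(config.volumes_dir / row["volume_file"], kind="gm")
            cubes = tile_cubes(gm, atlas, source=sid)
            rmat = resize_to_atlas(cubes)
            zmat = fisher_z(rmat)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=extract subject={sid}: {exc}") from exc
        mio.write_roi_matrix(rmat, mat_dir / f"{sid}_r.tsv")
        mio.write_roi_matrix(zmat, mat_dir / f"{sid}_z.tsv")
        zmats[sid] = zmat
        cube_counts[sid] = len(cubes)
    manifest = _base_manifest(config, "extract")
    manifest["cube_counts"] = cube_counts
    manifest["rotations"] = 24
    mio.write_manifest(config.out_dir / "manifest_extract.json", manifest)
    return zmats


def stage_threshold(config: RunConfig, zmats: dict) -> dict:
    """Binary networks per subject and sparsity level, stored as edge lists."""
    nets: dict[tuple[str, float], object] = {}
    net_dir = config.out_dir / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)
    for sid, zmat in zmats.items():
        for s in config.sparsity_levels:
            try:
                net = threshold_sparsity(zmat, s, source=sid)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage=threshold subject={sid} sparsity={s}: {exc}") from exc
            nets[(sid, s)] = net
            edges = net.edge_list()
            df = pd.DataFrame(
                {
                    "roi_i": zmat.roi_ids[edges[:, 0]],
                    "roi_j": zmat.roi_ids[edges[:, 1]],
                }
            )
            df.to_csv(net_dir / f"{sid}_s{int(round(s * 100)):02d}.tsv", sep="\t", index=False)
    manifest = _base_manifest(config, "threshold")
    manifest["sparsity_levels"] = list(config.sparsity_levels)
    manifest["n_edges"] = {f"{sid}@{s}": nets[(sid, s)].n_edges for (sid, s) in nets}
    mio.write_manifest(config.out_dir / "manifest_threshold.json", manifest)
    return nets


def stage_metrics(config: RunConfig, nets: dict, roi_ids: np.ndarray):
    """Global metrics table (one row per subject x sparsity) + nodal long table."""
    global_rows = []
    nodal_rows = []
    nodal_arrays: dict[tuple[float, str], dict[str, np.ndarray]] = {}
    subject_ids = sorted({sid for sid, _ in nets})
    for si, s in enumerate(config.sparsity_levels):
        for sid in subject_ids:
            net = nets[(sid, s)]
            subj_idx = subject_ids.index(sid)
            try:
                gm = compute_metrics(
                    net,
                    n_null=config.n_null,
                    seed=[config.seed, _SUB_SMALL_WORLD, si, subj_idx],
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage=metrics subject={sid} sparsity={s}: {exc}") from exc
            global_rows.append(
                {
                    "subject_id": sid,
                    "sparsity": s,
                    "mean_CP": gm.mean_CP,
                    "mean_DC": gm.mean_DC,
                    "LP": gm.LP,
                    "unreachable_fraction": gm.unreachable_fraction,
                    "E_glob": gm.E_glob,
                    "SW": gm.SW,
                }
            )
            nodal_arrays.setdefault((s, "BC"), {})[sid] = gm.nodal_betweenness
            nodal_arrays.setdefault((s, "DC"), {})[sid] = gm.nodal_degree.astype(float)
            nodal_arrays.setdefault((s, "CP"), {})[sid] = gm.nodal_clustering
            for metric, vec in (
                ("DC", gm.nodal_degree),
                ("CP", gm.nodal_clustering),
                ("BC", gm.nodal_betweenness),
            ):
                for roi, val in zip(roi_ids, vec):
                    nodal_rows.append(
                        {
                            "subject_id": sid,
                            "sparsity": s,
                            "roi": int(roi),
                            "metric": metric,
                            "value": float(val),
                        }
                    )
    gdf = pd.DataFrame(global_rows)
    ndf = pd.DataFrame(nodal_rows)
    gdf.to_csv(config.out_dir / "global_metrics.csv", index=False, float_format="%.10g")
    ndf.to_csv(config.out_dir / "nodal_metrics.csv", index=False, float_format="%.10g")
    manifest = _base_manifest(config, "metrics")
    manifest["null_spec"] = {"n_null": config.n_null, "swap_attempts_per_edge": 10}
    mio.write_manifest(config.out_dir / "manifest_metrics.json", manifest)
    return gdf, nodal_arrays


def _analysis_rows(scored: pd.DataFrame) -> pd.DataFrame:
    mask = scored["stress_group"].isin([stress.LOW, stress.HIGH])
    return scored[mask].reset_index(drop=True)


def stage_compare(
    config: RunConfig,
    scored: pd.DataFrame,
    global_df: pd.DataFrame,
    nodal_arrays: dict,
    roi_ids: np.ndarray,
) -> pd.DataFrame:
    """ANCOVA-style group models on global measures, hub tests with BH-FDR."""
    rows = _analysis_rows(scored)
    results = []
    hub_records = []
    cov_sets = {"base": list(config.covariates)}
    if config.include_ses_variant:
        cov_sets["with_ses"] = list(config.covariates) + ["SES"]
    subject_order = rows["subject_id"].tolist()

    for s in config.sparsity_levels:
        gsub = global_df[global_df["sparsity"] == s].set_index("subject_id")
        for variant, covs in cov_sets.items():
            pvals = []
            variant_results = []
            for measure in GLOBAL_MEASURES:
                y = gsub.loc[subject_order, measure].to_numpy(dtype=float)
                res = group_effect_lm(
                    y, rows, covariates=covs, family=f"global/{variant}@{s}"
                )
                res.term = f"{measure}:group[High]"
                res.extra["measure"] = measure
                res.extra["sparsity"] = s
                res.extra["model"] = variant
                variant_results.append(res)
                pvals.append(res.p)
            adjusted, _ = bh_fdr(pvals)
            for res, pc in zip(variant_results, adjusted):
                res.p_corr = float(pc)
            results.extend(variant_results)

        groups = rows["stress_group"].to_numpy()
        for metric in ("BC", "DC", "CP"):
            vals = np.stack([nodal_arrays[(s, metric)][sid] for sid in subject_order])
            if metric == "CP":
                tested = list(range(vals.shape[1]))  # all nodes for clustering
            else:
                tested = detect_hubs(vals, groups).tolist()
                for node in tested:
                    hub_records.append(
                        {"sparsity": s, "metric": metric, "roi": int(roi_ids[node])}
                    )
            if not tested:
                continue
            tres = hub_ttests(
                vals, groups, tested, node_ids=roi_ids, family=f"nodal/{metric}@{s}"
            )
            for r in tres:
                r.extra["measure"] = metric
                r.extra["sparsity"] = s
                r.extra["model"] = "ttest"
            results.extend(tres)

    out_rows = [
        {
            "measure": r.extra.get("measure", ""),
            "sparsity": r.extra.get("sparsity", np.nan),
            "model": r.extra.get("model", ""),
            "term": r.term,
            "node": r.extra.get("node", -1),
            "estimate": r.estimate,
            "statistic": r.statistic,
            "df": r.df,
            "p": r.p,
            "p_corr": r.p_corr,
            "family": r.family,
        }
        for r in results
    ]
    sdf = pd.DataFrame(out_rows)
    sdf.to_csv(config.out_dir / "group_stats.csv", index=False, float_format="%.10g")
    hdf = pd.DataFrame(hub_records, columns=["sparsity", "metric", "roi"])
    hdf.to_csv(config.out_dir / "hubs.csv", index=False)
    manifest = _base_manifest(config, "compare")
    manifest["covariate_sets"] = cov_sets
    manifest["n_analyzed"] = len(rows)
    mio.write_manifest(config.out_dir / "manifest_compare.json", manifest)
    return sdf


def stage_correlate(
    config: RunConfig, scored: pd.DataFrame, global_df: pd.DataFrame
) -> pd.DataFrame:
    """Whole-group partial correlations of stress level with global measures.

    Controls for age, sex, site and z-standardized PDS (no SES), across all
    scored subjects regardless of group membership.
    """
    rows = scored.dropna(subset=["age", "PDS"]).reset_index(drop=True)
    z = rows[["age", "sex", "site", "PDS"]].copy()
    z["PDS"] = (z["PDS"] - z["PDS"].mean()) / z["PDS"].std(ddof=1)
    out_rows = []
    for s in config.sparsity_levels:
        gsub = global_df[global_df["sparsity"] == s].set_index("subject_id")
        for measure in GLOBAL_MEASURES:
            y = gsub.loc[rows["subject_id"], measure].to_numpy(dtype=float)
            r, p = partial_correlation(rows["n_nle"].to_numpy(dtype=float), y, z)
            out_rows.append({"measure": measure, "sparsity": s, "r_partial": r, "p": p})
    cdf = pd.DataFrame(out_rows)
    cdf.to_csv(config.out_dir / "partial_correlations.csv", index=False, float_format="%.10g")
    manifest = _base_manifest(config, "correlate")
    manifest["controls"] = ["age", "sex", "site", "PDS(z)"]
    mio.write_manifest(config.out_dir / "manifest_correlate.json", manifest)
    return cdf


def stage_nbs(config: RunConfig, scored: pd.DataFrame, zmats: dict) -> pd.DataFrame:
    """Edge-strength permutation analysis on the unthresholded z matrices."""
    rows = _analysis_rows(scored)
    sids = rows["subject_id"].tolist()
    first = zmats[sids[0]]
    data = EdgeDataset(
        matrices=np.stack([zmats[sid].values for sid in sids]),
        groups=rows["stress_group"].to_numpy(),
        roi_ids=first.roi_ids,
        subject_ids=np.array(sids),
    )
    result = run_nbs(
        data,
        n_perm=config.nbs_n_perm,
        alpha=config.nbs_alpha,
        mode=config.nbs_mode,
        primary_threshold=config.nbs_primary_threshold,
        seed=[config.seed, _SUB_NBS],
    )
    lookup = mio.read_lookup(config.lookup).set_index("label")
    edge_rows = [
        {
            "roi_i": int(e["roi_i"]),
            "roi_j": int(e["roi_j"]),
            "network_i": lookup.loc[int(e["roi_i"]), "network"],
            "network_j": lookup.loc[int(e["roi_j"]), "network"],
            "t": e["t"],
            "p_corr": e["p_corr"],
        }
        for e in result.edges
    ]
    edf = pd.DataFrame(
        edge_rows, columns=["roi_i", "roi_j", "network_i", "network_j", "t", "p_corr"]
    )
    edf.to_csv(config.out_dir / "nbs_edges.tsv", sep="\t", index=False, float_format="%.10g")
    tdf = pd.DataFrame(result.t_matrix, index=first.roi_ids, columns=first.roi_ids)
    tdf.to_csv(config.out_dir / "nbs_tmatrix.tsv", sep="\t", float_format="%.10g", index_label="roi")
    manifest = _base_manifest(config, "nbs")
    manifest.update(
        {
            "n_perm": result.n_perm,
            "alpha": result.alpha,
            "mode": result.mode,
            "n_significant": len(result.edges),
        }
    )
    if "warning" in result.diagnostics:
        manifest["warning"] = result.diagnostics["warning"]
    mio.write_manifest(config.out_dir / "manifest_nbs.json", manifest)
    return edf


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the main in-memory products."""
    config.validate()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        out = fn(config, *args)
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-10s %.2fs", name, timings[name])
        return out

    scored = timed("score", stage_score)
    zmats = timed("extract", stage_extract, scored)
    roi_ids = next(iter(zmats.values())).roi_ids
    nets = timed("threshold", stage_threshold, zmats)
    global_df, nodal_arrays = timed("metrics", stage_metrics, nets, roi_ids)
    stats_df = timed("compare", stage_compare, scored, global_df, nodal_arrays, roi_ids)
    corr_df = timed("correlate", stage_correlate, scored, global_df)
    nbs_df = timed("nbs", stage_nbs, scored, zmats)

    manifest = _base_manifest(config, "run-all")
    manifest["stages"] = list(timings)
    mio.write_manifest(config.out_dir / "manifest_run.json", manifest)
    return {
        "scored": scored,
        "zmats": zmats,
        "global_metrics": global_df,
        "group_stats": stats_df,
        "partial_correlations": corr_df,
        "nbs_edges": nbs_df,
    }
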