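"""Study orchestration and plain-text I/O.

``run_study`` wires the synthetic study end to end -- simulate samples, local
variability maps, covSTATIS hull scores across a window grid, consistency and
reliability statistics, multiscale correlations with spin nulls, and the
spectral-exponent sweep -- writing TSV/JSON artifacts plus one machine-readable
summary. All randomness flows through named per-stage seeds in the config, so
an identical config reproduces an identical summary.

I/O dialects: regional maps are TSV (region_id, value); runs are TSV matrices
(rows = regions) with a JSON sidecar (subject_id, tr_s, age, run_label);
parcellations and receptor panels are CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import covstatis, inference, local_variability as lv, multiscale, spectral
from . import synthetic
from .containers import (
    RECEPTOR_ANNOTATIONS,
    Parcellation,
    ParcellatedRun,
    ReceptorPanel,
    RegionalMap,
)

logger = logging.getLogger("boldvar")

__all__ = [
    "StudyConfig",
    "run_study",
    "io_read_run",
    "io_write_run",
    "io_read_map",
    "io_write_map",
    "io_read_panel",
    "io_write_panel",
    "io_read_parcellation",
    "io_write_parcellation",
]


# ---------------------------------------------------------------- I/O helpers

def _check_no_nan(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {loc[0]} column {df.columns[loc[1]]!r}"
        )


def io_write_map(m: RegionalMap, path, region_ids: Optional[np.ndarray] = None) -> None:
    ids = np.arange(1, len(m) + 1) if region_ids is None else np.asarray(region_ids)
    pd.DataFrame({"region_id": ids, "value": m.values}).to_csv(
        path, sep="\t", index=False
    )


def io_read_map(path, parcellation: Optional[Parcellation] = None,
                label: str = "") -> RegionalMap:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["region_id", "value"]:
        raise ValueError(f"{path}: expected header 'region_id\\tvalue', got {list(df.columns)}")
    _check_no_nan(df, path)
    if parcellation is not None and not np.array_equal(
        df["region_id"].to_numpy(), parcellation.region_ids
    ):
        raise ValueError(f"{path}: region ids do not match the parcellation")
    ref = parcellation.name if parcellation is not None else "unknown"
    return RegionalMap(values=df["value"].to_numpy(float), parcellation_ref=ref,
                       label=label or Path(path).stem)


def io_write_run(run: ParcellatedRun, tsv_path) -> None:
    tsv_path = Path(tsv_path)
    pd.DataFrame(run.data).to_csv(tsv_path, sep="\t", index=False, header=False)
    sidecar = {
        "subject_id": run.subject_id,
        "tr_s": run.tr_s,
        "age": run.age,
        "run_label": run.run_label,
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def io_read_run(tsv_path) -> ParcellatedRun:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", header=None)
    _check_no_nan(df, tsv_path)
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    return ParcellatedRun(
        subject_id=meta["subject_id"],
        tr_s=float(meta["tr_s"]),
        data=df.to_numpy(float),
        age=meta.get("age"),
        run_label=meta.get("run_label", "run-1"),
    )


def io_write_parcellation(parc: Parcellation, path) -> None:
    parc.to_frame().to_csv(path, index=False)


def io_read_parcellation(path, name: str = "synthetic") -> Parcellation:
    df = pd.read_csv(path)
    _check_no_nan(df, path)
    return Parcellation.from_frame(df, name=name)


def io_write_panel(panel: ReceptorPanel, densities_path, annotations_path) -> None:
    out = panel.densities.copy()
    out.insert(0, "region_id", out.index)
    out.to_csv(densities_path, index=False)
    panel.annotations.to_csv(annotations_path, index=False)


def io_read_panel(densities_path, annotations_path=None,
                  parcellation_ref: str = "synthetic") -> ReceptorPanel:
    df = pd.read_csv(densities_path)
    _check_no_nan(df, densities_path)
    if "region_id" in df.columns:
        df = df.set_index("region_id")
    ann = (
        pd.read_csv(annotations_path)
        if annotations_path is not None
        else RECEPTOR_ANNOTATIONS.copy()
    )
    return ReceptorPanel(densities=df, annotations=ann,
                         parcellation_ref=parcellation_ref)


# --------------------------------------------------------------- study config

@dataclass
class StudyConfig:
    """Configuration of one end-to-end synthetic study run."""

    out_dir: str = "study_out"
    n_regions: int = 30
    n_networks7: int = 7
    samples: dict = field(
        default_factory=lambda: {"sample1": "young1", "sample2": "young2"}
    )
    n_subjects: int = 20
    window_s_grid: tuple = (45.0, 60.0)
    peel_fraction: float = 0.95
    n_components: int = 2
    n_spins: int = 1000
    n_maps: int = 4
    map_correlation_length: float = 0.5
    meg_n_per: int = 10
    seeds: dict = field(
        default_factory=lambda: {
            "parcellation": 11,
            "ground_truth": 12,
            "bold": 13,
            "maps": 14,
            "panel": 15,
            "spins": 16,
            "meg": 17,
        }
    )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["window_s_grid"] = list(self.window_s_grid)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["window_s_grid"] = tuple(d["window_s_grid"])
        return cls(**d)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(dataclasses.asdict(config))}
    seeds = config.seeds

    logger.info("stage: parcellation")
    parc = synthetic.make_parcellation(
        config.n_regions, config.n_networks7, seed=seeds["parcellation"]
    )
    io_write_parcellation(parc, out / "parcellation.csv")

    logger.info("stage: simulate")
    gt = synthetic.make_dynamics_ground_truth(
        parc,
        per_region_spread=np.linspace(0.1, 0.5, parc.n_regions),
        seed=seeds["ground_truth"],
    )
    datasets: dict[str, list[ParcellatedRun]] = {}
    for i, (name, profile) in enumerate(config.samples.items()):
        datasets[name] = synthetic.simulate_bold_dataset(
            parc, profile, config.n_subjects, gt, seed=seeds["bold"] + i
        )

    logger.info("stage: local variability")
    local_group: dict[str, RegionalMap] = {}
    for name, runs in datasets.items():
        maps = [
            lv.rmssd_map(lv.center_whole_brain(r), parcellation_ref=parc.name)
            for r in runs
        ]
        gmap = lv.group_map(maps)
        local_group[name] = gmap
        io_write_map(gmap, out / f"local_{name}.tsv", parc.region_ids)
    summary["local"] = {
        name: {"mean": float(m.values.mean()), "sd": float(m.values.std())}
        for name, m in local_group.items()
    }

    logger.info("stage: global variability")
    global_group: dict[str, RegionalMap] = {}
    hulls_by_window: dict[str, dict[float, covstatis.HullScores]] = {}
    for name, runs in datasets.items():
        hulls_by_window[name] = {}
        for w in config.window_s_grid:
            spec = covstatis.WindowSpec(window_s=w)
            hs = covstatis.global_variability(
                runs, spec, n_components=config.n_components,
                peel_fraction=config.peel_fraction,
            )
            hulls_by_window[name][w] = hs
            rows = pd.DataFrame(hs.areas, index=hs.subject_ids,
                                columns=parc.region_ids)
            rows.to_csv(out / f"hulls_{name}_w{int(w)}.tsv", sep="\t")
        w0 = config.window_s_grid[0]
        global_group[name] = RegionalMap(
            values=hulls_by_window[name][w0].group_mean(),
            parcellation_ref=parc.name,
            label=f"global:{name}",
        )
        io_write_map(global_group[name], out / f"global_{name}.tsv", parc.region_ids)

    logger.info("stage: consistency")
    consistency: dict = {}
    for name in datasets:
        grid = list(config.window_s_grid)
        subj_means = np.column_stack(
            [hulls_by_window[name][w].areas.mean(axis=1) for w in grid]
        )
        icc, lo, hi = inference.icc_consistency_avg(subj_means)
        spearman = {}
        for i in range(len(grid)):
            for j in range(i + 1, len(grid)):
                rho = stats.spearmanr(
                    hulls_by_window[name][grid[i]].group_mean(),
                    hulls_by_window[name][grid[j]].group_mean(),
                ).statistic
                spearman[f"{grid[i]}s-vs-{grid[j]}s"] = float(rho)
        consistency[name] = {"icc": icc, "icc_ci": [lo, hi],
                             "group_spearman": spearman}
    summary["consistency"] = consistency

    logger.info("stage: inter-sample reliability")
    names = list(datasets)
    if len(names) >= 2:
        a_local = np.vstack(
            [lv.rmssd_map(lv.center_whole_brain(r)).values for r in datasets[names[0]]]
        )
        b_local = np.vstack(
            [lv.rmssd_map(lv.center_whole_brain(r)).values for r in datasets[names[1]]]
        )
        rel = inference.welch_reliability(a_local, b_local, level="region")
        rel.to_csv(out / "reliability_local_region.tsv", sep="\t", index=False)
        net = inference.welch_reliability(
            a_local, b_local, level="network", networks=parc.network7
        )
        net.to_csv(out / "reliability_local_network.tsv", sep="\t", index=False)
        summary["reliability"] = {
            "group_r_local": float(
                stats.pearsonr(local_group[names[0]].values,
                               local_group[names[1]].values).statistic
            ),
            "group_r_global": float(
                stats.pearsonr(global_group[names[0]].values,
                               global_group[names[1]].values).statistic
            ),
            "frac_regions_reliable_local": float(rel["reliable"].mean()),
        }

    logger.info("stage: multiscale")
    ref_maps = synthetic.simulate_regional_maps(
        parc, config.map_correlation_length, config.n_maps, seed=seeds["maps"]
    )
    panel = synthetic.simulate_receptor_panel(parc, seed=seeds["panel"])
    io_write_panel(panel, out / "receptor_densities.csv",
                   out / "receptor_annotations.csv")
    composites = [
        multiscale.receptor_entropy(panel),
        multiscale.ei_ratio(panel),
        multiscale.class_density(panel, "ionotropic"),
        multiscale.class_density(panel, "metabotropic"),
    ]
    nulls = multiscale.hungarian_spins(parc, n_spins=config.n_spins,
                                       seed=seeds["spins"])
    all_maps = (
        [local_group[names[0]], global_group[names[0]]] + composites + ref_maps
    )
    corr, pvals = multiscale.metric_correlation_matrix(
        all_maps, nulls=nulls, variability_indices=(0, 1)
    )
    corr.to_csv(out / "multiscale_corr.tsv", sep="\t")
    pvals.to_csv(out / "multiscale_spin_p.tsv", sep="\t")
    communities = (
        ["variability", "variability"]
        + ["mesoscale"] * len(composites)
        + ["reference"] * len(ref_maps)
    )
    pc = multiscale.participation_coefficient(corr.to_numpy(), communities)
    summary["multiscale"] = {
        "participation_local": float(pc[0]),
        "participation_global": float(pc[1]),
    }
    predictors = np.column_stack([m.values for m in composites + ref_maps])
    dom = multiscale.dominance_analysis(predictors, local_group[names[0]])
    dom.to_csv(out / "dominance_local.tsv", sep="\t", index=False)
    summary["multiscale"]["dominance_full_r2"] = float(dom["full_r2"].iloc[0])

    logger.info("stage: spectral sweep")
    exp = spectral.exponent_variability_experiment(
        n_per=config.meg_n_per, seed=seeds["meg"]
    )
    exp.table.to_csv(out / "megsim.tsv", sep="\t", index=False)
    summary["megsim"] = {
        "n": exp.n,
        "r_squared": exp.r_squared,
        "slope": exp.slope,
        "slope_se": exp.slope_se,
        "conf_int": list(exp.conf_int),
    }

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1,
                                                 sort_keys=True))
    return summary
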