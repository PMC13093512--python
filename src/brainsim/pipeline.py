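"""End-to-end orchestration: simulate (or load) a cohort, build networks,
run the stability analysis, screen markers, compare them pairwise, classify
conversion, and map significant edges onto cytoarchitectural classes.

Configuration lives in a single YAML file (or a :class:`PipelineConfig`
constructed in code); every stage writes CSV/JSON artifacts into the output
directory and registers them, with content hashes, in ``manifest.json``.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    conversion_prediction,
    cytoarch_mapping,
    lme_screening,
    network_construction,
    synthetic_cohort,
)
from .synthetic_cohort import SimConfig

logger = logging.getLogger(__name__)

#: screening outcomes available from the synthetic cognitive battery
DEFAULT_OUTCOMES = ("pacc", "tmt_b")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    cohort_csv: str | None = None          # load instead of simulate
    groups: tuple[str, ...] = ("positive",)  # "incident" | "elevated" | "positive"
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    marker_types: tuple[str, ...] = ("similarity", "thickness", "volumes", "fluid")
    alpha: float = 0.05
    n_bootstrap: int = 1000
    cv_folds: int = 5
    train_frac: float = 0.8
    stability_sizes: tuple[int, ...] | None = None
    stability_reps: int = 1000
    icc_threshold: float = 0.75
    visit_window_months: float = 6.0
    max_compare_features: int = 10         # cap per marker in pairwise stage
    seed: int = 0
    outdir: str = "brainsim_output"

    @classmethod
    def default_synthetic(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Desk-scale synthetic configuration: 20 regions, 60 reference and
        30 target subjects, 3 visits, 200 bootstrap iterations."""
        sim = SimConfig(
            n_reference=60, n_incident=15, n_elevated=15,
            n_regions=20, n_visits=3, seed=seed,
        )
        cfg = cls(sim=sim, n_bootstrap=200, stability_reps=100, seed=seed)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "base_covariance" in sim_raw and sim_raw["base_covariance"] is not None:
            sim_raw["base_covariance"] = np.asarray(sim_raw["base_covariance"], float)
        if "perturbed_edges" in sim_raw and sim_raw["perturbed_edges"] is not None:
            sim_raw["perturbed_edges"] = [tuple(e) for e in sim_raw["perturbed_edges"]]
        if "conversion_betas" in sim_raw:
            sim_raw["conversion_betas"] = tuple(sim_raw["conversion_betas"])
        for key in ("groups", "outcomes", "marker_types", "stability_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        sim = SimConfig(**sim_raw)
        return cls(sim=sim, **raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"]["base_covariance"] = np.asarray(
            d["sim"]["base_covariance"]
        ).tolist()
        d["sim"]["perturbed_edges"] = [list(e) for e in d["sim"]["perturbed_edges"]]
        d["sim"]["conversion_betas"] = list(d["sim"]["conversion_betas"])
        for key in ("groups", "outcomes", "marker_types"):
            d[key] = list(d[key])
        if d["stability_sizes"] is not None:
            d["stability_sizes"] = list(d["stability_sizes"])
        return yaml.safe_dump(d)


def align_visits(cohort: pd.DataFrame, window_months: float = 6.0) -> pd.DataFrame:
    """Keep subject-visits whose companion acquisitions fall within the
    temporal window centered on the MRI date.

    Columns ending in ``_offset_months`` carry each modality's offset from
    the MRI scan; a row is retained only if every offset lies within
    +/- window/2.  Rows with missing offsets are dropped with a warning.
    """
    offset_cols = [c for c in cohort.columns if c.endswith("_offset_months")]
    if not offset_cols:
        return cohort.copy()
    half = window_months / 2.0
    offsets = cohort[offset_cols]
    missing = offsets.isna().any(axis=1)
    keep = (~missing) & (offsets.abs() <= half).all(axis=1)
    dropped = cohort.loc[~keep]
    if len(dropped):
        per_subject = dropped.groupby("subject_id").size()
        logger.warning(
            "visit alignment dropped %d rows (window %.1f months): %s",
            len(dropped), window_months, per_subject.to_dict(),
        )
    return cohort.loc[keep].copy()


def _group_mask(frame: pd.DataFrame, group: str) -> pd.Series:
    if group == "positive":
        return frame["group"].isin(["incident_positive", "elevated_positive"])
    return frame["group"] == f"{group}_positive"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: dict[str, dict] = {}

    def add(self, stage: str, path: Path) -> None:
        self.entries[str(path.relative_to(self.outdir))] = {
            "stage": stage,
            "sha256": _sha256(path),
        }

    def write(self, status: str = "complete") -> Path:
        path = self.outdir / "manifest.json"
        payload = {"status": status, "files": self.entries}
        path.write_text(json.dumps(payload, indent=2))
        return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the in-memory report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    bundle: dict = {"config": cfg}
    stage = "config"
    try:
        path = outdir / "pipeline_config.yaml"
        path.write_text(cfg.to_yaml())
        manifest.add(stage, path)

        # ---- cohort ---------------------------------------------------
        stage = "simulate"
        if cfg.cohort_csv:
            cohort, _ = synthetic_cohort.load_cohort(cfg.cohort_csv)
        else:
            cohort = synthetic_cohort.generate_cohort(cfg.sim)
        cohort = align_visits(cohort, cfg.visit_window_months)
        bundle["cohort"] = cohort
        path = outdir / "cohort.csv"
        synthetic_cohort.save_cohort(cohort, cfg.sim, path)
        manifest.add(stage, path)
        manifest.add(stage, outdir / "cohort_config.json")

        # ---- cognition preprocessing ---------------------------------
        stage = "cognition"
        tests = list(synthetic_cohort.COGNITIVE_TESTS)
        cohort = lme_screening.zscore_cognition(
            cohort, tests, invert=synthetic_cohort.DEFAULT_INVERT
        )
        cohort["pacc"] = lme_screening.compose_pacc(
            cohort, ["adasq4", "lmdrt", "tmt_b", "mmse"]
        )
        bundle["cohort"] = cohort

        reference = cohort[cohort["group"] == "stable_negative"]
        targets = cohort[cohort["group"] != "stable_negative"]

        # ---- reference network ---------------------------------------
        stage = "reference"
        ref_net = network_construction.build_reference_network(reference)
        bundle["reference_network"] = ref_net
        path = outdir / "reference_network.csv"
        network_construction.save_network_csv(ref_net, path)
        manifest.add(stage, path)

        # ---- individual similarity networks --------------------------
        stage = "similarity"
        nets = network_construction.build_individual_networks(
            targets, reference, ref_net
        )
        edge_table = network_construction.similarity_edge_table(
            nets, ref_net.region_names
        )
        edge_cols = network_construction.edge_names(ref_net.region_names)
        sim_long = targets[
            ["subject_id", "group", "visit_time", "age", "sex", "education", "tiv",
             "deviation", "converted", *list(cfg.outcomes)]
        ].merge(edge_table, on=["subject_id", "visit_time"])
        bundle["similarity"] = sim_long
        path = outdir / "similarity_edges.csv"
        edge_table.to_csv(path, index=False)
        manifest.add(stage, path)

        # ---- stability curve -----------------------------------------
        stage = "stability"
        n_ref = reference["subject_id"].nunique()
        sizes = cfg.stability_sizes or tuple(
            sorted({max(6, s) for s in np.linspace(10, n_ref, 6, dtype=int)})
        )
        curve = network_construction.stability_curve(
            reference, sizes, n_reps=cfg.stability_reps,
            threshold=cfg.icc_threshold, seed=cfg.seed,
        )
        bundle["stability"] = curve
        path = outdir / "stability_curve.csv"
        pd.DataFrame(
            {"sample_size": curve.sample_sizes, "mean_icc": curve.mean_icc}
        ).to_csv(path, index=False)
        manifest.add(stage, path)

        # ---- screening ------------------------------------------------
        stage = "screen"
        thickness_cols = network_construction.thickness_columns(cohort)
        volume_cols = ["hippocampal_volume", "ventricular_volume", "gray_matter_volume"]
        fluid_cols = list(synthetic_cohort.BIOMARKERS)
        marker_features = {
            "similarity": edge_cols,
            "thickness": thickness_cols,
            "volumes": volume_cols,
            "fluid": fluid_cols,
        }
        def _marker_data(group: str) -> pd.DataFrame:
            """Per-group target rows with baseline-only fluid biomarkers
            log-transformed and propagated to every visit (they enter the
            models as time-constant covariates interacting with time)."""
            frame = targets[_group_mask(targets, group)].copy()
            for col in fluid_cols:
                baseval = frame.groupby("subject_id")[col].transform("max")
                frame[col] = np.log(baseval)
            return frame

        screens: dict[tuple[str, str, str], lme_screening.ScreenSummary] = {}
        frames = []
        for group in cfg.groups:
            sim_data = sim_long[_group_mask(sim_long, group)]
            target_data = _marker_data(group)
            for outcome in cfg.outcomes:
                for marker in cfg.marker_types:
                    data = sim_data if marker == "similarity" else target_data
                    summary = lme_screening.screen_marker(
                        data, marker_features[marker], outcome,
                        group=group, marker_type=marker, alpha=cfg.alpha,
                        tiv_adjust=(marker == "volumes"),
                    )
                    screens[(marker, outcome, group)] = summary
                    frames.append(summary.to_frame())
        screen_frame = pd.concat(frames, ignore_index=True)
        bundle["screens"] = screens
        path = outdir / "screening_results.csv"
        screen_frame.to_csv(path, index=False)
        manifest.add(stage, path)
        medians = {
            f"{m}|{o}|{g}": s.median_r2_significant
            for (m, o, g), s in screens.items()
        }
        path = outdir / "screening_median_r2.json"
        path.write_text(json.dumps(medians, indent=2, default=float))
        manifest.add(stage, path)

        # ---- nested comparisons --------------------------------------
        stage = "compare"
        from . import nested_comparison  # local import keeps module list tidy

        comparisons = []
        for group in cfg.groups:
            sim_data = sim_long[_group_mask(sim_long, group)]
            target_data = _marker_data(group)
            for outcome in cfg.outcomes:
                sim_summary = screens.get(("similarity", outcome, group))
                if sim_summary is None:
                    continue
                sig_sim = _top_features(sim_summary, cfg.max_compare_features)
                for marker in cfg.marker_types:
                    if marker == "similarity":
                        continue
                    other = screens.get((marker, outcome, group))
                    if other is None:
                        continue
                    sig_other = _top_features(other, cfg.max_compare_features)
                    if not sig_sim or not sig_other:
                        continue
                    merged = sim_data.merge(
                        target_data[["subject_id", "visit_time", *sig_other]],
                        on=["subject_id", "visit_time"], suffixes=("", "_dup"),
                    )
                    pairs = nested_comparison.compare_marker_pairs(
                        merged, sig_sim, sig_other, outcome, alpha=cfg.alpha,
                        tiv_adjust=(marker == "volumes"),
                    )
                    if not pairs:
                        continue
                    summary = nested_comparison.summarize_wins(
                        pairs, marker_a="similarity", marker_b=marker
                    )
                    comparisons.append(
                        {"outcome": outcome, "group": group, **vars(summary)}
                    )
        bundle["comparisons"] = comparisons
        path = outdir / "nested_comparisons.csv"
        pd.DataFrame(comparisons).to_csv(path, index=False)
        manifest.add(stage, path)

        # ---- conversion classification -------------------------------
        stage = "classify"
        base_targets = targets.sort_values("visit_time").drop_duplicates("subject_id")
        base_sim = sim_long.sort_values("visit_time").drop_duplicates("subject_id")
        base_sim = base_sim.set_index("subject_id")
        base_targets = base_targets.set_index("subject_id").loc[base_sim.index]
        labels = base_targets["converted"].to_numpy(int)
        feature_sets = {
            "similarity": base_sim[edge_cols],
            "thickness": base_targets[thickness_cols],
            "volumes": base_targets[volume_cols],
            "fluid": np.log(base_targets[fluid_cols]),
        }
        classifiers = {}
        if labels.min() == labels.max():
            logger.warning("conversion labels single-class; classification skipped")
        else:
            for marker in cfg.marker_types:
                sel, res = conversion_prediction.classify_conversion(
                    feature_sets[marker], labels, folds=cfg.cv_folds,
                    n_iter=cfg.n_bootstrap, train_frac=cfg.train_frac, seed=cfg.seed,
                )
                classifiers[marker] = (sel, res)
            if "similarity" in cfg.marker_types and "fluid" in cfg.marker_types:
                sel, res = conversion_prediction.combined_model(
                    {"similarity": feature_sets["similarity"],
                     "fluid": feature_sets["fluid"]},
                    labels, folds=cfg.cv_folds, n_iter=cfg.n_bootstrap,
                    train_frac=cfg.train_frac, seed=cfg.seed,
                )
                classifiers["similarity+fluid"] = (sel, res)
        bundle["classifiers"] = classifiers
        summary_json = {}
        for marker, (sel, res) in classifiers.items():
            curve_frame, summary = conversion_prediction.result_to_frames(res)
            path = outdir / f"roc_{marker.replace('+', '_')}.csv"
            curve_frame.to_csv(path, index=False)
            manifest.add(stage, path)
            summary["lambda_opt"] = sel.lambda_opt
            summary_json[marker] = summary
        path = outdir / "classification_summary.json"
        path.write_text(json.dumps(summary_json, indent=2, default=float))
        manifest.add(stage, path)

        # ---- cytoarchitectural mapping -------------------------------
        stage = "cytoarch"
        mapping = None
        if cfg.sim.n_regions == 68 or cfg.cohort_csv:
            try:
                mapping = cytoarch_mapping.load_cytoarch_map(ref_net.region_names)
            except ValueError:
                mapping = None
        cyto = {}
        if mapping is not None:
            for group in cfg.groups:
                for outcome in cfg.outcomes:
                    summary = screens.get(("similarity", outcome, group))
                    if summary is None:
                        continue
                    sig = [r.feature_id for r in summary.significant]
                    if not sig:
                        continue
                    edges = cytoarch_mapping.edges_from_feature_ids(sig)
                    prop = cytoarch_mapping.edge_class_proportions(edges, mapping)
                    contrib = cytoarch_mapping.regional_contribution(edges, mapping)
                    key = f"{outcome}|{group}"
                    cyto[key] = {"proportion": prop, "contribution": contrib}
                    p1 = outdir / f"cytoarch_proportion_{outcome}_{group}.csv"
                    prop.to_csv(p1)
                    manifest.add(stage, p1)
                    p2 = outdir / f"cytoarch_contribution_{outcome}_{group}.csv"
                    contrib.to_csv(p2)
                    manifest.add(stage, p2)
        bundle["cytoarch"] = cyto

        manifest.write("complete")
        bundle["manifest"] = manifest.entries
        return bundle
    except Exception as exc:
        manifest.write(f"failed at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _top_features(summary: lme_screening.ScreenSummary, cap: int) -> list[str]:
    sig = sorted(summary.significant, key=lambda r: r.q_value)
    return [r.feature_id for r in sig[:cap]]
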