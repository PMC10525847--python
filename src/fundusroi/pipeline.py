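"""End-to-end orchestration: generate -> detect -> extract ROIs -> split ->
train branches -> tune cut-offs -> evaluate -> report, plus the ablation
harnesses (ROI-size sweep with an entire-image row, backbone comparison) and
the ROI-vs-whole-image advantage experiment.

All artifacts are plain text (CSV/JSON) and every stage draws randomness from
seeds recorded in the report, so re-running a config reproduces the report
byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import evaluate
from .classify import (
    BRANCH_REGION,
    BRANCH_TARGETS,
    BranchConfig,
    TrainedBranch,
    predict_assemble,
    split_dataset,
    train_branch,
)
from .classify.routing import ROUTED_BRANCHES
from .landmarks import DETECTOR_REGISTRY, Detector, DetectorConfig, select_landmarks
from .roi import ROIConfig, make_rois
from .synthdata import (
    SyntheticConfig,
    generate_dataset,
    load_image,
    load_manifest,
    record_from_row,
)
from .types import DISEASES, LabelVector

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    workdir: Path
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_images: int = 200
    manifest: Optional[Path] = None       # ingest instead of generate
    detector: str = "oracle"
    detector_jitter_sd: float = 0.0
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    branches: Dict[str, BranchConfig] = field(default_factory=dict)
    include_baseline: bool = False
    split_ratio: float = 0.9
    n_runs: int = 1
    seeds: Tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        if len(self.seeds) < self.n_runs:
            raise ValueError("need at least n_runs seeds")
        branch_ids = list(ROUTED_BRANCHES)
        if self.include_baseline:
            branch_ids.append("baseline_full6")
        for bid in branch_ids:
            self.branches.setdefault(bid, BranchConfig(branch_id=bid, epochs=5))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"workdir": Path(raw["workdir"])}
        if "synth" in raw:
            kwargs["synth"] = SyntheticConfig.from_dict(raw["synth"])
        if "detector_config" in raw:
            kwargs["detector_config"] = DetectorConfig(**raw["detector_config"])
        if "roi" in raw:
            kwargs["roi"] = ROIConfig(**raw["roi"])
        if "branches" in raw:
            kwargs["branches"] = {
                bid: BranchConfig(branch_id=bid, **cfg)
                for bid, cfg in raw["branches"].items()
            }
        for key in ("n_images", "detector", "detector_jitter_sd",
                    "include_baseline", "split_ratio", "n_runs"):
            if key in raw:
                kwargs[key] = raw[key]
        if "seeds" in raw:
            kwargs["seeds"] = tuple(raw["seeds"])
        if "manifest" in raw and raw["manifest"]:
            kwargs["manifest"] = Path(raw["manifest"])
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def _build_detector(config: PipelineConfig) -> Detector:
    if config.detector not in DETECTOR_REGISTRY:
        raise StageError("detect", f"unknown detector {config.detector!r}")
    cls = DETECTOR_REGISTRY[config.detector]
    return cls(jitter_sd=config.detector_jitter_sd)


def extract_regions(
    data_dir: Path,
    manifest: pd.DataFrame,
    detector: Detector,
    roi_config: ROIConfig,
    rng: np.random.Generator,
) -> Dict[str, List[np.ndarray]]:
    """Run detection + ROI extraction for every manifest row.

    Returns region name -> list of float [0, 1] arrays aligned with the
    manifest rows.
    """
    regions: Dict[str, List[np.ndarray]] = {"od_roi": [], "macula_roi": [], "full": []}
    for _, row in manifest.iterrows():
        record = record_from_row(row)
        try:
            image = load_image(data_dir, record.image_path)
            detections = detector.detect(record, rng)
            landmarks = select_landmarks(detections)
            roiset = make_rois(image, landmarks, roi_config)
        except Exception as exc:  # noqa: BLE001 - annotate the offending record
            raise StageError("extract-rois", f"{record.image_path}: {exc}") from exc
        regions["od_roi"].append(roiset.od_roi)
        regions["macula_roi"].append(roiset.macula_roi)
        regions["full"].append(roiset.full)
    return regions


def _targets_matrix(manifest: pd.DataFrame, targets: Sequence[str]) -> np.ndarray:
    return manifest[list(targets)].to_numpy(dtype=int)


def _labels_list(manifest: pd.DataFrame) -> List[LabelVector]:
    return [
        LabelVector.from_sequence(row)
        for row in manifest[list(DISEASES)].to_numpy(dtype=int)
    ]


def _run_once(config: PipelineConfig, data_dir: Path, manifest: pd.DataFrame,
              run_seed: int) -> Tuple[Dict, Dict[str, TrainedBranch]]:
    logger.info("[detect] run seed %d: extracting landmarks and ROIs", run_seed)
    detector = _build_detector(config)
    rng = np.random.default_rng(run_seed)
    regions = extract_regions(data_dir, manifest, detector, config.roi, rng)

    logger.info("[split] stratified split at ratio %.2f", config.split_ratio)
    manifest_idx = manifest.reset_index(drop=True).reset_index()
    train_m, val_m = split_dataset(manifest_idx, config.split_ratio, seed=run_seed)
    train_idx = train_m["index"].to_numpy()
    val_idx = val_m["index"].to_numpy()

    trained: Dict[str, TrainedBranch] = {}
    for b_offset, (bid, bcfg) in enumerate(sorted(config.branches.items())):
        region = BRANCH_REGION[bid]
        targets = BRANCH_TARGETS[bid]
        x_all = regions[region]
        x_train = [x_all[i] for i in train_idx]
        x_val = [x_all[i] for i in val_idx]
        y_train = _targets_matrix(train_m, targets)
        y_val = _targets_matrix(val_m, targets)
        bcfg = replace(bcfg, seed=run_seed * 1000 + b_offset)
        logger.info("[train] branch %s (%d train / %d val, %d epochs)",
                    bid, len(x_train), len(x_val), bcfg.epochs)
        try:
            trained[bid] = train_branch((x_train, y_train), (x_val, y_val), bcfg)
        except Exception as exc:  # noqa: BLE001
            raise StageError("train", f"branch {bid}: {exc}") from exc

    logger.info("[tune] assembling validation predictions and cut-offs")
    branch_logits = {
        bid: trained[bid].predict_logits(
            [regions[BRANCH_REGION[bid]][i] for i in val_idx]
        )
        for bid in ROUTED_BRANCHES
    }
    predictions = predict_assemble(branch_logits)
    val_labels = _labels_list(val_m)
    label_mat = np.asarray([lv.as_tuple() for lv in val_labels], dtype=int)
    thresholds = evaluate.ThresholdSet(tuple(
        evaluate.tune_threshold(predictions[:, j], label_mat[:, j])
        for j in range(len(DISEASES))
    ))

    logger.info("[evaluate] building report")
    report = evaluate.classification_report(predictions, val_labels, thresholds)
    report["seed"] = run_seed
    report["best_epochs"] = {bid: tb.best_epoch for bid, tb in sorted(trained.items())}
    report["misclassification_matrix"] = evaluate.misclassification_matrix(
        predictions, val_labels, thresholds
    ).tolist()

    if config.include_baseline:
        base = trained["baseline_full6"]
        base_probs = base.predict_proba(
            [regions["full"][i] for i in val_idx]
        )
        report["baseline"] = {
            name: evaluate.auc(base_probs[:, j], label_mat[:, j])
            for j, name in enumerate(DISEASES)
        }
    return report, trained


def run_end_to_end(config: PipelineConfig) -> Dict:
    """Execute the full pipeline and write ``report.json`` under the workdir."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    data_dir = workdir / "data"
    if config.manifest is not None:
        manifest_path = Path(config.manifest)
        data_dir = manifest_path.parent
    else:
        manifest_path = data_dir / "manifest.csv"
        if not manifest_path.exists():
            logger.info("[generate] rendering %d synthetic scenes", config.n_images)
            generate_dataset(config.synth, config.n_images, data_dir)
    manifest = load_manifest(manifest_path)

    runs = []
    for r in range(config.n_runs):
        report, _ = _run_once(config, data_dir, manifest, config.seeds[r])
        runs.append(report)

    final: Dict = {"runs": runs, "n_runs": config.n_runs,
                   "seeds": list(config.seeds[:config.n_runs])}
    if config.n_runs >= 2:
        slim = [
            {"per_class": {k: {m: v for m, v in d.items()}
                           for k, d in r["per_class"].items()},
             "micro": r["micro"]}
            for r in runs
        ]
        final["aggregate"] = evaluate.aggregate_runs(slim)

    report_path = workdir / "report.json"
    report_path.write_text(json.dumps(final, sort_keys=True, indent=2) + "\n")
    logger.info("[report] wrote %s", report_path)
    return final


# ---------------------------------------------------------------------------
# ablation harnesses

ENTIRE_IMAGE = "entire"


def ablate_roi_size(
    config: PipelineConfig,
    multipliers: Sequence,
    branch_id: str = "mac_erm_amd",
    out_csv: Optional[Path | str] = None,
) -> pd.DataFrame:
    """Sweep the ROI edge multiplier of one branch (``entire`` = whole image).

    Each sweep cell trains the branch identically except for the ROI edge and
    reports per-target validation AUC; failures are recorded per cell and the
    sweep continues.
    """
    if len(multipliers) < 1:
        raise ValueError("need at least one multiplier")
    if branch_id not in ("mac_erm_amd", "od_gs"):
        raise ValueError("sweep applies to the ROI branches")
    targets = BRANCH_TARGETS[branch_id]
    rows = []
    for mult in multipliers:
        if mult == ENTIRE_IMAGE:
            # whole-image sentinel: same targets, full region
            sweep_cfg = _with_region_override(config, branch_id, None)
        else:
            m = float(mult)
            roi = replace(config.roi, beta=m) if branch_id == "mac_erm_amd" \
                else replace(config.roi, alpha=m)
            sweep_cfg = dataclasses.replace(config, roi=roi)
            sweep_cfg.branches = dict(config.branches)
        row: Dict = {"multiplier": mult}
        try:
            aucs = _sweep_cell_aucs(sweep_cfg, branch_id)
            row.update(aucs)
            row["mean_auc"] = float(np.mean(list(aucs.values())))
        except Exception as exc:  # noqa: BLE001 - continue the sweep
            logger.warning("[ablate-roi] cell %r failed: %s", mult, exc)
            row.update({t: np.nan for t in targets})
            row["mean_auc"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def _with_region_override(config: PipelineConfig, branch_id: str, _unused) -> "PipelineConfig":
    cfg = dataclasses.replace(config)
    cfg.branches = dict(config.branches)
    cfg._region_override = branch_id  # type: ignore[attr-defined]
    return cfg


def _sweep_cell_aucs(config: PipelineConfig, branch_id: str) -> Dict[str, float]:
    """Train one branch under the given config; return per-target val AUC."""
    workdir = Path(config.workdir)
    data_dir = workdir / "data"
    manifest_path = (Path(config.manifest) if config.manifest is not None
                     else data_dir / "manifest.csv")
    if not manifest_path.exists():
        generate_dataset(config.synth, config.n_images, data_dir)
    manifest = load_manifest(manifest_path)
    run_seed = config.seeds[0]
    detector = _build_detector(config)
    rng = np.random.default_rng(run_seed)
    regions = extract_regions(manifest_path.parent, manifest, detector,
                              config.roi, rng)
    region = BRANCH_REGION[branch_id]
    if getattr(config, "_region_override", None) == branch_id:
        region = "full"
    manifest_idx = manifest.reset_index(drop=True).reset_index()
    train_m, val_m = split_dataset(manifest_idx, config.split_ratio, seed=run_seed)
    targets = BRANCH_TARGETS[branch_id]
    x_all = regions[region]
    x_train = [x_all[i] for i in train_m["index"].to_numpy()]
    x_val = [x_all[i] for i in val_m["index"].to_numpy()]
    bcfg = replace(config.branches[branch_id], seed=run_seed * 1000)
    tb = train_branch(
        (x_train, _targets_matrix(train_m, targets)),
        (x_val, _targets_matrix(val_m, targets)),
        bcfg,
    )
    best = tb.history[tb.best_epoch]["val_auc"]
    return {t: float(best[t]) for t in targets}


def compare_backbones(
    config: PipelineConfig,
    backbones: Sequence[str],
    out_csv: Optional[Path | str] = None,
) -> pd.DataFrame:
    """Train each routed branch once per backbone; flag the per-group argmax
    of mean AUC."""
    if len(backbones) < 1:
        raise ValueError("need at least one backbone")
    from .classify.backbones import BACKBONE_REGISTRY
    for name in backbones:
        if name not in BACKBONE_REGISTRY:
            raise KeyError(f"unregistered backbone {name!r}")
    rows = []
    for name in backbones:
        row: Dict = {"backbone": name}
        for bid in ROUTED_BRANCHES:
            cfg = dataclasses.replace(config)
            cfg.branches = dict(config.branches)
            cfg.branches[bid] = replace(cfg.branches[bid], backbone=name)
            aucs = _sweep_cell_aucs(cfg, bid)
            row.update({f"{bid}:{t}": v for t, v in aucs.items()})
            row[f"{bid}:mean"] = float(np.mean(list(aucs.values())))
        rows.append(row)
    table = pd.DataFrame(rows)
    for bid in ROUTED_BRANCHES:
        col = f"{bid}:mean"
        table[f"{bid}:selected"] = table[col] == table[col].max()
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


# ---------------------------------------------------------------------------
# ROI-vs-whole-image advantage experiment


def roi_advantage_experiment(
    workdir: Path | str,
    n_train: int = 600,
    n_val: int = 200,
    epochs: int = 10,
    seeds: Sequence[int] = (0, 1, 2),
    image_size: int = 128,
    input_size: int = 32,
    backbone: str = "tiny-mlp",
    prevalence: Tuple[float, ...] = (0.3,) * 6,
) -> List[Dict[str, float]]:
    """Train the macula branch, the optic-disc branch, and the whole-image
    all-six-label baseline under identical settings and compare validation
    AUC for the macular (AMD-like) and peridiscal (GS-like) diseases.

    Returns one dict per seed with keys ``mac_amd``, ``base_amd``, ``od_gs``,
    ``base_gs``.
    """
    workdir = Path(workdir)
    results = []
    for seed in seeds:
        synth = SyntheticConfig(image_size=image_size, prevalence=prevalence,
                                seed=seed)
        data_dir = workdir / f"seed{seed}"
        manifest_path = data_dir / "manifest.csv"
        if not manifest_path.exists():
            generate_dataset(synth, n_train + n_val, data_dir)
        manifest = load_manifest(manifest_path)
        detector = _build_detector(PipelineConfig(workdir=data_dir))
        rng = np.random.default_rng(seed)
        regions = extract_regions(data_dir, manifest, detector, ROIConfig(), rng)
        idx = np.arange(len(manifest))
        train_idx, val_idx = idx[:n_train], idx[n_train:]
        train_m = manifest.iloc[train_idx]
        val_m = manifest.iloc[val_idx]

        def _train(bid: str, region: str) -> TrainedBranch:
            targets = BRANCH_TARGETS[bid]
            cfg = BranchConfig(branch_id=bid, backbone=backbone,
                               input_size=input_size, epochs=epochs,
                               lr_init=1e-3, seed=seed)
            x_tr = [regions[region][i] for i in train_idx]
            x_va = [regions[region][i] for i in val_idx]
            return train_branch(
                (x_tr, _targets_matrix(train_m, targets)),
                (x_va, _targets_matrix(val_m, targets)), cfg)

        mac = _train("mac_erm_amd", "macula_roi")
        od = _train("od_gs", "od_roi")
        base = _train("baseline_full6", "full")

        label_mat = _targets_matrix(val_m, DISEASES)
        mac_probs = mac.predict_proba(
            [regions["macula_roi"][i] for i in val_idx])
        od_probs = od.predict_proba(
            [regions["od_roi"][i] for i in val_idx])
        base_probs = base.predict_proba(
            [regions["full"][i] for i in val_idx])
        results.append({
            "seed": seed,
            "mac_amd": evaluate.auc(mac_probs[:, 1], label_mat[:, DISEASES.index("amd")]),
            "base_amd": evaluate.auc(base_probs[:, DISEASES.index("amd")],
                                     label_mat[:, DISEASES.index("amd")]),
            "od_gs": evaluate.auc(od_probs[:, 0], label_mat[:, DISEASES.index("gs")]),
            "base_gs": evaluate.auc(base_probs[:, DISEASES.index("gs")],
                                    label_mat[:, DISEASES.index("gs")]),
        })
    return results
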