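"""End-to-end pipeline orchestration from a single declarative config.

Stages run in method order: simulate RF frames -> reconstruct B-mode ->
train the 2D segmentation network -> predict liver masks -> per-line
spectra -> ROI masking / normalization / gated augmentation -> train the
1D classifier -> frame-level prediction -> metrics report, for every
(task, spectrum-kind) pair.  Every stage's seed is derived from one master
seed, each stage directory records the hash of the config that produced
it, and ``resume=True`` skips stages whose outputs already match that
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmode, clf, metrics_eval, roispec, segnet, sim, spectra

log = logging.getLogger("rfpipe")


@dataclass
class PipelineConfig:
    out: str = "runs/rfpipe"
    seed: int = 0
    # simulation
    n_per_stage: int | None = 4
    total: int | None = None
    proportions: str = "paper"
    effect_scale: float = 1.0
    acq: sim.AcquisitionSpec = field(default_factory=sim.AcquisitionSpec)
    # segmentation
    seg: segnet.SegConfig = field(default_factory=segnet.SegConfig)
    seg_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    dynamic_range_db: float = 40.0
    # classification
    clf: clf.ClfConfig = field(default_factory=clf.ClfConfig)
    clf_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    tasks: tuple[str, ...] = ("geF1", "geF2", "geF3", "geF4")
    kinds: tuple[str, ...] = ("phase",)
    use_truth_masks: bool = False   # bypass the 2D CNN for the ROI masks

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "acq" in kw:
            kw["acq"] = sim.AcquisitionSpec(**kw["acq"])
        if "seg" in kw:
            d = kw["seg"]
            for k in ("input_shape", "encoder_widths", "betas"):
                if k in d:
                    d[k] = tuple(d[k])
            kw["seg"] = segnet.SegConfig(**d)
        if "clf" in kw:
            d = kw["clf"]
            for k in ("conv_channels", "kernel_sizes", "pool_sizes",
                      "fc_widths", "betas"):
                if k in d:
                    d[k] = tuple(d[k])
            kw["clf"] = clf.ClfConfig(**d)
        for k in ("seg_ratios", "clf_ratios", "tasks", "kinds"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def setup_logging(logfile: Path | None = None, verbose: bool = False) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        logfile.parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


class _Stage:
    """Skip-or-recompute bookkeeping for one pipeline stage directory."""

    def __init__(self, root: Path, name: str, cfg_hash: str, resume: bool):
        self.dir = root / name
        self.name = name
        self.marker = self.dir / "stage.json"
        self.cfg_hash = cfg_hash
        self.resume = resume

    def done(self) -> bool:
        if not (self.resume and self.marker.exists()):
            return False
        try:
            return json.loads(self.marker.read_text())["config_hash"] == self.cfg_hash
        except Exception:
            return False

    def begin(self):
        if self.dir.exists():
            shutil.rmtree(self.dir)
        self.dir.mkdir(parents=True)

    def finish(self):
        self.marker.write_text(json.dumps(
            {"stage": self.name, "config_hash": self.cfg_hash}))


def _split_with_both_classes(ids, labels_by_id, ratios, base_seed,
                             max_tries=200, require_val=True):
    """Participant-level split retried over derived seeds until the needed
    parts hold both classes (tiny cohorts make single-class parts likely).

    With ``require_val=False`` only train and test must be mixed-class: a
    cohort with fewer frames of one class than split parts cannot satisfy
    the strict requirement at all, yet training and evaluation remain
    well-defined with a single-class validation part.
    """
    for attempt in range(max_tries):
        s = sim.derive_seed(base_seed, attempt, "clf-split")
        split = bmode.split_dataset(ids, ratios=ratios, seed=s)
        parts = [split.train_ids, split.test_ids]
        if require_val:
            parts.append(split.val_ids)
        if all(len({labels_by_id[i] for i in part}) == 2 for part in parts):
            return split, s
    raise ValueError(
        f"no derived split of {len(ids)} frames at {ratios} puts both classes "
        f"in the required parts after {max_tries} attempts")


def _assemble(rois, tsk, labels, ratios, seed):
    """balance_and_assemble with a relaxed fallback for tiny cohorts.

    Frames whose (possibly predicted) ROI holds no full axial gate on any
    line cannot produce samples and are dropped with a warning first.
    """
    keep = [r for r in rois if roispec.eligible_line_count(r.mask) > 0]
    if len(keep) < len(rois):
        log.warning("%s: dropped %d/%d frames with gate-ineligible ROIs",
                    tsk.name, len(rois) - len(keep), len(rois))
    rois = keep
    by_id = {r.source_frame_id: r for r in rois}
    lab = {i: tsk.label_of(labels[i]) for i in by_id}
    try:
        split, s = _split_with_both_classes(sorted(by_id), lab, ratios, seed)
        return roispec.balance_and_assemble(rois, tsk, ratios=ratios, seed=s,
                                            pad_lateral=True)
    except ValueError:
        log.warning("%s: no split with both classes in every part; "
                    "falling back to mixed-class train/test only", tsk.name)
    split, _ = _split_with_both_classes(sorted(by_id), lab, ratios, seed,
                                        require_val=False)
    n_aug = roispec.augmentation_factor([lab[i] for i in split.train_ids])
    counts = [sum(lab[i] == c for i in split.train_ids) for c in (0, 1)]
    minority = int(counts[1] < counts[0])

    def emit(ids, augment):
        out = []
        for fid in ids:
            r = by_id[fid]
            k = n_aug if (augment and lab[fid] == minority) else 1
            out.extend(roispec.window_frames(
                roispec.gate_lines(r), k, label=lab[fid], source_frame_id=fid,
                pad_lateral=True))
        return out

    return (emit(split.train_ids, True), emit(split.val_ids, False),
            emit(split.test_ids, False))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``<out>/report.json``)."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "pipeline.log")
    h = cfg.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    log.info("pipeline start (config hash %s)", h)

    def stage(name):
        return _Stage(out, name, h, resume)

    # ---- 1. simulate -----------------------------------------------------
    st = stage("sim")
    if st.done():
        log.info("sim: resumed")
        frames = sim.load_dataset(st.dir / "dataset.npz")
    else:
        st.begin()
        frames = sim.simulate_dataset(
            n_per_stage=cfg.n_per_stage, total=cfg.total,
            proportions=cfg.proportions, acq=cfg.acq,
            effect_scale=cfg.effect_scale,
            seed=sim.derive_seed(cfg.seed, 0, "sim"))
        sim.save_dataset(frames, st.dir / "dataset.npz")
        st.finish()
    log.info("sim: %d frames", len(frames))

    # ---- 2. bmode + seg training ----------------------------------------
    report: dict = {"config_hash": h, "n_frames": len(frames)}
    net_shape = cfg.seg.input_shape
    images = {f.frame_id: bmode.resize_image(
        bmode.reconstruct_bmode(f, cfg.dynamic_range_db).pixels, net_shape)
        for f in frames}
    truth_net = {f.frame_id: bmode.resize_mask(f.truth_mask, net_shape)
                 for f in frames}

    st = stage("segnet")
    if cfg.use_truth_masks:
        masks_signal = {f.frame_id: f.truth_mask for f in frames}
        report["segmentation"] = {"skipped": "use_truth_masks"}
    else:
        if st.done():
            log.info("segnet: resumed")
            net = segnet.load_checkpoint(st.dir / "model.npz")
        else:
            st.begin()
            split = bmode.split_dataset([f.frame_id for f in frames],
                                        ratios=cfg.seg_ratios,
                                        seed=sim.derive_seed(cfg.seed, 0, "seg-split"))
            tr_i, tr_m = bmode.augment_images(
                [images[i] for i in split.train_ids],
                [truth_net[i] for i in split.train_ids],
                seed=sim.derive_seed(cfg.seed, 0, "seg-aug"))
            net = segnet.build_segnet(dataclasses.replace(
                cfg.seg, seed=sim.derive_seed(cfg.seed, 0, "seg-init")))
            net, hist = segnet.train_segnet(
                net, tr_i, tr_m,
                [images[i] for i in split.val_ids],
                [truth_net[i] for i in split.val_ids])
            hist.to_csv(st.dir / "history.csv", index=False)
            segnet.save_checkpoint(net, st.dir / "model.npz")
            pd.DataFrame({"frame_id": split.test_ids}).to_csv(
                st.dir / "test_ids.csv", index=False)
            st.finish()
        test_ids = pd.read_csv(st.dir / "test_ids.csv")["frame_id"].tolist() \
            if (st.dir / "test_ids.csv").exists() else []
        pairs = [(segnet.segment(net, images[i]).pixels, truth_net[i])
                 for i in test_ids]
        if pairs:
            m = metrics_eval.mean_seg_metrics(pairs)
            report["segmentation"] = m.as_dict()
            log.info("segnet: test DSC %.3f over %d frames", m.dsc, len(pairs))
        masks_signal = {
            f.frame_id: segnet.resize_mask_to_signal(
                segnet.clean_mask(segnet.segment(net, images[f.frame_id])),
                (cfg.acq.n_samples, cfg.acq.n_lines)).pixels
            for f in frames}

    # ---- 3. spectra + roispec + clf per (task, kind) ---------------------
    labels = {f.frame_id: f.label for f in frames}
    results = {}
    for kind in cfg.kinds:
        rois = []
        for f in frames:
            sf = spectra.spectrum_frame(f, kind)
            roi = roispec.apply_mask(sf, masks_signal[f.frame_id])
            rois.append(roispec.normalize(roi))
        for tname in cfg.tasks:
            tsk = roispec.task(tname)
            key = f"{tsk.name}:{kind}"
            st = stage(f"clf_{tname}_{kind}")
            if st.done():
                log.info("%s: resumed", key)
                results[key] = json.loads((st.dir / "metrics.json").read_text())
                continue
            st.begin()
            train, val, test = _assemble(rois, tsk, labels, cfg.clf_ratios,
                                         cfg.seed)
            ccfg = dataclasses.replace(
                cfg.clf, seed=sim.derive_seed(cfg.seed, 0, f"clf-{key}"))
            net1 = clf.build_clf(ccfg)
            net1, hist = clf.train_clf(net1, train, val, ccfg)
            hist.to_csv(st.dir / "history.csv", index=False)
            clf.save_checkpoint(net1, ccfg, st.dir / "model.npz")
            preds = [clf.predict_frame(net1, s) for s in test]
            table = clf.predictions_table(preds)
            table.to_csv(st.dir / "predictions.csv", index=False)
            mm = metrics_eval.roc_auc(
                np.array([p.score for p in preds]),
                np.array([p.true_label for p in preds]))
            mm_vote = metrics_eval.clf_metrics(
                np.array([p.predicted_class for p in preds]),
                np.array([p.true_label for p in preds]))
            res = {"acc": mm_vote.acc, "sen": mm_vote.sen, "spe": mm_vote.spe,
                   "auc": mm.auc,
                   "frame_accuracy": float(np.mean([p.frame_correct for p in preds])),
                   "n_test_frames": len(preds)}
            (st.dir / "metrics.json").write_text(json.dumps(res, indent=2))
            metrics_eval.save_roc_csv(mm, st.dir / "roc.csv")
            st.finish()
            results[key] = res
            log.info("%s: ACC %.3f AUC %.3f", key, res["acc"], res["auc"])

    report["classification"] = results
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline done")
    return report
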