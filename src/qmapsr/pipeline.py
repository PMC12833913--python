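"""End-to-end experiment: simulate -> degrade -> train -> reconstruct ->
evaluate -> report.

One :class:`ExperimentConfig` drives the whole run: a seeded synthetic
cohort is generated, each subject's ground-truth maps are degraded into
paired routine (high-resolution reference) and fast (low-resolution
input) acquisitions, one SRGAN per parameter map is trained on the
training split, the test split is reconstructed, and the image-quality
metrics plus the agreement-statistics battery are assembled into an
:class:`ExperimentReport`.

The default configuration is desk-scale (small grids, few subjects,
capped iterations) so a full smoke experiment completes in minutes on
one CPU; ``full_scale_config`` returns the full-size settings
(512-grid cohort, 200 epochs) for hardware that can afford them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acquisition as acq
from . import phantom as ph
from . import stats as st
from .io import load_lesion_roi_table
from .metrics import NIQE, psnr, ssim
from .srgan import LossWeights, SRGANConfig, SRGANSuperResolver, train

__all__ = ["ExperimentConfig", "ExperimentReport", "full_scale_config",
           "run_experiment", "verify_published_values", "simulate_subject"]

PARAMETERS = ("T1", "T2", "PD")


@dataclass
class ExperimentConfig:
    n_subjects: int = 12
    train_fraction: float = 2 / 3
    grid: int = 64                    # high-resolution grid (full scale: 512)
    seed: int = 0
    parameters: tuple = ("T1",)
    srgan: SRGANConfig = field(default_factory=lambda: SRGANConfig(
        base_channels=16, n_residual_blocks=3,
        disc_channel_plan=(16, 16, 32, 32, 64, 64, 64, 64),
        feat_channel_plan=(8, 8, 16, 16),
        batch_size=4, epochs=1000, max_iterations=1000))
    loss_weights: LossWeights = field(default_factory=LossWeights)
    enable_dl: bool = True
    enable_metrics: bool = True
    enable_stats: bool = True
    noisy: bool = True
    niqe_patch: int = 16              # 96 at full scale; smaller grids need
                                      # more patches for a stable covariance
    n_lesion_subjects: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def full_scale_config(seed: int = 0) -> ExperimentConfig:
    """Full-size settings (not exercised by the test suite)."""
    return ExperimentConfig(
        n_subjects=151, train_fraction=120 / 151, grid=512, seed=seed,
        parameters=PARAMETERS, srgan=SRGANConfig(), niqe_patch=96)


@dataclass
class ExperimentReport:
    config_hash: str
    seed: int
    metrics: pd.DataFrame | None = None        # tidy: subject, parameter, method, metric, value
    agreement: dict = field(default_factory=dict)
    training_logs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        out = {"config_hash": self.config_hash, "seed": self.seed,
               "agreement": {k: v.to_dict() for k, v in self.agreement.items()}}
        if self.metrics is not None:
            out["metrics"] = self.metrics.to_dict(orient="records")
        return json.dumps(out, indent=2, default=float)


def simulate_subject(member: ph.CohortMember, config: ExperimentConfig,
                     parameter: str):
    """(phantom, ground-truth map, routine map, fast map) for one subject."""
    scale = config.grid / ph.HR_GRID
    routine_p, fast_p = acq.default_protocols(parameter, noisy=config.noisy)
    routine_p = acq.scaled_protocol(routine_p, scale)
    fast_p = acq.scaled_protocol(fast_p, scale)
    phan = ph.make_phantom(member.subject_id, member.seed,
                           n_lesions=member.n_lesions,
                           lesion_classes=member.lesion_classes or ("WMH",),
                           grid=config.grid)
    idx = PARAMETERS.index(parameter)
    gt = ph.sample_quant_maps(phan, member.seed + 1)[idx]
    routine = acq.simulate_routine(gt, routine_p, rng_seed=member.seed + 2)
    fast = acq.simulate_fast(gt, fast_p, rng_seed=member.seed + 3)
    return phan, gt, routine, fast


def _stack_pairs(members, config, parameter):
    spec = acq.normalization_spec(parameter)
    lr, hr, phantoms, routines, fasts = [], [], [], [], []
    for m in members:
        phan, gt, routine, fast = simulate_subject(m, config, parameter)
        lr.append(acq.normalize(fast, spec))
        hr.append(acq.normalize(routine, spec))
        phantoms.append(phan)
        routines.append(routine)
        fasts.append(fast)
    return np.stack(lr), np.stack(hr), phantoms, routines, fasts


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute all stages for every configured parameter independently."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    train_set, test_set = ph.make_cohort(
        config.n_subjects, config.train_fraction, config.seed,
        n_test_lesion_subjects=config.n_lesion_subjects)
    report = ExperimentReport(config_hash=config.config_hash(), seed=config.seed)
    metric_rows = []
    for parameter in config.parameters:
        spec = acq.normalization_spec(parameter)
        lr_tr, hr_tr, *_ = _stack_pairs(train_set, config, parameter)
        lr_te, hr_te, phantoms, routines, fasts = _stack_pairs(
            test_set, config, parameter)

        model = None
        if config.enable_dl:
            srcfg = config.srgan
            srcfg.rng_seed = config.seed
            model, log = train(lr_tr, hr_tr, srcfg, config.loss_weights)
            report.training_logs[parameter] = log.to_frame()
            if outdir:
                log.to_frame().to_csv(outdir / f"train_log_{parameter}.csv",
                                      index=False)
        # reconstructions on the test split (stored-intensity for metrics);
        # full-reference metrics need the HR grid, so the fast maps are
        # zero-fill upsampled for PSNR/SSIM but NIQE scores them on their
        # native display grid, as acquired
        recon_methods: dict[str, list[np.ndarray]] = {"fast": [], "routine": []}
        fast_native: list[np.ndarray] = []
        if model is not None:
            recon_methods["DL"] = []
        for i, m in enumerate(test_set):
            hr_stored = acq.denormalize(hr_te[i], spec,
                                        routines[i].pixel_spacing).stored()
            fast_up = acq.zero_fill_upsample(fasts[i], config.grid)
            recon_methods["routine"].append(hr_stored)
            recon_methods["fast"].append(fast_up.stored())
            fast_native.append(fasts[i].stored())
            if model is not None:
                sr = model.transform(lr_te[i])
                dl_map = acq.denormalize(sr, spec, routines[i].pixel_spacing)
                recon_methods["DL"].append(dl_map.stored())

        if config.enable_metrics:
            # pristine corpus: routine-simulated maps from the training split
            # (plus the test routines), repeated to the 10-image minimum
            corpus = [acq.denormalize(h, spec, 1.0).stored().astype(float)
                      for h in hr_tr]
            corpus += [r.astype(float) for r in recon_methods["routine"]]
            corpus = corpus * max(1, -(-10 // len(corpus)))
            niqe_model = NIQE(patch_size=config.niqe_patch).fit(corpus)
            for i, m in enumerate(test_set):
                ref = recon_methods["routine"][i]
                for method, stack in recon_methods.items():
                    img = stack[i]
                    if method != "routine":
                        metric_rows += [
                            dict(subject_id=m.subject_id, parameter=parameter,
                                 method=method, metric="PSNR",
                                 value=psnr(ref, img)),
                            dict(subject_id=m.subject_id, parameter=parameter,
                                 method=method, metric="SSIM",
                                 value=ssim(ref, img))]
                    niqe_img = fast_native[i] if method == "fast" else img
                    metric_rows.append(
                        dict(subject_id=m.subject_id, parameter=parameter,
                             method=method, metric="NIQE",
                             value=niqe_model.score_image(niqe_img.astype(float))))

        if config.enable_stats:
            tissue_means: dict[str, dict[str, np.ndarray]] = {}
            region_means: dict[str, dict[str, np.ndarray]] = {}
            methods = list(recon_methods)
            test_method = "DL" if "DL" in methods else "fast"
            for tissue in ("GM", "WM"):
                tissue_means[tissue] = {meth: [] for meth in methods}
            region_names = list(phantoms[0].region_masks)
            for name in region_names:
                region_means[name] = {meth: [] for meth in methods}
            for i, phan in enumerate(phantoms):
                for meth in methods:
                    phys = recon_methods[meth][i] * ph.RESCALE_SLOPE
                    for tissue in ("GM", "WM"):
                        tissue_means[tissue][meth].append(
                            st.extract_mean(phys, phan.tissue_mask(tissue)))
                    for name in region_names:
                        if name in phan.region_masks:
                            region_means[name][meth].append(
                                st.extract_mean(phys, phan.region_masks[name]))
            tissue_means = {t: {m: np.asarray(v) for m, v in d.items()}
                            for t, d in tissue_means.items()}
            region_means = {r: {m: np.asarray(v) for m, v in d.items()}
                            for r, d in region_means.items()}
            report.agreement[parameter] = st.build_agreement_report(
                parameter, tissue_means, region_means,
                test_method=test_method, reference_method="routine")
    if metric_rows:
        report.metrics = pd.DataFrame(metric_rows)
        if outdir:
            report.metrics.to_csv(outdir / "metrics.csv", index=False)
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report


# --------------------------------------------------------- fixture checks

#: routine-scan tissue means (ms / ms / percent) used for the margins
ROUTINE_TISSUE_MEANS = {
    ("T1", "GM"): 1232.65, ("T2", "GM"): 93.33, ("PD", "GM"): 80.11,
    ("T1", "WM"): 837.86, ("T2", "WM"): 79.92, ("PD", "WM"): 68.21,
}
#: published +-5% equivalence margins for those means
EXPECTED_MARGINS = {
    ("T1", "GM"): 61.63, ("T2", "GM"): 4.67, ("PD", "GM"): 4.01,
    ("T1", "WM"): 41.89, ("T2", "WM"): 4.00, ("PD", "WM"): 3.41,
}
#: published lesion-table paired-test p-values (2-decimal).  The PD entry
#: as published does not reproduce under a paired t-test on the shipped
#: table (it matches an unpaired test instead); verify_published_values
#: reports that row as a failure.
EXPECTED_LESION_P = {"T1": 0.67, "T2": 0.73, "PD": 0.75}


def verify_published_values(roi_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the published margin and lesion-test values and compare.

    Returns a tidy table (check, expected, computed, passed); any row
    whose recomputed value disagrees at the printed precision is marked
    failed with the mismatching cell identified.
    """
    rows = []
    cfg = st.TOSTConfig()
    for (parameter, tissue), mean in ROUTINE_TISSUE_MEANS.items():
        got = round(cfg.margin(mean), 2)
        want = EXPECTED_MARGINS[(parameter, tissue)]
        rows.append({"check": f"margin_{parameter}_{tissue}", "expected": want,
                     "computed": got, "passed": bool(got == want)})
    table = roi_table if roi_table is not None else load_lesion_roi_table()
    res = st.lesion_table_compare(table)
    for _, r in res.iterrows():
        want = EXPECTED_LESION_P[r.parameter]
        got = round(float(r.p), 2)
        rows.append({"check": f"lesion_p_{r.parameter}", "expected": want,
                     "computed": got, "passed": bool(got == want)})
    return pd.DataFrame(rows)
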