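"""End-to-end pipeline: simulate -> coverage -> correct -> indices /
fluorescence / traits -> statistics, with manifest tracking.

The demo dataset mirrors the study design: 2 ecotypes x 3 treatments x
15 seedlings (90 in total) observed at 12 spectral timepoints, each
with a footprint photograph, a mixed shoot spectrum against the black
background, daily background spectra, one quenching trace per seedling,
a soil drying-down series and a long-format trait table.  Injected
treatment effects (drought lowers chlorophyll and raises xanthophyll
de-epoxidation with time) propagate to REP and PRI so the statistical
stage has real signal to find.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fluorescence import compute_parameters, default_protocol, extract_features, FluorescenceTrace
from .imaging import (
    BACKGROUND,
    SEEDLING,
    CoverageEstimate,
    FovGeometry,
    PixelTrainingSet,
    estimate_coverage,
    fov_radius_cm,
    load_image,
    train_pixel_classifier,
)
from .spectra import Spectrum, average_background, pri, rep, unmix_seedling
from .stats import fit_lmm_ar1, pairwise_comparisons, predicted_means, rda, wald_tests
from .synthetic import (
    EndmemberModel,
    FluorescenceTruth,
    SceneTruth,
    TraitEffectSpec,
    default_grid,
    generate_background_spectrum,
    generate_endmember_spectrum,
    generate_fluorescence_trace,
    generate_seedling_image,
    generate_soil_drying,
    generate_trait_dataset,
    mix_measurement,
)
from .traits_soil import fit_soil_calibration, pwp_from_potential

log = logging.getLogger("phenopine")

__all__ = ["RunConfig", "PipelineError", "make_demo_dataset", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    outdir: str
    seed: int = 0
    n_per_cell: int = 15
    n_dats: int = 12
    image_size: tuple[int, int] = (64, 64)
    knn_k: int = 5
    min_coverage: float = 0.10
    n_perm: int = 499
    spectral_subsample_nm: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _drought_model(treatment: str, dat_index: int, n_dats: int,
                   seedling_offset: float) -> EndmemberModel:
    """Endmember parameters drifting with drought severity over time."""
    severity = {"C": 0.0, "MD": 0.5, "D": 1.0}[treatment]
    progress = dat_index / max(n_dats - 1, 1)
    chl = max(1.2 - 0.6 * severity * progress + seedling_offset, 0.05)
    deepox = min(0.8 * severity * progress, 1.0)
    return EndmemberModel(chlorophyll_level=chl,
                          xanthophyll_deepoxidation=deepox)


def make_demo_dataset(outdir, seed: int = 0, n_per_cell: int = 15,
                      n_dats: int = 12, image_size=(64, 64)) -> dict:
    """Write a complete miniature study with a ground-truth JSON sidecar."""
    from PIL import Image

    out = Path(outdir)
    rng = np.random.default_rng(seed)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(exist_ok=True)
    (out / "fluorescence").mkdir(exist_ok=True)
    (out / "soil").mkdir(exist_ok=True)

    grid = default_grid()
    background = generate_background_spectrum(grid)
    background.to_csv(out / "spectra" / "background.csv")

    h, w = image_size
    radius = 0.42 * min(h, w)
    geometry = FovGeometry(pixels_per_cm=radius / fov_radius_cm(24.0, 25.0),
                           center_px=(h / 2.0, w / 2.0))

    # classifier training pixels drawn from the generator's colour model
    n_train = 600
    fg = np.stack([rng.integers(30, 70, n_train),
                   rng.integers(100, 170, n_train),
                   rng.integers(30, 80, n_train)], axis=1) / 255.0
    bg = rng.integers(2, 22, size=(n_train, 3)) / 255.0
    train = pd.DataFrame(np.vstack([fg, bg]), columns=["r", "g", "b"])
    train["label"] = [SEEDLING] * n_train + [BACKGROUND] * n_train
    train.to_csv(out / "train_pixels.csv", index=False)

    ecotypes = ["lowland", "upland"]
    treatments = ["C", "MD", "D"]
    manifest_rows = []
    truth: dict = {"seed": seed, "coverage": {}, "fluorescence": {},
                   "geometry": {"pixels_per_cm": geometry.pixels_per_cm,
                                "center_px": list(geometry.center_px)}}

    sid = 0
    for eco in ecotypes:
        for trt in treatments:
            for j in range(n_per_cell):
                seedling = f"S{sid:03d}"
                offset = float(rng.normal(0.0, 0.05))
                for d in range(n_dats):
                    cov = float(rng.uniform(0.30, 0.90))
                    scene = SceneTruth(cov, image_size=image_size,
                                       fov_center=geometry.center_px,
                                       fov_radius=radius,
                                       seed=int(rng.integers(2 ** 31)))
                    img, _ = generate_seedling_image(scene)
                    img_path = out / "images" / f"{seedling}_d{d:02d}.png"
                    Image.fromarray(img).save(img_path)
                    model = _drought_model(trt, d, n_dats, offset)
                    endmember = generate_endmember_spectrum(model, grid)
                    mixed = mix_measurement(endmember, background, cov)
                    spec_path = out / "spectra" / f"{seedling}_d{d:02d}.csv"
                    mixed.to_csv(spec_path)
                    truth["coverage"][f"{seedling}_d{d:02d}"] = cov
                    manifest_rows.append({
                        "seedling_id": seedling, "ecotype": eco,
                        "treatment": trt, "dat": d + 1,
                        "image": str(img_path.relative_to(out)),
                        "spectrum": str(spec_path.relative_to(out)),
                    })
                # one quenching trace per seedling at the final stress date
                npq_shift = {"C": 0.0, "MD": 0.06, "D": 0.12}[trt]
                ftruth = FluorescenceTruth(
                    FM_L=tuple(v - npq_shift for v in (0.75, 0.72, 0.70, 0.69, 0.68)),
                    seed=int(rng.integers(2 ** 31)),
                )
                trace = generate_fluorescence_trace(ftruth)
                trace.to_csv(out / "fluorescence" / f"{seedling}.csv")
                truth["fluorescence"][seedling] = {
                    "FM": ftruth.FM, "F0": ftruth.F0, "FM_Lss": ftruth.FM_L[-1]}
                sid += 1

    pd.DataFrame(manifest_rows).to_csv(out / "samples.csv", index=False)

    soil = generate_soil_drying(seed=seed)
    soil.calibration.to_csv(out / "soil" / "calibration.csv", index=False)
    soil.retention.to_csv(out / "soil" / "retention.csv", index=False)
    truth["soil"] = soil.truth

    trait_spec = TraitEffectSpec(
        dat_effects=tuple(np.linspace(-1, 1, n_dats) - np.mean(np.linspace(-1, 1, n_dats))),
        treatment_effects=(1.0, 0.0, -1.0),
        n_per_cell=n_per_cell,
        seed=seed,
    )
    traits = generate_trait_dataset(trait_spec)
    traits.to_csv(out / "traits.csv", index=False)
    truth["trait_spec"] = {
        "grand_mean": trait_spec.grand_mean,
        "treatment_effects": list(trait_spec.treatment_effects),
        "ar1_rho": trait_spec.ar1_rho,
        "block_dat_sd": trait_spec.block_dat_sd,
    }

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order and write a JSON manifest."""
    out = Path(config.outdir)
    if not out.parent.exists():
        raise FileNotFoundError(
            f"output location {out.parent} does not exist"
        )
    results = out / "results"
    results.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "stages": [], "status": "running"}

    def finish_stage(name: str, t0: float, outputs: list[Path]):
        manifest["stages"].append({
            "stage": name,
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _file_hash(p) for p in outputs},
        })
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    def write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    stage = "simulate"
    try:
        t0 = time.time()
        make_demo_dataset(out, seed=config.seed, n_per_cell=config.n_per_cell,
                          n_dats=config.n_dats, image_size=tuple(config.image_size))
        finish_stage(stage, t0, [out / "truth.json", out / "samples.csv",
                                 out / "traits.csv"])

        stage = "coverage"
        t0 = time.time()
        samples = pd.read_csv(out / "samples.csv")
        train = PixelTrainingSet.from_csv(out / "train_pixels.csv")
        clf = train_pixel_classifier(train, k=config.knn_k)
        with open(out / "truth.json") as fh:
            truth = json.load(fh)
        geometry = FovGeometry(
            pixels_per_cm=truth["geometry"]["pixels_per_cm"],
            center_px=tuple(truth["geometry"]["center_px"]),
        )
        coverages = {}
        for _, row in samples.iterrows():
            img = load_image(out / row["image"])
            est = estimate_coverage(img, clf, geometry)
            coverages[Path(row["image"]).stem] = est.c_seedling
        cov_path = results / "coverage.json"
        with open(cov_path, "w") as fh:
            json.dump(coverages, fh, indent=2)
        finish_stage(stage, t0, [cov_path])

        stage = "correct+indices"
        t0 = time.time()
        background = Spectrum.from_csv(out / "spectra" / "background.csv",
                                       role="background")
        background = average_background([background])
        rows = []
        for _, row in samples.iterrows():
            key = Path(row["spectrum"]).stem
            measured = Spectrum.from_csv(out / row["spectrum"])
            c1 = coverages[key]
            if c1 < config.min_coverage:
                continue
            corrected = unmix_seedling(measured, background, c1,
                                       min_coverage=config.min_coverage)
            rows.append({"seedling_id": row["seedling_id"],
                         "ecotype": row["ecotype"],
                         "treatment": row["treatment"], "dat": row["dat"],
                         "c1": c1, "pri": pri(corrected),
                         "rep": rep(corrected)})
        indices = pd.DataFrame(rows)
        idx_path = results / "indices.csv"
        indices.to_csv(idx_path, index=False)
        finish_stage(stage, t0, [idx_path])

        stage = "fluorescence"
        t0 = time.time()
        protocol = default_protocol()
        fl_rows = []
        meta = samples.drop_duplicates("seedling_id").set_index("seedling_id")
        for trace_file in sorted((out / "fluorescence").glob("*.csv")):
            tr = FluorescenceTrace.from_csv(trace_file)
            params = compute_parameters(extract_features(tr, protocol))
            rec = {"seedling_id": trace_file.stem,
                   "ecotype": meta.loc[trace_file.stem, "ecotype"],
                   "treatment": meta.loc[trace_file.stem, "treatment"]}
            rec.update(params.as_dict())
            fl_rows.append(rec)
        fluor = pd.DataFrame(fl_rows)
        fl_path = results / "fluorescence.csv"
        fluor.to_csv(fl_path, index=False)
        finish_stage(stage, t0, [fl_path])

        stage = "soil"
        t0 = time.time()
        cal_df = pd.read_csv(out / "soil" / "calibration.csv")
        cal = fit_soil_calibration(cal_df["raw"], cal_df["vwc"])
        ret = pd.read_csv(out / "soil" / "retention.csv")
        pwp = pwp_from_potential(ret["vwc"], ret["potential_mpa"])
        soil_path = results / "soil.json"
        with open(soil_path, "w") as fh:
            json.dump({"cal_intercept": float(cal.coefficients[0]),
                       "cal_slope": float(cal.coefficients[1]),
                       "pwp_vwc": pwp}, fh, indent=2)
        finish_stage(stage, t0, [soil_path])

        stage = "stats"
        t0 = time.time()
        traits = pd.read_csv(out / "traits.csv")
        fit = fit_lmm_ar1(traits)
        wald = wald_tests(fit)
        wald.to_csv(results / "wald.csv", index=False)
        means = predicted_means(fit, ["ecotype", "treatment"])
        means.to_csv(results / "predicted_means.csv", index=False)
        comp = pairwise_comparisons(fit, "treatment", by=["ecotype"])
        comp.to_csv(results / "comparisons.csv", index=False)
        # REP mixed model on the spectral index table
        rep_fit = fit_lmm_ar1(
            indices.assign(block=indices["seedling_id"].str[-1].astype(int)
                           % 5),
            value_col="rep",
        )
        wald_tests(rep_fit).to_csv(results / "wald_rep.csv", index=False)
        # ordination of final-date indices plus fluorescence parameters
        final = indices[indices["dat"] == indices["dat"].max()]
        merged = final.merge(
            fluor[["seedling_id", "QY_max", "NPQ_Lss", "Rfd_Lss"]],
            on="seedling_id")
        ord_res = rda(merged[["pri", "rep", "QY_max", "NPQ_Lss", "Rfd_Lss"]],
                      merged[["ecotype", "treatment"]],
                      n_perm=config.n_perm, seed=config.seed)
        with open(results / "rda.json", "w") as fh:
            json.dump({"r_squared": ord_res.r_squared,
                       "axis_fractions": ord_res.axis_fractions.tolist(),
                       "overall_p": ord_res.overall_p,
                       "predictor_p": ord_res.predictor_p}, fh, indent=2)
        finish_stage(stage, t0, [results / "wald.csv",
                                 results / "predicted_means.csv",
                                 results / "comparisons.csv",
                                 results / "wald_rep.csv",
                                 results / "rda.json"])
    except Exception as err:
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": stage, "error": str(err)}
        write_manifest()
        raise PipelineError(stage, err) from err

    manifest["status"] = "ok"
    write_manifest()
    return manifest
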