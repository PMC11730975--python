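"""End-to-end synthetic study harness.

Mirrors the structure of the full analysis on synthetic data: generate the
stimulus batteries, compute V1 population responses and image statistics,
simulate SSVEP recordings and discomfort ratings from known ground truth,
then run the PCA and mixed-model stages and write a report directory of
CSV tables plus a plain-text summary.  The whole run is a pure function of
the master seed: per-stage seeds are derived deterministically, and every
table is written with a fixed float format, so repeated runs with the same
configuration are byte-identical.

Default problem sizes are deliberately modest (128 px images, 200 model
cells, 1,500 retained edges) so the full study runs in well under a minute;
they are configuration values, not estimator defaults, and scale up freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imagestats, modeling, ssvep, stimuli, v1model

PCA_VARIABLES = [
    "slope_k", "fractal_D", "rms_contrast", "csf_contrast",
    "entropy_first", "entropy_second", "model_total",
]


@dataclass
class StudyConfig:
    master_seed: int = 0
    image_size: int = 128
    ppd: float = 16.0
    n_cells: int = 200
    bump_frequencies: tuple[float, ...] = (0.75, 1.5, 3.0, 6.0)
    grating_frequencies: tuple[float, ...] = (0.75, 1.5, 3.0, 6.0)
    stripe_frequencies: tuple[float, ...] = (1.5, 3.0, 6.0)
    natural_exponents: tuple[float, ...] = (-0.9, -1.0, -1.1, -1.2)
    grating_contrast: float = 0.8
    n_observers: int = 11
    observer_sd: float = 0.5
    residual_sd: float = 0.8
    rating_coefficients: dict = field(
        default_factory=lambda: {"model_total_z": 0.5, "model_kurtosis_z": 0.25}
    )
    intercept: float = 3.5
    ssvep_base_uv: float = 1.0
    ssvep_contrast_gain_uv: float = 2.0
    eeg_noise_rms_uv: float = 0.5
    edge_top: int = 1500
    pc_retain_override: tuple[int, ...] | None = None
    window_flat_px: int | None = None  # defaults to size // 4
    window_sigma_px: float = 10.0


def _seed_stream(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def build_battery(cfg: StudyConfig) -> list[tuple[str, stimuli.ImageStimulus]]:
    """The synthetic stimulus set: natural surrogates, bumps, gratings,
    stripe textures, each Gaussian-windowed as presented."""
    seeds = _seed_stream(cfg.master_seed, 64)
    flat = cfg.window_flat_px if cfg.window_flat_px is not None else cfg.image_size // 4
    items: list[tuple[str, stimuli.ImageStimulus]] = []

    def windowed(img: stimuli.ImageStimulus) -> stimuli.ImageStimulus:
        return stimuli.apply_gaussian_window(img, flat, cfg.window_sigma_px)

    si = 0
    for i, k in enumerate(cfg.natural_exponents):
        img = stimuli.make_onef_noise(k, cfg.image_size, seeds[si], cfg.ppd)
        si += 1
        items.append((f"natural_{i:02d}", windowed(img)))
    for f in cfg.bump_frequencies:
        spec = stimuli.BumpSpec(f0=f, size=cfg.image_size, seed=seeds[si])
        si += 1
        items.append((f"bump_{f:g}", windowed(stimuli.make_bump_noise(spec, cfg.ppd))))
    for f in cfg.grating_frequencies:
        spec = stimuli.GratingSpec(
            frequency=f, contrast=cfg.grating_contrast, size=cfg.image_size
        )
        items.append((f"grating_{f:g}", windowed(stimuli.make_grating(spec, cfg.ppd))))
    for f in cfg.stripe_frequencies:
        img = stimuli.make_stripe_texture(
            f, cfg.ppd, cfg.image_size, wiggle_amp_px=cfg.image_size / 32
        )
        items.append((f"stripe_{f:g}", windowed(img)))
    return items


def _spatial_frequency_of(image_id: str) -> float:
    for prefix in ("bump_", "grating_", "stripe_"):
        if image_id.startswith(prefix):
            return float(image_id[len(prefix):])
    return float("nan")


def run_full_synthetic_study(cfg: StudyConfig, out_dir) -> dict:
    """Run the whole pipeline and write report CSVs to ``out_dir``.

    Returns the in-memory tables keyed by report name.  Any stage failure
    propagates with the stage name and master seed attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(cfg.master_seed + 1, 8)
    report: dict[str, pd.DataFrame] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with stage + seed
                raise RuntimeError(
                    f"study stage {name!r} failed (master_seed={cfg.master_seed}): {exc}"
                ) from exc
        return wrap

    battery = stage("stimuli")(lambda: build_battery(cfg))
    meta = pd.DataFrame(
        {
            "image_id": [iid for iid, _ in battery],
            "category": [img.category for _, img in battery],
            "ppd": [img.ppd for _, img in battery],
            "spatial_frequency": [_spatial_frequency_of(iid) for iid, _ in battery],
        }
    )
    report["stimuli_metadata"] = meta

    def _stats():
        cfg_e = imagestats.EdgeExtractionConfig(top_edges=cfg.edge_top)
        recs = [
            imagestats.compute_all(img, iid, cfg_e, {"n_d_bins": 100})
            for iid, img in battery
        ]
        return imagestats.records_to_frame(recs)

    stats = stage("image_statistics")(_stats)
    report["image_stats"] = stats

    def _responses():
        # cap cell peak frequencies below the image Nyquist for this ppd
        f_hi = min(16.0, 0.75 * cfg.ppd / 2.0)
        pop = v1model.sample_population(
            cfg.n_cells, seeds[0], {"freq_range": (0.5, f_hi)}
        )
        rows = []
        for iid, img in battery:
            r = v1model.respond(img, pop)
            rows.append(
                {"image_id": iid, "model_total": r.total, "model_kurtosis": r.kurtosis}
            )
        return pd.DataFrame(rows)

    responses = stage("v1_model")(_responses)
    report["model_responses"] = responses

    table = meta.merge(stats.drop(columns=["category"]), on="image_id").merge(
        responses, on="image_id"
    )

    def _eeg():
        csf_map = dict(zip(table["image_id"], table["csf_contrast"]))
        amp_map = {
            iid: cfg.ssvep_base_uv + cfg.ssvep_contrast_gain_uv * csf_map[iid]
            for iid, _ in battery
        }
        truth = stimuli.SyntheticGroundTruth(
            rating_coefficients=dict(cfg.rating_coefficients),
            observer_sd=cfg.observer_sd,
            residual_sd=cfg.residual_sd,
            ssvep_amplitude_map=amp_map,
            intercept=cfg.intercept,
            seed=seeds[1],
        )
        rec = stimuli.generate_synthetic_eeg(
            [iid for iid, _ in battery], truth, noise_rms_uv=cfg.eeg_noise_rms_uv
        )
        res = ssvep.analyze(rec)
        return truth, res.rename(columns={"condition": "image_id"})

    truth, ssvep_table = stage("ssvep")(_eeg)
    report["ssvep_results"] = ssvep_table

    def _trials():
        merged = table.merge(ssvep_table, on="image_id")
        merged = stimuli.standardize_columns(
            merged, ["model_total", "model_kurtosis", "power_5hz"], suffix="_z"
        )
        return stimuli.generate_synthetic_ratings(
            merged, truth, cfg.n_observers,
            predictors=list(cfg.rating_coefficients),
        )

    trials = stage("synthetic_ratings")(_trials)
    report["trial_table"] = trials

    def _pca():
        pca_input = table.copy()
        pca_input.loc[pca_input["slope_k"].isna(), "slope_k"] = np.nan
        res = modeling.pca_image_stats(pca_input, PCA_VARIABLES)
        loadings = pd.DataFrame(
            res.loadings,
            index=res.variables,
            columns=[f"PC{i + 1}" for i in range(res.loadings.shape[1])],
        ).reset_index(names="variable")
        eig = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(res.eigenvalues))],
                "eigenvalue": res.eigenvalues,
                "variance_fraction": res.variance_explained,
                "kaiser_retained": [
                    i in res.retained for i in range(len(res.eigenvalues))
                ],
            }
        )
        return res, loadings, eig

    pca_res, loadings, eig = stage("pca")(_pca)
    report["pca_loadings"] = loadings
    report["pca_eigenvalues"] = eig

    def _fits():
        fit_main = modeling.fit_rating_model(
            trials, ["model_total_z", "model_kurtosis_z", "power_5hz_z"]
        )
        fit_cat = modeling.fit_rating_model(
            trials, ["category"], baseline_category="onef_noise"
        )
        sf_rows = trials[trials["category"].isin(["bump", "stripe_texture"])]
        fit_sf = modeling.fit_sf_tuning(sf_rows, category_col="category")
        tables = {}
        for name, fit in (
            ("coef_rating_model", fit_main),
            ("coef_category_model", fit_cat),
            ("coef_sf_tuning", fit_sf),
        ):
            t = fit.coef_table().reset_index(names="term")
            t["formula"] = fit.formula
            tables[name] = t
        return tables

    for name, t in stage("mixed_models")(_fits).items():
        report[name] = t

    for name, frame in report.items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")

    kept = int(ssvep_table["n_kept"].sum())
    rejected = int(ssvep_table["n_rejected"].sum())
    retained = ", ".join(f"PC{i + 1}" for i in pca_res.retained) or "none"
    summary = (
        "Synthetic efficient-coding discomfort study\n"
        f"master seed: {cfg.master_seed}\n"
        f"images: {len(battery)} ({cfg.image_size}x{cfg.image_size} px, "
        f"{cfg.ppd:g} px/deg)\n"
        f"model cells: {cfg.n_cells}\n"
        f"observers: {cfg.n_observers}\n"
        f"sub-epochs kept/rejected: {kept}/{rejected}\n"
        f"PCA variance fractions: "
        + ", ".join(f"{v:.3f}" for v in pca_res.variance_explained)
        + f"\nKaiser-retained components: {retained}\n"
        "note: no multiple-testing correction applied\n"
    )
    (out / "summary.txt").write_text(summary)
    report["_summary"] = summary
    return report
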