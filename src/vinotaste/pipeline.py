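"""End-to-end orchestration: simulate -> extract -> score -> pca -> train -> report.

Every stage reads and writes plain files (CSV/PNG/YAML/JSON) under the
run's output directory, so any stage can be re-run standalone or fed
user data in place of the synthetic inputs.  A manifest records seeds,
package version, and completed stages; a run is fully reproducible from
its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemicals import CHEMICALS
from .colorimetry import detect_wells, extract_features, feature_columns
from .pca import fit_pca, score_plot
from .selection import (
    grid_search,
    make_split,
    restricted_grid,
    table2_full_grid,
)
from .synthetic import (
    default_dye_model,
    generate_panel,
    load_image,
    panel_from_frame,
    panel_to_frame,
    render_image_pair,
    save_image,
    simulate_color_response,
)
from .taste import score_panel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "score", "pca", "train", "report")
TASTES = ("sweetness", "sourness", "astringency")


@dataclass
class RunConfig:
    out_dir: str = "vinotaste_run"
    seed: int = 1
    n_base: int = 23
    n_mixtures: int = 22
    noise_sd: float = 1.0  # colour-response noise, RGB counts
    pixel_noise_sd: float = 2.0  # per-pixel camera noise, RGB counts
    grid: str = "restricted"  # "restricted" | "full"
    max_epochs: int = 2000
    n_components: int = 3
    autoscale: bool = False
    include_formic: bool = True

    def __post_init__(self) -> None:
        if self.grid not in ("restricted", "full"):
            raise ValueError(f"unknown grid mode {self.grid!r}")
        # stable per-stage seeds derived from the master seed
        ss = np.random.SeedSequence(self.seed)
        kids = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
        self.panel_seed, self.dye_seed, self.response_seed, self.ann_seed = kids

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls) if f.init}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    """Panel CSV, dye model YAML, truth deltas CSV, and image-pair PNGs."""
    out = _out(config)
    panel = generate_panel(config.n_base, config.n_mixtures, config.panel_seed)
    panel_to_frame(panel).to_csv(out / "panel.csv", index=False)
    dye_model = default_dye_model(config.dye_seed)
    dye_model.to_yaml(out / "dye_model.yaml")
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    truth_rows = []
    rng = np.random.SeedSequence(config.response_seed)
    sample_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2 * len(panel))]
    for i, profile in enumerate(panel):
        delta = simulate_color_response(
            profile, dye_model, noise_sd=config.noise_sd, seed=sample_seeds[2 * i]
        )
        pair = render_image_pair(
            delta, dye_model, pixel_noise_sd=config.pixel_noise_sd,
            seed=sample_seeds[2 * i + 1],
        )
        save_image(pair.before, img_dir / f"{profile.sample_id}_before.png")
        save_image(pair.after, img_dir / f"{profile.sample_id}_after.png")
        truth_rows.append(
            {"sample_id": profile.sample_id,
             **dict(zip(feature_columns(), delta.ravel()))}
        )
    pd.DataFrame(truth_rows).to_csv(out / "truth_deltas.csv", index=False)


def stage_extract(config: RunConfig) -> None:
    """Well detection + 24-feature extraction for every image pair."""
    out = _out(config)
    panel = pd.read_csv(out / "panel.csv")
    rows = []
    for sample_id in panel["sample_id"]:
        before = load_image(out / "images" / f"{sample_id}_before.png")
        after = load_image(out / "images" / f"{sample_id}_after.png")
        wells = detect_wells(before)
        fv = extract_features(before, after, wells, sample_id=sample_id)
        rows.append({"sample_id": sample_id, **dict(zip(feature_columns(), fv.values))})
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)


def stage_score(config: RunConfig) -> None:
    """Sweetness/sourness/astringency targets from the panel chemistry."""
    out = _out(config)
    panel = panel_from_frame(pd.read_csv(out / "panel.csv"))
    scores = score_panel(panel, include_formic=config.include_formic)
    scores.to_csv(out / "scores.csv", index=False)


def stage_pca(config: RunConfig) -> None:
    """PCA of the feature matrix: scores, loadings, variance, score plots."""
    out = _out(config)
    features = pd.read_csv(out / "features.csv")
    panel = pd.read_csv(out / "panel.csv")
    X = features[feature_columns()].to_numpy()
    model = fit_pca(X, n_components=config.n_components, autoscale=config.autoscale)
    k = model.n_components
    pd.DataFrame(
        model.scores, columns=[f"PC{i + 1}" for i in range(k)]
    ).assign(sample_id=features["sample_id"]).to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame(
        model.loadings, index=feature_columns(),
        columns=[f"PC{i + 1}" for i in range(k)],
    ).to_csv(out / "pca_loadings.csv", index_label="feature")
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(k)],
         "explained_variance_pct": model.explained_variance_pct}
    ).to_csv(out / "pca_explained.csv", index=False)
    clusters = panel["cluster"].tolist()
    labels = features["sample_id"].tolist()
    score_plot(model, labels, clusters, pcs=(1, 2), path=out / "pca_pc1_pc2.png")
    if k >= 3:
        score_plot(model, labels, clusters, pcs=(1, 3), path=out / "pca_pc1_pc3.png")


def stage_train(config: RunConfig) -> None:
    """Grid search per taste; leaderboards, predictions, report JSON."""
    out = _out(config)
    features = pd.read_csv(out / "features.csv")
    scores = pd.read_csv(out / "scores.csv")
    merged = features.merge(scores, on="sample_id")
    X = merged[feature_columns()].to_numpy()
    split = make_split(len(merged), config.ann_seed)
    grid = (
        restricted_grid(config.max_epochs)
        if config.grid == "restricted"
        else table2_full_grid(max_epochs=config.max_epochs)
    )
    report: dict = {"split": dataclasses.asdict(split), "tastes": {}}
    for t_idx, taste in enumerate(TASTES):
        y = merged[taste].to_numpy()
        ev = grid_search(X, y, split, grid, seed=config.ann_seed + t_idx + 1)
        ev.leaderboard.to_csv(out / f"leaderboard_{taste}.csv", index=False)
        pd.DataFrame(
            {
                "sample_id": merged["sample_id"].to_numpy()[list(split.test)],
                "measured": y[list(split.test)],
                "predicted": ev.predictions_test,
            }
        ).to_csv(out / f"predictions_{taste}.csv", index=False)
        report["tastes"][taste] = ev.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)


def stage_report(config: RunConfig) -> None:
    """Measured-vs-predicted scatter plots from the stored predictions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = _out(config)
    with open(out / "report.json") as fh:
        report = json.load(fh)
    for taste in TASTES:
        pred = pd.read_csv(out / f"predictions_{taste}.csv")
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(pred["measured"], pred["predicted"], s=30)
        lims = [
            min(pred["measured"].min(), pred["predicted"].min()),
            max(pred["measured"].max(), pred["predicted"].max()),
        ]
        ax.plot(lims, lims, "k--", lw=0.8)
        info = report["tastes"][taste]
        ax.set_title(
            f"{taste}: R²={info['r2_test']:.3f}, "
            f"RMSEP={info['rmsep_test']:.3g} ({info['rmsep_pct']:.2f}%)"
        )
        ax.set_xlabel(f"measured {taste}")
        ax.set_ylabel(f"predicted {taste}")
        fig.tight_layout()
        fig.savefig(out / f"scatter_{taste}.png", dpi=120)
        plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "score": stage_score,
    "pca": stage_pca,
    "train": stage_train,
    "report": stage_report,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    out = _out(config)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    completed = []
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:  # halt with stage name and diagnostics
            raise StageError(stage, exc) from exc
        completed.append(stage)
    manifest = {
        "package": "vinotaste",
        "version": __version__,
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.init
        },
        "seeds": {
            "master": config.seed,
            "panel": config.panel_seed,
            "dye_model": config.dye_seed,
            "response": config.response_seed,
            "ann": config.ann_seed,
        },
        "chemicals": list(CHEMICALS),
        "stages_completed": completed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
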