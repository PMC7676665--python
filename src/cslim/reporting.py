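"""Group statistics, feature correlations and the end-to-end slide pipeline.

Group comparisons use the two-sided two-sample Student t-test (pooled
variance) by default, matching the study design; Welch's variant is
available for unequal group sizes/variances. Significance is flagged at a
configurable α (default 0.05). No multiple-testing correction is applied;
raw p-values are reported.

``quantify_slide`` chains the full pipeline over a directory of per-field
interferogram stacks: reconstruct → background-normalize → dry-mass density
→ quarter frames → mixture classification → stain mask → masked mass
integration, emitting per-tile records, per-label mass summaries, QC flags
and a log of every parameter used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .classification import (
    QUADRANTS,
    MixtureFit,
    TileRecord,
    classify_tiles,
    fit_two_gaussians,
    quarter_frames,
    tile_statistic,
)
from .dry_mass import MassSummary, OpticalConstants, integrate_mass, phase_to_density
from .errors import DegenerateDataError, SampleSizeError, ValidationError
from .image_io import DEFAULT_PIXEL_PITCH, read_interferogram_stack
from .phase_reconstruction import ChannelWeights, normalize_background, reconstruct_phase
from .stain_segmentation import apply_mask, filter_mask, hyperstain_flag, myelin_mask

FEATURE_COLUMNS = ("dry_mass", "mask_area", "stain_intensity")


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    alpha: float
    significant: bool
    variant: str


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    variant: str = "student",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided two-sample t-test between groups of per-slide/tile values."""
    xa = np.asarray(a, dtype=np.float64)
    xb = np.asarray(b, dtype=np.float64)
    if xa.size < 2 or xb.size < 2:
        raise SampleSizeError("each group needs at least 2 values")
    if xa.var(ddof=1) + xb.var(ddof=1) == 0 and xa.mean() == xb.mean():
        # identical constants in both groups: no test possible
        raise DegenerateDataError("zero pooled variance; t-test undefined")
    if variant not in ("student", "welch"):
        raise ValidationError("variant must be 'student' or 'welch'")
    res = stats.ttest_ind(xa, xb, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return GroupComparison(
        group_a=labels[0],
        group_b=labels[1],
        n_a=xa.size,
        n_b=xb.size,
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        t_stat=float(res.statistic),
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        variant=variant,
    )


def correlate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among dry_mass, mask_area and stain_intensity."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table lacks columns {missing}")
    sub = table.loc[:, list(FEATURE_COLUMNS)].dropna()
    if len(sub) < 3:
        raise SampleSizeError("need at least 3 complete rows")
    for c in FEATURE_COLUMNS:
        if sub[c].nunique() == 1:
            raise DegenerateDataError(f"column {c!r} is constant; correlation undefined")
    return sub.corr(method="pearson")


@dataclass
class SlideReport:
    """Everything `quantify_slide` computes for one slide."""

    tiles: pd.DataFrame
    fit: MixtureFit
    mass_high: MassSummary
    mass_low: MassSummary
    qc_flags: dict[str, bool] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


DEFAULT_CONFIG: dict = {
    "pixel_pitch": DEFAULT_PIXEL_PITCH,
    "weights": {"r": 0.1, "g": 0.6, "b": 0.3},
    "optics": {"wavelength_nm": 550.0, "eta_ml_per_g": 0.2},
    "normalize": {"enabled": True, "n_bins": 256},
    "mask": {
        "hue_min_deg": 170.0,
        "hue_max_deg": 280.0,
        "sat_min": None,
        "min_area_px": 50,
        "closing_radius_px": 1,
        "hyperstain_max_fraction": 0.9,
    },
    "classify": {"em_tol": 1e-8, "em_max_iter": 500, "seed": 0},
}


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a YAML file or dict over the pipeline defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if source is None:
        return cfg
    user = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _field_dirs(stack_dir: Path) -> list[Path]:
    dirs = sorted(d for d in stack_dir.iterdir() if d.is_dir() and (d / "frame_0.tif").exists())
    if dirs:
        return dirs
    if (stack_dir / "frame_0.tif").exists():
        return [stack_dir]
    raise ValidationError(f"{stack_dir}: no field directories with frame_0..3.tif found")


def quantify_slide(
    stack_dir: str | Path,
    config: str | Path | dict | None = None,
    out_dir: str | Path | None = None,
) -> SlideReport:
    """Run the full myelin-quantification pipeline over one slide directory.

    ``stack_dir`` holds one subdirectory per field, each with
    ``frame_0.tif`` … ``frame_3.tif`` (frame_0 = brightfield). Deterministic:
    identical inputs and config reproduce identical outputs.
    """
    cfg = load_config(config)
    stack_dir = Path(stack_dir)
    fields = _field_dirs(stack_dir)

    weights = ChannelWeights(**cfg["weights"])
    optics = OpticalConstants(**cfg["optics"])
    pitch = cfg["pixel_pitch"]
    mask_cfg = cfg["mask"]

    rows = []
    tile_maps = {}
    qc: dict[str, bool] = {}
    for fdir in fields:
        paths = [fdir / f"frame_{m}.tif" for m in range(4)]
        stack = read_interferogram_stack(paths, pixel_pitch=pitch, field_id=fdir.name)
        recon = reconstruct_phase(stack, weights)
        phase = recon.phase
        if cfg["normalize"]["enabled"]:
            phase = normalize_background(phase, n_bins=cfg["normalize"]["n_bins"])
        density = phase_to_density(phase, optics)

        raw_mask = myelin_mask(
            stack.brightfield,
            hue_window=(mask_cfg["hue_min_deg"], mask_cfg["hue_max_deg"]),
            sat_min=mask_cfg["sat_min"],
        )
        mask = filter_mask(
            raw_mask,
            min_area_px=mask_cfg["min_area_px"],
            closing_radius_px=mask_cfg["closing_radius_px"],
        )
        qc[f"{fdir.name}_hyperstained"] = hyperstain_flag(
            mask, mask_cfg["hyperstain_max_fraction"]
        )
        masked_density = apply_mask(density, mask)

        for quad, tile, masked_tile in zip(
            QUADRANTS, quarter_frames(density), quarter_frames(masked_density)
        ):
            rec = TileRecord(fdir.name, quad, tile_statistic(tile))
            rows.append(rec)
            tile_maps[(fdir.name, quad)] = masked_tile

    values = [r.mean_density for r in rows]
    fit = fit_two_gaussians(
        values,
        seed=cfg["classify"]["seed"],
        tol=cfg["classify"]["em_tol"],
        max_iter=cfg["classify"]["em_max_iter"],
    )
    labeled = classify_tiles(rows, fit)
    qc["non_bimodal_fit"] = not fit.bimodal

    summaries = {}
    for label in ("high", "low"):
        tiles = [tile_maps[(r.field_id, r.quadrant)] for r in labeled if r.label == label]
        if tiles:
            flat = np.concatenate([t.values.ravel() for t in tiles])
            px_area = (1.0 / pitch) ** 2
            total = float(flat.sum() * px_area)
            area = flat.size * px_area
            summaries[label] = MassSummary(total, area, total / area, flat.size)
        else:
            summaries[label] = MassSummary(0.0, 0.0, 0.0, 0)

    tiles_df = pd.DataFrame([asdict(r) for r in labeled])
    report = SlideReport(
        tiles=tiles_df,
        fit=fit,
        mass_high=summaries["high"],
        mass_low=summaries["low"],
        qc_flags=qc,
        params=cfg,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tiles_df.to_csv(out / "tiles.csv", index=False)
        (out / "slide_report.json").write_text(
            json.dumps(
                {
                    "mixture_fit": asdict(fit),
                    "mass_high": asdict(report.mass_high),
                    "mass_low": asdict(report.mass_low),
                    "qc_flags": qc,
                    "params": cfg,
                },
                indent=2,
            )
        )
    return report
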