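"""Per-eye quantification and cohort report orchestration.

`run_eye` turns one eye's radial B-scan set plus its two en face angiograms
into a single flat record: regional mean thicknesses for five layers
(C, TAZ, S, T, I, N regions) and regional capillary densities for both
capillary slabs (TAZ, C1..C6, S, T, I, N).  `run_cohort` consumes an
eye-level table and emits the comparison, correlation, and ROC report
bundle.  Cohort tools never read images: the eye record CSV is the
interface between the two stages.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__, angio, geometry, segmentation, stats
from .angio import Angiogram
from .config import PipelineConfig
from .segmentation import LAYER_DEFS, BScan

THICKNESS_LAYERS = ("NFL", "GCL+IPL", "GCC", "INL+ORL", "TOTAL")

#: Measures with the family-wise significance level applied.
FAMILY_MEASURE_PREFIXES = ("NFL", "GCLIPL", "GCC", "INLORL", "TOTAL",
                           "SRCL", "DRCL")


def _layer_key(layer: str) -> str:
    return layer.replace("+", "")


def quantify_thickness(
    bscans: Sequence[BScan],
    config: Optional[PipelineConfig] = None,
    laterality: str = "OD",
    grid_size: int = 256,
) -> Dict[str, float]:
    """Regional mean thickness (μm) for the five layers from a radial scan set.

    The B-scans must share their meridian angles evenly over 180° with the
    fovea at the lateral midpoint of every scan.  Lateral scales are
    corrected for ocular magnification before mapping.
    """
    config = config or PipelineConfig()
    seg = config.segmentation
    n_mer = len(bscans)
    angles = sorted(b.meridian_angle for b in bscans)
    bscans = sorted(bscans, key=lambda b: b.meridian_angle)

    profiles: Dict[str, List[np.ndarray]] = {layer: [] for layer in THICKNESS_LAYERS}
    spacings = []
    for b in bscans:
        bounds = segmentation.segment_boundaries(
            b, seg.polarities, seg.trace_order, seg.max_step,
            seg.min_gap, seg.smoothing_sigma,
        )
        factor = segmentation.magnification_correction(
            b.eye_axial_length, seg.reference_axial_length_mm
        )
        spacings.append(b.lateral_scale * factor / 1000.0)  # mm per sample
        for layer in THICKNESS_LAYERS:
            upper, lower = LAYER_DEFS[layer]
            profiles[layer].append(
                segmentation.layer_thickness(bounds, upper, lower, b.axial_scale)
            )
    spacing = float(np.mean(spacings))

    # analysis grid covering the 2.5 mm disk with margin
    extent_mm = 2.8
    grid = geometry.FoveaCenteredGrid.for_enface(grid_size, extent_mm, laterality)
    masks = {
        "C": geometry.make_central_mask(grid),
        "TAZ": geometry.make_taz_mask(grid),
    }
    masks.update(geometry.make_sector_masks(
        grid, temporal_side=config.geometry.temporal_side(laterality)))

    record: Dict[str, float] = {}
    for layer in THICKNESS_LAYERS:
        prof = np.stack(profiles[layer])
        tmap = segmentation.radial_to_map(prof, angles, spacing, grid, layer)
        means = segmentation.regional_mean_thickness(tmap, masks)
        for region, value in means.items():
            record[f"{_layer_key(layer)}_{region}"] = value
    return record


def quantify_angiogram(
    angiogram: Angiogram, config: Optional[PipelineConfig] = None
) -> Dict[str, float]:
    """Regional capillary densities (%) for one en face angiogram."""
    config = config or PipelineConfig()
    a = config.angio
    laterality = angiogram.laterality or "OD"
    profile, _ = angio.rcd_profile(
        angiogram,
        noise_k=a.noise_k,
        large_vessel_factor=a.large_vessel_factor,
        min_vessel_width_um=a.min_vessel_width_um,
        adaptive_window_mm=a.adaptive_window_mm,
        adaptive_offset=a.adaptive_offset,
        rcd_numerator=a.rcd_numerator,
        temporal_side=config.geometry.temporal_side(laterality),
        run_faz_detection=a.run_faz_detection,
    )
    return {f"{angiogram.layer}_{region}": v for region, v in profile.values.items()}


def run_eye(
    eye_id: str,
    bscans: Sequence[BScan],
    angiograms: Sequence[Angiogram],
    config: Optional[PipelineConfig] = None,
    laterality: str = "OD",
    strict: bool = False,
) -> Dict[str, object]:
    """Assemble one eye's full record from its scans.

    Angiograms failing the SSI gate (or any stage failure in permissive
    mode) leave their fields null and mark the record partial; in strict
    mode failures raise.
    """
    config = config or PipelineConfig()
    record: Dict[str, object] = {"eye_id": eye_id, "eye": laterality,
                                 "partial": False}
    try:
        record.update(quantify_thickness(bscans, config, laterality))
    except Exception as exc:
        if strict:
            raise
        warnings.warn(f"thickness stage failed for {eye_id}: {exc}")
        record["partial"] = True
    for a in angiograms:
        ok, reason = angio.quality_filter(a)
        if not ok:
            warnings.warn(f"{eye_id} {a.layer}: quality gate failed ({reason})")
            record["partial"] = True
            for region in geometry.RCD_REGION_NAMES:
                record[f"{a.layer}_{region}"] = None
            if strict:
                raise ValueError(f"quality gate failed for {eye_id} {a.layer}")
            continue
        try:
            record.update(quantify_angiogram(a, config))
        except Exception as exc:
            if strict:
                raise
            warnings.warn(f"angio stage failed for {eye_id} {a.layer}: {exc}")
            record["partial"] = True
            for region in geometry.RCD_REGION_NAMES:
                record[f"{a.layer}_{region}"] = None
    return record


def _comparison_table(
    records: pd.DataFrame, measures: Sequence[str], alpha: float
) -> pd.DataFrame:
    rows = []
    for m in measures:
        try:
            c = stats.group_compare(records, m, alpha)
        except ValueError as exc:
            warnings.warn(f"comparison for {m} skipped: {exc}")
            continue
        row = {"measure": m, "alpha": alpha}
        for g, (mean, sd, n) in c.group_stats.items():
            row[f"{g}_mean"] = round(mean, 3)
            row[f"{g}_sd"] = round(sd, 3)
            row[f"{g}_n"] = n
        for pair, p in c.pairwise_p.items():
            row[f"p_{pair}"] = round(p, 3)
            row[f"sig_{pair}"] = c.significant[pair]
        row["p_overall_robust"] = round(c.robust_overall_p, 3)
        row["p_anova"] = round(c.anova_p, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(
    records: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Path] = None,
    measures: Optional[Sequence[str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Cohort report bundle: comparisons, correlations, ROC tables, manifest.

    Floats in emitted CSVs are rounded half-even to 3 decimals.
    """
    config = config or PipelineConfig()
    required = {"patient_id", "eye", "group"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns: {sorted(missing)}")
    if records["group"].nunique() < 2:
        raise ValueError("need at least two groups")

    if measures is None:
        reserved = required | {"age", "sex", "IOP", "BCVA", "MD", "CAS",
                               "axial_length", "eye_id", "partial"}
        measures = [c for c in records.columns
                    if c not in reserved and pd.api.types.is_numeric_dtype(records[c])]
    thickness_measures = [m for m in measures
                          if m.split("_")[0] in ("NFL", "GCLIPL", "GCC",
                                                 "INLORL", "TOTAL")]
    rcd_measures = [m for m in measures if m.split("_")[0] in ("SRCL", "DRCL")]
    alpha = config.stats.alpha_family

    bundle: Dict[str, pd.DataFrame] = {}
    bundle["thickness_comparison"] = _comparison_table(
        records, thickness_measures, alpha)
    bundle["rcd_comparison"] = _comparison_table(records, rcd_measures, alpha)

    # GCC thickness vs superficial density in the pooled TAO groups
    tao = records["group"].isin(["nonDON", "DON"])
    corr_rows = []
    for region in ("TAZ", "S", "T", "I", "N"):
        a, b = f"GCC_{region}", f"SRCL_{region}"
        if a in records.columns and b in records.columns:
            try:
                r, p = stats.pearson(records, a, b, subset=tao)
                corr_rows.append({"x": a, "y": b, "r": round(r, 3),
                                  "p": round(p, 3), "n": int(tao.sum())})
            except ValueError as exc:
                warnings.warn(f"correlation {a}~{b} skipped: {exc}")
    bundle["correlations"] = pd.DataFrame(corr_rows)

    roc = stats.roc_report(
        records,
        positive_group=config.stats.positive_group,
        negative_group=config.stats.negative_group,
    )
    roc_out = roc.copy()
    for col in ("auc", "cutoff_a", "cutoff_b", "sensitivity_pct",
                "specificity_pct", "p_value"):
        roc_out[col] = roc_out[col].round(3)
    bundle["roc_single"] = roc_out[roc_out["kind"] == "single"].reset_index(drop=True)
    bundle["roc_composite"] = roc_out[roc_out["kind"] == "composite"].reset_index(drop=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.stats.seed,
            "n_records": int(len(records)),
            "groups": {g: int(n) for g, n in
                       records["group"].value_counts().items()},
            "macuquant_version": __version__,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
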