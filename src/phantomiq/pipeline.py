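"""Protocol orchestration: conditions -> measurements -> report tables.

A protocol binds named *conditions* (opaque labels — typically one per
reconstruction-algorithm x dose combination) to synthetic phantom
parameters or to directories of previously written images, runs every
enabled measurement on each condition, and writes:

* ``ct_number_table.csv`` — insert x condition, mean +- SD (HU);
* ``noise_table.csv`` — condition, mean SD (SE) in HU;
* ``ratio_table.csv`` — condition noise as integer percent of a reference;
* ``mtf_table.csv`` — condition, f50 (SE) and f10 (SE) in cycles/mm;
* ``detectability_table.csv`` — NPW-surrogate minimum detectable diameter;
* per-condition curve exports (NPS, normalized NPS, APC, MTF) as CSV;
* ``summary.md`` — a human-readable mirror of the tables;
* ``provenance.yaml`` — every default and parameter actually used.

Runs are deterministic for a given protocol seed: per-condition noise seeds
are derived from it, and rerunning the protocol reproduces byte-identical
CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import detectability as det
from . import mtf as mtf_mod
from . import noise as noise_mod
from . import roi as roi_mod
from .io import load_stack
from .phantom import (GridSpec, NoiseModel, PhantomSpec, catphan_presets,
                      generate_stack, LOW_CONTRAST_DIAMETERS_MM)
from .stack import ImageStack

__all__ = ["ConditionSpec", "ProtocolConfig", "StudyReport", "run_protocol",
           "load_stack", "PAPER_GAP_DEFAULTS"]

#: Defaults filled in where the measurement protocol leaves a choice open.
#: Logged into every report's provenance block.
PAPER_GAP_DEFAULTS = {
    "coordinate_convention": "physical mm, origin at image centre, x right / y up",
    "line_roi_interpolation": "bilinear",
    "ct_number_dispersion": "grand SD pooling all line-ROI samples",
    "nps_detrend": "per-ROI mean subtraction",
    "nps_estimator": "whole-ROI periodogram, one 256^2 realization per slice",
    "nps_radial_bin_width": "DFT frequency spacing 1/(roi_size*pixel_spacing)",
    "dose_ratio_rounding": "half-up to integer percent",
    "esf_bin_width": "0.1 pixel, empty bins linearly interpolated",
    "esf_binning": "bin means located at per-bin mean radius",
    "lsf_window": "Tukey taper over outer 25% of the record",
    "lsf_baseline": "mean of outer 10% tails subtracted",
    "mtf_readout": "first downward crossing, linear interpolation",
    "mtf_radius_refinement": "half-amplitude crossing of provisional ESF",
    "mtf_replicates": "independent replicate stacks of the same scene",
    "low_contrast_convention": "1.0% contrast = 10 HU (hu_per_percent=10)",
    "detectability_surrogate": "NPW matched filter, Rose threshold 5.0",
    "kappa_weighting": "unweighted",
    "noise_insertion": "post-blur (reconstruction noise)",
    "phantom_body": "circular, radius 150 mm, air (-1000 HU) outside",
    "antialiasing": "exact chord-overlap area fraction (sharp scenes)",
    "blur_rendering": "continuous-domain Gaussian x disk (Marcum-Q profile)",
}


@dataclass
class ConditionSpec:
    """One study condition: a label bound to phantom parameters or inputs.

    When ``inputs`` maps module names (``uniformity``, ``sensitometry``,
    ``low_contrast``) to stack paths, those stacks are loaded instead of
    being synthesized.
    """

    name: str
    sigma_hu: float = 0.0
    blur_sigma_mm: float = 0.0
    texture: str = "white"
    correlation_length_mm: Optional[float] = None
    n_slices: int = 50
    inputs: dict = dc_field(default_factory=dict)


@dataclass
class ProtocolConfig:
    """Declarative description of a full measurement protocol."""

    conditions: list
    output_dir: str = "phantomiq_out"
    seed: int = 0
    reference_condition: Optional[str] = None
    grid: GridSpec = dc_field(default_factory=GridSpec)
    analyses: dict = dc_field(default_factory=lambda: {
        "noise": True, "nps": True, "ct_number": True,
        "apc": True, "mtf": True, "detectability": True,
    })
    noise_roi_size: int = 256
    mtf_replicates: int = 1
    detectability_threshold: float = 5.0
    hu_per_percent: float = 10.0

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("condition names must be unique")
        if self.reference_condition is not None and \
                self.reference_condition not in names:
            raise ValueError(
                f"reference_condition {self.reference_condition!r} is not a condition")

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolConfig":
        d = yaml.safe_load(text)
        d["conditions"] = [ConditionSpec(**c) for c in d.get("conditions", [])]
        if "grid" in d:
            d["grid"] = GridSpec(**d["grid"])
        return cls(**d)


@dataclass
class StudyReport:
    """All tables and curve exports produced by one protocol run."""

    ct_number_table: Optional[pd.DataFrame]
    noise_table: Optional[pd.DataFrame]
    mtf_table: Optional[pd.DataFrame]
    ratio_table: Optional[pd.DataFrame]
    detectability_table: Optional[pd.DataFrame]
    curves: dict                 # logical name -> written CSV path
    provenance: dict
    records: list                # per-condition result/skip/error records


def _condition_seed(base_seed: int, index: int, module: str) -> int:
    code = {"uniformity": 1, "sensitometry": 2, "low_contrast": 3}[module]
    ss = np.random.SeedSequence([int(base_seed), int(index), code])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _condition_stack(cond: ConditionSpec, module: str, config: ProtocolConfig,
                     index: int, n_slices: Optional[int] = None):
    """Load or synthesize the stack for one (condition, module) pair."""
    if module in cond.inputs:
        return load_stack(cond.inputs[module]), None
    nm = NoiseModel(sigma_hu=cond.sigma_hu, texture=cond.texture,
                    correlation_length_mm=cond.correlation_length_mm,
                    seed=_condition_seed(config.seed, index, module))
    spec = catphan_presets(module, grid=config.grid, noise=nm,
                           blur_sigma_mm=cond.blur_sigma_mm,
                           n_slices=n_slices or cond.n_slices,
                           hu_per_percent=config.hu_per_percent)
    return generate_stack(spec), spec


def _fmt(mean, err, unit=""):
    if err is None:
        return f"{mean:.2f}"
    return f"{mean:.2f} ({err:.3f})"


def run_protocol(config: ProtocolConfig) -> StudyReport:
    """Run every enabled analysis for every condition and write the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list = []
    curves: dict = {}
    noise_rows, ct_rows, mtf_rows, det_rows = [], [], [], []
    noise_by_condition: dict = {}

    for idx, cond in enumerate(config.conditions):
        for analysis in ("noise", "nps", "ct_number", "apc", "mtf",
                         "detectability"):
            if not config.analyses.get(analysis, False):
                records.append({"condition": cond.name, "analysis": analysis,
                                "status": "skipped (disabled)"})
        try:
            _run_condition(cond, idx, config, out, records, curves,
                           noise_rows, ct_rows, mtf_rows, det_rows,
                           noise_by_condition)
        except Exception as exc:   # a failed condition must not abort others
            records.append({"condition": cond.name, "analysis": "condition",
                            "status": f"error: {exc}"})

    noise_table = pd.DataFrame(noise_rows) if noise_rows else None
    ct_table = pd.DataFrame(ct_rows) if ct_rows else None
    mtf_table = pd.DataFrame(mtf_rows) if mtf_rows else None
    det_table = pd.DataFrame(det_rows) if det_rows else None

    ratio_table = None
    ref = config.reference_condition
    if ref is not None and ref in noise_by_condition:
        ref_sd = noise_by_condition[ref]
        rows = []
        for name, sd in noise_by_condition.items():
            r = noise_mod.dose_ratio_percent(sd, ref_sd)
            rows.append({"condition": name, "percent_vs_reference": r.percent,
                         "noise_sd_hu": sd, "reference_sd_hu": ref_sd})
        ratio_table = pd.DataFrame(rows)

    provenance = {
        "seed": config.seed,
        "grid": {"matrix_size": config.grid.matrix_size,
                 "field_of_view_mm": config.grid.field_of_view,
                 "pixel_spacing_mm": config.grid.pixel_spacing,
                 "slice_thickness_mm": config.grid.slice_thickness},
        "noise_roi_size": config.noise_roi_size,
        "mtf_replicates": config.mtf_replicates,
        "detectability_threshold": config.detectability_threshold,
        "hu_per_percent": config.hu_per_percent,
        "defaults": dict(PAPER_GAP_DEFAULTS),
        "conditions": [{"name": c.name, "sigma_hu": c.sigma_hu,
                        "blur_sigma_mm": c.blur_sigma_mm,
                        "texture": c.texture, "n_slices": c.n_slices}
                       for c in config.conditions],
    }

    for name, table in (("noise_table", noise_table),
                        ("ct_number_table", ct_table),
                        ("mtf_table", mtf_table),
                        ("ratio_table", ratio_table),
                        ("detectability_table", det_table)):
        if table is not None:
            table.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance,
                                                        sort_keys=True))
    _write_summary(out, noise_table, ct_table, mtf_table, ratio_table,
                   det_table, records)
    return StudyReport(ct_number_table=ct_table, noise_table=noise_table,
                       mtf_table=mtf_table, ratio_table=ratio_table,
                       detectability_table=det_table, curves=curves,
                       provenance=provenance, records=records)


def _run_condition(cond, idx, config, out, records, curves,
                   noise_rows, ct_rows, mtf_rows, det_rows,
                   noise_by_condition) -> None:
    an = config.analyses
    noise_sd = None

    if an.get("noise", False) or an.get("nps", False) or \
            an.get("detectability", False):
        stack, _ = _condition_stack(cond, "uniformity", config, idx)
        if an.get("noise", False):
            nr = noise_mod.noise_magnitude(stack, config.noise_roi_size)
            noise_sd = nr.mean_sd_hu
            noise_by_condition[cond.name] = noise_sd
            noise_rows.append({"condition": cond.name,
                               "noise_sd_hu": nr.mean_sd_hu,
                               "se_hu": nr.se_hu,
                               "hu_se": _fmt(nr.mean_sd_hu, nr.se_hu)})
            records.append({"condition": cond.name, "analysis": "noise",
                            "status": "ok"})
        if an.get("nps", False):
            spec = noise_mod.compute_nps(stack, config.noise_roi_size)
            path = out / f"nps_{cond.name}.csv"
            pd.DataFrame({
                "frequency_cycles_per_mm": spec.frequencies,
                "nps_hu2_mm2": spec.nps,
                "normalized_nps": (spec.normalized_nps
                                   if spec.normalized_nps is not None
                                   else np.full_like(spec.nps, np.nan)),
            }).to_csv(path, index=False, float_format="%.6g")
            curves[f"nps_{cond.name}"] = str(path)
            records.append({"condition": cond.name, "analysis": "nps",
                            "status": "ok"})
        del stack

    if an.get("ct_number", False) or an.get("apc", False) or \
            an.get("mtf", False):
        stack, spec = _condition_stack(cond, "sensitometry", config, idx)
        inserts = {i.label: i for i in spec.inserts} if spec else {}
        if an.get("ct_number", False):
            for label in ("high", "moderate", "low"):
                ins = inserts.get(label)
                if ins is None:
                    continue
                res = roi_mod.measure_ct_number(stack, ins.center,
                                                insert_label=label)
                ct_rows.append({"condition": cond.name, "insert": label,
                                "nominal_hu": ins.contrast_hu,
                                "mean_hu": res.mean_hu, "sd_hu": res.sd_hu,
                                "mean_pm_sd": f"{res.mean_hu:.1f} ± {res.sd_hu:.1f}"})
            records.append({"condition": cond.name, "analysis": "ct_number",
                            "status": "ok"})
        if an.get("apc", False):
            for label in ("high", "moderate", "low"):
                ins = inserts.get(label)
                if ins is None:
                    continue
                apc = roi_mod.measure_apc(stack, ins.center)
                path = out / f"apc_{cond.name}_{label}.csv"
                pd.DataFrame({"position_mm": apc.positions,
                              "mean_hu": apc.mean_profile,
                              "sd_hu": apc.sd_profile}).to_csv(
                    path, index=False, float_format="%.6g")
                curves[f"apc_{cond.name}_{label}"] = str(path)
            records.append({"condition": cond.name, "analysis": "apc",
                            "status": "ok"})
        if an.get("mtf", False):
            ins = inserts.get("mtf")
            if ins is None:
                records.append({"condition": cond.name, "analysis": "mtf",
                                "status": "skipped (no MTF insert)"})
            else:
                stacks = [stack]
                for rep in range(1, config.mtf_replicates):
                    nm = NoiseModel(
                        sigma_hu=cond.sigma_hu, texture=cond.texture,
                        correlation_length_mm=cond.correlation_length_mm,
                        seed=_condition_seed(config.seed, idx,
                                             "sensitometry") + rep)
                    rep_spec = catphan_presets(
                        "sensitometry", grid=config.grid, noise=nm,
                        blur_sigma_mm=cond.blur_sigma_mm,
                        n_slices=cond.n_slices,
                        hu_per_percent=config.hu_per_percent)
                    stacks.append(generate_stack(rep_spec))
                res = mtf_mod.mtf_with_replicates(stacks, ins.center,
                                                  ins.radius)
                path = out / f"mtf_{cond.name}.csv"
                pd.DataFrame({"frequency_cycles_per_mm": res.frequencies,
                              "mtf": res.mtf}).to_csv(
                    path, index=False, float_format="%.6g")
                curves[f"mtf_{cond.name}"] = str(path)
                mtf_rows.append({"condition": cond.name,
                                 "f50_cycles_per_mm": res.f50,
                                 "f50_se": res.f50_se,
                                 "f10_cycles_per_mm": res.f10,
                                 "f10_se": res.f10_se,
                                 "f50_fmt": _fmt(res.f50, res.f50_se),
                                 "f10_fmt": _fmt(res.f10, res.f10_se)})
                records.append({"condition": cond.name, "analysis": "mtf",
                                "status": "ok"})
        del stack

    if an.get("detectability", False):
        sd = noise_sd if noise_sd is not None else cond.sigma_hu
        if sd <= 0:
            det_rows.append({"condition": cond.name,
                             "min_detectable_diameter_mm":
                                 min(LOW_CONTRAST_DIAMETERS_MM),
                             "noise_sd_hu": sd})
        else:
            est = det.min_detectable_diameter(
                LOW_CONTRAST_DIAMETERS_MM,
                contrast_hu=1.0 * config.hu_per_percent,
                noise_sd_hu=sd,
                pixel_spacing_mm=config.grid.pixel_spacing,
                threshold=config.detectability_threshold)
            det_rows.append({"condition": cond.name,
                             "min_detectable_diameter_mm":
                                 est.min_detectable_diameter,
                             "noise_sd_hu": sd})
        records.append({"condition": cond.name, "analysis": "detectability",
                        "status": "ok (NPW surrogate)"})


def _write_summary(out, noise_table, ct_table, mtf_table, ratio_table,
                   det_table, records) -> None:
    lines = ["# Phantom image-quality report", ""]

    def add(title, table, cols):
        lines.append(f"## {title}")
        lines.append("")
        if table is None:
            lines.append("(not computed)")
        else:
            lines.append("```\n" + table[cols].to_string(index=False) + "\n```")
        lines.append("")

    if ct_table is not None:
        add("CT number (mean ± SD, HU)", ct_table,
            ["condition", "insert", "nominal_hu", "mean_pm_sd"])
    if noise_table is not None:
        add("Image noise (HU (SE))", noise_table, ["condition", "hu_se"])
    if ratio_table is not None:
        add("Noise vs reference (%)", ratio_table,
            ["condition", "percent_vs_reference"])
    if mtf_table is not None:
        add("MTF readouts (cycles/mm (SE))", mtf_table,
            ["condition", "f50_fmt", "f10_fmt"])
    if det_table is not None:
        add("NPW-surrogate minimum detectable diameter (mm)", det_table,
            ["condition", "min_detectable_diameter_mm"])
    lines.append("## Run records")
    lines.append("")
    for r in records:
        lines.append(f"- {r['condition']} / {r['analysis']}: {r['status']}")
    lines.append("")
    (out / "summary.md").write_text("\n".join(lines))
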