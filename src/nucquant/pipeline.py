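"""Run configuration and the end-to-end pipeline driver.

``run_pipeline`` ties the stages together: simulate (scene sampling +
rendering, optionally tiled over several fields) -> deconvolve -> segment ->
measure -> statistics, with per-stage provenance (config hash, seeds, timings,
warnings). Populations larger than one field comfortably holds are split
across several independently rendered fields and the measurements pooled,
mirroring how cells from several microscope fields are pooled in practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from . import __version__
from .errors import ConfigurationError
from .optics import DeconvolutionSettings, PSFModel, deconvolve_mle
from .quant import (
    estimate_background,
    measure_nuclei,
    measurements_to_dataframe,
    segment_nuclei,
)
from .scene import DEFAULT_SPACING, NoiseModel, PRESETS, render_stack, sample_scene
from .stack import ImageStack
from .stats import (
    concentration_ratio,
    fit_constant_concentration,
    ploidy_peaks,
    spearman_bootstrap_ci,
    spearman_correlation,
)
from .tiffio import read_stack, write_stack

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

#: presets whose thin cultured-cell stacks need no depth bricks
_THIN_PRESET_BRICK = {
    "cycling_dapi": "one",
    "correlated_channels": "one",
    "constant_concentration": "one",
    "cortex": "more",
}


@dataclass
class SceneSection:
    preset: str = "constant_concentration"
    n_per_type: dict = dfield(default_factory=lambda: {"cell": 12})
    field_zyx_um: tuple | None = None
    background_level: float | None = None
    n_fields: int = 1
    preset_params: dict = dfield(default_factory=dict)


@dataclass
class OpticsSection:
    numerical_aperture: float = 1.30
    emission_wavelength_nm: float = 527.0
    refractive_index: float = 1.515
    depth_aberration: float = 0.01
    brick_mode: str | None = None  # None -> preset-appropriate default


@dataclass
class NoiseSection:
    photon_scale: float = 8000.0
    read_sigma: float = 2e-4
    offset: float = 1e-3


@dataclass
class DeconSection:
    snr: float = 10.0
    quality_change_threshold: float = 0.001
    max_iterations: int = 100


@dataclass
class SegSection:
    threshold: str | float = "auto"  # "auto" -> background mode + k_mad * MAD
    k_mad: float = 3.0
    min_volume_um3: float = 30.0
    merged_multiple: float = 2.5


@dataclass
class StatsSection:
    n_boot: int = 2000
    ploidy_n_boot: int = 500
    bandwidth: float | None = None
    prominence_frac: float = 0.05


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips losslessly via JSON."""

    spacing_zyx_um: tuple = DEFAULT_SPACING
    scene: SceneSection = dfield(default_factory=SceneSection)
    optics: OpticsSection = dfield(default_factory=OpticsSection)
    noise: NoiseSection = dfield(default_factory=NoiseSection)
    deconvolution: DeconSection = dfield(default_factory=DeconSection)
    segmentation: SegSection = dfield(default_factory=SegSection)
    stats: StatsSection = dfield(default_factory=StatsSection)
    seed: int = 0
    save_stacks: bool = False
    save_labels: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sections = {
            "scene": SceneSection,
            "optics": OpticsSection,
            "noise": NoiseSection,
            "deconvolution": DeconSection,
            "segmentation": SegSection,
            "stats": StatsSection,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                sub = dict(val)
                for tup in ("field_zyx_um",):
                    if tup in sub and sub[tup] is not None:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = sections[key](**sub)
            elif key == "spacing_zyx_um":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle returned by :func:`run_pipeline`."""

    measurements: list
    scenes: list
    stats: dict
    comparison: "object"  # pandas DataFrame or None
    provenance: dict
    n_kept: int


def _split_counts(n_per_type: Mapping[str, int], n_fields: int) -> list[dict]:
    """Largest-remainder split of each population across fields."""
    fields = [dict() for _ in range(n_fields)]
    for ctype, n in n_per_type.items():
        base, rem = divmod(int(n), n_fields)
        for i in range(n_fields):
            c = base + (1 if i < rem else 0)
            if c:
                fields[i][ctype] = c
    return [f for f in fields if f]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _analyze_stack(stack: ImageStack, config: RunConfig, psf: PSFModel):
    """Deconvolve, segment and measure one stack; returns (measurements, seg)."""
    bg = estimate_background(stack, 0, k=config.segmentation.k_mad)
    settings = DeconvolutionSettings(
        snr=config.deconvolution.snr,
        quality_change_threshold=config.deconvolution.quality_change_threshold,
        max_iterations=config.deconvolution.max_iterations,
        background_estimate=bg.mode,
    )
    decon = deconvolve_mle(stack, psf, settings)
    if config.segmentation.threshold == "auto":
        # the deconvolved stack is background-free, so the iso-surface level
        # "corresponding to the background/non-specific signal" is the raw
        # stack's noise scale above its mode: k * MAD of the raw image
        thr = config.segmentation.k_mad * bg.mad
    else:
        thr = float(config.segmentation.threshold)
    seg = segment_nuclei(
        decon,
        thr,
        config.segmentation.min_volume_um3,
        merged_multiple=config.segmentation.merged_multiple,
    )
    ms = measure_nuclei(decon, seg)
    return ms, seg, decon


def _match_truth(measurements, scene, max_dist_um=1.5):
    """Assign each measured nucleus its nearest truth record (within a gate)."""
    if not measurements:
        return []
    truth_pos = np.array([n.center for n in scene.nuclei])
    tree = cKDTree(truth_pos)
    rows = []
    for m in measurements:
        dist, idx = tree.query(m.centroid)
        nuc = scene.nuclei[int(idx)]
        matched = dist <= max_dist_um
        if matched:
            m.cell_type = nuc.cell_type
        rows.append(
            {
                "label": m.label,
                "field": m.field_index,
                "matched": bool(matched),
                "truth_id": int(nuc.id) if matched else -1,
                "cell_type": nuc.cell_type if matched else None,
                "centroid_dist_um": float(dist),
                "true_volume_um3": nuc.volume,
                "est_volume_um3": m.volume,
                "dna_content": nuc.dna_content,
                **{
                    f"true_total_{ch}": nuc.concentration.get(ch, 0.0) * nuc.volume
                    for ch in scene.channels
                },
                **{f"est_total_{ch}": m.total_signal[ch] for ch in scene.channels},
            }
        )
    return rows


def _preset_stats(preset, measurements, comparison, config):
    """Preset-appropriate statistics on the pooled measurements."""
    import pandas as pd

    stats: dict = {}
    if len(measurements) >= 5:
        channels = list(measurements[0].total_signal)
        fit = fit_constant_concentration(
            measurements, channels[0], n_boot=config.stats.n_boot, seed=config.seed
        )
        stats["constant_concentration_fit"] = {
            "channel": channels[0],
            "slope_au_per_um3": fit.slope,
            "slope_ci95": fit.slope_ci,
            "r2_through_origin": fit.r2_through_origin,
            "volume_concentration_spearman": fit.volume_concentration_spearman,
            "volume_concentration_spearman_ci95": fit.volume_concentration_spearman_ci,
            "n": fit.n,
        }
    if preset == "cortex":
        glia = [m for m in measurements if m.cell_type == "glia"]
        neuron = [m for m in measurements if m.cell_type == "neuron"]
        if len(glia) >= 3 and len(neuron) >= 3:
            r = concentration_ratio(
                glia, neuron, "yfp", n_boot=config.stats.n_boot, seed=config.seed
            )
            stats["glia_vs_neuron"] = {
                "percent_of_neuron": r.percent,
                "percent_ci95": r.percent_ci,
                "concentration_ratio": r.ratio,
                "fold_neuron_over_glia": r.inverse,
                "n_glia": r.n_a,
                "n_neuron": r.n_b,
            }
    elif preset == "cycling_dapi":
        totals = [m.total_signal["dna"] for m in measurements]
        if len(totals) >= 3:
            p = ploidy_peaks(
                totals,
                bandwidth=config.stats.bandwidth,
                prominence_frac=config.stats.prominence_frac,
                n_boot=config.stats.ploidy_n_boot,
                seed=config.seed,
            )
            stats["ploidy"] = {
                "peak_positions_normalized": p.peak_positions,
                "second_peak": p.second_peak,
                "peak_ratio_ci95": p.peak_ratio_ci,
                "bandwidth_au": p.bandwidth,
                "n": len(totals),
            }
    elif preset == "correlated_channels":
        x = [m.total_signal["mrna"] for m in measurements]
        y = [m.total_signal["factor"] for m in measurements]
        if len(x) >= 3:
            c = spearman_correlation(x, y, ("mrna", "factor"))
            ci = spearman_bootstrap_ci(x, y, n_boot=config.stats.n_boot, seed=config.seed)
            stats["channel_correlation"] = {
                "spearman_rho": c.rho,
                "rho_ci95": ci,
                "p_value": c.p_value,
                "method": c.method,
                "n": c.n,
            }
    return stats


def run_pipeline(
    config: RunConfig,
    mode: str = "simulate-and-analyze",
    out_dir: str | Path | None = None,
    stack_paths: list | None = None,
) -> PipelineResult:
    """Execute simulate -> deconvolve -> segment -> measure -> stats.

    ``mode="simulate-and-analyze"`` samples scenes per the config (tiled over
    ``scene.n_fields`` fields), renders and analyzes them, and adds a
    truth-vs-estimate comparison table. ``mode="analyze-only"`` reads
    previously written stacks from ``stack_paths``. With ``out_dir`` set, the
    bundle (measurements CSV, stats JSON, scene JSONs, provenance, optionally
    stacks/label maps) is written there.
    """
    import pandas as pd

    if mode not in ("simulate-and-analyze", "analyze-only"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    caught: list[str] = []
    sp = tuple(config.spacing_zyx_um)
    preset = config.scene.preset
    brick_mode = config.optics.brick_mode or _THIN_PRESET_BRICK.get(preset, "more")

    scenes, stacks = [], []
    if mode == "simulate-and-analyze":
        if preset not in PRESETS:
            raise ConfigurationError(f"unknown preset {preset!r}")
        splits = _split_counts(config.scene.n_per_type, max(1, config.scene.n_fields))
        ss = np.random.SeedSequence([int(config.seed), 11003])
        field_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * len(splits))]
        t = time.perf_counter()
        for i, counts in enumerate(splits):
            scene = sample_scene(
                preset,
                counts,
                field_seeds[2 * i],
                field_size=config.scene.field_zyx_um,
                background_level=config.scene.background_level,
                **config.scene.preset_params,
            )
            # rendered depth is the field depth rounded to whole z-planes
            depth = round(scene.field_size[0] / sp[0]) * sp[0]
            psf = PSFModel.theoretical(
                depth,
                spacing=sp,
                brick_mode=brick_mode,
                numerical_aperture=config.optics.numerical_aperture,
                emission_wavelength_nm=config.optics.emission_wavelength_nm,
                refractive_index=config.optics.refractive_index,
                depth_aberration=config.optics.depth_aberration,
            )
            stack = render_stack(
                scene,
                psf,
                NoiseModel(**dataclasses.asdict(config.noise)),
                sp,
                seed=field_seeds[2 * i + 1],
            )
            scenes.append(scene)
            stacks.append((stack, psf))
        timings["simulate"] = time.perf_counter() - t
    else:
        if not stack_paths:
            raise ConfigurationError("analyze-only mode needs stack_paths")
        for p in stack_paths:
            stack = read_stack(p, spacing=sp if sp else None)
            psf = PSFModel.theoretical(
                stack.depth_um,
                spacing=stack.spacing,
                brick_mode=brick_mode,
                numerical_aperture=config.optics.numerical_aperture,
                emission_wavelength_nm=config.optics.emission_wavelength_nm,
                refractive_index=config.optics.refractive_index,
                depth_aberration=config.optics.depth_aberration,
            )
            stacks.append((stack, psf))

    measurements = []
    comparisons = []
    segs = []
    t = time.perf_counter()
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for i, (stack, psf) in enumerate(stacks):
            ms, seg, _ = _analyze_stack(stack, config, psf)
            for m in ms:
                m.field_index = i
            segs.append(seg)
            if scenes:
                comparisons.extend(_match_truth(ms, scenes[i]))
            measurements.extend(ms)
    caught.extend(str(w.message) for w in wrec)
    timings["analyze"] = time.perf_counter() - t

    # pooled labels must stay unique across fields
    lab_off = 0
    for i, seg in enumerate(segs):
        for m in measurements:
            if m.field_index == i:
                m.label += lab_off
        for row in comparisons:
            if row["field"] == i:
                row["label"] += lab_off
        lab_off += seg.n_kept

    t = time.perf_counter()
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        stats = _preset_stats(preset if scenes else "", measurements, comparisons, config)
    caught.extend(str(w.message) for w in wrec)
    timings["stats"] = time.perf_counter() - t

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "mode": mode,
        "seed": int(config.seed),
        "n_fields": len(stacks),
        "n_raw": int(sum(s.n_raw for s in segs)),
        "n_kept": int(sum(s.n_kept for s in segs)),
        "rejected_counts": {
            reason: int(sum(1 for s in segs for _, r in s.rejected if r == reason))
            for reason in ("too_small", "truncated", "merged")
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.perf_counter() - t0, 3),
        "warnings": caught,
    }
    comparison_df = pd.DataFrame(comparisons) if comparisons else None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        measurements_to_dataframe(measurements).to_csv(out / "measurements.csv", index=False)
        (out / "stats.json").write_text(
            json.dumps(stats, indent=1, sort_keys=True, default=_json_default)
        )
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True, default=_json_default)
        )
        for i, scene in enumerate(scenes):
            scene.to_json(out / f"scene_{i}.json")
        if comparison_df is not None:
            comparison_df.to_csv(out / "comparison.csv", index=False)
        if config.save_stacks:
            for i, (stack, _) in enumerate(stacks):
                write_stack(stack, out / f"stack_{i}.tif")
        if config.save_labels:
            for i, seg in enumerate(segs):
                write_stack(
                    ImageStack(seg.label_map.astype(np.uint16), sp, ("labels",)),
                    out / f"labels_{i}.tif",
                )
    return PipelineResult(
        measurements=measurements,
        scenes=scenes,
        stats=stats,
        comparison=comparison_df,
        provenance=provenance,
        n_kept=provenance["n_kept"],
    )
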