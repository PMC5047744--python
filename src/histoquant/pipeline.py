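"""End-to-end pipeline driver: simulate -> quantify -> resolve -> stats -> report.

Each stage reads/writes the documented text formats under one output
directory, so stages can be re-run individually from files.  A manifest
(JSON) records the package version, seed, a hash of the configuration and
the SHA-256 of every written artifact, making runs reproducible and
comparable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import histone_model as hm
from . import io as hio
from .enrichment_stats import fold_change_table, pearson_matrix, variability_threshold
from .isomer_resolution import IsomerResolutionError, average_spectrum, resolve_isoforms
from .quantification import AbundanceTable, TIDY_COLUMNS, integrate_peak, relative_abundance, split_class
from .synthetic_data import SimConfig, default_config, simulate_run

log = logging.getLogger("histoquant")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "quantify_run", "resolve_run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Driver settings; everything has a usable default except the outdir."""

    outdir: Path
    seed: int = 0
    mz_tolerance_da: float = 0.4
    loq_fraction: float = 0.001
    variability_mode: str = "max_dev"
    integration_halfwidth_sigmas: float = 3.0
    comparisons: tuple[tuple[str, str], ...] = (("input", "BRD4short"), ("input", "B4N"))
    sim: SimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        sim_raw = raw.pop("sim", None)
        seed = int(raw.get("seed", 0))
        if sim_raw is not None:
            sim_raw.setdefault("seed", seed)
            sim = SimConfig(**sim_raw)
        comparisons = tuple(tuple(c) for c in raw.pop("comparisons", [])) or cls.comparisons
        return cls(
            outdir=Path(raw.pop("outdir", "results")),
            seed=seed,
            mz_tolerance_da=float(raw.pop("mz_tolerance_da", 0.4)),
            loq_fraction=float(raw.pop("loq_fraction", 0.001)),
            variability_mode=str(raw.pop("variability_mode", "max_dev")),
            integration_halfwidth_sigmas=float(raw.pop("integration_halfwidth_sigmas", 3.0)),
            comparisons=comparisons,
            sim=sim,
        )

    def to_dict(self) -> dict:
        d = dict(
            outdir=str(self.outdir),
            seed=self.seed,
            mz_tolerance_da=self.mz_tolerance_da,
            loq_fraction=self.loq_fraction,
            variability_mode=self.variability_mode,
            integration_halfwidth_sigmas=self.integration_halfwidth_sigmas,
            comparisons=[list(c) for c in self.comparisons],
        )
        if self.sim is not None:
            d["sim"] = {
                "seed": self.sim.seed,
                "backbones": list(self.sim.backbones),
                "replicate_cv": self.sim.replicate_cv,
                "ms2_noise_cv": self.sim.ms2_noise_cv,
                "n_replicates": dict(self.sim.n_replicates),
            }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sample_ids(sim: SimConfig) -> list[tuple[str, str, int]]:
    return [
        (f"{cond}_r{rep}", cond, rep)
        for cond in sim.conditions
        for rep in range(1, sim.n_replicates[cond] + 1)
    ]


def simulate_stage(config: PipelineConfig) -> list[Path]:
    """Write one synthetic LC-MS run (XIC + MS2 TSVs) per sample."""
    sim = config.sim or default_config(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)
    sigma = np.sqrt(np.log1p(sim.replicate_cv**2))
    written = []
    truths = {}
    for sample, cond, _rep in _sample_ids(sim):
        means = sim.condition_means(cond)
        draw = {}
        for fam, vec in means.items():
            ids = list(vec)
            vals = np.array([vec[u] for u in ids])
            if sigma > 0:
                vals = vals * rng.lognormal(-0.5 * sigma**2, sigma, size=vals.shape)
            if vals.sum() > 0:
                vals = vals / vals.sum()
            draw[fam] = dict(zip(ids, vals.astype(float)))
        traces, spectra, truth = simulate_run(sim, condition=cond, abundance_override=draw, rng=rng)
        hio.write_xic_tsv(outdir / f"xic_{sample}.tsv", traces)
        hio.write_ms2_tsv(outdir / f"ms2_{sample}.tsv", spectra)
        written += [outdir / f"xic_{sample}.tsv", outdir / f"ms2_{sample}.tsv"]
        truths[sample] = {
            "condition": cond,
            "abundances": truth.abundances,
            "theta": truth.theta,
        }
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(truths, indent=1, sort_keys=True))
    written.append(gt_path)
    return written


def quantify_run(
    traces: list,
    config: PipelineConfig,
    sim: SimConfig,
) -> tuple[dict[str, dict[str, float]], dict[str, bool], dict[str, tuple[float, float]]]:
    """Integrate each trace and normalize areas within backbone families.

    Returns (per-family fractions over units, below-limit flags, RT windows
    used per unit).
    """
    reg = hm.default_registry()
    fam_areas: dict[str, dict[str, float]] = {}
    windows: dict[str, tuple[float, float]] = {}
    for trace in traces:
        peak_rt = float(trace.rt_min[np.argmax(trace.intensity)])
        half = config.integration_halfwidth_sigmas * sim.peak_sigma_min
        window = (peak_rt - half, peak_rt + half)
        area, _baseline = integrate_peak(trace, window)
        windows[trace.trace_id] = window
        backbone_id = trace.trace_id.split(":", 1)[0]
        fam = reg[backbone_id].family
        fam_areas.setdefault(fam, {})[trace.trace_id] = area
    fractions: dict[str, dict[str, float]] = {}
    flags: dict[str, bool] = {}
    for fam, areas in fam_areas.items():
        frac, low, _dead = relative_abundance(areas, fam, loq_fraction=config.loq_fraction)
        fractions[fam] = frac
        flags.update(low)
    return fractions, flags, windows


def resolve_run(
    fractions: dict[str, dict[str, float]],
    spectra: list,
    traces: list,
    config: PipelineConfig,
) -> tuple[dict[str, dict[str, float]], dict[str, dict]]:
    """Split isobaric-class fractions into per-isomer fractions via MS/MS.

    Classes whose averaged spectrum carries no discriminating signal keep
    their class-level entry and are reported unresolved.
    """
    reg = hm.default_registry()
    trace_by_id = {t.trace_id: t for t in traces}
    by_class: dict[str, list] = {}
    for s in spectra:
        by_class.setdefault(s.precursor_id, []).append(s)
    estimates: dict[str, dict] = {}
    out = {fam: dict(units) for fam, units in fractions.items()}
    for class_id, cls_spectra in by_class.items():
        backbone_id = class_id.split(":", 1)[0]
        backbone = reg[backbone_id]
        forms = {f.id: f for f in hm.enumerate_forms(backbone)}
        classes = hm.group_isobaric(forms.values())
        if class_id not in classes or len(classes[class_id]) < 2:
            continue
        isoforms = classes[class_id]
        trace = trace_by_id.get(class_id)
        weights = [trace.intensity_at(s.rt_min) for s in cls_spectra] if trace else None
        avg = average_spectrum(cls_spectra, weights=weights, mz_tolerance=config.mz_tolerance_da)
        try:
            est = resolve_isoforms(avg, isoforms, tolerance=config.mz_tolerance_da)
        except IsomerResolutionError as e:
            estimates[class_id] = {"error": str(e)}
            continue
        estimates[class_id] = {
            "isoform_ids": list(est.isoform_ids),
            "theta": [float(t) for t in est.theta],
            "residual": est.residual,
            "n_ions_used": est.n_ions_used,
            "defined": est.defined,
        }
        if not est.defined:
            continue
        fam = backbone.family
        class_fraction = out[fam].pop(class_id, 0.0)
        split = split_class(class_fraction, est.theta, est.isoform_ids)
        out[fam].update(split)
    return out, estimates


def quantify_stage(config: PipelineConfig) -> Path:
    """Quantify + resolve every simulated run into one tidy abundance table."""
    sim = config.sim or default_config(config.seed)
    outdir = Path(config.outdir)
    rows = []
    estimates_all = {}
    for sample, cond, rep in _sample_ids(sim):
        xic_path = outdir / f"xic_{sample}.tsv"
        ms2_path = outdir / f"ms2_{sample}.tsv"
        if not xic_path.exists():
            raise PipelineError(f"quantify: missing XIC input {xic_path}")
        traces = hio.read_xic_tsv(xic_path)
        spectra = hio.read_ms2_tsv(ms2_path) if ms2_path.exists() else []
        fractions, flags, _windows = quantify_run(traces, config, sim)
        fractions, estimates = resolve_run(fractions, spectra, traces, config)
        estimates_all[sample] = estimates
        for fam, units in fractions.items():
            for uid, frac in units.items():
                rows.append((sample, cond, rep, fam, uid, frac, flags.get(uid, False)))
    table = AbundanceTable(pd.DataFrame(rows, columns=TIDY_COLUMNS))
    table.validate(atol=1e-6)
    out = outdir / "abundance.csv"
    hio.write_abundance_csv(out, table)
    (outdir / "isoform_estimates.json").write_text(json.dumps(estimates_all, indent=1, sort_keys=True))
    return out


def stats_stage(config: PipelineConfig) -> list[Path]:
    outdir = Path(config.outdir)
    table = hio.read_abundance_csv(outdir / "abundance.csv")
    thr = variability_threshold(table, mode=config.variability_mode)
    comparisons = [c for c in config.comparisons if
                   set(c) <= set(table.data["condition"])]
    enr = fold_change_table(table, comparisons, threshold=thr.threshold, qvalues=True)
    corr = pearson_matrix(table)
    hio.write_enrichment_csv(outdir / "enrichment.csv", enr)
    hio.write_correlations_csv(outdir / "correlations.csv", corr)
    (outdir / "threshold.json").write_text(
        json.dumps(
            {
                "threshold": thr.threshold,
                "spread": None if not np.isfinite(thr.spread) else thr.spread,
                "mode": thr.mode,
                "fallback": thr.fallback,
                "per_sample_ratio": thr.per_sample_ratio,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [outdir / "enrichment.csv", outdir / "correlations.csv", outdir / "threshold.json"]


def report_stage(config: PipelineConfig, plots: bool = False) -> Path:
    outdir = Path(config.outdir)
    artifacts = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    if plots:
        from . import plots as _plots

        table = hio.read_abundance_csv(outdir / "abundance.csv")
        _plots.abundance_barplots(table, outdir / "figures")
        _plots.scatter_matrix(table, outdir / "figures" / "pattern_correlation.png")
        artifacts = sorted(
            p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "histoquant",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


STAGES = ("simulate", "quantify", "stats", "report")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES, plots: bool = False) -> Path:
    """Run the requested stages in order; returns the manifest path.

    Any stage failure is re-raised as PipelineError naming the stage.
    """
    log.info("pipeline start: seed=%s outdir=%s config=%s", config.seed, config.outdir, config.to_dict())
    for stage in stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}; valid: {STAGES}")
        try:
            log.info("stage %s: start", stage)
            if stage == "simulate":
                simulate_stage(config)
            elif stage == "quantify":
                quantify_stage(config)
            elif stage == "stats":
                stats_stage(config)
            elif stage == "report":
                report_stage(config, plots=plots)
            log.info("stage %s: done", stage)
        except PipelineError:
            raise
        except Exception as e:
            log.error("stage %s: failed: %s", stage, e)
            raise PipelineError(f"{stage}: {e}") from e
    return Path(config.outdir) / "manifest.json"
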