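"""Synthetic LC-MS surrogate data with known ground truth.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without raw instrument files:

* Gaussian chromatographic elution peaks, one XIC per peptide form — except
  isobaric positional isomers, which share a single trace (identical
  precursor mass and, in the worst case modeled here, identical elution).
* MS2 spectra sampled on a fixed grid across each peak whose fragment
  intensities are theta-weighted mixtures of the isomer fragment ladders,
  with multiplicative log-normal noise and an additive intensity floor.
* Replicate relative-abundance tables: per-family simplex vectors with
  log-normal technical variation (default 20% CV, matching the observed
  spread of the H2A T16/S16 recovery control) and per-form fold-change
  effects for pulldown conditions relative to input.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import histone_model as hm
from .quantification import AbundanceTable, TIDY_COLUMNS
from .signals import Ms2Spectrum, XicTrace

__all__ = [
    "SimConfig",
    "SimUnit",
    "GroundTruth",
    "default_config",
    "simulate_run",
    "simulate_replicates",
]


class ConfigError(ValueError):
    """Invalid simulation configuration (e.g. a broken simplex)."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    ``true_abundances`` maps family -> unit id -> fraction for the *input*
    (genomic) condition; units are full form ids (``"H3_18-26:K18ac"``) or,
    for the modification-free H2A variant pair, backbone ids.  Forms not
    listed are truly absent (zero).  ``effect_sizes`` maps pulldown condition
    -> unit id -> fold change applied to the input mean before per-family
    renormalization.  ``n_replicates`` maps every condition (input included)
    to its replicate count.
    """

    seed: int
    backbones: tuple[str, ...]
    true_abundances: dict[str, dict[str, float]]
    n_replicates: dict[str, int]
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    input_condition: str = "input"
    replicate_cv: float = 0.20
    ms2_noise_cv: float = 0.0
    ms2_noise_floor: float = 0.0
    n_ms2_per_peak: int = 7
    peak_sigma_min: float = 0.10
    peak_spacing_min: float = 2.0
    rt_start_min: float = 10.0
    base_height: float = 1.0e6

    @property
    def conditions(self) -> list[str]:
        return list(self.n_replicates)

    def validate(self) -> None:
        reg = hm.default_registry()
        families = {reg[b].family for b in self.backbones}
        if set(self.true_abundances) != families:
            raise ConfigError(
                f"true_abundances families {sorted(self.true_abundances)} != "
                f"backbone families {sorted(families)}"
            )
        for fam, vec in self.true_abundances.items():
            vals = np.array(list(vec.values()), dtype=float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"family {fam}: abundances must be a simplex, got sum {vals.sum()}")
        if self.input_condition not in self.n_replicates:
            raise ConfigError(f"input condition {self.input_condition!r} missing from n_replicates")
        for cond in self.effect_sizes:
            if cond not in self.n_replicates:
                raise ConfigError(f"effect condition {cond!r} missing from n_replicates")
        if self.replicate_cv < 0 or self.ms2_noise_cv < 0 or self.ms2_noise_floor < 0:
            raise ConfigError("CVs and noise floor must be >= 0")

    def condition_means(self, condition: str) -> dict[str, dict[str, float]]:
        """Per-family simplex of expected abundances for one condition."""
        if condition == self.input_condition:
            return {f: dict(v) for f, v in self.true_abundances.items()}
        effects = self.effect_sizes.get(condition, {})
        out = {}
        for fam, vec in self.true_abundances.items():
            scaled = {u: frac * effects.get(u, 1.0) for u, frac in vec.items()}
            total = sum(scaled.values())
            if total <= 0:
                raise ConfigError(f"family {fam}: condition {condition} has zero total")
            out[fam] = {u: v / total for u, v in scaled.items()}
        return out


@dataclass
class SimUnit:
    """One chromatographic quantification unit (form or isobaric class)."""

    unit_id: str
    family: str
    member_ids: tuple[str, ...]  # >1 for co-eluting isobaric isomers
    rt_center_min: float
    sigma_min: float
    height: float

    @property
    def area(self) -> float:
        return self.height * self.sigma_min * np.sqrt(2.0 * np.pi)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated run."""

    condition: str
    abundances: dict[str, dict[str, float]]  # family -> form/unit id -> fraction
    theta: dict[str, dict[str, float]]  # class id -> isoform id -> mixing fraction
    units: list[SimUnit]


def _layout_units(config: SimConfig, condition: str) -> tuple[list[SimUnit], dict, dict]:
    """Deterministic chromatographic layout: one unit per form/class."""
    reg = hm.default_registry()
    means = config.condition_means(condition)
    units: list[SimUnit] = []
    theta: dict[str, dict[str, float]] = {}
    abundances: dict[str, dict[str, float]] = {}
    idx = 0
    for bid in config.backbones:
        backbone = reg[bid]
        fam = backbone.family
        fam_means = means[fam]
        abundances.setdefault(fam, {}).update(fam_means)
        if not backbone.mod_sites:
            frac = fam_means.get(bid, 0.0)
            rt = config.rt_start_min + idx * config.peak_spacing_min
            units.append(SimUnit(bid, fam, (bid,), rt, config.peak_sigma_min, frac * config.base_height))
            idx += 1
            continue
        forms = hm.enumerate_forms(backbone)
        for class_id, members in hm.group_isobaric(forms).items():
            member_ids = tuple(f.id for f in members)
            fracs = np.array([fam_means.get(fid, 0.0) for fid in member_ids])
            total = float(fracs.sum())
            rt = config.rt_start_min + idx * config.peak_spacing_min
            unit_id = class_id if len(members) > 1 else member_ids[0]
            units.append(
                SimUnit(unit_id, fam, member_ids, rt, config.peak_sigma_min, total * config.base_height)
            )
            idx += 1
            if len(members) > 1:
                if total > 0:
                    theta[class_id] = {fid: float(v / total) for fid, v in zip(member_ids, fracs)}
                else:
                    theta[class_id] = {fid: float("nan") for fid in member_ids}
    return units, theta, abundances


def simulate_run(
    config: SimConfig,
    condition: str | None = None,
    abundance_override: Mapping[str, Mapping[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[XicTrace], list[Ms2Spectrum], GroundTruth]:
    """Simulate one LC-MS run: XIC per unit plus MS2 across multi-isomer peaks.

    ``abundance_override`` substitutes the per-family abundance simplex (e.g.
    a replicate-level draw) while keeping the condition label.  Identical
    seeds give identical output.
    """
    config.validate()
    condition = condition or config.input_condition
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config
    if abundance_override is not None:
        cfg = replace(config, true_abundances={f: dict(v) for f, v in abundance_override.items()})
        cfg.validate()
        units, theta, abundances = _layout_units(cfg, cfg.input_condition)
    else:
        units, theta, abundances = _layout_units(cfg, condition)

    reg = hm.default_registry()
    traces: list[XicTrace] = []
    spectra: list[Ms2Spectrum] = []
    for unit in units:
        grid = unit.rt_center_min + np.linspace(-5, 5, 101) * unit.sigma_min
        intensity = unit.height * np.exp(-0.5 * ((grid - unit.rt_center_min) / unit.sigma_min) ** 2)
        traces.append(XicTrace(unit.unit_id, grid, intensity))
        if len(unit.member_ids) < 2 or unit.height <= 0:
            continue
        backbone_id = unit.member_ids[0].split(":", 1)[0]
        forms = {f.id: f for f in hm.enumerate_forms(reg[backbone_id])}
        isoforms = [forms[fid] for fid in unit.member_ids]
        clusters = hm.ion_partition(isoforms)
        th = np.array([theta[unit.unit_id][fid] for fid in unit.member_ids])
        ms2_rts = unit.rt_center_min + np.linspace(-2, 2, config.n_ms2_per_peak) * unit.sigma_min
        for rt in ms2_rts:
            precursor = unit.height * np.exp(-0.5 * ((rt - unit.rt_center_min) / unit.sigma_min) ** 2)
            mz = np.array([c.mz for c in clusters])
            base = precursor * np.array([float(np.dot(c.produced_by, th)) for c in clusters])
            if config.ms2_noise_cv > 0:
                sigma = np.sqrt(np.log1p(config.ms2_noise_cv**2))
                base = base * rng.lognormal(-0.5 * sigma**2, sigma, size=base.shape)
            if config.ms2_noise_floor > 0:
                base = base + rng.uniform(0, config.ms2_noise_floor, size=base.shape)
            keep = base > 0
            spectra.append(Ms2Spectrum(unit.unit_id, float(rt), mz[keep], base[keep]))
    return traces, spectra, GroundTruth(condition, abundances, theta, units)


def simulate_replicates(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, dict]:
    """Replicate relative-abundance tables for every configured condition.

    Per replicate and family, each unit's expected fraction (input mean times
    the condition's effect size, renormalized) is perturbed by mean-one
    log-normal noise with CV ``replicate_cv`` and the family is renormalized
    back onto the simplex.
    """
    config.validate()
    for cond, n in config.n_replicates.items():
        if n < 2:
            raise ConfigError(f"condition {cond!r}: need >= 2 replicates, got {n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.replicate_cv**2))
    rows = []
    truth = {"condition_means": {}, "replicate_cv": config.replicate_cv}
    for cond in config.conditions:
        means = config.condition_means(cond)
        truth["condition_means"][cond] = means
        for rep in range(1, config.n_replicates[cond] + 1):
            sample = f"{cond}_r{rep}"
            for fam, vec in means.items():
                ids = list(vec)
                vals = np.array([vec[u] for u in ids], dtype=float)
                if sigma > 0:
                    vals = vals * rng.lognormal(-0.5 * sigma**2, sigma, size=vals.shape)
                total = vals.sum()
                if total > 0:
                    vals = vals / total
                for uid, frac in zip(ids, vals):
                    rows.append((sample, cond, rep, fam, uid, float(frac), False))
    table = AbundanceTable(pd.DataFrame(rows, columns=TIDY_COLUMNS))
    table.validate()
    return table, truth


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default synthetic study: genomic input (n=4), a bromodomain
    pulldown (n=4) with acetylation-directed enrichment, and a fusion-protein
    pulldown (n=2) with stronger combinatorial enrichment.

    Input abundances are plausible steady-state histone PTM distributions for
    a human cell line (e.g. K23ac dominating H3 18-26 mono-acetylation at
    ~30% of the family); pulldown effect sizes echo the enrichment directions
    the assay is designed to detect (multi-fold gains in di/tri/tetra-
    acetylation and in K27/K36 combinatorial marks).
    """
    true_abundances = {
        "H3_18-26": {
            "H3_18-26:unmod": 0.55,
            "H3_18-26:K18ac": 0.05,
            "H3_18-26:K23ac": 0.30,
            "H3_18-26:K18acK23ac": 0.10,
        },
        "H3_9-17": {
            "H3_9-17:unmod": 0.70,
            "H3_9-17:K9ac": 0.05,
            "H3_9-17:K14ac": 0.15,
            "H3_9-17:K9acK14ac": 0.10,
        },
        "H3_73-83": {
            "H3_73-83:unmod": 0.45,
            "H3_73-83:K79me1": 0.35,
            "H3_73-83:K79me2": 0.15,
            "H3_73-83:K79me3": 0.05,
        },
        "H3.3_27-40": {
            "H3.3_27-40:unmod": 0.10,
            "H3.3_27-40:K27me1": 0.08,
            "H3.3_27-40:K27me2": 0.15,
            "H3.3_27-40:K27me3": 0.12,
            "H3.3_27-40:K27ac": 0.05,
            "H3.3_27-40:K36me1": 0.05,
            "H3.3_27-40:K36me2": 0.10,
            "H3.3_27-40:K36me3": 0.05,
            "H3.3_27-40:K27me1K36me1": 0.05,
            "H3.3_27-40:K27me1K36me2": 0.10,
            "H3.3_27-40:K27me1K36me3": 0.05,
            "H3.3_27-40:K27me2K36me1": 0.03,
            "H3.3_27-40:K27me3K36me1": 0.02,
            "H3.3_27-40:K27acK36me1": 0.01,
            "H3.3_27-40:K27acK36me2": 0.02,
            "H3.3_27-40:K27acK36me3": 0.02,
        },
        "H4_4-17": {
            "H4_4-17:unmod": 0.50,
            "H4_4-17:K16ac": 0.15,
            "H4_4-17:K12ac": 0.05,
            "H4_4-17:K8ac": 0.03,
            "H4_4-17:K5ac": 0.02,
            "H4_4-17:K12acK16ac": 0.08,
            "H4_4-17:K8acK16ac": 0.04,
            "H4_4-17:K5acK8ac": 0.03,
            "H4_4-17:K5acK8acK12ac": 0.02,
            "H4_4-17:K5acK8acK16ac": 0.02,
            "H4_4-17:K5acK12acK16ac": 0.02,
            "H4_4-17:K8acK12acK16ac": 0.02,
            "H4_4-17:K5acK8acK12acK16ac": 0.02,
        },
        "H2A_12-17": {
            "H2A_12-17_T": 0.5,
            "H2A_12-17_S": 0.5,
        },
    }
    effect_sizes = {
        "BRD4short": {
            "H3_18-26:K18acK23ac": 5.0,
            "H3_9-17:K9acK14ac": 4.0,
            "H3_73-83:K79me1": 2.0,
            "H4_4-17:K5acK8acK12ac": 6.0,
            "H4_4-17:K5acK8acK16ac": 6.0,
            "H4_4-17:K5acK12acK16ac": 6.0,
            "H4_4-17:K8acK12acK16ac": 6.0,
            "H4_4-17:K5acK8acK12acK16ac": 6.0,
        },
        "B4N": {
            "H3_18-26:K18acK23ac": 15.0,
            "H3_9-17:K9acK14ac": 8.0,
            "H3_73-83:K79me1": 3.0,
            "H4_4-17:K5acK8acK12ac": 12.0,
            "H4_4-17:K5acK8acK16ac": 12.0,
            "H4_4-17:K5acK12acK16ac": 6.0,
            "H4_4-17:K8acK12acK16ac": 6.0,
            "H4_4-17:K5acK8acK12acK16ac": 10.0,
            "H3.3_27-40:K27acK36me1": 8.0,
            "H3.3_27-40:K27acK36me2": 4.0,
            "H3.3_27-40:K27me1K36me2": 4.0,
            "H3.3_27-40:K27me1K36me3": 4.0,
        },
    }
    cfg = dict(
        seed=seed,
        backbones=(
            "H3_18-26",
            "H3_9-17",
            "H3_73-83",
            "H3.3_27-40",
            "H4_4-17",
            "H2A_12-17_T",
            "H2A_12-17_S",
        ),
        true_abundances=true_abundances,
        n_replicates={"input": 4, "BRD4short": 4, "B4N": 2},
        effect_sizes=effect_sizes,
    )
    cfg.update(overrides)
    config = SimConfig(**cfg)
    config.validate()
    return config
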