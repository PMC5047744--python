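"""Peak integration and within-family relative abundances.

The core quantification scheme: integrate each form's chromatographic peak
and normalize the area against all modified and unmodified forms of the same
peptide backbone, yielding a per-sample simplex over each backbone family.
Relative abundances are therefore compositional — a form's value is a
fraction of its family, not an absolute amount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import histone_model as hm
from .signals import XicTrace

__all__ = [
    "AbundanceTable",
    "integrate_peak",
    "relative_abundance",
    "split_class",
    "family_unit_ids",
]

#: area below this fraction of the family total is below the limit of
#: quantification (the concept is standard; the value is a package default).
DEFAULT_LOQ_FRACTION = 0.001

TIDY_COLUMNS = ["sample", "condition", "replicate", "backbone", "form", "fraction", "below_limit"]


@dataclass
class AbundanceTable:
    """Tidy sample x peptide-form relative-abundance table.

    Columns: sample, condition, replicate, backbone (family id), form,
    fraction, below_limit.  Within each (sample, family) group the fractions
    sum to 1 unless the whole group is below the limit of quantification.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TIDY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"abundance table missing columns {missing}")
        self.data = self.data[TIDY_COLUMNS].reset_index(drop=True)

    def validate(self, atol: float = 1e-6) -> None:
        if (self.data["fraction"] < -atol).any():
            raise ValueError("negative fractions")
        sums = self.data.groupby(["sample", "backbone"])["fraction"].sum()
        dead = self.data.groupby(["sample", "backbone"])["below_limit"].all()
        bad = sums[(~dead) & (np.abs(sums - 1.0) > atol)]
        if len(bad):
            raise ValueError(f"family groups not on the simplex: {bad.to_dict()}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def wide(self) -> pd.DataFrame:
        """Samples x forms matrix of fractions (below-limit cells -> NaN)."""
        d = self.data.copy()
        d.loc[d["below_limit"], "fraction"] = np.nan
        return d.pivot_table(index="sample", columns="form", values="fraction", dropna=False)

    def condition_of(self, sample: str) -> str:
        row = self.data[self.data["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return str(row["condition"].iloc[0])

    def group_values(self, condition: str, form: str) -> np.ndarray:
        """Per-replicate fractions of one form in one condition."""
        d = self.data
        sel = d[(d["condition"] == condition) & (d["form"] == form)]
        return sel["fraction"].to_numpy(dtype=float)

    def concat(self, other: "AbundanceTable") -> "AbundanceTable":
        return AbundanceTable(pd.concat([self.data, other.data], ignore_index=True))


def integrate_peak(
    trace: XicTrace,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Trapezoidal peak area over an RT window after flat-baseline subtraction.

    The baseline is the median intensity *outside* the window (0 if the whole
    trace lies inside), floored at zero; the baseline-subtracted signal is
    clipped at zero before integration so the area is non-negative.

    Returns ``(area, baseline)`` so callers can apply signal-to-baseline QC.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"empty or inverted window {window}")
    inside = (trace.rt_min >= lo) & (trace.rt_min <= hi)
    if inside.sum() < 2:
        raise ValueError(f"window {window} covers fewer than 2 trace points")
    outside = ~inside
    baseline = float(np.median(trace.intensity[outside])) if outside.any() else 0.0
    baseline = max(baseline, 0.0)
    y = np.clip(trace.intensity[inside] - baseline, 0.0, None)
    area = float(np.trapezoid(y, trace.rt_min[inside]))
    return max(area, 0.0), baseline


def family_unit_ids(
    family: str,
    registry: Mapping[str, hm.BackbonePeptide] | None = None,
) -> set[str]:
    """Valid quantification-unit ids of a family: form ids and isobaric-class ids."""
    reg = hm.default_registry() if registry is None else registry
    backbones = [b for b in reg.values() if b.family == family]
    if not backbones:
        raise hm.RegistryError(f"unknown family {family!r}")
    ids: set[str] = set()
    for b in backbones:
        forms = hm.enumerate_forms(b)
        ids.update(f.id for f in forms)
        ids.update(hm.group_isobaric(forms))
        if not b.mod_sites:
            ids.add(b.id)  # a modification-free backbone is its own unit
    return ids


def relative_abundance(
    areas: Mapping[str, float],
    family: str,
    registry: Mapping[str, hm.BackbonePeptide] | None = None,
    loq_fraction: float = DEFAULT_LOQ_FRACTION,
) -> tuple[dict[str, float], dict[str, bool], bool]:
    """Normalize areas to fractions over all forms of one backbone family.

    fraction_i = area_i / sum_j area_j.  Units whose area falls below
    ``loq_fraction`` of the family total are flagged below-limit and zeroed
    *before* normalization; if the whole family total is zero the group is
    flagged below-limit wholesale.

    Returns ``(fractions, below_limit flags, family_below_limit)``.
    """
    valid = family_unit_ids(family, registry)
    unknown = set(areas) - valid
    if unknown:
        raise KeyError(
            f"units {sorted(unknown)} are not enumerated forms/classes of family {family!r}"
        )
    ids = list(areas)
    vals = np.array([areas[i] for i in ids], dtype=float)
    if np.any(vals < 0):
        raise ValueError("areas must be non-negative")
    total = vals.sum()
    if total <= 0:
        return {i: 0.0 for i in ids}, {i: True for i in ids}, True
    low = vals < loq_fraction * total
    vals = np.where(low, 0.0, vals)
    total = vals.sum()
    if total <= 0:
        return {i: 0.0 for i in ids}, {i: True for i in ids}, True
    frac = vals / total
    return (
        {i: float(f) for i, f in zip(ids, frac)},
        {i: bool(l) for i, l in zip(ids, low)},
        False,
    )


def split_class(
    class_fraction: float,
    theta: Sequence[float] | np.ndarray,
    isoform_ids: Sequence[str] | None = None,
) -> dict[str, float] | np.ndarray:
    """Distribute an isobaric class's fraction over its positional isomers.

    isoform fraction = class fraction x theta; the class total is conserved
    exactly.  ``theta`` must lie on the probability simplex.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim != 1 or len(th) < 1:
        raise ValueError("theta must be a 1-D simplex vector")
    if isoform_ids is not None and len(isoform_ids) != len(th):
        raise ValueError(
            f"theta has {len(th)} components but {len(isoform_ids)} isoform ids given"
        )
    if np.any(th < -1e-9) or abs(th.sum() - 1.0) > 1e-6:
        raise ValueError(f"theta {th} is not on the probability simplex")
    parts = class_fraction * np.clip(th, 0.0, None)
    # conserve the class total exactly despite clipping/rounding
    if parts.sum() > 0:
        parts *= class_fraction / parts.sum()
    if isoform_ids is None:
        return parts
    return {i: float(p) for i, p in zip(isoform_ids, parts)}
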