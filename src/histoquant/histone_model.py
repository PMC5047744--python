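"""Histone backbone peptide registry and propionylation-aware mass model.

Bottom-up histone proteomics digests propionylated histones with trypsin,
yielding a small, fixed set of backbone peptides whose modified forms are
quantified relative to one another.  Propionic-anhydride derivatization
(applied before and after digestion) adds a propionyl group to every peptide
N-terminus and to every lysine whose epsilon-amine is still reactive —
unmodified and mono-methylated lysines.  Acetylated, di- and tri-methylated
lysines are not derivatized.  The resulting mass arithmetic makes, e.g., an
acetylated lysine lighter than an unmodified (propionylated) one by exactly
one methylene, and makes positional isomers such as H3K18ac vs H3K23ac
strictly isobaric: they can only be told apart by b/y fragment ions.

This module owns that arithmetic: the peptide registry (shipped as TSV data),
enumeration of modified forms, monoisotopic masses, b/y fragment ladders, and
the discriminating-ion analysis used for isomer deconvolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PTM_STATES",
    "PROTON",
    "WATER",
    "ModSite",
    "BackbonePeptide",
    "PeptideForm",
    "FragmentIon",
    "RegistryError",
    "load_registry",
    "default_registry",
    "get_backbone",
    "ptm_delta",
    "enumerate_forms",
    "make_form",
    "monoisotopic_mass",
    "fragment_ladder",
    "isobaric_class_id",
    "group_isobaric",
    "ion_partition",
    "discriminating_ions",
]

#: PTM states a lysine mod-site may take.  "un" means unmodified (and hence
#: propionylated after derivatization).
PTM_STATES: tuple[str, ...] = ("un", "ac", "me1", "me2", "me3")

#: States that leave the lysine epsilon-amine reactive toward propionylation.
PROPIONYLATABLE_STATES: frozenset[str] = frozenset({"un", "me1"})

PROTON: float = _pmass.nist_mass["H+"][0][0]
WATER: float = _pmass.calculate_mass(formula="H2O")


class RegistryError(KeyError):
    """Unknown backbone id or malformed registry entry."""


@dataclass(frozen=True)
class ModSite:
    """A modifiable residue within a backbone peptide (mature-protein numbering)."""

    position: int
    residue: str
    allowed: tuple[str, ...]


@dataclass(frozen=True)
class BackbonePeptide:
    """A fixed tryptic histone peptide whose modified forms are co-quantified.

    Coordinates are 1-based mature-protein numbering (initiator Met removed),
    so e.g. H3 18-26 spans K18..R26.  ``family`` is the normalization group:
    it equals ``id`` except for the H2A T16/S16 variant pair, whose two
    backbones share one family so their recovery ratio is well defined.
    """

    id: str
    protein: str
    family: str
    sequence: str
    start_pos: int
    mod_sites: tuple[ModSite, ...]

    @property
    def end_pos(self) -> int:
        return self.start_pos + len(self.sequence) - 1

    def residue_at(self, position: int) -> str:
        if not self.start_pos <= position <= self.end_pos:
            raise ValueError(f"position {position} outside {self.id} span")
        return self.sequence[position - self.start_pos]

    def validate(self) -> None:
        for site in self.mod_sites:
            if self.residue_at(site.position) != site.residue:
                raise RegistryError(
                    f"{self.id}: mod site {site.position} declared {site.residue}, "
                    f"sequence has {self.residue_at(site.position)}"
                )
            if site.residue not in {"K", "S", "T"}:
                raise RegistryError(f"{self.id}: unsupported mod-site residue {site.residue}")
            unknown = set(site.allowed) - set(PTM_STATES)
            if unknown:
                raise RegistryError(f"{self.id}: unknown PTM states {sorted(unknown)}")


@dataclass(frozen=True)
class PeptideForm:
    """One modified form of a backbone: a PTM state per declared mod site.

    ``mods`` holds a state for *every* mod site (position-ascending), "un"
    included, so forms of one backbone are directly comparable.
    """

    backbone: BackbonePeptide
    mods: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        declared = {s.position: s for s in self.backbone.mod_sites}
        positions = [p for p, _ in self.mods]
        if positions != sorted(declared):
            raise ValueError(
                f"{self.backbone.id}: form must assign a state to every mod site "
                f"in ascending order; got positions {positions}"
            )
        for pos, state in self.mods:
            if state not in declared[pos].allowed:
                raise ValueError(
                    f"{self.backbone.id}: state {state!r} not allowed at position {pos}"
                )

    @property
    def mod_map(self) -> dict[int, str]:
        return dict(self.mods)

    @property
    def id(self) -> str:
        tokens = [f"K{p}{s}" for p, s in self.mods if s != "un"]
        return f"{self.backbone.id}:{''.join(tokens) or 'unmod'}"

    @property
    def short_id(self) -> str:
        return self.id.split(":", 1)[1]

    @property
    def n_modified(self) -> int:
        return sum(1 for _, s in self.mods if s != "un")

    @property
    def ptm_multiset(self) -> tuple[str, ...]:
        """Sorted multiset of non-"un" PTM types; the isobaric-class key."""
        return tuple(sorted(s for _, s in self.mods if s != "un"))

    @property
    def propionyl_sites(self) -> frozenset[int]:
        """Positions of propionylated lysines (N-terminal propionyl is implicit).

        Every lysine in the sequence — mod site or not — is propionylated
        unless its state is ac/me2/me3.  Non-mod-site lysines are always "un".
        """
        states = self.mod_map
        out = set()
        for offset, res in enumerate(self.backbone.sequence):
            if res != "K":
                continue
            pos = self.backbone.start_pos + offset
            if states.get(pos, "un") in PROPIONYLATABLE_STATES:
                out.add(pos)
        return frozenset(out)


@dataclass(frozen=True)
class FragmentIon:
    """A singly/multiply protonated b or y ion of one peptide form."""

    series: str
    index: int
    charge: int
    mz: float
    source_form: PeptideForm

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"unknown ion series {self.series!r}")
        if not 1 <= self.index < len(self.source_form.backbone.sequence):
            raise ValueError("fragment index must satisfy 1 <= index < peptide length")


# ---------------------------------------------------------------------------
# Registry and PTM-delta loading


def _parse_mod_sites(text: str) -> tuple[ModSite, ...]:
    text = text.strip()
    if not text:
        return ()
    sites = []
    for chunk in text.split(";"):
        pos, res, allowed = chunk.split(":")
        sites.append(ModSite(int(pos), res, tuple(allowed.split("|"))))
    return tuple(sites)


def load_registry(path: str | Path | None = None) -> dict[str, BackbonePeptide]:
    """Load the backbone registry from TSV (default: the shipped table)."""
    if path is None:
        text = resources.files("histoquant.data").joinpath("peptides.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["id", "protein", "family", "start", "sequence", "mod_sites"]
    if header != expected:
        raise RegistryError(f"registry header {header} != {expected}")
    registry: dict[str, BackbonePeptide] = {}
    for ln in lines[1:]:
        cols = ln.split("\t")
        cols += [""] * (len(expected) - len(cols))
        bid, protein, family, start, seq, mod_sites = cols[: len(expected)]
        pep = BackbonePeptide(
            id=bid,
            protein=protein,
            family=family,
            sequence=seq,
            start_pos=int(start),
            mod_sites=_parse_mod_sites(mod_sites),
        )
        pep.validate()
        registry[bid] = pep
    return registry


@lru_cache(maxsize=1)
def default_registry() -> dict[str, BackbonePeptide]:
    return load_registry()


def get_backbone(backbone_id: str, registry: Mapping[str, BackbonePeptide] | None = None) -> BackbonePeptide:
    reg = default_registry() if registry is None else registry
    try:
        return reg[backbone_id]
    except KeyError:
        raise RegistryError(
            f"unknown backbone {backbone_id!r}; known: {sorted(reg)}"
        ) from None


@lru_cache(maxsize=1)
def _ptm_deltas() -> dict[str, float]:
    text = resources.files("histoquant.data").joinpath("ptm_deltas.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    deltas = {}
    for ln in lines[1:]:
        mod, formula = ln.split("\t")[:2]
        deltas[mod] = _pmass.calculate_mass(formula=formula)
    return deltas


def ptm_delta(mod: str) -> float:
    """Monoisotopic mass delta (Da) for a PTM or the propionyl group."""
    try:
        return _ptm_deltas()[mod]
    except KeyError:
        raise KeyError(f"unknown modification {mod!r}") from None


# ---------------------------------------------------------------------------
# Form enumeration and masses


def make_form(
    backbone: BackbonePeptide | str,
    mods: Mapping[int, str] | None = None,
    registry: Mapping[str, BackbonePeptide] | None = None,
) -> PeptideForm:
    """Build a form from a partial {position: state} mapping (missing = "un")."""
    if isinstance(backbone, str):
        backbone = get_backbone(backbone, registry)
    mods = dict(mods or {})
    declared = [s.position for s in backbone.mod_sites]
    unknown = set(mods) - set(declared)
    if unknown:
        raise ValueError(f"{backbone.id}: positions {sorted(unknown)} are not mod sites")
    assignment = tuple((p, mods.get(p, "un")) for p in sorted(declared))
    return PeptideForm(backbone, assignment)


def enumerate_forms(
    backbone: BackbonePeptide | str,
    max_total_mods: int | None = None,
    registry: Mapping[str, BackbonePeptide] | None = None,
) -> list[PeptideForm]:
    """All PTM assignments with at most ``max_total_mods`` modified sites.

    Canonical deterministic order: mod-site positions ascending, states in
    alphabetical order at each site (product order).
    """
    if isinstance(backbone, str):
        backbone = get_backbone(backbone, registry)
    if max_total_mods is not None and max_total_mods < 0:
        raise ValueError("max_total_mods must be >= 0")
    sites = sorted(backbone.mod_sites, key=lambda s: s.position)
    choices = [sorted(s.allowed) for s in sites]
    forms = []
    for combo in itertools.product(*choices):
        n_mod = sum(1 for s in combo if s != "un")
        if max_total_mods is not None and n_mod > max_total_mods:
            continue
        forms.append(PeptideForm(backbone, tuple(zip((s.position for s in sites), combo))))
    return forms


def _residue_masses(form: PeptideForm) -> np.ndarray:
    """Per-residue monoisotopic masses including PTM and propionyl deltas.

    The N-terminal propionyl is assigned to residue 1 so that cumulative sums
    give fragment masses directly.
    """
    seq = form.backbone.sequence
    start = form.backbone.start_pos
    states = form.mod_map
    prop_sites = form.propionyl_sites
    prop = ptm_delta("propionyl")
    masses = np.empty(len(seq))
    for i, res in enumerate(seq):
        m = _pmass.std_aa_mass[res]
        pos = start + i
        state = states.get(pos)
        if state and state != "un":
            m += ptm_delta(state)
        if pos in prop_sites:
            m += prop
        masses[i] = m
    masses[0] += prop  # N-terminal derivatization
    return masses


def monoisotopic_mass(form: PeptideForm) -> float:
    """Neutral monoisotopic mass (Da) of the fully derivatized form."""
    return float(_residue_masses(form).sum() + WATER)


def fragment_ladder(form: PeptideForm, series: str, charge: int = 1) -> list[FragmentIon]:
    """The full b or y ladder (indices 1..L-1) at the given charge state.

    b_i covers residues 1..i (with the N-terminal propionyl); y_j covers the
    last j residues plus water.  m/z = (neutral + z*proton)/z.  The sum rule
    b_i + y_(L-i) = M + 2*proton holds at charge 1 for every i.
    """
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    res = _residue_masses(form)
    L = len(res)
    if series == "b":
        neutral = np.cumsum(res)[:-1]
    else:
        neutral = np.cumsum(res[::-1])[:-1] + WATER
    mz = (neutral + charge * PROTON) / charge
    return [
        FragmentIon(series=series, index=i + 1, charge=charge, mz=float(m), source_form=form)
        for i, m in enumerate(mz)
    ]


# ---------------------------------------------------------------------------
# Isobaric classes and discriminating ions


def isobaric_class_id(form: PeptideForm) -> str:
    """Class label: backbone id + "+"-joined PTM multiset ("unmod" if empty)."""
    multiset = form.ptm_multiset
    return f"{form.backbone.id}:{'+'.join(multiset) or 'unmod'}"


def group_isobaric(forms: Iterable[PeptideForm]) -> dict[str, list[PeptideForm]]:
    """Group forms of one backbone into isobaric classes (same PTM multiset)."""
    classes: dict[str, list[PeptideForm]] = {}
    for f in forms:
        classes.setdefault(isobaric_class_id(f), []).append(f)
    return classes


@dataclass(frozen=True)
class IonCluster:
    """Theoretical ions from several isoforms that coincide in m/z."""

    mz: float
    representative: FragmentIon
    produced_by: tuple[int, ...]  # 0/1 per isoform, input order

    @property
    def shared(self) -> bool:
        return all(self.produced_by)


def ion_partition(
    isoforms: Sequence[PeptideForm],
    tolerance: float = 0.4,
    charge: int = 1,
) -> list[IonCluster]:
    """Cluster the pooled b/y ladders of isobaric isoforms by m/z.

    Two theoretical ions fall in one cluster when their m/z differ by at most
    ``tolerance`` from the running cluster mean (single-pass over the sorted
    pool; with unit-Da PTM spacings and sub-Da tolerances this is exact).
    """
    if len(isoforms) < 2:
        raise ValueError("need at least two isoforms")
    backbones = {f.backbone.id for f in isoforms}
    if len(backbones) > 1:
        raise ValueError(f"isoforms span multiple backbones: {sorted(backbones)}")
    masses = [monoisotopic_mass(f) for f in isoforms]
    if max(masses) - min(masses) > 1e-6:
        raise ValueError(
            "isoforms are not isobaric (they separate chromatographically, "
            "not by fragment ions)"
        )
    pool: list[tuple[float, int, FragmentIon]] = []
    for k, form in enumerate(isoforms):
        for series in ("b", "y"):
            for ion in fragment_ladder(form, series, charge):
                pool.append((ion.mz, k, ion))
    pool.sort(key=lambda t: (t[0], t[2].series, t[2].index, t[1]))

    clusters: list[IonCluster] = []
    current: list[tuple[float, int, FragmentIon]] = []

    def _flush() -> None:
        if not current:
            return
        mzs = [t[0] for t in current]
        produced = [0] * len(isoforms)
        for _, k, _ in current:
            produced[k] = 1
        rep = min(current, key=lambda t: (t[0], t[2].series, t[2].index, t[1]))[2]
        clusters.append(
            IonCluster(mz=float(np.mean(mzs)), representative=rep, produced_by=tuple(produced))
        )

    for item in pool:
        if current and abs(item[0] - np.mean([t[0] for t in current])) > tolerance:
            _flush()
            current = []
        current.append(item)
    _flush()
    return clusters


def discriminating_ions(
    isoforms: Sequence[PeptideForm],
    tolerance: float = 0.4,
    charge: int = 1,
) -> list[tuple[FragmentIon, np.ndarray]]:
    """Ions whose theoretical m/z is not shared by all isobaric isoforms.

    Returns (representative ion, 0/1 indicator over isoforms) pairs; an empty
    result means the isoforms are indistinguishable by MS/MS.  A singleton
    input trivially has no discriminating ions.
    """
    if len(isoforms) == 1:
        return []
    return [
        (c.representative, np.array(c.produced_by, dtype=float))
        for c in ion_partition(isoforms, tolerance=tolerance, charge=charge)
        if not c.shared
    ]
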