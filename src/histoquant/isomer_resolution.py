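"""Deconvolution of co-eluting isobaric positional isomers from averaged MS/MS.

Positional isomers such as H3K18ac vs H3K23ac share precursor mass and
elution time, so their mixing fractions must be estimated from fragment ions
unique to each isomer.  The estimator here averages the MS2 spectra across
the chromatographic peak (weighted by precursor intensity), matches the
theoretical discriminating ions, and solves a least-squares problem on the
probability simplex.  For two isomers this reduces to the intuitive ratio of
per-isomer unique-ion intensity sums; the simplex solver is the unique
generalization to the four tri-acetyl H4 isomers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import histone_model as hm
from .signals import Ms2Spectrum

__all__ = [
    "IsoformEstimate",
    "IsomerResolutionError",
    "average_spectrum",
    "match_ions",
    "resolve_isoforms",
    "simplex_lstsq",
]


class IsomerResolutionError(ValueError):
    """Isomers cannot be resolved (no discriminating ions, or no signal)."""


@dataclass
class IsoformEstimate:
    """Mixing fractions over co-eluting positional isomers.

    ``residual`` is the unexplained fraction of discriminating-ion intensity
    (L1, in [0, 1]); ``defined`` is False when no discriminating intensity was
    observed at all and theta is NaN.
    """

    class_id: str
    isoform_ids: tuple[str, ...]
    theta: np.ndarray
    residual: float
    n_ions_used: int
    scale: float
    defined: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.defined:
            if np.any(self.theta < -1e-9) or abs(self.theta.sum() - 1.0) > 1e-6:
                raise ValueError(f"theta {self.theta} not on the simplex")
            if not 0.0 <= self.residual <= 1.0:
                raise ValueError("residual must lie in [0, 1]")


def average_spectrum(
    spectra: Sequence[Ms2Spectrum],
    weights: Sequence[float] | None = None,
    mz_tolerance: float = 0.4,
) -> Ms2Spectrum:
    """Intensity-weighted average MS2 across a chromatographic peak.

    Peaks from all spectra are pooled and binned by m/z within ``mz_tolerance``
    of the running bin mean; each bin's intensity is the weighted mean over
    *all* spectra (a spectrum without a peak in the bin contributes zero), so
    averaging two identical spectra returns the original intensities.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    if weights is None:
        w = np.ones(len(spectra))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(spectra),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero, one per spectrum")
    wsum = w.sum()

    pool = []  # (mz, weighted intensity)
    for s, ws in zip(spectra, w):
        for mz, inten in zip(s.mz, s.intensity):
            pool.append((float(mz), ws * float(inten)))
    pool.sort()

    out_mz, out_int = [], []
    cur: list[tuple[float, float]] = []

    def _flush() -> None:
        if not cur:
            return
        total = sum(wi for _, wi in cur)
        if total > 0:
            center = sum(m * wi for m, wi in cur) / total
        else:
            center = float(np.mean([m for m, _ in cur]))
        out_mz.append(center)
        out_int.append(total / wsum)

    for mz, wi in pool:
        if cur and abs(mz - np.mean([m for m, _ in cur])) > mz_tolerance:
            _flush()
            cur = []
        cur.append((mz, wi))
    _flush()

    rt = float(np.average([s.rt_min for s in spectra], weights=w))
    return Ms2Spectrum(
        precursor_id=spectra[0].precursor_id,
        rt_min=rt,
        mz=np.array(out_mz),
        intensity=np.array(out_int),
    )


def match_ions(
    spectrum: Ms2Spectrum,
    ions: Sequence[hm.FragmentIon] | Sequence[float],
    tolerance: float = 0.4,
    ppm: bool = False,
) -> np.ndarray:
    """Observed intensity per theoretical ion (0 when unmatched).

    Each observed peak is assigned to at most one ion: candidate pairs within
    tolerance are ranked by m/z distance, ties broken toward the lower
    theoretical m/z, and assigned greedily.  ``ions`` may be FragmentIon
    objects or bare theoretical m/z values.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    theo = np.array([i.mz if isinstance(i, hm.FragmentIon) else float(i) for i in ions])
    out = np.zeros(len(theo))
    if len(spectrum.mz) == 0 or len(theo) == 0:
        return out
    candidates = []
    for i, t in enumerate(theo):
        tol = t * tolerance * 1e-6 if ppm else tolerance
        d = np.abs(spectrum.mz - t)
        for j in np.nonzero(d <= tol)[0]:
            candidates.append((float(d[j]), float(t), i, int(j)))
    candidates.sort()
    used_ion: set[int] = set()
    used_peak: set[int] = set()
    for _, _, i, j in candidates:
        if i in used_ion or j in used_peak:
            continue
        used_ion.add(i)
        used_peak.add(j)
        out[i] = spectrum.intensity[j]
    return out


def simplex_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact minimizer of ||b - A theta||^2 over the probability simplex.

    Active-set enumeration: for every nonempty support the equality-constrained
    (sum = 1) least-squares problem is solved via its KKT system; the feasible
    support with the lowest objective wins.  Intended for the small isomer
    counts seen here (k <= ~6).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    k = A.shape[1]
    best, best_obj = None, np.inf
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            As = A[:, support]
            G = As.T @ As
            h = As.T @ b
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = 2.0 * G
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.concatenate([2.0 * h, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:  # duplicate columns in this support
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            th_s = sol[:r]
            if np.any(th_s < -1e-9) or abs(th_s.sum() - 1.0) > 1e-6:
                continue
            th = np.zeros(k)
            th[list(support)] = np.clip(th_s, 0.0, None)
            th /= th.sum()
            obj = float(np.sum((b - A @ th) ** 2))
            if obj < best_obj - 1e-15:
                best, best_obj = th, obj
    if best is None:  # numerically extreme input; fall back to uniform
        best = np.full(k, 1.0 / k)
    return best


def resolve_isoforms(
    avg: Ms2Spectrum,
    isoforms: Sequence[hm.PeptideForm],
    tolerance: float = 0.4,
    ppm: bool = False,
) -> IsoformEstimate:
    """Estimate mixing fractions of isobaric isomers from an averaged spectrum.

    The discriminating-ion indicator matrix and a shared intensity scale
    (median observed intensity of ions common to all isomers) define the
    linear model ``observed = scale * indicator @ theta``; theta is fit on the
    probability simplex.  With two isomers this is solved in closed form as
    theta_1 = I_1 / (I_1 + I_2) over per-isomer unique-ion intensity sums.
    """
    if len(isoforms) < 2:
        raise IsomerResolutionError("need at least two isoforms to resolve")
    clusters = hm.ion_partition(isoforms, tolerance=tolerance)
    disc = [c for c in clusters if not c.shared]
    if not disc:
        raise IsomerResolutionError("isoforms share every fragment ion: unresolvable")
    shared = [c for c in clusters if c.shared]
    class_id = hm.isobaric_class_id(isoforms[0])
    iso_ids = tuple(f.id for f in isoforms)
    flags: list[str] = []

    obs = match_ions(avg, [c.mz for c in disc], tolerance=tolerance, ppm=ppm)
    A = np.array([c.produced_by for c in disc], dtype=float)
    total = obs.sum()
    if total <= 0:
        return IsoformEstimate(
            class_id=class_id,
            isoform_ids=iso_ids,
            theta=np.full(len(isoforms), np.nan),
            residual=1.0,
            n_ions_used=len(disc),
            scale=0.0,
            defined=False,
            flags=("no_discriminating_signal",),
        )

    shared_obs = match_ions(avg, [c.mz for c in shared], tolerance=tolerance, ppm=ppm)
    matched_shared = shared_obs[shared_obs > 0]
    if len(matched_shared):
        scale = float(np.median(matched_shared))
    else:
        # no shared-ion signal: calibrate from the discriminating ions under
        # the simplex constraint (exact when clusters are isomer-unique)
        scale = float(total / max(A.sum(axis=0).mean(), 1.0))
        flags.append("scale_from_discriminating_ions")

    if len(isoforms) == 2:
        unique_a = obs[(A[:, 0] == 1) & (A[:, 1] == 0)].sum()
        unique_b = obs[(A[:, 1] == 1) & (A[:, 0] == 0)].sum()
        if unique_a + unique_b <= 0:
            theta = simplex_lstsq(A, obs / scale)
        else:
            t1 = unique_a / (unique_a + unique_b)
            theta = np.array([t1, 1.0 - t1])
    else:
        # fit in scale-normalized units so the KKT system stays well conditioned
        theta = simplex_lstsq(A, obs / scale)

    resid = float(np.abs(obs - scale * (A @ theta)).sum() / total)
    return IsoformEstimate(
        class_id=class_id,
        isoform_ids=iso_ids,
        theta=theta,
        residual=min(max(resid, 0.0), 1.0),
        n_ions_used=len(disc),
        scale=scale,
        flags=tuple(flags),
    )
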