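"""Precursor window algebra, spectrum preprocessing and dot-product search.

The precursor acceptance region on the mass-error axis is a union of
intervals, one per allowed isotope misassignment offset: for offsets
k = 0..isotope_max the window ``[k*spacing - mme_minus, k*spacing + mme_plus]``
is accepted, and overlapping or touching windows merge.  For a symmetric
tolerance t at 1 Da spacing the separate isotope windows merge into a single
contiguous window exactly at t = 0.5 Da; past the merge the union grows along
two edges instead of four or six.

Scoring is a k-score-style normalized dot product between the square-root
transformed, binned experimental spectrum and a unit-weight template of
singly charged b- and y-ions.  The template deliberately contains no
ammonia/water-loss ion series: a spectrum of an unmodified N-terminal-Gln
peptide whose b-ions all lost NH3 is then better explained by the
pyroglutamate form of the same sequence (at ~+17 Da precursor mass error)
than by the unmodified form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .peptide_space import (
    DEFAULT_CONSTANTS,
    Fidelity,
    MassConstants,
    MassIndex,
    NTermMod,
    PeptideEntry,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalUnion:
    """An ordered union of disjoint open-ended mass intervals (low < high)."""

    intervals: tuple

    def __post_init__(self):
        prev_high = None
        for low, high in self.intervals:
            if not low < high:
                raise ValueError(f"degenerate interval ({low}, {high})")
            if prev_high is not None and low <= prev_high:
                raise ValueError("intervals must be disjoint and sorted")
            prev_high = high

    @classmethod
    def merge(cls, raw: Iterable) -> "IntervalUnion":
        """Build a union from raw (low, high) pairs, merging overlaps/touches.

        Zero-width pairs (low == high) are dropped: a degenerate tolerance
        accepts nothing.
        """
        pairs = sorted((lo, hi) for lo, hi in raw if lo < hi)
        merged = []
        for lo, hi in pairs:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return cls(tuple((lo, hi) for lo, hi in merged))

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def contains(self, x: float) -> bool:
        return any(lo <= x <= hi for lo, hi in self.intervals)


def effective_windows(
    mme_minus: float,
    mme_plus: float,
    isotope_max: int = 0,
    spacing: float = 1.0033548378,
) -> IntervalUnion:
    """Precursor acceptance windows on the raw mass-error axis.

    Union over isotope offsets k in 0..isotope_max of
    ``[k*spacing - mme_minus, k*spacing + mme_plus]``, merged where they
    overlap or touch.
    """
    if mme_minus < 0 or mme_plus < 0:
        raise ValueError("tolerances must be >= 0")
    if isotope_max < 0:
        raise ValueError("isotope_max must be >= 0")
    return IntervalUnion.merge(
        (k * spacing - mme_minus, k * spacing + mme_plus)
        for k in range(isotope_max + 1)
    )


def union_width(u: IntervalUnion) -> float:
    """Total width (Da) of the union."""
    return float(sum(hi - lo for lo, hi in u))


def edge_count(u: IntervalUnion) -> int:
    """Number of moving edges: two per disjoint interval."""
    return 2 * len(u)


@dataclass
class SearchParams:
    """Optimizable search parameters plus fixed scoring settings.

    ``mme_minus``/``mme_plus`` are the negative/positive precursor mass
    tolerances in Da (bounded by [0, 25] in the optimizer); ``isotope_max``
    allows misassignment to the +1/+2 isotope peak; ``missed_max`` and
    ``fidelity`` control the digestion the candidate index was built with.
    """

    mme_minus: float = 2.0
    mme_plus: float = 2.0
    isotope_max: int = 2
    missed_max: int = 2
    fidelity: Fidelity = Fidelity.FULL
    fdr_threshold: float = 0.01
    fitness_charge: int = 2
    bin_width: float = 1.0005
    isotope_spacing: float = 1.0033548378

    def __post_init__(self):
        if self.mme_minus < 0 or self.mme_plus < 0:
            raise ValueError("tolerances must be >= 0")
        if self.isotope_max not in (0, 1, 2):
            raise ValueError("isotope_max must be 0, 1 or 2")
        if not 0 <= self.missed_max <= 4:
            raise ValueError("missed_max must be in [0, 4]")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        self.fidelity = Fidelity(self.fidelity)

    def windows(self) -> IntervalUnion:
        return effective_windows(
            self.mme_minus, self.mme_plus, self.isotope_max, self.isotope_spacing
        )


@dataclass
class Spectrum:
    """One MS/MS scan: precursor, charge, retention time and peak list."""

    id: str
    precursor_mz: float
    charge: int
    rt: float  # minutes
    peaks: list  # (mz, intensity) pairs

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        self.peaks = sorted(self.peaks)


@dataclass
class PSMRecord:
    """Best peptide match for one spectrum."""

    spectrum_id: str
    peptide: PeptideEntry
    score: float
    raw_delta: float  # measured neutral mass - peptide mass (Da)
    isotope_offset: int
    is_decoy: bool
    charge: int
    rt: float
    q_value: float = float("nan")


class EmptySpectrumError(ValueError):
    """Spectrum has no usable (nonzero-intensity) peaks."""


@dataclass(frozen=True)
class BinnedVector:
    """Sparse unit-norm binned representation: parallel bin/value arrays."""

    bins: np.ndarray
    values: np.ndarray

    def dense(self, n_bins: int | None = None) -> np.ndarray:
        size = int(self.bins[-1]) + 1 if n_bins is None else n_bins
        v = np.zeros(size)
        mask = self.bins < size
        v[self.bins[mask]] = self.values[mask]
        return v


def preprocess_spectrum(s: Spectrum, bin_width: float = 1.0005) -> BinnedVector:
    """Square-root transform, bin, and unit-normalize a spectrum."""
    if not s.peaks:
        raise EmptySpectrumError(f"spectrum {s.id!r} has no peaks")
    mz = np.array([p[0] for p in s.peaks], dtype=float)
    inten = np.array([p[1] for p in s.peaks], dtype=float)
    if np.any(inten < 0):
        raise ValueError("negative intensity")
    if not np.any(inten > 0):
        raise EmptySpectrumError(f"spectrum {s.id!r} has all-zero intensities")
    bins = np.floor(mz / bin_width).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins = bins[order]
    vals = np.sqrt(inten[order])
    uniq, start = np.unique(bins, return_index=True)
    sums = np.add.reduceat(vals, start)
    norm = float(np.linalg.norm(sums))
    return BinnedVector(bins=uniq, values=sums / norm)


def fragment_mzs(
    sequence: str,
    nterm_mod: NTermMod = NTermMod.NONE,
    constants: MassConstants = DEFAULT_CONSTANTS,
    fixed_carbamidomethyl: bool = True,
) -> tuple:
    """Singly charged b- and y-ion m/z arrays for a peptide.

    The N-terminal modification shifts every b-ion (and the precursor) but
    leaves the y-ions untouched.
    """
    rm = constants.residue_mass
    masses = np.array(
        [
            rm[aa] + (constants.carbamidomethyl if aa == "C" and fixed_carbamidomethyl else 0.0)
            for aa in sequence
        ]
    )
    nterm_delta = 0.0
    if nterm_mod is NTermMod.PYROGLU_Q:
        nterm_delta = -constants.ammonia
    elif nterm_mod is NTermMod.PYROGLU_E:
        nterm_delta = -constants.water
    prefix = np.cumsum(masses)
    b = prefix[:-1] + constants.proton + nterm_delta
    suffix = np.cumsum(masses[::-1])[::-1]
    y = suffix[1:] + constants.water + constants.proton
    return b, y


def theoretical_template(
    p: PeptideEntry,
    charge: int = 2,
    bin_width: float = 1.0005,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> BinnedVector:
    """Unit-weight binned template of singly charged b/y ions.

    Each occupied bin gets weight 1 before unit normalization; ammonia/water
    loss series are intentionally absent (see module docstring).  ``charge``
    is the precursor charge and does not alter the fragment series.
    """
    if len(p.sequence) < 2:
        raise ValueError("peptide must have length >= 2")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    b, y = fragment_mzs(p.sequence, p.nterm_mod, constants)
    bins = np.unique(np.floor(np.concatenate([b, y]) / bin_width).astype(np.int64))
    w = 1.0 / np.sqrt(len(bins))
    return BinnedVector(bins=bins, values=np.full(len(bins), w))


def score(spec_vector: BinnedVector, template: BinnedVector) -> float:
    """Dot product of two unit-norm sparse binned vectors, in [0, 1]."""
    common, ia, ib = np.intersect1d(
        spec_vector.bins, template.bins, assume_unique=True, return_indices=True
    )
    return float(np.dot(spec_vector.values[ia], template.values[ib]))


def _isotope_offset(
    raw_delta: float, params: SearchParams
) -> tuple | None:
    """Best feasible isotope offset for a raw mass error, or None."""
    best = None
    for k in range(params.isotope_max + 1):
        resid = raw_delta - k * params.isotope_spacing
        if -params.mme_minus <= resid <= params.mme_plus:
            if best is None or abs(resid) < best[1]:
                best = (k, abs(resid))
    return best


class _SearchContext:
    """Caches shared across spectra of one dataset search."""

    def __init__(self, index: MassIndex, params: SearchParams,
                 constants: MassConstants):
        self.index = index
        self.params = params
        self.constants = constants
        windows = params.windows()
        # candidate peptide masses: M - window, flipped to the mass axis
        self.mass_intervals = tuple(
            (-hi, -lo) for lo, hi in reversed(windows.intervals)
        )
        self._templates: dict = {}

    def template_bins(self, entry: PeptideEntry) -> tuple:
        key = (entry.sequence, entry.nterm_mod)
        t = self._templates.get(key)
        if t is None:
            tpl = theoretical_template(
                entry, bin_width=self.params.bin_width, constants=self.constants
            )
            t = (tpl.bins, float(tpl.values[0]))
            self._templates[key] = t
        return t


def _search_one(
    s: Spectrum, ctx: _SearchContext
) -> PSMRecord | None:
    params = ctx.params
    constants = ctx.constants
    measured = (s.precursor_mz - constants.proton) * s.charge
    candidates = ctx.index.query(ctx.mass_intervals, offset=measured)
    if not candidates:
        return None
    try:
        spec = preprocess_spectrum(s, params.bin_width)
    except EmptySpectrumError:
        return None
    dense = spec.dense()
    n_bins = len(dense)
    best = None
    for entry in candidates:
        raw_delta = measured - entry.mass
        feas = _isotope_offset(raw_delta, params)
        if feas is None:
            continue  # numeric edge of the merged window
        k, resid = feas
        bins, weight = ctx.template_bins(entry)
        inside = bins[bins < n_bins]
        sc = float(dense[inside].sum()) * weight
        # maximize score; break ties by smaller centered residual, target
        # over decoy, then lexicographic sequence and modification name
        key = (-sc, resid, entry.is_decoy, entry.sequence, entry.nterm_mod.value)
        if best is None or key < best[0]:
            best = (key, entry, sc, raw_delta, k)
    if best is None:
        return None
    _, entry, sc, raw_delta, k = best
    return PSMRecord(
        spectrum_id=s.id,
        peptide=entry,
        score=sc,
        raw_delta=raw_delta,
        isotope_offset=k,
        is_decoy=entry.is_decoy,
        charge=s.charge,
        rt=s.rt,
    )


def search_spectrum(
    s: Spectrum,
    index: MassIndex,
    params: SearchParams,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> PSMRecord | None:
    """Best-scoring candidate peptide for one spectrum, or None.

    The measured neutral mass is ``(precursor_mz - proton) * charge``;
    candidates are index entries whose mass error falls inside the effective
    precursor windows.
    """
    return _search_one(s, _SearchContext(index, params, constants))


def search_dataset(
    spectra: Sequence,
    index: MassIndex,
    params: SearchParams,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list:
    """Search every spectrum; one record per spectrum with >= 1 candidate.

    Deterministic and independent of spectrum order (results are returned
    in input order but each spectrum is scored in isolation).
    """
    ctx = _SearchContext(index, params, constants)
    out = []
    for s in spectra:
        rec = _search_one(s, ctx)
        if rec is not None:
            out.append(rec)
    return out
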