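"""In-silico peptide space: tryptic digestion, decoys, modifications, mass index.

Peptides are produced by (semi-)tryptic digestion of protein sequences,
optionally expanded with the N-terminal pyroglutamate variable modification
(cyclization of Gln, losing NH3, or Glu, losing H2O), and organized in a
mass-sorted index supporting interval-union queries for precursor matching.
Decoy proteins are whole-sequence reversals searched concatenated with the
targets.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses (Da), standard 20 amino acids.
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301400,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102360,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}


class NTermMod(str, Enum):
    """N-terminal modification state of a peptide."""

    NONE = "none"
    PYROGLU_Q = "pyroglu_from_Q"
    PYROGLU_E = "pyroglu_from_E"


class Fidelity(str, Enum):
    """Enzymatic fidelity: both termini tryptic, or only one."""

    FULL = "full"
    SEMI = "semi"


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic mass constants used throughout the package.

    ``isotope_spacing`` is the 13C-12C mass difference; searches use it to
    model misassignment of the precursor to the +1/+2 isotopic peak.
    ``carbamidomethyl`` is the fixed Cys modification delta.
    """

    residue_mass: dict = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASS)
    )
    water: float = 18.0105646837
    proton: float = 1.00727646677
    ammonia: float = 17.02654910101
    carbamidomethyl: float = 57.02146372057
    isotope_spacing: float = 1.0033548378

    def __post_init__(self):
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("residue masses must be strictly positive")
        for name in ("water", "proton", "ammonia", "carbamidomethyl",
                     "isotope_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and decoy flag."""

    id: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass
class PeptideEntry:
    """A digested (possibly modified, possibly decoy) peptide."""

    sequence: str
    protein_ids: frozenset
    n_missed: int
    nterm_mod: NTermMod = NTermMod.NONE
    is_decoy: bool = False
    is_protein_nterm: bool = False
    is_protein_cterm: bool = False
    fully_tryptic_termini: int = 2
    mass: float = 0.0


class UnknownResidueError(ValueError):
    """A sequence contains a residue code outside the standard 20."""


def peptide_mass(
    sequence: str,
    nterm_mod: NTermMod = NTermMod.NONE,
    constants: MassConstants = DEFAULT_CONSTANTS,
    fixed_carbamidomethyl: bool = True,
) -> float:
    """Monoisotopic neutral mass of a peptide.

    Sum of residue masses plus one water, with carbamidomethyl added per
    cysteine when the fixed modification is on, and the N-terminal
    pyroglutamate delta (-NH3 from Gln, -H2O from Glu) when present.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = constants.water
    rm = constants.residue_mass
    for aa in sequence:
        try:
            total += rm[aa]
        except KeyError:
            raise UnknownResidueError(f"unknown residue code {aa!r}") from None
        if aa == "C" and fixed_carbamidomethyl:
            total += constants.carbamidomethyl
    if nterm_mod is NTermMod.PYROGLU_Q:
        if not sequence.startswith("Q"):
            raise ValueError("pyroglu_from_Q requires an N-terminal Q")
        total -= constants.ammonia
    elif nterm_mod is NTermMod.PYROGLU_E:
        if not sequence.startswith("E"):
            raise ValueError("pyroglu_from_E requires an N-terminal E")
        total -= constants.water
    return total


def cleavage_sites(sequence: str) -> list:
    """0-based positions after which trypsin cleaves (after K/R, not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    missed_max: int = 2,
    fidelity: Fidelity = Fidelity.FULL,
    length_bounds: tuple | None = (5, 50),
    constants: MassConstants = DEFAULT_CONSTANTS,
    on_nonstandard: str = "skip",
) -> list:
    """Digest one protein into :class:`PeptideEntry` objects.

    ``full`` fidelity requires both peptide termini at tryptic cleavage
    sites or protein termini; ``semi`` additionally yields every sub-peptide
    with exactly one conforming terminus.  Internal missed cleavages are
    bounded by ``missed_max``; the length filter is applied last.

    Peptides containing non-standard residues (B, Z, X, U, ...) are dropped
    with a logged count when ``on_nonstandard`` is ``"skip"``, or rejected
    with :class:`UnknownResidueError` when it is ``"strict"``.
    """
    if not 0 <= missed_max <= 4:
        raise ValueError("missed_max must be in [0, 4]")
    fidelity = Fidelity(fidelity)
    seq = protein.sequence
    n = len(seq)
    sites = cleavage_sites(seq)
    bounds = [0] + sites + [n]
    boundary_set = set(bounds)
    spans = {}  # (start, end) -> n_tryptic_termini

    # fully tryptic spans: consecutive boundary pairs, <= missed_max internal
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + missed_max, len(bounds))):
            spans[(bounds[a], bounds[b])] = 2

    if fidelity is Fidelity.SEMI:
        for a in range(len(bounds) - 1):
            bmax = min(a + 1 + missed_max, len(bounds) - 1)
            start = bounds[a]
            # conforming N-terminus, ragged C-terminus
            for j in range(start + 1, bounds[bmax]):
                if j not in boundary_set:
                    spans.setdefault((start, j), 1)
        for b in range(1, len(bounds)):
            bmin = max(b - 1 - missed_max, 0)
            end = bounds[b]
            # ragged N-terminus, conforming C-terminus
            for j in range(bounds[bmin] + 1, end):
                if j not in boundary_set:
                    spans.setdefault((j, end), 1)

    lo, hi = length_bounds if length_bounds else (1, n)
    out = []
    n_dropped = 0
    for (start, end), termini in sorted(spans.items()):
        if not lo <= end - start <= hi:
            continue
        pep = seq[start:end]
        try:
            mass = peptide_mass(pep, NTermMod.NONE, constants)
        except UnknownResidueError:
            if on_nonstandard == "strict":
                raise
            n_dropped += 1
            continue
        n_missed = bisect.bisect_left(sites, end) - bisect.bisect_right(sites, start)
        out.append(
            PeptideEntry(
                sequence=pep,
                protein_ids=frozenset({protein.id}),
                n_missed=n_missed,
                nterm_mod=NTermMod.NONE,
                is_decoy=protein.is_decoy,
                is_protein_nterm=start == 0,
                is_protein_cterm=end == n,
                fully_tryptic_termini=termini,
                mass=mass,
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d peptides of %s containing non-standard residues",
            n_dropped, protein.id,
        )
    return out


def make_decoys(proteins: Sequence) -> list:
    """One reversed-sequence decoy per target protein, ids prefixed DECOY_."""
    decoys = []
    for p in proteins:
        if p.is_decoy:
            raise ValueError(f"{p.id!r} is already a decoy")
        decoys.append(
            ProteinRecord(id="DECOY_" + p.id, sequence=p.sequence[::-1],
                          is_decoy=True)
        )
    return decoys


def expand_modifications(
    peptide: PeptideEntry, constants: MassConstants = DEFAULT_CONSTANTS
) -> list:
    """Return the unmodified peptide plus its pyroglutamate form, if any.

    Peptides starting with Q gain a pyroglu_from_Q form (mass - NH3); those
    starting with E gain a pyroglu_from_E form (mass - H2O).
    """
    if peptide.nterm_mod is not NTermMod.NONE:
        raise ValueError("expand_modifications expects an unmodified peptide")
    forms = [peptide]
    if peptide.sequence.startswith("Q"):
        mod = NTermMod.PYROGLU_Q
    elif peptide.sequence.startswith("E"):
        mod = NTermMod.PYROGLU_E
    else:
        return forms
    forms.append(
        replace(
            peptide,
            nterm_mod=mod,
            mass=peptide_mass(peptide.sequence, mod, constants),
        )
    )
    return forms


class MassIndex:
    """Peptide entries sorted by monoisotopic mass, for interval queries.

    Duplicate entries (same sequence and modification from different
    proteins) are merged with the union of their protein ids; a merged entry
    is a decoy only if every source protein was a decoy.
    """

    def __init__(self, peptides: Iterable):
        merged = {}
        for p in peptides:
            key = (p.sequence, p.nterm_mod)
            prev = merged.get(key)
            if prev is None:
                merged[key] = p
            else:
                merged[key] = replace(
                    prev,
                    protein_ids=prev.protein_ids | p.protein_ids,
                    is_decoy=prev.is_decoy and p.is_decoy,
                    n_missed=min(prev.n_missed, p.n_missed),
                )
        entries = sorted(merged.values(), key=lambda p: (p.mass, p.sequence))
        self.entries = entries
        self.masses = np.array([p.mass for p in entries], dtype=float)
        self.bounds = (
            (float(self.masses[0]), float(self.masses[-1]))
            if entries
            else (0.0, 0.0)
        )

    def __len__(self):
        return len(self.entries)

    def query(self, intervals, offset: float = 0.0) -> list:
        """Entries whose mass lies in any ``[low + offset, high + offset]``.

        ``intervals`` is an iterable of (low, high) pairs, disjoint and
        sorted; both endpoints are inclusive.
        """
        if not len(self.entries):
            return []
        out = []
        for low, high in intervals:
            i = int(np.searchsorted(self.masses, low + offset, side="left"))
            j = int(np.searchsorted(self.masses, high + offset, side="right"))
            out.extend(self.entries[i:j])
        return out


def build_index(peptides: Iterable) -> MassIndex:
    """Build a :class:`MassIndex` from peptide entries."""
    return MassIndex(peptides)


def digest_proteome(
    proteins: Sequence,
    missed_max: int = 2,
    fidelity: Fidelity = Fidelity.FULL,
    length_bounds: tuple | None = (5, 50),
    constants: MassConstants = DEFAULT_CONSTANTS,
    with_decoys: bool = True,
    with_modifications: bool = True,
) -> MassIndex:
    """Digest targets (plus reversed decoys), expand modifications, index."""
    pool = list(proteins)
    if with_decoys:
        pool += make_decoys([p for p in proteins if not p.is_decoy])
    peptides = []
    for prot in pool:
        for pep in digest(prot, missed_max, fidelity, length_bounds, constants):
            if with_modifications:
                peptides.extend(expand_modifications(pep, constants))
            else:
                peptides.append(pep)
    return build_index(peptides)
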