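"""Ground-truthed LC-MS/MS simulator.

Generates random tryptic proteomes and tandem mass spectra whose
statistical structure mirrors what shotgun proteomics datasets show when
searched with very wide precursor tolerance windows:

* roughly two thirds of precursors doubly charged;
* a narrow central precursor mass-error distribution plus +1/+2 Da
  satellites from isotope-peak misassignment;
* co-isolated ("freerider") precursors: the recorded precursor m/z lies
  anywhere within the isolation window while the fragments come from the
  co-eluting peptide that actually dominated the spectrum;
* unmodified N-terminal Gln/Glu peptides whose entire b-ion series lost
  ammonia (-17 Da) or water (-18 Da) during fragmentation, mass-identical
  to pyroglutamate formation;
* a fraction of unmatchable pure-noise spectra.

Retention times follow a planted linear composition model plus Gaussian
noise, so retention-time predictors can be validated against ground truth.
Every spectrum carries a ground-truth record naming its planted peptide and
event type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import rt_suite
from .peptide_space import (
    DEFAULT_CONSTANTS,
    Fidelity,
    MassConstants,
    NTermMod,
    ProteinRecord,
    digest,
)
from .rt_suite import RTKind, RTModel
from .search_core import Spectrum, fragment_mzs

logger = logging.getLogger(__name__)


class SimEvent(str, Enum):
    CLEAN = "clean"
    ISOTOPE_PLUS1 = "isotope_plus1"
    ISOTOPE_PLUS2 = "isotope_plus2"
    COISOLATION = "coisolation"
    NTERM_LOSS = "nterm_loss"
    UNMATCHABLE = "unmatchable"


@dataclass(frozen=True)
class GroundTruthRecord:
    spectrum_id: str
    true_peptide: str | None
    event: SimEvent
    true_rt: float

    def __post_init__(self):
        if self.event is SimEvent.NTERM_LOSS and (
            self.true_peptide is None or self.true_peptide[0] not in "QE"
        ):
            raise ValueError("nterm_loss requires an N-terminal Q/E peptide")
        if self.event is SimEvent.UNMATCHABLE and self.true_peptide is not None:
            raise ValueError("unmatchable spectra carry no peptide")


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    Defaults describe a desk-scale ion-trap-like dataset: a small bacterial
    proteome, 1,000 spectra with ~65% doubly charged precursors, a 0.05 Da
    precursor error sd, 15%/5% +1/+2 isotope misassignment, 10% co-isolation
    within a +-2.5 m/z isolation window, 30% N-terminal ammonia/water loss
    among Gln/Glu-initial peptides, and 20% unmatchable noise spectra.
    Fragment peaks are detected with probability 0.7 with log-normal
    intensities and ~15 random noise peaks per spectrum.
    """

    n_proteins: int = 50
    protein_length: int = 300
    n_spectra: int = 1000
    charge_probs: tuple = (0.10, 0.65, 0.25)
    precursor_sd: float = 0.05
    precursor_bias: float = 0.0
    p_isotope1: float = 0.15
    p_isotope2: float = 0.05
    p_coisolation: float = 0.10
    isolation_halfwidth: float = 2.5
    p_nh3_loss_event: float = 0.30
    p_unmatchable: float = 0.20
    fragment_noise_peaks: float = 15.0
    fragment_detect_prob: float = 0.7
    fragment_mz_sd: float = 0.1
    intensity_sigma: float = 0.8
    rt_noise_sd: float = 0.5
    rt_gradient_minutes: float = 60.0
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.p_isotope1,
            self.p_isotope2,
            self.p_coisolation,
            self.p_nh3_loss_event,
            self.p_unmatchable,
            self.fragment_detect_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_isotope1 + self.p_isotope2 > 1.0:
            raise ValueError("p_isotope1 + p_isotope2 must be <= 1")
        if abs(sum(self.charge_probs) - 1.0) > 1e-9:
            raise ValueError("charge_probs must sum to 1")


class EmptyPeptidePoolError(RuntimeError):
    """The proteome yields no digestible peptides."""


# residue sampling frequencies: K+R at ~10% combined for realistic tryptic
# peptide lengths, the rest uniform
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_FREQS = np.array([0.05 if aa in "KR" else 0.90 / 18 for aa in _ALPHABET])
_FREQS /= _FREQS.sum()


def generate_proteome(cfg: SimConfig, rng: np.random.Generator | None = None) -> list:
    """Random protein sequences over the 20 standard residues."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    proteins = []
    for i in range(cfg.n_proteins):
        length = max(30, int(rng.poisson(cfg.protein_length)))
        seq = "".join(
            np.array(list(_ALPHABET))[
                rng.choice(len(_ALPHABET), size=length, p=_FREQS)
            ]
        )
        proteins.append(ProteinRecord(id=f"SIM_{i:04d}", sequence=seq))
    return proteins


def _plant_rt_model(rng: np.random.Generator, cfg: SimConfig) -> RTModel:
    """Planted linear composition RT model with realistic coefficient scale."""
    coef = np.empty(21)
    coef[:20] = rng.normal(1.0, 0.8, size=20)
    coef[20] = cfg.rt_gradient_minutes * 0.1  # intercept
    return RTModel(
        kind=RTKind.LINEAR_COMPOSITION,
        params=coef,
        param_count=21,
        residual_sd=cfg.rt_noise_sd,
    )


def rt_truth(planted_rt: RTModel, peptide: str) -> float:
    """Deterministic planted retention time (minutes, pre-noise)."""
    return rt_suite.predict(planted_rt, peptide)


def _fragment_peaks(
    peptide: str,
    event: SimEvent,
    rng: np.random.Generator,
    cfg: SimConfig,
    constants: MassConstants,
) -> list:
    b, y = fragment_mzs(peptide, NTermMod.NONE, constants)
    if event is SimEvent.NTERM_LOSS:
        loss = constants.ammonia if peptide[0] == "Q" else constants.water
        b = b - loss
    mzs = np.concatenate([b, y])
    detected = rng.random(len(mzs)) < cfg.fragment_detect_prob
    if not detected.any():
        detected[int(rng.integers(0, len(mzs)))] = True
    mzs = mzs[detected] + rng.normal(0.0, cfg.fragment_mz_sd, size=detected.sum())
    intensities = rng.lognormal(0.0, cfg.intensity_sigma, size=len(mzs))
    peaks = list(zip(mzs.tolist(), intensities.tolist()))
    peaks.extend(_noise_peaks(rng, cfg, rng.poisson(cfg.fragment_noise_peaks)))
    return peaks


def _noise_peaks(rng, cfg, count) -> list:
    mzs = rng.uniform(100.0, 1600.0, size=int(count))
    intensities = rng.lognormal(-0.5, cfg.intensity_sigma, size=int(count))
    return list(zip(mzs.tolist(), intensities.tolist()))


def simulate_dataset(
    proteome: list,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> tuple:
    """Simulate spectra with ground truth and a planted RT model.

    Returns ``(spectra, truth_records, planted_rt_model)``.  Planted
    peptides are drawn from the fully tryptic digest with at most one
    missed cleavage and length 6-30.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool = []
    seen = set()
    for prot in proteome:
        for pep in digest(prot, missed_max=1, fidelity=Fidelity.FULL,
                          length_bounds=(6, 30), constants=constants):
            if pep.sequence not in seen:
                seen.add(pep.sequence)
                pool.append(pep)
    if not pool:
        raise EmptyPeptidePoolError("proteome yields no digestible peptides")
    planted_rt = _plant_rt_model(rng, cfg)
    charges = np.array([1, 2, 3])
    spectra, truth = [], []
    for i in range(cfg.n_spectra):
        sid = f"scan={i:05d}"
        charge = int(rng.choice(charges, p=np.asarray(cfg.charge_probs)))
        if rng.random() < cfg.p_unmatchable:
            peaks = _noise_peaks(rng, cfg, max(5, rng.poisson(40)))
            mz = float(rng.uniform(300.0, 1300.0))
            rt = float(rng.uniform(0.0, cfg.rt_gradient_minutes))
            spectra.append(Spectrum(sid, mz, charge, rt, peaks))
            truth.append(GroundTruthRecord(sid, None, SimEvent.UNMATCHABLE, rt))
            continue
        pep = pool[int(rng.integers(0, len(pool)))]
        if pep.sequence[0] in "QE" and rng.random() < cfg.p_nh3_loss_event:
            event = SimEvent.NTERM_LOSS
        else:
            u = rng.random()
            if u < cfg.p_isotope1:
                event = SimEvent.ISOTOPE_PLUS1
            elif u < cfg.p_isotope1 + cfg.p_isotope2:
                event = SimEvent.ISOTOPE_PLUS2
            elif u < cfg.p_isotope1 + cfg.p_isotope2 + cfg.p_coisolation:
                event = SimEvent.COISOLATION
            else:
                event = SimEvent.CLEAN
        mz = (pep.mass + charge * constants.proton) / charge
        mz += rng.normal(cfg.precursor_bias, cfg.precursor_sd) / charge
        if event is SimEvent.ISOTOPE_PLUS1:
            mz += constants.isotope_spacing / charge
        elif event is SimEvent.ISOTOPE_PLUS2:
            mz += 2 * constants.isotope_spacing / charge
        elif event is SimEvent.COISOLATION:
            # the recorded precursor is the co-eluting neighbor, anywhere in
            # the isolation window around the fragmenting peptide
            mz += float(rng.uniform(-cfg.isolation_halfwidth,
                                    cfg.isolation_halfwidth))
        true_rt = rt_truth(planted_rt, pep.sequence)
        rt = true_rt + float(rng.normal(0.0, cfg.rt_noise_sd))
        peaks = _fragment_peaks(pep.sequence, event, rng, cfg, constants)
        spectra.append(Spectrum(sid, float(mz), charge, rt, peaks))
        truth.append(GroundTruthRecord(sid, pep.sequence, event, true_rt))
    return spectra, truth, planted_rt


def truth_by_id(truth: list) -> dict:
    """Index ground-truth records by spectrum id."""
    return {t.spectrum_id: t for t in truth}
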