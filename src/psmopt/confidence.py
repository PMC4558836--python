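"""Target-decoy q-values, FDR filtering and the optimization fitness.

The fitness of a parameter set is the number of accepted doubly charged
target PSMs at the q-value threshold (default 1% FDR) divided by the total
number of tandem mass spectra searched — a robust per-spectrum yield that an
optimizer can maximize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FitnessConfig:
    """Configuration of the acceptance threshold and fitness denominator."""

    total_spectra: int
    fdr_threshold: float = 0.01
    charge: int = 2

    def __post_init__(self):
        if self.total_spectra < 0:
            raise ValueError("total_spectra must be >= 0")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")


def assign_qvalues(psms: list, pseudocount: bool = False) -> list:
    """Assign target-decoy q-values in place (records are also returned).

    At each score threshold s, FDR(s) = #{decoys >= s} / max(1, #{targets
    >= s}) (optionally with a +1 pseudocount in the numerator); the q-value
    is the monotonized running minimum of FDR over decreasing score.  Decoy
    records carry the q-value of their score as well.
    """
    if not psms:
        return psms
    if not any(p.is_decoy for p in psms):
        logger.warning("no decoy PSMs present; all q-values set to 0")
        for p in psms:
            p.q_value = 0.0
        return psms
    order = sorted(range(len(psms)), key=lambda i: -psms[i].score)
    n_targets = 0
    n_decoys = 0
    fdrs = np.empty(len(psms))
    for rank, i in enumerate(order):
        if psms[i].is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        num = n_decoys + (1 if pseudocount else 0)
        fdrs[rank] = num / max(1, n_targets)
    # ties share the FDR of the last record at the same score
    scores = np.array([psms[i].score for i in order])
    for rank in range(len(order) - 2, -1, -1):
        if scores[rank] == scores[rank + 1]:
            fdrs[rank] = fdrs[rank + 1]
    qvals = np.minimum.accumulate(fdrs[::-1])[::-1]
    for rank, i in enumerate(order):
        psms[i].q_value = float(min(qvals[rank], 1.0))
    return psms


def filter_fdr(psms: list, cfg: FitnessConfig, restrict_charge: bool = False) -> list:
    """Target PSMs with q <= threshold, optionally restricted to one charge."""
    out = [
        p
        for p in psms
        if not p.is_decoy and p.q_value <= cfg.fdr_threshold
    ]
    if restrict_charge:
        out = [p for p in out if p.charge == cfg.charge]
    return out


def fitness(psms: list, cfg: FitnessConfig) -> float:
    """Accepted doubly charged target PSMs per searched spectrum, in [0, 1]."""
    if cfg.total_spectra == 0:
        raise ValueError("total_spectra must be positive for a fitness value")
    accepted = filter_fdr(psms, cfg, restrict_charge=True)
    return len(accepted) / cfg.total_spectra


@dataclass(frozen=True)
class TruthCounts:
    """Outcome of comparing PSMs against simulator ground truth."""

    n_true: int
    n_false: int

    @property
    def realized_fdr(self) -> float:
        total = self.n_true + self.n_false
        return self.n_false / total if total else 0.0


def truth_eval(psms: list, truth: dict, ignore_nterm_mod: bool = True) -> TruthCounts:
    """Count true/false PSMs against a spectrum_id -> ground-truth mapping.

    A PSM is true iff its peptide sequence equals the planted peptide of its
    spectrum; by default the pyroglutamate flag is ignored, so identifying
    the cyclized form of the planted sequence still counts as correct.
    Spectra planted without a peptide (pure noise) can only yield false PSMs.
    """
    n_true = n_false = 0
    for p in psms:
        try:
            rec = truth[p.spectrum_id]
        except KeyError:
            raise ValueError(
                f"spectrum {p.spectrum_id!r} missing from ground truth"
            ) from None
        planted = rec.true_peptide
        if planted is not None and p.peptide.sequence == planted:
            if ignore_nterm_mod or p.peptide.nterm_mod.value == "none":
                n_true += 1
            else:
                n_false += 1
        else:
            n_false += 1
    return TruthCounts(n_true=n_true, n_false=n_false)
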