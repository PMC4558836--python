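"""Retention-time models: features, fitting, selection, Z filtering."""

import numpy as np
import pytest

from psmopt.peptide_space import STANDARD_RESIDUES, PeptideEntry, peptide_mass
from psmopt.rt_suite import (
    AllInfeasibleError,
    DegenerateModelError,
    Infeasible,
    RTKind,
    RTModel,
    RTObservation,
    RTSelectionConfig,
    crossval_rmsd,
    featurize,
    fit_model,
    param_count,
    predict,
    select_rt_model,
    zscore_filter,
)
from psmopt.search_core import PSMRecord

AA = STANDARD_RESIDUES


def random_peptides(rng, n, lo=6, hi=25):
    return ["".join(rng.choice(list(AA), size=int(rng.integers(lo, hi))))
            for _ in range(n)]


def planted_linear(rng):
    coef = rng.normal(1.0, 0.5, size=21)

    def rt_of(seq):
        counts = featurize(seq, RTKind.LINEAR_COMPOSITION)
        return float(counts @ coef[:20] + coef[20])

    return coef, rt_of


class TestFeaturize:
    def test_composition_counts(self):
        v = featurize("AAK", RTKind.LINEAR_COMPOSITION)
        assert v[AA.index("A")] == 2 and v[AA.index("K")] == 1
        assert v.sum() == 3

    def test_linear_permutation_invariant(self):
        a = featurize("KAAGW", RTKind.LINEAR_COMPOSITION)
        b = featurize("WAGAK", RTKind.LINEAR_COMPOSITION)
        assert np.array_equal(a, b)

    def test_extended_sees_nterm_positions(self):
        a = featurize("KAAGW", RTKind.COEFFICIENT_EXTENDED)
        b = featurize("AAKGW", RTKind.COEFFICIENT_EXTENDED)
        assert not np.array_equal(a, b)

    def test_param_counts_ordered(self):
        counts = [param_count(k) for k in
                  (RTKind.LINEAR_COMPOSITION, RTKind.COEFFICIENT_EXTENDED,
                   RTKind.ANN)]
        assert counts == [21, 43, 93]
        assert counts == sorted(counts)


class TestFitModel:
    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(0)
        coef, rt_of = planted_linear(rng)
        peps = random_peptides(rng, 200)
        model = fit_model(RTKind.LINEAR_COMPOSITION,
                          [(p, rt_of(p)) for p in peps])
        assert isinstance(model, RTModel)
        assert np.allclose(model.params, coef, atol=1e-6)
        assert model.residual_sd < 1e-6

    def test_feasibility_boundary_at_param_count(self):
        rng = np.random.default_rng(1)
        _, rt_of = planted_linear(rng)
        at_boundary = fit_model(
            RTKind.LINEAR_COMPOSITION,
            [(p, rt_of(p)) for p in random_peptides(rng, 21)],
        )
        assert isinstance(at_boundary, Infeasible)
        while True:  # full-rank 22-peptide design (almost surely immediate)
            peps = random_peptides(rng, 22)
            model = fit_model(RTKind.LINEAR_COMPOSITION,
                              [(p, rt_of(p)) for p in peps])
            if isinstance(model, RTModel):
                break
        assert model.param_count == 21

    def test_midsize_training_feasible_only_for_linear(self):
        rng = np.random.default_rng(2)
        _, rt_of = planted_linear(rng)
        train = [(p, rt_of(p)) for p in random_peptides(rng, 40)]
        assert isinstance(fit_model(RTKind.LINEAR_COMPOSITION, train), RTModel)
        assert isinstance(fit_model(RTKind.COEFFICIENT_EXTENDED, train),
                          Infeasible)
        assert isinstance(fit_model(RTKind.ANN, train), Infeasible)

    def test_rank_deficient_design_infeasible(self):
        rng = np.random.default_rng(3)
        _, rt_of = planted_linear(rng)
        peps = ["AAGK"] * 30  # one distinct composition
        assert isinstance(
            fit_model(RTKind.LINEAR_COMPOSITION, [(p, rt_of(p)) for p in peps]),
            Infeasible,
        )

    def test_noisy_recovery_low_bias(self):
        rng = np.random.default_rng(4)
        coef, rt_of = planted_linear(rng)
        peps = random_peptides(rng, 500)
        train = [(p, rt_of(p) + rng.normal(0, 0.5)) for p in peps]
        model = fit_model(RTKind.LINEAR_COMPOSITION, train)
        assert np.max(np.abs(model.params[:20] - coef[:20])) < 0.05 * 5


class TestPredict:
    def test_linearity_in_appended_residue(self):
        rng = np.random.default_rng(5)
        _, rt_of = planted_linear(rng)
        model = fit_model(RTKind.LINEAR_COMPOSITION,
                          [(p, rt_of(p)) for p in random_peptides(rng, 100)])
        base = predict(model, "AGKW")
        coefficient_w = predict(model, "AGKWW") - base
        assert coefficient_w == pytest.approx(
            model.params[AA.index("W")], abs=1e-8
        )

    def test_training_point_reproduced_noiseless(self):
        rng = np.random.default_rng(6)
        _, rt_of = planted_linear(rng)
        peps = random_peptides(rng, 80)
        model = fit_model(RTKind.LINEAR_COMPOSITION,
                          [(p, rt_of(p)) for p in peps])
        assert predict(model, peps[0]) == pytest.approx(rt_of(peps[0]),
                                                        abs=1e-6)


class TestCrossval:
    def _obs(self, rng, n, rt_of, noise=0.0):
        peps = random_peptides(rng, n)
        return [RTObservation(p, rt_of(p) + (rng.normal(0, noise) if noise
                                             else 0.0), 1.0) for p in peps]

    def test_each_peptide_validated_once(self):
        rng = np.random.default_rng(7)
        _, rt_of = planted_linear(rng)
        obs = self._obs(rng, 60, rt_of)
        cfg = RTSelectionConfig(folds=10, seed=3)
        # reconstruct folds exactly as crossval does and check the partition
        pool = [o for o in obs if o.confidence >= cfg.validation_cutoff]
        order = np.random.default_rng(cfg.seed).permutation(len(pool))
        folds = np.array_split(order, cfg.folds)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(len(pool)))

    def test_noiseless_rmsd_near_zero(self):
        rng = np.random.default_rng(8)
        _, rt_of = planted_linear(rng)
        obs = self._obs(rng, 80, rt_of)
        rmsd = crossval_rmsd(RTKind.LINEAR_COMPOSITION, obs, 0.9,
                             RTSelectionConfig(seed=1))
        assert rmsd < 1e-6

    def test_matches_hand_looped_reference(self):
        rng = np.random.default_rng(9)
        _, rt_of = planted_linear(rng)
        obs = self._obs(rng, 30, rt_of, noise=0.4)
        cfg = RTSelectionConfig(folds=10, seed=5)
        got = crossval_rmsd(RTKind.LINEAR_COMPOSITION, obs, 0.9, cfg)

        # independent loop: same partition, lstsq per fold, pooled RMSD
        order = np.random.default_rng(cfg.seed).permutation(len(obs))
        folds = np.array_split(order, cfg.folds)
        sq = []
        for fold in folds:
            held = set(fold.tolist())
            train = [obs[i] for i in range(len(obs)) if i not in held]
            X = np.array(
                [np.append(featurize(o.sequence, RTKind.LINEAR_COMPOSITION), 1)
                 for o in train]
            )
            y = np.array([o.rt for o in train])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            for i in fold:
                x = np.append(
                    featurize(obs[i].sequence, RTKind.LINEAR_COMPOSITION), 1
                )
                sq.append((obs[i].rt - x @ coef) ** 2)
        assert got == pytest.approx(float(np.sqrt(np.mean(sq))), abs=1e-9)

    def test_small_pool_infeasible_for_complex_kinds(self):
        rng = np.random.default_rng(10)
        _, rt_of = planted_linear(rng)
        obs = self._obs(rng, 30, rt_of)
        out = crossval_rmsd(RTKind.COEFFICIENT_EXTENDED, obs, 0.9,
                            RTSelectionConfig(seed=0))
        assert isinstance(out, Infeasible)


class TestSelectModel:
    def test_small_pool_selects_linear(self):
        rng = np.random.default_rng(11)
        _, rt_of = planted_linear(rng)
        obs = [RTObservation(p, rt_of(p), 1.0)
               for p in random_peptides(rng, 30)]
        kind, cutoff, table = select_rt_model(obs,
                                              cfg=RTSelectionConfig(seed=0))
        assert kind is RTKind.LINEAR_COMPOSITION
        assert not table[table["kind"] != "linear_composition"]["feasible"].any()

    def test_position_effects_favor_extended(self):
        rng = np.random.default_rng(12)
        coef, rt_of = planted_linear(rng)
        head_coef = rng.normal(0.0, 2.0, size=20)

        def rt_pos(seq):
            head = sum((3 - i) * head_coef[AA.index(a)]
                       for i, a in enumerate(seq[:3]))
            return rt_of(seq) + head

        obs = [RTObservation(p, rt_pos(p) + rng.normal(0, 0.1), 1.0)
               for p in random_peptides(rng, 1000)]
        cfg = RTSelectionConfig(seed=0)
        kind, _, table = select_rt_model(
            obs, kinds=(RTKind.LINEAR_COMPOSITION, RTKind.COEFFICIENT_EXTENDED),
            training_cutoffs=(0.9,), cfg=cfg,
        )
        assert kind is RTKind.COEFFICIENT_EXTENDED
        tab = table.set_index("kind")["rmsd"]
        assert tab["coefficient_extended"] < tab["linear_composition"]

    def test_all_infeasible_raises(self):
        obs = [RTObservation("AGKW", 5.0, 1.0)]
        with pytest.raises(AllInfeasibleError):
            select_rt_model(obs, cfg=RTSelectionConfig(seed=0))

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(13)
        _, rt_of = planted_linear(rng)
        obs = [RTObservation(p, rt_of(p) + rng.normal(0, 1.0), 1.0)
               for p in random_peptides(rng, 60)]
        kind, _, _ = select_rt_model(obs, kinds=(RTKind.LINEAR_COMPOSITION,),
                                     cfg=RTSelectionConfig(seed=0))
        assert kind is RTKind.LINEAR_COMPOSITION


def _psm_at(seq, rt):
    pep = PeptideEntry(sequence=seq, protein_ids=frozenset({"P"}), n_missed=0,
                       mass=peptide_mass(seq))
    return PSMRecord(spectrum_id=seq, peptide=pep, score=1.0, raw_delta=0.0,
                     isotope_offset=0, is_decoy=False, charge=2, rt=rt)


class TestZScoreFilter:
    def _model_and_psms(self, seed, n, noise_sd, n_outliers=0):
        rng = np.random.default_rng(seed)
        _, rt_of = planted_linear(rng)
        peps = random_peptides(rng, n)
        train = [(p, rt_of(p) + rng.normal(0, noise_sd)) for p in peps]
        model = fit_model(RTKind.LINEAR_COMPOSITION, train)
        psms = [_psm_at(p, rt) for p, rt in train]
        outliers = []
        for p in random_peptides(rng, n_outliers):
            outliers.append(_psm_at(p, rt_of(p) + 10 * noise_sd))
        return model, psms, outliers

    def test_infinite_zmax_removes_nothing(self):
        model, psms, _ = self._model_and_psms(0, 100, 0.5)
        kept, removed = zscore_filter(psms, model, zmax=np.inf)
        assert removed == [] and len(kept) == len(psms)

    def test_ten_sigma_outliers_all_removed(self):
        model, psms, outliers = self._model_and_psms(1, 200, 0.5,
                                                     n_outliers=10)
        _, removed = zscore_filter(psms + outliers, model, zmax=2.0)
        removed_ids = {p.spectrum_id for p in removed}
        assert {o.spectrum_id for o in outliers} <= removed_ids

    def test_hand_computed_removal_count(self):
        model = RTModel(kind=RTKind.LINEAR_COMPOSITION,
                        params=np.zeros(21), param_count=21, residual_sd=1.0)
        rts = [0.5, -0.5, 1.9, 2.1, -2.1, 0.0, 3.0, -1.5, 2.0, -2.0]
        psms = [_psm_at(f"AG{'K' * (i + 1)}"[:4] + "W", rt)
                for i, rt in enumerate(rts)]
        # prediction is 0 everywhere, sd 1 -> |rt| > 2 removed: 2.1, -2.1, 3.0
        _, removed = zscore_filter(psms, model, zmax=2.0)
        assert len(removed) == 3

    def test_degenerate_model_rejected(self):
        model = RTModel(kind=RTKind.LINEAR_COMPOSITION,
                        params=np.zeros(21), param_count=21, residual_sd=0.0)
        with pytest.raises(DegenerateModelError):
            zscore_filter([_psm_at("AGKW", 1.0)], model, zmax=2.0)
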