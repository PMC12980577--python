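"""Synthetic-data generator: determinism, spectra, EMG rates, cohort structure."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr

from betamod.montage import MontageError
from betamod.preprocess import process_emg
from betamod.simulate import (
    GROUPS,
    ParameterError,
    SimScenario,
    SubjectRecord,
    _background,
    cohort_frame,
    generate_cohort,
    generate_session,
    mean_subject,
)


def flat_subject(scenario, group="HC", index=0):
    """A no-dynamics subject: skips envelope calibration (fast)."""
    r = mean_subject(scenario, group, index)
    return SubjectRecord(id=r.id, index=r.index, group=r.group, features={},
                         true_beta=r.true_beta, rt_mean=r.rt_mean, no_dynamics=True)


class TestScenarioValidation:
    def test_bad_window_rejected(self):
        with pytest.raises(ParameterError):
            SimScenario(epoch_window=(-1.0, 1.0))

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ParameterError):
            SimScenario(snr=0.0)

    def test_unknown_centre_electrode_rejected(self):
        sc = SimScenario(centres={"frontal": "QQ7",
                                  "left_sensorimotor": "C4",
                                  "right_sensorimotor": "C3"})
        with pytest.raises(MontageError):
            sc.montage

    def test_default_depth_ordering(self):
        # MS-F < HC <= MS-NF for every region under defaults
        sc = SimScenario()
        for region, by_group in sc.beta_params.items():
            d = {g: p.depth_mean for g, p in by_group.items()}
            assert d["MS-F"] < d["HC"] <= d["MS-NF"]

    def test_infeasible_correlation_target_raises(self):
        sc = SimScenario(rho_targets={"FSS": (0.99, ("MS-F", "MS-NF"))})
        with pytest.raises(ParameterError, match="nearest"):
            generate_cohort(sc)


class TestSessionDeterminism:
    def test_same_seed_bit_identical(self):
        sc = SimScenario(seed=11, n_trials=6)
        r = flat_subject(sc)
        eeg1, emg1 = generate_session(sc, r)
        sc2 = SimScenario(seed=11, n_trials=6)
        eeg2, emg2 = generate_session(sc2, r)
        assert eeg1.data.tobytes() == eeg2.data.tobytes()
        assert emg1.data.tobytes() == emg2.data.tobytes()

    def test_different_seed_differs(self):
        r = flat_subject(SimScenario(seed=11, n_trials=4))
        eeg1, _ = generate_session(SimScenario(seed=11, n_trials=4), r)
        eeg2, _ = generate_session(SimScenario(seed=12, n_trials=4), r)
        assert not np.array_equal(eeg1.data, eeg2.data)

    def test_epoched_eeg_roundtrip(self, tmp_path):
        sc = SimScenario(seed=5, n_trials=3)
        eeg, _ = generate_session(sc, flat_subject(sc))
        path = tmp_path / "subject.npz"
        eeg.save(path)
        from betamod.containers import EpochedEEG
        loaded = EpochedEEG.load(path)
        assert np.array_equal(loaded.data, eeg.data)
        assert loaded.montage.labels == eeg.montage.labels
        assert loaded.fs == eeg.fs

    def test_epoch_shape_and_times(self):
        sc = SimScenario(seed=5, n_trials=3)
        eeg, emg = generate_session(sc, flat_subject(sc))
        assert eeg.data.shape == (3, 61, 512)
        assert eeg.fs == 256.0
        assert eeg.times[0] == pytest.approx(-0.5)
        assert eeg.times[-1] == pytest.approx(1.5 - 1 / 256.0)
        assert emg.data.shape[0] == 3


class TestFlatEnvelopePipeline:
    def test_no_dynamics_subject_excluded_downstream(self):
        # flat envelopes inject baseline beta but no movement-locked dip or
        # rebound: the pipeline's exclusion rule must flag the subject
        from betamod.pipeline import analyze_session
        sc = SimScenario(seed=13, n_trials=30)
        eeg, _ = generate_session(sc, flat_subject(sc))
        res = analyze_session(eeg)
        assert not res.kept
        # and the average time course shows no systematic modulation
        for m in res.metrics.values():
            assert abs(m.subject["mean_beta"]) < 0.05


class TestJointExclusion:
    def test_eeg_and_emg_trial_ids_agree_after_joint_exclusion(self):
        from betamod.pipeline import analyze_session
        sc = SimScenario(seed=14, n_trials=40)
        eeg, emg = generate_session(sc, flat_subject(sc))
        res = analyze_session(eeg, emg)
        kept = [m.trial_id for m in res.emg_metrics if m.kept]
        assert list(res.kept_trial_ids) == kept
        for m in res.metrics.values():
            assert list(m.trial_ids) == kept


class TestBackgroundSpectrum:
    def test_one_over_f_slope(self):
        sc = SimScenario(seed=2)
        rng = np.random.default_rng(0)
        x = _background(sc, 40, rng)  # (40, 61, 512)
        f, p = sps.welch(x[:, 5, :], fs=sc.fs, nperseg=512, axis=-1)
        p = p.mean(axis=0)
        band = (f >= 2.0) & (f <= 45.0)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert slope == pytest.approx(-sc.bg_slope, abs=0.3)

    def test_spatial_correlation_decays_with_distance(self):
        sc = SimScenario(seed=2)
        x = _background(sc, 30, np.random.default_rng(1))
        mont = sc.montage
        c3 = mont.index("C3")
        near = mont.index(mont.nearest_neighbours("C3", 1)[0])
        far = mont.index("O2")
        flat = x.transpose(1, 0, 2).reshape(61, -1)
        r_near = np.corrcoef(flat[c3], flat[near])[0, 1]
        r_far = np.corrcoef(flat[c3], flat[far])[0, 1]
        assert r_near > r_far
        assert r_near > 0.4


class TestEMGGeneration:
    def test_kept_fraction_matches_study_rate(self):
        # exclusion rate tuned to ~286 of 300 kept movements
        sc = SimScenario(seed=21, n_trials=300)
        _, emg = generate_session(sc, flat_subject(sc))
        metrics = process_emg(emg)
        kept = sum(m.kept for m in metrics)
        assert 270 <= kept <= 298

    def test_onsets_near_group_reaction_time(self):
        sc = SimScenario(seed=22, n_trials=60)
        r = flat_subject(sc, group="HC")
        _, emg = generate_session(sc, r)
        onsets = [m.onset for m in process_emg(emg) if m.kept]
        assert np.mean(onsets) == pytest.approx(r.rt_mean, abs=0.03)

    def test_group_rt_ordering(self):
        sc = SimScenario(seed=23, n_trials=60)
        means = {}
        for g in GROUPS:
            _, emg = generate_session(sc, flat_subject(sc, group=g, index=GROUPS.index(g)))
            means[g] = np.mean([m.onset for m in process_emg(emg) if m.kept])
        assert means["HC"] < means["MS-NF"] < means["MS-F"]


class TestCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        sc = SimScenario(seed=31, n_trials=10)
        records, factory = generate_cohort(sc)
        return sc, records, cohort_frame(records)

    def test_sizes_and_groups(self, cohort):
        sc, records, df = cohort
        assert len(records) == sum(sc.n_per_group)
        for g, n in zip(GROUPS, sc.n_per_group):
            assert (df["group"] == g).sum() == n

    def test_fss_cutoff_defines_labels(self, cohort):
        _, _, df = cohort
        pat = df[df["group"] != "HC"]
        assert ((pat["FSS"] >= 4.0) == (pat["group"] == "MS-F")).all()
        assert df["FSS"].dropna().between(1, 7).all()

    def test_hc_missing_patient_scales(self, cohort):
        _, _, df = cohort
        hc = df[df["group"] == "HC"]
        for col in ("EDSS", "mFIS_total", "MSQOL54_mh", "disease_duration"):
            assert hc[col].isna().all()
        assert hc["FSS"].notna().all()

    def test_lesion_counts_nonnegative_integers(self, cohort):
        _, _, df = cohort
        lc = df["lesion_count"].dropna()
        assert (lc >= 0).all()
        assert np.allclose(lc, np.round(lc))

    def test_determinism(self, cohort):
        sc, records, df = cohort
        sc2 = SimScenario(seed=31, n_trials=10)
        records2, _ = generate_cohort(sc2)
        df2 = cohort_frame(records2)
        assert df.equals(df2)

    def test_cohort_frame_carries_true_depths(self, cohort):
        _, records, df = cohort
        assert df.loc[0, "beta_depth_frontal"] == pytest.approx(
            records[0].true_beta["frontal"]["depth"])


class TestCorrelationTargets:
    def test_pooled_fss_depth_rho_near_target(self):
        sc = SimScenario(seed=41, n_per_group=(50, 50, 20))
        records, _ = generate_cohort(sc)
        df = cohort_frame(records)
        pat = df[df["group"] != "HC"]
        rho = spearmanr(pat["FSS"], pat["beta_depth_frontal"]).statistic
        assert -0.70 <= rho <= -0.38

    def test_pooled_icf_depth_rho_near_target(self):
        sc = SimScenario(seed=42, n_per_group=(40, 40, 40))
        records, _ = generate_cohort(sc)
        df = cohort_frame(records)
        ok = df["ICF"].notna()  # ICF carries deliberate missingness
        rho = spearmanr(df.loc[ok, "ICF"], df.loc[ok, "beta_depth_frontal"]).statistic
        assert 0.30 <= rho <= 0.68

    def test_null_correlations_stay_small(self):
        sc = SimScenario(seed=43, n_per_group=(50, 50, 0), rho_targets={})
        records, _ = generate_cohort(sc)
        df = cohort_frame(records)
        pat = df[df["group"] != "HC"]
        # remove the group-mean structure: within-group correlation only
        rhos = []
        for g in ("MS-F", "MS-NF"):
            sub = pat[pat["group"] == g]
            rhos.append(spearmanr(sub["MADRS"], sub["beta_depth_frontal"]).statistic)
        assert max(abs(r) for r in rhos) < 0.3

    def test_icf_group_difference_detectable(self):
        # Monte-Carlo power of Kruskal-Wallis on generated ICF at n=20/group
        from betamod.stats import kruskal_wallis
        base = SimScenario(seed=50, n_per_group=(20, 20, 20))
        loadings = None
        hits = 0
        n_rep = 60
        for k in range(n_rep):
            sc = SimScenario(seed=1000 + k, n_per_group=(20, 20, 20))
            if loadings is None:
                from betamod.simulate import _feature_loadings
                loadings = _feature_loadings(base)
            sc._cache["loadings"] = loadings  # reuse the solved copula loadings
            records, _ = generate_cohort(sc)
            df = cohort_frame(records)
            groups = [df.loc[df.group == g, "ICF"].dropna() for g in GROUPS]
            if kruskal_wallis(*groups).p < 0.05:
                hits += 1
        assert hits / n_rep >= 0.8
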