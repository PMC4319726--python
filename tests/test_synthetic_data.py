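import io

import numpy as np
import pytest
from scipy import stats

from snpcc import datasets
from snpcc.association import crude_or
from snpcc.data_model import make_contrast, tabulate_genotypes
from snpcc.errors import ComputationError, ValidationError
from snpcc.hwe import hwe_chisq
from snpcc.synthetic_data import (
    SimulationConfig,
    SnpSimSpec,
    expected_case_genotype_probs,
    null_dominant_pvalues,
    simulate_causal,
    simulate_marginal,
)


@pytest.fixture(scope="module")
def marginal_cfg():
    return SimulationConfig.from_margins(
        datasets.snp_defs(), datasets.genotype_counts(), datasets.covariate_margins()
    )


def _one_snp_causal(snp_defs, q=0.3, or_het=1.0, or_hom=1.0, **kwargs):
    return SimulationConfig(
        mode="causal",
        n_cases=kwargs.pop("n_cases", 500),
        n_controls=kwargs.pop("n_controls", 500),
        snps=(SnpSimSpec(snp=snp_defs["rs2294008"], q=q, or_het=or_het, or_hom=or_hom),),
        **kwargs,
    )


class TestSimulateMarginal:
    def test_exact_mode_reproduces_counts(self, marginal_cfg):
        cohort = simulate_marginal(marginal_cfg, seed=3, exact=True)
        counts = tabulate_genotypes(cohort, "rs2976392")
        assert counts.case == (319, 308, 65)
        assert counts.control == (403, 299, 72)

    def test_exact_mode_reproduces_all_margins(self, marginal_cfg):
        cohort = simulate_marginal(marginal_cfg, seed=11, exact=True)
        for snp_id, expected in datasets.genotype_counts().items():
            got = tabulate_genotypes(cohort, snp_id)
            assert got.case == expected.case, snp_id
            assert got.control == expected.control, snp_id

    def test_no_cases(self, marginal_cfg):
        cfg = SimulationConfig(
            mode="marginal", n_cases=0, n_controls=50,
            snps=marginal_cfg.snps,
            covariates_case=marginal_cfg.covariates_case,
            covariates_control=marginal_cfg.covariates_control,
        )
        cohort = simulate_marginal(cfg, seed=1)
        assert cohort.n_cases == 0 and cohort.n_controls == 50

    def test_same_seed_byte_identical(self, marginal_cfg):
        outputs = []
        for _ in range(2):
            buf = io.StringIO()
            simulate_marginal(marginal_cfg, seed=99, exact=True).write_tsv(buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_different_seed_differs(self, marginal_cfg):
        a = simulate_marginal(marginal_cfg, seed=1)
        b = simulate_marginal(marginal_cfg, seed=2)
        assert not a.df.equals(b.df)

    def test_wrong_mode(self, snp_defs):
        cfg = _one_snp_causal(snp_defs)
        with pytest.raises(ValidationError):
            simulate_marginal(cfg, seed=0)


class TestSimulateCausal:
    def test_sizes_and_truth_record(self, snp_defs):
        cfg = _one_snp_causal(snp_defs, or_het=1.3, or_hom=1.69)
        cohort, truth = simulate_causal(cfg, seed=5)
        assert cohort.n_cases == 500 and cohort.n_controls == 500
        assert truth["snps"]["rs2294008"]["or_het"] == 1.3
        assert truth["seed"] == 5

    def test_determinism(self, snp_defs):
        cfg = _one_snp_causal(snp_defs, or_het=1.3)
        a, _ = simulate_causal(cfg, seed=8)
        b, _ = simulate_causal(cfg, seed=8)
        assert a.df.equals(b.df)

    def test_unreachable_case_count(self, snp_defs):
        cfg = _one_snp_causal(
            snp_defs, n_cases=5000, n_controls=100,
            baseline_odds=1e-5, max_population=30_000,
        )
        with pytest.raises(ComputationError, match="max_population"):
            simulate_causal(cfg, seed=0)

    def test_copy_probability_one_duplicates_column(self, snp_defs):
        cfg = SimulationConfig(
            mode="causal", n_cases=200, n_controls=200,
            snps=(
                SnpSimSpec(snp=snp_defs["rs2294008"], q=0.3),
                SnpSimSpec(snp=snp_defs["rs2976392"], q=0.3),
            ),
            copy_pairs=(("rs2294008", "rs2976392", 1.0),),
        )
        cohort, _ = simulate_causal(cfg, seed=4)
        # same genotype index in every subject (labels differ per allele names)
        idx_a = cohort.df["rs2294008"].map(
            {g: i for i, g in enumerate(snp_defs["rs2294008"].genotypes)}
        )
        idx_b = cohort.df["rs2976392"].map(
            {g: i for i, g in enumerate(snp_defs["rs2976392"].genotypes)}
        )
        assert (idx_a == idx_b).all()

    def test_controls_near_hwe_for_rare_disease(self, snp_defs):
        cfg = _one_snp_causal(
            snp_defs, q=0.25, or_het=1.5, or_hom=2.25,
            n_cases=300, n_controls=3000, baseline_odds=0.01,
        )
        cohort, _ = simulate_causal(cfg, seed=21)
        counts = tabulate_genotypes(cohort, "rs2294008")
        res = hwe_chisq(counts.control)
        assert res.p > 0.001  # controls stay HWE-like when disease is rare
        assert abs(res.q - 0.25) < 0.02

    def test_truth_predicts_case_margins(self, snp_defs):
        spec = SnpSimSpec(snp=snp_defs["rs2294008"], q=0.3, or_het=1.5, or_hom=2.25)
        cfg = SimulationConfig(
            mode="causal", n_cases=4000, n_controls=100,
            snps=(spec,), baseline_odds=0.005,
        )
        cohort, _ = simulate_causal(cfg, seed=17)
        counts = tabulate_genotypes(cohort, "rs2294008")
        expected = np.array(expected_case_genotype_probs(spec)) * counts.n_cases
        chi2 = float(((np.array(counts.case) - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, 2) > 0.001  # margins agree within sampling error

    def test_hwe_p_uniform_over_seeds(self, snp_defs):
        """KS sanity check: control HWE p-values across seeds ~ Uniform."""
        pvals = []
        cfg = _one_snp_causal(
            snp_defs, q=0.3, n_cases=50, n_controls=400, baseline_odds=0.02
        )
        for seed in range(60):
            cohort, _ = simulate_causal(cfg, seed=seed)
            counts = tabulate_genotypes(cohort, "rs2294008")
            pvals.append(hwe_chisq(counts.control).p)
        # chi-square p-values are only asymptotically uniform; demand no
        # gross departure rather than exact uniformity
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestNullCalibration:
    def test_type_one_error_quick(self):
        pvals = null_dominant_pvalues(692, 774, q=0.28, n_reps=4000, seed=13)
        rate = float((pvals < 0.05).mean())
        assert abs(rate - 0.05) < 0.012, rate

    def test_matches_subject_level_simulator(self, snp_defs):
        """The vectorized null path and the causal simulator draw the same
        law: compare rejection rates at matched sizes."""
        cfg = _one_snp_causal(
            snp_defs, q=0.3, n_cases=250, n_controls=250, baseline_odds=0.05
        )
        from snpcc.association import chisq_2x2

        subject_level = []
        for seed in range(150):
            cohort, _ = simulate_causal(cfg, seed=seed)
            t = make_contrast(tabulate_genotypes(cohort, "rs2294008"), "dominant")
            subject_level.append(chisq_2x2(t).p < 0.05)
        fast = null_dominant_pvalues(250, 250, q=0.3, n_reps=4000, seed=7)
        rate_subject = np.mean(subject_level)
        rate_fast = float((fast < 0.05).mean())
        assert abs(rate_subject - rate_fast) < 0.06


class TestRecovery:
    def test_null_calibration_of_log_or(self, snp_defs):
        """No genotype effect: mean ln(OR) across replicates is ~0."""
        cfg = _one_snp_causal(snp_defs, q=0.3, n_cases=400, n_controls=400)
        log_ors = []
        for seed in range(80):
            cohort, _ = simulate_causal(cfg, seed=3000 + seed)
            t = make_contrast(tabulate_genotypes(cohort, "rs2294008"), "dominant")
            log_ors.append(crude_or(t).log_or)
        mean = np.mean(log_ors)
        se = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert abs(mean) < 3 * se, (mean, se)

    def test_dominant_or_recovery(self, snp_defs):
        """Injected dominant OR 1.5 at n = 20,000 recovered within (1.4, 1.6)
        in nearly all replicates (scaled-down replicate count)."""
        cfg = _one_snp_causal(
            snp_defs, q=0.3, or_het=1.5, or_hom=1.5,
            n_cases=10_000, n_controls=10_000, baseline_odds=0.05,
        )
        hits = 0
        n_reps = 12
        for seed in range(n_reps):
            cohort, _ = simulate_causal(cfg, seed=4000 + seed)
            t = make_contrast(tabulate_genotypes(cohort, "rs2294008"), "dominant")
            if 1.4 < crude_or(t).or_hat < 1.6:
                hits += 1
        assert hits >= n_reps - 1, hits


def test_yaml_round_trip(tmp_path, snp_defs):
    text = """\
mode: causal
n_cases: 100
n_controls: 100
baseline_odds: 0.05
snps:
  - id: rs2294008
    gene: PSCA
    alleles: C>T
    risk_genotypes: [CT, TT]
    q: 0.3
    or_het: 1.2
    or_hom: 1.4
covariate_ors:
  smoking_ever: 1.5
"""
    path = tmp_path / "sim.yaml"
    path.write_text(text)
    cfg = SimulationConfig.from_yaml(str(path))
    assert cfg.mode == "causal"
    assert cfg.snps[0].or_hom == 1.4
    cohort, truth = simulate_causal(cfg, seed=1)
    assert len(cohort) == 200


def test_yaml_unknown_key_rejected(tmp_path):
    path = tmp_path / "sim.yaml"
    path.write_text("mode: causal\nn_cases: 1\nn_controls: 1\nsnps: []\nbogus: 2\n")
    with pytest.raises(ValidationError, match="bogus"):
        SimulationConfig.from_yaml(str(path))
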