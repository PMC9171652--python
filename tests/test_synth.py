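"""Generator ground-truth round trips and the full-pipeline recovery test."""

import numpy as np
import pytest
from scipy import stats

from coccophys import (
    classify_efflux,
    classify_outward,
    compare_distributions,
    delta_h,
    drift_qc,
    growth_rate,
    h_budget_envelope,
    iv_curve,
    leak_subtract,
    ph_optimum,
    pic_quota,
    poc_quota,
    production_rates,
    relative_expression,
    volume_from_area,
)
from coccophys.synth import (
    CultureConfig,
    EphysConfig,
    MorphometryConfig,
    QPCRConfig,
    SnarfConfig,
    gen_culture,
    gen_current_family,
    gen_morphometrics,
    gen_qpcr,
    gen_snarf_traces,
)

# mode-separating threshold for the synthetic efflux subpopulations:
# responsive cells move ~300 nM of [H+], defective ones <15 nM
MODE_THRESHOLD = 50e-9


class TestDeterminism:
    def test_culture_same_seed_identical(self):
        a = gen_culture(CultureConfig(), 5)
        b = gen_culture(CultureConfig(), 5)
        assert all(x.densities == y.densities for x, y in zip(a, b))

    def test_snarf_same_seed_identical(self):
        (ta, la) = gen_snarf_traces(SnarfConfig(n_cells=5), 5)
        (tb, lb) = gen_snarf_traces(SnarfConfig(n_cells=5), 5)
        assert la == lb
        assert all(np.array_equal(x.F630, y.F630) for x, y in zip(ta, tb))

    def test_qpcr_same_seed_identical(self):
        cfg = QPCRConfig(ct_noise_sd=0.3)
        assert gen_qpcr(cfg, 2).equals(gen_qpcr(cfg, 2))


class TestCulture:
    def test_noise_free_growth_recovered_exactly(self):
        series = gen_culture(CultureConfig(mu=0.6, count_cv=0.0), 0)
        for s in series:
            assert growth_rate(s) == pytest.approx(0.6, abs=1e-12)

    def test_noisy_growth_unbiased(self):
        cfg = CultureConfig(mu=0.55, count_cv=0.05, n_replicates=100)
        mus = [growth_rate(s) for s in gen_culture(cfg, 17)]
        se = np.std(mus, ddof=1) / np.sqrt(len(mus))
        assert abs(np.mean(mus) - 0.55) < 2.0 * se + 1e-3

    def test_densities_in_window(self):
        for s in gen_culture(CultureConfig(), 3):
            assert all(100.0 <= d <= 50_000.0 for d in s.densities)


class TestMorphometrics:
    def test_zero_variance_matches_closed_form(self):
        cfg = MorphometryConfig(area_cv=0.0, length_cv=0.0, n_cells=5)
        for c in gen_morphometrics(cfg, 0):
            assert c.decalcified_area == cfg.median_area
            assert pic_quota(c.coccolith_count, c.coccolith_length) == pytest.approx(
                c.coccolith_count * 0.06 * 8.0 ** 3 * 2.7 * 12.011 / 100.087
            )

    def test_median_length_recovered(self):
        cfg = MorphometryConfig(n_cells=500)
        lengths = [c.coccolith_length for c in gen_morphometrics(cfg, 21)]
        # lognormal median CI via sign test on log scale
        assert np.median(lengths) == pytest.approx(cfg.median_length, rel=0.05)

    def test_counts_at_least_one(self):
        cfg = MorphometryConfig(mean_coccolith_count=1.0, n_cells=200)
        assert min(c.coccolith_count for c in gen_morphometrics(cfg, 2)) >= 1


class TestSnarfGenerator:
    def test_all_responsive_classified_responsive(self):
        traces, _ = gen_snarf_traces(SnarfConfig(n_cells=10, f_defective=0.0), 1)
        for tr in traces:
            assert classify_efflux(delta_h(tr), MODE_THRESHOLD) == "responsive"

    def test_half_defective_recovered_within_binomial_ci(self):
        cfg = SnarfConfig(n_cells=100, f_defective=0.5)
        traces, labels = gen_snarf_traces(cfg, 7)
        n_def = sum(
            classify_efflux(delta_h(tr), MODE_THRESHOLD) == "defective"
            for tr in traces
        )
        lo, hi = stats.binom.interval(0.95, cfg.n_cells, cfg.f_defective)
        assert lo <= n_def <= hi
        assert n_def == labels.count("defective")

    def test_imposed_terminal_drift_fails_qc(self):
        good, _ = gen_snarf_traces(SnarfConfig(n_cells=5, drift=0.0), 3)
        bad, _ = gen_snarf_traces(SnarfConfig(n_cells=5, drift=0.05), 3)
        assert all(drift_qc(tr) for tr in good)
        assert not any(drift_qc(tr) for tr in bad)


class TestEphysGenerator:
    def test_zero_conductance_is_defective(self):
        rec = gen_current_family(EphysConfig(g_out=0.0), 0)
        assert classify_outward(iv_curve(leak_subtract(rec))) == "defective"

    def test_five_pa_pf_is_responsive(self):
        # amplitude chosen so the +45 mV density is ~5 pA/pF
        cfg = EphysConfig(g_out=5.0 * 40.0 / (45.0 - (-70.0)))
        rec = gen_current_family(cfg, 0)
        assert classify_outward(iv_curve(leak_subtract(rec))) == "responsive"


class TestQpcrGenerator:
    def test_unit_fold_change_gives_unit_ratio(self):
        df = gen_qpcr(QPCRConfig(), 0)
        res = relative_expression(df, "pH8.15")
        assert np.allclose(res.ratio, 1.0)

    def test_configured_fold_change_recovered(self):
        cfg = QPCRConfig(fold_changes={("pH7.55", "HV1"): 2.0})
        res = relative_expression(gen_qpcr(cfg, 0), "pH8.15")
        got = res[(res.sample_id == "pH7.55") & (res.gene_id == "HV1")].iloc[0]
        assert got.ratio == pytest.approx(2.0, rel=1e-9)


class TestFullPipeline:
    """A synthetic acclimation experiment recovered end to end."""

    PH = (7.55, 7.85, 8.15, 8.45, 8.75)

    def test_acclimation_experiment_recovery(self):
        true_optimum = 8.32
        rng_seed = 100

        # growth response surface: concave quadratic over acclimation pH
        recovered = []
        for exp in range(3):
            mus = []
            for i, ph in enumerate(self.PH):
                mu_true = 0.6 * (1.0 - ((ph - true_optimum) / 1.6) ** 2)
                cfg = CultureConfig(mu=mu_true, count_cv=0.02, n_replicates=3)
                series = gen_culture(cfg, rng_seed + 10 * exp + i)
                mus.append(np.mean([growth_rate(s) for s in series]))
            recovered.append(mus)
        opt, se = ph_optimum(self.PH, recovered, n_experiments=3)
        assert opt == pytest.approx(true_optimum, abs=0.05)

        # quotas -> production -> budget envelope algebra is exact
        cells = gen_morphometrics(MorphometryConfig(n_cells=25), rng_seed)
        poc = np.mean([poc_quota(volume_from_area(c.decalcified_area)) for c in cells])
        pic = np.mean(
            [pic_quota(c.coccolith_count, c.coccolith_length) for c in cells]
        )
        rates = production_rates(0.55, float(poc), float(pic))
        low, high = h_budget_envelope(rates)
        assert high - low == pytest.approx(
            rates.POC_production + rates.PIC_production, abs=1e-12
        )

        # mixed subpopulations at low acclimation pH, none at control
        acid_cfg = SnarfConfig(n_cells=40, f_defective=0.5)
        ctrl_cfg = SnarfConfig(n_cells=40, f_defective=0.0)
        acid, acid_labels = gen_snarf_traces(acid_cfg, rng_seed)
        ctrl, _ = gen_snarf_traces(ctrl_cfg, rng_seed + 1)
        d_acid = [delta_h(tr) for tr in acid]
        d_ctrl = [delta_h(tr) for tr in ctrl]
        n_def = sum(classify_efflux(d, MODE_THRESHOLD) == "defective" for d in d_acid)
        lo, hi = stats.binom.interval(0.95, 40, 0.5)
        assert lo <= n_def <= hi
        _, p = compare_distributions(d_acid, d_ctrl)
        assert p < 0.05
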