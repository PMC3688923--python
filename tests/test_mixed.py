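import json
import math
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qpcrde as q
from qpcrde.data import GeneInfo
from qpcrde.mixed import ModelSpec, _ols_fit
from _oracles import anova_one_way_reml


def make_dataset(records, efficiencies):
    """records: (sample, animal, tissue, plate, gene, role, cp)"""
    obs = [
        q.CpObservation(
            sample_id=s, animal_id=a, tissue=t, plate_id=p, sex="male",
            gene=g, gene_role=r, cp_mean=cp, cp_replicates=(cp,), detectable=True,
        )
        for s, a, t, p, g, r, cp in records
    ]
    genes = {}
    for *_, g, r, _cp in records:
        genes.setdefault(g, GeneInfo(role=r, efficiency=efficiencies[g]))
    return q.Dataset(obs, genes)


class TestFoldChangeTransforms:
    def test_null_contrast_gives_unit_fc_symmetric_ci(self):
        assert q.fold_change(0.0) == 1.0
        lo, hi = q.fold_change_ci(0.0, 0.5)
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    @given(est=st.floats(-5, 5), se=st.floats(0, 2))
    @settings(max_examples=200, deadline=None)
    def test_ci_is_multiplicatively_symmetric_about_fc(self, est, se):
        fc = q.fold_change(est)
        lo, hi = q.fold_change_ci(est, se)
        assert lo <= fc <= hi
        assert lo * hi == pytest.approx(fc**2, rel=1e-9)

    @given(est=st.floats(-5, 5), se=st.floats(0.01, 2))
    @settings(max_examples=100, deadline=None)
    def test_swapping_classes_reciprocates_fc_and_ci(self, est, se):
        fc, (lo, hi) = q.fold_change(est), q.fold_change_ci(est, se)
        fc2, (lo2, hi2) = q.fold_change(-est), q.fold_change_ci(-est, se)
        assert fc2 == pytest.approx(1.0 / fc, rel=1e-9)
        assert lo2 == pytest.approx(1.0 / hi, rel=1e-9)
        assert hi2 == pytest.approx(1.0 / lo, rel=1e-9)


class TestBuildModel:
    def test_toy_design_counts(self):
        recs = []
        for a in ("a1", "a2", "a3"):
            for t in ("liver", "fat"):
                for g, r in (("T", "target"), ("R", "reference")):
                    recs.append((f"{a}:{t}", a, t, "p1", g, r, 25.0))
        ds = make_dataset(recs, {"T": 0.9, "R": 0.9})
        spec = q.build_model(ds, analysis="tissue")
        assert len(spec.cells) == 4
        assert spec.n_b_levels == 12
        assert spec.n_d_levels == 6
        assert "C(plate)" not in spec.formula  # single plate is absorbed

    def test_sex_term_present_only_when_requested(self, mimic_dataset):
        ds, _ = mimic_dataset
        spec = q.build_model(ds, genes=["LEPRa", "ACTB", "B2M"])
        assert "C(sex)" not in spec.formula
        # all-male design: even when requested, a constant sex factor drops
        spec2 = q.build_model(ds, genes=["LEPRa", "ACTB", "B2M"], include_sex=True)
        assert "C(sex)" not in spec2.formula
        cfg = q.paper_mimic_config(seed=21)
        cfg = q.SimulationConfig(
            seed=21, genes=cfg.genes, snps=cfg.snps, n_females=11, n_animals=51
        )
        ds2, truth2 = q.simulate_cp_dataset(cfg)
        spec3 = q.build_model(
            ds2, genes=["LEPRa", "ACTB", "B2M"], include_sex=True
        )
        assert "C(sex)" in spec3.formula

    def test_near_empty_homozygote_class_dropped(self):
        cfg = q.paper_mimic_config(seed=13)
        ds, _ = q.simulate_cp_dataset(cfg)
        animals = ds.animals  # 40 of them
        calls = ["GG"] * 20 + ["AG"] * 19 + ["AA"]  # single minor homozygote
        gt = q.GenotypeTable(
            animals=animals, snps=["snp"],
            calls=pd.DataFrame({"snp": calls}, index=animals, dtype=object),
        )
        with pytest.warns(UserWarning, match="dropped"):
            spec = q.build_model(
                ds, analysis="genotype", genes=["LEPRa", "ACTB", "B2M"],
                genotypes=gt, snp="snp",
            )
        classes = {c.split("|")[0] for c in spec.cells}
        assert classes == {"AG", "GG"}

    def test_flagged_cells_are_excluded_from_response(self, mimic_dataset):
        ds, _ = mimic_dataset
        spec = q.build_model(ds, genes=["LEPRb", "ACTB", "B2M"])
        leprb_cells = [c for c in spec.cells if c.endswith("|LEPRb")]
        assert leprb_cells == ["hypothalamus|LEPRb"]

    def test_unknown_snp_is_an_error(self, mimic_dataset):
        ds, truth = mimic_dataset
        with pytest.raises(ValueError, match="absent"):
            q.build_model(ds, analysis="genotype", genotypes=truth.genotypes,
                          snp="nope")


class TestFitReml:
    def test_noise_free_fit_equals_ols(self):
        cfg = q.SimulationConfig(
            seed=5,
            genes=(
                q.GeneSim("R", "reference", 0.93),
                q.GeneSim("T", "target", 0.90, levels={"liver": 1.5}),
            ),
            n_animals=10,
            tissues=("liver", "backfat"),
            n_plates=1,
            sigma2_b=0.0, sigma2_d=0.0, sigma2_e=0.0,
            plate_effect_sd=0.0, replicate_sd=0.0,
        )
        ds, _ = q.simulate_cp_dataset(cfg)
        spec = q.build_model(ds)
        fit = q.fit_reml(spec)
        ols = _ols_fit(spec)
        assert fit.fixed_estimates.to_numpy() == pytest.approx(
            ols.params.to_numpy(), abs=1e-8
        )
        assert all(v == 0.0 for v in fit.variance_components.values())

    def test_balanced_one_way_matches_anova_closed_form(self, rng):
        m, k = 12, 3
        mu, s_b, s_e = 23.0, 0.7, 0.4
        y = mu + rng.normal(0, s_b, size=(m, 1)) + rng.normal(0, s_e, size=(m, k))
        frame = pd.DataFrame(
            {
                "y": y.ravel(),
                "cell": "liver|G",
                "plate": "p1",
                "sex": "male",
                "sample": np.repeat([f"a{i}" for i in range(m)], k),
                "gene": "G",
            }
        )
        spec = ModelSpec(frame=frame, analysis="tissue", include_sex=False)
        fit = q.fit_reml(spec)
        grand, between, within = anova_one_way_reml(y)
        assert fit.fixed_estimates.iloc[0] == pytest.approx(grand, rel=1e-8)
        # closed form up to the REML optimizer's convergence tolerance
        assert fit.variance_components["sigma2_d"] == pytest.approx(between, rel=1e-4)
        assert fit.variance_components["sigma2_e"] == pytest.approx(within, rel=1e-4)
        assert fit.b_confounded  # single gene: B folds into the residual

    def test_variance_components_recovered_with_replicated_measurements(self):
        # all three components identifiable when each gene x sample is
        # measured twice; average estimates over replicates must come
        # within 3 Monte-Carlo SEs of (0.25, 0.25, 0.5)
        truth = {"sigma2_b": 0.25, "sigma2_d": 0.25, "sigma2_e": 0.5}
        n_rep = 30
        estimates = {k: [] for k in truth}
        master = np.random.default_rng(42)
        for _ in range(n_rep):
            rows = []
            for a in range(40):
                for t in ("liver", "fat"):
                    d_eff = master.normal(0, math.sqrt(truth["sigma2_d"]))
                    for g in ("R1", "R2", "T"):
                        b_eff = master.normal(0, math.sqrt(truth["sigma2_b"]))
                        for rep in range(2):
                            rows.append(
                                {
                                    "y": 24.0 + d_eff + b_eff
                                    + master.normal(0, math.sqrt(truth["sigma2_e"])),
                                    "cell": f"{t}|{g}",
                                    "plate": f"p{rep}",
                                    "sex": "male",
                                    "sample": f"a{a}|{t}",
                                    "gene": g,
                                }
                            )
            spec = ModelSpec(
                frame=pd.DataFrame(rows), analysis="tissue", include_sex=False
            )
            fit = q.fit_reml(spec)
            assert not fit.b_confounded
            for key in truth:
                estimates[key].append(fit.variance_components[key])
        for key, val in truth.items():
            arr = np.asarray(estimates[key])
            mc_se = arr.std(ddof=1) / math.sqrt(n_rep)
            assert abs(arr.mean() - val) < 3 * mc_se + 1e-9, (
                key, arr.mean(), mc_se
            )

    def test_matches_lme4_reml_on_shared_dataset(self, tmp_path):
        rng = np.random.default_rng(314)
        rows = []
        for a in range(20):
            for t in ("liver", "fat"):
                d_eff = rng.normal(0, 0.5)
                for g in ("R1", "R2", "T"):
                    b_eff = rng.normal(0, 0.5)
                    for rep in range(2):
                        rows.append(
                            {
                                "y": 24.0 + (1.2 if (t, g) == ("liver", "T") else 0.0)
                                + d_eff + b_eff + rng.normal(0, 0.7),
                                "cell": f"{t}.{g}",
                                "plate": f"p{(a + rep) % 4}",
                                "sex": "male",
                                "sample": f"a{a}.{t}",
                                "gene": g,
                            }
                        )
        frame = pd.DataFrame(rows)
        spec = ModelSpec(frame=frame, analysis="tissue", include_sex=False)
        fit = q.fit_reml(spec)

        csv = tmp_path / "d.csv"
        frame.to_csv(csv, index=False)
        out = tmp_path / "lme4.json"
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
m <- lmer(y ~ 0 + cell + plate + (1 | sample) + (1 | sample:gene),
          data = d, REML = TRUE,
          control = lmerControl(optCtrl = list(xtol_abs = 1e-12, ftol_abs = 1e-12)))
fe <- fixef(m)
vc <- as.data.frame(VarCorr(m))
vcomp <- setNames(as.list(vc$vcov), vc$grp)
res <- list(
  cells = as.list(fe[grepl("^cell", names(fe))]),
  vcomp = vcomp
)
write(toJSON(res, digits = 12, auto_unbox = TRUE), "{out}")
"""
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        ref = json.loads(out.read_text())
        for rname, val in ref["cells"].items():
            cell = rname[len("cell"):]
            ours = fit.fixed_estimates[f"C(cell)[{cell}]"]
            assert ours == pytest.approx(val, abs=2e-5), cell
        vcomp = ref["vcomp"]
        sigma_b_key = next(k for k in vcomp if k not in ("sample", "Residual"))
        assert fit.variance_components["sigma2_b"] == pytest.approx(
            vcomp[sigma_b_key], rel=1e-3, abs=1e-4
        )
        assert fit.variance_components["sigma2_d"] == pytest.approx(
            vcomp["sample"], rel=1e-3, abs=1e-4
        )
        assert fit.variance_components["sigma2_e"] == pytest.approx(
            vcomp["Residual"], rel=1e-3, abs=1e-4
        )


@pytest.fixture(scope="module")
def mimic_fit():
    cfg = q.paper_mimic_config(seed=7)
    ds, _ = q.simulate_cp_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = q.build_model(ds, genes=["LEPRglobal", "ACTB", "B2M"])
        fit = q.fit_reml(spec)
    return ds, fit


class TestNormalizedContrast:
    def test_reciprocity(self, mimic_fit):
        _, fit = mimic_fit
        refs = ["ACTB", "B2M"]
        ab = q.normalized_contrast(fit, "LEPRglobal", "liver", "backfat", refs)
        ba = q.normalized_contrast(fit, "LEPRglobal", "backfat", "liver", refs)
        assert ba.estimate == pytest.approx(-ab.estimate, rel=1e-12)
        assert ba.fold_change == pytest.approx(1.0 / ab.fold_change, rel=1e-12)
        assert ba.ci_low == pytest.approx(1.0 / ab.ci_high, rel=1e-12)
        assert ba.se == pytest.approx(ab.se, rel=1e-12)
        assert abs(ba.t_stat) == pytest.approx(abs(ab.t_stat), rel=1e-12)
        assert ba.p_value == pytest.approx(ab.p_value, rel=1e-12)

    def test_self_normalization_is_exactly_zero(self, mimic_fit):
        _, fit = mimic_fit
        res = q.normalized_contrast(
            fit, "LEPRglobal", "liver", "backfat", ["LEPRglobal"]
        )
        assert res.estimate == 0.0
        assert res.fold_change == 1.0

    def test_empty_reference_list_rejected(self, mimic_fit):
        _, fit = mimic_fit
        with pytest.raises(ValueError, match="reference"):
            q.normalized_contrast(fit, "LEPRglobal", "liver", "backfat", [])

    def test_flagged_cell_raises_contrast_error(self, mimic_dataset):
        ds, _ = mimic_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = q.build_model(ds, genes=["LEPRb", "ACTB", "B2M"])
            fit = q.fit_reml(spec)
        with pytest.raises(q.ContrastError, match="not estimated"):
            q.normalized_contrast(fit, "LEPRb", "liver", "hypothalamus",
                                  ["ACTB", "B2M"])

    def test_shifting_a_reference_gene_leaves_contrasts_unchanged(self):
        cfg = q.paper_mimic_config(seed=31)
        ds, _ = q.simulate_cp_dataset(cfg)
        refs = ["ACTB", "B2M"]

        def contrast(dataset):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = q.build_model(dataset, genes=["LEPRglobal", *refs])
                return q.normalized_contrast(
                    q.fit_reml(spec), "LEPRglobal", "liver", "backfat", refs
                )

        base = contrast(ds)
        # add a constant to all transformed Cp of ACTB via the Cp scale
        delta_cp = 2.0 / math.log2(1.0 + ds.efficiency_of("ACTB"))
        shifted_obs = [
            o if o.gene != "ACTB" else q.CpObservation(
                sample_id=o.sample_id, animal_id=o.animal_id, tissue=o.tissue,
                plate_id=o.plate_id, sex=o.sex, gene=o.gene, gene_role=o.gene_role,
                cp_mean=o.cp_mean + delta_cp,
                cp_replicates=tuple(c + delta_cp for c in o.cp_replicates),
                detectable=o.detectable,
            )
            for o in ds.observations
        ]
        shifted = q.Dataset(shifted_obs, ds.genes)
        moved = contrast(shifted)
        assert moved.estimate == pytest.approx(base.estimate, abs=1e-6)
        assert moved.se == pytest.approx(base.se, rel=1e-4)

    def test_explicit_df_uses_t_reference(self, mimic_fit):
        _, fit = mimic_fit
        refs = ["ACTB", "B2M"]
        z = q.normalized_contrast(fit, "LEPRglobal", "diaphragm",
                                  "longissimus_dorsi", refs)
        t = q.normalized_contrast(fit, "LEPRglobal", "diaphragm",
                                  "longissimus_dorsi", refs, df=30)
        assert t.p_value > z.p_value  # heavier tails
        assert t.ci_high - t.ci_low > z.ci_high - z.ci_low


class TestProfiles:
    def test_tissue_profile_orients_fold_changes_upward(self, mimic_fit):
        ds, fit = mimic_fit
        results = q.run_tissue_profile(ds, "LEPRglobal", ["ACTB", "B2M"], fit=fit)
        assert len(results) == 10  # C(5, 2)
        assert all(r.fold_change >= 1.0 for r in results)

    def test_planted_tissue_ordering_recovered(self, mimic_fit):
        ds, fit = mimic_fit
        results = q.run_tissue_profile(ds, "LEPRglobal", ["ACTB", "B2M"], fit=fit)
        liver_vs_backfat = next(
            r for r in results if {r.class_a, r.class_b} == {"liver", "backfat"}
        )
        # planted log2 excess of 4 in liver over backfat
        assert liver_vs_backfat.class_a == "liver"
        assert 8.0 < liver_vs_backfat.fold_change < 32.0

    def test_bh_adjustment_never_decreases_p(self, mimic_fit):
        ds, fit = mimic_fit
        raw = q.run_tissue_profile(ds, "LEPRglobal", ["ACTB", "B2M"], fit=fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = q.run_tissue_profile(ds, "LEPRglobal", ["ACTB", "B2M"], bh=True)
        for r_raw, r_adj in zip(raw, adj):
            assert r_adj.p_value >= r_raw.p_value - 1e-12

    def test_genotype_profile_reports_only_surviving_pair(self, mimic_dataset):
        ds, truth = mimic_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = q.run_genotype_profile(
                ds, truth.genotypes, "LEPR35856G.A", "LEPRa",
                ["ACTB", "B2M"], "liver",
            )
        assert [f"{r.class_a}-{r.class_b}" for r in results] == ["AG-GG"]
        tc = truth.true_contrast("LEPRa", "AG", "GG", tissue="liver",
                                 snp="LEPR35856G.A")
        assert results[0].estimate == pytest.approx(tc["estimate"], abs=1.0)

    def test_planted_additive_allele_effect_recovered(self):
        genes = (
            q.GeneSim("R1", "reference", 0.93),
            q.GeneSim("R2", "reference", 0.80),
            q.GeneSim("T", "target", 0.90),
        )
        snps = (q.SnpSim(("snp1",), maf=0.45, alleles=("T", "C"),
                         effects={("T", "liver"): 1.0}),)
        cfg = q.SimulationConfig(seed=77, genes=genes, snps=snps,
                                 tissues=("liver", "fat"))
        ests = {"CC-TT": [], "CT-TT": []}
        for seed in range(8):
            ds, truth = q.simulate_cp_dataset(cfg, seed=1000 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = q.run_genotype_profile(
                    ds, truth.genotypes, "snp1", "T", ["R1", "R2"], "liver"
                )
            for r in results:
                key = f"{r.class_a}-{r.class_b}"
                if key in ests:
                    ests[key].append(r.estimate)
        assert np.mean(ests["CC-TT"]) == pytest.approx(-2.0, abs=0.35)
        assert np.mean(ests["CT-TT"]) == pytest.approx(-1.0, abs=0.35)
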