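import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from triomix.expression import (
    DispersionEstimates,
    compute_fpkm,
    estimate_dispersion,
    tmm_factors,
)
from triomix.expression import test_de as run_de_test
from triomix.io import SampleSheet

from conftest import make_sheet, null_config, small_config


def zero_dispersion(counts) -> DispersionEstimates:
    zeros = pd.Series(0.0, index=counts.index)
    return DispersionEstimates(common=0.0, genewise=zeros, shrunk=zeros)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        norm = tmm_factors(counts)
        np.testing.assert_allclose(norm.factors, 1.0)

    def test_global_doubling_absorbed_by_library_size(self):
        # all M-values are zero, so the trimmed mean is zero and factors stay 1
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, size=300)
        counts = pd.DataFrame({"A": a, "B": 2 * a, "C": a})
        norm = tmm_factors(counts)
        np.testing.assert_allclose(norm.factors, 1.0, atol=1e-12)
        assert norm.effective_lib_sizes["B"] == 2 * norm.effective_lib_sizes["A"]

    def test_geometric_mean_is_one(self, cohort):
        norm = tmm_factors(cohort.counts)
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0)
        assert (norm.factors > 0).all()

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


class TestDispersion:
    def test_poisson_counts_recover_zero(self):
        from triomix import generate_cohort

        c = generate_cohort(null_config(n_genes=800, n_probes=10, nb_dispersion=0.0,
                                        n_dmrs=0, n_concordant=0, seed=7))
        disp = estimate_dispersion(c.counts, c.sheet, tmm_factors(c.counts))
        assert disp.genewise.median() <= 0.05
        assert disp.common <= 0.02

    def test_nb_dispersion_recovered_within_band(self):
        from triomix import generate_cohort

        c = generate_cohort(null_config(n_genes=2000, n_probes=10, nb_dispersion=0.4,
                                        n_dmrs=0, n_concordant=0, seed=8))
        disp = estimate_dispersion(c.counts, c.sheet, tmm_factors(c.counts))
        assert 0.25 <= disp.common <= 0.6

    def test_floor_at_zero(self, cohort):
        disp = estimate_dispersion(cohort.counts, cohort.sheet, tmm_factors(cohort.counts))
        assert (disp.genewise >= 0).all()
        assert (disp.shrunk >= 0).all()


class TestDeTest:
    def test_null_gene_has_zero_lfc_and_p_near_one(self):
        # identical counts for degraded and intact in every patient
        rng = np.random.default_rng(3)
        base = rng.integers(50, 500, size=(50, 6))
        sheet = make_sheet(6)
        cols = {}
        for j, pid in enumerate(sheet.pairs()["patient_id"]):
            cols[f"{pid}_I"] = base[:, j]
            cols[f"{pid}_D"] = base[:, j]
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])[sheet.sample_ids]
        de = run_de_test(counts, sheet, disp=zero_dispersion(counts))
        assert np.allclose(de["effect"], 0.0, atol=1e-8)
        assert (de["p"] > 0.99).all()

    def test_poisson_limit_matches_statsmodels_glm(self, cohort):
        """phi = 0 reduces the fit to paired Poisson regression; the LRT
        p-values must match an independent GLM implementation."""
        import statsmodels.api as sm

        counts = cohort.counts.iloc[:8]
        norm = tmm_factors(cohort.counts)
        de = run_de_test(counts, cohort.sheet, norm=norm, disp=zero_dispersion(counts))
        meta = cohort.sheet.table.set_index("sample_id").loc[counts.columns]
        patients = pd.get_dummies(meta["patient_id"], drop_first=True, dtype=float)
        status = (meta["status"] == "degraded").astype(float).rename("status")
        X1 = sm.add_constant(pd.concat([patients, status], axis=1))
        X0 = sm.add_constant(patients)
        offset = np.log(norm.effective_lib_sizes.loc[counts.columns].to_numpy())
        for gene in counts.index:
            y = counts.loc[gene].to_numpy()
            f1 = sm.GLM(y, X1, family=sm.families.Poisson(), offset=offset).fit()
            f0 = sm.GLM(y, X0, family=sm.families.Poisson(), offset=offset).fit()
            lrt = 2 * (f1.llf - f0.llf)
            p_ref = sps.chi2.sf(max(lrt, 0.0), df=1)
            assert de.loc[gene, "p"] == pytest.approx(p_ref, abs=1e-4)
            assert de.loc[gene, "effect"] == pytest.approx(
                f1.params["status"] / np.log(2), abs=1e-4
            )

    def test_direction_symmetry_under_label_swap(self, cohort):
        counts = cohort.counts.iloc[:200]
        swapped = cohort.sheet.table.copy()
        swapped["status"] = swapped["status"].map(
            {"intact": "degraded", "degraded": "intact"}
        )
        sheet_sw = SampleSheet(swapped)
        norm = tmm_factors(counts)
        disp = estimate_dispersion(counts, cohort.sheet, norm)
        de = run_de_test(counts, cohort.sheet, norm=norm, disp=disp)
        de_sw = run_de_test(counts, sheet_sw, norm=norm, disp=disp)
        ok = de["converged"] & de_sw["converged"]
        np.testing.assert_allclose(de.loc[ok, "effect"], -de_sw.loc[ok, "effect"],
                                   rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(de.loc[ok, "p"], de_sw.loc[ok, "p"],
                                   rtol=1e-3, atol=1e-8)

    def test_up_down_partition_sums_to_total(self, cohort):
        de = run_de_test(cohort.counts, cohort.sheet)
        sig = de[de["significant"]]
        n_up = (sig["direction"] == "up").sum()
        n_down = (sig["direction"] == "down").sum()
        assert n_up + n_down == len(sig)

    def test_truth_recovery_with_correct_signs(self, cohort):
        de = run_de_test(cohort.counts, cohort.sheet)
        truth = cohort.truth.de_genes
        called = set(de.index[de["significant"]])
        recall = len(called & set(truth)) / len(truth)
        fdr = len(called - set(truth)) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr <= 0.1
        for g in called & set(truth):
            assert np.sign(de.loc[g, "effect"]) == np.sign(truth[g])


class TestFpkm:
    @staticmethod
    def _gene_models(lengths):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(lengths)) * 10_000,
                "end": np.arange(len(lengths)) * 10_000 + lengths,
                "gene_id": [f"g{i}" for i in range(len(lengths))],
                "score": 0,
                "strand": "+",
                "length": lengths,
            }
        )

    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10, 10**6 - 10]}, index=["g0", "g1"])
        gm = self._gene_models(np.array([1000, 1000]))
        fpkm = compute_fpkm(counts, gm)
        assert fpkm.loc["g0", "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g0", "g1"])
        fpkm = compute_fpkm(counts, self._gene_models(np.array([1000, 500])))
        assert fpkm.loc["g0", "s1"] == 0.0

    def test_doubling_length_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [40, 60]}, index=["g0", "g1"])
        a = compute_fpkm(counts, self._gene_models(np.array([1000, 500])))
        b = compute_fpkm(counts, self._gene_models(np.array([2000, 500])))
        assert b.loc["g0", "s1"] == pytest.approx(a.loc["g0", "s1"] / 2)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="zero total count"):
            compute_fpkm(counts, self._gene_models(np.array([1000, 500])))
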