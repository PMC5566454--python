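import numpy as np
import pandas as pd
import pytest

from triomix.methylation import call_dmrs, map_dmrs_to_genes, promoter_analysis
from triomix.methylation import test_probes as run_probe_test

from conftest import paired_matrix


def dmr_oracle(sig, pos, min_sig=3, max_nonsig=3, max_gap=1000, mode="total"):
    """Exhaustive contiguous-window enumeration with greedy
    (start asc, end desc) non-overlapping selection."""
    n = len(sig)
    windows = []
    for i in range(n):
        if not sig[i]:
            continue
        for j in range(i, n):
            if not sig[j]:
                continue
            w = sig[i : j + 1]
            n_sig = int(np.sum(w))
            if n_sig < min_sig:
                continue
            if any(pos[k + 1] - pos[k] > max_gap for k in range(i, j)):
                continue
            if mode == "total":
                if (j - i + 1) - n_sig > max_nonsig:
                    continue
            else:
                run = best = 0
                for s in w:
                    run = 0 if s else run + 1
                    best = max(best, run)
                if best > max_nonsig:
                    continue
            windows.append((i, j))
    windows.sort(key=lambda ij: (ij[0], -ij[1]))
    chosen = []
    for a, b in windows:
        if all(b < c or a > d for c, d in chosen):
            chosen.append((a, b))
    return sorted(chosen)


def make_probe_inputs(sig, pos, chrom="chr1"):
    probe_ids = [f"cg{i}" for i in range(len(sig))]
    manifest = pd.DataFrame(
        {"probe_id": probe_ids, "chrom": chrom, "pos": pos, "gene": "", "feature": "Body"}
    )
    results = pd.DataFrame(
        {
            "delta_beta": np.where(sig, 0.2, 0.0),
            "t": 0.0,
            "p": np.where(sig, 1e-6, 0.9),
            "q": np.where(sig, 1e-4, 0.95),
            "significant": np.asarray(sig, dtype=bool),
        },
        index=probe_ids,
    )
    return results, manifest


class TestProbeTest:
    def test_equals_blocked_linear_model(self, cohort):
        """The paired t-test equals the status-coefficient t-test of the
        linear model with patient indicators, on complete pairs."""
        import statsmodels.formula.api as smf

        res = run_probe_test(cohort.beta, cohort.sheet)
        meta = cohort.sheet.table.set_index("sample_id")
        for probe in cohort.beta.index[:5]:
            df = pd.DataFrame(
                {
                    "beta": cohort.beta.loc[probe, meta.index].to_numpy(),
                    "patient": meta["patient_id"].to_numpy(),
                    "status": (meta["status"] == "degraded").astype(float).to_numpy(),
                }
            )
            fit = smf.ols("beta ~ C(patient) + status", data=df).fit()
            assert res.loc[probe, "t"] == pytest.approx(fit.tvalues["status"], abs=1e-6)
            assert res.loc[probe, "p"] == pytest.approx(fit.pvalues["status"], abs=1e-6)
            assert res.loc[probe, "delta_beta"] == pytest.approx(
                fit.params["status"], abs=1e-9
            )

    def test_constant_probe_gets_p_one(self):
        values, sheet = paired_matrix(np.zeros((1, 4)), intact_base=0.3)
        res = run_probe_test(values, sheet)
        assert res.iloc[0]["p"] == 1.0
        assert res.iloc[0]["delta_beta"] == 0.0

    def test_two_patient_constant_shift_degenerate(self):
        # intact (0.2, 0.3), degraded (0.4, 0.5): effect 0.2 with zero
        # residual variance -> degenerate rule gives p = 1, effect kept
        values = pd.DataFrame(
            {"P001_I": [0.2], "P001_D": [0.4], "P002_I": [0.3], "P002_D": [0.5]},
            index=["cg1"],
        )
        from conftest import make_sheet

        res = run_probe_test(values, make_sheet(2))
        assert res.iloc[0]["delta_beta"] == pytest.approx(0.2)
        assert res.iloc[0]["p"] == 1.0

    def test_missing_sample_rejected(self, cohort):
        with pytest.raises(ValueError, match="absent from matrix"):
            run_probe_test(cohort.beta.drop(columns=cohort.beta.columns[0]), cohort.sheet)


class TestCallDmrs:
    def test_minimal_region_three_significant(self):
        results, manifest = make_probe_inputs([True] * 3, [0, 100, 200])
        dmrs = call_dmrs(results, manifest)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert (row["start"], row["end"]) == (0, 201)
        assert row["n_significant"] == 3 and row["n_nonsignificant"] == 0

    def test_two_significant_probes_insufficient(self):
        results, manifest = make_probe_inputs([True, True], [0, 100])
        assert len(call_dmrs(results, manifest)) == 0

    def test_gap_over_1kb_splits(self):
        results, manifest = make_probe_inputs([True] * 6, [0, 100, 200, 1500, 1600, 1700])
        dmrs = call_dmrs(results, manifest)
        assert len(dmrs) == 2
        assert list(dmrs["start"]) == [0, 1500]

    def test_endpoints_trimmed_to_significant(self):
        sig = [False, True, True, True, False]
        results, manifest = make_probe_inputs(sig, [0, 10, 20, 30, 40])
        dmrs = call_dmrs(results, manifest)
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["probe_ids"] == ["cg1", "cg2", "cg3"]

    def test_unsorted_manifest_rejected(self):
        results, manifest = make_probe_inputs([True] * 3, [200, 100, 0])
        with pytest.raises(ValueError, match="not position-sorted"):
            call_dmrs(results, manifest)

    @pytest.mark.parametrize("mode", ["total", "consecutive"])
    def test_matches_exhaustive_oracle_on_random_manifests(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 21))
            pos = np.cumsum(rng.integers(1, 1500, size=n))
            sig = rng.random(n) < 0.5
            results, manifest = make_probe_inputs(sig, pos)
            dmrs = call_dmrs(results, manifest, nonsig_mode=mode)
            got = sorted(
                (int(np.where(manifest["probe_id"] == r["probe_ids"][0])[0][0]),
                 int(np.where(manifest["probe_id"] == r["probe_ids"][-1])[0][0]))
                for _, r in dmrs.iterrows()
            )
            expected = dmr_oracle(sig, pos, mode=mode)
            assert got == expected, f"sig={sig.tolist()} pos={pos.tolist()}"

    def test_reported_regions_satisfy_type_invariants(self, cohort):
        res = run_probe_test(cohort.beta, cohort.sheet)
        dmrs = call_dmrs(res, cohort.annotation.manifest)
        pos = cohort.annotation.manifest.set_index("probe_id")["pos"]
        for _, d in dmrs.iterrows():
            assert d["n_significant"] >= 3
            assert d["n_nonsignificant"] <= 3
            member_pos = pos.loc[d["probe_ids"]].to_numpy()
            assert (np.diff(member_pos) <= 1000).all()
            assert res.loc[d["probe_ids"][0], "significant"]
            assert res.loc[d["probe_ids"][-1], "significant"]

    def test_stricter_fdr_never_adds_significant_probes(self, cohort):
        res = run_probe_test(cohort.beta, cohort.sheet)
        strict = res.copy()
        strict["significant"] = strict["q"] <= 0.01
        loose_dmrs = call_dmrs(res, cohort.annotation.manifest)
        strict_dmrs = call_dmrs(strict, cohort.annotation.manifest)
        loose_total = sum(loose_dmrs["n_significant"])
        strict_total = sum(strict_dmrs["n_significant"])
        assert strict_total <= loose_total


class TestMapDmrsToGenes:
    @staticmethod
    def _gene_models():
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [6000], "end": [9000], "gene_id": ["G1"],
             "score": [0], "strand": ["+"], "length": [3000]}
        )

    @staticmethod
    def _dmr(start, end):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": start, "end": end, "probe_ids": ["cg1"],
              "n_significant": 3, "n_nonsignificant": 0, "mean_delta_beta": 0.1,
              "genes": set()}]
        )

    def test_promoter_extension_reaches_upstream_gene(self):
        # promoter window [4500, 9000) intersects DMR [5000, 5300)
        out = map_dmrs_to_genes(self._dmr(5000, 5300), self._gene_models(), 1500)
        assert out.iloc[0]["genes"] == {"G1"}

    def test_no_extension_no_assignment(self):
        out = map_dmrs_to_genes(self._dmr(5000, 5300), self._gene_models(), 0)
        assert out.iloc[0]["genes"] == set()

    def test_gene_body_containment_independent_of_extension(self):
        out = map_dmrs_to_genes(self._dmr(7000, 7100), self._gene_models(), 0)
        assert out.iloc[0]["genes"] == {"G1"}

    def test_minus_strand_extension_goes_downstream_coordinate(self):
        gm = self._gene_models().assign(strand="-")
        # minus-strand TSS is at end; window is [6000, 10500)
        assert map_dmrs_to_genes(self._dmr(9100, 9200), gm, 1500).iloc[0]["genes"] == {"G1"}
        assert map_dmrs_to_genes(self._dmr(5000, 5300), gm, 1500).iloc[0]["genes"] == set()


class TestPromoterAnalysis:
    @staticmethod
    def _inputs(diffs):
        values, sheet = paired_matrix(np.asarray(diffs)[None, :], intact_base=0.2)
        manifest = pd.DataFrame(
            {"probe_id": ["f0"], "chrom": "chr1", "pos": [100], "gene": ["G1"],
             "feature": ["TSS200"]}
        )
        return values, manifest, sheet

    def test_worked_t_statistic(self):
        # per-patient differences (0.1, 0.2, 0.3): t = 0.2/(0.1/sqrt(3))
        values, manifest, sheet = self._inputs([0.1, 0.2, 0.3])
        table = promoter_analysis(values, manifest, sheet)
        assert table.iloc[0]["t"] == pytest.approx(3.4641016, abs=1e-6)
        assert table.iloc[0]["p"] == pytest.approx(0.074180, abs=1e-5)
        assert table.iloc[0]["effect"] == pytest.approx(0.2)

    def test_zero_differences_give_p_one(self):
        values, manifest, sheet = self._inputs([0.0, 0.0, 0.0])
        table = promoter_analysis(values, manifest, sheet)
        assert table.iloc[0]["p"] == 1.0
        assert table.iloc[0]["effect"] == 0.0

    def test_gene_without_promoter_probes_excluded(self, cohort):
        manifest = cohort.annotation.manifest.copy()
        table = promoter_analysis(cohort.beta, manifest, cohort.sheet)
        genes_with_promoters = set(
            manifest.loc[manifest["feature"].isin(["TSS200", "TSS1500"]), "gene"]
        ) - {""}
        assert set(table.index) <= genes_with_promoters

    def test_promoter_means_averaged_over_probes(self):
        # two promoter probes: per-sample promoter value is their mean
        values, sheet = paired_matrix(np.array([[0.1, 0.1], [0.3, 0.3]]), intact_base=0.2)
        manifest = pd.DataFrame(
            {"probe_id": ["f0", "f1"], "chrom": "chr1", "pos": [100, 200],
             "gene": ["G1", "G1"], "feature": ["TSS200", "TSS1500"]}
        )
        table = promoter_analysis(values, manifest, sheet)
        assert len(table) == 1
        assert table.iloc[0]["effect"] == pytest.approx(0.2)
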