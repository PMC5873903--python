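"""Ground-truth generators: determinism, conservation, stated structure."""

import numpy as np
import pandas as pd
import pytest

import tnpool as tp
from tnpool.synth import SizingError


class TestGenAnnotation:
    def test_empty_case(self):
        ann = tp.gen_annotation(n_genes=0, genome_length=1000, seed=0)
        assert ann.n_genes == 0
        assert ann.pathway_labels == {}

    def test_pathway_count_conservation(self):
        ann = tp.gen_annotation(
            n_genes=100, genome_length=300_000, pathway_sizes={"ko1": 10}, seed=1
        )
        assert int(ann.pathway_sizes()["ko1"]) == 10

    def test_same_seed_identical_tables(self):
        kw = dict(n_genes=50, genome_length=120_000, pathway_sizes={"p": 5})
        a1 = tp.gen_annotation(seed=42, **kw)
        a2 = tp.gen_annotation(seed=42, **kw)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        assert a1.pathway_labels == a2.pathway_labels

    def test_genes_do_not_overlap(self, annotation):
        g = annotation.genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()

    def test_infeasible_packing_rejected(self):
        with pytest.raises(SizingError):
            tp.gen_annotation(n_genes=100, genome_length=5_000, seed=0)

    def test_oversized_pathway_rejected(self):
        with pytest.raises(SizingError):
            tp.gen_annotation(
                n_genes=5, genome_length=50_000, pathway_sizes={"p": 10}, seed=0
            )


class TestGenLibrary:
    def test_all_genes_essential_forces_intergenic(self, annotation):
        lib = tp.gen_library(
            annotation,
            n_mutants=50,
            essential_genes=set(annotation.gene_ids),
            intergenic_fraction=1.0,
            sister_clone_rate=0.0,
            seed=2,
        )
        genes = annotation.genes
        for r in lib.records:
            _, pos, _ = r.insertion_site
            inside = (genes["start"] <= pos) & (genes["end"] >= pos)
            assert not inside.any()

    def test_no_sisters_means_unique_sites(self, library):
        sites = [r.insertion_site for r in library.records]
        assert len(set(sites)) == len(sites)

    def test_960_mutants_fill_10_plates(self, annotation):
        lib = tp.gen_library(annotation, n_mutants=960, sister_clone_rate=0.0, seed=3)
        plates = {r.plate for r in lib.records}
        assert plates == set(range(1, 11))
        from collections import Counter

        assert all(v == 96 for v in Counter(r.plate for r in lib.records).values())

    def test_record_count_conservation(self, library):
        assert len(library.records) == 180

    def test_essential_genes_never_hit(self, annotation):
        essential = set(annotation.gene_ids[:40])
        lib = tp.gen_library(
            annotation, n_mutants=400, essential_genes=essential,
            intergenic_fraction=0.0, sister_clone_rate=0.0, seed=5,
        )
        ess = annotation.genes[annotation.genes["gene_id"].isin(essential)]
        for r in lib.records:
            _, pos, _ = r.insertion_site
            assert not ((ess["start"] <= pos) & (ess["end"] >= pos)).any()

    def test_intergenic_fraction_realized(self, annotation):
        lib = tp.gen_library(
            annotation, n_mutants=2000, intergenic_fraction=0.3,
            sister_clone_rate=0.0, seed=7,
        )
        genes = annotation.genes
        n_inter = sum(
            not ((genes["start"] <= r.insertion_site[1]) & (genes["end"] >= r.insertion_site[1])).any()
            for r in lib.records
        )
        assert n_inter / len(lib.records) == pytest.approx(0.3, abs=0.04)

    def test_sisters_share_site_distinct_wells(self, annotation):
        lib = tp.gen_library(annotation, n_mutants=300, sister_clone_rate=0.2, seed=9)
        sisters = [r for r in lib.records if r.is_sister_clone]
        assert sisters
        by_site = {}
        for r in lib.records:
            by_site.setdefault(r.insertion_site, []).append((r.plate, r.well))
        for r in sisters:
            wells = by_site[r.insertion_site]
            assert len(wells) >= 2
            assert len(set(wells)) == len(wells)

    def test_unknown_essential_gene_rejected(self, annotation):
        with pytest.raises(ValueError):
            tp.gen_library(annotation, n_mutants=5, essential_genes={"nope"}, seed=0)


class TestGenPoolReads:
    def test_noiseless_pattern_equals_codeword(self, library, small_design, clean_matrix):
        cw_by_site = {
            r.insertion_site: small_design.assign(r.plate, r.well) for r in library.records
        }
        for site, row in zip(clean_matrix.sites, np.asarray(clean_matrix.counts)):
            observed = sum(1 << i for i in np.nonzero(row >= 50)[0])
            assert observed == cw_by_site[site]

    def test_sister_union_is_bitwise_or(self, annotation, small_design):
        lib = tp.gen_library(annotation, n_mutants=180, sister_clone_rate=0.25, seed=19)
        mat = tp.gen_pool_reads(
            lib, small_design, dropout_p=0.0, noise_mean=0.0, dispersion=0.0, seed=21
        )
        union_by_site: dict = {}
        for r in lib.records:
            cw = small_design.assign(r.plate, r.well)
            union_by_site[r.insertion_site] = union_by_site.get(r.insertion_site, 0) | cw
        for site, row in zip(mat.sites, np.asarray(mat.counts)):
            observed = sum(1 << i for i in np.nonzero(row >= 50)[0])
            assert observed == union_by_site[site]

    def test_determinism(self, library, small_design):
        m1 = tp.gen_pool_reads(library, small_design, seed=55)
        m2 = tp.gen_pool_reads(library, small_design, seed=55)
        assert m1.sites == m2.sites
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_well_missing_from_design_rejected(self, library):
        tiny = tp.build_design(n_plates=1, seed=0)  # library spans 2 plates
        with pytest.raises(ValueError, match="absent from design"):
            tp.gen_pool_reads(library, tiny, seed=0)


class TestGenStrainPanel:
    def test_degenerate_all_equal(self):
        panel = tp.gen_strain_panel(
            n_strains=5, n_ogs=3, sd_experiment=0, sd_strain=0, sd_residual=0, seed=0
        )
        assert panel.phenotypes["cfu_count"].nunique() == 1

    def test_effect_recovered_in_sample_means(self):
        # one OG shifting log CFU by +2; with tiny other variance the mean
        # carrier / non-carrier log-CFU difference estimates the effect
        panel = tp.gen_strain_panel(
            n_strains=200, n_ogs=2, effect_ogs={"OG_0001": 2.0},
            n_experiments=5, reps_per_cell=10,
            sd_experiment=0.01, sd_strain=0.01, sd_residual=0.01, seed=1,
        )
        logs = np.log(panel.phenotypes["cfu_count"].to_numpy())
        carrier = panel.phenotypes["strain_id"].map(panel.og_presence["OG_0001"]).to_numpy()
        diff = logs[carrier == 1].mean() - logs[carrier == 0].mean()
        assert diff == pytest.approx(2.0, abs=0.05)

    def test_study_scale_shape(self):
        panel = tp.gen_strain_panel(seed=2)
        assert panel.og_presence.shape[0] == 41
        assert len(panel.phenotypes) == 41 * 3 * 3

    def test_variance_components_recovered_coarsely(self):
        sd_e, sd_s, sd_r = 0.6, 0.9, 0.4
        panel = tp.gen_strain_panel(
            n_strains=400, n_ogs=1, n_experiments=200, reps_per_cell=4,
            sd_experiment=sd_e, sd_strain=sd_s, sd_residual=sd_r, seed=3,
        )
        df = panel.phenotypes.copy()
        df["y"] = np.log(df["cfu_count"].astype(float))
        # method-of-moments decomposition on the balanced crossed layout
        cell = df.groupby(["strain_id", "experiment_id"])["y"].mean()
        resid_var = df.groupby(["strain_id", "experiment_id"])["y"].var().mean()
        strain_var = cell.groupby("strain_id").mean().var()
        exp_var = cell.groupby("experiment_id").mean().var()
        assert np.sqrt(resid_var) == pytest.approx(sd_r, rel=0.15)
        assert np.sqrt(max(strain_var - resid_var / (200 * 4), 0)) == pytest.approx(sd_s, rel=0.2)
        assert np.sqrt(max(exp_var - resid_var / (400 * 4), 0)) == pytest.approx(sd_e, rel=0.2)

    def test_cfu_counts_rounded_nonnegative(self):
        panel = tp.gen_strain_panel(n_strains=10, n_ogs=2, baseline_log_cfu=0.5, seed=4)
        assert (panel.phenotypes["cfu_count"] >= 0).all()
        assert pd.api.types.is_integer_dtype(panel.phenotypes["cfu_count"])


class TestGenLoadTable:
    def test_degenerate_all_equal(self):
        lt = tp.gen_load_table(
            ["WT", "mut"], sd_experiment=0, sd_residual=0, seed=0
        )
        assert lt.rows["cfu_count"].nunique() == 1

    def test_cardinality(self):
        lt = tp.gen_load_table(["WT", "a", "b", "c", "d"], seed=1)
        assert len(lt.rows) == 5 * 3 * 3

    def test_negative_delta_lowers_mean(self):
        lt = tp.gen_load_table(
            ["WT", "lpxC"], {"lpxC": -2.0}, n_experiments=30, reps=30, seed=2
        )
        logs = np.log(lt.rows["cfu_count"].clip(lower=1).astype(float))
        by = logs.groupby(lt.rows["treatment_id"]).mean()
        assert by["lpxC"] < by["WT"] - 1.5

    def test_control_delta_must_be_zero(self):
        with pytest.raises(ValueError):
            tp.gen_load_table(["WT", "m"], {"WT": 1.0}, seed=0)

    def test_determinism(self):
        a = tp.gen_load_table(["WT", "m"], {"m": -1.0}, seed=5)
        b = tp.gen_load_table(["WT", "m"], {"m": -1.0}, seed=5)
        pd.testing.assert_frame_equal(a.rows, b.rows)
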