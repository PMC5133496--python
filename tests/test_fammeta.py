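"""Family-module testing, overlap matching, common sets, joint tests."""

import numpy as np
import pandas as pd
import pytest

from famnet import fammeta, lmm, netbuild, preprocess, simulate as sim
from famnet.fammeta import AssociationResult, MetaError
from famnet.netbuild import Eigengene, ModulePartition


def make_nets(partitions: dict[str, dict[str, list[str]]],
              universe: list[str]) -> fammeta.FamilyNetworkSet:
    """FamilyNetworkSet from literal module membership dicts (no eigengenes)."""
    nets = {}
    for fam, modules in partitions.items():
        labels = pd.Series(netbuild.GREY, index=pd.Index(universe, name="probe_id"))
        for mid, genes in modules.items():
            labels.loc[genes] = mid
        nets[fam] = (ModulePartition(labels), {})
    return fammeta.FamilyNetworkSet(nets)


class TestSelectTopModule:
    def res(self, unit, fam, beta, se, p):
        return AssociationResult(unit, fam, beta, se, p, 40)

    def test_unique_minimum_wins(self):
        results = [self.res("m1", "F1", 1, 1, 0.5),
                   self.res("m2", "F1", 1, 1, 0.01),
                   self.res("m1", "F2", 1, 1, 0.2)]
        assert fammeta.select_top_module(results) == ("F1", "m2")

    def test_p_tie_broken_by_larger_z(self):
        results = [self.res("weak", "F1", 1.0, 1.0, 0.04),
                   self.res("strong", "F2", 3.0, 1.0, 0.04)]
        assert fammeta.select_top_module(results) == ("F2", "strong")

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        results = [self.res(f"m{i}", f"F{i % 3}", rng.normal(), 1.0,
                            rng.uniform()) for i in range(12)]
        ref = fammeta.select_top_module(results)
        for _ in range(5):
            rng.shuffle(results)
            assert fammeta.select_top_module(results) == ref

    def test_no_usable_results_raises(self):
        with pytest.raises(MetaError):
            fammeta.select_top_module(
                [self.res("m", "F1", np.nan, 1.0, np.nan)])


class TestMatchModules:
    def test_exact_match_chooses_itself(self):
        universe = [f"g{i}" for i in range(30)]
        nets = make_nets(
            {"F1": {"a": universe[:10], "b": universe[10:25]},
             "F2": {"a": universe[5:20]}},
            universe)
        matched, ids = fammeta.match_modules_by_overlap(
            set(universe[:10]), nets)
        assert ids["F1"] == "a"
        assert matched["F1"] == set(universe[:10])

    def test_highest_raw_overlap_wins_over_jaccard(self):
        # big module shares 6 genes (low jaccard), small shares 4 (high)
        universe = [f"g{i}" for i in range(60)]
        ref = set(universe[:10])
        nets = make_nets(
            {"F1": {"big": universe[4:40], "small": universe[:4]}},
            universe)
        matched, ids = fammeta.match_modules_by_overlap(ref, nets)
        assert ids["F1"] == "big"

    def test_zero_overlap_family_maps_to_empty(self):
        universe = [f"g{i}" for i in range(20)]
        nets = make_nets({"F1": {"a": universe[10:]}}, universe)
        with pytest.warns(UserWarning, match="no module overlaps"):
            matched, ids = fammeta.match_modules_by_overlap(
                set(universe[:5]), nets)
        assert matched["F1"] == set()

    def test_empty_reference_raises(self):
        nets = make_nets({"F1": {}}, ["g0"])
        with pytest.raises(MetaError):
            fammeta.match_modules_by_overlap(set(), nets)


class TestCommonSets:
    def test_identical_modules(self):
        s = {"g1", "g2", "g3"}
        cs = fammeta.build_common_sets({"F1": set(s), "F2": set(s)})
        assert cs.intersection == s and cs.union == s

    def test_disjoint_modules_empty_intersection(self):
        with pytest.warns(UserWarning, match="empty"):
            cs = fammeta.build_common_sets(
                {"F1": {"a", "b"}, "F2": {"c"}})
        assert cs.intersection == set()
        assert cs.union == {"a", "b", "c"}

    def test_planted_shared_core_recovered(self):
        rng = np.random.default_rng(1)
        core = {f"core{i}" for i in range(62)}
        matched = {}
        for fam, extra in zip("ABCDE", (384, 632, 437, 648, 384)):
            matched[fam] = core | {f"{fam}_x{j}" for j in range(extra)}
        cs = fammeta.build_common_sets(matched)
        assert cs.intersection == core
        assert cs.intersection <= cs.union
        for m in matched.values():
            assert cs.intersection <= m <= cs.union

    def test_single_family_rejected(self):
        with pytest.raises(MetaError):
            fammeta.build_common_sets({"F1": {"a"}})


class TestFamilyEigengene:
    def _expr_by_family(self, rng, gene_ids, n_per_family=30, families=3,
                        loading=0.9):
        out = {}
        for f in range(families):
            F = rng.normal(size=n_per_family)
            rows = [loading * F + np.sqrt(1 - loading**2)
                    * rng.normal(size=n_per_family) for _ in gene_ids]
            cols = [f"F{f}-s{i}" for i in range(n_per_family)]
            out[f"F{f}"] = pd.DataFrame(rows, index=gene_ids, columns=cols)
        return out

    def test_tight_intersection_beats_diffuse_union(self):
        rng = np.random.default_rng(2)
        inter_genes = [f"c{i}" for i in range(10)]
        union_extra = [f"u{i}" for i in range(30)]
        expr = {}
        for fam, block in self._expr_by_family(rng, inter_genes).items():
            noise = pd.DataFrame(
                rng.normal(size=(30, block.shape[1])),
                index=union_extra, columns=block.columns)
            expr[fam] = pd.concat([block, noise])
        sets = fammeta.CommonSets(
            matched_modules={}, matched_ids={},
            intersection=set(inter_genes),
            union=set(inter_genes) | set(union_extra))
        e_f, chosen, varexp = fammeta.family_eigengene(expr, sets)
        assert chosen == "intersection"
        assert min(varexp.values()) > 0.5
        assert len(e_f) == 90

    def test_empty_intersection_forces_union(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        expr = self._expr_by_family(rng, genes)
        sets = fammeta.CommonSets({}, {}, set(), set(genes))
        _, chosen, _ = fammeta.family_eigengene(expr, sets)
        assert chosen == "union"

    def test_single_family_reduces_to_module_eigengene(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(6)]
        expr = self._expr_by_family(rng, genes, families=1)
        sets = fammeta.CommonSets({}, {}, set(genes), set(genes))
        e_f, chosen, varexp = fammeta.family_eigengene(expr, sets)
        direct = netbuild.module_eigengene(expr["F0"], sorted(genes))
        np.testing.assert_allclose(e_f.to_numpy(), direct.scores.to_numpy())

    def test_both_sets_empty_raises(self):
        with pytest.raises(MetaError):
            fammeta.family_eigengene({}, fammeta.CommonSets({}, {}, set(), set()))

    def test_recovers_latent_factor_per_family(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        factors = {}
        expr = {}
        for f in range(3):
            F = rng.normal(size=40)
            factors[f"F{f}"] = F
            rows = [0.9 * F + 0.3 * rng.normal(size=40) for _ in genes]
            expr[f"F{f}"] = pd.DataFrame(
                rows, index=genes,
                columns=[f"F{f}-s{i}" for i in range(40)])
        sets = fammeta.CommonSets({}, {}, set(genes), set(genes))
        e_f, chosen, _ = fammeta.family_eigengene(expr, sets)
        for fam, F in factors.items():
            scores = e_f.loc[[c for c in e_f.index if c.startswith(fam)]]
            assert abs(np.corrcoef(scores, F)[0, 1]) > 0.9


class TestJointAndFamilyTests:
    def test_single_module_single_family_output_length(
            self, five_family_ped, five_family_kinship):
        fam = five_family_ped.family_ids[0]
        members = five_family_ped.members(fam)
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=len(members)), index=members)
        eig = Eigengene(["g1", "g2"], scores, 0.7)
        labels = pd.Series(["m1", "m1"], index=pd.Index(["g1", "g2"],
                                                        name="probe_id"))
        nets = fammeta.FamilyNetworkSet(
            {fam: (ModulePartition(labels), {"m1": eig})})
        pheno = pd.DataFrame({"T": rng.normal(size=len(members))},
                             index=pd.Index(members, name="sample_id"))
        out = fammeta.test_family_modules(nets, pheno, "T",
                                          five_family_kinship)
        assert len(out) == 1
        assert out[0].family_id == fam and out[0].unit_id == "m1"

    def test_small_family_skipped_with_warning(self, trio_ped):
        K = __import__("famnet.pedkin", fromlist=["kinship_matrix"]) \
            .kinship_matrix(trio_ped)
        scores = pd.Series([0.1, -0.2, 0.3], index=["dad", "mom", "kid"])
        labels = pd.Series(["m1", "m1"],
                           index=pd.Index(["g1", "g2"], name="probe_id"))
        nets = fammeta.FamilyNetworkSet(
            {"F1": (ModulePartition(labels),
                    {"m1": Eigengene(["g1", "g2"], scores, 0.5)})})
        pheno = pd.DataFrame({"T": [1.0, 2.0, 3.0]},
                             index=pd.Index(["dad", "mom", "kid"],
                                            name="sample_id"))
        with pytest.warns(UserWarning, match="fewer than"):
            out = fammeta.test_family_modules(nets, pheno, "T", K)
        assert out == []

    def test_joint_test_detects_planted_effect(
            self, five_family_ped, five_family_kinship, genetic_chol):
        ids = five_family_ped.individual_ids
        rng = np.random.default_rng(7)
        E = pd.Series(rng.normal(size=len(ids)),
                      index=pd.Index(ids, name="sample_id"))
        y = 0.8 * E.to_numpy() + genetic_chol @ rng.normal(size=len(ids)) \
            + rng.normal(size=len(ids))
        pheno = pd.DataFrame({"T": y}, index=E.index)
        res = fammeta.test_joint(E, pheno, "T", five_family_kinship,
                                 five_family_ped)
        assert res.p < 1e-4
        assert res.beta == pytest.approx(0.8, abs=0.3)

    def test_permuting_within_family_destroys_association(
            self, five_family_ped, five_family_kinship, genetic_chol):
        ids = five_family_ped.individual_ids
        n = len(ids)
        rng = np.random.default_rng(8)
        fams = np.array([five_family_ped.family_of(i) for i in ids])
        ps = []
        for rep in range(10):
            E = rng.normal(size=n)
            y = 0.8 * E + genetic_chol @ rng.normal(size=n) \
                + rng.normal(size=n)
            perm = E.copy()
            for f in np.unique(fams):
                sel = np.flatnonzero(fams == f)
                perm[sel] = perm[rng.permutation(sel)]
            pheno = pd.DataFrame({"T": y}, index=pd.Index(ids, name="sample_id"))
            res = fammeta.test_joint(
                pd.Series(perm, index=pheno.index), pheno, "T",
                five_family_kinship, five_family_ped)
            ps.append(res.p)
        assert np.median(ps) > 0.2

    def test_misaligned_samples_raise(self, five_family_ped,
                                      five_family_kinship):
        ids = five_family_ped.individual_ids
        E = pd.Series(np.zeros(3), index=["x1", "x2", "x3"])
        pheno = pd.DataFrame({"T": np.zeros(len(ids))},
                             index=pd.Index(ids, name="sample_id"))
        with pytest.raises(MetaError, match="missing"):
            fammeta.test_joint(E, pheno, "T", five_family_kinship,
                               five_family_ped)


class TestBonferroni:
    @pytest.mark.parametrize("p,n,adj,sig", [
        (0.01, 50, 0.5, False),
        (1e-4, 45, 4.5e-3, True),
        (0.03, 1, 0.03, True),
    ])
    def test_adjustment(self, p, n, adj, sig):
        results = [AssociationResult("m", "all", 1.0, 1.0, p, 30)]
        out = fammeta.bonferroni(results, n)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(adj)
        assert bool(out.loc[0, "significant"]) is sig

    def test_invalid_denominator(self):
        with pytest.raises(MetaError):
            fammeta.bonferroni([], 0)


class TestNaivePipelines:
    def test_probe_universe_identical_across_tracks(self, planted_dataset):
        ped, expr, pheno, truth = planted_dataset
        from famnet import pedkin
        K = pedkin.kinship_matrix(ped)
        covs = pheno[["age", "sex"]].to_numpy()
        adj = preprocess.regress_out_covariates(expr, covs)
        star = lmm.decorrelate(adj, K, ped)
        pheno_adj = pheno.copy()
        pheno_adj["SBP"] = preprocess.regress_out_covariates(
            pheno["SBP"].to_numpy(), covs)
        tracks = fammeta.naive_pipelines(adj, star, pheno_adj, "SBP", K, ped)
        assert set(tracks) == {"naive", "naive-decor"}
        for part, eigs, results in tracks.values():
            assert list(part.labels.index) == list(expr.index)
            for r in results:
                assert 0 <= r.p <= 1

    def test_mismatched_matrices_rejected(self, five_family_ped,
                                          five_family_kinship):
        a = pd.DataFrame(np.zeros((3, 4)), index=list("abc"))
        b = pd.DataFrame(np.zeros((3, 4)), index=list("abd"))
        with pytest.raises(MetaError, match="share"):
            fammeta.naive_pipelines(a, b, pd.DataFrame(), "T",
                                    five_family_kinship, five_family_ped)


class TestFamilyPipeline:
    def test_end_to_end_on_planted_data(self, planted_dataset):
        ped, expr, pheno, truth = planted_dataset
        from famnet import pedkin
        K = pedkin.kinship_matrix(ped)
        covs = pheno[["age", "sex"]].to_numpy()
        adj = preprocess.regress_out_covariates(expr, covs)
        pheno_adj = pheno.copy()
        pheno_adj["SBP"] = preprocess.regress_out_covariates(
            pheno["SBP"].to_numpy(), covs)
        res = fammeta.family_pipeline(adj, ped, K, pheno_adj, "SBP",
                                      min_module_size=20)
        assert res.common_sets.intersection <= res.common_sets.union
        assert res.chosen_set in ("intersection", "union")
        assert len(res.e_f) == sum(40 for _ in range(5))
        assert 0 <= res.joint_test.p <= 1
        # every family's matched module comes from that family's partition
        for fam, mid in res.common_sets.matched_ids.items():
            if mid:
                genes = res.networks.module_genes(fam, mid)
                assert res.common_sets.matched_modules[fam] == genes
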