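"""Family-based module meta-analysis and the naïve whole-sample baselines.

The family approach builds one coexpression network per family, tests every
module eigengene against the trait inside its own family (genetic kernel
only — a family-constant environmental effect is confounded with the
intercept within a single family), selects the overall most significant
module, matches it against every other family's network by highest gene
overlap, and combines the matched modules into two candidate common sets
(intersection and union).  The candidate whose per-family eigengenes
explain more variance — judged by the worst family — defines the family
eigengene E_F, which is then tested jointly across all families with the
full genetic + shared-family + residual model.

Two naïve baselines build a single whole-sample network instead: one on the
raw expression (ignoring relatedness) and one on mixed-model-decorrelated
expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm, netbuild, preprocess
from .netbuild import GREY, Eigengene, ModulePartition
from .pedkin import KinshipMatrix, Pedigree

__all__ = [
    "MetaError",
    "AssociationResult",
    "FamilyNetworkSet",
    "CommonSets",
    "build_family_networks",
    "test_family_modules",
    "select_top_module",
    "match_modules_by_overlap",
    "build_common_sets",
    "family_eigengene",
    "test_joint",
    "naive_pipelines",
    "bonferroni",
    "family_pipeline",
    "results_frame",
]

logger = logging.getLogger(__name__)

MIN_FAMILY_SAMPLES = 10


class MetaError(ValueError):
    pass


@dataclass
class AssociationResult:
    """One eigengene- or probe-trait test: effect, SE, p, sample count."""

    unit_id: str
    family_id: str  # "all" for joint tests
    beta: float
    se: float
    p: float
    n: int
    track: str = "family"


@dataclass
class FamilyNetworkSet:
    """Per-family partitions and module eigengenes over one probe universe."""

    networks: dict[str, tuple[ModulePartition, dict[str, Eigengene]]]

    def families(self) -> list[str]:
        return list(self.networks)

    def partition(self, family_id: str) -> ModulePartition:
        return self.networks[family_id][0]

    def eigengenes(self, family_id: str) -> dict[str, Eigengene]:
        return self.networks[family_id][1]

    def module_genes(self, family_id: str, module_id: str) -> set[str]:
        return set(self.partition(family_id).genes(module_id))


@dataclass
class CommonSets:
    """Matched family modules and their intersection / union gene sets."""

    matched_modules: dict[str, set[str]]
    matched_ids: dict[str, str]
    intersection: set[str]
    union: set[str]


def build_family_networks(
    expr_by_family: dict[str, pd.DataFrame],
    gamma: float = 6.0,
    min_module_size: int = 30,
    dissimilarity: str = "tom",
    cohesion: float = 0.5,
) -> FamilyNetworkSet:
    """One signed network + module eigengenes per family data set."""
    nets = {}
    for fam, expr in expr_by_family.items():
        part = netbuild.network_modules(
            expr, gamma=gamma, min_module_size=min_module_size,
            dissimilarity=dissimilarity, cohesion=cohesion,
        )
        eigs = netbuild.module_eigengenes(expr, part)
        nets[fam] = (part, eigs)
        logger.info("family %s: %d modules", fam, part.n_modules())
    return FamilyNetworkSet(nets)


def test_family_modules(
    nets: FamilyNetworkSet,
    pheno: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
) -> list[AssociationResult]:
    """Model-per-family tests of every non-grey module eigengene.

    Within one family the trait is regressed on the module eigengene with
    a genetic (2K, restricted to the family) plus residual covariance;
    grey is never tested.  Families with fewer than 10 phenotyped samples
    are skipped with a warning.
    """
    results: list[AssociationResult] = []
    for fam in nets.families():
        eigs = nets.eigengenes(fam)
        if not eigs:
            continue
        any_eig = next(iter(eigs.values()))
        sample_ids = [s for s in any_eig.scores.index if s in pheno.index]
        if len(sample_ids) < MIN_FAMILY_SAMPLES:
            warnings.warn(f"family {fam}: fewer than {MIN_FAMILY_SAMPLES} "
                          "phenotyped samples; skipped")
            continue
        y = pheno.loc[sample_ids, trait].to_numpy(dtype=float)
        kernels = [("genetic", lmm.genetic_kernel(K, sample_ids))]
        for module_id, eig in eigs.items():
            design = np.column_stack(
                [np.ones(len(sample_ids)), eig.scores.loc[sample_ids].to_numpy()]
            )
            try:
                fit = lmm.fit_lmm(lmm.LMMSpec(y, design, kernels))
                beta, se, p = lmm.wald_test(fit, 1)
            except (lmm.LMMError, lmm.ConvergenceError) as exc:
                logger.warning("family %s module %s: fit failed (%s)",
                               fam, module_id, exc)
                continue
            results.append(AssociationResult(module_id, fam, beta, se, p,
                                             len(sample_ids)))
    return results


def select_top_module(results: list[AssociationResult]) -> tuple[str, str]:
    """The overall most significant (family, module) pair.

    Per family the smallest-p module is taken first; across families the
    smallest p wins.  Exact p ties are broken by the larger |beta|/se,
    then by lexicographic module id — the selection is independent of the
    input ordering.
    """
    usable = [r for r in results if np.isfinite(r.p)]
    if not usable:
        raise MetaError("no usable association results to select from")

    def key(r: AssociationResult):
        return (r.p, -abs(r.beta) / r.se, r.unit_id, r.family_id)

    per_family: dict[str, AssociationResult] = {}
    for r in usable:
        best = per_family.get(r.family_id)
        if best is None or key(r) < key(best):
            per_family[r.family_id] = r
    top = min(per_family.values(), key=key)
    return top.family_id, top.unit_id


def match_modules_by_overlap(
    reference: set[str],
    nets: FamilyNetworkSet,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Per family, the non-grey module sharing most genes with ``reference``.

    The overlap metric is the raw shared-gene count; ties are broken by
    higher Jaccard index, then smaller module size, then lexicographic
    module id.  A family with zero overlap everywhere maps to the empty
    set (warned) — the downstream intersection then collapses to empty.
    """
    if not reference:
        raise MetaError("reference gene set is empty")
    matched: dict[str, set[str]] = {}
    matched_ids: dict[str, str] = {}
    for fam in nets.families():
        best_key = None
        best: tuple[str, set[str]] | None = None
        for module_id in nets.partition(fam).module_ids():
            genes = nets.module_genes(fam, module_id)
            inter = len(genes & reference)
            jac = inter / len(genes | reference)
            key = (-inter, -jac, len(genes), module_id)
            if best_key is None or key < best_key:
                best_key = key
                best = (module_id, genes)
        if best is None or best_key[0] == 0:
            warnings.warn(f"family {fam}: no module overlaps the reference; "
                          "mapped to the empty set")
            matched[fam] = set()
            matched_ids[fam] = ""
        else:
            matched[fam] = best[1]
            matched_ids[fam] = best[0]
    return matched, matched_ids


def build_common_sets(
    matched: dict[str, set[str]],
    matched_ids: dict[str, str] | None = None,
) -> CommonSets:
    """Intersection and union of the matched family modules."""
    if len(matched) < 2:
        raise MetaError("need matched modules from at least 2 families")
    sets = list(matched.values())
    inter = set.intersection(*sets)
    union = set.union(*sets)
    if not inter:
        warnings.warn("intersection of matched modules is empty; "
                      "only the union set is usable")
    return CommonSets(
        matched_modules={f: set(s) for f, s in matched.items()},
        matched_ids=dict(matched_ids or {}),
        intersection=inter,
        union=union,
    )


def family_eigengene(
    expr_by_family: dict[str, pd.DataFrame],
    sets: CommonSets,
) -> tuple[pd.Series, str, dict[str, float]]:
    """The family-approach eigengene E_F over a common gene set.

    For each candidate set (intersection, union) a per-family eigengene is
    computed on that family's samples; a candidate is summarized by the
    minimum variance explained across families (a worst-family criterion)
    and the better-summarized candidate wins, the intersection on ties.
    The chosen per-family score vectors are concatenated, in family order,
    into one score per sample.

    Returns ``(E_F, chosen_set_name, per_family_variance_explained)``.
    """
    candidates: dict[str, set[str]] = {}
    if len(sets.intersection) >= 2:
        candidates["intersection"] = sets.intersection
    if len(sets.union) >= 2:
        candidates["union"] = sets.union
    if not candidates:
        raise MetaError("both common sets are empty (or below 2 genes); "
                        "cannot build a family eigengene")

    summaries: dict[str, tuple[float, dict[str, float], pd.Series]] = {}
    for name, gene_set in candidates.items():
        per_family: dict[str, float] = {}
        scores = []
        try:
            for fam, expr in expr_by_family.items():
                genes = sorted(g for g in gene_set if g in expr.index)
                eig = netbuild.module_eigengene(expr, genes)
                per_family[fam] = eig.variance_explained
                scores.append(eig.scores)
        except netbuild.NetworkError as exc:
            logger.warning("candidate %s unusable: %s", name, exc)
            continue
        summaries[name] = (min(per_family.values()), per_family,
                           pd.concat(scores))
    if not summaries:
        raise MetaError("no usable candidate common set")
    # larger worst-family variance explained wins; intersection on ties
    order = {"intersection": 0, "union": 1}
    chosen = min(summaries, key=lambda nm: (-summaries[nm][0], order[nm]))
    _, per_family, scores = summaries[chosen]
    scores.name = "E_F"
    return scores, chosen, per_family


def test_joint(
    E: pd.Series,
    pheno: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
    ped: Pedigree,
    unit_id: str = "E",
    track: str = "family",
) -> AssociationResult:
    """Joint eigengene-trait test across all families.

    Fits ``Y = mu + u + v + beta * E + e`` with the genetic (2K),
    shared-family and residual kernels over every sample carrying both a
    score and a phenotype, and Wald-tests beta.
    """
    sample_ids = [s for s in E.index if s in pheno.index]
    if len(sample_ids) != len(E):
        missing = sorted(set(E.index) - set(sample_ids))
        raise MetaError(f"eigengene samples missing from phenotypes: {missing[:5]}")
    y = pheno.loc[sample_ids, trait].to_numpy(dtype=float)
    kernels = [
        ("genetic", lmm.genetic_kernel(K, sample_ids)),
        ("family", lmm.family_block_kernel(ped, sample_ids)),
    ]
    design = np.column_stack(
        [np.ones(len(sample_ids)), E.loc[sample_ids].to_numpy(dtype=float)]
    )
    fit = lmm.fit_lmm(lmm.LMMSpec(y, design, kernels))
    beta, se, p = lmm.wald_test(fit, 1)
    return AssociationResult(unit_id, "all", beta, se, p, len(sample_ids), track)


def naive_pipelines(
    expr: pd.DataFrame,
    expr_star: pd.DataFrame,
    pheno: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
    ped: Pedigree,
    gamma: float = 6.0,
    min_module_size: int = 30,
    dissimilarity: str = "tom",
    cohesion: float = 0.5,
) -> dict[str, tuple[ModulePartition, dict[str, Eigengene], list[AssociationResult]]]:
    """The two whole-sample baselines.

    ``naive`` clusters the raw expression (family structure ignored at the
    network stage); ``naive-decor`` clusters the mixed-model-decorrelated
    expression.  Both test every module eigengene with the joint model.
    Network settings are identical across tracks.
    """
    if list(expr.index) != list(expr_star.index) or \
            list(expr.columns) != list(expr_star.columns):
        raise MetaError("raw and decorrelated matrices must share probes/samples")
    out = {}
    for track, mat in (("naive", expr), ("naive-decor", expr_star)):
        try:
            part = netbuild.network_modules(
                mat, gamma=gamma, min_module_size=min_module_size,
                dissimilarity=dissimilarity, cohesion=cohesion,
            )
            eigs = netbuild.module_eigengenes(mat, part)
            results = [
                test_joint(eig.scores, pheno, trait, K, ped,
                           unit_id=m, track=track)
                for m, eig in eigs.items()
            ]
        except (netbuild.NetworkError, lmm.LMMError) as exc:
            logger.warning("track %s failed: %s", track, exc)
            out[track] = (None, {}, [])
            continue
        out[track] = (part, eigs, results)
    return out


def bonferroni(
    results: list[AssociationResult],
    n_tests: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni adjustment: significant iff p <= alpha / n_tests."""
    if n_tests <= 0:
        raise MetaError("n_tests must be positive")
    if n_tests < len(results):
        raise MetaError("n_tests smaller than the number of results")
    df = results_frame(results)
    df["p_bonferroni"] = np.minimum(df["p"] * n_tests, 1.0)
    df["significant"] = df["p"] <= alpha / n_tests
    return df


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.track, r.family_id, r.unit_id, r.beta, r.se, r.p, r.n)
         for r in results],
        columns=["track", "family_id", "unit_id", "beta", "se", "p", "n"],
    )


@dataclass
class FamilyPipelineResult:
    """Everything the family approach produces for one trait."""

    networks: FamilyNetworkSet
    module_tests: list[AssociationResult]
    module_tests_table: pd.DataFrame
    top_family: str
    top_module: str
    common_sets: CommonSets
    e_f: pd.Series
    chosen_set: str
    variance_explained: dict[str, float]
    joint_test: AssociationResult
    field_notes: dict = field(default_factory=dict)


def family_pipeline(
    expr: pd.DataFrame,
    ped: Pedigree,
    K: KinshipMatrix,
    pheno: pd.DataFrame,
    trait: str,
    gamma: float = 6.0,
    min_module_size: int = 30,
    dissimilarity: str = "tom",
    cohesion: float = 0.5,
) -> FamilyPipelineResult:
    """End-to-end family approach for one trait.

    Split by family, build per-family networks, test modules within
    families, select the top module, match by overlap, build common sets,
    construct E_F, and test it jointly.  The per-family module tests are
    Bonferroni-adjusted over the total number of tests performed.
    """
    expr_by_family = preprocess.split_by_family(expr, ped)
    nets = build_family_networks(
        expr_by_family, gamma=gamma, min_module_size=min_module_size,
        dissimilarity=dissimilarity, cohesion=cohesion,
    )
    module_tests = test_family_modules(nets, pheno, trait, K)
    if not module_tests:
        raise MetaError("no testable family modules (all networks empty?)")
    top_family, top_module = select_top_module(module_tests)
    reference = nets.module_genes(top_family, top_module)
    matched, matched_ids = match_modules_by_overlap(reference, nets)
    sets = build_common_sets(matched, matched_ids)
    e_f, chosen, varexp = family_eigengene(expr_by_family, sets)
    joint = test_joint(e_f, pheno, trait, K, ped, unit_id=f"E_F[{chosen}]")
    table = bonferroni(module_tests, n_tests=len(module_tests))
    return FamilyPipelineResult(
        networks=nets,
        module_tests=module_tests,
        module_tests_table=table,
        top_family=top_family,
        top_module=top_module,
        common_sets=sets,
        e_f=e_f,
        chosen_set=chosen,
        variance_explained=varexp,
        joint_test=joint,
    )
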