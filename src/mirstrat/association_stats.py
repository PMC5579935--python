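"""Age-association statistics for miRNA functional profiles.

Implements the statistical battery applied to miRNA ages: Spearman rank
correlation of age against disease/target/tissue counts, per-disease age
enrichment (Mann-Whitney members vs non-members with Benjamini-Hochberg
adjustment alongside raw thresholds), MeSH-hierarchy disease collapsing,
the target-age permutation null (shuffling which target set belongs to
which miRNA), expression-breadth summarization from replicate profiles,
binary Jaccard profile similarity within/between miRNA families, the van
Elteren stratified Mann-Whitney test used for age-stratified family vs
singleton contrasts, and transcription-factor target fractions.

Tie handling is uniform: mid-ranks with tie-corrected variances.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirstrat.results import StatResult

logger = logging.getLogger(__name__)

#: Disease-term pattern for the cancer-merged reduced catalog.
CANCER_PATTERN = re.compile(
    r"carcinoma|cancer|leukemia|lymphoma|tumor|neoplasm|blastoma|sarcoma|melanoma",
    re.IGNORECASE,
)


# ---------------------------------------------------------------------------
# rank-test primitives
# ---------------------------------------------------------------------------

def _rank_sum_moments(pooled_ranks: np.ndarray, n1: int) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the group-1 rank sum."""
    n = pooled_ranks.size
    n2 = n - n1
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var = 0.0
    return mean, max(var, 0.0)


def mwu_z(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Mann-Whitney z (mid-ranks, no continuity correction).

    Zero when the variance degenerates (all observations tied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    mean, var = _rank_sum_moments(ranks, x.size)
    if var <= 0:
        return 0.0
    return (w - mean) / np.sqrt(var)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    For small tie-free samples (both groups <= 8) the exact null
    enumeration is used; otherwise the tie-corrected normal
    approximation.  The statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    if not has_ties and x.size <= 8 and y.size <= 8:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "mannwhitneyu_exact"
    else:
        z = mwu_z(x, y)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "mannwhitneyu_normal"
    return StatResult(
        method=method,
        statistic=u1,
        pvalue=min(p, 1.0),
        n=(int(x.size), int(y.size)),
        effect={"z": mwu_z(x, y)},
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Mid-rank Spearman correlation with tie-corrected t-approximation p.

    A constant input vector leaves rho undefined; the result is flagged
    (``defined=False``) rather than silently NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("input lengths differ")
    if x.size < 3:
        return StatResult(
            "spearman", float("nan"), float("nan"), int(x.size),
            defined=False, note="fewer than 3 observations",
        )
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return StatResult(
            "spearman", float("nan"), float("nan"), int(x.size),
            defined=False, note="constant input vector",
        )
    rho, p = stats.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), int(x.size), effect={"rho": float(rho)})


def stratified_mwu(
    values: Sequence[float],
    group: Sequence[bool],
    stratum: Sequence,
) -> StatResult:
    """van Elteren stratified Mann-Whitney test.

    Within each stratum containing both groups, the group-1 rank sum is
    centered at its null mean; stratum contributions are combined with
    weights 1/(n_s + 1) and standardized by the summed tie-corrected
    variances, giving a z statistic and two-sided normal p.  Strata
    missing one group are dropped (logged); with a single informative
    stratum the statistic reduces exactly to the tie-corrected
    Mann-Whitney z.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=bool)
    stratum = np.asarray(stratum)
    if not (values.size == group.size == stratum.size):
        raise ValueError("values, group and stratum must have equal length")
    num = 0.0
    var = 0.0
    n_used = 0
    n_strata = 0
    for s in pd.unique(stratum):
        mask = stratum == s
        g = group[mask]
        if g.all() or not g.any():
            logger.info("stratum %r dropped: only one group present", s)
            continue
        v = values[mask]
        ranks = stats.rankdata(v)
        n1 = int(g.sum())
        w = float(ranks[g].sum())
        mean, v_s = _rank_sum_moments(ranks, n1)
        weight = 1.0 / (v.size + 1.0)
        num += weight * (w - mean)
        var += weight**2 * v_s
        n_used += v.size
        n_strata += 1
    if n_strata == 0:
        raise ValueError("no stratum contains both groups")
    if var <= 0:
        z = 0.0
    else:
        z = num / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return StatResult(
        "van_elteren", float(z), p, n_used,
        effect={"n_strata": n_strata},
    )


# ---------------------------------------------------------------------------
# disease catalog
# ---------------------------------------------------------------------------

@dataclass
class DiseaseCatalog:
    """miRNA-disease associations with optional MeSH tree numbers.

    ``associations`` maps each disease term to the set of associated
    miRNA accessions; ``mesh`` maps a disease term to its dot-delimited
    MeSH tree numbers (a term may sit at several places in the
    hierarchy).  ``collapsed`` marks catalogs produced by a merging
    operation (cancer merge or MeSH truncation).
    """

    associations: dict = field(default_factory=dict)
    mesh: dict = field(default_factory=dict)
    collapsed: bool = False

    @property
    def diseases(self) -> list[str]:
        return sorted(self.associations)

    @property
    def mirnas(self) -> set:
        out: set = set()
        for members in self.associations.values():
            out |= members
        return out

    def mirna_counts(self, universe: Iterable[str]) -> pd.Series:
        """Per-miRNA number of associated diseases over a fixed universe.

        miRNAs with no association are included with count 0.
        """
        universe = sorted(set(universe))
        counts = pd.Series(0, index=universe, dtype=int)
        for members in self.associations.values():
            hit = counts.index.intersection(sorted(members))
            counts.loc[hit] += 1
        return counts

    def collapse_cancer(self, pattern: re.Pattern = CANCER_PATTERN) -> "DiseaseCatalog":
        """Reduced catalog with all cancer terms merged into one entry."""
        assoc: dict[str, set] = {}
        mesh: dict[str, tuple] = {}
        merged: set = set()
        for term in self.diseases:
            if pattern.search(term):
                merged |= self.associations[term]
            else:
                assoc[term] = set(self.associations[term])
                if term in self.mesh:
                    mesh[term] = tuple(self.mesh[term])
        if merged:
            assoc["cancer_merged"] = merged
        return DiseaseCatalog(assoc, mesh, collapsed=True)

    @classmethod
    def read_tsv(cls, path) -> "DiseaseCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        required = {"mirna", "disease_term"}
        if required - set(df.columns):
            raise ValueError(f"disease table missing columns: {sorted(required - set(df.columns))}")
        assoc: dict[str, set] = {}
        mesh: dict[str, tuple] = {}
        for row in df.itertuples(index=False):
            assoc.setdefault(row.disease_term, set()).add(row.mirna)
            paths = getattr(row, "mesh_tree_numbers", "")
            if paths:
                mesh[row.disease_term] = tuple(p for p in paths.split(";") if p)
        return cls(assoc, mesh)

    def write_tsv(self, path) -> None:
        rows = []
        for term in self.diseases:
            paths = ";".join(self.mesh.get(term, ()))
            for m in sorted(self.associations[term]):
                rows.append({"mirna": m, "disease_term": term, "mesh_tree_numbers": paths})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def mesh_collapse(catalog: DiseaseCatalog, level: int) -> DiseaseCatalog:
    """Merge diseases at a coarser MeSH level.

    Each disease is relabeled by its MeSH tree number truncated to
    ``level`` dot-separated components; the miRNA sets of merged
    diseases are unioned.  A disease with several tree numbers
    contributes to each truncated label.  Diseases without a MeSH path
    are kept uncollapsed under their original term (logged).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    assoc: dict[str, set] = {}
    n_missing = 0
    for term in catalog.diseases:
        paths = catalog.mesh.get(term, ())
        if not paths:
            n_missing += 1
            assoc.setdefault(term, set()).update(catalog.associations[term])
            continue
        for path in paths:
            label = ".".join(path.split(".")[:level])
            assoc.setdefault(label, set()).update(catalog.associations[term])
    if n_missing:
        logger.warning("%d diseases without MeSH paths kept uncollapsed", n_missing)
    return DiseaseCatalog(assoc, {}, collapsed=True)


def disease_count_vs_age(
    ages: pd.DataFrame,
    catalog: DiseaseCatalog,
    collapse: str = "none",
    mesh_level: int = 1,
    associated_only: bool = False,
) -> tuple[StatResult, pd.Series]:
    """Correlation of per-miRNA disease count with age.

    ``collapse`` selects the counting universe of diseases: ``"none"``,
    ``"cancer_merged"`` (all cancer terms merged to one entry), or
    ``"mesh_level_k"`` (MeSH truncation at ``mesh_level``).  All miRNAs
    in the age table are counted, with zero-association miRNAs included
    at count 0; ``associated_only`` restricts to miRNAs with at least
    one association (robustness variant).  Returns the Spearman result
    and the per-miRNA counts.
    """
    if collapse == "none":
        cat = catalog
    elif collapse == "cancer_merged":
        cat = catalog.collapse_cancer()
    elif collapse == "mesh_level_k":
        cat = mesh_collapse(catalog, mesh_level)
    else:
        raise ValueError(f"unknown collapse mode: {collapse!r}")
    age_by_acc = ages.set_index("accession")["age_my"]
    counts = cat.mirna_counts(age_by_acc.index).reindex(age_by_acc.index)
    if associated_only:
        keep = counts[counts > 0].index
        counts = counts.loc[keep]
        age_by_acc = age_by_acc.loc[keep]
    res = spearman_corr(age_by_acc.to_numpy(), counts.to_numpy())
    return res, counts


def disease_age_enrichment(
    ages: pd.DataFrame,
    catalog: DiseaseCatalog,
    alpha: float = 0.01,
    background: str = "nonmembers",
) -> pd.DataFrame:
    """Per-disease age enrichment against the miRNA background.

    For every disease, member ages are compared with the background by a
    two-sided Mann-Whitney test.  ``background="nonmembers"`` (default)
    compares members vs non-members; ``"all"`` compares members vs the
    full age set including themselves.  Diseases with fewer than two
    aged members are skipped (logged).  Output columns include the raw
    p, Benjamini-Hochberg adjusted p, direction (older/younger by median
    shift), and a boolean ``significant`` at raw p < alpha.
    """
    if background not in ("nonmembers", "all"):
        raise ValueError(f"unknown background mode: {background!r}")
    age_by_acc = ages.set_index("accession")["age_my"]
    all_ages = age_by_acc.to_numpy()
    rows = []
    for term in catalog.diseases:
        members = sorted(catalog.associations[term] & set(age_by_acc.index))
        if len(members) < 2:
            logger.info("disease %r skipped: fewer than 2 aged members", term)
            continue
        member_ages = age_by_acc.loc[members].to_numpy()
        if background == "nonmembers":
            other = age_by_acc.drop(members).to_numpy()
        else:
            other = all_ages
        if other.size == 0:
            logger.info("disease %r skipped: empty background", term)
            continue
        res = mann_whitney(member_ages, other)
        rows.append(
            {
                "disease": term,
                "n_members": len(members),
                "median_member_age": float(np.median(member_ages)),
                "median_background_age": float(np.median(other)),
                "U": res.statistic,
                "direction": "older"
                if np.median(member_ages) > np.median(other)
                else "younger",
                "p_raw": res.pvalue,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "disease", "n_members", "median_member_age", "median_background_age",
            "U", "direction", "p_raw",
        ],
    )
    if len(table):
        table["p_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
        table["significant"] = table["p_raw"] < alpha
    else:
        table["p_bh"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@dataclass
class TargetTable:
    """Validated miRNA-target interactions with gene ages and TF flags."""

    targets: dict = field(default_factory=dict)  # mirna -> set of gene ids
    gene_ages: dict = field(default_factory=dict)  # gene id -> age (MY)
    tf_flags: dict = field(default_factory=dict)  # gene id -> bool

    def target_ages(self, accession: str) -> np.ndarray:
        genes = sorted(self.targets.get(accession, ()))
        return np.array([self.gene_ages[g] for g in genes if g in self.gene_ages], dtype=float)

    def target_counts(self, universe: Iterable[str]) -> pd.Series:
        universe = sorted(set(universe))
        return pd.Series(
            [len(self.targets.get(m, ())) for m in universe], index=universe, dtype=int
        )

    @classmethod
    def read_tsv(cls, path) -> "TargetTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        required = {"mirna", "gene_id", "gene_age_my", "is_tf"}
        if required - set(df.columns):
            raise ValueError(f"target table missing columns: {sorted(required - set(df.columns))}")
        t = cls()
        for row in df.itertuples(index=False):
            t.targets.setdefault(row.mirna, set()).add(row.gene_id)
            t.gene_ages[row.gene_id] = float(row.gene_age_my)
            t.tf_flags[row.gene_id] = row.is_tf in ("1", "True", "true")
        return t

    def write_tsv(self, path) -> None:
        rows = []
        for m in sorted(self.targets):
            for g in sorted(self.targets[m]):
                rows.append(
                    {
                        "mirna": m,
                        "gene_id": g,
                        "gene_age_my": self.gene_ages.get(g, float("nan")),
                        "is_tf": int(self.tf_flags.get(g, False)),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def target_age_fraction(mirna_age: float, target_ages: Sequence[float]) -> float:
    """Fraction of targets strictly older than the miRNA.

    Ties (equal age) count as not-older.  An empty target list leaves
    the fraction undefined (raise), so callers exclude such miRNAs.
    """
    target_ages = np.asarray(target_ages, dtype=float)
    if target_ages.size == 0:
        raise ValueError("target list is empty; fraction undefined")
    return float(np.mean(target_ages > mirna_age))


def permutation_target_test(
    ages: Mapping[str, float],
    targets: TargetTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> StatResult:
    """Permutation null for the mean fraction of targets older than the miRNA.

    The observed statistic is the mean, over miRNAs with at least one
    aged target, of the fraction of their targets strictly older than
    they are.  The null preserves each target set's composition but
    shuffles which set is paired with which miRNA age; the empirical p
    is (r + 1)/(n_perm + 1) with r the number of null statistics at
    least as large as the observed one.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mirnas = sorted(m for m in targets.targets if m in ages and targets.target_ages(m).size > 0)
    if len(mirnas) < 2:
        raise ValueError("need at least 2 miRNAs with aged targets")
    age_vec = np.array([ages[m] for m in mirnas], dtype=float)
    sets = [np.sort(targets.target_ages(m)) for m in mirnas]
    m = len(mirnas)
    # frac[i, j]: fraction of target set j strictly older than miRNA i
    frac = np.empty((m, m), dtype=float)
    for j, s in enumerate(sets):
        frac[:, j] = 1.0 - np.searchsorted(s, age_vec, side="right") / s.size
    observed = float(np.mean(np.diag(frac)))
    rng = np.random.default_rng(seed)
    idx = np.arange(m)
    null = np.empty(n_perm, dtype=float)
    for k in range(n_perm):
        perm = rng.permutation(idx)
        null[k] = frac[idx, perm].mean()
    r = int(np.sum(null >= observed - 1e-12))
    p = (r + 1) / (n_perm + 1)
    return StatResult(
        "permutation", observed, float(p), m,
        effect={"null_mean": float(null.mean()), "n_perm": n_perm},
    )


def tf_target_fraction(targets: TargetTable, subset: Iterable[str]) -> float:
    """Mean per-miRNA fraction of targets with transcription-factor activity.

    miRNAs in ``subset`` without targets are excluded (logged); an empty
    subset after exclusions is an error.
    """
    fracs = []
    n_excluded = 0
    for m in sorted(set(subset)):
        genes = sorted(targets.targets.get(m, ()))
        if not genes:
            n_excluded += 1
            continue
        fracs.append(np.mean([targets.tf_flags.get(g, False) for g in genes]))
    if n_excluded:
        logger.info("tf_target_fraction: excluded %d miRNAs without targets", n_excluded)
    if not fracs:
        raise ValueError("no miRNA in subset has targets")
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSummary:
    """Per-miRNA tissue presence after replicate consolidation."""

    tissues: dict  # mirna -> set of tissues where present
    tissue_universe: tuple

    @property
    def breadth(self) -> pd.Series:
        return pd.Series({m: len(self.tissues[m]) for m in sorted(self.tissues)}, dtype=int)

    def profile_frame(self) -> pd.DataFrame:
        """Binary miRNA x tissue presence matrix."""
        idx = sorted(self.tissues)
        cols = list(self.tissue_universe)
        data = [[t in self.tissues[m] for t in cols] for m in idx]
        return pd.DataFrame(data, index=idx, columns=cols, dtype=int)


def expression_breadth(
    matrix: pd.DataFrame,
    sample_tissue_map: Mapping[str, str],
    presence_rule: str = "any_positive",
    threshold: float = 0.0,
) -> ExpressionSummary:
    """Consolidate a miRNA x sample expression matrix into tissue presence.

    Each sample column must be mapped to a tissue; a miRNA is present in
    a tissue iff the presence rule holds over that tissue's replicate
    columns.  Rules: ``"any_positive"`` (default; expression > 0 in at
    least one replicate) or ``"mean_above"`` (replicate mean >
    ``threshold``).  Breadth is the count of present tissues.
    """
    unmapped = [c for c in matrix.columns if c not in sample_tissue_map]
    if unmapped:
        raise ValueError(f"samples without tissue mapping: {unmapped}")
    tissues = sorted(set(sample_tissue_map[c] for c in matrix.columns))
    presence: dict[str, set] = {m: set() for m in matrix.index}
    for tissue in tissues:
        cols = [c for c in matrix.columns if sample_tissue_map[c] == tissue]
        sub = matrix[cols]
        if presence_rule == "any_positive":
            present = (sub > 0).any(axis=1)
        elif presence_rule == "mean_above":
            present = sub.mean(axis=1) > threshold
        else:
            raise ValueError(f"unknown presence rule: {presence_rule!r}")
        for m in matrix.index[present]:
            presence[m].add(tissue)
    return ExpressionSummary(tissues=presence, tissue_universe=tuple(tissues))


def breadth_vs_age(
    summary: ExpressionSummary,
    ages: pd.DataFrame,
    young_threshold_my: float = 100.0,
) -> tuple[StatResult, StatResult]:
    """Age-vs-breadth Spearman correlation and the old-vs-young breadth test."""
    age_by_acc = ages.set_index("accession")["age_my"]
    common = sorted(set(summary.tissues) & set(age_by_acc.index))
    breadth = np.array([len(summary.tissues[m]) for m in common], dtype=float)
    age = age_by_acc.loc[common].to_numpy()
    corr = spearman_corr(age, breadth)
    old = breadth[age >= young_threshold_my]
    young = breadth[age < young_threshold_my]
    if old.size and young.size:
        comp = mann_whitney(old, young)
        comp.effect.update(
            median_old=float(np.median(old)), median_young=float(np.median(young))
        )
    else:
        comp = StatResult(
            "mannwhitneyu_normal", float("nan"), float("nan"),
            (int(old.size), int(young.size)), defined=False,
            note="one age class is empty",
        )
    return corr, comp


# ---------------------------------------------------------------------------
# Jaccard profile similarity
# ---------------------------------------------------------------------------

def jaccard(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard similarity |A∩B|/|A∪B| of two binary vectors.

    Vectors must share one label universe (same length).  When both
    vectors are empty the similarity is undefined and NaN is returned;
    pair statistics exclude such pairs.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors are indexed by different label universes")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.info("jaccard undefined: both vectors empty")
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)


def _jaccard_matrix(profiles: pd.DataFrame) -> np.ndarray:
    a = profiles.to_numpy(dtype=float)
    inter = a @ a.T
    sizes = a.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1.0), np.nan)
    return jac


@dataclass
class PairwiseSimilarity:
    """Jaccard similarity populations by family relationship."""

    within_family: np.ndarray
    between_family: np.ndarray
    singleton: np.ndarray
    tests: dict = field(default_factory=dict)  # comparison tag -> StatResult


def pairwise_profile_similarity(
    profiles: pd.DataFrame,
    families,
    min_family_size: int = 5,
    strata: Optional[Mapping[str, object]] = None,
) -> PairwiseSimilarity:
    """Within-family vs between-family vs singleton profile similarity.

    ``profiles`` is a binary miRNA x label matrix; ``families`` a
    :class:`mirstrat.ortho_grouping.FamilyTable`.  Families below the
    size filter (default: more than four members) are ignored.  All
    unordered pairs are enumerated per category — within one qualifying
    family, between two different qualifying families, and between two
    singletons — and the within-family population is compared to each
    other population by Mann-Whitney.  Pairs where both profiles are
    empty are excluded (logged).  With ``strata`` (accession -> stratum
    label, e.g. origin-node bins) pairs whose members share a stratum
    are additionally compared by the van Elteren stratified test.
    """
    fams = families.families(min_size=min_family_size)
    fam_of: dict[str, str] = {}
    for fid, members in fams.items():
        for m in members:
            fam_of[m] = fid
    singles = families.singletons() & set(profiles.index)
    fam_accs = set(fam_of) & set(profiles.index)
    accs = sorted(fam_accs | singles)
    if len(accs) < 2:
        raise ValueError("need at least 2 miRNAs across categories")
    sub = profiles.loc[accs]
    jac = _jaccard_matrix(sub)
    idx_of = {a: i for i, a in enumerate(accs)}

    cats: dict[str, list] = {"within": [], "between": [], "singleton": []}
    strat_pairs: dict[str, list] = {"within": [], "singleton": [], "between": []}
    n_undefined = 0
    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            j = idx_of[b]
            if a in fam_of and b in fam_of:
                cat = "within" if fam_of[a] == fam_of[b] else "between"
            elif a in singles and b in singles:
                cat = "singleton"
            else:
                continue  # family-vs-singleton pairs belong to no category
            v = jac[i, j]
            if v != v:  # NaN: both profiles empty
                n_undefined += 1
                continue
            cats[cat].append(v)
            if strata is not None:
                sa, sb = strata.get(a), strata.get(b)
                if sa is not None and sa == sb:
                    strat_pairs[cat].append((v, sa))
    if n_undefined:
        logger.info("excluded %d pairs with two empty profiles", n_undefined)

    out = PairwiseSimilarity(
        within_family=np.array(cats["within"], dtype=float),
        between_family=np.array(cats["between"], dtype=float),
        singleton=np.array(cats["singleton"], dtype=float),
    )
    for tag, other in (
        ("within_vs_singleton", out.singleton),
        ("within_vs_between", out.between_family),
    ):
        if out.within_family.size and other.size:
            res = mann_whitney(out.within_family, other)
            res.effect.update(
                mean_within=float(out.within_family.mean()), mean_other=float(other.mean())
            )
            out.tests[tag] = res
        else:
            logger.info("comparison %s skipped: empty category", tag)
    if strata is not None:
        for tag, other_key in (("within_vs_singleton", "singleton"), ("within_vs_between", "between")):
            w = strat_pairs["within"]
            o = strat_pairs[other_key]
            if not w or not o:
                continue
            vals = np.array([v for v, _ in w] + [v for v, _ in o])
            grp = np.array([True] * len(w) + [False] * len(o))
            strat = np.array([s for _, s in w] + [s for _, s in o], dtype=object)
            try:
                out.tests[f"{tag}_stratified"] = stratified_mwu(vals, grp, strat)
            except ValueError as exc:
                logger.info("stratified comparison %s skipped: %s", tag, exc)
    return out
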