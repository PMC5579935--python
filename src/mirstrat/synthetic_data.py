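"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes — a calibrated species tree,
Dollo gain/loss presence characters, age-dependent disease/target/tissue
profiles with family sharing, and genomic interval tracks — together
with the ground truth (planted origin nodes, ages, family memberships,
generation rates, and planted genomic flags), so every stage can be
tested for parameter recovery without external downloads.  All
generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mirstrat import genomic_context, ortho_grouping, phylo_age
from mirstrat.association_stats import DiseaseCatalog, TargetTable
from mirstrat.genomic_context import GenomicInterval
from mirstrat.ortho_grouping import FamilyTable
from mirstrat.phylo_age import TaxonTree


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Rates named ``*_intercept``/``*_slope`` parameterize per-miRNA count
    means as lambda(age) = intercept + slope * age_MY; tissue presence
    uses a logistic in age instead.  ``loss_rate`` is the expected
    number of loss events per character per branch (losses are rare
    under the Dollo assumption, hence a low default).
    """

    # tree / characters
    n_species: int = 25
    tree_depth_my: float = 800.0
    n_mirnas: int = 500
    loss_rate: float = 0.02
    require_species: Optional[str] = "hsa"
    # diseases
    n_diseases: int = 50
    cancer_fraction: float = 0.4
    disease_intercept: float = 0.5
    disease_slope: float = 0.02
    plant_old_disease: bool = False
    # targets / genes
    n_genes: int = 2000
    gene_age_shape: float = 2.0
    gene_age_scale: float = 600.0
    target_intercept: float = 2.0
    target_slope: float = 0.03
    target_older_bias: float = 0.92
    tf_fraction: float = 0.06
    # expression
    n_tissues: int = 20
    n_replicates: int = 3
    expr_intercept: float = -1.5
    expr_slope: float = 0.01
    # families
    family_count: int = 30
    family_mean_size: float = 5.0
    family_profile_retention: float = 0.9
    family_noise_rate: float = 0.5
    # genomic intervals
    chrom_length: int = 2_000_000
    precursor_length: int = 100
    intron_fraction: float = 0.38
    te_base_prob: float = 0.10
    te_young_odds: float = 4.0
    tfbs_base_prob: float = 0.15
    tfbs_old_odds: float = 4.0
    cons_base: float = 400.0
    cons_slope: float = 0.2
    cons_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loss_rate", "disease_intercept", "target_intercept",
            "family_noise_rate", "te_base_prob", "tfbs_base_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.family_profile_retention <= 1.0):
            raise ValueError("family_profile_retention must be in [0, 1]")
        for a, b in (
            (self.disease_intercept, self.disease_slope),
            (self.target_intercept, self.target_slope),
        ):
            if a + b * self.tree_depth_my < 0 or a < 0:
                raise ValueError("count rate lambda(age) negative over the age range")

    def spawn_seeds(self, n: int) -> list[int]:
        state = np.random.SeedSequence(self.seed).generate_state(n)
        return [int(s % 2**31) for s in state]


@dataclass
class SimulatedTree:
    tree: TaxonTree
    newick: str
    calibrations: dict


def simulate_tree(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedTree:
    """Random ultrametric bifurcating species tree of depth ``tree_depth_my``.

    Leaves are species codes (the first is ``require_species`` when
    set); internal nodes are labeled and each carries a single "expert"
    calibration, so the calibration path of the dating module is
    exercised end to end.
    """
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    first = config.require_species or "sp00"
    species = [first] + [f"sp{i:02d}" for i in range(1, config.n_species)]
    heights = np.sort(rng.uniform(0.0, 1.0, size=config.n_species - 1))
    heights = heights / heights[-1] * config.tree_depth_my
    clades = [(sp,) for sp in species]
    newicks = {(sp,): sp for sp in species}
    calibrations: dict[str, list] = {}
    for k, h in enumerate(heights):
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        a, b = clades[i], clades[j]
        label = f"n{k:02d}"
        merged = tuple(sorted(a + b))
        newicks[merged] = f"({newicks.pop(a)},{newicks.pop(b)}){label}"
        calibrations[label] = [(float(h), "expert")]
        clades = [c for c in clades if c not in (a, b)] + [merged]
    newick = newicks[clades[0]] + ";"
    tree = TaxonTree.from_newick(newick)
    tree.calibrate(calibrations)
    return SimulatedTree(tree=tree, newick=newick, calibrations=calibrations)


@dataclass
class SimulatedCharacters:
    presence: pd.DataFrame  # group x species, binary
    truth: pd.DataFrame  # mirna, accession, origin_node, age_my


def simulate_characters(
    tree: TaxonTree, config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedCharacters:
    """Dollo gain/loss characters on a calibrated tree.

    Each character gains at one uniformly chosen node (restricted to the
    ancestors of ``require_species`` when set, so every character has a
    human member) and is present at all descendant leaves except those
    under branches hit by a loss event (Poisson per branch with rate
    ``loss_rate``).  Characters losing all required presence are
    redrawn.  The truth records the planted gain node and its age.
    """
    if not tree.is_calibrated:
        raise ValueError("tree must be calibrated")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    req = config.require_species
    if req is not None and req not in tree.leaf_labels:
        raise ValueError(f"require_species {req!r} is not a leaf")
    if req is None:
        eligible = tree.nodes()
    else:
        node = tree.leaf(req)
        eligible = []
        while node is not None:
            eligible.append(node)
            node = node.parent_node
    p_loss = -math.expm1(-config.loss_rate)  # P(Poisson(rate) >= 1)

    leaf_order = tree.leaf_labels
    rows = np.zeros((config.n_mirnas, len(leaf_order)), dtype="int8")
    col = {sp: i for i, sp in enumerate(leaf_order)}
    truth_rows = []
    for i in range(config.n_mirnas):
        for _ in range(10_000):
            gain = eligible[int(rng.integers(len(eligible)))]
            present: list[str] = []
            stack = [gain]
            while stack:
                node = stack.pop()
                if node.is_leaf():
                    present.append(node.taxon.label)
                    continue
                for child in node.child_nodes():
                    if p_loss > 0 and rng.random() < p_loss:
                        continue  # loss: whole subtree absent
                    stack.append(child)
            if present and (req is None or req in present):
                break
        else:  # pragma: no cover - loss_rate would have to be extreme
            raise RuntimeError("failed to draw a surviving character")
        mid = f"mir-{i:04d}"
        for sp in present:
            rows[i, col[sp]] = 1
        truth_rows.append(
            {
                "mirna": mid,
                "accession": f"{req or present[0]}-{mid}",
                "origin_node": gain.label,
                "age_my": float(gain.age_my),
            }
        )
    presence = pd.DataFrame(
        rows, index=[f"mir-{i:04d}" for i in range(config.n_mirnas)], columns=leaf_order
    )
    return SimulatedCharacters(presence=presence, truth=pd.DataFrame(truth_rows))


@dataclass
class SimulatedProfiles:
    catalog: DiseaseCatalog
    targets: TargetTable
    expression: pd.DataFrame  # mirna x sample
    sample_tissue_map: dict
    families: FamilyTable
    rates: pd.DataFrame  # per-miRNA planted generation rates


def _draw_labels(rng, labels: list, k: int) -> set:
    k = min(k, len(labels))
    if k == 0:
        return set()
    return set(rng.choice(labels, size=k, replace=False))


def simulate_profiles(
    truth: pd.DataFrame, config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedProfiles:
    """Age-dependent functional profiles with family sharing.

    Disease and target counts per miRNA are Poisson with mean
    lambda(age) = intercept + slope*age; tissue presence is Bernoulli
    with a logistic-in-age probability.  Target genes are drawn with a
    configurable bias toward genes older than the miRNA.  Family members
    copy a family base profile, retaining each label with probability
    ``family_profile_retention`` plus independent noise labels;
    singletons draw independently from their own age.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    accs = list(truth["accession"])
    ages = dict(zip(truth["accession"], truth["age_my"]))

    # -- families ------------------------------------------------------
    pool = list(rng.permutation(sorted(accs)))
    fam_map: dict[str, set] = {}
    for f in range(config.family_count):
        size = 2 + int(rng.poisson(max(config.family_mean_size - 2.0, 0.0)))
        if len(pool) < size:
            break
        members, pool = pool[:size], pool[size:]
        fam_map[f"fam-{f:02d}"] = set(members)
    families = ortho_grouping.family_table_from_mapping(fam_map, accs)
    fam_of: dict[str, str] = {}
    for fid, members in fam_map.items():
        for m in members:
            fam_of[m] = fid
    fam_mean_age = {
        fid: float(np.mean([ages[m] for m in sorted(members)]))
        for fid, members in fam_map.items()
    }

    # -- disease universe ---------------------------------------------
    n_cancer = int(round(config.cancer_fraction * config.n_diseases))
    cancer_terms = [f"carcinoma-{i:02d}" for i in range(n_cancer)]
    other_terms = [f"disease-{i:02d}" for i in range(config.n_diseases - n_cancer)]
    disease_terms = cancer_terms + other_terms
    mesh: dict[str, tuple] = {}
    for i, term in enumerate(cancer_terms):
        mesh[term] = (f"C04.{550 + i % 10}.{100 + i}",)
    categories = ["C06", "C10", "C14", "F03"]
    for i, term in enumerate(other_terms):
        cat = categories[i % len(categories)]
        paths = [f"{cat}.{500 + i % 7}.{200 + i}"]
        if i % 5 == 0:
            alt = categories[(i + 1) % len(categories)]
            paths.append(f"{alt}.{600 + i % 5}.{300 + i}")
        mesh[term] = tuple(paths)

    def lam_disease(age: float) -> float:
        return config.disease_intercept + config.disease_slope * age

    def lam_target(age: float) -> float:
        return config.target_intercept + config.target_slope * age

    # family base profiles (labels are drawn from the family mean age)
    fam_disease_base = {
        fid: _draw_labels(rng, disease_terms, int(rng.poisson(lam_disease(fam_mean_age[fid]))))
        for fid in sorted(fam_map)
    }

    # -- gene pool -----------------------------------------------------
    gene_ids = [f"gene-{i:04d}" for i in range(config.n_genes)]
    gene_age_arr = rng.gamma(config.gene_age_shape, config.gene_age_scale, size=config.n_genes)
    gene_ages = dict(zip(gene_ids, gene_age_arr.astype(float)))
    tf_flags = dict(zip(gene_ids, (rng.random(config.n_genes) < config.tf_fraction).tolist()))
    order = np.argsort(gene_age_arr, kind="stable")
    genes_by_age = [gene_ids[i] for i in order]
    sorted_gene_ages = gene_age_arr[order]

    def draw_targets(k: int, age: float) -> set:
        if k <= 0:
            return set()
        cut = int(np.searchsorted(sorted_gene_ages, age, side="right"))
        older = genes_by_age[cut:]
        chosen: set = set()
        if older:
            n_old = int(rng.binomial(k, config.target_older_bias))
            chosen |= _draw_labels(rng, older, n_old)
        chosen |= _draw_labels(rng, gene_ids, k - len(chosen))
        return chosen

    fam_target_base = {
        fid: draw_targets(int(rng.poisson(lam_target(fam_mean_age[fid]))), fam_mean_age[fid])
        for fid in sorted(fam_map)
    }

    def p_tissue(age: float) -> float:
        return 1.0 / (1.0 + math.exp(-(config.expr_intercept + config.expr_slope * age)))

    tissue_names = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    fam_tissue_base = {
        fid: set(
            t for t in tissue_names if rng.random() < p_tissue(fam_mean_age[fid])
        )
        for fid in sorted(fam_map)
    }

    def with_family_sharing(base: set, labels: list, noise_k: int, retention: float) -> set:
        kept = {l for l in sorted(base) if rng.random() < retention}
        kept |= _draw_labels(rng, labels, noise_k)
        return kept

    assoc: dict[str, set] = {t: set() for t in disease_terms}
    targets = TargetTable(targets={}, gene_ages=gene_ages, tf_flags=tf_flags)
    tissue_presence: dict[str, set] = {}
    rate_rows = []
    for acc in sorted(accs):
        age = ages[acc]
        fid = fam_of.get(acc)
        if fid is not None:
            dz = with_family_sharing(
                fam_disease_base[fid], disease_terms,
                int(rng.poisson(config.family_noise_rate)),
                config.family_profile_retention,
            )
            tg = with_family_sharing(
                fam_target_base[fid], [],
                0, config.family_profile_retention,
            )
            tg |= draw_targets(int(rng.poisson(config.family_noise_rate)), age)
            base_t = fam_tissue_base[fid]
            tis = {t for t in sorted(base_t) if rng.random() < config.family_profile_retention}
            tis |= {t for t in tissue_names if t not in base_t and rng.random() < 0.05}
        else:
            dz = _draw_labels(rng, disease_terms, int(rng.poisson(lam_disease(age))))
            tg = draw_targets(int(rng.poisson(lam_target(age))), age)
            tis = {t for t in tissue_names if rng.random() < p_tissue(age)}
        for term in dz:
            assoc[term].add(acc)
        targets.targets[acc] = tg
        tissue_presence[acc] = tis
        rate_rows.append(
            {
                "accession": acc,
                "disease_lambda": lam_disease(age),
                "target_lambda": lam_target(age),
                "tissue_p": p_tissue(age),
                "family_id": fid or "",
            }
        )

    if config.plant_old_disease:
        q75 = float(np.quantile(truth["age_my"], 0.75))
        old_pool = sorted(a for a in accs if ages[a] >= q75)
        size = min(len(old_pool), max(8, len(accs) // 25))
        assoc["planted-old-disease"] = set(rng.choice(old_pool, size=size, replace=False))

    catalog = DiseaseCatalog(
        {t: m for t, m in assoc.items() if m}, mesh, collapsed=False
    )

    # -- expression matrix --------------------------------------------
    samples = [f"{t}_r{j}" for t in tissue_names for j in range(1, config.n_replicates + 1)]
    sample_tissue_map = {s: s.rsplit("_", 1)[0] for s in samples}
    mat = np.zeros((len(accs), len(samples)))
    acc_sorted = sorted(accs)
    for i, acc in enumerate(acc_sorted):
        for t_idx, t in enumerate(tissue_names):
            if t not in tissue_presence[acc]:
                continue
            vals = rng.gamma(2.0, 5.0, size=config.n_replicates)
            dropout = rng.random(config.n_replicates) < 0.3
            if dropout.all():
                dropout[int(rng.integers(config.n_replicates))] = False
            vals[dropout] = 0.0
            mat[i, t_idx * config.n_replicates:(t_idx + 1) * config.n_replicates] = vals
    expression = pd.DataFrame(mat, index=acc_sorted, columns=samples)

    return SimulatedProfiles(
        catalog=catalog,
        targets=targets,
        expression=expression,
        sample_tissue_map=sample_tissue_map,
        families=families,
        rates=pd.DataFrame(rate_rows),
    )


@dataclass
class SimulatedIntervals:
    precursors: dict  # accession -> GenomicInterval
    introns: list
    tes: list
    tfbs: list
    cons_elements: list
    truth: pd.DataFrame  # accession, is_intronic, is_te_derived, has_tfbs, cons_score


def simulate_intervals(
    truth: pd.DataFrame, config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedIntervals:
    """Genomic tracks with planted, age-biased annotation flags.

    Precursors are placed on a virtual chromosome in disjoint slots;
    intron/TE/TFBS overlaps are constructed (or withheld) per miRNA so
    the planted flags are recovered exactly by interval intersection.
    TE overlap is planted preferentially on young miRNAs and TFBS on old
    ones, per the configured odds.  Conservation elements tile each
    precursor with age-trending scores.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(truth)
    slot = config.chrom_length // max(n, 1)
    if slot < max(4 * config.precursor_length, 4000):
        raise ValueError("chromosome too short to place all precursors")
    chrom = "chrS"
    young_cut = phylo_age.YOUNG_AGE_THRESHOLD_MY

    precursors: dict[str, GenomicInterval] = {}
    introns: list[GenomicInterval] = []
    tes: list[GenomicInterval] = []
    tfbs: list[GenomicInterval] = []
    cons: list[GenomicInterval] = []
    rows = []
    recs = truth.sort_values("accession").reset_index(drop=True)
    for i, row in recs.iterrows():
        acc, age = row["accession"], float(row["age_my"])
        young = age < young_cut
        base = i * slot
        start = base + int(rng.integers(slot // 4, slot // 2))
        end = start + config.precursor_length
        mid = (start + end) // 2
        precursors[acc] = GenomicInterval(chrom, start, end, label=acc)

        is_intronic = bool(rng.random() < config.intron_fraction)
        if is_intronic:
            ext = int(rng.integers(200, min(1000, slot // 4)))
            introns.append(GenomicInterval(chrom, start - ext, end + ext, label=f"intron_{acc}"))
        else:
            introns.append(
                GenomicInterval(chrom, base + 10, base + slot // 8, label=f"bg_intron_{i}")
            )

        p_te = min(config.te_base_prob * (config.te_young_odds if young else 1.0), 0.95)
        is_te = bool(rng.random() < p_te)
        if is_te:
            tes.append(GenomicInterval(chrom, start - 20, start + 30, label=f"te_{acc}"))
        else:
            tes.append(GenomicInterval(chrom, base + slot * 3 // 4, base + slot * 3 // 4 + 50,
                                       label=f"bg_te_{i}"))

        p_tf = min(config.tfbs_base_prob * (1.0 if young else config.tfbs_old_odds), 0.95)
        has_tf = bool(rng.random() < p_tf)
        if has_tf:
            tfbs.append(GenomicInterval(chrom, mid - 10, mid + 10, label=f"tfbs_{acc}"))
        else:
            tfbs.append(GenomicInterval(chrom, base + slot * 3 // 4 + 60,
                                        base + slot * 3 // 4 + 80, label=f"bg_tfbs_{i}"))

        s1, s2 = np.maximum(
            rng.normal(config.cons_base + config.cons_slope * age, config.cons_sd, size=2), 1.0
        )
        cons.append(GenomicInterval(chrom, start, mid, score=float(s1), label=f"cons_{acc}_a"))
        cons.append(GenomicInterval(chrom, mid, end, score=float(s2), label=f"cons_{acc}_b"))
        l1, l2 = mid - start, end - mid
        rows.append(
            {
                "accession": acc,
                "is_intronic": is_intronic,
                "is_te_derived": is_te,
                "has_tfbs": has_tf,
                "cons_score": float((s1 * l1 + s2 * l2) / (l1 + l2)),
            }
        )
    return SimulatedIntervals(
        precursors=precursors,
        introns=introns,
        tes=tes,
        tfbs=tfbs,
        cons_elements=cons,
        truth=pd.DataFrame(rows),
    )


@dataclass
class Bundle:
    """A complete on-disk fixture bundle plus in-memory objects."""

    config: SimulationConfig
    tree: SimulatedTree
    characters: SimulatedCharacters
    profiles: SimulatedProfiles
    intervals: SimulatedIntervals
    paths: dict = field(default_factory=dict)


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Run all generators with seeds derived from ``config.seed``."""
    s_tree, s_char, s_prof, s_int = config.spawn_seeds(4)
    sim_tree = simulate_tree(config, seed=s_tree)
    chars = simulate_characters(sim_tree.tree, config, seed=s_char)
    profiles = simulate_profiles(chars.truth, config, seed=s_prof)
    intervals = simulate_intervals(chars.truth, config, seed=s_int)
    return Bundle(config, sim_tree, chars, profiles, intervals)


def write_bundle(outdir, config: SimulationConfig) -> Bundle:
    """Generate and write a complete fixture bundle directory.

    Emits exactly the TSV/Newick/BED dialects the analysis modules read,
    plus ``truth.tsv`` with the planted ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    paths = bundle.paths

    # annotation table: one record per (species, character) presence
    recs = []
    fam_of: dict[str, str] = {}
    for fid, members in bundle.profiles.families.family_members.items():
        for m in members:
            fam_of[m] = fid
    req = config.require_species or "sp00"
    for mid, row in bundle.characters.presence.iterrows():
        for sp in bundle.characters.presence.columns:
            if not row[sp]:
                continue
            acc = f"{sp}-{mid}"
            recs.append(
                {
                    "accession": acc,
                    "species": sp,
                    "name": acc,
                    "family_id": fam_of.get(acc, "") if sp == req else "",
                }
            )
    paths["mirnas"] = outdir / "mirnas.tsv"
    pd.DataFrame(recs).to_csv(paths["mirnas"], sep="\t", index=False)

    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(bundle.tree.newick + "\n")
    paths["calibrations"] = outdir / "calibrations.tsv"
    phylo_age.write_calibration_table(paths["calibrations"], bundle.tree.calibrations)

    paths["disease"] = outdir / "disease.tsv"
    bundle.profiles.catalog.write_tsv(paths["disease"])
    paths["targets"] = outdir / "targets.tsv"
    bundle.profiles.targets.write_tsv(paths["targets"])

    paths["expression"] = outdir / "expression.tsv"
    bundle.profiles.expression.to_csv(paths["expression"], sep="\t", index_label="mirna")
    paths["samples"] = outdir / "samples.tsv"
    pd.DataFrame(
        sorted(bundle.profiles.sample_tissue_map.items()), columns=["sample", "tissue"]
    ).to_csv(paths["samples"], sep="\t", index=False)

    paths["precursors"] = outdir / "precursors.bed"
    genomic_context.write_bed(
        paths["precursors"],
        [bundle.intervals.precursors[a] for a in sorted(bundle.intervals.precursors)],
    )
    for key, track in (
        ("introns", bundle.intervals.introns),
        ("te", bundle.intervals.tes),
        ("tfbs", bundle.intervals.tfbs),
        ("conservation", bundle.intervals.cons_elements),
    ):
        paths[key] = outdir / f"{key}.bed"
        genomic_context.write_bed(paths[key], track)

    truth = bundle.characters.truth.merge(bundle.profiles.rates, on="accession")
    truth = truth.merge(bundle.intervals.truth, on="accession")
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")

    cfg_lines = [f"{k}={v}" for k, v in sorted(asdict(config).items())]
    paths["sim_config"] = outdir / "sim_config.txt"
    paths["sim_config"].write_text("\n".join(cfg_lines) + "\n")
    return bundle
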