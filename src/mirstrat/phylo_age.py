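"""Dollo-parsimony dating of miRNA origins on a calibrated species tree.

Each ortho-group is a binary presence/absence character over the leaves
of a rooted species phylogeny.  Under a Dollo model (one gain, any
number of losses) the loss-minimizing gain placement for a character is
the most recent common ancestor (MRCA) of the species possessing it, so
the age of a human miRNA is the calibrated age, in millions of years
(MY), of that MRCA node.  This is a lower bound on the true age: any
unobserved loss pulls the MRCA toward the present, never away from it.

Node ages come from a calibration table of published divergence-time
estimates; uncalibrated internal nodes are interpolated between their
nearest calibrated ancestor and oldest calibrated descendant.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from mirstrat.results import StatResult

logger = logging.getLogger(__name__)

#: Age threshold separating "young" from "old"/"ancient" miRNAs, in MY.
#: The young class is strict: an origin at exactly the threshold is old.
YOUNG_AGE_THRESHOLD_MY = 100.0


class TreeParseError(ValueError):
    """Raised for malformed Newick input (naming the offending token when known)."""


class CalibrationError(ValueError):
    """Raised for inconsistent or insufficient node-age calibrations."""


class TaxonTree:
    """Rooted species tree with species-coded leaves and per-node ages.

    Wraps a :class:`dendropy.Tree`.  Leaves carry species codes; internal
    nodes carry clade labels (unlabeled internal nodes receive stable
    ``node<k>`` labels in preorder).  Ages (MY) are attached by
    :meth:`calibrate`; leaves are always age 0.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dups = {l for l in labels if labels.count(l) > 1}
        if dups:
            raise TreeParseError(f"duplicate leaf labels: {sorted(dups)}")
        self._leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        k = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.label = node.taxon.label
            elif not node.label:
                node.label = f"node{k}"
            k += 1
        self._node_by_label = {n.label: n for n in tree.preorder_node_iter()}
        self._calibrated = False

    @classmethod
    def from_newick(cls, newick_text: str) -> "TaxonTree":
        try:
            tree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"invalid Newick: {exc}") from exc
        if next(tree.leaf_node_iter(), None) is None:
            raise TreeParseError("tree has no leaves")
        return cls(tree)

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaf_by_label)

    @property
    def is_calibrated(self) -> bool:
        return self._calibrated

    def nodes(self) -> list[dendropy.Node]:
        return list(self._tree.preorder_node_iter())

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._node_by_label[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r}") from None

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"no leaf labeled {label!r}") from None

    def age_of(self, node_or_label) -> float:
        node = node_or_label
        if isinstance(node_or_label, str):
            node = self.node(node_or_label)
        if not self._calibrated:
            raise CalibrationError("tree is not calibrated")
        return node.age_my

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {l.taxon.label for l in node.leaf_iter()}

    def mrca(self, leaf_labels: Iterable[str]) -> dendropy.Node:
        """MRCA of a set of leaves (a single leaf is its own MRCA)."""
        labels = sorted(set(leaf_labels))
        if not labels:
            raise ValueError("mrca of an empty leaf set")
        node = self.leaf(labels[0])
        if len(labels) == 1:
            return node
        chain = []
        idx = {}
        while node is not None:
            idx[id(node)] = len(chain)
            chain.append(node)
            node = node.parent_node
        best = 0
        for lab in labels[1:]:
            n = self.leaf(lab)
            while id(n) not in idx:
                n = n.parent_node
                if n is None:  # pragma: no cover - single root guarantees a hit
                    raise ValueError("leaves do not share a root")
            best = max(best, idx[id(n)])
        return chain[best]

    # -- calibration ---------------------------------------------------

    def calibrate(self, table: Mapping[str, Sequence[tuple[float, str]]]) -> None:
        """Attach ages (MY) to every node from a calibration table.

        ``table`` maps a node key to a list of ``(estimate_my, source)``
        pairs.  A key is either an internal-node clade label or a leaf
        pair ``"A|B"`` naming the MRCA of A and B.  If any estimate is
        flagged with source ``"expert"``, the (mean of the) expert
        estimate(s) is used; otherwise the arithmetic mean of all
        published estimates.  Leaves are fixed at 0.  Internal nodes
        without a calibration receive the midpoint of their nearest
        calibrated ancestor and oldest calibrated descendant.  A parent
        calibrated younger than a child raises :class:`CalibrationError`
        naming the node pair.
        """
        for node in self.nodes():
            node.age_my = 0.0 if node.is_leaf() else None

        for key, estimates in table.items():
            if not estimates:
                raise CalibrationError(f"empty estimate list for node {key!r}")
            if "|" in key:
                leaves = key.split("|")
                node = self.mrca(leaves)
            elif key in self._node_by_label:
                node = self._node_by_label[key]
            else:
                raise CalibrationError(f"calibration names unknown node {key!r}")
            if node.is_leaf():
                continue  # leaves are 0 by definition
            expert = [e for e, src in estimates if src == "expert"]
            vals = expert if expert else [e for e, _ in estimates]
            if any(v <= 0 for v in vals):
                raise CalibrationError(f"non-positive estimate for internal node {key!r}")
            node.age_my = float(np.mean(vals))

        root = self.root
        if not root.is_leaf() and root.age_my is None:
            raise CalibrationError("root has no calibration and cannot be interpolated")

        calibrated = {id(n): n.age_my is not None for n in self.nodes()}

        # oldest calibrated descendant per node (leaves count, at age 0)
        max_cal_desc: dict[int, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                max_cal_desc[id(node)] = 0.0
            else:
                child_max = max(max_cal_desc[id(c)] for c in node.child_nodes())
                own = node.age_my if calibrated[id(node)] else -np.inf
                max_cal_desc[id(node)] = max(child_max, own)

        # interpolate top-down; interpolated nodes do not themselves act as
        # calibrations for deeper uncalibrated nodes
        nearest_cal_anc: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                anc = node.age_my  # root is calibrated (checked above)
            elif calibrated[id(parent)]:
                anc = parent.age_my
            else:
                anc = nearest_cal_anc[id(parent)]
            nearest_cal_anc[id(node)] = anc
            if not node.is_leaf() and node.age_my is None:
                desc = max(max_cal_desc[id(c)] for c in node.child_nodes())
                node.age_my = (anc + desc) / 2.0

        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                if node.age_my < child.age_my - 1e-9:
                    raise CalibrationError(
                        f"calibration conflict: node {node.label!r} "
                        f"({node.age_my:.3f} MY) is younger than its child "
                        f"{child.label!r} ({child.age_my:.3f} MY)"
                    )
        self._calibrated = True

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_tree(newick_text: str) -> TaxonTree:
    """Parse Newick text into an (uncalibrated) :class:`TaxonTree`."""
    return TaxonTree.from_newick(newick_text)


def read_calibration_table(path) -> dict[str, list[tuple[float, str]]]:
    """Read a calibration TSV (node_label_or_leafpair, estimate_my, source)."""
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "source": str}, comment="#")
    required = {"node", "estimate_my"}
    if required - set(df.columns):
        raise ValueError(f"calibration table missing columns: {sorted(required - set(df.columns))}")
    table: dict[str, list[tuple[float, str]]] = {}
    for row in df.itertuples(index=False):
        src = getattr(row, "source", "") or ""
        table.setdefault(row.node, []).append((float(row.estimate_my), src))
    return table


def write_calibration_table(path, table: Mapping[str, Sequence[tuple[float, str]]]) -> None:
    rows = [
        {"node": key, "estimate_my": est, "source": src}
        for key in sorted(table)
        for est, src in table[key]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def calibrate(tree: TaxonTree, table: Mapping[str, Sequence[tuple[float, str]]]) -> TaxonTree:
    """Calibrate ``tree`` in place and return it (functional-style alias)."""
    tree.calibrate(table)
    return tree


def dollo_origin(tree: TaxonTree, presence) -> dendropy.Node:
    """Loss-minimizing gain node for a binary character under Dollo parsimony.

    ``presence`` is either a set/iterable of present leaf labels or a
    mapping leaf label -> {0,1}.  Under a single-gain model the unique
    placement minimizing the number of loss events is the MRCA of all
    present leaves; a character present in a single species originates
    on that terminal branch (the leaf node is returned).
    """
    if isinstance(presence, Mapping):
        present = {k for k, v in presence.items() if v}
    else:
        present = set(presence)
    if not present:
        raise ValueError("character is absent from every leaf (unobserved)")
    unknown = present - set(tree.leaf_labels)
    if unknown:
        raise KeyError(f"presence names unknown leaves: {sorted(unknown)}")
    return tree.mrca(present)


def assign_ages(
    presence: pd.DataFrame,
    tree: TaxonTree,
    human_code: str = "hsa",
    human_members: Optional[Mapping[str, Iterable[str]]] = None,
    young_threshold_my: float = YOUNG_AGE_THRESHOLD_MY,
) -> pd.DataFrame:
    """Per-miRNA origin nodes and ages from a group presence matrix.

    Only groups present in ``human_code`` yield rows.  ``human_members``
    optionally maps group_id to the human accessions in that group (one
    output row per accession); without it, rows are keyed by group_id.
    The reported age is the age of the origin MRCA node — the younger
    end of the origin branch, hence a lower bound — with the parent
    node's age emitted alongside as the upper end of the branch.  The
    young/old class is strict at the threshold: age < threshold is
    young, the boundary value itself is old.
    """
    if not tree.is_calibrated:
        raise CalibrationError("assign_ages requires a calibrated tree")
    if human_code not in tree.leaf_labels:
        raise KeyError(f"human code {human_code!r} is not a tree leaf")
    leaf_set = set(tree.leaf_labels)
    rows = []
    n_skipped = 0
    for group_id, row in presence.iterrows():
        present = {sp for sp, v in row.items() if v}
        if human_code not in present:
            continue
        present &= leaf_set
        if not present:
            n_skipped += 1
            logger.warning("group %s: empty presence after species filtering", group_id)
            continue
        origin = dollo_origin(tree, present)
        age = origin.age_my
        parent = origin.parent_node
        parent_age = parent.age_my if parent is not None else np.nan
        accs = list(human_members[group_id]) if human_members else [group_id]
        for acc in sorted(accs):
            rows.append(
                {
                    "accession": acc,
                    "group_id": group_id,
                    "origin_node": origin.label,
                    "age_my": age,
                    "parent_age_my": parent_age,
                    "age_class": "young" if age < young_threshold_my else "old",
                }
            )
    if n_skipped:
        logger.warning("skipped %d groups with empty filtered presence", n_skipped)
    return pd.DataFrame(
        rows,
        columns=["accession", "group_id", "origin_node", "age_my", "parent_age_my", "age_class"],
    )


def age_distribution_compare(ages_a: Sequence[float], ages_b: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney comparison of two age distributions.

    Reports the U statistic for the first sample, the two-sided p-value
    (exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise), and the medians and means of both groups.
    """
    from mirstrat.association_stats import mann_whitney

    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both age lists must be nonempty")
    res = mann_whitney(a, b)
    res.effect.update(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
    )
    return res


def write_age_table(path, ages: pd.DataFrame) -> None:
    ages.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_age_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
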