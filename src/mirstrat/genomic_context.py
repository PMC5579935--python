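"""Interval annotation of miRNA precursors and age/family-class contrasts.

Precursor coordinates are intersected with intron, transposable-element
(TE), transcription-factor-binding-site (TFBS), and scored conservation
tracks.  All coordinates are BED-convention 0-based half-open; touching
intervals do not overlap.  Per-miRNA flags and a conservation score are
then compared across age, family, and disease classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from mirstrat import association_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom is empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_bed(path, strict: bool = False) -> list[GenomicInterval]:
    """Read a BED3+ file (chrom, start, end[, name, score, strand]).

    Malformed lines are rejected with their line numbers logged; with
    ``strict=True`` the first malformed line raises instead.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                strand = fields[5] if len(fields) > 5 else "."
                out.append(GenomicInterval(chrom, start, end, strand, score, label))
            except ValueError as exc:
                msg = f"{path}:{lineno}: rejected BED line ({exc})"
                if strict:
                    raise ValueError(msg) from None
                logger.warning(msg)
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.label or ".",
                        "." if iv.score is None else f"{iv.score:g}",
                        iv.strand,
                    ]
                )
                + "\n"
            )


class IntervalIndex:
    """Per-chromosome interval tree over a subject track."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def query(self, query: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))

    def query_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.at(pos)), key=lambda iv: (iv.start, iv.end))


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap(
    query: GenomicInterval,
    subjects: Iterable[GenomicInterval],
    min_frac: float = 0.0,
    stranded: bool = False,
) -> list[GenomicInterval]:
    """Subjects overlapping ``query`` by at least ``min_frac`` of its length.

    ``min_frac=0`` means any positive overlap; touching half-open
    intervals never overlap.  Strand is ignored unless ``stranded``.
    """
    if not (0.0 <= min_frac <= 1.0):
        raise ValueError("min_frac must be in [0, 1]")
    if isinstance(subjects, IntervalIndex):
        candidates = subjects.query(query)
    else:
        candidates = sorted(
            (s for s in subjects if s.chrom == query.chrom),
            key=lambda iv: (iv.start, iv.end),
        )
    required = min_frac * len(query)
    out = []
    for s in candidates:
        if stranded and s.strand != query.strand:
            continue
        ol = overlap_length(query, s)
        if ol > 0 and ol >= required:
            out.append(s)
    return out


@dataclass
class AnnotationRules:
    """Intersection rules for precursor annotation.

    ``intron_rule``: "midpoint" (default; the precursor midpoint falls
    inside an intron), "any_overlap", or "containment" (precursor fully
    inside one intron).  ``cons_reduction``: "weighted_mean"
    (overlap-length-weighted mean of element scores; default) or "max".
    ``min_frac`` applies to TE/TFBS detection (0 = any positive
    overlap).
    """

    intron_rule: str = "midpoint"
    cons_reduction: str = "weighted_mean"
    min_frac: float = 0.0
    stranded: bool = False


def annotate_mirnas(
    mirna_intervals: Mapping[str, GenomicInterval],
    introns: Iterable[GenomicInterval],
    tes: Iterable[GenomicInterval],
    tfbs: Iterable[GenomicInterval],
    cons_elements: Iterable[GenomicInterval],
    rules: Optional[AnnotationRules] = None,
) -> pd.DataFrame:
    """Per-miRNA genomic annotation from interval intersection.

    Returns a DataFrame indexed by accession with columns is_intronic,
    is_te_derived, has_tfbs (booleans) and cons_score (NaN when no
    conservation element overlaps).  miRNAs mapped to ``None`` (no
    coordinates) yield a row of missing values (logged).
    """
    rules = rules or AnnotationRules()
    intron_idx = IntervalIndex(introns)
    te_idx = IntervalIndex(tes)
    tfbs_idx = IntervalIndex(tfbs)
    cons_idx = IntervalIndex(cons_elements)
    rows = []
    for acc in sorted(mirna_intervals):
        iv = mirna_intervals[acc]
        if iv is None:
            logger.warning("miRNA %s has no coordinates; emitting missing annotation", acc)
            rows.append(
                {"accession": acc, "is_intronic": pd.NA, "is_te_derived": pd.NA,
                 "has_tfbs": pd.NA, "cons_score": np.nan}
            )
            continue
        if rules.intron_rule == "midpoint":
            is_intronic = bool(intron_idx.query_point(iv.chrom, iv.midpoint))
        elif rules.intron_rule == "any_overlap":
            is_intronic = bool(overlap(iv, intron_idx, min_frac=0.0, stranded=rules.stranded))
        elif rules.intron_rule == "containment":
            is_intronic = any(
                h.start <= iv.start and iv.end <= h.end for h in intron_idx.query(iv)
            )
        else:
            raise ValueError(f"unknown intron rule: {rules.intron_rule!r}")
        is_te = bool(overlap(iv, te_idx, min_frac=rules.min_frac, stranded=rules.stranded))
        has_tfbs = bool(overlap(iv, tfbs_idx, min_frac=rules.min_frac, stranded=rules.stranded))
        cons_hits = [h for h in cons_idx.query(iv) if h.score is not None]
        if cons_hits:
            if rules.cons_reduction == "weighted_mean":
                weights = np.array([overlap_length(iv, h) for h in cons_hits], dtype=float)
                scores = np.array([h.score for h in cons_hits], dtype=float)
                cons = float(np.average(scores, weights=weights))
            elif rules.cons_reduction == "max":
                cons = float(max(h.score for h in cons_hits))
            else:
                raise ValueError(f"unknown conservation reduction: {rules.cons_reduction!r}")
        else:
            cons = np.nan
        rows.append(
            {"accession": acc, "is_intronic": is_intronic, "is_te_derived": is_te,
             "has_tfbs": has_tfbs, "cons_score": cons}
        )
    return pd.DataFrame(rows).set_index("accession")


def context_by_class(
    annotation: pd.DataFrame,
    ages: pd.DataFrame,
    families,
    disease_mirnas: Optional[Iterable[str]] = None,
    min_family_size: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Genomic-context summaries per age/family/disease class.

    For each class (old vs young, family vs singleton, and — when
    ``disease_mirnas`` is given — disease vs non-disease) the table
    reports the fraction intronic, TE-derived, and TFBS-bearing, the
    mean conservation score, and the mean age of TFBS-positive members.
    Classes are compared pairwise by Mann-Whitney on the flag indicators
    and conservation scores; empty classes are omitted (logged).
    """
    age_by_acc = ages.set_index("accession")
    common = sorted(set(annotation.index) & set(age_by_acc.index))
    df = annotation.loc[common].copy()
    df["age_my"] = age_by_acc.loc[common, "age_my"]
    df["age_class"] = age_by_acc.loc[common, "age_class"]

    fam_members: set = set()
    for members in families.families(min_size=min_family_size).values():
        fam_members |= members
    singles = families.singletons()

    def class_masks() -> dict[str, pd.Series]:
        masks = {
            "old": df["age_class"] == "old",
            "young": df["age_class"] == "young",
            "family": df.index.to_series().isin(sorted(fam_members)),
            "singleton": df.index.to_series().isin(sorted(singles)),
        }
        if disease_mirnas is not None:
            dz = set(disease_mirnas)
            masks["disease"] = df.index.to_series().isin(sorted(dz))
            masks["non_disease"] = ~masks["disease"]
        return masks

    rows = []
    masks = class_masks()
    for name, mask in masks.items():
        sub = df[mask]
        if sub.empty:
            logger.info("class %r is empty; omitted", name)
            continue
        tf_pos = sub[sub["has_tfbs"] == True]  # noqa: E712 - nullable boolean
        rows.append(
            {
                "class": name,
                "n": len(sub),
                "intron_fraction": float((sub["is_intronic"] == True).mean()),  # noqa: E712
                "te_fraction": float((sub["is_te_derived"] == True).mean()),  # noqa: E712
                "tfbs_fraction": float((sub["has_tfbs"] == True).mean()),  # noqa: E712
                "mean_cons_score": float(sub["cons_score"].mean()),
                "mean_age_my": float(sub["age_my"].mean()),
                "mean_age_tfbs_positive": float(tf_pos["age_my"].mean())
                if len(tf_pos)
                else np.nan,
            }
        )
    summary = pd.DataFrame(rows)

    tests: dict[str, object] = {}
    pairs = [("old", "young"), ("family", "singleton")]
    if disease_mirnas is not None:
        pairs.append(("disease", "non_disease"))
    for a, b in pairs:
        ma, mb = masks[a], masks[b]
        if not ma.any() or not mb.any():
            logger.info("comparison %s_vs_%s skipped: empty class", a, b)
            continue
        for col in ("is_intronic", "is_te_derived", "has_tfbs"):
            xa = df.loc[ma, col].dropna().astype(float).to_numpy()
            xb = df.loc[mb, col].dropna().astype(float).to_numpy()
            if xa.size and xb.size:
                tests[f"{a}_vs_{b}:{col}"] = association_stats.mann_whitney(xa, xb)
        for col in ("cons_score", "age_my"):
            xa = df.loc[ma, col].dropna().to_numpy()
            xb = df.loc[mb, col].dropna().to_numpy()
            if xa.size and xb.size:
                tests[f"{a}_vs_{b}:{col}"] = association_stats.mann_whitney(xa, xb)
    return summary, tests
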