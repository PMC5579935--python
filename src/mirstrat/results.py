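"""Shared container for statistical test results."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class StatResult:
    """Outcome of a statistical test or summary.

    Attributes
    ----------
    method:
        Short tag naming the procedure (e.g. ``"mannwhitneyu"``,
        ``"spearman"``, ``"van_elteren"``, ``"permutation"``).
    statistic:
        The test statistic on its native scale (U, rho, z, ...).
    pvalue:
        Two-sided p-value in [0, 1]; ``nan`` when undefined.
    n:
        Sample size(s) used: an int, or a tuple of per-group sizes.
    effect:
        Free-form effect summaries (medians, means, direction flags ...).
    defined:
        False when the statistic is undefined for the input (e.g. a
        constant vector in a rank correlation); callers must check this
        instead of relying on silent NaN propagation.
    note:
        Human-readable detail, mostly used when ``defined`` is False.
    """

    method: str
    statistic: float
    pvalue: float
    n: object
    effect: dict = field(default_factory=dict)
    defined: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.defined and not (self.pvalue != self.pvalue or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of range: {self.pvalue}")
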