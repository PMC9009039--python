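"""Shared analysis parameters and treatment constants.

The four treatment states of the feeding-regimen design:

``AL``
    ad libitum controls,
``CR``
    chronic daily restriction (~70% of ad libitum intake),
``F2``
    intermittently fasted birds sampled on the second consecutive fed day,
``SK``
    intermittently fasted birds sampled on the fasting ("skip") day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

#: The four treatment labels, in canonical order.
TREATMENTS: tuple[str, ...] = ("AL", "CR", "F2", "SK")

#: The six unordered treatment pairs, stored once as ordered (X, Y) tuples.
#: Effect direction is always reported for the first-named group: a positive
#: ``delta`` for pair (X, Y) means higher expression in X.
PAIRS: tuple[tuple[str, str], ...] = (
    ("F2", "AL"),
    ("SK", "AL"),
    ("CR", "AL"),
    ("F2", "CR"),
    ("SK", "CR"),
    ("F2", "SK"),
)


def pair_key(x: str, y: str) -> str:
    """Canonical string key for a treatment pair, e.g. ``"F2_vs_AL"``."""
    return f"{x}_vs_{y}"


PAIR_KEYS: tuple[str, ...] = tuple(pair_key(x, y) for x, y in PAIRS)


@dataclass(frozen=True)
class AnalysisParams:
    """Tuning knobs of the differential-expression and downstream stages.

    Parameters
    ----------
    alpha_de
        Significance level of the inclusion filter (default 0.01).
    fc_min
        Minimum fold change on the natural (non-log) scale; a gene passes a
        contrast only when ``2**|delta_log2| >= fc_min`` (default 1.4, so
        |delta| >= log2(1.4) ≈ 0.485).
    use_adjusted_p
        Apply the alpha criterion to Benjamini–Hochberg adjusted p-values
        (default) rather than raw p-values.
    moderation
        ``"ebayes"`` (default) shrinks gene variances toward an empirical-Bayes
        prior; ``"ordinary"`` uses raw pooled variances (d0 = 0).
    k_clusters
        Number of gene clusters for the hierarchical cut (default 4).
    alpha_corr_family
        Family-wise level for trait correlations (default 0.05).
    m_corr
        Bonferroni family size for trait correlations; with the ten traits this
        gives a per-test threshold of 0.05 / 10 = 0.005.
    """

    alpha_de: float = 0.01
    fc_min: float = 1.4
    use_adjusted_p: bool = True
    moderation: str = "ebayes"
    k_clusters: int = 4
    alpha_corr_family: float = 0.05
    m_corr: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_de < 1.0:
            raise ValidationError(f"alpha_de must be in (0, 1), got {self.alpha_de}")
        if not self.fc_min > 1.0:
            raise ValidationError(f"fc_min must exceed 1, got {self.fc_min}")
        if self.moderation not in ("ebayes", "ordinary"):
            raise ValidationError(
                f"moderation must be 'ebayes' or 'ordinary', got {self.moderation!r}"
            )
        if self.m_corr < 1:
            raise ValidationError(f"m_corr must be >= 1, got {self.m_corr}")
        if self.k_clusters < 1:
            raise ValidationError(f"k_clusters must be >= 1, got {self.k_clusters}")

    @property
    def delta_min(self) -> float:
        """Fold-change threshold on the log2 scale."""
        return math.log2(self.fc_min)

    @property
    def corr_threshold(self) -> float:
        """Bonferroni per-test p threshold for trait correlations."""
        return self.alpha_corr_family / self.m_corr
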