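"""Publication-bias correction: per-gene publication-count filtering.

Better-studied genes accumulate both interaction annotations and disease
associations, so raw overlap statistics partly reflect research attention.
The correction removes set members below a publication-count threshold
(default 10, inclusive) before testing.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .types import LabeledGeneSet


@dataclass(frozen=True)
class PbcReport:
    """Per-threshold summary of how much each set loses to the filter."""

    threshold: int
    per_set: Mapping[str, tuple[int, int, float]]  # name -> (n_before, n_after, fraction_lost)


def apply_publication_filter(
    s: LabeledGeneSet,
    pub_count: Mapping[str, int],
    threshold: int = 10,
    inclusive: bool = True,
) -> LabeledGeneSet:
    """Keep members with at least ``threshold`` publications.

    Genes missing from ``pub_count`` count as unpublished (0) and are
    removed for any positive threshold. ``inclusive=False`` switches the
    comparison to strictly-greater-than.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if inclusive:
        keep = {g for g in s.members if pub_count.get(g, 0) >= threshold}
    else:
        keep = {g for g in s.members if pub_count.get(g, 0) > threshold}
    return s.replace_members(keep)


def sweep_thresholds(
    sets: Sequence[LabeledGeneSet],
    pub_count: Mapping[str, int],
    thresholds: Iterable[int],
    inclusive: bool = True,
) -> list[PbcReport]:
    """One :class:`PbcReport` per candidate threshold."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold range is empty")
    reports = []
    for t in thresholds:
        per_set = {}
        for s in sets:
            n_before = len(s.members)
            n_after = len(apply_publication_filter(s, pub_count, t, inclusive).members)
            lost = (n_before - n_after) / n_before if n_before else 0.0
            per_set[s.name] = (n_before, n_after, lost)
        reports.append(PbcReport(threshold=t, per_set=per_set))
    return reports


def publication_summary(
    genes: Iterable[str], pub_count: Mapping[str, int]
) -> tuple[float, float]:
    """(mean, median) publication count over a gene set; missing counts as 0."""
    counts = sorted(pub_count.get(g, 0) for g in genes)
    if not counts:
        raise ValueError("publication_summary of an empty gene set")
    return statistics.fmean(counts), float(statistics.median(counts))
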