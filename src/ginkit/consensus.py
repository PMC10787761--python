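"""Cross-database consensus: exhaustive overlap (upset) tables.

For a chosen element kind — gene symbols, unified chemical IDs, or SIFI edge
triples — every element of the union is assigned to the exact subset of
databases that contain it, and subsets are counted.  This is the upset-plot
decomposition: counts over subsets partition the universe, so they sum to the
size of the union.  Per-database uniqueness statistics (how many of a
database's elements appear nowhere else) fall out of the singleton rows.

Databases contributing no element of the requested kind are excluded from
that kind's table (and logged): a chemicals-only resource does not belong in
the gene overlap, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ELEMENT_KINDS = ("gene", "chemical", "edge")


@dataclass
class OverlapTable:
    """Counts of elements per exact database subset."""

    element_kind: str
    tags: tuple[str, ...]
    rows: dict[frozenset, int]

    @property
    def universe_size(self) -> int:
        return sum(self.rows.values())

    def count(self, *tags: str) -> int:
        return self.rows.get(frozenset(tags), 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subset (comma-joined sorted tags), count."""
        records = sorted(
            (",".join(sorted(subset)), count) for subset, count in self.rows.items()
        )
        return pd.DataFrame(records, columns=["subset", "count"])


def overlap_analysis(
    per_db_elements: Mapping[str, Iterable[Hashable]],
    element_kind: str,
) -> OverlapTable:
    """Assign each element of the union to its exact subset of databases.

    Input order of databases is irrelevant; empty databases are excluded
    with a log line.  An empty input yields an empty table.
    """
    sets = {tag: set(elements) for tag, elements in per_db_elements.items()}
    excluded = sorted(tag for tag, elements in sets.items() if not elements)
    for tag in excluded:
        logger.info("excluding %s from %s overlap: no elements", tag, element_kind)
        del sets[tag]

    membership: dict[Hashable, set[str]] = {}
    for tag, elements in sets.items():
        for element in elements:
            membership.setdefault(element, set()).add(tag)

    rows: dict[frozenset, int] = {}
    for subset in membership.values():
        key = frozenset(subset)
        rows[key] = rows.get(key, 0) + 1
    return OverlapTable(
        element_kind=element_kind, tags=tuple(sorted(sets)), rows=rows
    )


def uniqueness_stats(table: OverlapTable) -> pd.DataFrame:
    """Per-database unique/total element counts and unique fraction.

    ``unique_count`` is the singleton-subset row for that database; ``total``
    sums every subset containing it.
    """
    records = []
    for tag in table.tags:
        unique = table.rows.get(frozenset({tag}), 0)
        total = sum(
            count for subset, count in table.rows.items() if tag in subset
        )
        records.append(
            {
                "database": tag,
                "unique_count": unique,
                "total_count": total,
                "unique_fraction": unique / total if total else 0.0,
            }
        )
    return pd.DataFrame(records).set_index("database")


def write_overlap_table(table: OverlapTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def plot_upset(table: OverlapTable, path, max_subsets: int = 40) -> None:
    """Upset-style rendering: subset-count bars over a membership dot matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subsets = sorted(table.rows.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    subsets = subsets[:max_subsets]
    tags = list(table.tags)
    fig, (ax_bars, ax_matrix) = plt.subplots(
        2, 1, figsize=(max(6, 0.4 * len(subsets)), 4 + 0.25 * len(tags)),
        sharex=True, height_ratios=[3, 1],
    )
    xs = range(len(subsets))
    ax_bars.bar(xs, [count for _, count in subsets], color="0.25")
    ax_bars.set_ylabel(f"{table.element_kind}s per subset")
    for x, (subset, _) in zip(xs, subsets):
        for y, tag in enumerate(tags):
            filled = tag in subset
            ax_matrix.plot(
                x, y, "o",
                color="0.2" if filled else "0.85", markersize=5,
            )
    ax_matrix.set_yticks(range(len(tags)), tags)
    ax_matrix.set_xticks([])
    ax_matrix.set_ylim(-0.5, len(tags) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
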