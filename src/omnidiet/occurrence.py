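"""From annotated read counts to occurrence and frequency-of-occurrence.

Read counts from metabarcoding are, at best, a coarse proxy for diet, so the
pipeline reduces them to presence/absence through a fixed filtering ladder:

1. keep ASVs of the marker's target phylum only,
2. keep ASVs assigned at least to genus,
3. drop bait genera (e.g. *Arachis*, *Avena* from peanut-butter/oat bait),
4. convert counts to relative read abundance (RRA) within each sample,
5. call a taxon present in a sample when its RRA is >= 1% (inclusive).

Percent frequency of occurrence (%FOO) is then the share of samples in which
a taxon is present; sources for the isotope mixing model are the taxa at
>= 5% FOO.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnnotatedASVTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceMatrix:
    """Binary sample x taxon presence, derived only from retained taxa.

    Samples with zero retained reads stay in the matrix as all-absent rows:
    they are real samples and belong in %FOO denominators.
    """

    presence: pd.DataFrame  # samples x taxa, values in {0, 1}
    zero_total_samples: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.presence.columns)


def filter_asv_table(
    table: AnnotatedASVTable,
    target_phylum: str,
    min_rank: str = "genus",
    excluded_genera: tuple[str, ...] = (),
) -> AnnotatedASVTable:
    """Apply the phylum / rank-assignment / bait-exclusion ladder.

    Retains ASVs whose phylum equals ``target_phylum``, whose ``min_rank`` is
    assigned (non-empty), and whose genus is not excluded.  The sample set is
    unchanged.  An empty result is a warning, not an error.
    """
    if min_rank != "genus":
        raise ValidationError("only genus-level filtering is supported")
    tax = table.taxonomy
    keep = (
        (tax["phylum"] == target_phylum)
        & (tax["genus"] != "")
        & (~tax["genus"].isin(excluded_genera))
    )
    kept = list(tax.index[keep])
    if not kept:
        warnings.warn(
            f"no ASVs retained after filtering ({table.marker})", stacklevel=2
        )
    return table.subset_asvs(kept)


def relative_read_abundance(table: AnnotatedASVTable) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample read proportions.

    Each sample's counts are divided by that sample's total retained reads,
    so rows of the result sum to 1.  Samples with zero total reads are
    returned as all-zero rows and flagged in the second return value.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = list(counts.index[totals == 0])
    if zero:
        logger.info("samples with zero retained reads: %s", zero)
    safe_totals = totals.replace(0, np.nan)
    rra = counts.div(safe_totals, axis=0).fillna(0.0)
    return rra, zero


def occurrence_from_rra(rra: pd.DataFrame, threshold: float = 0.01,
                        zero_total_samples: list[str] | None = None) -> OccurrenceMatrix:
    """Presence = 1 iff RRA >= threshold (inclusive, matching the >=1% rule)."""
    if not 0 < threshold < 1:
        raise ValidationError(f"presence threshold must be in (0, 1), got {threshold}")
    presence = (rra >= threshold).astype(int)
    return OccurrenceMatrix(
        presence=presence, zero_total_samples=list(zero_total_samples or [])
    )


def foo_summary(occ: OccurrenceMatrix, taxonomy: pd.DataFrame | None = None) -> pd.DataFrame:
    """Detection counts and %FOO per taxon, in descending-count order.

    ``foo_percent`` is exact (100 * count / n_samples); round only for
    display.  When a taxonomy frame is given, its rank columns are echoed.
    """
    if occ.presence.shape[1] == 0:
        raise ValidationError("occurrence matrix has no taxa")
    n = len(occ.presence.index)
    counts = occ.presence.sum(axis=0)
    out = pd.DataFrame(
        {
            "detection_count": counts.astype(int),
            "foo_percent": 100.0 * counts / n,
        }
    )
    out.index.name = "taxon"
    if taxonomy is not None:
        echo = taxonomy.reindex(out.index).fillna("")
        out = pd.concat([echo, out], axis=1)
    out = out.sort_values(
        ["detection_count", "taxon"], ascending=[False, True], kind="mergesort"
    )
    out.attrs["n_samples"] = n
    return out


def select_sources(
    foo: pd.DataFrame,
    min_foo: float = 0.05,
    forced_additions: tuple[str, ...] = (),
) -> list[str]:
    """Mixing-model source list: taxa at >= ``min_foo`` FOO (inclusive).

    ``forced_additions`` covers sources known from other evidence but
    undetectable by the marker (e.g. seabird tissue).  Order is stable:
    descending detection count, then name, with forced additions appended.
    """
    sel = foo[foo["foo_percent"] >= 100.0 * min_foo]
    out = list(sel.index)
    for name in forced_additions:
        if name not in out:
            out.append(name)
    return out


def per_group_foo(
    occ: OccurrenceMatrix, metadata: pd.DataFrame, group_by: str
) -> dict[str | int, pd.DataFrame]:
    """%FOO within each level of a metadata factor (habitat or session).

    Each level's own sample count is the denominator.  Levels with zero
    samples are omitted with a warning.
    """
    missing = occ.presence.index.difference(metadata.index)
    if len(missing):
        raise ValidationError(f"metadata missing sample(s) {list(missing)[:5]}")
    levels = metadata.loc[occ.presence.index, group_by]
    out: dict = {}
    for level in pd.unique(levels):
        members = occ.presence.index[levels == level]
        if len(members) == 0:  # pragma: no cover - unreachable via pd.unique
            warnings.warn(f"group {level!r} has no samples; omitted", stacklevel=2)
            continue
        sub = OccurrenceMatrix(
            presence=occ.presence.loc[members],
            zero_total_samples=[s for s in occ.zero_total_samples if s in members],
        )
        out[level] = foo_summary(sub)
    return out
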