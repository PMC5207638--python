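"""Singleton identification, density-based aging, and binning.

A singleton is a variant whose alternate allele is observed in exactly one
strain.  Its "age" is the density of its carrier strain's singletons on that
chromosome: if a strain carries n singletons on a chromosome of L kb, each of
those n singletons is assigned age n/L (events per kb).  Low density means
the carrier diverged recently from its closest relative, so its unique
mutations are young on average — the density is a proxy for identity by
descent, not an exact age.

Ages are grouped per (carrier strain, chromosome) by default, the strain's
chromosome being the lineage unit; a pooled-across-strains variant is
available for comparison.  Binning is equal-count over the bulk with tied
ages kept together, optionally preceded by fixed edges for the youngest
range (e.g. a 0.005/kb cut-off for the young singleton class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class Singleton:
    """A variant private to one strain, with its density age (events/kb)."""

    variant: VariantRecord
    carrier: str
    age: float | None = None

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def ref(self) -> str:
        return self.variant.ref

    @property
    def alt(self) -> str:
        return self.variant.alt


@dataclass
class AgeBin:
    """A half-open age interval [low, high) with its member variants."""

    label: str
    low: float
    high: float
    members: list

    def __len__(self) -> int:
        return len(self.members)


def population_frequency(
    records: Sequence[VariantRecord], n_strains: int
) -> pd.DataFrame:
    """Per-variant carrier count k and frequency k/n_strains.

    A strain carries a variant when it has at least one alternate allele.
    Records with no carrier left after filtering are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    for r in records:
        k = r.n_carriers
        if k == 0:
            n_dropped += 1
            continue
        rows.append(
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "k": k, "freq": k / n_strains}
        )
    if n_dropped:
        logger.warning("dropped %d records with no carrier strain", n_dropped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "k", "freq"])


def site_frequency_spectrum(
    records: Sequence[VariantRecord], n_strains: int
) -> pd.Series:
    """Histogram of variant counts over carrier-count classes k = 1..n_strains."""
    counts = np.zeros(n_strains, dtype=np.int64)
    for r in records:
        k = r.n_carriers
        if 1 <= k <= n_strains:
            counts[k - 1] += 1
    return pd.Series(
        counts, index=pd.RangeIndex(1, n_strains + 1, name="k"), name="count"
    )


def identify_singletons(records: Iterable[VariantRecord]) -> list[Singleton]:
    """Variants whose alternate allele occurs in exactly one strain.

    Presence, not dosage: a heterozygous unique variant counts once, since
    strains are the sampling unit and natural ploidy varies.
    """
    out = []
    for r in records:
        if r.n_carriers == 1:
            out.append(Singleton(variant=r, carrier=r.carriers[0]))
    return out


def _density_ages(
    items: Sequence,
    chromosome_lengths: Mapping[str, int],
    get_chrom: Callable,
    get_carrier: Callable,
    pooled: bool = False,
) -> list[float]:
    """Density age per item: (group count) / (chromosome length in kb)."""
    keys = []
    for item in items:
        chrom = get_chrom(item)
        if chrom not in chromosome_lengths:
            raise ValueError(f"unknown chromosome id {chrom!r}")
        keys.append(chrom if pooled else (get_carrier(item), chrom))
    group_sizes: dict = {}
    for key in keys:
        group_sizes[key] = group_sizes.get(key, 0) + 1
    ages = []
    for item, key in zip(items, keys):
        length_kb = chromosome_lengths[get_chrom(item)] / 1000.0
        ages.append(group_sizes[key] / length_kb)
    return ages


def assign_ages(
    singletons: Sequence[Singleton],
    chromosome_lengths: Mapping[str, int],
    pooled: bool = False,
) -> list[Singleton]:
    """Assign the density age to every singleton.

    For each (carrier strain, chromosome) group of size n on a chromosome of
    L kb, every member gets age n/L.  ``chromosome_lengths`` is in bp; pass
    effective (mask-subtracted) lengths to age against analysed length
    instead of full length.  With ``pooled=True`` the count is over all
    strains' singletons on the chromosome.
    """
    ages = _density_ages(
        singletons, chromosome_lengths,
        get_chrom=lambda s: s.chrom, get_carrier=lambda s: s.carrier,
        pooled=pooled,
    )
    return [replace(s, age=a) for s, a in zip(singletons, ages)]


def bin_by_age(
    singletons: Sequence,
    n_bins: int,
    young_edges: Sequence[float] | None = None,
) -> list[AgeBin]:
    """Partition aged items into ordered age bins.

    Items below the supplied ``young_edges`` (ascending) go into fixed-edge
    bins; the remainder is split into ``n_bins`` equal-count bins with tied
    ages always kept in one bin, so bin sizes can differ by up to the largest
    tie-group size.  Works for any objects with an ``age`` attribute
    (SNP singletons, indel records).
    """
    items = sorted(singletons, key=lambda s: s.age)
    if any(s.age is None for s in items):
        raise ValueError("all items must have an assigned age")
    bins: list[AgeBin] = []
    lower = 0.0
    if young_edges:
        for edge in sorted(young_edges):
            members = [s for s in items if lower <= s.age < edge]
            bins.append(AgeBin(
                label=f"[{lower:.4g},{edge:.4g})", low=lower, high=edge,
                members=members,
            ))
            lower = edge
        items = [s for s in items if s.age >= lower]
    if not items:
        return bins
    # equal-count binning over the remainder, ties kept together
    ages = np.array([s.age for s in items])
    distinct = np.unique(ages)
    if len(distinct) == 1:
        # all ages tied: one bin regardless of the requested count
        if n_bins > 1:
            logger.warning(
                "all ages identical; emitting a single bin instead of %d",
                n_bins,
            )
        hi = float(np.nextafter(distinct[0], np.inf))
        bins.append(AgeBin(
            label=f"[{lower:.4g},{hi:.4g})", low=lower, high=hi, members=items
        ))
        return bins
    if n_bins > len(distinct):
        raise ValueError(
            f"requested {n_bins} bins but only {len(distinct)} distinct ages"
        )
    groups: list[list] = []
    for s in items:
        if groups and groups[-1][0].age == s.age:
            groups[-1].append(s)
        else:
            groups.append([s])
    remaining = len(items)
    bins_left = n_bins
    current: list = []
    chunks: list[list] = []
    for g in groups:
        current.extend(g)
        remaining -= len(g)
        target = (remaining + len(current)) / bins_left
        if len(current) >= target and bins_left > 1:
            chunks.append(current)
            current = []
            bins_left -= 1
    if current:
        chunks.append(current)
    for i, chunk in enumerate(chunks):
        low = lower if i == 0 else bins[-1].high
        if i + 1 < len(chunks):
            # boundary halfway between the adjacent observed ages
            high = float(chunk[-1].age + (chunks[i + 1][0].age - chunk[-1].age) / 2)
        else:
            high = float(np.nextafter(chunk[-1].age, np.inf))
        bins.append(AgeBin(
            label=f"[{low:.4g},{high:.4g})", low=low, high=high, members=chunk
        ))
    return bins


def singletons_to_frame(
    singletons: Sequence[Singleton],
    bins: Sequence[AgeBin] | None = None,
) -> pd.DataFrame:
    """Tidy table of singletons (chrom, pos, ref, alt, carrier, age[, bin])."""
    df = pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
             "carrier": s.carrier, "age": s.age}
            for s in singletons
        ],
        columns=["chrom", "pos", "ref", "alt", "carrier", "age"],
    )
    if bins is not None:
        label_of = {}
        for b in bins:
            for s in b.members:
                label_of[id(s)] = b.label
        df["bin"] = [label_of.get(id(s), "") for s in singletons]
    return df
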